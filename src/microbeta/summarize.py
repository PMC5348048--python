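"""Collapse local interaction tensors into global directed interaction values.

The local tensor carries one value per ordered taxon pair, environmental
parameter and sample.  Summaries proceed in two stages:

1. per parameter, the sample values are classified by sign (a configurable
   majority, default 80%, decides the direction; otherwise the parameter is
   excluded) and condensed to the median of the dominant density peak — a
   deliberately conservative center that ignores secondary modes and
   outliers;
2. per ordered pair, the surviving per-parameter peak medians are combined
   by the same majority rule, falling back to a magnitude-ratio rule
   (dominant sign wins if its median is more than twice the other's in
   absolute value), else the pair is declared indeterminate.

Weighted linear combinations across parameters and Euclidean norms over any
axis are provided for users who prefer classical summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .fields import LocalInteractionField


class SummarizeError(ValueError):
    pass


class Direction(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


class Status(str, Enum):
    DETERMINATE = "determinate"
    INDETERMINATE = "indeterminate"
    NO_QUALIFYING_PARAMETER = "no_qualifying_parameter"


@dataclass(frozen=True)
class SummaryWeights:
    """Per-parameter weights ``C_a`` (e.g. constrained-ordination eigenvalues)."""

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        if C.ndim != 1 or not np.isfinite(C).all() or (C < 0).any():
            raise SummarizeError("weights must be a finite nonnegative vector")
        if not (C > 0).any():
            raise SummarizeError("at least one weight must be positive")


@dataclass(frozen=True)
class PeakSummary:
    """Per-(pair, parameter) peak median with sign-majority direction."""

    M: float
    direction: Direction
    support: float  # fraction of non-zero values sharing the majority sign
    reason: str = ""

    @property
    def qualifies(self) -> bool:
        return self.direction is not Direction.EXCLUDED


@dataclass(frozen=True)
class GlobalInteractionMatrix:
    """Directed global ``beta[i, j]`` (influence of j on i) with status flags."""

    beta: np.ndarray  # d x d, NaN where not determinate
    status: np.ndarray  # d x d of Status
    taxon_ids: tuple[str, ...]
    method: str = "peak-majority"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=list(self.taxon_ids),
                            columns=list(self.taxon_ids))

    def status_frame(self) -> pd.DataFrame:
        return pd.DataFrame(np.vectorize(lambda s: s.value)(self.status),
                            index=list(self.taxon_ids),
                            columns=list(self.taxon_ids))


def weight_combine(field: LocalInteractionField, w: SummaryWeights) -> np.ndarray:
    """Linear combination across parameters: ``beta[i, j, k] = sum_a C_a * beta[i, j, a, k]``."""
    if len(w.C) != len(field.param_ids):
        raise SummarizeError(
            f"{len(w.C)} weights for {len(field.param_ids)} parameters")
    return np.einsum("ijak,a->ijk", field.beta, w.C)


def norm_summary(values: np.ndarray | LocalInteractionField,
                 axis: int | tuple[int, ...]) -> np.ndarray:
    """Euclidean norm over the collapsed axes (direction information is lost)."""
    if isinstance(values, LocalInteractionField):
        values = values.beta
    values = np.asarray(values, dtype=float)
    axes = (axis,) if isinstance(axis, int) else tuple(axis)
    if len(axes) == 0:
        raise SummarizeError("empty axis selection")
    for ax in axes:
        if values.shape[ax] == 0:
            raise SummarizeError("cannot collapse an empty axis")
    return np.sqrt(np.sum(values ** 2, axis=axes))


def basic_summary(values: np.ndarray | LocalInteractionField,
                  stat: str, axis: int | tuple[int, ...]) -> np.ndarray:
    """Mean / median / max / min over the collapsed axes."""
    if isinstance(values, LocalInteractionField):
        values = values.beta
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise SummarizeError("empty selection")
    funcs = {"mean": np.mean, "median": np.median,
             "max": np.max, "min": np.min}
    if stat not in funcs:
        raise SummarizeError(f"unknown statistic {stat!r}")
    return funcs[stat](values, axis=axis)


def peak_median(values: np.ndarray, majority: float = 0.8, *,
                min_values: int = 5, bw_method: str | float = "silverman",
                peak_rel_height: float = 0.5) -> PeakSummary:
    """Condense one (pair, parameter) vector of per-sample values.

    Exact zeros carry no sign and are excluded from the majority count.  If
    neither sign reaches the majority threshold the parameter is excluded.
    Otherwise a Gaussian kernel density estimate over the values locates the
    dominant mode; the contiguous run of sorted values whose density stays
    above ``peak_rel_height`` times the mode density forms the peak, and its
    median is returned.
    """
    if not 0 < majority <= 1:
        raise SummarizeError("majority threshold must be in (0, 1]")
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    if v.size < min_values:
        return PeakSummary(np.nan, Direction.EXCLUDED, 0.0,
                           reason=f"fewer than {min_values} non-zero values")
    frac_pos = float((v > 0).mean())
    frac_neg = 1.0 - frac_pos
    support = max(frac_pos, frac_neg)
    if frac_pos >= majority:
        direction = Direction.POSITIVE
    elif frac_neg >= majority:
        direction = Direction.NEGATIVE
    else:
        return PeakSummary(np.nan, Direction.EXCLUDED, support,
                           reason="no sign majority")
    v = np.sort(v)
    if v[0] == v[-1]:  # degenerate distribution: the peak is the point mass
        return PeakSummary(float(v[0]), direction, support)
    kde = gaussian_kde(v, bw_method=bw_method)
    grid = np.linspace(v[0], v[-1], 512)
    mode_density = float(kde(grid).max())
    dens = kde(v)
    anchor = int(np.argmax(dens))
    threshold = peak_rel_height * mode_density
    lo = anchor
    while lo > 0 and dens[lo - 1] >= threshold:
        lo -= 1
    hi = anchor
    while hi < v.size - 1 and dens[hi + 1] >= threshold:
        hi += 1
    members = v[lo:hi + 1]
    return PeakSummary(float(np.median(members)), direction, support)


def global_beta(peaks: Sequence[PeakSummary], majority: float = 0.8,
                ratio_threshold: float = 2.0) -> tuple[float, Status]:
    """Combine per-parameter peak medians into one global directed value.

    Majority rule first; then the magnitude-ratio fallback (strictly larger
    than ``ratio_threshold`` wins); otherwise indeterminate.  With no
    qualifying parameter at all the pair is flagged as such.
    """
    M = np.array([p.M for p in peaks if p.qualifies])
    if M.size == 0:
        return np.nan, Status.NO_QUALIFYING_PARAMETER
    pos, neg = M[M > 0], M[M < 0]
    for same_sign in (pos, neg):
        if same_sign.size / M.size >= majority:
            return float(np.median(same_sign)), Status.DETERMINATE
    if pos.size == 0 or neg.size == 0:
        # all one sign but below majority cannot happen; guard anyway
        rest = pos if pos.size else neg
        return float(np.median(rest)), Status.DETERMINATE
    m_plus = float(np.median(pos))
    m_minus = float(np.median(neg))
    hi, lo = max(abs(m_plus), abs(m_minus)), min(abs(m_plus), abs(m_minus))
    if lo > 0 and hi / lo > ratio_threshold:
        return (m_plus if abs(m_plus) >= abs(m_minus) else m_minus,
                Status.DETERMINATE)
    return np.nan, Status.INDETERMINATE


def summarize_field(field: LocalInteractionField, majority: float = 0.8,
                    ratio_threshold: float = 2.0, *,
                    weights: SummaryWeights | None = None,
                    min_values: int = 5) -> tuple[GlobalInteractionMatrix, dict]:
    """Run the full peak-majority chain over every ordered taxon pair.

    Optional weights rescale each parameter slice before summarization (the
    weighted values pass through the same peak/majority machinery).  Returns
    the global matrix and the per-(i, j, parameter) peak summaries.
    """
    beta = field.beta
    if weights is not None:
        if len(weights.C) != len(field.param_ids):
            raise SummarizeError("weight length does not match parameters")
        beta = beta * weights.C[None, None, :, None]
    d = len(field.taxon_ids)
    m = len(field.param_ids)
    out = np.full((d, d), np.nan)
    status = np.empty((d, d), dtype=object)
    peaks: dict[tuple[str, str, str], PeakSummary] = {}
    for i in range(d):
        for j in range(d):
            per_param = []
            for a in range(m):
                pk = peak_median(beta[i, j, a, :], majority,
                                 min_values=min_values)
                peaks[(field.taxon_ids[i], field.taxon_ids[j],
                       field.param_ids[a])] = pk
                per_param.append(pk)
            value, st = global_beta(per_param, majority, ratio_threshold)
            out[i, j] = value
            status[i, j] = st
    return GlobalInteractionMatrix(out, status, field.taxon_ids), peaks
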