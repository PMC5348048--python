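"""Per-sample slope and interaction tensors from Taylor-difference regressions.

For a fixed reference sample ``k`` the first-order Taylor expansion of a
taxon's abundance around that sample turns every other sample ``l`` into one
regression row of differences: the response is the abundance difference and
the regressors are differences of environmental parameters (and, in the
full variant, of the other taxa's abundances).  The fitted coefficients of
the parameter differences are the local abundance slopes ``p[i, a, k]``.

Repeating the construction with the slopes as response and abundance
differences as regressors yields the coefficient ``dp_ia/dA_j``; divided by
the focal taxon's abundance in sample ``k`` it is the directed, per-sample,
per-gradient interaction coefficient ``beta[i, j, a, k]`` — the influence
of taxon ``j`` on taxon ``i``.  Self-interaction (``j == i``) is estimated
like any other pair.  No intercept appears anywhere: the difference of a
sample with itself is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .regression import UnderdeterminedError, robust_fit_no_intercept
from .tables import AbundanceTable, EnvironmentTable

Variant = Literal["reduced", "full"]


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class LocalSlopeField:
    """Abundance rate-of-change tensor ``p[i, a, k] = dA_i/dTheta_a`` at sample k."""

    p: np.ndarray  # d x m x N
    taxon_ids: tuple[str, ...]
    param_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    model_variant: Variant = "reduced"
    cross_slopes: np.ndarray | None = None  # d x d x N, dA_i/dA_j (full variant)

    def __post_init__(self) -> None:
        d, m, n = len(self.taxon_ids), len(self.param_ids), len(self.sample_ids)
        if self.p.shape != (d, m, n):
            raise EstimationError(f"slope tensor shape {self.p.shape} != {(d, m, n)}")
        if not np.isfinite(self.p).all():
            raise EstimationError("slope tensor contains non-finite entries")

    def to_long_frame(self) -> pd.DataFrame:
        d, m, n = self.p.shape
        ti, pa, sa = np.meshgrid(range(d), range(m), range(n), indexing="ij")
        return pd.DataFrame({
            "taxon": np.array(self.taxon_ids)[ti.ravel()],
            "parameter": np.array(self.param_ids)[pa.ravel()],
            "sample": np.array(self.sample_ids)[sa.ravel()],
            "value": self.p.ravel(),
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False,
                                    float_format="%.17g")


@dataclass(frozen=True)
class LocalInteractionField:
    """Directed interaction tensor ``beta[i, j, a, k]``: influence of j on i."""

    beta: np.ndarray  # d x d x m x N
    taxon_ids: tuple[str, ...]
    param_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    model_variant: Variant = "reduced"
    env_sensitivity: np.ndarray | None = None  # d x m x m x N (full variant)

    def __post_init__(self) -> None:
        d, m, n = len(self.taxon_ids), len(self.param_ids), len(self.sample_ids)
        if self.beta.shape != (d, d, m, n):
            raise EstimationError(
                f"interaction tensor shape {self.beta.shape} != {(d, d, m, n)}")
        if not np.isfinite(self.beta).all():
            raise EstimationError("interaction tensor contains non-finite entries")

    def to_long_frame(self) -> pd.DataFrame:
        d, _, m, n = self.beta.shape
        ti, tj, pa, sa = np.meshgrid(range(d), range(d), range(m), range(n),
                                     indexing="ij")
        return pd.DataFrame({
            "taxon_i": np.array(self.taxon_ids)[ti.ravel()],
            "taxon_j": np.array(self.taxon_ids)[tj.ravel()],
            "parameter": np.array(self.param_ids)[pa.ravel()],
            "sample": np.array(self.sample_ids)[sa.ravel()],
            "value": self.beta.ravel(),
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False,
                                    float_format="%.17g")


def _check_design(X: np.ndarray, where: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(f"singular difference design at {where}")


def estimate_p(a: AbundanceTable, e: EnvironmentTable,
               variant: Variant = "reduced", *,
               max_iter: int = 100, tol: float = 1e-6) -> LocalSlopeField:
    """Estimate the local slope field from preprocessed tables.

    reduced: regressors are the environmental differences only (m of them).
    full: additionally the other taxa's abundance differences (m + d - 1);
    their coefficients are returned as ``cross_slopes``.
    """
    if a.sample_ids != e.sample_ids:
        raise EstimationError("tables are not aligned")
    A, T = a.values, e.values
    n, d = A.shape
    m = T.shape[1]
    n_reg = m if variant == "reduced" else m + d - 1
    if n - 1 <= n_reg:
        raise UnderdeterminedError(
            f"{n} samples cannot support {n_reg} difference regressors")
    p = np.empty((d, m, n))
    cross = np.zeros((d, d, n)) if variant == "full" else None
    for k in range(n):
        dT = np.delete(T - T[k], k, axis=0)
        dA = np.delete(A - A[k], k, axis=0)
        if variant == "reduced":
            _check_design(dT, f"sample {a.sample_ids[k]!r}")
            coef = robust_fit_no_intercept(dT, dA, max_iter=max_iter, tol=tol)
            p[:, :, k] = coef.T
        else:
            for i in range(d):
                others = [j for j in range(d) if j != i]
                X = np.hstack([dT, dA[:, others]])
                _check_design(
                    X, f"taxon {a.taxon_ids[i]!r}, sample {a.sample_ids[k]!r}")
                coef = robust_fit_no_intercept(X, dA[:, i],
                                               max_iter=max_iter, tol=tol)
                p[i, :, k] = coef[:m]
                cross[i, others, k] = coef[m:]
    return LocalSlopeField(p, a.taxon_ids, e.param_ids, a.sample_ids,
                           model_variant=variant, cross_slopes=cross)


def estimate_beta(p: LocalSlopeField, a: AbundanceTable, e: EnvironmentTable,
                  variant: Variant = "reduced", *,
                  max_iter: int = 100, tol: float = 1e-6) -> LocalInteractionField:
    """Estimate the interaction field from a slope field and its tables.

    For each reference sample the slope differences of every (taxon,
    parameter) pair are regressed on the abundance differences of all taxa
    (full variant: plus environmental differences, whose coefficients are
    returned as ``env_sensitivity``).  The abundance coefficient for taxon
    ``j`` divided by ``A[k, i]`` is ``beta[i, j, a, k]``; division is safe
    because zero-containing taxa were dropped upstream.
    """
    if a.sample_ids != e.sample_ids or p.sample_ids != a.sample_ids:
        raise EstimationError("slope field and tables are not aligned")
    if p.taxon_ids != a.taxon_ids or p.param_ids != e.param_ids:
        raise EstimationError("slope field does not match table identifiers")
    A, T = a.values, e.values
    n, d = A.shape
    m = T.shape[1]
    if (A <= 0).any():
        raise EstimationError("all abundances must be strictly positive "
                              "(run drop_zero_taxa first)")
    n_reg = d if variant == "reduced" else d + m
    if n - 1 <= n_reg:
        raise UnderdeterminedError(
            f"{n} samples cannot support {n_reg} difference regressors")
    beta = np.empty((d, d, m, n))
    env_sens = np.zeros((d, m, m, n)) if variant == "full" else None
    for k in range(n):
        dA = np.delete(A - A[k], k, axis=0)
        X = dA if variant == "reduced" else np.hstack(
            [dA, np.delete(T - T[k], k, axis=0)])
        _check_design(X, f"sample {a.sample_ids[k]!r}")
        # responses: slope differences for every (taxon i, parameter a)
        dP = np.delete(p.p - p.p[:, :, k][:, :, None], k, axis=2)  # d x m x (n-1)
        Y = dP.reshape(d * m, n - 1).T  # (n-1) x (d*m)
        coef = robust_fit_no_intercept(X, Y, max_iter=max_iter, tol=tol)
        by_resp = coef.T.reshape(d, m, X.shape[1])  # i, a, regressor
        beta[:, :, :, k] = np.transpose(by_resp[:, :, :d], (0, 2, 1)) \
            / A[k, :, None, None]
        if variant == "full":
            env_sens[:, :, :, k] = by_resp[:, :, d:]
    return LocalInteractionField(beta, a.taxon_ids, e.param_ids, a.sample_ids,
                                 model_variant=variant,
                                 env_sensitivity=env_sens)
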