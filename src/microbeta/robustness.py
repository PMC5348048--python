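"""Stability of global interaction values under data perturbation.

Two perturbation families probe different error sources: multiplicative
uniform noise on the raw environment and/or abundance values emulates
measurement imprecision (each entry is scaled by ``1 + u * e`` with
``u ~ Uniform(-1, 1)``, so the relative error is bounded by ``e``), and
subsampling without replacement emulates sampling-site choice.  Sampling
*with* replacement is deliberately avoided: duplicated samples produce
exactly-zero difference rows that carry no information in the difference
regressions.

Every iteration reruns the complete chain from the perturbed raw data
(including rescaling and pruning); only iterations whose global value for a
pair is determinate enter that pair's statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats

from .pipeline import PipelineConfig, infer_interactions
from .summarize import Status
from .tables import AbundanceTable, EnvironmentTable

Target = Literal["environment", "abundance", "both", "subsample"]

#: Error-level presets matching the perturbation panel convention
#: (0.01%, 0.1%, 5%, 10%, 20%, 50%).
ERROR_LEVEL_PRESETS = (0.0001, 0.001, 0.05, 0.10, 0.20, 0.50)


class RobustnessError(ValueError):
    pass


@dataclass(frozen=True)
class PerturbationSpec:
    target: Target
    error_level: float = 0.0
    subsample_fraction: float = 0.9
    n_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in ("environment", "abundance", "both", "subsample"):
            raise RobustnessError(f"unknown perturbation target {self.target!r}")
        if self.error_level < 0:
            raise RobustnessError("error level must be nonnegative")
        if not 0 < self.subsample_fraction <= 1:
            raise RobustnessError("subsample fraction must be in (0, 1]")
        if self.n_iter < 1:
            raise RobustnessError("need at least one iteration")


@dataclass(frozen=True)
class PairRobustness:
    base: float
    n_valid: int
    mean: float
    ci_low: float
    ci_high: float
    ci_low_percentile: float
    ci_high_percentile: float
    t_statistic: float
    p_value: float
    values: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class RobustnessReport:
    spec: PerturbationSpec
    taxon_ids: tuple[str, ...]
    pairs: dict[tuple[str, str], PairRobustness]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (ti, tj), pr in self.pairs.items():
            rows.append({"taxon_i": ti, "taxon_j": tj, "base": pr.base,
                         "n_valid": pr.n_valid, "mean": pr.mean,
                         "ci_low": pr.ci_low, "ci_high": pr.ci_high,
                         "ci_low_percentile": pr.ci_low_percentile,
                         "ci_high_percentile": pr.ci_high_percentile,
                         "t_statistic": pr.t_statistic,
                         "p_value": pr.p_value})
        return pd.DataFrame(rows)


def perturb(values: np.ndarray, e: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative uniform perturbation, relative error bounded by ``e``."""
    if e < 0:
        raise RobustnessError("error level must be nonnegative")
    if e == 0:
        return np.array(values, dtype=float, copy=True)
    return values * (1 + rng.uniform(-1, 1, size=np.shape(values)) * e)


def subsample(a: AbundanceTable, e: EnvironmentTable, fraction: float,
              rng: np.random.Generator, n_variables: int | None = None
              ) -> tuple[AbundanceTable, EnvironmentTable]:
    """Retain ``floor(fraction * N)`` shared samples, without replacement."""
    if a.sample_ids != e.sample_ids:
        raise RobustnessError("tables must be aligned before subsampling")
    n = a.n_samples
    keep = int(np.floor(fraction * n))
    if n_variables is None:
        n_variables = max(a.n_taxa, e.n_params)
    if keep <= n_variables:
        raise RobustnessError(
            f"retaining {keep} of {n} samples cannot support "
            f"{n_variables} regression variables")
    idx = np.sort(rng.choice(n, size=keep, replace=False))
    ids = [a.sample_ids[i] for i in idx]
    return a.select_samples(ids), e.select_samples(ids)


def _summarize_values(base: float, vals: np.ndarray,
                      confidence: float = 0.95) -> PairRobustness:
    n = vals.size
    if n == 0:
        return PairRobustness(base, 0, np.nan, np.nan, np.nan, np.nan,
                              np.nan, np.nan, np.nan, values=vals)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    if sd <= 1e-12 * max(1.0, abs(mean)):
        sd = 0.0  # identical iterations up to float accumulation noise
    if n > 1 and sd > 0:
        half = scipy.stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / np.sqrt(n)
        t_stat, p_val = scipy.stats.ttest_1samp(vals, 0.0)
        t_stat, p_val = float(t_stat), float(p_val)
    else:
        # degenerate spread: zero-width interval, decisive test vs 0
        half = 0.0
        t_stat = np.inf if mean != 0 else 0.0
        p_val = 0.0 if mean != 0 else 1.0
    lo_q, hi_q = (1 - confidence) / 2, 1 - (1 - confidence) / 2
    return PairRobustness(
        base, int(n), mean, mean - half, mean + half,
        float(np.quantile(vals, lo_q)), float(np.quantile(vals, hi_q)),
        t_stat, p_val, values=vals)


def robustness_run(a: AbundanceTable, e: EnvironmentTable,
                   spec: PerturbationSpec,
                   config: PipelineConfig = PipelineConfig()
                   ) -> RobustnessReport:
    """Perturb, rerun the full chain, and summarize per ordered pair.

    Confidence intervals are two-sided 95% t-intervals of the iteration
    mean (a percentile interval is reported alongside); the test is a
    two-sided one-sample t-test against zero.  Requires ``n_iter >= 2`` so
    that a spread is defined.  Deterministic for a given spec seed.
    """
    if spec.n_iter < 2:
        raise RobustnessError(
            "confidence intervals require at least 2 iterations")
    base = infer_interactions(a, e, config)
    taxa = base.global_matrix.taxon_ids
    collected: dict[tuple[str, str], list[float]] = {
        (ti, tj): [] for ti in taxa for tj in taxa}

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_iter)
    for it in range(spec.n_iter):
        rng = np.random.default_rng(seeds[it])
        ai, ei = a, e
        if spec.target in ("environment", "both"):
            ei = EnvironmentTable(e.sample_ids, e.param_ids,
                                  perturb(e.values, spec.error_level, rng))
        if spec.target in ("abundance", "both"):
            ai = AbundanceTable(a.sample_ids, a.taxon_ids,
                                perturb(a.values, spec.error_level, rng),
                                mode=a.mode)
        if spec.target == "subsample":
            n_vars = max(a.n_taxa, e.n_params)
            ai, ei = subsample(a, e, spec.subsample_fraction, rng,
                               n_variables=n_vars)
        try:
            res = infer_interactions(ai, ei, config)
        except Exception:  # a degenerate iteration contributes nothing
            continue
        gm = res.global_matrix
        for i, ti in enumerate(gm.taxon_ids):
            for j, tj in enumerate(gm.taxon_ids):
                if gm.status[i, j] is Status.DETERMINATE and (ti, tj) in collected:
                    collected[(ti, tj)].append(float(gm.beta[i, j]))

    pairs = {}
    gm0 = base.global_matrix
    base_lookup = {(ti, tj): gm0.beta[i, j]
                   for i, ti in enumerate(taxa) for j, tj in enumerate(taxa)}
    for key, vals in collected.items():
        pairs[key] = _summarize_values(float(base_lookup[key]),
                                       np.asarray(vals, dtype=float))
    return RobustnessReport(spec, taxa, pairs)
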