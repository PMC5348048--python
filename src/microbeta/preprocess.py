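"""Pre-estimation conditioning: zero filtering, scaling, collinearity pruning.

The interaction estimators divide by per-sample abundance and regress on
cross-sample differences, so every retained taxon must be observed in every
sample, all columns are put on a common scale (unit sample variance, no
centering), and both design matrices must have full column rank.  Rank
deficiency is resolved by randomly discarding one dependent column at a time
and re-testing, which also dampens closure-induced dependence among relative
abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .tables import AbundanceTable, EnvironmentTable, TableValidationError

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


class DimensionError(PreprocessError):
    pass


@dataclass
class PreprocessReport:
    """What preprocessing changed, for the run manifest."""

    dropped_taxa: list[str] = field(default_factory=list)
    removed_collinear: list[tuple[str, str]] = field(default_factory=list)  # (label, kind)
    ranks: dict[str, tuple[int, int]] = field(default_factory=dict)  # matrix -> (before, after)
    scale_factors: dict[str, float] = field(default_factory=dict)
    dimension_status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "dropped_taxa": list(self.dropped_taxa),
            "removed_collinear": [list(t) for t in self.removed_collinear],
            "ranks": {k: list(v) for k, v in self.ranks.items()},
            "scale_factors": dict(self.scale_factors),
            "dimension_status": self.dimension_status,
        }


def drop_zero_taxa(a: AbundanceTable) -> tuple[AbundanceTable, list[str]]:
    """Keep only taxa with strictly positive abundance in every sample.

    A taxon absent from any sample cannot enter the analysis (its abundance
    appears in a denominator), so it is removed outright.
    """
    keep = (a.values > 0).all(axis=0)
    if not keep.any():
        raise PreprocessError("no taxon observed in all samples")
    dropped = [t for t, k in zip(a.taxon_ids, keep) if not k]
    if not dropped:
        return a, []
    kept = [t for t, k in zip(a.taxon_ids, keep) if k]
    logger.info("drop_zero_taxa removed %d taxa: %s", len(dropped), dropped)
    return a.select_taxa(kept), dropped


def scale_unit_variance(values: np.ndarray, labels=None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Divide each column by its sample standard deviation (no centering).

    Returns the scaled matrix and the scale factors.  Uncentered scaling
    keeps zero at zero and preserves every entry's sign, which matters
    because downstream coefficients are divided by scaled abundances.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=0, ddof=1)
    bad = ~(sd > 0)
    if bad.any():
        j = int(np.argmax(bad))
        name = labels[j] if labels is not None else f"column {j}"
        raise PreprocessError(f"constant column cannot be scaled: {name}")
    return values / sd, sd


def numerical_rank(values: np.ndarray) -> int:
    """Matrix rank with the standard singular-value tolerance."""
    return int(np.linalg.matrix_rank(values))


def _dependent_candidates(values: np.ndarray, rank: int) -> np.ndarray:
    """Columns flagged as pivot-dependent by column-pivoted QR."""
    _, _, piv = scipy.linalg.qr(values, mode="economic", pivoting=True)
    return piv[rank:]


def collinearity_prune(values: np.ndarray, labels, seed: int
                       ) -> tuple[np.ndarray, list[str]]:
    """Remove columns until the matrix has full column rank.

    While rank < columns, one column is drawn uniformly from the pivot-
    dependent candidates of a column-pivoted QR and removed; the test is
    then repeated.  Deterministic for a given seed.  Returns the pruned
    matrix and removed labels in removal order.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if values.shape[1] != len(labels):
        raise PreprocessError("label count does not match column count")
    rng = np.random.default_rng(seed)
    removed: list[str] = []
    while values.shape[1] > 0:
        rank = numerical_rank(values)
        if rank == values.shape[1]:
            break
        candidates = _dependent_candidates(values, rank)
        j = int(rng.choice(candidates))
        removed.append(labels[j])
        logger.info("collinearity_prune removed %r (rank %d < %d columns)",
                    labels[j], rank, values.shape[1])
        values = np.delete(values, j, axis=1)
        del labels[j]
    return values, removed


def check_dimensions(n_samples: int, n_variables: int) -> str:
    """Sample-size adequacy for the difference regressions.

    The regressions are underdetermined unless samples exceed regressors;
    fewer than two samples per regressor is flagged as risky.
    """
    if n_samples <= 0 or n_variables <= 0:
        raise ValueError("sample and variable counts must be positive")
    if n_samples <= n_variables:
        raise DimensionError(
            f"{n_samples} samples with {n_variables} variables: "
            "regression would be underdetermined")
    if n_samples < 2 * n_variables:
        logger.warning("only %d samples for %d variables (< 2x)",
                       n_samples, n_variables)
        return "warning"
    return "ok"


def preprocess(a: AbundanceTable, e: EnvironmentTable, seed: int = 0,
               variant: str = "reduced"
               ) -> tuple[AbundanceTable, EnvironmentTable, PreprocessReport]:
    """Full conditioning chain on pre-aligned tables.

    Order: drop zero taxa -> scale both matrices to unit variance ->
    collinearity-prune abundance, then environment -> dimension check.
    The scaled tables keep the original identifiers so that coefficients
    can be mapped back (and unscaled via the reported factors).
    """
    if a.sample_ids != e.sample_ids:
        raise TableValidationError("tables must be aligned before preprocessing")
    report = PreprocessReport()
    a, report.dropped_taxa = drop_zero_taxa(a)

    av, a_sd = scale_unit_variance(a.values, a.taxon_ids)
    ev, e_sd = scale_unit_variance(e.values, e.param_ids)
    report.scale_factors.update(
        {t: float(s) for t, s in zip(a.taxon_ids, a_sd)})
    report.scale_factors.update(
        {p: float(s) for p, s in zip(e.param_ids, e_sd)})

    rank_a0 = numerical_rank(av)
    av, removed_taxa = collinearity_prune(av, a.taxon_ids, seed)
    report.removed_collinear += [(t, "taxon") for t in removed_taxa]
    report.ranks["abundance"] = (rank_a0, av.shape[1])

    rank_e0 = numerical_rank(ev)
    ev, removed_params = collinearity_prune(ev, e.param_ids, seed + 1)
    report.removed_collinear += [(p, "parameter") for p in removed_params]
    report.ranks["environment"] = (rank_e0, ev.shape[1])

    kept_taxa = [t for t in a.taxon_ids if t not in removed_taxa]
    kept_params = [p for p in e.param_ids if p not in removed_params]
    a_out = AbundanceTable(a.sample_ids, tuple(kept_taxa), av, mode="absolute")
    e_out = EnvironmentTable(e.sample_ids, tuple(kept_params), ev)

    d, m = a_out.n_taxa, e_out.n_params
    # regressor counts: slope fit uses m (reduced) or m+d-1 (full);
    # interaction fit uses d (reduced) or d+m (full)
    n_vars = {"reduced": max(m, d), "full": max(m + d - 1, d + m)}[variant]
    report.dimension_status = check_dimensions(a_out.n_samples, n_vars)
    return a_out, e_out, report
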