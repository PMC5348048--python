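"""One-call orchestration of the full inference chain.

``infer_interactions`` runs align -> preprocess -> slope field ->
interaction field -> global summarization and returns everything a caller
(or the CLI / robustness machinery) needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal



from . import preprocess as pp
from .fields import (LocalInteractionField, LocalSlopeField, estimate_beta,
                     estimate_p)
from .summarize import GlobalInteractionMatrix, PeakSummary, SummaryWeights, \
    summarize_field
from .tables import AbundanceTable, EnvironmentTable, align_tables


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the default chain (all thresholds user-adjustable)."""

    variant: Literal["reduced", "full"] = "reduced"
    majority: float = 0.8
    ratio_threshold: float = 2.0
    min_values: int = 5
    weights: SummaryWeights | None = None
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "majority": self.majority,
            "ratio_threshold": self.ratio_threshold,
            "min_values": self.min_values,
            "weights": None if self.weights is None else
                       [float(c) for c in self.weights.C],
            "max_iter": self.max_iter,
            "tol": self.tol,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class InferenceResult:
    abundance: AbundanceTable  # preprocessed (scaled) tables actually used
    environment: EnvironmentTable
    report: pp.PreprocessReport
    slopes: LocalSlopeField
    interactions: LocalInteractionField
    global_matrix: GlobalInteractionMatrix
    peaks: dict[tuple[str, str, str], PeakSummary] = dc_field(repr=False,
                                                             default_factory=dict)


def infer_interactions(a: AbundanceTable, e: EnvironmentTable,
                       config: PipelineConfig = PipelineConfig()
                       ) -> InferenceResult:
    """Run the complete chain on raw (unscaled, possibly unaligned) tables."""
    a, e = align_tables(a, e)
    a2, e2, report = pp.preprocess(a, e, seed=config.seed,
                                   variant=config.variant)
    slopes = estimate_p(a2, e2, config.variant,
                        max_iter=config.max_iter, tol=config.tol)
    interactions = estimate_beta(slopes, a2, e2, config.variant,
                                 max_iter=config.max_iter, tol=config.tol)
    gmat, peaks = summarize_field(interactions, config.majority,
                                  config.ratio_threshold,
                                  weights=config.weights,
                                  min_values=config.min_values)
    return InferenceResult(a2, e2, report, slopes, interactions, gmat, peaks)
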