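"""Scaled simulation study: accuracy of the pipeline on arrays of known truth.

Re-runs the simulation-based evaluation at desk scale: nine mosaic morphs of
5 kb units (average divergence 4.4%, of which 4.2% from mosaic sampling and
0.2% from random mutations), copy counts drawn in 1-15 (about 40 copies per
array), HiFi-like reads at 35x and ONT-like ultralong reads at 60x with a
25 kb mean length and 5% error.  Each replicate simulates a fresh array, runs
the reference-based pipeline end to end, and scores the assembled morphs
against the ground truth under the 99% identity / 99% coverage criterion.

Reported metrics: Pearson correlation of predicted morph coverage (loop
count) vs truth copy count pooled over replicates; overall sensitivity (no
abundance filter, averaged over replicates); and sensitivity/specificity
restricted to abundant morphs (truth copy count >= 5 for sensitivity,
predicted coverage >= 30 for specificity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .evaluate import score_assembly
from .pipeline import PipelineConfig, PipelineError, run_ref_pipeline
from .simulate import ReadProfile, SimParams, simulate_dataset

__all__ = ["StudySummary", "study_params", "run_replicate", "run_study", "STUDY_ONT_PROFILE"]

# ultralong profile at study scale: 25 kb mean, heavy tail, ~5% error
STUDY_ONT_PROFILE = ReadProfile(25_000, 0.40, 0.025, 0.012, 0.013, 1.5)

MORPH_LENGTH = 5_000
HIFI_COVERAGE = 35.0
ONT_COVERAGE = 60.0
ABUNDANT_MIN_COPIES = 5
ABUNDANT_MIN_COVERAGE = 30


def study_params(seed: int) -> SimParams:
    """Study conditions for one replicate array."""
    return SimParams(
        n_sources=9,
        morph_length=MORPH_LENGTH,
        n_morphs=9,
        mosaic_divergence=0.042,
        mutation_rate=0.002,
        copy_count_law=("geometric", 0.25, 1, 15),
        seed=seed,
    )


@dataclass
class ReplicateResult:
    seed: int
    sensitivity_overall: float
    sensitivity_abundant: Optional[float]
    specificity_abundant: Optional[float]
    coverage_copy_pairs: List[Tuple[int, int]]
    n_truth: int
    n_predicted: int
    epsilon: int


@dataclass
class StudySummary:
    pearson_pooled: Optional[float]
    sensitivity_overall: float  # percent
    sensitivity_abundant: float  # percent
    specificity_abundant: float  # percent
    replicates: List[ReplicateResult] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return sum(len(r.coverage_copy_pairs) for r in self.replicates)


def run_replicate(seed: int) -> ReplicateResult:
    """Simulate one array, run the pipeline and score it against truth."""
    params = study_params(seed)
    array, reference, hifi, ont = simulate_dataset(
        params,
        hifi_coverage=HIFI_COVERAGE,
        ont_coverage=ONT_COVERAGE,
        ont_profile=STUDY_ONT_PROFILE,
    )
    config = PipelineConfig(
        reference=reference,
        hifi=hifi,
        ont=ont,
        approx_morph_size=MORPH_LENGTH,
        seed=seed,
    )
    result = run_ref_pipeline(config)
    overall = score_assembly(array.morphs, result.morphs)
    abundant = score_assembly(
        array.morphs,
        result.morphs,
        min_truth_copies=ABUNDANT_MIN_COPIES,
        min_pred_coverage=ABUNDANT_MIN_COVERAGE,
    )
    return ReplicateResult(
        seed=seed,
        sensitivity_overall=overall.sensitivity,
        sensitivity_abundant=(
            abundant.sensitivity if abundant.n_truth > 0 else None
        ),
        specificity_abundant=abundant.specificity,
        coverage_copy_pairs=overall.coverage_copy_pairs,
        n_truth=len(array.morphs),
        n_predicted=len(result.morphs),
        epsilon=result.epsilon,
    )


def run_study(n_replicates: int = 5, seed: int = 1) -> StudySummary:
    """Run ``n_replicates`` seeded replicates and aggregate the metrics."""
    reps = [run_replicate(seed + 1000 * i) for i in range(n_replicates)]
    pairs = [p for r in reps for p in r.coverage_copy_pairs]
    pearson = None
    if len(pairs) >= 3:
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        if x.std() > 0 and y.std() > 0:
            pearson = float(np.corrcoef(x, y)[0, 1])
    sens = 100.0 * float(np.mean([r.sensitivity_overall for r in reps]))
    sens_ab = [r.sensitivity_abundant for r in reps if r.sensitivity_abundant is not None]
    spec_ab = [r.specificity_abundant for r in reps if r.specificity_abundant is not None]
    return StudySummary(
        pearson_pooled=pearson,
        sensitivity_overall=sens,
        sensitivity_abundant=100.0 * float(np.mean(sens_ab)) if sens_ab else float("nan"),
        specificity_abundant=100.0 * float(np.mean(spec_ab)) if spec_ab else float("nan"),
        replicates=reps,
    )
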