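"""End-to-end convenience wrappers: cohort in, regulation classes out.

``simulate_cohort`` bundles one fully synthetic study (design,
ascorbate profile, truth panel, paired matrices); ``regulation_screen``
runs the complete downstream path for one sex — variance filter,
validity and fold gates, sex-stratified Spearman screen at both layers,
layer pairing and nine-quadrant classification — and returns every
intermediate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .correlate import correlate_features
from .design import CohortDesign, generate_cohort
from .integrate import pair_layers, quadrant_table
from .matrices import ExpressionMatrix
from .preprocess import tpm_variance_filter
from .simulate import (
    AscorbateProfile,
    SimulationTruth,
    default_truth_panel,
    simulate_ascorbate,
    simulate_dual_omics,
)
from .spearman import critical_rho


@dataclass
class SyntheticCohort:
    """One simulated study with its ground truth."""

    design: CohortDesign
    ascorbate: AscorbateProfile
    truth: SimulationTruth
    tpm: ExpressionMatrix = field(repr=False)
    lfq: ExpressionMatrix = field(repr=False)


def simulate_cohort(
    seed: int = 0,
    n_per_cell: int = 3,
    truth: SimulationTruth | None = None,
    **omics_kwargs,
) -> SyntheticCohort:
    """Generate a complete synthetic cohort from one seed.

    The same seed drives the ascorbate draw and the omics noise (via
    distinct streams), so identical calls are bit-identical.
    """
    design = generate_cohort(n_per_cell=n_per_cell, seed=seed)
    if truth is None:
        truth = default_truth_panel(seed=seed)
    ascorbate = simulate_ascorbate(design, seed=seed)
    tpm, lfq = simulate_dual_omics(design, ascorbate, truth,
                                   seed=seed + 1, **omics_kwargs)
    return SyntheticCohort(design, ascorbate, truth, tpm, lfq)


@dataclass
class ScreenResult:
    """All outputs of one sex-stratified regulation screen."""

    stratum: str
    threshold: float
    transcript_records: pd.DataFrame = field(repr=False)
    protein_records: pd.DataFrame = field(repr=False)
    paired: pd.DataFrame = field(repr=False)
    quadrants: pd.DataFrame = field(repr=False)
    unpaired: dict = field(default_factory=dict)


def regulation_screen(
    tpm: ExpressionMatrix,
    lfq: ExpressionMatrix,
    ascorbate: AscorbateProfile,
    design: CohortDesign,
    stratum: str,
    alpha: float = 0.05,
) -> ScreenResult:
    """Run the full transcript + protein screen for one sex.

    The quadrant threshold is the critical rho of the stratum's sample
    size at ``alpha`` (0.4696 for n = 18 at the 5% level under the
    Edgeworth null).
    """
    kept = tpm_variance_filter(tpm)
    tpm_kept = tpm.subset_features(kept)
    transcript = correlate_features(tpm_kept, ascorbate, design, stratum, alpha=alpha)
    protein = correlate_features(lfq, ascorbate, design, stratum, alpha=alpha)

    n = len(design.stratum_ids(stratum))
    threshold = critical_rho(n, alpha)
    if threshold is None:
        raise ValueError(f"no achievable significance threshold at n={n}, alpha={alpha}")

    # pairing requires the >70% validity gate on both layers
    t_ok = transcript[transcript["validity_pass"]]
    p_ok = protein[protein["validity_pass"]]
    paired, unpaired = pair_layers(t_ok, p_ok)
    quadrants = quadrant_table(paired, threshold)
    return ScreenResult(
        stratum=stratum,
        threshold=threshold,
        transcript_records=transcript,
        protein_records=protein,
        paired=paired,
        quadrants=quadrants,
        unpaired=unpaired,
    )
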