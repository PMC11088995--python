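"""Synthetic paired-omics cohorts with known ground truth.

The generator emulates, at the matrix level, a 36-animal study in which
hepatic ascorbate concentration varies over a dose ladder (six treatment
groups x two sexes x >= 3 replicates) and every downstream question is
about association between a feature's abundance and that per-animal
covariate. It produces:

* per-sample hepatic ascorbate (ng/mg tissue), dose-monotone in
  expectation with truncated-Gaussian animal-to-animal scatter;
* a transcript matrix (TPM) and a protein matrix (LFQ intensity) over a
  shared gene panel, log-normal around per-gene baselines with a planted
  class-dependent ascorbate term, plus left-censored (missing-not-at-
  random) protein values and per-protein peptide counts;
* polysome absorbance traces with a controlled polysomal mass fraction;
* qPCR Ct plates generated by inverting the delta-Ct model.

Planted gene classes
--------------------
``null``
    no association at either layer;
``sex_dimorphic``
    a sex offset, no ascorbate term;
``transcriptional_pos`` / ``transcriptional_neg``
    ascorbate term at the transcript layer, mirrored by the protein;
``post_transcriptional_pos`` / ``post_transcriptional_neg``
    ascorbate term at the protein layer only (transcript is null);
``translation_shifted``
    total transcript unchanged while translational engagement (and
    hence protein output) follows ascorbate — at the matrix level this
    behaves like a post-transcriptional gene; its distinctive signature
    lives in the polysome-fraction qPCR simulation.

The abundance model is linear in centred log2-ascorbate on the log2
abundance scale — the simplest generative model consistent with a
monotone rank-correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import GROUPS, CohortDesign
from .matrices import ConsistencyError, ExpressionMatrix
from .polysome import FractionScheme, PolysomeTrace

#: Default group means for hepatic ascorbate, ng per mg tissue. The dose
#: ordering GL00 < GL01 < GL05 < GL40 is the designed contrast; the
#: rescue group (GLR40) and the wild type sit near the fully treated
#: group. Magnitudes are order-of-magnitude placeholders for a liver
#: ascorbate assay, configurable rather than hard-coded.
DEFAULT_ASCORBATE_MEANS: dict[str, float] = {
    "GL00": 25.0,
    "GL01": 90.0,
    "GL05": 250.0,
    "GL40": 600.0,
    "GLR40": 560.0,
    "WT00": 500.0,
}

#: Default animal-to-animal scatter of hepatic ascorbate (ng/mg).
DEFAULT_ASCORBATE_SD = 20.0

GENE_CLASSES = (
    "null",
    "sex_dimorphic",
    "transcriptional_pos",
    "transcriptional_neg",
    "post_transcriptional_pos",
    "post_transcriptional_neg",
    "translation_shifted",
)

#: classes whose ascorbate term appears at the transcript layer
_TRANSCRIPT_CLASSES = {"transcriptional_pos", "transcriptional_neg"}
#: classes whose ascorbate term appears at the protein layer
_PROTEIN_CLASSES = _TRANSCRIPT_CLASSES | {
    "post_transcriptional_pos",
    "post_transcriptional_neg",
    "translation_shifted",
}


class ParameterError(ValueError):
    """Raised for out-of-range generator parameters."""


@dataclass(frozen=True)
class AscorbateProfile:
    """Per-sample hepatic ascorbate concentration (ng/mg tissue)."""

    values: pd.Series = field(repr=False)  # indexed by sample_id

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ParameterError("ascorbate concentrations must be non-negative")

    def check_design(self, design: CohortDesign) -> None:
        if list(self.values.index) != design.sample_ids:
            raise ConsistencyError("ascorbate profile does not match the cohort design")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth gene panel for the dual-omics generator.

    Parameters
    ----------
    genes
        DataFrame indexed by gene id with columns ``gene_class``,
        ``effect`` (log2 abundance units per unit centred
        log2-ascorbate; 0 exactly for null and sex_dimorphic genes),
        ``sex_effect`` (log2 F-minus-M offset), ``baseline_tpm_log2``,
        ``baseline_lfq_log2`` and ``peptide_count``.
    censor_log2
        Left-censoring threshold on log2 LFQ intensity: true values
        below it are reported missing.
    """

    genes: pd.DataFrame = field(repr=False)
    censor_log2: float = 21.0

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ParameterError("truth panel must be non-empty")
        bad = set(self.genes["gene_class"]) - set(GENE_CLASSES)
        if bad:
            raise ParameterError(f"unknown gene classes: {sorted(bad)}")
        flat = self.genes["gene_class"].isin(["null", "sex_dimorphic"])
        if (self.genes.loc[flat, "effect"] != 0).any():
            raise ParameterError("null and sex_dimorphic genes must have effect 0")
        if (self.genes.loc[~flat, "effect"] == 0).any():
            raise ParameterError("ascorbate-responsive genes must have effect != 0")

    def ids_of(self, gene_class: str) -> list[str]:
        return list(self.genes.index[self.genes["gene_class"] == gene_class])


def default_truth_panel(
    n_null: int = 200,
    n_per_class: int = 12,
    effect: float = 0.5,
    sex_effect: float = 2.0,
    censor_log2: float = 21.0,
    seed: int = 0,
) -> SimulationTruth:
    """Standard gene panel: ``n_null`` null genes plus ``n_per_class``
    genes of each planted class.

    ``effect`` = 0.5 log2 units per unit centred log2-ascorbate spans
    roughly a 5-fold abundance change over the default dose ladder
    (deficient to fully treated), comfortably past the two-fold gate;
    ``sex_effect`` = 2.0 log2 units is a four-fold sex difference.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(gene_class: str, count: int, eff: float, sex_eff: float) -> None:
        for k in range(count):
            rows.append(
                {
                    "gene_id": f"{gene_class}_{k:03d}",
                    "gene_class": gene_class,
                    "effect": eff,
                    "sex_effect": sex_eff,
                }
            )

    add("null", n_null, 0.0, 0.0)
    add("sex_dimorphic", n_per_class, 0.0, sex_effect)
    add("transcriptional_pos", n_per_class, effect, 0.0)
    add("transcriptional_neg", n_per_class, -effect, 0.0)
    add("post_transcriptional_pos", n_per_class, effect, 0.0)
    add("post_transcriptional_neg", n_per_class, -effect, 0.0)
    add("translation_shifted", n_per_class, -effect, 0.0)
    genes = pd.DataFrame(rows).set_index("gene_id")
    m = len(genes)
    genes["baseline_tpm_log2"] = rng.normal(5.0, 1.6, size=m)
    genes["baseline_lfq_log2"] = rng.normal(25.0, 1.6, size=m)
    # a small tail of one-peptide identifications exercises the
    # two-peptide quantifiability gate on null genes only
    pep = rng.poisson(7.0, size=m) + 2
    one_pep = (genes["gene_class"] == "null") & (rng.random(m) < 0.04)
    pep[one_pep.to_numpy()] = 1
    genes["peptide_count"] = pep
    return SimulationTruth(genes=genes, censor_log2=censor_log2)


def simulate_ascorbate(
    design: CohortDesign,
    group_means: dict[str, float] | None = None,
    noise_sd: float = DEFAULT_ASCORBATE_SD,
    seed: int = 0,
) -> AscorbateProfile:
    """Draw per-animal hepatic ascorbate around dose-group means.

    Values are Gaussian around the group mean, truncated at zero (the
    assay cannot report negative concentrations); with ``noise_sd=0``
    each sample equals its group mean exactly.
    """
    means = dict(DEFAULT_ASCORBATE_MEANS if group_means is None else group_means)
    missing = set(GROUPS) - set(means)
    if missing:
        raise ParameterError(f"group_means missing groups: {sorted(missing)}")
    if any(v < 0 for v in means.values()):
        raise ParameterError("group means must be non-negative")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mu = design.samples["group"].map(means).to_numpy(dtype=float)
    if noise_sd == 0:
        vals = mu
    else:
        a = (0.0 - mu) / noise_sd  # truncate at zero
        vals = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=noise_sd,
                                   random_state=rng)
    return AscorbateProfile(pd.Series(vals, index=design.sample_ids, name="ascorbate"))


def simulate_dual_omics(
    design: CohortDesign,
    ascorbate: AscorbateProfile,
    truth: SimulationTruth,
    seed: int = 0,
    tpm_noise_sd: float = 0.35,
    lfq_noise_sd: float = 0.35,
    dropout_rate: float = 0.0,
    n_transcript_only: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Generate paired TPM and LFQ matrices from a truth panel.

    The transcript abundance of gene g in sample i is log-normal:

        log2 TPM_gi = baseline_g + beta_t_g * x_i + s_g * sex_i + eps

    with x_i the centred log2-ascorbate and beta_t nonzero only for
    transcriptional classes. The protein layer carries beta_p * x_i with
    beta_p = beta_t for transcriptional classes (protein mirrors the
    transcript) and beta_p = effect for post-transcriptional and
    translation-shifted classes (the term exists only at the protein
    layer). LFQ values below the truth's censoring threshold are
    reported missing; optional uniform dropout adds missingness that is
    independent of intensity.

    ``n_transcript_only`` appends that many extra null transcripts with
    no protein counterpart, for exercising the layer-pairing step.
    """
    ascorbate.check_design(design)
    if not 0.0 <= dropout_rate < 1.0:
        raise ParameterError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    n_genes = len(genes)
    n_samples = design.n_samples

    log_asc = np.log2(np.maximum(ascorbate.values.to_numpy(dtype=float), 1e-3))
    x = log_asc - log_asc.mean()
    sex_ind = (design.samples["sex"] == "F").to_numpy(dtype=float) - 0.5

    cls = genes["gene_class"]
    effect = genes["effect"].to_numpy(dtype=float)
    beta_t = np.where(cls.isin(_TRANSCRIPT_CLASSES), effect, 0.0)
    beta_p = np.where(cls.isin(_PROTEIN_CLASSES), effect, 0.0)
    sex_eff = genes["sex_effect"].to_numpy(dtype=float)

    base_t = genes["baseline_tpm_log2"].to_numpy(dtype=float)[:, None]
    base_p = genes["baseline_lfq_log2"].to_numpy(dtype=float)[:, None]
    signal_t = base_t + np.outer(beta_t, x) + np.outer(sex_eff, sex_ind)
    signal_p = base_p + np.outer(beta_p, x) + np.outer(sex_eff, sex_ind)

    log_tpm = signal_t + rng.normal(0.0, tpm_noise_sd, size=(n_genes, n_samples))
    log_lfq = signal_p + rng.normal(0.0, lfq_noise_sd, size=(n_genes, n_samples))

    tpm_vals = pd.DataFrame(
        np.exp2(log_tpm), index=genes.index.copy(), columns=design.sample_ids
    )
    lfq_raw = np.exp2(log_lfq)
    missing = log_lfq < truth.censor_log2
    if dropout_rate > 0:
        missing |= rng.random(size=log_lfq.shape) < dropout_rate
    lfq_raw[missing] = np.nan
    lfq_vals = pd.DataFrame(lfq_raw, index=genes.index.copy(), columns=design.sample_ids)

    if n_transcript_only > 0:
        extra_base = rng.normal(5.0, 1.6, size=n_transcript_only)[:, None]
        extra = extra_base + rng.normal(0.0, tpm_noise_sd,
                                        size=(n_transcript_only, n_samples))
        extra_df = pd.DataFrame(
            np.exp2(extra),
            index=[f"transcript_only_{k:03d}" for k in range(n_transcript_only)],
            columns=design.sample_ids,
        )
        tpm_vals = pd.concat([tpm_vals, extra_df])

    tpm = ExpressionMatrix(tpm_vals, layer="TPM")
    lfq = ExpressionMatrix(
        lfq_vals, layer="LFQ", peptide_counts=genes["peptide_count"].astype(int)
    )
    return tpm, lfq


# ---------------------------------------------------------------------------
# polysome traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolysomeTraceParams:
    """Peak layout of an A254 absorbance trace over a sucrose gradient.

    Exactly three sub-polysomal peaks (the 40S and 60S ribosomal
    subunits and the 80S monosome) and twelve polysomal peaks; centres
    must be strictly increasing along the gradient.
    """

    sub_centers: tuple[float, ...] = (12.0, 16.0, 21.0)
    sub_heights: tuple[float, ...] = (0.35, 0.45, 0.90)
    sub_widths: tuple[float, ...] = (1.2, 1.2, 1.5)
    poly_centers: tuple[float, ...] = tuple(27.0 + 5.0 * k for k in range(12))
    poly_heights: tuple[float, ...] = tuple(0.80 * 0.85 ** k for k in range(12))
    poly_widths: tuple[float, ...] = (1.8,) * 12
    baseline: float = 0.05
    step: float = 0.1
    span: float = 95.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.sub_centers) != 3 or len(self.poly_centers) != 12:
            raise ParameterError("need exactly 3 sub-polysomal and 12 polysomal peaks")
        centers = (*self.sub_centers, *self.poly_centers)
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ParameterError("peak centers must be strictly increasing")
        if any(w <= 0 for w in (*self.sub_widths, *self.poly_widths)):
            raise ParameterError("peak widths must be positive")
        if any(h < 0 for h in (*self.sub_heights, *self.poly_heights)):
            raise ParameterError("peak heights must be non-negative")
        if self.noise_sd < 0 or self.step <= 0:
            raise ParameterError("noise_sd >= 0 and step > 0 required")


def _gaussian_area(heights, widths) -> float:
    return float(np.sqrt(2.0 * np.pi) * np.sum(np.asarray(heights) * np.asarray(widths)))


def simulate_polysome_trace(
    params: PolysomeTraceParams | None = None,
    polysome_mass_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[PolysomeTrace, FractionScheme]:
    """Build a trace whose above-baseline polysomal area fraction is known.

    The polysomal peak heights are rescaled so that, analytically, the
    above-baseline area in the polysomal region divided by the total
    above-baseline area equals ``polysome_mass_fraction``. The returned
    scheme records the ground-truth sub-polysomal/polysomal boundary and
    the monosome / light-polysome / heavy-polysome pools.
    """
    if params is None:
        params = PolysomeTraceParams()
    if not 0.0 < polysome_mass_fraction < 1.0:
        raise ParameterError("polysome_mass_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    a_sub = _gaussian_area(params.sub_heights, params.sub_widths)
    a_poly = _gaussian_area(params.poly_heights, params.poly_widths)
    f = polysome_mass_fraction
    scale = f * a_sub / ((1.0 - f) * a_poly)
    poly_heights = np.asarray(params.poly_heights) * scale

    pos = np.arange(0.0, params.span + params.step / 2, params.step)
    absorb = np.full_like(pos, params.baseline)
    for c, h, w in zip(params.sub_centers, params.sub_heights, params.sub_widths):
        absorb += h * np.exp(-0.5 * ((pos - c) / w) ** 2)
    for c, h, w in zip(params.poly_centers, poly_heights, params.poly_widths):
        absorb += h * np.exp(-0.5 * ((pos - c) / w) ** 2)
    if params.noise_sd > 0:
        absorb = absorb + rng.normal(0.0, params.noise_sd, size=pos.size)

    boundary = 0.5 * (params.sub_centers[-1] + params.poly_centers[0])
    trace = PolysomeTrace(positions=pos, absorbance=absorb)

    # pools: monosome region around the 80S peak; polysome peaks 1-4 =
    # light, 5-8 = first heavy, 9-12 = second heavy
    mono_start = 0.5 * (params.sub_centers[1] + params.sub_centers[2])
    lp_end = 0.5 * (params.poly_centers[3] + params.poly_centers[4])
    hp1_end = 0.5 * (params.poly_centers[7] + params.poly_centers[8])
    scheme = FractionScheme(
        intervals={
            "sub": (pos[0], boundary),
            "poly": (boundary, pos[-1]),
        },
        polysomal=("poly",),
        pools={
            "M": (mono_start, boundary),
            "LP": (boundary, lp_end),
            "HP1": (lp_end, hp1_end),
            "HP2": (hp1_end, pos[-1]),
        },
    )
    return trace, scheme


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_qpcr_plate(
    samples,
    genes,
    relative_quantities,
    reference_genes=("Atp5o", "Ubc"),
    fractions=("total",),
    reference_ct: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Invert the delta-Ct model: Ct = reference Ct - log2(quantity) + noise.

    Parameters
    ----------
    samples
        Iterable of ``(sample_id, group)`` pairs.
    genes
        Target gene ids (reference genes are appended automatically with
        planted quantity 1 in every sample and fraction).
    relative_quantities
        Mapping ``(gene, group, fraction) -> quantity > 0``; keys
        ``(gene, group)`` are accepted when only one fraction is used.
        Missing keys default to 1.
    reference_ct
        Ct a quantity-1 target amplifies at (plate calibration level).

    Returns
    -------
    DataFrame
        Columns ``sample_id, group, fraction, gene, ct``.
    """
    rng = np.random.default_rng(seed)

    def lookup(gene: str, group: str, fraction: str) -> float:
        if gene in reference_genes:
            return 1.0
        for key in ((gene, group, fraction), (gene, group)):
            if key in relative_quantities:
                return float(relative_quantities[key])
        return 1.0

    rows = []
    for sample_id, group in samples:
        for fraction in fractions:
            for gene in (*genes, *reference_genes):
                q = lookup(gene, group, fraction)
                if q <= 0:
                    raise ParameterError(
                        f"relative quantity for {gene!r} in {group!r} must be positive"
                    )
                ct = reference_ct - np.log2(q)
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "fraction": fraction,
                        "gene": gene,
                        "ct": float(ct),
                    }
                )
    return pd.DataFrame(rows)
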