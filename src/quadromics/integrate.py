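"""Nine-quadrant joint classification of paired transcript/protein screens.

The scatter of per-gene rank correlations — protein rho against
ascorbate on x, transcript rho on y — is cut into a 3x3 grid at the
+/- significance threshold:

    y (transcript rho)
    ^   +-----+-----+-----+
    t   |  1  |  2  |  3  |   3: both positive  -> transcriptional (+)
    .   +-----+-----+-----+   7: both negative  -> transcriptional (-)
    .   |  4  |  5  |  6  |   6, 9: protein-only positive
    -t  +-----+-----+-----+   1, 4: protein-only negative
        |  7  |  8  |  9  |         -> post-transcriptional
        +-----+-----+-----+   2, 8: transcript-only; 5: neither
          -t    .     t    -> x (protein rho)

A gene is assigned a regulation class only when its protein abundance
also differs at least two-fold between the deficient and fully treated
groups (the ``fold2`` flag); quadrant 5 and unflagged outer quadrants
classify as ``none``.

The module also carries the corroborating statistics: a balanced
two-way ANOVA (sex x treatment with interaction) per feature, and a
generic hypergeometric over-representation test with Bonferroni
control for annotation terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CohortDesign
from .matrices import ExpressionMatrix

REGULATION_CLASSES = (
    "transcriptional_pos",
    "transcriptional_neg",
    "post_transcriptional_pos",
    "post_transcriptional_neg",
    "discordant",
    "transcript_only_pos",
    "transcript_only_neg",
    "none",
)


class AmbiguityError(ValueError):
    """Raised when a layer carries duplicate gene ids."""


def pair_layers(
    transcript_records: pd.DataFrame, protein_records: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Inner-join transcript and protein records on gene id.

    Returns the paired table (columns ``transcript_rho, protein_rho``
    plus per-layer gate columns prefixed ``transcript_``/``protein_``)
    and a report of unpaired ids per layer.
    """
    for name, rec in (("transcript", transcript_records),
                      ("protein", protein_records)):
        if rec.index.duplicated().any():
            dupes = sorted(set(rec.index[rec.index.duplicated()]))
            raise AmbiguityError(f"duplicate gene ids in {name} layer: {dupes[:5]}")
    shared = transcript_records.index.intersection(protein_records.index)
    leftover = {
        "transcript_only": sorted(transcript_records.index.difference(shared)),
        "protein_only": sorted(protein_records.index.difference(shared)),
    }
    t = transcript_records.loc[shared].add_prefix("transcript_")
    p = protein_records.loc[shared].add_prefix("protein_")
    return pd.concat([t, p], axis=1), leftover


def assign_quadrant(protein_rho, transcript_rho, threshold: float,
                    boundary: str = "significant"):
    """Quadrant 1-9 of a (protein rho, transcript rho) pair.

    Row-major 3x3 numbering from the top-left: quadrant 1 is
    (x <= -t, y >= t), 3 is (x >= t, y >= t), 5 the central
    non-significant box, 9 (x >= t, y <= -t). Accepts scalars or
    arrays. ``boundary="significant"`` assigns |rho| exactly equal to
    the threshold to the significant side; ``"central"`` to the middle
    band.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(protein_rho, dtype=float)
    y = np.asarray(transcript_rho, dtype=float)
    if np.any(np.abs(x) > 1) or np.any(np.abs(y) > 1):
        raise ValueError("rho values must lie in [-1, 1]")
    if boundary == "significant":
        col = np.where(x <= -threshold, 0, np.where(x >= threshold, 2, 1))
        row = np.where(y >= threshold, 0, np.where(y <= -threshold, 2, 1))
    elif boundary == "central":
        col = np.where(x < -threshold, 0, np.where(x > threshold, 2, 1))
        row = np.where(y > threshold, 0, np.where(y < -threshold, 2, 1))
    else:
        raise ValueError("boundary must be 'significant' or 'central'")
    quadrant = 3 * row + col + 1
    if quadrant.ndim == 0:
        return int(quadrant)
    return quadrant.astype(int)


_QUADRANT_CLASS = {
    3: "transcriptional_pos",
    7: "transcriptional_neg",
    6: "post_transcriptional_pos",
    9: "post_transcriptional_pos",
    1: "post_transcriptional_neg",
    4: "post_transcriptional_neg",
    2: "transcript_only_pos",
    8: "transcript_only_neg",
    5: "none",
}


def classify_regulation(quadrant: int, fold2_flag: bool) -> str:
    """Regulation class of a gene given its quadrant and fold-change flag.

    Outer quadrants carry a class only when the protein abundance also
    changed at least two-fold (``fold2_flag``); the transcript-only
    quadrants 2 and 8 are labelled regardless, since their defining
    feature is precisely that the protein did not follow.
    """
    if quadrant not in _QUADRANT_CLASS:
        raise ValueError(f"quadrant must be 1..9, got {quadrant!r}")
    cls = _QUADRANT_CLASS[quadrant]
    if cls in ("transcript_only_pos", "transcript_only_neg", "none"):
        return cls
    return cls if fold2_flag else "none"


def quadrant_table(
    paired: pd.DataFrame,
    threshold: float,
    fold2_column: str = "protein_fold_pass",
) -> pd.DataFrame:
    """Quadrant and regulation class for every paired gene.

    ``paired`` is the output of :func:`pair_layers` (needs
    ``protein_rho`` and ``transcript_rho``; the two-fold flag is taken
    from ``fold2_column`` when present, else assumed False).
    """
    quad = assign_quadrant(
        paired["protein_rho"].to_numpy(), paired["transcript_rho"].to_numpy(),
        threshold,
    )
    if fold2_column in paired.columns:
        fold2 = paired[fold2_column].fillna(False).to_numpy(dtype=bool)
    else:
        fold2 = np.zeros(len(paired), dtype=bool)
    out = paired[["protein_rho", "transcript_rho"]].copy()
    out["quadrant"] = quad
    out["fold2"] = fold2
    out["regulation"] = [
        classify_regulation(int(q), bool(f)) for q, f in zip(quad, fold2)
    ]
    return out


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaRecord:
    """Fixed-effects 2 (sex) x 6 (treatment) ANOVA for one feature."""

    feature_id: str
    f_sex: float
    f_treatment: float
    f_interaction: float
    p_sex: float
    p_treatment: float
    p_interaction: float
    df_sex: int
    df_treatment: int
    df_interaction: int
    df_residual: int
    defined: bool = True


class SexTermError(ValueError):
    """Raised when a feature is quantifiable in only one sex."""


def balanced_two_way_anova(y, factor_a, factor_b,
                           feature_id: str = "") -> AnovaRecord:
    """Fixed-effects two-way ANOVA with interaction on a balanced layout.

    Sums of squares are computed directly from cell means; on a
    balanced layout the type-I/II/III partitions coincide, so the
    result carries no partitioning convention. Unbalanced cell sizes
    are rejected rather than silently switching conventions. With all
    responses identical, every sum of squares is zero and the F ratios
    are undefined (``defined=False``).
    """
    yv = np.asarray(y, dtype=float)
    cells = pd.DataFrame({"y": yv, "a": np.asarray(factor_a),
                          "b": np.asarray(factor_b)})
    sizes = cells.groupby(["a", "b"]).size()
    a = cells["a"].nunique()
    b = cells["b"].nunique()
    if a < 2 or b < 2:
        raise ValueError("each factor needs >= 2 levels")
    if len(sizes) != a * b or sizes.nunique() != 1:
        raise ValueError(
            f"unbalanced cell sizes {dict(sizes)}; balanced design required"
        )
    r = int(sizes.iloc[0])
    if r < 2:
        raise ValueError("interaction term needs >= 2 replicates per cell")

    grand = yv.mean()
    mean_a = cells.groupby("a")["y"].mean()
    mean_b = cells.groupby("b")["y"].mean()
    mean_cell = cells.groupby(["a", "b"])["y"].mean()

    ss_a = b * r * float(((mean_a - grand) ** 2).sum())
    ss_b = a * r * float(((mean_b - grand) ** 2).sum())
    inter = {
        (la, lb): mean_cell[(la, lb)] - mean_a[la] - mean_b[lb] + grand
        for la, lb in mean_cell.index
    }
    ss_int = r * float(sum(v ** 2 for v in inter.values()))
    fitted = cells.set_index(["a", "b"]).index.map(mean_cell)
    ss_res = float(((yv - np.asarray(fitted)) ** 2).sum())

    df_a, df_b = a - 1, b - 1
    df_int = df_a * df_b
    df_res = a * b * (r - 1)
    ms_res = ss_res / df_res
    # an (almost) constant response: every sum of squares at rounding
    # level, so no F ratio is defined
    scale = max(ss_a, ss_b, ss_int, ss_res)
    if scale <= 1e-20 * max(1.0, grand * grand) * yv.size:
        nan = float("nan")
        return AnovaRecord(feature_id, nan, nan, nan, nan, nan, nan,
                           df_a, df_b, df_int, df_res, defined=False)

    def f_and_p(ss: float, df: int) -> tuple[float, float]:
        if ms_res == 0:
            return (float("inf"), 0.0) if ss > 0 else (float("nan"), float("nan"))
        f = (ss / df) / ms_res
        return f, float(stats.f.sf(f, df, df_res))

    f_a, p_a = f_and_p(ss_a, df_a)
    f_g, p_g = f_and_p(ss_b, df_b)
    f_i, p_i = f_and_p(ss_int, df_int)
    return AnovaRecord(feature_id, f_a, f_g, f_i, p_a, p_g, p_i,
                       df_a, df_b, df_int, df_res)


def two_way_anova(
    m: ExpressionMatrix,
    design: CohortDesign,
    feature_id: str,
    pseudocount: float = 1.0,
) -> AnovaRecord:
    """Two-way ANOVA of one feature's log2 abundance on sex and treatment.

    A feature observed in only one sex raises :class:`SexTermError` —
    the sex term cannot be estimated, mirroring how single-sex proteins
    must be excluded from this corroboration step. Missing values that
    leave the remaining layout unbalanced are rejected.
    """
    m.check_design(design)
    row = m.values.loc[feature_id]
    if m.layer == "TPM":
        yv = np.log2(row.to_numpy(dtype=float) + pseudocount)
    else:
        yv = np.log2(row.to_numpy(dtype=float))
    sex = design.samples["sex"].to_numpy()
    grp = design.samples["group"].to_numpy()
    ok = ~np.isnan(yv)
    observed_sexes = set(sex[ok])
    if len(observed_sexes) < 2:
        raise SexTermError(
            f"feature {feature_id!r} quantifiable only in "
            f"{''.join(sorted(observed_sexes)) or 'no'} samples: "
            "two-way ANOVA cannot estimate the sex term"
        )
    try:
        return balanced_two_way_anova(yv[ok], sex[ok], grp[ok],
                                      feature_id=feature_id)
    except ValueError as exc:
        raise ValueError(f"feature {feature_id!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def overrepresentation_test(
    selection, background, annotation: dict
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms.

    For each term with at least one member in the background, tests
    whether the selection contains more term members than expected when
    drawing ``n = |selection|`` genes from ``N = |background|`` without
    replacement (upper-tail hypergeometric, k = 0 giving p = 1), with
    Bonferroni correction over the tested terms. This is a generic
    gene-set test over user-supplied annotations; it does not emulate
    web-service scores such as DAVID's EASE-adjusted statistic.
    """
    selection = set(selection)
    background = set(background)
    if not selection <= background:
        extra = sorted(selection - background)
        raise ValueError(f"selection not contained in background: {extra[:5]}")
    n_sel = len(selection)
    n_bg = len(background)
    rows = []
    for term, members in annotation.items():
        term_bg = set(members) & background
        if not term_bg:
            continue
        k = len(selection & term_bg)
        kk = len(term_bg)
        raw = float(stats.hypergeom.sf(k - 1, n_bg, kk, n_sel))
        rows.append({"term": term, "k": k, "n": n_sel, "K": kk, "N": n_bg,
                     "p": raw})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    n_terms = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * n_terms)
    return out.sort_values(["p_bonferroni", "p", "term"]).reset_index(drop=True)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: ``term <tab> description <tab> genes...``."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    return terms
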