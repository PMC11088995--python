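"""Sex-differential screen, PCA and replicate-correlation diagnostics.

Liver expression is strongly sexually dimorphic, which is why every
ascorbate screen in this package is sex-stratified. The functions here
quantify that dimorphism (Welch t-test per feature with
Benjamini-Hochberg control and a two-fold gate), and provide the two
standard cohort-level diagnostics: PCA of samples and within-cell
replicate Pearson grids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .design import GROUPS, SEXES, CohortDesign
from .matrices import ExpressionMatrix


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, capped at 1.

    Equivalent to ``min over j >= i of m * p_(j) / j`` on the sorted
    vector; monotone in each input and never below the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_by_sex(
    m: ExpressionMatrix,
    design: CohortDesign,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Female-vs-male differential test per feature.

    The t-test runs on log2-transformed values (log2(TPM + pseudocount)
    for transcripts, log2 LFQ intensity for proteins, missing values
    omitted); Welch's unequal-variance flavour by default. The fold
    change is the ratio of sex means on the abundance scale. A feature
    is ``significant`` when the BH-adjusted p is below ``alpha`` AND the
    change exceeds ``fold_threshold`` in either direction.
    """
    m.check_design(design)
    ids_f = design.stratum_ids("F")
    ids_m = design.stratum_ids("M")
    if len(ids_f) < 2 or len(ids_m) < 2:
        raise ValueError("each sex needs >= 2 samples for a t-test")

    vals = m.values
    if m.layer == "TPM":
        logged = np.log2(vals + pseudocount)
    else:
        logged = np.log2(vals)

    with np.errstate(invalid="ignore"):
        res = stats.ttest_ind(
            logged[ids_f], logged[ids_m], axis=1,
            equal_var=equal_var, nan_policy="omit",
        )
    raw_p = np.asarray(res.pvalue, dtype=float)
    raw_p = np.where(np.isnan(raw_p), 1.0, raw_p)

    mean_f = vals[ids_f].mean(axis=1)
    mean_m = vals[ids_m].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_f / mean_m
        either_way = np.maximum(fold, 1.0 / fold)

    adj_p = benjamini_hochberg(raw_p)
    out = pd.DataFrame(
        {
            "mean_F": mean_f,
            "mean_M": mean_m,
            "fold_change": fold,
            "p": raw_p,
            "p_adj": adj_p,
        },
        index=vals.index,
    )
    out["significant"] = (out["p_adj"] < alpha) & (either_way > fold_threshold).fillna(False)
    return out


def pca_decompose(
    m: ExpressionMatrix,
    transform: str = "log2",
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Principal components of the samples.

    Parameters
    ----------
    transform
        ``"log2"`` applies log2(value + pseudocount) first; ``"none"``
        decomposes raw abundances.

    Returns
    -------
    (scores, loadings, explained)
        Scores are samples x components; loadings components x
        features (orthonormal rows); explained variance fractions sum
        to 1 across the full decomposition.
    """
    if m.values.isna().any().any():
        raise ValueError("matrix contains missing values; run lfq_impute first")
    if m.values.shape[0] < 2 or m.values.shape[1] < 2:
        raise ValueError("need >= 2 features and >= 2 samples")
    if transform == "log2":
        data = np.log2(m.values + pseudocount)
    elif transform == "none":
        data = m.values
    else:
        raise ValueError("transform must be 'log2' or 'none'")

    x = data.to_numpy(dtype=float).T  # samples x features
    pca = PCA(n_components=min(x.shape[0], x.shape[1]), svd_solver="full")
    scores = pca.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=m.sample_ids, columns=comp_names)
    loadings_df = pd.DataFrame(pca.components_, index=comp_names, columns=m.feature_ids)
    return scores_df, loadings_df, pca.explained_variance_ratio_


def replicate_pearson_grid(
    m: ExpressionMatrix,
    design: CohortDesign,
    pseudocount: float = 1.0,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Pairwise Pearson r between replicates within each sex x group cell.

    Computed on log2 values (log2(TPM + pseudocount) for transcripts;
    log2 LFQ with missing values dropped pairwise). Each grid is
    symmetric with unit diagonal; a zero-variance replicate yields NaN
    against every partner, reported as such.
    """
    m.check_design(design)
    if m.layer == "TPM":
        logged = np.log2(m.values + pseudocount)
    else:
        logged = np.log2(m.values)
    grids: dict[tuple[str, str], pd.DataFrame] = {}
    for sex in SEXES:
        for group in GROUPS:
            ids = design.cell_ids(sex, group)
            if len(ids) < 2:
                raise ValueError(f"cell ({sex}, {group}) has < 2 replicates")
            grids[(sex, group)] = logged[ids].corr(method="pearson")
    return grids
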