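"""Cohort diagnostics: sex-differential screen, PCA, replicate grids.

Sexual dimorphism dominates liver expression, so the per-feature
female-vs-male Welch test (BH-corrected, two-fold gate) and the sample
PCA both separate the sexes before any ascorbate effect is visible;
within-cell replicate Pearson grids check technical reproducibility.
"""

import numpy as np
from sklearn.metrics import silhouette_score

from quadromics import (
    differential_by_sex,
    lfq_impute,
    pca_decompose,
    replicate_pearson_grid,
    simulate_cohort,
)

cohort = simulate_cohort(seed=1)

diff = differential_by_sex(cohort.tpm, cohort.design)
hits = diff[diff["significant"]]
print(f"sex-differential transcripts (adj p < 0.05, >2-fold): {len(hits)}")
print(hits[["fold_change", "p_adj"]].head().round(4).to_string())

scores, _, evr = pca_decompose(cohort.tpm)
print(f"\nPCA: PC1 {evr[0]:.1%} / PC2 {evr[1]:.1%} of variance")
sex = cohort.design.sex_of().reindex(scores.index)
sil = silhouette_score(scores[["PC1", "PC2"]], sex)
print(f"silhouette of F vs M on PC1-PC2: {sil:.3f} "
      "(> 0 means the sexes separate)")

imputed = lfq_impute(cohort.lfq, cohort.design, on_empty="feature_floor")
grids = replicate_pearson_grid(imputed, cohort.design)
lo = min(np.nanmin(g.to_numpy()[np.triu_indices(3, 1)]) for g in grids.values())
hi = max(np.nanmax(g.to_numpy()[np.triu_indices(3, 1)]) for g in grids.values())
print(f"\nwithin-cell replicate Pearson r range: {lo:.4f} to {hi:.4f}")
print("(biological replicates of the same sex x dose cell should sit near 1)")
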