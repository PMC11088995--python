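# Methods

## The regulation-classification model

The pipeline asks, per gene, whether protein abundance tracks a
continuous per-animal covariate (hepatic ascorbate, ng/mg tissue) and,
if so, whether the transcript tracks it too. The inference is purely
rank-based: Spearman's ρ between abundance and covariate, computed
separately within each sex because liver expression is strongly
sexually dimorphic and pooling sexes would both inflate variance and
confound dose with sex. Concordant significant correlation at both
layers (with a two-fold protein change between the deficient and fully
treated groups) is read as transcriptional regulation; significant
protein correlation with a non-significant transcript is read as
post-transcriptional. The classification is deliberately assumption-light:
no linear model links the layers, only the joint placement of the two
rank correlations on a 3×3 grid.

Assumptions worth stating: (i) the covariate is measured per animal and
ordered without error at the resolution of ranks; (ii) samples are
exchangeable within sex under the null; (iii) the two-fold gate refers
to group means on the abundance scale; (iv) left-censored protein
missingness is the dominant missingness mechanism.

## Spearman p-values and the critical ρ

With n = 18 untied observations per sex, the choice of null
approximation moves the 5 % critical value in the third decimal, so the
package implements three and records which one it used:

* **exact** — full enumeration of the n! permutation null of
  S = Σ(rank xᵢ − rank yᵢ)², used for untied n ≤ 9 (cached);
* **edgeworth** — an Edgeworth-corrected tail of S in the style of
  applied-statistics algorithm AS 89, the standard refinement for
  moderate untied n; default for untied n ≥ 10;
* **t** — t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom, used whenever
  ties make the rank-statistic nulls inapplicable.

Two-sided p doubles the smaller tail and caps at 1; the discrete lower
tail is taken as the exact complement of the upper tail two units of S
away (the support of S steps by 2).

`critical_rho(n, alpha)` returns the threshold used to draw the
quadrant lines. Under the exact null it scans the achievable
correlations ρ = 1 − 6S/(n³−n) and returns the smallest magnitude with
p < α (returning "not achievable" when even ρ = 1 is non-significant,
as at n = 3, α = 0.05, where the smallest two-sided p is 1/3). Under
the Edgeworth and t nulls the continuous crossing p(ρ) = α is solved
directly, because near n = 18 an achievable S value (S = 514,
ρ = 0.46956) sits within 2·10⁻⁵ of p = 0.05 and a discrete scan would
be knife-edged across numerically equivalent implementations. The
resulting conventions at n = 18, two-sided α = 0.05:

| null | critical ρ |
|---|---|
| Edgeworth crossing (default) | 0.46956 |
| Student-t inversion | 0.46828 |
| exact permutation (achievable) | 0.47162 |

Published thresholds for this design sit in the same 0.468–0.472 band;
which convention produced any particular printed value is usually not
recoverable, and with measured (tied) covariates the observed smallest
significant |ρ| can fall between the achievable untied values. Boundary
ties on the quadrant plot (|ρ| exactly at the threshold) are assigned
to the significant side, consistent with gating on p < α strictly;
`boundary="central"` flips the convention.

## Gates

* **Variance** (transcripts): across-sample SD > 0, i.e. the feature
  carries any rank information at all.
* **Validity**: valid values (TPM > 0; LFQ non-missing) in strictly
  more than a fraction f = 0.70 of the stratum; the threshold is
  ⌊f·n⌋+1, hence 13 of 18.
* **Quantifiability** (proteins): ≥ 2 peptides and ≥ 3 observed
  intensities in at least one of the two contrasted cells.
* **Fold change**: mean(GL40 cell)/mean(GL00 cell) on the abundance
  scale, passed when max(r, 1/r) > 2 — two-fold in either direction,
  since both induced and repressed features are of interest. A zero or
  unobserved denominator leaves the ratio undefined and the gate
  failed, with a logged warning.

## Left-censored imputation and where it is used

Missing LFQ intensities are treated as left-censored (below detection),
so the imputed stand-in is a noise floor, not an estimate: the
1st percentile (linear interpolation between order statistics) of the
feature's observed values within the same condition. "Condition"
defaults to the sex × group cell and can be relaxed to group only. A
feature with no observed value in a condition has no defined floor;
this raises an error by default, or falls back to the feature's global
1st percentile with `on_empty="feature_floor"`.

Two deliberate asymmetries in the screen:

* ρ is computed on **observed values only** (n_used recorded).
  Imputation would place several samples exactly at the floor,
  manufacturing ties at the bottom of the ranking and degrading the
  rank statistic.
* the **fold gate uses noise-floor-imputed abundances**. Censoring
  removes precisely the low values of the deficient cell, so an
  observed-only mean is biased upward and genuinely changed proteins
  would fail the gate; filling censored entries at the floor restores
  the contrast. This interaction was observed directly in round-trip
  simulations (~10–15 % of planted low-abundance positives lost with
  observed-only gating) and is the package's default
  (`fold_on="imputed"`); `fold_on="observed"` reproduces the naive
  behaviour.

## Corroborating statistics

* **Sex-differential screen**: Welch t-test (pooled-variance available)
  on log2 values — log2(TPM+1) with configurable pseudocount, log2 LFQ —
  Benjamini–Hochberg step-up control, and the same two-fold-either-way
  gate on sex means.
* **PCA**: full SVD on feature-centred log2 data; explained-variance
  fractions sum to 1 and loadings are orthonormal, so scores reproduce
  the centred data exactly. Missing values must be imputed first (the
  error message says so).
* **Two-way ANOVA**: fixed-effects sex × treatment with interaction,
  computed from cell means. The design is balanced by construction, so
  type-I/II/III sums of squares coincide and no convention needs
  choosing; an unbalanced observed pattern is rejected rather than
  silently re-partitioned. A feature observed in one sex only raises a
  dedicated error (the sex term is inestimable). An (almost) constant
  response reports undefined F ratios rather than 0/0 noise.
* **Over-representation**: upper-tail hypergeometric per annotation
  term (k = 0 ⇒ p = 1), Bonferroni over the terms tested against the
  background. This is a generic gene-set test over user-supplied GMT
  files; it does not emulate web-service statistics such as
  EASE-adjusted scores.
* **Polysome quantification**: baseline = global trace minimum (the
  lowest point on the chart; per-segment baselines configurable),
  above-baseline signal integrated by the trapezoidal rule on a
  cumulative grid so adjacent intervals add exactly; ratio =
  polysomal / (sub-polysomal + polysomal). Group comparison by the
  exact Mann–Whitney U test for ≤ 10 total untied observations, normal
  approximation with tie correction otherwise; "non-parametric t-test"
  is ambiguous in common usage and the rank test is the standard
  reading — a permutation t-test can be substituted by the caller.
* **ΔCt quantification**: ΔCt = Ct(target) − mean Ct(references)
  (arithmetic mean of Ct ≡ geometric mean of quantities),
  RQ = 2^−ΔCt rescaled so the control-group mean is 1 per fraction.
  Housekeeping references (Atp5o, Ubc) for total RNA; 18S rRNA for
  polysome fractions. Invariant to per-sample plate offsets.

## The synthetic cohort generator

The generator emulates the matrix-level structure the statistics
consume, with known ground truth; it does not simulate reads or spectra.

* **Design**: 6 groups × 2 sexes × n ≥ 3 replicates (default 3 → 36
  samples); below-minimum replication is an error.
* **Ascorbate**: truncated-Gaussian around dose-monotone group means.
  Defaults (ng/mg): GL00 25, GL01 90, GL05 250, GL40 600, GLR40 560,
  WT00 500, animal-to-animal SD 20. The dose ordering and the
  rescue/wild-type placement near full treatment are the designed
  structure; the magnitudes are order-of-magnitude placeholders for a
  liver ascorbate assay and are configuration, not science — real
  per-animal values belong in the ascorbate TSV.
* **Abundance model**: log2 abundance = per-gene baseline + β·x + s·sex
  + ε, with x the centred log2-ascorbate, ε Gaussian (SD 0.35), TPM
  baselines ~N(5, 1.6), LFQ baselines ~N(25, 1.6) (log2 scale). β = 0.5
  spans ≈ 5-fold over the ladder, comfortably past the two-fold gate;
  sex-dimorphic genes get a 4-fold sex offset and β = 0. Linearity in
  log-covariate on the log-abundance scale is the simplest generative
  model consistent with a monotone rank screen — a modelling choice,
  not a claim about liver biology. β appears at the transcript layer
  (mirrored by protein) for transcriptional classes and at the protein
  layer only for post-transcriptional classes. Translation-shifted
  genes also carry β at the protein layer only: a translational shift
  changes protein output while total mRNA is flat, so at the matrix
  level they are indistinguishable from post-transcriptional genes and
  only the polysome/qPCR simulators reveal their mechanism.
* **Missingness**: deterministic left-censoring of log2 LFQ below a
  threshold (default 21.0, i.e. ≈ 2.4 SD below the median baseline —
  a light, low-abundance-concentrated missingness of well under a
  percent of entries at default settings), plus optional
  intensity-independent dropout. P(missing) is non-increasing in true
  intensity by construction.
* **Peptide counts**: 2 + Poisson(7), with a 4 % tail of one-peptide
  identifications among null genes to exercise the two-peptide gate.
* **Polysome traces**: 3 sub-polysomal + 12 polysomal Gaussian peaks on
  a flat baseline; polysomal heights are rescaled analytically so the
  above-baseline polysomal area fraction equals the requested mass
  fraction exactly, which is what makes the 1 %-accuracy round trip a
  meaningful test of the integrator rather than of the generator.
* **qPCR plates**: Ct = reference Ct − log2(quantity) + noise — the
  ΔCt model inverted — with reference genes planted at quantity 1.

What the generator does **not** emulate: count-based TPM noise
(mean–variance coupling), shared transcript–protein noise, batch
effects, normalisation artefacts, peptide-level missingness, or tied
covariate values. Passing round-trip tests therefore demonstrates that
the pipeline recovers the planted structure under its own stated
assumptions, not that it is robust to every failure mode of real data.

## Problem sizes and numerics

Default simulated panels are 272 genes (200 null + 12 per planted
class); recovery statistics in the tests pool 50 seeded cohorts at
n = 18 per sex, sizes chosen so the whole suite runs in minutes on one
core while leaving binomial noise on a 90 % rate near ±1 %. All
generators are driven by `numpy.random.default_rng(seed)` and are
bit-reproducible for a given seed. Tolerances: PCA reconstruction and
orthonormality at 1e−8; ANOVA oracle agreement at 1e−10; area
additivity at 1e−9; enumeration equivalences at 1e−12.

## Known limitations

* The Edgeworth tail degrades in the extreme tails (|ρ| → 1); p-values
  there are clipped to [0, 1] and reported as ≈ 0, which is harmless
  for screening at α = 0.05.
* `critical_rho` under ties is not defined (ties make the achievable-ρ
  grid data-dependent); the t inversion is the pragmatic stand-in.
* The per-feature-per-condition imputation cannot fill a condition
  with zero observed values without the explicit global-floor fallback;
  column-distribution imputation (as some proteomics GUIs do) is out
  of scope.
* Enrichment results depend entirely on the annotation supplied; no
  term database ships with the package.
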