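"""Generate one synthetic 36-mouse cohort and write its tables to TSV.

The cohort has six ascorbate-dose groups x two sexes x three replicates,
a per-animal hepatic ascorbate concentration, and paired TPM/LFQ
matrices over a gene panel with known planted regulation classes.
"""

from pathlib import Path

from quadromics import io, simulate_cohort

out = Path("cohort_out")
out.mkdir(exist_ok=True)

cohort = simulate_cohort(seed=1)
io.write_design(cohort.design, out / "design.tsv")
io.write_ascorbate(cohort.ascorbate, out / "ascorbate.tsv")
io.write_matrix(cohort.tpm, out / "tpm.tsv")
io.write_matrix(cohort.lfq, out / "lfq.tsv")
io.write_truth(cohort.truth, out / "truth.tsv")

print(f"samples:           {cohort.design.n_samples}")
print(f"gene panel:        {len(cohort.truth.genes)} "
      f"({dict(cohort.truth.genes['gene_class'].value_counts())})")
asc = cohort.ascorbate.values
by_group = asc.groupby(cohort.design.group_of()).mean().round(1)
print("mean hepatic ascorbate (ng/mg) by group:")
print(by_group.to_string())
miss = cohort.lfq.values.isna().mean().mean()
print(f"LFQ missingness:   {miss:.1%} (left-censored below the noise floor)")
print(f"tables written to  {out}/")
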