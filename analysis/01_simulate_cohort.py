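"""Generate the synthetic four-study cohort and write its on-disk forms.

Produces per-study dosage VCFs, expression TSVs, covariates, gene
annotation (BED-like) and the planted ground truth — the inputs every later
step consumes. Prints the cohort dimensions and the planted effects.
"""

from liverqtl import io

from common import load_cohort, outdir

out = outdir("cohort")
cohort = load_cohort()

for name, gm in cohort.genotypes.items():
    io.write_vcf(gm, out / f"{name}.vcf")
    io.write_expression_tsv(cohort.expression[name], out / f"{name}_expression.tsv")
io.write_covariates_tsv(cohort.covariates, out / "covariates.tsv")
io.write_gene_bed(cohort.genes, out / "genes.bed")
io.write_truth_tsv(cohort.effects, out / "truth.tsv")

print(f"studies: {cohort.study_names}")
print(f"samples: {[g.n_samples for g in cohort.genotypes.values()]} "
      f"(total {sum(g.n_samples for g in cohort.genotypes.values())})")
print(f"variants per panel: {next(iter(cohort.genotypes.values())).n_variants}")
print(f"genes: {len(cohort.genes)}")
print("planted effects:")
print(cohort.effects.entries.to_string(index=False))
print(f"wrote cohort files to {out}")
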