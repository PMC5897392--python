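"""cis-eQTL mapping: per-study scans and the pooled mega-analysis.

Each scan regresses normalized expression on allele dosage with age, sex
and genotype PCs, over all gene-variant pairs within 1 Mb, controlling the
FDR jointly at Q < 0.001. Reports how many planted effects each scan finds.
"""

from liverqtl.containers import ExpressionMatrix, GenotypeMatrix
from liverqtl.eqtl import map_all

from common import outdir, prepared

out = outdir("eqtl")
cohort, merged, cleaned, expression, covariates = prepared()
planted = set(cohort.effects.entries["gene"])

for name, gm in cleaned.items():
    samples = expression.samples.intersection(gm.samples)
    res = map_all(
        ExpressionMatrix(expression.values.loc[samples], expression.study),
        GenotypeMatrix(gm.dosages.loc[samples], gm.variants, study=name),
        covariates.loc[samples, ["age", "sex"]],
        cohort.genes,
    )
    res.to_csv(out / f"eqtl_{name}.tsv", sep="\t", index=False)
    sig = res[res["significant"]]
    print(f"{name} (n={len(samples)}): {len(sig)} significant pairs, "
          f"{sig['gene'].nunique()} genes "
          f"({len(set(sig['gene']) & planted)}/{len(planted)} planted)")

mega = map_all(expression, merged, covariates, cohort.genes)
mega.to_csv(out / "eqtl_mega.tsv", sep="\t", index=False)
sig = mega[mega["significant"]]
print(f"mega (n={len(expression.samples)}): {len(sig)} significant pairs, "
      f"{sig['gene'].nunique()} genes "
      f"({len(set(sig['gene']) & planted)}/{len(planted)} planted)")
print(f"wrote per-study and mega tables to {out}")
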