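"""Per-study genotype QC and panel merging.

Harmonizes each study's alleles against the reference panel, applies the
reference-AF (10%), MAF (0.05), HWE (1e-6) and autosome filters, merges the
panels (variants genotyped in >=100 samples, cross-study AF within 15%) and
writes the merged VCF plus a per-filter removal report.
"""

import pandas as pd

from liverqtl import io, simulate
from liverqtl.genotype_qc import merge_panels, run_study_qc

from common import COHORT, load_cohort, outdir

out = outdir("qc")
cohort = load_cohort()

panel = simulate.variant_panel(COHORT)
reference = panel[["chrom", "pos", "ref", "alt"]].copy()
reference["af"] = panel["maf"]

cleaned, rows = [], []
for name, gm in cohort.genotypes.items():
    qcd, report = run_study_qc(gm, reference)
    cleaned.append(qcd)
    rows.append({"study": name, "variants_in": report.n_variants_in,
                 "variants_out": report.n_variants_out, **report.removed})
    print(f"{name}: {report.n_variants_in} -> {report.n_variants_out} variants "
          f"({report.removed or 'nothing removed'})")

merged, merge_report = merge_panels(cleaned)
rows.append({"study": "merged", "variants_in": merge_report.n_variants_in,
             "variants_out": merge_report.n_variants_out, **merge_report.removed})
print(f"merged panel: {merged.n_variants} variants x {merged.n_samples} samples; "
      f"merge filters removed {sum(merge_report.removed.values())}")

io.write_vcf(merged, out / "merged.vcf")
pd.DataFrame(rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)
print(f"wrote {out / 'merged.vcf'} and qc_report.tsv")
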