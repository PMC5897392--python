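"""Random-effects meta-analysis versus the pooled mega-analysis.

Combines the per-study effect estimates with the DerSimonian-Laird model,
then cross-tabulates per-study, meta and mega significant gene sets — the
synthetic counterpart of the published replication table, which is also
recomputed here from the printed cohort counts.
"""

import pandas as pd

from liverqtl import published
from liverqtl.meta import meta_map
from liverqtl.pipeline import crosstab_from_counts, summary_counts

from common import outdir

out = outdir("meta")
eqtl_dir = outdir("eqtl")

per_study = {
    p.stem.removeprefix("eqtl_"): pd.read_csv(p, sep="\t")
    for p in sorted(eqtl_dir.glob("eqtl_study*.tsv"))
}
if not per_study:
    raise SystemExit("run 04_map_eqtl.py first")
mega = pd.read_csv(eqtl_dir / "eqtl_mega.tsv", sep="\t")

meta = meta_map(per_study, min_studies=2)
meta.to_csv(out / "eqtl_meta.tsv", sep="\t", index=False)
print(f"meta-analysis: {len(meta)} combined pairs, "
      f"{int(meta['significant'].sum())} significant, "
      f"{meta.loc[meta['significant'], 'gene'].nunique()} genes")

results = dict(per_study)
results["meta"] = meta
results["mega"] = mega
counts = summary_counts(results)
counts.to_csv(out / "summary_counts.tsv", sep="\t", index=False)
print(counts.to_string(index=False))

print("\npublished four-cohort cross-tab (percentages recomputed from counts):")
for label, overlap in (("meta", published.STUDY_OVERLAP_META),
                       ("mega", published.STUDY_OVERLAP_MEGA)):
    tab = crosstab_from_counts(published.STUDY_EQTL_GENES, overlap)
    tab.to_csv(out / f"published_crosstab_{label}.tsv", sep="\t", index=False)
    print(f"  vs {label}: " + ", ".join(
        f"{r.study} {r.pct_overlap}%" for r in tab.itertuples(index=False)))
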