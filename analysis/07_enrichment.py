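"""Characterization of eQTL variants: regulatory-class enrichment against a
matched random control set and the TSS-distance profile of top signals.
"""

import pandas as pd

from liverqtl.enrichment import (
    class_enrichment_test,
    draw_control_variants,
    tss_distance_summary,
)
from liverqtl.simulate import simulate_annotations

from common import COHORT, SEED, outdir, prepared

out = outdir("enrichment")
cohort, merged, _, _, _ = prepared()
mega = pd.read_csv(outdir("eqtl") / "eqtl_mega.tsv", sep="\t")
sig = mega[mega["significant"]]

controls = draw_control_variants(
    merged.variants, cohort.genes, n=min(1000, merged.n_variants // 2), seed=SEED
)
annotations = simulate_annotations(
    merged.variants.index, set(cohort.effects.entries["variant"]), COHORT
)
annotations.to_csv(out / "annotations.tsv", sep="\t")

enr = class_enrichment_test(
    annotations.loc[annotations.index.intersection(set(sig["variant"])), "regulome_class"],
    annotations.loc[controls, "regulome_class"],
)
enr.to_csv(out / "class_enrichment.tsv", sep="\t", index=False)
print("regulatory-class enrichment (eQTL vs control):")
print(enr.round(4).to_string(index=False))

top = sig[sig["gene"].isin(sig["gene"])].loc[sig.groupby("gene")["p_value"].idxmin()]
n_within, n_total, frac = tss_distance_summary(top["tss_distance"])
print(f"\ntop signals within 100 kb of the TSS: {n_within}/{n_total} "
      f"({100 * frac:.1f}%)" if n_total else "\nno significant signals")
pd.DataFrame([{"n_within_100kb": n_within, "n_total": n_total,
               "fraction": frac}]).to_csv(out / "tss_summary.tsv", sep="\t", index=False)
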