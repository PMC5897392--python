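"""End-to-end orchestration: QC -> normalization -> mapping (single-study /
meta / mega) -> conditional scan -> enrichment -> summary surfaces.

Every stage writes a plain TSV into the run directory and the run ends with
a machine-readable ``summary.json`` echoing all thresholds, so the summary
can be regenerated from the stage outputs without recomputation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import eqtl, genotype_qc, io, meta, simulate
from .conditional import run_conditional_scan
from .config import PipelineConfig
from .containers import ExpressionMatrix, GenotypeMatrix
from .enrichment import class_enrichment_test, draw_control_variants, tss_distance_summary
from .expression import normalize_studies

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _round_pct(numerator: int, denominator: int) -> float:
    """Percentage to two decimals, round-half-even; NaN on empty denominator."""
    if not denominator:
        return float("nan")
    return round(100.0 * numerator / denominator, 2)


def summary_counts(results_per_mode: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Significant pair / unique-variant / unique-gene counts per analysis mode,
    with per-mode gene overlaps against the meta and mega sets (percentages to
    two decimals)."""
    gene_sets = {
        mode: set(tab.loc[tab["significant"], "gene"])
        for mode, tab in results_per_mode.items()
    }
    rows = []
    for mode, tab in results_per_mode.items():
        sig = tab[tab["significant"]]
        row = {
            "mode": mode,
            "n_significant_pairs": int(len(sig)),
            "n_eqtl_variants_unique": int(sig["variant"].nunique()),
            "n_eqtl_genes_unique": int(sig["gene"].nunique()),
        }
        for combined in ("meta", "mega"):
            if combined in gene_sets:
                overlap = len(gene_sets[mode] & gene_sets[combined])
                row[f"n_overlap_{combined}"] = overlap
                row[f"pct_overlap_{combined}"] = _round_pct(overlap, len(gene_sets[mode]))
        rows.append(row)
    return pd.DataFrame(rows)


def crosstab_from_counts(
    study_genes: dict[str, int],
    study_overlap: dict[str, int],
) -> pd.DataFrame:
    """Replication percentages recomputed from printed per-study counts."""
    rows = [
        {
            "study": s,
            "n_genes": study_genes[s],
            "n_overlap": study_overlap[s],
            "pct_overlap": _round_pct(study_overlap[s], study_genes[s]),
        }
        for s in study_genes
    ]
    return pd.DataFrame(rows)


def gwas_overlap(
    eqtl_table: pd.DataFrame,
    gwas_variants: list[str],
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Which GWAS tag variants are significant eQTL, and for which genes.

    Returns one row per (GWAS variant, gene) with q below the threshold,
    mirroring the effect-size table surface (beta, se, p, q, TSS distance),
    plus ``not_imputable`` rows for tag variants absent from the panel.
    """
    cols = [c for c in ("gene", "variant", "beta", "se", "p_value", "q_value",
                        "tss_distance") if c in eqtl_table.columns]
    panel = set(eqtl_table["variant"])
    rows = []
    for vid in gwas_variants:
        if vid not in panel:
            rows.append({"variant": vid, "status": "not_imputable"})
            continue
        hits = eqtl_table[(eqtl_table["variant"] == vid)
                          & (eqtl_table["q_value"] < q_threshold)]
        for _, hit in hits.iterrows():
            rec = {k: hit[k] for k in cols}
            rec["status"] = "eqtl"
            rows.append(rec)
    table = pd.DataFrame(rows, columns=cols + ["status"])
    eqtl_rows = table[table["status"] == "eqtl"] if len(table) else table
    summary = {
        "n_gwas_variants": len(gwas_variants),
        "n_overlapping_variants": int(eqtl_rows["variant"].nunique()) if len(eqtl_rows) else 0,
        "n_unique_genes": int(eqtl_rows["gene"].nunique()) if len(eqtl_rows) else 0,
        "n_not_imputable": int((table["status"] == "not_imputable").sum()) if len(table) else 0,
    }
    return table, summary


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _qc_stage(
    study_set: simulate.StudySet, cfg: PipelineConfig
) -> tuple[GenotypeMatrix, dict[str, GenotypeMatrix], dict]:
    sim = study_set.config
    panel = simulate.variant_panel(sim)
    reference = panel[["chrom", "pos", "ref", "alt"]].copy()
    reference["af"] = panel["maf"]  # alternate-allele frequency of the panel

    qc_counts = {}
    cleaned: dict[str, GenotypeMatrix] = {}
    for name, gm in study_set.genotypes.items():
        out, report = genotype_qc.run_study_qc(
            gm,
            reference,
            maf_min=cfg.maf_min,
            hwe_p_min=cfg.hwe_p_min,
            reference_af_max_diff=cfg.reference_af_max_diff,
        )
        if sim.outlier_pop_fraction > 0:
            ref_gm, pops = simulate.simulate_reference_cohort(sim)
            keep = genotype_qc.pca_ancestry_filter(
                out, ref_gm, pops, n_variants=min(2000, out.n_variants), seed=cfg.seed
            )
            report.samples_removed_ancestry = out.n_samples - len(keep)
            out = GenotypeMatrix(out.dosages.loc[keep], out.variants, study=out.study)
        cleaned[name] = out
        qc_counts[name] = {"report": report.removed,
                           "n_in": report.n_variants_in, "n_out": report.n_variants_out,
                           "samples_removed": report.samples_removed_ancestry}
    merged, merge_report = genotype_qc.merge_panels(
        list(cleaned.values()),
        min_genotyped=cfg.min_genotyped,
        cross_study_af_max_diff=cfg.cross_study_af_max_diff,
    )
    qc_counts["merge"] = {"report": merge_report.removed,
                          "n_in": merge_report.n_variants_in,
                          "n_out": merge_report.n_variants_out}
    return merged, cleaned, qc_counts


def run_pipeline(
    config: PipelineConfig,
    study_set: simulate.StudySet | None = None,
    gwas_variants: list[str] | None = None,
) -> dict:
    """Run the configured stages end to end; returns the summary dict.

    Without an explicit ``study_set`` the synthetic cohort described by
    ``config.simulation`` is generated first. Stage outputs land in
    ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"thresholds": config.thresholds(), "mode": config.mode}

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        stage("simulate")
        if study_set is None:
            study_set = simulate.simulate_study_set(config.simulation)
        io.write_truth_tsv(study_set.effects, out_dir / "truth.tsv")
        io.write_gene_bed(study_set.genes, out_dir / "genes.bed")
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"simulate: {exc}") from exc

    try:
        stage("genotype_qc")
        merged, cleaned, qc_counts = _qc_stage(study_set, config)
        summary["qc"] = qc_counts
        io.write_vcf(merged, out_dir / "merged.vcf")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"genotype_qc: {exc}") from exc

    try:
        stage("normalize")
        retained = merged.samples
        per_study = {
            name: ExpressionMatrix(
                em.values.loc[em.samples.intersection(retained)],
                em.study.loc[em.study.index.intersection(retained)],
            )
            for name, em in study_set.expression.items()
        }
        expression = normalize_studies(per_study, knn_k=config.knn_k)
        io.write_expression_tsv(expression, out_dir / "expression_normalized.tsv")
    except Exception as exc:
        raise StageError(f"normalize: {exc}") from exc

    try:
        stage("map")
        expression = ExpressionMatrix(
            expression.values.loc[merged.samples.intersection(expression.samples)],
            expression.study,
        )
        merged_aligned = GenotypeMatrix(
            merged.dosages.loc[expression.samples], merged.variants, study=None
        )
        covariates = eqtl.build_covariates(
            study_set.covariates.reindex(expression.samples), merged_aligned, n_pcs=5
        )
        results: dict[str, pd.DataFrame] = {}
        per_study_tables: dict[str, pd.DataFrame] = {}
        for name, gm in cleaned.items():
            samples = expression.samples.intersection(gm.samples)
            sub_expr = ExpressionMatrix(expression.values.loc[samples], expression.study)
            sub_gm = GenotypeMatrix(gm.dosages.loc[samples], gm.variants, study=name)
            tab = eqtl.map_all(
                sub_expr, sub_gm, covariates.loc[samples].drop(columns=[c for c in covariates if c.startswith("PC")]),
                study_set.genes, window=config.cis_window, q_threshold=config.q_threshold,
            )
            per_study_tables[name] = tab
            results[name] = tab
            tab.to_csv(out_dir / f"eqtl_{name}.tsv", sep="\t", index=False)
        if config.mode in ("mega", "full"):
            mega = eqtl.map_all(
                expression, merged_aligned, covariates, study_set.genes,
                window=config.cis_window, q_threshold=config.q_threshold,
            )
            results["mega"] = mega
            mega.to_csv(out_dir / "eqtl_mega.tsv", sep="\t", index=False)
        if config.mode in ("meta", "full"):
            meta_tab = meta.meta_map(
                per_study_tables, min_studies=config.min_studies_meta,
                q_threshold=config.q_threshold,
            )
            meta_tab = meta_tab.rename(columns={"combined_beta": "beta", "combined_se": "se"})
            results["meta"] = meta_tab
            meta_tab.to_csv(out_dir / "eqtl_meta.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(f"map: {exc}") from exc

    try:
        stage("summary_counts")
        counts = summary_counts(results)
        counts.to_csv(out_dir / "summary_counts.tsv", sep="\t", index=False)
        summary["counts"] = counts.to_dict(orient="records")
    except Exception as exc:
        raise StageError(f"summary_counts: {exc}") from exc

    signals = pd.DataFrame()
    if config.mode in ("mega", "full"):
        try:
            stage("conditional")
            signals, cond_summary = run_conditional_scan(
                results["mega"], expression, merged_aligned, covariates,
                study_set.genes, window=config.cis_window,
                p_threshold=config.conditional_p_threshold,
            )
            signals.to_csv(out_dir / "independent_signals.tsv", sep="\t", index=False)
            summary["conditional"] = cond_summary
        except Exception as exc:
            raise StageError(f"conditional: {exc}") from exc

        try:
            stage("enrichment")
            mega = results["mega"]
            sig_variants = set(mega.loc[mega["significant"], "variant"])
            controls = draw_control_variants(
                merged.variants, study_set.genes,
                n=min(2000, merged.n_variants), window=config.cis_window,
                seed=config.seed,
            )
            annotations = simulate.simulate_annotations(
                merged.variants.index,
                set(study_set.effects.entries["variant"]),
                study_set.config,
            )
            if sig_variants:
                enr = class_enrichment_test(
                    annotations.loc[annotations.index.intersection(sig_variants), "regulome_class"],
                    annotations.loc[controls, "regulome_class"],
                )
                enr.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
            top = mega[mega["top"] & mega["significant"]]
            tss_all = pd.concat([
                top["tss_distance"],
                mega.merge(signals[signals["round"] >= 2], on=["gene", "variant"])["tss_distance"]
                if len(signals) else pd.Series(dtype=float),
            ])
            n_within, n_total, frac = tss_distance_summary(tss_all.to_numpy())
            summary["tss"] = {"n_within_100kb": n_within, "n_total": n_total,
                              "fraction": frac}
        except Exception as exc:
            raise StageError(f"enrichment: {exc}") from exc

        try:
            stage("gwas_overlap")
            if gwas_variants is None:
                planted = list(study_set.effects.entries["variant"].head(3))
                gwas_variants = planted + ["rs_absent_tag"]
            gtab, gsummary = gwas_overlap(
                results["mega"], gwas_variants, q_threshold=config.gwas_q_threshold
            )
            gtab.to_csv(out_dir / "gwas_overlap.tsv", sep="\t", index=False)
            summary["gwas_overlap"] = gsummary
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"gwas_overlap: {exc}") from exc

    summary["n_samples"] = int(len(expression.samples))
    summary["n_variants_merged"] = int(merged.n_variants)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
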