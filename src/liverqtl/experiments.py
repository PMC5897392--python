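"""Reference experiments: simulation studies that probe the pipeline's
statistical contracts (engine exactness, FDR control, effect recovery,
conditional-signal recovery, mega-vs-meta power, normalization guarantees).

Each function runs the full relevant code path on freshly simulated data at
a stated design and returns plain summary numbers. The designs mirror the
four-study liver setting: 588 pooled samples (178 + 149 + 178 + 83), ~2,000
cis variants per gene in LD blocks, planted effects on the scale of the
reported eQTL effect sizes (0.2-1.1 expression SD per allele).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import published
from .config import SimulationConfig
from .conditional import find_independent_signals
from .containers import ExpressionMatrix, GenotypeMatrix, TrueEffects
from .eqtl import compute_ld, map_all
from .expression import combat_correct, quantile_normalize
from .meta import dersimonian_laird, meta_map
from .pipeline import crosstab_from_counts
from .simulate import simulate_covariates, simulate_expression, simulate_genotypes

POOLED_DESIGN = (178, 149, 178, 83)  # per-study sample sizes, 588 pooled


def _single_cohort(n_samples: int, n_variants: int, n_genes: int, seed: int,
                   maf_range=(0.05, 0.5), ld_rho: float = 0.8,
                   spacing: int = 1000) -> SimulationConfig:
    return SimulationConfig(
        n_studies=1, samples_per_study=(n_samples,), n_variants=n_variants,
        n_genes=n_genes, maf_range=maf_range, ld_rho=ld_rho,
        n_primary_effects=0, n_secondary_effects=0, batch_shift_sd=0.0,
        batch_scale_range=(1.0, 1.0), missing_rate=0.0, panel_overlap=1.0,
        variant_spacing=spacing, seed=seed,
    )


def _simulate_cohort(cfg: SimulationConfig, effects: TrueEffects):
    gm = simulate_genotypes(cfg, 0)
    cov = simulate_covariates(cfg, 0)
    expr = simulate_expression(gm, effects, cov, cfg, 0)
    return gm, expr, cov[["age", "sex"]].astype(float)


# ---------------------------------------------------------------------------
# engine exactness
# ---------------------------------------------------------------------------

def ols_engine_vs_normal_equations(
    n_genes: int = 50, n_variants: int = 500, n_samples: int = 100, seed: int = 0
) -> dict:
    """Bulk scan versus an explicit per-pair normal-equations fit.

    The reference solves (X'X) b = X'y for each pair with the full design
    (intercept, two covariates, dosage) and computes se/t/p from the residual
    sum of squares — an independent route to the same OLS estimand.
    Returns the largest absolute discrepancies over all pairs.
    """
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, n_variants)
    dos = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(float)
    cov = pd.DataFrame(
        rng.standard_normal((n_samples, 2)), columns=["c1", "c2"],
        index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample"),
    )
    y = rng.standard_normal((n_samples, n_genes))

    variants = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, n_variants + 1),
         "ref": "A", "alt": "G"},
        index=pd.Index([f"v{j}" for j in range(n_variants)], name="variant"),
    )
    genes = pd.DataFrame(
        {"chrom": "1", "start": 1, "end": 2, "strand": "+"},
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
    )
    gm = GenotypeMatrix(pd.DataFrame(dos, index=cov.index, columns=variants.index), variants)
    em = ExpressionMatrix(
        pd.DataFrame(y, index=cov.index, columns=genes.index),
        pd.Series("study", index=cov.index),
    )
    res = map_all(em, gm, cov, genes, window=n_variants + 10)

    c = np.column_stack([np.ones(n_samples), cov.to_numpy()])
    gene_idx = {g: i for i, g in enumerate(genes.index)}
    var_idx = {v: j for j, v in enumerate(variants.index)}
    diffs = {"beta": 0.0, "se": 0.0, "t": 0.0, "p": 0.0}
    df = n_samples - 4
    for row in res.itertuples(index=False):
        x = np.column_stack([c, dos[:, var_idx[row.variant]]])
        yy = y[:, gene_idx[row.gene]]
        xtx = x.T @ x
        b = np.linalg.solve(xtx, x.T @ yy)
        resid = yy - x @ b
        sigma2 = resid @ resid / df
        se = np.sqrt(sigma2 * np.linalg.inv(xtx)[-1, -1])
        t = b[-1] / se
        p = 2 * stats.t.sf(abs(t), df)
        diffs["beta"] = max(diffs["beta"], abs(row.beta - b[-1]))
        diffs["se"] = max(diffs["se"], abs(row.se - se))
        diffs["t"] = max(diffs["t"], abs(row.t_stat - t))
        diffs["p"] = max(diffs["p"], abs(row.p_value - p))
    diffs["n_pairs"] = len(res)
    return diffs


# ---------------------------------------------------------------------------
# FDR control under the global null
# ---------------------------------------------------------------------------

def fdr_null_experiment(
    n_replicates: int = 20, n_genes: int = 200, n_variants: int = 2000,
    n_samples: int = 588, q_threshold: float = 1e-3, seed: int = 0,
) -> dict:
    """Global-null scans: mean number of significant genes per replicate."""
    from .simulate import gene_annotation

    counts = []
    for rep in range(n_replicates):
        cfg = _single_cohort(n_samples, n_variants, n_genes, seed=seed * 1009 + rep)
        gm, expr, cov = _simulate_cohort(cfg, TrueEffects())
        res = map_all(expr, gm, cov, gene_annotation(cfg), q_threshold=q_threshold)
        counts.append(res.loc[res["significant"], "gene"].nunique())
    counts = np.asarray(counts, dtype=float)
    return {
        "mean_significant_genes": float(counts.mean()),
        "max_significant_genes": float(counts.max()),
        "n_replicates": n_replicates,
        "n_tests_per_replicate": int(n_genes) * int(n_variants),
    }


# ---------------------------------------------------------------------------
# planted-effect detection and recovery
# ---------------------------------------------------------------------------

def detection_experiment(
    beta: float = 0.7, maf: float = 0.3, n_samples: int = 588,
    n_replicates: int = 50, n_genes: int = 10, n_variants: int = 1000,
    q_threshold: float = 1e-3, seed: int = 0,
) -> dict:
    """Power and bias for a single planted cis effect.

    One gene carries expression = beta x dosage + covariates + N(0,1) noise;
    the scan runs over all genes and cis variants jointly. Reports the
    fraction of replicates in which the planted gene is significant and the
    mean estimated slope at the planted variant.
    """
    from .simulate import gene_annotation

    detected, betas = [], []
    for rep in range(n_replicates):
        cfg = _single_cohort(n_samples, n_variants, n_genes,
                             seed=seed * 2003 + rep, maf_range=(maf, maf))
        genes = gene_annotation(cfg)
        gene = genes.index[n_genes // 2]
        mid = genes.loc[gene, "start"]
        panel_pos = (np.arange(n_variants) + 1) * cfg.variant_spacing
        variant = f"var{int(np.argmin(np.abs(panel_pos - mid))) + 1:05d}"
        effects = TrueEffects(pd.DataFrame(
            [{"gene": gene, "variant": variant, "beta": beta, "rank": "primary"}]
        ))
        gm, expr, cov = _simulate_cohort(cfg, effects)
        res = map_all(expr, gm, cov, genes, q_threshold=q_threshold)
        hit = res[(res["gene"] == gene) & (res["variant"] == variant)]
        detected.append(bool(res.loc[res["gene"] == gene, "significant"].any()))
        if len(hit):
            betas.append(float(hit["beta"].iloc[0]))
    mean_beta = float(np.mean(betas))
    return {
        "detection_rate": float(np.mean(detected)),
        "mean_beta": mean_beta,
        "relative_bias": float(abs(mean_beta - beta) / beta),
        "n_replicates": n_replicates,
        "planted_beta": beta,
    }


# ---------------------------------------------------------------------------
# conditional analysis
# ---------------------------------------------------------------------------

def _planted_gene_scan(gm: GenotypeMatrix, cov: pd.DataFrame, entries: list[dict],
                       noise_rng: np.random.Generator, p_threshold: float = 1e-6):
    """Expression from planted entries + N(0,1); conditional scan on all variants."""
    y = noise_rng.standard_normal(gm.n_samples)
    for e in entries:
        y = y + e["beta"] * gm.dosages[e["variant"]].to_numpy()
    return find_independent_signals(
        "gene", y, gm.dosages, cov, p_threshold=p_threshold,
        positions=gm.variants["pos"],
    )


def two_signal_experiment(
    beta1: float = 1.0, beta2: float = 0.6, n_samples: int = 588,
    n_variants: int = 2000, n_replicates: int = 50, seed: int = 0,
) -> dict:
    """Recovery of two planted independent signals in the right order.

    The two effect variants sit in different LD blocks (realised dosage
    r^2 < 0.05). Success = the scan reports the stronger variant (or an
    r^2 > 0.8 proxy) first and the weaker one second.
    """
    successes, spurious_third = [], []
    for rep in range(n_replicates):
        cfg = _single_cohort(n_samples, n_variants, 1, seed=seed * 3001 + rep,
                             maf_range=(0.2, 0.4))
        gm = simulate_genotypes(cfg, 0)
        rng = np.random.default_rng([cfg.seed, 91])
        blocks = gm.variants["block"].to_numpy()
        v1 = int(rng.integers(0, n_variants))
        far = np.where(np.abs(blocks - blocks[v1]) > 1)[0]
        v2 = int(rng.choice(far))
        ids = list(gm.dosages.columns)
        if compute_ld(gm.dosages[ids[v1]], gm.dosages[ids[v2]]) >= 0.05:
            successes.append(False)
            continue
        cov = simulate_covariates(cfg, 0)[["age", "sex"]].astype(float)
        sigs = _planted_gene_scan(
            gm, cov,
            [{"variant": ids[v1], "beta": beta1}, {"variant": ids[v2], "beta": beta2}],
            rng,
        )
        def matches(sig, target):
            return sig.variant == target or compute_ld(
                gm.dosages[sig.variant], gm.dosages[target]) > 0.8
        ok = (
            len(sigs) >= 2
            and matches(sigs[0], ids[v1])
            and matches(sigs[1], ids[v2])
        )
        successes.append(bool(ok))
        spurious_third.append(len(sigs) > 2)
    return {
        "ordered_recovery_rate": float(np.mean(successes)),
        "extra_signal_rate": float(np.mean(spurious_third)),
        "n_replicates": n_replicates,
    }


def false_secondary_experiment(
    n_genes: int = 500, n_samples: int = 588, n_variants: int = 2000,
    beta: float = 1.0, genes_per_panel: int = 50, seed: int = 0,
) -> dict:
    """Spurious-secondary rate on single-signal genes.

    Each gene carries exactly one planted effect; any second conditional
    signal is a false positive. Genotype panels are refreshed every
    ``genes_per_panel`` genes; expression noise is independent per gene.
    """
    n_multi = 0
    single_recovered = 0
    for g in range(n_genes):
        if g % genes_per_panel == 0:
            cfg = _single_cohort(n_samples, n_variants, 1,
                                 seed=seed * 4001 + g // genes_per_panel,
                                 maf_range=(0.2, 0.4))
            gm = simulate_genotypes(cfg, 0)
            cov = simulate_covariates(cfg, 0)[["age", "sex"]].astype(float)
            ids = list(gm.dosages.columns)
        rng = np.random.default_rng([seed, 5, g])
        v = ids[int(rng.integers(0, n_variants))]
        sigs = _planted_gene_scan(gm, cov, [{"variant": v, "beta": beta}], rng)
        if len(sigs) >= 1:
            single_recovered += 1
        if len(sigs) >= 2:
            n_multi += 1
    return {
        "spurious_secondary_rate": n_multi / n_genes,
        "primary_recovery_rate": single_recovered / n_genes,
        "n_genes": n_genes,
    }


# ---------------------------------------------------------------------------
# mega vs meta power
# ---------------------------------------------------------------------------

def mega_vs_meta_experiment(
    n_replicates: int = 20, n_effects: int = 50, beta: float = 0.3,
    n_variants: int = 1000, window: int = 50_000, q_threshold: float = 1e-3,
    seed: int = 0,
) -> dict:
    """Pooled mega-analysis versus DL meta-analysis at the detection margin.

    Four homogeneous studies (178/149/178/83 samples, no batch shifts) share
    a panel; each of ``n_effects`` genes carries one planted cis effect of
    +/-``beta`` expression SD per allele — sized so detection at Q < 0.001
    is marginal. Reports the fraction of replicates in which the pooled
    analysis detects at least as many planted genes as the meta-analysis.
    """
    from .simulate import gene_annotation

    mega_tp, meta_tp = [], []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_studies=4, samples_per_study=POOLED_DESIGN, n_variants=n_variants,
            n_genes=n_effects, maf_range=(0.2, 0.4), ld_rho=0.8,
            n_primary_effects=0, n_secondary_effects=0, batch_shift_sd=0.0,
            batch_scale_range=(1.0, 1.0), missing_rate=0.0, panel_overlap=1.0,
            variant_spacing=1000, seed=seed * 5003 + rep,
        )
        genes = gene_annotation(cfg)
        rng = np.random.default_rng([cfg.seed, 17])
        pos = (np.arange(n_variants) + 1) * cfg.variant_spacing
        rows = []
        for gene, grow in genes.iterrows():
            cis = np.where((pos >= grow["start"] - window) & (pos <= grow["end"] + window))[0]
            v = int(rng.choice(cis))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            rows.append({"gene": gene, "variant": f"var{v + 1:05d}",
                         "beta": sign * beta, "rank": "primary"})
        effects = TrueEffects(pd.DataFrame(rows))
        planted_genes = set(effects.entries["gene"])

        per_study, pooled_dos, pooled_y, pooled_cov = {}, [], [], []
        for s in range(4):
            gm = simulate_genotypes(cfg, s)
            cov = simulate_covariates(cfg, s)
            expr = simulate_expression(gm, effects, cov, cfg, s)
            covn = cov[["age", "sex"]].astype(float)
            per_study[f"study{s + 1}"] = map_all(
                expr, gm, covn, genes, window=window, q_threshold=q_threshold
            )
            pooled_dos.append(gm.dosages)
            pooled_y.append(expr.values)
            pooled_cov.append(covn)

        dos = pd.concat(pooled_dos)
        gm_all = GenotypeMatrix(dos, gm.variants)
        em_all = ExpressionMatrix(pd.concat(pooled_y), pd.Series("pooled", index=dos.index))
        mega = map_all(em_all, gm_all, pd.concat(pooled_cov), genes,
                       window=window, q_threshold=q_threshold)
        meta_tab = meta_map(per_study, min_studies=2, q_threshold=q_threshold)

        mega_tp.append(len(set(mega.loc[mega["significant"], "gene"]) & planted_genes))
        meta_tp.append(len(set(meta_tab.loc[meta_tab["significant"], "gene"]) & planted_genes))
    mega_tp = np.asarray(mega_tp)
    meta_tp = np.asarray(meta_tp)
    return {
        "fraction_mega_ge_meta": float(np.mean(mega_tp >= meta_tp)),
        "mean_mega_true_positives": float(mega_tp.mean()),
        "mean_meta_true_positives": float(meta_tp.mean()),
        "n_replicates": n_replicates,
        "n_planted_effects": n_effects,
    }


# ---------------------------------------------------------------------------
# closed forms and normalization contracts
# ---------------------------------------------------------------------------

def dl_closed_forms() -> dict:
    """The three DerSimonian-Laird reference cases."""
    single = dersimonian_laird([0.5], [0.1])
    homog = dersimonian_laird([0.4, 0.4], [0.1, 0.1])
    heterog = dersimonian_laird([0.2, 0.8], [0.1, 0.1])
    return {
        "k1_beta": single["combined_beta"], "k1_se": single["combined_se"],
        "homog_tau2": homog["tau2"], "homog_se": homog["combined_se"],
        "heterog_q": heterog["het_q"], "heterog_tau2": heterog["tau2"],
        "heterog_beta": heterog["combined_beta"], "heterog_se": heterog["combined_se"],
    }


def normalization_contracts(seed: int = 0, n_samples: int = 50, n_genes: int = 200) -> dict:
    """Quantile-normalization idempotence and batch-shift/scale removal."""
    rng = np.random.default_rng(seed)
    base = pd.DataFrame(
        rng.standard_normal((n_samples, n_genes)) + rng.normal(0, 1, n_genes),
        index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample"),
        columns=[f"g{j}" for j in range(n_genes)],
    )
    qn1 = quantile_normalize(base)
    qn2 = quantile_normalize(qn1)
    idem = float(np.max(np.abs(qn1.to_numpy() - qn2.to_numpy())))

    batch = pd.Series(["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2),
                      index=base.index)
    shifted = base.copy()
    shifted.loc[batch == "B"] += 2.0
    corr = combat_correct(shifted, batch)
    # residual batch bias: the average gene-mean difference left after correction
    mean_diff = float(abs(
        (corr[batch == "A"].mean() - corr[batch == "B"].mean()).mean()
    ))

    scaled = base.copy()
    scaled.loc[batch == "B"] = (
        scaled.loc[batch == "B"] - scaled.loc[batch == "B"].mean()
    ) * 3.0 + scaled.loc[batch == "B"].mean()
    corr2 = combat_correct(scaled, batch)
    var_ratio = float(np.mean(
        corr2[batch == "B"].var() / corr2[batch == "A"].var()
    ))
    return {
        "qn_idempotence_max_diff": idem,
        "combat_mean_batch_diff_after_shift": mean_diff,
        "combat_var_ratio_after_scale": var_ratio,
    }


def table1_crosstab() -> dict:
    """Replication percentages recomputed from the published cohort counts."""
    meta_tab = crosstab_from_counts(published.STUDY_EQTL_GENES, published.STUDY_OVERLAP_META)
    mega_tab = crosstab_from_counts(published.STUDY_EQTL_GENES, published.STUDY_OVERLAP_MEGA)
    out = {
        f"pct_{row.study.lower()}_in_meta": row.pct_overlap
        for row in meta_tab.itertuples(index=False)
    }
    out.update({
        f"pct_{row.study.lower()}_in_mega": row.pct_overlap
        for row in mega_tab.itertuples(index=False)
    })
    out["pct_mega_genes_in_meta"] = round(
        100.0 * published.META_MEGA_SHARED_GENES / published.MEGA_EQTL_GENES, 2
    )
    out["pct_meta_genes_in_mega"] = round(
        100.0 * published.META_MEGA_SHARED_GENES / published.META_EQTL_GENES, 2
    )
    out["mega_minus_meta_avg_points"] = round(float(np.mean(
        mega_tab["pct_overlap"].to_numpy() - meta_tab["pct_overlap"].to_numpy()
    )), 2)
    return out
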