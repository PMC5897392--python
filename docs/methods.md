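# Methods

## Scope and design

The package reconstructs a joint cis-eQTL analysis over several liver
expression cohorts profiled on different genotyping and expression
platforms. The pipeline has five stages — genotype QC/harmonization,
expression normalization, cis-eQTL mapping, study combination
(meta vs. mega), conditional signal dissection — plus a characterization
stage for the resulting variant sets. Each stage is a library module; the
numbered scripts under `analysis/` and the `liverqtl` CLI are thin drivers.

## Genotype QC

Per study, variants are matched to a reference panel by id. Allele pairs
equal to the reference pair are kept; pairs equal after complementing both
alleles are treated as strand flips (dosages untouched); pairs matching in
reversed order are allele-swapped (dosage → 2 − dosage). Multi-allelic and
unmatched variants are removed. Palindromic A/T and C/G pairs carry no
strand information; they are kept only when the study MAF is < 0.4 and the
alternate-allele frequency matches the reference within 0.10, otherwise
removed — the standard harmonization compromise, logged per variant.

Frequency filters use strict inequalities at their thresholds ("more than"
semantics): variants are dropped when |study AF − reference AF| > 0.10,
MAF < 0.05, Hardy–Weinberg exact P < 1×10⁻⁶, off-autosome, cross-study AF
spread > 0.15, or genotyped in fewer than 100 samples after merging. All
filters are pointwise predicates, so the cascade's outcome is order
independent; a `QcReport` reconciles removal counts against matrix sizes
exactly.

The HWE test is the exact conditional test: given the allele counts, the
probabilities of all heterozygote counts of matching parity are evaluated
by a two-sided recurrence from the distribution's mode, and those no more
likely than the observed count are summed. The chi-square approximation is
deliberately not used — the 1×10⁻⁶ threshold is conventionally applied to
the exact test.

Ancestry outliers are removed by PCA: the study is projected jointly with a
reference cohort at 30,000 randomly chosen shared variants
(mean-imputed, standardized dosages), and a sample is retained iff its
PC1–PC2 distance to the reference target-population centroid is at most 1.5×
the largest distance of any reference target-population sample. The
multiplier is configurable; 1.5 keeps essentially all in-population samples
(≤2% loss in simulation) while removing ≥95% of samples drifted by
Fst ≈ 0.1. Note the variant count matters: at this Fst and ~10% outliers,
the ancestry eigenvalue falls below the Marchenko–Pastur noise edge for
panels much smaller than ~10⁴ variants, so the filter is run at the full
30,000-variant design.

After merging, missing dosages (unshared panel variants) are mean-imputed
per variant at regression time, and `n_used` records the genotyped count.
Genotype imputation against an external haplotype reference is out of
scope; mean imputation is unbiased under missing-completely-at-random
panel gaps and keeps the engine self-contained.

## Expression normalization

Per-study order: log₂(x + 0.001) where inputs are raw abundances → probe
collapse → replicate merging → outlier clamping (configured studies only:
raw values outside (−2, 2) set missing, strict inequalities) → cross-study
merge → KNN imputation → quantile normalization → ComBat.

Probe collapsing uses the **variance-weighted** mean — probes with larger
cross-sample variance contribute more. This is intentional and follows the
source protocol, although inverse-variance weighting is the more common
convention; zero-variance probes get weight zero, and an all-zero-weight
gene falls back to the plain mean.

KNN imputation treats genes as neighbours (k = 10, unweighted mean,
Euclidean distance over shared observed samples; k is configurable since
the protocol names only the method). Genes with no observed value in some
study cannot be imputed there and are removed from the merge.

Quantile normalization forces every sample's sorted vector to the
across-sample mean of sorted vectors; tied entries share the mean of the
quantile values their ranks span, making the map deterministic,
order-invariant and idempotent on tie-free data.

Batch correction is parametric empirical-Bayes ComBat with the study label
as the batch (no covariates in the batch model; the protocol supplies only
study labels), delegated to scanpy's implementation. Because the per-batch
location estimates are shrunk toward a cross-gene prior, gene grand means
are preserved only up to the shrinkage scale (~10⁻³ on standardized data),
not exactly; the tests bound the residual batch bias (<0.05 after a planted
+2 shift) and the variance ratio (within [0.8, 1.25] after a ×3 scale)
rather than asserting exact mean preservation.

## cis-eQTL mapping

Cis pairs are all gene–variant combinations on the same chromosome with
variant position in [gene start − 1 Mb, gene end + 1 Mb], boundaries
inclusive; BED input (0-based half-open) is converted to 1-based inclusive
coordinates internally. Signed TSS distances are strand-aware (negative =
upstream of transcription): pos − start on +, end − pos on −.

The scan residualizes expression and dosages against the covariate design
(intercept, age, sex, five genotype PCs) once per gene/panel and computes
slope, SE, t and p per pair from the residual cross-products — numerically
identical (≤10⁻¹⁰) to fitting each full OLS model, by the
Frisch–Waugh–Lovell theorem, but linear-algebra bound. Degrees of freedom
are n − (covariates + intercept + 1). Monomorphic variants are excluded;
an exact fit reports the smallest positive float rather than p = 0.

FDR is controlled **jointly over all cis tests** (one Benjamini–Hochberg
q-value scale for the scan, not per gene), matching how a single
significance scale across hundreds of thousands of eQTL variants is
reported; Storey's π₀-scaled variant is available as an option. The
per-gene top variant is flagged with a deterministic tie-break: smallest p,
then largest |t|, then smallest position.

## Meta vs. mega

The meta-analysis combines per-study (β̂, se) pairs present in ≥2 studies
(configurable; the source protocol does not state how panel-gap variants
were handled) with the DerSimonian–Laird moment estimator for τ² and a
normal reference for the combined z — classic DL practice. Studies must be
allele-harmonized upstream; conflicting ref/alt orientations raise an
error. The mega-analysis simply pools individual-level data after ComBat
and refits. On four homogeneous simulated studies with effects at the
detection margin, pooling detects at least as many planted effects as the
meta-analysis in every replicate observed (mean ~31 vs ~23 of 50 planted) —
the power ordering that motivates preferring the mega results.

## Conditional signals

For each significant gene, round r regresses expression on each remaining
cis variant with the covariates plus the dosages of the r−1 previously
selected variants, selects the smallest conditional p if p < 1×10⁻⁶
(nominal, applied to the conditional slope — not FDR-adjusted), and
repeats until nothing passes. A safety cap of 10 rounds guarantees
termination; candidates with r² > 0.99 to the conditioning set are skipped.
Covariate PCs are not recomputed between rounds. Tie-breaks equal the
primary scan's.

## Characterization

Control variants are drawn uniformly without replacement from all variants
within 1 Mb of any gene span (seeded). Class enrichment compares eQTL vs.
control sets per regulatory class (ordinal 1–7) or consequence category in
a 2×2 table — Fisher's exact test, switching to chi-square with continuity
correction when any cell exceeds 10⁴ (the enrichment test is not named in
the source protocol; this two-proportion comparison is the standard
choice). Zero margins report p = 1 / OR = NA. "Within 100 kb of the TSS"
is inclusive: |distance| ≤ 100,000.

## Synthetic cohorts

The generator emulates the four-study design: cohorts of 178/149/178/83
samples (588 pooled), a shared panel in LD blocks, per-study panel overlap
(default 90%; the complement is missing wholesale per study), planted
primary and secondary cis effects, and per-gene study batch shifts
(N(0, 1)) and scales (U[0.8, 1.25]) on expression, plus 2% missing cells.
LD comes from block-wise Gaussian copula thresholding: haplotype alleles in
a block share a latent factor with correlation ld_rho (default 0.8), one
MAF per block drawn from U(0.05, 0.5). Thresholding attenuates realised
dosage correlation below the latent value (e.g. ~0.5–0.65 at rho 0.8),
which is acceptable: downstream only needs strong within-block and ~zero
cross-block LD, and secondary effects are always planted in a different
block (realised r² < 0.05). Effect sizes default to N(0, 0.7 SD/allele)
with magnitudes floored at 0.2 — the scale of reported liver eQTL effects
(0.17–1.12 per risk allele). Covariates are age ~ U{20..80} and
sex ~ Bernoulli(0.5) with small linear effects. Ancestry outliers use
Balding–Nichols drift at Fst 0.1. Regulatory annotations (classes 1–7,
consequence categories) are drawn with configurable odds enrichment among
true effect variants.

What the generator does **not** emulate: recombination maps and long-range
LD, count-level RNA-seq noise, probe cross-hybridization, population
substructure beyond a single drifted outlier group, and realistic gene
geometry (genes are evenly spaced, so planted variants are not concentrated
near TSSs — TSS-distance summaries on synthetic data describe the planted
geometry, not biology). Passing tests therefore certify the statistical
machinery, not the biological realism of any particular dataset.

## Problem sizes and numerical choices

The test and acceptance experiments run at: 50×500×100 for engine
exactness (tolerance 10⁻¹⁰); 20 global-null replicates of 200 genes ×
2,000 variants at n = 588; 50 detection replicates (β = 0.7, MAF 0.3,
n = 588); 50 two-signal replicates and 500 single-signal genes (~2,000 cis
variants each) for the conditional scan; 20 four-study replicates of 50
marginal effects (β = 0.3) for the power ordering. These sizes give stable
rates while keeping a full run in minutes on one CPU. Seeds for every
stream derive from a single configuration seed via numpy's seed-sequence
spawning; identical seeds give byte-identical outputs. Dosages are written
to VCF with three decimals (DS field), the round-trip tolerance tests use
half that resolution.

## Known limitations

Genotype phasing/imputation, probe re-annotation against transcript
databases, live regulatory-database or consequence-predictor queries, and
trans-eQTL are out of scope. The meta-analysis assumes independent studies
and normal within-study estimates; no meta-regression or correlated-effects
support. The conditional scan is forward stepwise — it does not revisit
earlier selections and can, like all stepwise procedures, split a single
haplotype effect across proxies when LD is long-ranged.
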