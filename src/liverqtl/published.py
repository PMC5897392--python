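"""Published summary counts of the four liver cohorts (Schadt, Schroeder,
Innocenti and GTEx liver) and of their combined meta-/mega-analyses.

These printed counts are inputs to the cross-tabulation arithmetic (overlap
percentages, mega-vs-meta replication advantage); the percentages themselves
are always recomputed from the counts, never stored.
"""

STUDIES = ("Schadt", "Schroeder", "Innocenti", "GTEx")

SAMPLES_AFTER_QC = {"Schadt": 178, "Schroeder": 149, "Innocenti": 178, "GTEx": 83}
N_SAMPLES_TOTAL = 588
N_GENES_ANALYSED = 24_123

# unique significant eQTL genes per analysis (Q < 1e-3)
STUDY_EQTL_GENES = {"Schadt": 363, "Schroeder": 913, "Innocenti": 670, "GTEx": 387}
META_EQTL_GENES = 1_313
MEGA_EQTL_GENES = 1_959

# per-study gene overlap with the combined analyses
STUDY_OVERLAP_META = {"Schadt": 215, "Schroeder": 491, "Innocenti": 408, "GTEx": 149}
STUDY_OVERLAP_MEGA = {"Schadt": 288, "Schroeder": 688, "Innocenti": 537, "GTEx": 207}
META_MEGA_SHARED_GENES = 1_260

# significant eQTL variant counts (Q < 1e-3)
META_EQTL_VARIANTS = 101_148
MEGA_EQTL_VARIANTS = 202_489
MEGA_EQTL_VARIANTS_UNIQUE = 183_872

# conditional (independent-signal) analysis of the mega results
N_SECONDARY_SIGNALS = 101
N_GENES_WITH_SECONDARY = 93
N_INDEPENDENT_SIGNALS_TOTAL = 2_060  # 1,959 primary + 101 secondary
N_WITHIN_100KB_OF_TSS = 1_599
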