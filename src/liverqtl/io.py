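"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF with per-sample dosages in the ``DS`` FORMAT field
(read back through cyvcf2). Expression is TSV with genes on rows and samples
in columns; gene annotation is BED-like TSV (0-based half-open, strand);
covariates and truth tables are plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import ExpressionMatrix, GenotypeMatrix, TrueEffects

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
"""

DOSAGE_DECIMALS = 3  # VCF round-trip precision for DS


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage VCF (DS FORMAT field, '.' for missing)."""
    path = Path(path)
    variants = gm.variants.sort_values(["chrom", "pos"])
    dos = gm.dosages.loc[:, variants.index]
    af = dos.mean(axis=0, skipna=True) / 2.0
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        mat = dos.to_numpy(dtype=float)
        for j, (vid, row) in enumerate(variants.iterrows()):
            cells = [
                "." if np.isnan(d) else f"{d:.{DOSAGE_DECIMALS}f}" for d in mat[:, j]
            ]
            a = af.iloc[j]
            info = "." if np.isnan(a) else f"AF={a:.4f}"
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t{info}\tDS\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | Path, study: str | None = None) -> GenotypeMatrix:
    """Read a dosage VCF written by :func:`write_vcf` (or any VCF with DS)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        ds = np.where(np.isfinite(ds) & (ds >= 0) & (ds <= 2), ds, np.nan)
        rows.append(ds)
    vcf.close()
    dosages = pd.DataFrame(
        np.column_stack(rows) if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample"),
        columns=pd.Index(ids, name="variant"),
    )
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=dosages.columns,
    )
    variants["n_genotyped"] = dosages.notna().sum(axis=0).to_numpy()
    return GenotypeMatrix(dosages, variants, study=study)


# ---------------------------------------------------------------------------
# TSV surfaces
# ---------------------------------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    """Genes on rows, samples in columns."""
    expr.values.T.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def read_expression_tsv(path: str | Path, study_labels: pd.Series) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0, na_values="NA").T
    values.index.name = "sample"
    return ExpressionMatrix(values, study_labels.reindex(values.index))


def write_covariates_tsv(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """BED-like TSV: chrom, start (0-based), end (half-open), strand, gene id."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int) - 1,
            "end": genes["end"].astype(int),
            "strand": genes["strand"],
            "gene": genes.index,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read BED-like annotation into the internal 1-based inclusive convention."""
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "strand", "gene"],
        dtype={"chrom": str},
    )
    if bed["strand"].isna().any() or (~bed["strand"].isin(["+", "-"])).any():
        raise ValueError("gene annotation requires a +/- strand column")
    genes = pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
        },
        index=pd.Index(bed["gene"], name="gene"),
    )
    return genes


def write_truth_tsv(effects: TrueEffects, path: str | Path) -> None:
    effects.entries.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> TrueEffects:
    return TrueEffects(pd.read_csv(path, sep="\t"))
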