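"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: FASTA genome, BED6 gene models, a Bismark-CX-like per-cytosine
report (chrom, 1-based pos, strand, context, methylated reads, unmethylated
reads), VCF v4.2 with DP/MQ/AF INFO keys, and a gene->pathway TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from .enrich import GeneModel

CX_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "unmeth_count"]


# ---------------------------------------------------------------- genome ---

def load_genome(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA into an uppercase in-memory dict (small genomes only)."""
    fa = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------- cytosine report ---

def read_cytosine_report(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cytosine report TSV into the internal site table.

    Internal columns: chrom, pos, strand, context, meth_count, total_count.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=CX_COLUMNS,
        dtype={"chrom": str, "pos": int, "strand": str, "context": str,
               "meth_count": int, "unmeth_count": int},
        comment="#",
    )
    bad = df.loc[(df["meth_count"] < 0) | (df["unmeth_count"] < 0)]
    if len(bad):
        raise ValueError(f"negative read counts in {path} (first at row {bad.index[0]})")
    df["total_count"] = df["meth_count"] + df["unmeth_count"]
    return df.drop(columns=["unmeth_count"])


def write_cytosine_report(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df[["chrom", "pos", "strand", "context", "meth_count"]].copy()
    out["unmeth_count"] = df["total_count"] - df["meth_count"]
    out.to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------- BED ---

def read_gene_bed(path: str | os.PathLike) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            genes.append(GeneModel(chrom, int(start), int(end), strand, name))
    return genes


def write_gene_bed(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ------------------------------------------------------------------- VCF ---

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the variant position">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction">
"""


def write_vcf(
    records: list[dict],
    path: str | os.PathLike,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write simple single-sample-free VCF rows.

    Each record dict needs chrom, pos, ref, alt, depth, mapping_quality,
    allele_fraction. Rows are written sorted by (chrom, pos, ref, alt).
    """
    recs = sorted(records, key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]))
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in recs:
            info = (
                f"DP={int(r['depth'])};MQ={r['mapping_quality']:.1f};"
                f"AF={r['allele_fraction']:.4f}"
            )
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t100\tPASS\t{info}\n"
            )


# ---------------------------------------------------------- pathway map ---

PATHWAY_COLUMNS = ["gene_id", "pathway_id", "pathway_name"]


def read_pathway_map(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=PATHWAY_COLUMNS, dtype=str, comment="#")
    return df


def write_pathway_map_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[PATHWAY_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
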