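"""Paired-tissue exome variant accounting.

The mucosa of each mouse carries both germline and somatic variants; the
muscularis of the same mouse serves as the germline reference.  After
filtering raw calls on mapping quality (>20) and depth at the variant
position (>4) — strict inequalities — somatic variants are the mucosa
records whose exact key (chrom, pos, ref, alt) is absent from the matched
muscularis.  Per-sample summaries count SNPs and InDels and accumulate the
frequency SUM (the sum of somatic allele fractions); variants are assigned
to genes by whole-interval containment and gene sets from multiple mice are
intersected exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .enrich import GeneModel

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    mapping_quality: float
    allele_fraction: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")

    @property
    def vtype(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "InDel"

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_variants(vcf_path) -> tuple[list[VariantRecord], int]:
    """Load a VCF; multi-allelic records are split one record per alt.

    Returns (records, n_missing) where n_missing counts alt records dropped
    for lacking any of DP/MQ/AF.
    """
    records: list[VariantRecord] = []
    n_missing = 0
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {vcf_path}: {exc}") from exc
    with vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            info = rec.info
            dp = info.get("DP")
            mq = info.get("MQ")
            af = info.get("AF")
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                af_i = af[i] if isinstance(af, tuple) else af
                if dp is None or mq is None or af_i is None:
                    n_missing += 1
                    continue
                records.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        depth=int(dp), mapping_quality=float(mq),
                        allele_fraction=float(af_i),
                    )
                )
    return records, n_missing


def filter_variants(
    records: list[VariantRecord], min_mq: float = 20.0, min_depth_exclusive: int = 4
) -> list[VariantRecord]:
    """Keep records with mapping quality > min_mq AND depth > min_depth (strict)."""
    return [
        r for r in records
        if r.mapping_quality > min_mq and r.depth > min_depth_exclusive
    ]


def subtract_germline(
    mucosa: list[VariantRecord], muscularis: list[VariantRecord]
) -> list[VariantRecord]:
    """Somatic = mucosa records whose exact key is absent from muscularis."""
    germ_keys = {r.key for r in muscularis}
    return [r for r in mucosa if r.key not in germ_keys]


@dataclass
class SampleVariantSummary:
    sample_id: str
    n_total: int
    n_somatic: int
    n_snp: int
    n_indel: int
    freq_sum: float
    gene_set: set[str] = field(default_factory=set)


def summarize_sample(
    somatic: list[VariantRecord],
    sample_id: str,
    n_total: int | None = None,
    gene_set: set[str] | None = None,
) -> SampleVariantSummary:
    n_snp = sum(1 for r in somatic if r.vtype == "SNP")
    freq_sum = round(sum(r.allele_fraction for r in somatic), 3)
    return SampleVariantSummary(
        sample_id=sample_id,
        n_total=len(somatic) if n_total is None else n_total,
        n_somatic=len(somatic),
        n_snp=n_snp,
        n_indel=len(somatic) - n_snp,
        freq_sum=freq_sum,
        gene_set=gene_set or set(),
    )


def assign_genes(
    variants: list[VariantRecord], genes: list[GeneModel]
) -> tuple[set[str], dict[VariantKey, set[str]], int]:
    """Map each variant to every gene whose interval contains its position.

    Returns (union of hit gene ids, per-variant gene sets, intergenic count).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    hit: set[str] = set()
    per_variant: dict[VariantKey, set[str]] = {}
    n_intergenic = 0
    for v in variants:
        ids = {
            g.gene_id
            for g in by_chrom.get(v.chrom, [])
            if g.start1 <= v.pos <= g.end1
        }
        per_variant[v.key] = ids
        if ids:
            hit |= ids
        else:
            n_intergenic += 1
    return hit, per_variant, n_intergenic


def intersect_gene_sets(sets: list[set[str]]) -> list[str]:
    """Exact intersection of >=2 gene id sets, emitted sorted."""
    if len(sets) < 2:
        raise ValueError("need at least two gene sets to intersect")
    common = set(sets[0])
    for s in sets[1:]:
        common &= s
    return sorted(common)
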