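"""DMR-to-gene zone assignment and hypergeometric pathway enrichment.

A gene defines three strand-aware zones: the 2-kb flank 5' of the TSS
(``up2k``), the gene body, and the 2-kb flank 3' of the TES (``down2k``).
A differentially methylated region is assigned to every (gene, zone) whose
interval it overlaps by at least one base pair; regions hitting no zone are
intergenic.  Over-representation of a pathway among DMR-hit genes is scored
with the hypergeometric upper tail against a whole-annotation background and
corrected to Q-values (Benjamini-Hochberg by default); pathways with
q < 0.05 are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ZONES = ("up2k", "body", "down2k")
FLANK = 2000


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene interval. ``start``/``end`` are 0-based half-open (BED)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.gene_id}")

    @property
    def start1(self) -> int:
        """1-based inclusive start."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end (equals the BED end)."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def zone_interval(self, zone: str) -> tuple[int, int]:
        """1-based inclusive interval of a zone, clipped at position 1.

        For a minus-strand gene the upstream flank lies to the right of the
        body and the downstream flank to the left.
        """
        if zone == "body":
            return self.start1, self.end1
        left = (max(1, self.start1 - FLANK), self.start1 - 1)
        right = (self.end1 + 1, self.end1 + FLANK)
        if zone == "up2k":
            return left if self.strand == "+" else right
        if zone == "down2k":
            return right if self.strand == "+" else left
        raise ValueError(f"unknown zone {zone!r}")


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k: int  # DMR-gene hits in the pathway
    K: int  # pathway size within the background
    n: int  # DMR-gene count within the background
    N: int  # background size
    p: float
    q: float = float("nan")
    significant: bool = False


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """>=1 bp overlap between two 1-based inclusive intervals."""
    return a_start <= b_end and b_start <= a_end


def assign_dmr_genes(
    dmrs: pd.DataFrame, genes: list[GeneModel]
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Map DMRs onto gene zones.

    Parameters
    ----------
    dmrs : DataFrame with columns chrom, start, end (1-based inclusive).
    genes : gene models sharing the DMR coordinate system.

    Returns
    -------
    zone_map : dict zone -> set of gene ids hit in that zone (plus key
        ``intergenic`` -> empty set placeholder is NOT included; intergenic
        DMRs appear only in the assignment table).
    assignments : one row per (DMR, gene, zone) overlap; DMRs overlapping no
        zone get a single row with gene_id "" and zone "intergenic".
    """
    zone_map: dict[str, set[str]] = {z: set() for z in ZONES}
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for idx, dmr in dmrs.iterrows():
        hit = False
        for g in by_chrom.get(dmr["chrom"], []):
            for zone in ZONES:
                zs, ze = g.zone_interval(zone)
                if zs > ze:
                    continue  # flank fully clipped off the chromosome start
                if _overlaps(int(dmr["start"]), int(dmr["end"]), zs, ze):
                    zone_map[zone].add(g.gene_id)
                    rows.append(
                        {
                            "dmr_index": idx,
                            "chrom": dmr["chrom"],
                            "start": int(dmr["start"]),
                            "end": int(dmr["end"]),
                            "gene_id": g.gene_id,
                            "zone": zone,
                        }
                    )
                    hit = True
        if not hit:
            rows.append(
                {
                    "dmr_index": idx,
                    "chrom": dmr["chrom"],
                    "start": int(dmr["start"]),
                    "end": int(dmr["end"]),
                    "gene_id": "",
                    "zone": "intergenic",
                }
            )
    cols = ["dmr_index", "chrom", "start", "end", "gene_id", "zone"]
    return zone_map, pd.DataFrame(rows, columns=cols)


def hypergeometric_enrich(
    hit_genes: set[str], pathway_map: pd.DataFrame, background: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per pathway.

    p = P(X >= k) with X ~ Hypergeom(N population, K pathway members,
    n draws = hit genes).  Pathways and hits are intersected with the
    background first; results are sorted by p ascending.
    """
    if not background:
        raise ValueError("background gene set is empty")
    hits = set(hit_genes) & background
    n = len(hits)
    N = len(background)
    rows = []
    for (pid, pname), grp in pathway_map.groupby(
        ["pathway_id", "pathway_name"], sort=True
    ):
        members = set(grp["gene_id"]) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway_id": pid, "pathway_name": pname, "k": k, "K": K, "n": n,
             "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(
        rows, columns=["pathway_id", "pathway_name", "k", "K", "n", "N", "p"]
    )
    return out.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)


def adjust_q(
    results: pd.DataFrame, method: str = "fdr_bh", alpha: float = 0.05
) -> pd.DataFrame:
    """Fill in corrected Q-values; significant iff q < alpha."""
    out = results.copy()
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    _, q, _, _ = multipletests(out["p"].to_numpy(), method=method)
    out["q"] = q
    out["significant"] = out["q"] < alpha
    return out


def enrich_zone_genes(
    zone_genes: set[str],
    pathway_map: pd.DataFrame,
    background: set[str] | None = None,
    method: str = "fdr_bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Convenience wrapper: test + correction in one call."""
    if background is None:
        background = set(pathway_map["gene_id"])
    res = hypergeometric_enrich(zone_genes, pathway_map, background)
    return adjust_q(res, method=method, alpha=alpha)
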