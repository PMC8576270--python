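"""Six-criterion DMR identification between two methylomes, per context.

A differentially methylated region between two samples must satisfy, all at
once: (1) at least ``min_meth_sites`` methylated cytosines in at least one
sample; (2) coverage >= ``min_site_coverage`` at every member cytosine in
both samples, and >= ``min_meth_reads`` methylated reads at every cytosine
called methylated; (3) length within [``min_len``, ``max_len``];
(4) adjacent methylated sites closer than ``max_gap``; (5) fold change of
the pooled methylation level > ``min_fold``; (6) Pearson's chi-square test
on the pooled 2x2 read table with p <= ``max_p``.

Candidates are maximal chains of seed sites (methylated in >=1 sample and
passing the coverage screens); chains outside the length window are
discarded whole, not split.  No multiple-testing correction is applied
across regions by default (raw p <= 0.05), matching the procedure this
implements; a BH option is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylome import CONTEXTS, call_methylated_sites

logger = logging.getLogger(__name__)


@dataclass
class DMRConfig:
    min_meth_sites: int = 5
    min_site_coverage: int = 10
    min_meth_reads: int = 4
    min_len: int = 40
    max_len: int = 10_000
    max_gap: int = 200
    min_fold: float = 2.0
    max_p: float = 0.05
    # methylated-site calling parameters (passed through to the methylome rule)
    error_rate: float = 0.005
    alpha: float = 0.05
    min_call_coverage: int = 4
    bh_across_regions: bool = False

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len exceeds max_len")
        for name in ("min_meth_sites", "min_site_coverage", "min_meth_reads",
                     "min_len", "max_len", "max_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CandidateRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    context: str
    pos: np.ndarray = field(repr=False, default=None)
    meth_a: np.ndarray = field(repr=False, default=None)
    total_a: np.ndarray = field(repr=False, default=None)
    meth_b: np.ndarray = field(repr=False, default=None)
    total_b: np.ndarray = field(repr=False, default=None)
    flag_a: np.ndarray = field(repr=False, default=None)
    flag_b: np.ndarray = field(repr=False, default=None)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_sites(self) -> int:
        return len(self.pos)


@dataclass
class DMRRecord:
    chrom: str
    start: int
    end: int
    context: str
    n_sites: int
    level_a: float
    level_b: float
    fold_change: float  # >= 1, orientation-free
    direction: int  # +1 hyper in B relative to A, -1 hypo
    chi2: float
    p: float


def pearson_chi2_2x2(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Returns (statistic, p). Degenerate tables (a zero marginal) give (0, 1).
    """
    a, b, c, d = float(meth_a), float(unmeth_a), float(meth_b), float(unmeth_b)
    n = a + b + c + d
    marg = (a + b) * (c + d) * (a + c) * (b + d)
    if n == 0 or marg == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / marg
    return chi2, float(stats.chi2.sf(chi2, df=1))


def merge_samples(sample_a: pd.DataFrame, sample_b: pd.DataFrame,
                  flags_a: np.ndarray, flags_b: np.ndarray) -> pd.DataFrame:
    """Inner join of the two site tables on (chrom, pos, strand, context)."""
    chroms_a, chroms_b = set(sample_a["chrom"]), set(sample_b["chrom"])
    if chroms_a != chroms_b:
        raise ValueError(
            f"samples cover different chromosomes: {sorted(chroms_a ^ chroms_b)}"
        )
    a = sample_a[["chrom", "pos", "strand", "context", "meth_count", "total_count"]].copy()
    a["flag"] = flags_a
    b = sample_b[["chrom", "pos", "strand", "context", "meth_count", "total_count"]].copy()
    b["flag"] = flags_b
    return a.merge(b, on=["chrom", "pos", "strand", "context"], suffixes=("_a", "_b"))


def build_candidate_regions(
    merged: pd.DataFrame, cfg: DMRConfig, context: str
) -> list[CandidateRegion]:
    """Chain seed sites of one context into candidate regions.

    Seeds are sites methylated in >=1 sample, with coverage >=
    ``min_site_coverage`` in both samples, and (where flagged) >=
    ``min_meth_reads`` methylated reads in the flagged sample.  Consecutive
    seeds with gap < ``max_gap`` chain; maximal chains with span inside
    [min_len, max_len] become candidates.
    """
    sub = merged.loc[merged["context"] == context]
    cov_ok = (sub["total_count_a"] >= cfg.min_site_coverage) & (
        sub["total_count_b"] >= cfg.min_site_coverage
    )
    meth_ok = (~sub["flag_a"] | (sub["meth_count_a"] >= cfg.min_meth_reads)) & (
        ~sub["flag_b"] | (sub["meth_count_b"] >= cfg.min_meth_reads)
    )
    seeds = sub.loc[(sub["flag_a"] | sub["flag_b"]) & cov_ok & meth_ok]
    regions: list[CandidateRegion] = []
    for chrom, grp in seeds.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "strand"], kind="mergesort")
        pos = grp["pos"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.nonzero(np.diff(pos) >= cfg.max_gap)[0] + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            g = grp.iloc[chunk]
            start, end = int(g["pos"].iloc[0]), int(g["pos"].iloc[-1])
            span = end - start + 1
            if span < cfg.min_len or span > cfg.max_len:
                continue
            regions.append(
                CandidateRegion(
                    chrom=chrom, start=start, end=end, context=context,
                    pos=g["pos"].to_numpy(),
                    meth_a=g["meth_count_a"].to_numpy(),
                    total_a=g["total_count_a"].to_numpy(),
                    meth_b=g["meth_count_b"].to_numpy(),
                    total_b=g["total_count_b"].to_numpy(),
                    flag_a=g["flag_a"].to_numpy(),
                    flag_b=g["flag_b"].to_numpy(),
                )
            )
    return regions


def evaluate_region(region: CandidateRegion, cfg: DMRConfig) -> tuple[DMRRecord | None, str]:
    """Apply the count, fold-change and chi-square criteria to one candidate.

    Returns (record, "accepted") or (None, rejection reason code).
    """
    n_meth_a = int(region.flag_a.sum())
    n_meth_b = int(region.flag_b.sum())
    if max(n_meth_a, n_meth_b) < cfg.min_meth_sites:
        return None, "min_meth_sites"
    M_a, T_a = int(region.meth_a.sum()), int(region.total_a.sum())
    M_b, T_b = int(region.meth_b.sum()), int(region.total_b.sum())
    if T_a == 0 or T_b == 0:
        return None, "zero_coverage"
    level_a, level_b = M_a / T_a, M_b / T_b
    lo, hi = min(level_a, level_b), max(level_a, level_b)
    if lo == 0.0:
        if hi == 0.0:
            return None, "fold_change"
        fold = math.inf  # zero-denominator rule: 0 vs >0 passes the fold criterion
    else:
        fold = hi / lo
        if fold <= cfg.min_fold:
            return None, "fold_change"
    chi2, p = pearson_chi2_2x2(M_a, T_a - M_a, M_b, T_b - M_b)
    expected_min = min(
        (M_a + M_b) * T_a, (M_a + M_b) * T_b,
        (T_a - M_a + T_b - M_b) * T_a, (T_a - M_a + T_b - M_b) * T_b,
    ) / (T_a + T_b)
    if expected_min < 5:
        logger.warning(
            "chi-square expected count %.2f < 5 in %s:%d-%d",
            expected_min, region.chrom, region.start, region.end,
        )
    if p > cfg.max_p:
        return None, "chi2_p"
    rec = DMRRecord(
        chrom=region.chrom, start=region.start, end=region.end,
        context=region.context, n_sites=region.n_sites,
        level_a=level_a, level_b=level_b, fold_change=fold,
        direction=1 if level_b > level_a else -1, chi2=chi2, p=p,
    )
    return rec, "accepted"


DMR_COLUMNS = ["chrom", "start", "end", "context", "n_sites", "level_a",
               "level_b", "fold_change", "direction", "chi2", "p"]


def call_dmrs(
    sample_a: pd.DataFrame, sample_b: pd.DataFrame, cfg: DMRConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Call DMRs over all three contexts between two site tables.

    Returns the accepted records sorted by coordinate and a tally of
    rejection reasons across evaluated candidates.
    """
    cfg = cfg or DMRConfig()
    flags_a = call_methylated_sites(
        sample_a, cfg.error_rate, cfg.alpha, cfg.min_call_coverage
    )
    flags_b = call_methylated_sites(
        sample_b, cfg.error_rate, cfg.alpha, cfg.min_call_coverage
    )
    merged = merge_samples(sample_a, sample_b, flags_a, flags_b)
    records: list[DMRRecord] = []
    tally: dict[str, int] = {}
    for context in CONTEXTS:
        for region in build_candidate_regions(merged, cfg, context):
            rec, reason = evaluate_region(region, cfg)
            tally[reason] = tally.get(reason, 0) + 1
            if rec is not None:
                records.append(rec)
    df = pd.DataFrame([vars(r) for r in records], columns=DMR_COLUMNS)
    if cfg.bh_across_regions and len(df):
        _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        keep = q <= cfg.max_p
        tally["bh_across_regions"] = int((~keep).sum())
        df = df.loc[keep]
    df = df.sort_values(["chrom", "start", "context"], kind="mergesort").reset_index(drop=True)
    return df, tally


def write_dmr_tsv(dmrs: pd.DataFrame, path) -> None:
    dmrs.to_csv(path, sep="\t", index=False)


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6: name = context:direction, score = -10*log10 is not used; the
    score column carries -log10(p) capped at 1000."""
    with open(path, "w") as fh:
        for r in dmrs.itertuples(index=False):
            name = f"{r.context}:{'hyper' if r.direction > 0 else 'hypo'}"
            score = 1000.0 if r.p <= 0 else min(1000.0, -math.log10(r.p))
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{score:.1f}\t+\n"
            )
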