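"""Site-level and summary methylome statistics from cytosine reports.

The atom is a strand-specific cytosine with a sequence context (CG, CHG or
CHH, H = A/C/T read 5'->3' on the cytosine's strand), a methylated read
count and a total read count.  A cytosine is called methylated when its
methylated read count is inconsistent with the bisulfite non-conversion
error rate under a one-sided binomial test, Benjamini-Hochberg corrected
across all tested sites.  On top of the calls this module computes mC-type
ratios, per-chromosome densities, the 9-bp sequence context matrix around
(methylated) CG sites, and strand-aware metagene profiles binned at 100 bp
over 2-kb gene flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
BASES = "ACGT"


# ------------------------------------------------------ context classify ---

def classify_context(
    genome: dict[str, str], chrom: str, pos: int, strand: str
) -> str | None:
    """Sequence context of the cytosine at 1-based ``pos`` on ``strand``.

    Returns CG if the next base (5'->3' on the cytosine's strand) is G,
    CHG if the base after next is G, else CHH; None when the reference base
    is not a C on that strand or the lookahead runs off the chromosome.
    """
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside {chrom} (length {len(seq)})")
    i = pos - 1
    if strand == "+":
        if seq[i] != "C":
            return None
        if i + 1 >= len(seq):
            return None
        if seq[i + 1] == "G":
            return "CG"
        if i + 2 >= len(seq):
            return None
        return "CHG" if seq[i + 2] == "G" else "CHH"
    if strand == "-":
        if seq[i] != "G":  # C on the minus strand reads as G on the reference
            return None
        if i - 1 < 0:
            return None
        if seq[i - 1] == "C":
            return "CG"
        if i - 2 < 0:
            return None
        return "CHG" if seq[i - 2] == "C" else "CHH"
    raise ValueError(f"invalid strand {strand!r}")


def enumerate_cytosines(seq: str) -> pd.DataFrame:
    """All classifiable cytosines of one chromosome, both strands.

    Vectorised companion of :func:`classify_context`; the unit tests assert
    the two agree.  Returns columns pos (1-based), strand, context.
    """
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    L = len(b)
    C, G = ord("C"), ord("G")
    frames = []
    # plus strand: cytosine at i, lookahead i+1, i+2
    idx = np.nonzero(b == C)[0]
    idx = idx[idx + 1 < L]
    nxt_g = b[idx + 1] == G
    ctx = np.full(idx.shape, "", dtype="U3")
    ctx[nxt_g] = "CG"
    rest = ~nxt_g
    ok2 = rest & (idx + 2 < L)
    nn = np.zeros(idx.shape, bool)
    nn[ok2] = b[idx[ok2] + 2] == G
    ctx[ok2] = np.where(nn[ok2], "CHG", "CHH")
    keep = ctx != ""
    frames.append(
        pd.DataFrame({"pos": idx[keep] + 1, "strand": "+", "context": ctx[keep]})
    )
    # minus strand: reference G at i, lookbehind i-1, i-2
    idx = np.nonzero(b == G)[0]
    idx = idx[idx - 1 >= 0]
    nxt_c = b[idx - 1] == C
    ctx = np.full(idx.shape, "", dtype="U3")
    ctx[nxt_c] = "CG"
    rest = ~nxt_c
    ok2 = rest & (idx - 2 >= 0)
    nn = np.zeros(idx.shape, bool)
    nn[ok2] = b[idx[ok2] - 2] == C
    ctx[ok2] = np.where(nn[ok2], "CHG", "CHH")
    keep = ctx != ""
    frames.append(
        pd.DataFrame({"pos": idx[keep] + 1, "strand": "-", "context": ctx[keep]})
    )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


# ----------------------------------------------------------- site calling ---

def call_methylated_sites(
    records: pd.DataFrame,
    error_rate: float = 0.005,
    alpha: float = 0.05,
    min_coverage: int = 4,
) -> np.ndarray:
    """Flag methylated cytosines by a one-sided binomial test.

    P(X >= meth_count | total_count, error_rate) is BH-adjusted across all
    covered sites; a site is methylated iff its adjusted p <= alpha, it has
    at least one methylated read and coverage >= min_coverage.
    """
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    meth = records["meth_count"].to_numpy()
    total = records["total_count"].to_numpy()
    flags = np.zeros(len(records), dtype=bool)
    tested = total > 0
    if tested.sum() == 0:
        return flags
    pvals = stats.binom.sf(meth[tested] - 1, total[tested], error_rate)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    ok = (qvals <= alpha) & (meth[tested] > 0) & (total[tested] >= min_coverage)
    flags[np.nonzero(tested)[0][ok]] = True
    return flags


# -------------------------------------------------------------- summaries ---

@dataclass
class MethylomeSummary:
    """mC counts/shares per context, plus mean levels by context and chromosome."""

    mc_counts: dict[str, int] = field(default_factory=dict)
    mc_shares: dict[str, float] = field(default_factory=dict)
    mean_level: dict[str, float] = field(default_factory=dict)
    chrom_mean_level: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "context": c,
                "mc_count": self.mc_counts.get(c, 0),
                "mc_share": self.mc_shares.get(c, 0.0),
                "mean_level": self.mean_level.get(c, float("nan")),
            }
            for c in CONTEXTS
        ]
        return pd.DataFrame(rows)


def summarize(records: pd.DataFrame, flags: np.ndarray) -> MethylomeSummary:
    """Per-context methylated-site counts, their shares of total mC, and
    mean site levels per context and per chromosome (covered sites only)."""
    s = MethylomeSummary()
    counts = {c: 0 for c in CONTEXTS}
    if len(records):
        vc = records.loc[flags, "context"].value_counts()
        counts.update({c: int(vc.get(c, 0)) for c in CONTEXTS})
    s.mc_counts = counts
    total_mc = sum(counts.values())
    s.mc_shares = {
        c: (counts[c] / total_mc if total_mc > 0 else 0.0) for c in CONTEXTS
    }
    covered = records.loc[records["total_count"] > 0].copy()
    if len(covered):
        covered["level"] = covered["meth_count"] / covered["total_count"]
        s.mean_level = covered.groupby("context")["level"].mean().to_dict()
        s.chrom_mean_level = (
            covered.groupby(["chrom", "context"])["level"].mean().unstack(fill_value=float("nan"))
        )
    else:
        s.mean_level = {}
        s.chrom_mean_level = pd.DataFrame()
    return s


def chromosome_density(
    records: pd.DataFrame,
    flags: np.ndarray,
    window: int,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Counts of methylated sites in half-open windows tiling each chromosome.

    Windows are [k*window, (k+1)*window) in 0-based coordinates; every window
    up to the chromosome length (or the last covered site) is emitted,
    including empty ones.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    flagged = records.loc[flags]
    chroms = sorted(set(records["chrom"]))
    for chrom in chroms:
        sub = flagged.loc[flagged["chrom"] == chrom]
        if chrom_sizes and chrom in chrom_sizes:
            length = chrom_sizes[chrom]
        else:
            length = int(records.loc[records["chrom"] == chrom, "pos"].max())
        n_win = max(1, -(-length // window))
        counts = np.zeros(n_win, dtype=int)
        if len(sub):
            w = (sub["pos"].to_numpy() - 1) // window
            np.add.at(counts, w, 1)
        for k in range(n_win):
            rows.append(
                {"chrom": chrom, "start": k * window,
                 "end": min((k + 1) * window, length), "mc_count": int(counts[k])}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mc_count"])


# -------------------------------------------------------- 9-bp context ---

_COMP = str.maketrans("ACGT", "TGCA")


def _flank_9bp(seq: str, pos: int, strand: str) -> str | None:
    i = pos - 1
    if i - 4 < 0 or i + 4 >= len(seq):
        return None
    win = seq[i - 4 : i + 5]
    return win if strand == "+" else win.translate(_COMP)[::-1]


def context_matrix_9bp(
    genome: dict[str, str], records: pd.DataFrame, flags: np.ndarray
) -> dict:
    """Base-frequency matrices (4x9, offsets -4..+4) around CG cytosines.

    Returns ``{"mcg": ..., "cg": ..., "skipped": int}`` where ``mcg`` counts
    only methylated CG sites and ``cg`` all CG sites; minus-strand flanks are
    reverse-complemented so the center column is all-C.  Columns are
    normalised to sum to 1 (or left at 0 with no sites).
    """
    mats = {"mcg": np.zeros((4, 9)), "cg": np.zeros((4, 9))}
    skipped = 0
    cg = records["context"] == "CG"
    sub = records.loc[cg, ["chrom", "pos", "strand"]]
    sub_flags = flags[cg.to_numpy()]
    base_idx = {b: i for i, b in enumerate(BASES)}
    for (chrom, pos, strand), is_m in zip(
        sub.itertuples(index=False), sub_flags
    ):
        win = _flank_9bp(genome[chrom], int(pos), strand)
        if win is None:
            skipped += 1
            continue
        for j, b in enumerate(win):
            if b in base_idx:
                mats["cg"][base_idx[b], j] += 1
                if is_m:
                    mats["mcg"][base_idx[b], j] += 1
    for key in ("mcg", "cg"):
        colsum = mats[key].sum(axis=0)
        nz = colsum > 0
        mats[key][:, nz] /= colsum[nz]
    mats["skipped"] = skipped
    return mats


# --------------------------------------------------------------- metagene ---

def metagene_profile(
    records: pd.DataFrame,
    genes: list,
    flank: int = 2000,
    bin_size: int = 100,
    body_bins: int = 20,
) -> pd.DataFrame:
    """Mean methylation in fixed bins across aligned genes, per context.

    Flanks are binned at ``bin_size`` in 5'->3' gene orientation (upstream
    bin 0 is the flank edge farthest from the TSS); gene bodies are split
    into ``body_bins`` equal fractions.  Bin value = mean of site levels in
    the bin, averaged across genes ignoring empty bins.  Genes shorter than
    ``body_bins`` bp are skipped with a warning.

    Returns a DataFrame with columns segment, bin, and one column per context.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_flank = flank // bin_size
    n_bins = 2 * n_flank + body_bins
    covered = records.loc[records["total_count"] > 0].copy()
    covered["level"] = covered["meth_count"] / covered["total_count"]
    by_chrom = {c: g.sort_values("pos") for c, g in covered.groupby("chrom")}

    sums = {c: np.zeros(n_bins) for c in CONTEXTS}
    ngene = {c: np.zeros(n_bins) for c in CONTEXTS}
    for gene in genes:
        if gene.length < body_bins:
            logger.warning("gene %s shorter than %d bp, skipped", gene.gene_id, body_bins)
            continue
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        gs, ge = gene.start1, gene.end1
        lo, hi = gs - flank, ge + flank
        pos = sub["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [lo, hi + 1])
        window = sub.iloc[i0:i1]
        if not len(window):
            continue
        p = window["pos"].to_numpy()
        if gene.strand == "+":
            upstream = p < gs
            downstream = p > ge
            bidx = np.empty(len(p), dtype=int)
            bidx[upstream] = (p[upstream] - lo) // bin_size
            body = ~upstream & ~downstream
            frac = (p[body] - gs) / gene.length
            bidx[body] = n_flank + np.minimum((frac * body_bins).astype(int), body_bins - 1)
            bidx[downstream] = n_flank + body_bins + (p[downstream] - ge - 1) // bin_size
        else:
            upstream = p > ge
            downstream = p < gs
            bidx = np.empty(len(p), dtype=int)
            bidx[upstream] = (hi - p[upstream]) // bin_size
            body = ~upstream & ~downstream
            frac = (ge - p[body]) / gene.length
            bidx[body] = n_flank + np.minimum((frac * body_bins).astype(int), body_bins - 1)
            bidx[downstream] = n_flank + body_bins + (gs - 1 - p[downstream]) // bin_size
        lv = window["level"].to_numpy()
        ctx = window["context"].to_numpy()
        for c in CONTEXTS:
            m = ctx == c
            if not m.any():
                continue
            bsum = np.zeros(n_bins)
            bcnt = np.zeros(n_bins)
            np.add.at(bsum, bidx[m], lv[m])
            np.add.at(bcnt, bidx[m], 1)
            has = bcnt > 0
            sums[c][has] += bsum[has] / bcnt[has]
            ngene[c][has] += 1

    segment = (["up2k"] * n_flank) + (["body"] * body_bins) + (["down2k"] * n_flank)
    out = pd.DataFrame({"segment": segment, "bin": range(n_bins)})
    for c in CONTEXTS:
        with np.errstate(invalid="ignore"):
            out[c] = np.where(ngene[c] > 0, sums[c] / np.maximum(ngene[c], 1), np.nan)
    return out
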