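"""Synthetic genome, methylomes and paired variant sets with planted truth.

Everything downstream of read alignment is exercised on data this module
generates: a random genome at a configurable GC fraction, non-overlapping
stranded gene models with room for 2-kb flanks, two-condition whole-genome
cytosine reports with planted context-specific DMRs, paired mucosa /
muscularis VCFs sharing germline variants, and a gene->pathway map in which
one designated pathway is over-represented among DMR-hosting genes.  The
planted truth (DMR intervals and levels, germline/somatic variant keys, the
enriched pathway id) is recorded in :class:`SimTruth` for recovery checks.

Methylome model.  CpG methylation is bimodal and spatially organised, so CG
background states are drawn per CpG dyad (both strands share the state)
inside a domain/desert architecture: fully methylated ~2-kb domains cover a
fraction of the genome calibrated so the genome-wide mean CG level equals
``baseline_level_cg``; outside domains dyads are methylated with a small
desert probability.  CHG/CHH states are independent per site at their
(low) baselines.  Background states are shared between the two conditions —
the correct null — while read counts are always drawn independently per
condition.  Planted DMRs are continuous-level regions (control = baseline,
treated = baseline + delta) placed in deserts, so they chain in isolation
and satisfy the fold-change criterion by construction.  Bisulfite
non-conversion appears only as false methylation on unmethylated cytosines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iomod
from .enrich import GeneModel, ZONES
from .methylome import enumerate_cytosines

DESERT_P = 0.02  # dyad methylation probability outside domains
DOMAIN_P = 0.95  # dyad methylation probability inside domains
DOMAIN_LEN = 2000  # bp per methylated domain
DMR_BUFFER = 500  # desert margin kept clear around planted DMRs
GENE_MARGIN = 2000  # genes stay this far from chromosome ends
GENE_GAP = 4200  # minimum gap between gene bodies (> two 2-kb flanks)
INTERGENIC_FRACTION = 0.15  # share of planted DMRs placed outside gene zones
INTERGENIC_MARGIN = 300  # clearance between intergenic DMRs and gene zones
SNP_FRACTION = 0.8  # remaining variants are small InDels
N_HOTSPOT_GENES = 3  # genes guaranteed a somatic hit in every mucosa
N_PATHWAYS = 10
DESIGNATED_PATHWAY = "P01"
HOST_PATHWAY_COVERAGE = 0.9  # share of DMR-hosting genes put in P01


class ConfigError(ValueError):
    """A SimConfig field is out of range; the message names the field."""


class PlacementError(RuntimeError):
    """An interval could not be placed after bounded retries."""


@dataclass
class SimConfig:
    n_chroms: int = 2
    chrom_length: int = 300_000
    gc_fraction: float = 0.42
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (2000, 6000)
    n_planted_dmrs: int = 20  # per context
    dmr_length_range: tuple[int, int] = (300, 800)
    baseline_level_cg: float = 0.2
    baseline_level_chg: float = 0.05
    baseline_level_chh: float = 0.02
    dmr_delta: float = 0.4
    mean_coverage: float = 30.0
    coverage_dispersion: float = 0.1
    bisulfite_error: float = 0.005
    n_mice: int = 4  # mouse 1 is the control, the rest are colitis
    n_germline_variants: int = 300
    n_somatic_variants: int = 80
    somatic_af_range: tuple[float, float] = (0.05, 0.5)
    subthreshold_fraction: float = 0.1
    variant_mean_depth: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("gc_fraction", "baseline_level_cg", "baseline_level_chg",
                     "baseline_level_chh", "bisulfite_error",
                     "subthreshold_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.somatic_af_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"somatic_af_range must be an ordered pair in [0, 1]")
        dlo, dhi = self.dmr_length_range
        if not (40 <= dlo <= dhi <= 10_000):
            raise ConfigError("dmr_length_range must lie within [40, 10000]")
        glo, ghi = self.gene_length_range
        if not (0 < glo <= ghi):
            raise ConfigError("gene_length_range must be an ordered positive pair")
        if self.chrom_length < ghi + 2 * GENE_MARGIN:
            raise ConfigError(
                "chrom_length must be at least the maximum gene length plus 4 kb flanks"
            )
        for name in ("n_chroms", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("n_genes", "n_planted_dmrs", "n_germline_variants",
                     "n_somatic_variants", "n_mice", "seed"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not -1.0 <= self.dmr_delta <= 1.0:
            raise ConfigError("dmr_delta must be in [-1, 1]")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        if self.coverage_dispersion < 0:
            raise ConfigError("coverage_dispersion must be non-negative")


@dataclass
class PlantedDMR:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    context: str
    zone: str  # up2k | body | down2k | intergenic
    gene_id: str  # "" for intergenic
    level_control: float
    level_treated: float


@dataclass
class SimTruth:
    """Recovery oracle: what was planted, keyed for downstream comparison."""

    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    germline_by_mouse: dict[str, list[tuple]] = field(default_factory=dict)
    somatic_by_sample: dict[str, list[tuple]] = field(default_factory=dict)
    subthreshold_by_sample: dict[str, list[tuple]] = field(default_factory=dict)
    enriched_pathway_id: str = ""
    dmr_host_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        obj = {
            "planted_dmrs": [asdict(d) for d in self.planted_dmrs],
            "germline_by_mouse": {k: [list(t) for t in v]
                                  for k, v in self.germline_by_mouse.items()},
            "somatic_by_sample": {k: [list(t) for t in v]
                                  for k, v in self.somatic_by_sample.items()},
            "subthreshold_by_sample": {k: [list(t) for t in v]
                                       for k, v in self.subthreshold_by_sample.items()},
            "enriched_pathway_id": self.enriched_pathway_id,
            "dmr_host_genes": self.dmr_host_genes,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            planted_dmrs=[PlantedDMR(**d) for d in obj["planted_dmrs"]],
            germline_by_mouse={k: [tuple(t) for t in v]
                               for k, v in obj["germline_by_mouse"].items()},
            somatic_by_sample={k: [tuple(t) for t in v]
                               for k, v in obj["somatic_by_sample"].items()},
            subthreshold_by_sample={k: [tuple(t) for t in v]
                                    for k, v in obj["subthreshold_by_sample"].items()},
            enriched_pathway_id=obj["enriched_pathway_id"],
            dmr_host_genes=obj["dmr_host_genes"],
        )


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, stage])


# ----------------------------------------------------------------- genome ---

def generate_genome(cfg: SimConfig) -> dict[str, str]:
    """Random nucleotide sequences at the configured GC fraction."""
    cfg.validate()
    rng = _rng(cfg, 0)
    gc = cfg.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(cfg.n_chroms):
        draw = rng.choice(4, size=cfg.chrom_length, p=p)
        genome[f"chr{i + 1}"] = alphabet[draw].tobytes().decode("ascii")
    return genome


# ------------------------------------------------------------------ genes ---

def _random_gaps(rng: np.random.Generator, free: int, k: int) -> np.ndarray:
    """Split ``free`` bp into k non-negative integer gaps, randomly."""
    if k == 0:
        return np.array([], dtype=int)
    w = rng.random(k)
    gaps = np.floor(w / w.sum() * free).astype(int)
    gaps[-1] += free - gaps.sum()
    return gaps


def generate_gene_models(cfg: SimConfig, genome: dict[str, str]) -> list[GeneModel]:
    """Non-overlapping stranded genes, each >= 2 kb from chromosome ends and
    >= ``GENE_GAP`` apart so 2-kb flank zones never collide."""
    cfg.validate()
    rng = _rng(cfg, 1)
    chroms = sorted(genome)
    per_chrom = [cfg.n_genes // len(chroms)] * len(chroms)
    for i in range(cfg.n_genes % len(chroms)):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    counter = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        L = len(genome[chrom])
        lo, hi = cfg.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=k)
        usable = L - 2 * GENE_MARGIN
        needed = int(lengths.sum()) + (k - 1) * GENE_GAP
        free = usable - needed
        if free < 0:
            raise ConfigError(
                f"n_genes: chromosome {chrom} ({L} bp) cannot hold {k} genes"
            )
        gaps = _random_gaps(rng, free, k + 1)
        cursor = GENE_MARGIN + int(gaps[0])
        for j in range(k):
            counter += 1
            start = cursor  # 0-based
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(chrom, start, end, strand, f"gene{counter:04d}"))
            cursor = end + GENE_GAP + int(gaps[j + 1])
    return genes


# ------------------------------------------------------------ planted DMRs ---

def _subtract_intervals(
    length: int, occupied: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Complement of 1-based inclusive intervals within [1, length]."""
    segs = []
    cursor = 1
    for s, e in sorted(occupied):
        if s > cursor:
            segs.append((cursor, min(s - 1, length)))
        cursor = max(cursor, e + 1)
    if cursor <= length:
        segs.append((cursor, length))
    return [(s, e) for s, e in segs if e >= s]


def plant_dmrs(
    cfg: SimConfig, genome: dict[str, str], genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[list[PlantedDMR], list[str]]:
    """Choose planted DMR intervals for all three contexts.

    A pool of host genes supplies (gene, zone) slots — every host gene
    contributes its up2k, body and down2k once, so intervals never overlap —
    and the remaining DMRs go to intergenic gaps clear of all gene zones.
    Returns (planted DMRs, host gene ids).
    """
    n = cfg.n_planted_dmrs
    if n == 0:
        return [], []
    n_intergenic = round(INTERGENIC_FRACTION * n)
    n_hosted = n - n_intergenic
    if n_hosted > len(genes):
        raise ConfigError(
            f"n_planted_dmrs: need {n_hosted} host genes but only {len(genes)} exist"
        )
    order = list(rng.permutation(len(genes)))
    hosts = [genes[i] for i in order[:n_hosted]]
    slots = [(g, z) for g in hosts for z in ZONES]
    slots = [slots[i] for i in rng.permutation(len(slots))]

    lvl = {
        "CG": cfg.baseline_level_cg,
        "CHG": cfg.baseline_level_chg,
        "CHH": cfg.baseline_level_chh,
    }
    dlo, dhi = cfg.dmr_length_range
    planted: list[PlantedDMR] = []

    def levels(ctx: str) -> tuple[float, float]:
        c = lvl[ctx]
        return c, min(1.0, max(0.0, c + cfg.dmr_delta))

    for ci, ctx in enumerate(("CG", "CHG", "CHH")):
        for gene, zone in slots[ci * n_hosted : (ci + 1) * n_hosted]:
            zs, ze = gene.zone_interval(zone)
            span = ze - zs + 1
            dmr_len = int(min(rng.integers(dlo, dhi + 1), span))
            start = zs + int(rng.integers(0, span - dmr_len + 1))
            lc, lt = levels(ctx)
            planted.append(
                PlantedDMR(gene.chrom, start, start + dmr_len - 1, ctx, zone,
                           gene.gene_id, lc, lt)
            )

    # intergenic placements: gaps clear of every gene's zone extent
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for g in genes:
        occupied[g.chrom].append((max(1, g.start1 - 2000), g.end1 + 2000))
    for d in planted:
        occupied[d.chrom].append((d.start, d.end))
    segments = []
    for chrom in sorted(genome):
        for s, e in _subtract_intervals(len(genome[chrom]), occupied[chrom]):
            segments.append((chrom, s, e))
    for ctx in ("CG", "CHG", "CHH"):
        lc, lt = levels(ctx)
        for _ in range(n_intergenic):
            placed = False
            for _attempt in range(200):
                dmr_len = int(rng.integers(dlo, dhi + 1))
                need = dmr_len + 2 * INTERGENIC_MARGIN
                fits = [i for i, (c, s, e) in enumerate(segments) if e - s + 1 >= need]
                if not fits:
                    break
                i = int(rng.choice(fits))
                chrom, s, e = segments[i]
                start = s + INTERGENIC_MARGIN + int(
                    rng.integers(0, e - s + 1 - need + 1)
                )
                planted.append(
                    PlantedDMR(chrom, start, start + dmr_len - 1, ctx,
                               "intergenic", "", lc, lt)
                )
                # split the segment around the new DMR
                left = (chrom, s, start - 1)
                right = (chrom, start + dmr_len, e)
                segments[i : i + 1] = [
                    seg for seg in (left, right) if seg[2] - seg[1] + 1 > 0
                ]
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place an intergenic {ctx} DMR after bounded retries"
                )
    return planted, [g.gene_id for g in hosts]


# -------------------------------------------------------------- methylomes ---

def _place_domains(
    rng: np.random.Generator, length: int, baseline: float,
    exclusions: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Methylated-domain intervals (1-based inclusive) covering the fraction
    of the chromosome that makes the mean dyad methylation equal baseline."""
    if baseline <= DESERT_P or baseline >= DOMAIN_P:
        return []
    phi = (baseline - DESERT_P) / (DOMAIN_P - DESERT_P)
    domains = []
    for s, e in _subtract_intervals(length, exclusions):
        seg_len = e - s + 1
        k = min(seg_len // DOMAIN_LEN, round(phi * seg_len / DOMAIN_LEN))
        if k <= 0:
            continue
        free = seg_len - k * DOMAIN_LEN
        gaps = _random_gaps(rng, free, k + 1)
        cursor = s + int(gaps[0])
        for j in range(k):
            domains.append((cursor, cursor + DOMAIN_LEN - 1))
            cursor += DOMAIN_LEN + int(gaps[j + 1])
    return domains


def _in_intervals(pos: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for s, e in intervals:
        mask |= (pos >= s) & (pos <= e)
    return mask


def simulate_methylomes(
    cfg: SimConfig, genome: dict[str, str], genes: list[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame, list[PlantedDMR], list[str]]:
    """Two-condition cytosine reports with planted DMRs.

    Returns (control, treated, planted DMRs, host gene ids); the site tables
    carry every classifiable cytosine on both strands.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    planted, hosts = plant_dmrs(cfg, genome, genes, rng)
    lvl = {
        "CG": cfg.baseline_level_cg,
        "CHG": cfg.baseline_level_chg,
        "CHH": cfg.baseline_level_chh,
    }
    frames_c, frames_t = [], []
    for chrom in sorted(genome):
        seq = genome[chrom]
        sites = enumerate_cytosines(seq)
        pos = sites["pos"].to_numpy()
        strand = sites["strand"].to_numpy()
        ctx = sites["context"].to_numpy()
        true_c = np.zeros(len(sites))
        # CG background: shared dyad states in a domain/desert architecture
        cg_dmrs = [(d.start, d.end) for d in planted
                   if d.chrom == chrom and d.context == "CG"]
        excl = [(max(1, s - DMR_BUFFER), e + DMR_BUFFER) for s, e in cg_dmrs]
        domains = _place_domains(rng, len(seq), lvl["CG"], excl)
        b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        dyad0 = np.nonzero((b[:-1] == ord("C")) & (b[1:] == ord("G")))[0]
        dyad_pos = dyad0 + 1  # 1-based position of the plus-strand C
        if lvl["CG"] <= DESERT_P or lvl["CG"] >= DOMAIN_P:
            dyad_p = np.full(len(dyad_pos), lvl["CG"])
        else:
            in_dom = _in_intervals(dyad_pos, domains)
            dyad_p = np.where(in_dom, DOMAIN_P, DESERT_P)
        dyad_state = rng.random(len(dyad_pos)) < dyad_p
        state_by_pos = {}
        for dp, st in zip(dyad_pos, dyad_state):
            state_by_pos[(int(dp), "+")] = st
            state_by_pos[(int(dp) + 1, "-")] = st
        is_cg = ctx == "CG"
        cg_states = np.array(
            [state_by_pos.get((int(p), s), False)
             for p, s in zip(pos[is_cg], strand[is_cg])]
        )
        true_c[is_cg] = cg_states.astype(float)
        # CHG/CHH background: independent per-site states at the baseline
        for c in ("CHG", "CHH"):
            m = ctx == c
            true_c[m] = (rng.random(m.sum()) < lvl[c]).astype(float)
        true_t = true_c.copy()  # states shared between conditions
        # planted DMR overrides: continuous levels, independent read draws
        for d in planted:
            if d.chrom != chrom:
                continue
            m = (ctx == d.context) & (pos >= d.start) & (pos <= d.end)
            true_c[m] = d.level_control
            true_t[m] = d.level_treated
        err = cfg.bisulfite_error
        for true_lvl, frames in ((true_c, frames_c), (true_t, frames_t)):
            prob = true_lvl + (1.0 - true_lvl) * err
            if cfg.coverage_dispersion > 0:
                r = 1.0 / cfg.coverage_dispersion
                cov = rng.negative_binomial(
                    r, r / (r + cfg.mean_coverage), size=len(sites)
                )
            else:
                cov = rng.poisson(cfg.mean_coverage, size=len(sites))
            meth = rng.binomial(cov, prob)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "strand": strand,
                     "context": ctx, "meth_count": meth, "total_count": cov}
                )
            )
    control = pd.concat(frames_c, ignore_index=True)
    treated = pd.concat(frames_t, ignore_index=True)
    return control, treated, planted, hosts


# ----------------------------------------------------------------- variants ---

_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _make_variant(
    rng: np.random.Generator, seq: str, pos: int
) -> tuple[str, str]:
    """(ref, alt) at a 1-based position: 80% SNP, else 1-3 bp ins/del."""
    base = seq[pos - 1]
    if rng.random() < SNP_FRACTION:
        return base, _OTHER[base][int(rng.integers(0, 3))]
    size = int(rng.integers(1, 4))
    if rng.random() < 0.5 and pos + size <= len(seq):  # deletion
        return seq[pos - 1 : pos - 1 + size + 1], base
    ins = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=size))
    return base, base + ins


def simulate_variant_tables(
    cfg: SimConfig, genome: dict[str, str], genes: list[GeneModel]
) -> tuple[dict[str, list[dict]], SimTruth]:
    """Paired mucosa/muscularis variant rows per mouse, plus the truth keys.

    Germline variants appear in both tissues (AF 0.5 or 1.0) and always pass
    the depth/quality filters; somatic variants appear only in the mucosa
    with AF from ``somatic_af_range``, and a configurable fraction of them is
    deliberately pushed below the MQ>20 / DP>4 thresholds.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    chroms = sorted(genome)
    truth = SimTruth()
    tables: dict[str, list[dict]] = {}
    hotspot = []
    if genes and cfg.n_somatic_variants >= N_HOTSPOT_GENES:
        idx = rng.permutation(len(genes))[:N_HOTSPOT_GENES]
        hotspot = [genes[i] for i in sorted(idx)]

    def depth(rng: np.random.Generator) -> int:
        d = rng.negative_binomial(10, 10 / (10 + cfg.variant_mean_depth))
        return int(max(5, d))

    for m in range(1, cfg.n_mice + 1):
        used: set[tuple[str, int]] = set()

        def draw_pos(gene: GeneModel | None = None) -> tuple[str, int]:
            for _ in range(1000):
                if gene is not None:
                    chrom = gene.chrom
                    p = int(rng.integers(gene.start1, gene.end1 + 1))
                else:
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    p = int(rng.integers(2, len(genome[chrom]) - 4))
                if (chrom, p) not in used:
                    used.add((chrom, p))
                    return chrom, p
            raise PlacementError("could not place a variant after bounded retries")

        mucosa, muscularis = [], []
        germ_keys, som_keys, sub_keys = [], [], []
        for _ in range(cfg.n_germline_variants):
            chrom, p = draw_pos()
            ref, alt = _make_variant(rng, genome[chrom], p)
            af = 0.5 if rng.random() < 0.5 else 1.0
            key = (chrom, p, ref, alt)
            germ_keys.append(key)
            for table in (mucosa, muscularis):
                table.append(
                    {"chrom": chrom, "pos": p, "ref": ref, "alt": alt,
                     "depth": depth(rng),
                     "mapping_quality": float(rng.uniform(30, 60)),
                     "allele_fraction": af}
                )
        n_sub = round(cfg.subthreshold_fraction * cfg.n_somatic_variants)
        sub_idx = set(
            rng.permutation(cfg.n_somatic_variants)[:n_sub].tolist()
        ) if cfg.n_somatic_variants else set()
        for j in range(cfg.n_somatic_variants):
            gene = hotspot[j] if j < len(hotspot) else None
            chrom, p = draw_pos(gene)
            ref, alt = _make_variant(rng, genome[chrom], p)
            key = (chrom, p, ref, alt)
            som_keys.append(key)
            row = {"chrom": chrom, "pos": p, "ref": ref, "alt": alt,
                   "depth": depth(rng),
                   "mapping_quality": float(rng.uniform(30, 60)),
                   "allele_fraction": float(rng.uniform(*cfg.somatic_af_range))}
            if j in sub_idx:
                sub_keys.append(key)
                if rng.random() < 0.5:
                    row["mapping_quality"] = float(rng.uniform(5, 20))
                else:
                    row["depth"] = int(rng.integers(1, 5))
            mucosa.append(row)
        tables[f"mucosa_{m}"] = mucosa
        tables[f"muscularis_{m}"] = muscularis
        truth.germline_by_mouse[f"mouse_{m}"] = germ_keys
        truth.somatic_by_sample[f"mucosa_{m}"] = som_keys
        truth.subthreshold_by_sample[f"mucosa_{m}"] = sub_keys
    return tables, truth


# --------------------------------------------------------------- pathways ---

def build_pathway_map(
    cfg: SimConfig, genes: list[GeneModel], host_genes: list[str],
) -> tuple[pd.DataFrame, str]:
    """Gene->pathway map with one pathway over-represented among DMR hosts.

    Every gene gets one background pathway (P02..P10); the designated P01
    additionally contains >= ``HOST_PATHWAY_COVERAGE`` of the DMR-hosting
    genes plus a sprinkle of non-host genes.
    """
    rng = _rng(cfg, 4)
    if not genes:
        return pd.DataFrame(columns=iomod.PATHWAY_COLUMNS), DESIGNATED_PATHWAY
    names = {DESIGNATED_PATHWAY: "planted_signaling_pathway"}
    for i in range(2, N_PATHWAYS + 1):
        names[f"P{i:02d}"] = f"background_pathway_{i:02d}"
    rows = []
    background_ids = [f"P{i:02d}" for i in range(2, N_PATHWAYS + 1)]
    for g in genes:
        pid = background_ids[int(rng.integers(0, len(background_ids)))]
        rows.append({"gene_id": g.gene_id, "pathway_id": pid,
                     "pathway_name": names[pid]})
    hosts = sorted(set(host_genes))
    n_in = math.ceil(HOST_PATHWAY_COVERAGE * len(hosts))
    chosen = [hosts[i] for i in sorted(rng.permutation(len(hosts))[:n_in])]
    non_hosts = sorted(set(g.gene_id for g in genes) - set(hosts))
    n_extra = max(1, len(non_hosts) // 10) if non_hosts else 0
    extra = [non_hosts[i] for i in sorted(rng.permutation(len(non_hosts))[:n_extra])]
    for gid in chosen + extra:
        rows.append({"gene_id": gid, "pathway_id": DESIGNATED_PATHWAY,
                     "pathway_name": names[DESIGNATED_PATHWAY]})
    df = pd.DataFrame(rows, columns=iomod.PATHWAY_COLUMNS)
    df = df.drop_duplicates().sort_values(
        ["pathway_id", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    return df, DESIGNATED_PATHWAY


# ------------------------------------------------------------ orchestration ---

@dataclass
class SimulationResult:
    genome: dict[str, str]
    genes: list[GeneModel]
    control: pd.DataFrame
    treated: pd.DataFrame
    vcf_tables: dict[str, list[dict]]
    pathway_map: pd.DataFrame
    truth: SimTruth


def simulate_all(cfg: SimConfig, outdir: str | Path | None = None) -> SimulationResult:
    """Run every generator stage; optionally write all artifacts to ``outdir``."""
    cfg.validate()
    genome = generate_genome(cfg)
    genes = generate_gene_models(cfg, genome)
    control, treated, planted, hosts = simulate_methylomes(cfg, genome, genes)
    vcf_tables, truth = simulate_variant_tables(cfg, genome, genes)
    pathway_map, designated = build_pathway_map(cfg, genes, hosts)
    truth.planted_dmrs = planted
    truth.dmr_host_genes = hosts
    truth.enriched_pathway_id = designated
    result = SimulationResult(genome, genes, control, treated, vcf_tables,
                              pathway_map, truth)
    if outdir is not None:
        out = iomod.ensure_dir(outdir)
        iomod.write_fasta(genome, out / "genome.fa")
        iomod.write_gene_bed(genes, out / "genes.bed")
        iomod.write_cytosine_report(control, out / "control.cx.tsv")
        iomod.write_cytosine_report(treated, out / "treated.cx.tsv")
        contigs = {c: len(s) for c, s in genome.items()}
        for sample, rows in vcf_tables.items():
            iomod.write_vcf(rows, out / f"{sample}.vcf", contigs)
        iomod.write_pathway_map_tsv(pathway_map, out / "pathways.tsv")
        truth.to_json(out / "truth.json")
    return result
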