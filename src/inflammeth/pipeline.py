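"""End-to-end orchestration: simulate -> methylome -> dmr -> somatic -> enrich.

A single config (YAML or in-memory) drives every stage with one seed; each
stage logs record counts in/out, writes its tables under the run directory,
and registers output checksums in ``manifest.json`` so a rerun with the same
config reproduces identical files.  ``report`` renders the figure-level
tables (variant counts and frequency SUMs, mC-type ratios, DMR counts per
context and zone, top pathways) plus planted-truth recovery metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from . import somatic as som
from .dmrcall import DMRConfig, call_dmrs, write_dmr_bed, write_dmr_tsv
from .enrich import ZONES, assign_dmr_genes, enrich_zone_genes
from .methylome import (
    CONTEXTS,
    call_methylated_sites,
    chromosome_density,
    context_matrix_9bp,
    metagene_profile,
    summarize,
)
from .simdata import PlantedDMR, SimConfig, SimTruth, simulate_all

logger = logging.getLogger(__name__)

STAGES = ("simulate", "methylome", "dmr", "somatic", "enrich")


class PipelineValidationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class MethylomeParams:
    error_rate: float = 0.005
    alpha: float = 0.05
    min_call_coverage: int = 4
    density_window: int = 10_000
    flank: int = 2000
    bin_size: int = 100
    body_bins: int = 20


@dataclass
class SomaticParams:
    min_mq: float = 20.0
    min_depth: int = 4


@dataclass
class EnrichParams:
    method: str = "fdr_bh"
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    dmr: DMRConfig = field(default_factory=DMRConfig)
    methylome: MethylomeParams = field(default_factory=MethylomeParams)
    somatic: SomaticParams = field(default_factory=SomaticParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )

    def __post_init__(self) -> None:
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for name, klass in (
            ("sim", SimConfig), ("dmr", DMRConfig), ("methylome", MethylomeParams),
            ("somatic", SomaticParams), ("enrich", EnrichParams),
        ):
            block = raw.get(name, {})
            unknown = set(block) - {f.name for f in dataclasses.fields(klass)}
            if unknown:
                raise PipelineValidationError(
                    f"unknown keys in {name!r} block: {sorted(unknown)}"
                )
            # YAML lists become tuples where the dataclass expects pairs
            block = {
                k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
            }
            kwargs[name] = klass(**block)
        stages = {s: True for s in STAGES}
        stages.update(raw.get("stages", {}))
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise PipelineValidationError(f"unknown stages: {sorted(unknown)}")
        return cls(seed=int(raw.get("seed", 0)), stages=stages, **kwargs)

    def validate(self, run_dir: Path) -> None:
        self.sim.validate()
        if not self.stages.get("simulate", True):
            sim_dir = run_dir / "sim"
            needed = ["genome.fa", "genes.bed", "control.cx.tsv", "treated.cx.tsv"]
            missing = [f for f in needed if not (sim_dir / f).exists()]
            if missing:
                raise PipelineValidationError(
                    f"simulate stage disabled but inputs missing from {sim_dir}: {missing}"
                )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------- recovery oracle ---

def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def dmr_recovery(
    called: pd.DataFrame, planted: list[PlantedDMR], context: str | None = None
) -> tuple[float, float]:
    """(sensitivity, precision) by >=1 bp interval overlap, same context."""
    pl = [d for d in planted if context is None or d.context == context]
    ca = called if context is None else called.loc[called["context"] == context]
    if len(pl) == 0:
        sens = float("nan")
    else:
        hit = 0
        for d in pl:
            sub = ca.loc[(ca["chrom"] == d.chrom) & (ca["context"] == d.context)]
            if any(
                _interval_overlap((d.start, d.end), (int(r.start), int(r.end)))
                for r in sub.itertuples(index=False)
            ):
                hit += 1
        sens = hit / len(pl)
    if len(ca) == 0:
        prec = float("nan")
    else:
        good = 0
        for r in ca.itertuples(index=False):
            if any(
                d.chrom == r.chrom and d.context == r.context
                and _interval_overlap((d.start, d.end), (int(r.start), int(r.end)))
                for d in pl
            ):
                good += 1
        prec = good / len(ca)
    return sens, prec


def somatic_recovery(
    recovered_keys: set[tuple], truth: SimTruth, sample: str
) -> dict[str, float]:
    """Compare recovered somatic keys to the planted truth for one sample."""
    planted = set(truth.somatic_by_sample.get(sample, []))
    sub = set(truth.subthreshold_by_sample.get(sample, []))
    expected = planted - sub  # records designed to fail filters are not expected
    return {
        "n_planted": len(planted),
        "n_expected": len(expected),
        "n_recovered": len(recovered_keys),
        "n_correct": len(recovered_keys & planted),
        "exact": float(recovered_keys == expected),
    }


# ------------------------------------------------------------------ stages ---

def _stage_methylome(cfg: PipelineConfig, run_dir: Path, genes) -> dict:
    mp = cfg.methylome
    out = iomod.ensure_dir(run_dir / "methylome")
    genome = iomod.load_genome(run_dir / "sim" / "genome.fa")
    sizes = {c: len(s) for c, s in genome.items()}
    shares = {}
    for sample in ("control", "treated"):
        df = iomod.read_cytosine_report(run_dir / "sim" / f"{sample}.cx.tsv")
        flags = call_methylated_sites(
            df, mp.error_rate, mp.alpha, mp.min_call_coverage
        )
        summ = summarize(df, flags)
        summ.to_frame().to_csv(out / f"{sample}.summary.tsv", sep="\t", index=False)
        summ.chrom_mean_level.to_csv(out / f"{sample}.chrom_levels.tsv", sep="\t")
        chromosome_density(df, flags, mp.density_window, sizes).to_csv(
            out / f"{sample}.density.tsv", sep="\t", index=False
        )
        mats = context_matrix_9bp(genome, df, flags)
        for key in ("mcg", "cg"):
            pd.DataFrame(
                mats[key], index=list("ACGT"),
                columns=[str(o) for o in range(-4, 5)],
            ).to_csv(out / f"{sample}.matrix_{key}.tsv", sep="\t")
        metagene_profile(df, genes, mp.flank, mp.bin_size, mp.body_bins).to_csv(
            out / f"{sample}.metagene.tsv", sep="\t", index=False
        )
        shares[sample] = summ.mc_shares
        logger.info("methylome %s: %d sites, %d flagged", sample, len(df), flags.sum())
    return {"mc_shares": shares}


def _stage_dmr(cfg: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    out = iomod.ensure_dir(run_dir / "dmr")
    a = iomod.read_cytosine_report(run_dir / "sim" / "control.cx.tsv")
    b = iomod.read_cytosine_report(run_dir / "sim" / "treated.cx.tsv")
    dmrs, tally = call_dmrs(a, b, cfg.dmr)
    write_dmr_tsv(dmrs, out / "dmrs.tsv")
    write_dmr_bed(dmrs, out / "dmrs.bed")
    pd.DataFrame(
        sorted(tally.items()), columns=["reason", "count"]
    ).to_csv(out / "rejections.tsv", sep="\t", index=False)
    logger.info("dmr: %d DMRs, rejections %s", len(dmrs), tally)
    return dmrs


def _stage_somatic(cfg: PipelineConfig, run_dir: Path, genes) -> pd.DataFrame:
    out = iomod.ensure_dir(run_dir / "somatic")
    sp = cfg.somatic
    sim_dir = run_dir / "sim"
    rows = []
    gene_sets = {}
    for mucosa_path in sorted(sim_dir.glob("mucosa_*.vcf")):
        m = mucosa_path.stem.split("_")[1]
        musc_path = sim_dir / f"muscularis_{m}.vcf"
        mucosa, _ = som.read_variants(mucosa_path)
        muscularis, _ = som.read_variants(musc_path)
        mucosa_f = som.filter_variants(mucosa, sp.min_mq, sp.min_depth)
        musc_f = som.filter_variants(muscularis, sp.min_mq, sp.min_depth)
        somatic = som.subtract_germline(mucosa_f, musc_f)
        hit, _, n_inter = som.assign_genes(somatic, genes)
        sample = f"mucosa_{m}"
        gene_sets[sample] = hit
        summ = som.summarize_sample(somatic, sample, n_total=len(mucosa_f), gene_set=hit)
        rows.append(
            {"sample": sample, "n_total": summ.n_total, "n_somatic": summ.n_somatic,
             "n_snp": summ.n_snp, "n_indel": summ.n_indel,
             "freq_sum": summ.freq_sum, "n_genes": len(hit),
             "n_intergenic": n_inter}
        )
        pd.DataFrame(
            [{"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
              "vtype": v.vtype, "depth": v.depth, "mq": v.mapping_quality,
              "af": v.allele_fraction} for v in somatic]
        ).to_csv(out / f"somatic_{sample}.tsv", sep="\t", index=False)
    summaries = pd.DataFrame(rows)
    summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
    colitis = sorted(s for s in gene_sets if s != "mucosa_1")
    if len(colitis) >= 2:
        common = som.intersect_gene_sets([gene_sets[s] for s in colitis])
    else:
        common = []
    (out / "intersection_genes.txt").write_text("\n".join(common) + ("\n" if common else ""))
    logger.info("somatic: %d samples, %d intersected genes", len(rows), len(common))
    return summaries


def _stage_enrich(cfg: PipelineConfig, run_dir: Path, genes) -> None:
    out = iomod.ensure_dir(run_dir / "enrich")
    dmrs = pd.read_csv(run_dir / "dmr" / "dmrs.tsv", sep="\t")
    pathway_map = iomod.read_pathway_map(run_dir / "sim" / "pathways.tsv")
    zone_map, assignments = assign_dmr_genes(dmrs, genes)
    assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    background = set(pathway_map["gene_id"])
    all_genes = set().union(*zone_map.values()) if zone_map else set()
    for zone, hit in list(zone_map.items()) + [("combined", all_genes)]:
        res = enrich_zone_genes(
            hit, pathway_map, background, cfg.enrich.method, cfg.enrich.alpha
        )
        res.to_csv(out / f"enrichment_{zone}.tsv", sep="\t", index=False)
        (out / f"genes_{zone}.txt").write_text(
            "\n".join(sorted(hit)) + ("\n" if hit else "")
        )


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    run_dir = iomod.ensure_dir(outdir)
    config.validate(run_dir)
    manifest: dict = {"seed": config.seed, "stages": {}}
    genes = None

    def record(stage: str, params: dict) -> None:
        stage_dir = run_dir / ("sim" if stage == "simulate" else stage)
        files = {}
        if stage_dir.is_dir():
            for f in sorted(stage_dir.rglob("*")):
                if f.is_file():
                    files[str(f.relative_to(run_dir))] = _sha256(f)
        manifest["stages"][stage] = {"params": params, "files": files}

    if config.stages.get("simulate", True):
        try:
            simulate_all(config.sim, run_dir / "sim")
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        record("simulate", dataclasses.asdict(config.sim))
    genes = iomod.read_gene_bed(run_dir / "sim" / "genes.bed")
    if config.stages.get("methylome", True):
        try:
            _stage_methylome(config, run_dir, genes)
        except Exception as exc:
            raise StageError("methylome", exc) from exc
        record("methylome", dataclasses.asdict(config.methylome))
    if config.stages.get("dmr", True):
        try:
            _stage_dmr(config, run_dir)
        except Exception as exc:
            raise StageError("dmr", exc) from exc
        record("dmr", dataclasses.asdict(config.dmr))
    if config.stages.get("somatic", True):
        try:
            _stage_somatic(config, run_dir, genes)
        except Exception as exc:
            raise StageError("somatic", exc) from exc
        record("somatic", dataclasses.asdict(config.somatic))
    if config.stages.get("enrich", True):
        try:
            _stage_enrich(config, run_dir, genes)
        except Exception as exc:
            raise StageError("enrich", exc) from exc
        record("enrich", dataclasses.asdict(config.enrich))
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ------------------------------------------------------------------ report ---

def report(run_dir) -> str:
    """Summary document over a completed run directory (markdown, also
    written to ``report.md``); includes planted-truth recovery metrics."""
    run_dir = Path(run_dir)
    missing = [
        s for s, d in (("simulate", "sim"), ("methylome", "methylome"),
                       ("dmr", "dmr"), ("somatic", "somatic"), ("enrich", "enrich"))
        if not (run_dir / d).is_dir()
    ]
    lines = ["# Synthetic-cohort run report", ""]
    if missing:
        lines.append(f"Incomplete run; missing stages: {', '.join(missing)}")
        text = "\n".join(lines) + "\n"
        (run_dir / "report.md").write_text(text)
        return text
    truth = SimTruth.from_json(run_dir / "sim" / "truth.json")

    lines.append("## Somatic variants per sample")
    summaries = pd.read_csv(run_dir / "somatic" / "summaries.tsv", sep="\t")
    lines.append(summaries.to_string(index=False))
    inter = (run_dir / "somatic" / "intersection_genes.txt").read_text().split()
    lines.append("")
    lines.append(f"Genes with somatic variants shared by all colitis mice: {len(inter)}")

    lines.append("")
    lines.append("## mC type ratios")
    for sample in ("control", "treated"):
        s = pd.read_csv(run_dir / "methylome" / f"{sample}.summary.tsv", sep="\t")
        total = s["mc_count"].sum()
        shares = ", ".join(
            f"m{r.context} {100 * r.mc_share:.2f}%" for r in s.itertuples(index=False)
        )
        lines.append(f"- {sample}: {total} mC sites ({shares})")

    lines.append("")
    lines.append("## DMRs")
    dmrs = pd.read_csv(run_dir / "dmr" / "dmrs.tsv", sep="\t")
    counts = dmrs["context"].value_counts()
    lines.append(
        "Called DMRs: " + ", ".join(f"{c}: {int(counts.get(c, 0))}" for c in CONTEXTS)
    )
    assignments = pd.read_csv(run_dir / "enrich" / "assignments.tsv", sep="\t")
    zc = assignments["zone"].value_counts()
    lines.append(
        "DMR-zone assignments: "
        + ", ".join(f"{z}: {int(zc.get(z, 0))}" for z in list(ZONES) + ["intergenic"])
    )
    lines.append("")
    lines.append("### Planted-truth recovery")
    for ctx in CONTEXTS:
        sens, prec = dmr_recovery(dmrs, truth.planted_dmrs, ctx)
        n = sum(1 for d in truth.planted_dmrs if d.context == ctx)
        lines.append(
            f"- {ctx}: {n} planted, sensitivity {sens:.3f}, precision {prec:.3f}"
        )

    lines.append("")
    lines.append("## Somatic-truth recovery")
    for sample in sorted(truth.somatic_by_sample):
        path = run_dir / "somatic" / f"somatic_{sample}.tsv"
        rec = pd.read_csv(path, sep="\t") if path.stat().st_size > 1 else pd.DataFrame()
        keys = (
            {(r.chrom, int(r.pos), r.ref, r.alt) for r in rec.itertuples(index=False)}
            if len(rec) else set()
        )
        m = somatic_recovery(keys, truth, sample)
        lines.append(
            f"- {sample}: planted {m['n_planted']}, expected after filters "
            f"{m['n_expected']}, recovered {m['n_recovered']} "
            f"({m['n_correct']} correct), exact={bool(m['exact'])}"
        )

    lines.append("")
    lines.append("## Top enriched pathways (combined zones)")
    enr = pd.read_csv(run_dir / "enrich" / "enrichment_combined.tsv", sep="\t")
    lines.append(enr.head(20).to_string(index=False))
    lines.append("")
    lines.append(f"Planted pathway: {truth.enriched_pathway_id}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
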