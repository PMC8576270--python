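"""Generator properties: determinism, placement constraints, planted truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from inflammeth import io as iomod
from inflammeth.simdata import (
    ConfigError,
    SimConfig,
    build_pathway_map,
    generate_gene_models,
    generate_genome,
    simulate_all,
    simulate_methylomes,
    simulate_variant_tables,
)


def test_genome_deterministic_by_seed(tmp_path):
    cfg = SimConfig(n_chroms=1, chrom_length=12_000, seed=1)
    g1 = generate_genome(cfg)
    g2 = generate_genome(cfg)
    assert g1 == g2
    iomod.write_fasta(g1, tmp_path / "a.fa")
    iomod.write_fasta(g2, tmp_path / "b.fa")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


def test_genome_gc_boundary_and_target():
    only_at = generate_genome(SimConfig(n_chroms=1, chrom_length=12_000, gc_fraction=0.0, seed=2))
    assert set(only_at["chr1"]) <= {"A", "T"}
    g = generate_genome(SimConfig(n_chroms=1, chrom_length=100_000, gc_fraction=0.5, seed=3))
    gc = sum(g["chr1"].count(b) for b in "GC") / len(g["chr1"])
    # binomial: sd of the GC fraction at n=1e5 is ~0.0016, so +-0.01 is ~6 sd
    assert 0.49 <= gc <= 0.51


def test_gene_models_nonoverlapping_with_flank_margins():
    cfg = SimConfig(n_chroms=1, chrom_length=1_000_000, n_genes=10, seed=4)
    genome = generate_genome(cfg)
    genes = generate_gene_models(cfg, genome)
    assert len(genes) == 10
    # brute-force pairwise interval check
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            assert a.end <= b.start or b.end <= a.start
    for g in genes:
        assert g.start >= 2000
        assert g.end <= cfg.chrom_length - 2000
    assert {g.strand for g in genes} == {"+", "-"}


def test_zero_genes_gives_empty_bed(tmp_path):
    cfg = SimConfig(n_chroms=1, chrom_length=50_000, n_genes=0,
                    n_planted_dmrs=0, n_somatic_variants=0, seed=5)
    genes = generate_gene_models(cfg, generate_genome(cfg))
    assert genes == []
    iomod.write_gene_bed(genes, tmp_path / "g.bed")
    assert (tmp_path / "g.bed").read_text() == ""


def test_gene_capacity_error():
    cfg = SimConfig(n_chroms=1, chrom_length=50_000, n_genes=50, seed=6)
    with pytest.raises(ConfigError, match="n_genes"):
        generate_gene_models(cfg, generate_genome(cfg))


def test_config_validation_names_offending_field():
    with pytest.raises(ConfigError, match="gc_fraction"):
        SimConfig(gc_fraction=1.5).validate()
    with pytest.raises(ConfigError, match="dmr_length_range"):
        SimConfig(dmr_length_range=(10, 500)).validate()
    with pytest.raises(ConfigError, match="chrom_length"):
        SimConfig(chrom_length=7000, gene_length_range=(2000, 6000)).validate()


def test_methylome_mean_recovers_baseline():
    # binomial-mean oracle: with >=1e4 CG sites the mean observed level sits
    # within +-0.01 of the configured baseline (sd of the mean ~0.005)
    cfg = SimConfig(n_chroms=1, chrom_length=120_000, n_genes=0,
                    n_planted_dmrs=0, baseline_level_cg=0.7, seed=7)
    genome = generate_genome(cfg)
    control, _, _, _ = simulate_methylomes(cfg, genome, [])
    cg = control[(control.context == "CG") & (control.total_count > 0)]
    assert len(cg) > 10_000
    mean = (cg.meth_count / cg.total_count).mean()
    assert 0.69 <= mean <= 0.71


def test_null_delta_gives_identical_site_expectations(tiny_cfg):
    cfg = dataclasses.replace(tiny_cfg, dmr_delta=0.0, seed=8)
    genome = generate_genome(cfg)
    genes = generate_gene_models(cfg, genome)
    control, treated, planted, _ = simulate_methylomes(cfg, genome, genes)
    for d in planted:
        assert d.level_control == d.level_treated
    # genome-wide means agree to sampling error
    for df_a, df_b in [(control, treated)]:
        for ctx in ("CG", "CHG", "CHH"):
            a = df_a[(df_a.context == ctx) & (df_a.total_count > 0)]
            b = df_b[(df_b.context == ctx) & (df_b.total_count > 0)]
            ma = (a.meth_count / a.total_count).mean()
            mb = (b.meth_count / b.total_count).mean()
            assert abs(ma - mb) < 0.01


def test_planted_dmrs_satisfy_construction_invariants(default_sim):
    planted = default_sim.truth.planted_dmrs
    genes = {g.gene_id: g for g in default_sim.genes}
    intervals = [(d.chrom, d.start, d.end) for d in planted]
    for i, (c1, s1, e1) in enumerate(intervals):
        for c2, s2, e2 in intervals[i + 1 :]:
            assert not (c1 == c2 and s1 <= e2 and s2 <= e1), "planted DMRs overlap"
    for d in planted:
        assert 40 <= d.end - d.start + 1 <= 10_000
        # fold change of the true levels exceeds the caller's threshold
        assert d.level_treated / d.level_control > 2
        if d.zone != "intergenic":
            zs, ze = genes[d.gene_id].zone_interval(d.zone)
            assert zs <= d.start and d.end <= ze, "DMR escapes its recorded zone"


def test_variant_conservation_and_pairing(tiny_cfg):
    cfg = dataclasses.replace(tiny_cfg, subthreshold_fraction=0.0, seed=9)
    genome = generate_genome(cfg)
    genes = generate_gene_models(cfg, genome)
    tables, truth = simulate_variant_tables(cfg, genome, genes)
    for m in range(1, cfg.n_mice + 1):
        muc = {(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in tables[f"mucosa_{m}"]}
        mus = {(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in tables[f"muscularis_{m}"]}
        germ = set(truth.germline_by_mouse[f"mouse_{m}"])
        som = set(truth.somatic_by_sample[f"mucosa_{m}"])
        assert muc == germ | som and not (germ & som)
        assert mus == germ
        assert som.isdisjoint(mus)
    vtypes = {("SNP" if len(r["ref"]) == len(r["alt"]) == 1 else "InDel")
              for r in tables["mucosa_1"]}
    assert vtypes == {"SNP", "InDel"}


def test_zero_somatic_gives_identical_tissues(tiny_cfg):
    cfg = dataclasses.replace(tiny_cfg, n_somatic_variants=0, seed=10)
    genome = generate_genome(cfg)
    tables, _ = simulate_variant_tables(cfg, genome, [])
    muc = {(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in tables["mucosa_1"]}
    mus = {(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in tables["muscularis_1"]}
    assert muc == mus


def test_pathway_map_structure(default_sim, tmp_path):
    pm = default_sim.pathway_map
    truth = default_sim.truth
    all_genes = {g.gene_id for g in default_sim.genes}
    assert set(pm["gene_id"]) == all_genes  # every gene has >=1 pathway
    designated = set(pm.loc[pm.pathway_id == truth.enriched_pathway_id, "gene_id"])
    hosts = set(truth.dmr_host_genes)
    assert len(designated & hosts) / len(hosts) >= 0.8
    # round-trip through the reader
    iomod.write_pathway_map_tsv(pm, tmp_path / "p.tsv")
    back = iomod.read_pathway_map(tmp_path / "p.tsv")
    pd.testing.assert_frame_equal(back, pm[iomod.PATHWAY_COLUMNS].reset_index(drop=True))


def test_simulation_outputs_byte_identical_across_runs(tiny_cfg, tmp_path):
    simulate_all(tiny_cfg, tmp_path / "a")
    simulate_all(tiny_cfg, tmp_path / "b")
    files_a = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*"))
    files_b = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*"))
    assert files_a == files_b and files_a
    for rel in files_a:
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
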