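"""DMR caller: chaining, criterion checks, calibration, symmetry."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inflammeth.dmrcall import (
    CandidateRegion,
    DMRConfig,
    build_candidate_regions,
    call_dmrs,
    evaluate_region,
    merge_samples,
    pearson_chi2_2x2,
)
from inflammeth.methylome import call_methylated_sites


def merged_frame(pos, meth_a, tot_a, meth_b, tot_b, flag_a, flag_b, context="CG"):
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "pos": pos,
            "strand": ["+"] * n,
            "context": [context] * n,
            "meth_count_a": meth_a,
            "total_count_a": tot_a,
            "flag_a": flag_a,
            "meth_count_b": meth_b,
            "total_count_b": tot_b,
            "flag_b": flag_b,
        }
    )


def seeds_frame(positions, context="CG"):
    n = len(positions)
    return merged_frame(
        positions, [12] * n, [15] * n, [2] * n, [15] * n,
        [True] * n, [False] * n, context,
    )


def test_chaining_hand_trace():
    # gaps: 150 (<200, chains), 350 (breaks); singleton span 1 < 40 dropped
    regions = build_candidate_regions(seeds_frame([100, 250, 600]), DMRConfig(), "CG")
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.span, r.n_sites) == (100, 250, 151, 2)


def test_no_candidates_when_gaps_exceed_max_gap():
    regions = build_candidate_regions(seeds_frame([100, 300, 500]), DMRConfig(), "CG")
    assert regions == []


def test_overlong_chain_discarded_not_split():
    positions = list(range(100, 15_000, 150))  # one chain spanning ~15 kb
    regions = build_candidate_regions(seeds_frame(positions), DMRConfig(), "CG")
    assert regions == []


def test_coverage_and_meth_read_screens_drop_sites():
    cfg = DMRConfig()
    df = merged_frame(
        pos=[100, 150, 200],
        meth_a=[12, 12, 3], tot_a=[15, 8, 15],
        meth_b=[2, 2, 2], tot_b=[15, 15, 15],
        flag_a=[True, True, True], flag_b=[False, False, False],
    )
    # site 150: coverage 8 < 10 in sample A; site 200: flagged with 3 < 4 meth reads
    regions = build_candidate_regions(df, cfg, "CG")
    assert regions == []  # only pos 100 survives -> singleton below min_len


def region_from(meth_a, tot_a, meth_b, tot_b, n_sites=6, flags=("a",)):
    """Candidate with pooled counts split evenly over n_sites."""
    pos = np.arange(100, 100 + 50 * n_sites, 50)
    return CandidateRegion(
        chrom="chr1", start=int(pos[0]), end=int(pos[-1]), context="CG",
        pos=pos,
        meth_a=np.full(n_sites, meth_a // n_sites),
        total_a=np.full(n_sites, tot_a // n_sites),
        meth_b=np.full(n_sites, meth_b // n_sites),
        total_b=np.full(n_sites, tot_b // n_sites),
        flag_a=np.full(n_sites, "a" in flags),
        flag_b=np.full(n_sites, "b" in flags),
    )


def test_chi2_oracle_2x2():
    chi2, p = pearson_chi2_2x2(90, 10, 20, 80)
    assert chi2 == pytest.approx(98.98989898989899, rel=1e-12)
    ref = stats.chi2_contingency([[90, 10], [20, 80]], correction=False)
    assert chi2 == pytest.approx(ref[0]) and p == pytest.approx(ref[1])


def test_evaluate_region_accepts_strong_dmr():
    # pooled 90/100 vs 20/100: levels 0.9/0.2, fold 4.5, chi2 ~98.99
    reg = region_from(90, 100, 20, 100, n_sites=5)
    rec, reason = evaluate_region(reg, DMRConfig())
    assert reason == "accepted"
    assert rec.level_a == pytest.approx(0.9)
    assert rec.level_b == pytest.approx(0.2)
    assert rec.fold_change == pytest.approx(4.5)
    assert rec.chi2 == pytest.approx(98.9899, abs=1e-3)
    assert rec.p < 0.05 and rec.direction == -1


def test_evaluate_region_rejections():
    cfg = DMRConfig()
    # identical pooled counts: fold 1
    rec, reason = evaluate_region(region_from(50, 100, 50, 100), cfg)
    assert rec is None and reason == "fold_change"
    # <5 methylated cytosines in both samples, rejected regardless of fold
    reg = region_from(90, 100, 20, 100, n_sites=6)
    reg.flag_a[:] = False
    reg.flag_a[:3] = True
    reg.flag_b[:] = False
    reg.flag_b[:3] = True
    rec, reason = evaluate_region(reg, cfg)
    assert rec is None and reason == "min_meth_sites"
    # zero coverage in one sample is a rejection code, not an exception
    reg = region_from(90, 100, 0, 0, n_sites=5)
    rec, reason = evaluate_region(reg, cfg)
    assert rec is None and reason == "zero_coverage"


def test_zero_denominator_fold_rule():
    # min level 0 with max > 0: the fold criterion passes by the zero rule
    reg = region_from(60, 100, 0, 100, n_sites=5)
    rec, reason = evaluate_region(reg, DMRConfig())
    assert reason == "accepted"
    assert rec.fold_change == np.inf and rec.level_b == 0.0


def test_sample_against_itself_yields_no_dmrs(tiny_sim):
    dmrs, _ = call_dmrs(tiny_sim.control, tiny_sim.control, DMRConfig())
    assert len(dmrs) == 0


def test_swap_symmetry(tiny_sim):
    cfg = DMRConfig()
    ab, _ = call_dmrs(tiny_sim.control, tiny_sim.treated, cfg)
    ba, _ = call_dmrs(tiny_sim.treated, tiny_sim.control, cfg)
    assert len(ab) > 0
    key_cols = ["chrom", "start", "end", "context", "n_sites"]
    pd.testing.assert_frame_equal(ab[key_cols], ba[key_cols])
    assert (ab["direction"].to_numpy() == -ba["direction"].to_numpy()).all()
    np.testing.assert_allclose(ab["fold_change"], ba["fold_change"])


def test_threshold_monotonicity(tiny_sim):
    base = DMRConfig()
    n0 = len(call_dmrs(tiny_sim.control, tiny_sim.treated, base)[0])
    stricter_fold = dataclasses.replace(base, min_fold=3.0)
    stricter_p = dataclasses.replace(base, max_p=0.001)
    assert len(call_dmrs(tiny_sim.control, tiny_sim.treated, stricter_fold)[0]) <= n0
    assert len(call_dmrs(tiny_sim.control, tiny_sim.treated, stricter_p)[0]) <= n0


def random_site_tables(rng, n_sites=120, planted=True):
    """Two small site tables on one chromosome with random counts."""
    pos = np.sort(rng.choice(np.arange(10, 20_000), size=n_sites, replace=False))
    ctx = rng.choice(["CG", "CHG", "CHH"], size=n_sites, p=[0.5, 0.2, 0.3])
    base = rng.uniform(0.0, 0.4, size=n_sites)
    lvl_a = base.copy()
    lvl_b = base.copy()
    if planted:
        lo, hi = sorted(rng.choice(pos, size=2, replace=False))
        lvl_b = np.where((pos >= lo) & (pos <= hi), np.clip(base + 0.5, 0, 1), base)
    rows = []
    for lvl in (lvl_a, lvl_b):
        cov = rng.poisson(25, size=n_sites)
        meth = rng.binomial(cov, lvl)
        rows.append(pd.DataFrame({
            "chrom": "chr1", "pos": pos, "strand": "+", "context": ctx,
            "meth_count": meth, "total_count": cov,
        }))
    return rows[0], rows[1]


def check_record_against_all_criteria(rec, merged, cfg):
    """Recompute every criterion for one emitted DMR from the raw site data."""
    sub = merged[(merged.chrom == rec.chrom) & (merged.context == rec.context)
                 & (merged.pos >= rec.start) & (merged.pos <= rec.end)]
    cov_ok = (sub.total_count_a >= cfg.min_site_coverage) & \
             (sub.total_count_b >= cfg.min_site_coverage)
    meth_ok = (~sub.flag_a | (sub.meth_count_a >= cfg.min_meth_reads)) & \
              (~sub.flag_b | (sub.meth_count_b >= cfg.min_meth_reads))
    seeds = sub[(sub.flag_a | sub.flag_b) & cov_ok & meth_ok]
    # criterion 1: >= min_meth_sites methylated cytosines in >= 1 sample
    assert max(seeds.flag_a.sum(), seeds.flag_b.sum()) >= cfg.min_meth_sites
    # criterion 2 is enforced by the seed screen above (non-empty match)
    assert len(seeds) == rec.n_sites
    # criterion 3: length window
    assert cfg.min_len <= rec.end - rec.start + 1 <= cfg.max_len
    # criterion 4: adjacent methylated sites < max_gap apart
    gaps = np.diff(np.sort(seeds.pos.to_numpy()))
    assert (gaps < cfg.max_gap).all()
    # criterion 5: fold change of pooled levels > min_fold (zero rule allowed)
    la = seeds.meth_count_a.sum() / seeds.total_count_a.sum()
    lb = seeds.meth_count_b.sum() / seeds.total_count_b.sum()
    lo, hi = min(la, lb), max(la, lb)
    assert (lo == 0 and hi > 0) or hi / lo > cfg.min_fold
    # criterion 6: Pearson chi-square p <= max_p (independent scipy route)
    table = [[seeds.meth_count_a.sum(), seeds.total_count_a.sum() - seeds.meth_count_a.sum()],
             [seeds.meth_count_b.sum(), seeds.total_count_b.sum() - seeds.meth_count_b.sum()]]
    p = stats.chi2_contingency(table, correction=False)[1]
    assert p <= cfg.max_p
    assert rec.p == pytest.approx(p, rel=1e-9)


def test_every_emitted_dmr_satisfies_all_six_criteria_fuzzed():
    rng = np.random.default_rng(99)
    cfg = DMRConfig()
    n_emitted = 0
    for trial in range(100):
        a, b = random_site_tables(rng, planted=trial % 2 == 0)
        dmrs, _ = call_dmrs(a, b, cfg)
        if not len(dmrs):
            continue
        fa = call_methylated_sites(a, cfg.error_rate, cfg.alpha, cfg.min_call_coverage)
        fb = call_methylated_sites(b, cfg.error_rate, cfg.alpha, cfg.min_call_coverage)
        merged = merge_samples(a, b, fa, fb)
        for rec in dmrs.itertuples(index=False):
            check_record_against_all_criteria(rec, merged, cfg)
            n_emitted += 1
    assert n_emitted > 0  # the fuzz actually exercised acceptances


def test_mismatched_chromosomes_rejected():
    a = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "strand": ["+"],
                      "context": ["CG"], "meth_count": [1], "total_count": [2]})
    b = a.assign(chrom="chr2")
    with pytest.raises(ValueError, match="chromosome"):
        merge_samples(a, b, np.array([False]), np.array([False]))


def test_config_validation():
    with pytest.raises(ValueError):
        DMRConfig(min_len=500, max_len=40)
    with pytest.raises(ValueError):
        DMRConfig(max_gap=0)
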