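"""RT-stop peak calling, NB differential test, region classification."""

import numpy as np
import pandas as pd
import pytest

from g4coop.rtstop_rg4 import (
    RTstopPeak,
    classify_regions,
    differential_rg4_test,
    filter_constructs,
    find_seeds,
    merge_condition_peaks,
    nb_wald_test,
    peaks_from_seeds,
    propensity,
    run_rtstop_pipeline,
    size_factors,
)
from g4coop.synthetic_data import SimulationConfig, gen_oligo_library, gen_rtstop_counts


def _track(**positions):
    t = np.zeros(200)
    for pos, count in positions.items():
        t[int(pos[1:]) - 1] = count
    return t


# ---------------------------------------------------------------------------
# seeds and peaks


def test_seed_rules():
    assert find_seeds(np.zeros(200)) == []
    assert find_seeds(_track(p10=100)) == []          # 5' exclusion zone
    assert find_seeds(_track(p30=6)) == [30]
    assert find_seeds(_track(p30=5)) == []


def test_peak_requires_two_covered_positions():
    track = _track(p30=8, p31=2)
    peaks = peaks_from_seeds([30], track)
    assert [(p.start, p.end) for p in peaks] == [(29, 31)]
    isolated = _track(p40=9)
    assert peaks_from_seeds([40], isolated) == []


def test_close_seeds_resolved_by_signal():
    """Of two seeds 2 nt apart the stronger claims the window."""
    track = _track(p30=10, p32=7, p31=1)
    peaks = peaks_from_seeds([30, 32], track)
    assert len(peaks) == 1
    assert peaks[0].start == 29 and peaks[0].end == 31


def test_peaks_clamped_inside_19_200():
    track = np.zeros(200)
    track[18] = 10   # position 19
    track[19] = 3
    peaks = peaks_from_seeds([19], track)
    assert peaks[0].start == 19
    track2 = np.zeros(200)
    track2[199] = 10
    track2[198] = 3
    peaks2 = peaks_from_seeds([200], track2)
    assert peaks2[0].end == 200


def test_merge_identical_and_disjoint_peaks():
    track = np.zeros(200)
    track[28:31] = [5, 9, 5]
    a = RTstopPeak("c", 29, 31)
    b = RTstopPeak("c", 29, 31)
    assert len(merge_condition_peaks([a], [b], track)) == 1
    far = RTstopPeak("c", 50, 52)
    track[49:52] = 4
    merged = merge_condition_peaks([a], [far], track)
    assert [(p.start, p.end) for p in merged] == [(29, 31), (50, 52)]


def test_merge_partial_overlap_recenters_on_combined_maximum():
    track = np.zeros(200)
    track[28:32] = [2, 5, 9, 4]        # combined max at position 31
    merged = merge_condition_peaks([RTstopPeak("c", 29, 31)],
                                   [RTstopPeak("c", 30, 32)], track)
    assert [(p.start, p.end) for p in merged] == [(30, 32)]


# ---------------------------------------------------------------------------
# filters and differential testing


def test_size_factors_median_of_ratios():
    totals = pd.DataFrame({"a": [100, 200, 400], "b": [200, 400, 800]},
                          index=["c1", "c2", "c3"])
    sf = size_factors(totals)
    assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-12)


def test_filter_drops_shallow_and_condition_variable_constructs():
    rng = np.random.default_rng(0)
    n = 40
    base = rng.integers(800, 1200, size=n).astype(float)
    cols = {}
    condition_of = {}
    for cond in ("KCl", "NaCl"):
        for rep in range(3):
            name = f"{cond}_{rep + 1}"
            condition_of[name] = cond
            vals = base * rng.normal(1.0, 0.05, size=n)
            cols[name] = np.round(vals)
    totals = pd.DataFrame(cols, index=[f"c{i}" for i in range(n)])
    # c0: shallow; c1: 4-fold higher in KCl with tight replicates
    totals.loc["c0"] = 50
    for name in condition_of:
        totals.loc["c1", name] = 4000 if condition_of[name] == "KCl" else 1000
    kept = filter_constructs(totals, condition_of)
    assert "c0" not in kept
    assert "c1" not in kept
    assert len(kept) >= n - 4


def test_nb_wald_power_and_sign():
    """KCl 50 vs NaCl 5 at dispersion 0.1 is detected >= 95% of the time."""
    rng = np.random.default_rng(3)
    ones = np.ones(3)
    hits = 0
    n_sim = 200
    for _ in range(n_sim):
        kcl = rng.negative_binomial(10, 10 / (10 + 50), size=3)
        nacl = rng.negative_binomial(10, 10 / (10 + 5), size=3)
        l2fc, _, p = nb_wald_test(kcl, nacl, ones, ones)
        if p < 0.05 and l2fc < 0:
            hits += 1
    assert hits / n_sim >= 0.95


def test_nb_wald_type_i_error_controlled():
    """Null rG4-call rate (padj < 0.05 and negative shrunken L2FC) <= 5%."""
    rng = np.random.default_rng(7)
    n_peaks = 1000
    counts = pd.DataFrame(
        rng.negative_binomial(5, 5 / (5 + 30), size=(n_peaks, 6)),
        columns=["KCl_1", "KCl_2", "KCl_3", "NaCl_1", "NaCl_2", "NaCl_3"])
    condition_of = {c: c.split("_")[0] for c in counts.columns}
    res = differential_rg4_test(counts, condition_of)
    assert res["is_rg4"].mean() <= 0.05


def test_differential_requires_negative_shrunken_l2fc():
    """A NaCl > KCl change, however significant, is not an rG4 call."""
    counts = pd.DataFrame({"KCl_1": [5], "KCl_2": [6], "KCl_3": [4],
                           "NaCl_1": [400], "NaCl_2": [420], "NaCl_3": [390]})
    condition_of = {c: c.split("_")[0] for c in counts.columns}
    res = differential_rg4_test(counts, condition_of)
    assert res["padj"].iloc[0] < 0.05
    assert not res["is_rg4"].iloc[0]


def test_all_zero_peak_not_tested():
    counts = pd.DataFrame({"KCl_1": [0, 10], "KCl_2": [0, 12],
                           "NaCl_1": [0, 11], "NaCl_2": [0, 9]})
    condition_of = {c: c.split("_")[0] for c in counts.columns}
    res = differential_rg4_test(counts, condition_of)
    assert np.isnan(res["p"].iloc[0])
    assert not res["is_rg4"].iloc[0]


def test_differential_calls_concordant_with_deseq2():
    """rG4 calls agree with an independent DESeq2 analysis of the same peaks."""
    import warnings

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(5)
    n = 60
    mu_kcl = rng.uniform(20, 200, n)
    fold = np.ones(n)
    fold[:20] = 0.15                       # true rG4 peaks: signal lost in NaCl
    mu_nacl = mu_kcl * fold

    def nb(mu):
        r = 10.0
        return rng.negative_binomial(r, r / (r + mu), size=n)

    cols = {f"{cond}_{i + 1}": nb(mu_kcl if cond == "KCl" else mu_nacl)
            for cond in ("KCl", "NaCl") for i in range(3)}
    counts = pd.DataFrame(cols, index=[f"p{i}" for i in range(n)])
    condition_of = {c: c.split("_")[0] for c in counts.columns}

    mine = differential_rg4_test(counts, condition_of)
    my_calls = ((mine["padj"] < 0.05) & (mine["l2fc_shrunk"] < 0)).to_numpy()

    meta = pd.DataFrame({"condition": [condition_of[c] for c in counts.columns]},
                        index=counts.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "NaCl", "KCl"], quiet=True)
        ds.summary()
    ref = ds.results_df
    ref_calls = ((ref["padj"] < 0.05) & (ref["log2FoldChange"] < 0)).to_numpy()

    assert (my_calls == ref_calls).mean() >= 0.9
    assert my_calls[:20].mean() >= 0.9         # true peaks found by both
    assert my_calls[20:].mean() <= 0.1


# ---------------------------------------------------------------------------
# region classification and propensity


@pytest.mark.parametrize("flags,expected", [
    ((True, True, False, False), "rG4"),
    ((True, False, False, False), "inconsistent"),
    ((False, False, False, False), "non_rG4"),
    ((True, True, True, True), "rG4"),
])
def test_region_classification_rules(flags, expected):
    df = pd.DataFrame({
        "region_id": "r1",
        "construct_id": [f"c{i}" for i in range(4)],
        "is_rg4": flags,
        "total_reads": [10, 40, 20, 30],
    })
    (cls,) = classify_regions(df)
    assert cls.status == expected
    assert cls.representative_construct == "c1"   # highest read count


def test_propensity_arithmetic():
    track = np.zeros(200)
    track[:] = 0
    track[29:32] = [5, 10, 5]      # peak 30..32: 20 of 100 reads
    track[0] = 80
    peak = RTstopPeak("c", 30, 32)
    scores = propensity("c", [peak], {(30, 32): True}, track)
    assert scores.peak_ratios[(30, 32)] == pytest.approx(0.2)
    assert scores.g4_propensity == pytest.approx(0.2)
    assert scores.total_construct_ratio == pytest.approx(0.2)


def test_propensity_two_rg4_peaks():
    track = np.zeros(200)
    track[0] = 70
    track[29:32] = [5, 10, 5]    # ratio 0.2
    track[59:62] = [3, 4, 3]     # ratio 0.1
    peaks = [RTstopPeak("c", 30, 32), RTstopPeak("c", 60, 62)]
    scores = propensity("c", peaks, {(30, 32): True, (60, 62): True}, track)
    assert scores.g4_propensity == pytest.approx(0.3)
    assert scores.total_construct_ratio == pytest.approx(0.15)
    assert scores.representative_peak == (30, 32)


def test_propensity_no_peaks_is_zero():
    scores = propensity("c", [], {}, np.ones(200))
    assert scores.g4_propensity == 0.0 and scores.total_construct_ratio == 0.0


def test_propensity_scale_invariant():
    track = np.zeros(200)
    track[0] = 80
    track[29:32] = [5, 10, 5]
    peak = RTstopPeak("c", 30, 32)
    a = propensity("c", [peak], {(30, 32): True}, track)
    b = propensity("c", [peak], {(30, 32): True}, track * 7.5)
    assert a.g4_propensity == pytest.approx(b.g4_propensity)


# ---------------------------------------------------------------------------
# end-to-end recovery on synthetic libraries


def _pipeline_counts(cfg, manifest):
    counts = {}
    for salt in ("KCl", "NaCl"):
        per = gen_rtstop_counts(manifest, cfg, (salt, "GTP"))
        for cid, mat in per.items():
            counts.setdefault(cid, {})[salt] = mat
    return counts


def test_end_to_end_recovery_rate():
    """>= 90% of planted rG4 regions recovered, <= 5% false region calls."""
    tp = fp = n_rg4 = n_ctrl = 0
    for seed in (101, 202):
        cfg = SimulationConfig(seed=seed, n_regions=15, rg4_fraction=0.5,
                               background_rate=1.0, stall_intensity=50.0,
                               five_prime_intensity=30.0)
        _, manifest = gen_oligo_library(cfg)
        _, regions = run_rtstop_pipeline(_pipeline_counts(cfg, manifest), manifest)
        truth = manifest.groupby("region_id")["has_rg4"].any()
        for r in regions:
            if truth[r.region_id]:
                n_rg4 += 1
                tp += r.status == "rG4"
            else:
                n_ctrl += 1
                fp += r.status == "rG4"
    assert tp / n_rg4 >= 0.90
    assert fp / n_ctrl <= 0.05


def test_null_library_type_i_control():
    """With stall_intensity = 0 almost no region is called rG4."""
    cfg = SimulationConfig(seed=77, n_regions=20, rg4_fraction=0.5,
                           background_rate=1.5, stall_intensity=0.0,
                           five_prime_intensity=30.0)
    _, manifest = gen_oligo_library(cfg)
    _, regions = run_rtstop_pipeline(_pipeline_counts(cfg, manifest), manifest)
    called = sum(r.status == "rG4" for r in regions)
    assert called / max(len(regions), 1) <= 0.05


def test_peak_width_and_exclusion_invariants(small_library):
    cfg, _, manifest = small_library
    counts = _pipeline_counts(cfg, manifest)
    from g4coop.rtstop_rg4 import call_rtstop_peaks
    for cid, by_cond in counts.items():
        peaks = call_rtstop_peaks(by_cond, cid)
        for p in peaks:
            assert p.end - p.start == 2 and p.start >= 19
        for a, b in zip(peaks, peaks[1:]):
            assert b.start > a.end
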