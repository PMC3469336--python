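"""Copy-number thresholding, weak-region runs, susceptibility geometry, and
exponential nick-rate recovery."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from tufscan import (
    GenomicInterval,
    NickRateEstimator,
    ProbeManifest,
    WaveCorrector,
    annotate_susceptibility,
    detect_weak_regions,
    estimate_nick_rate,
    infer_copy_number,
    quantile_normalize,
    suppression_profile,
)
from tufscan.content import TufElement

from conftest import make_cohort


# -------------------------------------------------------- infer_copy_number
def test_threshold_classifier():
    lrr = pd.DataFrame([[0.0, -0.5, -0.3, -0.29]], index=["s"], columns=list("abcd"))
    calls = infer_copy_number(lrr)
    assert calls.loc["s"].tolist() == [2, 1, 1, 2]


def test_affected_sample_cn1_enriched_near_elements(wave_bench):
    """CN-1 calls concentrate at susceptible probes (odds ratio > 5)."""
    cfg = replace(
        wave_bench["config"],
        n_positive=1, n_negative=0, n_null=0,
        wave_coefficients={},
        stratum_offset_sd=0.0,
        noise_sd=0.1,
        nick_rate={"positive": 5e-5, "negative": 2e-3, "null": 2e-3},
        suppression_amplitude={"positive": 0.8, "negative": 0.0, "null": 0.0},
    )
    truth, im, _ = make_cohort(
        cfg, wave_bench["elements"], wave_bench["manifest"], wave_bench["content"], 5
    )
    calls = infer_copy_number(im.lrr)
    ann = annotate_susceptibility(wave_bench["manifest"], wave_bench["elements"], 10_000)
    cn1 = (calls.iloc[0] == 1).to_numpy()
    sus = ann["susceptible"].to_numpy()
    a = (cn1 & sus).sum() + 0.5
    b = (~cn1 & sus).sum() + 0.5
    c = (cn1 & ~sus).sum() + 0.5
    d = (~cn1 & ~sus).sum() + 0.5
    assert (a * d) / (b * c) > 5


# ------------------------------------------------------ detect_weak_regions
def _manifest12():
    return ProbeManifest.from_records(
        [(f"p{i:02d}", "chr2", 1_000 * (i + 1)) for i in range(12)]
    )


def test_all_diploid_cohort_has_no_regions():
    calls = pd.DataFrame(2, index=["s1", "s2"], columns=[f"p{i:02d}" for i in range(12)])
    assert detect_weak_regions(calls, _manifest12(), ["s1", "s2"]) == []


def test_hand_built_run_of_six_is_found_exactly():
    """3 samples x 12 probes with one planted concordant run at probes 4..9."""
    probes = [f"p{i:02d}" for i in range(12)]
    calls = pd.DataFrame(2, index=["s1", "s2", "s3"], columns=probes)
    calls.loc[["s1", "s2"], probes[3:9]] = 1  # 2/3 samples >= 0.5 support
    regions = detect_weak_regions(calls, _manifest12(), ["s1", "s2", "s3"])
    assert len(regions) == 1
    r = regions[0]
    assert (r.interval.start, r.interval.end) == (4_000, 9_000)
    assert r.n_probes == 6
    assert r.support == pytest.approx(2 / 3)


def test_short_runs_are_discarded():
    probes = [f"p{i:02d}" for i in range(12)]
    calls = pd.DataFrame(2, index=["s1", "s2"], columns=probes)
    calls.loc[:, probes[2:6]] = 1  # run of 4 < min_run 5
    assert detect_weak_regions(calls, _manifest12(), ["s1", "s2"]) == []


def test_region_detection_invariant_to_sample_order():
    probes = [f"p{i:02d}" for i in range(12)]
    rng = np.random.default_rng(0)
    calls = pd.DataFrame(
        rng.choice([1, 2], size=(4, 12)), index=["s1", "s2", "s3", "s4"], columns=probes
    )
    a = detect_weak_regions(calls, _manifest12(), ["s1", "s2", "s3", "s4"], min_run=2)
    b = detect_weak_regions(
        calls.iloc[::-1], _manifest12(), ["s4", "s2", "s3", "s1"], min_run=2
    )
    assert a == b


def test_no_affected_samples_warns_and_returns_empty():
    calls = pd.DataFrame(1, index=["s1"], columns=["p00"])
    with pytest.warns(UserWarning, match="no affected"):
        out = detect_weak_regions(calls, _manifest12(), [])
    assert out == []


def test_weak_regions_overlap_planted_element_flanks(wave_bench):
    """Detected regions cover the truth susceptible set (Jaccard >= 0.5)."""
    cfg = replace(
        wave_bench["config"],
        n_positive=4, n_negative=0, n_null=0,
        wave_coefficients={},
        stratum_offset_sd=0.0,
        noise_sd=0.08,
        nick_rate={"positive": 1e-4, "negative": 2e-3, "null": 2e-3},
        suppression_amplitude={"positive": 0.9, "negative": 0.0, "null": 0.0},
    )
    truth, im, _ = make_cohort(
        cfg, wave_bench["elements"], wave_bench["manifest"], wave_bench["content"], 9
    )
    calls = infer_copy_number(im.lrr)
    regions = detect_weak_regions(
        calls, wave_bench["manifest"], list(im.sample_ids), min_run=3
    )
    assert regions
    # truth set: probes whose expected LRR crosses the CN-1 threshold,
    # i.e. A * exp(-rho d) >= 0.3  <=>  d <= ln(A/0.3)/rho
    d_star = np.log(0.9 / 0.3) / 1e-4
    d = truth.distances
    strong = d[np.isfinite(d) & (d <= d_star)]
    frame = wave_bench["manifest"].frame.set_index("probe_id")
    in_region = pd.Series(False, index=frame.index)
    for r in regions:
        in_region |= (frame["pos"] >= r.interval.start) & (frame["pos"] <= r.interval.end)
    truth_set = set(strong.index)
    found_set = set(in_region[in_region].index)
    jaccard = len(truth_set & found_set) / len(truth_set | found_set)
    assert jaccard >= 0.5


# --------------------------------------------------- annotate_susceptibility
def test_susceptibility_geometry():
    elements = [
        TufElement(GenomicInterval("chr1", 10_000, 11_000), 0.75, 1_001),
    ]
    manifest = ProbeManifest.from_records(
        [
            ("inside", "chr1", 10_500),
            ("left1k", "chr1", 9_000),
            ("right2k", "chr1", 13_000),
            ("far", "chr1", 500_000),
            ("other", "chr9", 10_500),
        ]
    )
    ann = annotate_susceptibility(manifest, elements, d_max=50_000)
    assert ann.loc["inside", "distance"] == 0
    assert ann.loc["left1k", "distance"] == 1_000
    assert ann.loc["right2k", "distance"] == 2_000
    assert np.isinf(ann.loc["far", "distance"]) and not ann.loc["far", "susceptible"]
    assert np.isinf(ann.loc["other", "distance"])


# ------------------------------------------------------- estimate_nick_rate
def test_noiseless_exact_recovery():
    d = np.repeat([0.0, 1_000.0, 2_000.0], 10)
    delta = 0.4 * np.exp(-1e-3 * d)
    fit = estimate_nick_rate(delta, d, n_bins=10)
    assert fit.amplitude == pytest.approx(0.4, rel=1e-8)
    assert fit.rate == pytest.approx(1e-3, rel=1e-8)


def test_all_zero_suppression_returns_zero_amplitude():
    d = np.linspace(0, 5_000, 40)
    fit = estimate_nick_rate(np.zeros(40), d)
    assert fit.amplitude == 0.0
    assert fit.zero and np.isnan(fit.rate)


def test_scale_consistency():
    """Doubling A doubles the amplitude estimate, leaves rho unchanged."""
    rng = np.random.default_rng(3)
    d = rng.uniform(0, 8_000, 200)
    base = 0.3 * np.exp(-5e-4 * d)
    f1 = estimate_nick_rate(base, d)
    f2 = estimate_nick_rate(2 * base, d)
    assert f2.amplitude == pytest.approx(2 * f1.amplitude, rel=1e-6)
    assert f2.rate == pytest.approx(f1.rate, rel=1e-6)


def test_too_few_or_degenerate_inputs():
    with pytest.raises(ValueError, match=">= 20"):
        estimate_nick_rate(np.ones(5), np.arange(5.0))
    with pytest.raises(ValueError, match="distinct"):
        estimate_nick_rate(np.ones(25), np.full(25, 7.0))


def test_simulated_recovery_rate(wave_bench):
    """rho within 15% relative error in >= 80/100 noisy samples."""
    ann = annotate_susceptibility(wave_bench["manifest"], wave_bench["elements"], 50_000)
    d = ann["distance"].to_numpy()
    A, rho = 0.5, 5e-4
    truth_delta = np.where(np.isfinite(d), A * np.exp(-rho * np.nan_to_num(d, posinf=0.0)), 0.0)
    ok = 0
    for seed in range(100):
        rng = np.random.default_rng(30_000 + seed)
        delta = truth_delta + rng.normal(0, 0.1, len(d))
        fit = estimate_nick_rate(delta, d, n_bins=10, d_max=50_000)
        ok += abs(fit.rate - rho) / rho <= 0.15
    assert ok >= 80


def test_estimator_wrapper_predicts_decay():
    d = np.repeat([0.0, 500.0, 1_500.0, 3_000.0], 10)
    delta = 0.6 * np.exp(-2e-4 * d)
    est = NickRateEstimator().fit(d, delta)
    assert est.amplitude_ == pytest.approx(0.6, rel=1e-6)
    np.testing.assert_allclose(est.predict([0.0]), [0.6], rtol=1e-6)


def test_higher_nick_rate_means_fewer_weak_calls(wave_bench):
    """More nicks (degraded DNA) -> fewer suppressed probes called CN 1."""
    counts = []
    for rho in (1e-4, 5e-4, 2e-3):
        cfg = replace(
            wave_bench["config"],
            n_positive=1, n_negative=0, n_null=0,
            wave_coefficients={},
            stratum_offset_sd=0.0,
            noise_sd=0.05,
            nick_rate={"positive": rho, "negative": rho, "null": rho},
            suppression_amplitude={"positive": 0.8, "negative": 0.8, "null": 0.8},
        )
        truth, im, _ = make_cohort(
            cfg, wave_bench["elements"], wave_bench["manifest"], wave_bench["content"], 4
        )
        counts.append(int((infer_copy_number(im.lrr).iloc[0] == 1).sum()))
    assert counts[0] > counts[1] > counts[2]


def test_suppression_profile_recovers_decay_parameters(wave_bench):
    """Baseline-relative suppression of a wave-free affected sample recovers
    the planted amplitude and nick rate."""
    cfg = replace(
        wave_bench["config"],
        n_positive=1, n_negative=0, n_null=0,
        wave_coefficients={},
        stratum_offset_sd=0.0,
        noise_sd=0.05,
        nick_rate={"positive": 5e-4, "negative": 2e-3, "null": 2e-3},
        suppression_amplitude={"positive": 0.5, "negative": 0.0, "null": 0.0},
    )
    truth, im, _ = make_cohort(
        cfg, wave_bench["elements"], wave_bench["manifest"], wave_bench["content"], 11
    )
    ann = annotate_susceptibility(wave_bench["manifest"], wave_bench["elements"], 50_000)
    prof = suppression_profile(im.lrr.iloc[0], ann)
    fit = estimate_nick_rate(prof["delta"], prof["distance"], d_max=50_000)
    assert abs(fit.rate - 5e-4) / 5e-4 < 0.5
    assert abs(fit.amplitude - 0.5) < 0.15
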