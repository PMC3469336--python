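"""Generator contracts: determinism, planted structure, closed-form moments,
fragmentation mechanics, PRT readout behavior."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from tufscan import (
    RestrictionEnzyme,
    SimulationConfig,
    apply_fragmentation,
    find_gc_elements,
    simulate_cohort,
    simulate_genome,
    simulate_prt_readout,
    simulate_study,
)
from tufscan.content import build_content_matrix
from tufscan.simulate import build_truth


def test_background_gc_is_binomial(small_config):
    cfg = replace(small_config, n_elements=0, genome_length=100_000)
    seq, elements, _ = simulate_genome(cfg)
    assert elements == []
    gc = sum(b in "GC" for b in seq) / len(seq)
    se = np.sqrt(0.4 * 0.6 / 100_000)
    assert abs(gc - 0.40) < 3 * se


def test_planted_elements_are_recoverable(small_study, small_config):
    """Cross-module oracle: the element finder recovers every planted block."""
    found = find_gc_elements(small_study["sequence"], min_length=500, min_gc=0.70)
    for el in small_study["elements"]:
        assert any(
            f.interval.start <= el.interval.end and f.interval.end >= el.interval.start
            for f in found
        )


def test_same_seed_reproduces_everything(small_config):
    a = simulate_study(small_config)
    b = simulate_study(small_config)
    assert a["sequence"] == b["sequence"]
    pd.testing.assert_frame_equal(a["intensity"].lrr, b["intensity"].lrr)
    pd.testing.assert_frame_equal(a["prt"], b["prt"])


def test_distinct_seeds_differ(small_config):
    a = simulate_study(small_config, seed=1)
    b = simulate_study(small_config, seed=2)
    assert not a["intensity"].lrr.equals(b["intensity"].lrr)


def test_element_placement_failure_raises():
    cfg = SimulationConfig(genome_length=5_000, n_elements=10, element_length=1_100)
    with pytest.raises(RuntimeError, match="place"):
        simulate_genome(cfg)


def _tiny_design(seed=0, **overrides):
    cfg = SimulationConfig(
        genome_length=60_000,
        probe_spacing=200,
        n_elements=1,
        window_sizes=(50, 100),
        n_positive=2,
        n_negative=2,
        n_null=1,
        seed=seed,
        **overrides,
    )
    seq, elements, manifest = simulate_genome(cfg)
    content = build_content_matrix({cfg.chrom: seq}, manifest, cfg.window_sizes)
    return cfg, seq, elements, manifest, content


def test_null_model_is_constant():
    """No waves, no offsets, no suppression, no noise -> constant baseline."""
    cfg, seq, elements, manifest, content = _tiny_design(
        wave_coefficients={},
        stratum_offset_sd=0.0,
        suppression_amplitude={"positive": 0.0, "negative": 0.0, "null": 0.0},
        noise_sd=0.0,
        baseline=0.25,
    )
    truth = build_truth(cfg, elements, manifest)
    im = simulate_cohort(cfg, truth, content)
    np.testing.assert_allclose(im.lrr.to_numpy(), 0.25)


def test_zero_distance_suppression_equals_amplitude():
    cfg, seq, elements, manifest, content = _tiny_design(
        wave_coefficients={},
        stratum_offset_sd=0.0,
        noise_sd=0.0,
    )
    truth = build_truth(cfg, elements, manifest)
    im = simulate_cohort(cfg, truth, content)
    inside = truth.distances[truth.distances == 0].index
    assert len(inside) > 0
    for rec in truth.samples.itertuples(index=False):
        np.testing.assert_allclose(
            im.lrr.loc[rec.sample_id, inside], -rec.amplitude, atol=1e-12
        )


def test_noise_variance_matches_sigma():
    """Null-sample LRR variance sits in the chi-square band around sigma^2."""
    cfg = SimulationConfig(
        genome_length=1_000_000,
        probe_spacing=200,
        n_elements=0,
        window_sizes=(50,),
        n_positive=0,
        n_negative=0,
        n_null=1,
        stratum_offset_sd=0.0,
        noise_sd=0.1,
        seed=13,
    )
    seq, elements, manifest = simulate_genome(cfg)
    content = build_content_matrix({cfg.chrom: seq}, manifest, cfg.window_sizes)
    truth = build_truth(cfg, elements, manifest)
    im = simulate_cohort(cfg, truth, content)
    assert im.lrr.shape == (1, 5_000)
    var = float(im.lrr.iloc[0].var())
    assert abs(var - 0.01) / 0.01 < 0.05


# ---------------------------------------------------------- fragmentation
def test_digestion_between_all_pairs_removes_suppression():
    cfg, seq, elements, manifest, content = _tiny_design(seed=3)
    truth = build_truth(cfg, elements, manifest)
    el = elements[0].interval
    # synthetic enzyme cutting immediately on both sides of the element
    seq2 = list(seq)
    left = "GAATTC"
    seq2[el.start - 8 : el.start - 2] = left
    seq2[el.end + 2 : el.end + 8] = left
    seq2 = "".join(seq2)
    cut = apply_fragmentation(
        truth, "digestion", enzyme=RestrictionEnzyme("EcoRI", "GAATTC", 1), sequence=seq2
    )
    outside = truth.distances[(truth.distances > 10) & np.isfinite(truth.distances)]
    assert np.isinf(cut.distances[outside.index]).all()
    # and the suppression term vanishes in the simulated LRR
    cfg0 = replace(cfg, wave_coefficients={}, stratum_offset_sd=0.0, noise_sd=0.0)
    truth0 = build_truth(cfg0, elements, manifest)
    cut0 = apply_fragmentation(
        truth0, "digestion", enzyme=RestrictionEnzyme("EcoRI", "GAATTC", 1), sequence=seq2
    )
    im = simulate_cohort(cfg0, cut0, content)
    far = cut0.distances[np.isinf(cut0.distances)].index
    np.testing.assert_allclose(im.lrr.loc[:, far].to_numpy(), 0.0, atol=1e-12)


def test_enzyme_with_no_sites_leaves_truth_unchanged():
    cfg, seq, elements, manifest, content = _tiny_design(seed=4)
    truth = build_truth(cfg, elements, manifest)
    cut = apply_fragmentation(
        truth,
        "digestion",
        enzyme=RestrictionEnzyme("none", "GCGGCCGCAT", 1),
        sequence="A" * cfg.genome_length,
    )
    pd.testing.assert_series_equal(cut.distances, truth.distances)


def test_sonication_linkage_survival_is_poissonian():
    """Fraction of probes at distance d keeping linkage ~ exp(-d / L)."""
    cfg = SimulationConfig(
        genome_length=2_000_000,
        probe_spacing=100,
        n_elements=1,
        element_length=1_100,
        window_sizes=(50,),
        seed=19,
    )
    seq, elements, manifest = simulate_genome(cfg)
    truth = build_truth(cfg, elements, manifest)
    L = 5_000.0
    d = truth.distances.to_numpy()
    # a single tracked probe keeps the replicates independent Bernoulli draws
    probe = int(np.argmin(np.abs(d - L)))
    d_probe = float(d[probe])
    kept = 0
    n_rep = 1_000
    for rep in range(n_rep):
        cut = apply_fragmentation(truth, "sonication", mean_fragment=L, seed=100 + rep)
        kept += bool(np.isfinite(cut.distances.to_numpy()[probe]))
    expected = float(np.exp(-d_probe / L))
    se = np.sqrt(expected * (1 - expected) / n_rep)
    assert abs(kept / n_rep - expected) < 4 * se


def test_sonication_requires_positive_fragment_size(small_study):
    with pytest.raises(ValueError):
        apply_fragmentation(small_study["truth"], "sonication", mean_fragment=0)


# ------------------------------------------------------------ PRT readout
def test_unsuppressed_prt_ratio_is_equal_efficiency():
    cfg, seq, elements, manifest, content = _tiny_design(
        suppression_amplitude={"positive": 0.0, "negative": 0.0, "null": 0.0},
        prt_noise_sd=0.0,
    )
    truth = build_truth(cfg, elements, manifest)
    out = simulate_prt_readout(truth, 1_000, cfg)
    np.testing.assert_allclose(out["ratio"], 1.43)


def test_separated_prt_ratio_returns_to_equal_efficiency():
    cfg, seq, elements, manifest, content = _tiny_design(prt_noise_sd=0.0)
    truth = build_truth(cfg, elements, manifest)
    out = simulate_prt_readout(truth, np.inf, cfg)
    np.testing.assert_allclose(out["ratio"], 1.43)


def test_prt_ratio_closed_form():
    cfg, seq, elements, manifest, content = _tiny_design(
        nick_rate={"positive": 1e-3, "negative": 1e-3, "null": 1e-3},
        suppression_amplitude={"positive": 0.8, "negative": 0.8, "null": 0.8},
        prt_noise_sd=0.0,
    )
    truth = build_truth(cfg, elements, manifest)
    out = simulate_prt_readout(truth, 1_000, cfg)
    np.testing.assert_allclose(out["ratio"], 1.43 * (1 - 0.8 * np.exp(-1)))


def test_lower_nick_rate_lowers_prt_ratio():
    """Ligase analogue: repairing nicks (smaller rho) worsens amplification."""
    ratios = []
    for rho in (2e-3, 5e-4, 1e-4, 1e-5):
        cfg, seq, elements, manifest, content = _tiny_design(
            nick_rate={c: rho for c in ("positive", "negative", "null")},
            prt_noise_sd=0.0,
        )
        truth = build_truth(cfg, elements, manifest)
        out = simulate_prt_readout(truth, 1_000, cfg)
        ratios.append(float(out["ratio"].mean()))
    assert all(a > b for a, b in zip(ratios, ratios[1:]))


def test_sonication_raises_prt_ratio_toward_equal_efficiency():
    """Paired over seeds: small fragments restore the test amplicon."""
    gains = []
    for seed in range(5):
        cfg, seq, elements, manifest, content = _tiny_design(seed=seed, prt_noise_sd=0.0)
        truth = build_truth(cfg, elements, manifest)
        before = simulate_prt_readout(truth, 1_000, cfg)["ratio"].mean()
        el = elements[0].interval
        d_probe = 1_000.0
        # sonication to 300 bp fragments separates nearly all probes
        rng = np.random.default_rng(seed)
        linked = rng.random(len(truth.samples)) < np.exp(-d_probe / 300.0)
        d_after = np.where(linked, d_probe, np.inf)
        after = simulate_prt_readout(truth, d_after, cfg)["ratio"].mean()
        gains.append(after - before)
    assert all(g > 0 for g in gains)
    cfg, seq, elements, manifest, content = _tiny_design(prt_noise_sd=0.0)
    truth = build_truth(cfg, elements, manifest)
    assert simulate_prt_readout(truth, np.inf, cfg)["ratio"].mean() == pytest.approx(1.43)


def test_config_yaml_round_trip(tmp_path, small_config):
    path = tmp_path / "cfg.yaml"
    small_config.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back == small_config
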