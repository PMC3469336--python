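import warnings
from dataclasses import replace

import numpy as np
import pytest

from tufscan import (
    SimulationConfig,
    build_content_matrix,
    simulate_genome,
    simulate_study,
)
from tufscan.simulate import build_truth


@pytest.fixture(autouse=True)
def _quiet_design_warnings():
    # small fixtures trip the <10x probes-per-term advisory warning
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* probes for")
        yield


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 300 kb genome, 4 window scales, 11 samples."""
    return SimulationConfig(
        genome_length=300_000,
        probe_spacing=300,
        n_elements=2,
        window_sizes=(50, 100, 500, 1_000),
        n_positive=4,
        n_negative=4,
        n_null=3,
        noise_sd=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def wave_bench():
    """Shared 5000-probe design for wave/nick-rate recovery experiments.

    One genome with six high-GC elements; cohorts redraw sample effects and
    noise on top of the fixed probe design, as on a real array.
    """
    cfg = SimulationConfig(
        genome_length=1_000_000,
        probe_spacing=200,
        n_elements=6,
        window_sizes=(50, 100, 500, 1_000),
        noise_sd=0.05,
        seed=7,
    )
    seq, elements, manifest = simulate_genome(cfg)
    content = build_content_matrix({cfg.chrom: seq}, manifest, cfg.window_sizes)
    return {
        "config": cfg,
        "sequence": seq,
        "elements": elements,
        "manifest": manifest,
        "content": content,
    }


def make_cohort(cfg, elements, manifest, content, seed):
    """Draw one cohort (truth, LRR, PRT) on a fixed genome/content design."""
    from tufscan import simulate_cohort, simulate_prt_readout

    c = replace(cfg, seed=int(seed))
    ss = np.random.SeedSequence(c.seed)
    r_truth, r_lrr, r_prt = (np.random.default_rng(s) for s in ss.spawn(3))
    truth = build_truth(c, elements, manifest, r_truth)
    intensity = simulate_cohort(c, truth, content, r_lrr)
    prt = simulate_prt_readout(truth, c.prt_distance, c, r_prt)
    return truth, intensity, prt
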