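"""Mechanistic synthetic cohort generator.

Emulates the observable consequences of Thermodynamically Ultra-Fastened
(TUF) genome regions on SNP-array intensities: a genome carrying planted
extreme-GC elements, probe log-R-ratios (LRR) with additive polynomial
GC/CpG waves, chip-stratum offsets, Gaussian noise, and a distance-dependent
suppression term

    LRR(s, i) = c_s + wave(s, i) + gamma_{s, strip(i)}
                - A_s * exp(-rho_s * d_i) * 1[d_i <= D_max] + eps

where d_i is probe i's distance to the nearest intact high-GC element and
rho_s is the sample's nick density (single-strand discontinuities per bp).
exp(-rho_s * d_i) is the probability that no nick falls between probe and
element when nicks are Poisson along the molecule, i.e. the probability the
probe remains physically tethered to the un-melted element. A paired
paralogue-ratio-test (PRT) readout per sample follows the same suppression
law. Full ground truth is emitted for every downstream stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .content import TufElement, WindowContentMatrix, RestrictionEnzyme, \
    find_restriction_sites, distance_to_elements
from .intervals import GenomicInterval, ProbeManifest

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "IntensityMatrix",
    "simulate_genome",
    "simulate_cohort",
    "apply_fragmentation",
    "simulate_prt_readout",
    "simulate_study",
]

CLASSES = ("positive", "negative", "null")

TermKey = Tuple[str, int, int]  # (metric, window, polynomial degree)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's default conditions.

    The sample class mix (24 positive / 19 negative / 11 null) mirrors the
    54-sample validation cohort; positive and negative classes carry
    GC waves of opposite sign at the 100 bp window. Nick rates encode sample
    quality: intact (low-rho) DNA is the most suppression-prone. The
    equal-efficiency PRT ratio is 1.43.
    """

    genome_length: int = 2_000_000
    background_gc: float = 0.40
    n_elements: int = 6
    element_length: int = 1_100
    element_gc: float = 0.73
    chrom: str = "chr1"
    probe_spacing: int = 500
    window_sizes: tuple = (50, 100, 500, 1_000, 10_000, 50_000, 100_000, 250_000, 1_000_000)
    n_positive: int = 24
    n_negative: int = 19
    n_null: int = 11
    # nicks per bp by class: intact DNA (low rho) is most TUF-vulnerable;
    # the negative-wave class models a non-TUF (concentration-type) artifact
    # on ordinary-quality DNA, so its PRT behaves like the null class
    nick_rate: Dict[str, float] = field(
        default_factory=lambda: {"positive": 1e-4, "negative": 2e-3, "null": 2e-3}
    )
    suppression_amplitude: Dict[str, float] = field(
        default_factory=lambda: {"positive": 0.6, "negative": 0.6, "null": 0.6}
    )
    # wave coefficients for the positive class; negated for the negative
    # class, zero for nulls. Keys are (metric, window bp, degree).
    wave_coefficients: Dict[TermKey, float] = field(
        default_factory=lambda: {("GC", 100, 1): 4.0, ("GC", 100, 2): 4.0}
    )
    n_strata: int = 4
    stratum_offset_sd: float = 0.05
    baseline: float = 0.0
    noise_sd: float = 0.10
    d_max: int = 50_000
    r_eq: float = 1.43
    prt_noise_sd: float = 0.05
    prt_distance: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in CLASSES:
            if self.nick_rate.get(cls, 0.0) < 0:
                raise ValueError("nick rates must be >= 0")
            if self.suppression_amplitude.get(cls, 0.0) < 0:
                raise ValueError("suppression amplitudes must be >= 0")
        if self.noise_sd < 0 or self.prt_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if min(self.n_positive, self.n_negative, self.n_null) < 0:
            raise ValueError("class counts must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_positive + self.n_negative + self.n_null

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_sizes"] = list(self.window_sizes)
        d["wave_coefficients"] = [
            [m, w, p, v] for (m, w, p), v in self.wave_coefficients.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "window_sizes" in d:
            d["window_sizes"] = tuple(int(w) for w in d["window_sizes"])
        if "wave_coefficients" in d and not isinstance(d["wave_coefficients"], dict):
            d["wave_coefficients"] = {
                (str(m), int(w), int(p)): float(v)
                for m, w, p, v in d["wave_coefficients"]
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class CohortTruth:
    """Ground truth emitted alongside the simulated data.

    ``distances`` holds each probe's distance d_i (bp) to the nearest intact
    element, with ``inf`` as the separated / out-of-range sentinel.
    ``samples`` has one row per sample: class label, nick rate rho_s,
    suppression amplitude A_s and baseline c_s. ``wave`` maps sample id to
    its per-term wave coefficients; ``stratum_offsets`` is samples x strata.
    """

    elements: list
    manifest: ProbeManifest
    distances: pd.Series
    samples: pd.DataFrame
    wave: Dict[str, Dict[TermKey, float]]
    stratum_offsets: pd.DataFrame
    strata: pd.Series  # probe -> stratum label
    config: SimulationConfig

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])


@dataclass
class IntensityMatrix:
    """Samples x probes LRR values plus the per-probe chip-stratum label."""

    lrr: pd.DataFrame  # index: sample ids, columns: probe ids
    strata: pd.Series  # index: probe ids

    def __post_init__(self) -> None:
        if not np.isfinite(self.lrr.to_numpy()).all():
            raise ValueError("LRR values must be finite")
        if not self.lrr.columns.equals(self.strata.index):
            raise ValueError("strata index must match LRR probe columns")

    @property
    def sample_ids(self) -> pd.Index:
        return self.lrr.index

    def to_tsv(self, path) -> None:
        out = self.lrr.T
        out.index.name = "probe_id"
        out.insert(0, "stratum", self.strata)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id", comment="#")
        strata = df.pop("stratum")
        return cls(df.T, strata)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[str, list, ProbeManifest]:
    """Draw a genome with planted high-GC elements and a regular probe grid.

    Background bases are i.i.d. at ``background_gc``; elements are placed at
    uniformly drawn, non-overlapping loci and filled i.i.d. at
    ``element_gc``; probes sit every ``probe_spacing`` bp. Reproducible under
    a fixed seed.
    """
    rng = _rng(config.seed if rng is None else rng)
    L = config.genome_length
    p_gc = config.background_gc
    bases = np.array([b"A"[0], b"C"[0], b"G"[0], b"T"[0]], dtype=np.uint8)
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    genome = rng.choice(bases, size=L, p=probs)

    elen = config.element_length
    starts: list[int] = []
    for _ in range(10_000):
        if len(starts) == config.n_elements:
            break
        cand = int(rng.integers(1, L - elen + 2))
        if all(abs(cand - s) >= elen + 1 for s in starts):
            starts.append(cand)
    else:
        raise RuntimeError(
            f"could not place {config.n_elements} non-overlapping elements "
            f"of {elen} bp in {L} bp"
        )
    starts.sort()
    pe = config.element_gc
    eprobs = [(1 - pe) / 2, pe / 2, pe / 2, (1 - pe) / 2]
    elements = []
    for k, s in enumerate(starts):
        block = rng.choice(bases, size=elen, p=eprobs)
        genome[s - 1 : s - 1 + elen] = block
        gc = float(np.isin(block, bases[[1, 2]]).mean())
        elements.append(
            TufElement(
                GenomicInterval(config.chrom, s, s + elen - 1, f"el{k + 1:02d}"),
                gc,
                elen,
            )
        )
    sequence = genome.tobytes().decode("ascii")
    pos = np.arange(config.probe_spacing, L + 1, config.probe_spacing)
    manifest = ProbeManifest.from_records(
        [(f"p{i + 1:06d}", config.chrom, int(x)) for i, x in enumerate(pos)]
    )
    return sequence, elements, manifest


def _sample_table(config: SimulationConfig, rng: np.random.Generator):
    labels = (
        ["positive"] * config.n_positive
        + ["negative"] * config.n_negative
        + ["null"] * config.n_null
    )
    ids = [f"s{i + 1:03d}" for i in range(len(labels))]
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "label": labels,
            "nick_rate": [config.nick_rate[c] for c in labels],
            "amplitude": [config.suppression_amplitude[c] for c in labels],
            "baseline": config.baseline,
        }
    )
    sign = {"positive": 1.0, "negative": -1.0, "null": 0.0}
    wave = {
        sid: {k: sign[lab] * v for k, v in config.wave_coefficients.items()}
        for sid, lab in zip(ids, labels)
    }
    offsets = pd.DataFrame(
        rng.normal(0.0, config.stratum_offset_sd, size=(len(ids), config.n_strata)),
        index=ids,
        columns=[f"strip{k}" for k in range(config.n_strata)],
    )
    return samples, wave, offsets


def build_truth(
    config: SimulationConfig,
    elements: list,
    manifest: ProbeManifest,
    rng: Optional[np.random.Generator] = None,
) -> CohortTruth:
    """Assemble the ground-truth table: distances, sample params, strata."""
    rng = _rng(config.seed + 1 if rng is None else rng)
    n = len(manifest)
    dist = np.full(n, np.inf)
    for chrom in manifest.chroms:
        mask = (manifest.frame["chrom"] == chrom).to_numpy()
        dist[mask] = distance_to_elements(
            manifest.frame.loc[mask, "pos"].to_numpy(), elements, chrom
        )
    distances = pd.Series(dist, index=manifest.probe_ids, name="distance")
    samples, wave, offsets = _sample_table(config, rng)
    strip = np.arange(n) * config.n_strata // max(n, 1)
    strata = pd.Series(
        [f"strip{k}" for k in strip], index=manifest.probe_ids, name="stratum"
    )
    return CohortTruth(elements, manifest, distances, samples, wave, offsets, strata, config)


def expected_lrr(truth: CohortTruth, content: WindowContentMatrix) -> pd.DataFrame:
    """Noise-free expected LRR for every sample (all terms except eps)."""
    config = truth.config
    centered = content.values - content.values.mean(axis=0)
    d = truth.distances.to_numpy()
    supp_mask = np.isfinite(d) & (d <= config.d_max)
    strat_idx = truth.strata.map(
        {c: i for i, c in enumerate(truth.stratum_offsets.columns)}
    ).to_numpy()
    rows = []
    for rec in truth.samples.itertuples(index=False):
        mu = np.full(len(content.values), rec.baseline)
        for (metric, window, degree), beta in truth.wave[rec.sample_id].items():
            if beta == 0.0:
                continue
            mu = mu + beta * centered[(metric, int(window))].to_numpy() ** degree
        mu = mu + truth.stratum_offsets.loc[rec.sample_id].to_numpy()[strat_idx]
        supp = np.zeros(len(mu))
        supp[supp_mask] = rec.amplitude * np.exp(-rec.nick_rate * d[supp_mask])
        rows.append(mu - supp)
    return pd.DataFrame(rows, index=truth.sample_ids, columns=content.probe_ids)


def simulate_cohort(
    config: SimulationConfig,
    truth: CohortTruth,
    content: WindowContentMatrix,
    rng: Optional[np.random.Generator] = None,
) -> IntensityMatrix:
    """Draw the samples x probes LRR matrix under the mechanistic model."""
    if not content.probe_ids.equals(truth.manifest.probe_ids):
        raise ValueError("content rows do not match the manifest")
    rng = _rng(config.seed + 2 if rng is None else rng)
    mu = expected_lrr(truth, content)
    noise = rng.normal(0.0, config.noise_sd, size=mu.shape)
    return IntensityMatrix(mu + noise, truth.strata)


def _nearest_boundary(truth: CohortTruth) -> pd.Series:
    """Coordinate of the proximal boundary of each probe's nearest element."""
    frame = truth.manifest.frame
    out = np.full(len(frame), np.nan)
    for i, (pos, chrom) in enumerate(zip(frame["pos"], frame["chrom"])):
        best, bound = np.inf, np.nan
        for el in truth.elements:
            if el.interval.chrom != chrom:
                continue
            d = el.interval.distance_to(int(pos))
            if d < best:
                best = d
                if el.interval.contains(int(pos)):
                    bound = pos
                else:
                    bound = el.interval.start if pos < el.interval.start else el.interval.end
        out[i] = bound
    return pd.Series(out, index=truth.manifest.probe_ids)


def apply_fragmentation(
    truth: CohortTruth,
    mode: str,
    mean_fragment: Optional[float] = None,
    enzyme: Optional[RestrictionEnzyme] = None,
    sequence: Optional[str] = None,
    seed: Optional[int] = None,
) -> CohortTruth:
    """Break the template DNA and sever probe-element linkages.

    ``mode='sonication'`` draws Poisson breakpoints at rate 1/``mean_fragment``
    per bp; ``mode='digestion'`` breaks deterministically at the enzyme's cut
    positions in ``sequence``. A probe's distance becomes ``inf`` whenever a
    break lies strictly between it and its nearest element boundary, which
    removes that probe's suppression term entirely.
    """
    if mode == "sonication":
        if mean_fragment is None or mean_fragment <= 0:
            raise ValueError("mean_fragment must be > 0 for sonication")
        rng = np.random.default_rng(seed)
        L = truth.config.genome_length
        n_breaks = rng.poisson(L / mean_fragment)
        breaks = np.sort(rng.integers(2, L + 1, size=n_breaks))
    elif mode == "digestion":
        if enzyme is None or sequence is None:
            raise ValueError("digestion requires an enzyme and the sequence")
        breaks = np.asarray(find_restriction_sites(sequence, enzyme))
    else:
        raise ValueError(f"unknown fragmentation mode {mode!r}")

    pos = truth.manifest.frame["pos"].to_numpy(dtype=float)
    bound = _nearest_boundary(truth).to_numpy()
    new_d = truth.distances.to_numpy().copy()
    if breaks.size:
        lo = np.minimum(pos, bound)
        hi = np.maximum(pos, bound)
        # break at p separates x from b iff min < p <= max
        n_between = np.searchsorted(breaks, hi, side="right") - np.searchsorted(
            breaks, lo, side="right"
        )
        severed = np.isfinite(new_d) & (n_between > 0)
        new_d[severed] = np.inf
    return replace(truth, distances=pd.Series(new_d, index=truth.distances.index, name="distance"))


def simulate_prt_readout(
    truth: CohortTruth,
    d_prt: Union[float, np.ndarray, None] = None,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-sample PRT test:reference ratio under the suppression model.

    ratio_s = R_eq * (1 - min(A_s, 1) * exp(-rho_s * d_prt)) + noise,
    clipped at zero. ``d_prt`` is the distance (bp) between the test amplicon
    and its nearest high-GC element; ``inf`` (physically separated) restores
    the equal-efficiency ratio R_eq.
    """
    config = truth.config if config is None else config
    if d_prt is None:
        d_prt = config.prt_distance
    if np.ndim(d_prt) == 0 and float(d_prt) < 0:
        raise ValueError("d_prt must be >= 0")
    rng = _rng(config.seed + 3 if rng is None else rng)
    d = np.broadcast_to(np.asarray(d_prt, dtype=float), (len(truth.samples),))
    A = np.minimum(truth.samples["amplitude"].to_numpy(), 1.0)
    rho = truth.samples["nick_rate"].to_numpy()
    with np.errstate(invalid="ignore"):
        link = np.where(np.isfinite(d), np.exp(-rho * d), 0.0)
    ratio = config.r_eq * (1.0 - A * link)
    ratio = ratio + rng.normal(0.0, config.prt_noise_sd, size=ratio.shape)
    return pd.DataFrame(
        {
            "sample_id": truth.samples["sample_id"],
            "label": truth.samples["label"],
            "ratio": np.clip(ratio, 0.0, None),
        }
    )


def simulate_study(
    config: SimulationConfig, seed: Optional[int] = None
) -> dict:
    """Run the full generator: genome, content, truth, LRR matrix, PRT.

    A single seed is fanned out to independent per-stage streams via
    ``numpy.random.SeedSequence.spawn`` so stages stay reproducible in
    isolation.
    """
    from .content import build_content_matrix

    if seed is not None:
        config = replace(config, seed=int(seed))
    ss = np.random.SeedSequence(config.seed)
    r_genome, r_truth, r_lrr, r_prt = (np.random.default_rng(s) for s in ss.spawn(4))
    sequence, elements, manifest = simulate_genome(config, r_genome)
    content = build_content_matrix({config.chrom: sequence}, manifest, config.window_sizes)
    truth = build_truth(config, elements, manifest, r_truth)
    intensity = simulate_cohort(config, truth, content, r_lrr)
    prt = simulate_prt_readout(truth, config.prt_distance, config, r_prt)
    return {
        "config": config,
        "sequence": sequence,
        "elements": elements,
        "manifest": manifest,
        "content": content,
        "truth": truth,
        "intensity": intensity,
        "prt": prt,
    }
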