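"""Weak-signal-region detection and nick-rate estimation.

Across poorly performing samples, probes inside TUF-affected domains drop to
an apparent copy-number-one intensity level. This module thresholds LRR into
discrete signal-strength classes, finds runs of concordantly weak probes,
annotates each probe's distance to the nearest high-GC element, and fits the
exponential suppression-vs-distance decay delta = A * exp(-rho * d) whose
rate parameter is the sample's nick density.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .content import TufElement, distance_to_elements
from .intervals import GenomicInterval, ProbeManifest, write_bed

__all__ = [
    "infer_copy_number",
    "WeakRegion",
    "detect_weak_regions",
    "annotate_susceptibility",
    "NickRateFit",
    "estimate_nick_rate",
    "NickRateEstimator",
    "suppression_profile",
]


def infer_copy_number(lrr, cn1_threshold: float = -0.3) -> pd.DataFrame:
    """Classify probe signal strength: CN 1 if LRR <= threshold, else CN 2.

    Accepts a samples x probes DataFrame (or a single sample Series) and
    returns integer calls of the same shape.
    """
    if isinstance(lrr, pd.Series):
        lrr = lrr.to_frame().T
    if hasattr(lrr, "lrr"):
        lrr = lrr.lrr
    vals = lrr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("LRR must be finite")
    calls = np.where(vals <= cn1_threshold, 1, 2)
    return pd.DataFrame(calls, index=lrr.index, columns=lrr.columns)


@dataclass(frozen=True)
class WeakRegion:
    """A run of consecutive probes concordantly called CN 1."""

    interval: GenomicInterval
    n_probes: int
    support: float  # mean fraction of affected samples calling CN 1


def detect_weak_regions(
    calls: pd.DataFrame,
    manifest: ProbeManifest,
    affected_samples: Iterable[str],
    min_run: int = 5,
    min_sample_fraction: float = 0.5,
) -> list[WeakRegion]:
    """Maximal runs of probes weakly concordant across affected samples.

    A probe supports a region when the fraction of affected samples calling
    CN 1 at it is >= ``min_sample_fraction``; runs shorter than ``min_run``
    probes are discarded. Output is invariant to sample order.
    """
    affected = [s for s in affected_samples]
    if len(affected) == 0:
        warnings.warn("no affected samples; returning no weak regions")
        return []
    if len(affected) < 2:
        raise ValueError("need >= 2 affected samples")
    sub = calls.loc[affected]
    frac = (sub == 1).mean(axis=0)  # per probe
    regions: list[WeakRegion] = []
    frame = manifest.frame
    for chrom, group in frame.groupby("chrom", sort=False):
        ids = group["probe_id"].to_numpy()
        pos = group["pos"].to_numpy()
        mask = frac.reindex(ids).to_numpy() >= min_sample_fraction
        i = 0
        while i < len(mask):
            if not mask[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                regions.append(
                    WeakRegion(
                        GenomicInterval(chrom, int(pos[i]), int(pos[j])),
                        j - i + 1,
                        float(frac.reindex(ids[i : j + 1]).mean()),
                    )
                )
            i = j + 1
    return regions


def weak_regions_to_bed(regions: Iterable[WeakRegion], path) -> None:
    regions = list(regions)
    write_bed(
        path,
        [r.interval for r in regions],
        scores=[round(1000 * r.support) for r in regions],
    )


def annotate_susceptibility(
    manifest: ProbeManifest,
    elements: Iterable[TufElement],
    d_max: float = 50_000,
) -> pd.DataFrame:
    """Distance of each probe to the nearest element boundary.

    ``distance`` is 0 inside an element, the gap in bp otherwise, and ``inf``
    when no element lies within ``d_max`` on the probe's chromosome.
    ``susceptible`` flags distance <= d_max.
    """
    elements = list(elements)
    frame = manifest.frame
    dist = np.full(len(frame), np.inf)
    for chrom in manifest.chroms:
        mask = (frame["chrom"] == chrom).to_numpy()
        dist[mask] = distance_to_elements(
            frame.loc[mask, "pos"].to_numpy(), elements, chrom
        )
    susceptible = dist <= d_max
    dist = np.where(susceptible, dist, np.inf)
    return pd.DataFrame(
        {
            "probe_id": frame["probe_id"],
            "distance": dist,
            "susceptible": susceptible,
        }
    ).set_index("probe_id")


@dataclass
class NickRateFit:
    """Result of fitting delta = A * exp(-rho * d) to binned suppression."""

    amplitude: float
    rate: float
    amplitude_se: float
    rate_se: float
    n_bins: int
    n_probes: int
    zero: bool = False  # True when no suppression signal was present

    @property
    def undefined_rate(self) -> bool:
        return self.zero


def _bin_means(
    distances: np.ndarray, values: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count distance bins; falls back to grouping by distinct distance."""
    distinct = np.unique(distances)
    if len(distinct) <= n_bins:
        d_mean = distinct
        v_mean = np.array([values[distances == d].mean() for d in distinct])
        return d_mean, v_mean
    qs = np.quantile(distances, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1
    idx = np.clip(np.searchsorted(qs, distances, side="right") - 1, 0, n_bins - 1)
    d_mean, v_mean = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            d_mean.append(distances[m].mean())
            v_mean.append(values[m].mean())
    return np.asarray(d_mean), np.asarray(v_mean)


def estimate_nick_rate(
    suppression,
    distances,
    n_bins: int = 10,
    d_max: Optional[float] = None,
) -> NickRateFit:
    """Fit the exponential distance decay of per-probe suppression.

    ``suppression`` holds delta_i, the intensity deficit of probe i relative
    to the unaffected baseline; ``distances`` the matching d_i in bp
    (``inf`` entries are ignored). Distances are reduced to ``n_bins``
    equal-count bin means before the least-squares fit (trust-region
    Gauss-Newton via scipy), initialized from a log-linear regression on the
    positive bins. Returns amplitude 0 with an undefined rate when every
    suppression is (numerically) zero.
    """
    delta = np.asarray(suppression, dtype=float)
    d = np.asarray(distances, dtype=float)
    keep = np.isfinite(d) & np.isfinite(delta)
    if d_max is not None:
        keep &= d <= d_max
    delta, d = delta[keep], d[keep]
    if len(d) < 20:
        raise ValueError(f"need >= 20 susceptible probes, got {len(d)}")
    if len(np.unique(d)) < 2:
        raise ValueError("need >= 2 distinct distances")
    if np.allclose(delta, 0.0, atol=1e-9):
        return NickRateFit(0.0, np.nan, 0.0, np.nan, 0, len(d), zero=True)

    db, vb = _bin_means(d, delta, n_bins)
    pos = vb > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(db[pos], np.log(vb[pos]), 1)
        a0 = float(np.exp(intercept))
        rho0 = float(max(-slope, 1e-12))
    else:
        a0 = float(max(vb.max(), 1e-6))
        rho0 = 1.0 / max(np.median(db), 1.0)
    try:
        popt, pcov = curve_fit(
            lambda x, a, rho: a * np.exp(-rho * x),
            db,
            vb,
            p0=[a0, rho0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"nick-rate fit did not converge (init A={a0:.4g}, rho={rho0:.4g}, "
            f"{len(db)} bins): {err}"
        ) from err
    se = np.sqrt(np.diag(pcov))
    return NickRateFit(
        amplitude=float(popt[0]),
        rate=float(popt[1]),
        amplitude_se=float(se[0]),
        rate_se=float(se[1]),
        n_bins=len(db),
        n_probes=len(d),
    )


class NickRateEstimator(BaseEstimator, RegressorMixin):
    """Estimator wrapper around :func:`estimate_nick_rate`.

    ``fit(X, y)`` takes distances (bp) as ``X`` and per-probe suppression as
    ``y``; fitted attributes are ``amplitude_`` and ``rate_`` (nicks/bp).
    """

    def __init__(self, n_bins: int = 10, d_max: Optional[float] = None):
        self.n_bins = n_bins
        self.d_max = d_max

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        result = estimate_nick_rate(y, X, n_bins=self.n_bins, d_max=self.d_max)
        self.result_ = result
        self.amplitude_ = result.amplitude
        self.rate_ = result.rate
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.amplitude_ * np.exp(-np.nan_to_num(self.rate_) * X)


def suppression_profile(
    corrected_lrr: pd.Series, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-probe suppression delta_i relative to the unsusceptible baseline.

    The baseline is the median corrected LRR over probes with no element
    within range; delta_i = baseline - LRR_i, so suppressed probes have
    positive delta.
    """
    ann = annotation.reindex(corrected_lrr.index)
    baseline_probes = ~ann["susceptible"].to_numpy(dtype=bool)
    if baseline_probes.sum() == 0:
        raise ValueError("no unsusceptible probes to define a baseline")
    baseline = float(corrected_lrr[baseline_probes].median())
    return pd.DataFrame(
        {
            "delta": baseline - corrected_lrr,
            "distance": ann["distance"],
            "susceptible": ann["susceptible"],
        }
    )
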