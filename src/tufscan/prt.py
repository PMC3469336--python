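"""Paralogue ratio test (PRT) readouts and their association with per-sample
wave statistics.

A PRT co-amplifies a 'test' locus (inside a suspect, hard-to-denature
region) and a 'reference' locus with one primer pair; the test:reference
product ratio measures relative amplification efficiency. The association
report correlates each sample's per-term wave Z score with its PRT ratio,
one row per window scale, with parametric (Pearson), rank (Spearman) and
permutation p-values available.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

__all__ = [
    "PrtAssay",
    "prt_ratio",
    "summarize_replicates",
    "test_association",
    "table2_report",
]


@dataclass(frozen=True)
class PrtAssay:
    """Paired test (suspect-region) and reference amplicon of one PRT design."""

    assay_id: str
    test: GenomicInterval
    reference: GenomicInterval
    forward_primer: Optional[str] = None
    reverse_primer: Optional[str] = None

    @property
    def test_length(self) -> int:
        return self.test.length

    @property
    def reference_length(self) -> int:
        return self.reference.length


def prt_ratio(test_peak_height: float, ref_peak_height: float) -> float:
    """Test:reference product ratio from gel peak heights."""
    if test_peak_height <= 0 or ref_peak_height <= 0:
        raise ValueError("peak heights must be > 0")
    return test_peak_height / ref_peak_height


def summarize_replicates(ratios: Iterable[float]) -> dict:
    """Mean with min/max (the error-bar convention for replicate ratios)."""
    vals = np.asarray(list(ratios), dtype=float)
    if len(vals) == 0:
        raise ValueError("no replicate ratios supplied")
    if (vals < 0).any():
        raise ValueError("ratios must be >= 0")
    return {"mean": float(vals.mean()), "min": float(vals.min()), "max": float(vals.max())}


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 8).

    All n! rank permutations are scored in one matrix product: with centered
    rank vectors, |rho| is proportional to |P @ rx_centered|.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    scale = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    obs = abs(rxc @ ryc) / scale
    P = np.array(list(permutations(ry))) - ry.mean()
    rhos = np.abs(P @ rxc) / scale
    return float((rhos >= obs - 1e-12).mean())


def test_association(
    sample_statistic,
    prt_ratios,
    method: str = "pearson",
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    exact: Optional[bool] = None,
) -> float:
    """Two-sided p-value for association between a per-sample statistic and
    PRT ratios.

    ``pearson``: product-moment correlation with the t approximation;
    ``spearman``: rank correlation (exact permutation enumeration when
    n <= 8, t approximation otherwise, overridable via ``exact``);
    ``permutation``: Monte-Carlo permutation of the Pearson correlation.
    """
    x = np.asarray(sample_statistic, dtype=float)
    y = np.asarray(prt_ratios, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must be paired")
    if len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        return float(stats.pearsonr(x, y).pvalue)
    if method == "spearman":
        if exact is None:
            exact = len(x) <= 8
        if exact:
            if len(x) > 8:
                raise ValueError("exact enumeration limited to n <= 8")
            return float(_exact_spearman_p(x, y))
        return float(stats.spearmanr(x, y).pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        obs = abs(np.corrcoef(x, y)[0, 1])
        hits = 0
        y_perm = y.copy()
        for _ in range(n_permutations):
            rng.shuffle(y_perm)
            hits += abs(np.corrcoef(x, y_perm)[0, 1]) >= obs - 1e-12
        return (1 + hits) / (n_permutations + 1)
    raise ValueError(f"unknown method {method!r}")


def table2_report(
    models,
    readouts: pd.DataFrame,
    windows: Optional[Sequence[int]] = None,
    metrics: Sequence[str] = ("GC", "CpG"),
    degree: int = 1,
    statistic: str = "z",
    permutation_seed: Optional[int] = None,
) -> pd.DataFrame:
    """Association table: window scales x (metric, test) p-values.

    For each (metric, window) the per-sample statistic is that content
    term's Z score from the sample's wave-correction model (degree-1 term by
    default; ``statistic='prop_explained'`` uses the signed variance
    explained instead). Both Pearson and Spearman p-values are reported,
    with rows ordered from the largest window down, mirroring the classical
    presentation.
    """
    models = list(models)
    model_ids = [m.sample_id for m in models]
    readouts = readouts.set_index("sample_id") if "sample_id" in readouts else readouts
    missing = sorted(set(model_ids) - set(readouts.index))
    if missing:
        raise ValueError(f"PRT readouts missing for samples: {missing}")
    ratios = readouts.loc[model_ids, "ratio"].to_numpy(dtype=float)

    if windows is None:
        windows = sorted(
            {t[1] for m in models for t in m.terms if isinstance(t, tuple)},
            reverse=True,
        )
    else:
        windows = sorted({int(w) for w in windows}, reverse=True)

    columns = pd.MultiIndex.from_tuples(
        [(m, test) for m in metrics for test in ("pearson_p", "spearman_p")]
    )
    out = pd.DataFrame(index=pd.Index(windows, name="window"), columns=columns, dtype=float)
    for metric in metrics:
        for w in windows:
            stat_vals = []
            for m in models:
                if statistic == "z":
                    zs = m.z_for(metric=metric, degree=degree)
                    key = (metric, int(w), degree)
                    if key not in zs.index:
                        raise KeyError(f"term {key} absent from model {m.sample_id}")
                    stat_vals.append(float(zs[key]))
                elif statistic == "prop_explained":
                    zs = m.z_for(metric=metric, degree=degree)
                    key = (metric, int(w), degree)
                    sign = np.sign(zs[key]) if key in zs.index else 1.0
                    stat_vals.append(float(sign * m.r_squared))
                else:
                    raise ValueError(f"unknown statistic {statistic!r}")
            x = np.asarray(stat_vals)
            out.loc[w, (metric, "pearson_p")] = test_association(x, ratios, "pearson")
            out.loc[w, (metric, "spearman_p")] = test_association(
                x, ratios, "spearman", seed=permutation_seed
            )
    return out


def write_table2_tsv(report: pd.DataFrame, path) -> None:
    flat = report.copy()
    flat.columns = [f"{m}_{t}" for m, t in flat.columns]
    flat.to_csv(path, sep="\t")


def read_table2_tsv(path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col="window", comment="#")
    cols = [c.split("_", 1) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples([(m, t) for m, t in cols])
    return flat
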