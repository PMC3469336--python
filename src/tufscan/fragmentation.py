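"""Fragmentation advice: which treatments physically separate a target
amplicon from its nearest high-GC element, and the predicted amplification
restoration.

Amplification of a target is suppressed only while it shares an intact DNA
fragment with a high-GC element; a restriction cut (or sonication break)
between the two restores the equal-efficiency ratio R_eq. A cut landing
inside the target destroys the amplicon itself, which is reported as a
distinct verdict, not as separation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .content import RestrictionEnzyme, TufElement, find_restriction_sites
from .intervals import GenomicInterval

__all__ = ["DigestVerdict", "advise_digest", "rank_treatments"]


@dataclass
class DigestVerdict:
    """Outcome of one in-silico digest for a target/element pair."""

    treatment: str
    separated: bool
    destroyed: bool
    cut_between: Optional[int]  # nearest cut position between target and element
    n_cuts_inside: int  # cuts within the target amplicon
    n_cuts_context: int  # cuts within +-d_max of the target
    predicted_ratio: float
    note: str = ""


def _suppressed_ratio(r_eq: float, amplitude: float, nick_rate: float, d: float) -> float:
    if not np.isfinite(d):
        return r_eq
    return r_eq * (1.0 - min(amplitude, 1.0) * float(np.exp(-nick_rate * d)))


def _nearest_element(
    target: GenomicInterval, elements: Iterable[TufElement]
) -> tuple[Optional[TufElement], float]:
    best, best_d = None, np.inf
    for el in elements:
        if el.interval.chrom != target.chrom:
            continue
        if target.overlaps(el.interval):
            return el, 0.0
        if el.interval.start > target.end:
            d = el.interval.start - target.end
        else:
            d = target.start - el.interval.end
        if d < best_d:
            best, best_d = el, float(d)
    return best, best_d


def advise_digest(
    target: GenomicInterval,
    elements: Sequence[TufElement],
    enzymes: Sequence[RestrictionEnzyme],
    sequence: str,
    amplitude: float = 0.6,
    nick_rate: float = 1e-4,
    r_eq: float = 1.43,
    d_max: float = 50_000,
) -> list[DigestVerdict]:
    """Per-enzyme verdict: separated / destroyed / still suppressed.

    Separation requires at least one cut strictly between the target's
    proximal boundary and the nearest element's proximal boundary, and no
    cut inside the target. Coordinates are linear (circular molecules
    unsupported); only the nearest element is considered.
    """
    element, d = _nearest_element(target, elements)
    verdicts = []
    for enz in enzymes:
        cuts = np.asarray(find_restriction_sites(sequence, enz))
        # a cut at p severs before base p: inside the amplicon iff start < p <= end
        inside = cuts[(cuts > target.start) & (cuts <= target.end)]
        context_lo, context_hi = target.start - d_max, target.end + d_max
        n_context = int(((cuts > context_lo) & (cuts <= context_hi)).sum())
        if element is None or d > d_max:
            verdicts.append(
                DigestVerdict(
                    enz.name, False, len(inside) > 0, None, len(inside), n_context,
                    float("nan") if len(inside) else r_eq,
                    "no element within range",
                )
            )
            continue
        if d == 0.0:
            verdicts.append(
                DigestVerdict(
                    enz.name, False, len(inside) > 0, None, len(inside), n_context,
                    float("nan") if len(inside)
                    else _suppressed_ratio(r_eq, amplitude, nick_rate, 0.0),
                    "target overlaps the element: inseparable",
                )
            )
            continue
        if element.interval.start > target.end:
            lo, hi = target.end, element.interval.start
        else:
            lo, hi = element.interval.end, target.start
        between = cuts[(cuts > lo) & (cuts <= hi)]
        if len(inside) > 0:
            verdicts.append(
                DigestVerdict(
                    enz.name, False, True,
                    int(between[np.argmin(np.abs(between - target.start))]) if len(between) else None,
                    len(inside), n_context, float("nan"),
                    "assay destroyed: cut inside the target amplicon",
                )
            )
        elif len(between) > 0:
            nearest = int(between[np.argmin(np.abs(between - (target.start + target.end) / 2))])
            verdicts.append(
                DigestVerdict(
                    enz.name, True, False, nearest, 0, n_context, r_eq,
                    "target separated from the element",
                )
            )
        else:
            verdicts.append(
                DigestVerdict(
                    enz.name, False, False, None, 0, n_context,
                    _suppressed_ratio(r_eq, amplitude, nick_rate, d),
                    "target and element remain on one fragment",
                )
            )
    return verdicts


def sonication_verdict(
    label: str,
    mean_fragment: float,
    distance: float,
    amplitude: float = 0.6,
    nick_rate: float = 1e-4,
    r_eq: float = 1.43,
) -> DigestVerdict:
    """Expected ratio under sonication: linkage survives with exp(-d/L).

    Sonication breaks are Poisson at rate 1/L per bp, so the probability
    that no break falls in the d bp between target and element is
    exp(-d/L); the expected ratio follows by averaging the suppression over
    that Bernoulli linkage.
    """
    if mean_fragment <= 0:
        raise ValueError("mean_fragment must be > 0")
    if np.isfinite(distance):
        linked = float(np.exp(-distance / mean_fragment))
        supp = min(amplitude, 1.0) * float(np.exp(-nick_rate * distance))
        ratio = r_eq * (1.0 - supp * linked)
    else:
        ratio = r_eq
    return DigestVerdict(
        label, False, False, None, 0, 0, ratio,
        f"sonication, mean fragment {mean_fragment:g} bp",
    )


def rank_treatments(verdicts: Sequence[DigestVerdict]) -> pd.DataFrame:
    """Order treatments by predicted ratio, best first.

    Destroyed assays sort last regardless of ratio; ties break first by
    fewer cuts in the +-D_max context, then by input order (deterministic).
    """
    if len(verdicts) == 0:
        raise ValueError("no verdicts to rank")
    rows = []
    for i, v in enumerate(verdicts):
        rows.append(
            {
                "treatment": v.treatment,
                "separated": v.separated,
                "destroyed": v.destroyed,
                "predicted_ratio": v.predicted_ratio,
                "n_cuts_inside": v.n_cuts_inside,
                "n_cuts_context": v.n_cuts_context,
                "note": v.note,
                "_order": i,
            }
        )
    df = pd.DataFrame(rows)
    df["_ratio_key"] = np.where(df["destroyed"], -np.inf, df["predicted_ratio"])
    df = df.sort_values(
        ["_ratio_key", "n_cuts_context", "_order"],
        ascending=[False, True, True],
        kind="stable",
    ).drop(columns=["_ratio_key", "_order"])
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)
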