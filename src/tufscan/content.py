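"""Sequence content: multi-scale GC/CpG window fractions, high-GC element
discovery, and restriction-site mapping.

The window centered at a 1-based position ``c`` with size ``w`` spans
positions ``c - (w-1)//2 .. c + w//2`` (exactly ``w`` bases away from contig
edges). Windows overhanging a contig end are clipped and the effective length
is used as the denominator. Ambiguous bases (anything outside A/C/G/T) are
excluded from both numerator and denominator, so fractions are unbiased under
masking; a window with no unambiguous bases yields NaN.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .intervals import GenomicInterval

__all__ = [
    "DEFAULT_WINDOW_SIZES",
    "window_content",
    "window_bounds",
    "WindowContentMatrix",
    "build_content_matrix",
    "TufElement",
    "find_gc_elements",
    "RestrictionEnzyme",
    "find_restriction_sites",
    "read_enzyme_table",
    "distance_to_elements",
    "amplicon_gc_summary",
]

#: The nine window scales used for the wave-correction covariates.
DEFAULT_WINDOW_SIZES = (50, 100, 500, 1_000, 10_000, 50_000, 100_000, 250_000, 1_000_000)

_ACGT = frozenset("ACGT")


def window_bounds(center: int, window_size: int, seq_len: int) -> tuple[int, int]:
    """Clipped 1-based inclusive bounds of the window around ``center``."""
    if window_size < 2:
        raise ValueError(f"window_size must be >= 2, got {window_size}")
    if not 1 <= center <= seq_len:
        raise ValueError(f"center {center} outside sequence of length {seq_len}")
    start = max(1, center - (window_size - 1) // 2)
    end = min(seq_len, center + window_size // 2)
    return start, end


def window_content(
    sequence: str, center: int, window_size: int, metric: str
) -> float:
    """GC or CpG fraction of the window centered at a 1-based position.

    GC = (#G + #C) / (#unambiguous bases); CpG = (#CG dinucleotides) /
    (#dinucleotide slots with both bases unambiguous). Returns NaN when the
    denominator is zero.
    """
    start, end = window_bounds(center, window_size, len(sequence))
    window = sequence[start - 1 : end].upper()
    if metric == "GC":
        valid = sum(1 for b in window if b in _ACGT)
        if valid == 0:
            return float("nan")
        return sum(1 for b in window if b in "GC") / valid
    if metric == "CpG":
        slots = sum(
            1
            for a, b in zip(window, window[1:])
            if a in _ACGT and b in _ACGT
        )
        if slots == 0:
            return float("nan")
        cg = sum(1 for a, b in zip(window, window[1:]) if a == "C" and b == "G")
        return cg / slots
    raise ValueError(f"metric must be 'GC' or 'CpG', got {metric!r}")


class _ChromContent:
    """Prefix-sum counters over one contig for O(1) window queries.

    Exactly reproduces substring counting: integer cumulative sums of
    unambiguous-base, G/C-base, valid-dinucleotide-slot and CG-dinucleotide
    indicators.
    """

    def __init__(self, sequence: str):
        a = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
        self.length = len(a)
        valid = (a == ord("A")) | (a == ord("C")) | (a == ord("G")) | (a == ord("T"))
        gc = (a == ord("G")) | (a == ord("C"))
        self._valid = np.concatenate(([0], np.cumsum(valid, dtype=np.int64)))
        self._gc = np.concatenate(([0], np.cumsum(gc, dtype=np.int64)))
        if len(a) > 1:
            cg = (a[:-1] == ord("C")) & (a[1:] == ord("G"))
            slot = valid[:-1] & valid[1:]
        else:
            cg = np.zeros(0, dtype=bool)
            slot = np.zeros(0, dtype=bool)
        self._cg = np.concatenate(([0], np.cumsum(cg, dtype=np.int64)))
        self._slot = np.concatenate(([0], np.cumsum(slot, dtype=np.int64)))

    def gc_fraction(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Vectorized GC fraction over 1-based inclusive spans."""
        num = self._gc[end] - self._gc[start - 1]
        den = self._valid[end] - self._valid[start - 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    def cpg_fraction(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        # dinucleotide slot i covers bases (i, i+1); slots within [start, end]
        # are start .. end-1
        num = self._cg[np.maximum(end - 1, start - 1)] - self._cg[start - 1]
        den = self._slot[np.maximum(end - 1, start - 1)] - self._slot[start - 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1), np.nan)


@dataclass
class WindowContentMatrix:
    """Probes x (metric, window) table of GC/CpG fractions.

    ``values`` is indexed by probe_id with MultiIndex columns
    (metric in {GC, CpG}, window size in bp); all entries lie in [0, 1]
    (or NaN where undefined).
    """

    values: pd.DataFrame
    window_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        self.window_sizes = tuple(int(w) for w in self.window_sizes)
        finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("content fractions must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def column(self, metric: str, window: int) -> pd.Series:
        return self.values[(metric, int(window))]

    def to_tsv(self, path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{m}_{w}" for m, w in flat.columns]
        flat.index.name = "probe_id"
        flat.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "WindowContentMatrix":
        flat = pd.read_csv(path, sep="\t", index_col="probe_id", comment="#")
        cols = [c.rsplit("_", 1) for c in flat.columns]
        flat.columns = pd.MultiIndex.from_tuples([(m, int(w)) for m, w in cols])
        windows = tuple(dict.fromkeys(w for _, w in flat.columns))
        return cls(flat, windows)


FastaLike = Union[Mapping[str, str], str]


def _as_sequences(fasta: FastaLike) -> Mapping[str, str]:
    """Accept a {chrom: sequence} mapping or a FASTA path (via pyfaidx)."""
    if isinstance(fasta, Mapping):
        return fasta
    import pyfaidx

    fa = pyfaidx.Fasta(str(fasta))
    return {name: str(fa[name][:]) for name in fa.keys()}


def build_content_matrix(
    fasta: FastaLike,
    manifest,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
) -> WindowContentMatrix:
    """GC and CpG fractions at every window scale for every manifest probe.

    Row order follows the manifest; columns are (metric, window) pairs.
    Raises a KeyError naming the first probe whose chromosome is absent.
    """
    seqs = _as_sequences(fasta)
    window_sizes = tuple(int(w) for w in window_sizes)
    frame = manifest.frame
    missing = set(frame["chrom"]) - set(seqs)
    if missing:
        probe = frame.loc[frame["chrom"].isin(missing), "probe_id"].iloc[0]
        raise KeyError(
            f"chromosome {sorted(missing)[0]!r} (probe {probe!r}) not in FASTA"
        )
    out = np.empty((len(frame), 2 * len(window_sizes)))
    columns = pd.MultiIndex.from_tuples(
        [(m, w) for m in ("GC", "CpG") for w in window_sizes]
    )
    engines = {chrom: _ChromContent(seqs[chrom]) for chrom in set(frame["chrom"])}
    for chrom, sub in frame.groupby("chrom", sort=False):
        eng = engines[chrom]
        pos = sub["pos"].to_numpy()
        if pos.max() > eng.length:
            bad = sub.loc[sub["pos"] > eng.length, "probe_id"].iloc[0]
            raise ValueError(f"probe {bad!r} lies beyond the end of {chrom!r}")
        rows = sub.index.to_numpy()
        for j, w in enumerate(window_sizes):
            start = np.maximum(1, pos - (w - 1) // 2)
            end = np.minimum(eng.length, pos + w // 2)
            out[rows, j] = eng.gc_fraction(start, end)
            out[rows, len(window_sizes) + j] = eng.cpg_fraction(start, end)
    values = pd.DataFrame(out, index=manifest.probe_ids, columns=columns)
    return WindowContentMatrix(values, window_sizes)


@dataclass(frozen=True)
class TufElement:
    """A contiguous high-GC sequence element (a candidate re-annealing nucleus)."""

    interval: GenomicInterval
    gc_fraction: float
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp != self.interval.length:
            raise ValueError("length_bp inconsistent with interval")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")


def find_gc_elements(
    sequence: str,
    min_length: int = 500,
    min_gc: float = 0.70,
    step: int = 50,
    chrom: str = "chr1",
) -> list[TufElement]:
    """Locate contiguous elements of extreme GC content.

    Windows of ``min_length`` bp are evaluated every ``step`` bp; qualifying
    windows (GC >= ``min_gc``) are merged into maximal runs, then boundaries
    are refined greedily: trimmed inward to the outermost G/C base and
    extended outward while the adjacent base is G or C. Elements closer than
    ``step`` end up merged because their qualifying windows overlap.
    Reported elements are sorted and non-overlapping; a recomputed GC
    fraction may fall below ``min_gc`` by at most ``step / min_length``.
    """
    if not 0 < min_gc <= 1:
        raise ValueError(f"min_gc must be in (0, 1], got {min_gc}")
    if len(sequence) < min_length:
        raise ValueError("sequence shorter than min_length")
    eng = _ChromContent(sequence)
    L = eng.length
    starts = np.arange(1, L - min_length + 2, step)
    ends = starts + min_length - 1
    frac = eng.gc_fraction(starts, ends)
    ok = np.where(np.nan_to_num(frac) >= min_gc)[0]
    if ok.size == 0:
        return []
    # merge runs of qualifying windows; overlapping windows chain naturally
    spans: list[list[int]] = []
    for i in ok:
        s, e = int(starts[i]), int(ends[i])
        if spans and s <= spans[-1][1] + 1:
            spans[-1][1] = max(spans[-1][1], e)
        else:
            spans.append([s, e])
    upper = sequence.upper()
    refined: list[list[int]] = []
    for s, e in spans:
        # trim inward to the outermost G/C base
        while s < e and upper[s - 1] not in "GC":
            s += 1
        while e > s and upper[e - 1] not in "GC":
            e -= 1
        # greedy outward extension through contiguous G/C
        while s > 1 and upper[s - 2] in "GC":
            s -= 1
        while e < L and upper[e] in "GC":
            e += 1
        if refined and s <= refined[-1][1]:
            refined[-1][1] = max(refined[-1][1], e)
        else:
            refined.append([s, e])
    elements = []
    tol = step / min_length
    for s, e in refined:
        if e - s + 1 < min_length:
            continue
        gc = float(eng.gc_fraction(np.array([s]), np.array([e]))[0])
        if gc < min_gc - tol:
            continue
        elements.append(
            TufElement(GenomicInterval(chrom, s, e), gc, e - s + 1)
        )
    return elements


_IUPAC = {code.upper(): set(bases.upper()) for code, bases in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition sequence (IUPAC) and cut offset.

    The cut offset is the 0-based position within the recognition site after
    which the duplex is cleaved. Matching is forward-strand only; the common
    type II enzymes have palindromic sites, for which this is exhaustive.
    """

    name: str
    recognition: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")
        bad = set(self.recognition.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes in recognition: {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition site")

    def regex(self) -> re.Pattern:
        parts = []
        for code in self.recognition.upper():
            bases = sorted(_IUPAC[code])
            parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
        return re.compile("(?=" + "".join(parts) + ")")


def find_restriction_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based cut positions on the forward strand, overlapping matches included.

    A cut at position ``p`` severs the backbone immediately before base ``p``
    (fragments ``..p-1`` and ``p..``).
    """
    pattern = enzyme.regex()
    upper = sequence.upper()
    return [m.start() + 1 + enzyme.cut_offset for m in pattern.finditer(upper)]


def read_enzyme_table(path) -> list[RestrictionEnzyme]:
    """Read a TSV of (name, recognition, cut_offset) into enzymes."""
    table = pd.read_csv(path, sep="\t", comment="#")
    return [
        RestrictionEnzyme(str(r.name), str(r.recognition), int(r.cut_offset))
        for r in table.itertuples(index=False)
    ]


def distance_to_elements(
    positions: np.ndarray, elements: Iterable[TufElement], chrom: Optional[str] = None
) -> np.ndarray:
    """Distance in bp from each position to the nearest element boundary.

    0 inside an element; ``inf`` when no element exists on the chromosome.
    When ``chrom`` is given only elements on that chromosome are considered.
    """
    positions = np.asarray(positions, dtype=float)
    out = np.full(positions.shape, np.inf)
    for el in elements:
        if chrom is not None and el.interval.chrom != chrom:
            continue
        s, e = el.interval.start, el.interval.end
        d = np.where(
            (positions >= s) & (positions <= e),
            0.0,
            np.where(positions < s, s - positions, positions - e),
        )
        out = np.minimum(out, d)
    return out


def amplicon_gc_summary(fasta: FastaLike, intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    """Per-amplicon GC fraction plus the across-amplicon mean (as attrs).

    Useful for comparing test vs reference amplicon composition of paralogue
    ratio test designs against a reference genome.
    """
    seqs = _as_sequences(fasta)
    rows = []
    for iv in intervals:
        if iv.chrom not in seqs:
            raise KeyError(f"chromosome {iv.chrom!r} not in FASTA")
        eng = _ChromContent(seqs[iv.chrom])
        gc = float(eng.gc_fraction(np.array([iv.start]), np.array([iv.end]))[0])
        rows.append({"region": str(iv), "label": iv.label, "length": iv.length, "gc": gc})
    out = pd.DataFrame(rows)
    out.attrs["mean_gc"] = float(out["gc"].mean()) if len(out) else float("nan")
    return out
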