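"""Genomic coordinate primitives.

All user-facing coordinates are 1-based and fully closed, the convention used
by genome browsers and PCR amplicon tables: the interval chr2:100-102 covers
three bases. BED input/output converts to/from the 0-based half-open BED
convention losslessly.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "GenomicInterval",
    "interval_length",
    "ProbeManifest",
    "read_bed",
    "write_bed",
]

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        """Number of bases covered (end - start + 1)."""
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def distance_to(self, pos: int) -> int:
        """Gap in bp between ``pos`` and the nearest boundary; 0 if inside."""
        if self.contains(pos):
            return 0
        return self.start - pos if pos < self.start else pos - self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    @classmethod
    def from_string(cls, region: str, label: Optional[str] = None) -> "GenomicInterval":
        """Parse ``chr2:241,151,005-241,151,733`` style region strings."""
        m = _REGION_RE.match(region.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {region!r}")
        chrom, start, end = m.groups()
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")), label)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp of a 1-based fully-closed interval (end - start + 1)."""
    return interval.length


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file (0-based half-open) into 1-based closed intervals.

    Only the first four columns (chrom, chromStart, chromEnd, name) are used.
    """
    intervals = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        label = fields[3] if len(fields) > 3 else None
        intervals.append(GenomicInterval(chrom, start0 + 1, end0, label))
    return intervals


def write_bed(path, intervals: Iterable[GenomicInterval], scores=None) -> None:
    """Write intervals as BED (0-based half-open), with optional scores."""
    intervals = list(intervals)
    if scores is None:
        scores = [0] * len(intervals)
    with open(path, "w") as fh:
        for iv, score in zip(intervals, scores):
            name = iv.label if iv.label is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\n")


class ProbeManifest:
    """Ordered table of array probes: (probe_id, chrom, pos).

    Records are kept sorted by (chrom, pos); probe ids must be unique.
    Mirrors the information carried by an array manifest file.
    """

    COLUMNS = ("probe_id", "chrom", "pos")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["pos"] = frame["pos"].astype(int)
        if frame["probe_id"].duplicated().any():
            dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if (frame["pos"] < 1).any():
            raise ValueError("probe positions must be 1-based (>= 1)")
        frame = frame.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self.frame.itertuples(index=False))

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.frame["probe_id"])

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def positions(self, chrom: str) -> pd.Series:
        sub = self.frame[self.frame["chrom"] == chrom]
        return sub.set_index("probe_id")["pos"]

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "ProbeManifest":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def from_tsv(cls, path) -> "ProbeManifest":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeManifest) and self.frame.equals(other.frame)
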