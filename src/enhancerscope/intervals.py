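"""Interval algebra, BED/bedGraph I/O, in-silico digestion and coverage.

Coordinates are 0-based half-open throughout, the BED native convention.
Any 1-based inclusive coordinate (the usual browser display) must be
converted at the boundary of the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "FragmentMap",
    "read_bed",
    "write_bed",
    "write_bed9_rgb",
    "read_bedgraph",
    "write_bedgraph",
    "digest",
    "mean_coverage_in_window",
    "overlap_count",
    "overlapping_sets",
    "parse_region",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: shared bases exist iff max(starts) < min(ends)."""
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return replace(
            self, start=max(self.start, other.start), end=min(self.end, other.end)
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (0-based half-open) into an interval."""
    m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", text.replace(",", ""))
    if m is None:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    return GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3)))


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals.

    Raises :class:`ValueError` naming the offending line on malformed
    coordinates (non-integer, or start >= end).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def write_bed9_rgb(
    records: Sequence[GenomicInterval],
    path: str | Path,
    low_color: tuple[int, int, int] = (255, 255, 255),
    high_color: tuple[int, int, int] = (255, 0, 0),
) -> None:
    """Write a BED9 activity track with itemRgb proportional to score.

    Scores are min-max scaled onto a linear ramp from ``low_color`` to
    ``high_color``; monotone scores map to monotone colour intensity and
    equal scores receive equal colours.
    """
    records = list(records)
    if not records:
        Path(path).write_text("")
        return
    scores = np.array([iv.score for iv in records], dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite for RGB export")
    lo, hi = scores.min(), scores.max()
    span = hi - lo if hi > lo else 1.0
    lo_c = np.array(low_color, dtype=float)
    hi_c = np.array(high_color, dtype=float)
    with open(path, "w") as fh:
        for iv, s in zip(records, scores):
            t = (s - lo) / span
            rgb = np.rint(lo_c + t * (hi_c - lo_c)).astype(int)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t"
                f"{iv.strand}\t{iv.start}\t{iv.end}\t{rgb[0]},{rgb[1]},{rgb[2]}\n"
            )


# ---------------------------------------------------------------------------
# Signal tracks (bedGraph)


@dataclass
class SignalTrack:
    """Sorted, non-overlapping intervals with one value each (bedGraph)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts, ends, values must have equal length")
        if np.any(self.starts >= self.ends):
            raise ValueError("every interval needs start < end")
        if len(self.starts) > 1:
            if np.any(np.diff(self.starts) < 0):
                raise ValueError("intervals must be sorted by start")
            if np.any(self.ends[:-1] > self.starts[1:]):
                raise ValueError("intervals must not overlap")

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[GenomicInterval], values: Sequence[float]
    ) -> "SignalTrack":
        ivs = sorted(intervals)
        order = sorted(range(len(intervals)), key=lambda i: intervals[i])
        return cls(
            ivs[0].chrom if ivs else "chr",
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
            np.array([values[i] for i in order], dtype=float),
        )

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, int(s), int(e))
            for s, e in zip(self.starts, self.ends)
        ]


def read_bedgraph(path: str | Path) -> SignalTrack:
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need 4 columns in bedGraph")
            chroms.append(fields[0])
            starts.append(int(fields[1]))
            ends.append(int(fields[2]))
            values.append(float(fields[3]))
    if chroms and len(set(chroms)) > 1:
        raise ValueError("SignalTrack supports a single chromosome per file")
    return SignalTrack(chroms[0] if chroms else "chr", starts, ends, values)


def write_bedgraph(track: SignalTrack, path: str | Path, precision: int = 6) -> None:
    """Write a bedGraph; NaN values (masked bins) are omitted from the file."""
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.values):
            if np.isnan(v):
                continue
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.{precision}g}\n")


# ---------------------------------------------------------------------------
# Restriction digestion


@dataclass
class FragmentMap:
    """Restriction fragments tiling one chromosome without gaps.

    ``boundaries`` holds the n+1 fragment edges including 0 and the
    chromosome length; fragment i is ``[boundaries[i], boundaries[i+1])``.
    """

    chrom: str
    boundaries: np.ndarray
    enzyme_site: str

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        if len(self.boundaries) < 2 or self.boundaries[0] != 0:
            raise ValueError("boundaries must start at 0 and define >=1 fragment")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    def __len__(self) -> int:
        return len(self.boundaries) - 1

    @property
    def chrom_length(self) -> int:
        return int(self.boundaries[-1])

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.boundaries[:-1] + self.boundaries[1:]) // 2

    def fragments(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, int(s), int(e), name=f"frag_{i}")
            for i, (s, e) in enumerate(zip(self.boundaries[:-1], self.boundaries[1:]))
        ]

    def fragment_at(self, position: int) -> int:
        """Index of the fragment containing a base position."""
        if not 0 <= position < self.chrom_length:
            raise ValueError(f"position {position} outside chromosome")
        return int(np.searchsorted(self.boundaries, position, side="right") - 1)


def digest(sequence: str, site: str, chrom: str = "chr") -> FragmentMap:
    """In-silico restriction digest of a nucleotide sequence.

    A cut is placed at the first base of every occurrence of the
    recognition ``site`` (e.g. GATC for DpnII, GTAC for Csp6I); the
    resulting fragments tile ``[0, len(sequence))``.  A sequence without
    the site yields one fragment covering the whole sequence.
    """
    if not site:
        raise ValueError("recognition site must be non-empty")
    seq = sequence.upper()
    if not set(seq) <= set("ACGT"):
        raise ValueError("sequence must be over the alphabet {A, C, G, T}")
    cuts = [0]
    pos = seq.find(site)
    while pos != -1:
        if pos > 0:
            cuts.append(pos)
        pos = seq.find(site, pos + 1)
    cuts.append(len(seq))
    return FragmentMap(chrom, np.unique(cuts), site)


# ---------------------------------------------------------------------------
# Coverage and overlap


def mean_coverage_in_window(track: SignalTrack, window: GenomicInterval) -> float:
    """Length-weighted mean of track values over a window.

    Bases not covered by any track interval contribute value 0, matching
    bedGraph sparse-representation semantics.
    """
    if window.chrom != track.chrom:
        raise ValueError(
            f"window chromosome {window.chrom!r} != track chromosome {track.chrom!r}"
        )
    if window.width == 0:
        raise ValueError("zero-length window")
    ov = np.minimum(track.ends, window.end) - np.maximum(track.starts, window.start)
    ov = np.clip(ov, 0, None)
    return float(np.sum(ov * track.values) / window.width)


def overlapping_sets(
    target: GenomicInterval,
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> list[str]:
    """Names of the peak sets with at least one peak overlapping target."""
    return [
        name
        for name, peaks in peak_sets.items()
        if any(target.overlaps(p) for p in peaks)
    ]


def overlap_count(
    target: GenomicInterval,
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> int:
    """Number of distinct peak sets with >=1 peak overlapping target."""
    return len(overlapping_sets(target, peak_sets))
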