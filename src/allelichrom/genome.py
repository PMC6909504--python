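"""Genomic coordinate backbone: intervals, restriction fragments, fixed-width bins.

All internal coordinates are 0-based half-open. Region strings in the
``chr7:5,000,001-5,250,000`` style (as printed in genome browsers and
papers) are 1-based inclusive and are converted on input by
:meth:`GenomicInterval.from_region_string`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "RestrictionFragmentMap",
    "BinnedTrack",
    "SubdomainPartition",
    "digest",
    "locate_fragment",
    "bin_positions",
    "coverage_track",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, position: float) -> bool:
        return self.start <= position < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @classmethod
    def from_region_string(cls, region: str) -> "GenomicInterval":
        """Parse a 1-based inclusive region string into 0-based half-open.

        ``"chr7:5,000,001-5,250,000"`` -> ``GenomicInterval("chr7",
        5000000, 5250000)``.
        """
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", region.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {region!r}")
        start_1 = int(m.group(2).replace(",", ""))
        end_1 = int(m.group(3).replace(",", ""))
        return cls(m.group(1), start_1 - 1, end_1)

    def __str__(self) -> str:  # browser style, back to 1-based inclusive
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class RestrictionFragmentMap:
    """Tiling restriction fragments of one chromosome.

    ``boundaries`` has ``n_fragments + 1`` strictly increasing positions;
    fragment ``i`` is ``[boundaries[i], boundaries[i+1])``.
    """

    chrom: str
    boundaries: np.ndarray
    enzyme_name: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=np.int64)
        object.__setattr__(self, "boundaries", b)
        if b.size < 2:
            raise ValueError("need at least 2 boundaries (one fragment)")
        if not np.all(np.diff(b) > 0):
            raise ValueError("fragment boundaries must be strictly increasing")

    @property
    def n_fragments(self) -> int:
        return self.boundaries.size - 1

    @property
    def chrom_length(self) -> int:
        return int(self.boundaries[-1])

    @property
    def starts(self) -> np.ndarray:
        return self.boundaries[:-1]

    @property
    def ends(self) -> np.ndarray:
        return self.boundaries[1:]

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def fragment(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, int(self.boundaries[i]), int(self.boundaries[i + 1])
        )

    def __len__(self) -> int:
        return self.n_fragments


def digest(
    sequence: str | None = None,
    enzyme_motif: str | None = None,
    chrom_length: int | None = None,
    cut_sites: Sequence[int] | None = None,
    chrom: str = "chr",
    enzyme_name: str = "",
) -> RestrictionFragmentMap:
    """In-silico restriction digestion.

    Either scan ``sequence`` for every (possibly overlapping) occurrence of
    ``enzyme_motif`` — the cut is placed at the motif start, the convention
    for blunt 4-cutters such as DpnII (^GATC) — or accept an explicit
    ``cut_sites`` list with a ``chrom_length``.
    """
    if sequence is not None:
        if not sequence:
            raise ValueError("empty sequence")
        if not enzyme_motif:
            raise ValueError("enzyme motif must be non-empty")
        if len(enzyme_motif) > len(sequence):
            raise ValueError("motif longer than sequence")
        seq = sequence.upper()
        motif = enzyme_motif.upper()
        # overlapping scan via lookahead
        cuts = [m.start() for m in re.finditer(f"(?={re.escape(motif)})", seq)]
        length = len(seq) if chrom_length is None else int(chrom_length)
    else:
        if cut_sites is None or chrom_length is None:
            raise ValueError("need either sequence+motif or cut_sites+chrom_length")
        length = int(chrom_length)
        cuts = sorted(int(c) for c in cut_sites)
        if cuts and (cuts[0] < 0 or cuts[-1] > length):
            raise ValueError("cut positions outside [0, chrom_length]")
    boundaries = sorted({0, length, *cuts})
    return RestrictionFragmentMap(
        chrom=chrom, boundaries=np.array(boundaries), enzyme_name=enzyme_name
    )


def locate_fragment(fragment_map: RestrictionFragmentMap, position: int) -> int:
    """Index of the fragment whose half-open span contains ``position``."""
    b = fragment_map.boundaries
    if not (b[0] <= position < b[-1]):
        raise ValueError(
            f"position {position} outside fragment map [{b[0]}, {b[-1]})"
        )
    return int(np.searchsorted(b, position, side="right") - 1)


@dataclass
class BinnedTrack:
    """Fixed-width binned coverage: bin ``k`` spans
    ``[origin + k*bin_width, origin + (k+1)*bin_width)``."""

    chrom: str
    origin: int
    bin_width: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_index(self, position: int) -> int:
        k = (position - self.origin) // self.bin_width
        if not (0 <= k < self.n_bins):
            raise ValueError(f"position {position} outside track")
        return int(k)

    def bin_interval(self, k: int) -> GenomicInterval:
        start = self.origin + k * self.bin_width
        return GenomicInterval(self.chrom, start, start + self.bin_width)

    def copy_with(self, values: np.ndarray) -> "BinnedTrack":
        return BinnedTrack(self.chrom, self.origin, self.bin_width, values)


def bin_positions(
    positions: Sequence[int],
    origin: int,
    bin_width: int,
    n_bins: int,
    chrom: str = "chr",
) -> tuple[BinnedTrack, int]:
    """Count positions into fixed-width bins.

    Returns the track together with the number of out-of-range positions,
    which are reported rather than silently dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pos = np.asarray(positions, dtype=np.int64)
    k = (pos - origin) // bin_width if pos.size else pos
    in_range = (k >= 0) & (k < n_bins)
    counts = np.bincount(k[in_range], minlength=n_bins).astype(float)
    n_outside = int(pos.size - in_range.sum())
    if n_outside:
        logger.info("bin_positions: %d positions outside the track", n_outside)
    return BinnedTrack(chrom, origin, bin_width, counts), n_outside


def coverage_track(
    intervals: Sequence[GenomicInterval],
    origin: int,
    bin_width: int,
    n_bins: int,
    chrom: str = "chr",
) -> BinnedTrack:
    """Per-base coverage of intervals accumulated into bins.

    Each interval contributes its overlap length (in bp) to every bin it
    touches; this equals per-base accumulation followed by per-bin summation.
    """
    values = np.zeros(n_bins, dtype=float)
    track_end = origin + n_bins * bin_width
    for iv in intervals:
        lo = max(iv.start, origin)
        hi = min(iv.end, track_end)
        if lo >= hi:
            continue
        k0 = (lo - origin) // bin_width
        k1 = (hi - 1 - origin) // bin_width
        for k in range(k0, k1 + 1):
            bin_lo = origin + k * bin_width
            values[k] += min(hi, bin_lo + bin_width) - max(lo, bin_lo)
    return BinnedTrack(chrom, origin, bin_width, values)


@dataclass(frozen=True)
class SubdomainPartition:
    """Named, sorted, non-overlapping sub-domains inside a parent domain.

    Mirrors the sub-TAD partitions used for allelic contact quantification
    (e.g. a centromeric sub-domain, a small CTCF-anchored sub-TAD, and a
    telomeric sub-domain inside one TAD).
    """

    domain: GenomicInterval
    parts: tuple = field(default_factory=tuple)  # of (name, GenomicInterval)

    def __post_init__(self) -> None:
        parts = tuple(self.parts)
        object.__setattr__(self, "parts", parts)
        prev_end = None
        for name, iv in parts:
            if not self.domain.contains_interval(iv):
                raise ValueError(f"part {name!r} not contained in domain")
            if prev_end is not None and iv.start < prev_end:
                raise ValueError("parts must be sorted and non-overlapping")
            prev_end = iv.end

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.parts]

    def interval(self, name: str) -> GenomicInterval:
        for n, iv in self.parts:
            if n == name:
                return iv
        raise KeyError(name)

    def __iter__(self):
        return iter(self.parts)

    def __len__(self) -> int:
        return len(self.parts)
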