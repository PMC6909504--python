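"""Plain-text readers/writers: BED, bedGraph, dense matrix, TSV tables.

Writers are deterministic: rows sorted by (chrom, start), numbers formatted
with 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GenomicInterval, RestrictionFragmentMap

__all__ = [
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_binned_track",
    "read_binned_track",
    "write_fragment_track",
    "read_fragment_map",
    "write_fragment_map",
    "write_dense_matrix",
    "read_dense_matrix",
]

_FMT = "{:.6g}"


def _fmt(x: float) -> str:
    return _FMT.format(float(x))


def write_bed(
    path: str | Path,
    intervals: Iterable[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        row = [iv.chrom, iv.start, iv.end]
        if names is not None:
            row.append(names[i])
        if scores is not None:
            if names is None:
                row.append(".")
            row.append(_fmt(scores[i]))
        rows.append(row)
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str | None]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            name = fields[3] if len(fields) > 3 else None
            out.append((iv, name))
    return out


def write_bedgraph(
    path: str | Path,
    intervals: Iterable[GenomicInterval],
    values: Sequence[float],
) -> None:
    rows = sorted(
        ((iv.chrom, iv.start, iv.end, v) for iv, v in zip(intervals, values)),
        key=lambda r: (r[0], r[1]),
    )
    with open(path, "w") as fh:
        for chrom, start, end, v in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(v)}\n")


def read_bedgraph(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            out.append((GenomicInterval(chrom, int(start), int(end)), float(value)))
    return out


def write_binned_track(path: str | Path, track: BinnedTrack) -> None:
    intervals = [track.bin_interval(k) for k in range(track.n_bins)]
    write_bedgraph(path, intervals, track.values)


def read_binned_track(path: str | Path) -> BinnedTrack:
    """Read a bedGraph of equal-width, contiguous bins back into a track."""
    rows = read_bedgraph(path)
    if not rows:
        raise ValueError(f"empty bedGraph: {path}")
    rows.sort(key=lambda r: r[0].start)
    widths = {iv.width for iv, _ in rows}
    if len(widths) != 1:
        raise ValueError("bedGraph bins are not equal-width")
    (width,) = widths
    chrom = rows[0][0].chrom
    origin = rows[0][0].start
    n_bins = (rows[-1][0].end - origin) // width
    values = np.zeros(n_bins)
    for iv, v in rows:
        values[(iv.start - origin) // width] = v
    return BinnedTrack(chrom, origin, width, values)


def write_fragment_track(
    path: str | Path, fragment_map: RestrictionFragmentMap, values: Sequence[float]
) -> None:
    intervals = [fragment_map.fragment(i) for i in range(fragment_map.n_fragments)]
    write_bedgraph(path, intervals, values)


def write_fragment_map(path: str | Path, fragment_map: RestrictionFragmentMap) -> None:
    intervals = [fragment_map.fragment(i) for i in range(fragment_map.n_fragments)]
    write_bed(path, intervals, names=[str(i) for i in range(len(intervals))])


def read_fragment_map(path: str | Path, enzyme_name: str = "") -> RestrictionFragmentMap:
    rows = read_bed(path)
    if not rows:
        raise ValueError(f"empty fragment BED: {path}")
    rows.sort(key=lambda r: r[0].start)
    boundaries = [rows[0][0].start] + [iv.end for iv, _ in rows]
    return RestrictionFragmentMap(
        chrom=rows[0][0].chrom, boundaries=np.array(boundaries), enzyme_name=enzyme_name
    )


def write_dense_matrix(path: str | Path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.6g", delimiter="\t")


def read_dense_matrix(path: str | Path) -> np.ndarray:
    values = np.loadtxt(path, ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix in {path} is not square: {values.shape}")
    return values


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
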