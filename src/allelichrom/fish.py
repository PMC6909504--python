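"""3D DNA-FISH distance analysis.

Consumes segmented spot centers of mass (this module does not segment
images): spots outside the DAPI-segmented nucleus mask are discarded,
closest-neighbor inter-probe distances are measured between channels,
distances are normalized to the genomic separation of the probes, and
conditions are compared with a two-tailed unpaired Mann-Whitney test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm, rankdata

from .stats import TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "EllipsoidMask",
    "Nucleus",
    "DistanceRecord",
    "filter_spots",
    "pair_closest",
    "normalize_distance",
    "mann_whitney",
]


@dataclass(frozen=True)
class EllipsoidMask:
    """Axis-aligned ellipsoid nucleus mask (a sphere when radii are equal)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    @classmethod
    def sphere(cls, center, radius: float) -> "EllipsoidMask":
        return cls(tuple(center), (radius, radius, radius))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - np.asarray(self.center)) / np.asarray(self.radii)
        return (rel**2).sum(axis=1) <= 1.0


@dataclass
class Nucleus:
    """One segmented nucleus: mask plus per-channel 3D spot coordinates (um)."""

    id: str
    mask: EllipsoidMask
    spots: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for channel, coords in self.spots.items():
            coords = np.asarray(coords, dtype=float).reshape(-1, 3)
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"non-finite spot coordinates in channel {channel}")
            clean[channel] = coords
        self.spots = clean


@dataclass(frozen=True)
class DistanceRecord:
    nucleus_id: str
    channel_a: str
    channel_b: str
    distance: float  # um
    genomic_separation: int = 0  # bp
    normalized_distance: float = float("nan")

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def filter_spots(nucleus: Nucleus) -> Nucleus:
    """Keep only spots inside the nucleus mask; removals are logged."""
    kept = {}
    n_removed = 0
    for channel, coords in nucleus.spots.items():
        if coords.shape[0] == 0:
            kept[channel] = coords
            continue
        inside = nucleus.mask.contains(coords)
        n_removed += int((~inside).sum())
        kept[channel] = coords[inside]
    if n_removed:
        logger.info("nucleus %s: removed %d spots outside mask", nucleus.id, n_removed)
    return Nucleus(nucleus.id, nucleus.mask, kept)


def pair_closest(
    spots_a: np.ndarray, spots_b: np.ndarray
) -> list[tuple[int, int, float]]:
    """Mutual-nearest-neighbor spot pairing between two channels.

    Each A-spot is matched to its nearest B-spot (Euclidean) and the pair is
    kept only when the A-spot is also that B-spot's nearest neighbor, which
    avoids double assignment when spot counts differ (e.g. two alleles plus
    a noise spot). Returns (index_a, index_b, distance) triples.
    """
    a = np.asarray(spots_a, dtype=float).reshape(-1, 3)
    b = np.asarray(spots_b, dtype=float).reshape(-1, 3)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty spot channel")
    d = cdist(a, b)
    nearest_b = d.argmin(axis=1)
    nearest_a = d.argmin(axis=0)
    pairs = []
    for i, j in enumerate(nearest_b):
        if nearest_a[j] == i:
            pairs.append((i, int(j), float(d[i, j])))
    return pairs


def normalize_distance(
    distance_um: float, genomic_separation_bp: int, model=None
) -> float:
    """Normalize a physical distance to the probes' genomic separation.

    Default model: micrometers per megabase (distance / separation-in-Mb);
    any callable mapping bp -> expected scale can be supplied instead.
    """
    if genomic_separation_bp <= 0:
        raise ValueError("genomic separation must be positive")
    scale = (
        genomic_separation_bp / 1e6 if model is None else model(genomic_separation_bp)
    )
    return float(distance_um) / scale


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #ties, via joint average ranks."""
    nx = x.size
    ranks = rankdata(np.concatenate([x, y]), method="average")
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact permutation p-value for U, tie-aware.

    Enumerates the rank-sum distribution over all C(nx+ny, nx) assignments
    of the pooled values to the first group, via a generating-function
    convolution over doubled average ranks (doubling keeps half-ranks from
    tie groups integral). Equivalent to complete enumeration; exact integer
    arithmetic throughout.
    """
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * rankdata(pooled, method="average")).astype(int)
    n = nx + ny
    # dp[k][s]: number of size-k subsets with doubled-rank sum s
    max_sum = int(ranks2.sum())
    dp = [[0] * (max_sum + 1) for _ in range(nx + 1)]
    dp[0][0] = 1
    for r in ranks2.tolist():
        for k in range(min(nx, n) - 1, -1, -1):
            row = dp[k]
            nxt = dp[k + 1]
            for s in range(max_sum - r, -1, -1):
                c = row[s]
                if c:
                    nxt[s + r] += c
    mu2 = nx * ny  # doubled-scale mean of U
    offset2 = nx * (nx + 1)
    dev_obs = abs(2 * u_obs - mu2)
    n_hits = 0
    n_total = 0
    for s, count in enumerate(dp[nx]):
        if count:
            n_total += count
            if abs((s - offset2) - mu2) >= dev_obs - 1e-9:
                n_hits += count
    return n_hits / n_total


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-tailed unpaired Mann-Whitney test.

    U counts (x, y) pairs with x > y, plus half of the ties. For combined
    sample sizes up to 20 (``mode="auto"`` or ``"exact"``) the two-sided
    p-value is exact: every assignment of the pooled values to the two
    groups is enumerated and p is the fraction with |U - nx*ny/2| at least
    as large as observed, which handles ties correctly. Larger samples use
    the normal approximation with tie-corrected variance and continuity
    correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("empty sample")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    u_obs = _u_statistic(x, y)
    mu = nx * ny / 2.0
    use_exact = mode == "exact" or (mode == "auto" and nx + ny <= 20)
    if use_exact:
        p = _exact_two_sided_p(x, y, u_obs)
        return TestResult("U", u_obs, p, exact=True, n=nx + ny)
    # normal approximation with tie correction and continuity correction
    pooled = np.concatenate([x, y])
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values identical
        return TestResult("U", u_obs, 1.0, exact=False, n=n)
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return TestResult("U", u_obs, p, exact=False, n=n)
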