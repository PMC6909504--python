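"""Hi-C matrix balancing and insulation-based TAD-border calling.

Binned contact matrices (10-kb default) are balanced by iterative correction
(ICE): rows/columns are alternately rescaled until every unmasked row sum
equals the mean. TAD borders are then called as local minima of the
insulation index — the mean contact signal in a square window sliding along
the diagonal — that fall at or below a cutoff. The published absolute cutoff
(21.75) is specific to the published normalization scale, so a percentile
cutoff is accepted as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMatrix",
    "InsulationProfile",
    "IceConvergenceError",
    "ice_balance",
    "insulation_index",
    "call_boundaries",
]


class IceConvergenceError(RuntimeError):
    pass


@dataclass
class ContactMatrix:
    """Square symmetric binned contact matrix."""

    bin_width: int
    origin: int
    values: np.ndarray
    chrom: str = "chr"
    balanced: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if v.shape[0] < 3:
            raise ValueError("matrix must be at least 3x3")
        if np.any(v < 0):
            raise ValueError("contacts must be non-negative")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric within 1e-9")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_mask(self) -> np.ndarray:
        """True for unusable (all-zero) bins."""
        return self.values.sum(axis=0) == 0

    def copy_with(self, values: np.ndarray, balanced: bool | None = None) -> "ContactMatrix":
        return ContactMatrix(
            self.bin_width,
            self.origin,
            values,
            self.chrom,
            self.balanced if balanced is None else balanced,
        )


def ice_balance(
    matrix: ContactMatrix, tolerance: float = 1e-5, max_iter: int = 200
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction: equalize row/column sums of a symmetric matrix.

    All-zero rows are masked out first. Iterates M <- M / (b b^T) with
    b = rowsum / mean(rowsum) until every unmasked row sum is within
    ``tolerance`` (relative) of the mean; the total signal is preserved.
    Returns the balanced matrix and the per-bin scaling vector (masked bins
    get a scaling of 0).

    Raises :class:`IceConvergenceError` with the final residual if the
    iteration does not converge within ``max_iter``.
    """
    m = matrix.values.copy()
    masked = matrix.bin_mask
    active = ~masked
    if not active.any():
        raise ValueError("matrix has no non-zero rows")
    bias = np.ones(matrix.n_bins)
    residual = np.inf
    for _ in range(max_iter):
        s = m.sum(axis=1)
        mean_s = s[active].mean()
        residual = float(np.abs(s[active] / mean_s - 1.0).max())
        if residual <= tolerance:
            break
        update = np.where(active, s / mean_s, 1.0)
        m /= np.outer(update, update)
        bias *= update
    else:
        raise IceConvergenceError(
            f"ICE did not converge in {max_iter} iterations "
            f"(final residual {residual:.3e}, tolerance {tolerance:.3e})"
        )
    # preserve total signal exactly
    total_in, total_out = matrix.values.sum(), m.sum()
    if total_out > 0:
        m *= total_in / total_out
    bias[masked] = 0.0
    return matrix.copy_with(m, balanced=True), bias


@dataclass
class InsulationProfile:
    """Per-bin insulation index with a validity mask for edge/masked bins."""

    values: np.ndarray  # NaN where invalid
    window_bp: int
    bin_width: int
    origin: int
    chrom: str = "chr"
    valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.isfinite(self.values)


def insulation_index(
    matrix: ContactMatrix,
    window_bp: int = 500_000,
    min_coverage: float = 0.5,
) -> InsulationProfile:
    """Mean contact signal in the w x w square across each bin.

    Index at bin i averages entries over rows (i-w .. i-1) and columns
    (i+1 .. i+w), w = window_bp / bin_width. Bins without a full square
    (within w of either matrix edge) are masked. Squares overlapping masked
    (all-zero) bins average the available entries and require at least
    ``min_coverage`` of the square to be usable, else they are masked too.
    """
    if window_bp % matrix.bin_width != 0:
        raise ValueError("window must be a multiple of the bin width")
    w = window_bp // matrix.bin_width
    n = matrix.n_bins
    if w < 1 or 2 * w + 1 > n:
        raise ValueError("window too large for matrix")
    good = ~matrix.bin_mask
    values = np.full(n, np.nan)
    m = matrix.values
    for i in range(w, n - w):
        rows = slice(i - w, i)
        cols = slice(i + 1, i + 1 + w)
        weight = np.outer(good[rows], good[cols])
        n_valid = weight.sum()
        if n_valid < min_coverage * w * w:
            continue
        values[i] = float((m[rows, cols] * weight).sum() / n_valid)
    return InsulationProfile(
        values, window_bp, matrix.bin_width, matrix.origin, matrix.chrom
    )


def call_boundaries(
    profile: InsulationProfile,
    cutoff: float | None = None,
    cutoff_percentile: float | None = None,
) -> list[int]:
    """Boundary bins: local insulation minima with index value <= cutoff.

    A minimum must be strictly lower than the nearest differing valid
    neighbors on both sides; a plateau of equal minimal values yields its
    center bin. ``cutoff_percentile`` computes the cutoff from the valid
    index values (e.g. 10 for the 10th percentile).
    """
    v = profile.values
    valid_idx = np.flatnonzero(profile.valid)
    if valid_idx.size == 0:
        return []
    if cutoff_percentile is not None:
        if cutoff is not None:
            raise ValueError("give either cutoff or cutoff_percentile, not both")
        cutoff = float(np.percentile(v[valid_idx], cutoff_percentile))
    if cutoff is None or not np.isfinite(cutoff):
        raise ValueError("a finite cutoff (or percentile) is required")
    vv = v[valid_idx]  # contiguous valid profile
    boundaries = []
    i = 0
    while i < vv.size:
        j = i
        while j + 1 < vv.size and vv[j + 1] == vv[i]:
            j += 1
        lower_left = i > 0 and vv[i - 1] > vv[i]
        lower_right = j < vv.size - 1 and vv[j + 1] > vv[i]
        if lower_left and lower_right and vv[i] <= cutoff:
            boundaries.append(int(valid_idx[(i + j) // 2]))
        i = j + 1
    return boundaries
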