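"""RNA-seq detection and differential-expression compound rule.

Applied to transcript-level TPM tables from two mono-parental samples
(parthenogenetic, two maternal genomes, vs androgenetic, two paternal
genomes), so a sample-level expression difference is an allele-level
difference. Replicates are quantile-normalized against each other and
averaged; a transcript is *detected* when its combined TPM reaches 5 in
either sample, and *differential* when additionally the larger/smaller fold
is >= 1.5 and (largest TPM) x (fold) >= 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip import quantile_normalize

__all__ = [
    "ExpressionTable",
    "combine_replicates",
    "detect_genes",
    "call_differential_expression",
]

#: the smaller TPM is floored here before fold computation, so a zero
#: denominator yields a large finite fold rather than an undefined one
ZERO_TPM_FLOOR = 0.1


@dataclass
class ExpressionTable:
    """Replicate-level TPM table plus the sample each column belongs to."""

    replicates: pd.DataFrame  # transcripts x replicate columns
    sample_of: dict[str, str]  # replicate column -> sample label
    combined: pd.DataFrame | None = None  # transcripts x sample columns

    def __post_init__(self) -> None:
        if (self.replicates.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.replicates.columns) - set(self.sample_of)
        if missing:
            raise ValueError(f"replicate columns without a sample label: {missing}")
        sums = self.replicates.sum(axis=0)
        off = sums[(sums - 1e6).abs() > 1e3]
        if len(off):
            warnings.warn(
                f"replicate columns do not sum to 1e6 within 0.1%: {list(off.index)}",
                stacklevel=2,
            )

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for col in self.replicates.columns:
            s = self.sample_of[col]
            if s not in seen:
                seen.append(s)
        return seen


def combine_replicates(table: ExpressionTable) -> ExpressionTable:
    """Quantile-normalize all replicate columns together, then average per
    sample. With a single replicate overall, normalization is skipped with a
    warning."""
    df = table.replicates
    if df.shape[1] >= 2:
        normalized = quantile_normalize([df[c].to_numpy(float) for c in df.columns])
        norm_df = pd.DataFrame(
            np.column_stack(normalized), index=df.index, columns=df.columns
        )
    else:
        warnings.warn("single replicate: skipping quantile normalization", stacklevel=2)
        norm_df = df.astype(float)
    combined = pd.DataFrame(index=df.index)
    for sample in table.samples:
        cols = [c for c in df.columns if table.sample_of[c] == sample]
        combined[sample] = norm_df[cols].mean(axis=1)
    return ExpressionTable(table.replicates, table.sample_of, combined)


def _require_combined(table: ExpressionTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        combined = table
    else:
        if table.combined is None:
            raise ValueError("run combine_replicates first")
        combined = table.combined
    if combined.shape[1] != 2:
        raise ValueError("expected exactly two combined samples")
    if (combined.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    return combined


def detect_genes(
    table: ExpressionTable | pd.DataFrame, tpm_min: float = 5.0
) -> pd.Series:
    """Detected iff the combined TPM in either sample is >= ``tpm_min``
    (inclusive)."""
    combined = _require_combined(table)
    return combined.max(axis=1) >= tpm_min


def call_differential_expression(
    table: ExpressionTable | pd.DataFrame,
    tpm_min: float = 5.0,
    fold_min: float = 1.5,
    product_min: float = 50.0,
    zero_floor: float = ZERO_TPM_FLOOR,
) -> pd.DataFrame:
    """The compound differential rule on two combined samples.

    Differential iff max TPM >= ``tpm_min`` AND fold (max over
    floored min) >= ``fold_min`` AND max * fold >= ``product_min``; all
    thresholds inclusive. Returns a frame with the per-transcript max, fold,
    product, detected/differential flags and the higher-expressed sample.
    """
    combined = _require_combined(table)
    hi = combined.max(axis=1)
    lo = combined.min(axis=1).clip(lower=zero_floor)
    fold = hi / lo
    out = pd.DataFrame(index=combined.index)
    for c in combined.columns:
        out[c] = combined[c]
    out["max_tpm"] = hi
    out["fold"] = fold
    out["product"] = hi * fold
    out["detected"] = hi >= tpm_min
    out["differential"] = (
        (hi >= tpm_min) & (fold >= fold_min) & (hi * fold >= product_min)
    )
    out["direction"] = combined.idxmax(axis=1).where(out["differential"], "")
    return out
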