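"""SNP-based allelic read assignment and strand-aware read extension.

In a hybrid cross (e.g. C57BL/6 x JF1) every read overlapping a known strain
polymorphism can be assigned to the maternal or paternal chromosome by exact
base comparison at the SNP positions it covers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = ["Read", "SnpTable", "AlleleCall", "assign_allele", "extend_read", "assign_reads"]

MATERNAL = "maternal"
PATERNAL = "paternal"
UNINFORMATIVE = "uninformative"
CONFLICTING = "conflicting"


@dataclass(frozen=True)
class Read:
    chrom: str
    start: int
    length: int
    strand: str = "+"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("read length must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match read length")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class SnpTable:
    """Known strain polymorphisms distinguishing the parental genomes."""

    positions: np.ndarray
    maternal_bases: str
    paternal_bases: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if len(self.maternal_bases) != pos.size or len(self.paternal_bases) != pos.size:
            raise ValueError("one base per allele per SNP position required")
        if pos.size and not np.all(np.diff(pos) > 0):
            raise ValueError("SNP positions must be strictly increasing")
        for m, p in zip(self.maternal_bases, self.paternal_bases):
            if m == p:
                raise ValueError("maternal and paternal base must differ at every SNP")

    def __len__(self) -> int:
        return self.positions.size

    def swapped(self) -> "SnpTable":
        return SnpTable(self.positions, self.paternal_bases, self.maternal_bases)


@dataclass(frozen=True)
class AlleleCall:
    label: str
    n_maternal_matches: int
    n_paternal_matches: int
    n_mismatches: int


def assign_allele(read: Read, snps: SnpTable) -> AlleleCall:
    """Assign a read to a parental allele from the SNPs it covers.

    maternal / paternal: at least one SNP matches that allele and none the
    other; conflicting: both alleles matched at different SNPs;
    uninformative: no SNP overlapped, or every overlapped base matched
    neither allele (sequencing error or unknown variant). Ambiguous IUPAC
    codes count as mismatches.
    """
    if read.sequence is None:
        raise ValueError("read has no sequence")
    idx = np.searchsorted(snps.positions, [read.start, read.end])
    n_mat = n_pat = n_mis = 0
    for i in range(idx[0], idx[1]):
        base = read.sequence[snps.positions[i] - read.start].upper()
        if base == snps.maternal_bases[i].upper():
            n_mat += 1
        elif base == snps.paternal_bases[i].upper():
            n_pat += 1
        else:
            n_mis += 1
    if n_mat > 0 and n_pat == 0:
        label = MATERNAL
    elif n_pat > 0 and n_mat == 0:
        label = PATERNAL
    elif n_mat > 0 and n_pat > 0:
        label = CONFLICTING
    else:
        label = UNINFORMATIVE
    return AlleleCall(label, n_mat, n_pat, n_mis)


def extend_read(
    read: Read, target_length: int = 200, chrom_length: int | None = None
) -> GenomicInterval:
    """Extend a read to ``target_length`` bp in its 3' direction.

    Plus-strand reads keep their start and grow rightwards; minus-strand
    reads keep their (rightmost) 5' end and grow leftwards. The result is
    clipped to chromosome bounds, so reads near an edge yield shorter
    intervals rather than negative coordinates.
    """
    if target_length < read.length:
        raise ValueError("target_length must be >= read length")
    if read.strand == "+":
        start, end = read.start, read.start + target_length
    else:
        start, end = read.end - target_length, read.end
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(read.chrom, start, end)


def assign_reads(
    reads: Iterable[Read], snps: SnpTable
) -> dict[str, list[Read]]:
    """Partition reads by allele call; conflicting reads are excluded from
    the allelic groups and counted in the log."""
    groups: dict[str, list[Read]] = {
        MATERNAL: [],
        PATERNAL: [],
        UNINFORMATIVE: [],
        CONFLICTING: [],
    }
    for read in reads:
        groups[assign_allele(read, snps).label].append(read)
    logger.info(
        "allele assignment: %d maternal, %d paternal, %d uninformative, "
        "%d conflicting (excluded from allelic tracks)",
        *(len(groups[k]) for k in (MATERNAL, PATERNAL, UNINFORMATIVE, CONFLICTING)),
    )
    return groups
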