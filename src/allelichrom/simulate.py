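"""Synthetic allelic multi-omic data with known planted structure.

The generator emulates a paternally imprinted locus: one ~3-Mb chromosome
carrying a 1.6-Mb TAD split into three named sub-domains (a centromeric
sub-domain, a small CTCF-anchored sub-TAD, and a telomeric sub-domain),
mirroring the scale of an imprinted domain such as *Dlk1-Dio3*. Per-allele
contact matrices carry a power-law distance decay with multiplicative TAD
and sub-TAD blocks; 4C fragment counts are the multinomially sampled
viewpoint row; ChIP coverage is Poisson around rectangular planted peaks;
SNP-bearing reads carry hidden true-allele labels; expression tables plant
transcripts satisfying the differential rule; FISH nuclei place probe-pair
spots at polymer-scaling distances inside a spherical mask.

Every simulator takes an explicit seed and is bit-stable for a given seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fish import EllipsoidMask, Nucleus
from .fourc import FragmentTrack
from .genome import (
    BinnedTrack,
    GenomicInterval,
    RestrictionFragmentMap,
    SubdomainPartition,
)
from .hic import ContactMatrix
from .reads import Read, SnpTable

logger = logging.getLogger(__name__)

__all__ = [
    "DomainSpec",
    "PlantedPeakSpec",
    "default_domain_spec",
    "simulate_fragment_map",
    "simulate_snp_table",
    "simulate_contact_matrix",
    "conserving_subtad_boosts",
    "simulate_4c_counts",
    "simulate_chip_bins",
    "simulate_snp_reads",
    "simulate_expression",
    "simulate_fish_nuclei",
]

MATERNAL = "maternal"
PATERNAL = "paternal"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed is required")
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DomainSpec:
    """Geometry of the simulated imprinted locus."""

    chrom: str
    chrom_length: int
    tad: GenomicInterval
    partition: SubdomainPartition
    allele_labels: tuple[str, str] = (MATERNAL, PATERNAL)

    def __post_init__(self) -> None:
        if self.tad.end > self.chrom_length:
            raise ValueError("TAD extends beyond the chromosome")
        parts = self.partition.parts
        if not parts:
            raise ValueError("partition must have at least one part")
        if parts[0][1].start != self.tad.start or parts[-1][1].end != self.tad.end:
            raise ValueError("partition must cover the TAD")
        for (_, a), (_, b) in zip(parts, parts[1:]):
            if a.end != b.start:
                raise ValueError("partition parts must tile the TAD")


def default_domain_spec() -> DomainSpec:
    """One 3-Mb chromosome with a 1.6-Mb TAD split three ways.

    The middle part is a small (150-kb) sub-TAD between a 550-kb
    centromeric and a 900-kb telomeric sub-domain, matching the proportions
    of a large imprinted TAD.
    """
    chrom = "chrSim"
    tad = GenomicInterval(chrom, 700_000, 2_300_000)
    partition = SubdomainPartition(
        domain=tad,
        parts=(
            ("centromeric", GenomicInterval(chrom, 700_000, 1_250_000)),
            ("subtad", GenomicInterval(chrom, 1_250_000, 1_400_000)),
            ("telomeric", GenomicInterval(chrom, 1_400_000, 2_300_000)),
        ),
    )
    return DomainSpec(chrom=chrom, chrom_length=3_000_000, tad=tad, partition=partition)


@dataclass(frozen=True)
class PlantedPeakSpec:
    """A planted ChIP peak.

    ``height`` is the expected per-bin coverage on the paternal (baseline)
    allele; ``allele_fold`` is the expected maternal/paternal ratio, so the
    maternal height is ``height * allele_fold`` (1 = bi-allelic).
    """

    center: int
    width: int
    height: float
    allele_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.allele_fold <= 0:
            raise ValueError("allele_fold must be positive")


def simulate_fragment_map(
    chrom_length: int,
    mean_spacing: float = 400.0,
    seed=None,
    chrom: str = "chrSim",
) -> RestrictionFragmentMap:
    """Restriction-fragment boundaries as a Poisson process.

    Cut sites of a 4-cutter along random sequence are Poisson; exponential
    spacings with the given mean (~400 bp, DpnII-like) reproduce that.
    """
    rng = _rng(seed)
    n_draw = int(chrom_length / mean_spacing * 1.5) + 10
    spacings = rng.exponential(mean_spacing, size=n_draw)
    cuts = np.unique(np.cumsum(spacings).astype(np.int64))
    cuts = cuts[(cuts > 0) & (cuts < chrom_length)]
    boundaries = np.concatenate(([0], cuts, [chrom_length]))
    return RestrictionFragmentMap(chrom, boundaries, enzyme_name="sim4cutter")


def simulate_snp_table(
    chrom_length: int, density: float = 1.0 / 150.0, seed=None
) -> SnpTable:
    """Random strain SNPs at the given per-bp density with differing bases."""
    rng = _rng(seed)
    n = rng.poisson(chrom_length * density)
    positions = np.sort(rng.choice(chrom_length, size=n, replace=False))
    bases = "ACGT"
    mat, pat = [], []
    for _ in range(positions.size):
        i, j = rng.choice(4, size=2, replace=False)
        mat.append(bases[i])
        pat.append(bases[j])
    return SnpTable(positions, "".join(mat), "".join(pat))


def _expected_contacts(
    spec: DomainSpec,
    bin_width: int,
    decay_exponent: float,
    tad_boost: float,
    part_boosts: dict[str, float],
    base: float,
) -> np.ndarray:
    n = spec.chrom_length // bin_width
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = base * np.maximum(dist, 1) ** float(decay_exponent)
    centers = (idx + 0.5) * bin_width
    in_tad = (centers >= spec.tad.start) & (centers < spec.tad.end)
    expected[np.outer(in_tad, in_tad)] *= tad_boost
    for key, boost in part_boosts.items():
        if boost == 1.0:
            continue
        names = (key,) if isinstance(key, str) else tuple(key)
        in_block = np.zeros(n, dtype=bool)
        for name in names:
            iv = spec.partition.interval(name)
            in_block |= (centers >= iv.start) & (centers < iv.end)
        expected[np.outer(in_block, in_block)] *= boost
    return expected


def simulate_contact_matrix(
    spec: DomainSpec,
    bin_width: int = 10_000,
    decay_exponent: float = -1.0,
    tad_boost: float = 3.0,
    subtad_boost_by_allele: dict[str, dict[str, float]] | None = None,
    noise_dispersion: float | None = 0.1,
    base: float = 100.0,
    seed=None,
) -> dict[str, ContactMatrix]:
    """Per-allele contact matrices with planted TAD/sub-TAD blocks.

    Expected contact between bins i, j is ``base * max(|i-j|, 1)**decay``
    (the diagonal uses the distance-1 value), multiplied by ``tad_boost``
    when both bins are in the TAD and by that allele's sub-domain boost when
    both share a sub-domain block. Boost keys are part names or tuples of
    part names (a tuple plants one block over the union, e.g. a paternal
    sub-TAD spanning two maternal sub-domains). With ``noise_dispersion=None``
    the expected
    matrix is returned exactly; otherwise counts are negative-binomial
    (gamma-Poisson; dispersion 0 means pure Poisson), sampled on the upper
    triangle and mirrored.
    """
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    if tad_boost < 1:
        raise ValueError("boosts must be >= 1... or at least the TAD boost")
    if spec.chrom_length % bin_width != 0:
        warnings.warn(
            "bin width does not divide the chromosome evenly; last partial "
            "bin truncated",
            stacklevel=2,
        )
    boosts = subtad_boost_by_allele or {}
    rng = _rng(seed) if noise_dispersion is not None else None
    out = {}
    for allele in spec.allele_labels:
        expected = _expected_contacts(
            spec,
            bin_width,
            decay_exponent,
            tad_boost,
            boosts.get(allele, {}),
            base,
        )
        if noise_dispersion is None:
            values = expected
        else:
            n = expected.shape[0]
            iu = np.triu_indices(n)
            mu = expected[iu]
            if noise_dispersion > 0:
                lam = rng.gamma(
                    shape=1.0 / noise_dispersion, scale=mu * noise_dispersion
                )
            else:
                lam = mu
            counts = rng.poisson(lam).astype(float)
            values = np.zeros_like(expected)
            values[iu] = counts
            values = values + values.T - np.diag(np.diag(values))
        out[allele] = ContactMatrix(bin_width, 0, values, spec.chrom)
    return out


def conserving_subtad_boosts(
    spec: DomainSpec,
    viewpoint_bin: int,
    boosted_part: str,
    compensated_part: str,
    boost: float = 2.0,
    bin_width: int = 10_000,
    decay_exponent: float = -1.0,
    tad_boost: float = 3.0,
    base: float = 100.0,
) -> dict[str, dict[str, float]]:
    """Pure redistribution of contacts between two sub-domains.

    The maternal allele gets a sub-TAD block of the given ``boost`` over
    ``boosted_part`` only; the paternal allele gets one weaker block over
    the union of both parts (a paternal sub-TAD that the maternal-specific
    one splits), with its boost chosen so that the expected viewpoint-row
    total over the two sub-domains is identical between alleles. Seen from
    a viewpoint inside the boosted part, the maternal allele gains there and
    loses in the other part while the combined signal stays equal — an
    allele-specific sub-TAD inside an otherwise unchanged TAD.
    """
    expected = _expected_contacts(spec, bin_width, decay_exponent, tad_boost, {}, base)
    row = expected[viewpoint_bin]
    centers = (np.arange(row.size) + 0.5) * bin_width
    iv_a = spec.partition.interval(boosted_part)
    iv_b = spec.partition.interval(compensated_part)
    s_a = row[(centers >= iv_a.start) & (centers < iv_a.end)].sum()
    s_b = row[(centers >= iv_b.start) & (centers < iv_b.end)].sum()
    if s_a <= 0 or s_b <= 0:
        raise ValueError("both parts need expected viewpoint-row signal")
    union_boost = (boost * s_a + s_b) / (s_a + s_b)
    return {
        MATERNAL: {boosted_part: boost},
        PATERNAL: {(boosted_part, compensated_part): union_boost},
    }


def simulate_4c_counts(
    matrix: ContactMatrix,
    viewpoint_bin: int,
    n_reads: int,
    fragment_map: RestrictionFragmentMap,
    seed=None,
    allele: str = "combined",
) -> FragmentTrack:
    """Multinomial 4C fragment counts from the viewpoint row of a matrix.

    Per-fragment probabilities are proportional to the viewpoint-row value
    of the bin containing the fragment midpoint, spread uniformly over the
    fragments within each bin; counts sum to ``n_reads`` exactly.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not (0 <= viewpoint_bin < matrix.n_bins):
        raise ValueError("viewpoint bin outside matrix")
    rng = _rng(seed)
    row = matrix.values[viewpoint_bin]
    if row.sum() <= 0:
        raise ValueError("all-zero viewpoint row")
    mids = fragment_map.midpoints
    frag_bin = ((mids - matrix.origin) // matrix.bin_width).astype(int)
    in_range = (frag_bin >= 0) & (frag_bin < matrix.n_bins)
    frags_per_bin = np.bincount(frag_bin[in_range], minlength=matrix.n_bins)
    probs = np.zeros(fragment_map.n_fragments)
    ok = in_range.copy()
    ok[in_range] = frags_per_bin[frag_bin[in_range]] > 0
    probs[ok] = row[frag_bin[ok]] / frags_per_bin[frag_bin[ok]]
    probs /= probs.sum()
    counts = rng.multinomial(n_reads, probs).astype(float)
    vp_start = matrix.origin + viewpoint_bin * matrix.bin_width
    viewpoint = GenomicInterval(matrix.chrom, vp_start, vp_start + matrix.bin_width)
    return FragmentTrack(fragment_map, counts, viewpoint, allele=allele)


def simulate_chip_bins(
    peaks: list[PlantedPeakSpec],
    n_bins: int,
    background_rate: float = 1.0,
    input_rate: float = 20.0,
    bin_width: int = 50,
    origin: int = 0,
    input_artifacts: list[tuple[int, int, float]] | None = None,
    seed=None,
    chrom: str = "chrSim",
) -> tuple[BinnedTrack, BinnedTrack, BinnedTrack]:
    """Per-allele ChIP coverage plus an input track.

    Counts are Poisson around background plus rectangular peak profiles
    (overlapping peaks add). The input is peak-free background at
    ``input_rate``; ``input_artifacts`` are (start_bin, end_bin, factor)
    regions whose expected input is multiplied by ``factor`` (0 plants a
    no-signal region, large values plant alignment-artifact spikes) for
    blacklist testing. Returns (maternal, paternal, input).
    """
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = _rng(seed)
    expected_mat = np.full(n_bins, float(background_rate))
    expected_pat = np.full(n_bins, float(background_rate))
    for peak in peaks:
        k0 = max(0, (peak.center - peak.width // 2 - origin) // bin_width)
        k1 = min(n_bins, -(-(peak.center + peak.width // 2 - origin) // bin_width))
        expected_pat[k0:k1] += peak.height
        expected_mat[k0:k1] += peak.height * peak.allele_fold
    expected_input = np.full(n_bins, float(input_rate))
    for k0, k1, factor in input_artifacts or []:
        expected_input[k0:k1] *= factor
    maternal = BinnedTrack(chrom, origin, bin_width, rng.poisson(expected_mat))
    paternal = BinnedTrack(chrom, origin, bin_width, rng.poisson(expected_pat))
    inp = BinnedTrack(chrom, origin, bin_width, rng.poisson(expected_input))
    return maternal, paternal, inp


def simulate_snp_reads(
    snp_table: SnpTable,
    n_reads: int,
    read_length: int = 86,
    maternal_fraction: float = 0.5,
    error_rate: float = 0.0,
    chrom_length: int | None = None,
    seed=None,
    chrom: str = "chrSim",
) -> list[tuple[Read, str]]:
    """Reads of known parental origin with SNP-bearing sequences.

    The reference is 'A' at every non-SNP position; at SNPs the true
    allele's base is used; each base is then substituted with probability
    ``error_rate`` by a uniformly chosen different base. Returns (read,
    true_allele_label) pairs — the label is the hidden truth, not the call.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if not (0.0 <= maternal_fraction <= 1.0):
        raise ValueError("maternal_fraction must be in [0, 1]")
    rng = _rng(seed)
    if chrom_length is None:
        chrom_length = int(snp_table.positions[-1]) + read_length if len(snp_table) else 10 * read_length
    bases = np.array(list("ACGT"))
    out = []
    starts = rng.integers(0, max(1, chrom_length - read_length), size=n_reads)
    is_mat = rng.random(n_reads) < maternal_fraction
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    for start, mat, strand in zip(starts, is_mat, strands):
        start = int(start)
        seq = np.full(read_length, "A")
        lo, hi = np.searchsorted(snp_table.positions, [start, start + read_length])
        allele_bases = snp_table.maternal_bases if mat else snp_table.paternal_bases
        for i in range(lo, hi):
            seq[snp_table.positions[i] - start] = allele_bases[i]
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            for k in errs:
                others = bases[bases != seq[k]]
                seq[k] = others[rng.integers(0, 3)]
        read = Read(chrom, start, read_length, str(strand), "".join(seq))
        out.append((read, MATERNAL if mat else PATERNAL))
    return out


def simulate_expression(
    n_transcripts: int,
    planted: list[tuple[float, float]] | None = None,
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    base_sigma: float = 2.5,
    sample_labels: tuple[str, str] = ("PG", "AG"),
    seed=None,
) -> "pd.DataFrame":
    """Two-sample replicate-level TPM table with planted fold changes.

    ``planted`` lists (high_tpm, fold) pairs occupying the first transcripts
    (directions alternate between the two mono-parental samples: high in PG,
    then high in AG, ...). Null transcripts share a lognormal baseline and
    are scaled so each sample's expected total, planted mass included, is
    exactly 1e6; every replicate column is then rescaled to sum to 1e6
    exactly. With ``noise_cv=0`` replicates equal the expectation, making
    the planted rule arithmetic exact.

    Returns a transcripts x replicates DataFrame with columns
    ``"<sample>_<replicate>"``.
    """
    if base_sigma <= 0:
        raise ValueError("degenerate spec: base_sigma must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    planted = planted or []
    if len(planted) >= n_transcripts:
        raise ValueError("more planted transcripts than transcripts")
    rng = _rng(seed)
    n_null = n_transcripts - len(planted)
    means = {s: np.zeros(n_transcripts) for s in sample_labels}
    planted_mass = {s: 0.0 for s in sample_labels}
    for i, (high_tpm, fold) in enumerate(planted):
        if high_tpm <= 0 or fold < 1:
            raise ValueError("planted high_tpm must be > 0 and fold >= 1")
        hi_sample = sample_labels[i % 2]
        lo_sample = sample_labels[(i + 1) % 2]
        means[hi_sample][i] = high_tpm
        means[lo_sample][i] = high_tpm / fold
        planted_mass[hi_sample] += high_tpm
        planted_mass[lo_sample] += high_tpm / fold
    baseline = rng.lognormal(mean=1.0, sigma=base_sigma, size=n_null)
    for s in sample_labels:
        budget = 1e6 - planted_mass[s]
        if budget <= 0:
            raise ValueError("planted mass exceeds the TPM budget")
        means[s][len(planted):] = baseline * (budget / baseline.sum())
    columns = {}
    for s in sample_labels:
        for r in range(1, n_replicates + 1):
            if noise_cv > 0:
                sigma = np.sqrt(np.log1p(noise_cv**2))
                noise = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_transcripts)
                col = means[s] * noise
            else:
                col = means[s].copy()
            columns[f"{s}_{r}"] = col * (1e6 / col.sum())
    index = [f"tx{i:05d}" for i in range(n_transcripts)]
    return pd.DataFrame(columns, index=index)


def default_fish_scale_model(genomic_separation_bp: float, c: float = 1.0) -> float:
    """Globular-polymer scaling: expected distance (um) = c * (Mb)^(1/3)."""
    return c * (genomic_separation_bp / 1e6) ** (1.0 / 3.0)


def simulate_fish_nuclei(
    n_nuclei: int,
    probe_pairs: list[tuple[str, str]],
    genomic_separations: list[int],
    scale_model=None,
    noise_sd: float = 0.1,
    nucleus_radius: float = 5.0,
    seed=None,
) -> list[Nucleus]:
    """Nuclei with one spot pair per probe pair inside a spherical mask.

    The second spot sits at the model distance from the first in a random
    direction, plus isotropic Gaussian noise of ``noise_sd`` um per axis;
    placements are rejected until both spots fall inside the mask, so with
    ``noise_sd=0`` the measured distance equals the model value exactly.
    """
    if len(probe_pairs) != len(genomic_separations):
        raise ValueError("one genomic separation per probe pair required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    model = scale_model or default_fish_scale_model
    mask = EllipsoidMask.sphere((0.0, 0.0, 0.0), nucleus_radius)
    nuclei = []
    for k in range(n_nuclei):
        spots: dict[str, list] = {}
        for (ch_a, ch_b), sep in zip(probe_pairs, genomic_separations):
            d = float(model(sep))
            for _ in range(1000):
                a = rng.uniform(-nucleus_radius, nucleus_radius, size=3)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                b = a + d * direction + rng.normal(scale=noise_sd, size=3)
                if mask.contains(a[None, :])[0] and mask.contains(b[None, :])[0]:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not place spots inside the nucleus")
            spots.setdefault(ch_a, []).append(a)
            spots.setdefault(ch_b, []).append(b)
        nuclei.append(
            Nucleus(
                id=f"nuc{k:04d}",
                mask=mask,
                spots={ch: np.array(v) for ch, v in spots.items()},
            )
        )
    return nuclei
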