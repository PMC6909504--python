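# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not
establish about real data.

## Coordinates and fragments

All internal coordinates are 0-based half-open; BED/bedGraph output follows
the same convention. Region strings in browser style
(`chr7:5,000,001-5,250,000`) are 1-based inclusive and converted on
input. In-silico digestion places the cut at the motif start, the convention
for blunt 4-cutters such as DpnII (^GATC); only relative fragment structure
matters downstream. Reads are represented by their 5′ position and length;
the only strand-aware operation is ChIP read extension (a + read grows
rightwards from its start to 200 bp, a − read grows leftwards from its 3′
end), clipped at chromosome bounds. Reads and fragments are matched by the
position of the read's 5′ end; fragments are assigned to sub-domains by
their midpoint, which is unambiguous for border-straddling fragments.

## ChIP-seq peak pipeline

Stages run in this order: input-based blacklisting, quantile normalization,
peak calling, differential calling. A bin is blacklisted when the input is
zero or ≥ median + 3·IQR; quantiles are linear-interpolation (type 7)
throughout, and a constant input (zero IQR) degenerately blacklists
everything — warned, not hidden. All thresholds are inclusive (≥). The
value-20 peak threshold is applied to quantile-normalized values, matching
the stage order above.

Quantile normalization maps each sample's rank-r value to the across-sample
mean of sorted values; tied values share the mean reference over their tied
span. Peak cores are maximal runs of ≥ 4 consecutive bins ≥ 20 *within a
single sample*, pooled across samples ("in at least one cell type"),
extended one bin each side, with overlapping extensions merged.

`peak_value` defaults to the **mean** over the un-extended core ("max" and
"sum" are options). The reason is a property of cross-sample quantile
normalization: if one sample has N more peak-level bins than the other (a
mono-allelic peak), exactly N sorted ranks pair a peak-level value in one
sample with a background value in the other, and the averaged reference at
those ranks lands on single bins. A max statistic picks precisely those
damaged bins and systematically shrinks the observed fold of mono-allelic
peaks; the core mean — whose between-sample fold equals the fold of core
sums — is robust to single-bin damage.

## Allelic read assignment

A read is maternal if at least one covered SNP matches the maternal base and
none the paternal (symmetrically for paternal), conflicting if both alleles
match at different SNPs, and uninformative otherwise. Matching is exact base
equality; IUPAC ambiguity codes count as mismatches. Conflicting reads are
excluded from allelic tracks and counted in logs — assignment here validates
allelic signal rather than quantifying it, so exclusion is the conservative
default.

## 4C-seq quantification

Each fragment track is normalized so that its signal inside a wide window
around the viewpoint (the scale of several TADs) sums to 10⁶. Any positive
constant gives identical ratios and shares; 10⁶ makes values readable as
"signal per million in window". The viewpoint fragment ± 1 fragment is
excluded from normalization sums and distributions (self-ligation and
undigested-fragment artifacts dominate there in real libraries);
the pad is configurable. Display ratios use 11-fragment running-mean
smoothing (truncated at track edges, so constants are preserved and window
1 is the identity); sub-domain distributions use unsmoothed normalized
values. These are two different consumers of the same track, not one
pipeline stage.

The fragment-fraction test classifies each usable fragment as
maternal-higher or paternal-higher and tests the 2×2 region-by-direction
table with G = 2·Σ O ln(O/E) (zero cells contribute the x·ln x → 0 limit;
Williams' adjustment available but off, as the plain statistic is the
standard form). The p-value is the χ²(1) upper tail computed via the
regularized upper incomplete gamma function.

Direction classification uses a 1% relative tolerance: a fragment is
maternal-higher only if maternal > paternal × 1.01, and symmetrically;
everything else is a tie and dropped (ties are logged). The tolerance exists
because per-track normalization scales the two alleles by slightly different
factors; under strict inequality that scale difference breaks every exact
underlying count tie in the same direction, and because tie frequency
differs between high-coverage (viewpoint-proximal) and low-coverage regions,
the artifact inflates the test's null rejection rate (~9/100 at p < 0.01 in
our null configuration). With the tolerance the test is calibrated (1/200 at
p < 0.01 measured) and power is unaffected; a sub-1% per-fragment difference
is never meaningful at realistic coverage.

## Hi-C balancing and TAD borders

ICE balancing alternates row/column rescaling of the symmetric matrix until
every unmasked row sum is within a relative tolerance (default 1e-5) of the
mean, preserving total signal; all-zero rows are masked and their scaling
reported as 0. Non-convergence raises with the final residual.

The insulation index at bin i is the mean contact in the w×w square of
(upstream rows) × (downstream columns), w = window/bin width (default
500 kb / 10 kb = 50 bins); bins within w of a matrix edge are masked, and
squares overlapping masked bins average available entries but require ≥ 50%
coverage. Boundaries are local minima at or below a cutoff; a plateau of
equal minimal values yields its center bin (deterministic tie-break).
Published absolute cutoffs (e.g. 21.75) are specific to the normalization
scale of the data they were derived on, so the module also accepts a
percentile cutoff; the 10th percentile of valid insulation values is the
default in the CLI and recovers planted boundaries with recall 1.0 in the
synthetic benchmark.

## Expression filter

Replicates are quantile-normalized together and averaged per sample;
detection (max TPM ≥ 5) and the compound differential rule (fold ≥ 1.5 and
max × fold ≥ 50, all inclusive) follow. "Fold" is larger/smaller,
symmetric in the samples. A zero smaller TPM is floored at 0.1 before the
fold, keeping the product criterion finite and meaningful; the floor is
configurable.

## FISH distances

Spots outside the nucleus mask are discarded. Pairing is mutual-nearest:
an A-spot and B-spot pair only if each is the other's nearest neighbor,
which prevents double assignment when spot counts differ (two alleles plus
a noise spot). Distances are normalized per megabase of genomic separation
by default; any callable scale model can be substituted, since no canonical
functional form exists for this normalization. The Mann-Whitney statistic is
U = #(x > y) + ties/2; for combined n ≤ 20 the two-sided p-value is exact —
the permutation distribution over all C(n, nx) group assignments, computed
by a generating-function convolution over doubled average ranks (exact
integer arithmetic, tie-exact, identical to complete enumeration) — and
beyond that a normal approximation with tie-corrected variance and 0.5
continuity correction.

## Synthetic data: what it emulates

The default geometry is a 3-Mb chromosome with a 1.6-Mb TAD split into a
550-kb centromeric sub-domain, a 150-kb sub-TAD and a 900-kb telomeric
sub-domain — the scale and proportions of a large imprinted domain.
Restriction fragments are a Poisson process with 400-bp mean spacing
(4-cutter statistics); SNPs default to 1 per 150 bp (hybrid-strain scale;
configurable). Expected contacts follow base·max(|i−j|, 1)^(−1), ×3 inside
the TAD, × a per-allele block boost when both bins share a sub-domain block;
block keys may be tuples of part names, planting one block over their union
(how a paternal sub-TAD spanning two maternal sub-domains is expressed).
The diagonal uses the distance-1 value so balancing masks nothing
spuriously.

Noise models: negative-binomial (gamma-Poisson, dispersion 0.1) for Hi-C
counts; multinomial over fragments for 4C reads (probabilities proportional
to the viewpoint row, spread uniformly over each bin's fragments); Poisson
for ChIP bins; lognormal replicate noise for TPM tables; isotropic Gaussian
for FISH spot placement with rejection sampling inside a spherical nucleus,
so zero noise gives the model distance exactly. The FISH scale model is
globular-polymer scaling, distance = c·(Mb)^(1/3) with c = 1 µm.

The 4C hypothesis-testing conditions (power, size, conservation) sample
reads from the *expected* contact matrix rather than an NB-noised
realization: NB noise is drawn per 10-kb bin and shared by the ~25 fragments
within it, which correlates fragment directions in a way a fragment-level
test does not model; the 4C noise source is read sampling. The pure
redistribution configuration (`conserving_subtad_boosts`) gives the maternal
allele a 2× block over the sub-TAD and the paternal allele one weaker block
over the union of sub-TAD and telomeric sub-domain, solved so the expected
viewpoint-row total over the two regions is allele-equal — combined signal
is conserved while its split shifts.

ChIP study conditions: the full 3-Mb chromosome at 50-bp bins (60,000 bins),
background 2 reads/bin (~15× peak enrichment), input 20 reads/bin, twelve
bi-allelic peaks (height 30) plus one mono-allelic peak (paternal height 4,
allele fold 8), peak width 500 bp (a CTCF footprint smeared by 200-bp read
extension). Track length matters: shrinking to a few thousand bins makes
quantile normalization's discrete rank collisions pathological in a way
genome-scale data is not. Expression tables need thousands of transcripts
for the same reason — planted TPMs must rank inside the heavy-tailed
(lognormal, σ = 2.5) null distribution for cross-sample quantile
normalization to separate the samples.

What passing these tests shows: the pipeline implements its stated rules
exactly (oracle equivalence), its statistics match their closed forms and
are calibrated under the generator's null, and planted structure at
realistic magnitudes is recovered. What it does not show: robustness to
mappability artifacts, GC and restriction-site density bias, chimeric
reads, segmentation errors in microscopy, or biological confounders —
none of which the generator emulates.

## Degenerate inputs and tie-breaks

Constant input tracks blacklist everything (warned). Zero normalization
windows, all-zero viewpoint rows, zero-margin 2×2 tables, empty FISH
channels and empty samples raise errors rather than returning silent
defaults. Insulation plateaus resolve to their center bin; mutual-nearest
pairing leaves unmatched spots unpaired; conflicting reads are retained in
logs but excluded from tracks. All randomized components consume an
explicit seed or generator; no global random state is touched.
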