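# Methods

This note documents the statistical model behind `haplobin`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Setting and assumptions

The input population is a set of haploid gamete genomes derived from one
heterozygous diploid. Each gamete genome is a mosaic of the diploid's two
haplotypes with switch points at meiotic crossovers. The method assumes:

* markers are biallelic and heterozygous in the donor (allele frequency
  ≈ 0.5 in pooled reads), so each gamete carries exactly one allele;
* gametes are sequenced independently and shallowly (well below 1×), so
  genotype calls are sparse and occasionally wrong, but the population is
  large (hundreds);
* crossovers are reciprocal and occur between homologous positions
  (non-allelic exchanges exist but are rare and are surfaced only as a
  pseudo-heterozygosity diagnostic, not called automatically);
* no crossover interference (Haldane world): CO counts are Poisson and the
  mapping function is d = −50·ln(1−2r) cM, capped at 50 cM when r
  approaches 0.5 (ε = 10⁻⁶). Kosambi would be the alternative if
  interference mattered; the choice is configurable at the call sites that
  take a mapping function distance.

## Marker model

SNP candidates are filtered on three inclusive bands: alternative allele
frequency within [0.38, 0.62], alternative-allele depth within [60, 140],
and total depth within [120, 280]. The depth bands are meaningful relative
to a pooled mode depth of 208×; `SnpFilterConfig.rescaled(mode)` and
`RegionClassifierConfig.rescaled(mode)` scale them proportionally for other
datasets. All bounds are inclusive: the sources of these rules phrase the
depth rule as "less than or equal to", and inclusivity is the reading
consistent with that. A depth-histogram valley detector
(`depth_histogram_valley`) is provided to *derive* a deletion ceiling from
data; it is advisory and never applied silently.

Marker-free intervals are maximal runs of non-SNP bases per contig
(0-based, half-open), kept when strictly longer than 2 kb. A region whose
pooled mean depth is at most the deletion ceiling (default 146, i.e. the
valley between the half-depth and full-depth peaks of a 208× pool) is a
haplotype-specific "deletion" marker; otherwise it is conserved sequence
shared by both haplotypes.

## Genotyping and the doublet screen

Per gamete and SNP: missing if uncovered; the pure allele if only one is
seen; with conflicting reads, the majority allele only when it outnumbers
the minority by the dominance ratio (default 3), else missing. The
conflict rule is this package's choice — at < 1× almost all covered sites
have depth 1, so the rule rarely fires, but it protects doublet detection
from being washed out by forced calls.

Deletion markers are genotyped by read presence (`a`) versus absence. A
zero count is recoded to the complementary allele `b` only when the
gamete's depth made ≥ 2 reads likely in that region; otherwise absence is
uninformative (`n`). Absence of evidence is evidence of absence only when
evidence was expected.

Doublets (two nuclei sharing a barcode) are detected from phased calls:
a haploid gamete's genotype string switches only at genuine crossovers
(rate ≈ λ per chromosome) plus isolated errors, while a doublet's calls
alternate between two mosaics, so its transition rate approaches the
inter-haplotype mismatch rate. The deterministic rule — doublet iff
transitions/covered > 5/100 (strict) — replaces the scatter-plot
clustering sometimes used for this decision, for reproducibility. Gametes
with fewer than 30 covered markers are labelled haploid-with-warning
rather than classified. Phasing is run once with all gametes to produce
the screen (majority voting is robust to a minority of doublets), then
re-run with doublets excluded.

A caveat established while testing: a doublet whose two components
happened to inherit near-identical mosaics is *intrinsically* undetectable
by any genotype-based screen. The probability of such a collision falls
rapidly with chromosome count; on two-chromosome toy genomes it is a few
percent, so the sensitivity test uses four chromosomes (real karyotypes
have more).

## Phasing

"Bi-marker majority voting" is implemented as adjacent-pair co-segregation
chaining: for markers i, i+1, count over gametes covering both S (same raw
symbol) and D (different); orientation(i+1) = orientation(i) if S ≥ D else
flipped; S = D keeps the previous orientation and flags the adjacency. The
first marker is +1 by convention, so the solution is defined up to one
global flip per contig. Because each adjacency's contribution to the total
agreement is independent of the others, the greedy chain attains the
global optimum Σ max(S, D); the test suite verifies this against
exhaustive search over all orientation vectors for up to 12 markers.
Unweighted gamete votes are used (depth weighting would add little at
depth ≈ 1).

Virtual end markers impute each gamete's genotype at a contig's head and
tail as the consensus of its first/last *strong block* (see crossover
segmentation below), falling back to the raw first/last non-missing symbol
when no block reaches the support threshold; this resists isolated
genotyping errors at contig ends.

## Genetic map

The haploid two-point LOD compares the linkage likelihood at the observed
r against independent segregation: LOD = NR·log10(2(1−r)) + R·log10(2r),
with LOD = (R+NR)·log10 2 at R = 0 and LOD = 0 for uninformative pairs.
Marker phases are arbitrary, so R > NR triggers a phase flip (recorded and
later propagated). Pairwise linkage over all markers is computed by one
matrix product over a ±1/0 encoding.

Grouping takes connected components of the LOD > 3.0 graph (strict
inequality). The two ends of a contig are forced into one group — the one
holding the stronger edge — with a warning, since contigs are physical.
Markers missing in more than 10% of gametes are dropped before grouping
(the filter is applied before, not after, grouping; the alternative order
would only re-admit markers that cannot be placed reliably anyway).

Ordering is greedy nearest-neighbour seriation (seeded at the max-LOD
pair, attaching the unplaced marker with smallest r to either chain end;
ties by higher LOD, then id) followed by 2-opt segment reversal minimizing
the sum of adjacent r. The 2-opt objective never increases, and for groups
of ≤ 8 markers the result equals the exhaustive optimum (test oracle).
Uninformative adjacencies are joined at the 50-cM cap with a warning.
Per-marker phase values (0/1, 1 = flipped to the group convention) are
propagated along the maximum-LOD spanning tree from the first marker in
map order; a contig's phase is its head entry's.

Deletion markers are placed at the position of the placed marker with the
minimum genotype-sequence divergence (mismatches / informative overlaps,
minimized over both phase assignments), accepted when the minimum is
≤ 0.1 with ≥ 30 informative gametes. With sparse data many deletion
markers legitimately stay unplaced; they then simply contribute no
binning evidence.

## Crossovers and the landscape

A gamete's call string (missing symbols removed) is split into maximal
runs; runs of ≥ 5 markers are strong blocks, shorter runs are treated as
noise absorbed into the flanking context. One crossover is emitted between
each pair of consecutive strong blocks with opposite symbols, localized to
the interval between the last left-block marker and the first right-block
marker; the point estimate is the interval midpoint and the resolution is
the interval length. The support threshold (default 5 markers) is the
package's explicit replacement for an HMM-based caller; it is configurable
and is reported in CO output headers. Consequences: crossovers closer to a
chromosome end than ~5 observed markers are undetectable, and two true
crossovers within one support window merge or cancel — both visible as the
few-percent deficit in λ recovery tests.

The landscape counts, per sliding window (default 500 kb at 50-kb steps),
the number C of distinct gametes with a CO midpoint inside; recombination
frequency = 100·C/n/(w/10⁶) cM/Mb, with SNP and gene densities as counts
per Mb in the same windows. Events from gametes at ≤ 0.1× depth are
excluded (strictly "over 0.1×") before landscape building.

## Read binning

Reads are assigned by best alignment, one decision per read, in case
order: (1) SNP votes — the read base at each covered phased marker (its
recorded substitution, else the reference base) votes for the haplotype
carrying that allele after contig orientation and group phase are applied;
majority wins, ties break by seeded coin flip, bases matching neither
allele abstain; (2) deletion overlap — the read joins the haplotype
possessing the region; (3) conserved overlap — seeded uniform random
assignment (such reads are haplotype-neutral by construction, and random
halving keeps per-bin coverage balanced for downstream assembly).
Everything else is unassigned. An optional purity threshold demotes
mixed-vote reads to the non-SNP cases. Votes are unweighted; base
qualities are not modelled.

## k-mer validation

Canonical k-mers (lexicographic min of k-mer and reverse complement,
2-bit packed, default k = 21) are counted vectorized; windows touching a
non-ACGT symbol are dropped. Haplotype-specific and parent-specific sets
use band filters: target band 10–60× for assembly-derived sets, exclusion
from the other parent at count ≥ 2 ("over 1×" read strictly: a single copy
is tolerated as sequencing error), presence in the own-parent band
10–300×. Precision per haplotype is
100·|r_X ∩ p_P| / (|r_X ∩ p_P| + |r_X ∩ p_Q|); the parent/haplotype
pairing maximizing the weighted average is chosen and reported, and a
haplotype with an empty denominator is excluded from the average with a
warning. k must be odd (even k admits self-reverse-complement palindromes
whose strand is ambiguous).

## The synthetic-data generator

`SimulationConfig` defaults define the desk-scale study conditions: two
1-Mb chromosomes; one SNP per 500 bp placed outside special regions; 10%
of each chromosome in haplotype-specific regions (mean 15 kb) and 10% in
conserved marker-free regions (mean 10 kb); contigs with ~200-kb mean
(30-kb minimum) exponential fragmentation; 200 gametes; Poisson(λ = 1)
crossovers per chromosome per gamete at uniform positions (interference
not modelled; an optional minimum CO distance and an obligate-CO switch
exist); mean coverage 0.3× with log-normal gamete-to-gamete spread
(σ = 0.5, emulating the broad empirical depth distributions of single-cell
libraries); 0.5% per-base genotyping error; no doublets unless requested;
10,000 reads of 15 ± 1.5 kb. λ = 1 is a round obligate-CO-scale value
consistent with typical plant meiosis (~0.7–1 CO per chromosome arm pair
per gamete). Given a fixed seed every stage is byte-reproducible; stages
draw from independent seed streams so adding reads does not perturb
gametes.

Deliberate simplifications, and what they mean for the tests:

* Deletion regions are modelled at the read-count level on one shared
  coordinate frame (the haplotype lacking a region yields no reads there);
  sequence is excised only when haplotype FASTA is requested. Alignment
  artifacts at deletion boundaries are therefore not emulated.
* Long reads carry substitution noise only at marker sites (the only
  positions that influence binning); indel noise and chimeras are not
  modelled, and each read is clipped to a single contig, as a real
  aligner's split alignments would be.
* Contigs are emitted in forward orientation. Orientation errors enter the
  method only through genotype-sequence flips, which the map's phase
  values exercise fully; reverse-complemented coordinates would test the
  aligner, not this method.
* Pooled candidate depths are drawn directly (Poisson around the mode, or
  half of it in deletion regions) rather than accumulated from simulated
  reads; low-frequency error candidates are injected to exercise the
  frequency filter.

Passing tests on this generator demonstrate the method's statistical
machinery — phasing, grouping, ordering, CO calling, binning — under the
stated noise model; they do not certify behaviour under alignment
artifacts, reference bias, segmental duplication or contamination, which
real data add on top.

## Problem sizes and tolerances

The default test/acceptance problem (2 × 1 Mb, 200 gametes, 10,000 reads)
was chosen so each full pipeline run takes a few seconds while every
statistical regime of the full-scale method is still present (hundreds of
markers per contig, tens of informative gametes per adjacency, LOD values
far above and below the 3.0 threshold). Stochastic assertions use 3σ
bounds under the generating model or thresholds from the method's own
claims (≥ 99% binning precision, ≥ 95% doublet sensitivity, λ recovery
within 10%, |Kendall tau| ≥ 0.9), evaluated at fixed seeds; the
acceptance script averages binning precision over five seeds.

## Known limitations

* Two-point grouping can split a physically contiguous chromosome when a
  contig spans many centimorgans relative to the population's information
  content (its own ends decouple); the contig-end forcing rule repairs the
  common case, with a warning.
* The CO caller's support threshold trades end sensitivity for error
  robustness; gene-conversion-scale events (well below the marker spacing
  times the support threshold) are invisible by design.
* Deletion-marker placement requires informative presence/absence in
  enough gametes; at 0.3× many regions stay unplaced and contribute
  nothing (they are never wrongly forced into the map).
* Non-allelic crossover detection is exposed only as a per-gamete
  pseudo-heterozygosity diagnostic table, not an automated caller.
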