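# Methods

## The design being modelled

`haplink` implements single-family linkage mapping from conifer
megagametophytes. A megagametophyte is the haploid maternal nutritive
tissue of a conifer seed; genetically it is a single meiotic product of
the mother tree. Sampling n seeds from one mother therefore yields n
haploid gametes genotyped directly — no cross is needed, the (unknown)
father never enters, and at every locus where the mother is heterozygous
(A/B) the gametes segregate 1:1. The reference design emulated throughout
is a *Platycladus orientalis* study population: one mother tree, 139
megagametophytes, 11 chromosomes, a genome of roughly 1,443–1,507 cM
genotyped by ddRAD-seq.

## Locus classification and the filter funnel

Because each gamete carries exactly one maternal allele, the set of
distinct alleles observed at a locus classifies it directly:

* 1 allele — monomorphic (uninformative);
* 2 alleles — polymorphic (usable);
* more than 2 — repetitive: collapsed paralogues, impossible for a true
  single-copy locus in haploid tissue.

Polymorphic loci then pass three per-locus screens, applied in a fixed
narrative order (the screens are independent, so the surviving set does
not depend on the order):

1. **Mother concordance** — the two gamete alleles must equal the
   mother's heterozygous pair as a set. Loci with an unknown or
   homozygous mother genotype are dropped (two observed alleles over a
   homozygous mother indicate genotyping error or paralogy).
2. **Missing rate** — keep loci with at most 20% missing calls. The
   boundary is inclusive (≤ 0.20) by default with the comparator exposed
   in `FilterConfig`, since the 20% threshold is quoted both exclusively
   and inclusively in common usage and boundary loci are rare.
3. **1:1 segregation** — chi-square χ² = (n₁−n₂)²/(n₁+n₂) on the
   non-missing calls, 1 df, no continuity correction, no multiple-testing
   adjustment; discard if p ≤ 0.05. An exact binomial alternative is
   available (`exact_binomial=True`).

A property worth knowing: at n = 139 the test statistic is discrete (n₁−n₂
is odd), so the realised level of the α = 0.05 screen is exactly 4.14%,
computable by binomial enumeration; the acceptance machinery checks the
empirical rate against that enumerated value, not against the nominal 5%.
A second property, easy to miss: segregation ratios of *linked* loci are
strongly correlated, so a chance excursion of the allele-count random walk
discards a contiguous chromosome chunk, not scattered loci. If the
resulting hole is wider than the LOD-5 connectivity distance (34.56 cM at
n = 139, closed form below) the linkage group necessarily splits. This is
a property of the screening protocol itself, visible even on noise-free
simulations, and the tests assert it as such.

## Two-point estimation

For loci x, y with n gametes non-missing at both and d mismatches, the
parental phase is unknown, so the recombination fraction is
phase-minimised: k = min(d, n−d), r̂ = k/n. The LOD score is the base-10
likelihood ratio of linkage at r̂ against free recombination:

    LOD = (n−k)·log₁₀(2(1−r̂)) + k·log₁₀(2r̂),   0·log₁₀0 ≡ 0.

LOD is always ≥ 0 (r̂ is the MLE) and 0 when r̂ = ½. Pairs with fewer
than `n_min_overlap` (default 20) shared gametes are uninformative and
receive r = `default_r` (0.4) with LOD 0; the scalar
`estimate_two_point` applies `n_min=1` so that small worked examples
behave as printed. All-pairs matrices are computed by three matrix
products on the valid-call indicators.

## Co-segregation bins

At n = 139, markers closer than ~0.7 cM frequently show zero recombinants
and are statistically indistinguishable. Markers whose patterns are
identical (or exactly complementary — a pure phase flip) over at least
`bin_n_min` (20) shared gametes are collapsed into bins by transitive
closure. One representative per bin (fewest missing calls, ties by ID)
carries the bin through grouping and ordering; members inherit its
position with zero-length intervals. This both mirrors the "duplicates"
handling of standard pedigree mappers and reduces the O(m²) pair work to
bins. The exact duplicate definition used by those tools is not published;
zero-mismatch transitive closure is this package's stated reconstruction.

## Grouping and singleton joining

Linkage groups are connected components of the representative graph with
edges at LOD ≥ 5 (single linkage). Groups are numbered LG01, LG02, … by
descending size. Singleton components may then be attached to the group
holding their best LOD, provided the best is ≥ the joining threshold and
strictly exceeds the second-best group (ties stay single); the sweep
iterates to a fixpoint so joined markers can recruit further singletons.

The widest gap that can still be bridged follows in closed form from the
LOD expression: solving n[(1−r)log₁₀2(1−r) + r log₁₀2r] = 5 at n = 139
gives r* = 0.299, i.e. 34.56 cM after Kosambi conversion. Gaps wider than
this split a group no matter how dense the flanking markers are.

## Ordering

Ordering maximises a two-point composite likelihood: the sum of
adjacent-pair LOD along the marker chain — an open-path travelling
salesman objective with LOD as the gain of adjacency. Each of 10 runs
starts a greedy nearest-neighbour chain from a random marker and polishes
it by best-improvement local search (2-opt segment reversals plus
single-marker relocation, both evaluated vectorised in O(m²) per sweep)
until no move improves; the best run wins and its seed and objective are
logged. Orientation is normalised so the first marker ID sorts before the
last. The composite objective was chosen over a multipoint HMM likelihood
deliberately: it is deterministic given the data, desk-scale, and
checkable against exhaustive permutation search — the tests verify that
the heuristic attains the exhaustive optimum for groups of up to 8 markers
on clean data. Markers separated by near-zero recombination distance are
unorderable in principle at finite n; recovered orders are therefore
compared to truth by rank correlation, with exact-order assertions
reserved for well-spaced subsets.

## Error-prone loci

After ordering, each locus is scored by its singleton-double-recombinant
rate: the fraction of gametes (non-missing at the locus and both flanking
neighbours; terminal markers use their two nearest neighbours) whose
phase-aligned allele disagrees with *both* flanks. Genuine double
crossovers within a few cM are vanishingly rare, so a high rate is the
fingerprint of genotyping error. Loci above the 0.3 threshold are removed
and the group re-ordered once. The precise "error rate" definition of the
reference tooling is unpublished; this rate is the package's documented
reconstruction.

## Map assembly and the Kosambi function

Within each ordered group, positions are cumulative sums of map distances
of adjacent r̂, using Kosambi's function

    d(cM) = 25·ln[(1+2r)/(1−2r)],    r(d) = ½·tanh(d/50),

which allows moderate crossover interference (Haldane is available as an
option). r ≥ 0.5 is clipped to `r_cap` (0.4999) with a warning. LG length
is the last position; the total is the sum over LGs.

The crossover **simulator** draws each gamete's start phase per LG
uniformly and recombines each adjacent interval independently with
probability r = Kosambi⁻¹(interval length). Adjacent intervals are thus
exactly recoverable under the Kosambi conversion, which makes
parameter-recovery tests sharp; what this deliberately does not model is
genuine crossover interference across intervals (a renewal/gamma process),
read-level noise, or depth-dependent missingness. Noise is injected
afterwards by `degrade`: monomorphic, repetitive (three equiprobable
alleles) and mother-discordant loci are converted by exact rounded count
(so tests can assert composition exactly), allele-flip errors are applied
per call to biallelic loci only (flipping a monomorphic locus would
silently change its class), missing calls are masked per call, and
segregation distortion is applied at gamete generation by viability
rejection so that linkage with neighbours is preserved. Passing tests on
these simulations therefore demonstrate correctness of the estimation
machinery under the stated generative model, not robustness to every
artefact of real ddRAD data.

## Framework map and marker statistics

The framework map keeps one marker per co-segregation bin, chosen
uniformly at random under a seed, and re-orders and re-assembles the
selected set from scratch. Interval statistics count adjacent intervals
within LGs over all mapped markers (bin members contribute zero-length
intervals; a map with m markers on L groups has m − L intervals), and
report the fractions below 0.2 cM and above 1 cM at one decimal.

The marker-distribution test tiles each LG with half-open 10 cM blocks
anchored at 0, keeping the final partial block, pools block counts over
LGs, and compares the observed count-class frequencies with Poisson
expectations n_blocks·e^(−μ)μ^x/x! at μ = markers/blocks. The
goodness-of-fit chi-square pools upper-tail classes until every expected
frequency is ≥ 5, with df = classes − 2. Map-to-map synteny matches LGs
by shared-marker majority, orients each partner LG (possibly reversing
it) to maximise the rank correlation, and reports per-LG Spearman's ρ
(Kendall available) plus a link table for circos-style plotting.

## Numerical and design choices

* Tie-breaks are lexicographic on marker IDs everywhere; every stochastic
  step takes an explicit seed and identical seeds give bit-identical
  output end to end.
* The reference protocol's "initial recombination probability 0.4" is
  realised as `default_r`: the value assigned to uninformative pairs.
* cM values are printed at 2 decimals, percentages at 1 decimal.
* The published per-LG reference summary embedded in `haplink.datasets`
  is input data; every derived figure (totals, means, inflation,
  percentages) is recomputed from it at run time. Its per-LG full-map
  lengths sum to 1,506.76 while the printed total is 1,506.75 — a 0.01
  rounding inconsistency internal to the published table, reported as
  recomputed.
* Problem sizes used by the test-suite experiments: 11 LGs at the
  published framework lengths, 139 gametes, 70–80 markers per LG, 20
  replicates for recovery, 10,000 loci for the null screen — the scale at
  which the asserted properties are statistically sharp.

## Known limitations

* No multipoint HMM likelihood or genotyping-error EM; ordering is
  two-point composite only.
* No crossover interference beyond the Kosambi map function's implicit
  level; simulated intervals recombine independently.
* ddRAD digestion is sequence-exact: methylation sensitivity (relevant to
  EcoRV in heavily methylated plant genomes) and degenerate recognition
  sites are not modelled; palindromic sites are scanned on the forward
  strand only.
* The VCF reader accepts haploid GT calls only and is a convenience path;
  TSV is canonical.
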