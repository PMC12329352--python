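# Methods

## The system and the model

Two pond frog species hybridise where their ranges meet in the rice
paddies of central Japan: *Pelophylax nigromaculatus* and *P. porosus*,
the latter split into the subspecies *P. p. porosus* (Matsumoto Basin)
and *P. p. brevipodus* (Ina Basin).  F1 males are sterile but F1
females remain fertile, so hybrid lineages persist by repeated maternal
backcrossing.  Three observable channels carry ancestry information:

* **morphology** — a field call of N, P, B, or H (putative hybrid);
* **mtDNA (cytochrome *b*)** — strictly maternal, so it marks the
  founding mother's species no matter how many backcross generations
  follow;
* **nuclear Tyrosinase** — a single short amplicon, treated as one
  non-recombining allele per gamete.  At a species-diagnostic site a
  hybrid carrying one chromosome from each species shows a Sanger
  double peak, encoded as a two-base IUPAC code (R/Y/S/W/K/M).

## Diagnostic-site discovery

A column is diagnostic when every reference sequence within each taxon
carries the same unambiguous base and at least two taxa differ.
Columns with any within-taxon polymorphism are excluded even if taxa
differ there, and columns containing gap/N in any reference are
excluded: missing data cannot certify fixation.  References containing
ambiguity codes are rejected outright rather than skipped — a
heterozygous "reference" is not a reference.  `min_per_taxon`
defaults to 2 because a single sequence cannot demonstrate fixation;
it is configurable because the number of allopatric reference
specimens behind the published panel is not stated anywhere.

## Genotype calling

Each panel position is decoded as homozygous (A/C/G/T), heterozygous
(two-base code) or missing (N, gap, three/four-base codes — these never
count as evidence of anything).  The summary is:

* `insufficient` below `min_informative` readable panel sites (default
  5 of 10: a majority of the panel must be readable; there is no
  published threshold, so the parameter is exposed);
* `novel` if any observed base matches no taxon's allele at its site,
  or if the homozygous pattern fits no single taxon and no heterozygous
  pair (a mosaic, possible only through miscalls or missed double
  peaks).  Novel calls are deliberately *not* hybrid evidence — the
  guiding principle throughout is to avoid overestimating hybrids;
* `het(a, b)` if at least one diagnostic site is heterozygous with its
  two bases matching two taxa; the reported pair is the two-taxon model
  consistent with the most informative sites (ties broken in fixed
  taxon order).  A single heterozygous diagnostic site suffices, since
  with one sequenced locus every double peak at a fixed difference is
  informative; `n_informative` is reported so users can impose stricter
  thresholds.  Heterozygosity between the two *porosus* subspecies is
  species-concordant and flagged separately (`subspecies_het`) rather
  than pooled with between-species hybrids;
* `hom(taxa)` otherwise; more than one taxon is listed only when the
  readable sites cannot separate the subspecies.

mtDNA haplogroup assignment is nearest-reference Hamming distance over
positions where both query and reference are unambiguous; ties across
taxa leave the specimen unassigned (margin 0) instead of guessing.

## Haplotype collapse and median-joining networks

Masking is complete deletion: any column with a gap, N or ambiguity
code in any sequence is dropped for all sequences (the standard DnaSP
convention; it is also why a sequenced fragment shrinks to a shorter
"available" region when surveys are combined).  Distances are Hamming
counts on the masked cores; identical cores form one haplotype, and
labels are the haplogroup initial plus a rank by descending frequency
(ties by smallest member id), so labelling is input-order independent.

The network algorithm iterates to a fixed point:

1. build the minimum spanning network over current nodes — an edge
   (u, v) is kept iff d(u, v) ≤ bottleneck(u, v) + ε, where the
   bottleneck is the largest edge on the minimum-spanning-tree path
   (ε = 0, the usual default, gives the union of all MSTs);
2. for every mutually linked triplet, form the per-column majority
   consensus (a three-way tie takes the base of the first node in label
   order — a deterministic tie-break); add the consensus as a median
   node if it shortens the network's spanning-tree length;
3. prune median nodes with fewer than three links (they merely
   subdivide paths), cascading.

The reported `total_length` is the parsimony length — the weight of a
spanning tree over observed plus median nodes, the quantity median
vectors exist to reduce.  On an exhaustive enumeration of all ≤4-
haplotype instances over three- and four-column binary alignments
(distances ≤ 3), the algorithm attains the brute-force Steiner optimum
in every instance; this exhaustive check at small alignment length is
the package's correctness anchor for the network stage, alongside an
independent brute-force minimum-spanning-network oracle.  Post-hoc
maximum-parsimony pruning of superfluous links is out of scope.

## Integrative classification

Rules are applied in order: (1) species-level nuclear heterozygosity →
hybrid; (2) homozygous nuclear species ≠ mtDNA species → hybrid
(mito-nuclear discordance); (3) hybrid morphology, or morphology
contradicting the genetic species → hybrid; (4) all available channels
agree on one species → pure, with the *porosus* subspecies resolved by
the subspecies-diagnostic nuclear sites first and the mtDNA haplogroup
as fallback; (5) otherwise unresolved.  Consequences worth noting:

* a specimen with an uninformative nuclear call (novel/insufficient)
  but concordant morphology and mtDNA is *pure* — matching the survey
  convention that specimens without double peaks whose mtDNA and
  morphology agree are taken as pure-bred;
* hybrids are undercounted, never overcounted: on error-free synthetic
  data no true pure specimen is ever classified hybrid, and removing an
  evidence channel can move calls only toward unresolved/pure;
* a backcross lineage is detectable through the nuclear locus with
  probability (1/2)^g (heterozygosity halves each generation) but
  through mtDNA discordance with probability 1 whenever the maternal
  lineage's species differs from the bearer's apparent species — the
  mechanism by which one species' mitochondria can ride a backcross
  lineage across a basin.  Both rates are verified against the closed
  form by simulation;
* unresolved specimens are excluded from proportion denominators and
  reported separately.

Whether a "pure" call should require non-missing morphology is
genuinely open; this package does not require it (genetic concordance
with morphology missing is still pure), because the published classes
are explicitly *genetically* pure-bred.

## Proportions and tests

Class percentages are printed to one decimal with half-up rounding,
the convention that reproduces the published tables.  Changes between
surveys are tested per class (class vs rest × year vs year) with the
Pearson 2×2 chi-squared statistic n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
df = 1, no Yates correction by default (samples exceed 100 per margin;
the flag exists).  Bonferroni multiplies each p by k, defaulting to
the number of classes actually tested per basin (3 here — classes
absent in both years are skipped and do not inflate k), with
significance at corrected p < 0.05.  The null rejection rate of this
procedure with k = 1, estimated over 2000 simulated equal-proportion
surveys at study-scale sample sizes, sits near the nominal 5%.

## The synthetic generator

`simulate.generate` plants a diagnostic panel with the 7/2/1 site
pattern of the real one (seven species sites, two *brevipodus*-private,
one *porosus*-private) on a random 747-bp background, builds three
mtDNA haplogroups (centrals 12 mutations apart by default, each with
star-like single-mutation minor variants drawn at frequency 0.2), and
emits specimens cohort by cohort.  Ancestry is explicit (pure, F1, or
BC with g maternal backcrosses), mtDNA follows the founding mother,
and the nuclear allele pair follows the single-locus transmission
model.  Detection error is injectable: `miss_double_peak_rate` reads
one allele at random instead of the ambiguity code, and
`missing_data_rate` replaces bases with N.  All randomness flows
through one seeded NumPy generator in a fixed order, so a seed
determines the output byte for byte.

The default scenario mirrors the study's scale — 30 sites in three
basins, two survey years, ten specimens per site-year at the default
cohort width — so pipeline outputs exercise the real table layouts in
seconds.  What the generator does *not* emulate: sequencing noise
beyond the two error channels above, intra-locus recombination (the
real amplicon is short and its diagnostic sites co-segregate), unequal
catchability, spatial dispersal dynamics, and selection.  Passing
recovery tests therefore demonstrates correctness of the calling and
classification logic under the stated inheritance model, not
robustness to every artefact of real chromatograms.

## Numerical and degenerate-input choices

* All tie-breaks (haplotype labels, median candidates, taxon pairs)
  are lexicographic, making every stage deterministic.
* Sequences are validated against the IUPAC alphabet at construction;
  positions are 1-based from the 5′ end everywhere.
* Zero retained columns after masking, empty selections, zero-margin
  2×2 tables, and g < 1 backcrosses raise typed errors; degenerate
  classification inputs route to `unresolved` instead of raising.
* The published 493-bp "available" mtDNA region is a consequence of
  complete deletion across the combined surveys, not a fixed trim;
  the masking rule and ε are configuration, as the originals' settings
  are unpublished.  Re-deriving the published haplotype counts (22
  combined, 19 in 2010, 13 in 2020) requires the deposited GenBank
  sequences and is therefore accession-dependent; the collapse
  machinery is instead verified on synthetic data with known counts.

## Problem sizes used in the checks

Recovery checks run on 300–600-specimen synthetic datasets; backcross
transmission on 10,000 replicate lineages (3-standard-error bands);
network optimality on the exhaustive ≤4-haplotype enumeration (154
instances); null calibration on 2000 simulated surveys.  These sizes
give sub-minute runs while keeping binomial bands tight.
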