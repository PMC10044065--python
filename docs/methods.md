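# Methods

This note documents the models, conventions and numerical choices behind
`hv1pop`, in the order the pipeline applies them.

## Coordinate frame and window projection

All analyses operate on a fixed window of the mitochondrial control
region.  Coordinates are 1-based and inclusive in the numbering of the
reference mitochondrial genome; the window spans
`start_pos .. start_pos + L − 1`, by default 15,458–16,039 (L = 582), the
HV1 segment conventionally analysed in dog surveys.  Both `start_pos` and
`L` are configurable — nothing in the code assumes the canine defaults.

Raw sequences are projected into the window by *per-sequence global
pairwise alignment* to the reference rather than by a multiple alignment:
pairwise projection is deterministic, independent of input order, and
sufficient when the target is a fixed coordinate frame rather than a
phylogenetic alignment.  Scoring is match +1, mismatch −1, gap open −5,
gap extend −1, with end gaps free on both sequences so that flanking
primer-side sequence and truncated reads cost nothing.  `N` scores 0
against every base so masked positions cannot distort gap placement.  The
alignment itself is delegated to Biopython's `PairwiseAligner`; where
several placements score equally (e.g. a gap sliding within a
homopolymer run) its deterministic traceback picks one, and the window
projection treats all such placements identically.

Projection keeps every alignment column in which the reference has a
base: insertions relative to the reference are dropped, deletions inside
the covered span become `-`, and window positions outside the read's span
become `N`.  Two guards reject non-HV1 input: fewer than 50% of window
positions covered ("insufficient overlap") or identity below 70% over
covered determinate positions ("unalignable").

Degenerate IUPAC codes other than N are rejected outright rather than
silently mapped, because the caller's exact-match semantics must not be
polluted by ambiguous bases.

## Distances and missing data

The distance used everywhere is the substitution count with *pairwise
deletion*: positions carrying `N` or `-` in either sequence are skipped,
and indels are recorded in variant profiles but never counted as
differences.  This matches the convention under which published haplotype
separations ("differs by three nucleotides") are substitution counts.  No
per-site completeness threshold is applied.

## Haplotype calling

A window sequence matches a catalog record when every position that is
determinate in both agrees — i.e. missing positions wildcard-match.  This
is the least surprising semantics for Sanger data, where reads routinely
truncate at either end.  If several records match only because of
wildcards, the lexicographically smallest name is returned and the call
is flagged ambiguous.

Unmatched windows are registered as novel haplotypes, provided no more
than 10% of the window is missing (`max_missing`, configurable); the
haplogroup is inherited from the nearest catalog record by Hamming
distance.  An equal-distance tie across *different* haplogroups is a hard
error requiring manual assignment — guessing a clade for a sequence
equidistant from two clades would be silently wrong half the time.  Novel
names are `<haplogroup>n<k>` with per-haplogroup counters (An1, An2, …,
Cn1, …); the registered sequence is the reference with the window's
determinate differences applied, so re-calling the same window (or the
same haplotype observed in another sample) returns the registered name
rather than creating a duplicate.  Sites at which no other catalog record
is polymorphic are reported as novel polymorphic sites.

Sub-haplogroup labels (a1…a5, b1, b2, c2, …) are assigned from the
nearest catalog record that carries an annotation, within a default
radius of 5 substitutions; beyond that the label is left absent.

The package ships no haplotype catalog of its own: published catalogs are
the property of their surveys, and the caller runs with any catalog
supplied as TSV (`name, haplogroup, subhaplogroup, profile`) or FASTA
(`name|haplogroup|subhaplogroup` headers).  The simulation module
generates fully-formed synthetic catalogs for testing and demonstration.

## Diversity estimators

For a population of n sequences with haplotype frequencies pᵢ:

* **Haplotype diversity** (Nei):
  `h = n/(n−1) · (1 − Σ pᵢ²)`, with sampling variance
  `V(h) = 2/(n(n−1)) · { 2(n−2)[Σpᵢ³ − (Σpᵢ²)²] + Σpᵢ² − (Σpᵢ²)² }`.
* **Mean pairwise differences**:
  `k = Σ_{i<j} d_ij / C(n,2)`, with Tajima's *total* variance
  `V(k) = [3n(n+1)k + 2(n²+n+3)k²] / [11(n²−7n+6)]`.  The total variance
  includes the evolutionary (coalescent) component, not merely sampling
  noise, which is the convention of the standard population-genetics
  packages.  Its denominator `11(n−1)(n−6)` vanishes at n = 6, so the sd
  is reported as NaN for n < 7.
* **Nucleotide diversity**: `π = k / L_eff`, with
  `V(π) = (n+1)π / (3(n−1)L_eff) + 2(n²+n+3)π² / (9n(n−1))`.

`L_eff`, the effective alignment length dividing k, defaults to the
window length L but is an explicit parameter: published tables sometimes
normalise by the alignment's column count (L plus indel columns), which
can differ from L by one or two, and the choice is the table author's,
not derivable from the data.  `π · L_eff = k` holds exactly by
construction.

Percentages in frequency tables are rounded half-up to one decimal, the
common table convention (banker's rounding would turn 5.45% into 5.4%).

k is computed sequence-by-sequence; an alternative route from a haplotype
spectrum plus a haplotype-level distance matrix
(`Σ_{i<j} cᵢcⱼ d_ij / C(n,2)`) is provided and the two are held equal by
an equivalence test.

## Rarefaction

Populations of unequal size are compared at a common size g by
*with-replacement* resampling: each replicate is one multinomial draw of
g individuals from the empirical frequencies, and richness is the number
of haplotypes drawn at least once.  The reported sd is the population
standard deviation across replicates (ddof = 0; the replicates are the
full Monte-Carlo population, not a sample from it).  Because sampling is
with replacement, the expectation has the closed form
`E[S_g] = Σᵢ [1 − (1 − pᵢ)ᵍ]`, implemented separately as an analytic
oracle; the Monte-Carlo mean is required (by test) to agree with it
within 4 sd/√B.

Resampling a population at its own size (g = n) still loses haplotypes in
expectation — `E[S_n] < H` whenever H > 1 — so the result carries an
`at_own_size` flag rather than special-casing the reference population to
its observed count.

Each replicate derives its RNG stream from `(seed, replicate_index)`, so
results are independent of any batching or parallelisation of replicates.

## AMOVA and Φ_ST

The two-level analysis of molecular variance is computed from the
pairwise distance matrix:

```
SSD_total  = (1/N)  Σ_{i<j} d_ij
SSD_within = Σ_p (1/n_p) Σ_{i<j∈p} d_ij
SSD_among  = SSD_total − SSD_within
```

with the substitution count d_ij used directly as the squared-distance
surrogate (the convention of distance-matrix AMOVA for haplotype data —
documented prominently because conventions differ).  Variance components
follow from the expected mean squares with the unequal-size correction
`n' = (N − Σn_p²/N)/(P−1)`, and `Φ_ST = σ²_a/(σ²_a + σ²_w)`.  Negative
estimates are reported as computed, never clamped; a degenerate input
with zero total variation returns Φ_ST = 0 with a `no_variation` flag.

Significance is by permutation of individuals among populations
(sizes preserved), one-sided, with the +1/+1 correction
`p = (1 + #{Φ_perm ≥ Φ_obs})/(1 + B)`; B defaults to 10,000 and the seed
is a logged parameter.  The two-population case is exposed as
`pairwise_phi_st`, a thin wrapper over the AMOVA, so the two agree
bit-for-bit for the same seed.  A haplotype-identity (0/1) distance mode
is available for the frequency-based F_ST analogue; molecular Φ_ST is the
default.

## Minimum-spanning networks

The network is formalised as the union of all minimum spanning trees,
optionally relaxed by an integer ε.  Construction is Kruskal-style over
distance classes in increasing order; components are snapshotted when a
class opens and every class edge joining two distinct snapshot components
is admitted, which makes the result independent of within-class edge
order.  An admitted edge is marked `in_all_msts` when it is a bridge of
its class's component multigraph (no alternative same-class connection
between the same components).  With ε > 0, edges up to `class minimum
+ ε` joining distinct snapshot components are also admitted, always as
optional (non-mandatory) edges.  The ε = 0 network is verified against
exhaustive spanning-tree enumeration on small graphs.  No intermediate
(unsampled) nodes are ever inferred; haplotypes with identical sequences
must be collapsed upstream and are rejected with an error.

## Synthetic surveys

The generator emulates the structure of a real HV1 survey, not its
specific sequences.  A random reference of length L is drawn; each
haplogroup receives a founder `between_group_distance` substitutions from
the reference (default 12) at positions disjoint across founders, and the
remaining haplotypes of the group add 1..`within_group_max_distance`
substitutions (default ≤ 3) at fresh positions, star-wise around the
founder.  The constraint `between > 2·within_max` guarantees that
nearest-neighbour haplogroup assignment is unambiguous.  Population
samples are multinomial draws from per-population spectra: haplogroup
weights come from the configuration, and the mass within a haplogroup is
split by a Dirichlet draw (concentration 0.8) to produce realistically
skewed haplotype frequencies.  Optional perturbations are a private novel
substitution per sample (at positions nowhere polymorphic in the
catalog) with probability `novel_mutation_rate`, and independent
per-base N-masking with probability `missing_rate`.

The default configuration is survey-like: four haplogroups A/B/C/E with
overall weights ≈ 0.54/0.23/0.15/0.08, three populations of sizes
318/44/55 whose spectra confine the rare haplogroup E to the largest
population and skew the smallest-diversity population heavily toward
haplogroup A.  These defaults make demonstration output qualitatively
resemble real village-dog surveys without claiming to reproduce any
particular data set.

What the generator does *not* emulate: sequencing error beyond uniform
N-masking, heteroplasmy, indel polymorphism within populations,
phylogenetic (coalescent) correlation among haplotype frequencies, and
geographic substructure below the population level.  Passing end-to-end
tests therefore demonstrate correctness of the calling and estimation
machinery under clean and moderately masked inputs, not robustness to
every artefact of real Sanger data.

## Problem sizes and determinism

The test suite validates at deliberately modest scales chosen for tight
oracles: exhaustive spanning-tree enumeration at 6 nodes, permutation
calibration with 500 replicates of 24 sequences, rarefaction against the
analytic expectation at B = 10,000, and end-to-end truth recovery on
simulated surveys of 1000 samples across multiple seeds.  The pipeline
itself is deterministic given its seeds: re-running an identical
configuration reproduces every output byte except the run log's
timestamp line.

## Known limitations

* Haplotype calling is exact-match; it will not rescue a read whose only
  error is a miscalled determinate base (that read becomes a novel
  haplotype, as it would in manual curation).
* The Tajima total variances assume neutrality and no recombination;
  they are conventions for comparability, not model-checked intervals.
* AMOVA permutations permute individuals, not populations within groups;
  only the two-level design is implemented.
* Networks over haplotype sets with heavy wildcard content can be
  distorted, since pairwise deletion shortens the effective comparison
  length; the caller's 10% missing-data ceiling bounds this in practice.
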