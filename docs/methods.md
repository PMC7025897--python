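# Methods

This note documents the models and procedures implemented in `svrearrange`,
the assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and breakends

All internal coordinates are 0-based with half-open intervals; a breakend is
a single base position plus a *side* (`left`: the retained/joined sequence
lies at coordinates ≤ pos; `right`: ≥ pos). BEDPE strands (`+`/`-`) and VCF
breakend brackets are mapped onto this vocabulary at import, which removes
the strand-convention ambiguity between SV callers. Junctions store their
breakends in canonical (chromosome rank, position) order.

The background copy number of a sample is the coverage-weighted modal total
copy number rounded to the nearest 0.5. Cluster patterns are read relative
to this background, reflecting that rearrangement interpretation happens on
a chromosome background with roughly the tumour's average ploidy.

## Derivative chromosomes as the single source of truth

A derivative chromosome is an ordered list of oriented reference pieces.
One emission routine converts any derivative (plus the set of reference
intervals it replaced) into the junctions and copy-number deltas it implies:
consecutive pieces that are not reference-adjacent emit a junction; coverage
minus consumption gives the CN delta profile. Three components share this
machinery:

* the **simulator** builds every event as a derivative first, so its
  junctions and CN output cannot be mutually inconsistent;
* the **classifier** replays every templated-insertion path it reports as a
  derivative and verifies that the emission reproduces the cluster exactly
  (the replay oracle);
* the **configuration library** enumerates abstract derivatives over
  unit-width segments.

For chain topologies the replay consumes only a 10-kb window beyond each
unbalanced end: how far a terminal loss extends is not encoded in the
junctions, so the oracle asserts the loss adjacent to the junction and stays
agnostic about its extent.

## Clustering model

Junction breakpoints are grouped by single-linkage agglomeration under a
homogeneous Poisson null: with `n` breakpoints in a callable genome of `G`
bp, the nearest-neighbour distance satisfies `P(D ≤ d) = 1 − exp(−λd)` with
`λ = n/G`, and two breakends from different junctions merge when this
probability falls below `p_merge` (default 10⁻³, i.e. a critical distance
`d* = −ln(1−p_merge)/λ ≈ p_merge/λ`). The two breakends of one junction are
always co-clustered but their own separation is excluded from the statistic,
so a 5-Mb simple deletion remains a single cluster with two one-breakend
footprints. Footprints are maximal runs of member breakends whose adjacent
gaps are below `d*`. The callable size defaults to 90% of the build length.
This null is an explicit, isolated stand-in for the consortium's clustering
statistic (which additionally modelled the event-size distribution); the
size dependence survives here only through the intra-junction exclusion.
Calibration: on uniform random junctions the spurious-merge rate per
adjacent gap equals `p_merge` up to binomial noise (checked by simulation).

Pre-filters (applied before clustering, in this order):

1. **Segment-bypassing removal** — a junction is dropped when a chain of ≥2
   other junctions, linked end-to-end across copy-number segments (opposite
   sides within 50 bp), reproduces its two breakends (same side, within
   50 bp). Removals are logged with the bypassing path.
2. **Fold-back artefact filter** — an inverted junction spanning < 5 kb is
   kept only if a total-CN step ≥ 0.5 lies within 10 kb of the fold-back
   point. A side effect, visible in the recovery tests, is that genuinely
   small copy-neutral reciprocal inversions are also removed; this is the
   filter's intended trade-off, not a defect of the tests.
3. **Balanced-overlap resolution** — junction pairs sharing both breakend
   loci within 100 bp with reciprocal sides are tagged: if either shared
   locus delimits a retained segment (right side at the lower position, left
   at the higher) the pair is a candidate very short templated insertion;
   otherwise it is a mutually overlapping balanced pair.

Refinement then (a) splits clusters into independent simple events when a
member junction is a CN-consistent deletion/duplication with no foreign
breakend inside its span *and* no foreign breakend within 100 bp of its own
breakends (the latter guard keeps phased structures such as local–distant
clusters intact), and (b) merges clusters whose footprints overlap.

## Configuration library

Patterns, not coordinates, are compared. Enumeration runs on an abstract
alphabet (by default two reference chromosomes of three unit segments) with
cuts at strict-interior offsets, so every operation creates at least one
junction; whole-chromosome gains/losses are separate operators. Operations:
deletion, tandem duplication, inversion, balanced and unbalanced
translocation, chromosome gain and loss. Breadth-first search deduplicates
*structures* (up to chromosome relabeling and global mirror), which is sound
because structurally identical states reach identical pattern sets; keys
record only minimal-length operation sequences. Depth is capped at 5 by a
combinatorial guard.

A **PatternKey** serializes, per involved chromosome, the ordered breakend
side groups at each cut position and the integer CN level (relative to
background, capped at ±3) of every interval between cuts, plus the junction
wiring. Canonicalization minimizes the serialization over chromosome
permutations and the global mirror (which reverses orders and flips sides);
identical duplicated junctions collapse to multiplicities, and residual ties
among same-side breakends at one cut are resolved by minimizing the wiring
over their orderings. Observed clusters are reduced to the same key with
interval CN read as length-weighted means (flanks over a 1-Mb window), so a
dictionary lookup returns all minimal generating sequences; an empty result
marks the pattern as unexplained at that depth — a candidate copy-and-paste
or complex event. Templated-insertion cycles are deliberately *not*
derivable from the operator set; their absence from the library is the
signal the library exists to provide.

## Classification

Decision order per cluster (mutually exclusive, exhaustive):

1. single junction: deletion / tandem duplication (orientation + interior CN
   within 0.5 copies of background∓/±1), unbalanced translocation (CN step
   ≥ 0.5 at both breakends), fold-back inversion (inverted, span < 5 kb,
   CN step within 10 kb);
2. two junctions: reciprocal inversion / reciprocal translocation (matched
   loci within 100 bp, flat CN), then the three local 2-jump structures
   matched by PatternKey against reference derivatives (dup–inverted-
   triplication–dup; two duplications linked by inverted junctions; loss
   plus inverted duplication);
3. templated-insertion path: an alternating walk (junction, gained segment,
   junction, …) using every junction once, every interior segment with CN
   gain ≥ 1. Topology from the walk ends — same chromosome with the
   inter-end segment gained ⇒ **cycle**; same chromosome with the inter-end
   segment lost or absent ⇒ **bridge**; different chromosomes at unbalanced
   transitions ⇒ **chain**. Ties between walks prefer fewer templates, then
   lexicographic order. Every reported path must pass the replay oracle;
4. local clusters: all footprints on one chromosome within 1 Mb ⇒ local
   n-jump; exactly one distant footprint ⇒ local–distant;
5. ≥ 3 junctions, all breakends CN-flat, ≥ 2 chromosomes ⇒ chromoplexy;
6. ≥ 10 junctions with ≥ 10 oscillations between two CN states on one
   chromosome ⇒ chromothripsis-like (a deliberately coarse flag; full
   characterization is out of scope);
7. otherwise complex unclassified. Missing CN coverage never crashes a run;
   such clusters are flagged and fall through to complex unclassified.

CN flatness means |step| < 0.5 total copies, appropriate for real-valued
consensus copy number.

## Genome properties and microhomology

The genome is tiled into 1-kb pixels (hg19 autosomes + chrX give exactly
3,036,315) and property tracks are averaged into the grid with
coverage weighting. For association testing, one side of each junction is
chosen at random, observed pixel values are pooled with uniform draws from
the covered pixels (10⁶ by default, scalable down), jointly rank-transformed
to [0,1] with mid-ranks, and tested against uniformity with a one-sided KS
test in the better-fitting direction; the reported p is doubled to correct
for the data-driven direction choice, so it is calibrated under the null. A
constant track yields all-0.5 quantiles and is reported as non-significant
by construction. Benjamini–Yekutieli controls the FDR across the suite
(threshold 0.01); the signed statistic and the median observed quantile give
the direction and magnitude of the shift.

Partner-permutation enrichment keeps every breakend (position, side, label)
fixed and re-pairs breakends uniformly at random within the sample (1,000
permutations by default), preserving per-genome composition; fold change and
z are computed against the permuted distribution. The same machinery applied
to footprint local-pattern types quantifies footprint connectivity.

Microhomology regimes: junction counts by homology length are fit with three
least-squares lines on log₁₀(count+1) over a grid of integer changepoints
(b₁ ∈ 1..8, b₂ ∈ 8..15, b₁ < b₂), choosing the global RSS minimizer (first
grid point on ties). Regimes are labelled NHEJ (< b₁), MMEJ ([b₁, b₂)) and
SSA (≥ b₂), matching the mechanistic reading of little, 2–7 bp and ≥ 10 bp
of junction homology.

## Categories and signatures

The default catalogue (version d1) holds 30 mutually exclusive categories:
one fragile-site category plus deletions and tandem duplications split at
50 kb/500 kb with the two smaller bins split by replication timing (11
del/TD categories in total); reciprocal inversions split at 500 kb;
templated-insertion cycles, bridges and chains split at 100 kb of total
template span; the translocation classes, the 2-jump subtypes, local
n-jump/distant, chromoplexy, the chromothripsis flag and a complex
remainder. Replication timing is read from a supplied track with "early" =
top tercile (the middle tercile is grouped with "late" for a binary,
exhaustive split). A cohort-frequency filter (minimum 50 by default) can
fold rare categories into an `other_rare` column. The exact bin boundaries
are not uniquely determined by the source material; the catalogue is
versioned so alternative binnings are one configuration change.

Signatures are extracted by KL-divergence (Poisson) NMF with seeded random
restarts (30 by default). For each rank K, stability is the mean cosine of
Hungarian-matched signatures between each restart and the best-loss restart;
the chosen K is the largest rank with stability ≥ 0.95 whose every step up
from the smallest rank still reduces reconstruction error by ≥ 5% (an elbow
rule). If no rank is stable the report says so and the smallest rank is
returned — on effectively rank-1 data the factorization is not identifiable
and only the reconstruction, not individual components, is meaningful.
Signature rows are renormalized to sum to one with exposures rescaled
compensatingly. Split-half stability re-extracts in two random halves of the
cohort and reports matched cosines.

The optional HDP backend is a direct-assignment Gibbs sampler for a
two-level Dirichlet-process mixture of categoricals (α = γ = 1, symmetric
Dirichlet η = 0.1 on spectra): token-level indicator resampling given the
global stick weights, Chinese-restaurant table counts, and a Dirichlet
update of the weights. K is inferred; spectra are posterior means over
samples at the modal K with 95% intervals, and a split-R̂ on K across chains
flags non-convergence above 1.2. It is a compact cross-check of the NMF
backend, not a production-scale extractor.

Driver associations fit, per (gene group, signature), the linear model
`exposure ~ mutated + histology` by OLS with a two-sided test on the gene
coefficient and Benjamini–Hochberg correction across all pairs (the milder
correction is appropriate here and switchable); groups mutated in fewer than
3 patients are skipped. Gene groups pool families such as the MSH
mismatch-repair genes.

## Simulator: what it emulates, and what it does not

Defaults define the study conditions: an hg19-scale genome with ~500 events
per genome across all supported classes (six simple classes, three
templated-insertion topologies, chromoplexy, the three 2-jump subtypes,
local–distant and local n-jump). Deletion/duplication/inversion sizes follow
a bimodal log-normal mixture (modes near 10 kb and 250 kb); templated-
insertion fragments follow the dominant sub-kilobase mode (mixture medians
500 bp and 1 kb) with ~30% of templates inserted in inverted orientation and
1–3 templates per event; re-replicated or deleted host segments are a few
hundred bp; terminal losses at unbalanced events are ~300 kb windows rather
than whole arms so that hundreds of events pack into one genome. A smooth
deterministic replication-timing wave (3.7-Mb wavelength) supports per-class
placement bias; copy-number segments receive Gaussian noise (sd 0.1,
truncated at 0) on their means. Desk-scale fixtures on the 3×50-Mb toy build
carry ~20× the breakpoint density per bp of the genome-scale configuration,
so their inner event segments are scaled down proportionally to stay within
clustering range — a fixture-scale choice, not a change of the study
conditions.

The exposure-level driver cohort plants a +20-count gene effect on one
signature on top of histology effects, with within-histology exposure noise
of sd ≈ 7 counts so that the effect is estimated to about 1.2 counts
(standard error) at 300 patients — the ±3 recovery band then corresponds to
roughly 2.6 standard errors.

Cohort mode plants three well-separated signatures (small deletions + small
reciprocal inversions; tandem duplications; templated insertions) with
Gamma-distributed exposures (shape 1.5, mean 40 per signature) and Poisson
category counts. Counts can optionally be instantiated as events per
patient, with sizes drawn inside each category's bin and placements
rejection-sampled against the same replication-timing labeler and fragile-
site list used downstream, so full-pipeline category counts round-trip to
the planted truth.

What passing tests do *not* show about real data: simulated events never
overlap, CN boundaries coincide exactly with junction positions (real
consensus CN is off by caller resolution), the clustering null is exactly
the generative model (real breakpoints are themselves clustered), and
chromothripsis is not simulated at all — with the local-cluster precedence a
compact simulated chromothripsis would be labelled local n-jump, and a
genome-scale one does not survive the stand-in clustering null at 500
events/genome. Recovery rates on real genomes will be lower than the ≥95%
(simple) and ≥90% (templated) measured here.

## Problem sizes used in tests and the acceptance script

Enumeration checks run on the 2-chromosome × 3-unit alphabet (depth-3
soundness against 9,324 raw states; depth-2 contents against a raw-path
enumerator). Recovery uses one ~500-event hg19-scale genome per condition.
Clustering calibration uses 200 junctions × 100 replicates; the KS null
suite 20 tests × 200 replicates at 10⁴ random positions; microhomology 100
Poisson replicates; signature recovery 10 cohorts of 200 patients with 10
NMF restarts per rank plus one 400-patient split-half; driver checks one
300-patient planted cohort and 100 null cohorts. These sizes were chosen so
the complete suite and the acceptance script each run in minutes on one CPU
while keeping every Monte-Carlo interval tight enough for its threshold.
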