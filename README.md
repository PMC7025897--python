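# svrearrange

Clustering, classification and signature analysis of somatic structural
variants (SVs) in cancer genomes.

Somatic rearrangements rarely come one at a time: over half of the breakpoint
junctions in a tumour arise inside clusters of several or many SVs, and a
junction that merely *looks* like a deletion may be one strand of a far more
complex event. `svrearrange` implements the analysis stack needed to read
rearrangements in context:

* **Clustering** — junction breakpoints are grouped when they are
  significantly closer than expected by chance under a Poisson null
  (`P(D ≤ d) = 1 − exp(−λd)` with `λ = n_breakpoints / callable_size`;
  merge when below `p_merge = 10⁻³`), after removing segment-bypassing
  junctions and unsupported fold-back artefacts. Clusters carry *footprints*,
  the contiguous runs of co-located breakends.
* **Configuration library** — exhaustive enumeration of the derivative-genome
  patterns reachable by ≤ *k* simple operations (deletion, tandem
  duplication, inversion, balanced/unbalanced translocation, chromosome
  gain/loss), canonicalized into pattern keys that are invariant to
  chromosome relabeling, mirror reflection and junction order. Matching an
  observed cluster against the library yields all minimal generating
  sequences — or none, flagging a candidate copy-and-paste event.
* **Classification** — each cluster receives one event class: the simple
  classes, fold-back inversions, templated-insertion **cycles** (the inserted
  string returns to the host chromosome re-replicating a segment),
  **bridges** (returns leaving a deleted gap) and **chains** (never returns),
  local 2-jumps and n-jumps, chromoplexy, a coarse chromothripsis flag, or
  complex unclassified. Every reported templated-insertion path is replayed
  as an explicit derivative chromosome and must regenerate the cluster's
  junctions and copy-number gains exactly.
* **Genome properties** — 1-kb pixel tiling (hg19 chr1–22+X → 3,036,315
  pixels), rank-based Kolmogorov–Smirnov association of breakpoints with
  property tracks (Benjamini–Yekutieli FDR), breakpoint-partner permutation
  enrichment, footprint-connectivity enrichment, and a three-regime
  (NHEJ / MMEJ / SSA) changepoint fit to the junction-microhomology spectrum.
* **Signatures** — patients × category count matrices over a versioned
  catalogue (deletions/duplications split by size, replication timing and
  fragile sites; templated insertions split by template span, …), signature
  extraction by KL-divergence NMF with stability-based rank selection (an
  HDP Gibbs sampler is available as a second backend), split-half stability,
  and histology-adjusted driver-gene association.
* **Simulator** — synthetic rearranged genomes and cohorts with ground
  truth. Every event is built as a derivative chromosome first and its
  junctions/CN are *emitted* from that structure, so simulated data are
  internally consistent by construction.

## Worked example

Simulate a small genome, classify it, and read the per-class counts:

```bash
svrearrange simulate --seed 4 --build toy --total-events 25 --out sim/
svrearrange classify --junctions sim/junctions.bedpe --cn sim/cn_segments.tsv \
    --build toy --sample sim --out run/
column -t run/class_counts.tsv
```

With seed 4 the simulator draws 39 events (62 junctions); the classifier
reports:

```
event_class                 count
deletion                    12
tandem_duplication          9
reciprocal_inversion        3
reciprocal_translocation    3
unbalanced_translocation    2
foldback_inversion          1
templated_insertion_cycle   3
templated_insertion_bridge  4
templated_insertion_chain   2
chromoplexy                 1
```

Each count is a *cluster* of junctions, not a junction: the chromoplexy row
is a single balanced chain of three inter-chromosomal junctions, and each
templated-insertion row records a reconstructed path — for example one chain
here inserts a single 346-bp template from chr3 (forward orientation, copy
gain +1) between two other chromosomes. `run/classifications.tsv` carries
the footprints, reconstructed paths and library matches per cluster, and
`run/breakpoints.tsv` the per-breakpoint table with simple- vs
complex-cluster membership.

The same steps are available as library calls (`simulate_genome`,
`classify_all`, `extract_signatures_nmf`, …) for use in notebooks and
pipelines.

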