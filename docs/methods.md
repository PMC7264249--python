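# Methods

## Coordinate and data conventions

All genomic spans are BED-convention 0-based half-open intervals. ChIP
peaks are unstranded; strand enters only in motif scanning (both strands
always scanned) and in orienting peak-to-gene distances. A peak's summit
is an absolute position inside its interval; when the caller supplied no
summit column the floor of the interval midpoint is used. Signal is a
piecewise-constant density per base (`SignalTrack`, the in-memory form of
a bedGraph); queries outside any run return 0, and adjacent equal-valued
runs may be coalesced without changing any query or area.

## Super-enhancer identification

The procedure follows the stitched-enhancer (ROSE) lineage:

1. **Distal filter.** A peak is promoter-distal when its nearest boundary
   is ≥ 1.5 kb from the nearest TSS *or* its center is ≥ 3 kb from the
   nearest TSS. The two clauses are read as alternative sufficiency
   criteria (a disjunction); `PipelineParams.distal_conjunction` switches
   to requiring both, since the rule's wording admits either reading.
2. **Stitching.** Single-linkage merge per chromosome: peaks whose gap is
   *strictly* shorter than 12.5 kb join one enhancer. Stitching is
   idempotent and every input peak lands in exactly one output region.
3. **Quantification.** Total signal is the exact area of the track
   intersected with the region (no input-track subtraction or
   copy-number normalization — raw area). Ranks ascend with signal; ties
   break by genomic position for determinism.
4. **Tangency cutoff.** Ranks and signals are scaled to the unit square
   (x = rank/(N−1), y = signal/max). The cutoff is the support point of
   the slope-1 line touching the curve from below, i.e. the index
   minimizing y − x; for a convex ascending curve this is exactly where
   the discrete slope crosses 1 (verified analytically on y = x², slope 1
   at x = 1/2). Ties at the minimum resolve to the higher-signal index,
   which yields the more conservative (smaller) super set. Enhancers with
   signal strictly above the tangency signal are super-enhancers. The
   labels are invariant under scaling all signals by a positive constant.
   A flat curve (max = min) reports zero super-enhancers rather than an
   error: "no elbow" is a meaningful outcome. Fewer than 3 enhancers or an
   all-zero curve is an error.

Note a consequence of the geometry: when the typical-signal distribution
is heavy-tailed, the tangency can land inside the upper tail, so a few
strong typical regions may be labelled super alongside every planted
high-signal region. This is inherent to the slope-1 rule, not an
implementation artifact.

## Motif enrichment and co-regulator prediction

Fixed-width (default 200 bp) sequences centred on peak summits are
extracted from the genome; windows clipped by a chromosome end are
discarded and logged. Each sequence is scored against a PWM by the
**average odds**: the arithmetic mean, over every offset on the forward
strand and every offset on the reverse complement (2·(len−L+1) windows),
of ∏ᵢ p_motif(bᵢ)/p_bg(bᵢ). Windows containing N contribute odds 1.0
(neutral) so window counts stay comparable across sequences. The score is
exactly invariant under reverse-complementing the input. PWMs get a 1e-4
pseudocount at read time and rows are renormalized, guaranteeing finite
odds; backgrounds come from the MEME file's background block or default
to uniform.

Enrichment of a motif in condition vs control flanks is the one-sided
Wilcoxon rank-sum test (alternative: condition scores larger), computed
exactly when the combined sample size is ≤ 25 with no ties and by the
normal approximation with tie and continuity corrections otherwise (the
exact branch is cheap in that range; the approximation's error at the
branch boundary is below 0.01 for groups of ≥ 5). P-values are reported
raw at α = 0.05 by default, matching the usual report threshold of the
AME-style workflow; a Bonferroni option is available.

A motif is retained as a **candidate co-regulator** when it is enriched
in the stimulated condition versus the control (p ≤ α) and *not* enriched
in the reverse direction (control vs condition p > α). The reverse filter
removes motifs present in both sets (constitutive binding or sequence
composition bias) and motifs actually enriched in the control.

## Target genes and co-binding

Each peak is annotated to the gene whose TSS is nearest its summit
(ties: smaller absolute distance, then lexicographic gene id), with the
distance signed by gene strand (negative = upstream). No
promoter/exon/intron categorization is attempted — only the adjacent-gene
set feeds downstream logic. Target genes are the intersection of the
bound-gene set with the DEG table, carrying the up/down direction; DEGs
missing from the annotation are warned about but retained. Set summaries
are exact Venn counts obeying inclusion–exclusion.

Two TF peak sets co-bind a site when their summit-to-summit distance is
strictly below 200 bp (199 merges, 200 does not); an edge-to-edge mode is
available since the published rule does not say which distance was used.
Matching is greedy nearest-first with each peak used at most once, giving
a deterministic, exhaustive and disjoint partition into pairs and
set-unique peaks.

## Synthetic data

The generator emulates the statistical structure of the study inputs at
desk scale, not their biology:

- **Genome**: one chromosome (default 20 Mb) of i.i.d. uniform bases,
  mutable so exact consensus instances can be planted.
- **Enhancer landscape**: 500 typical + 25 super slots (defaults) on a
  24 kb grid, so constituent gaps (200–800 bp) always stitch within a
  slot and inter-slot gaps (≥ 15.6 kb) never stitch across slots.
  Typical constituents draw exponential totals (mean 100 signal units,
  an arbitrary coverage scale); super slots carry 3–5 constituents
  totalling 50× the typical mean (±20%). 50 additional promoter-proximal
  peaks exercise the distal filter. Signal is piecewise-constant per
  constituent; no read-level simulation.
- **TF summits**: 200 per condition; half sit within ±500 bp of a
  planted bound gene's TSS, the rest are placed in the enhancer zone by
  rejection sampling at least 1 kb from every existing summit, so the
  only summit pairs within 200 bp are the deliberately shared
  condition-1/control pairs (jitter ≤ 99 bp) recorded as co-binding
  truth.
- **Motifs**: a sharp planted PWM (0.97 per consensus base) plus 10
  weaker decoys. The consensus (not a matrix sample) is written into a
  `plant_rate` fraction (default 0.30) of condition summit flanks at a
  uniform offset and strand, chosen preferentially among summits not
  shared with the control so control flanks stay clean; planting the
  consensus makes recovery monotone in the plant rate. For the second
  condition a handful of planted sites can fall inside control flanks
  via shared bound genes; enrichment remains far from the null.
- **DEGs**: 60 up + 40 down per condition, 70% drawn from that
  condition's bound genes, giving a known bound × DEG target set.

One `numpy` Generator keyed by a single seed, with fixed draw order,
makes bundles byte-identical across runs; infeasible layouts (chromosome
too short) fail before any file is written.

What passing the recovery tests shows is that the pipeline's operations
implement their definitions and recover planted structure under clean
conditions; it does not show robustness to real-data features the
generator omits (mappability and GC structure, ragged peak shapes,
replicate noise, copy-number distortion of H3K27ac signal, correlated
motif co-occurrence).

## Problem sizes and determinism

The test suite runs a scaled-down bundle (50 genes, 60+5 enhancers, 40
peaks/condition on 3 Mb); the acceptance script runs the full default
conditions (200 genes, 500+25 enhancers, 200 peaks/condition on 20 Mb),
100-replicate null calibration with 50+50 flanks of 100 bp, and the
200+200-flank motif-recovery experiment. Every stochastic step takes an
explicit seed or Generator; pipeline runs write a manifest with input
SHA-256 digests and per-stage row counts, and rerunning with the same
seed reproduces it exactly.

## Known limitations

- Nearest-TSS annotation assigns distal peaks to *some* gene regardless
  of distance, as the HOMER-style adjacent-gene convention does; there is
  no maximum-distance guard.
- The rank-sum normal approximation is used above combined n = 25; for
  highly tied score distributions (e.g. many identical sequences) exact
  conditional p-values are not attempted.
- The tangency rule assumes an overall convex-ish ranked curve; on
  pathological non-monotone-slope curves the support-line definition is
  used (and property-tested), which may differ from eyeballing "the
  elbow".
- Multi-sample differential super-enhancer calling, input-track
  normalization and promoter-proximal enhancer rescue are out of scope.
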