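# Methods

## The analysis model

The pipeline's unit of data is a genes × time-points matrix of merged
FPKM values over a strictly increasing grid of sampling times (hours after
white prepupa; the default grid is 42, 52, 62, 72, 80, 88, 96).  Replicates
are assumed to have been merged upstream (as Cuffdiff-style estimation
reports them); an optional per-replicate table is carried only for
dispersion diagnostics.  "Neighboring time points" always means adjacent
labels in sort order — the grid need not be evenly spaced.

### Stage specificity

A gene's specificity profile is its per-time fraction of summed FPKM.  The
statistic is scale-free: rescaling a gene's row, or the whole matrix,
leaves it unchanged.  Genes with zero total FPKM have undefined fractions
and are excluded from every count.  All comparisons driven by "greater
than" wording (expression floor, specificity threshold α, cumulative
share) are strict; the transcription-factor screen thresholds ("30 or
greater", "at least 4 fold") are inclusive, and the fold-category table
thresholds (">10 fold", ">100 fold") are strict again.  These choices track
each criterion's phrasing and are all configurable.

The default universe for specificity counts is the expressed set
(max FPKM > 1).  Because the universe behind the published stage-specific
counts is not fully pinned down, `count_stage_specific` also exposes a
minimum-total-FPKM floor (default 0) rather than hard-coding one reading.

Fold changes between two FPKM values use `(max+pseudo)/(min+pseudo)` with
pseudo = 0 by default: 0 vs 0 is defined as fold 1 (no change), x vs 0 as
+∞, which satisfies any finite threshold.  A pseudocount is available but
off by default so thresholded counts are conservative and reproducible.

### Jensen-Shannon distance and clustering

Profiles (a sample's column over genes, or a gene's trajectory over time)
are normalized to probability vectors; the distance is the square root of
the Jensen-Shannon divergence with base-2 logarithms, so values lie in
[0, 1] and satisfy the metric axioms.  The log base is a configuration
option for cross-checking other conventions.  The log10(FPKM+1) transform
seen on trajectory plots is a display convention only (used for medoid
curves); distances always use the normalized profiles, which makes cluster
assignment invariant under per-gene rescaling.

PAM (partitioning around medoids) is deterministic: greedy BUILD
initialization (start from the 1-medoid optimum, repeatedly add the item
with the largest cost reduction), then steepest-descent SWAP applying the
single best strictly improving (medoid, non-medoid) exchange until a local
optimum, with all ties broken toward the lowest item index.  Instances of
at most 12 items are instead solved exactly by enumerating every medoid
subset: single-swap descent can stall on equal-cost plateaus (two
coordinated swaps needed to escape), and tiny instances make such plateaus
likely while also making enumeration trivial; ties take the
lexicographically smallest medoid set.  The 12-item bound keeps the
enumeration below ~1000 subsets in the worst case.

Silhouettes use the standard s = (b−a)/max(a,b) on the precomputed
distance matrix; an item in a singleton cluster scores 0, as does an item
with a = b = 0.  Medoids are always assigned to their own cluster even
under distance ties, so no cluster can empty out on degenerate
(all-identical) inputs.

Sample dendrograms use scipy's agglomerative clustering (average linkage
by default; complete and single available — the linkage behind the
published figure is unstated, so exact reproduction of its heights is not
promised) and are written as Newick with branch lengths in JS-distance
units.

### Isoform switching

The operational switch definition (the published analysis does not print
its criteria, so this artifact states its own): at an adjacent pair
(t, t′), the identity of the gene's dominant isoform changes, the outgoing
dominant has FPKM ≥ `min_fpkm` (default 1) at t and the incoming dominant
at t′, and each one's within-gene fraction moves by ≥ `min_delta` (default
0.25).  The fraction criterion makes calls invariant to rescaling all
isoforms at a time point; the absolute floor screens out noise-dominated
genes.  Because the definition is ours, published bulk counts of isoform
changes are reported only under this stated rule, never as a reproduction.
Bulk "isoform change" counting is looser by design: the max fold between
any two time points (not only neighbors), with the same zero-handling
conventions as gene folds.

### Composition screen

Per-protein residue fractions are exact counts over the 20 standard amino
acids; non-standard letters (X, U, B, Z, ...) are excluded from the
denominator and reported separately, which keeps the fractions-sum-to-one
invariant testable.  Default flags: short < 200 aa; per-residue absence;
single residue ≥ 20% and ≥ 30%; max fraction > 10% (the "average protein"
ceiling).  All thresholds configurable.

### Enrichment and two-group tests

Per-cluster label fractions are exact.  The two-group comparison of
fractions is a two-sample t-test, Student's (pooled variance) by default
with Welch's available, since the published analysis names only "t-test";
identical zero-variance groups are defined to give t = 0, p = 1 (the
textbook 0/0 case).  Category over/under-representation uses exact
hypergeometric tails per (cluster, category) against the clustered-gene
universe (configurable), with Benjamini–Hochberg q-values within each
cluster; no ontology propagation is performed — category files are taken
as flat gene → term lists.

### qPCR and thickness validation

Comparative-Ct quantification: per replicate, ΔCt = Ct(target) −
Ct(control); ΔΔCt subtracts the calibrator sample's mean ΔCt; the reported
RQ per sample is 2^(−mean ΔΔCt) — the geometric mean of per-replicate RQs —
with the spread reported as the SD of per-replicate RQs.  The geometric
form is chosen so the calibrator's RQ is exactly 1 by construction (an
arithmetic mean of replicate RQs would exceed 1 for any noisy calibrator,
by convexity of 2^x).  RQ is invariant to a constant Ct shift applied to
the whole plate.  RNA-seq expression is made comparable by dividing a
gene's per-time FPKM by its across-time mean (a "theoretical calibrator"
equal to the arithmetic mean of all samples), so relative values average
to 1.

Thickness comparisons: per wing, each surface's measurements are averaged
and the ratio taken either thicker-over-thinner (wild-type sections, where
dorsal/ventral orientation cannot be assigned with certainty) or in a
fixed orientation (knockdown wings, keyed by the marked surface); groups
of per-wing ratios are compared with a two-sample t-test (Student's
default, Welch reported alongside, as the published test's variance
assumption is unstated).

## The synthetic-data generators

The generators emulate the statistical structure the analysis assumes —
they are study-condition models, not fits to any dataset.

* **Time course.**  Five trajectory archetypes (single-stage spike at a
  configurable time, monotone geometric rise, monotone fall, flat,
  bimodal early+late) in equal proportions over 500 genes by default.
  Per-gene total FPKM is log-normal (median 300, log-SD 0.8) — deliberately
  above the noise floor so the archetypes are separable; that margin is the
  documented separation behind the planted-recovery guarantees.  Noise is
  multiplicative log-normal with mean-one factors and
  CV²(FPKM) = a/FPKM + b (defaults a = 1, b = 0.005, i.e. CV² = 1.0 at
  FPKM 1 falling to 0.015 at FPKM 100); the decreasing form echoes the
  cross-replicate variability of duplicate RNA-seq libraries, whose exact
  functional shape is not published — the hyperbola is this artifact's
  choice.  Two replicates are generated and merged by mean.
* **Isoforms.**  100 two-isoform genes, 20 with a planted dominance swap
  (0.8 ↔ 0.2) at an adjacent pair assigned round-robin over the three
  earliest pairs (where real switching concentrated); non-switching genes
  keep a stable 0.8 dominant.  Log-normal FPKM noise with σ = 0.1 cannot
  flip a 0.8/0.2 dominance, so detection at the default thresholds is
  expected to be exact; the 0.6 fraction margin is the documented
  separation.
* **Proteins.**  Twenty candidate-like proteins whose residue *counts* are
  constructed, not sampled (only the order is randomized), so planted
  truths hold exactly: 10 short, 9 Trp-free, scattered Asn/Asp absences,
  two >20% Ala, one each >20% Val, >20% His, >30% Gly — mirroring the flag
  spectrum reported for highly expressed unstudied genes.
* **Thickness.**  Per-wing ratios drawn from group normals — wild type
  1.2 ± 0.11, perturbed 2.1 ± 0.43, eight wings per group, ten
  measurements per surface — with 2% multiplicative measurement jitter.
  Draws ≤ 1 are redrawn (≈3% of wild-type draws) so thicker-over-thinner
  recovers the drawn value; the induced upward bias on the group mean is
  well under the group SD.
* **qPCR.**  Plates are built by inverting the ΔΔCt model from chosen true
  RQ values (control Ct 20, base ΔCt 2, triplicate wells, 0.1-cycle
  noise), so recovery is exact at zero noise.

What the generators do **not** emulate: realistic genome-scale gene counts
and FPKM dynamic range, library-size and gene-length biases, correlated
noise across genes, partial/ambiguous isoform assignment, realistic
protein sequence grammar, or section-angle artifacts in thickness
measurements.  Passing tests therefore demonstrate the correctness of the
statistics and the detectors under their stated assumptions, not
performance on real libraries.

## Problem sizes and determinism

The test suite and the acceptance script run the generators at their
default sizes (500 genes × 7 time points, 100 isoform genes, 20 proteins,
8 wings per group), which exercise every code path in seconds.  All
randomness flows through one integer seed via independent named
substreams (`default_rng([seed, stream])`), so every generator is
bit-reproducible and the report pipeline's outputs are byte-identical
across re-runs; analysis algorithms themselves are seed-free and
deterministic (PAM tie-breaks by index, sorted outputs).

## Known limitations

* PAM above 12 items is a greedy local search; it is deterministic but not
  guaranteed optimal (an optional multi-restart exists only implicitly via
  permuting input order; none is wired into the CLI).
* Exact reproduction of published cluster numberings, dendrogram heights
  or q-values is out of scope: cluster identity is meaningful only by
  composition, and upstream differential-expression estimation is consumed
  as input, never recomputed.
* The enrichment module performs no GO-graph propagation; term files are
  flat.
* Isoform switch counts depend on this package's stated operational
  definition; published bulk counts derived from unstated criteria are not
  comparable.
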