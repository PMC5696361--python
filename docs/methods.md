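# Methods

## The data model

Every analysis consumes a *labeled spine pattern*: the spines of one
dendrite in imaging order, each a 3D point (x, y, z in μm) with a binary
potentiation label. All distances are 3D Euclidean; all statistics are
computed within a dendrite — spines on different dendrites are never
neighbors. Patterns carry animal/slice/dendrite identifiers and region
(CA1 or DG) × condition (home cage or novel context) factors used only
for grouping and reporting. The table format is a plain CSV with header
`animal_id, slice_id, dendrite_id, region, condition, spine_id, x, y, z,
arc_position, positive`; `arc_position` (distance along the dendrite) is
carried alongside the 3D coordinates because neighbor *order* is defined
along the dendrite while neighbor *distance* is defined in 3D, and tests
compare the two conventions.

## Spatial statistics

**First-neighbor distances.** d_PP (d_PN) is the minimum 3D distance
from a potentiated spine to any other potentiated (non-potentiated)
spine of the same dendrite. Undefined values — a dendrite's only
potentiated spine has no d_PP — are skipped and counted, never imputed.

**Shuffle null.** The null hypothesis is label exchangeability: the
labels are permuted uniformly at random over the dendrite's fixed spine
positions, preserving T, p and the geometry, and the distance statistics
are recomputed. Five shuffles per dendrite is the default; shuffling is
per dendrite (each dendrite's p is preserved). Any permutation-invariant
statistic therefore has, under exchangeable labels, the same
distribution observed and shuffled — the calibration the test suite
checks on the generator's `random` mode.

**Neighbor-rank probability curve.** For each potentiated focal spine,
the 20 nearest other spines (ranked by 3D Euclidean distance to the
focal spine, ties broken by along-dendrite order; both sides of the
focal spine are eligible) contribute one row of labels to an N×20
matrix. probability(i) is the column-i mean; the per-dendrite expected
value under exchangeability is (p−1)/(T−1) — the chance that a specific
*other* spine is potentiated, given the focal one is — and
increase(i) = probability(i)/expected. The normalization is computed per
dendrite with that dendrite's realized p and T, then the increase values
are averaged across dendrites unweighted. A flag (`rank_mode="ordinal"`)
ranks neighbors by ordinal position along the dendrite instead; the
default is Euclidean, and the calibration properties hold under both.
Dendrites are excluded from this analysis only when (i) p/T < 0.05 or
(ii) T < 21 (a full 20-neighbor row cannot be formed); exclusions are
logged with their rule. All other statistics keep every dendrite.

**z-test against 1.** Per rank, increase values across dendrites are
tested with a one-sample z statistic (mean − 1)/(sd/√n), sd with one
delta degree of freedom, two-sided normal p-value. A sample identically
equal to 1 returns (z = 0, p = 1), the natural 0/0 limit; any other
zero-variance sample is an error. At typical batch sizes (tens of
dendrites) the normal reference is slightly anticonservative for this
skewed ratio statistic; the measured false-positive rate at α = 0.01 is
~1–3%, which the acceptance suite bounds at ≤ 2% under its fixed seeds.

**Spine units.** Potentiated spines are partitioned by single-linkage
clustering with a strict < 2 μm cutoff: two spines share a unit iff they
are connected by a chain of pairwise distances strictly below the
cutoff, so a pair at exactly 2.0 μm stays separate. The dendrogram comes
from `scipy.cluster.hierarchy.linkage(method="single")`; the cut walks
the merge list and joins only merges with height < cutoff (scipy's
`fcluster` uses ≤ t and would mislabel the boundary). Single linkage
with a cutoff is mathematically the connected components of the
proximity graph, and the test suite verifies that equivalence against an
independent graph-components oracle, exhaustively on small collinear
grids (which realize exact-cutoff ties) and on random 3D patterns.
Units of size ≥ 2 are clusters; singletons are units of dimension 1 and
enter the mean unit size but not the cluster-dimension percentiles.

**Separation Index.** Per slice, f = Σp/ΣT over the slice's dendrites;
per dendrite p\* = f·T and SI = |p − p\*|/p\*. SI ≥ 0 with equality iff
p = p\*; a slice with no potentiated spines has a degenerate expectation
and yields NaN (logged), not zero.

## Intensity metrics

**Enrichment Index.** EI = (spine mean − background)/(shaft mean −
background), shaft measured 1–2 μm from the spine junction along the
dendrite (arc distance — the only convention consistent with curved
dendrites). Background is one scalar per record, supplied upstream; a
non-positive denominator invalidates the record (excluded and logged,
not clamped). EI is invariant under affine rescaling I → aI + b when the
background shares the transform.

**PSD enrichment.** Integrated intensity over the PSD divided by the
dendrite mean; spines that do not express the reporter are assigned 0 so
they remain in population-level correlations.

**Docked classification.** A spine is *docked* if its reporter peak
falls inside the PSD extent, *positive_not_docked* if outside the extent
but within 0.6 μm of the PSD center, *negative* otherwise; a missing
peak (no expression) is negative. The PSD extent is an explicit input
radius — the PSD boundary is an imaging/segmentation product, not
something this package infers. The peak location is likewise an input
(max-voxel vs centroid conventions are upstream choices).

**Time courses.** ΔCh/Ch(t) = [I_c(t) − I_c(−5′)]/I_c(−5′) on the
reporter channel; ΔV/V is the same formula on the filler channel after
dividing each timepoint by the dendrite mean beneath the spine. The −5′
reference must be present and positive.

**ΔF/F integration.** After subtracting the dark level from every
sample, F0 is the mean over the baseline window (default: the 50
pre-stimulus frames, configurable) and ΔF/F = (F − F0)/F0. The integral
sums the 200 frames after the stimulus frame. The operation is linear in
F − F0. Traces default to 500 frames at 20 ms with the stimulus at
frame 50.

**Laminar profiles.** Each 325 μm profile is shifted so its anatomical
anchor (start of the stratum pyramidale) sits at 100 μm, its baseline
subtracted, samples averaged in 5 μm windows, profiles averaged
pointwise over their common aligned support, and the result divided by
its maximum (so max = 1 whenever the input is not identically ≤ 0). A
running median (window = 1% of binned samples) is available as a
display-only smoothing flag and is never applied to quantified output.

## The synthetic-data generator

The generator emulates the in-vivo study conditions, not the microscope:
no images, point-spread functions or branching topology — only
coordinate and intensity tables with known ground truth.

* **Geometry.** Each dendrite is a gently wandering 3D curve of arc
  length 50 μm (unit tangent with small Gaussian increments), carrying
  a uniform number of spines drawn from 50–90 — ~70 spines per dendrite,
  ≈1.4 μm⁻¹, the density implied by the study's aggregate counts and
  typical of hippocampal pyramidal dendrites. Spines sit at uniform arc
  positions with isotropic Gaussian offsets (SD 0.5 μm, a spine-neck
  length scale) in the plane normal to the backbone.
* **Labels.** `random` mode labels each spine independently with
  probability `label_fraction` (default 0.2, matching observed positive
  fractions) — exchangeable by construction, the null for every
  calibration test. `clustered` mode drops Poisson seeds along the arc
  (rate 0.05 μm⁻¹) and labels spines within `cluster_radius` (2 μm — the
  ground-truth radius maps directly onto the 2 μm analysis cutoff) of a
  seed with `within_cluster_label_prob` (0.9); uncovered spines get the
  residual rate that makes the expected marginal fraction equal
  `label_fraction` (solved from the Poisson void probability; exact up
  to edge effects of order 0.01).
* **Intensities.** Positive spines receive spine-region means of
  baseline × enrichment (default 3×) with multiplicative Gaussian noise
  (CV 0.1); negatives and shafts receive baseline; all records share one
  background level. A configurable fraction (default 0.8) of positive
  spines is docked — reporter peak drawn inside the PSD radius (0.3 μm)
  — and the rest peak between the PSD radius and 0.6 μm.
* **Traces.** `flat`, `step_decay` (exponential transient with
  amplitude A and time constant τ frames starting at the first
  post-stimulus frame — which makes the noise-free integral exactly
  Σ_{k=0..199} e^{−k/τ}) and `event` (Poisson-timed transients), with
  optional additive noise.
* **Determinism.** All randomness flows from one seed; each dendrite
  uses a substream derived from (seed, dendrite index), so datasets are
  byte-identical across runs and machines for a fixed configuration.

What the generator does *not* emulate: segmentation errors, missed or
merged spines, anisotropic z-resolution, dendrite-to-dendrite density
gradients and branching. Passing calibration/sensitivity tests therefore
demonstrates correctness of the statistics under clean exchangeable or
Matérn-like alternatives, not robustness of the full imaging pipeline.

## Numerical choices and reproducibility

* Distances via `scipy.spatial.distance.pdist` (exact, no spatial
  indexing — dendrites have ≤ a few hundred spines).
* Neighbor-rank ties broken deterministically by spine order; cluster
  cuts strict; percentiles use numpy's default linear interpolation.
* The pipeline writes floats with `%.6f`, making every data output
  byte-identical for a fixed seed; the JSON run summary carries a sha256
  manifest of the data files. The summary also records wall-clock per
  stage, which is the one field that legitimately differs between
  reruns — the reproducibility contract covers the data outputs and
  their manifest.
* Monte-Carlo problem sizes in the test and acceptance suites (e.g.
  2400 dendrites for the null-calibration band, 50 batches of 40 for
  the false-positive rate, 200 dendrites per clustering level) were
  sized so the Monte-Carlo standard error is small against the asserted
  bands, and run in well under a minute each.

## Known limitations

* The probability curve needs T ≥ 21 and p ≥ 2; very sparse dendrites
  contribute only to the distance, cluster and SI statistics.
* The z-test inherits the normal approximation; for small dendrite
  counts a permutation test would be more exact, but the z form is the
  one defined for this pipeline.
* Group-level omnibus comparisons of d_PP/d_PN distributions
  (Kruskal–Wallis and post-hoc tests) are deliberately left to standard
  statistics packages on the tidy TSV outputs; only the bespoke
  statistics are implemented here.
* No raw-image processing: spine detection, peak localization and PSD
  extents are inputs.
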