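# Methods

## Pipeline model

The package treats a structural brain network as an undirected weighted
graph: nodes are gray-matter ROIs from a subject-space parcellation, edges
are evidence from whole-brain tractography. A streamline contributes to the
edge `{a, b}` exactly when its first endpoint lies in ROI `a` and its last
in ROI `b` (or vice versa), with `a ≠ b`; streamlines merely passing through
an ROI, ending in background, or ending outside the grid contribute
nothing. This endpoint-only rule is the standard connectome convention and
the only one consistent with counting streamlines *between* two regions.

Three weightings are derived per subject:

* **NOS** — the streamline count per ROI pair;
* **binary** — `1` when NOS ≥ 1;
* **FA** — the mean over connecting streamlines of each streamline's mean
  FA. FA is sampled by trilinear interpolation at every streamline point
  (points are off-grid in general; nearest-voxel sampling would alias).
  Averaging per streamline first, then across streamlines, gives every
  streamline equal weight regardless of its length or point spacing; the
  alternative (pooling all points) would overweight long streamlines. This
  was a genuinely open choice; the per-streamline form is the default and
  only behaviour.

Points outside the FA grid sample as 0 and still count toward the mean, so
degenerate inputs degrade gracefully instead of raising mid-cohort; the
event is logged.

### Coordinates

Voxel indices are 0-based; world space is RAS+ mm. A world point maps to
the voxel `floor(inv(affine) @ p + 0.5)` per axis — the nearest voxel
centre, half-way cases rounding to the higher index. All tractogram I/O
(TRK/TCK via nibabel) normalizes to world mm on load.

### Cohort-level processing

Edges present in fewer than a fraction (default 0.5) of *all* subjects —
patients and controls pooled — are removed everywhere. The boundary is
inclusive: an edge in exactly half of the subjects survives, since only
connections in strictly fewer are discarded. FA and NOS matrices are then
divided by their respective cohort-wide maxima: a single constant per
weighting, so between-subject ratios are untouched and the post-threshold
maximum is exactly 1, as the efficiency formulas require weights in [0, 1].

### Efficiency

Connection weights map to lengths by reciprocal (`0 → +inf`); distances are
Dijkstra per source node (tie-breaking is irrelevant because only distances
are used). Nodal global efficiency is the mean inverse distance to all
other nodes with `1/inf = 0`. Binary local efficiency is the efficiency of
the subgraph induced by a node's neighbours; the weighted form uses the
cube-root combination `(w_ij · w_ih / d_jh(N(i)))^{1/3}` normalized by
`k(k−1)`, the 2010 formulation of the weighted local efficiency (later
corrected variants exist; the 2010 form is implemented deliberately, as the
variant the surrounding literature used). Nodes of degree < 2 score 0.
Nodes isolated by thresholding keep their slot with `E_glob = E_loc = 0`,
so nodal vectors stay aligned across subjects, and whole-brain values are
unweighted means over all nodes including isolated ones.

### Statistics

"Student t-test" is read literally as the pooled-variance two-sample test
(Welch is available behind a flag). Pearson correlations use only the
patient group (controls carry no motor score). All tests are two-sided.
Benjamini–Hochberg FDR at q = 0.05 is applied separately to each family of
nodal tests — one family per measure × weighting × test type (group
comparison and correlation are corrected as separate families). Whole-brain
tests are reported uncorrected. Degenerate families (zero variance, e.g.
binary matrices identical across subjects of a phantom cohort) report
`r = nan, p = 1` rather than aborting the analysis.

## Putamen splitting

The splitting plane is defined in AC–PC-aligned space: through the anterior
commissure, orthogonal to the AC–PC (y) axis, +y anterior (RAS+). Voxels
are classified in native space by mapping each voxel centre through the
forward transform and comparing its AC–PC y-coordinate with the AC point's;
this is algebraically identical to intersecting the inverse-transformed
plane with the native grid, and is checked against per-voxel brute-force
classification in the tests. The nominal 2-mm plane thickness exists for
visualization only; labelling uses the signed distance to the plane's
central surface, with exact ties assigned posterior — a deterministic,
thickness-independent rule (which side of the slab should win is not
determinable from the original procedure's description). Anterior plus
posterior voxel counts always equal the original region count. A region
entirely on one side produces a warning and an empty part (kept in the
label table so the node count is stable); callers decide whether to
proceed.

## Synthetic cohorts

The generator emulates the per-subject triplet the pipeline consumes, not
the upstream MRI: no diffusion signal, tensor fitting, tractography
artifacts, motion, or anatomically shaped ROIs are simulated.

* **Parcellation** — `n_rois` rectangular blocks (≥ 8 voxels each) inside a
  one-voxel background margin; the seed permutes label placement.
* **FA map** — Gaussian field `clip(N(fa_mean, fa_noise_sd²), 0, 1)` inside
  labelled voxels, 0 in background. Defaults 0.5 ± 0.05, a typical
  white-matter-adjacent FA scale.
* **Tractogram** — two-point streamlines between voxel centres of the two
  ROIs of each requested edge, so every endpoint maps back into its ROI
  exactly and the builder recovers the requested NOS counts edge-for-edge.
* **Cohort** — defaults of 14 patients and 15 controls match the target
  study design; motor scores are uniform on (8, 29) (mean 18.5, SD ≈ 6.1,
  matching a moderately affected cohort) rather than normal: the uniform
  spreads leverage for correlation recovery and cannot go negative. All
  subjects share one geometry (parcellation and edge set), so the consensus
  threshold retains every generated edge and group differences are nil by
  construction.

The UPDRS–weight association is injected on FA edge weights, not on
efficiency directly, so recovering it exercises the full pipeline path. For
each affected edge, a dedicated endpoint-voxel pair carries the value
`w = fa_mean + r·σ·z + sqrt(1−r²)·σ·ε` with `z` the population-standardized
motor score, `σ = fa_noise_sd`, `ε ~ N(0,1)`; the population correlation
between score and weight is exactly `effect_r`, and the edge-weight SD
equals the FA noise SD regardless of `r`. Because trilinear interpolation
at a voxel centre returns that voxel's value, the builder recovers `w`
exactly. Controls get noise-only weights on the same edges.
`|effect_r| = 1` with nonzero noise is rejected as unattainable. Randomness
is one seed sequence per cohort, split per subject by counter, so adding a
subject never changes the others.

What passing tests show: the pipeline's algebra, thresholding, metric
formulas and statistical calibration are correct under the stated
generative model. What they do not show: robustness to real tractography
failure modes (spurious/missing streamlines, partial-volume FA,
registration error, anatomically irregular ROIs).

## Problem sizes and numerical choices

Monte-Carlo suites run at sizes chosen to make sampling error small
relative to the asserted bands while keeping the default run quick on one
CPU: oracle equivalence on 200 random graphs of 3–8 nodes (exhaustive
simple-path enumeration is exponential, so graphs stay tiny); power/null
calibration on 200 replicate cohorts of 10 nodes on a 16³ grid (14 PD + 15
HC each, 200 patients per cohort for direct edge-level calibration checks);
localization on 100 replicates; split conservation on 20 random
region/transform pairs. Efficiency routines agree with the enumeration
oracle to ≤ 1e-10 (observed at machine precision); normalization ratio
preservation is asserted at 1e-12. Whole-brain detection power for a −0.7
per-edge effect exceeds 80% at n = 14 because averaging over the affected
edges concentrates the signal (the effective whole-brain correlation is
stronger than the per-edge one).

## Known limitations

* Phantom geometry is shared across subjects within a cohort; consensus
  thresholding is therefore exercised mainly at its boundary logic, not on
  realistic between-subject edge variability.
* The weighted local-efficiency variant is the 2010 cube-root form; results
  differ from later corrected formulations on the same matrix.
* No covariate adjustment, nonparametric tests, or permutation-based
  network statistics; no streamline filtering by length or anatomy.
* FA values outside [0, 1] are rejected at validation rather than clipped.
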