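# Methods

## Scope and model

`loopfold` reconstructs the 3D fold of a short (~33 kb), contiguously
Oligopaint-stained chromatin region from single-molecule localization data.
The core modelling assumption is geometric: probes tile the fiber densely
and contiguously, so the genomic order of the detected probe positions is
the order of a shortest visiting path through them. This assumption holds
when (a) the inter-probe spacing along the fiber is smaller than the
distance between spatially adjacent but genomically distant fiber segments,
and (b) staining gaps are not so large that a spline bridge misrepresents
the missing region. Both failure modes are quantified by the shipped
simulation studies rather than assumed away.

## Localization processing

A localization is a blinking event with 3D position (nm), per-axis
uncertainty σ (nm), photon count and frame index. Processing stages:

1. *Permissive pre-filter*: keep events with σ < 30 nm on every axis.
2. *Strict filter*: remove events whose σ exceeds 15 nm on **all three**
   axes simultaneously. This conjunctive reading is deliberately literal;
   it is unusually permissive (an event with one precise axis survives), so
   the mode switch `any_axis`/`all_axes` lets users apply the disjunctive
   reading instead. Default is the conjunctive rule.
3. *Grouping*: one oligo blinks many times; events are clustered by DBSCAN
   with `eps = radius` (default 50 nm) and `min_samples = min_events`
   (default 2), and each cluster's photon-weighted centroid becomes a group
   peak. The radius default reflects real acquisition noise (σ up to
   ~15 nm after filtering, so re-blinks scatter over tens of nm) while
   distinct oligos on a decondensed fiber sit farther apart; for synthetic
   noise-free fixtures whose oligos are a few nm apart the radius must be
   scaled down with the noise (the tests use 2 nm).
4. *QC*: an image qualifies for modelling only if the group-peak count
   reaches `ceil(min_fraction × n_designed_oligos)` (default 30% of 336,
   i.e. 101). Convex-hull volume (0 for degenerate point sets) and
   per-stage counts are reported alongside.

Frame indices are retained but unused by grouping: grouping is purely
spatial, since no temporal grouping rule is defined for this data.

## Path ordering

The greedy stage treats every point as a singleton path and repeatedly
connects the two closest joinable path endpoints (equivalently: accepts
candidate edges in ascending length, skipping edges that would give a
vertex degree > 2 or close a cycle). Ties are broken by lexicographic edge
index, making the result deterministic given the input order.

Greedy solutions are then improved by best-improvement local search over
two move classes: 2-opt segment reversals (including prefix/suffix
reversals, which on an open path replace a single edge) and single-point
relocations. Each scan is vectorized over all O(n²) candidate moves; the
best improving move is applied and the scan repeated until no move improves
or a cap of 1000 moves is hit. Total path length never increases. On
exhaustively enumerable instances (n ≤ 8) the heuristic never beats the
optimum (it cannot) and matches it in over 80% of random trials.

Finally the open path is closed into a tour and the single longest tour
edge is deleted. This is the only reading of "delete the longest
connection" that always yields one open path whose endpoints are the
mutually most distant pair; with first-encountered tie-breaking it is
deterministic. A diagnostic mode records the longest interior edge without
removing it.

Path orientation is fundamentally unidentifiable with single-color
staining: a reversed path is an equally valid reconstruction. Reversing the
bead order flips the distance map about its anti-diagonal, so entry-wise
map comparison is *not* orientation-free; all reconstruction-vs-truth
scoring therefore evaluates both orientations and keeps the better score
(`imj_orientation_free`, and the efficiency sweep's RMSD likewise takes the
better orientation).

## Interpolation and genomic annotation

Ordered centroids are smoothed by a natural cubic spline parameterized by
cumulative chord length and resampled uniformly in arc length (numerical
inversion on a 10× oversampled curve; resulting bead spacing has CV < 1%).
Fewer than 4 distinct points fall back to piecewise-linear resampling.
Bead count is `floor(region_length_bp / bp_per_bead)`; bead *i* (1-based)
covers the left-open interval `(origin + bp·(i−1), origin + bp·i]`.

For the target region the modelled extent is 33,312 bp with origin
chr14:23,016,030 — not the displayed browser start 23,016,000. The
printed display region, the 33,312 bp extent and the anchor beads
1000/2331 at 10 bp/bead are mutually inconsistent unless the origin is
23,016,030; that derived origin is the package default and both origin and
convention are configurable. The probe-design span used for
genomic-resolution arithmetic is the designed 33 kb staining region
(13 kb loop + 2 × 10 kb flanks): 33,000 / 110 detected probes = 300 bp,
33,000 / 275 = 120 bp.

One exception to "always resample": when a reconstructed point set already
has the target bead count (the lossless efficiency-1.0 limit), the ordered
points are returned unchanged. Nothing is missing, so there is nothing to
re-space, and resampling would only shift knots slightly because spline arc
length exceeds chord length between knots.

PDB export writes one HETATM per bead with CONECT chain connectivity; the
nm → coordinate-unit factor (default 0.1) is recorded in a REMARK. Counts
beyond the 99,999-serial format limit are rejected with advice to coarsen
`bp_per_bead`.

## Distance maps and the Modified Jaccard Index

All quantitative structure comparison happens on pairwise Euclidean
distance maps (nm), which are invariant to rigid motion. Maps are
normalized by their mean off-diagonal entry before comparison, making
scores invariant to uniform scaling — image models (nm) and contact-matrix
embeddings (arbitrary units) are directly comparable. Two IMJ variants:

* **weighted** — `100 · Σ_{i<j} min(a_ij, b_ij) / Σ_{i<j} max(a_ij, b_ij)`;
* **contact** (default) — binarize each normalized map at a threshold
  (default: the 10th percentile of the pooled off-diagonal normalized
  distances of the two maps) and return the plain Jaccard percentage of
  the two contact sets.

Degenerate conventions: two all-zero maps score 100 (identical), one
all-zero map scores 0. Maps of models at different bead counts can be
binned to a common genomic bin (default 100 bp) before comparison.

**Calibration and a known limitation.** The default contact variant and
threshold were chosen by scoring disjoint pairs of independent 340-bead
self-avoiding walks (`scripts/calibrate_imj.py`). The literature baseline
for unrelated chromatin conformations under this family of statistics is
around 30%. Neither shipped variant reaches that floor under these
structure conditions: the contact variant bottoms out near 35% (single
orientation; ~37–38% orientation-free) across threshold quantiles
0.02–0.10, and the weighted variant sits near 70%, because both structures
always share the trivial near-diagonal proximity band of any continuous
chain. The default stays at quantile 0.10 (indistinguishable from the grid
minimum within sampling noise). Consequently, at the most extreme depletion
(230 of 340 beads missing) the sweep median (~36–38%) exceeds the cited
30% baseline but only marginally exceeds the *recomputed* orientation-free
floor — at that depletion the genomic registration of the reconstruction is
dominated by the spline bridge across the gap, and most of the residual
score is the generic chain band. Intermediate gaps (≲ 100 beads) separate
clearly from the floor.

## Rigid alignment and order recovery

Kabsch superposition (SVD of the cross-covariance of centered coordinates)
gives the minimum RMSD over rotations + translations; reflections are
excluded by default to preserve chirality, with an explicit opt-in.

Order recovery compares a true and an inferred visiting order by Spearman
rank correlation with a two-sided test. Reversal flips the sign of ρ but
not the p-value, so |ρ| is reported with the matching orientation noted.
Under the null (random permutations, n = 340) the significant fraction at
α = 0.05 calibrates to ~5%.

## Simulators

**Self-avoiding walks.** Off-lattice growth with fixed bond length
(default `step` = 30 nm — a reasonable physical scale for the ~100 bp of
10 nm fiber that one probe covers) and uniformly random step directions;
placements closer than `excluded_radius` to any non-adjacent bead are
rejected, with single-bead backtracking after repeated local failure and a
global attempt cap. Default `excluded_radius = step` (a chain of touching
hard spheres). This default is load-bearing: if the excluded radius were
smaller than the bond length, non-adjacent beads could sit closer together
than chain neighbors and the chain would no longer be the shortest
Hamiltonian path through its own beads — the TSP assumption would fail on
the control ensemble by construction (measured small-gap reconstruction
medians collapse from >90% to ~40%). With `excluded_radius ≥ step` the
chain is provably the unique shortest path (every non-chain edge is at
least as long as every chain edge). Radii up to just below `2·step` remain
generable; the generator refuses larger values.

**MDS embeddings.** A contact matrix is thresholded into an adjacency
graph (default: any nonzero contact; optional 1/frequency edge weights),
all-pairs shortest-path distances are computed, and metric MDS (SMACOF,
one random initialization per model) embeds the bins into 3D — one bead
per bin. Distinct random initializations are what turn one matrix into an
ensemble of conformations. Disconnected graphs are rejected with the
isolated bins listed. A pure path-graph matrix embeds monotonically (rank
correlation > 0.99 between bin index and position along the principal
axis).

**Synthetic images.** Oligo targets are placed at equal genomic spacing
(default 99 bp → 336 oligos over the modelled target region) at the
corresponding arc-length positions along the truth polymer; each is
retained with probability `efficiency`; each retained oligo emits
Poisson-many events (a deterministic-count mode exists for exact fixtures)
at its position plus per-axis Gaussian noise (defaults within the 2–22 nm
precision range of the real acquisitions); photon counts are gamma with
the configured mean. What this generator does *not* emulate: fluorophore
duty cycles and bleaching, PSF shape, drift residuals, background
localizations, and the real probe set's variable density (6.7–11.57
oligos/kb; a per-segment spacing can approximate it). Passing tests on
these fixtures therefore demonstrate the pipeline's geometric correctness,
not robustness to every instrumental artifact.

**Subsampling.** `random_fraction` keeps `round(f·n)` beads uniformly
(staining efficiency); `contiguous_gap` deletes one uniformly positioned
run of consecutive beads (an unstained sub-region). Surviving original
indices are returned for order-recovery scoring.

All generators are bit-for-bit reproducible from their seeds (child seeds
spawned from a master seed sequence).

## Validation studies

*Efficiency sweep*: for each (truth model, efficiency in 5%..95%,
replicate) — subsample, shuffle (so reconstruction cannot inherit input
order), reconstruct, interpolate to the truth bead count, score IMJ, |ρ|
and best-orientation RMSD. Replicates default to 10 per cell, matching the
gap study. *Gap sweep*: same with a contiguous gap, IMJ only, per-gap-size
medians. *Order-recovery evaluation*: per ordered trace, shuffle →
reconstruct → Spearman; traces with < 3 valid points are skipped; the
summary reports the significant fraction and the share with p < 10⁻⁵.
*Random baseline*: IMJ between disjoint pairs of independent SAWs — the
no-signal floor.

At the full study design (20 SAWs × 340 beads, 10 replicates per cell) the
gap-sweep medians run from ~96% at gap 1 down to ~36–38% at gap 230, and
the sweep completes in about two minutes on one CPU; the acceptance script
uses a gap grid of {1, 10, 20, …, 230}. Alignment RMSD is recorded in the
efficiency sweep for inspection, but IMJ — alignment-free — is the primary
score.

## Numerical choices

* Greedy tie-break: ascending (length, i, j); local search applies the
  single best move per scan; all steps deterministic given input order.
* Spline: natural boundary conditions; endpoints pinned to the curve ends;
  consecutive duplicate input points dropped before fitting.
* IMJ degenerate cases as above; contact threshold computed on the pooled
  pair, so `imj(A, A) = 100` holds exactly for every valid map.
* QC threshold uses `ceil`, so 30% of 336 means ≥ 101 group peaks.
* PDB coordinates: fixed-width %8.3f at scale 0.1 → 0.005 nm round-trip
  precision.

## Known limitations

* Group-peak counts on real images depend on the grouping radius and
  minimum event count; the upstream instrument software's proprietary
  grouping is approximated, not replicated, so real-image group counts
  match only approximately.
* The IMJ random-pair floor is ~35–38%, not the cited ~30% (see above);
  comparisons against "the baseline" should use the recomputed floor, and
  similarity claims at extreme depletion (> ~1/3 of the region missing in
  one run) should be treated as weak.
* At large contiguous gaps the spline bridge compresses the missing region
  into few beads, distorting genomic registration of everything downstream
  of the gap; this is a property of any reconstruction that cannot know
  the gap's genomic extent.
* The MDS ensemble inherits the usual SMACOF caveats (local minima,
  stress-dependent scale); models are comparable through normalized
  distance maps only.
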