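# Methods

## Model and statistic

The dataset is D = {xᵢ, yᵢ}: N genomic bins embedded in d ∈ {2, 3}
dimensions with binary labels, B = Σyᵢ positives.  A pivot p induces λₚ,
the label vector ranked by Euclidean distance from p (distance ties break
by bin index — measure-zero for embedded data, deterministic on synthetic
grids).  The mHG statistic is the minimum hypergeometric upper tail over
all prefixes of λₚ; the smallest prefix length attaining the minimum is
reported, with the ball radius given by the distance to that prefix's last
bin.  Degenerate label vectors (B = 0 or B = N) score 1 at threshold 1 by
convention; upstream annotation mapping rejects B < 4 anyway.

Hypergeometric tails come from `scipy.stats.hypergeom.sf` (log-space
stable to N ~ 10⁴) and are cached per (N, B) as an (N+1)×(B+1) table; all
search inner loops are table lookups.

### Exact corrected p-value

P(mHG ≤ s) under uniform placement of the B ones is computed by a dynamic
program on the (prefix length n, one-count b) lattice.  A monotone lattice
path describes one arrangement; the arrangement attains mHG ≤ s iff its
path touches a cell whose tail is ≤ s.  The DP carries reaching
probabilities (not path counts, avoiding overflow) forward in n, absorbing
the mass that enters rejection cells; the p-value is the total absorbed
mass.  Accumulating absorbed mass directly — rather than 1 minus the
surviving mass — keeps p-values of order 10⁻¹⁶ exact to relative rounding
(no cancellation).  Cells are compared against s with relative slack 10⁻⁹,
far below the 1/C(N,B) spacing of distinct achievable tails.  The test
suite certifies the DP against a rational-arithmetic enumeration of all
C(N,B) arrangements for every N ≤ 12 and every achievable score.

## Geometry and searches

One bisector per ('1','0') pair: the hyperplane through the midpoint with
unit normal along the connecting segment, oriented so the plane value is
positive where a pivot is strictly closer to the positive point
("satisfied").  Coincident opposite-label points yield no plane and are
skipped with a warning.

**Sampling search.**  Each non-degenerate d-tuple of bisectors meets in a
point; the cell representative steps ε off the intersection (re-solving
each bisector for its dependent coordinate and averaging), yielding the
cell's bottom-most pivot with respect to the perturbed axis.  Generic path:
solve X, perturb Y (axes permuted per bisector when an X coefficient
vanishes, e.g. axis-aligned synthetic grids).  ε defaults to 10⁻⁶ of the
bounding-box diagonal — far below bisector separations at desk scale, and
sampled rankings are verified invariant over two decades of ε.  Bead pivots
(the bins themselves) are always scored too.  Full enumeration is C(m, d)
for m = B(N−B) bisectors and becomes infeasible around N ≈ 100; above a
caller-set `max_pivots` the tuples are sub-sampled with a seeded RNG.

A structural limitation, inherited from the vertex construction: cells of
the arrangement unbounded below in the perturbed axis have no bottom-most
vertex and therefore no representative.  On small uniform instances the
global optimum falls in such a cell a few percent of the time, where the
sampling search returns a (still valid) upper bound strictly above the
brute-force optimum.  The octree search does not share this blind spot.

**Octree branch-and-bound.**  The root cube is the bounding box expanded by
10% of the diagonal per side (hotspot centres may lie outside the data's
convex hull).  Cubes are processed best-first by a lower bound computed at
the cube centre: with k = number of bisectors intersecting the cube that
are unsatisfied at the centre, the best any pivot in the cube could achieve
is obtained by promoting up to k additional positives immediately after
every prefix (including the empty one), never exceeding B.  The bound is
sound because a ranking inside the cube can differ from the centre's only
across planes crossing the cube, and each favourable flip moves one
positive earlier; Monte-Carlo soundness is asserted in the tests.  A cube
crossed by no bisector has constant ranking and is a leaf; because a plane
crossing a cube crosses some descendant at every depth, a `max_depth`
parameter (default 24) guarantees termination.  The queue orders by
(bound, depth, insertion); pruning drops cubes whose bound exceeds the
incumbent and provably never loses the optimum (verified against prune-free
traversal).  The pivot budget defaults to 10⁵ evaluations.

Both searches resolve score ties toward the smallest ball radius, so the
reported pivot is the tightest sphere realising the enrichment — without
this, the first-found optimal cell (which may extend far from the hotspot)
would set the reported location.

`exhaustive_oracle` (tests only) scores all sampled pivots, all beads and a
dense lattice over the expanded box, guarded to N ≤ 16.

## Controls

* **Bead control** — minimum over pivots restricted to the bins; each bead
  ranks itself first at distance zero with its own label counted.
* **1D control** — per chromosome (genomic distance between chromosomes is
  undefined), each bead ranks same-chromosome bins by |bin-index
  difference|, equidistant ties upstream-first; per-chromosome N and B feed
  the null.  Chromosomes with < 2 bins are skipped.
* **Simulation control** — n (default 100) uniform label shuffles, each
  searched with both heuristics; the statistic is the smaller of the two
  scores.  P_sim = (r+1)/(n+1) where r counts shuffles at least as extreme
  as the observed statistic — never exactly zero; r and n are retained so
  "P_sim < 1/n" can be reported when r = 0.  A `fast` switch restricts
  shuffles to the sampling heuristic (off by default).  Permutation draws
  are index-sorted before computing statistics so exact ties (e.g. the
  degenerate full-pool draw) are recognised in floating point.
* **FDR** — Benjamini–Hochberg via statsmodels, applied across the
  annotation sets tested in one dataset × method run.

Two set-level permutation tests: median (or mean) pairwise distance of an
assignment of positives against uniform re-assignments within a candidate
pool, and mean cross-pair distance between a fixed and a second bin set
against uniform redraws of the second set; both use the (r+1)/(n+1)
convention.

## Embedding (sNMDS)

Counts map to dissimilarities by a monotone-decreasing transform — default
d = (1+c)⁻¹ rescaled to [0, 1]; rank and power alternatives exposed.  Only
the ordering matters to nonmetric MDS, so "inverse" and "rank" are
rank-equivalent.  Zero-count pairs are *missing* (unobserved sparse
measurements, not maximal distances) and are excluded from the stress via
weights.

NMDS is weighted nonmetric SMACOF: isotonic regression of embedded
distances on dissimilarity values over observed pairs yields disparities
(rescaled to the distances each iteration), followed by a weighted Guttman
transform (V-matrix pseudo-inverse, computed once per call).
Initialisation is classical scaling with missing entries imputed at the
observed maximum plus a 10⁻⁹ seeded jitter — deterministic given the
config seed.  Stress-1 convergence tolerance 10⁻⁶, max 300 iterations;
non-convergence returns the configuration with a warning flag.  sklearn's
SMACOF cannot weight out missing pairs, hence the in-package implementation;
on fully observed matrices the two agree (cross-checked in tests).

**Discontinuity smoothing.**  Distances between genomically consecutive
bins (the discrete derivative) are computed within chromosomes (those with
< 3 bins are skipped) and Z-scored against the pooled distribution across
chromosomes (per-chromosome pooling is available); zero pooled variance
means no outliers.  Bins flanked by any derivative with Z above the
threshold (default 3.0) are flagged and replaced by linear interpolation
between the nearest valid genomic neighbours — runs jointly, terminal runs
extrapolated from the two nearest valid bins, an all-flagged chromosome
left unchanged with a warning.

The sNMDS loop alternates correction with NMDS refinement initialised at
the corrected configuration (re-embedding restores stress optimality after
coordinates were edited), up to 10 rounds.  The loop always *ends* with
correction-only passes: when the contact map itself encodes a jump (the
synthetic corruption scenario), refinement would re-create it, so the
returned configuration is guaranteed smooth at the threshold while the
reported stress comes from the last refinement.  Hitting the round cap is
reported via a warning.

Procrustes alignment (translation + rotation + scale, reflection optionally
forbidden by a determinant correction) returns the transformed embedding
and the disparity normalised by the reference's centred sum of squares.

## Annotation labelling

Bins are half-open 0-based fixed-size tiles.  An annotation labels every
bin it overlaps by ≥ 1 bp (midpoint assignment available); sets reaching
fewer than 4 positive bins are returned as typed rejections.  CGH probes
aggregate per bin as sum/√(probe count) — a Stouffer-style statistic
up-weighting well-covered bins; the plain mean is a switch since the
aggregation convention is genuinely ambiguous — bins with < 20 probes are
masked, and labels are 1 where the statistic exceeds μ + 2σ over kept bins
(one-sided high).  Differential labelling of two same-binning maps:
per chromosome, each intra-chromosomal matrix is Z-scored over its own
entries (zeros included; nonzero-only is a switch), entries beyond the
|i−j| ≤ 5 band are zeroed, the per-locus statistic is the Euclidean
distance between corresponding masked rows, and loci with |Z| > 1.96 over
the per-chromosome distance distribution are labelled.  Every Z step maps
zero variance to all-zero scores.

## Synthetic data

The generator emulates exactly the structure the method assumes: per
chromosome a Gaussian random walk (step 1.0 embedding unit), smoothed by a
5-bin moving average, offset into a territory and confined to a common
ball; Poisson contact counts with expectation k·d⁻ᵅ (α = 1 keeps
long-range ordinal signal; depth 10⁶ expected reads for ~200 bins — ~99%
of pairs observed); hotspot labels drawn uniformly inside a stated ball
(and optionally outside); discontinuities injected by teleporting
non-adjacent interior bins.  All generators are deterministic per seed.

What it does not emulate: polymer physics (loop extrusion, confinement
forces), mappability or coverage bias, replicate structure, or any real
organism's map.  Passing tests therefore demonstrate correctness of the
statistics and algorithms under the stated generative model, not biological
validity on real Hi-C.  One realistic artefact is emergent: bins inside a
spatial ball of a smooth polymer are largely consecutive in the genome, so
planted hotspots are often partly "explainable" by the 1D control — the
confounding that control exists to expose.

## Problem sizes and defaults

The validation suite runs at desk scale, chosen once: p-value exactness at
N ≤ 12 (exhaustive), heuristic/oracle comparisons at N ≤ 10 (2D) and
N ≤ 30 (3D, octree depth 4), bound soundness on 100 random cloud/cube
pairs × 10³ pivots, hotspot recovery on 200-bin genomes (12 positives, 20
seeds; observed grid budget 2000, shuffle budget 150 with 500 sampled
tuples — shuffles need significance, not localisation), null calibration
on 200 datasets of 30 bins (100 shuffles each), sNMDS round trips on
100-bin maps, and permutation-test calibration with 200 repeats × 500
permutations.  Library defaults remain the production values (grid budget
10⁵, full tuple enumeration unless capped, NMDS 300 iterations).

## Known limitations

* Both heuristics return upper bounds on the spatial optimum; neither
  guarantees recall of all significant hotspots.
* The sampling search cannot represent cells unbounded below (above).
* The exact mHG p-value corrects prefix multiplicity for one pivot; the
  multiplicity across cells has no exact correction — q-values and P_sim
  are the published mitigations.
* sNMDS configurations are latent coordinates; only distance ordinality is
  optimised, and mirror images are equally valid (hence Procrustes with
  optional reflection for comparisons).
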