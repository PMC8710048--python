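# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `leafangle3d`, in the order the pipeline runs.

## Imaging geometry and the camera model

World coordinates are right-handed with z up; the turntable axis is the
z axis and the reconstruction volume is a cube of side `volume_side`
(default 600 mm) with the soil plane at z = 0.  Cameras are ideal
pinholes.  A side view at turntable angle α is modeled by rotating the
world by −α about z and projecting through a camera at distance
`camera_distance` (default 3000 mm) from the axis at half volume
height, looking horizontally at the axis; the top view looks straight
down from `camera_distance` above the soil plane (default 3500 mm).
The 2D `axis_offset` displaces plant coordinates before the turntable
rotation, expressing the calibration fact that a pot need not sit
exactly on the rotation axis.  Calibration parameters are inputs — the
package does not estimate them.

Defaults (640×640 px, focal length 2400 px) place the 600 mm volume
within every frustum with roughly 0.9 mm of object space per pixel,
a deliberately scaled-down stand-in for megapixel greenhouse cameras
that keeps test runtimes short without changing any algorithm.

## Synthetic plants

`synthplant` generates single-culm, sorghum-like plants: a straight,
slightly leaning stem (lean ≤ 1.5°, height 450 mm, radius 9 mm) and
`n_leaves` leaves at strictly increasing insertion heights between
80 mm and 97% of stem height.  The youngest leaf inserts near the stem
apex, as in a real grass where the top of the culm is the whorl from
which the youngest leaf emerges; this also means the skeleton has no
bare apical stem segment, which the stem/leaf segmentation rule would
otherwise report as an extra "leaf".

Each leaf is a constant-thickness tube (8 mm) along a curve whose
initial tangent realizes the true (θ, φ) exactly; the optional droop
parameter bends only the distal 60% of the blade, so the proximal
region used for measurement stays straight and the recorded ground
truth remains well defined.  Polar angles default to Uniform(20°, 70°),
typical of sorghum insertion angles; azimuths follow alternate
(distichous) phyllotaxy with ±30° jitter; lengths are
Uniform(120, 200) mm.  The default droop is zero because the insertion
angle is a property of the proximal blade; tests that exercise droop
set it explicitly.

Silhouettes are rendered by sampling the tube centerlines at 2 mm
spacing, splatting each sample as a disk of its projected tube radius
(plus a 1 px anti-gap margin) and morphologically closing small holes.
This is not photorealistic and has no self-occlusion subtleties — a
silhouette is exactly the projected solid — which is the right fidelity
level for validating carving, since real segmentation quality is a
separate concern upstream of this package.

What the generator does **not** emulate: flat leaf blades (tubes have
no width/twist), tillers, overlapping plants, segmentation noise,
lighting artifacts.  Passing tests therefore demonstrate correctness of
the geometry pipeline, not robustness to segmentation errors in real
images; the QC stage (below) is the designed defense for those.

## Voxel carving and QC

Carving tests each voxel **center**: a voxel survives iff its center
projects to a foreground pixel in every view in which it projects
inside the image.  This is the standard fast choice; the error of
ignoring the voxel's 8 corners is bounded by one voxel diagonal.  A
view that is entirely background short-circuits to an empty grid (no
plant present).  The resulting set is the discrete visual hull: a
guaranteed superset of the true solid whenever the silhouettes cover
the exact projections, and monotonically non-increasing in the number
of views.  Occupancy is kept as a boolean array in memory and persisted
as a one-line JSON header plus packed bits; all algorithms are correct
at any resolution ≥ 8 (tests run at 48–128 for speed, the production
default is 512).

Reprojection splats every occupied voxel as a square block of pixels.
The block edge defaults to the voxel's projected size (at least 2 px),
so coarse test grids reproject without aliasing holes; at the 512³
working resolution a voxel covers about one pixel and the fixed 2×2
footprint is equivalent.

Concordance between an original silhouette and the hull's reprojection
is the Jaccard index |A∩B| / |A∪B| — symmetric, 1 iff identical, and
defined as 1 (with a warning) for two empty masks.  The quality gate
fails a reconstruction whose concordance falls below 0.8 in any view.
The Dice coefficient can be substituted by callers; the 0.8 threshold
here is calibrated for Jaccard.

## Skeletonization

Thinning is sequential simple-point deletion: a voxel may be removed
iff it is not a curve endpoint (≥ 2 foreground 26-neighbours are
required) and its deletion preserves local topology — exactly one
26-connected foreground component in the 26-neighbourhood and exactly
one 6-connected background component in the 18-neighbourhood touching a
face neighbour (the Bertrand–Malandain characterization).  Deletion
proceeds in six directional sub-iterations (up, down, the four lateral
faces) for symmetric erosion.  Within each sub-iteration, border
voxels are partitioned into the eight (x, y, z)-parity subfields:
voxels of one subfield are never 26-adjacent, so their deletion
decisions are mutually independent and erosion cannot cascade along a
thin limb — a failure mode that otherwise deletes entire even-width
columns.  Ties are broken in (z, y, x) lexicographic order, making the
result platform-stable and fully deterministic.  The simple-point test
is memoized on the 27-bit neighbourhood pattern.

Guarantees (tested): skeleton ⊆ input voxels; one skeleton component
per input component; no fully-occupied 3×3×3 neighbourhood remains;
one-voxel-wide curves are fixed points; limb tips erode by at most
about the limb radius.

**Pruning** removes terminal branches that are shorter than
`min_branch_len` voxels (default 10) or whose end-to-end /
along-path length ratio is below `min_branch_straightness` (default
0.5), iterating to a fixed point; junctions that drop to degree 2
dissolve on the next branch decomposition.  The longest root-to-tip
path is never pruned, and a pruning that would delete everything keeps
that path with a warning.  This deterministic rule replaces a trained
spurious-branch classifier used by some production systems; the
`engine`-style hook point is the `prune` function itself, which can be
swapped for a learned decision.

**Component connection** bridges disconnected skeleton fragments
(typically a leaf tip whose hull pinched off) by greedily joining each
minor component's nearest node to the nearest node of the growing main
component, inserting interpolated connector nodes flagged `synthetic`.

**Soil–stem junction.**  Candidate stem bases are endpoints whose
incident branch's principal direction lies within 30° of vertical.
Among candidates within the lowest height band (lowest candidate plus
15% of the plant's height extent), the most vertical branch wins, with
ties broken by lower height then (z, y, x) index — so a basal tiller
loses to the true stem even when its tip hangs lower.  Confidence is
the fraction of the basal branch locally within the verticality
tolerance (windowed over 5 nodes); below 0.5 the plant is flagged
`no-stem-junction`, one of the QC failure classes.

## Organ segmentation

Shortest (Euclidean-weighted) paths are traced from the stem base to
every other endpoint.  Nodes on ≥ 2 paths form the stem; nodes on
exactly one path form that endpoint's leaf; the leaf's junction node is
its first node adjacent to the stem, and junction height is its world z
in mm (resolution-independent).  On a skeleton that is a single simple
path the plant is stem-only (warned).  Nodes on no path — possible only
when hull artifacts create cycles — are attached to the organ of their
nearest assigned neighbour by breadth-first search, so the partition
property (disjoint cover of all nodes) always holds.  Leaves are
numbered by ascending junction height with a deterministic index
tie-break.

Interpretation note: "path" here means root-to-endpoint path, which
makes the entire stem below the topmost junction shared and hence
contiguous stem.  The apical segment above the last junction lies on
one path only and is therefore carried by the topmost leaf; with the
whorl-type generator geometry this segment is a few voxels and is
absorbed by pruning, but on real plants it is one reason uppermost-leaf
measurements are unreliable and analyses cap the usable leaf index
(default 7, flagged `above-cap`, still reported).

## Angle measurement

The stem frame is the PCA of the stem node coordinates: v1 is the
first principal axis oriented upward (v1_z ≥ 0; if exactly horizontal,
the sign rule falls through x then y), v2 the second axis with sign
fixed by v2·x ≥ 0 (then y).  An exactly collinear stem leaves v2
undefined; a fixed horizontal direction orthogonal to v1 is substituted
and the record flagged `stem-degenerate`.  Each leaf's direction is the
PCA axis of its first min(k, n) nodes ordered by along-path distance
from the junction (k = 20 voxels — at the 512³ working resolution about
23 mm, i.e. the ligule region; `n_voxels_used` records truncation),
sign-oriented away from the junction.

θ = arccos(clamp(v_leaf·v1, −1, 1)) in degrees.  φ is the signed angle
from v2 to p = v_leaf − (v_leaf·v1)v1 about v1, counter-clockwise
viewed from +v1, mapped to [0°, 360°); when the leaf is parallel to the
stem (|p| < 1e−9) φ is recorded as missing.  θ is measured against the
stem axis, not gravity, and drooping leaves can legitimately exceed
90°; the raw arccos value is reported unclipped.  The sign conventions
for v2 and the rotation sense are package choices (the geometry itself
does not prefer one); consequently φ is reproducible but its origin is
conventional, and comparisons across software should use φ differences
between leaves, which are convention-free.

Measured accuracy on straight-leaf synthetic plants at R = 128 (20
seeded plants, 3–6 leaves): leaf count recovered in ≥ 95% of plants,
median |θ error| ≈ 1°, dominated by the top whorl leaf (median ≈ 30°
there) whose proximal skeleton merges with the stem apex.  Accuracy
improves from R = 96 to R = 192 but degrades again by R = 256: the
fixed 20-voxel window then spans only ~47 mm and sits inside the
hull-fusion zone near the junction.  The window length k should scale
with resolution if finer grids are used; the default k = 20 is tuned to
the 512³ / megapixel operating point it mimics.

## Genetics

**Aggregation.**  Per plant, the median across timepoints within each
leaf, then the median across the requested leaves (missing cells are
skipped and counted).  Medians, not means, for robustness to single
bad reconstructions.

**Heritability.**  H² = σ²_G / (σ²_G + σ²_e/2), with variance
components from the REML fit of the one-way random-effects model
yᵢ = μ + tᵢ + eᵢ (genotype random; statsmodels `MixedLM`).  The
residual divisor is a fixed 2 — the estimator as used with phenotypes
that are medians of repeated measurements — and is **not** adjusted to
the realized replicate counts (2–8 in the motivating design); with
unequal replication it is therefore an approximation, and H² for a
trait with σ²_G = 1, σ²_e = 2 is 0.5 by construction.  If the REML
optimizer fails to converge the one-way ANOVA (method-of-moments)
estimator is used, with the unbalanced-design effective replicate
number n₀; the `VarianceComponents.method` field records which path
ran.  For balanced data the two coincide.

**BLUP screen.**  The BLUP of genotype i is its centered mean shrunk by
σ²_G / (σ²_G + σ²_e/nᵢ) toward the REML grand mean — the exact
mixed-model BLUP for this model (verified against a brute-force REML
oracle in the tests).  Genotypes with |BLUP − mean| > 5 SD of the BLUP
distribution are removed in a single pass, without re-iteration.  The
screen uses the shrunken effects, not raw means.

**Marker QC.**  MAF and heterozygosity are computed on non-missing
calls; a marker is kept iff MAF ≥ 0.05 and het ≤ 0.05 (all-missing
markers dropped).  The filter is idempotent and logs a per-marker
reason.

**Thresholds.**  `bonferroni_threshold(α, n) = α/n`.  The effective
number of independent tests is an input, not estimated: 0.05/78,251 =
6.39e−7 and 0.05/232,113 = 2.15e−7 reproduce the working thresholds of
the motivating analysis to three significant figures.

**Association engine.**  Single-marker additive linear model with
optional covariates and genotype-matrix principal components, computed
by residualizing phenotype and (mean-imputed) dosages against the
covariate span and converting the squared partial correlation to an F
test.  Constant markers score p = 1.  This engine is deliberately
simple plumbing for simulations and resampling studies — it has no
kinship correction and is not a substitute for a dedicated mixed-model
GWAS; real analyses should plug their engine into `resample_rmip`'s
`engine` argument.

**RMIP.**  `n_runs` (default 100) random genotype subsets of size
round(0.87·n) — the published description gives both "87%" and a
subset count whose ratio is 0.877; the explicit `subset_size` parameter
lets either be chosen — are scored by the engine; a marker counts a
hit when p < 0.05/n_markers, and markers with ≥ `min_hits` (default
10) hits are the stable set.  With defaults the planted-QTL simulation
(200 genotypes, 500 markers, 15% variance QTL, H² ≈ 0.6) recovers the
planted marker in ≥ 90% of runs with no stable false positives.
Engine failures skip the run (warned) rather than aborting the scan.

## Numerical and determinism notes

* All stochastic functions take an explicit integer seed
  (`numpy.random.default_rng`); pipeline geometry is fully
  deterministic.
* PCA sign ambiguities, skeleton tie-breaks and leaf-number ties are
  all resolved by fixed lexicographic rules so repeated runs are
  byte-identical across platforms.
* arccos arguments are clamped to [−1, 1]; azimuth projections below
  1e−9 are treated as undefined; REML variance estimates are floored at
  0.
* Angles are reported in degrees, rounded to 2 decimals in CSV output
  only (in-memory records keep full precision).

## Problem sizes used in validation

Tests and the acceptance script run the geometry pipeline at 64³–128³
on 600 mm volumes with 640×640 px views (the production geometry is
512³ with megapixel images — identical code paths, larger constants),
20-plant recovery studies, 200-replicate heritability simulations and
10–20 RMIP populations of 200 genotypes × 500 markers.  These sizes
were chosen so the whole suite runs in a few minutes on one CPU while
keeping every Monte-Carlo assertion's sampling error well inside its
tolerance.

## Known limitations

* Leaves are modeled as midrib tubes; blade width, twist and curl are
  not represented, so silhouette-level phenomena they cause in real
  images (self-occlusion, merged blades) are exercised only indirectly
  via QC failure paths.
* Visual hulls cannot recover concavities; two leaves crossing in many
  views can fuse, which surfaces as a missed leaf or a displaced
  junction.  The QC concordance gate catches gross failures but not
  all fusions.
* The spurious-branch rule (length + straightness) is a transparent
  stand-in for a learned classifier; on real data its thresholds may
  need retuning, and recovered leaf counts can differ from systems
  using trained pruning.
* No tiller handling: a large basal tiller violates the single-culm
  assumption and typically fails the stem-base confidence check (by
  design).
* The built-in association engine ignores kinship/population structure
  beyond optional PCs.
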