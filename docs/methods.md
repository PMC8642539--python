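# Methods

This note records the models, numerical choices and known limitations of
`glioquant`. Defaults quoted here are the package defaults; all are
overridable through the API or YAML configs.

## Synthetic organoid scenes (`synth3d`)

The organoid is modeled as a sphere of radius `R` (default scenes use
`R` = 90–150 µm) filled with nuclei at a density of 1.5×10⁻³ nuclei/µm³
(about one nucleus per 8.7 µm cube — the packing of dense neural tissue),
with 60% of nuclei concentrated in the outer 20% of the radius to mimic
the dense DAPI rim of real organoids. A sphere was chosen over irregular
shapes because it admits exact analytic oracles (radius, volume, area,
depth) for every downstream measurement; real organoids are irregular, so
passing tests demonstrate correctness of the measurement chain, not
robustness to arbitrary morphology.

Tumor cells are placed at radius `R − d` along uniform random directions,
with depth `d` drawn from an exponential, gamma or fixed law. Negative
depths put cells outside the shell; depths exceeding `R` are clipped at
the centre and the stored truth updated accordingly. A scalar `shrinkage`
factor (default 1.0) uniformly scales the scene, standing in for the
uniform tissue shrinkage of solvent-based clearing whose magnitude is not
quantified; no other optical effect of clearing is modeled.

Rendering follows the real acquisition: 85 optical sections at a 3 µm
z-step (total 255 µm), 1.2 µm xy pixels (10× objective scale; the
acquisition protocol does not state the pixel pitch), intensities on an
arbitrary 8-bit-like scale. Each cell becomes an isotropic Gaussian blob
(σ = 2 µm). The first section sits one z-step below the organoid bottom,
reproducing the situation that motivates blank-slice padding. Optional
shot noise is scaled Poisson; with the scale at 0 the render is
noise-free and bit-deterministic. Cells outside the field of view are
clipped with a warning and counted, never silently dropped.

## Surface reconstruction (`geometry`)

"Surface detail 25 µm" is implemented as Gaussian smoothing with
FWHM = 25 µm (σ = 25/2.355 µm), per axis in voxel units. The commercial
operator is proprietary; FWHM-matched Gaussian smoothing is the standard
open equivalent.

**Threshold.** The default rule places the iso-surface at the half height
of the blurred boundary: an initial Otsu split separates foreground, and
the threshold is the midpoint between the background median and the 95th
percentile of the foreground. On smooth-edged objects plain Otsu lands
well below the edge midpoint and dilates the object by several µm (we
measured +6 µm on a 100 µm sphere, i.e. ~+19% volume); the half-height
rule recovers the radius to ~1 µm. Otsu and fixed numeric thresholds
remain available.

**Extraction.** The thresholded mask is hole-filled (organoid interiors
are darker than the rim at high thresholds), reduced to its largest
connected component (stacks contain one organoid), lightly smoothed
(σ = 1.5 voxels) and triangulated with marching cubes in physical µm.
Pass-1 surfaces are open wherever the organoid crosses the stack top.

**Pass 2 (outside-mask re-surfacing).** A channel equal to `fill_value`
(default 150) outside the pass-1 mask and 0 inside is re-surfaced at level
`fill_value/2`, making the geometry independent of the fill value. If the
mask touches the top image plane, the interior is first extruded straight
upward by `extend_um` (default 150 µm) and capped above; the closure is
thereby displaced well beyond the acquired data, so distances of cells
near the stack top are measured to the organoid's lateral wall rather
than to an artificial cap. The pass-2 mesh is watertight. The extrusion
assumes the organoid continues roughly cylindrically above the imaged
volume; distances to surface regions above the stack top are
approximations by construction, as they are in any truncated acquisition.

**Spots.** Scale-matched LoG detection at σ = diameter/(2√3) per axis
(10 µm spot size ⇒ σ ≈ 2.9 µm), response maxima above a relative
threshold (default 10% of the peak response), refined to sub-voxel
precision by a local intensity centroid. Two cells closer than the spot
size may merge — the outcome is deterministic for a fixed input.

**Signed distance.** Unsigned distance is the exact minimum over all
triangles of the closest-point distance (vectorized vertex/edge/face
classification). The default "pruned" path bounds the answer by the
nearest-vertex distance and evaluates only triangles that could beat it;
it is exactly equal to the brute-force path (asserted to 10⁻⁶ µm in
tests). The sign comes from the generalized winding number (sum of
triangle solid angles), robust to the edge-degeneracies of ray-parity
tests; inside is positive by default so that deeper invasion reads as a
larger distance. The convention is flippable (`inside_positive=False`)
because the original workflow's sign is not documented. Distances to open
(pass-1) meshes are refused with a pointer to pass 2.

Volume is the signed-tetrahedron sum and area the triangle-area sum
(delegated to `trimesh`); volume requires watertightness, area does not.

## Invasion statistics (`invasion_stats`)

Quantiles are type-7 (linear interpolation between order statistics),
the numpy default; the source workflow does not state its quantile
method, so this is documented and switchable. The invasion threshold is
computed on min-normalized distances (the published figures normalize
each organoid's minimum to 0); a flag allows raw distances. "Exceeds the
threshold" is strict (`>`). The two-sample test defaults to the
pooled-variance Student t (Welch available); ANOVA + Tukey HSD uses the
studentized-range distribution with N − k error degrees of freedom via
`statsmodels`, cross-checked in tests against `scipy.stats.tukey_hsd` to
10⁻⁴ and against the q = √2·|t| identity at k = 2 to 10⁻⁶. KDE profiles
use Gaussian kernels with Scott's rule per organoid (or a fixed
bandwidth), each curve normalized to unit area on a shared grid so
profiles can be stacked. Degenerate samples (all values equal) fall back
to a single Gaussian of the requested bandwidth.

The unit-of-analysis question (cells vs organoids) is left to the caller:
tests in the pipelines run on per-organoid summaries (counts), and the
per-cell tables are exported so either aggregation can be reproduced.

## Synthetic single-cell data (`synth_sc`)

Counts are gamma-Poisson (negative binomial, dispersion 10) over a
~2,000-gene human panel — the 43 S-phase and 54 G2/M signature genes, the
13 mitochondrial protein-coding genes, optional per-cluster marker genes,
and background — plus 400 mouse background genes for barnyard captures.
Library sizes are log-normal (median 2,500 UMIs on the panel, σ = 0.35);
on a 2,000-gene panel this matches the per-gene depth of a real ~10⁴-UMI
droplet capture over a whole transcriptome. The default design captures
10,000 cells per arm, 76% human, 5% ambient cross-species UMIs per
library. Phase mixtures default to 55/25/20% (G1/S/G2M) in the control
arm and 70/17/13% in the treated arm — a planted +15-point G1 shift.
S (G2/M) cells express their program genes at `fold_effect` (default 4)
times the base rate. Small planted QC-violator fractions (4% very high
mito, 2% very shallow libraries) give the QC filter known targets. All
truth lives in `obs`; the counts alone never reveal it. The generators do
not model doublets, read-level noise, batch effects, or ambient-RNA
profiles beyond the uniform cross-species fraction — so passing recovery
tests validates the estimators under clean NB sampling, not robustness to
those artifacts.

## Single-cell quantification (`sc_quant`)

Scoring uses counts-per-10k + log1p normalization (the upstream published
pipeline used a variance-stabilizing transform for clustering; module
scoring in the cited technique operates on log-normalized data, so that
is what is implemented). Module scores bin genes into 24 equal-frequency
bins of population-average expression and draw 100 control genes per
program gene from its bin; the score is the program mean minus the
average of the per-gene control means. Two deliberate refinements for
small panels: control means are averaged per program gene (keeping the
program's bin weighting) rather than pooled into one flat union, and
program genes are excluded from their own control pools (on a 2,000-gene
panel they can dominate a bin and cancel their own signal). Scores are
deterministic given the seed.

Phase binning: both scores ≤ 0 → G1 ("cells with lower G2M and S scores"),
otherwise the larger score wins, exact ties going to S. Phase-assignment
noise mixes categories and therefore attenuates planted proportion
shifts: a +15-point planted G1 shift is typically recovered as +12.5 to
+14.5 points at realistic depths — the recovery tests account for this.

Species assignment: percent of UMIs on human-tagged features, `human` at
≥ 90%, `mouse` at ≥ 90% mouse, otherwise `ambiguous` and excluded. The
original analysis separated species "in tandem with" graph clustering
without stating a decision rule; the threshold (and an optional 1-D
two-means refinement) is a documented stand-in, not a claim about the
original rule. QC retention is `200 ≤ detected genes ≤ 6000` and
`pct_mito ≤ 10` — the published discard rules are strict inequalities, so
boundary cells are kept.

Volcano classification takes any (gene, log2FC, Bonferroni-p) table; the
thresholds default to log2FC 0.23 and p < 1×10⁻⁸, reading the published
"10e-9" literally as 1.0×10⁻⁸ (configurable to 10⁻⁹, which the caption
may have intended). The hurdle-model DE engine used upstream is out of
scope; a transparent rank-sum + Bonferroni generator is provided for
synthetic tests. Graph clustering is likewise out of scope — cluster
labels come from planted truth or any external labeling.

## Problem sizes and determinism

Default validation sizes: spheres of R = 100 and 150 µm (85 and 110
sections) for geometry recovery; 1,000 random points for the distance
oracle; 2,000 barcodes for species recovery, 1,500 cells/arm for phase
recovery, 5,000 cells/arm for shift recovery; 100 replicates of
8 organoids/arm × 200 cells for the invasion power property. These sizes
make the full validation run in a few minutes while keeping Monte-Carlo
margins comfortable. Every stochastic component takes an explicit seed
and is bit-reproducible; pipeline runs write a JSON manifest with all
parameters and versions.

## Known limitations

* Spherical truth only exercises genus-0, convex-ish geometry; strongly
  concave organoids would stress the largest-component rule and the
  extrusion heuristic.
* Surface placement accuracy degrades when the object radius approaches
  the 25 µm smoothing scale (volume errors >10% below R ≈ 70 µm) and when
  nuclear density falls much below ~1×10⁻³/µm³ (lumpy masks).
* The distance "pruned" path is exact but O(candidates) per point; meshes
  beyond ~10⁶ triangles would want a BVH.
* The single-cell generators are deliberately minimal; estimator behavior
  under ambient-profile contamination, doublets or batch structure is
  untested.
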