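# Methods

`blastomorph` quantifies the link between blastomere geometry and the
subcellular localisation of the Hippo effector YAP in preimplantation
embryos (2- to 64-cell stage). It consists of four analysis stages —
surface-domain decomposition, shape/position descriptors, compartment
intensity ratios, and unsupervised statistics — plus a synthetic embryo
generator that provides ground-truthed inputs for all of them. This note
records the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## Surface domains

Each segmented blastomere's limiting membrane is decomposed into three
domains: **exposed** (apical membrane facing the embryo exterior),
**contact** (basolateral membrane apposed to neighbouring cells) and
**junctional** (the narrow band at their boundary, corresponding to the
apical junction).

Surfaces are extracted per cell by marching cubes on the binary mask at the
physical voxel spacing, after a light Gaussian pre-smoothing of the mask
(`smoothing_um`, default 0.8 µm). The smoothing removes the staircase bias
of iso-surfacing binary data — raw marching cubes overestimates a digital
sphere's area by ~8%, the smoothed mesh is within ~1% — while leaving flat
cell–cell interfaces unchanged (they are level sets of a half-space).
Sharp-edged synthetic test solids should be meshed with `smoothing_um=0`.

Classification is a proximity rule with two length parameters
(`DomainParams`):

* `contact_distance` δ (default 1.0 µm): a triangle is contact when its
  centroid lies within δ of the nearest voxel of a different cell
  (distance transform of the other-cell mask, sampled at triangle
  centroids). δ should be at least half the coarsest voxel spacing.
* `junction_width` w (default 1.0 µm): triangles of either class within w
  of a centroid of the opposite class are relabelled junctional.

Both defaults correspond to one z-step at the 1 µm axial sampling typical
of whole-embryo confocal stacks; the true band width of the apical junction
is not observable at this resolution, so both are exposed configuration
knobs rather than constants. Because every triangle carries exactly one
tag, exposed + junctional + contact area equals the total mesh area
exactly, and the three proportions sum to 1 to floating-point precision.
All three proportions use the total surface area as denominator. The A/J
ratio is exposed area / junctional area (dimensionless; larger for a domed,
protruding apical surface) and is reported absent when the band is empty
(isolated cells, or w = 0).

A brute-force **voxel-face oracle** (`voxel_face_domains`) implements the
same exposed/contact decision by 6-connectivity face counting directly on
the label volume, scanning up to δ along each face normal for a different
cell. It shares no code with the mesh path and is used to ground-truth it;
note the voxel-face area of a smooth surface carries staircase bias
(up to ×1.5), so the two routes are compared on area *proportions*.

## Shape and position descriptors

Per cell: volume (voxel count × voxel volume); sphericity
Ψ = π^(1/3)·(6V)^(2/3)/A with A the mesh area; and an equivalent
solid-uniform ellipsoid fitted from the second central moments of the voxel
centres (a per-axis s²/12 term accounts for the voxels' own extent). With
semi-axes a ≥ b ≥ c = √(5λ) the package defines **prolateness** = (a−b)/a
(rugby-ball elongation) and **oblateness** = (b−c)/b (flying-saucer
flattening). These normalised definitions are this package's own — the
commercial toolchains that report "oblate/prolate" do not document a public
formula — and recover 0.5 on digital ellipsoids with 2:1 axis ratios. A
rank-deficient moment matrix flags the record `degenerate_moments` instead
of raising. Cells under 8 voxels are skipped with a warning.

## Intensity ratios

* **N/C YAP**: mean YAP intensity over nucleus voxels ÷ mean over
  cytoplasm voxels (cell minus nucleus, membrane shells included — no
  erosion rule is imposed). Means rather than sums keep the ratio
  comparable across cell sizes; any positive rescaling of the channel
  cancels. No background subtraction by default (synthetic volumes are
  background-free); a constant offset argument exists for real data.
* **A/B pERM**: mean intensity over the apical shell (cell voxels within
  `shell_thickness` t of the exposed surface, default 1 µm) ÷ mean over
  the basolateral shell (within t of contact surface, mirroring the
  δ-proximity rule at voxel resolution).

Missing compartments (empty nucleus, fully internal cell with no apical
shell) yield NaN with a `qc_flags` note, never an exception: they are
per-cell QC failures. Dividing cells are excluded at record-assembly time
from the annotation table, and the number removed is logged.

## Statistics

* **High/low YAP threshold**: 1-D k-means (k = 2, 10 restarts, fixed seed,
  ties broken toward the lower centroid) on standardised N/C values; the
  cut is reported on the raw scale as the midpoint between the maximum of
  the low and the minimum of the high cluster. Standardising for the fit
  and back-reporting on the raw scale makes the split equivariant under
  affine rescaling. A cell is "high" iff its value strictly exceeds the
  threshold.
* **Hierarchical clustering**: z-scored variables (default
  {N/C YAP, prop. exposed}), Euclidean distance, Ward linkage. The cluster
  count comes from a dynamic-tree-cut-style rule: among the flat cuts
  k ∈ [2, 6] whose every cluster keeps ≥ max(3, 6% n) members, pick the k
  whose cut falls in the widest relative merge-height gap; if no gap ratio
  reaches 1.4 the data are treated as unimodal and the model falls back to
  k = 3 (the canonical inside-like / outside-like / undefined split) with
  a warning. Clusters are named from raw-scale centroid ordering: lowest
  exposure *and* lowest YAP → inside-like; highest YAP → outside-like;
  highest exposure → undefined; any inconsistency (e.g. one cluster
  extreme in both variables) leaves names unset with a warning rather than
  guessing.
* **Correlations**: pairwise Spearman ρ with tie-corrected p over the
  descriptor panel, optionally restricted to stage subsets; constant
  columns report NaN.
* **Group tests**: per-group Shapiro–Wilk at α = 0.05 gates one-way ANOVA
  + Tukey HSD (all groups normal) versus Kruskal–Wallis + Dunn's test.
  Dunn's post-hoc (rank z statistics with tie correction) reports raw and
  Holm-adjusted p — the adjustment choice is this package's, made because
  unadjusted pairwise rank tests inflate the family-wise error. Fisher's
  exact test covers 2×2 count tables (e.g. high/low YAP by stage). Groups
  under 3 observations skip the omnibus test with a warning.
* **Confinement comparison**: per-variable pooled medians and gated shift
  tests between a control and a confined cohort, plus a joint Ward
  clustering of the pooled arms with per-cluster composition percentages.
  Cohort medians pool the blastomeres of all replicate embryos, the same
  statistic a marginal-density comparison of the two arms uses.

## Synthetic embryo generator

No public dataset of segmented blastomeres with per-cell YAP quantification
exists, so the generator is a first-class, tested component that emulates
the imaging data end to end. One integer seed drives a single generator
stream; outputs are bit-reproducible from the config.

**Geometry.** Seed points are packed inside the embryo envelope by iterated
pairwise repulsion (deterministic, 80 iterations). Each cell is the
intersection of the envelope interior, the Voronoi region of its seed and a
ball of radius r_g around the seed. r_g interpolates with compaction γ from
"balls just touching" (γ = 0: loosely apposed blastomeres, median exposed
proportion ≈ 0.87 at the 8-cell stage) to envelope-filling (γ = 1: a packed
partition, ≈ 0.42); the quadratic ramp r_g = r_touch + γ²(r_fill − r_touch)
keeps the low-γ end graded. An earlier design that shrank inter-cell gaps
on Voronoi faces was rejected: at intermediate γ every internal wall opens
a gap wider than δ, so every cell reads 100% exposed — a degenerate, not a
graded, compaction phenotype. Per-stage default γ
(`STAGE_COMPACTION` = 0.25/0.35/0.6/0.85/1.0/1.0 for 2→64 cells) encodes
compaction at the 8-cell stage. Blastomere volumes are equal in
expectation: no quantitative distribution of per-stage volume asymmetry is
available to emulate, so seeds carry equal weights. Nuclei are spheres at
each cell's inscribed-distance maximum, radius
`nucleus_radius_fraction` (default 0.5) of the equivalent cell radius,
capped so they lie strictly inside the cell. Embryo volume is stage
independent (cleavage conserves volume), set by `reference_radius`
(default 25 µm).

**Envelopes.**

* `sphere` — free embryo of radius `reference_radius`.
* `cylinder` — hydrogel channel, nominal radius 12.5 µm (a 25 µm bore).
  A rigid, volume-preserving channel of that radius *cannot* reproduce the
  observed drop in exposed proportion at the 8-cell stage: the sausage's
  envelope area exceeds the sphere's (isoperimetry), so a space-filling
  partition necessarily raises the aggregate exposed fraction
  (single-file plugs measure ≈ 0.57 vs ≈ 0.42 for spherical controls).
  Soft (~4 kPa) gels, however, are stretched during embryo insertion, so
  the generator models wall compliance: effective radius
  max(nominal, `channel_dilation` × cell radius), `channel_dilation`
  default 1.4, with volume-preserving length. Cells then overlap deeply
  along the axis — a roll of mutually flattened cells — which is what
  embeds them (median exposed ≈ 0.35, below controls for every seed
  tested). Confinement pressure also forces γ ≥ 0.9 in the channel.
* `slab` — planar confinement under a hydrogel sheet: a single cell layer
  of half-thickness 0.8 × cell radius (override via `envelope_radius`),
  lateral disk radius volume-preserving. Pooled median exposure matches
  spherical controls within a few percent, reproducing the null planar
  contrast.

**Intensities.** Cytoplasm 100 arbitrary units; nucleus
100 × coupling(m·p) where p is the cell's true exposed proportion (computed
by the voxel-face oracle at δ = 1 µm, matching the classifier default), the
coupling is affine r(p) = base + slope·p (defaults 1 + p, non-decreasing
slope enforced) and m is the stage maturity. With
`coupling_maturity="developmental"` (m = 0.2/0.25/0.5/1/1/1 for 2→64
cells) position sensing emerges at compaction: early blastomeres show
intermediate N/C YAP despite large exposure, which is what creates the
"undefined" cluster archetype; the default (m ≡ 1) keeps the coupling
contract pure for recovery tests. The pERM channel paints membrane shells
(1 µm): basolateral 100, apical 100·(1 + 3·`perm_polarity`), so the A/B
ratio is 1 + 3·polarity; polarity 0 emulates pharmacological loss of
apical pERM. `noise_sd` sets both a per-voxel multiplicative log-normal
noise and an equal-σ per-cell jitter of the painted nuclear level. The
per-cell term matters: voxel noise alone averages out over thousands of
compartment voxels (σ_mean ≈ σ/√N), which would make every
exposure–YAP correlation trivially ≈ 1; the per-cell term represents
biological variability around the coupling. Defaults: `noise_sd` 0
(contract tests); cohort analyses in this package use 0.1 as the
"study-like" regime and {slope 2, noise 0.05} as the strong-coupling,
low-noise regime.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: optical blur and anisotropic PSFs, segmentation
errors, cell division and volume asymmetry, cavity (blastocoel) formation,
zona pellucida, membrane ruffling, and any mechanics of hydrogel
deformation or compaction dynamics (confinement responses are encoded as
the geometric models above, not simulated). Real-data conclusions rest on
the real segmentation; the synthetic cohort establishes that the pipeline
measures what it claims to measure on known geometry.

## Numerical choices and degenerate inputs

* Coordinates: voxel indices are 0-based (z, y, x); physical position =
  index × spacing (voxel centres); all thresholds in µm; areas µm²,
  volumes µm³.
* Label volumes int16; intensity volumes float32 in memory, rounded to
  uint16 on disk (TIFF pages = z-slices, increasing; NRRD raw
  little-endian, fast-to-slow sizes; every volume carries a sidecar JSON
  naming the axis order and spacing).
* Ward linkage on duplicated rows assigns duplicates identically (they
  merge at height 0).
* `f_oneway` on identical groups rounds to a tiny negative F; the package
  clamps to 0 and recomputes p.
* Infeasible packings (cell radius under 2 × the coarsest spacing, or any
  generated cell under 8 voxels) raise `PackingError` naming the
  constraint.
* Problem sizes used by the test-suite and acceptance script — 8-cell
  embryos on ~55³ voxel grids at 1 µm, cohorts of 3 replicates × stages
  {16, 32, 64} and 10 replicates per confinement arm — were chosen as the
  smallest sizes at which packing variability averages out; each analysis
  completes in seconds on one core.

## Known limitations

The proximity parameters δ and w are conventions, not measurements; domain
areas shift smoothly with both (contact monotone in δ, junctional in w).
The oblateness/prolateness definitions are package-specific, so absolute
values are not comparable to other toolchains (rank orders are). The
generator's confinement models encode the observed geometric responses
rather than deriving them mechanically; they should not be used to predict
responses to new confinement geometries. Spearman values measured on
synthetic cohorts depend on the chosen noise regime and are qualitative
analogues of, not estimates of, any real-data coefficient.
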