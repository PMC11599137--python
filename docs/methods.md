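# Methods

This note documents the models, conventions and numerical choices behind
`gscmorph`, and what the synthetic benchmarks do and do not establish.

## Coordinate and unit conventions

All images are 0-based `(row, col)` arrays with pixel centers on the
integer grid; a pixel belongs to a continuous shape iff its center does.
Physical quantities are reported in µm (lengths) and µm² (areas) using a
per-image `pixel_size_um`; when a TIFF carries no pixel-size metadata,
1.0 µm/px is assumed and a warning is logged. Skeleton operations use
8-connectivity throughout.

## Single-cell morphometrics

**Crops.** Each labelled cell is re-centered in its own square array whose
side is the largest bounding-box side over all kept cells (area filter
default 50 px to suppress segmentation fragments). The bounding box is
centered in the square; for the near-symmetric cells this pipeline targets,
the centroid then sits at the array center to within a pixel. Cells
touching the image border, and labels split into several connected
components, are kept but flagged and excluded from morphometrics by
default — segmentation output does not say how such cells were truncated.

**Shape descriptors.** Area, perimeter and the moment ellipse come from
`skimage.measure.regionprops`: axis lengths are `4·sqrt(eigenvalue)` of the
central second-moment matrix, and the perimeter is the weighted
boundary-step estimator (√2 weight for diagonal steps). Eccentricity is
computed from the axes, `e = sqrt(1 − (minor/major)²)`, so the
eccentricity–axis identity holds to machine precision; 0 means a circle,
values toward 1 mean line-like elongation. Degenerate 1-D masks cap
eccentricity at 1 − 1e-12 with an axis-ratio floor of 1e-12; masks under
5 px are rejected (their moments are noise).

**Soma.** The soma center is the arg-max of the Euclidean distance
transform (ties resolved toward the smallest row, then column — this is a
ridge for elongated cells, so "the" center is defined only up to that
ridge), and the soma mask is the connected component containing the center
after morphological opening with a disk of half the inscribed radius.
Masks thinner than 3 px everywhere fall back to the whole mask, flagged.
The distance-transform maximum, not the centroid, anchors the Sholl
circles because the centroid can fall outside concave cells.

**Protrusions.** The mask is thinned to a topology-preserving skeleton and
cut at the soma boundary dilated by 1 px; each connected piece attached to
the soma is one primary protrusion, and each skeleton tip is one
protrusion, so one bifurcation adds one protrusion and the branching index
`n_total / n_primary` is ≥ 1 whenever defined. "Tips" rather than "branch
segments" is an interpretation (the alternative is a config choice away in
the skeleton graph); it keeps the branching index consistent with a ratio
that exceeds 1 exactly for branched cells. Spurs shorter than `prune_um`
(default 1.0 µm) are removed iteratively, and components left with no soma
attachment or no tip are dropped as thinning debris.

Tip length is geodesic along the skeleton from the soma boundary to the
tip — a traced-process measurement, not a Euclidean offset — with three
geometric corrections applied a priori:

* path length is measured on ~4-px chords through the path pixels, because
  summing unit/√2 steps overestimates a digitized curve by up to ~8% at
  intermediate angles;
* the root is projected back to the soma boundary (the attachment pixel
  sits ~2 px outside it);
* the tip is extended by marching along its outgoing direction to the mask
  boundary and subtracting the local half-width (the EDT at the tip),
  which recovers the end retraction of thinning.

On phantom panels these corrections leave a residual per-tip error of
≈ 0.0 ± 0.8 px; that scatter is inherent to measuring a digitized 3–4-px
wide stroke and does not shrink with protrusion length.

**Sholl profiles.** For radii starting one step (default 5 µm) beyond the
soma inscribed radius, the profile counts connected components of skeleton
pixels meeting the circle. Membership combines a 1-px distance band with
edges whose endpoints straddle the circle (pure banding misses radial
crossings, since adjacent skeleton pixels can differ by √2 in radius), and
each tip is continued along its measured extension so circles between the
skeleton tip and the true process end still register.

## Morphoclass assignment and dynamics

The four morphoclasses are assigned by a first-match rule cascade on
quantitative features: (1) nonpolar — no primary protrusion; (2) elongated
— eccentricity ≥ 0.85, or a protrusion at least 2 soma equivalent
diameters long; (3) circular multipolar — ≥ 3 primary protrusions on a
round body smaller than 1000 µm²; (4) flat polar otherwise. The class
definitions in the literature are qualitative; these thresholds are
explicit config (`ClassifierConfig`) with the stated defaults, and the
classifier is validated by agreement with generator intent on synthetic
panels, not against manual scores.

Track tables are tidy CSVs (`cell_id, parent_id, frame, class, x_px, y_px,
mitosis`); a mitosis flag marks a mother's final row, and her daughters
reference her via `parent_id`. Interphase transition matrices count
frame-to-frame class steps excluding the step into a mitosis frame; any
frame-to-frame class change counts as "acquiring a new morphology" (the
alternative — sustained changes only — is not well defined without a
dwell-time threshold). Mitotic inheritance reads the mother's class at the
mitosis frame and each daughter's at her first frame. All proportion rows
sum to 1 within 1e-12 or are flagged empty. MST is the Euclidean nucleus
displacement in the single time step preceding mitosis; TTC density is
connections per 100 µm of perimeter (connection identification is manual
and supplied as counts); the invasion index is total neurosphere area over
core area, ≥ 1 and increasing with invasion, with a flag for the
reciprocal convention that also circulates.

## Gene prioritization

Enrichment of a gene family among k selected genes is the upper-tail
hypergeometric probability P(X ≥ x), X ~ Hypergeom(N, n, k) — identical to
the one-sided Fisher exact test for this design. With N = 19,396
protein-coding genes, n = 3 adducins, k = 30 selected, x = 3 hits, this
gives P = 3.34 × 10⁻⁹.

Basal-expression gating fits a two-component Gaussian mixture to per-gene
mean log2(TPM+1) by EM (seeded k-means++ initialization, best of 10
restarts by likelihood, `reg_covar` 1e-9); a gene is "highly expressed"
when its posterior for the higher-mean component exceeds 0.5. The 0.5
threshold is the natural Bayes rule; a manual expression cutoff is
available for users who prefer a visual threshold. All-equal inputs raise:
no gate is identifiable.

Dependency scaling is per cell line: `s(x) = (x − m_non)/(m_non − m_ess)`,
mapping the non-essential anchor median to 0 and the essential anchor
median to −1 (the scale on which −1 means "as depleted as core-fitness
genes"). The 0 anchor is the conventional choice; only the −1 anchor is
forced by the definition. Candidates are ranked by minimum scaled
depletion across lines (most negative first) after removing core-fitness
genes; `median(scaled) − min(scaled)` operationalizes context specificity
(large when a few lines drive the dependency), and the arg-min line
identifies the most dependent model. The core-fitness catalogue and anchor
sets are inputs — the package does not bundle a DepMap release.

The DE-signature consistency test standardizes each gene to zero mean and
unit variance across lines, takes the upper triangle of the all-pairs
Pearson correlation matrix as the null, and compares the focal-gene-vs-set
correlations to it with a two-sample Welch t-test, one call per signature
direction.

## The synthetic generators

`synth.cells` renders a cell as a jittered soma ellipse plus protrusion
centerlines stroked with a disk — a Minkowski sum, so the planted
centerline length is exactly the rendered stroke's medial length, and the
planted tip/branch counts are exact graph truth. Jitter applies to soma
polygon vertices only, never to centerlines. Three validity rules keep the
ground-truth record truthful at raster resolution: at most one branch per
protrusion, rejection sampling of geometries whose strokes would merge
(including a branch tip that fails to clear its parent stroke), and
anchoring of primary strokes slightly inside the soma so jitter cannot
detach them. The benchmark panel draws soma radius 9–14 px, aspect
1.0–1.3, stroke half-width 1.2–2.0 px, jitter 0.5 px, 0–6 protrusions of
10–60 px with ≤ 2 branch points, per-segment turns ≤ 0.25 rad.

`synth.tracks` runs a per-frame 4-state Markov chain per cell with an
isotropic Gaussian nucleus walk; mitosis (per-frame probability) ends the
mother track and spawns two daughters whose classes are drawn from the
inheritance matrix row of the mother. `synth.omics` draws per-gene mean
expression from a two-component Gaussian mixture (defaults: low
N(1, 0.5²), high N(5, 1²), high fraction 0.6 — a 4σ separation on the
wider component, typical of expressed-vs-silent bimodality on the
log2(TPM+1) scale), adds per-line noise, and builds a dependency table
with essential anchors at −0.8, non-essential at 0, a few highly expressed
core-fitness genes, and one planted gene with the extreme depletion of one
designated line.

What the generators deliberately do not emulate: optics (PSF, shot noise,
uneven illumination), touching or overlapping cells, segmentation errors,
intensity textures, 3-D structure, realistic gene–gene correlation
structure. Passing the benchmarks therefore demonstrates that the
measurement chain is correct and unbiased on clean single-cell masks and
well-separated mixtures — not that it is robust to segmentation artifacts
or to expression distributions far from bimodal.

## Benchmark sizes and tolerances

The test suite and `scripts/acceptance.py` use: 200 phantom cells for
protrusion recovery (a cell passes when both counts are exact and every
tip length is within max(2 px, 5%); ≥ 95% of cells must pass — the per-tip
scatter quoted above makes a strict per-tip maximum over hundreds of tips
meaningless, so the 95%-of-cells criterion is applied to the whole
clause); 50 cells for Sholl-vs-continuous equality, compared at radii
where the crossing count is well posed (away from branch points, chain
ends, tangencies, and radii where two strokes have not yet separated by
their combined widths — elsewhere the rendered mask genuinely contains one
merged process); rasterized 2:1 ellipses with semi-major 20/40/80 px at 5
rotations for shape features (eccentricity within 0.02 of the pixel-moment
oracle, 0.03 of the continuous value); 500 tracks × 100 frames for matrix
recovery at 3 binomial SE per entry; 20 seeds × 500 genes for the mixture
gate (≥ 95% accuracy, means within 3 SE); and exhaustive enumeration of
every hypergeometric case with N ≤ 12. These sizes make the whole suite
run in well under a minute on one core while keeping every recovery test
far from its statistical floor.

## Known limitations

* Protrusion metrics assume one cell per mask; touching cells must be
  resolved upstream.
* The soma model (distance-transform peak + opening) can split very
  dumbbell-shaped cells into "soma + one giant protrusion"; such shapes
  are rare in the four-morphoclass taxonomy but the behavior is
  deterministic and documented (the larger lobe wins).
* Tip lengths carry ±1 px irreducible digitization scatter; differences
  between conditions smaller than that per cell need the usual averaging
  over hundreds of cells.
* The classifier thresholds are fixed config, not learned; they encode the
  qualitative class descriptions and should be re-tuned for cell lines
  with very different scale.
* Under-segmented (merged) labels are only flagged, not repaired.
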