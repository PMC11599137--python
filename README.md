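# gscmorph

Quantitative morphology and gene prioritization for glioblastoma stem cells
(GSCs), built as a reusable, tested Python library.

Glioblastoma stem cells are morphologically heterogeneous: the same culture
contains round cells without processes, large flat cells, small multipolar
cells bristling with short protrusions, and elongated cells trailing long
thin processes. This heterogeneity matters — protrusion-rich, interconnected
cells proliferate and respond to therapy differently from unconnected ones —
so it needs to be measured, classified, and tracked, and the genes that
control it need to be found. `gscmorph` implements that whole quantitative
workflow for anyone working downstream of a cell-segmentation step:

* **Morphometrics** from 2-D segmentation label masks: centered single-cell
  crops, moment-ellipse shape descriptors (area *A*, perimeter *P*, major and
  minor axis lengths from the eigenvalues of the second central moment
  matrix, eccentricity *e* = √(1 − (b/a)²)), skeleton-based protrusion
  counts and geodesic lengths, branching index (total protrusions /
  primary protrusions), and Sholl profiles (process intersections with
  concentric circles around the soma).
* **Morphoclass dynamics**: a rule-based classifier for the four GSC
  morphoclasses (nonpolar, flat polar, circular multipolar, elongated),
  class distributions with SEM over replicates, interphase transition
  matrices and mitotic inheritance matrices from time-lapse tracks, mitotic
  somal translocation (MST), tumor–tumor-connection density per 100 µm of
  perimeter, and the neurosphere invasion index.
* **Gene prioritization**: gene-list intersection, upper-tail hypergeometric
  (one-sided Fisher) enrichment P(X ≥ x) for X ~ Hypergeom(N, n, k),
  two-component Gaussian-mixture gating of bimodal basal expression,
  CRISPR depletion fold changes rescaled so essential-anchor medians map to
  −1 and non-essential to 0, core-fitness exclusion, ranking by minimum
  scaled depletion, and a DE-signature consistency test against the
  all-pairs correlation null.
* **Synthetic data with exact ground truth** (`gscmorph.synth`): phantom
  cells built as an elliptical soma plus stroked branched centerlines (the
  centerline length is the exact geodesic truth), time-lapse tracks driven
  by a planted 4×4 Markov chain with mitotic splitting, and omics tables
  with a planted expression mixture, dependency anchors and one planted
  context-specific dependency. Every analysis stage is benchmarked against
  these generators.

## Worked example

Build a phantom cell with three primary protrusions, one of which branches,
then run the full per-cell pipeline on the rendered mask:

```python
from gscmorph.synth.cells import CellSpec, ProtrusionSpec, generate_cell_mask
from gscmorph.pipeline import analyze_cell
from gscmorph.prioritize import hypergeom_upper_tail

branch = ProtrusionSpec(origin_angle=0.8, segments=[(15.0, 0.0)], width_px=1.5)
spec = CellSpec(
    soma_radius_px=12.0,
    protrusions=[
        ProtrusionSpec(origin_angle=0.0, segments=[(35.0, 0.0)], width_px=1.5),
        ProtrusionSpec(origin_angle=2.1, segments=[(30.0, 0.1)],
                       branches=[(0, 0.5, branch)], width_px=1.5),
        ProtrusionSpec(origin_angle=4.2, segments=[(25.0, -0.1)], width_px=1.5),
    ],
    image_shape=(128, 128),
)
mask, truth = generate_cell_mask(spec, seed=0)
result = analyze_cell(mask, pixel_size_um=1.0)
```

This prints (via the obvious `print` statements):

```
planted: 3 primary, 4 tips
measured: 3 primary, 4 tips, branching index 1.33
tip lengths (um): [25.9, 30.2, 30.2, 34.1]
eccentricity 0.712, area 806 um^2, morphoclass: circular_multipolar
Sholl: [3, 3, 3, 4, 4, 2, 1, 0]
```

The measured counts equal the planted ones; the tip lengths are the
planted centerline lengths (25, 30, 30+15·offset…) recovered to ~1 px; the
Sholl profile rises to 4 after the branch point and decays to zero beyond
the longest process. The classifier calls the cell circular multipolar:
three or more primary protrusions on a round (e < 0.85), small body.

The enrichment statistic used to flag the adducin family — all 3 adducins
among 30 candidate genes drawn from 19,396 protein-coding genes:

```python
hypergeom_upper_tail(N=19396, n=3, k=30, x=3).p_value   # 3.34e-09
```

A command line covers the same stages for file-based runs
(`gscmorph simulate | morpho | transitions | prioritize | correlate`); every
run writes a `manifest.json` with the parameters and seeds needed to
reproduce it.

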