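"""Per-cell analysis pipeline: mask -> features -> protrusions -> class.

Glue used by the command line and by batch analyses; each stage is the
corresponding library function, so results are identical to calling the
modules directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gscmorph.dynamics import ClassifierConfig, classify_morphoclass
from gscmorph.image_io import CellCrop
from gscmorph.protrusions import (
    ProtrusionMetrics,
    ShollProfile,
    SomaModel,
    build_skeleton,
    estimate_soma,
    protrusion_metrics,
    sholl_profile,
)
from gscmorph.shape import ShapeFeatures, compute_shape_features

__all__ = ["CellAnalysis", "analyze_cell", "analyses_to_tables"]


@dataclass
class CellAnalysis:
    """All per-cell results for one mask."""

    label: int
    shape: ShapeFeatures
    soma: SomaModel
    protrusions: ProtrusionMetrics
    sholl: ShollProfile
    morphoclass: str


def analyze_cell(
    mask: np.ndarray | CellCrop,
    pixel_size_um: float = 1.0,
    prune_um: float = 1.0,
    sholl_step_um: float = 5.0,
    cfg: ClassifierConfig | None = None,
    label: int = 0,
) -> CellAnalysis:
    """Run the full morphometric pipeline on one single-cell mask."""
    if isinstance(mask, CellCrop):
        pixel_size_um = mask.pixel_size_um
        label = mask.source_label
    shape = compute_shape_features(mask, pixel_size_um)
    soma = estimate_soma(mask)
    skeleton = build_skeleton(mask, soma, prune_um=prune_um, pixel_size_um=pixel_size_um)
    prot = protrusion_metrics(skeleton, pixel_size_um=pixel_size_um)
    sholl = sholl_profile(skeleton, soma, step_um=sholl_step_um, pixel_size_um=pixel_size_um)
    cls = classify_morphoclass(shape, prot, soma, cfg, pixel_size_um=pixel_size_um)
    return CellAnalysis(
        label=label,
        shape=shape,
        soma=soma,
        protrusions=prot,
        sholl=sholl,
        morphoclass=cls,
    )


def analyses_to_tables(
    analyses: list[CellAnalysis],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten analyses into (per-cell features table, long-format Sholl table)."""
    rows = []
    sholl_rows = []
    for a in analyses:
        rows.append(
            {
                "label": a.label,
                "area_um2": a.shape.area_um2,
                "perimeter_um": a.shape.perimeter_um,
                "major_axis_um": a.shape.major_axis_um,
                "minor_axis_um": a.shape.minor_axis_um,
                "eccentricity": a.shape.eccentricity,
                "axis_ratio": a.shape.axis_ratio,
                "n_primary": a.protrusions.n_primary,
                "n_total": a.protrusions.n_total,
                "avg_length_um": a.protrusions.avg_length_um,
                "max_length_um": a.protrusions.max_length_um,
                "branching_index": a.protrusions.branching_index,
                "morphoclass": a.morphoclass,
            }
        )
        for r_um, n in zip(a.sholl.radii_um, a.sholl.intersections):
            sholl_rows.append(
                {"label": a.label, "radius_um": float(r_um), "intersections": int(n)}
            )
    return pd.DataFrame(rows), pd.DataFrame(
        sholl_rows, columns=["label", "radius_um", "intersections"]
    )
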