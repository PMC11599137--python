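"""The four-morphoclass taxonomy: assignment, distributions, and dynamics.

GSCs fall into four morphoclasses — nonpolar (no protrusions), flat polar
(large flat body, a few protrusions), circular multipolar (small round body,
many short protrusions) and elongated (long thin body and/or long thin
protrusions).  This module assigns classes from quantitative features via a
rule cascade, summarizes class distributions over replicates, and computes
the time-lapse statistics: interphase transition matrices, mitotic
inheritance matrices, mitotic somal translocation (MST), tumor-tumor
connection (TTC) density and the neurosphere invasion index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gscmorph.errors import ValidationError
from gscmorph.protrusions import ProtrusionMetrics, SomaModel
from gscmorph.shape import ShapeFeatures

__all__ = [
    "MORPHOCLASSES",
    "ClassifierConfig",
    "TransitionMatrix",
    "classify_morphoclass",
    "interphase_transitions",
    "invasion_index",
    "mitotic_inheritance",
    "morphoclass_distribution",
    "mst_length",
    "ttc_density",
]

#: Canonical order of the four morphoclasses.
MORPHOCLASSES = ("nonpolar", "flat_polar", "circular_multipolar", "elongated")

_CLASS_INDEX = {name: i for i, name in enumerate(MORPHOCLASSES)}


@dataclass
class ClassifierConfig:
    """Thresholds of the rule-based morphoclass classifier.

    ``long_protrusion_factor`` is expressed in units of the soma equivalent
    diameter; ``flat_area_um2_threshold`` separates the small circular
    multipolar body from the big flat polar one.
    """

    ecc_threshold: float = 0.85
    long_protrusion_factor: float = 2.0
    multipolar_min_primary: int = 3
    flat_area_um2_threshold: float = 1000.0

    def validate(self) -> None:
        if not 0.0 < self.ecc_threshold < 1.0:
            raise ValidationError("ecc_threshold must be in (0, 1)")
        if self.long_protrusion_factor <= 0 or self.flat_area_um2_threshold <= 0:
            raise ValidationError("classifier thresholds must be positive")
        if self.multipolar_min_primary < 1:
            raise ValidationError("multipolar_min_primary must be >= 1")


@dataclass
class TransitionMatrix:
    """4x4 counts and row-normalized proportions over the morphoclasses.

    ``row_totals`` are the denominators; rows with zero counts have NaN
    proportions and appear in ``empty_rows``.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    row_totals: pd.Series
    empty_rows: list[str] = field(default_factory=list)


def _matrix_from_counts(counts: np.ndarray) -> TransitionMatrix:
    counts_df = pd.DataFrame(
        counts, index=list(MORPHOCLASSES), columns=list(MORPHOCLASSES), dtype=int
    )
    totals = counts_df.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts_df.div(totals, axis=0)
    empty = [cls for cls in MORPHOCLASSES if totals[cls] == 0]
    return TransitionMatrix(
        counts=counts_df, proportions=props, row_totals=totals, empty_rows=empty
    )


def classify_morphoclass(
    shape: ShapeFeatures,
    prot: ProtrusionMetrics,
    soma: SomaModel,
    cfg: ClassifierConfig | None = None,
    pixel_size_um: float = 1.0,
) -> str:
    """Assign one of the four morphoclasses; first matching rule wins.

    1. nonpolar: no primary protrusion;
    2. elongated: eccentric body, or a protrusion longer than
       ``long_protrusion_factor`` soma equivalent diameters;
    3. circular multipolar: at least ``multipolar_min_primary`` protrusions
       on a round, small body;
    4. flat polar otherwise.
    """
    cfg = cfg or ClassifierConfig()
    cfg.validate()
    if prot.n_primary == 0:
        return "nonpolar"
    if prot.max_length_um is None:
        raise ValidationError("max_length_um undefined despite n_primary > 0")
    soma_equiv_diam_um = soma.equivalent_diameter_px * pixel_size_um
    if (
        shape.eccentricity >= cfg.ecc_threshold
        or prot.max_length_um >= cfg.long_protrusion_factor * soma_equiv_diam_um
    ):
        return "elongated"
    if (
        prot.n_primary >= cfg.multipolar_min_primary
        and shape.eccentricity < cfg.ecc_threshold
        and shape.area_um2 < cfg.flat_area_um2_threshold
    ):
        return "circular_multipolar"
    return "flat_polar"


def morphoclass_distribution(
    replicates: list[list[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate morphoclass proportions, with mean and SEM over replicates.

    Returns ``(per_replicate, summary)``; each per-replicate row sums to 1.
    Empty replicates are excluded with a warning.
    """
    kept = []
    for i, labels in enumerate(replicates):
        if not labels:
            warnings.warn(f"replicate {i} is empty and was excluded", stacklevel=2)
            continue
        unknown = set(labels) - set(MORPHOCLASSES)
        if unknown:
            raise ValidationError(f"unknown morphoclass labels: {sorted(unknown)}")
        counts = pd.Series(labels).value_counts()
        props = counts.reindex(MORPHOCLASSES, fill_value=0) / len(labels)
        kept.append(props)
    if not kept:
        raise ValidationError("no non-empty replicates")
    per_rep = pd.DataFrame(kept).reset_index(drop=True)
    n = len(per_rep)
    summary = pd.DataFrame(
        {
            "mean": per_rep.mean(axis=0),
            "sem": per_rep.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        }
    )
    return per_rep, summary


def _validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    required = {"cell_id", "frame", "class"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValidationError(f"track table missing columns: {sorted(missing)}")
    unknown = set(tracks["class"]) - set(MORPHOCLASSES)
    if unknown:
        raise ValidationError(f"unknown morphoclass labels: {sorted(unknown)}")
    return tracks.sort_values(["cell_id", "frame"], kind="stable")


def interphase_transitions(
    tracks: pd.DataFrame,
) -> tuple[TransitionMatrix, pd.Series]:
    """Frame-to-frame class-transition matrix over interphase steps.

    Steps landing on a mitosis-flagged frame are excluded (the division
    itself is scored by :func:`mitotic_inheritance`).  Also returns, per
    starting class, the fraction of cells that acquire at least one new
    morphology during their interphase.
    """
    tracks = _validate_tracks(tracks)
    counts = np.zeros((4, 4), dtype=int)
    changed: dict[str, list[bool]] = {cls: [] for cls in MORPHOCLASSES}
    has_mitosis = "mitosis" in tracks.columns
    for _cid, grp in tracks.groupby("cell_id", sort=False):
        classes = grp["class"].to_numpy()
        if has_mitosis:
            mito = grp["mitosis"].to_numpy().astype(bool)
        else:
            mito = np.zeros(len(grp), dtype=bool)
        any_change = False
        for i in range(len(classes) - 1):
            if mito[i + 1]:
                continue
            a, b = _CLASS_INDEX[classes[i]], _CLASS_INDEX[classes[i + 1]]
            counts[a, b] += 1
            if a != b:
                any_change = True
        changed[classes[0]].append(any_change)
    change_fraction = pd.Series(
        {
            cls: (float(np.mean(vals)) if vals else np.nan)
            for cls, vals in changed.items()
        },
        name="fraction_changed",
    )
    return _matrix_from_counts(counts), change_fraction


def mitotic_inheritance(tracks: pd.DataFrame) -> TransitionMatrix:
    """Daughter-class distribution per mother class at mitosis.

    The mother's class is read at her mitosis-flagged (final) frame and each
    daughter's at her first frame.  ``row_totals`` counts daughters; mothers
    per class are in ``counts.attrs['mothers']``.  A child referencing a
    parent without a mitosis row raises, listing the offending ids.
    """
    tracks = _validate_tracks(tracks)
    if "mitosis" not in tracks.columns or "parent_id" not in tracks.columns:
        raise ValidationError("track table needs 'mitosis' and 'parent_id' columns")
    mothers = tracks[tracks["mitosis"].astype(bool)]
    mother_class = dict(zip(mothers["cell_id"], mothers["class"]))
    children = tracks.dropna(subset=["parent_id"])
    first_rows = children.loc[children.groupby("cell_id")["frame"].idxmin()]
    orphans = sorted(
        int(cid)
        for cid, pid in zip(first_rows["cell_id"], first_rows["parent_id"])
        if pid not in mother_class
    )
    if orphans:
        raise ValidationError(
            f"daughter cells with no mitotic mother row: {orphans}"
        )
    counts = np.zeros((4, 4), dtype=int)
    mother_counts = pd.Series(0, index=list(MORPHOCLASSES))
    for cls in mothers["class"]:
        mother_counts[cls] += 1
    for _row, rec in first_rows.iterrows():
        i = _CLASS_INDEX[mother_class[rec["parent_id"]]]
        j = _CLASS_INDEX[rec["class"]]
        counts[i, j] += 1
    matrix = _matrix_from_counts(counts)
    matrix.counts.attrs["mothers"] = mother_counts
    return matrix


def mst_length(track_rows: pd.DataFrame, pixel_size_um: float = 1.0) -> float | None:
    """Mitotic somal translocation: nucleus displacement in the step before mitosis.

    ``track_rows`` is one cell's track; returns the Euclidean distance (µm)
    between the nucleus position at the mitosis-flagged frame and the
    immediately preceding frame, or ``None`` (with a warning) when mitosis
    falls on the first frame.
    """
    rows = track_rows.sort_values("frame", kind="stable")
    mito_idx = np.nonzero(rows["mitosis"].to_numpy().astype(bool))[0]
    if len(mito_idx) == 0:
        raise ValidationError("track has no mitosis-flagged frame")
    i = int(mito_idx[0])
    if i == 0:
        warnings.warn("mitosis at first frame: MST undefined", stacklevel=2)
        return None
    dx = rows["x_px"].iloc[i] - rows["x_px"].iloc[i - 1]
    dy = rows["y_px"].iloc[i] - rows["y_px"].iloc[i - 1]
    return float(np.hypot(dx, dy)) * pixel_size_um


def ttc_density(n_connections: int, perimeter_um: float) -> float:
    """Tumor-tumor connections per 100 µm of cell perimeter."""
    if n_connections < 0:
        raise ValidationError("n_connections must be >= 0")
    if not perimeter_um > 0:
        raise ValidationError("perimeter_um must be > 0")
    return n_connections / perimeter_um * 100.0


def invasion_index(
    core_area: float, total_area: float, core_over_total: bool = False
) -> float:
    """Neurosphere invasion index: total area over core area (>= 1).

    ``core_over_total=True`` returns the reciprocal convention instead.
    """
    if not 0 < core_area <= total_area:
        raise ValidationError("need 0 < core_area <= total_area")
    ratio = total_area / core_area
    return 1.0 / ratio if core_over_total else ratio
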