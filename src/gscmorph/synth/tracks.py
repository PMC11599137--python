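"""Simulated time-lapse tracks of morphoclass dynamics.

Each cell carries a morphoclass that evolves as a per-frame Markov chain
(``transition_matrix``), a nucleus position performing an isotropic Gaussian
random walk, and a per-frame mitosis probability.  A mitosis terminates the
mother track (its last row carries ``mitosis=True``) and spawns two daughter
tracks whose initial classes are drawn from ``inheritance_matrix`` row of
the mother's class; daughters then evolve independently and may divide again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gscmorph.dynamics import MORPHOCLASSES
from gscmorph.errors import ValidationError

__all__ = ["TrackSimSpec", "generate_tracks", "TRACK_COLUMNS"]

TRACK_COLUMNS = ["cell_id", "parent_id", "frame", "class", "x_px", "y_px", "mitosis"]


def _check_stochastic(matrix: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValidationError(f"{name} must be 4x4, got {m.shape}")
    if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
        raise ValidationError(f"{name} rows must be non-negative and sum to 1")
    return m


@dataclass
class TrackSimSpec:
    """Parameters of the track simulation.

    ``mitosis_rate`` is the per-frame division probability; the spatial
    field is arbitrary (positions in px, starting uniform in ``field_px``).
    """

    n_cells: int
    n_frames: int
    transition_matrix: np.ndarray
    mitosis_rate: float = 0.0
    inheritance_matrix: np.ndarray | None = None
    nucleus_step_sd_px: float = 2.0
    field_px: float = 1000.0
    initial_class_probs: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0 or self.n_frames < 1:
            raise ValidationError("n_cells must be >= 0 and n_frames >= 1")
        _check_stochastic(self.transition_matrix, "transition_matrix")
        if self.inheritance_matrix is not None:
            _check_stochastic(self.inheritance_matrix, "inheritance_matrix")
        elif self.mitosis_rate > 0:
            raise ValidationError("mitosis_rate > 0 requires an inheritance_matrix")
        if not 0.0 <= self.mitosis_rate <= 1.0:
            raise ValidationError("mitosis_rate must be in [0, 1]")
        if self.nucleus_step_sd_px < 0:
            raise ValidationError("nucleus_step_sd_px must be >= 0")


@dataclass
class _Cell:
    cell_id: int
    parent_id: int | None
    start_frame: int
    cls: int
    pos: np.ndarray
    rows: list = field(default_factory=list)


def generate_tracks(spec: TrackSimSpec) -> pd.DataFrame:
    """Simulate tracks and return them as a tidy table (one row per cell-frame).

    Columns: ``cell_id, parent_id, frame, class, x_px, y_px, mitosis`` with
    classes as morphoclass names.  Deterministic for a fixed spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    trans = np.asarray(spec.transition_matrix, dtype=float)
    inherit = (
        np.asarray(spec.inheritance_matrix, dtype=float)
        if spec.inheritance_matrix is not None
        else None
    )
    init_probs = (
        np.full(4, 0.25)
        if spec.initial_class_probs is None
        else np.asarray(spec.initial_class_probs, dtype=float)
    )
    if np.abs(init_probs.sum() - 1.0) > 1e-12:
        raise ValidationError("initial_class_probs must sum to 1")

    rows: list[tuple] = []
    next_id = 0
    active: list[_Cell] = []
    for _ in range(spec.n_cells):
        active.append(
            _Cell(
                cell_id=next_id,
                parent_id=None,
                start_frame=0,
                cls=int(rng.choice(4, p=init_probs)),
                pos=rng.uniform(0.0, spec.field_px, size=2),
            )
        )
        next_id += 1

    for frame in range(spec.n_frames):
        newborn: list[_Cell] = []
        survivors: list[_Cell] = []
        for cell in active:
            # a division on the final frame would leave daughters without rows
            divides = (
                frame < spec.n_frames - 1
                and spec.mitosis_rate > 0
                and rng.random() < spec.mitosis_rate
            )
            rows.append(
                (
                    cell.cell_id,
                    cell.parent_id,
                    frame,
                    MORPHOCLASSES[cell.cls],
                    float(cell.pos[0]),
                    float(cell.pos[1]),
                    divides,
                )
            )
            if divides:
                for _d in range(2):
                    newborn.append(
                        _Cell(
                            cell_id=next_id,
                            parent_id=cell.cell_id,
                            start_frame=frame + 1,
                            cls=int(rng.choice(4, p=inherit[cell.cls])),
                            pos=cell.pos
                            + rng.normal(0.0, spec.nucleus_step_sd_px, size=2),
                        )
                    )
                    next_id += 1
            else:
                cell.cls = int(rng.choice(4, p=trans[cell.cls]))
                cell.pos = cell.pos + rng.normal(0.0, spec.nucleus_step_sd_px, size=2)
                survivors.append(cell)
        active = survivors + newborn

    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df["parent_id"] = df["parent_id"].astype("Int64")
    return df
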