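"""Synthetic single-cell masks: elliptical soma plus branched protrusions.

A cell is modelled as an ellipse (the soma) with protrusions growing from
its boundary.  Each protrusion is a piecewise-linear centerline, optionally
carrying branches, stroked with a disk of radius ``width_px``.  Because the
stroke is a Minkowski sum of the centerline with a disk, the centerline
length is the exact geodesic ground truth for the rendered protrusion, which
is what makes the generator a usable oracle for skeleton-based metrics.

Coordinates are 0-based ``(row, col)`` with pixel centers on the integer
grid; a pixel is foreground iff its center lies inside the continuous shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label

from gscmorph.errors import GenerationError, InternalConsistencyError, ValidationError

__all__ = [
    "CellSpec",
    "GroundTruth",
    "ProtrusionSpec",
    "centerline_chains",
    "generate_cell_mask",
    "ground_truth_from_json",
    "ground_truth_to_json",
    "random_cell_panel",
]


@dataclass
class ProtrusionSpec:
    """One protrusion tree.

    ``origin_angle`` is the ellipse parameter (radians) of the attachment
    point for a primary protrusion; for a branch it is the angle relative to
    the parent segment's direction.  ``segments`` is an ordered list of
    ``(length_px, turn_angle)`` pairs: each segment's direction is the
    previous direction rotated by ``turn_angle``.  ``branches`` holds
    ``(segment_index, offset_fraction, ProtrusionSpec)`` triples.
    """

    origin_angle: float
    segments: list[tuple[float, float]]
    branches: list[tuple[int, float, "ProtrusionSpec"]] = field(default_factory=list)
    width_px: float = 1.5

    def validate(self, _depth: int = 0) -> None:
        if _depth > 8:
            raise ValidationError("protrusion branch recursion deeper than 8")
        if not self.segments:
            raise ValidationError("protrusion must have at least one segment")
        for length, _turn in self.segments:
            if not length > 0:
                raise ValidationError(f"segment length must be > 0, got {length}")
        if not self.width_px > 0:
            raise ValidationError("width_px must be > 0")
        for seg_idx, frac, sub in self.branches:
            if not 0 <= seg_idx < len(self.segments):
                raise ValidationError(f"branch segment_index {seg_idx} out of range")
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"branch offset_fraction {frac} outside [0, 1]")
            sub.validate(_depth + 1)


@dataclass
class CellSpec:
    """Geometry of one synthetic cell.

    The soma is an ellipse with semi-axes ``soma_radius_px * soma_aspect``
    (along ``soma_orientation``) and ``soma_radius_px``.  ``boundary_jitter_px``
    is the s.d. of the Gaussian displacement applied to each soma polygon
    vertex before rasterization; protrusion centerlines are never jittered so
    their length ground truth stays exact.
    """

    soma_radius_px: float
    soma_aspect: float = 1.0
    soma_orientation: float = 0.0
    protrusions: list[ProtrusionSpec] = field(default_factory=list)
    boundary_jitter_px: float = 0.0
    pixel_size_um: float = 1.0
    image_shape: tuple[int, int] = (192, 192)

    def validate(self) -> None:
        if not self.soma_radius_px >= 2:
            raise ValidationError("soma_radius_px must be >= 2")
        if not self.soma_aspect >= 1:
            raise ValidationError("soma_aspect must be >= 1")
        if self.boundary_jitter_px < 0:
            raise ValidationError("boundary_jitter_px must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        for p in self.protrusions:
            p.validate()

    @property
    def soma_semi_axes(self) -> tuple[float, float]:
        return (self.soma_radius_px * self.soma_aspect, self.soma_radius_px)


@dataclass
class GroundTruth:
    """Planted topology and geometry of one generated cell.

    ``centerlines`` is a list of polylines (``(k, 2)`` float arrays in
    absolute ``(row, col)`` pixel coordinates), one per *chain*: the main
    run of each protrusion plus one chain per branch, so the chains tile the
    protrusion trees without duplication and the number of chains equals the
    number of tips.  ``tip_lengths_px`` are soma-boundary-to-tip geodesic
    lengths along the planted centerlines, index-aligned with
    ``centerlines``.
    """

    n_primary: int
    n_total_tips: int
    tip_lengths_px: list[float]
    centerlines: list[np.ndarray]
    soma_center: tuple[float, float]
    soma_radius_px: float
    soma_semi_axes: tuple[float, float]
    soma_orientation: float
    intended_morphoclass: str | None = None

    def __post_init__(self) -> None:
        if self.n_total_tips != len(self.tip_lengths_px):
            raise InternalConsistencyError(
                "n_total_tips must equal len(tip_lengths_px)"
            )
        if self.n_total_tips != len(self.centerlines):
            raise InternalConsistencyError("one centerline chain per tip expected")
        if not self.centerlines and self.n_primary != 0:
            raise InternalConsistencyError("no centerlines but n_primary > 0")


# --------------------------------------------------------------------------
# continuous geometry


def _unit(angle: float) -> np.ndarray:
    return np.array([np.cos(angle), np.sin(angle)])


def _rotate(vec: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _ellipse_point_normal(spec: CellSpec, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Boundary point and outward unit normal of the soma ellipse at parameter t."""
    a, b = spec.soma_semi_axes
    e1 = _unit(spec.soma_orientation)
    e2 = np.array([-e1[1], e1[0]])
    point = a * np.cos(t) * e1 + b * np.sin(t) * e2
    normal = (np.cos(t) / a) * e1 + (np.sin(t) / b) * e2
    return point, normal / np.linalg.norm(normal)


@dataclass
class _Chain:
    points: np.ndarray  # (k, 2) relative to soma center
    base_length: float  # geodesic distance from the soma boundary to points[0]
    width_px: float
    protrusion_index: int

    @property
    def tip_length(self) -> float:
        return self.base_length + float(
            np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1))
        )


def _walk(
    spec: ProtrusionSpec,
    p0: np.ndarray,
    d0: np.ndarray,
    base_length: float,
    prot_index: int,
) -> list[_Chain]:
    points = [p0]
    directions = []
    d = d0
    for length, turn in spec.segments:
        d = _rotate(d, turn)
        directions.append(d)
        points.append(points[-1] + length * d)
    chains = [_Chain(np.array(points), base_length, spec.width_px, prot_index)]
    seg_lengths = [length for length, _ in spec.segments]
    for seg_idx, frac, sub in spec.branches:
        origin = points[seg_idx] + frac * seg_lengths[seg_idx] * directions[seg_idx]
        branch_base = base_length + sum(seg_lengths[:seg_idx]) + frac * seg_lengths[seg_idx]
        branch_dir = _rotate(directions[seg_idx], sub.origin_angle)
        chains.extend(_walk(sub, origin, branch_dir, branch_base, prot_index))
    return chains


def centerline_chains(spec: CellSpec) -> list[_Chain]:
    """All centerline chains of a cell, in coordinates relative to the soma center.

    One chain per tip; chains tile the protrusion trees without overlap
    (each branch chain starts at its branch point).
    """
    chains: list[_Chain] = []
    for i, prot in enumerate(spec.protrusions):
        p0, normal = _ellipse_point_normal(spec, prot.origin_angle)
        chains.extend(_walk(prot, p0, normal, 0.0, i))
    return chains


# --------------------------------------------------------------------------
# rasterization


def _soma_polygon(spec: CellSpec, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a, _b = spec.soma_semi_axes
    n_vertices = max(48, int(np.ceil(4 * np.pi * a)))
    ts = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    e1 = _unit(spec.soma_orientation)
    e2 = np.array([-e1[1], e1[0]])
    verts = (
        center
        + np.outer(spec.soma_semi_axes[0] * np.cos(ts), e1)
        + np.outer(spec.soma_semi_axes[1] * np.sin(ts), e2)
    )
    if spec.boundary_jitter_px > 0:
        verts = verts + rng.normal(0.0, spec.boundary_jitter_px, size=verts.shape)
    return verts


def _stroke_segment(mask: np.ndarray, p: np.ndarray, q: np.ndarray, width: float) -> None:
    """Set pixels whose center is within ``width`` of segment pq (round caps)."""
    rows, cols = mask.shape
    r_lo = max(0, int(np.floor(min(p[0], q[0]) - width - 1)))
    r_hi = min(rows - 1, int(np.ceil(max(p[0], q[0]) + width + 1)))
    c_lo = max(0, int(np.floor(min(p[1], q[1]) - width - 1)))
    c_hi = min(cols - 1, int(np.ceil(max(p[1], q[1]) + width + 1)))
    if r_hi < r_lo or c_hi < c_lo:
        return
    rr, cc = np.meshgrid(
        np.arange(r_lo, r_hi + 1), np.arange(c_lo, c_hi + 1), indexing="ij"
    )
    pts = np.stack([rr, cc], axis=-1).astype(float)
    seg = q - p
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0.0:
        dist = np.linalg.norm(pts - p, axis=-1)
    else:
        t = np.clip(((pts - p) @ seg) / seg_len2, 0.0, 1.0)
        proj = p + t[..., None] * seg
        dist = np.linalg.norm(pts - proj, axis=-1)
    mask[r_lo : r_hi + 1, c_lo : c_hi + 1] |= dist <= width


def _intended_morphoclass(spec: CellSpec, chains: list[_Chain]) -> str:
    """Class the generator intends, mirroring the classifier's semantics."""
    a, b = spec.soma_semi_axes
    if not spec.protrusions:
        return "nonpolar"
    equiv_diam = 2.0 * np.sqrt(a * b)
    max_tip = max(c.tip_length for c in chains)
    if spec.soma_aspect >= 2.5 or max_tip >= 2.0 * equiv_diam:
        return "elongated"
    soma_area = np.pi * a * b
    if len(spec.protrusions) >= 3 and soma_area * spec.pixel_size_um**2 < 1000.0:
        return "circular_multipolar"
    return "flat_polar"


def generate_cell_mask(spec: CellSpec, seed: int) -> tuple[np.ndarray, GroundTruth]:
    """Render a cell spec to a binary mask and its ground-truth record.

    Deterministic: identical ``(spec, seed)`` yields a bit-identical mask.
    Raises :class:`GenerationError` if any protrusion (inflated by its
    stroke width) or the soma would leave the image bounds.
    """
    spec.validate()
    rows, cols = spec.image_shape
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    chains = centerline_chains(spec)

    a, _ = spec.soma_semi_axes
    margin = 2.0 + spec.boundary_jitter_px * 3.0
    if (
        center[0] - a - margin < 0
        or center[1] - a - margin < 0
        or center[0] + a + margin > rows - 1
        or center[1] + a + margin > cols - 1
    ):
        raise GenerationError("soma ellipse does not fit inside image_shape")
    for chain in chains:
        pts = chain.points + center
        pad = chain.width_px + 2.0
        if (
            pts.min() < pad
            or pts[:, 0].max() > rows - 1 - pad
            or pts[:, 1].max() > cols - 1 - pad
        ):
            raise GenerationError(
                f"protrusion {chain.protrusion_index} leaves the image bounds"
            )

    rng = np.random.default_rng(seed)
    mask = polygon2mask((rows, cols), _soma_polygon(spec, center, rng))
    if spec.boundary_jitter_px > 0:
        # vertex jitter can fold the polygon and rasterize stray specks;
        # the soma is the largest component
        lab = cc_label(mask, connectivity=2)
        if lab.max() > 1:
            sizes = np.bincount(lab.ravel())[1:]
            mask = lab == (int(np.argmax(sizes)) + 1)
    for chain in chains:
        pts = chain.points + center
        if chain.base_length == 0.0:
            # anchor primary protrusions inside the soma so boundary jitter
            # cannot detach the stroke; ground truth is unaffected (lengths
            # are measured from the unjittered boundary point pts[0])
            inward = pts[0] - pts[1]
            norm = np.linalg.norm(inward)
            if norm > 0:
                inset = pts[0] + (2.0 + 3.0 * spec.boundary_jitter_px) * inward / norm
                _stroke_segment(mask, inset, pts[0], chain.width_px)
        for i in range(len(pts) - 1):
            _stroke_segment(mask, pts[i], pts[i + 1], chain.width_px)

    n_components = int(cc_label(mask, connectivity=2).max())
    if n_components != 1:
        raise GenerationError(
            f"rendered mask has {n_components} 8-connected components, expected 1"
        )

    truth = GroundTruth(
        n_primary=len(spec.protrusions),
        n_total_tips=len(chains),
        tip_lengths_px=[c.tip_length for c in chains],
        centerlines=[c.points + center for c in chains],
        soma_center=(float(center[0]), float(center[1])),
        soma_radius_px=spec.soma_radius_px,
        soma_semi_axes=spec.soma_semi_axes,
        soma_orientation=spec.soma_orientation,
        intended_morphoclass=_intended_morphoclass(spec, chains),
    )
    return mask, truth


# --------------------------------------------------------------------------
# randomized panel


def _random_protrusion(
    rng: np.random.Generator,
    total_length: float,
    origin_angle: float,
    width_px: float,
) -> ProtrusionSpec:
    n_seg = int(rng.integers(1, 4))
    cuts = np.sort(rng.uniform(0.2, 0.8, size=n_seg - 1)) if n_seg > 1 else np.array([])
    bounds = np.concatenate([[0.0], cuts, [1.0]]) * total_length
    seg_lengths = np.diff(bounds)
    turns = np.clip(rng.normal(0.0, 0.12, size=n_seg), -0.25, 0.25)
    turns[0] = np.clip(rng.normal(0.0, 0.08), -0.15, 0.15)
    segments = [(float(sl), float(t)) for sl, t in zip(seg_lengths, turns)]
    return ProtrusionSpec(origin_angle=origin_angle, segments=segments, width_px=width_px)


def _attach_branch(rng: np.random.Generator, prot: ProtrusionSpec) -> None:
    """Plant one branch on ``prot`` at 30-70% of its arc length."""
    seg_lengths = np.array([length for length, _ in prot.segments])
    total = float(seg_lengths.sum())
    s = float(rng.uniform(0.3, 0.7)) * total
    cum = np.concatenate([[0.0], np.cumsum(seg_lengths)])
    seg_idx = int(np.searchsorted(cum, s, side="right") - 1)
    seg_idx = min(seg_idx, len(prot.segments) - 1)
    frac = (s - cum[seg_idx]) / seg_lengths[seg_idx]
    angle = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 0.9))
    length = float(rng.uniform(8.0, 20.0))
    branch = ProtrusionSpec(
        origin_angle=angle,
        segments=[(length, 0.0)],
        width_px=prot.width_px,
    )
    prot.branches.append((seg_idx, float(frac), branch))


def _chains_collide(spec: CellSpec, clearance: float = 1.5) -> bool:
    """True when two chains pass close enough for their strokes to merge.

    A merge would make the rendered mask's geodesics differ from the planted
    centerline lengths, i.e. the ground-truth record would be wrong; the
    panel generator rejects such geometries.  Chain pairs are compared on
    1-px samples, ignoring the neighborhood of a branch chain's own origin.
    """
    chains = centerline_chains(spec)
    if len(chains) < 2:
        return False
    sampled = []
    for ch in chains:
        pts = ch.points
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        samples = [pts[0]]
        for i, L in enumerate(seg_len):
            n = max(1, int(np.ceil(L)))
            ts = np.linspace(0.0, 1.0, n + 1)[1:]
            samples.extend(pts[i] + ts[:, None] * seg[i])
        sampled.append(np.asarray(samples))

    def is_child(child_idx: int, parent_idx: int) -> bool:
        origin = chains[child_idx].points[0]
        return bool(
            np.min(np.linalg.norm(sampled[parent_idx] - origin, axis=1)) < 0.75
        )

    soma_b = spec.soma_semi_axes[1]
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            a, b = sampled[i], sampled[j]
            thresh = chains[i].width_px + chains[j].width_px + clearance
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
            excluded = np.zeros_like(d, dtype=bool)
            if is_child(j, i) or is_child(i, j):
                child, parent = (j, i) if is_child(j, i) else (i, j)
                origin = chains[child].points[0]
                near_a = np.linalg.norm(a - origin, axis=1) < 1.5 * thresh
                near_b = np.linalg.norm(b - origin, axis=1) < 1.5 * thresh
                excluded = near_a[:, None] & near_b[None, :]
                # the branch tip must clear the parent stroke or the two
                # tips are unresolvable in the rendered mask
                tip = chains[child].points[-1]
                if np.min(np.linalg.norm(sampled[parent] - tip, axis=1)) < thresh:
                    return True
            elif chains[i].base_length == 0.0 and chains[j].base_length == 0.0:
                # primary chains may legitimately run close right at the
                # soma, where the soma fills the gap anyway
                ra = np.linalg.norm(a, axis=1) < soma_b + 2.0
                rb = np.linalg.norm(b, axis=1) < soma_b + 2.0
                excluded = ra[:, None] & rb[None, :]
            if np.any((d < thresh) & ~excluded):
                return True
    return False


def random_cell_panel(
    n_cells: int,
    seed: int,
    *,
    max_protrusions: int = 6,
    length_range: tuple[float, float] = (10.0, 60.0),
    max_branch_points: int = 2,
    soma_radius_range: tuple[float, float] = (9.0, 14.0),
    soma_aspect_range: tuple[float, float] = (1.0, 1.3),
    width_range: tuple[float, float] = (1.2, 2.0),
    boundary_jitter_px: float = 0.5,
    pixel_size_um: float = 1.0,
) -> list[tuple[CellSpec, np.ndarray, GroundTruth]]:
    """Generate a seeded panel of random cells with exact ground truth.

    Defaults emulate the benchmark conditions used throughout the test
    suite: 0-6 protrusions per cell with 10-60 px tip lengths and at most
    two branch points.  Protrusion origins are spread around the soma with a
    guaranteed angular gap so strokes do not merge near their base.
    """
    master = np.random.default_rng(seed)
    panel = []
    for _ in range(n_cells):
        for _attempt in range(30):
            cell_rng = np.random.default_rng(master.integers(2**31))
            result = _try_random_cell(
                cell_rng,
                max_protrusions=max_protrusions,
                length_range=length_range,
                max_branch_points=max_branch_points,
                soma_radius_range=soma_radius_range,
                soma_aspect_range=soma_aspect_range,
                width_range=width_range,
                boundary_jitter_px=boundary_jitter_px,
                pixel_size_um=pixel_size_um,
            )
            if result is not None:
                panel.append(result)
                break
        else:
            raise GenerationError("could not draw a collision-free cell in 30 tries")
    return panel


def _try_random_cell(
    cell_rng: np.random.Generator,
    *,
    max_protrusions: int,
    length_range: tuple[float, float],
    max_branch_points: int,
    soma_radius_range: tuple[float, float],
    soma_aspect_range: tuple[float, float],
    width_range: tuple[float, float],
    boundary_jitter_px: float,
    pixel_size_um: float,
) -> tuple[CellSpec, np.ndarray, GroundTruth] | None:
    """One draw for :func:`random_cell_panel`; None when geometry collides."""
    soma_radius = float(cell_rng.uniform(*soma_radius_range))
    aspect = float(cell_rng.uniform(*soma_aspect_range))
    orientation = float(cell_rng.uniform(0.0, np.pi))
    n_prot = int(cell_rng.integers(0, max_protrusions + 1))
    width = float(cell_rng.uniform(*width_range))

    protrusions: list[ProtrusionSpec] = []
    if n_prot > 0:
        offset = cell_rng.uniform(0.0, 2 * np.pi)
        angles = (
            offset
            + 2 * np.pi * np.arange(n_prot) / n_prot
            + cell_rng.uniform(-0.2, 0.2, size=n_prot)
        )
        for ang in angles:
            total_length = float(cell_rng.uniform(*length_range))
            protrusions.append(
                _random_protrusion(cell_rng, total_length, float(ang), width)
            )
        # one branch per protrusion: planted branches must stay geometrically
        # distinct or the recorded topology would not be the rendered one
        eligible = [p for p in protrusions if sum(s[0] for s in p.segments) >= 25.0]
        n_branches = int(cell_rng.integers(0, max_branch_points + 1))
        cell_rng.shuffle(eligible)
        for host in eligible[:n_branches]:
            _attach_branch(cell_rng, host)

    spec = CellSpec(
        soma_radius_px=soma_radius,
        soma_aspect=aspect,
        soma_orientation=orientation,
        protrusions=protrusions,
        boundary_jitter_px=boundary_jitter_px,
        pixel_size_um=pixel_size_um,
        image_shape=(0, 0),  # placeholder, sized below
    )
    if _chains_collide(spec):
        return None
    chains = centerline_chains(spec)
    extent = soma_radius * aspect
    for chain in chains:
        extent = max(extent, float(np.abs(chain.points).max()) + width)
    half = int(np.ceil(extent)) + 6
    spec.image_shape = (2 * half + 1, 2 * half + 1)
    mask_seed = int(cell_rng.integers(2**31))
    try:
        mask, truth = generate_cell_mask(spec, mask_seed)
    except GenerationError:
        return None
    return spec, mask, truth


# --------------------------------------------------------------------------
# JSON sidecar


def ground_truth_to_json(truth: GroundTruth) -> str:
    payload = {
        "n_primary": truth.n_primary,
        "n_total_tips": truth.n_total_tips,
        "tip_lengths_px": truth.tip_lengths_px,
        "centerlines": [c.tolist() for c in truth.centerlines],
        "soma_center": list(truth.soma_center),
        "soma_radius_px": truth.soma_radius_px,
        "soma_semi_axes": list(truth.soma_semi_axes),
        "soma_orientation": truth.soma_orientation,
        "intended_morphoclass": truth.intended_morphoclass,
    }
    return json.dumps(payload, indent=2)


def ground_truth_from_json(text: str) -> GroundTruth:
    d = json.loads(text)
    return GroundTruth(
        n_primary=d["n_primary"],
        n_total_tips=d["n_total_tips"],
        tip_lengths_px=d["tip_lengths_px"],
        centerlines=[np.asarray(c, dtype=float) for c in d["centerlines"]],
        soma_center=tuple(d["soma_center"]),
        soma_radius_px=d["soma_radius_px"],
        soma_semi_axes=tuple(d["soma_semi_axes"]),
        soma_orientation=d["soma_orientation"],
        intended_morphoclass=d["intended_morphoclass"],
    )
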