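"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package's
implementation: continuous geometry via shapely, brute-force pixel loops,
exhaustive enumeration.  They are deliberately slow and simple.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union


def continuous_cell_area(spec) -> float:
    """Analytic area of soma ellipse union stroked centerlines (shapely)."""
    from gscmorph.synth.cells import centerline_chains, _ellipse_point_normal

    a, b = spec.soma_semi_axes
    ts = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    boundary = np.array([_ellipse_point_normal(spec, t)[0] for t in ts])
    shapes = [Polygon(boundary)]
    for chain in centerline_chains(spec):
        shapes.append(LineString(chain.points).buffer(chain.width_px))
    return float(unary_union(shapes).area)


def pixel_moment_ellipse(mask: np.ndarray) -> tuple[float, float, float]:
    """(major_px, minor_px, eccentricity) from explicit central-moment sums."""
    rows, cols = np.nonzero(mask)
    r0, c0 = rows.mean(), cols.mean()
    mrr = np.mean((rows - r0) ** 2)
    mcc = np.mean((cols - c0) ** 2)
    mrc = np.mean((rows - r0) * (cols - c0))
    common = np.sqrt(((mrr - mcc) / 2) ** 2 + mrc**2)
    l1 = (mrr + mcc) / 2 + common
    l2 = (mrr + mcc) / 2 - common
    major = 4 * np.sqrt(max(l1, 0.0))
    minor = 4 * np.sqrt(max(l2, 0.0))
    ecc = np.sqrt(max(0.0, 1 - (minor / major) ** 2)) if major > 0 else 0.0
    return float(major), float(minor), float(ecc)


def hypergeom_enumerate(N: int, n: int, k: int, x: int) -> float:
    """P(X >= x) by counting all C(N, k) draws explicitly (tiny N only)."""
    success = set(range(n))
    hits = sum(
        1 for draw in combinations(range(N), k) if len(success & set(draw)) >= x
    )
    return hits / comb(N, k)


def hypergeom_upper_tail_table(N: int, n: int, k: int) -> dict[int, float]:
    """P(X >= x) for every x, from one exhaustive pass over all C(N, k) draws."""
    success = set(range(n))
    counts = np.zeros(min(n, k) + 1, dtype=np.int64)
    for draw in combinations(range(N), k):
        counts[len(success & set(draw))] += 1
    total = comb(N, k)
    tail = np.cumsum(counts[::-1])[::-1]
    return {x: float(tail[x]) / total for x in range(min(n, k) + 1)}


def _chain_samples(chain: np.ndarray, per_px: int = 8) -> np.ndarray:
    pts = []
    for i in range(len(chain) - 1):
        seg = chain[i + 1] - chain[i]
        length = np.linalg.norm(seg)
        ts = np.linspace(0.0, 1.0, max(2, int(np.ceil(length * per_px))))
        pts.extend(chain[i] + ts[:, None] * seg)
    return np.asarray(pts)


def continuous_sholl_crossings(truth, center: np.ndarray, radius: float) -> int:
    """Crossings of the planted centerlines with one circle, and the points."""
    n = 0
    for chain in truth.centerlines:
        s = _chain_samples(chain)
        dd = np.linalg.norm(s - center, axis=1) - radius
        n += int(np.sum((dd[:-1] * dd[1:]) < 0))
    return n


def sholl_well_posed_radii(spec, truth, center: np.ndarray, radii: np.ndarray):
    """Radii where the circle-crossing count is well defined for a stroked mask.

    Excludes radii near chain endpoints / branch points, near radial
    tangencies (crossing count unstable), and radii where two crossing
    points lie closer than the strokes' merge distance (the rendered mask
    has one merged process there).
    """
    width = max([p.width_px for p in spec.protrusions], default=1.5)
    special = [np.linalg.norm(ch[0] - center) for ch in truth.centerlines]
    special += [np.linalg.norm(ch[-1] - center) for ch in truth.centerlines]
    extrema = []
    for ch in truth.centerlines:
        dd = np.linalg.norm(_chain_samples(ch) - center, axis=1)
        interior = (dd[1:-1] - dd[:-2]) * (dd[2:] - dd[1:-1]) < 0
        extrema.extend(dd[1:-1][interior])
    keep = []
    for r in radii:
        if any(abs(d - r) < 2.5 for d in special):
            continue
        if any(abs(d - r) < 1.5 for d in extrema):
            continue
        pts = []
        for chain in truth.centerlines:
            s = _chain_samples(chain)
            dd = np.linalg.norm(s - center, axis=1) - r
            for i in np.nonzero((dd[:-1] * dd[1:]) < 0)[0]:
                pts.append(s[i])
        if len(pts) > 1:
            pts = np.asarray(pts)
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 2 * width + 2.0:
                continue
        keep.append(float(r))
    return keep
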