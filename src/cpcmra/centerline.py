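"""Vessel centerline extraction and metrics.

Centerlines are ordered millimetre polylines with arc-length
parameterization and an optional per-point maximal-inscribed-sphere
radius.  Extraction is a distance-transform-weighted shortest path
(per-voxel cost ``1 / (dt + eps)``), which keeps the path on the locus of
locally maximal wall distance; on tubular shapes this coincides with the
Voronoi-based definition to within a voxel.

Curvature is ``|c' x c''| / |c'|^3`` with derivatives taken by central
finite differences on the arc-length parameterization; tortuosity is
``L / D - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from cpcmra.errors import ValidationError
from cpcmra.segmentation import BinaryMask

MM_PER_M = 1000.0


@dataclass
class Centerline:
    """Ordered 3D polyline (mm) with cumulative arc length."""

    points: np.ndarray  # (n, 3) mm
    radius: np.ndarray | None = None  # (n,) mm
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValidationError("a centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValidationError("consecutive centerline points must be distinct")
        if self.radius is not None:
            self.radius = np.asarray(self.radius, dtype=float)
            if len(self.radius) != len(self.points):
                raise ValidationError("radius series length must match points")

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class BifurcationSystem:
    """Local reference frame of a single bifurcation."""

    reference_point: np.ndarray
    parent_direction: np.ndarray
    daughter_directions: tuple[np.ndarray, np.ndarray]
    bifurcation_plane_normal: np.ndarray


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero-length direction vector")
    return v / n


def extract_centerline(
    mask: BinaryMask, endpoints: tuple, eps: float = 1e-6
) -> Centerline:
    """Minimum-cost path between two points, weighted away from the wall.

    ``endpoints`` are two world points (mm) that must fall inside the mask.
    The per-point radius is the Euclidean distance transform sampled along
    the path (maximal inscribed sphere radius).
    """
    voxels = mask.voxels
    grid = mask.grid
    spacing = np.asarray(grid.spacing)

    idx_pts = []
    for p in endpoints:
        idx = np.round(grid.world_to_index(p)[0]).astype(int)
        if (
            np.any(idx < 0)
            or np.any(idx >= np.asarray(grid.shape))
            or not voxels[tuple(idx)]
        ):
            raise ValidationError(f"endpoint {tuple(np.asarray(p))} is outside the mask")
        idx_pts.append(idx)

    dt = ndimage.distance_transform_edt(voxels, sampling=spacing)
    cost = np.zeros_like(dt)
    cost[voxels] = 1.0 / (dt[voxels] + eps)

    # sparse 26-neighbour graph over mask voxels
    flat_ids = -np.ones(voxels.shape, dtype=np.int64)
    coords = np.argwhere(voxels)
    flat_ids[tuple(coords.T)] = np.arange(len(coords))

    rows, cols, weights = [], [], []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    shape = np.asarray(voxels.shape)
    for off in offsets:
        off = np.asarray(off)
        lo = np.maximum(0, -off)
        hi = shape - np.maximum(0, off)
        src = voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        dstlo = lo + off
        dsthi = hi + off
        dst = voxels[dstlo[0] : dsthi[0], dstlo[1] : dsthi[1], dstlo[2] : dsthi[2]]
        both = src & dst
        if not both.any():
            continue
        ci = np.argwhere(both) + lo
        cj = ci + off
        step = np.linalg.norm(off * spacing)
        w = step * 0.5 * (cost[tuple(ci.T)] + cost[tuple(cj.T)])
        rows.append(flat_ids[tuple(ci.T)])
        cols.append(flat_ids[tuple(cj.T)])
        weights.append(w)

    if not rows:
        raise ValidationError("no path: mask has no connected voxels")
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    n = len(coords)
    graph = coo_matrix(
        (np.concatenate([weights, weights]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()

    start = flat_ids[tuple(idx_pts[0])]
    goal = flat_ids[tuple(idx_pts[1])]
    dist, predecessors = dijkstra(
        graph, directed=False, indices=start, return_predecessors=True
    )
    if np.isinf(dist[goal]):
        raise ValidationError("no path: endpoints are disconnected in the mask")

    path = [goal]
    while path[-1] != start:
        path.append(predecessors[path[-1]])
    path.reverse()
    path_idx = coords[path]
    points = grid.index_to_world(path_idx)
    radius = dt[tuple(path_idx.T)]
    return Centerline(points=points, radius=radius)


def resample_smooth(
    line: Centerline,
    interval: float = 3.0,
    factor: float = 0.5,
    iterations: int = 100,
) -> Centerline:
    """Uniform arc-length resampling followed by pinned Laplacian relaxation.

    Resamples to segments as close as possible to ``interval`` mm, then
    applies ``p_i <- p_i + factor * ((p_(i-1) + p_(i+1))/2 - p_i)`` for the
    stated iterations with both endpoints fixed.
    """
    s = line.arc_length
    total = line.length
    if interval >= total:
        raise ValidationError(
            f"resampling interval {interval} mm >= centerline length {total:.3f} mm"
        )
    # exact-interval stations; the endpoint is kept, so the final segment
    # may be shorter than the interval
    s_new = np.arange(0.0, total, interval)
    if total - s_new[-1] > 1e-9:
        s_new = np.append(s_new, total)
    pts = np.column_stack(
        [np.interp(s_new, s, line.points[:, k]) for k in range(3)]
    )
    radius = None
    if line.radius is not None:
        radius = np.interp(s_new, s, line.radius)

    for _ in range(iterations):
        if len(pts) < 3:
            break
        avg = 0.5 * (pts[:-2] + pts[2:])
        pts[1:-1] += factor * (avg - pts[1:-1])
    return Centerline(points=pts, radius=radius, labels=dict(line.labels))


def curvature(line: Centerline) -> np.ndarray:
    """Per-point curvature in 1/m.

    Derivatives are taken with :func:`numpy.gradient` on the arc-length
    parameter (central differences in the interior, one-sided at the ends).
    Degenerate (collinear) regions return 0.
    """
    if len(line.points) < 3:
        raise ValidationError("curvature needs at least 3 points")
    s = line.arc_length
    d1 = np.gradient(line.points, s, axis=0)
    d2 = np.gradient(d1, s, axis=0)
    cross = np.cross(d1, d2)
    num = np.linalg.norm(cross, axis=1)
    den = np.linalg.norm(d1, axis=1) ** 3
    kappa_per_mm = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return kappa_per_mm * MM_PER_M


def tortuosity(line: Centerline) -> float:
    """Relative excess of arc length over the endpoint chord, L/D - 1."""
    d = float(np.linalg.norm(line.points[-1] - line.points[0]))
    if d == 0:
        raise ValidationError("tortuosity undefined: coincident endpoints")
    return line.length / d - 1.0


def bifurcation_angle(
    parent: Centerline,
    daughters: tuple[Centerline, Centerline],
    reference_point,
    tangent_length: float = 10.0,
) -> tuple[float, BifurcationSystem]:
    """Angle (degrees) between the in-plane daughter branch directions.

    Each daughter direction is the least-squares line through its first
    ``tangent_length`` mm, oriented away from the reference point; the
    bifurcation plane is spanned by the two daughter directions.
    """
    ref = np.asarray(reference_point, dtype=float)

    def initial_direction(line: Centerline) -> np.ndarray:
        s = line.arc_length
        pts = line.points[s <= s[0] + tangent_length]
        if len(pts) < 2:
            pts = line.points[:2]
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d = vt[0]
        # orient away from the reference point
        if np.dot(d, pts[-1] - ref) < 0:
            d = -d
        return _unit(d)

    d1 = initial_direction(daughters[0])
    d2 = initial_direction(daughters[1])
    normal = np.cross(d1, d2)
    if np.linalg.norm(normal) < 1e-12:
        warnings.warn("parallel daughter branches: bifurcation angle 0", stacklevel=2)
        normal = np.array([0.0, 0.0, 1.0])
        angle = 0.0
    else:
        normal = _unit(normal)
        angle = float(np.degrees(np.arccos(np.clip(np.dot(d1, d2), -1.0, 1.0))))

    s = parent.arc_length
    tail = parent.points[s >= s[-1] - tangent_length]
    if len(tail) < 2:
        tail = parent.points[-2:]
    centered = tail - tail.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    p_dir = vt[0]
    if np.dot(p_dir, ref - parent.points[0]) < 0:
        p_dir = -p_dir

    system = BifurcationSystem(
        reference_point=ref,
        parent_direction=_unit(p_dir),
        daughter_directions=(d1, d2),
        bifurcation_plane_normal=normal,
    )
    return angle, system


def dissected_radius(radius_true, radius_false) -> np.ndarray:
    """Effective radius of a dissected lumen: true + false lumen radii."""
    a = np.asarray(radius_true, dtype=float)
    b = np.asarray(radius_false, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("radius series must have equal length")
    return a + b


# ---------------------------------------------------------------------------
# CSV exchange
# ---------------------------------------------------------------------------

def write_centerline_csv(line: Centerline, path) -> None:
    import pandas as pd

    s = line.arc_length
    index_labels = {v: k for k, v in line.labels.items()}
    df = pd.DataFrame(
        {
            "x_mm": line.points[:, 0],
            "y_mm": line.points[:, 1],
            "z_mm": line.points[:, 2],
            "arclength_mm": s,
            "radius_mm": line.radius if line.radius is not None else np.nan,
            "label": [index_labels.get(i, "") for i in range(len(line.points))],
        }
    )
    df.to_csv(path, index=False)


def read_centerline_csv(path) -> Centerline:
    import pandas as pd

    df = pd.read_csv(path)
    radius = None
    if "radius_mm" in df and not df["radius_mm"].isna().all():
        radius = df["radius_mm"].to_numpy()
    labels = {}
    if "label" in df:
        for i, lab in enumerate(df["label"].fillna("")):
            if lab:
                labels[str(lab)] = i
    return Centerline(
        points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(), radius=radius, labels=labels
    )
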