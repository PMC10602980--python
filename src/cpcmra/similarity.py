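"""Agreement metrics between reconstructed lumen surfaces.

Provides two-landmark rigid alignment, volumetric Dice on a common grid,
exact point-set Hausdorff distances, and the slice-wise Hausdorff protocol
(equally spaced transverse planes with a 95th-percentile summary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from cpcmra.errors import ValidationError
from cpcmra.io_volumes import VoxelGrid
from cpcmra.meshes import SurfaceModel, plane_contour_points
from cpcmra.segmentation import BinaryMask, voxelize_surface


@dataclass
class AlignmentTransform:
    """Rigid map ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValidationError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class HDReport:
    """Slice-wise Hausdorff summary."""

    per_plane_hd: np.ndarray
    hd_mean: float
    hd_sd: float
    hd_p95: float
    forward_hd: float
    backward_hd: float
    symmetric_hd: float
    n_planes_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "hd_mean_mm": self.hd_mean,
            "hd_sd_mm": self.hd_sd,
            "hd_p95_mm": self.hd_p95,
            "forward_hd_mm": self.forward_hd,
            "backward_hd_mm": self.backward_hd,
            "symmetric_hd_mm": self.symmetric_hd,
            "n_planes_evaluated": int(len(self.per_plane_hd)),
            "n_planes_skipped": int(self.n_planes_skipped),
        }


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction u onto direction v (Rodrigues)."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-14:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def align_by_landmarks(
    moving: SurfaceModel,
    fixed: SurfaceModel,
    landmark_names: tuple[str, str],
) -> tuple[AlignmentTransform, SurfaceModel]:
    """Two-point rigid alignment.

    The first landmark pair is superposed exactly; the minimal rotation
    maps the moving landmark-difference vector onto the fixed one.  Roll
    about the landmark axis is unresolvable from two points and left at 0.
    """
    for name in landmark_names:
        for surf, role in ((moving, "moving"), (fixed, "fixed")):
            if name not in surf.landmarks:
                raise ValidationError(f"missing landmark {name!r} on {role} surface")
    m0 = moving.landmarks[landmark_names[0]]
    m1 = moving.landmarks[landmark_names[1]]
    f0 = fixed.landmarks[landmark_names[0]]
    f1 = fixed.landmarks[landmark_names[1]]

    u = m1 - m0
    v = f1 - f0
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise ValidationError("landmark pairs must be distinct points")
    rotation = _rotation_between(u, v)
    translation = f0 - rotation @ m0
    transform = AlignmentTransform(rotation, translation)
    return transform, moving.transformed(rotation, translation)


def dice(a, b, resolution: float = 0.5) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Accepts two binary masks on the same grid, or two watertight surfaces
    (voxelized on one common grid covering both).  Empty-vs-empty is
    defined as 1.
    """
    if isinstance(a, BinaryMask) and isinstance(b, BinaryMask):
        if a.grid.shape != b.grid.shape or not np.allclose(
            a.grid.spacing, b.grid.spacing
        ):
            raise ValidationError("masks must share a voxel grid")
        va, vb = a.voxels, b.voxels
    elif isinstance(a, SurfaceModel) and isinstance(b, SurfaceModel):
        if resolution <= 0:
            raise ValidationError("resolution must be > 0")
        lo = np.minimum(a.bounds()[0], b.bounds()[0]) - 2 * resolution
        hi = np.maximum(a.bounds()[1], b.bounds()[1]) + 2 * resolution
        shape = np.ceil((hi - lo) / resolution).astype(int) + 1
        grid = VoxelGrid(tuple(shape), (resolution,) * 3, tuple(lo))
        va = voxelize_surface(a, resolution, grid=grid).voxels
        vb = voxelize_surface(b, resolution, grid=grid).voxels
    else:
        raise ValidationError("dice expects two masks or two surfaces")

    na, nb = int(va.sum()), int(vb.sum())
    if na + nb == 0:
        import warnings

        warnings.warn("both volumes empty: DSC defined as 1", stacklevel=2)
        return 1.0
    inter = int(np.logical_and(va, vb).sum())
    return 2.0 * inter / (na + nb)


def hausdorff_pointsets(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Exact forward, backward and symmetric Hausdorff distances."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("point sets must be non-empty")
    tree_b = cKDTree(b)
    tree_a = cKDTree(a)
    forward = float(tree_b.query(a)[0].max())
    backward = float(tree_a.query(b)[0].max())
    return forward, backward, max(forward, backward)


def slicewise_hd(
    a: SurfaceModel,
    b: SurfaceModel,
    n_planes: int = 1000,
    contour_spacing: float = 0.1,
) -> HDReport:
    """Symmetric 2D Hausdorff distance on equally spaced transverse planes.

    Planes span the shared z-extent of the (already aligned) surfaces;
    planes where either cross-section is empty are skipped and counted.
    The 95th percentile over per-plane symmetric HDs summarises the
    distribution robustly to outliers.
    """
    if n_planes < 1:
        raise ValidationError("n_planes must be >= 1")
    za0, za1 = a.bounds()[0][2], a.bounds()[1][2]
    zb0, zb1 = b.bounds()[0][2], b.bounds()[1][2]
    z_lo, z_hi = max(za0, zb0), min(za1, zb1)
    if z_hi <= z_lo:
        raise ValidationError("surfaces have no overlapping axial extent")
    # inset so end planes do not graze the caps tangentially
    span = z_hi - z_lo
    zs = np.linspace(z_lo + 1e-6 * span, z_hi - 1e-6 * span, n_planes)

    per_plane = []
    fwd = bwd = 0.0
    skipped = 0
    for z in zs:
        pa = plane_contour_points(a, z, contour_spacing)
        pb = plane_contour_points(b, z, contour_spacing)
        if len(pa) == 0 or len(pb) == 0:
            skipped += 1
            continue
        f, w, h = hausdorff_pointsets(pa[:, :2], pb[:, :2])
        per_plane.append(h)
        fwd = max(fwd, f)
        bwd = max(bwd, w)
    if not per_plane:
        raise ValidationError("all planes were empty for one of the surfaces")
    per_plane = np.asarray(per_plane)
    return HDReport(
        per_plane_hd=per_plane,
        hd_mean=float(per_plane.mean()),
        hd_sd=float(per_plane.std(ddof=1)) if len(per_plane) > 1 else 0.0,
        hd_p95=float(np.percentile(per_plane, 95)),
        forward_hd=fwd,
        backward_hd=bwd,
        symmetric_hd=max(fwd, bwd),
        n_planes_skipped=skipped,
    )


def truncate_at_landmark(surface: SurfaceModel, z: float, keep: str = "below") -> SurfaceModel:
    """Drop all triangles entirely on one side of the plane ``z = const``.

    Supports the protocol of truncating both models at a common anatomical
    landmark before slice-wise comparison.  The cut is face-granular (no
    re-meshing), so the result is open at the cut.
    """
    tri_z = surface.vertices[surface.faces][:, :, 2]
    if keep == "below":
        keep_mask = tri_z.min(axis=1) <= z
    elif keep == "above":
        keep_mask = tri_z.max(axis=1) >= z
    else:
        raise ValidationError("keep must be 'below' or 'above'")
    return SurfaceModel(
        surface.vertices.copy(), surface.faces[keep_mask], dict(surface.landmarks)
    )
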