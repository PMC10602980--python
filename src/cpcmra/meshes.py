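"""Triangulated surface models: containers, I/O, and geometric utilities.

Vertices are millimetre coordinates; faces are triangle index triples with
consistent outward orientation.  STL (ASCII and binary) and ASCII PLY are
supported for exchange.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cpcmra.errors import ValidationError


@dataclass
class SurfaceModel:
    """Closed triangulated lumen surface with optional named landmarks."""

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValidationError("face index out of range")
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}

    # -- topology -----------------------------------------------------------

    def edge_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def open_edges(self) -> list[tuple[int, int]]:
        return [e for e, c in self.edge_counts().items() if c != 2]

    def is_watertight(self) -> bool:
        if len(self.faces) == 0:
            return False
        return not self.open_edges()

    # -- geometry -----------------------------------------------------------

    def triangle_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return n

    def area(self) -> float:
        return float(0.5 * np.linalg.norm(self.triangle_normals(), axis=1).sum())

    def volume(self) -> float:
        """Enclosed volume (mm^3) by the divergence theorem; needs
        consistent outward orientation."""
        v = self.vertices
        f = self.faces
        signed = np.einsum(
            "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
        ) / 6.0
        return float(abs(signed.sum()))

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceModel":
        verts = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        lms = {
            k: np.asarray(rotation) @ v + np.asarray(translation)
            for k, v in self.landmarks.items()
        }
        return SurfaceModel(verts, self.faces.copy(), lms)

    def snap_landmark(self, name: str, point_mm) -> None:
        """Attach a landmark at the surface vertex nearest to a point."""
        d = np.linalg.norm(self.vertices - np.asarray(point_mm, dtype=float), axis=1)
        self.landmarks[name] = self.vertices[int(np.argmin(d))].copy()


# ---------------------------------------------------------------------------
# plane sections
# ---------------------------------------------------------------------------

def plane_section_segments(
    surface: SurfaceModel, z: float
) -> np.ndarray:
    """Intersect the mesh with the plane ``z = const``.

    Returns an array of segments with shape (k, 2, 3): each triangle that
    crosses the plane contributes the chord between its two edge crossings.
    """
    v = surface.vertices
    f = surface.faces
    zv = v[:, 2]
    tri_z = zv[f]  # (m, 3)
    zmin = tri_z.min(axis=1)
    zmax = tri_z.max(axis=1)
    crossing = (zmin < z) & (zmax > z)
    segments = []
    for tri in f[crossing]:
        pts = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            za, zb = zv[a], zv[b]
            if (za - z) * (zb - z) < 0:
                t = (z - za) / (zb - za)
                pts.append(v[a] + t * (v[b] - v[a]))
            elif za == z and zb == z:
                pts.extend([v[a], v[b]])
        if len(pts) >= 2:
            segments.append([pts[0], pts[1]])
    if not segments:
        return np.empty((0, 2, 3))
    return np.asarray(segments)


def plane_contour_points(
    surface: SurfaceModel, z: float, max_spacing: float = 0.1
) -> np.ndarray:
    """Densely sampled boundary points of the cross-section at ``z``.

    Every intersection chord is resampled at most ``max_spacing`` mm apart,
    making point-set distances insensitive to the tessellation.
    """
    segments = plane_section_segments(surface, z)
    if len(segments) == 0:
        return np.empty((0, 3))
    points = []
    for p0, p1 in segments:
        length = np.linalg.norm(p1 - p0)
        n = max(int(np.ceil(length / max_spacing)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        points.append(p0 + t * (p1 - p0))
    return np.vstack(points)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stl(surface: SurfaceModel, path, binary: bool = False) -> None:
    path = Path(path)
    v = surface.vertices
    f = surface.faces
    normals = surface.triangle_normals()
    norms = np.linalg.norm(normals, axis=1)
    norms[norms == 0] = 1.0
    normals = normals / norms[:, None]
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"\x00" * 80)
            fh.write(struct.pack("<I", len(f)))
            for i, tri in enumerate(f):
                fh.write(struct.pack("<3f", *normals[i]))
                for idx in tri:
                    fh.write(struct.pack("<3f", *v[idx]))
                fh.write(struct.pack("<H", 0))
    else:
        with open(path, "w") as fh:
            fh.write("solid cpcmra\n")
            for i, tri in enumerate(f):
                fh.write(f"  facet normal {normals[i][0]:.9g} {normals[i][1]:.9g} {normals[i][2]:.9g}\n")
                fh.write("    outer loop\n")
                for idx in tri:
                    fh.write(f"      vertex {v[idx][0]:.9g} {v[idx][1]:.9g} {v[idx][2]:.9g}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid cpcmra\n")


def _dedupe_vertices(tri_vertices: np.ndarray) -> SurfaceModel:
    """Build an indexed mesh from per-triangle vertex triples."""
    flat = tri_vertices.reshape(-1, 3)
    rounded = np.round(flat, 6)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return SurfaceModel(uniq, faces)


def read_stl(path) -> SurfaceModel:
    path = Path(path)
    raw = path.read_bytes()
    is_ascii = raw.lstrip()[:5] == b"solid" and b"facet" in raw[:1000]
    if is_ascii:
        verts = []
        for line in raw.decode().splitlines():
            line = line.strip()
            if line.startswith("vertex"):
                verts.append([float(x) for x in line.split()[1:4]])
        tri = np.asarray(verts).reshape(-1, 3, 3)
    else:
        (n,) = struct.unpack_from("<I", raw, 80)
        data = np.frombuffer(raw, dtype=np.uint8, count=n * 50, offset=84)
        data = data.reshape(n, 50)
        floats = data[:, :48].copy().view("<f4").reshape(n, 4, 3)
        tri = floats[:, 1:4].astype(float)
    return _dedupe_vertices(tri)


def write_ply(surface: SurfaceModel, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(surface.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(surface.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in surface.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in surface.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path) -> SurfaceModel:
    lines = Path(path).read_text().splitlines()
    n_vert = n_face = 0
    i = 0
    while lines[i].strip() != "end_header":
        parts = lines[i].split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        i += 1
    i += 1
    verts = np.asarray(
        [[float(x) for x in lines[i + k].split()[:3]] for k in range(n_vert)]
    )
    faces = np.asarray(
        [[int(x) for x in lines[i + n_vert + k].split()[1:4]] for k in range(n_face)]
    )
    return SurfaceModel(verts, faces)


# ---------------------------------------------------------------------------
# parametric generators (analytic ground-truth surfaces)
# ---------------------------------------------------------------------------

def cylinder_mesh(
    radius: float,
    length: float,
    center: np.ndarray | tuple = (0.0, 0.0, 0.0),
    axis: str = "z",
    n_theta: int = 128,
    n_axial: int = 32,
) -> SurfaceModel:
    """Watertight capped cylinder aligned with a coordinate axis."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    h = np.linspace(-length / 2, length / 2, n_axial + 1)
    ring = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)

    verts = []
    for z in h:
        verts.append(np.column_stack([ring, np.full(n_theta, z)]))
    verts = np.vstack(verts)
    faces = []
    for i in range(n_axial):
        base0 = i * n_theta
        base1 = (i + 1) * n_theta
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            faces.append([base0 + j, base0 + j1, base1 + j])
            faces.append([base0 + j1, base1 + j1, base1 + j])
    # caps: fan to centre points (outward orientation)
    c_bot = len(verts)
    c_top = len(verts) + 1
    verts = np.vstack([verts, [[0, 0, h[0]], [0, 0, h[-1]]]])
    top0 = n_axial * n_theta
    for j in range(n_theta):
        j1 = (j + 1) % n_theta
        faces.append([c_bot, j1, j])
        faces.append([c_top, top0 + j, top0 + j1])
    verts = np.asarray(verts, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)

    order = {"x": (2, 1, 0), "y": (0, 2, 1), "z": (0, 1, 2)}[axis]
    verts = verts[:, order]
    if axis == "x":  # odd permutation: flip one pair to keep orientation
        faces = faces[:, [0, 2, 1]]
    elif axis == "y":
        faces = faces[:, [0, 2, 1]]
    verts = verts + np.asarray(center, dtype=float)
    return SurfaceModel(verts, faces)


def torus_segment_mesh(
    bend_radius: float,
    tube_radius: float,
    sweep_deg: float = 90.0,
    center: np.ndarray | tuple = (0.0, 0.0, 0.0),
    n_sweep: int = 64,
    n_theta: int = 64,
) -> SurfaceModel:
    """Watertight capped tube following a circular arc in the x-z plane.

    The arc lies in the plane y = 0, centred at ``center``, starting at
    angle 0 (point ``center + (bend_radius, 0, 0)``) and sweeping towards
    +z.
    """
    phi = np.radians(np.linspace(0.0, sweep_deg, n_sweep + 1))
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    verts = []
    for p in phi:
        # local frame: radial direction in x-z plane, binormal y
        cx = np.array([np.cos(p), 0.0, np.sin(p)])
        axis_pt = np.asarray(center) + bend_radius * cx
        ring = (
            axis_pt
            + tube_radius * np.outer(np.cos(theta), cx)
            + tube_radius * np.outer(np.sin(theta), np.array([0.0, 1.0, 0.0]))
        )
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for i in range(n_sweep):
        base0 = i * n_theta
        base1 = (i + 1) * n_theta
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            faces.append([base0 + j, base1 + j, base0 + j1])
            faces.append([base0 + j1, base1 + j, base1 + j1])
    c0 = len(verts)
    c1 = len(verts) + 1
    axis0 = np.asarray(center) + bend_radius * np.array([1.0, 0.0, 0.0])
    p_end = phi[-1]
    axis1 = np.asarray(center) + bend_radius * np.array(
        [np.cos(p_end), 0.0, np.sin(p_end)]
    )
    verts = np.vstack([verts, [axis0, axis1]])
    last = n_sweep * n_theta
    for j in range(n_theta):
        j1 = (j + 1) % n_theta
        faces.append([c0, j, j1])
        faces.append([c1, last + j1, last + j])
    return SurfaceModel(np.asarray(verts), np.asarray(faces, dtype=np.int64))
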