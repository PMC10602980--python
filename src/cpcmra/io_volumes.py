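"""Volumetric data containers and I/O for time-resolved velocity-encoded MRI.

Conventions
-----------
* World coordinates are millimetres in a right-handed patient-based LPS
  frame.  Volumes are indexed ``[ix, iy, iz]``; voxel centre ``i`` sits at
  ``origin + i * spacing``.  Samples outside the grid evaluate to 0.
* ``transverse`` slices are fixed-z, ``coronal`` fixed-y, ``sagittal``
  fixed-x.
* Velocity is stored internally as signed m/s components.  Sources that
  store integer phase are rescaled at read time (``v = p / 4096 * venc``)
  and never persisted as phase.

Supported containers: NIfTI-1 (via nibabel, with a JSON sidecar for
VENC / period / frame times), a minimal explicit-VR little-endian DICOM
series dialect (see :mod:`cpcmra._dicom`), and a write-only PNG preview.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from cpcmra.errors import (
    GridMismatchError,
    IncompleteDatasetError,
    ValidationError,
)

PLANES = ("transverse", "coronal", "sagittal")

#: axis held fixed by each slicing plane (index into x, y, z)
PLANE_NORMAL_AXIS = {"transverse": 2, "coronal": 1, "sagittal": 0}

#: integer full-scale used by phase-encoded velocity sources
PHASE_FULL_SCALE = 4096

_CHANNELS = ("magnitude", "vx", "vy", "vz")


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D sampling grid in patient (LPS) millimetre coordinates."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: str = "LPS"

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValidationError(f"shape components must be >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent(self) -> np.ndarray:
        """Physical size (mm) spanned by voxel centres along each axis."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points (mm)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class Flow4DDataset:
    """One cardiac cycle of magnitude + three velocity-component volumes.

    ``magnitude`` has shape ``(n_frames, nx, ny, nz)``; ``velocity`` has
    shape ``(n_frames, 3, nx, ny, nz)`` in m/s.  Velocity components are
    clipped to ``[-venc, venc]`` on construction.
    """

    grid: VoxelGrid
    frame_times: np.ndarray
    period_T: float
    magnitude: np.ndarray
    velocity: np.ndarray
    venc: float

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        n = self.n_frames
        if self.frame_times.ndim != 1 or n < 1:
            raise ValidationError("frame_times must be a non-empty 1D array")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if np.any(self.frame_times < 0) or np.any(self.frame_times >= self.period_T):
            raise ValidationError("frame_times must lie in [0, period_T)")
        if self.magnitude.shape != (n, *self.grid.shape):
            raise GridMismatchError(
                f"magnitude shape {self.magnitude.shape} != (n_frames, *grid.shape)"
            )
        if self.velocity.shape != (n, 3, *self.grid.shape):
            raise GridMismatchError(
                f"velocity shape {self.velocity.shape} != (n_frames, 3, *grid.shape)"
            )
        if np.any(self.magnitude < 0):
            raise ValidationError("magnitude must be non-negative")
        if self.venc <= 0:
            raise ValidationError("venc must be positive")
        np.clip(self.velocity, -self.venc, self.venc, out=self.velocity)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


@dataclass
class ImageStack:
    """Stack of parallel 2D slices in one anatomical plane.

    ``pixels`` has shape ``(n_slices, n_u, n_v)`` where (u, v) are the two
    in-plane axes in ascending world-axis order: (x, y) for transverse,
    (x, z) for coronal, (y, z) for sagittal.  ``origin`` is the world
    position (mm) of pixel (0, 0) of slice 0.
    """

    plane: str
    pixels: np.ndarray
    slice_gap: float
    in_plane_spacing: tuple[float, float]
    I_max: float = 4095.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    above_threshold: np.ndarray | None = None

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValidationError(
                f"unknown plane {self.plane!r}; expected one of {PLANES}"
            )
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ValidationError("pixels must be (n_slices >= 1, n_u, n_v)")
        if self.slice_gap <= 0:
            raise ValidationError("slice_gap must be > 0")
        if any(s <= 0 for s in self.in_plane_spacing):
            raise ValidationError("in_plane_spacing must be > 0")
        if np.any(self.pixels < 0) or np.any(self.pixels > self.I_max):
            raise ValidationError("intensities must lie in [0, I_max]")

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]

    def to_grid(self) -> VoxelGrid:
        """The 3D voxel grid the stack samples (slice normal included)."""
        axis = PLANE_NORMAL_AXIS[self.plane]
        n_u, n_v = self.pixels.shape[1], self.pixels.shape[2]
        shape = [0, 0, 0]
        spacing = [0.0, 0.0, 0.0]
        in_plane = [a for a in range(3) if a != axis]
        shape[in_plane[0]], shape[in_plane[1]] = n_u, n_v
        shape[axis] = self.n_slices
        spacing[in_plane[0]], spacing[in_plane[1]] = self.in_plane_spacing
        spacing[axis] = self.slice_gap
        return VoxelGrid(tuple(shape), tuple(spacing), tuple(self.origin))

    def to_volume(self) -> np.ndarray:
        """Reassemble pixels into an (nx, ny, nz) volume on :meth:`to_grid`."""
        axis = PLANE_NORMAL_AXIS[self.plane]
        # pixels is (slice, u, v); move the slice axis into its world slot
        return np.moveaxis(self.pixels, 0, axis)


def sample_volume(volume: np.ndarray, grid: VoxelGrid, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of a scalar volume at world points; outside -> 0."""
    idx = grid.world_to_index(points_mm)
    return map_coordinates(
        np.asarray(volume, dtype=float), idx.T, order=1, mode="constant", cval=0.0
    )


def reslice(
    volume: np.ndarray,
    grid: VoxelGrid,
    plane: str,
    n_slices: int,
    slice_gap: float,
    I_max: float | None = None,
) -> ImageStack:
    """Resample a volume into parallel slices along an anatomical plane.

    Slice ``i`` is sampled at offset ``i * slice_gap`` (mm) from the grid
    origin along the plane normal, by trilinear interpolation; in-plane
    sampling is at the native spacing.
    """
    if plane not in PLANES:
        raise ValidationError(f"unknown plane {plane!r}; expected one of {PLANES}")
    if n_slices < 1:
        raise ValidationError("n_slices must be >= 1")
    if slice_gap <= 0:
        raise ValidationError("slice_gap must be > 0")
    volume = np.asarray(volume, dtype=float)
    if volume.shape != grid.shape:
        raise GridMismatchError(f"volume shape {volume.shape} != grid shape {grid.shape}")

    axis = PLANE_NORMAL_AXIS[plane]
    extent = grid.extent[axis]
    if (n_slices - 1) * slice_gap > extent + 1e-9:
        warnings.warn(
            f"requested stack extent {(n_slices - 1) * slice_gap:.3f} mm exceeds the "
            f"volume extent {extent:.3f} mm along the {plane} normal; "
            "out-of-volume slices sample 0",
            stacklevel=2,
        )

    in_plane = [a for a in range(3) if a != axis]
    n_u, n_v = grid.shape[in_plane[0]], grid.shape[in_plane[1]]

    # continuous index coordinates: native in-plane, gap-spaced along normal
    coords = np.empty((3, n_slices, n_u, n_v), dtype=float)
    w = np.arange(n_slices) * slice_gap / grid.spacing[axis]
    u = np.arange(n_u, dtype=float)
    v = np.arange(n_v, dtype=float)
    W, U, V = np.meshgrid(w, u, v, indexing="ij")
    coords[axis] = W
    coords[in_plane[0]] = U
    coords[in_plane[1]] = V

    pixels = map_coordinates(volume, coords, order=1, mode="constant", cval=0.0)
    return ImageStack(
        plane=plane,
        pixels=pixels,
        slice_gap=float(slice_gap),
        in_plane_spacing=(grid.spacing[in_plane[0]], grid.spacing[in_plane[1]]),
        I_max=float(I_max) if I_max is not None else max(float(pixels.max()), 1.0),
        origin=grid.origin,
    )


# ---------------------------------------------------------------------------
# Flow4DDataset read / write
# ---------------------------------------------------------------------------

def write_flow4d(dataset: Flow4DDataset, path, format: str = "nifti") -> None:
    """Write a dataset as NIfTI volumes or a DICOM series plus JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "venc_m_per_s": dataset.venc,
        "period_T_s": dataset.period_T,
        "frame_times_s": dataset.frame_times.tolist(),
        "spacing_mm": list(dataset.grid.spacing),
        "origin_mm": list(dataset.grid.origin),
    }
    (path / "flow4d.json").write_text(json.dumps(sidecar, indent=2))

    if format == "nifti":
        import nibabel as nib

        affine = np.diag([*dataset.grid.spacing, 1.0])
        affine[:3, 3] = dataset.grid.origin
        channels = {
            "magnitude": dataset.magnitude,
            "vx": dataset.velocity[:, 0],
            "vy": dataset.velocity[:, 1],
            "vz": dataset.velocity[:, 2],
        }
        for name, data in channels.items():
            # nibabel wants (nx, ny, nz, t)
            img = nib.Nifti1Image(np.moveaxis(data, 0, -1).astype(np.float32), affine)
            nib.save(img, str(path / f"{name}.nii"))
    elif format == "dicom-series":
        from cpcmra import _dicom

        for name in _CHANNELS:
            for f in range(dataset.n_frames):
                if name == "magnitude":
                    vol = dataset.magnitude[f]
                    arr = np.clip(np.round(vol), 0, 65535).astype(np.uint16)
                else:
                    comp = "xyz".index(name[1])
                    vol = dataset.velocity[f, comp]
                    phase = np.round(vol / dataset.venc * PHASE_FULL_SCALE)
                    arr = np.clip(phase, -PHASE_FULL_SCALE, PHASE_FULL_SCALE - 1).astype(np.int16)
                _dicom.write_series(
                    path / name / f"frame{f:03d}",
                    arr,
                    spacing=dataset.grid.spacing,
                    origin=dataset.grid.origin,
                    trigger_time_ms=dataset.frame_times[f] * 1000.0,
                )
    else:
        raise ValidationError(f"unknown flow4d format {format!r}")


def read_flow4d(path, format: str = "nifti") -> Flow4DDataset:
    """Read a dataset written by :func:`write_flow4d`.

    For ``dicom-series`` input the four channels live in subdirectories
    ``magnitude/``, ``vx/``, ``vy/``, ``vz/``; velocity channels store
    signed integer phase which is rescaled to m/s via the sidecar VENC
    (``v = p / 4096 * venc``).
    """
    path = Path(path)
    sidecar_file = path / "flow4d.json"
    if not sidecar_file.exists():
        raise FileNotFoundError(f"no flow4d.json sidecar under {path}")
    meta = json.loads(sidecar_file.read_text())
    venc = float(meta["venc_m_per_s"])
    frame_times = np.asarray(meta["frame_times_s"], dtype=float)

    if format == "nifti":
        import nibabel as nib

        volumes = {}
        for name in _CHANNELS:
            f = path / f"{name}.nii"
            if not f.exists():
                raise IncompleteDatasetError(name)
            img = nib.load(str(f))
            volumes[name] = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        spacing = tuple(meta["spacing_mm"])
        origin = tuple(meta["origin_mm"])
    elif format == "dicom-series":
        from cpcmra import _dicom

        volumes = {}
        for name in _CHANNELS:
            chan_dir = path / name
            if not chan_dir.is_dir():
                raise IncompleteDatasetError(name)
            frames, times_ms = [], []
            for frame_dir in sorted(chan_dir.iterdir()):
                arr, spacing, origin, trigger = _dicom.read_series(frame_dir)
                frames.append(arr)
                times_ms.append(trigger)
            stack = np.stack(frames, axis=0).astype(float)
            if name == "magnitude":
                volumes[name] = stack
            else:
                volumes[name] = stack / PHASE_FULL_SCALE * venc
        if len(times_ms) == len(frame_times):
            frame_times = np.asarray(times_ms, dtype=float) / 1000.0
    else:
        raise ValidationError(f"unknown flow4d format {format!r}")

    shapes = {name: v.shape for name, v in volumes.items()}
    if len(set(shapes.values())) != 1:
        raise GridMismatchError(f"channel shapes differ: {shapes}")

    mag = volumes["magnitude"]
    grid = VoxelGrid(mag.shape[1:], spacing, origin)
    velocity = np.stack([volumes["vx"], volumes["vy"], volumes["vz"]], axis=1)
    return Flow4DDataset(
        grid=grid,
        frame_times=frame_times,
        period_T=float(meta["period_T_s"]),
        magnitude=mag,
        velocity=velocity,
        venc=venc,
    )


# ---------------------------------------------------------------------------
# ImageStack read / write
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path, format: str = "nifti") -> list[Path]:
    """Write an image stack; ``png-sequence`` is a geometry-lossy preview."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "plane": stack.plane,
        "n_slices": stack.n_slices,
        "slice_gap_mm": stack.slice_gap,
        "in_plane_spacing_mm": list(stack.in_plane_spacing),
        "I_max": stack.I_max,
        "origin_mm": list(stack.origin),
    }
    (path / "stack.json").write_text(json.dumps(meta, indent=2))
    written = [path / "stack.json"]

    if format == "nifti":
        import nibabel as nib

        grid = stack.to_grid()
        affine = np.diag([*grid.spacing, 1.0])
        affine[:3, 3] = grid.origin
        img = nib.Nifti1Image(stack.to_volume().astype(np.float32), affine)
        out = path / "stack.nii"
        nib.save(img, str(out))
        written.append(out)
    elif format == "dicom-series":
        from cpcmra import _dicom

        grid = stack.to_grid()
        axis = PLANE_NORMAL_AXIS[stack.plane]
        # slice axis last; spacing/origin reordered to match, undone on read
        volume = np.moveaxis(stack.to_volume(), axis, 2)
        order = [a for a in range(3) if a != axis] + [axis]
        arr16 = np.clip(np.round(volume), 0, 65535).astype(np.uint16)
        written += _dicom.write_series(
            path / "dicom",
            arr16,
            spacing=tuple(grid.spacing[a] for a in order),
            origin=tuple(grid.origin[a] for a in order),
        )
    elif format == "png-sequence":
        import imageio.v3 as iio

        scale = 65535.0 / stack.I_max if stack.I_max > 0 else 1.0
        for i in range(stack.n_slices):
            out = path / f"slice_{i:04d}.png"
            iio.imwrite(out, np.round(stack.pixels[i] * scale).astype(np.uint16))
            written.append(out)
    else:
        raise ValidationError(f"unknown stack format {format!r}")
    return written


def read_stack(path, format: str = "nifti") -> ImageStack:
    path = Path(path)
    meta = json.loads((path / "stack.json").read_text())
    plane = meta["plane"]
    axis = PLANE_NORMAL_AXIS[plane]

    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path / "stack.nii"))
        volume = np.asarray(img.dataobj, dtype=float)
        pixels = np.moveaxis(volume, axis, 0)
    elif format == "dicom-series":
        from cpcmra import _dicom

        volume, _, _, _ = _dicom.read_series(path / "dicom")
        # slices were written along the last axis; restore world axis order
        pixels = np.moveaxis(volume.astype(float), 2, 0)
    else:
        raise ValidationError(f"unknown stack format {format!r} for reading")

    return ImageStack(
        plane=plane,
        pixels=pixels,
        slice_gap=float(meta["slice_gap_mm"]),
        in_plane_spacing=tuple(meta["in_plane_spacing_mm"]),
        I_max=float(meta["I_max"]),
        origin=tuple(meta["origin_mm"]),
    )
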