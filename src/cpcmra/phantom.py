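"""Synthetic pulsatile 4D flow datasets with analytic ground truth.

Phantoms are tubes (straight, torus bend, or Y bifurcation) carrying an
axial parabolic velocity profile ``u(r, t) = 2 U(t - lag(s)) (1 - (r/R)^2)``
with a systolic-dominated waveform, a low-contrast two-level magnitude
background with Rician noise, and Gaussian noise on velocity components.
All randomness is drawn from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cpcmra.centerline import Centerline
from cpcmra.errors import ValidationError
from cpcmra.hemodynamics import FlowWaveform, FluidProperties, WSSField
from cpcmra.io_volumes import Flow4DDataset, VoxelGrid
from cpcmra.meshes import SurfaceModel, cylinder_mesh, torus_segment_mesh

DEFAULT_I_MAX = 4095.0
SHAPES = ("straight-tube", "torus-bend", "y-bifurcation")
WAVEFORMS = ("systolic", "constant", "sinusoid")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic 4D flow phantom."""

    shape: str = "straight-tube"
    tube_radius: float = 6.0  # mm
    bend_radius: float = 50.0  # mm (torus)
    bifurcation_angle: float = 60.0  # degrees (Y)
    grid: VoxelGrid = field(
        default_factory=lambda: VoxelGrid((40, 40, 40), (2.0, 2.0, 2.0))
    )
    n_frames: int = 20
    period_T: float = 1.0
    waveform: str = "systolic"
    peak_frame: int = 5
    peak_velocity: float = 0.8  # m/s, spatial-mean velocity at the peak
    venc: float = 1.5  # m/s
    noise_sigma: float = 0.0  # fraction of I_max (Rician) / of venc (velocity)
    distal_lag: float = 0.0  # frames of pulse delay at the distal end
    seed: int = 0

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValidationError(f"unknown phantom shape {self.shape!r}")
        if self.waveform not in WAVEFORMS:
            raise ValidationError(f"unknown waveform {self.waveform!r}")
        if self.peak_velocity > self.venc:
            raise ValidationError("peak mean velocity must not exceed venc")
        if self.tube_radius <= 0:
            raise ValidationError("tube_radius must be > 0")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.period_T / self.n_frames

    def mean_velocity(self, t) -> np.ndarray:
        """Spatial-mean axial velocity waveform U(t), m/s (periodic)."""
        t = np.asarray(t, dtype=float)
        T = self.period_T
        t_peak = self.peak_frame * T / self.n_frames
        if self.waveform == "constant":
            return np.full_like(t, self.peak_velocity)
        if self.waveform == "sinusoid":
            return self.peak_velocity * np.sin(2 * np.pi * (t - t_peak) / T + np.pi / 2)
        base = 0.05 * self.peak_velocity
        width = 0.12 * T
        # wrapped Gaussian bump: systolic pulse, small diastolic base
        dt = (t - t_peak + T / 2) % T - T / 2
        return base + (self.peak_velocity - base) * np.exp(-((dt / width) ** 2))


@dataclass
class PhantomTruth:
    """Analytic ground truth matching a :class:`PhantomSpec`."""

    surface: SurfaceModel
    centerline: Centerline
    radius: float  # mm
    curvature: float  # 1/m
    bifurcation_angle: float | None
    waveform: FlowWaveform
    wall_shear: np.ndarray  # Pa per frame (straight tube, Poiseuille)


def _grid_points(grid: VoxelGrid):
    x = grid.origin[0] + np.arange(grid.shape[0]) * grid.spacing[0]
    y = grid.origin[1] + np.arange(grid.shape[1]) * grid.spacing[1]
    z = grid.origin[2] + np.arange(grid.shape[2]) * grid.spacing[2]
    return np.meshgrid(x, y, z, indexing="ij")


def _geometry_fields(spec: PhantomSpec):
    """Per-voxel (distance to axis, axial unit direction, arc coordinate s,
    velocity scale) plus metadata about the axis."""
    grid = spec.grid
    X, Y, Z = _grid_points(grid)
    center = np.asarray(grid.origin) + grid.extent / 2.0
    R = spec.tube_radius

    if spec.shape == "straight-tube":
        d = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2)
        s = Z - grid.origin[2]
        dirs = np.zeros((*grid.shape, 3))
        dirs[..., 2] = 1.0
        scale = np.ones(grid.shape)
        z0, z1 = grid.origin[2], grid.origin[2] + grid.extent[2]
        axis_pts = np.column_stack(
            [
                np.full(50, center[0]),
                np.full(50, center[1]),
                np.linspace(z0, z1, 50),
            ]
        )
        extras = {"s_max": grid.extent[2], "length": grid.extent[2], "center": center}
        return d, dirs, s, scale, axis_pts, extras

    if spec.shape == "torus-bend":
        Rb = spec.bend_radius
        # arc centre placed so the quarter arc spans the grid interior
        c = center - np.array([Rb / np.sqrt(2), 0.0, Rb / np.sqrt(2)])
        rho = np.sqrt((X - c[0]) ** 2 + (Z - c[2]) ** 2)
        phi = np.arctan2(Z - c[2], X - c[0])
        d = np.sqrt((rho - Rb) ** 2 + (Y - c[1]) ** 2)
        d = np.where((phi >= 0) & (phi <= np.pi / 2), d, np.inf)
        s = Rb * np.clip(phi, 0, np.pi / 2)
        dirs = np.zeros((*grid.shape, 3))
        dirs[..., 0] = -np.sin(phi)
        dirs[..., 2] = np.cos(phi)
        scale = np.ones(grid.shape)
        phis = np.linspace(0, np.pi / 2, 100)
        axis_pts = c + Rb * np.column_stack(
            [np.cos(phis), np.zeros_like(phis), np.sin(phis)]
        )
        extras = {"s_max": Rb * np.pi / 2, "arc_center": c}
        return d, dirs, s, scale, axis_pts, extras

    # y-bifurcation: parent along +z up to the branch point, two daughters
    half = np.radians(spec.bifurcation_angle / 2.0)
    z0 = grid.origin[2]
    branch_z = center[2]
    branch = np.array([center[0], center[1], branch_z])
    d_parent = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2)
    d_parent = np.where(Z <= branch_z, d_parent, np.inf)

    dir1 = np.array([np.sin(half), 0.0, np.cos(half)])
    dir2 = np.array([-np.sin(half), 0.0, np.cos(half)])
    P = np.stack([X - branch[0], Y - branch[1], Z - branch[2]], axis=-1)

    def seg_dist(direction):
        proj = P @ direction
        proj_c = np.clip(proj, 0.0, None)
        closest = proj_c[..., None] * direction
        dd = np.linalg.norm(P - closest, axis=-1)
        return np.where(proj >= 0, dd, np.inf), proj_c

    d1, s1 = seg_dist(dir1)
    d2, s2 = seg_dist(dir2)

    d = np.minimum(d_parent, np.minimum(d1, d2))
    dirs = np.zeros((*grid.shape, 3))
    dirs[..., 2] = 1.0
    use1 = (d1 <= d2) & (d1 < d_parent)
    use2 = (d2 < d1) & (d2 < d_parent)
    for k in range(3):
        dirs[..., k] = np.where(use1, dir1[k], dirs[..., k])
        dirs[..., k] = np.where(use2, dir2[k], dirs[..., k])
    s = np.where(Z <= branch_z, Z - z0, (branch_z - z0) + np.where(use1, s1, s2))
    # mass conservation: each daughter carries half the parent flow
    scale = np.where(use1 | use2, 0.5, 1.0)
    axis_pts = np.column_stack(
        [
            np.full(50, center[0]),
            np.full(50, center[1]),
            np.linspace(z0, branch_z, 50),
        ]
    )
    extras = {
        "s_max": (branch_z - z0) + grid.extent[2] / 2,
        "branch_point": branch,
        "daughter_dirs": (dir1, dir2),
    }
    return d, dirs, s, scale, axis_pts, extras


def make_phantom(spec: PhantomSpec) -> tuple[Flow4DDataset, PhantomTruth]:
    """Generate the dataset and its analytic ground truth."""
    grid = spec.grid
    R = spec.tube_radius
    d, dirs, s, scale, axis_pts, extras = _geometry_fields(spec)
    if np.isfinite(d).any() and d[np.isfinite(d)].min() > R:
        raise ValidationError("tube does not intersect the voxel grid")
    lo, hi = np.array(grid.origin), np.array(grid.origin) + grid.extent
    near_axis = axis_pts[((axis_pts >= lo - R) & (axis_pts <= hi + R)).all(axis=1)]
    if len(near_axis) < len(axis_pts):
        raise ValidationError("phantom geometry exceeds the voxel grid")

    inside = d <= R
    profile = np.where(inside, 2.0 * (1.0 - (np.minimum(d, R) / R) ** 2), 0.0)

    rng = np.random.default_rng(spec.seed)
    frame_dt = spec.period_T / spec.n_frames
    lag = spec.distal_lag * frame_dt * (s / extras["s_max"])

    n = spec.n_frames
    velocity = np.zeros((n, 3, *grid.shape))
    magnitude = np.zeros((n, *grid.shape))

    # low-contrast two-level background (arbitrary units)
    X, Y, Z = _grid_points(grid)
    background = np.where(Y < np.median(Y), 0.15, 0.22) * DEFAULT_I_MAX

    sigma_v = spec.noise_sigma * spec.venc
    sigma_m = spec.noise_sigma * DEFAULT_I_MAX
    for f, t in enumerate(spec.frame_times):
        U = spec.mean_velocity(t - lag) * scale
        u = profile * U
        for k in range(3):
            velocity[f, k] = dirs[..., k] * u
        if sigma_v > 0:
            velocity[f] += rng.normal(0.0, sigma_v, size=(3, *grid.shape))
        mag = background.copy()
        if sigma_m > 0:
            mag = np.sqrt(
                (mag + rng.normal(0.0, sigma_m, size=grid.shape)) ** 2
                + rng.normal(0.0, sigma_m, size=grid.shape) ** 2
            )
        magnitude[f] = mag

    dataset = Flow4DDataset(
        grid=grid,
        frame_times=spec.frame_times,
        period_T=spec.period_T,
        magnitude=magnitude,
        velocity=velocity,
        venc=spec.venc,
    )

    truth = _make_truth(spec, axis_pts, extras)
    return dataset, truth


def _make_truth(spec: PhantomSpec, axis_pts: np.ndarray, extras: dict) -> PhantomTruth:
    grid = spec.grid
    R = spec.tube_radius

    if spec.shape == "straight-tube":
        center = extras["center"]
        surface = cylinder_mesh(
            R, extras["length"], center=(center[0], center[1], center[2]), axis="z"
        )
        kappa = 0.0
        angle = None
    elif spec.shape == "torus-bend":
        surface = torus_segment_mesh(
            spec.bend_radius, R, sweep_deg=90.0, center=tuple(extras["arc_center"])
        )
        kappa = 1000.0 / spec.bend_radius  # mm -> 1/m
        angle = None
    else:
        # Y: indicator-function iso-surface on a fine grid
        from cpcmra.segmentation import BinaryMask, mask_to_surface

        fine = VoxelGrid(
            tuple(np.maximum(np.asarray(grid.shape) * 2, 2)),
            tuple(np.asarray(grid.spacing) / 2.0),
            grid.origin,
        )
        fine_spec = PhantomSpec(
            shape=spec.shape,
            tube_radius=spec.tube_radius,
            bifurcation_angle=spec.bifurcation_angle,
            grid=fine,
            n_frames=spec.n_frames,
            peak_velocity=spec.peak_velocity,
            venc=spec.venc,
        )
        d, _, _, _, _, _ = _geometry_fields(fine_spec)
        mask = BinaryMask(fine, d <= R)
        surface = mask_to_surface(mask, smoothing_iterations=0)
        kappa = 0.0
        angle = spec.bifurcation_angle

    centerline = Centerline(points=axis_pts, radius=np.full(len(axis_pts), R))

    t = spec.frame_times
    U = spec.mean_velocity(t)
    area_m2 = np.pi * (R * 1e-3) ** 2
    q = U * area_m2
    from scipy.interpolate import CubicSpline

    spline = CubicSpline(t, q, bc_type="natural")
    t_dense = np.arange(t[0], t[-1] + 5e-4, 1e-3)
    waveform = FlowWaveform(
        times=t,
        q_mean=q,
        q_sd=np.zeros_like(q),
        interp_times=t_dense,
        interp_q=spline(t_dense),
    )

    mu = FluidProperties().dynamic_viscosity
    wall_shear = 4.0 * mu * q / (np.pi * (R * 1e-3) ** 3)

    return PhantomTruth(
        surface=surface,
        centerline=centerline,
        radius=R,
        curvature=kappa,
        bifurcation_angle=angle,
        waveform=waveform,
        wall_shear=wall_shear,
    )


def phantom_wss(
    spec: PhantomSpec,
    n_theta: int = 24,
    n_axial: int = 16,
    fluid: FluidProperties | None = None,
) -> WSSField:
    """Closed-form Poiseuille wall shear field on the straight-tube wall.

    Elements tile the cylinder wall; each carries an axial shear vector of
    magnitude ``4 mu Q(t) / (pi R^3)`` signed by the flow direction.
    """
    if spec.shape != "straight-tube":
        raise ValidationError("closed form unavailable for non-straight phantoms")
    fluid = fluid or FluidProperties()
    R_m = spec.tube_radius * 1e-3
    length = spec.grid.extent[2]

    t = spec.frame_times
    q = spec.mean_velocity(t) * np.pi * R_m**2
    tau_mag = 4.0 * fluid.dynamic_viscosity * q / (np.pi * R_m**3)

    n_el = n_theta * n_axial
    area = (2 * np.pi * spec.tube_radius / n_theta) * (length / n_axial)  # mm^2
    tau = np.zeros((n_el, len(t), 3))
    tau[:, :, 2] = tau_mag[None, :]
    return WSSField(
        element_ids=np.arange(n_el),
        element_areas=np.full(n_el, area),
        times=t,
        tau=tau,
        period_T=spec.period_T,
    )
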