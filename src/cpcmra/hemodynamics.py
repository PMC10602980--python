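"""Hemodynamic post-processing of wall-shear-stress and velocity data.

Time-averaged wall shear stress (TAWSS) and the oscillatory shear index
(OSI) are computed per surface element over one cardiac cycle:

    TAWSS = (1/T) * integral_0^T |tau(t)| dt
    OSI   = 1/2 * (1 - |integral_0^T tau(t) dt| / integral_0^T |tau(t)| dt)

Integrals use the trapezoid rule on the sampled times; if the export does
not duplicate the cycle endpoint, the cycle is closed by wrapping the
first sample to t = T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from cpcmra.errors import ValidationError


@dataclass
class FluidProperties:
    """Newtonian blood properties."""

    density: float = 1060.0  # kg/m^3
    dynamic_viscosity: float = 0.004  # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValidationError("fluid properties must be positive")


@dataclass
class WSSField:
    """Per-element wall-shear-stress vector time series over one cycle."""

    element_ids: np.ndarray  # (n,)
    element_areas: np.ndarray  # (n,) mm^2
    times: np.ndarray  # (m,) s in [0, T]
    tau: np.ndarray  # (n, m, 3) Pa
    period_T: float

    def __post_init__(self):
        self.element_ids = np.asarray(self.element_ids)
        self.element_areas = np.asarray(self.element_areas, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] > self.period_T + 1e-12:
            raise ValidationError("times must span [0, T]")
        if np.any(self.element_areas <= 0):
            raise ValidationError("element areas must be > 0")
        n, m = len(self.element_ids), len(self.times)
        if self.tau.shape != (n, m, 3):
            raise ValidationError(f"tau shape {self.tau.shape} != (n, m, 3)")

    def closed_cycle(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and tau with periodic closure at t = T."""
        if np.isclose(self.times[-1], self.period_T):
            return self.times, self.tau
        t = np.concatenate([self.times, [self.period_T]])
        tau = np.concatenate([self.tau, self.tau[:, :1, :]], axis=1)
        return t, tau


@dataclass
class FlowWaveform:
    """Cross-sectional flow rate over one cycle, raw and densely interpolated."""

    times: np.ndarray  # s
    q_mean: np.ndarray  # m^3/s, mean over analysis planes
    q_sd: np.ndarray  # m^3/s
    interp_times: np.ndarray  # s at dt = 0.001
    interp_q: np.ndarray  # m^3/s

    def peak_flow(self) -> float:
        return float(self.interp_q.max())


def tawss(field: WSSField) -> np.ndarray:
    """Time-averaged magnitude of the wall shear stress vector, per element."""
    if len(field.times) < 2:
        raise ValidationError("need at least 2 time samples")
    t, tau = field.closed_cycle()
    mag = np.linalg.norm(tau, axis=2)
    return np.trapezoid(mag, t, axis=1) / field.period_T


def osi(field: WSSField) -> np.ndarray:
    """Oscillatory shear index in [0, 0.5], per element.

    Elements with zero integrated shear magnitude are defined as OSI 0.
    """
    if len(field.times) < 2:
        raise ValidationError("need at least 2 time samples")
    t, tau = field.closed_cycle()
    mag_int = np.trapezoid(np.linalg.norm(tau, axis=2), t, axis=1)
    vec_int = np.linalg.norm(np.trapezoid(tau, t, axis=1), axis=1)
    ratio = np.divide(
        vec_int, mag_int, out=np.ones_like(vec_int), where=mag_int > 0
    )
    return 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))


def extreme_regions(
    values: np.ndarray,
    element_ids: np.ndarray | None = None,
    fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Elements in the upper and lower ``fraction`` tails by count.

    Quantiles are computed over element counts (not area weighted); ties at
    the cut value are included, so a subset may exceed the nominal count.
    Returns (upper ids, lower ids).
    """
    if not (0 < fraction < 0.5):
        raise ValidationError("fraction must lie in (0, 0.5)")
    values = np.asarray(values, dtype=float)
    if element_ids is None:
        element_ids = np.arange(len(values))
    element_ids = np.asarray(element_ids)
    hi = np.quantile(values, 1 - fraction)
    lo = np.quantile(values, fraction)
    upper = element_ids[values >= hi]
    lower = element_ids[values <= lo]
    if len(upper) == len(values) and len(lower) == len(values):
        warnings.warn("all values equal: extreme subsets cover all elements", stacklevel=2)
    return upper, lower


def flow_waveform(
    dataset,
    plane_positions_mm,
    lumen_mask,
    dt: float = 0.001,
) -> FlowWaveform:
    """Flow-rate waveform from through-plane velocity on transverse planes.

    For each frame and each plane, the flow rate is the sum of the
    through-plane (z) velocity times pixel area over lumen pixels; the mean
    and sd across planes are interpolated to ``dt`` with a natural cubic
    spline.
    """
    from cpcmra.io_volumes import Flow4DDataset  # local import avoids cycle

    assert isinstance(dataset, Flow4DDataset)
    grid = dataset.grid
    voxels = lumen_mask.voxels
    pixel_area_m2 = (grid.spacing[0] * 1e-3) * (grid.spacing[1] * 1e-3)

    plane_indices = []
    for z in plane_positions_mm:
        k = int(np.round((z - grid.origin[2]) / grid.spacing[2]))
        if not (0 <= k < grid.shape[2]) or not voxels[:, :, k].any():
            raise ValidationError(f"plane z = {z} mm does not intersect the lumen")
        plane_indices.append(k)

    n_frames = dataset.n_frames
    q = np.zeros((n_frames, len(plane_indices)))
    for f in range(n_frames):
        vz = dataset.velocity[f, 2]
        for j, k in enumerate(plane_indices):
            sel = voxels[:, :, k]
            q[f, j] = vz[:, :, k][sel].sum() * pixel_area_m2

    q_mean = q.mean(axis=1)
    q_sd = q.std(axis=1, ddof=0)
    spline = CubicSpline(dataset.frame_times, q_mean, bc_type="natural")
    t_dense = np.arange(dataset.frame_times[0], dataset.frame_times[-1] + dt / 2, dt)
    return FlowWaveform(
        times=dataset.frame_times.copy(),
        q_mean=q_mean,
        q_sd=q_sd,
        interp_times=t_dense,
        interp_q=spline(t_dense),
    )


def parabolic_profile(q: float, radius: float, r) -> np.ndarray:
    """Poiseuille velocity profile u(r) = 2 (q / pi R^2) (1 - (r/R)^2).

    SI units: q in m^3/s, radius in m.  Positions beyond the radius return
    0 (no-slip wall and outside).
    """
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    r = np.asarray(r, dtype=float)
    u_mean = q / (np.pi * radius**2)
    u = 2.0 * u_mean * (1.0 - (r / radius) ** 2)
    return np.where(np.abs(r) <= radius, u, 0.0)


def reynolds(fluid: FluidProperties, U: float, D: float) -> float:
    """Reynolds number rho U D / mu."""
    if U <= 0 or D <= 0:
        raise ValidationError("U and D must be > 0")
    return fluid.density * U * D / fluid.dynamic_viscosity


# ---------------------------------------------------------------------------
# tabular exchange
# ---------------------------------------------------------------------------

def read_wss_csv(path, period_T: float | None = None) -> WSSField:
    """Long-format WSS table: element_id, area_mm2, t_s, taux_Pa, tauy_Pa, tauz_Pa."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"element_id", "area_mm2", "t_s", "taux_Pa", "tauy_Pa", "tauz_Pa"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"WSS table missing columns: {sorted(missing)}")
    times = np.sort(df["t_s"].unique())
    ids = np.sort(df["element_id"].unique())
    pivot = df.set_index(["element_id", "t_s"]).sort_index()
    tau = np.stack(
        [
            pivot[c].to_numpy().reshape(len(ids), len(times))
            for c in ("taux_Pa", "tauy_Pa", "tauz_Pa")
        ],
        axis=2,
    )
    areas = df.groupby("element_id")["area_mm2"].first().loc[ids].to_numpy()
    if period_T is None:
        period_T = float(times[-1])
    return WSSField(
        element_ids=ids, element_areas=areas, times=times, tau=tau, period_T=period_T
    )


def write_waveform_csv(waveform: FlowWaveform, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"t_s": waveform.times, "q_m3s": waveform.q_mean, "q_sd": waveform.q_sd}
    ).to_csv(path, index=False)
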