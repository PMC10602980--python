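"""Composite phase-contrast MRA construction.

Velocity fields at selected systolic cardiac phases (systolic acceleration,
peak systole, systolic deceleration) are resliced into image stacks whose
pixel intensity is proportional to the instantaneous velocity magnitude
above a threshold, then merged slice-by-slice into one composite stack and
contrast-stretched to span the full intensity range.

Blending note: a raw per-slice sum triples the intensity where all phases
overlap, so the default ``alpha-mean`` blend averages the contributing
stacks with equal weights before stretching; ``pixel-max`` is offered as an
alternative.  Both leave uniform-lumen regions uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cpcmra.errors import StackMismatchError, ValidationError
from cpcmra.io_volumes import Flow4DDataset, ImageStack, reslice

DEFAULT_V_THRESHOLD = 0.25  # m/s
DEFAULT_I_MAX = 4095.0
BACKGROUND_CEILING_FRACTION = 0.25  # retained magnitude capped at 25% of I_max


@dataclass
class CPCConfig:
    """Parameters of the composite construction."""

    v_threshold: float = DEFAULT_V_THRESHOLD
    v_ceiling: float | None = None  # None -> dataset VENC
    phases: tuple[int, ...] | None = None  # None -> automatic SA/PS/SD
    blend_mode: str = "alpha-mean"
    background_mode: str = "suppress"
    stretch_saturation: float = 0.01
    I_max: float = DEFAULT_I_MAX

    def __post_init__(self):
        if self.v_threshold < 0:
            raise ValidationError("v_threshold must be >= 0")
        if self.v_ceiling is not None and self.v_ceiling <= self.v_threshold:
            raise ValidationError("require 0 <= v_threshold < v_ceiling")
        if not (0 <= self.stretch_saturation < 0.5):
            raise ValidationError("stretch_saturation must lie in [0, 0.5)")
        if self.blend_mode not in ("alpha-mean", "pixel-max"):
            raise ValidationError(f"unknown blend_mode {self.blend_mode!r}")
        if self.background_mode not in ("retain-magnitude", "suppress"):
            raise ValidationError(f"unknown background_mode {self.background_mode!r}")
        if self.phases is not None:
            self.phases = tuple(int(p) for p in self.phases)
            if len(self.phases) == 0:
                raise ValidationError("phases must be non-empty")

    def ceiling(self, dataset: Flow4DDataset) -> float:
        return self.v_ceiling if self.v_ceiling is not None else dataset.venc


@dataclass
class CPCStack:
    """A composite stack plus its configuration and per-pixel provenance.

    ``phase_provenance`` is an integer bit field per pixel: bit ``i`` is set
    where input stack ``i`` exceeded the velocity threshold.
    """

    stack: ImageStack
    config: CPCConfig
    phase_provenance: np.ndarray

    def __post_init__(self):
        if self.phase_provenance.shape != self.stack.pixels.shape:
            raise StackMismatchError("provenance shape must match pixels")

    @property
    def pixels(self) -> np.ndarray:
        return self.stack.pixels

    @property
    def above_threshold(self) -> np.ndarray:
        return self.phase_provenance > 0


def velocity_magnitude(dataset: Flow4DDataset, frame: int) -> np.ndarray:
    """Per-voxel speed (m/s) of one cardiac frame."""
    if not (0 <= frame < dataset.n_frames):
        raise IndexError(f"frame {frame} out of range [0, {dataset.n_frames})")
    v = dataset.velocity[frame]
    return np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)


def mean_speed_series(
    dataset: Flow4DDataset, v_threshold: float = DEFAULT_V_THRESHOLD
) -> np.ndarray:
    """Spatial-mean speed per frame, restricted to above-threshold voxels.

    Frames with no voxel above threshold contribute 0.
    """
    series = np.zeros(dataset.n_frames)
    for f in range(dataset.n_frames):
        speed = velocity_magnitude(dataset, f)
        mask = speed >= v_threshold
        if mask.any():
            series[f] = speed[mask].mean()
    return series


def select_systolic_phases(
    dataset: Flow4DDataset, v_threshold: float = DEFAULT_V_THRESHOLD
) -> tuple[int, int, int]:
    """Automatic choice of the three frames to merge.

    Peak systole (PS) is the frame maximising the above-threshold mean
    speed.  Systolic acceleration (SA) is chosen among the frames cyclically
    preceding PS whose mean is at least half the peak, taking the one with
    the largest forward temporal gradient; systolic deceleration (SD) is the
    symmetric choice after PS (most negative gradient).
    """
    if dataset.n_frames < 3:
        raise ValidationError("need at least 3 frames to select SA/PS/SD")
    series = mean_speed_series(dataset, v_threshold)
    if np.all(series == 0):
        raise ValidationError("no systolic phase detectable: zero-flow dataset")
    n = dataset.n_frames
    ps = int(np.argmax(series))
    grad = np.empty(n)
    for f in range(n):
        grad[f] = series[(f + 1) % n] - series[(f - 1) % n]

    half_peak = 0.5 * series[ps]

    def _pick(offsets, best_by):
        candidates = [
            (ps + off) % n for off in offsets if series[(ps + off) % n] >= half_peak
        ]
        if not candidates:
            return None
        return max(candidates, key=best_by)

    # frames cyclically before / after the peak (nearest first, exclude peak
    # and its antipode so the two searches cannot collide)
    before = _pick(range(-1, -(n // 2) - 1, -1), lambda f: grad[f])
    after = _pick(range(1, (n - 1) // 2 + 1), lambda f: -grad[f])
    sa = before if before is not None else (ps - 1) % n
    sd = after if after is not None else (ps + 1) % n
    if sa == (ps - 1) % n and sd == (ps + 1) % n and np.ptp(series) == 0:
        warnings.warn(
            "constant flow: SA/PS/SD degenerate to adjacent frames", stacklevel=2
        )
    return sa, ps, sd


def phase_stack(
    dataset: Flow4DDataset,
    frame: int,
    config: CPCConfig,
    plane: str = "transverse",
    n_slices: int = 64,
    slice_gap: float = 0.35,
) -> ImageStack:
    """Velocity-proportional grayscale stack for one cardiac phase.

    Above the velocity threshold, intensity is
    ``I_max * min(v, v_ceiling) / v_ceiling``; below it, the pixel takes the
    background value (0 under ``suppress``; under ``retain-magnitude`` a
    rescale of the resliced magnitude image capped at 25% of ``I_max``).
    """
    grid = dataset.grid
    ceiling = config.ceiling(dataset)
    speed = velocity_magnitude(dataset, frame)
    v_stack = reslice(speed, grid, plane, n_slices, slice_gap, I_max=config.I_max)
    v = v_stack.pixels

    above = v >= config.v_threshold
    intensity = np.zeros_like(v)
    intensity[above] = config.I_max * np.minimum(v[above], ceiling) / ceiling

    if config.background_mode == "retain-magnitude":
        m_stack = reslice(
            dataset.magnitude[frame], grid, plane, n_slices, slice_gap,
            I_max=config.I_max,
        )
        m = m_stack.pixels
        if m.max() > 0:
            background = m * (BACKGROUND_CEILING_FRACTION * config.I_max / m.max())
            intensity[~above] = background[~above]

    out = ImageStack(
        plane=plane,
        pixels=intensity,
        slice_gap=float(slice_gap),
        in_plane_spacing=v_stack.in_plane_spacing,
        I_max=config.I_max,
        origin=v_stack.origin,
    )
    out.above_threshold = above
    return out


def _check_geometry(stacks: list[ImageStack]) -> None:
    ref = stacks[0]
    for s in stacks[1:]:
        if (
            s.plane != ref.plane
            or s.pixels.shape != ref.pixels.shape
            or not np.isclose(s.slice_gap, ref.slice_gap)
            or not np.allclose(s.in_plane_spacing, ref.in_plane_spacing)
        ):
            raise StackMismatchError("stack mismatch: stacks differ in geometry")


def contrast_stretch(stack: ImageStack, saturation: float = 0.01) -> ImageStack:
    """Linear remap sending the tail quantiles to 0 and ``I_max``.

    The ``saturation`` quantile maps to 0 and the ``1 - saturation``
    quantile to ``I_max``, with clipping outside; constant images are
    returned unchanged.
    """
    if not (0 <= saturation < 0.5):
        raise ValidationError("saturation must lie in [0, 0.5)")
    lo = float(np.quantile(stack.pixels, saturation))
    hi = float(np.quantile(stack.pixels, 1 - saturation))
    if hi <= lo:
        return ImageStack(
            plane=stack.plane,
            pixels=stack.pixels.copy(),
            slice_gap=stack.slice_gap,
            in_plane_spacing=stack.in_plane_spacing,
            I_max=stack.I_max,
            origin=stack.origin,
        )
    remapped = np.clip((stack.pixels - lo) / (hi - lo), 0.0, 1.0) * stack.I_max
    return ImageStack(
        plane=stack.plane,
        pixels=remapped,
        slice_gap=stack.slice_gap,
        in_plane_spacing=stack.in_plane_spacing,
        I_max=stack.I_max,
        origin=stack.origin,
    )


def composite(stacks: list[ImageStack], config: CPCConfig) -> CPCStack:
    """Merge per-phase stacks slice-by-slice into one composite stack."""
    if len(stacks) < 1:
        raise ValidationError("composite requires at least one stack")
    _check_geometry(stacks)

    pix = np.stack([s.pixels for s in stacks], axis=0)
    if config.blend_mode == "pixel-max":
        merged = pix.max(axis=0)
    else:
        merged = pix.mean(axis=0)

    provenance = np.zeros(stacks[0].pixels.shape, dtype=np.uint8)
    for i, s in enumerate(stacks):
        if s.above_threshold is not None:
            mask = s.above_threshold
        else:
            # fall back to the intensity image of the threshold rule
            ceiling = config.v_ceiling if config.v_ceiling is not None else 1.0
            mask = s.pixels >= config.I_max * config.v_threshold / ceiling
        provenance |= (mask.astype(np.uint8) << i)

    ref = stacks[0]
    merged_stack = ImageStack(
        plane=ref.plane,
        pixels=merged,
        slice_gap=ref.slice_gap,
        in_plane_spacing=ref.in_plane_spacing,
        I_max=config.I_max,
        origin=ref.origin,
    )
    stretched = contrast_stretch(merged_stack, config.stretch_saturation)
    stretched.above_threshold = provenance > 0
    return CPCStack(stack=stretched, config=config, phase_provenance=provenance)


def build_cpc_stack(
    dataset: Flow4DDataset,
    config: CPCConfig | None = None,
    plane: str = "transverse",
    n_slices: int = 64,
    slice_gap: float = 0.35,
) -> CPCStack:
    """End-to-end composite: select phases, build per-phase stacks, merge."""
    config = config or CPCConfig()
    if config.phases is not None:
        phases = config.phases
    else:
        phases = select_systolic_phases(dataset, config.v_threshold)
    stacks = [
        phase_stack(dataset, f, config, plane, n_slices, slice_gap) for f in phases
    ]
    return composite(stacks, config)


def false_color_overlay(
    sa: ImageStack, ps: ImageStack, sd: ImageStack
) -> np.ndarray:
    """RGB rendering of phase agreement.

    Pixels above threshold in all three phases render white; pixels bright
    only at peak systole render magenta, only at systolic deceleration
    green, only at systolic acceleration blue.  Returns an array of shape
    ``(n_slices, n_u, n_v, 3)`` scaled to [0, 1].
    """
    stacks = [sa, ps, sd]
    _check_geometry(stacks)
    masks = []
    for s in stacks:
        if s.above_threshold is None:
            raise ValidationError("stacks must carry above_threshold masks")
        masks.append(s.above_threshold)
    m_sa, m_ps, m_sd = masks

    norm = [s.pixels / s.I_max for s in stacks]
    rgb = np.zeros((*sa.pixels.shape, 3))
    all_three = m_sa & m_ps & m_sd
    for c in range(3):
        rgb[..., c][all_three] = np.mean([n[all_three] for n in norm], axis=0)
    # phase-specific excess: magenta (R+B) for PS, green for SD, blue for SA
    ps_only = m_ps & ~all_three
    sd_only = m_sd & ~all_three & ~ps_only
    sa_only = m_sa & ~all_three & ~ps_only & ~sd_only
    rgb[..., 0][ps_only] = norm[1][ps_only]
    rgb[..., 2][ps_only] = norm[1][ps_only]
    rgb[..., 1][sd_only] = norm[2][sd_only]
    rgb[..., 2][sa_only] = norm[0][sa_only]
    return np.clip(rgb, 0.0, 1.0)
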