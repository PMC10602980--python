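import numpy as np
import pytest

from cpcmra import (
    CPCConfig,
    Flow4DDataset,
    ImageStack,
    PhantomSpec,
    VoxelGrid,
    composite,
    contrast_stretch,
    false_color_overlay,
    make_phantom,
    phase_stack,
    select_systolic_phases,
    velocity_magnitude,
)
from cpcmra.compositor import mean_speed_series
from cpcmra.errors import StackMismatchError, ValidationError


def dataset_with_speeds(speeds, shape=(6, 6, 6), venc=1.5):
    """Frames with spatially uniform axial velocity per entry of speeds."""
    n = len(speeds)
    velocity = np.zeros((n, 3, *shape))
    for f, s in enumerate(speeds):
        velocity[f, 2] = s
    return Flow4DDataset(
        grid=VoxelGrid(shape, (1.0, 1.0, 1.0)),
        frame_times=np.arange(n) / n,
        period_T=1.0,
        magnitude=np.ones((n, *shape)),
        velocity=velocity,
        venc=venc,
    )


class TestVelocityMagnitude:
    def test_pythagorean_triple(self):
        ds = dataset_with_speeds([0.0])
        ds.velocity[0, 0, 0, 0, 0] = 0.3
        ds.velocity[0, 1, 0, 0, 0] = 0.4
        ds.velocity[0, 2, 0, 0, 0] = 0.0
        assert velocity_magnitude(ds, 0)[0, 0, 0] == pytest.approx(0.5)

    def test_zero_frame(self):
        ds = dataset_with_speeds([0.0])
        assert np.all(velocity_magnitude(ds, 0) == 0)

    def test_brute_force_oracle(self, rng):
        ds = dataset_with_speeds([0.0], shape=(8, 8, 8))
        ds.velocity[0] = rng.uniform(-1, 1, size=(3, 8, 8, 8))
        got = velocity_magnitude(ds, 0)
        for _ in range(50):
            i, j, k = rng.integers(0, 8, size=3)
            expect = 0.0
            for c in range(3):
                expect += ds.velocity[0, c, i, j, k] ** 2
            assert got[i, j, k] == pytest.approx(np.sqrt(expect))

    def test_frame_out_of_range(self):
        ds = dataset_with_speeds([0.3])
        with pytest.raises(IndexError):
            velocity_magnitude(ds, 5)


class TestSelectSystolicPhases:
    def waveform_speeds(self, n=20, peak=5):
        t = np.arange(n) / n
        return 0.05 + 0.75 * np.exp(-(((t - peak / n) / 0.1) ** 2))

    def test_peak_detection(self):
        ds = dataset_with_speeds(self.waveform_speeds())
        sa, ps, sd = select_systolic_phases(ds)
        # exhaustive oracle over the mean-speed series
        series = mean_speed_series(ds)
        assert ps == int(np.argmax(series))
        assert ps == 5 and sa < 5 < sd

    def test_circular_shift_equivariance(self):
        speeds = self.waveform_speeds()
        base = select_systolic_phases(dataset_with_speeds(speeds))
        k = 7
        shifted = select_systolic_phases(dataset_with_speeds(np.roll(speeds, k)))
        assert tuple((x + k) % 20 for x in base) == shifted

    def test_zero_flow_error(self):
        ds = dataset_with_speeds(np.zeros(5))
        with pytest.raises(ValidationError, match="no systolic phase"):
            select_systolic_phases(ds)

    def test_constant_flow_degenerate(self):
        ds = dataset_with_speeds(np.full(8, 0.6))
        with pytest.warns(UserWarning, match="constant flow"):
            sa, ps, sd = select_systolic_phases(ds)
        assert sa == (ps - 1) % 8 and sd == (ps + 1) % 8


class TestPhaseStack:
    def test_ceiling_tube_suppress(self, clean_tube):
        spec, ds, _ = clean_tube
        config = CPCConfig(v_ceiling=0.5, v_threshold=0.25)
        ds2 = dataset_with_speeds([0.5])
        stack = phase_stack(ds2, 0, config, "transverse", 6, 1.0)
        np.testing.assert_allclose(stack.pixels, config.I_max)

    def test_just_below_threshold_is_background(self):
        config = CPCConfig(v_threshold=0.25, v_ceiling=1.5)
        ds = dataset_with_speeds([0.249])
        stack = phase_stack(ds, 0, config, "transverse", 6, 1.0)
        np.testing.assert_allclose(stack.pixels, 0.0)
        ds_hi = dataset_with_speeds([0.25])
        stack_hi = phase_stack(ds_hi, 0, config, "transverse", 6, 1.0)
        assert np.all(stack_hi.pixels > 0)

    def test_linear_in_velocity(self):
        config = CPCConfig(v_threshold=0.25, v_ceiling=1.5)
        s1 = phase_stack(dataset_with_speeds([0.3]), 0, config, "transverse", 6, 1.0)
        s2 = phase_stack(dataset_with_speeds([0.6]), 0, config, "transverse", 6, 1.0)
        np.testing.assert_allclose(s2.pixels, 2 * s1.pixels, rtol=1e-12)

    def test_retain_magnitude_background_capped(self):
        config = CPCConfig(background_mode="retain-magnitude", v_ceiling=1.5)
        ds = dataset_with_speeds([0.0])
        ds.magnitude[0] = np.linspace(0, 800, ds.magnitude[0].size).reshape(
            ds.magnitude[0].shape
        )
        stack = phase_stack(ds, 0, config, "transverse", 6, 1.0)
        assert stack.pixels.max() <= 0.25 * config.I_max + 1e-9


class TestComposite:
    def make_stack(self, pixels, above=None):
        s = ImageStack(
            plane="transverse",
            pixels=pixels,
            slice_gap=1.0,
            in_plane_spacing=(1.0, 1.0),
        )
        s.above_threshold = (
            above if above is not None else pixels > 0
        )
        return s

    def test_idempotence(self, rng):
        pix = rng.uniform(0, 4095, size=(3, 8, 8))
        config = CPCConfig(stretch_saturation=0.0)
        for mode in ("alpha-mean", "pixel-max"):
            config.blend_mode = mode
            stacks = [self.make_stack(pix.copy()) for _ in range(3)]
            cpc = composite(stacks, config)
            single = contrast_stretch(stacks[0], 0.0)
            np.testing.assert_allclose(cpc.pixels, single.pixels, rtol=1e-9)

    def test_disjoint_regions_union(self):
        config = CPCConfig(blend_mode="pixel-max", stretch_saturation=0.0)
        pix = [np.zeros((1, 9, 9)) for _ in range(3)]
        pix[0][0, 0:2, 0:2] = 3000.0
        pix[1][0, 4:6, 4:6] = 4095.0
        pix[2][0, 7:9, 7:9] = 2000.0
        stacks = [self.make_stack(p) for p in pix]
        cpc = composite(stacks, config)
        # union coverage with per-pixel max oracle
        expected = np.maximum.reduce(pix)
        np.testing.assert_allclose(cpc.pixels, expected, rtol=1e-9)
        assert np.array_equal(cpc.above_threshold, expected[0:1] > 0)

    def test_single_stack_identity(self, rng):
        pix = rng.uniform(0, 4095, size=(2, 5, 5))
        config = CPCConfig(stretch_saturation=0.01)
        cpc = composite([self.make_stack(pix)], config)
        np.testing.assert_allclose(
            cpc.pixels, contrast_stretch(self.make_stack(pix), 0.01).pixels
        )

    def test_geometry_mismatch(self):
        a = self.make_stack(np.zeros((2, 5, 5)))
        b = self.make_stack(np.zeros((2, 6, 5)))
        with pytest.raises(StackMismatchError):
            composite([a, b], CPCConfig())


class TestContrastStretch:
    def make(self, pixels):
        return ImageStack(
            plane="transverse", pixels=pixels, slice_gap=1.0, in_plane_spacing=(1, 1)
        )

    def test_half_range_doubles(self):
        pix = np.linspace(0, 0.5 * 4095, 64).reshape(1, 8, 8)
        out = contrast_stretch(self.make(pix), 0.0)
        np.testing.assert_allclose(out.pixels, 2 * pix, rtol=1e-12)

    def test_constant_unchanged(self):
        pix = np.full((2, 4, 4), 1234.0)
        out = contrast_stretch(self.make(pix), 0.01)
        np.testing.assert_allclose(out.pixels, pix)

    def test_quantile_oracle(self, rng):
        pix = rng.uniform(0, 4095, size=(4, 32, 32))
        sat = 0.01
        out = contrast_stretch(self.make(pix), sat)
        # sort-based quantile oracle (linear interpolation, matches numpy)
        flat = np.sort(pix.ravel())
        n = len(flat)
        def q(frac):
            pos = frac * (n - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            w = pos - lo
            return flat[lo] * (1 - w) + flat[hi] * w
        lo, hi = q(sat), q(1 - sat)
        expected = np.clip((pix - lo) / (hi - lo), 0, 1) * 4095
        np.testing.assert_allclose(out.pixels, expected, rtol=1e-9)
        n_low = (out.pixels == 0).sum()
        n_high = (out.pixels == 4095).sum()
        assert abs(n_low - sat * pix.size) <= pix.size * sat + 1
        assert n_low >= 1 and n_high >= 1


class TestFalseColor:
    def stack_with_mask(self, bright):
        pix = np.where(bright, 4000.0, 0.0)
        s = ImageStack(
            plane="transverse", pixels=pix, slice_gap=1.0, in_plane_spacing=(1, 1)
        )
        s.above_threshold = bright
        return s

    def test_identical_stacks_white(self):
        bright = np.zeros((1, 6, 6), dtype=bool)
        bright[0, 2:4, 2:4] = True
        stacks = [self.stack_with_mask(bright) for _ in range(3)]
        rgb = false_color_overlay(*stacks)
        lumen = rgb[bright]
        assert np.all(lumen[:, 0] == lumen[:, 1]) and np.all(lumen[:, 1] == lumen[:, 2])
        assert np.all(lumen > 0.9)
        assert np.all(rgb[~bright] == 0)

    def test_ps_only_magenta(self):
        quiet = np.zeros((1, 6, 6), dtype=bool)
        bright = np.zeros((1, 6, 6), dtype=bool)
        bright[0, 1, 1] = True
        rgb = false_color_overlay(
            self.stack_with_mask(quiet),
            self.stack_with_mask(bright),
            self.stack_with_mask(quiet),
        )
        r, g, b = rgb[0, 1, 1]
        assert r > 0 and b > 0 and g == 0

    def test_all_zero_black(self):
        quiet = np.zeros((1, 6, 6), dtype=bool)
        rgb = false_color_overlay(*[self.stack_with_mask(quiet) for _ in range(3)])
        assert np.all(rgb == 0)


class TestCompositeProperties:
    def test_monotone_in_velocity(self):
        config = CPCConfig(v_threshold=0.25, v_ceiling=1.5, stretch_saturation=0.0)
        base = dataset_with_speeds([0.4, 0.5, 0.6])
        stacks = [phase_stack(base, f, config, "transverse", 6, 1.0) for f in range(3)]
        lo = composite(stacks, config)
        bumped = dataset_with_speeds([0.4, 0.5, 0.6])
        bumped.velocity[1, 2, 3, 3, 3] = 0.9
        stacks_hi = [phase_stack(bumped, f, config, "transverse", 6, 1.0) for f in range(3)]
        hi = composite(stacks_hi, config)
        assert hi.pixels[3, 3, 3] >= lo.pixels[3, 3, 3]

    def test_threshold_consistency_suppress(self, clean_tube):
        spec, ds, _ = clean_tube
        config = CPCConfig(background_mode="suppress", phases=(3, 5, 7))
        stacks = [phase_stack(ds, f, config, "transverse", 20, 4.0) for f in (3, 5, 7)]
        cpc = composite(stacks, config)
        nonzero = cpc.pixels > 0
        assert np.all(cpc.phase_provenance[nonzero] > 0)

    def test_union_property(self, clean_tube):
        spec, ds, _ = clean_tube
        config = CPCConfig(phases=(3, 5, 7))
        stacks = [phase_stack(ds, f, config, "transverse", 20, 4.0) for f in (3, 5, 7)]
        cpc = composite(stacks, config)
        union = np.zeros_like(stacks[0].above_threshold)
        for s in stacks:
            union |= s.above_threshold
        assert np.array_equal(cpc.above_threshold, union)

    def test_threshold_mask_monotone(self, clean_tube):
        spec, ds, _ = clean_tube
        masks = {}
        for vt in (0.25, 0.40):
            config = CPCConfig(v_threshold=vt)
            s = phase_stack(ds, 5, config, "transverse", 20, 4.0)
            masks[vt] = s.above_threshold
        assert np.all(masks[0.40] <= masks[0.25])
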