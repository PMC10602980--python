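import numpy as np
import pytest

from cpcmra import (
    BinaryMask,
    Centerline,
    VoxelGrid,
    bifurcation_angle,
    curvature,
    dissected_radius,
    extract_centerline,
    resample_smooth,
    tortuosity,
)
from cpcmra.errors import ValidationError


def tube_mask(radius=5.0, shape=(24, 24, 40), spacing=1.0):
    grid = VoxelGrid(shape, (spacing,) * 3)
    x, y, _ = np.meshgrid(*[np.arange(n) * spacing for n in shape], indexing="ij")
    cx, cy = (shape[0] - 1) * spacing / 2, (shape[1] - 1) * spacing / 2
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
    return BinaryMask(grid, inside), (cx, cy)


class TestExtractCenterline:
    def test_straight_tube_axis_and_radius(self):
        mask, (cx, cy) = tube_mask()
        p0 = (cx, cy, 2.0)
        p1 = (cx, cy, 37.0)
        line = extract_centerline(mask, (p0, p1))
        # path stays within one voxel of the analytic axis
        off = np.linalg.norm(line.points[:, :2] - [cx, cy], axis=1)
        assert off.max() <= 1.0 + 1e-9
        # inscribed-sphere radius within one voxel of the tube radius
        assert abs(line.radius[len(line.points) // 2] - 5.0) <= 1.0 + 1e-9

    def test_torus_tracks_axis(self):
        # quarter-torus, bend radius 20 mm, tube radius 4 mm, 1 mm grid
        grid = VoxelGrid((30, 12, 30), (1.0, 1.0, 1.0))
        x, y, z = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
        c = np.array([2.0, 5.5, 2.0])
        rho = np.sqrt((x - c[0]) ** 2 + (z - c[2]) ** 2)
        phi = np.arctan2(z - c[2], x - c[0])
        d = np.sqrt((rho - 20.0) ** 2 + (y - c[1]) ** 2)
        mask = BinaryMask(grid, (d <= 4.0) & (phi >= 0) & (phi <= np.pi / 2))
        p0 = (22.0, 5.5, 2.0)
        p1 = (2.0, 5.5, 22.0)
        line = extract_centerline(mask, (p0, p1))
        rho_p = np.sqrt((line.points[:, 0] - c[0]) ** 2 + (line.points[:, 2] - c[2]) ** 2)
        dev = np.sqrt((rho_p - 20.0) ** 2 + (line.points[:, 1] - c[1]) ** 2)
        assert dev.max() <= np.sqrt(3) + 1e-9  # one voxel diagonal

    def test_endpoint_outside_error(self):
        mask, (cx, cy) = tube_mask()
        with pytest.raises(ValidationError, match="outside"):
            extract_centerline(mask, ((0.0, 0.0, 0.0), (cx, cy, 20.0)))

    def test_disconnected_error(self):
        mask, (cx, cy) = tube_mask()
        mask.voxels[:, :, 20] = False  # cut the tube
        with pytest.raises(ValidationError, match="no path"):
            extract_centerline(mask, ((cx, cy, 2.0), (cx, cy, 37.0)))

    def test_radius_bounded_by_dt_max(self):
        from scipy.ndimage import distance_transform_edt

        mask, (cx, cy) = tube_mask()
        line = extract_centerline(mask, ((cx, cy, 2.0), (cx, cy, 37.0)))
        dt_max = distance_transform_edt(mask.voxels, sampling=mask.grid.spacing).max()
        assert line.radius.max() <= dt_max + 1e-9


class TestResampleSmooth:
    def test_straight_line_fixed_point(self):
        line = Centerline(np.column_stack([np.zeros(50), np.zeros(50), np.linspace(0, 99, 50)]))
        out = resample_smooth(line, 3.0, 0.5, 100)
        np.testing.assert_allclose(out.points[:, :2], 0.0, atol=1e-12)
        assert out.points[0, 2] == 0.0 and out.points[-1, 2] == 99.0

    def test_zigzag_damped_and_matches_direct_iteration(self):
        n = 41
        # alternating +/-1 mm interior perturbation, endpoints on the axis;
        # segment length is exactly 3 mm so resampling at 3 mm reproduces
        # the zig-zag points
        z = np.arange(n) * np.sqrt(9.0 - 4.0)
        x = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        x[0] = x[-1] = 0.0
        line = Centerline(np.column_stack([x, np.zeros(n), z]))
        out = resample_smooth(line, 3.0, 0.5, 100)
        # direct-iteration oracle on the resampled points
        s = line.arc_length
        s_new = np.arange(0.0, s[-1], 3.0)
        if s[-1] - s_new[-1] > 1e-9:
            s_new = np.append(s_new, s[-1])
        pts = np.column_stack([np.interp(s_new, s, line.points[:, k]) for k in range(3)])
        for _ in range(100):
            avg = 0.5 * (pts[:-2] + pts[2:])
            pts[1:-1] += 0.5 * (avg - pts[1:-1])
        np.testing.assert_allclose(out.points, pts, atol=1e-12)
        assert np.abs(out.points[1:-1, 0]).max() <= 0.1  # >= 90% reduction

    def test_resampled_spacing(self):
        t = np.linspace(0, 2 * np.pi / 3, 300)
        line = Centerline(np.column_stack([90 * np.cos(t), 90 * np.sin(t), np.zeros_like(t)]))
        out = resample_smooth(line, 3.0, 0.5, 0)
        spacing = np.diff(out.arc_length)
        np.testing.assert_allclose(spacing[:-1], 3.0, rtol=0.01)

    def test_interval_too_long(self):
        line = Centerline([[0, 0, 0], [0, 0, 2]])
        with pytest.raises(ValidationError):
            resample_smooth(line, 3.0)


class TestCurvature:
    def test_circle_closed_form(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        line = Centerline(np.column_stack([200 * np.cos(th), 200 * np.sin(th), 0 * th]))
        k = curvature(line)
        assert np.median(k) == pytest.approx(5.0, rel=0.01)

    def test_straight_line_zero(self):
        line = Centerline(np.column_stack([np.zeros(20), np.zeros(20), np.arange(20.0)]))
        np.testing.assert_allclose(curvature(line), 0.0, atol=1e-12)

    def test_helix_closed_form(self):
        t = np.linspace(0, 4 * np.pi, 200)
        line = Centerline(np.column_stack([100 * np.cos(t), 100 * np.sin(t), 50 * t]))
        k = curvature(line)
        expected = 0.1 / (0.1**2 + 0.05**2)  # a / (a^2 + b^2), metres
        assert np.median(k) == pytest.approx(expected, rel=0.01)

    def test_rigid_motion_invariance(self, rng):
        t = np.linspace(0, np.pi, 80)
        pts = np.column_stack([50 * np.cos(t), 50 * np.sin(t), 3 * t])
        ang = 0.7
        R = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        k1 = curvature(Centerline(pts))
        k2 = curvature(Centerline(pts @ R.T + [5.0, -3.0, 11.0]))
        np.testing.assert_allclose(k1, k2, rtol=1e-9)

    def test_density_change_tolerance(self):
        th1 = np.linspace(0.1, np.pi, 60)
        th2 = np.linspace(0.1, np.pi, 120)
        k1 = curvature(Centerline(np.column_stack([100 * np.cos(th1), 100 * np.sin(th1), 0 * th1])))
        k2 = curvature(Centerline(np.column_stack([100 * np.cos(th2), 100 * np.sin(th2), 0 * th2])))
        assert np.median(k1) == pytest.approx(np.median(k2), rel=0.02)


class TestTortuosity:
    def test_straight_zero(self):
        assert tortuosity(Centerline([[0, 0, 0], [0, 0, 50]])) == 0.0

    def test_semicircle(self):
        th = np.linspace(0, np.pi, 400)
        line = Centerline(np.column_stack([30 * np.cos(th), 30 * np.sin(th), 0 * th]))
        assert tortuosity(line) == pytest.approx(np.pi / 2 - 1, rel=0.01)

    def test_segment_sum_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(25, 3))
        line = Centerline(pts)
        L = sum(
            float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(len(pts) - 1)
        )
        D = float(np.linalg.norm(pts[-1] - pts[0]))
        assert tortuosity(line) == pytest.approx(L / D - 1, rel=1e-12)

    def test_scale_invariance(self, rng):
        pts = rng.uniform(0, 10, size=(15, 3))
        line = Centerline(pts)
        scaled = Centerline(7.3 * pts)
        assert tortuosity(scaled) == pytest.approx(tortuosity(line), rel=1e-12)

    def test_coincident_endpoints_error(self):
        square = Centerline(
            [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0], [0, 0, 0]]
        )
        with pytest.raises(ValidationError):
            tortuosity(square)


class TestBifurcationAngle:
    @staticmethod
    def y_lines(angle_deg, plane_tilt=0.0):
        half = np.radians(angle_deg / 2)
        parent = Centerline(np.column_stack([np.zeros(20), np.zeros(20), np.linspace(-40, 0, 20)]))
        s = np.linspace(0, 30, 15)
        d1 = np.column_stack([s * np.sin(half), np.zeros_like(s), s * np.cos(half)])
        d2 = np.column_stack([-s * np.sin(half), np.zeros_like(s), s * np.cos(half)])
        if plane_tilt:
            c, sn = np.cos(plane_tilt), np.sin(plane_tilt)
            R = np.array([[1, 0, 0], [0, c, -sn], [0, sn, c]])
            d1, d2 = d1 @ R.T, d2 @ R.T
        return parent, Centerline(d1), Centerline(d2)

    def test_symmetric_60(self):
        parent, d1, d2 = self.y_lines(60.0)
        ang, system = bifurcation_angle(parent, (d1, d2), (0, 0, 0))
        assert ang == pytest.approx(60.0, abs=1e-6)
        np.testing.assert_allclose(np.linalg.norm(system.parent_direction), 1.0)

    def test_perpendicular_90(self):
        parent, d1, d2 = self.y_lines(90.0, plane_tilt=0.4)
        ang, _ = bifurcation_angle(parent, (d1, d2), (0, 0, 0))
        assert ang == pytest.approx(90.0, abs=1e-6)

    def test_parallel_daughters_warn(self):
        parent, d1, _ = self.y_lines(0.0)
        with pytest.warns(UserWarning, match="parallel"):
            ang, _ = bifurcation_angle(parent, (d1, d1), (0, 0, 0))
        assert ang == 0.0


class TestDissectedRadius:
    def test_arithmetic(self):
        out = dissected_radius([3.0, 3.1], [1.0, 0.9])
        np.testing.assert_allclose(out, [4.0, 4.0])

    def test_zero_false_lumen_identity(self):
        out = dissected_radius([2.0, 2.5, 3.0], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(out, [2.0, 2.5, 3.0])

    def test_random_oracle(self, rng):
        a = rng.uniform(1, 5, 30)
        b = rng.uniform(0, 2, 30)
        np.testing.assert_allclose(dissected_radius(a, b), a + b)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            dissected_radius([1.0], [1.0, 2.0])


class TestCenterlineCSV:
    def test_round_trip(self, tmp_path, rng):
        from cpcmra.centerline import read_centerline_csv, write_centerline_csv

        pts = np.cumsum(rng.uniform(0.5, 1.5, size=(10, 3)), axis=0)
        line = Centerline(pts, radius=rng.uniform(2, 5, 10), labels={"bifurcation": 3})
        write_centerline_csv(line, tmp_path / "c.csv")
        back = read_centerline_csv(tmp_path / "c.csv")
        np.testing.assert_allclose(back.points, line.points)
        np.testing.assert_allclose(back.radius, line.radius)
        assert back.labels == {"bifurcation": 3}
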