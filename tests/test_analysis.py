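import numpy as np
import pytest

from astersim import HexagonDomain, SimulationConfig
from astersim.analysis import (
    SyntheticFrame,
    coarse_hexagon_segmentation,
    detect_asters,
    divergence_map,
    elastic_energy,
    energy_accounting,
    kymograph,
    mean_motor_force,
    plus_end_connectedness,
    render_frame,
    roi_mean_intensity,
)
from astersim.dynamics import drag_coefficients

from .conftest import make_state


def ideal_aster(rng, center, n=300, rmax=1.0):
    """Plus-ends around a center with orientations pointing inward."""
    ang = rng.uniform(0, 2 * np.pi, n)
    rad = rng.uniform(0.05, rmax, n)
    pe = np.asarray(center) + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    theta = np.arctan2(center[1] - pe[:, 1], center[0] - pe[:, 0])
    return pe, theta


class TestDivergenceMap:
    def test_hand_computed_central_differences(self, domain):
        # single plus-end pointing +x in a known box: the neighbors' divX
        # must be +/- Vx / (2h), the box itself zero
        h = 0.125
        dm = divergence_map(np.array([[0.0, 0.0]]), np.array([0.0]), domain, h)
        iy = np.searchsorted(dm.y_edges, 0.0, side='right') - 1
        ix = np.searchsorted(dm.x_edges, 0.0, side='right') - 1
        assert dm.vx[iy, ix] == 1.0
        # Vx rises toward the source from the left and falls past it, so the
        # central difference is positive one box left, negative one box right
        assert dm.div[iy, ix - 1] == pytest.approx(1.0 / (2 * h))
        assert dm.div[iy, ix + 1] == pytest.approx(-1.0 / (2 * h))
        assert dm.div[iy, ix] == pytest.approx(0.0)

    def test_manual_three_by_three_grid(self, domain):
        # three plus-ends in a row of boxes with mixed angles; compare to a
        # manual finite-difference evaluation of the V field
        h = 0.125
        pts = np.array([[0.0, 0.0], [h, 0.0], [-h, 0.0]])
        angs = np.array([0.0, np.pi / 2, np.pi])
        dm = divergence_map(pts, angs, domain, h)
        iy = np.searchsorted(dm.y_edges, 0.0, side='right') - 1
        ix = np.searchsorted(dm.x_edges, 0.0, side='right') - 1
        # center box: Vx neighbors are cos(pi/2)=0 (right) and cos(pi)=-1
        # (left); Vy neighbors above/below are empty
        assert dm.divx[iy, ix] == pytest.approx((0.0 - (-1.0)) / (2 * h))
        assert dm.divy[iy, ix] == pytest.approx(0.0)
        assert dm.div[iy, ix] == dm.divx[iy, ix] + dm.divy[iy, ix]

    def test_uniform_parallel_lattice_zero_divergence_interior(self, domain):
        xs = np.arange(-1.0, 1.01, 0.125)
        gx, gy = np.meshgrid(xs, xs)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        dm = divergence_map(pts, np.zeros(len(pts)), domain, 0.125)
        occupied = dm.counts > 0
        # strictly interior occupied boxes see identical neighbors -> DIV 0
        interior = occupied.copy()
        interior[:, :] = False
        interior[1:-1, 1:-1] = (
            occupied[1:-1, 1:-1] & occupied[1:-1, :-2] & occupied[1:-1, 2:]
            & occupied[:-2, 1:-1] & occupied[2:, 1:-1]
        )
        assert np.abs(dm.div[interior]).max() == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_filament_sets(self, rng, domain):
        pe1, th1 = ideal_aster(rng, (0.5, 0.0), n=100)
        pe2 = domain.sample_uniform(rng, 150)
        th2 = rng.uniform(0, 2 * np.pi, 150)
        a = divergence_map(pe1, th1, domain, 0.125)
        b = divergence_map(pe2, th2, domain, 0.125)
        both = divergence_map(
            np.vstack([pe1, pe2]), np.concatenate([th1, th2]), domain, 0.125
        )
        np.testing.assert_allclose(both.div, a.div + b.div, atol=1e-10)


class TestDetectAsters:
    def test_uniform_random_zero(self, domain):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pe = domain.sample_uniform(rng, 800)
            th = rng.uniform(0, 2 * np.pi, 800)
            assert detect_asters(divergence_map(pe, th, domain, 0.125)).count == 0

    def test_single_ideal_aster_found_at_center(self, rng, domain):
        pe, th = ideal_aster(rng, (0.4, -0.3))
        det = detect_asters(divergence_map(pe, th, domain, 0.125))
        assert det.count == 1
        np.testing.assert_allclose(det.centers[0], [0.4, -0.3], atol=0.13)

    def test_two_separated_asters_found(self, rng, domain):
        pe1, th1 = ideal_aster(rng, (-1.2, -0.6), n=200, rmax=0.7)
        pe2, th2 = ideal_aster(rng, (1.2, 0.8), n=200, rmax=0.7)
        det = detect_asters(
            divergence_map(
                np.vstack([pe1, pe2]), np.concatenate([th1, th2]), domain, 0.125
            )
        )
        assert det.count == 2


class TestRendering:
    def cfg(self):
        return SimulationConfig(n_filaments=2, n_motors=1, hexagon_circumradius=2.5)

    def test_empty_state_all_zero(self):
        cfg = SimulationConfig(n_filaments=0, n_motors=0, hexagon_circumradius=2.5)
        state = make_state()
        assert render_frame(state, cfg).intensity.sum() == 0

    def test_overlapping_filaments_add(self):
        cfg = self.cfg()
        state = make_state(fil=[(0, 0, 0.3), (0, 0, 0.3)], motors=[dict(pos=(0, 0))])
        img = render_frame(state, cfg, channel="filament").intensity
        assert img.max() == 2.0

    def test_horizontal_filament_pixel_count(self):
        # 1 um rod at 0.05 um/px: ~21 pixels in a single row
        cfg = self.cfg()
        state = make_state(fil=[(0, 0, 0.0), (0, 1.0, np.pi / 2)], motors=[dict(pos=(2, 2))])
        img = render_frame(state, cfg, pixel_size=0.05, channel="filament").intensity
        rows_lit = np.nonzero((img > 0).any(axis=1))[0]
        horiz_row = (img > 0).sum(axis=1).argmax()
        assert (img[horiz_row] > 0).sum() == pytest.approx(21, abs=1)
        assert rows_lit.size > 2  # the vertical rod spans many rows

    def test_intensity_conservation(self, rng, domain):
        cfg = SimulationConfig(n_filaments=40, n_motors=0, hexagon_circumradius=2.5)
        from astersim.patterning import init_random

        state = init_random(cfg, rng)
        img = render_frame(state, cfg, pixel_size=0.05).intensity
        px_per_fil = 1.0 / 0.05
        assert img.sum() == pytest.approx(40 * px_per_fil, abs=40 * 2)

    def test_motor_channel_counts_motors(self):
        cfg = self.cfg()
        state = make_state(fil=[(0, 0, 0)], motors=[dict(pos=(0.5, 0.5))])
        img = render_frame(state, cfg, channel="motor").intensity
        assert img.sum() == 1.0


def _const_frames(values, shape=(40, 40)):
    return [
        SyntheticFrame(np.full(shape, v, dtype=float), 0.05, (-1.0, -1.0), "filament")
        for v in values
    ]


class TestRoiAndKymograph:
    def test_constant_frames_constant_series(self):
        series = roi_mean_intensity(_const_frames([2.0, 2.0, 2.0]), (0, 0), 0.3)
        np.testing.assert_allclose(series, 1.0)  # normalized by frame mean

    def test_normalization_ratio(self):
        frames = _const_frames([1.0])
        frames[0].intensity[18:22, 18:22] = 9.0  # bright patch in the ROI
        val = roi_mean_intensity(frames, (0, 0), 0.08, normalize=True)[0]
        raw = roi_mean_intensity(frames, (0, 0), 0.08, normalize=False)[0]
        assert raw > val > 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_mean_intensity(_const_frames([1.0]), (50.0, 50.0), 0.01)

    def test_static_frames_give_identical_kymograph_columns(self):
        frames = _const_frames([1.0, 1.0, 1.0, 1.0])
        for f in frames:
            f.intensity[20, :] = 5.0
        kymo = kymograph(frames, (-0.9, 0.0), (0.9, 0.0))
        assert kymo.shape[1] == 4
        for t in range(1, 4):
            np.testing.assert_array_equal(kymo[:, t], kymo[:, 0])
        assert kymo.max() == 5.0


class TestHexSegmentation:
    def _frames_with_blobs(self, centers, value=10.0):
        shape = (100, 100)
        img = np.ones(shape)
        for cx, cy in centers:
            ix = int((cx + 2.5) / 0.05)
            iy = int((cy + 2.5) / 0.05)
            img[iy - 5 : iy + 5, ix - 5 : ix + 5] = value
        return [SyntheticFrame(img, 0.05, (-2.5, -2.5), "filament")]

    def test_uniform_stack_no_regions(self, domain):
        frames = [SyntheticFrame(np.ones((100, 100)), 0.05, (-2.5, -2.5), "f")]
        seg = coarse_hexagon_segmentation(frames, domain, hex_size=0.3)
        assert seg.n_regions[0] == 0

    def test_single_blob_one_region(self, domain):
        seg = coarse_hexagon_segmentation(
            self._frames_with_blobs([(0.0, 0.0)]), domain, hex_size=0.15
        )
        assert seg.n_regions[0] == 1
        assert seg.area[0] > 0
        assert seg.min_boundary_distance[0] > 1.0

    def test_two_blobs_two_regions_merge_to_one(self, domain):
        seg2 = coarse_hexagon_segmentation(
            self._frames_with_blobs([(-1.2, 0.0), (1.2, 0.0)]), domain, hex_size=0.15
        )
        assert seg2.n_regions[0] == 2
        seg1 = coarse_hexagon_segmentation(
            self._frames_with_blobs([(-0.2, 0.0), (0.2, 0.0)]), domain, hex_size=0.15
        )
        assert seg1.n_regions[0] == 1


class TestMotorForceStats:
    def test_no_two_bound_mean_zero(self):
        cfg = SimulationConfig(n_filaments=1, n_motors=2, hexagon_circumradius=2.5)
        state = make_state(
            fil=[(0, 0, 0)],
            motors=[dict(pos=(1, 1)), dict(bound=(0, None), lens=(0.1, 0))],
        )
        assert mean_motor_force(state, cfg) == (0.0, 0.0)

    def test_fully_stretched_motor_exerts_maximum(self):
        cfg = SimulationConfig(n_filaments=2, n_motors=1, hexagon_circumradius=2.5)
        state = make_state(
            fil=[(0.0, 0.0, 0.0), (0.0, 0.3, 0.0)],
            motors=[dict(bound=(0, 1), lens=(0.0, 0.0))],
        )
        overall, exerting = mean_motor_force(state, cfg)
        assert exerting == pytest.approx(0.9)
        assert overall == pytest.approx(0.9)


class TestConnectedness:
    def brute_force_largest_cluster(self, pts, radius):
        n = len(pts)
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(pts[i] - pts[j]) < radius:
                    parent[find(i)] = find(j)
        sizes = {}
        for i in range(n):
            r = find(i)
            sizes[r] = sizes.get(r, 0) + 1
        return max(sizes.values()) / n

    def test_single_point_cluster(self):
        pts = np.zeros((50, 2))
        assert plus_end_connectedness(pts, 0.6) == 1.0

    def test_all_singletons(self):
        pts = np.arange(20, dtype=float)[:, None] * [10.0, 0.0]
        assert plus_end_connectedness(pts, 0.6) == pytest.approx(1 / 20)

    def test_matches_brute_force_union_find(self, rng):
        pts = rng.uniform(-1, 1, size=(120, 2))
        for radius in (0.1, 0.25, 0.5):
            assert plus_end_connectedness(pts, radius) == pytest.approx(
                self.brute_force_largest_cluster(pts, radius)
            )

    def test_collapsed_set_more_connected_than_uniform(self, rng, domain):
        uniform = domain.sample_uniform(rng, 100)
        collapsed = 0.3 * rng.uniform(-1, 1, size=(100, 2))
        r = 0.6
        assert plus_end_connectedness(collapsed, r) > plus_end_connectedness(uniform, r)


class TestEnergy:
    def test_idle_system_all_zero(self):
        cfg = SimulationConfig(n_filaments=1, n_motors=1, hexagon_circumradius=2.5)
        state = make_state(fil=[(0, 0, 0)], motors=[dict(pos=(1, 1))])
        drags = drag_coefficients(1.0, 0.008, 1.0)
        row = energy_accounting(state, state.copy(), cfg, drags, 0.01)
        assert row.elastic_energy == 0.0
        assert row.dissipation == 0.0

    def test_stretched_connector_elastic_energy(self):
        cfg = SimulationConfig(n_filaments=2, n_motors=1, hexagon_circumradius=2.5)
        state = make_state(
            fil=[(0.0, 0.0, 0.0), (0.0, 0.3, 0.0)],
            motors=[dict(bound=(0, 1), lens=(0.0, 0.0))],
        )
        assert elastic_energy(state, cfg) == pytest.approx(0.135)

    def test_pure_parallel_glide_dissipation(self):
        cfg = SimulationConfig(n_filaments=1, n_motors=0, hexagon_circumradius=2.5)
        drags = drag_coefficients(1.0, 0.008, 1.0)
        before = make_state(fil=[(0.0, 0.0, 0.0)])
        after = before.copy()
        u = 0.5  # um/s for one 0.01 s step
        after.fil_center[0, 0] += u * 0.01
        row = energy_accounting(before, after, cfg, drags, 0.01)
        assert row.dissipation == pytest.approx(drags.par * u**2 * 0.01)
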