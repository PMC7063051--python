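"""Screw-axis estimation and ideal alpha-helix refitting."""

import numpy as np
import pytest

import cryotrace as ct
from cryotrace.helix import (
    HELIX_OMEGA, HELIX_RADIUS, HELIX_RISE, HelixParams, ScrewAxis,
    detect_helix_segments, estimate_screw_axis, ideal_helix_point, refit_helix,
)


def straight_axis(length=30.0, lo=-3.0):
    return ScrewAxis(np.array([[0.0, 0.0, lo], [0.0, 0.0, lo + length]]))


def ideal_points(axis, t0, t1, s=0.0, r=0.0):
    p = HelixParams(axis=axis, s=s, r=r)
    return np.stack([ideal_helix_point(t, p) for t in np.arange(t0, t1, HELIX_RISE)])


class TestScrewAxis:
    def test_straight_helix_axis_on_z(self):
        k = np.arange(20)
        pts = np.stack([2.3 * np.cos(k * np.deg2rad(100)),
                        2.3 * np.sin(k * np.deg2rad(100)), 1.5 * k], axis=1)
        axis = estimate_screw_axis(pts)
        assert np.linalg.norm(axis.polyline[:, :2], axis=1).max() < 0.25

    def test_bent_helix_axis_follows_arc(self):
        radius_curv = 30.0
        tt = np.arange(0, 30, 1.5) / radius_curv
        arc = np.stack([radius_curv * np.sin(tt),
                        radius_curv * (1 - np.cos(tt)),
                        np.zeros_like(tt)], axis=1)
        axis_true = ScrewAxis(arc)
        pts = ideal_points(axis_true, 0.0, axis_true.length)
        est = estimate_screw_axis(pts)
        center = np.array([0.0, radius_curv, 0.0])
        devs = []
        for p in est.polyline:
            q = p - center
            devs.append(np.hypot(np.hypot(q[0], q[1]) - radius_curv, p[2]))
        assert max(devs) < 0.5

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            estimate_screw_axis(np.zeros((3, 3)), window=4)

    def test_arclength_parameterization(self):
        axis = ScrewAxis(np.array([[0, 0, 0], [0, 3, 4], [0, 6, 8]], float))
        assert axis.length == pytest.approx(10.0)
        assert np.allclose(axis.point_at(5.0), [0, 3, 4])
        assert np.allclose(axis.tangent_at(2.0), [0, 0.6, 0.8])
        with pytest.raises(ValueError):
            axis.point_at(11.0)


class TestIdealHelixPoint:
    def test_t_zero_point(self):
        p = ideal_helix_point(3.0, HelixParams(axis=straight_axis(), s=3.0, r=0.0))
        # theta = 0: offset is radius * local y = (0, -2.11, 0) in this frame
        assert np.allclose(p, [0.0, -HELIX_RADIUS, p[2]], atol=1e-12)
        assert np.hypot(p[0], p[1]) == pytest.approx(HELIX_RADIUS)

    @pytest.mark.parametrize("t", [0.0, 1.5, 7.3, 19.2])
    def test_distance_to_axis_is_radius(self, t):
        p = ideal_helix_point(t, HelixParams(axis=straight_axis(lo=0.0), s=0.4, r=1.1))
        assert np.hypot(p[0], p[1]) == pytest.approx(HELIX_RADIUS, abs=1e-12)

    def test_radius_on_random_smooth_axis(self, rng):
        # gently curved axis
        tt = np.linspace(0, 1, 12)
        poly = np.stack([20 * tt, 3 * np.sin(2 * tt), 2 * tt**2], axis=1)
        axis = ScrewAxis(poly)
        for t in rng.uniform(0, axis.length, 5):
            p = ideal_helix_point(float(t), HelixParams(axis=axis, s=0.2, r=2.0))
            d = np.linalg.norm(p - axis.point_at(float(t)))
            assert d == pytest.approx(HELIX_RADIUS, abs=1e-9)

    def test_angular_advance_matches_omega(self):
        prm = HelixParams(axis=straight_axis(lo=0.0))
        dt = 1.5
        a = ideal_helix_point(2.0, prm)
        b = ideal_helix_point(2.0 + dt, prm)
        ang = np.arctan2(b[1], b[0]) - np.arctan2(a[1], a[0])
        ang = (ang + np.pi) % (2 * np.pi) - np.pi
        assert abs(ang) == pytest.approx(HELIX_OMEGA * dt, abs=1e-9)

    def test_scalar_evaluation_oracle(self):
        """theta = 1.149 * 1.5 at t = 1.5 from phase zero."""
        prm = HelixParams(axis=straight_axis(lo=0.0), s=0.0, r=0.0)
        p = ideal_helix_point(1.5, prm)
        theta = 1.149 * 1.5
        # frame at +z tangent: local x = (1,0,0), local y = (0,-1,0)
        assert p[0] == pytest.approx(2.11 * np.sin(theta), abs=1e-9)
        assert p[1] == pytest.approx(-2.11 * np.cos(theta), abs=1e-9)
        assert p[2] == pytest.approx(1.5)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            ideal_helix_point(1000.0, HelixParams(axis=straight_axis()))

    def test_right_handed_chirality(self):
        """Cross product of successive radial offsets points along +tangent."""
        prm = HelixParams(axis=straight_axis(lo=0.0))
        a = ideal_helix_point(1.0, prm)
        b = ideal_helix_point(1.5, prm)
        ra, rb = a.copy(), b.copy()
        ra[2] = rb[2] = 0
        assert np.cross(ra, rb)[2] > 0


class TestRefitHelix:
    def test_self_consistency_on_ideal_input(self):
        axis = straight_axis(36.0)
        pts = ideal_points(axis, 3.0, 33.0, r=0.7)
        out = refit_helix(pts)
        d = np.linalg.norm(out.points[:, None] - pts[None], axis=-1).min(axis=1)
        assert abs(len(out) - len(pts)) <= 1
        assert d.max() < 0.1

    def test_rise_and_radius_of_refit(self):
        """Successive refit atoms advance 1.5 A along the axis at radius 2.11.

        Checked in the world frame on the interior of the helix, where the
        estimated axis coincides with the true z axis; the extrapolated axis
        ends wobble within a tenth of an Angstrom.
        """
        axis = straight_axis(36.0)
        pts = ideal_points(axis, 3.0, 33.0, r=1.2)
        out = refit_helix(pts)
        z = np.diff(out.points[:, 2])
        assert np.allclose(np.abs(z), HELIX_RISE, atol=0.1)
        interior = out.points[3:-3]
        assert np.allclose(np.diff(interior[:, 2]), np.sign(z[3]) * HELIX_RISE,
                           atol=1e-3)
        radial = np.linalg.norm(interior[:, :2], axis=1)
        assert np.allclose(radial, HELIX_RADIUS, atol=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_jitter_shrinks_after_refit(self, seed):
        axis = straight_axis(36.0)
        ideal = ideal_points(axis, 3.0, 33.0, r=0.3)
        rng = np.random.default_rng(seed)
        noisy = ideal + rng.normal(scale=0.3, size=ideal.shape)
        out = refit_helix(noisy)
        before = np.linalg.norm(noisy[:, None] - ideal[None], axis=-1).min(axis=1).mean()
        after = np.linalg.norm(out.points[:, None] - ideal[None], axis=-1).min(axis=1).mean()
        assert after < before

    def test_objective_optimal_among_grid(self):
        axis = straight_axis(24.0)
        pts = ideal_points(axis, 1.5, 22.5, s=0.8, r=2.0)
        out = refit_helix(pts)

        def objective(placed):
            d = np.linalg.norm(placed[:, None] - pts[None], axis=-1)
            return d.min(axis=1).mean()

        val_opt = objective(out.points)
        prm = lambda s, r: HelixParams(axis=estimate_screw_axis(pts), s=s, r=r)
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = float(rng.uniform(0, HELIX_RISE))
            r = float(rng.uniform(0, 2 * np.pi))
            axis_e = estimate_screw_axis(pts)
            ts = np.arange(s, axis_e.length, HELIX_RISE)
            placed = np.stack([ideal_helix_point(t, HelixParams(axis=axis_e, s=s, r=r))
                               for t in ts])
            assert val_opt <= objective(placed) + 1e-6


class TestDetectHelixSegments:
    def test_oracle_maps_mark_helix_run(self, small_protein, small_oracle):
        traces = ct.trace_all(small_oracle)
        g = ct.traces_to_graph(traces)
        segs = detect_helix_segments(g, small_oracle)
        assert len(segs) >= 1
        # the protein starts with a 15-residue helix
        assert max(len(s) for s in segs) >= 10

    def test_short_run_not_reported(self, rng):
        model = ct.generate_synthetic_protein([("helix", 4), ("loop", 8)], seed=3)
        dm = ct.simulate_density(model, 3.0)
        maps = ct.oracle_confidence(model, dm)
        traces = ct.trace_all(maps)
        g = ct.traces_to_graph(traces)
        segs = detect_helix_segments(g, maps, min_len=6)
        assert all(len(s) >= 6 for s in segs)
        assert len(segs) == 0
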