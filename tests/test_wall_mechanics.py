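"""WSS estimator: gradient tensor, traction, temporal averaging,
decomposition and OSI, checked against symbolic/closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from aortaflow import (
    VelocityField4D, LumenMask, WallShearSeries, deformation_tensor_at,
    wss_vector, temporal_average, decompose, osi, compute_wall_shear,
    component_table, build_wall_frames, extract_centerline,
)
from aortaflow.geometry import WallFrameSet

from conftest import mid_section

ETA = 0.004


def _box_field(fn, n=24, h=0.1, wall_frac=0.5):
    """Velocity field fn(x, y, z) -> (vx, vy, vz) on a box whose lumen is
    the lower-y half; returns (vel, mask, wall_y)."""
    c = (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    vx, vy, vz = fn(X, Y, Z)
    data = np.stack([np.broadcast_to(a, X.shape) for a in (vx, vy, vz)])[None]
    vel = VelocityField4D(np.array(data, dtype=float), [h] * 3)
    m = np.zeros((n, n, n), bool)
    k = int(n * wall_frac)
    m[:, :k, :] = True
    return vel, LumenMask(m[None], [h] * 3), c[k - 1] + h / 2


class TestDeformationTensor:
    def test_uniform_field_zero_tensor(self):
        vel, mask, wy = _box_field(lambda X, Y, Z: (30.0, 10.0, -5.0))
        eps = deformation_tensor_at([1.2, wy, 1.2], [0, -1, 0], vel, mask, 0)
        np.testing.assert_allclose(eps, 0.0, atol=1e-6)

    def test_planar_shear(self):
        # v_x = k y with k = 100 1/s  (= 10 (cm/s)/mm)
        vel, mask, wy = _box_field(lambda X, Y, Z: (10.0 * Y, 0.0, 0.0))
        eps = deformation_tensor_at([1.2, wy, 1.2], [0, -1, 0], vel, mask, 0)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 50.0
        np.testing.assert_allclose(eps, expected, atol=0.5)

    def test_rigid_rotation_cancels(self):
        # v = omega x r has antisymmetric gradient -> eps = 0
        om = 5.0  # (cm/s)/mm
        vel, mask, wy = _box_field(
            lambda X, Y, Z: (-om * (Y - 1.2), om * (X - 1.2), 0.0))
        eps = deformation_tensor_at([1.2, wy, 1.2], [0, -1, 0], vel, mask, 0)
        np.testing.assert_allclose(eps, 0.0, atol=0.5)

    def test_too_few_interior_samples(self):
        vel, mask, wy = _box_field(lambda X, Y, Z: (10.0 * Y, 0.0, 0.0))
        # outward normal: the ray leaves the lumen immediately
        with pytest.raises(ValueError, match="interior samples"):
            deformation_tensor_at([1.2, wy, 1.2], [0, 1, 0], vel, mask, 0)


class TestWssVector:
    def test_zero_tensor_zero_vector(self):
        np.testing.assert_array_equal(
            wss_vector(np.zeros((3, 3)), np.array([0, 1.0, 0]), ETA), 0.0)

    def test_planar_shear_hand_value(self):
        # 2 * 0.004 * 50 = 0.4 Pa along x for wall normal y
        eps = np.zeros((3, 3))
        eps[0, 1] = eps[1, 0] = 50.0
        tau = wss_vector(eps, np.array([0, 1.0, 0]), ETA)
        np.testing.assert_allclose(tau, [0.4, 0, 0], atol=1e-12)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            wss_vector(np.eye(3), np.array([0, 2.0, 0]), ETA)
        with pytest.raises(ValueError, match="eta"):
            wss_vector(np.eye(3), np.array([0, 1.0, 0]), 0.0)

    def test_poiseuille_magnitude(self, poiseuille, poiseuille_mesh,
                                  poiseuille_wss):
        spec, _, _, truth = poiseuille
        mid = mid_section(poiseuille_mesh, 0.5, spec.length - 0.5)
        ok = poiseuille_wss.valid & mid
        mag = np.linalg.norm(poiseuille_wss.tau_mean, axis=1)
        assert mag[ok].mean() == pytest.approx(truth.wss_long_wall, rel=0.10)


class TestTemporalAverage:
    def test_constant_series(self):
        tau = np.tile([1.0, 2.0, 3.0], (5, 1, 1))
        s = WallShearSeries(np.array([0]), tau, np.array([True]))
        np.testing.assert_allclose(temporal_average(s)[0], [1, 2, 3])

    def test_cancellation(self):
        a = np.array([1.0, 0, 0])
        tau = np.stack([a, -a, a, -a])[:, None, :]
        s = WallShearSeries(np.array([0]), tau, np.array([True]))
        np.testing.assert_allclose(temporal_average(s), 0.0, atol=1e-15)

    def test_fifteen_five_split(self):
        a = np.array([1.0, 0, 0])
        tau = np.concatenate([np.tile(a, (15, 1)), np.tile(-a, (5, 1))])[:, None, :]
        s = WallShearSeries(np.array([0]), tau, np.array([True]))
        np.testing.assert_allclose(temporal_average(s)[0], [0.5, 0, 0])


def _random_frame(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return WallFrameSet(node_id=np.array([0]), l_hat=q[None, :, 0],
                        c_hat=q[None, :, 1], r_hat=q[None, :, 2],
                        theta=np.array([0.0]), z=np.array([0.0]),
                        valid=np.array([True]))


class TestDecompose:
    def test_aligned_case(self):
        rng = np.random.default_rng(0)
        f = _random_frame(rng)
        tau = 2.0 * f.l_hat[0]
        lo, ci, ra = decompose(tau, f)
        assert lo[0] == pytest.approx(2.0, abs=1e-12)
        assert abs(ci[0]) < 1e-12 and abs(ra[0]) < 1e-12

    def test_toward_centerline_positive(self):
        rng = np.random.default_rng(1)
        f = _random_frame(rng)
        tau = 0.7 * f.r_hat[0]  # r_hat points toward the centerline
        assert decompose(tau, f)[2][0] > 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_parseval(self, seed):
        rng = np.random.default_rng(seed)
        f = _random_frame(rng)
        tau = rng.normal(size=3)
        lo, ci, ra = decompose(tau, f)
        assert lo[0]**2 + ci[0]**2 + ra[0]**2 == pytest.approx(
            np.sum(tau**2), rel=1e-9)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        f = _random_frame(rng)
        tau = rng.normal(size=3)
        lo, ci, ra = decompose(tau, f)
        rec = lo[0] * f.l_hat[0] + ci[0] * f.c_hat[0] + ra[0] * f.r_hat[0]
        np.testing.assert_allclose(rec, tau, atol=1e-9)


def _series(taus):
    return WallShearSeries(np.array([0]), np.asarray(taus, float)[:, None, :],
                           np.array([True]))


class TestOsi:
    def test_constant_series_zero(self):
        assert osi(_series([[1.0, 0, 0]] * 20))[0] == 0.0

    def test_balanced_alternation_fifty(self):
        a = [1.0, 0, 0]
        assert osi(_series([a] * 10 + [[-1.0, 0, 0]] * 10))[0] == pytest.approx(50.0)

    def test_fifteen_five_twentyfive(self):
        s = _series([[2.0, 0, 0]] * 15 + [[-2.0, 0, 0]] * 5)
        assert osi(s)[0] == pytest.approx(25.0)

    def test_all_zero_maps_to_zero(self):
        assert osi(_series([[0.0, 0, 0]] * 20))[0] == 0.0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            osi(_series([[1.0, 0, 0]]))

    @given(hnp.arrays(np.float64, (20, 3),
                      elements=st.floats(-100, 100, allow_nan=False)))
    @settings(max_examples=200, deadline=None)
    def test_range_invariant(self, taus):
        val = osi(_series(taus))[0]
        assert 0.0 <= val <= 50.0


class TestComputeWallShear:
    def test_linearity_in_velocity(self, poiseuille, poiseuille_mesh):
        _, vel, mask, _ = poiseuille
        s1 = compute_wall_shear(vel, mask, poiseuille_mesh, eta=ETA)
        scaled = VelocityField4D(3.0 * vel.data, vel.spacing, vel.origin,
                                 vel.frame_times)
        s3 = compute_wall_shear(scaled, mask, poiseuille_mesh, eta=ETA)
        np.testing.assert_allclose(s3.tau, 3.0 * s1.tau, rtol=1e-9, atol=1e-8)

    def test_component_table_schema(self, poiseuille, poiseuille_mesh,
                                    poiseuille_wss):
        _, _, mask, _ = poiseuille
        cl = extract_centerline(mask)
        frames = build_wall_frames(poiseuille_mesh, cl)
        df = component_table(poiseuille_wss, frames)
        assert set(df.columns) >= {"node_id", "z_mm", "theta_deg",
                                   "long_wss_pa", "circ_wss_pa",
                                   "rad_strain_pa", "osi_pct", "valid"}
        ok = df["valid"].to_numpy()
        mag2 = (df["long_wss_pa"]**2 + df["circ_wss_pa"]**2
                + df["rad_strain_pa"]**2).to_numpy()
        tau2 = np.sum(poiseuille_wss.tau_mean**2, axis=1)
        np.testing.assert_allclose(mag2[ok], tau2[ok], rtol=1e-9)
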