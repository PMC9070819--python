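"""Three-link inverse dynamics against closed-form statics and an independent
pinned-chain Newton-Euler oracle."""

import numpy as np
import pytest

from felanding.exceptions import ConfigurationError, SignalError
from felanding.inverse_dynamics import (G, INERTIAS_KGM2, MASS_FRACTIONS,
                                        LinkKinematics, SegmentParams,
                                        compute_joint_loads,
                                        differentiate_kinematics,
                                        moments_to_trajectories)


def static_kinematics(alpha_deg, n=50):
    a = np.deg2rad(np.asarray(alpha_deg, float))[:, None] * np.ones(n)
    return LinkKinematics(alpha=a, alpha_dot=np.zeros_like(a),
                          alpha_ddot=np.zeros_like(a))


def pinned_chain_oracle(grf_y, grf_z, alpha, dt, params, g=G):
    """Independent free-body recursion: joint/COM positions of the chain
    pinned at the contact point, COM accelerations by numerical
    differentiation, moment balance via explicit 2-D cross products."""
    L = params.lengths
    cf = params.com_fractions
    e_y = np.cos(alpha)
    e_z = np.sin(alpha)
    cross = lambda ry, rz, fy, fz: ry * fz - rz * fy

    def d2(x):
        return np.gradient(np.gradient(x, dt, edge_order=2), dt, edge_order=2)

    joint_y = np.zeros_like(alpha[0])
    joint_z = np.zeros_like(alpha[0])
    Fy_d, Fz_d, M_d = grf_y, grf_z, np.zeros_like(grf_y)
    moments = []
    for i in range(3):
        com_y = joint_y + cf[i] * L[i] * e_y[i]
        com_z = joint_z + cf[i] * L[i] * e_z[i]
        a_y, a_z = d2(com_y), d2(com_z)
        add = d2(alpha[i])
        Fy_p = Fy_d + params.masses[i] * a_y
        Fz_p = Fz_d + params.masses[i] * g + params.masses[i] * a_z
        # lever arms from the COM to the proximal and distal endpoints
        rp_y, rp_z = (1 - cf[i]) * L[i] * e_y[i], (1 - cf[i]) * L[i] * e_z[i]
        rd_y, rd_z = -cf[i] * L[i] * e_y[i], -cf[i] * L[i] * e_z[i]
        M_p = (M_d - params.inertias[i] * add
               + cross(rp_y, rp_z, Fy_p, Fz_p)
               + cross(rd_y, rd_z, -Fy_d, -Fz_d))
        moments.append(M_p)
        joint_y = joint_y + L[i] * e_y[i]
        joint_z = joint_z + L[i] * e_z[i]
        Fy_d, Fz_d, M_d = Fy_p, Fz_p, M_p
    return np.vstack(moments)


PARAMS = SegmentParams.from_body_mass(4.0, (0.05, 0.10, 0.11))


class TestDifferentiation:
    def test_constant_angles_zero_derivatives(self):
        kin = differentiate_kinematics(np.full((3, 100), 0.7), 1000.0)
        np.testing.assert_allclose(kin.alpha_dot, 0, atol=1e-12)
        np.testing.assert_allclose(kin.alpha_ddot, 0, atol=1e-12)

    def test_linear_ramp_exact_at_interior(self):
        t = np.arange(200) / 1000.0
        kin = differentiate_kinematics(np.vstack([3.0 * t] * 3), 1000.0)
        np.testing.assert_allclose(kin.alpha_dot[:, 1:-1], 3.0, atol=1e-9)
        np.testing.assert_allclose(kin.alpha_ddot[:, 2:-2], 0.0, atol=1e-6)

    def test_sine_error_within_second_order_bound(self):
        fs, w = 1000.0, 2 * np.pi * 3.0
        t = np.arange(2000) / fs
        kin = differentiate_kinematics(np.sin(w * t)[None, :].repeat(3, 0), fs)
        dt = 1 / fs
        sl = slice(5, -5)  # one-sided boundary stencils are noisier
        vel_err = np.max(np.abs(kin.alpha_dot[0] - w * np.cos(w * t))[sl])
        acc_err = np.max(np.abs(kin.alpha_ddot[0] + w ** 2 * np.sin(w * t))[sl])
        assert vel_err < w ** 3 * dt ** 2  # O(dt^2), generous constant
        assert acc_err < 10 * w ** 4 * dt ** 2

    def test_too_few_samples(self):
        with pytest.raises(SignalError):
            differentiate_kinematics(np.zeros((3, 4)), 1000.0)


class TestStatics:
    def test_vertical_segment_zero_wrist_moment(self):
        kin = static_kinematics([90, 90, 90])
        loads = compute_joint_loads(np.zeros(50), np.full(50, 25.0), kin, PARAMS)
        np.testing.assert_allclose(loads.wrist, 0.0, atol=1e-12)

    def test_horizontal_segment_hand_worked_example(self):
        # m1 = 0.1 kg, L1 = 0.1 m, Fz = 20 N: F1z = 20.981 N,
        # M1 = (F1z + Fz) * L1/2 = 2.049 N*m  (static free-body equilibrium)
        params = SegmentParams(masses=(0.1, 0.2, 0.3), lengths=(0.1, 0.12, 0.13))
        kin = static_kinematics([0, 45, 80])
        loads = compute_joint_loads(np.zeros(50), np.full(50, 20.0), kin, params)
        np.testing.assert_allclose(loads.reactions_z[0], 20.0 + 0.1 * G, atol=1e-12)
        np.testing.assert_allclose(loads.wrist, (2 * 20.0 + 0.1 * G) * 0.05, atol=1e-12)

    def test_static_vertical_reactions_telescope_to_supported_weight(self):
        kin = static_kinematics([30, 60, 100])
        fz = np.full(50, 18.0)
        loads = compute_joint_loads(np.zeros(50), fz, kin, PARAMS)
        total_weight = sum(PARAMS.masses) * G
        np.testing.assert_allclose(loads.reactions_z[2], 18.0 + total_weight, atol=1e-12)

    def test_doubling_mass_doubles_gravity_moment_component(self):
        kin = static_kinematics([10, 40, 70])
        zero = np.zeros(50)
        single = compute_joint_loads(zero, zero, kin, PARAMS)
        doubled = compute_joint_loads(
            zero, zero, kin,
            SegmentParams(masses=tuple(2 * m for m in PARAMS.masses),
                          lengths=PARAMS.lengths, inertias=PARAMS.inertias))
        np.testing.assert_allclose(doubled.moments, 2 * single.moments, atol=1e-12)

    def test_gravity_only_matches_closed_form_per_sample(self):
        # static horizontal chain, no GRF: each proximal moment is the torque
        # of the supported segment weights about that joint
        params = SegmentParams(masses=(0.1, 0.2, 0.3), lengths=(0.1, 0.2, 0.3))
        kin = static_kinematics([0, 0, 0], n=10)
        zero = np.zeros(10)
        loads = compute_joint_loads(zero, zero, kin, params)
        m1 = 0.1 * G * 0.05
        np.testing.assert_allclose(loads.wrist, m1, atol=1e-12)
        m2 = m1 + (loads.reactions_z[1][0] + loads.reactions_z[0][0]) * 0.1
        np.testing.assert_allclose(loads.elbow, m2, atol=1e-12)


class TestOracleEquivalence:
    def test_matches_pinned_chain_oracle_on_analytic_trajectories(self):
        """Closed-form recursion vs independent numerically-differentiated
        free-body oracle, <= 1e-6 relative on smooth noise-free trajectories."""
        fs = 10_000.0
        t = np.arange(3000) / fs
        rng = np.random.default_rng(7)
        for _ in range(5):
            w = rng.uniform(4.0, 12.0, size=3)       # rad/s
            phase = rng.uniform(0, 2 * np.pi, size=3)
            amp = rng.uniform(0.2, 0.6, size=3)
            base = np.deg2rad([30, 60, 100])
            alpha = base[:, None] + amp[:, None] * np.sin(w[:, None] * t + phase[:, None])
            alpha_dot = amp[:, None] * w[:, None] * np.cos(w[:, None] * t + phase[:, None])
            alpha_ddot = -amp[:, None] * w[:, None] ** 2 * np.sin(w[:, None] * t + phase[:, None])
            grf_y = 5.0 * np.sin(2 * np.pi * 3 * t)
            grf_z = 40.0 + 30.0 * np.sin(2 * np.pi * 2 * t)
            kin = LinkKinematics(alpha=alpha, alpha_dot=alpha_dot, alpha_ddot=alpha_ddot)
            loads = compute_joint_loads(grf_y, grf_z, kin, PARAMS)
            oracle = pinned_chain_oracle(grf_y, grf_z, alpha, 1 / fs, PARAMS)
            # exclude the one-sided-difference edges of the oracle
            sl = slice(5, -5)
            for i in range(3):
                scale = np.max(np.abs(loads.moments[i][sl]))
                err = np.max(np.abs(loads.moments[i][sl] - oracle[i][sl]))
                assert err / scale < 1e-6

    def test_off_midpoint_com_also_matches_oracle(self):
        fs = 10_000.0
        t = np.arange(2000) / fs
        params = SegmentParams(masses=(0.05, 0.2, 0.35), lengths=(0.05, 0.1, 0.12),
                               com_fractions=(0.4, 0.55, 0.45))
        alpha = np.deg2rad(np.vstack([
            20 + 10 * np.sin(2 * np.pi * 1.5 * t),
            60 + 12 * np.cos(2 * np.pi * 1.2 * t),
            100 + 8 * np.sin(2 * np.pi * 1.8 * t),
        ]))
        kin = differentiate_kinematics(alpha, fs)
        grf_z = 50 + 20 * np.sin(2 * np.pi * 2.5 * t)
        loads = compute_joint_loads(np.zeros_like(t), grf_z, kin, params)
        oracle = pinned_chain_oracle(np.zeros_like(t), grf_z, alpha, 1 / fs, params)
        sl = slice(5, -5)
        for i in range(3):
            scale = np.max(np.abs(loads.moments[i][sl]))
            assert np.max(np.abs(loads.moments[i][sl] - oracle[i][sl])) / scale < 1e-5


class TestValidationAndTrajectories:
    def test_non_finite_input_names_channel(self):
        kin = static_kinematics([0, 45, 90], n=20)
        bad = np.zeros(20)
        bad[7] = np.nan
        with pytest.raises(SignalError, match="grf_z.*7"):
            compute_joint_loads(np.zeros(20), bad, kin, PARAMS)

    def test_segment_params_validation(self):
        with pytest.raises(ConfigurationError):
            SegmentParams(masses=(0, 1, 1), lengths=(0.1, 0.1, 0.1))
        with pytest.raises(ConfigurationError):
            SegmentParams(masses=(1, 1, 1), lengths=(0.1, 0.1, 0.1),
                          com_fractions=(0.5, 0.5, 1.5))

    def test_default_parameter_table(self):
        p = SegmentParams.from_body_mass(4.0, (0.05, 0.1, 0.11))
        np.testing.assert_allclose(p.masses, [4.0 * f for f in MASS_FRACTIONS])
        assert p.inertias == INERTIAS_KGM2
        # distal (carpal) link is the lightest, arm the heaviest
        assert p.masses[0] < p.masses[1] < p.masses[2]

    def test_constant_moments_give_constant_100_point_curves(self):
        kin = static_kinematics([0, 45, 90], n=37)
        loads = compute_joint_loads(np.zeros(37), np.full(37, 20.0), kin, PARAMS)
        curves = moments_to_trajectories(loads)
        assert set(curves) == {"wrist_moment", "elbow_moment", "shoulder_moment"}
        for c in curves.values():
            assert c.shape == (100,)
            assert np.ptp(c) < 1e-12
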