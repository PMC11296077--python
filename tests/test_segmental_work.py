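"""Internal work, inverse dynamics, joint power and the partition."""

import numpy as np
import pytest

from bouncework import errors
from bouncework.body_model import SegmentFractions, build_segments
from bouncework.com_mechanics import EnergyCurve, WorkIncrements, work_increments
from bouncework.segmental_work import (
    JointKinetics,
    internal_energy,
    inverse_dynamics_limb,
    joint_power_work,
    partition_work,
)
from bouncework.trial_io import ForceSeries

from test_body_model import META, static_markers

G = 9.81


def make_segment(vel, omega, mass, inertia):
    """Minimal rigid-segment stand-in for energy bookkeeping tests."""
    from bouncework.body_model import SegmentState
    n = vel.shape[0]
    zeros = np.zeros((n, 2))
    return SegmentState(name="synthetic", proximal=zeros, distal=zeros,
                        com=zeros, vel=vel, acc=zeros,
                        angle=np.zeros(n), omega=omega,
                        alpha=np.zeros(n), mass=mass, inertia=inertia,
                        length=0.4)


class TestInternalEnergy:
    def test_segments_riding_on_com_have_zero_energy(self):
        n = 100
        t = np.arange(n) / 1000.0
        v = np.tile([1.0, 0.2], (n, 1))
        seg = make_segment(v, np.zeros(n), 3.0, 0.05)
        curve = internal_energy([seg], v, "E", t)
        np.testing.assert_allclose(curve.E, 0.0, atol=1e-12)

    def test_single_segment_formula_value(self):
        """m=3 kg at V'=2 m/s plus I=0.05 kg·m² at ω=10 rad/s: 6 + 2.5 J."""
        n = 10
        t = np.arange(n) / 1000.0
        seg = make_segment(np.tile([2.0, 0.0], (n, 1)),
                           np.full(n, 10.0), 3.0, 0.05)
        curve = internal_energy([seg], np.zeros((n, 2)), "E", t)
        np.testing.assert_allclose(curve.E, 8.5, rtol=1e-12)

    def test_ipsilateral_transfer_absorbs_antiphase_exchange(self):
        """Two segments with exactly antiphase energy curves: the limb sum
        is constant (W+ = 0) while per-segment increments are positive."""
        fs = 1000.0
        t = np.arange(0, 1.0, 1 / fs)
        e = 1.0 + 0.5 * np.sin(2 * np.pi * 2 * t)
        c = 3.0
        v1 = np.column_stack([np.sqrt(2 * e / 2.0), np.zeros(t.size)])
        v2 = np.column_stack([np.sqrt(2 * (c - e) / 2.0), np.zeros(t.size)])
        seg1 = make_segment(v1, np.zeros(t.size), 2.0, 0.01)
        seg2 = make_segment(v2, np.zeros(t.size), 2.0, 0.01)
        v_com = np.zeros((t.size, 2))
        stride = [(0, t.size)]
        limb = internal_energy([seg1, seg2], v_com, "limb", t)
        w_limb = work_increments(limb, stride)
        np.testing.assert_allclose(w_limb.W_plus[0], 0.0, atol=1e-9)
        w_seg = work_increments(internal_energy([seg1], v_com, "s1", t),
                                stride)
        assert w_seg.W_plus[0] > 0.4  # exchange visible per segment


def static_force_series(n=500, F_z=70 * G, cop=0.10):
    t = np.arange(n) / 1000.0
    return ForceSeries(t, np.zeros(n), np.full(n, F_z), np.full(n, cop))


class TestInverseDynamics:
    def run_static(self, cop, table=None):
        n = 500
        markers = static_markers(n=n)
        forces = static_force_series(n=n, cop=cop)
        segs = build_segments(markers, META, table)
        mask = np.ones(n, dtype=bool)
        return inverse_dynamics_limb(forces, mask, [(0, n)], segs, "R",
                                     segs["trunk"], G)

    def test_massless_foot_cop_under_ankle(self):
        """COP directly below the ankle with a (near) massless foot gives a
        vanishing ankle moment: zero lever arm."""
        tiny = {k: (SegmentFractions(1e-9, v.com_fraction, v.gyration_fraction)
                    if k == "foot" else v)
                for k, v in __import__("bouncework.body_model",
                                       fromlist=["WINTER_TABLE"]
                                       ).WINTER_TABLE.items()}
        kin = self.run_static(cop=0.0, table=tiny)
        assert np.max(np.abs(kin.M["ankle"])) < 1e-5

    def test_static_ankle_moment_matches_hand_oracle(self):
        """Full static balance against an independently derived moment
        (foot mass from the table; dominant term 686.7·0.10 = 68.67 N·m,
        extension-positive)."""
        kin = self.run_static(cop=0.10)
        # independent scalar derivation of the same statics
        F_z = 70 * G
        m_f = 0.0145 * META.mass
        ankle = np.array([0.0, 0.08])
        foot_distal = 0.5 * (np.array([-0.06, 0.04]) + np.array([0.12, 0.04]))
        com_f = ankle + 0.50 * (foot_distal - ankle)
        R_az = m_f * G - F_z                      # ankle reaction, vertical
        M_grf = (0.10 - com_f[0]) * F_z           # GRF moment about foot CoM
        M_reac = (ankle[0] - com_f[0]) * R_az     # reaction moment
        oracle_reported = -(0.0 - M_grf - M_reac)
        measured = kin.M["ankle"][100]
        assert abs(measured - oracle_reported) < 1e-9 * abs(oracle_reported)
        assert abs(oracle_reported - 68.67) < 1.0  # dominant-term sanity

    def test_power_is_moment_times_angular_velocity(self, clean_results):
        for side in ("R", "L"):
            kin = clean_results.kinetics[side]
            for j in ("ankle", "knee", "hip"):
                np.testing.assert_array_equal(kin.P[j],
                                              kin.M[j] * kin.omega[j])

    def test_rigid_generator_moments_match_ledger(self, clean_sim,
                                                  clean_results):
        """Recovered M_j within 3% RMS of the generator's independently
        computed (d'Alembert) joint moments, noise-free data path."""
        _, _, truth = clean_sim
        lo, hi = clean_results.com.span
        for side in ("R", "L"):
            kin = clean_results.kinetics[side]
            for j in ("ankle", "knee", "hip"):
                ref = truth.joint_moments[side][j][lo:hi]
                err = kin.M[j][lo:hi] - ref
                assert (np.sqrt(np.mean(err**2))
                        < 0.03 * np.sqrt(np.mean(ref**2))), (side, j)


class TestJointPowerWork:
    @staticmethod
    def kinetics_from_powers(t, P_ankle, P_knee, P_hip):
        ones = np.ones_like(t)
        return JointKinetics(side="R", time=t,
                             M={"ankle": P_ankle, "knee": P_knee,
                                "hip": P_hip},
                             omega={"ankle": ones, "knee": ones,
                                    "hip": ones})

    def test_zero_moments_zero_work(self):
        t = np.arange(701) / 1000.0
        z = np.zeros_like(t)
        _, w = joint_power_work(self.kinetics_from_powers(t, z, z, z),
                                [(0, 701)])
        assert w.W_plus[0] == 0.0 and w.W_minus[0] == 0.0

    def test_antiphase_joint_powers_cancel_before_integration(self):
        t = np.arange(0, 1.0, 1e-3)
        s = np.sin(2 * np.pi * 3 * t)
        _, w = joint_power_work(
            self.kinetics_from_powers(t, s, -s, np.zeros_like(t)),
            [(0, t.size)])
        np.testing.assert_allclose(w.W_plus[0], 0.0, atol=1e-12)

    def test_constant_power_rectangle(self):
        """P_limb = 50 W over a 0.7 s stride: W_j+ = 35 J, W_j− = 0."""
        t = np.arange(701) / 1000.0
        z = np.zeros_like(t)
        _, w = joint_power_work(
            self.kinetics_from_powers(t, np.full_like(t, 50.0), z, z),
            [(0, 701)])
        np.testing.assert_allclose(w.W_plus[0], 35.0, rtol=1e-12)
        assert w.W_minus[0] == 0.0


class TestPartition:
    @staticmethod
    def inc(plus, minus):
        return WorkIncrements(np.atleast_1d(np.asarray(plus, float)),
                              np.atleast_1d(np.asarray(minus, float)))

    def test_identities_hold_exactly(self):
        z = self.inc(0.0, 0.0)
        bd = partition_work(1.0, self.inc(2.0, -2.0), z, z, z,
                            self.inc(0.8, -0.7), self.inc(0.8, -0.9))
        np.testing.assert_allclose(bd.W_tot.W_plus, 2.0)
        np.testing.assert_allclose(bd.W_ST.W_plus, 0.4)
        np.testing.assert_allclose(bd.W_ST.W_minus, -0.4)

    def test_joint_work_equal_to_total_means_zero_soft_tissue(self):
        z = self.inc(0.0, 0.0)
        bd = partition_work(1.0, self.inc(2.0, -2.0), z, z, z,
                            self.inc(1.0, -1.0), self.inc(1.0, -1.0))
        np.testing.assert_allclose(bd.W_ST.W_plus, 0.0, atol=1e-15)
        np.testing.assert_allclose(bd.W_ST.W_minus, 0.0, atol=1e-15)

    def test_mismatched_stride_sets_rejected(self):
        z = self.inc(0.0, 0.0)
        two = WorkIncrements(np.zeros(2), np.zeros(2))
        with pytest.raises(errors.AlignmentError):
            partition_work(1.0, z, z, z, z, two, z)

    def test_breakdown_frame_identities(self, rigid_results):
        w = rigid_results.work
        np.testing.assert_allclose(
            w["W_tot+"],
            w["W_com+"] + w["W_int_R+"] + w["W_int_L+"] + w["W_int_trunk+"],
            rtol=1e-12)
        np.testing.assert_allclose(
            w["W_ST-"], w["W_tot-"] - w["W_j_R-"] - w["W_j_L-"], rtol=1e-9,
            atol=1e-12)

    def test_wobble_makes_negative_soft_tissue_work_dominate(
            self, wobble_results):
        """With a dissipative wobbling mass, |W_ST−| ≥ |W_ST+|."""
        w = wobble_results.work
        assert abs(w["W_ST-"].mean()) >= abs(w["W_ST+"].mean())
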