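"""Discrete/continuous jerk metrics and the jerk ratio."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as stn
from scipy.integrate import quad

import armsmooth as am
from armsmooth.errors import InvalidArgumentError, UndefinedRatioError
from armsmooth.jerk import JerkValue


def quintic_jerk_integral(D, T):
    """Independent symbolic oracle: ∫‖x⃛‖²dt of the minimum-jerk quintic."""
    t, DD, TT = sympy.symbols("t D T", positive=True)
    tau = t / TT
    pos = DD * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    j = sympy.lambdify(t, sympy.diff(pos, t, 3).subs({DD: D, TT: T}), "numpy")
    val, _ = quad(lambda x: j(x) ** 2, 0, T)
    return val


class TestDiscreteJerk:
    def test_constant_acceleration_has_zero_jerk(self):
        acc = np.tile([1.0, -2.0, 3.0], (50, 1))
        assert am.discrete_jerk(acc, 0, 48) == 0.0

    def test_hand_computed_sum(self):
        acc = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]])
        assert am.discrete_jerk(acc, 0, 1) == 1.0

    def test_window_errors(self):
        acc = np.zeros((10, 3))
        with pytest.raises(InvalidArgumentError):
            am.discrete_jerk(acc, 5, 4)
        with pytest.raises(InvalidArgumentError):
            am.discrete_jerk(acc, 0, 9)  # needs a(t_end + 1)

    def test_additivity_telescopes_exactly(self, rng):
        acc = rng.normal(size=(200, 3))
        whole = am.discrete_jerk(acc, 10, 150)
        parts = am.discrete_jerk(acc, 10, 80) + am.discrete_jerk(acc, 81, 150)
        # telescoping is exact up to float summation order
        assert whole == pytest.approx(parts, rel=1e-12)

    @given(c=stn.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_scale_law_quadratic_in_acceleration(self, c):
        acc = np.random.default_rng(7).normal(size=(100, 3))
        j1 = am.discrete_jerk(acc, 0, 98)
        j2 = am.discrete_jerk(c * acc, 0, 98)
        assert j2 == pytest.approx(c**2 * j1, rel=1e-9)

    @pytest.mark.parametrize("fs", [100, 200, 500, 1000])
    def test_physical_scaling_approaches_continuous_integral(self, fs):
        _, _, _, acc = am.min_jerk_profile(1.0, 1.0, fs)
        j = am.discrete_jerk(acc[:, None], 0, len(acc) - 2, physical=True, fs=fs)
        assert j == pytest.approx(720.0, rel=0.02)

    def test_convergence_error_decreases_with_sampling_rate(self):
        errors = []
        for fs in (100, 200, 500, 1000):
            _, _, _, acc = am.min_jerk_profile(1.0, 1.0, fs)
            j = am.discrete_jerk(acc[:, None], 0, len(acc) - 2, physical=True, fs=fs)
            errors.append(abs(j - 720.0))
        assert errors == sorted(errors, reverse=True)


class TestContinuousJerk:
    def test_constant_velocity_has_zero_jerk(self):
        t = np.linspace(0, 1, 1001)
        pos = np.column_stack([2 * t, -t, 0 * t])
        assert am.continuous_jerk(pos, fs=1000) == pytest.approx(0.0, abs=1e-9)

    def test_unit_third_derivative(self):
        t = np.linspace(0, 1, 2001)
        pos = np.column_stack([t**3 / 6, 0 * t, 0 * t])
        assert am.continuous_jerk(pos, fs=2000) == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("D,T", [(1.0, 1.0), (1.0, 2.0), (0.5, 3.0)])
    def test_minimum_jerk_quintic_matches_symbolic_oracle(self, D, T):
        expected = quintic_jerk_integral(D, T)
        assert expected == pytest.approx(720 * D**2 / T**5, rel=1e-9)
        fs = 2000
        _, pos, _, _ = am.min_jerk_profile(D, T, fs)
        got = am.continuous_jerk(pos[:, None], fs=fs)
        assert got == pytest.approx(expected, rel=1e-3)


class TestTotalJerk:
    def test_pythagorean_fusion(self):
        jl = JerkValue(3.0, "left", 0, 10)
        jr = JerkValue(4.0, "right", 0, 10)
        assert am.total_jerk(jl, jr).value == pytest.approx(5.0)
        assert am.total_jerk(jl, jr, rule="sum").value == pytest.approx(7.0)

    def test_zero_side_is_identity(self):
        jl = JerkValue(0.0, "left", 0, 10)
        jr = JerkValue(2.5, "right", 0, 10)
        assert am.total_jerk(jl, jr).value == pytest.approx(2.5)

    def test_mismatched_windows_rejected(self):
        with pytest.raises(InvalidArgumentError):
            am.total_jerk(JerkValue(1, "left", 0, 10), JerkValue(1, "right", 0, 11))

    def test_total_at_least_max_side(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0, 10, 2)
            tot = am.total_jerk(JerkValue(a, "l"), JerkValue(b, "r")).value
            assert tot >= max(a, b) - 1e-12


class TestJerkRatio:
    def test_equal_jerks_give_half(self):
        assert am.jerk_ratio(3.3, 3.3).r == 0.5

    def test_strong_difference_anchor(self):
        assert am.jerk_ratio(1.0, 9.0).r == pytest.approx(0.1)

    @given(
        j1=stn.floats(min_value=1e-6, max_value=1e6),
        j2=stn.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_complement_identity(self, j1, j2):
        assert am.jerk_ratio(j1, j2).r + am.jerk_ratio(j2, j1).r == pytest.approx(
            1.0, abs=1e-12
        )

    def test_monotone_in_numerator(self):
        rs = [am.jerk_ratio(j, 2.0).r for j in np.linspace(0.1, 10, 30)]
        assert np.all(np.diff(rs) > 0)

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            am.jerk_ratio(0.0, 0.0)


class TestPhaseJerks:
    @pytest.fixture(scope="class")
    @staticmethod
    def clean_recording():
        spec = am.MotionSpec(
            "sym",
            laterality="bilateral",
            saccade_rate_per_phase={},
            tremor_amplitude=0.0,
            noise_sd=0.0,
        )
        sess = am.simulate_session([spec], rng_seed=11)
        return sess.movements[0]

    @staticmethod
    def seg_from_truth(gt):
        return am.SegmentationResult(
            fs=gt.fs,
            n_samples=gt.n_samples,
            boundaries=gt.boundaries,
            midpoints=gt.midpoints,
        )

    def test_phases_partition_full_window(self, clean_recording):
        mov = clean_recording
        table = am.phase_jerks(
            {a: mov.sensors[a].accel for a in ("left", "right")},
            self.seg_from_truth(mov.ground_truth),
            fs=100.0,
        )
        for (trial, arm), df in table.groupby(["trial", "arm"]):
            by_phase = df.set_index("phase")["jerk"]
            assert by_phase["ascending"] + by_phase["lowering"] == pytest.approx(
                by_phase["full"], rel=1e-12
            )

    def test_symmetric_profile_phase_ratio_near_half(self, clean_recording):
        mov = clean_recording
        table = am.phase_jerks(
            {a: mov.sensors[a].accel for a in ("left", "right")},
            self.seg_from_truth(mov.ground_truth),
            fs=100.0,
        )
        tot = table[table.arm == "total"].groupby("phase")["jerk"].sum()
        r = am.jerk_ratio(tot["ascending"], tot["lowering"]).r
        assert r == pytest.approx(0.5, abs=0.02)

    def test_bilateral_total_is_sqrt2_of_single_side(self, clean_recording):
        mov = clean_recording
        table = am.phase_jerks(
            {a: mov.sensors[a].accel for a in ("left", "right")},
            self.seg_from_truth(mov.ground_truth),
            fs=100.0,
        )
        full = table[table.phase == "full"].groupby("arm")["jerk"].sum()
        assert full["total"] == pytest.approx(np.sqrt(2) * full["right"], rel=0.05)

    def test_lowering_saccades_push_ratio_below_half(self):
        spec = am.MotionSpec(
            "skew",
            laterality="bilateral",
            saccade_rate_per_phase={
                ("right", "lowering"): 6.0,
                ("left", "lowering"): 6.0,
            },
            tremor_amplitude=0.0,
            noise_sd=0.0,
        )
        sess = am.simulate_session([spec], rng_seed=2)
        mov = sess.movements[0]
        from armsmooth.kinematics import lowpass

        table = am.phase_jerks(
            {a: lowpass(mov.sensors[a].accel, 100.0) for a in ("left", "right")},
            self.seg_from_truth(mov.ground_truth),
            fs=100.0,
        )
        tot = table[table.arm == "total"].groupby("phase")["jerk"].sum()
        assert am.jerk_ratio(tot["ascending"], tot["lowering"]).r < 0.5

    def test_functional_movement_gets_full_phase_only(self):
        spec = am.MotionSpec(
            "func", laterality="unilateral_right", functional=True
        )
        sess = am.simulate_session([spec], rng_seed=4)
        mov = sess.movements[0]
        table = am.phase_jerks(
            {a: mov.sensors[a].accel for a in ("left", "right")},
            self.seg_from_truth(mov.ground_truth),
            fs=100.0,
            functional=True,
        )
        assert set(table.phase) == {"full"}
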