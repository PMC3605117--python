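"""Unit and property tests of the plateau-type FitzHugh-Nagumo model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uterosim as us
from uterosim.fhn import (
    IntegrationError,
    NonExcitableError,
    PacemakerSpec,
    integrate_space_clamped,
    ionic_current,
    nullcline_fixed_points,
    recovery_rate,
    resting_state,
    stimulus_current,
)
from uterosim.params import IonicParams, IonicState, surface_to_volume


class TestIonicCurrent:
    def test_zero_at_cubic_root(self, params):
        assert ionic_current(IonicState(params.v1, 0.0), params) == 0.0

    def test_only_recovery_term_at_v2(self, params):
        w = 0.0123
        assert ionic_current(IonicState(params.v2, w), params) == pytest.approx(
            w / params.eps1
        )

    def test_term_parameter_value(self, params):
        # -(1/200) * 1e4 * (-0.01)(-0.01)(0.035) = -1.75e-4
        val = ionic_current(IonicState(-0.03, 0.0), params)
        assert val == pytest.approx(-1.75e-4, rel=1e-12)

    def test_cubic_in_v_linear_in_w(self, params):
        # fit a cubic through 5 v-samples: the 4th difference must vanish;
        # w enters with constant coefficient 1/eps1
        v = np.linspace(-0.08, 0.01, 7)
        vals = np.array(
            [ionic_current(IonicState(vi, 0.0), params) for vi in v]
        )
        coeffs = np.polyfit(v, vals, 3)
        assert np.allclose(np.polyval(coeffs, v), vals, rtol=0, atol=1e-12)
        for vi in (-0.05, 0.0):
            dw = (
                ionic_current(IonicState(vi, 1.0), params)
                - ionic_current(IonicState(vi, 0.0), params)
            )
            assert dw == pytest.approx(1.0 / params.eps1)


class TestRecovery:
    def test_zero_on_nullcline(self, params):
        v = -0.033
        w = (params.beta * v + params.delta) / params.gamma
        assert recovery_rate(IonicState(v, w), params) == pytest.approx(0.0, abs=1e-15)

    def test_zero_at_resting_state(self, params):
        st_ = resting_state(params)
        assert recovery_rate(st_, params) == pytest.approx(0.0, abs=1e-15)

    def test_pure_decay(self):
        p = IonicParams(beta=0.0, delta=0.0)
        assert recovery_rate(IonicState(-0.05, 0.3), p) < 0


class TestStimulus:
    def test_outside_support_zero(self, params):
        pm = PacemakerSpec.fundus_cap()
        assert stimulus_current(np.array([0.0, 0.0, 0.0]), 0.05, [pm], params) == 0.0

    def test_results_pacemaker_value(self, params):
        # ||r|| = 0.155*..., z >= 0.15, t in window: (1/eps1)*nu = 2/200 = 0.01
        pm = PacemakerSpec.fundus_cap(nu=2.0)
        r = np.array([0.0, 0.0, 0.155])
        assert stimulus_current(r, 0.05, [pm], params) == pytest.approx(0.01)

    def test_additive_over_pacemakers(self, params):
        pm = PacemakerSpec.fundus_cap(nu=2.0)
        r = np.array([0.0, 0.0, 0.155])
        one = stimulus_current(r, 0.05, [pm], params)
        two = stimulus_current(r, 0.05, [pm, pm], params)
        assert two == pytest.approx(2 * one)


class TestFixedPoints:
    def test_term_values(self, params):
        roots = nullcline_fixed_points(params)
        # independent bisection oracle on the cubic sign changes
        w0 = (params.beta * params.v_mr + params.delta) / params.gamma

        def f(v):
            return (
                params.k
                * (v - params.v1)
                * (params.v2 - v)
                * (v - params.v3)
                - w0
            )

        oracle = []
        grid = np.linspace(-0.09, 0.01, 20001)
        fv = f(grid)
        for i in np.where(np.sign(fv[:-1]) != np.sign(fv[1:]))[0]:
            lo, hi = grid[i], grid[i + 1]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if np.sign(f(mid)) == np.sign(f(lo)):
                    lo = mid
                else:
                    hi = mid
            oracle.append(0.5 * (lo + hi))
        assert np.allclose(roots, oracle, atol=1e-10)
        assert np.allclose(roots, [-0.060000, -0.048508, -0.016492], atol=5e-7)

    def test_constant_term_vanishes(self, params):
        # delta with beta*v_mr + delta = 0: roots are exactly (v3, v2, v1)
        p = IonicParams(delta=-params.beta * params.v_mr)
        roots = nullcline_fixed_points(p)
        assert np.allclose(roots, sorted([p.v1, p.v2, p.v3]), atol=1e-14)

    def test_roots_move_continuously(self, params):
        r0 = nullcline_fixed_points(params)
        p = IonicParams(delta=params.delta + 1e-6)
        r1 = nullcline_fixed_points(p)
        assert np.all(np.abs(r1 - r0) < 1e-3)

    def test_nonexcitable_raises(self, params):
        # huge constant term pushes the cubic to one real root
        p = IonicParams(delta=0.5)
        with pytest.raises(NonExcitableError):
            nullcline_fixed_points(p)

    def test_roots_are_frozen_recovery_equilibria(self, params):
        """Cross-validation: the roots zero the v-equation with w held on
        its nullcline at the resting state."""
        w0 = (params.beta * params.v_mr + params.delta) / params.gamma
        for v in nullcline_fixed_points(params):
            assert ionic_current(IonicState(v, w0), params) == pytest.approx(
                0.0, abs=1e-12
            )


class TestRestingState:
    def test_term_values(self, params):
        s = resting_state(params)
        assert s.v_m == pytest.approx(-0.056)
        assert s.w == pytest.approx(-0.04)  # (1*(-0.056)+0.052)/0.1

    @pytest.mark.parametrize(
        "kw, expected_w",
        [
            (dict(beta=0.0, delta=0.0), 0.0),
            (dict(gamma=1.0, delta=0.0, beta=1.0), -0.056),
        ],
    )
    def test_limits(self, kw, expected_w):
        p = IonicParams(**kw)
        s = resting_state(p)
        assert s.v_m == p.v_mr
        assert s.w == pytest.approx(expected_w)


class TestSurfaceToVolume:
    def test_term_value_five_significant_figures(self):
        assert surface_to_volume(7e-6, 450e-6) == pytest.approx(5.7587e5, rel=1e-5)

    def test_long_cylinder_limit(self):
        assert surface_to_volume(7e-6, 1e6) == pytest.approx(4 / 7e-6, rel=1e-9)

    def test_arithmetic(self):
        assert surface_to_volume(4.0, 2.0) == pytest.approx(2.0)


def _pulse_drive(params, t0=1.0, dur=0.1, nu=2.0, extra=()):
    windows = [(t0, t0 + dur)] + [(a, a + dur) for a in extra]

    def drive(t):
        return (nu / params.eps1) if any(a <= t <= b for a, b in windows) else 0.0

    return drive


class TestSpaceClamped:
    def test_no_stimulus_converges_to_stable_fixed_point(self, params):
        traj = integrate_space_clamped(params, None, (0.0, 500.0), dt=0.05)
        v1_star = nullcline_fixed_points(params)[0]
        # stays near rest and settles close to the lower fixed point
        assert np.all(np.abs(traj.v_m - params.v_mr) < 0.01)
        assert abs(traj.v_m[-1] - v1_star) < 0.004
        assert np.all(np.abs(traj.v_m) < 1.0) and np.all(np.abs(traj.w) < 1.0)

    def test_suprathreshold_pulse_plateau_and_hyperpolarization(self, params):
        traj = integrate_space_clamped(
            params, _pulse_drive(params), (0.0, 120.0), dt=0.02
        )
        assert traj.v_m.max() > -0.03  # excursion into the plateau range
        assert traj.v_m.min() < params.v_mr - 0.005  # undershoot afterwards

    def test_refractory_second_pulse_fails(self, params):
        traj = integrate_space_clamped(
            params, _pulse_drive(params, extra=(11.0,)), (0.0, 60.0), dt=0.02
        )
        # second pulse lands on the plateau: no second upstroke from rest,
        # i.e. v never dips below resting between the pulses
        m = (traj.t > 1.2) & (traj.t < 11.0)
        assert not np.any(traj.v_m[m] < params.v_mr)
        # and the trace shows exactly one hyperpolarized undershoot (the
        # slow pre-stimulus drift toward the true equilibrium stays above
        # v_mr - 7 mV; the post-AP undershoot reaches ~-68 mV)
        below = traj.v_m < params.v_mr - 0.007
        runs = np.sum(np.diff(below.astype(int)) == 1)
        assert runs == 1

    def test_midpoint_matches_bdf_and_converges(self, params):
        ref = integrate_space_clamped(
            params, _pulse_drive(params), (0.0, 20.0), dt=0.005
        )
        errs = []
        for dt in (0.04, 0.02):
            mid = integrate_space_clamped(
                params, _pulse_drive(params), (0.0, 20.0), dt=dt, method="midpoint"
            )
            vi = np.interp(ref.t, mid.t, mid.v_m)
            errs.append(np.max(np.abs(vi - ref.v_m)))
        assert errs[1] < 0.6 * errs[0]  # at least first-order decay
        assert errs[1] < 2e-3

    def test_instability_raises(self, params):
        with pytest.raises(IntegrationError):
            integrate_space_clamped(
                params,
                lambda t: 1e4,  # absurd drive
                (0.0, 400.0),
                dt=100.0,
                method="midpoint",
            )


@settings(max_examples=25, deadline=None)
@given(
    v=st.floats(-0.09, 0.02),
    w=st.floats(-0.06, 0.06),
)
def test_current_matches_polynomial_expansion(v, w):
    """J_ion equals its factored cubic form exactly over the state range."""
    p = IonicParams()
    assert ionic_current(IonicState(v, w), p) == pytest.approx(
        -(p.k * (v - p.v1) * (p.v2 - v) * (v - p.v3) - w) / p.eps1, rel=1e-12
    )
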