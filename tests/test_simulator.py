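"""Time integration: fixed points, conservation, steady-state detection,
grid-doubling audit, high-diffusion trend."""

import numpy as np
import pytest

from spatmotif import (
    SolverSettings,
    build_domain,
    build_motif,
    find_steady_state,
    homogeneous_steady,
    integrate,
    make_signal,
)
from spatmotif.oracles import high_diffusion_steady
from spatmotif.signals import SignalProfile


def _cyclic2(k1=1.0, k2=1.0, D=0.0):
    return build_motif("cyclic", dict(k_1=k1, k_2=k2),
                       {"X1": D, "X2": D}, dict(X=1.0))


def _gk(DX=0.0, DXs=0.0):
    return build_motif("goldbeter_koshland",
                       dict(k_sx=1.0, k_r=1.0, U=1.0, K_M1=0.01, K_M2=0.01),
                       {"X*": DXs, "X": DX}, dict(X=1.0))


def _pair_x(D=0.0):
    """Coherent feedforward used as carrier of a single reversible pair X."""
    return build_motif(
        "coherent_ff",
        dict(k_sx=1.0, k_x=0.0, k_mx=1.0, k_sy=1.0, k_y=0.1, k_my=1.0,
             k_xr=1.0, k_yr=1.0, k_r=0.0, k_mr=1.0),
        {"X*": D, "Y*": 0.0, "R*": 0.0},
        dict(X=1.0, Y=1.0, R=1.0),
    )


class TestIntegrate:
    def test_reversible_pair_equilibrates_to_unit_ratio(self):
        # two-species cycle with k_1*S = k_2 ends at X2/X1 = 1 everywhere
        d = build_domain(32)
        m = _cyclic2()
        sig = np.ones(32)
        init = np.stack([np.full(32, 0.9), np.full(32, 0.1)])
        res = integrate(m, init, sig, d, SolverSettings(t_max=500.0))
        assert res.converged
        assert np.allclose(res.state[1] / res.state[0], 1.0, atol=1e-6)

    def test_fixed_point_stays_fixed(self):
        d = build_domain(32)
        m = _pair_x()
        sig = np.ones(32)
        xs = 0.5  # k_sx*S/(k_sx*S + k_mx) with S=1
        init = np.stack([np.full(32, xs), np.full(32, 11.0 / 21.0),
                         np.full(32, 43.0 / 85.0)])
        res = integrate(m, init, sig, d, SolverSettings(t_max=100.0))
        assert res.converged
        assert np.max(np.abs(res.state - init)) < 1e-6

    def test_gk_pool_conserved_with_equal_diffusion(self):
        d = build_domain(64)
        m = _gk(DX=1.0, DXs=1.0)
        sig = make_signal(SignalProfile(form="cosine_gradient", a=1.0, b=0.5), d)
        init = np.stack([0.2 + 0.1 * np.cos(d.theta), 0.8 - 0.1 * np.cos(d.theta)])
        res = integrate(m, init, sig, d, SolverSettings(t_max=200.0))
        assert res.conservation_drift["X"] < 1e-6

    def test_positivity_along_trajectory(self):
        d = build_domain(32)
        m = _gk()
        sig = make_signal(SignalProfile(form="sine_gradient", a=1.0, b=0.5), d)
        init = np.stack([np.zeros(32), np.ones(32)])
        res = integrate(m, init, sig, d, SolverSettings(t_max=100.0))
        assert res.trajectory.min() > -1e-6

    def test_early_termination_reports_residual(self):
        d = build_domain(32)
        m = _pair_x()
        sig = np.ones(32)
        init = np.zeros((3, 32))
        res = integrate(m, init, sig, d, SolverSettings(t_max=1e4, steady_tol=1e-8))
        assert res.converged
        assert res.residual <= 1e-8
        assert res.times[-1] < 1e4


class TestFindSteadyState:
    def test_coherent_ff_response_coaligned(self):
        from spatmotif.scenarios import coherent_ff_model

        d = build_domain(64)
        sig = make_signal(SignalProfile(form="cosine_gradient", a=1.0, b=0.5), d)
        res = find_steady_state(coherent_ff_model("none"), sig, d,
                                SolverSettings(t_max=5000.0, grid_check=False))
        r = res.species_profile("R*")
        assert int(np.argmax(r)) == int(np.argmax(sig))

    def test_incoherent_ff_response_counteraligned(self):
        from spatmotif.scenarios import incoherent_ff_1_model

        d = build_domain(64)
        sig = make_signal(SignalProfile(form="cosine_gradient", a=1.0, b=0.5), d)
        res = find_steady_state(incoherent_ff_1_model("none"), sig, d,
                                SolverSettings(t_max=5000.0, grid_check=False))
        r = res.species_profile("R*")
        assert int(np.argmax(r)) == int(np.argmin(sig))

    def test_bistable_two_uniform_states_inside_window(self):
        from spatmotif.scenarios import bistable_model

        m = bistable_model()
        lo = homogeneous_steady(m, 2.5)
        hi = homogeneous_steady(m, 2.5, initial=np.array([1.5, 1e-6]))
        assert hi[0] > 2 * lo[0]

    def test_grid_doubling_audit_small_for_smooth_profile(self):
        from spatmotif.scenarios import coherent_ff_model

        d = build_domain(100)
        sig = make_signal(SignalProfile(form="cosine_gradient", a=1.0, b=0.5), d)
        res = find_steady_state(coherent_ff_model("none"), sig, d,
                                SolverSettings(t_max=5000.0, grid_check=True))
        assert res.grid_check is not None
        assert res.grid_check < 0.005
        assert not res.unresolved


class TestHighDiffusionTrend:
    def test_deviation_from_uniform_level_shrinks_with_d(self):
        d = build_domain(64)
        sig = make_signal(SignalProfile(form="cosine_gradient", a=1.0, b=0.5), d)
        x0 = high_diffusion_steady(1.0, 1.0, 0.0, 1.0, sig, d)
        devs = []
        for D in (50.0, 500.0):
            m = _pair_x(D=D)
            res = find_steady_state(m, sig, d, SolverSettings(t_max=5000.0, grid_check=False))
            devs.append(np.max(np.abs(res.species_profile("X*") - x0)))
        assert devs[1] < devs[0]
        # leading-order 1/D scaling: tenfold D cuts the deviation ~tenfold
        assert devs[0] / devs[1] == pytest.approx(10.0, rel=0.3)


class TestDeterminism:
    def test_identical_runs_bitwise_identical(self):
        d = build_domain(32)
        m = _gk()
        sig = make_signal(SignalProfile(form="sine_gradient", a=1.0, b=0.5), d)
        init = np.stack([np.zeros(32), np.ones(32)])
        r1 = integrate(m, init, sig, d, SolverSettings(t_max=50.0))
        r2 = integrate(m, init, sig, d, SolverSettings(t_max=50.0))
        assert np.array_equal(r1.state, r2.state)
        assert np.array_equal(r1.trajectory, r2.trajectory)
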