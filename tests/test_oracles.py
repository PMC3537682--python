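"""Closed-form steady-state oracles: arithmetic identities, limiting cases,
and agreement with the PDE solver in the high-diffusion regime."""

import numpy as np
import pytest

from spatmotif import (
    KineticsError,
    SolverSettings,
    ValidityError,
    build_domain,
    build_motif,
    find_steady_state,
    make_signal,
)
from spatmotif.oracles import (
    ReducedFeedbackParams,
    bistable_diffusible_steady,
    coherent_ff_steady,
    cyclic_steady,
    gk_diffusible_amplification,
    high_diffusion_steady,
    hill_switch_diffusible_steady,
    incoherent_ff_steady,
    negative_fb_full_steady,
    negative_fb_steady,
    positive_fb_steady,
    reduced_feedback_params,
    transcritical_steady,
)
from spatmotif.scenarios import (
    bistable_model,
    coherent_ff_model,
    incoherent_ff_1_model,
    negative_fb_model,
    positive_fb_model,
    transcritical_model,
)
from spatmotif.signals import SignalProfile


@pytest.fixture
def domain():
    return build_domain(200)


@pytest.fixture
def cosine(domain):
    return make_signal(SignalProfile(form="cosine_gradient", a=1.0, b=0.5), domain)


class TestHighDiffusionSteady:
    def test_cosine_average_sets_level(self, domain, cosine):
        # <S> = 1, so X0 = 1*(1)/(1+1) = 0.5
        assert high_diffusion_steady(1.0, 1.0, 0.0, 1.0, cosine, domain) == pytest.approx(0.5)

    def test_signal_decouples_when_ksx_zero(self, domain, cosine):
        x0 = high_diffusion_steady(2.0, 0.0, 0.3, 0.7, cosine, domain)
        assert x0 == pytest.approx(2.0 * 0.3 / 1.0)

    def test_uniform_signal_is_local_fixed_point(self, domain):
        s = np.full(domain.n_points, 1.7)
        x0 = high_diffusion_steady(1.0, 1.0, 0.1, 1.0, s, domain)
        assert x0 == pytest.approx(1.8 / 2.8)

    def test_degenerate_kinetics_error(self, domain):
        with pytest.raises(KineticsError):
            high_diffusion_steady(1.0, 0.0, 0.0, 0.0, np.zeros(domain.n_points), domain)

    def test_matches_pde_solve_at_high_d(self, domain, cosine):
        m = coherent_ff_model("X")
        p = m.params
        x0 = high_diffusion_steady(1.0, p["k_sx"], p["k_x"], p["k_mx"], cosine, domain)
        res = find_steady_state(m, cosine, domain,
                                SolverSettings(t_max=5000.0, grid_check=False))
        xs = res.species_profile("X*")
        assert np.max(np.abs(xs - x0)) / x0 < 0.01


class TestFeedforwardOracles:
    def test_coherent_uniform_signal_local_fixed_point(self, domain):
        m = coherent_ff_model("none")
        s = np.full(domain.n_points, 1.0)
        r = coherent_ff_steady(m, s, "none", domain)
        assert np.ptp(r) < 1e-14

    def test_coherent_diffusible_x_raises_baseline(self, domain):
        m = coherent_ff_model("none")
        sig = make_signal(SignalProfile(form="localized_bump", a=0.2, A=1.0,
                                        theta0=np.pi, alpha=0.5), domain)
        r_none = coherent_ff_steady(m, sig, "none", domain)
        r_diff = coherent_ff_steady(m, sig, "X", domain)
        antipode = int(np.argmin(sig))
        assert r_diff[antipode] > r_none[antipode]

    def test_coherent_stronger_pathway_diffusible_weakens_contrast(self, domain, cosine):
        m = coherent_ff_model("none")  # k_xr > k_yr
        rx = coherent_ff_steady(m, cosine, "X", domain)
        ry = coherent_ff_steady(m, cosine, "Y", domain)
        assert np.ptp(rx) < np.ptp(ry)

    def test_incoherent_adaptation_ratio_invariance(self):
        # deep linear regime: response to S and 2S identical to 1e-6 relative
        d = build_domain(64)
        m = build_motif(
            "incoherent_ff_1",
            dict(k_sx=1.0, k_x=0.0, k_mx=1e6, k_sy=0.5, k_y=0.0, k_my=1e6,
                 k_xr=2.0, k_yr=1.0, k_r=0.0, k_mr=0.0),
            {"X*": 500.0, "Y*": 0.0, "R*": 0.0},
            dict(X=1.0, Y=1.0, R=1.0),
        )
        r1 = incoherent_ff_steady(m, np.full(64, 1.0), "X", d)
        r2 = incoherent_ff_steady(m, np.full(64, 2.0), "X", d)
        assert np.max(np.abs(r2 - r1) / r1) < 1e-6

    def test_incoherent_alignment_flips_with_diffusible_pathway(self, domain, cosine):
        m = incoherent_ff_1_model("none")
        rx = incoherent_ff_steady(m, cosine, "X", domain)
        ry = incoherent_ff_steady(m, cosine, "Y", domain)
        assert int(np.argmax(rx)) == int(np.argmax(cosine))
        assert int(np.argmax(ry)) == int(np.argmin(cosine))


class TestFeedbackOracles:
    def test_positive_fb_reduced_arithmetic(self, domain):
        pars = ReducedFeedbackParams(alpha=0.1, beta=0.5)
        s = np.ones(domain.n_points)
        r = positive_fb_steady(pars, s, "none", domain)
        assert np.allclose(r, 0.2)

    def test_positive_fb_diffusible_amplitude_smaller(self, domain, cosine):
        pars = ReducedFeedbackParams(alpha=0.1, beta=0.5)
        r_none = positive_fb_steady(pars, cosine, "none", domain)
        r_diff = positive_fb_steady(pars, cosine, "Y", domain)
        assert np.ptp(r_diff) == pytest.approx(0.1 * 1.0)  # alpha*(Smax-Smin)
        assert np.ptp(r_none) == pytest.approx(0.1 * 1.0 / 0.5)
        assert np.ptp(r_diff) < np.ptp(r_none)

    def test_no_feedback_limit(self, domain, cosine):
        pars = ReducedFeedbackParams(alpha=0.3, beta=0.0)
        for diff in ("none", "Y"):
            assert np.allclose(positive_fb_steady(pars, cosine, diff, domain),
                               0.3 * cosine)
            assert np.allclose(negative_fb_steady(pars, cosine, diff, domain),
                               0.3 * cosine)

    def test_positive_fb_beta_validity(self, domain, cosine):
        with pytest.raises(ValidityError):
            positive_fb_steady(ReducedFeedbackParams(alpha=0.1, beta=1.1),
                               cosine, "none", domain)

    def test_negative_fb_perfect_square_case(self, domain):
        # alpha*<S> = 2, beta = 1: R0 = (sqrt(9)-1)/2 = 1, so R* = alpha*S/2
        s = np.full(domain.n_points, 1.0)
        pars = ReducedFeedbackParams(alpha=2.0, beta=1.0)
        r = negative_fb_steady(pars, s, "Y", domain)
        assert np.allclose(r, 2.0 * s / 2.0)

    def test_negative_fb_diffusible_contrast_greater(self, domain, cosine):
        pars = ReducedFeedbackParams(alpha=1.0, beta=2.0)
        r_none = negative_fb_steady(pars, cosine, "none", domain)
        r_diff = negative_fb_steady(pars, cosine, "Y", domain)
        assert np.ptp(r_diff) > np.ptp(r_none)

    def test_reduced_matches_full_far_from_saturation(self, domain, cosine):
        # invariant: 5% agreement while active fractions stay below 10%
        for model, fn, reduced in (
            (positive_fb_model(2.0), "positive", positive_fb_steady),
            (negative_fb_model(14.0), "negative", negative_fb_steady),
        ):
            pars = reduced_feedback_params(model)
            from spatmotif.oracles import negative_fb_full_steady, positive_fb_full_steady

            full = (positive_fb_full_steady if fn == "positive"
                    else negative_fb_full_steady)(model, cosine, "none", domain)
            red = reduced(pars, cosine, "none", domain)
            assert np.max(np.abs(full - red)) / np.max(full) < 0.05

    def test_reduction_error_grows_with_saturation(self, domain, cosine):
        # scaling k_sx up pushes active fractions up and the discrepancy grows
        from spatmotif.oracles import negative_fb_full_steady

        errs = []
        for ksx in (0.02, 0.2, 2.0):
            m = negative_fb_model(14.0)
            params = dict(m.params, k_sx=ksx)
            m2 = build_motif("negative_fb", params, m.diffusivities, m.totals)
            pars = reduced_feedback_params(m2)
            full = negative_fb_full_steady(m2, cosine, "none", domain)
            red = negative_fb_steady(pars, cosine, "none", domain)
            errs.append(np.max(np.abs(full - red)) / np.max(full))
        assert errs[0] < errs[1] < errs[2]


class TestCyclicOracle:
    def _model(self, n=4, diffusible_index=None):
        from spatmotif.scenarios import cyclic_model

        return cyclic_model(n, diffusible_index)

    def test_two_species_uniform_arithmetic(self, domain):
        m = self._model(2)
        s = np.full(domain.n_points, 1.0)
        sol = cyclic_steady(m, s, "none", domain)
        assert np.allclose(sol.F, 0.5)
        assert np.allclose(sol.levels, 0.5)

    def test_downstream_diffusible_homogenizes_all_but_first(self, domain, cosine):
        sol = cyclic_steady(self._model(4, 3), cosine, 3, domain)
        for i in (1, 2, 3):
            assert np.ptp(sol.levels[i]) < 1e-14
        # X1 proportional to 1/S
        ratio = sol.levels[0] * cosine
        assert np.ptp(ratio) / np.mean(ratio) < 1e-12

    def test_n2_special_cases_match_general_formulas(self, domain, cosine):
        m = self._model(2)
        sbar = np.mean(cosine)
        sol1 = cyclic_steady(m, cosine, 1, domain)
        x1 = 1.0 / (1.0 + sbar)
        assert np.allclose(sol1.levels[0], x1)
        assert np.allclose(sol1.levels[1], cosine * x1)
        sol2 = cyclic_steady(m, cosine, 2, domain)
        # global conservation uses the harmonic signal mean <1/S>
        f = 1.0 / (np.mean(1.0 / cosine) + 1.0)
        assert np.allclose(sol2.levels[1], f)
        assert np.allclose(sol2.levels[0], f / cosine)

    def test_flux_identity(self, domain, cosine):
        sol = cyclic_steady(self._model(4), cosine, "none", domain)
        for i in (1, 2, 3):
            assert np.allclose(sol.levels[i] * 1.0, sol.F)

    def test_averaging_identity(self, domain, cosine):
        # the global species feels only the signal mean: arithmetic when it is
        # driven by <S> (species 1 global), harmonic when conservation couples
        # it through <1/S> (downstream species global)
        sol_g = cyclic_steady(self._model(4, 1), cosine, 1, domain)
        sol_u = cyclic_steady(self._model(4, 1), np.full_like(cosine, np.mean(cosine)),
                              1, domain)
        assert np.allclose(sol_g.levels[0], sol_u.levels[0])
        harm = 1.0 / np.mean(1.0 / cosine)
        sol_g3 = cyclic_steady(self._model(4, 3), cosine, 3, domain)
        sol_u3 = cyclic_steady(self._model(4, 3), np.full_like(cosine, harm), 3, domain)
        assert np.allclose(sol_g3.levels[2], sol_u3.levels[2])


class TestSwitchOracles:
    def test_gk_amplification_arithmetic(self, domain):
        x0 = gk_diffusible_amplification(1.0, (0.0, np.pi), 0.0, domain)
        assert x0 == pytest.approx(2.0)
        x0 = gk_diffusible_amplification(1.0, (0.0, 2 * np.pi - 1e-12), 0.2, domain)
        assert x0 == pytest.approx(0.8, rel=1e-9)

    def test_hill_uniform_limit(self, domain):
        f = np.ones(domain.n_points)
        r = hill_switch_diffusible_steady(1.0, 1.0, 0.5, f, domain)
        assert np.allclose(r, 1.0 / 1.5)

    def test_hill_narrow_activation_amplifies(self, domain):
        f = np.zeros(domain.n_points)
        f[: domain.n_points // 10] = 1.0
        r = hill_switch_diffusible_steady(1.0, 10.0, 1.0, f, domain)
        assert np.max(r) == pytest.approx(10.0 / (10.0 * 0.1 + 1.0))
        assert np.max(r) > 1.0  # exceeds R_tot


class TestBistableOracle:
    def test_uniform_signal_reproduces_temporal_states(self, domain):
        m = bistable_model("Y")
        s = np.full(domain.n_points, 2.5)
        roots = bistable_diffusible_steady(m, s, domain)
        assert len(roots) == 2
        for r in roots:
            assert np.ptp(r["X_profile"]) < 1e-12

    def test_gradient_two_monotone_profiles(self, domain, cosine):
        m = bistable_model("Y")
        sig = make_signal(SignalProfile(form="cosine_gradient", a=2.5, b=1.0), domain)
        roots = bistable_diffusible_steady(m, sig, domain)
        assert len(roots) == 2
        for r in roots:
            # monotone in S: the profile is a smooth increasing map of the
            # signal (ties in the symmetric cosine map to equal values)
            order = np.argsort(sig)
            assert np.all(np.diff(r["X_profile"][order]) >= 0)
            assert r["X_profile"][order][-1] > r["X_profile"][order][0]

    def test_profiles_are_pde_attractors(self):
        d = build_domain(100)
        sig = make_signal(SignalProfile(form="cosine_gradient", a=2.5, b=1.0), d)
        m = bistable_model("Y")
        roots = bistable_diffusible_steady(m, sig, d)
        from spatmotif.simulate import integrate

        for r in roots:
            ys = r["Y_star"]
            init = np.stack([r["X_profile"], np.full(d.n_points, ys)])
            res = integrate(m, init, sig, d, SolverSettings(t_max=2000.0))
            drift = np.max(np.abs(res.species_profile("X*") - r["X_profile"]))
            assert drift / np.max(r["X_profile"]) < 0.01


class TestTranscriticalOracle:
    def test_all_ones_branch(self, domain):
        m = transcritical_model("none")
        s = np.full(domain.n_points, 0.4)
        assert np.allclose(transcritical_steady(m, s, "none", domain), 0.6)
        s = np.full(domain.n_points, 1.3)
        assert np.allclose(transcritical_steady(m, s, "none", domain), 0.0)

    def test_gradient_zero_above_critical(self, domain, cosine):
        m = transcritical_model("none")
        x = transcritical_steady(m, cosine, "none", domain)
        assert np.all(x[cosine > 1.0] == 0.0)
        assert np.all(x[cosine < 1.0] > 0.0)

    def test_diffusible_strictly_positive_or_zero(self, domain, cosine):
        m = transcritical_model("Y")
        x = transcritical_steady(m, cosine, "Y", domain)
        assert np.all(x > 0.0)  # mean(1/S) = 1/sqrt(1-0.25) > 1
        high = make_signal(SignalProfile(form="cosine_gradient", a=2.0, b=0.5), domain)
        x2 = transcritical_steady(m, high, "Y", domain)
        assert np.all(x2 == 0.0)
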