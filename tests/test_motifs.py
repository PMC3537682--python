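"""Kinetic scheme constructors and rate functions."""

import numpy as np
import pytest

from spatmotif import (
    ConfigurationError,
    build_domain,
    build_motif,
    full_rhs,
    make_signal,
    reaction_rhs,
)
from spatmotif.motifs import MOTIF_REGISTRY, conserved_pools
from spatmotif.signals import SignalProfile

COHERENT_PARAMS = dict(k_sx=1.0, k_x=0.1, k_mx=2.0, k_sy=1.0, k_y=0.1, k_my=2.0,
                       k_xr=2.0, k_yr=0.5, k_r=0.05, k_mr=2.0)
TOTALS3 = dict(X=1.0, Y=1.0, R=1.0)
DIFF3 = {"X*": 0.0, "Y*": 0.0, "R*": 0.0}


class TestBuildMotif:
    def test_coherent_ff_constructor(self):
        m = build_motif("coherent_ff", COHERENT_PARAMS, DIFF3, TOTALS3)
        assert m.species == ("X*", "Y*", "R*")

    def test_cyclic_n4_species_and_total(self):
        m = build_motif("cyclic", {f"k_{i}": 1.0 for i in range(1, 5)},
                        {f"X{i}": 0.0 for i in range(1, 5)}, dict(X=1.0))
        assert m.species == ("X1", "X2", "X3", "X4")
        assert conserved_pools(m) == {"X": (0, 1, 2, 3)}

    def test_missing_parameter_named_in_error(self):
        params = dict(k_sx=1.0, k_r=1.0, U=1.0, K_M1=0.01)  # K_M2 missing
        with pytest.raises(ConfigurationError, match="K_M2"):
            build_motif("goldbeter_koshland", params, {"X*": 0.0, "X": 0.0}, dict(X=1.0))

    def test_extra_parameter_rejected(self):
        params = dict(COHERENT_PARAMS, k_zz=1.0)
        with pytest.raises(ConfigurationError, match="k_zz"):
            build_motif("coherent_ff", params, DIFF3, TOTALS3)

    def test_unknown_motif(self):
        with pytest.raises(ConfigurationError):
            build_motif("nonexistent", {}, {}, {})

    def test_missing_diffusivity(self):
        with pytest.raises(ConfigurationError, match="R"):
            build_motif("coherent_ff", COHERENT_PARAMS,
                        {"X*": 0.0, "Y*": 0.0}, TOTALS3)

    def test_negative_parameter_rejected(self):
        params = dict(COHERENT_PARAMS, k_sx=-1.0)
        with pytest.raises(ConfigurationError):
            build_motif("coherent_ff", params, DIFF3, TOTALS3)

    def test_cyclic_requires_consecutive_rates(self):
        with pytest.raises(ConfigurationError):
            build_motif("cyclic", {"k_1": 1.0, "k_3": 1.0},
                        {"X1": 0.0, "X2": 0.0}, dict(X=1.0))


class TestReactionRates:
    @pytest.fixture
    def domain(self):
        return build_domain(32)

    @pytest.fixture
    def signal(self, domain):
        return make_signal(SignalProfile(form="cosine_gradient", a=1.0, b=0.5), domain)

    def test_cyclic_rates_sum_to_zero(self, domain, signal):
        m = build_motif("cyclic", {f"k_{i}": float(i) for i in range(1, 5)},
                        {f"X{i}": 0.0 for i in range(1, 5)}, dict(X=1.0))
        state = np.abs(np.sin(np.arange(4)[:, None] + domain.theta[None, :])) + 0.1
        rates = reaction_rhs(m, state, signal)
        assert np.max(np.abs(rates.sum(axis=0))) < 1e-14

    def test_coherent_ff_local_fixed_point_of_x(self, domain, signal):
        p = COHERENT_PARAMS
        m = build_motif("coherent_ff", p, DIFF3, TOTALS3)
        drive = p["k_sx"] * signal + p["k_x"]
        xs = TOTALS3["X"] * drive / (drive + p["k_mx"])
        state = np.stack([xs, 0.3 * np.ones_like(xs), 0.2 * np.ones_like(xs)])
        rates = reaction_rhs(m, state, signal)
        assert np.max(np.abs(rates[0])) < 1e-14

    @pytest.mark.parametrize("motif_id", sorted(MOTIF_REGISTRY))
    def test_species_at_zero_cannot_go_negative(self, motif_id, domain, signal):
        m = _example_model(motif_id)
        for j in range(m.n_species):
            state = 0.3 * np.ones((m.n_species, domain.n_points))
            state[j] = 0.0
            rates = reaction_rhs(m, state, signal)
            assert np.all(rates[j] >= -1e-14), f"{motif_id} species {m.species[j]}"

    def test_rotation_equivariance(self, domain, signal):
        m = _example_model("negative_fb")
        state = np.stack([0.2 + 0.1 * np.cos(domain.theta),
                          0.3 + 0.05 * np.sin(domain.theta),
                          0.1 + 0.02 * np.cos(2 * domain.theta)])
        r1 = reaction_rhs(m, state, signal)
        r2 = reaction_rhs(m, np.roll(state, 1, axis=1), np.roll(signal, 1))
        assert np.allclose(np.roll(r1, 1, axis=1), r2, atol=1e-14)

    def test_gk_saturation_bounds(self, domain):
        m = _example_model("goldbeter_koshland")
        sig = np.ones(domain.n_points)
        # forward rate vanishes as X -> 0
        state = np.stack([np.full(domain.n_points, 0.5), np.zeros(domain.n_points)])
        rates = reaction_rhs(m, state, sig)
        assert np.all(rates[0] <= 0)
        # backward rate vanishes as X* -> 0
        state = np.stack([np.zeros(domain.n_points), np.full(domain.n_points, 0.5)])
        rates = reaction_rhs(m, state, sig)
        assert np.all(rates[0] >= 0)


class TestFullRhs:
    @pytest.fixture
    def domain(self):
        return build_domain(32)

    def test_zero_diffusion_equals_reaction(self, domain):
        m = _example_model("coherent_ff")
        sig = np.ones(domain.n_points)
        state = 0.2 + 0.1 * np.sin(np.arange(3)[:, None] + domain.theta[None, :])
        assert np.array_equal(full_rhs(m, state, sig, domain),
                              reaction_rhs(m, state, sig))

    def test_uniform_state_diffusion_inert(self, domain):
        m = _example_model("coherent_ff", D=5.0)
        sig = np.ones(domain.n_points)
        state = np.tile(np.array([0.2, 0.3, 0.1])[:, None], (1, domain.n_points))
        assert np.allclose(full_rhs(m, state, sig, domain),
                           reaction_rhs(m, state, sig), atol=1e-14)

    def test_gk_pool_obeys_pure_diffusion(self, domain):
        # with equal diffusivities the rate of X + X* is D * Laplacian(X + X*)
        from spatmotif.domain import periodic_laplacian

        m = build_motif("goldbeter_koshland",
                        dict(k_sx=1.0, k_r=1.0, U=1.0, K_M1=0.01, K_M2=0.01),
                        {"X*": 2.0, "X": 2.0}, dict(X=1.0))
        sig = 1.0 + 0.5 * np.cos(domain.theta)
        state = np.stack([0.3 + 0.2 * np.cos(domain.theta),
                          0.5 + 0.1 * np.sin(domain.theta)])
        rates = full_rhs(m, state, sig, domain)
        pool_rate = rates.sum(axis=0)
        assert np.allclose(pool_rate, 2.0 * periodic_laplacian(state.sum(axis=0), domain),
                           atol=1e-10)


def _example_model(motif_id, D=0.0):
    """A valid example model of each scheme for generic rate-function tests."""
    if motif_id == "coherent_ff":
        return build_motif(motif_id, COHERENT_PARAMS,
                           {s: D for s in ("X*", "Y*", "R*")}, TOTALS3)
    if motif_id == "incoherent_ff_1":
        return build_motif(motif_id, COHERENT_PARAMS,
                           {s: D for s in ("X*", "Y*", "R*")}, TOTALS3)
    if motif_id == "incoherent_ff_2":
        params = {k: v for k, v in COHERENT_PARAMS.items() if k != "k_r"}
        return build_motif(motif_id, params,
                           {s: D for s in ("X*", "Y*", "R*")}, TOTALS3)
    if motif_id in ("positive_fb", "negative_fb"):
        params = dict(k_sx=0.1, k_x=0.0, k_mx=1.0, k_yx=1.0, k_xr=1.0, k_r=0.0,
                      k_mr=1.0, k_ry=1.0, k_y=0.0, k_my=1.0)
        return build_motif(motif_id, params,
                           {s: D for s in ("X*", "R*", "Y*")}, TOTALS3)
    if motif_id == "cyclic":
        return build_motif(motif_id, {f"k_{i}": 1.0 for i in range(1, 5)},
                           {f"X{i}": D for i in range(1, 5)}, dict(X=1.0))
    if motif_id == "goldbeter_koshland":
        return build_motif(motif_id, dict(k_sx=1.0, k_r=1.0, U=1.0, K_M1=0.01, K_M2=0.01),
                           {"X*": D, "X": D}, dict(X=1.0))
    if motif_id == "bistable_mutual_inhibition":
        return build_motif(motif_id,
                           dict(k_0=0.02, k_1=0.1, k_2=0.5, k_21=2.0, k_3=1.0, k_4=0.2,
                                K_M3=0.01, K_M4=0.01),
                           {"X*": D, "Y*": D}, dict(Y=1.0))
    if motif_id == "nf_oscillator":
        return build_motif(motif_id,
                           dict(k_0=0.01, k_1=0.2, k_2=0.1, k_21=2.0, k_3=1.0, k_4=0.3,
                                k_5=1.0, k_6=0.3, K_M3=0.05, K_M4=0.05, K_M5=0.05,
                                K_M6=0.05),
                           {"X*": D, "R*": D, "Y*": D}, dict(R=1.0, Y=1.0))
    if motif_id == "transcritical":
        return build_motif(motif_id, dict(k_sx=1.0, k_1=1.0, k_2=1.0, k_my=1.0),
                           {"X*": D, "Y*": D}, dict(X=1.0, Y=1.0))
    if motif_id == "hill_switch":
        return build_motif(motif_id, dict(k_f=1.0, k_r=0.1, K_h=1.0, n_h=8.0),
                           {"R*": D, "R": D}, dict(R=1.0))
    raise AssertionError(motif_id)
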