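"""Oracle-vs-simulation verification for scenarios with a closed form.

For every scenario whose steady state has an analytic (or reduced algebraic)
solution, this module recomputes the prediction and compares it with the PDE
steady state in sup-norm relative error. The high-diffusion oracles are exact
only in the D -> infinity limit, so the default tolerance (2%) reflects the
leading-order truncation at the package's D = 500 convention.
"""

from __future__ import annotations

from .domain import build_domain
from .errors import RegistryError
from .motifs import hill_activation
from .oracles import (
    OracleReport,
    bistable_diffusible_steady,
    coherent_ff_steady,
    compare_oracle,
    cyclic_steady,
    hill_switch_diffusible_steady,
    incoherent_ff_steady,
    negative_fb_full_steady,
    positive_fb_full_steady,
    transcritical_steady,
)
from .scenarios import get_scenario, initial_state
from .signals import make_signal
from .simulate import integrate


def _diffusible_tag(model) -> str:
    for name, D in model.diffusivities.items():
        if D > 0:
            return name.rstrip("*")
    return "none"


def _predict(scenario, signal, domain):
    model = scenario.model
    tag = _diffusible_tag(model)
    mid = model.motif_id
    if mid == "coherent_ff":
        return coherent_ff_steady(model, signal, tag, domain)
    if mid == "incoherent_ff_1":
        return incoherent_ff_steady(model, signal, tag, domain)
    if mid == "positive_fb":
        return positive_fb_full_steady(model, signal, tag, domain)
    if mid == "negative_fb":
        return negative_fb_full_steady(model, signal, tag, domain)
    if mid == "cyclic":
        diffusible = "none"
        for i, name in enumerate(model.species):
            if model.diffusivities[name] > 0:
                diffusible = i + 1
                break
        sol = cyclic_steady(model, signal, diffusible, domain)
        return sol.levels[model.species.index(scenario.response)]
    if mid == "hill_switch":
        p = model.params
        f = hill_activation(signal, p["K_h"], p["n_h"])
        return hill_switch_diffusible_steady(model.totals["R"], p["k_f"], p["k_r"], f, domain)
    if mid == "bistable_mutual_inhibition":
        roots = bistable_diffusible_steady(model, signal, domain)
        # scenario starts on the lower branch: smallest-mean stable profile
        return min(roots, key=lambda r: r["X_mean"])["X_profile"]
    if mid == "transcritical":
        return transcritical_steady(model, signal, tag, domain)
    raise RegistryError(f"no closed-form oracle for motif {mid!r}")


def verify_scenario(scenario_id: str, tolerance: float = 0.02) -> OracleReport:
    """Run a scenario's PDE steady state and compare with its oracle."""
    sc = get_scenario(scenario_id)
    domain = build_domain(sc.n_points)
    signal = make_signal(sc.signal, domain)
    predicted = _predict(sc, signal, domain)
    init = initial_state(sc, domain, signal)
    result = integrate(sc.model, init, signal, domain, sc.settings)
    simulated = result.species_profile(sc.response)
    return compare_oracle(scenario_id, predicted, simulated, tolerance)
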