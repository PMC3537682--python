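"""Figure-level scenario fixtures: parameter sets, signals, initial conditions.

Each scenario binds one motif with a frozen kinetic parameter set, a spatial
signal, an initial-condition rule and solver settings, and carries a list of
expected qualitative diagnostics. Parameter sets are chosen once to realize
the dynamical regime each scenario needs (bistable signal window, Hopf window,
zero-order switching, far-from-saturation feedback reductions) and are
validated by :func:`calibrate_regimes`. Scenarios are pure data: no randomness
anywhere, so repeated generation is identical field-by-field.

Transport regimes use the package-wide conventions D = 500 (highly
diffusible / global), D = 0.005 (weakly diffusible), D = 0 (non-diffusible).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .bifurcation import oscillation_window, scan_branches
from .domain import SpatialDomain, build_domain
from .errors import CalibrationError, RegistryError
from .motifs import D_HIGH, D_NONE, D_WEAK, MotifModel, build_motif
from .signals import SignalProfile, make_signal
from .simulate import SimulationResult, SolverSettings, homogeneous_steady, integrate

__all__ = [
    "Scenario",
    "list_scenarios",
    "get_scenario",
    "execute_scenario",
    "calibrate_regimes",
]

TWO_PI = 2.0 * np.pi
DEFAULT_N_POINTS = 200
#: coarser grid for long oscillatory trajectory scenarios (documented choice:
#: adjacent-node signal separation large enough to expose incommensurate
#: local frequencies within the integration horizon)
OSC_N_POINTS = 64


# ---------------------------------------------------------------------------
# frozen kinetic parameter sets (one per motif, plus named variants)
# ---------------------------------------------------------------------------


def coherent_ff_model(diffusible: str = "none") -> MotifModel:
    """Coherent feedforward, X pathway stronger (k_xr > k_yr)."""
    D = {"X*": D_NONE, "Y*": D_NONE, "R*": D_NONE}
    if diffusible != "none":
        D[f"{diffusible}*"] = D_HIGH
    return build_motif(
        "coherent_ff",
        dict(k_sx=1.0, k_x=0.05, k_mx=10.0, k_sy=1.0, k_y=0.05, k_my=10.0,
             k_xr=2.0, k_yr=0.5, k_r=0.02, k_mr=10.0),
        D,
        dict(X=1.0, Y=1.0, R=1.0),
    )


def incoherent_ff_1_model(diffusible: str = "none") -> MotifModel:
    """Incoherent feedforward type 1: inhibitor X stronger than activator Y.

    The inhibitor pathway responds linearly to the signal (large k_mx) while
    the activator saturates (small k_my), so with everything local the X*/Y*
    ratio grows with S and the response opposes the signal."""
    D = {"X*": D_NONE, "Y*": D_NONE, "R*": D_NONE}
    if diffusible != "none":
        D[f"{diffusible}*"] = D_HIGH
    return build_motif(
        "incoherent_ff_1",
        dict(k_sx=1.0, k_x=0.0, k_mx=50.0, k_sy=1.0, k_y=0.0, k_my=2.0,
             k_xr=2.0, k_yr=1.0, k_r=0.0, k_mr=0.0),
        D,
        dict(X=1.0, Y=1.0, R=1.0),
    )


def incoherent_ff_1_adaptation_model(diffusible: str = "X") -> MotifModel:
    """Far-from-saturation variant of the type-1 incoherent feedforward loop:
    both pathways linear in S, so the homogeneous steady response depends only
    on the ratio k_sy/k_sx and adapts (near-)perfectly to step changes."""
    D = {"X*": D_NONE, "Y*": D_NONE, "R*": D_NONE}
    if diffusible != "none":
        D[f"{diffusible}*"] = D_HIGH
    return build_motif(
        "incoherent_ff_1",
        dict(k_sx=1.0, k_x=0.0, k_mx=50.0, k_sy=0.5, k_y=0.0, k_my=50.0,
             k_xr=2.0, k_yr=1.0, k_r=0.0, k_mr=0.0),
        D,
        dict(X=1.0, Y=1.0, R=1.0),
    )


def incoherent_ff_2_model(diffusible: str = "none") -> MotifModel:
    """Incoherent feedforward type 2 (signal suppresses Y): biphasic in S."""
    D = {"X*": D_NONE, "Y*": D_NONE, "R*": D_NONE}
    if diffusible != "none":
        D[f"{diffusible}*"] = D_HIGH
    return build_motif(
        "incoherent_ff_2",
        dict(k_sx=2.0, k_x=0.1, k_mx=1.0, k_sy=1.0, k_y=1.0, k_my=0.1,
             k_xr=2.0, k_yr=2.0, k_mr=2.0),
        D,
        dict(X=1.0, Y=1.0, R=1.0),
    )


def positive_fb_model(k_yx: float = 2.0, diffusible: str = "none") -> MotifModel:
    """Positive feedback; loop gain beta = 0.2*k_yx stays clearly below 1 and
    active fractions stay below ~1%, inside the linear-reduction regime."""
    D = {"X*": D_NONE, "R*": D_NONE, "Y*": D_NONE}
    if diffusible != "none":
        D[f"{diffusible}*"] = D_HIGH
    return build_motif(
        "positive_fb",
        dict(k_sx=0.016, k_x=0.0, k_mx=10.0, k_yx=k_yx, k_xr=20.0, k_r=0.0,
             k_mr=10.0, k_ry=10.0, k_y=0.0, k_my=10.0),
        D,
        dict(X=1.0, Y=1.0, R=1.0),
    )


def negative_fb_model(k_yx: float = 14.0, diffusible: str = "none") -> MotifModel:
    """Negative feedback in the far-from-saturation regime (fractions ~2%)."""
    D = {"X*": D_NONE, "R*": D_NONE, "Y*": D_NONE}
    if diffusible != "none":
        D[f"{diffusible}*"] = D_HIGH
    return build_motif(
        "negative_fb",
        dict(k_sx=0.02, k_x=0.0, k_mx=1.0, k_yx=k_yx, k_xr=10.0, k_r=0.0,
             k_mr=10.0, k_ry=10.0, k_y=0.0, k_my=10.0),
        D,
        dict(X=1.0, Y=1.0, R=1.0),
    )


def negative_fb_strong_model() -> MotifModel:
    """Strong-feedback variant used to demonstrate partial (under-)adaptation
    of the negative feedback loop in homogeneous stimuli."""
    return build_motif(
        "negative_fb",
        dict(k_sx=0.2, k_x=0.0, k_mx=1.0, k_yx=14.0, k_xr=10.0, k_r=0.0,
             k_mr=10.0, k_ry=100.0, k_y=0.0, k_my=10.0),
        {"X*": D_NONE, "R*": D_NONE, "Y*": D_NONE},
        dict(X=1.0, Y=1.0, R=1.0),
    )


def cyclic_model(n: int = 4, diffusible_index=None) -> MotifModel:
    """Irreversible cycle, n species, signal on the 1->2 step, unit rates."""
    params = {f"k_{i + 1}": 1.0 for i in range(n)}
    D = {f"X{i + 1}": D_NONE for i in range(n)}
    if diffusible_index is not None:
        D[f"X{int(diffusible_index)}"] = D_HIGH
    return build_motif("cyclic", params, D, dict(X=1.0))


def goldbeter_koshland_model(diffusible: str = "none") -> MotifModel:
    """Zero-order (Goldbeter-Koshland) switch: K_M = 0.01 << X_tot = 1,
    threshold at k_sx S = k_r U, i.e. S = 1."""
    D = {"X*": D_NONE, "X": D_NONE}
    if diffusible == "X":
        D["X"] = D_HIGH
    elif diffusible == "X*":
        D["X*"] = D_HIGH
    return build_motif(
        "goldbeter_koshland",
        dict(k_sx=1.0, k_r=1.0, U=1.0, K_M1=0.01, K_M2=0.01),
        D,
        dict(X=1.0),
    )


def hill_switch_model(diffusible: str = "none") -> MotifModel:
    """Hill-cooperativity monostable switch (comparison to the zero-order switch)."""
    D = {"R*": D_NONE, "R": D_NONE}
    if diffusible == "R":
        D["R"] = D_HIGH
    elif diffusible == "R*":
        D["R*"] = D_HIGH
    return build_motif(
        "hill_switch",
        dict(k_f=1.0, k_r=0.1, K_h=1.0, n_h=8.0),
        D,
        dict(R=1.0),
    )


def bistable_model(diffusible: str = "none", weak: bool = False) -> MotifModel:
    """Mutual-inhibition bistable switch; bistable for S in ~[1.22, 4.03]."""
    if weak:
        D = {"X*": D_WEAK, "Y*": D_WEAK}
    else:
        D = {"X*": D_NONE, "Y*": D_NONE}
        if diffusible == "Y":
            D["Y*"] = D_HIGH
    return build_motif(
        "bistable_mutual_inhibition",
        dict(k_0=0.02, k_1=0.1, k_2=0.5, k_21=2.0, k_3=1.0, k_4=0.2,
             K_M3=0.01, K_M4=0.01),
        D,
        dict(Y=1.0),
    )


def nf_oscillator_model(diffusible: str = "none") -> MotifModel:
    """Negative-feedback relaxation oscillator with a Hopf window in S."""
    D = {"X*": D_NONE, "R*": D_NONE, "Y*": D_NONE}
    if diffusible == "Y":
        D["Y*"] = D_HIGH
    return build_motif(
        "nf_oscillator",
        dict(k_0=0.01, k_1=0.2, k_2=0.1, k_21=2.0, k_3=1.0, k_4=0.3,
             k_5=1.0, k_6=0.3, K_M3=0.05, K_M4=0.05, K_M5=0.05, K_M6=0.05),
        D,
        dict(R=1.0, Y=1.0),
    )


def transcritical_model(diffusible: str = "none") -> MotifModel:
    """Transcritical switch with all-ones parameters: critical signal S_c = 1."""
    D = {"X*": D_NONE, "Y*": D_NONE}
    if diffusible == "Y":
        D["Y*"] = D_HIGH
    return build_motif(
        "transcritical",
        dict(k_sx=1.0, k_1=1.0, k_2=1.0, k_my=1.0),
        D,
        dict(X=1.0, Y=1.0),
    )


# calibration anchors (verified by calibrate_regimes, used by tests/signals)
BISTABLE_SCAN_RANGE = (0.2, 6.0)
OSCILLATOR_SCAN_RANGE = (0.05, 3.0)


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    scenario_id: str
    description: str
    model: MotifModel
    signal: SignalProfile
    n_points: int = DEFAULT_N_POINTS
    initial: str = "kinetic_min"  # kinetic_min | upper_branch | mixed_halves
    settings: SolverSettings = field(
        default_factory=lambda: SolverSettings(t_max=5000.0)
    )
    # expected qualitative diagnostics: (kind, species, expectation)
    expected: Tuple[Tuple, ...] = ()
    response: str = "R*"


_GRADIENT = SignalProfile(form="cosine_gradient", a=1.0, b=0.5)
_LOCALIZED = SignalProfile(form="localized_bump", a=0.2, A=1.0, theta0=np.pi, alpha=0.5)

_OSC_SETTINGS = SolverSettings(
    t_max=4000.0,
    detect_steady=False,
    rel_tol=1e-7,
    abs_tol=1e-9,
    sample_times=np.linspace(0.0, 4000.0, 8001),
)


def _build_registry() -> Dict[str, Scenario]:
    reg: Dict[str, Scenario] = {}

    def add(s: Scenario):
        reg[s.scenario_id] = s

    # --- coherent feedforward (gradient + localized, each transport case)
    for tag, diff in (("nondiff", "none"), ("diffX", "X"), ("diffY", "Y")):
        add(Scenario(
            f"fig2_cohff_{tag}_gradient",
            f"coherent feedforward, cosine gradient, {tag}",
            coherent_ff_model(diff), _GRADIENT,
            expected=(("alignment", "R*", "co"),),
        ))
    for tag, diff in (("nondiff", "none"), ("diffX", "X")):
        add(Scenario(
            f"fig2_cohff_{tag}_localized",
            f"coherent feedforward, localized bump, {tag}",
            coherent_ff_model(diff), _LOCALIZED,
            expected=(("alignment", "R*", "co"),),
        ))

    # --- incoherent feedforward type 1
    add(Scenario(
        "fig3_incohff1_nondiff_gradient",
        "incoherent feedforward 1 (inhibitor stronger), non-diffusible",
        incoherent_ff_1_model("none"), _GRADIENT,
        expected=(("alignment", "R*", "counter"),),
    ))
    add(Scenario(
        "fig3_incohff1_diffX_gradient",
        "incoherent feedforward 1, global inhibitor X",
        incoherent_ff_1_model("X"), _GRADIENT,
        expected=(("alignment", "R*", "co"),),
    ))
    add(Scenario(
        "fig3_incohff1_diffY_gradient",
        "incoherent feedforward 1, global activator Y",
        incoherent_ff_1_model("Y"), _GRADIENT,
        expected=(("alignment", "R*", "counter"),),
    ))

    # --- incoherent feedforward type 2 (biphasic)
    low = SignalProfile(form="cosine_gradient", a=0.3, b=0.2)
    high = SignalProfile(form="cosine_gradient", a=2.0, b=0.5)
    add(Scenario(
        "fig3_incohff2_nondiff_lowmean",
        "incoherent feedforward 2, low-mean gradient (ascending branch)",
        incoherent_ff_2_model("none"), low,
        expected=(("alignment", "R*", "co"),),
    ))
    add(Scenario(
        "fig3_incohff2_nondiff_highmean",
        "incoherent feedforward 2, high-mean gradient (descending branch)",
        incoherent_ff_2_model("none"), high,
        expected=(("alignment", "R*", "counter"),),
    ))
    add(Scenario(
        "fig3_incohff2_diffX_lowmean",
        "incoherent feedforward 2, global X, low-mean gradient",
        incoherent_ff_2_model("X"), low,
        expected=(("alignment", "R*", "counter"),),
    ))
    add(Scenario(
        "fig3_incohff2_diffX_highmean",
        "incoherent feedforward 2, global X, high-mean gradient",
        incoherent_ff_2_model("X"), high,
        expected=(("alignment", "R*", "counter"),),
    ))

    # --- positive feedback (printed k_yx values 0.5 and 2.0)
    for kyx, ktag in ((0.5, "kyx05"), (2.0, "kyx2")):
        add(Scenario(
            f"fig4_posfb_nondiff_{ktag}",
            f"positive feedback, non-diffusible, k_yx={kyx}",
            positive_fb_model(kyx, "none"), _GRADIENT,
            expected=(("alignment", "R*", "co"),),
        ))
        add(Scenario(
            f"fig4_posfb_diffY_{ktag}",
            f"positive feedback, global feedback element Y, k_yx={kyx}",
            positive_fb_model(kyx, "Y"), _GRADIENT,
            expected=(("alignment", "R*", "co"),),
        ))
    for tag, diff in (("nondiff", "none"), ("diffY", "Y")):
        add(Scenario(
            f"fig4_posfb_{tag}_localized",
            f"positive feedback, localized bump, k_yx=1.0, {tag}",
            positive_fb_model(1.0, diff), _LOCALIZED,
            expected=(("alignment", "R*", "co"),),
        ))

    # --- negative feedback (printed k_yx values 10.0 and 14.0)
    for kyx, ktag in ((10.0, "kyx10"), (14.0, "kyx14")):
        add(Scenario(
            f"fig5_negfb_nondiff_{ktag}",
            f"negative feedback, non-diffusible, k_yx={kyx}",
            negative_fb_model(kyx, "none"), _GRADIENT,
            expected=(("alignment", "R*", "co"),),
        ))
        add(Scenario(
            f"fig5_negfb_diffY_{ktag}",
            f"negative feedback, global feedback element Y, k_yx={kyx}",
            negative_fb_model(kyx, "Y"), _GRADIENT,
            expected=(("alignment", "R*", "co"),),
        ))

    # --- cyclic
    cyc_localized = SignalProfile(form="localized_bump", a=0.5, A=1.0,
                                  theta0=np.pi, alpha=0.5)
    add(Scenario(
        "fig6_cyclic_nondiff_gradient",
        "cyclic n=4, non-diffusible, gradient",
        cyclic_model(4), _GRADIENT,
        expected=(("alignment", "X1", "counter"), ("alignment", "X2", "co")),
        response="X2",
    ))
    add(Scenario(
        "fig6_cyclic_nondiff_localized",
        "cyclic n=4, non-diffusible, localized signal",
        cyclic_model(4), cyc_localized,
        expected=(("alignment", "X1", "counter"), ("alignment", "X2", "co")),
        response="X2",
    ))
    add(Scenario(
        "fig7_cyclic_X1_diffusible",
        "cyclic n=4, signal-regulated species X1 global",
        cyclic_model(4, diffusible_index=1), _GRADIENT,
        expected=(("uniform", "X1", 0.01), ("alignment", "X2", "co")),
        response="X2",
    ))
    add(Scenario(
        "fig7_cyclic_X3_diffusible",
        "cyclic n=4, downstream species X3 global",
        cyclic_model(4, diffusible_index=3), _GRADIENT,
        expected=(
            ("uniform", "X2", 0.01), ("uniform", "X3", 0.01),
            ("uniform", "X4", 0.01), ("alignment", "X1", "counter"),
        ),
        response="X1",
    ))

    # --- Goldbeter-Koshland switch
    gk_gradient = SignalProfile(form="sine_gradient", a=1.0, b=0.5)
    gk_pulse = SignalProfile(form="square_pulse", a=0.5, A=1.0,
                             theta1=np.pi / 2, theta2=3 * np.pi / 2)
    add(Scenario(
        "fig8_gk_nondiff_gradient",
        "zero-order switch, non-diffusible, sine gradient straddling threshold",
        goldbeter_koshland_model("none"), gk_gradient,
        expected=(("switch", "X*", True),), response="X*",
    ))
    add(Scenario(
        "fig8_gk_diffX_gradient",
        "zero-order switch, inactive form X global, sine gradient: the "
        "response sharpens into an amplified peak at the signal maximum "
        "(well beyond the local total)",
        goldbeter_koshland_model("X"), gk_gradient,
        expected=(("max_above", "X*", 1.0),), response="X*",
    ))
    add(Scenario(
        "fig8_gk_nondiff_pulse",
        "zero-order switch, non-diffusible, square pulse on half the domain",
        goldbeter_koshland_model("none"), gk_pulse,
        expected=(("switch", "X*", True),), response="X*",
    ))
    add(Scenario(
        "fig8_gk_diffX_pulse",
        "zero-order switch, inactive form X global, square pulse",
        goldbeter_koshland_model("X"), gk_pulse,
        expected=(("switch", "X*", True),), response="X*",
    ))
    add(Scenario(
        "fig8_hill_diffR_pulse",
        "Hill switch comparison, inactive form R global, square pulse",
        hill_switch_model("R"), gk_pulse,
        expected=(("switch", "R*", True),), response="R*",
    ))

    # --- bistable switch
    below = SignalProfile(form="cosine_gradient", a=2.5, b=1.0)
    straddle = SignalProfile(form="cosine_gradient", a=4.0, b=1.5)
    bi_settings = SolverSettings(t_max=20000.0)
    add(Scenario(
        "fig9_bistable_below_s2",
        "bistable switch, gradient entirely below S2, lower-branch start",
        bistable_model("none"), below, settings=bi_settings,
        expected=(("switch", "X*", False), ("alignment", "X*", "co")),
        response="X*",
    ))
    add(Scenario(
        "fig9_bistable_straddle_s2",
        "bistable switch, gradient straddling S2: spatial switch",
        bistable_model("none"), straddle, settings=bi_settings,
        expected=(("switch", "X*", True),), response="X*",
    ))
    add(Scenario(
        "fig9e_bistable_history",
        "bistable switch, weak diffusion, mixed-branch history: pinned front "
        "(checked as front stationarity and branch coexistence; the resolved "
        "front has intermediate node values, so no two-plateau gap)",
        bistable_model(weak=True), below, initial="mixed_halves",
        # tight residual threshold so late-time front drift is bounded by
        # residual * horizon well below the stationarity check
        settings=SolverSettings(t_max=20000.0, steady_tol=1e-10),
        expected=(), response="X*",
    ))
    add(Scenario(
        "fig10_bistable_diffY",
        "bistable switch, global Y: heterogeneous profile, no spatial switch",
        bistable_model("Y"), straddle, settings=bi_settings,
        expected=(("switch", "X*", False), ("alignment", "X*", "co")),
        response="X*",
    ))

    # --- oscillator (signal windows anchored to the Hopf window of the
    #     fixture parameters; see calibrate_regimes)
    # a stronger gradient with a global feedback element quenches the
    # oscillation outright (amplitude death), so the synchronized-oscillation
    # case uses a gentler gradient with the same in-window mean
    osc_gradient = SignalProfile(form="cosine_gradient", a=1.0, b=0.8)
    osc_inwindow = SignalProfile(form="cosine_gradient", a=1.0, b=0.1)
    osc_below = SignalProfile(form="cosine_gradient", a=0.25, b=0.15)
    add(Scenario(
        "fig11_osc_nondiff",
        "oscillator, non-diffusible, gradient partly inside the Hopf window",
        nf_oscillator_model("none"), osc_gradient, n_points=OSC_N_POINTS,
        settings=_OSC_SETTINGS, expected=(), response="R*",
    ))
    add(Scenario(
        "fig12_osc_diffY_inwindow",
        "oscillator, global Y, signal average inside the Hopf window",
        nf_oscillator_model("Y"), osc_inwindow, n_points=OSC_N_POINTS,
        initial="small", settings=_OSC_SETTINGS, expected=(), response="R*",
    ))
    add(Scenario(
        "fig12_osc_diffY_belowwindow",
        "oscillator, global Y, signal average below the Hopf window",
        nf_oscillator_model("Y"), osc_below, n_points=OSC_N_POINTS,
        settings=replace(_OSC_SETTINGS, detect_steady=True),
        expected=(), response="R*",
    ))

    # --- transcritical switch
    tc_straddle = SignalProfile(form="cosine_gradient", a=1.0, b=0.5)
    tc_below = SignalProfile(form="cosine_gradient", a=0.6, b=0.3)
    tc_high = SignalProfile(form="cosine_gradient", a=2.0, b=0.5)
    # long horizon: relaxation onto the zero branch slows algebraically at
    # nodes where the local signal approaches the critical level
    tc_settings = SolverSettings(t_max=20000.0)
    add(Scenario(
        "fig14_transcritical_nondiff_below",
        "transcritical switch, gradient below S_c: counter-aligned response",
        transcritical_model("none"), tc_below, initial="upper_branch",
        settings=tc_settings,
        expected=(("alignment", "X*", "counter"),), response="X*",
    ))
    add(Scenario(
        "fig14_transcritical_nondiff_straddle",
        "transcritical switch, gradient straddling S_c: response zero beyond "
        "the critical level, positive below (a continuous spatial threshold, "
        "so the two-plateau gap detector stays quiet)",
        transcritical_model("none"), tc_straddle, initial="upper_branch",
        settings=tc_settings,
        expected=(("switch", "X*", False),), response="X*",
    ))
    add(Scenario(
        "fig14_transcritical_diffY_straddle",
        "transcritical switch, global Y, same gradient: no spatial switch",
        transcritical_model("Y"), tc_straddle, initial="upper_branch",
        settings=tc_settings,
        expected=(("switch", "X*", False), ("positive", "X*", 1e-6)),
        response="X*",
    ))
    add(Scenario(
        "fig14_transcritical_diffY_high",
        "transcritical switch, global Y, high gradient: uniform zero response",
        transcritical_model("Y"), tc_high, initial="upper_branch",
        settings=tc_settings,
        expected=(("max_below", "X*", 1e-6),), response="X*",
    ))
    return reg


_REGISTRY: Optional[Dict[str, Scenario]] = None


def _registry() -> Dict[str, Scenario]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _build_registry()
    return _REGISTRY


def list_scenarios() -> List[str]:
    """Stable-ordered list of scenario ids."""
    return sorted(_registry())


def get_scenario(scenario_id: str) -> Scenario:
    reg = _registry()
    if scenario_id not in reg:
        raise RegistryError(
            f"unknown scenario {scenario_id!r}; known ids: {sorted(reg)}"
        )
    return reg[scenario_id]


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def _bistable_branch_states(model: MotifModel, S: float) -> Tuple[np.ndarray, np.ndarray]:
    """(lower, upper) homogeneous states of the bistable module at signal S."""
    p = model.params
    lower = homogeneous_steady(model, S)  # default start relaxes to lower branch
    x_hi = (p["k_0"] + p["k_1"] * S) / p["k_2"]
    upper = homogeneous_steady(model, S, initial=np.array([x_hi, 1e-6]))
    return lower, upper


def initial_state(scenario: Scenario, domain: SpatialDomain, signal: np.ndarray) -> np.ndarray:
    """Resolve a scenario's initial-condition rule to a state field."""
    model = scenario.model
    S_min = float(np.min(signal))
    if scenario.initial == "kinetic_min":
        x0 = homogeneous_steady(model, S_min)
        return np.repeat(x0[:, None], domain.n_points, axis=1)
    if scenario.initial == "small":
        # small positive state with conserved pools in the inactive member;
        # used where the kinetics at min(S) has no stable fixed point
        from .simulate import _default_homogeneous_initial

        x0 = _default_homogeneous_initial(model)
        return np.repeat(x0[:, None], domain.n_points, axis=1)
    if scenario.initial == "upper_branch":
        if model.motif_id == "transcritical":
            # positive branch: start with most of the pools active
            x0 = np.array([0.9 * model.totals["X"], 0.9 * model.totals["Y"]])
        else:
            x0 = _bistable_branch_states(model, S_min)[1]
        return np.repeat(x0[:, None], domain.n_points, axis=1)
    if scenario.initial == "mixed_halves":
        S_mid = float(np.mean(signal))
        lower, upper = _bistable_branch_states(model, S_mid)
        state = np.repeat(lower[:, None], domain.n_points, axis=1)
        high_half = np.cos(domain.theta) > 0  # align the upper half with the signal max
        state[:, high_half] = upper[:, None]
        return state
    raise RegistryError(f"unknown initial rule {scenario.initial!r}")


def execute_scenario(scenario_id: str):
    """Run a scenario end-to-end and attach diagnostics.

    Returns (SimulationResult, DiagnosticsReport).
    """
    from .diagnostics import (
        DiagnosticsReport,
        classify_alignment,
        detect_spatial_switch,
        oscillation_analysis,
        response_baseline,
        response_contrast,
    )

    sc = get_scenario(scenario_id)
    domain = build_domain(sc.n_points)
    signal = make_signal(sc.signal, domain)
    init = initial_state(sc, domain, signal)
    result = integrate(sc.model, init, signal, domain, sc.settings)

    report = DiagnosticsReport()
    profile = result.species_profile(sc.response)
    report.alignment, report.correlation = classify_alignment(profile, signal, domain)
    report.contrast = response_contrast(profile)
    report.baseline = response_baseline(profile, signal)
    report.switch = detect_spatial_switch(profile, domain)
    if not sc.settings.detect_steady:
        report.oscillation = oscillation_analysis(
            result.times, result.species_series(sc.response),
            transient_fraction=sc.settings.transient_fraction,
        )
    _check_expected(sc, result, report)
    return result, report


def _check_expected(sc: Scenario, result: SimulationResult, report) -> None:
    from .diagnostics import classify_alignment, detect_spatial_switch

    domain = result.domain
    for kind, species, expect in sc.expected:
        profile = result.species_profile(species)
        if kind == "alignment":
            got, _ = classify_alignment(profile, result.signal, domain)
            ok = got == expect
        elif kind == "switch":
            ok = detect_spatial_switch(profile, domain).detected == expect
        elif kind == "uniform":
            mean = float(np.mean(np.abs(profile)))
            ok = mean > 0 and (np.max(profile) - np.min(profile)) / mean < expect
        elif kind == "positive":
            ok = bool(np.all(profile > expect))
        elif kind == "max_below":
            ok = bool(np.max(np.abs(profile)) < expect)
        elif kind == "max_above":
            ok = bool(np.max(profile) > expect)
        else:
            raise RegistryError(f"unknown expectation kind {kind!r}")
        if not ok:
            raise CalibrationError(
                f"scenario {sc.scenario_id}: expectation {kind}({species}) = "
                f"{expect!r} not met"
            )


# ---------------------------------------------------------------------------
# regime calibration
# ---------------------------------------------------------------------------


def calibrate_regimes() -> Dict:
    """Verify that the frozen fixture parameters realize their regimes.

    Checks: bistable window width >= 20% of its midpoint; oscillator Hopf
    window nonempty; the zero-order switch operates with K_M <= 0.02 X_tot;
    feedback reductions stay far from saturation (active fractions < 10% at
    fixture signals). Returns the realized S1, S2 and Hopf endpoints.

    Raises CalibrationError naming the failing fixture.
    """
    report: Dict = {}

    branch = scan_branches(bistable_model(), BISTABLE_SCAN_RANGE, n_scan=120)
    folds = sorted(sp.S_located for sp in branch.special_points if sp.type == "fold")
    if len(folds) != 2:
        raise CalibrationError(
            f"bistable fixture: expected 2 folds, found {len(folds)}"
        )
    S1, S2 = folds
    if (S2 - S1) < 0.2 * 0.5 * (S1 + S2):
        raise CalibrationError("bistable fixture: S window narrower than 20% of midpoint")
    report["bistable_S1"], report["bistable_S2"] = S1, S2

    window = oscillation_window(nf_oscillator_model(), OSCILLATOR_SCAN_RANGE, n_scan=120)
    if window is None:
        raise CalibrationError("oscillator fixture: no Hopf window found")
    report["hopf_low"], report["hopf_high"] = window

    gk = goldbeter_koshland_model()
    if gk.params["K_M1"] > 0.02 * gk.totals["X"] or gk.params["K_M2"] > 0.02 * gk.totals["X"]:
        raise CalibrationError("zero-order switch fixture: K_M too large for zero-order regime")
    report["gk_zero_order"] = True

    domain = build_domain(DEFAULT_N_POINTS)
    signal = make_signal(_GRADIENT, domain)
    for name, model in (("positive_fb", positive_fb_model(2.0)),
                        ("negative_fb", negative_fb_model(14.0))):
        S_hi = float(np.max(signal))
        x = homogeneous_steady(model, S_hi)
        fractions = {
            sp: x[i] / model.totals[t]
            for i, (sp, t) in enumerate(zip(model.species, ("X", "R", "Y")))
        }
        worst = max(fractions.values())
        if worst >= 0.10:
            raise CalibrationError(
                f"{name} fixture: active fraction {worst:.2%} >= 10%; "
                "far-from-saturation reduction invalid"
            )
        report[f"{name}_max_active_fraction"] = worst
    return report
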