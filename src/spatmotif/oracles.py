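"""Closed-form and reduced steady-state solutions used as verification oracles.

Each function evaluates a steady state that can be derived analytically, in
most cases in the limit where one network element is so diffusible that its
concentration is uniform and set by the *spatial average* of its drive (the
leading order of a 1/D perturbation expansion). These serve both as
user-facing calculators and as independent cross-checks of the PDE solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.optimize import brentq

from .domain import SpatialDomain, spatial_average
from .errors import KineticsError, ShapeError, ValidityError
from .motifs import MotifModel

__all__ = [
    "ReducedFeedbackParams",
    "CyclicSolution",
    "OracleReport",
    "high_diffusion_steady",
    "coherent_ff_steady",
    "incoherent_ff_steady",
    "reduced_feedback_params",
    "positive_fb_steady",
    "positive_fb_full_steady",
    "negative_fb_steady",
    "negative_fb_full_steady",
    "cyclic_steady",
    "gk_diffusible_amplification",
    "hill_switch_diffusible_steady",
    "bistable_diffusible_steady",
    "transcritical_steady",
    "compare_oracle",
]

_BISECT_TOL = 1e-12


@dataclass(frozen=True)
class ReducedFeedbackParams:
    """Lumped gain/feedback parameters of the far-from-saturation reductions.

    alpha is the open-loop gain from signal to response, beta the loop gain of
    the feedback (dimensionless). The positive-feedback closed forms are valid
    only for beta clearly below 1; beyond that saturation terms matter.
    """

    alpha: float
    beta: float
    R0: float = 0.0

    def __post_init__(self):
        if self.alpha < 0 or self.R0 < 0:
            raise ValidityError("alpha and R0 must be non-negative")


@dataclass(frozen=True)
class CyclicSolution:
    """Steady state of the irreversible cycle: common flux F and species levels."""

    F: np.ndarray  # scalar flux broadcast per node (uniform in all solved cases)
    levels: np.ndarray  # (n_species, n_nodes)


@dataclass
class OracleReport:
    """Predicted-vs-simulated comparison for one oracle."""

    oracle_id: str
    predicted: np.ndarray
    simulated: np.ndarray
    sup_rel_error: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.sup_rel_error <= self.tolerance


def compare_oracle(oracle_id, predicted, simulated, tolerance) -> OracleReport:
    """Sup-norm relative comparison, scaled by the predicted field's maximum."""
    p = np.asarray(predicted, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if p.shape != s.shape:
        raise ShapeError(f"oracle {oracle_id}: shapes {p.shape} vs {s.shape}")
    scale = max(float(np.max(np.abs(p))), 1e-300)
    err = float(np.max(np.abs(p - s))) / scale
    return OracleReport(oracle_id, p, s, err, tolerance)


# ---------------------------------------------------------------------------
# High-diffusion limit of a linear interconversion pair
# ---------------------------------------------------------------------------


def high_diffusion_steady(
    total: float,
    k_fwd_of_S: float,
    k_basal_fwd: float,
    k_basal_rev: float,
    signal,
    domain: SpatialDomain,
    k_rev_of_S: float = 0.0,
) -> float:
    """Leading-order uniform steady state of a highly diffusible pair species.

    For activation rate a(theta) = k_fwd_of_S*S + k_basal_fwd and deactivation
    b(theta) = k_rev_of_S*S + k_basal_rev, the solvability condition of the
    1/D expansion gives the uniform level

        X0 = total * <a> / (<a> + <b>),

    i.e. the local kinetic fixed point evaluated at the spatial average of the
    signal.
    """
    Sbar = spatial_average(signal, domain)
    a = k_fwd_of_S * Sbar + k_basal_fwd
    b = k_rev_of_S * Sbar + k_basal_rev
    if a + b == 0:
        raise KineticsError("all rate constants vanish; steady state undetermined")
    return float(total * a / (a + b))


# ---------------------------------------------------------------------------
# Feedforward modules
# ---------------------------------------------------------------------------


def _pair_steady(total, k_sig, k_fwd, k_rev, S):
    drive = k_sig * S + k_fwd
    return total * drive / (drive + k_rev)


def coherent_ff_steady(
    model: MotifModel, signal, diffusible: str, domain: SpatialDomain
) -> np.ndarray:
    """Steady response R*(theta) of the coherent feedforward module.

    ``diffusible`` in {"none", "X", "Y"}: the named pathway element is taken
    uniform at the level set by the spatial average of the signal.
    """
    if model.motif_id != "coherent_ff":
        raise ValidityError("model must be coherent_ff")
    p, t = model.params, model.totals
    S = domain.check_field(signal)
    Sbar = spatial_average(S, domain)
    if diffusible == "none":
        Xs = _pair_steady(t["X"], p["k_sx"], p["k_x"], p["k_mx"], S)
        Ys = _pair_steady(t["Y"], p["k_sy"], p["k_y"], p["k_my"], S)
    elif diffusible == "X":
        Xs = _pair_steady(t["X"], p["k_sx"], p["k_x"], p["k_mx"], Sbar)
        Ys = _pair_steady(t["Y"], p["k_sy"], p["k_y"], p["k_my"], S)
    elif diffusible == "Y":
        Xs = _pair_steady(t["X"], p["k_sx"], p["k_x"], p["k_mx"], S)
        Ys = _pair_steady(t["Y"], p["k_sy"], p["k_y"], p["k_my"], Sbar)
    else:
        raise ValidityError(f"unknown diffusible tag {diffusible!r}")
    drive = p["k_xr"] * Xs + p["k_yr"] * Ys + p["k_r"]
    return np.broadcast_to(t["R"] * drive / (drive + p["k_mr"]), S.shape).copy()


def incoherent_ff_steady(
    model: MotifModel, signal, diffusible: str, domain: SpatialDomain
) -> np.ndarray:
    """Steady response of the incoherent feedforward module (inhibitor X,
    activator Y, X* enhancing R* deactivation)."""
    if model.motif_id != "incoherent_ff_1":
        raise ValidityError("model must be incoherent_ff_1")
    p, t = model.params, model.totals
    S = domain.check_field(signal)
    Sbar = spatial_average(S, domain)
    SX, SY = S, S
    if diffusible == "X":
        SX = Sbar
    elif diffusible == "Y":
        SY = Sbar
    elif diffusible != "none":
        raise ValidityError(f"unknown diffusible tag {diffusible!r}")
    Xs = _pair_steady(t["X"], p["k_sx"], p["k_x"], p["k_mx"], SX)
    Ys = _pair_steady(t["Y"], p["k_sy"], p["k_y"], p["k_my"], SY)
    num = p["k_r"] + p["k_yr"] * Ys
    return np.broadcast_to(
        t["R"] * num / (num + p["k_mr"] + p["k_xr"] * Xs), S.shape
    ).copy()


# ---------------------------------------------------------------------------
# Feedback modules: far-from-saturation reductions and full fixed points
# ---------------------------------------------------------------------------


def reduced_feedback_params(model: MotifModel) -> ReducedFeedbackParams:
    """Lumped alpha/beta of the far-from-saturation feedback reductions.

    positive_fb: alpha = k_xr k_sx Xtot Rtot/(k_mr k_mx),
                 beta  = Xtot Ytot Rtot k_xr k_yx k_ry/(k_mr k_mx k_my).
    negative_fb: alpha = k_sx Xtot Rtot k_xr/(k_mr k_mx),
                 beta  = k_yx Ytot k_ry/(k_my k_mx).
    """
    p, t = model.params, model.totals
    if model.motif_id == "positive_fb":
        alpha = p["k_xr"] * p["k_sx"] * t["X"] * t["R"] / (p["k_mr"] * p["k_mx"])
        beta = (
            t["X"] * t["Y"] * t["R"] * p["k_xr"] * p["k_yx"] * p["k_ry"]
            / (p["k_mr"] * p["k_mx"] * p["k_my"])
        )
    elif model.motif_id == "negative_fb":
        alpha = p["k_sx"] * t["X"] * t["R"] * p["k_xr"] / (p["k_mr"] * p["k_mx"])
        beta = p["k_yx"] * t["Y"] * p["k_ry"] / (p["k_my"] * p["k_mx"])
    else:
        raise ValidityError("reduced feedback parameters exist for positive_fb/negative_fb")
    return ReducedFeedbackParams(alpha=alpha, beta=beta)


def positive_fb_steady(
    params: ReducedFeedbackParams, signal, diffusible: str, domain: SpatialDomain
) -> np.ndarray:
    """Reduced positive-feedback response.

    non-diffusible: R* = alpha*S/(1-beta);
    diffusible Y:   R* = alpha*S + beta/(1-beta) * alpha*<S>.
    Valid only for beta clearly below 1.
    """
    a, b = params.alpha, params.beta
    if b >= 1:
        raise ValidityError(
            f"positive-feedback reduction requires beta < 1 (got {b:.3g}); "
            "saturation effects dominate beyond that"
        )
    S = domain.check_field(signal)
    if diffusible == "none":
        return a * S / (1.0 - b)
    if diffusible == "Y":
        return a * S + b / (1.0 - b) * a * spatial_average(S, domain)
    raise ValidityError(f"unknown diffusible tag {diffusible!r}")


def negative_fb_steady(
    params: ReducedFeedbackParams, signal, diffusible: str, domain: SpatialDomain
) -> np.ndarray:
    """Reduced negative-feedback response.

    non-diffusible: positive root of beta*R*^2 + R* - alpha*S = 0 per node;
    diffusible Y:   R* = alpha*S/(1+beta*R0) with
                    R0 = (sqrt(1+4*alpha*<S>*beta)-1)/(2*beta).
    """
    a, b = params.alpha, params.beta
    S = domain.check_field(signal)
    if diffusible == "none":
        if b == 0:
            return a * S
        return (np.sqrt(1.0 + 4.0 * a * b * S) - 1.0) / (2.0 * b)
    if diffusible == "Y":
        Sbar = spatial_average(S, domain)
        if b == 0:
            R0 = a * Sbar
        else:
            R0 = (np.sqrt(1.0 + 4.0 * a * Sbar * b) - 1.0) / (2.0 * b)
        return a * S / (1.0 + b * R0)
    raise ValidityError(f"unknown diffusible tag {diffusible!r}")


def _fb_fixed_point(model, S_local, Y_drive):
    """One damped fixed-point sweep helper for the full feedback systems."""
    p, t = model.params, model.totals
    sign = 1.0 if model.motif_id == "positive_fb" else -1.0

    def step(Xs, Rs, Ys, Y_for_X):
        drive_r = p["k_xr"] * Xs + p["k_r"]
        Rs_new = t["R"] * drive_r / (drive_r + p["k_mr"])
        drive_y = p["k_ry"] * Y_drive(Rs_new) + p["k_y"]
        Ys_new = t["Y"] * drive_y / (drive_y + p["k_my"])
        if sign > 0:
            num = p["k_sx"] * S_local + p["k_x"] + p["k_yx"] * Y_for_X(Ys_new)
            Xs_new = t["X"] * num / (num + p["k_mx"])
        else:
            num = p["k_sx"] * S_local + p["k_x"]
            Xs_new = t["X"] * num / (num + p["k_yx"] * Y_for_X(Ys_new) + p["k_mx"])
        return Xs_new, Rs_new, Ys_new

    return step


def _solve_fb_full(model, signal, diffusible, domain, damping=0.5, max_iter=20000):
    p, t = model.params, model.totals
    S = domain.check_field(signal)
    if diffusible == "Y":
        Y_drive = lambda Rs: spatial_average(Rs, domain)
        Y_for_X = lambda Ys: Ys  # uniform scalar broadcast
    elif diffusible == "none":
        Y_drive = lambda Rs: Rs
        Y_for_X = lambda Ys: Ys
    else:
        raise ValidityError(f"unknown diffusible tag {diffusible!r}")
    step = _fb_fixed_point(model, S, Y_drive)
    Xs = np.zeros_like(S)
    Rs = np.zeros_like(S)
    Ys = np.zeros_like(S)
    for _ in range(max_iter):
        Xn, Rn, Yn = step(Xs, Rs, Ys, Y_for_X)
        Xn = (1 - damping) * Xs + damping * Xn
        Rn = (1 - damping) * Rs + damping * Rn
        Yn = (1 - damping) * Ys + damping * Yn
        change = max(
            np.max(np.abs(Xn - Xs)), np.max(np.abs(Rn - Rs)), np.max(np.abs(Yn - Ys))
        )
        Xs, Rs, Ys = Xn, Rn, Yn
        if change < _BISECT_TOL:
            return Xs, Rs, Ys
    raise KineticsError("feedback fixed-point iteration did not converge")


def positive_fb_full_steady(model, signal, diffusible, domain) -> np.ndarray:
    """Full (unsimplified) positive-feedback fixed point by damped iteration."""
    if model.motif_id != "positive_fb":
        raise ValidityError("model must be positive_fb")
    return _solve_fb_full(model, signal, diffusible, domain)[1]


def negative_fb_full_steady(model, signal, diffusible, domain) -> np.ndarray:
    """Full (unsimplified) negative-feedback fixed point by damped iteration."""
    if model.motif_id != "negative_fb":
        raise ValidityError("model must be negative_fb")
    return _solve_fb_full(model, signal, diffusible, domain)[1]


# ---------------------------------------------------------------------------
# Cyclic module
# ---------------------------------------------------------------------------


def cyclic_steady(
    model: MotifModel, signal, diffusible_index, domain: SpatialDomain
) -> CyclicSolution:
    """Steady state of the irreversible cycle.

    diffusible_index: "none" (all local), 1 (the signal-regulated species is
    global) or k > 1 (any later species is global). With species 1 global,
    species 2..n carry the signal's shape; with any k > 1 global, every
    species except species 1 is uniform and X1 varies inversely with S.
    """
    if model.motif_id != "cyclic":
        raise ValidityError("model must be cyclic")
    p, t = model.params, model.totals
    n = model.n_species
    S = domain.check_field(signal)
    k = np.array([p[f"k_{i + 1}"] for i in range(n)])
    inv_sum = np.sum(1.0 / k[1:])
    Xtot = t["X"]

    if diffusible_index == "none":
        if np.any(S <= 0):
            raise KineticsError("cyclic steady state requires a strictly positive signal")
        F = Xtot / (1.0 / (k[0] * S) + inv_sum)
        levels = np.empty((n, S.size))
        levels[0] = F / (k[0] * S)
        for i in range(1, n):
            levels[i] = F / k[i]
        return CyclicSolution(F=F, levels=levels)

    Sbar = spatial_average(S, domain)
    if diffusible_index == 1:
        X1 = Xtot / (1.0 + k[0] * Sbar * inv_sum)
        levels = np.empty((n, S.size))
        levels[0] = np.full(S.size, X1)
        for i in range(1, n):
            levels[i] = k[0] * X1 * S / k[i]
        F = np.full(S.size, k[0] * X1 * Sbar)
        return CyclicSolution(F=F, levels=levels)

    kd = int(diffusible_index)
    if not 1 < kd <= n:
        raise ValidityError(f"diffusible_index must be 'none', 1, or 2..{n}")
    if np.any(S <= 0):
        raise KineticsError("X1 is unbounded where the signal vanishes")
    # equal-flux solution with the global conservation <sum X_i> = X_tot:
    # <X_1> = F <1/(k_1 S)>, so the harmonic mean of the signal enters (the
    # arithmetic mean would overestimate F for any non-uniform signal)
    F = Xtot / (spatial_average(1.0 / (k[0] * S), domain) + inv_sum)
    levels = np.empty((n, S.size))
    levels[0] = F / (k[0] * S)
    for i in range(1, n):
        levels[i] = np.full(S.size, F / k[i])
    return CyclicSolution(F=np.full(S.size, F), levels=levels)


# ---------------------------------------------------------------------------
# Switch modules
# ---------------------------------------------------------------------------


def gk_diffusible_amplification(
    X_tot: float, switch_interval: Tuple[float, float], residual_X: float,
    domain: SpatialDomain,
) -> float:
    """Plateau level of the zero-order switch with globally diffusible X.

    When the switch is on over [theta1, theta2) the diffusible inactive pool
    is funnelled into that interval, so by global conservation

        X0 = (X_tot - X) * L / (theta2 - theta1),

    which exceeds X_tot once the interval is narrower than the domain.
    """
    t1, t2 = switch_interval
    width = (t2 - t1) % domain.length
    if width <= 0:
        raise KineticsError("empty switch interval")
    return float((X_tot - residual_X) * domain.length / width)


def hill_switch_diffusible_steady(
    R_tot: float, k_f: float, k_r: float, f_of_S, domain: SpatialDomain
) -> np.ndarray:
    """Hill-switch response with the inactive form globally diffusible:
    R* = R_tot * k_f f(S) / (k_f <f(S)> + k_r)."""
    f = domain.check_field(f_of_S)
    if np.any((f < 0) | (f > 1)):
        raise ValidityError("f(S) values must lie in [0, 1]")
    fbar = spatial_average(f, domain)
    return R_tot * k_f * f / (k_f * fbar + k_r)


def _bistable_Y_residual(model, Xbar, Ys):
    p, t = model.params, model.totals
    Y = t["Y"] - Ys
    return -p["k_3"] * Xbar * Ys / (p["K_M3"] + Ys) + p["k_4"] * Y / (p["K_M4"] + Y)


def _bistable_jacobian(model, Xs, Ys):
    p, t = model.params, model.totals
    Y = t["Y"] - Ys
    j11 = -p["k_2"] - p["k_21"] * Ys
    j12 = -p["k_21"] * Xs
    j21 = -p["k_3"] * Ys / (p["K_M3"] + Ys)
    j22 = (
        -p["k_3"] * Xs * p["K_M3"] / (p["K_M3"] + Ys) ** 2
        - p["k_4"] * p["K_M4"] / (p["K_M4"] + Y) ** 2
    )
    return np.array([[j11, j12], [j21, j22]])


def bistable_diffusible_steady(
    model: MotifModel, signal, domain: SpatialDomain, n_brackets: int = 1000
) -> List[Dict]:
    """Heterogeneous steady states of the bistable switch with global Y.

    Solves the spatially averaged fixed-point system for all roots in Y* by a
    sign-change scan + bisection, keeps the stable ones (temporal Jacobian at
    <X*>, Y*), and maps each to the profile X*(theta) = (k0+k1 S)/(k2+k21 Y*).

    Returns a list of dicts with keys "X_profile", "Y_star", "X_mean",
    "stable".
    """
    if model.motif_id != "bistable_mutual_inhibition":
        raise ValidityError("model must be bistable_mutual_inhibition")
    p, t = model.params, model.totals
    S = domain.check_field(signal)
    Sbar = spatial_average(S, domain)

    def xbar_of(Ys):
        return (p["k_0"] + p["k_1"] * Sbar) / (p["k_2"] + p["k_21"] * Ys)

    def g(Ys):
        return _bistable_Y_residual(model, xbar_of(Ys), Ys)

    ys_grid = np.linspace(1e-12, t["Y"] - 1e-12, n_brackets + 1)
    vals = np.array([g(y) for y in ys_grid])
    roots = []
    for i in range(n_brackets):
        if vals[i] == 0.0:
            roots.append(ys_grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, ys_grid[i], ys_grid[i + 1], xtol=_BISECT_TOL))
    if not roots:
        raise KineticsError("no real root of the averaged bistable system")

    out = []
    for Ys in roots:
        Xbar = xbar_of(Ys)
        eigs = np.linalg.eigvals(_bistable_jacobian(model, Xbar, Ys))
        stable = bool(np.all(eigs.real < 0))
        profile = (p["k_0"] + p["k_1"] * S) / (p["k_2"] + p["k_21"] * Ys)
        out.append(
            {"X_profile": profile, "Y_star": float(Ys), "X_mean": float(Xbar),
             "stable": stable}
        )
    return [r for r in out if r["stable"]] or out


def transcritical_steady(
    model: MotifModel, signal, diffusible: str, domain: SpatialDomain
) -> np.ndarray:
    """Steady X* of the transcritical switch (Y far from saturation).

    non-diffusible: stable-branch selection per node,
        X* = max(0, X_tot - k_sx S k_my / (k_1 Y_tot k_2)).
    diffusible Y: the self-consistent positive profile
        X* = X_tot A <X*> / (k_sx S + A <X*>), A = Y_tot k_1 k_2 / k_my,
    if the averaged equation admits a positive root, else the uniform zero
    profile.
    """
    if model.motif_id != "transcritical":
        raise ValidityError("model must be transcritical")
    p, t = model.params, model.totals
    S = domain.check_field(signal)
    if diffusible == "none":
        return np.maximum(
            0.0, t["X"] - p["k_sx"] * S * p["k_my"] / (p["k_1"] * t["Y"] * p["k_2"])
        )
    if diffusible != "Y":
        raise ValidityError(f"unknown diffusible tag {diffusible!r}")
    A = t["Y"] * p["k_1"] * p["k_2"] / p["k_my"]

    def g(m):
        return float(np.mean(t["X"] * A * m / (p["k_sx"] * S + A * m))) - m

    # positive root exists iff the small-m slope of the mean exceeds 1
    if np.all(S > 0) and float(np.mean(t["X"] * A / (p["k_sx"] * S))) <= 1.0:
        return np.zeros_like(S)
    lo, hi = 1e-14, t["X"]
    if g(lo) <= 0:
        return np.zeros_like(S)
    m = brentq(g, lo, hi, xtol=_BISECT_TOL)
    return t["X"] * A * m / (p["k_sx"] * S + A * m)
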