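"""Kinetic schemes of the signalling motifs: species, parameters, rates.

Each motif is a small mass-action (or Michaelis-Menten) network driven by a
spatial signal S(theta). Species interconvert between active (starred) and
inactive forms; wherever the two forms share a diffusivity the inactive form
is eliminated through the conserved total (X = X_tot - X*), so the dynamic
state holds active forms only. The Goldbeter-Koshland and Hill switches keep
both forms as dynamic fields so that the inactive form can be given its own
(possibly much larger) diffusivity.

Parameter naming: ``k_sx`` is the signal-mediated activation of X, ``k_x`` /
``k_mx`` the basal forward/reverse constants (``k_mx`` is the ASCII alias of
the subscript-minus notation "k_-x"), ``k_xr`` the X*-mediated activation of R, ``k_yx``
the feedback constant, and so on. Michaelis constants are ``K_M1``..``K_M6``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Tuple

import numpy as np

from .domain import SpatialDomain, periodic_laplacian
from .errors import ConfigurationError, ShapeError

log = logging.getLogger(__name__)

#: Diffusivity conventions for the three transport regimes. The kinetic rate
#: constants are O(1) and the domain circumference is 2*pi, so D = 500 makes a
#: species effectively uniform (global), D = 0.005 weakly coupling, D = 0 local.
D_HIGH = 500.0
D_WEAK = 0.005
D_NONE = 0.0


@dataclass(frozen=True)
class MotifSpec:
    """Registry entry: what a motif needs and how its rates are computed."""

    motif_id: str
    species: Tuple[str, ...]
    required_params: Tuple[str, ...]
    required_totals: Tuple[str, ...]
    rhs: Callable
    # conserved pools among *dynamic* species: name -> tuple of species indices
    dynamic_pools: Dict[str, Tuple[int, ...]] = field(default_factory=dict)
    # pairs (active species index, total name) for eliminated inactive forms
    eliminated_pairs: Tuple[Tuple[int, str], ...] = ()


@dataclass(frozen=True)
class MotifModel:
    """A validated motif instance: scheme + kinetic parameters + transport.

    Attributes
    ----------
    motif_id : str
        Which kinetic scheme.
    species : tuple of str
        Ordered dynamic species names (active forms, unless the scheme keeps
        both forms explicitly).
    params : dict
        Kinetic rate constants; the required subset depends on the scheme.
    diffusivities : dict
        Per-species diffusion coefficient D_j >= 0.
    totals : dict
        Conserved pool totals (X_tot etc.).
    """

    motif_id: str
    species: Tuple[str, ...]
    params: Mapping[str, float]
    diffusivities: Mapping[str, float]
    totals: Mapping[str, float]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def spec(self) -> MotifSpec:
        return MOTIF_REGISTRY[self.motif_id]

    def diffusivity_array(self) -> np.ndarray:
        return np.array([self.diffusivities[s] for s in self.species], dtype=float)


# ---------------------------------------------------------------------------
# Rate functions. state has shape (n_species, n_nodes); signal shape (n_nodes,).
# Each returns an array of the same shape as state. No diffusion terms here.
# ---------------------------------------------------------------------------


def _clip_state(state):
    if np.any(state < 0):
        worst = float(state.min())
        if worst < -1e-6:
            log.warning("clipping negative concentrations (min %.3g)", worst)
        else:
            log.debug("clipping negative concentrations (min %.3g)", worst)
        state = np.maximum(state, 0.0)
    return state


def _rhs_coherent_ff(p, totals, state, S):
    Xs, Ys, Rs = state
    X = totals["X"] - Xs
    Y = totals["Y"] - Ys
    R = totals["R"] - Rs
    dX = (p["k_sx"] * S + p["k_x"]) * X - p["k_mx"] * Xs
    dY = (p["k_sy"] * S + p["k_y"]) * Y - p["k_my"] * Ys
    dR = (p["k_xr"] * Xs + p["k_yr"] * Ys + p["k_r"]) * R - p["k_mr"] * Rs
    return np.stack([dX, dY, dR])


def _rhs_incoherent_ff_1(p, totals, state, S):
    Xs, Ys, Rs = state
    X = totals["X"] - Xs
    Y = totals["Y"] - Ys
    R = totals["R"] - Rs
    dX = (p["k_sx"] * S + p["k_x"]) * X - p["k_mx"] * Xs
    dY = (p["k_sy"] * S + p["k_y"]) * Y - p["k_my"] * Ys
    dR = p["k_yr"] * Ys * R - p["k_xr"] * Xs * Rs + p["k_r"] * R - p["k_mr"] * Rs
    return np.stack([dX, dY, dR])


def _rhs_incoherent_ff_2(p, totals, state, S):
    # signal activates X and *de*activates Y; basal k_r of the response is zero
    Xs, Ys, Rs = state
    X = totals["X"] - Xs
    Y = totals["Y"] - Ys
    R = totals["R"] - Rs
    dX = (p["k_sx"] * S + p["k_x"]) * X - p["k_mx"] * Xs
    dY = p["k_y"] * Y - (p["k_sy"] * S + p["k_my"]) * Ys
    dR = (p["k_xr"] * Xs + p["k_yr"] * Ys) * R - p["k_mr"] * Rs
    return np.stack([dX, dY, dR])


def _rhs_positive_fb(p, totals, state, S):
    Xs, Rs, Ys = state
    X = totals["X"] - Xs
    R = totals["R"] - Rs
    Y = totals["Y"] - Ys
    dX = (p["k_sx"] * S + p["k_x"]) * X - p["k_mx"] * Xs + p["k_yx"] * X * Ys
    dR = (p["k_xr"] * Xs + p["k_r"]) * R - p["k_mr"] * Rs
    dY = (p["k_ry"] * Rs + p["k_y"]) * Y - p["k_my"] * Ys
    return np.stack([dX, dR, dY])


def _rhs_negative_fb(p, totals, state, S):
    Xs, Rs, Ys = state
    X = totals["X"] - Xs
    R = totals["R"] - Rs
    Y = totals["Y"] - Ys
    dX = (p["k_sx"] * S + p["k_x"]) * X - p["k_mx"] * Xs - p["k_yx"] * Xs * Ys
    dR = (p["k_xr"] * Xs + p["k_r"]) * R - p["k_mr"] * Rs
    dY = (p["k_ry"] * Rs + p["k_y"]) * Y - p["k_my"] * Ys
    return np.stack([dX, dR, dY])


def _rhs_cyclic(p, totals, state, S):
    n = state.shape[0]
    k = np.array([p[f"k_{i + 1}"] for i in range(n)])
    # step i -> i+1 flux; step 1 is signal-catalyzed (k_1 second order in S)
    flux = np.empty_like(state)
    flux[0] = k[0] * S * state[0]
    for i in range(1, n):
        flux[i] = k[i] * state[i]
    return np.roll(flux, 1, axis=0) - flux


def _rhs_goldbeter_koshland(p, totals, state, S):
    Xs, X = state
    fwd = p["k_sx"] * S * X / (p["K_M1"] + X)
    bwd = p["k_r"] * p["U"] * Xs / (p["K_M2"] + Xs)
    return np.stack([fwd - bwd, bwd - fwd])


def _rhs_bistable(p, totals, state, S):
    Xs, Ys = state
    Y = totals["Y"] - Ys
    dX = p["k_0"] + p["k_1"] * S - p["k_2"] * Xs - p["k_21"] * Xs * Ys
    dY = -p["k_3"] * Xs * Ys / (p["K_M3"] + Ys) + p["k_4"] * Y / (p["K_M4"] + Y)
    return np.stack([dX, dY])


def _rhs_nf_oscillator(p, totals, state, S):
    Xs, Rs, Ys = state
    R = totals["R"] - Rs
    Y = totals["Y"] - Ys
    dX = p["k_0"] + p["k_1"] * S - p["k_2"] * Xs - p["k_21"] * Xs * Ys
    dR = p["k_3"] * Xs * R / (p["K_M3"] + R) - p["k_4"] * Rs / (p["K_M4"] + Rs)
    dY = p["k_5"] * Rs * Y / (p["K_M5"] + Y) - p["k_6"] * Ys / (p["K_M6"] + Ys)
    return np.stack([dX, dR, dY])


def _rhs_transcritical(p, totals, state, S):
    Xs, Ys = state
    X = totals["X"] - Xs
    Y = totals["Y"] - Ys
    dX = -p["k_sx"] * S * Xs + p["k_1"] * X * Ys
    dY = p["k_2"] * Xs * Y - p["k_my"] * Ys
    return np.stack([dX, dY])


def _rhs_hill_switch(p, totals, state, S):
    # monostable switch through Hill cooperativity: f(S) = S^h / (K^h + S^h)
    Rs, R = state
    f = S ** p["n_h"] / (p["K_h"] ** p["n_h"] + S ** p["n_h"])
    fwd = p["k_f"] * f * R
    bwd = p["k_r"] * Rs
    return np.stack([fwd - bwd, bwd - fwd])


def hill_activation(S, K_h, n_h):
    """Hill activation function f(S) = S^h/(K^h + S^h) on an array of signals."""
    S = np.asarray(S, dtype=float)
    return S ** n_h / (K_h ** n_h + S ** n_h)


_FB_PARAMS = (
    "k_sx", "k_x", "k_mx", "k_yx", "k_xr", "k_r", "k_mr", "k_ry", "k_y", "k_my",
)

MOTIF_REGISTRY: Dict[str, MotifSpec] = {
    "coherent_ff": MotifSpec(
        "coherent_ff",
        ("X*", "Y*", "R*"),
        ("k_sx", "k_x", "k_mx", "k_sy", "k_y", "k_my", "k_xr", "k_yr", "k_r", "k_mr"),
        ("X", "Y", "R"),
        _rhs_coherent_ff,
        eliminated_pairs=((0, "X"), (1, "Y"), (2, "R")),
    ),
    "incoherent_ff_1": MotifSpec(
        "incoherent_ff_1",
        ("X*", "Y*", "R*"),
        ("k_sx", "k_x", "k_mx", "k_sy", "k_y", "k_my", "k_xr", "k_yr", "k_r", "k_mr"),
        ("X", "Y", "R"),
        _rhs_incoherent_ff_1,
        eliminated_pairs=((0, "X"), (1, "Y"), (2, "R")),
    ),
    "incoherent_ff_2": MotifSpec(
        "incoherent_ff_2",
        ("X*", "Y*", "R*"),
        ("k_sx", "k_x", "k_mx", "k_sy", "k_y", "k_my", "k_xr", "k_yr", "k_mr"),
        ("X", "Y", "R"),
        _rhs_incoherent_ff_2,
        eliminated_pairs=((0, "X"), (1, "Y"), (2, "R")),
    ),
    "positive_fb": MotifSpec(
        "positive_fb",
        ("X*", "R*", "Y*"),
        _FB_PARAMS,
        ("X", "Y", "R"),
        _rhs_positive_fb,
        eliminated_pairs=((0, "X"), (1, "R"), (2, "Y")),
    ),
    "negative_fb": MotifSpec(
        "negative_fb",
        ("X*", "R*", "Y*"),
        _FB_PARAMS,
        ("X", "Y", "R"),
        _rhs_negative_fb,
        eliminated_pairs=((0, "X"), (1, "R"), (2, "Y")),
    ),
    # species list is built per-instance for cyclic (depends on n)
    "cyclic": MotifSpec(
        "cyclic",
        (),
        (),
        ("X",),
        _rhs_cyclic,
    ),
    "goldbeter_koshland": MotifSpec(
        "goldbeter_koshland",
        ("X*", "X"),
        ("k_sx", "k_r", "U", "K_M1", "K_M2"),
        ("X",),
        _rhs_goldbeter_koshland,
        dynamic_pools={"X": (0, 1)},
    ),
    "bistable_mutual_inhibition": MotifSpec(
        "bistable_mutual_inhibition",
        ("X*", "Y*"),
        ("k_0", "k_1", "k_2", "k_21", "k_3", "k_4", "K_M3", "K_M4"),
        ("Y",),
        _rhs_bistable,
        eliminated_pairs=((1, "Y"),),
    ),
    "nf_oscillator": MotifSpec(
        "nf_oscillator",
        ("X*", "R*", "Y*"),
        (
            "k_0", "k_1", "k_2", "k_21", "k_3", "k_4", "k_5", "k_6",
            "K_M3", "K_M4", "K_M5", "K_M6",
        ),
        ("R", "Y"),
        _rhs_nf_oscillator,
        eliminated_pairs=((1, "R"), (2, "Y")),
    ),
    "transcritical": MotifSpec(
        "transcritical",
        ("X*", "Y*"),
        ("k_sx", "k_1", "k_2", "k_my"),
        ("X", "Y"),
        _rhs_transcritical,
        eliminated_pairs=((0, "X"), (1, "Y")),
    ),
    "hill_switch": MotifSpec(
        "hill_switch",
        ("R*", "R"),
        ("k_f", "k_r", "K_h", "n_h"),
        ("R",),
        _rhs_hill_switch,
        dynamic_pools={"R": (0, 1)},
    ),
}


def motif_registry() -> Dict[str, MotifSpec]:
    """The table of known motif schemes (id -> required parameters/totals)."""
    return dict(MOTIF_REGISTRY)


def _cyclic_species(params) -> Tuple[str, ...]:
    ks = sorted(
        int(key.split("_", 1)[1])
        for key in params
        if key.startswith("k_") and key.split("_", 1)[1].isdigit()
    )
    n = len(ks)
    if n < 2 or ks != list(range(1, n + 1)):
        raise ConfigurationError(
            f"cyclic motif requires consecutive rate constants k_1..k_n with "
            f"n >= 2, got {sorted(params)}"
        )
    return tuple(f"X{i + 1}" for i in range(n))


def build_motif(
    motif_id: str,
    params: Mapping[str, float],
    diffusivities: Mapping[str, float],
    totals: Mapping[str, float],
) -> MotifModel:
    """Construct and validate a motif model.

    Raises
    ------
    ConfigurationError
        On unknown motif id, missing/extra/negative parameters, missing
        diffusivity or total entries.
    """
    if motif_id not in MOTIF_REGISTRY:
        raise ConfigurationError(
            f"unknown motif {motif_id!r}; known: {sorted(MOTIF_REGISTRY)}"
        )
    spec = MOTIF_REGISTRY[motif_id]
    if motif_id == "cyclic":
        species = _cyclic_species(params)
        required = tuple(f"k_{i + 1}" for i in range(len(species)))
    else:
        species = spec.species
        required = spec.required_params

    missing = [k for k in required if k not in params]
    if missing:
        raise ConfigurationError(f"{motif_id}: missing parameter(s) {missing}")
    extra = [k for k in params if k not in required]
    if extra:
        raise ConfigurationError(f"{motif_id}: unknown parameter(s) {extra}")
    for k, v in params.items():
        if v < 0:
            raise ConfigurationError(f"{motif_id}: parameter {k} must be >= 0, got {v}")
        if k.startswith("K_M") and not v > 0:
            raise ConfigurationError(f"{motif_id}: Michaelis constant {k} must be > 0")

    missing_totals = [t for t in spec.required_totals if t not in totals]
    if missing_totals:
        raise ConfigurationError(f"{motif_id}: missing total(s) {missing_totals}")

    diff = dict(diffusivities)
    missing_d = [s for s in species if s not in diff]
    if missing_d:
        raise ConfigurationError(f"{motif_id}: missing diffusivity for {missing_d}")
    for s, d in diff.items():
        if s not in species:
            raise ConfigurationError(f"{motif_id}: diffusivity given for unknown species {s!r}")
        if d < 0:
            raise ConfigurationError(f"{motif_id}: diffusivity of {s} must be >= 0")

    return MotifModel(
        motif_id=motif_id,
        species=species,
        params={k: float(v) for k, v in params.items()},
        diffusivities={s: float(diff[s]) for s in species},
        totals={t: float(v) for t, v in totals.items()},
    )


def _check_state(model: MotifModel, state) -> np.ndarray:
    arr = np.asarray(state, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None] if arr.shape[0] == model.n_species else arr[None, :]
    if arr.ndim != 2 or arr.shape[0] != model.n_species:
        raise ShapeError(
            f"state of shape {np.shape(state)} does not match the "
            f"{model.n_species} species of {model.motif_id}"
        )
    return arr


def reaction_rhs(model: MotifModel, state, signal, clip: bool = True) -> np.ndarray:
    """Pointwise kinetic rates (no diffusion), shape (n_species, n_nodes).

    Negative concentrations from integrator overshoot are clipped at zero
    before evaluation (pass ``clip=False`` for smooth extension past zero, as
    needed by finite-difference Jacobians at boundary fixed points).
    """
    arr = _check_state(model, state)
    S = np.asarray(signal, dtype=float)
    if S.ndim == 0:
        S = np.full(arr.shape[1], float(S))
    if S.shape[0] != arr.shape[1]:
        raise ShapeError(
            f"signal with {S.shape[0]} nodes does not match state with "
            f"{arr.shape[1]} nodes"
        )
    if clip:
        arr = _clip_state(arr)
    return model.spec.rhs(model.params, model.totals, arr, S)


def full_rhs(model: MotifModel, state, signal, domain: SpatialDomain) -> np.ndarray:
    """Reaction rates plus D_j * periodic Laplacian per species."""
    arr = _check_state(model, state)
    if arr.shape[1] != domain.n_points:
        raise ShapeError("state does not match the domain grid")
    rates = reaction_rhs(model, arr, signal)
    for j, name in enumerate(model.species):
        D = model.diffusivities[name]
        if D > 0:
            rates[j] += D * periodic_laplacian(arr[j], domain)
    return rates


def conserved_pools(model: MotifModel) -> Dict[str, Tuple[int, ...]]:
    """Pools conserved among dynamic species (cyclic chain, explicit pairs)."""
    if model.motif_id == "cyclic":
        return {"X": tuple(range(model.n_species))}
    return dict(model.spec.dynamic_pools)
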