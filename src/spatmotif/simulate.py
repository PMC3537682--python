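"""Method-of-lines time integration of motif models on the periodic grid.

The PDEs are discretized with the 3-point periodic Laplacian and integrated
with a stiff BDF multistep method (scipy's BDF). Steady state is declared when the sup-norm of
the full right-hand side falls below ``steady_tol``; converged steady states
are optionally re-solved at doubled grid resolution and the relative change
recorded as a convergence audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .domain import SpatialDomain, periodic_interp
from .errors import NonConvergenceError, ShapeError
from .motifs import MotifModel, conserved_pools, full_rhs, reaction_rhs

__all__ = [
    "SolverSettings",
    "SimulationResult",
    "integrate",
    "find_steady_state",
    "homogeneous_steady",
    "run_scenario",
]


@dataclass(frozen=True)
class SolverSettings:
    """Integrator and convergence settings.

    rel_tol/abs_tol bound the integrator error well below steady_tol so that
    steady-state declaration is limited by the residual threshold, not by
    integration error. For oscillatory regimes set ``detect_steady=False`` and
    the run goes to t_max, discarding ``transient_fraction`` of the trajectory
    before any diagnostics.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    t_max: float = 2000.0
    steady_tol: float = 1e-8
    sample_times: Optional[np.ndarray] = None
    stiff: bool = True
    detect_steady: bool = True
    transient_fraction: float = 0.5
    grid_check: bool = False

    def __post_init__(self):
        if not (self.rel_tol > 0 and self.abs_tol > 0 and self.steady_tol > 0):
            raise ValueError("tolerances must be positive")


@dataclass
class SimulationResult:
    """Trajectory and/or converged steady state per species on the grid."""

    model: MotifModel
    domain: SpatialDomain
    signal: np.ndarray
    times: np.ndarray
    trajectory: np.ndarray  # (n_times, n_species, n_nodes)
    state: np.ndarray  # final (n_species, n_nodes)
    converged: bool
    residual: float
    conservation_drift: Dict[str, float] = field(default_factory=dict)
    grid_check: Optional[float] = None
    unresolved: bool = False

    def species_profile(self, name: str) -> np.ndarray:
        return self.state[self.model.species.index(name)]

    def species_series(self, name: str) -> np.ndarray:
        """Trajectory of one species, shape (n_times, n_nodes)."""
        return self.trajectory[:, self.model.species.index(name), :]


def _jac_sparsity(model: MotifModel, n_nodes: int):
    """Jacobian sparsity pattern: dense species blocks per node + per-species
    periodic tridiagonal diffusion stencils."""
    ns = model.n_species
    N = ns * n_nodes
    pat = lil_matrix((N, N), dtype=np.int8)
    # kinetic coupling: all species at the same node
    for i in range(n_nodes):
        for a in range(ns):
            for b in range(ns):
                pat[a * n_nodes + i, b * n_nodes + i] = 1
    # diffusion: neighbours of the same species
    D = model.diffusivity_array()
    idx = np.arange(n_nodes)
    for a in range(ns):
        if D[a] > 0:
            base = a * n_nodes
            pat[base + idx, base + (idx + 1) % n_nodes] = 1
            pat[base + idx, base + (idx - 1) % n_nodes] = 1
    return pat.tocsr()


def _residual(model, state, signal, domain) -> float:
    return float(np.max(np.abs(full_rhs(model, state, signal, domain))))


def _conservation_drift(model, initial, final) -> Dict[str, float]:
    drift = {}
    for pool, idx in conserved_pools(model).items():
        # node-sums are conserved for any diffusivities on a periodic grid
        # (the discrete Laplacian has exactly zero column sums)
        s0 = float(np.sum(initial[list(idx)]))
        s1 = float(np.sum(final[list(idx)]))
        drift[pool] = abs(s1 - s0) / max(abs(s0), 1e-300)
    return drift


def integrate(
    model: MotifModel,
    initial,
    signal,
    domain: SpatialDomain,
    settings: SolverSettings = SolverSettings(),
) -> SimulationResult:
    """Integrate a motif PDE system to t_max or to steady state.

    Terminates early (converged=True) when the sup-norm of the full RHS drops
    below ``settings.steady_tol``; otherwise runs to t_max (converged=False
    unless the final residual happens to satisfy the threshold).
    """
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (model.n_species, domain.n_points):
        raise ShapeError(
            f"initial state shape {y0.shape} does not match "
            f"({model.n_species}, {domain.n_points})"
        )
    if np.any(y0 < -1e-9):
        raise ShapeError("initial state must be non-negative")
    S = domain.check_field(signal)
    shape = y0.shape

    def rhs_flat(t, y):
        return full_rhs(model, y.reshape(shape), S, domain).ravel()

    if settings.sample_times is not None:
        t_eval = np.asarray(settings.sample_times, dtype=float)
    else:
        t_eval = np.linspace(0.0, settings.t_max, 201)

    method = "BDF" if settings.stiff else "RK45"
    kwargs = {}
    if settings.stiff:
        kwargs["jac_sparsity"] = _jac_sparsity(model, domain.n_points)

    # steady detection by chunked integration: the run is split at a geometric
    # sequence of checkpoints and stops at the first checkpoint where the
    # sup-norm residual is below threshold (robust, unlike root-finding on the
    # non-smooth sup-norm; the convergence *time* is only needed coarsely)
    if settings.detect_steady:
        checkpoints = [settings.t_max]
        t_c = settings.t_max / 2.0
        while t_c > max(1e-3 * settings.t_max, 1.0):
            checkpoints.append(t_c)
            t_c /= 4.0
        checkpoints = sorted(checkpoints)
    else:
        checkpoints = [settings.t_max]

    if settings.detect_steady and _residual(model, y0, S, domain) <= settings.steady_tol:
        return SimulationResult(
            model=model, domain=domain, signal=S,
            times=np.array([0.0]), trajectory=y0[None],
            state=y0.copy(), converged=True,
            residual=_residual(model, y0, S, domain),
            conservation_drift=_conservation_drift(model, y0, y0),
        )

    times_acc = [np.array([0.0])]
    traj_acc = [y0[None]]
    y_now = y0.ravel().copy()
    t_now = 0.0
    converged = False
    for t_next in checkpoints:
        seg_eval = t_eval[(t_eval > t_now) & (t_eval <= t_next)]
        sol = solve_ivp(
            rhs_flat, (t_now, t_next), y_now,
            method=method, rtol=settings.rel_tol, atol=settings.abs_tol,
            t_eval=np.unique(np.append(seg_eval, t_next)), **kwargs,
        )
        if sol.status == -1:
            last = sol.y[:, -1].reshape(shape) if sol.y.size else y_now.reshape(shape)
            raise NonConvergenceError(
                f"integrator step failure: {sol.message}", last_state=last,
                t=sol.t[-1] if sol.t.size else t_now,
            )
        if sol.t.size:
            keep = np.isin(sol.t, seg_eval)
            times_acc.append(sol.t[keep])
            traj_acc.append(sol.y[:, keep].T.reshape(-1, *shape))
            y_now = sol.y[:, -1].copy()
            t_now = float(sol.t[-1])
        if settings.detect_steady:
            if _residual(model, y_now.reshape(shape), S, domain) <= settings.steady_tol:
                converged = True
                break

    final = y_now.reshape(shape)
    residual = _residual(model, final, S, domain)
    if residual <= settings.steady_tol:
        converged = True

    times = np.concatenate(times_acc)
    traj = np.concatenate(traj_acc, axis=0)
    return SimulationResult(
        model=model, domain=domain, signal=S,
        times=times, trajectory=traj, state=final,
        converged=converged, residual=residual,
        conservation_drift=_conservation_drift(model, y0, final),
    )


def _refine_state(state, domain: SpatialDomain, fine: SpatialDomain) -> np.ndarray:
    return np.stack(
        [periodic_interp(fine.theta, domain.theta, row, domain.length) for row in state]
    )


def find_steady_state(
    model: MotifModel,
    signal,
    domain: SpatialDomain,
    settings: SolverSettings = SolverSettings(grid_check=True),
    initial=None,
) -> SimulationResult:
    """Integrate to steady state and audit the result by grid doubling.

    If no initial state is supplied the run starts from the homogeneous
    kinetic steady state at the spatial minimum of the signal (which places
    bistable runs on the lower branch).
    """
    S = domain.check_field(signal)
    if initial is None:
        x0 = homogeneous_steady(model, float(np.min(S)))
        initial = np.repeat(x0[:, None], domain.n_points, axis=1)
    result = integrate(model, initial, S, domain, settings)

    if settings.grid_check and result.converged:
        fine = domain.doubled()
        fine_signal = periodic_interp(fine.theta, domain.theta, S, domain.length)
        fine_init = _refine_state(result.state, domain, fine)
        fine_res = integrate(model, fine_init, fine_signal, fine, replace(settings, grid_check=False))
        coarse_on_fine = fine_res.state[:, ::2]
        scale = max(float(np.max(np.abs(result.state))), 1e-300)
        result.grid_check = float(np.max(np.abs(coarse_on_fine - result.state))) / scale
        result.unresolved = result.grid_check > 0.005
    return result


def homogeneous_steady(
    model: MotifModel,
    S: float,
    initial: Optional[np.ndarray] = None,
    t_max: float = 1e6,
    steady_tol: float = 1e-11,
) -> np.ndarray:
    """Kinetic (well-mixed) steady state at a uniform signal level.

    Integrates the homogeneous ODE system with the stiff solver until the
    sup-norm of the rates falls below ``steady_tol``. The default initial
    condition is a small positive state (1e-6 of each conserved total),
    which relaxes onto the attracting branch reachable from near-zero.
    """
    if initial is None:
        initial = _default_homogeneous_initial(model)
    y0 = np.asarray(initial, dtype=float).reshape(model.n_species)

    def rhs(t, y):
        return reaction_rhs(model, y[:, None], np.array([S]))[:, 0]

    def residual(y):
        return float(np.max(np.abs(rhs(0.0, y))))

    if residual(y0) <= steady_tol:
        return y0.copy()
    t_now, y_now = 0.0, y0
    t_next = 10.0
    while t_now < t_max:
        t_next = min(t_next, t_max)
        sol = solve_ivp(rhs, (t_now, t_next), y_now, method="BDF",
                        rtol=1e-10, atol=1e-12)
        if sol.status == -1:
            raise NonConvergenceError(f"homogeneous steady state failed: {sol.message}")
        y_now = sol.y[:, -1]
        t_now = float(sol.t[-1])
        if residual(y_now) <= steady_tol:
            return y_now
        t_next = t_now * 8.0
    return y_now


def _default_homogeneous_initial(model: MotifModel) -> np.ndarray:
    x0 = np.zeros(model.n_species)
    spec = model.spec
    # start explicit conserved pools entirely in the inactive member
    for pool, idx in spec.dynamic_pools.items():
        x0[idx[-1]] = model.totals[pool]
    if model.motif_id == "cyclic":
        x0[:] = 0.0
        x0[0] = model.totals["X"]
    if model.motif_id == "bistable_mutual_inhibition":
        # inhibitor fully active: relaxes onto the lower (low-X*) branch
        x0[1] = model.totals["Y"]
    x0 += 1e-6
    return x0


def run_scenario(scenario_id: str):
    """End-to-end deterministic run of a registered figure-level scenario.

    Returns (SimulationResult, DiagnosticsReport). Imported lazily to keep the
    scenario registry and diagnostics optional for library users.
    """
    from .scenarios import execute_scenario

    return execute_scenario(scenario_id)
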