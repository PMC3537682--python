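"""Steady-state scan of the well-mixed kinetics over the signal level S.

A natural-parameter scan with deterministic multistart root finding stands in
for full numerical continuation: the kinetic systems here are at most
4-dimensional after conservation elimination, so exhaustive seeding plus
deduplication reliably enumerates all fixed points. Stability comes from the
Jacobian spectrum (finite differences), with conservation zero modes projected
out; fold, Hopf and transcritical points are located by bisection between scan
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import root

from .errors import KineticsError
from .motifs import MotifModel, conserved_pools, reaction_rhs

__all__ = [
    "FixedPoint",
    "SpecialPoint",
    "BifurcationBranch",
    "scan_branches",
    "locate_special_points",
    "oscillation_window",
]

_STAB_EPS = 1e-9
_DEDUP_TOL = 1e-8


@dataclass
class FixedPoint:
    S: float
    state: np.ndarray
    eigenvalues: np.ndarray  # reduced spectrum (conservation modes removed)
    stable: bool
    marginal: bool = False


@dataclass
class SpecialPoint:
    type: str  # fold | hopf | transcritical
    S_located: float
    state: np.ndarray


@dataclass
class BifurcationBranch:
    """Scan result: all fixed points per signal level, plus refined events."""

    model: MotifModel
    S_values: np.ndarray
    points: List[List[FixedPoint]]  # per S, deduplicated fixed points
    special_points: List[SpecialPoint] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        return np.array([len(pts) for pts in self.points])

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(p.stable for p in pts) for pts in self.points])


# ---------------------------------------------------------------------------
# homogeneous kinetics helpers
# ---------------------------------------------------------------------------


def _kinetic_rhs(model: MotifModel, x: np.ndarray, S: float) -> np.ndarray:
    # unclipped: smooth extension past zero so Jacobians and root solves are
    # well-behaved at boundary fixed points (unphysical roots filtered later)
    return reaction_rhs(model, x[:, None], np.array([S]), clip=False)[:, 0]


def _pool_constraints(model: MotifModel) -> List[Tuple[Tuple[int, ...], float]]:
    return [
        (idx, model.totals[pool]) for pool, idx in conserved_pools(model).items()
    ]


def _constrained_system(model: MotifModel):
    """Replace one rate equation per conserved pool with the pool constraint
    (the replaced equations are linearly dependent on the rest)."""
    constraints = _pool_constraints(model)

    def fun(x, S):
        r = _kinetic_rhs(model, x, S)
        for j, (idx, total) in enumerate(constraints):
            r[idx[-1 - (j % len(idx))]] = np.sum(x[list(idx)]) - total
        return r

    return fun


def _state_bounds(model: MotifModel, S_max: float) -> np.ndarray:
    """Upper bound per species for seeding and plausibility filtering."""
    p, t = model.params, model.totals
    ub = np.empty(model.n_species)
    spec = model.spec
    bounded = {}
    for i, total_name in spec.eliminated_pairs:
        bounded[i] = t[total_name]
    for pool, idx in conserved_pools(model).items():
        for i in idx:
            bounded[i] = t[pool]
    for i in range(model.n_species):
        if i in bounded:
            ub[i] = bounded[i]
        elif model.motif_id in ("bistable_mutual_inhibition", "nf_oscillator"):
            # X* balances production k_0 + k_1 S against basal decay k_2
            ub[i] = 2.0 * (p["k_0"] + p["k_1"] * S_max) / max(p["k_2"], 1e-12)
        else:  # pragma: no cover - all current motifs covered above
            ub[i] = 1.0
    return ub


def _jacobian_fd(model: MotifModel, x: np.ndarray, S: float) -> np.ndarray:
    n = x.size
    J = np.empty((n, n))
    scale = max(float(np.max(np.abs(x))), 1.0)
    h = 1e-6 * scale
    for j in range(n):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (_kinetic_rhs(model, xp, S) - _kinetic_rhs(model, xm, S)) / (2 * h)
    return J


def _reduced_eigenvalues(model: MotifModel, x: np.ndarray, S: float) -> np.ndarray:
    """Jacobian spectrum with conservation zero modes deflated by projecting
    onto the tangent space of the conserved-pool constraints."""
    J = _jacobian_fd(model, x, S)
    constraints = _pool_constraints(model)
    if not constraints:
        return np.linalg.eigvals(J)
    n = x.size
    C = np.zeros((len(constraints), n))
    for j, (idx, _) in enumerate(constraints):
        C[j, list(idx)] = 1.0
    # orthonormal basis of the null space of C
    _, s, Vt = np.linalg.svd(C)
    rank = int(np.sum(s > 1e-12))
    B = Vt[rank:].T
    return np.linalg.eigvals(B.T @ J @ B)


def _classify(model, x, S) -> FixedPoint:
    eigs = _reduced_eigenvalues(model, x, S)
    max_re = float(np.max(eigs.real)) if eigs.size else -np.inf
    marginal = abs(max_re) <= _STAB_EPS
    return FixedPoint(S=S, state=x, eigenvalues=eigs,
                      stable=max_re < -_STAB_EPS, marginal=marginal)


def _find_fixed_points(
    model: MotifModel, S: float, seeds: np.ndarray, ub: np.ndarray
) -> List[np.ndarray]:
    fun = _constrained_system(model)
    found: List[np.ndarray] = []
    for x0 in seeds:
        sol = root(fun, x0, args=(S,), method="hybr", tol=1e-12)
        if not sol.success:
            continue
        x = sol.x
        if np.any(x < -1e-7) or np.any(x > ub * (1 + 1e-6) + 1e-7):
            continue
        if np.max(np.abs(fun(x, S))) > 1e-8:
            continue
        x = np.maximum(x, 0.0)
        if all(np.max(np.abs(x - y)) > _DEDUP_TOL * (1 + np.max(np.abs(y))) for y in found):
            found.append(x)
    return found


def _seed_lattice(ub: np.ndarray, n_seeds: int) -> np.ndarray:
    axes = [np.linspace(0.0, u, n_seeds) for u in ub]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


def scan_branches(
    model: MotifModel,
    S_range: Tuple[float, float],
    n_scan: int = 400,
    n_seeds: int = 3,
) -> BifurcationBranch:
    """Enumerate homogeneous fixed points on a grid of signal levels.

    Seeds are a deterministic lattice over [0, bound] per species, augmented
    with the fixed points found at the previous scan level (continuity
    seeding). No randomness anywhere.
    """
    S_lo, S_hi = S_range
    if not (S_lo > 0 or S_lo == 0) or S_hi <= S_lo:
        raise KineticsError("S_range must satisfy 0 <= S_lo < S_hi")
    S_values = np.linspace(S_lo, S_hi, n_scan)
    ub = _state_bounds(model, S_hi)
    lattice = _seed_lattice(ub, n_seeds)

    points: List[List[FixedPoint]] = []
    prev: List[np.ndarray] = []
    for S in S_values:
        seeds = np.vstack([np.array(prev), lattice]) if prev else lattice
        roots = _find_fixed_points(model, float(S), seeds, ub)
        if not roots:
            raise KineticsError(f"no fixed point found at S = {S:.6g}")
        points.append([_classify(model, x, float(S)) for x in roots])
        prev = roots
    branch = BifurcationBranch(model=model, S_values=S_values, points=points)
    branch.special_points = locate_special_points(branch, n_seeds=n_seeds)
    return branch


# ---------------------------------------------------------------------------
# special-point refinement
# ---------------------------------------------------------------------------


def _count_at(model, S, seeds, ub) -> List[np.ndarray]:
    return _find_fixed_points(model, S, seeds, ub)


def _match(x, candidates):
    if not candidates:
        return None
    d = [np.max(np.abs(x - c)) for c in candidates]
    return candidates[int(np.argmin(d))]


def _bisect_event(f, lo, hi, tol, max_iter=200):
    flo = f(lo)
    for _ in range(max_iter):
        if hi - lo < tol:
            break
        mid = 0.5 * (lo + hi)
        if f(mid) == flo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def locate_special_points(
    branch: BifurcationBranch, n_seeds: int = 3
) -> List[SpecialPoint]:
    """Refine fold / Hopf / transcritical events between adjacent scan points.

    Folds are bisected on the fixed-point count; stability changes of a
    persisting root are bisected on the crossing eigenvalue and classified
    Hopf (complex pair) or transcritical (real crossing, root count
    unchanged).
    """
    model = branch.model
    S_values = branch.S_values
    tol = 1e-9 * (S_values[-1] - S_values[0])
    ub = _state_bounds(model, float(S_values[-1]))
    lattice = _seed_lattice(ub, n_seeds)
    specials: List[SpecialPoint] = []

    counts = branch.counts()
    for i in range(len(S_values) - 1):
        lo, hi = float(S_values[i]), float(S_values[i + 1])
        seeds_here = np.vstack([np.array([p.state for p in branch.points[i]]), lattice])

        # persisting roots whose stability flips across the interval
        flips = []
        if counts[i] == counts[i + 1]:
            # counts equal: nearest-neighbour matching tracks moving branches
            for p in branch.points[i]:
                q_state = _match(p.state, [q.state for q in branch.points[i + 1]])
                q = next(
                    q2 for q2 in branch.points[i + 1]
                    if np.array_equal(q2.state, q_state)
                )
                if p.stable != q.stable and not (p.marginal or q.marginal):
                    flips.append((p, q))
        else:
            # counts differ: only a root that barely moves counts as persisting
            # (a stability exchange there is a transcritical crossing, not a fold)
            for p in branch.points[i]:
                for q in branch.points[i + 1]:
                    scale = 1.0 + max(np.max(np.abs(p.state)), np.max(np.abs(q.state)))
                    if np.max(np.abs(p.state - q.state)) < 1e-3 * scale and (
                        p.stable != q.stable and not (p.marginal or q.marginal)
                    ):
                        flips.append((p, q))

        if counts[i] != counts[i + 1] and not flips:
            # branch count change without an exchange of stability: fold
            ref_count = counts[i]

            def count_match(S):
                return len(_count_at(model, S, seeds_here, ub)) == ref_count

            S_f = _bisect_event(count_match, lo, hi, tol)
            roots = _count_at(model, S_f, seeds_here, ub)
            specials.append(SpecialPoint("fold", S_f, roots[0] if roots else np.array([])))
            continue

        for p, q in flips:
            complex_pair = bool(
                np.any(np.abs(p.eigenvalues.imag) > 1e-9)
                and np.any(np.abs(q.eigenvalues.imag) > 1e-9)
            )

            def max_re_sign(S, ref=p.state):
                roots = _count_at(model, S, np.vstack([[ref], lattice]), ub)
                r = _match(ref, roots)
                eigs = _reduced_eigenvalues(model, r, S)
                return float(np.max(eigs.real)) > 0

            S_c = _bisect_event(max_re_sign, lo, hi, tol)
            kind = "hopf" if complex_pair else "transcritical"
            specials.append(SpecialPoint(kind, S_c, p.state.copy()))
    return specials


def oscillation_window(
    model: MotifModel, S_range: Tuple[float, float], n_scan: int = 400
) -> Optional[Tuple[float, float]]:
    """Signal window between the two Hopf bifurcations, or None if no pair."""
    branch = scan_branches(model, S_range, n_scan=n_scan)
    hopfs = sorted(sp.S_located for sp in branch.special_points if sp.type == "hopf")
    if len(hopfs) < 2:
        return None
    return (hopfs[0], hopfs[-1])
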