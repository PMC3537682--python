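# Methods

## Scope and model class

`spatmotif` studies how small, fixed-topology signalling motifs transduce a
*spatially varying* steady input on a closed 1-D domain (a circle of
circumference 2π, representing a membrane or a slice of cytosol). Each motif
is a reaction–diffusion system

    ∂u_j/∂t = f_j(u, S(θ)) + D_j ∂²u_j/∂θ²,   θ ∈ [0, 2π), periodic,

where `f_j` is mass-action or Michaelis–Menten kinetics, `S(θ)` a prescribed
signal profile, and `D_j` a per-species diffusivity. Eleven schemes are
registered: coherent and two incoherent feedforward loops, positive and
negative feedback loops, an irreversible cycle of n species, the zero-order
(Goldbeter–Koshland) switch, a Hill-cooperativity switch (the comparison
monostable switch), a mutual-inhibition bistable switch, a three-species
negative-feedback relaxation oscillator, and a transcritical (positive
feedback, signal-degraded) switch.

Where an active/inactive pair shares one diffusivity, the inactive form is
eliminated through the conserved total (X = X_tot − X*), reducing the state
to the active forms. The two monostable switches keep both forms as dynamic
fields so the inactive form can be given its own (much larger) diffusivity —
the case in which the switch amplitude becomes amplified beyond the local
total.

## Transport regimes

Rate constants are O(1) and the domain has length 2π, so the three regimes
are encoded as fixed diffusivity conventions:

| regime            | D     | behaviour                                         |
|-------------------|-------|---------------------------------------------------|
| non-diffusible    | 0     | purely local kinetics, node-decoupled             |
| weakly diffusible | 0.005 | fronts and phases couple, profiles barely smoothed|
| global            | 500   | uniform to ≲0.5%, level set by the spatial mean   |

"Global" means the species' Laplacian term dominates: a 1/D perturbation
expansion of the steady state gives, at leading order, a uniform level fixed
by a solvability (domain-average) condition. For a linear interconversion pair
with activation a(θ) and deactivation b(θ) this is X0 = total·⟨a⟩/(⟨a⟩+⟨b⟩).
The package implements only this leading order; the O(1/D) correction is
visible as the residual non-uniformity of PDE solutions at finite D, and the
oracle–simulator tests verify it shrinks ∝ 1/D between D = 50 and D = 500.

## Numerics

* **Spatial discretization.** Uniform periodic grid (default 200 nodes),
  3-point central-difference Laplacian. The stencil annihilates constants
  exactly and has exactly zero row sums, so diffusion conserves mass to
  machine precision. Grid means are plain node averages (exact for
  trigonometric modes below Nyquist).
* **Time integration.** Stiff BDF (scipy `solve_ivp`) with a sparsity pattern
  assembled from the kinetic block structure plus the periodic tridiagonal
  diffusion stencil; default tolerances rtol 1e-8 / atol 1e-10 keep the
  integration error well below the steady-state threshold.
* **Steady-state declaration.** The run is split at a geometric sequence of
  checkpoints and stops at the first one where the sup-norm of the full
  right-hand side drops below `steady_tol` (default 1e-8). Checking at
  checkpoints rather than by event root-finding is deliberate: the sup-norm
  residual is non-smooth in time, and only a coarse convergence time is
  needed. For oscillatory regimes detection is disabled and the run goes to
  `t_max`, discarding the first half of the trajectory before diagnostics.
* **Grid audit.** Converged steady states are re-solved at doubled resolution
  from the periodically interpolated state; a relative sup-norm change above
  0.5% flags the run "unresolved" (advisory, not fatal).
* **Positivity.** Concentrations are clipped at zero inside rate evaluation
  (integrator overshoot is at tolerance level); excursions beyond −1e-6 are
  logged as warnings. Finite-difference Jacobians and fixed-point solvers use
  the unclipped smooth extension so boundary fixed points (e.g. the zero
  branch of the transcritical switch) have correct spectra.
* **Determinism.** There is no randomness anywhere — multistart seeds are a
  deterministic lattice — so identical configurations produce bitwise
  identical CSV output.

## Bifurcation scanning

The well-mixed kinetics (≤ 4 state dimensions after elimination) are scanned
over the signal level S by natural-parameter stepping with multistart
root-finding (deterministic lattice seeds over [0, total] per species plus
continuity seeds from the previous level), deduplication, and stability
classification from the finite-difference Jacobian spectrum. Conservation
zero modes (cyclic chain, explicit pairs) are removed by projecting the
Jacobian onto the tangent space of the conservation constraints. Events are
refined by bisection: fold points on the fixed-point count, Hopf and
transcritical points on the sign of the leading eigenvalue of the persisting
root; a stability exchange of a root that persists across a count change is
classified transcritical rather than fold. This deliberately replaces
pseudo-arclength continuation: the systems are low-dimensional and
dissipative, and exhaustive multistart is robust, simple, and derivative-free.
Branch switching onto periodic orbits and codimension-2 analysis are out of
scope.

## Closed-form steady states

The analytic oracles mirror the reductions that make each motif transparent:

* **Feedforward loops**: composition of local pair fixed points, with ⟨S⟩
  substituted into whichever pathway is global.
* **Feedback loops, far from saturation** (basal forward rates zero, active
  fractions small): the response obeys R* = αS + βR* (positive) or
  R* = αS/(1+βR*) (negative), with lumped gain α and loop gain β. The global
  variants replace the feedback drive by its spatial average, giving
  R* = αS + αβ⟨S⟩/(1−β) and R* = αS/(1+βR0),
  R0 = (√(1+4αβ⟨S⟩)−1)/(2β). The positive-feedback form is valid only for
  β clearly below 1. The full (saturating) algebraic systems are also solved
  by damped fixed-point iteration as the general path; the reduction error
  grows monotonically with the active fractions, which the fixture regimes
  keep below 10% (in practice ≈2%, giving agreement within 5%).
* **Cycle**: equal-flux solution k_i X_i = F with the conservation total;
  with species 1 global, the others inherit the signal's shape; with any
  later species global, every species except species 1 is uniform and X_1 ∝
  1/S — a single global element homogenizes both its upstream and downstream
  neighbours.
* **Zero-order switch with global inactive form**: the plateau follows from
  global conservation, X0 = (X_tot − X̄)·2π/(θ2−θ1), exceeding X_tot once the
  switched-on interval is a strict sub-interval; the Hill-switch analogue has
  the exact averaged solution R* = R_tot·k_f f(S)/(k_f⟨f⟩ + k_r).
* **Bistable switch with global Y**: the spatially averaged pair (⟨X*⟩, Y*)
  satisfies the same algebraic system as the well-mixed module at ⟨S⟩; roots
  are enumerated by a 1000-bracket sign-change scan + bisection (tolerance
  1e-12) and mapped to profiles X*(θ) = (k0+k1S)/(k2+k21 Y*) — smooth,
  monotone in S, no spatial switching.
* **Transcritical switch**: stable-branch selection
  X* = max(0, X_tot − k_sx S k_-y/(k_1 Y_tot k_2)) locally; with global Y the
  averaged self-consistency equation admits a positive profile iff
  ⟨X_tot·A/(k_sx S)⟩ > 1 (A = Y_tot k_1 k_2/k_-y), else the uniform zero
  state.

## Diagnostics

The source behaviours are qualitative, so each is operationalized as an
explicit, threshold-exposed classifier: mean-removed circular correlation for
co/counter/flat alignment (|ρ| threshold 0.5, flatness 1% contrast/mean);
exact 1-D two-means clustering for two-plateau spatial switches — the cluster
gap is trimmed (10th percentile of the upper cluster minus 90th of the lower)
so that the one or two mid-level nodes a steep front leaves behind do not mask
the plateau separation, while a smooth profile's abutting clusters keep the
trimmed gap small (detection: gap > 0.5× range, plateaus ≥ 3 nodes); homogeneous step-doubling for the
adaptation index 1 − |R₂−R₁|/max(R₁,R₂); peak detection (minimum separation
5 samples, prominence 10% of amplitude) for per-node periods; synchrony
1 − (T_max−T_min)/T̄ over oscillating nodes; and quasiperiodicity as the
occupancy of a 50×50 binning of the adjacent-node phase portrait — a closed
curve (synchronized) occupies ≲15% of cells, incommensurate local frequencies
fill > 50%. Wave pinning is demonstrated, not measured: the scenario asserts
the front is stationary (state change < 1e-6 over the final 10% of the run).

## Fixture parameter choices

Printed parameter values are honored verbatim (feedback strengths
k_yx ∈ {0.5, 2.0} for positive and {10.0, 14.0} for negative feedback).
All other rate constants are package choices, selected once to realize the
regime each scenario needs and frozen; `calibrate_regimes()` re-verifies them:

* bistable window S ∈ [≈1.22, ≈4.03] (width ≈ 107% of midpoint; ≥ 20%
  required), realized with a zero-order inhibitor switch (K_M = 0.01);
* oscillator Hopf window S ∈ [≈0.345, ≈1.667], supercritical at both ends,
  period rising from ≈9.7 to ≈11.0 across the window;
* zero-order switch with K_M = 0.01 ≤ 0.02·X_tot, threshold at k_sx S = k_r U
  (S = 1);
* feedback fixtures with active fractions ≈ 2% (positive: ≲1%) at the fixture
  signals, inside the far-from-saturation regime of the reduced forms.

Two deliberate fixture subtleties:

* The type-1 incoherent feedforward figure fixture realizes "inhibitor
  stronger" through asymmetric saturation (linear inhibitor, saturating
  activator), because with both pathways exactly linear the response ratio is
  signal-independent and the gradient response would be flat. A separate
  fully linear variant demonstrates (near-perfect, index > 0.99) adaptation.
* With a global feedback element, a *strong* gradient quenches the oscillator
  outright (amplitude death) rather than synchronizing it; the synchronized
  scenario therefore uses a gentle gradient (b = 0.1) with the same in-window
  mean, and the quenched case is exercised separately via a below-window mean.

## Problem sizes

Steady-state scenarios run on 200 nodes (audited at 400). Oscillatory
trajectory scenarios run on 64 nodes for 4000 time units (≈ 200 oscillation
periods over the post-transient half, 8001 samples): the coarser grid gives
adjacent nodes a signal separation large enough that their incommensurate
local periods wind through the joint phase portrait within the horizon, which
is what the occupancy diagnostic measures. Bifurcation scans use 120–400
signal levels with lattice multistart (3 seeds per dimension).

## Degenerate inputs and edge cases

Signals must be non-negative (gradients require |b| ≤ a); cyclic closed forms
reject zero-signal nodes when a downstream species is global (X_1 ∝ 1/S
diverges); β → 0 feedback limits are handled by analytic branches, not
numerical cancellation; the square pulse is left-closed/right-open and snapped
to nodes, so grid doubling cannot move its edges. Near the transcritical
critical signal the spectral gap closes and relaxation onto the zero branch
becomes algebraic, so finite-horizon runs retain algebraic tails at nodes
within a few percent of S_c; assertions about the zero region therefore
exclude a ±5% band around S_c.

## Known limitations

Only periodic 1-D domains (the behaviours carry over to no-flux boundaries
and higher dimensions, but none of that is implemented); only the nine fixed
motif topologies plus the Hill-switch comparison — no user-defined networks;
no Turing-type self-organized patterning (all spatial structure is driven by
the input signal); no stochastic simulation; leading-order high-D theory only;
natural-parameter scanning cannot follow periodic-orbit branches. The
synthetic signal families are steady; time-varying inputs are untested
surface. What passing tests show is fidelity to the stated kinetic models
under the stated transport regimes — not quantitative agreement with any
particular biological system.
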