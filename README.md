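# spatmotif

Spatial signal transduction in cell-signalling motifs: a reaction–diffusion
simulator, analytic steady-state calculators, a bifurcation scanner, and
response classifiers for the canonical small signalling circuits — coherent
and incoherent feedforward loops, positive and negative feedback, irreversible
cycles, zero-order (Goldbeter–Koshland), Hill, bistable and transcritical
switches, and a negative-feedback oscillator — driven by a *spatially graded*
or *localized* signal on a periodic 1-D domain.

## Who this is for

Cells transduce signals that vary across the cell — membrane gradients,
localized cues — through the same network motifs that are usually analysed as
purely temporal circuits. A single highly diffusible ("global") component
changes the rules: it feels only the spatial average ⟨S⟩ of its drive and
couples every location to every other. `spatmotif` is for systems/quantitative
biologists who want to explore, with a few lines of code, how each motif's
temporal signal-processing repertoire (adaptation, switching, bistability,
oscillation) translates — or fails to translate — into spatial responses, and
to verify the simulations against the closed-form limits.

## The model

Each motif is a system of reaction–diffusion equations on the circle
θ ∈ [0, 2π):

    ∂u_j/∂t = f_j(u, S(θ)) + D_j ∂²u_j/∂θ²    (periodic boundary conditions)

with mass-action / Michaelis–Menten kinetics `f_j` and per-species
diffusivities. In the high-diffusion limit a species becomes uniform at the
level set by the spatially averaged kinetics (the leading order of a 1/D
expansion); e.g. for a reversible pair activated at rate k_sx·S + k_x and
deactivated at k_-x:

    X* → X_tot (k_sx⟨S⟩ + k_x) / (k_sx⟨S⟩ + k_x + k_-x).

These averaged closed forms exist for every motif here and ship as callable
oracles (`spatmotif.oracles`), so every simulated steady state can be checked
against an independent prediction. See `docs/methods.md` for the full model
and numerics account.

## Worked example: global negative feedback sharpens a gradient response

Local negative feedback damps a response, so one might expect it to flatten
spatial contrast too. With the feedback element Y made global the opposite
happens — the inhibition is set by the domain average while the activation
stays local:

```python
import numpy as np
from spatmotif import (build_domain, make_signal, SignalProfile,
                       find_steady_state, SolverSettings)
from spatmotif.scenarios import negative_fb_model
from spatmotif.oracles import reduced_feedback_params, negative_fb_steady

domain = build_domain(200)
signal = make_signal(SignalProfile(form="cosine_gradient", a=1.0, b=0.5), domain)

for tag, diff in (("local", "none"), ("global Y", "Y")):
    model = negative_fb_model(14.0, diff)          # printed feedback strength
    res = find_steady_state(model, signal, domain,
                            SolverSettings(t_max=5000.0, grid_check=True))
    r = res.species_profile("R*")
    pred = negative_fb_steady(reduced_feedback_params(model), signal, diff, domain)
    print(f"{tag:9s} contrast={np.ptp(r):.5f}  "
          f"closed-form err={100*np.max(np.abs(r-pred))/np.max(pred):.2f}%  "
          f"grid_check={res.grid_check:.2e}")
```

prints

```
local     contrast=0.01327  closed-form err=3.18%  grid_check=2.36e-07
global Y  contrast=0.01534  closed-form err=4.08%  grid_check=1.06e-06
```

The spatial contrast (max − min of R*) rises from 0.0133 to 0.0153 when Y is
global — the gradient response is *accentuated*, not smoothed. Both profiles
agree with the far-from-saturation closed forms
R* = (√(1+4αβS)−1)/(2β) (local) and R* = αS/(1+βR₀) with
R₀ evaluated at ⟨S⟩ (global) to within ~4% (α = 0.02, β = 14 here; the
residual discrepancy is the documented saturation correction), and the
steady states change by ≲1e-6 under grid doubling.

## Command line

```sh
spatmotif scenarios list                      # figure-level fixture scenarios
spatmotif scenarios export --id fig8_gk_nondiff_gradient --out run.cfg
spatmotif simulate --config run.cfg --out out/      # profiles.csv, meta.json
spatmotif bifurcate --motif bistable_mutual_inhibition --config run.cfg \
          --s-min 0.2 --s-max 6 --out scan/         # branches + fold/Hopf points
spatmotif verify --scenario fig7_cyclic_X3_diffusible --tol 0.02
spatmotif diagnose --scenario fig11_osc_nondiff --out report.json
```

All outputs are plain CSV/JSON and bitwise reproducible (the package contains
no randomness).

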