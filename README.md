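# micellex

Single-chain mean-field (SCMF) simulation of triblock-copolymer micelle
self-assembly and chain-exchange kinetics, together with the three-parameter
modified Eyring model and universal master-curve scaling used to analyse
exchange relaxation functions from simulation or from TR-SANS-style
experiments.

The package is aimed at people studying amphiphile self-assembly and micelle
kinetics — with coarse-grained simulation, with scattering or fluorescence
exchange experiments, or both. It models the L44 poloxamer
(EO10‑PO23‑EO10) in implicit water at 37 °C with tunable chain stiffness
(rigid Kuhn segments of adjustable length), and it treats exchange
relaxation curves F(t) from any source with one kinetic model.

## The model in brief

**Equilibrium.** One explicit self-avoiding chain interacts with the mean
concentration fields of all other chains and the solvent, discretised on
concentric spherical shells around the micelle. Minimising the free-energy
functional

F = N⟨U_intra⟩ + ∑_{xy} (ε_xy/z)∫⟨Φ_x⟩c_y + N∑_α P[α] ln P[α] + ∫c_s(ln φ_s − 1)

under incompressibility yields chain weights P[α] ∝ e^{−H[α]} and the shell
fields self-consistently. Scanning the number of chains N gives the
standard chemical-potential difference per chain, Δμ(N) = (μ_N⁰ − μ₁⁰)/k_BT;
its interior minimum marks the preferred aggregation number N* and sets the
critical micelle concentration, CMC = 55.5 mol/L · e^{min Δμ}.

**Dynamics.** Chains evolve by Metropolis Monte Carlo (sub-chain pivots and
rigid translations) in shell fields re-solved every cycle. Tagging the
in-micelle chains at t = 0 and counting the tagged ones still inside gives
the exchange relaxation function F(t), the simulation analogue of the
TR-SANS relaxation function; free-chain diffusion plus Stokes–Einstein
converts Monte-Carlo cycles to seconds.

**Kinetics.** F(t) obeys the modified Eyring equation

dF/dt = −k₁e^{F/ε} − k₂ + (k₁+k₂)e^{−F/ε},  F(0) = 1,

with a fast initial regime, a logarithmic regime starting at
τ₁ = (ε/k₁)e^{−1/ε}, and exponential decay controlled by k₂. The ratio
γ = k₁/k₂ splits systems into type a (γ > 1, straight to terminal decay)
and type b (γ < 1, a universal second intermediate regime). Rescaling
t* = t·k₂/ε and y* = γ·e^{F/ε} collapses all type-b curves onto one master
curve with slope −1 in a log–log plot. The package provides the exact
closed-form solution, the asymptotic approximants, a robust fitter and the
classification/collapse tooling.

## Worked example

```python
import numpy as np
from micellex.eyring import EyringParams, eyring_solution, fit
from micellex.synthetic import synth_curve

# the published fit to the flexible-chain simulation data
p = EyringParams(eps=2.6e-2, k1=1.0e-8, k2=6.8e5)
d = p.derived()
print(f"gamma = {d.gamma:.2e}  (type b)   tau1 = {d.tau1:.2e} s")

t = np.array([1e-11, 1e-9, 1e-7])
print(np.round(eyring_solution(t, p), 3))

# round-trip: fit a noiseless synthetic curve back
res = fit(synth_curve(p, noise=0.0))
print(f"recovered eps = {res.params.eps:.4g}, k1 = {res.params.k1:.3g}, "
      f"k2 = {res.params.k2:.3g}, R^2 = {res.r2:.4f}")
```

prints

```
gamma = 1.47e-14  (type b)   tau1 = 5.14e-11 s
[0.995 0.921 0.762]
recovered eps = 0.026, k1 = 1e-08, k2 = 6.8e+05, R^2 = 1.0000
```

i.e. the onset of the logarithmic regime sits at ~5×10⁻¹¹ s, F has decayed
by ~24 % four decades into that regime, and the fitter recovers the exact
parameters from a clean curve.

More complete narrative examples live in `examples/`:

* `kinetic_model_basics.py` — regimes and derived time scales,
* `fit_and_collapse.py` — fitting noisy curves and the master-curve overlay,
* `micellization_scan.py` — Δμ(N), N* and the CMC for the real L44 chain,
* `exchange_dynamics.py` — a tagged-chain exchange run with time calibration,
* `exit_pathway_profiles.py` — hairpin signatures along the exit path.

A thin command-line interface mirrors the library
(`micellex equilibrium|dynamics|profiles|fit|collapse|synth`); every
stochastic command requires a seed and persists its resolved configuration
next to the outputs.

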