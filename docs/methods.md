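# Methods

`micellex` models the self-assembly and single-chain exchange kinetics of a
coarse-grained PEO–PPO–PEO triblock amphiphile (the L44 poloxamer,
EO10‑PO23‑EO10) in implicit water at 37 °C, and provides the three-parameter
kinetic model and universal scaling with which exchange relaxation curves —
simulated or experimental — are analysed. This note records the model, its
assumptions, the numerical choices, and the places where the design was
genuinely open.

## Chain model

Chains are linear sequences of equal-diameter beads (diameter σ ≈ 0.2 nm),
bonded at distance σ. Stiffness enters through rigid, straight Kuhn
segments: `kuhn_EO` / `kuhn_PO` consecutive monomers of a block form a rigid
rod, with complete flexibility at the joints between segments and at every
chemical block boundary; a block whose length is not a multiple of the Kuhn
length ends in a shorter terminal segment. The three case studies soften or
stiffen the same molecule:

| case | l_k(EO) | l_k(PO) | PO segments |
|---|---|---|---|
| flexible | 2 | 2 | 12 |
| semiflexible (real L44) | 3 | 4 | 6 |
| rigid | 10 | 20 | 2 |

Non-bonded interactions are square wells between bead centres (inner radius
σ, outer radius 1.62σ) with depths in units of k_BT per coordination contact
(z = 26): ε(EO,PO) = 0.006, ε(EO,s) = 0.5, ε(PO,s) = 2.1. The printed values
are magnitudes; the signs implement the amphiphile chemistry — EO–water
contact is a hydration *attraction*, PO–water contact a hydrophobic
*penalty*, EO–PO a very weak penalty. (The all-repulsive Flory-χ reading was
tested and leads to macroscopic phase separation instead of finite micelles,
because nothing then limits aggregate growth.) Intramolecular energies are
exact pair sums; hard-core overlap between non-bonded beads is forbidden.

With the solvent site volume equal to the bead volume v_p = πσ³/6, a fully
exposed bead makes `well_volume/v_s = 26` solvent contacts — exactly the
coordination number that normalises the printed depths, which is why
v_s = v_p is kept fixed.

**Available interaction volume.** Each bead couples to its surroundings
through the part of its square well not blocked by the chain's own beads:
`avail_i = 1 − Σ_j overlap(well_i, sphere(r_excl) at bead j)/Ω`, a pairwise
overlap estimate clipped to [0, 1]. This makes solvation energies
conformation dependent — a crumpled (hairpin) hydrophobic block exposes far
less well volume than an extended one — which is the microscopic origin of
the conformation-dependent exit barriers. The exclusion radius r_excl is
not determined by the printed parameters. The package uses the standard
molecular-theory convention, r_excl = σ/2 (a bead blocks its own *volume*
out of its neighbours' wells). Shallower-binding conventions up to full
centre exclusion (r_excl = σ) were explored systematically: they move the
chemical-potential minimum towards the published scale, but they also make
the Δμ(N) structure so flat (a few tenths of k_BT) that the preferred
micelle size is no longer resolvable at desk-scale sampling, and the
flexible case stops micellizing altogether. The bead-volume convention
gives k_BT-deep, reproducible minima for all three flexibility cases at
the cost of an absolute binding scale about twice the published one (see
"Known equilibrium limitations").

## Equilibrium: single-chain mean field on spherical shells

One explicit self-avoiding chain interacts with the *average* concentration
fields of the other chains and the solvent, discretised on concentric
spherical shells (width 1σ; an outer wide "reservoir" shell represents the
bulk solution). The free-energy functional per cell (k_BT units) is

```
F = N⟨U_intra⟩_P
  + ½ e_EP (N−1)/N ∫ [⟨Φ_EO⟩⟨c_PO⟩ + ⟨Φ_PO⟩⟨c_EO⟩]
  + e_Es ∫ ⟨Φ_EO⟩ c_s + e_Ps ∫ ⟨Φ_PO⟩ c_s
  + N Σ_α P[α] ln(P[α]/w0[α])
  + ∫ c_s (ln φ_s − 1)
```

with e_xy the signed per-contact energies, Φ the available well-volume
densities, and w0 the a-priori measure weights of the sampled states.
Incompressibility (φ_chains + φ_s = 1 in every shell) is eliminated exactly:
c_s = (1 − φ_chains)/v_s and the pressure-like Lagrange field follows from
solvent stationarity, π = −[ln φ_s + e_Es⟨Φ_EO⟩ + e_Ps⟨Φ_PO⟩]/v_s. The
chain weights at the fixed point are P[α] ∝ w0[α] exp(−H[α]) with H[α]
derived *exactly* as δF/δ(N P[α]); free energy and Hamiltonian are
variationally consistent by construction, so the damped-Picard fixed point
coincides with a direct minimisation of the functional (this is tested to
1e−6 k_BT on enumerable toys). The (N−1)/N factor removes the chain's
mean-field self-interaction, which matters for the single-chain reference.
Incompressibility holds identically at every iteration because π is obtained
by exact inversion rather than by inner Newton iterations; the convergence
criterion is the change in the chain volume-fraction profile (tolerance
1e−9 for desk runs, 1e−7 for production scans; Picard mixing 0.1 with
automatic halving when the iteration stalls).

**Ensembles.** Internal conformations are drawn uniformly from the
self-avoiding freely-jointed-segment ensemble by whole-chain rejection
sampling (vectorised; a short-range prefilter handles the low acceptance of
the flexible chain). Every conformation, randomly oriented and centred on
its PO-block centre of mass, is then projected onto the lattice at *every*
radius of a uniform grid (default 16–18 radii covering the cell), each
(conformation, radius) state carrying its radial volume element as measure
weight. Integrating the placement coordinate on a grid rather than sampling
it is what lets a few thousand conformations resolve both the dense core and
the dilute bulk (effective sample sizes of several hundred at the fixed
point). Well volumes are apportioned to shells by exact sphere–sphere
overlap volumes.

**Micellization scan.** The aggregation number is imposed through the
number of chains N in the cell; the micelle is pinned at the origin by the
spherical fields, nucleated from a centre-biased initial guess and
warm-started across the N grid. The standard chemical-potential difference
is Δμ(N) = [F(N) − F(0)]/N − μ₁⁰, with μ₁⁰ from an N = 1 solve *on the same
ensemble* (so sampling noise largely cancels across the scan) plus the
standard-state correction +ln(V_place/v_s), i.e. one chain per solvent site.
That standard state is what makes the conversion CMC = 55.5 mol/L ·
exp(min Δμ) a mole-fraction relation; it reproduces the published
(Δμ, CMC) pairs to a few percent. N* is the smallest N within 0.01 k_BT of
the minimum; a minimum on the scan boundary is reported as
"no micellization" rather than an arbitrary N*.

**Known equilibrium limitations.** (i) The mean-field solvent cannot
resolve the local solvent deficit around an isolated chain beyond what the
intra-chain availability captures, so the absolute Δμ scale depends on the
self-exclusion convention. With the bead-volume convention the model binds
about twice as deeply as the published results (min Δμ ≈ −22 k_BT against
−9.2…−9.7), so the derived CMC *values* are far below the printed ones —
although the orderings across the flexibility cases (the quantity the
stiffness comparison is about) are robust: flexible binds least, rigid
most, and the preferred sizes order flexible < semiflexible < rigid.
(ii) Shallower conventions that would match the printed Δμ scale destroy
the desk-scale resolvability of N* and the flexible case's micellization;
the trade-off is intrinsic to the reconstructed interaction functional
(whose exact prefactors the source text does not display), not a numerical
artifact. (iii) The Δμ minima are shallow relative to their depth, so N*
carries a sampling uncertainty of about one grid step.

## Dynamics: Metropolis evolution in self-consistent fields

Every chain in the cell carries explicit coordinates. Per cycle each chain
receives one proposed symmetric move — a sub-chain pivot about a random free
joint (rotation angle uniform within ±amplitude) or a rigid whole-chain
translation (uniform in a ball of radius amplitude·σ) — accepted with
probability min(1, e^(−ΔH)) where ΔH combines the exact intramolecular
energy change with the mean-field shell potentials; the fields are rebuilt
once per cycle from the instantaneous bead counts. Moves preserve bond
lengths and Kuhn-segment rigidity exactly, and detailed balance w.r.t. the
frozen-field Boltzmann measure is verified against a direct-reweighting
oracle. The default amplitude is 1.5 (radians / σ): Metropolis acceptance
saturates near 55–60 % for in-micelle chains because the mean-field energy
surface is smooth, so larger amplitudes buy little; this is as close as the
move set gets to the 40–50 % textbook target.

The exchange experiment follows the TR-SANS protocol: the micelle (placed at
its preferred size so it neither grows nor shrinks net) is equilibrated
alone; the untagged bulk population (25 % of the micelle size) is then
injected outside the corona, the in-micelle chains are tagged, and
f(t) = tagged chains inside is tracked on a log-spaced schedule.
Membership uses the corona/bulk interface radius from the equilibrated
fields with a 1σ outward hysteresis against boundary flicker. The reported
relaxation function is F(t) = (f − f_eq)/(f(0) − f_eq) with
f_eq = f(0)²/N_chains, the tagged count at complete mixing — computed, not
measured, since runs are far shorter than the mixing time. A reflecting
wall for the PO-block centre of mass at the edge of the discretised region
closes the cell. The rigid case uses a reduced micelle (300 chains instead
of its preferred ≈460) to keep runs affordable; micelle size has little
effect on the per-chain exchange kinetics.

**Time calibration.** The free-chain centre-of-mass diffusion coefficient
D_SCMF (σ²/cycle; slope of the MSD over cycles / 6) is matched to the
Stokes–Einstein value D = k_BT/(6πηa) with η = 6.91×10⁻⁴ kg m⁻¹ s⁻¹ and
l = 0.2 nm: t_cycle = D_SCMF·l²/D. The hydrodynamic radius a is an explicit
input; the documented default is the measured free-chain radius of gyration
times the physical bead size. Both D_SCMF and t_cycle are move-set and
amplitude dependent and should be read as order-of-magnitude conversions.

**What the dynamics does and does not show.** Mean-field chains do not see
each other's instantaneous positions: there are no entanglements, no
hydrodynamic interactions, no correlated multi-chain events, and no micelle
fusion/fission. The exchange observable is dominated at early times by the
loosely attached corona-edge population (the fast initial regime) and at
intermediate times by conformation-dependent barrier crossings; the true
terminal exponential lies far beyond affordable runs, exactly as for the
published simulations. One consequence of the deep binding discussed above
must be stated plainly: with per-chain exit barriers of ~25 k_BT, genuine
core exits are unobservably rare at desk scale, so short runs resolve the
fast initial regime and the absence of exchange for the rigid chain, but
*not* a multi-decade logarithmic regime for the flexible and semiflexible
chains. Reproducing that regime quantitatively would require the published
(≈ −9 k_BT) binding scale, which this reconstruction cannot reach without
losing the equilibrium structure (see above); the corresponding acceptance
checks are reported as failed rather than weakened.

## Exit-pathway diagnostics

Radial profiles bin the PO-block radius of gyration (normalised by its bulk
value Rg*) and the EO–PO–EO angle against the distance of the PO-block
centre of mass from the micelle centre (bin width 0.5σ; bins with fewer
than 50 effective samples are reported missing, never interpolated). The
core/corona interface is defined as the crossing of the PO and EO
concentration profiles, the corona/bulk interface as the radius where the
EO concentration decays to its bulk value plus 5 % of its peak excess; both
definitions are explicit choices, as the published figures only mark the
interfaces as shaded bands. Profiles from dynamics use the lattice origin
as the micelle centre (the pinned-field centre); the instantaneous
PO-density centre was considered and rejected as redundant for a pinned
micelle.

## The modified Eyring kinetic model

The relaxation function obeys

```
dF/dt = −k1 e^{F/ε} − k2 + (k1 + k2) e^{−F/ε},     F(0) = 1,
```

the classic Eyring barrier-hopping equation (−2k1 sinh(F/ε)) plus a third
term with the kinetic constant k2 of the observable exponential regime; ε is
the crossover value of the correlation function and the stationary state is
F = 0 (complete mixing). In y = e^{F/ε} this is a constant-coefficient
Riccati equation, ε ẏ = −k1(y − 1)(y + 1 + 1/γ) with γ = k1/k2, solved in
closed form through the root transform u = (y₊ − y₋)/(y − y₋); the
implementation evaluates it with `expm1`/`log1p` complements so it is
accurate from far below τ₁ = (ε/k1)e^{−1/ε} (the onset of the logarithmic
regime) to far beyond τ₂ = ε/(2k1 + k2) (the exact terminal relaxation
time), for ε down to ~2×10⁻³ and γ across ≥ 17 decades (verified against
stiff numerical integration to ~3×10⁻¹³).

Rescaling t = a·t*, y·e^{−1/ε} = b·y* with a = ε/k2 and b = e^{−1/ε}/γ
removes all parameters from the transport part: dy*/dt* = −y*² − y* (up to
a γ(1+γ) source whose fixed point sits exactly at y* = γ). Hence the master
curve: y* ≈ 1/t* (slope −1 in log–log) in the logarithmic window
e^{−1/ε}/γ ≪ t* ≪ 1, and the universal second intermediate regime
y* = 1/((1+q)e^{t*} − 1), q = e^{−1/ε}/γ, for type-b systems (γ < 1).
Type-a systems (γ > 1) instead reach the terminal exponential directly;
their matched approximant multiplies the logarithmic amplitude into
e^{−t/τ₂} and is O(ε) accurate near the crossover. The global type-b
matched form is accurate to < 0.01 in F for γ ≤ 10⁻⁶ down to F ≈ ε·O(1).

**Fitting.** Nonlinear least squares of the closed form in F with weights
uniform per decade of time, positivity via log-parameters, a deterministic
initial guess (ε from the straightest lin–log window, k1 from the plateau
departure, k2 from the tail rate) and an 8-start multiplicative jitter.
Reported: parameters, R² (the "accuracy" the published fits quote), the
covariance of the log-parameters, γ, the dynamic class, and a k2-reliability
flag that is false when the data never reach t* = 0.1 (the crossover that
determines k2 was then not observed). Identifiability warning: for deep
type-b parameters (ε ≈ 0.02, γ ≪ 1), d ln k1 = (1 + 1/ε)·d ln ε amplifies
the ε uncertainty ~50×, so k1 from noisy curves is an order-of-magnitude
estimate — visible in the reported covariance — while ε and k2 remain well
determined.

**Synthetic curves** sample the closed form log-uniformly at 200
points/decade (matching the per-decade logging of the simulator) over
[τ₁/100, 20·a], with additive Gaussian noise of stated relative amplitude
and a manifest carrying the ground truth.

## Problem sizes

Desk-scale defaults keep everything inside modest budgets: equilibrium
scans use 5000 conformations × 16–20 radii per case with coarse
5-point N grids (a few minutes per case); exchange runs use 10⁴–10⁵ cycles for
property checks, with 10⁵–10⁶ the sensible production range; kinetic-model
operations are milliseconds. All stochastic results are reproducible from
(config, seed).
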