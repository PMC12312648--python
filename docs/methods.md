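# Methods

## Model formalism

`genebond` compiles biochemical networks written as species plus
flux-generating elements into ODEs that are thermodynamically consistent by
construction.

**Species (C / Se components).** A species carries a thermodynamic constant
K (per molecule) and an amount x (molecules); its dimensionless chemical
potential is μ̄ = ln(K·x) in units of k_B·T (amounts in molecules, time in
minutes; k_B·T never appears explicitly). Three kinds are supported:
`dynamic` (accumulates flux), `chemostat_amount` (fixed amount — an external
supply), and `chemostat_potential` (the potential itself is clamped; used
e.g. to approximate instantaneous removal of a product by clamping its
potential very low).

**Reactions (Re components).** Mass-action fluxes follow the
Marcelin–de Donder form v = r(e^{μ̄f} − e^{μ̄r}), with μ̄f, μ̄r the
stoichiometry-weighted potential sums of the two sides. Expanding the
exponentials shows this is ordinary mass action with forward/reverse
constants k_f = r·∏K^{s_f}, k_r = r·∏K^{s_r} (`to_mass_action` returns
them), but the (K, r) parameterization cannot express a
detailed-balance-violating rate set: at any state where μ̄f = μ̄r for every
reaction, all fluxes vanish regardless of the r values (Wegscheider
consistency). The per-reaction dissipation (μ̄f − μ̄r)·v is non-negative at
every state and is exposed by `power_dissipation`; the test suite asserts it
along single-gene, toggle-switch and repressilator trajectories.

**Junctions and transformers.** Common-potential (0), common-flow (1) and
stoichiometric-transformer elements are compile-time constructs: their
balance relations reduce exactly to the forward/reverse stoichiometric
matrices Sf, Sr and the mass balance ẋ = (Sr − Sf)·v, so no graph structure
is kept at run time. Conserved moieties are the integer-scaled left null
space of the net matrix with chemostatted rows removed (computed over the
rationals via sympy; basis vectors oriented so the first nonzero entry is
positive).

**Zero amounts.** The potential at x = 0 is −∞. Fluxes are therefore
evaluated in activity form (activities a = K·x, with clamped species
contributing e^{μ̄}), and a zero reactant annihilates its one-way term
exactly; amounts are floored at zero so solver undershoot cannot produce
negative activities. How zero amounts should be treated is not forced by
the formalism; this guard is our choice and keeps the rate field defined on
the closed positive orthant.

## Transcription component

Transcription converts the generic energy species A into mRNA M as an
enzyme-catalysed reaction with non-competitive inhibition, under a
quasi-steady-state rate law

v = r̄ (e^{μ̄A} − e^{μ̄M}) / [(1 + e^{μ̄A}/R_bA + e^{μ̄M}/R_bM)(1 + e^{h·μ̄I}/R_bI)]

with rate parameter r̄ and affinity parameters R_bA, R_bM, R_bI. The Hill
modulus h (default 2) enters as a transformer on the inhibitor potential
only — the inhibitor port carries no net flux (modulation only; repressor
sequestration by promoter binding is not modelled). The flux saturates at
r̄·R_bA for large μ̄A, vanishes when μ̄A = μ̄M, and its denominator is
strictly positive, so its dissipation (μ̄A − μ̄M)·v is non-negative.
Promoter *activation* kinetics are not implemented.

## Translation and the lumped elongation law

The explicit translation scheme is

- binding: M + R ⇌ C₀ (k_b, k_u) — further ribosomes can initiate once the
  mRNA is released,
- first elongation step: C₀ + A ⇌ C₁ + M (k_f1, k_r1), releasing the mRNA,
- chain: Cᵢ + A ⇌ Cᵢ₊₁ for i = 1..n−1 (per-step k_f, k_r),
- termination: C_n ⇌ R + P (k_t, k_z),

where n is the ATP cost of the protein (four per amino acid;
`n_from_protein_length`). Ribosomes are assumed not to obstruct each other
and all steps are sequence-independent. The ribosome moiety R + ΣCᵢ is
conserved.

**Reduction.** Treating the interior complexes as fast relative to the
boundary complexes, the chain between C_first and C_last supports the
steady-state flux

v_el = k_r (C_first·Â^m − C_last)(1 − Â)/(1 − Â^m),  Â = (k_f/k_r)·A,

with m the number of lumped steps. This is *exact* for the isolated chain:
telescoping the per-step steady-state relations gives
v·Σ_{k<m} a^k b^{m−1−k} = a^m C_first − b^m C_last with a = k_f·A, b = k_r,
which is the same expression. The test suite uses that linear solve as an
independent oracle (randomized over k_f, k_r ∈ [0.1, 10], Â ∈ [0.25, 4],
m ≤ 50; agreement to 1e−9 relative). The reduced scheme keeps C₀ and C_n as
explicit states, replaces C₁..C_{n−1} by one lumped complex Cx (or several),
and drives Cx → C_n with v_el; the state dimension is independent of n.
Initial conditions for lumps are the sums of their member complexes
(`lump_initial_conditions`), which preserves complex mass exactly; per-step
k_f, k_r are used unscaled inside the lump law. With k lumps the m steps are
partitioned as evenly as possible (earlier lumps take the remainder) and
chained through k elongation components.

**Numerics of the law.** Â^m overflows for the biologically default
m ≈ 10³, so the law is evaluated as
k_r(C_first − C_last·Â^{−m})(Â − 1)/(1 − Â^{−m}) for Â > 1 and in the direct
form for Â < 1, letting the vanishing power underflow harmlessly; within
|Â − 1| < 1e−6 the geometric sum is computed as expm1(m·log1p(Â−1))/(Â−1),
which is uniformly accurate through the removable singularity
(limit k_r(C_first − C_last)/m). A potential-based three-port wrapper
(`elongation_rate_from_potentials`) converts potentials back to amounts and
calls the kinetic form, so both interfaces are numerically identical; a
directly parameterized potential-form law is deliberately not offered.

**Thermodynamic gauge.** Builders accept kinetic constants and derive the
bond-graph parameters: K_M, K_R are free gauge choices (1e−4 by default),
K_A = k_f/k_r makes all chain complexes share one constant, and detailed
balance then pins K of every complex and of the protein — the protein's
thermodynamic constant is a *consequence* of the synthesis route, not a free
parameter. With the default set this gives μ̄P ≈ −14 at typical protein
counts. The elongation component's dissipation sign is guaranteed under this
gauge (the flux sign and the potential drop agree when K_A = k_f/k_r and the
boundary complexes share K).

## Gene modules and circuits

A gene module = transcription + reduced translation + first-order
degradation of M and P. Degradation is energy-free and modelled as a
mass-action flow into a potential-clamped sink; the bond-graph rate
parameter is r_deg/K_species so the forward flux is exactly r_deg·x. The
sink clamp defaults to −40 k_B·T, making the reverse leak < 1e−9 of the
forward flux at typical protein potentials (≈ −14).

Modules expose A, R and the inhibitor port and merge by species name
(`compose`): shared species must agree on K and kind, appear once, and
collect flux from every module. A is a fixed-amount chemostat by default —
the resource sweeps treat energy as an independent axis, and whether the
energy pool is replenished dynamically or clamped is an assumption we make
explicit (both flavours are available). R is a finite conserved pool, so
ribosome competition between genes — and hence retroactivity — emerges from
composition rather than being added by hand.

Under excess energy the single-gene steady state has the closed form

x_M = r̄·R_bA / (r_deg,M (1 + e^{h·μ̄I}/R_bI)),  x_P = k_b·x_R·x_M / r_deg,P,

used as an independent cross-check of simulated steady states (agreement to
1% under the default regime, where ribosome binding is effectively
irreversible and few ribosomes are sequestered).

Circuits: the toggle switch wires two genes so each protein is the other's
inhibitor port; the repressilator wires three in a ring (1 ⊣ 2 ⊣ 3 ⊣ 1).
Exactly symmetric circuits started from exactly symmetric states stay
symmetric forever (and therefore never oscillate), so the default initial
conditions are asymmetric: toggle runs start from (P₁, P₂) = (10000, 0) or
(0, 10000); the repressilator seeds gene 1's protein at 4000 with the others
at zero.

## Simulation and metrics

`integrate` wraps scipy's `solve_ivp` (LSODA by default — the models are
stiff, with per-step elongation rates of ~5·10³/min against protein
half-lives of minutes) at rtol 1e−9 / atol 1e−12. Moiety drift along test
trajectories is ≤ 1e−6 relative, and halving the tolerances moves the
reported circuit metrics by < 0.1%.

`find_steady_state` integrates over doubling horizons and accepts a state
when the scale-free residual max |ẋᵢ|/(|xᵢ| + atol) < 1e−9 (compatible with
zero-amount species), optionally polishing with a Newton solve restricted to
the moiety-consistent manifold so conserved totals are preserved exactly.
The polish only *refines*: corrections that move any species by more than 1%
are rejected, because from a limit-cycle trajectory the root finder would
happily land on the unstable symmetric fixed point inside the cycle.
Non-contracting trajectories raise a no-steady-state error and callers use
the limit-cycle path instead.

Circuit metrics:

- **switching time** — normalized distance
  d = √(((P₁−P₁*)/P₁*)² + ((P₂−P₂*)/P₂*)²); the switching time is the first
  time d < 0.01 *and remains below to the end of the trajectory* (arrival,
  not first touch); never-arriving trajectories return an infinite sentinel;
- **bistability index** — steady-state P₁ from the "gene-1-high" initial
  condition over steady-state P₁ from the "gene-2-high" one (1 when
  monostable);
- **amplitude / period** — peaks located with scipy's `find_peaks`; the
  transient is discarded until consecutive peak heights differ by < 0.1%
  (our choice of convergence rule), at least four converged peaks are
  required, amplitude is max − min over the converged cycles (a convention;
  fold-change comparisons are insensitive to it) and period is the mean
  peak-to-peak interval.

## Default parameters (placeholders, calibrated once)

Published parameter sets for this class of model are not bundled; the
defaults in `params.py` are documented placeholders pinned to single-cell
*E. coli* scales and then frozen:

| quantity | default | rationale |
| --- | --- | --- |
| energy-rich ATP pool A | 5.8e6 molecules | energy-rich cell |
| free ribosomes R | 5000 | typical free-ribosome count |
| induced steady state | 41 mRNA, ~10⁴ protein | typical single-gene copy numbers; fixes r̄ and k_b |
| mRNA half-life | 2.5 min | bacterial mRNA scale; sets r_deg,M |
| protein half-life | 4 min | median of the heterogeneity screens; sets r_deg,P |
| per-step elongation | k_f·A = 4800 ATP/min at rich A | 20 aa/s × 4 ATP per residue |
| k_r (per-step reverse) | 40 /min | places the energy half-saturation of translation near 10⁵ molecules (≈ 0.2 mM) |
| protein cost n | 1200 ATP | 300-residue protein |
| termination k_t, k_z | 10³ /min, 10⁻⁹ | fast, effectively irreversible |
| binding k_u | 1 /min | binding effectively irreversible once elongation starts |
| repression half-point | 300 protein copies | keeps the repressilator oscillating from R = 1000 to beyond 5000 (see below) |
| Hill h | 2 | standard cooperativity for these circuits |

With these values the repressilator's period is ≈ 63 min and its amplitude
falls ≈ 7-fold when the ribosome pool drops from 5000 to 1000; the toggle
switch is strongly bistable with a switching-time minimum at intermediate
ribosome numbers (≈ 2000–3000). A weaker repression (half-point ≳ 3000
copies) would put the default circuit near its Hopf boundary — oscillation
dies there — so the chosen value trades a larger absolute amplitude
(≈ 6900 molecules) for robustness of the oscillating regime across the
resource and heterogeneity screens.

## Heterogeneity screens

Cell-to-cell variability is emulated by redrawing one parameter per
simulated cell: energy (left-truncated normal in molecule units — inverse
CDF sampling, exact and rejection-free; ATP concentrations convert to
molecules at 1 µm³ cell volume via Avogadro's number), ribosome count
(lognormal around a median of 5000; a coefficient of variation c maps to
log-sd √ln(1+c²)), or protein half-life (lognormal around 4 min whose
central 95% interval spans half to twice the median, i.e. log-sd
ln 2 / 1.959964, applied identically to every gene — a perfectly correlated
global fluctuation). Samples that do not oscillate are excluded and counted;
results are bitwise reproducible under a fixed seed. The generator emulates
*independent* cells only: no growth, division, volume change, extrinsic
noise within a cell, or intercellular coupling — so passing screens say
nothing about population-level synchronization, only about parametric
sensitivity of the single-cell circuit.

## Known limitations

- **Transient fidelity of the reduction.** The lumped law removes the
  pipeline-fill delay of the explicit chain (~n per-step times), so the
  time for the *translation rate itself* to reach 90% of steady state can
  differ by more than the steady-state error: the full/reduced t90 ratio
  grows roughly linearly in n (≈ 1.7 at n = 10, ≈ 10 at n = 100 under the
  defaults) even though both remain below ~2 s. Because protein dynamics
  evolve on minutes, circuit-level trajectories still agree to < 2%
  (sup-norm, post-transient); more lumps shrink the transient deviation
  monotonically.
- **Amplitude scale.** The absolute repressilator amplitude depends strongly
  on the repression affinity, which is a placeholder here; fold-changes
  across conditions are the robust readout.
- **Scope.** No stochastic (SSA) simulation, no ribosome collisions or
  codon-specific rates, no promoter activation, no energetic cost of
  degradation, no cell populations or signalling, no bifurcation/continuation
  analysis.
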