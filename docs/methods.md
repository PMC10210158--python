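# Methods

## Model

`allokin` simulates how an allosteric modulator — a ligand binding anywhere
but the substrate site — changes the partial-reaction rates and the
steady-state substrate-uptake velocity of a solute carrier (SLC).

Three layers compose the model:

**1. Eyring equation.** Every unidirectional rate constant corresponds to an
activation free energy,

    k = kappa * (k_B T / h) * exp(-dG_act / RT),

with the transmission coefficient kappa = 1 by default (retained as a field
for generality). `thermo.barrier_to_rate` / `rate_to_barrier` are exact
inverses of each other.

**2. Ground-state stabilization and the LFER.** A ligand at concentration
[M] with dissociation constant K_D lowers a ground state's free energy by the
binding polynomial

    ddG = -RT * ln(1 + [M]/K_D),

never by the saturating approximation -RT·ln([M]/K_D); at millimolar
concentrations against micromolar K_Ds the two agree to the rounding shown in
our outputs, but the polynomial stays correct at low occupancy. The linear
free energy relationship places the transition-state shift between the two
ground-state shifts,

    ddG_ts = alpha * ddG_P + (1 - alpha) * ddG_R,      0 <= alpha <= 1,

where alpha is the Bronsted-type position of the transition state on the
reaction coordinate (0 = reactant-like, 1 = product-like). Substituting into
the Eyring equation gives the modulated rate constants

    k_fw' = k_fw * exp(-(ddG_ts - ddG_R)/RT),
    k_bw' = k_bw * exp(-(ddG_ts - ddG_P)/RT).

Two structural consequences follow and are enforced as invariants: the
equilibrium shift k_fw'/k_bw' depends only on ddG_P - ddG_R (alpha merely
splits it between the two directions, so every alpha respects detailed
balance), and only the K_D *ratio* matters — a 10/1 nM modulator at 1 uM acts
exactly like a 10/1 uM modulator at 1 mM. Alphas outside [0, 1] are computed
and flagged (`lfer_compliant = False`) rather than rejected: they violate the
LFER bracketing assumption but not thermodynamics. Inverting the LFER,

    alpha = (ddG_ts - ddG_R) / (ddG_P - ddG_R),

is how `extract_alpha` recovers alpha from observed rate changes; the
denominator follows from the defining equation (it is the difference of the
ground-state shifts, undefined when they are equal, in which case we raise).

**3. The 8-state transport cycle.** The carrier cycles through
To → ToNaS → TiNaS → Ti → To (outward-facing empty, loaded, inward-facing
loaded, inward-facing empty), with a modulator-bound mirror loop
ToM → ToNaSM → TiNaSM → TiM and four binding edges connecting them. Default
rate constants (s^-1, concentrations in M):

| step | forward | backward |
|---|---|---|
| co-binding (out) | 1e16·[Na_out]·[S_out] | 1e12 |
| translocation | 1e6 | 1e6 |
| release (in) | 1e12 | 1e16·[Na_in]·[S_in] |
| empty return | 2 | 2 |
| modulator on | 1e6·[M] | K_D-dependent off |

The lumped co-binding constants absorb sequential Na+ and substrate binding;
multiplied by their molar concentration factors they act as first-order rates
in s^-1. The cycle is biased forward by [Na_out] = 0.15 M,
[S_out] = 1 mM, internal concentrations zero; the 2 s^-1 empty-carrier
return is then rate-limiting, so baseline turnover is ~2 substrate molecules
per transporter per second.

*Positive modulator:* K_D(To) = 1 uM (off-rate 1 s^-1), loaded states 10 uM
(off-rate 10 s^-1), K_D(Ti) = selectivity uM, so `selectivity` is the OF/IF
affinity contrast across the rate-limiting step. The rear return step runs at
2·selectivity·X forward, 2·X backward with X = selectivity^(alpha-1) — the
discrete realization of the LFER split at saturation. Detailed-balance
completion then fixes the remaining rear constants (the counter-clockwise
release ToNaSM → ToM at 1e13 s^-1 and the rear re-binding step scaled by
selectivity/10). The completion is not unique: this one was chosen because it
reproduces the EC50 right-shift with selectivity (the ligand must still
occupy the low-affinity IF state) and attains the full gain = selectivity at
saturation. Its one known departure from the alternative completions is that
the gain-versus-selectivity curve at alpha = 1 and sub-saturating [M] rises
to the plateau 1 + [M]/K_D(To) instead of peaking: at alpha = 1 the
acceleration (∝ selectivity) exactly compensates the IF-occupancy loss
(∝ 1/selectivity). The interior maximum (bell shape) appears for alpha < 1.

*Negative modulator:* K_D(ToNaS) = 1 uM, all other states selectivity uM;
the substrate translocation step (base 100 s^-1) is the modified reaction,
running at 100·selectivity^(-alpha) forward in the bound loop, and the 2 s^-1
return step is untouched. Because even a tenfold-slowed translocation
(10 s^-1) still outpaces the return step, inhibition of uptake is partial:
residual uptake at saturation shrinks with selectivity but never vanishes.

`check_detailed_balance` validates every constructed scheme on an undirected
cycle basis of the reaction graph with all concentration factors at a common
reference of 1 M (so only rate-constant consistency is tested, not the
kinetic bias); balance on a basis implies balance on all cycles.

## Numerical choices

- **Steady states** are computed with the GTH (Grassmann–Taksar–Heyman)
  state-reduction algorithm on the unique closed communicating class, not a
  generic linear solve: rate constants span ~13 orders of magnitude and GTH,
  which performs no subtractions, returns every occupancy with small
  *relative* error, so net edge fluxes (differences of nearly-cancelling
  ~1e12-scale terms) are reliable to the 1e-8 relative flux-continuity
  tolerance we assert. States outside the closed class receive exactly zero;
  multiple closed classes raise an error listing the components.
- **Uptake** is the net probability flux across the translocation cut
  (ToNaS → TiNaS plus ToNaSM → TiNaSM); by flux continuity any cut is
  equivalent, and the cut used is recorded on the result object.
- **Time integration** uses `scipy.integrate.solve_ivp` with LSODA,
  rtol 1e-8, atol 1e-12 and the analytic Jacobian (the generator itself);
  stiffness handling is mandatory at these rate contrasts.
- **Stochastic cross-check:** a Gillespie jump simulation (default seed
  20230505) estimates occupancies from dwell-time fractions. On the 8-state
  preset most jumps are picosecond bounces between fast states, so the
  oracle-vs-solver comparison is run on a moderate-rate 4-state cycle where
  2e5 events sample every state well; on the stiff preset only the
  rate-limiting state's dominance is checked.
- **EC50/IC50** are extracted by log-linear interpolation at the half-effect
  level of the curve normalized between baseline and plateau (inhibition
  curves are renormalized to [0, 1] between 1 and the residual plateau
  first). Non-monotone normalized curves yield NaN plus a warning record
  rather than a guess.
- **Composite reactions** (two barriers flanking a short-lived occluded
  intermediate) are reduced by the quasi-steady-state formula
  k_FW = a·c/(b+c), k_BW = d·b/(b+c); a dominant-eigenvalue reduction of the
  3-state generator is provided as an alternative (`method="eigen"`) and the
  two agree to <1% whenever the intermediate lifetime (default 10 us) is
  short against the composite rates — otherwise a warning is attached. The
  apparent alpha of the composite is obtained by pushing the observable
  rate change back through `extract_alpha`; detailed balance guarantees the
  forward- and backward-derived values coincide, which is asserted. The
  elementary rates behind a composite scenario are under-determined by its
  observables, so the preset exposes the intermediate branching ratio
  b/(b+c) as a configuration knob instead of hard-coding a value.
- **Scan grids** default to alpha in {0, 0.05, …, 1}, concentrations
  10^-8–1 M (31 log-spaced points), selectivities {10, 100, 1000, 10000}.
  Every scan point is a full deterministic steady-state solve (~0.1 ms), so
  whole figure-scale scans complete in well under a second.

## Defaults and units

| parameter | default | unit | rationale |
|---|---|---|---|
| temperature | 293.15 | K | reproduces the 5.6 kJ/mol magnitude of RT·ln 10 printed in our outputs; configurable |
| kappa | 1 | – | no barrier recrossing |
| [Na_out], [S_out] | 0.15, 1e-3 | M | physiological forward bias |
| [Na_in], [S_in] | 0 | M | fully forward-biased cycle |
| empty return | 2 | s^-1 | rate-limiting step of monoamine-transporter-like cycles |
| translocation (negative scenario) | 100 | s^-1 | fast, non-rate-limiting target step |
| saturating [M] | >= 100 × largest K_D | M | presets use 1 mM and 1 M |

All config keys carry units in their names (`conc_M`, `rate_per_s`,
`temperature_K`) and floats are serialized with full round-trip precision, so
a saved configuration reloads bit-identically and reruns byte-identically.

## What the presets emulate — and what they do not

The preset scenarios are idealized single-modulator cycles: one ligand
species, state-independent on-rates (affinity differences realized purely
through off-rates), no membrane potential or electrogenic steps, no
pre-steady-state currents, and no transporter heterogeneity. Passing tests
therefore demonstrate the internal consistency of the thermodynamic
machinery and the qualitative pharmacology it predicts (gain bounded by
selectivity, partial inhibition, EC50/IC50 shifts) — not quantitative
agreement with any measured transporter, whose rate constants, alphas and
K_Ds must be determined experimentally before the same machinery can be
applied.

## Known limitations

- The detailed-balance completion of the rear loop for selectivities other
  than 10 is a modelling choice (see above); alternative completions shift
  where the gain-versus-selectivity curve peaks at alpha = 1.
- The capped-cycle scans inherit the forced 10x rear co-binding asymmetry of
  the printed K_Ds, so once translocation is capped the alpha = 0 capped
  gain is ~0.67 rather than exactly 1; the gain(alpha=0) = 1 invariant holds
  for uncapped surfaces.
- alpha_app of a composite depends on the unobservable branching ratio of
  the intermediate; we report envelopes over that knob rather than a single
  number.
- No Arrhenius/temperature-dependence analysis: temperature enters only
  through RT and the attempt frequency.
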