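# Methods

## The model

`protcoop` models a well-mixed liquid coculture of two isogenic
*Bacillus subtilis* strains: a wild-type producer `W` that secretes the
full suite of extracellular proteases, and a non-producer `C` (the Δ8
mutant, lacking all eight protease genes).  Eight nondimensional state
variables evolve by ordinary differential equations: the vegetative
densities `W` and `C`, their spores `Ws` and `Cs`, an accessible
nutrient `A` (glutamic acid/glycerol analogue), a polymeric nutrient
`B` (BSA analogue), its degraded form `Bd`, and the shared extracellular
protease pool `E`:

    W'  = max(0, γ_A g(A) + γ_Bd g(Bd) − χ f(E)) W − s(A+Bd) W
    C'  = (γ_A g(A) + γ_Bd g(Bd)) C − s(A+Bd) C
    Ws' = s(A+Bd) W          Cs' = s(A+Bd) C
    B'  = −h(B,E)            Bd' = h(B,E) − g(Bd)(W+C)
    A'  = −g(A)(W+C)         E'  = f(E) W

with

    g(X)   = k1 X² / (k2² + X²)          (Hill uptake, coefficient 2)
    s(X)   = k3 (1 − X² / (k4² + X²))    (sporulation, decreasing Hill)
    f(E)   = k5 (1 − E/k6)               (self-limiting enzyme production)
    h(B,E) = k7 B E / (k8 + B)           (Michaelis–Menten degradation)

Assumptions worth making explicit:

* Both strains grow on `A` and on `Bd`, with yields `γ_A > γ_Bd > 0` —
  degraded polymer is the poorer substrate.  `B` itself is inedible.
* Only `W` produces enzyme, and only `W` pays the production cost
  `χ f(E)` per unit biomass; `χ` is the *absolute cost* per unit of
  protease produced.  The producer's net growth term (growth minus
  cost, before sporulation) is clamped at zero: there is no death
  phase in the model, so an uncovered cost stalls division rather than
  shrinking the population.  Sporulation sits outside the clamp and
  keeps draining `W` into `Ws` at low nutrient.
* Sporulation responds to the total growth-supporting nutrient
  `A + Bd` and is effectively an on/off switch (`k4` is small).
* Enzyme production is self-limiting (negative feedback through
  quorum-signal degradation), capping `E` at `k6`.
* `f(E)` is evaluated as written and may go negative if a caller
  supplies `E(0) > k6`; admissible initial conditions have `E(0) = 0`
  and the flow never leaves `[0, k6]`, so no clamp is applied there —
  silently clamping would mask configuration errors.

Default parameters (nondimensional): `γ_A = 4`, `γ_Bd = 1`, `χ = 1`,
`k1 = 3`, `k2 = 0.02`, `k3 = 0.4`, `k4 = 0.003`, `k5 = 0.03`,
`k6 = 0.2`, `k7 = 0.5`, `k8 = 0.45`.

## Derived statistics

* **Total yield**: `W + C + Ws + Cs` at `t_end`; normalized yields
  divide by the producer-monoculture stationary density in the GA
  medium (which therefore normalizes to 1).
* **Relative fitness** `RF_C`: the non-producer's final share divided
  by its initial share.  The default uses vegetative shares
  `C/(W+C)`, as the definition is displayed; `include_spores=True`
  gives the lineage-inclusive variant `(C+Cs)/(W+Ws+C+Cs)`, which is
  what a CFU count after heat treatment plus plating measures.  Both
  are computed and tested; the headline numbers use the vegetative
  reading.  When every cell has sporulated well before `t_end` the
  vegetative densities decay below the solver's absolute tolerance;
  both lineages then decay at the identical sporulation rate, so the
  share is frozen and is read at the latest numerically resolved time.
* **Relative cost** `C_rel = P_tot / G_tot`, with
  `P_tot = ∫_T χ f(E) dt`, `G_tot = ∫_T γ_A g(A) + γ_Bd g(Bd) dt`, and
  `T = {t ≤ t_end : χ f(E) < γ_A g(A) + γ_Bd g(Bd)}` the set where the
  producer actively divides.  The strict inequality makes
  `0 ≤ C_rel ≤ 1`.  `T` is located by scanning the margin's sign on a
  dense grid (4001 points by default) and refining each sign change by
  Brent bracketing to absolute time tolerance 1e-6; the integrals use
  adaptive quadrature on the solver's dense output (`epsabs = 1e-12`,
  `epsrel = 1e-9`).  An empty `T` returns `C_rel = 0`: no division
  happened, so no cost was paid during growth.  `C_rel` is computed on
  the coculture trajectory of each grid point (not on a re-run
  producer monoculture).

## Scenarios and calibration

Two media contexts are predefined, with all runs starting from
`Ws = Cs = Bd = E = 0`:

| medium   | A0    | B0 | represents                         |
|----------|-------|----|------------------------------------|
| GA_GLY   | 1.0   | 0  | glutamic acid + glycerol           |
| BSA_GLY  | 0.006 | 5  | BSA + glycerol (polymer nutrient)  |

The total vegetative inoculum defaults to `W0 + C0 = 0.01`, mirroring
the OD600-0.01 inoculum of the experimental protocol, and the horizon
is `t_end = 100` model-time units for all headline sweeps.

The initial nutrient abundances are a calibration, since only their
qualitative relations are prescribed (`B0 > 0` with `A0` small but
non-zero in the BSA context, capturing nutrient carryover between
media).  They were fixed, once, so that the model reproduces the
anchor behaviour of the system: the producer grows in both media with
a lower BSA-medium yield; the non-producer grows only on accessible
nutrient and sporulates (>90%) on polymer; and in the BSA-medium
coculture a 10% non-producer inoculum depresses total yield by roughly
a third while an even split depresses it about tenfold.  The essential
feature is that `B0` is large enough that enzymatic degradation — and
hence the producer share of the inoculum — remains rate-limiting over
the horizon; with a small `B0` the polymer is exhausted early and the
dilemma disappears.  All of these values are exposed in the scenario
configuration for recalibration.

The experimental mixing grid is expressed as initial non-producer
fractions {0, 0.05, 0.15, 0.25, 0.50, 0.75, 1.0}; sweep analyses over
mixed cultures use the interior subset.

## Numerics

The system is integrated with `scipy.integrate.solve_ivp` (LSODA,
automatic stiffness handling; `rtol = 1e-8`, `atol = 1e-10`) with
dense output retained for the interval location and quadrature above.
Terminal states are insensitive (relative change < 1e-4 in total
yield) to tightening both tolerances tenfold, and agree with an
independent fixed-step fourth-order Runge–Kutta integration at step
1e-3 to relative error < 1e-3 on short horizons.  Sub-tolerance
negative undershoots are clipped to zero only at output time, never
inside the right-hand side, preserving the solver's error control.
The sporulating tail decays exponentially below `atol`, where the
solver no longer resolves relative values; statistics that depend on
vegetative ratios handle this as described above.

## Synthetic observations

The `synth` module generates data with the structure of the study's
assays so the analysis layer can be tested end-to-end:

* **OD600 curves**: `od = scale · (W+C+Ws+Cs)(t) · exp(ε)`,
  `ε ~ N(0, cv²)` per reading (multiplicative lognormal noise —
  positive and heteroscedastic, like a plate reader).
* **Serial-dilution CFU**: plate counts are Poisson with mean
  density/dilution, at the smallest power-of-ten dilution placing the
  expectation in a countable 30–300 range (1 density unit ≡ 1e8
  CFU/mL by default).  Heat treatment is modelled as perfect — it
  kills every vegetative cell and spares every spore — because that is
  the operational definition of a spore count.  Per-strain counts
  split the total plate count binomially by the lineage share,
  emulating fluorescent colony identification.
* **Protease activity**: `gain · E(t) · exp(ε)`, normalized by an
  independently-noised OD, as in the fluorescence assay.

Model time maps to clock time linearly with `t = 100` ↔ 48 h (the
coculture endpoint); the mapping and all noise magnitudes are
configurable — the defaults (`cv = 0.1`) are plausible placeholders,
since the assays' real noise levels are not prescribed.  Replicates
draw from independent child seeds of one top-level seed, so a study is
fully reproducible.

What the generator does **not** emulate: germination dynamics, plate
saturation or counting error beyond Poisson, pipetting covariance
between the total and heat-treated series, day effects, or any death
phase.  Passing round-trip tests therefore shows the estimators are
consistent with the model's observables under idealized sampling — not
that the model fits any particular laboratory data set.

## Problem sizes used in tests

The property suite integrates 50 random admissible scenarios on a
t = 30 (or 20) horizon with 101–201 output points; Monte-Carlo checks
use 500 plates (spore fraction), 1000 OD draws (noise CV), and 6–10
replicate plates per ratio (proportion recovery).  The full ratio
sweep (two media × seven fractions, t_end = 100) solves in a few
seconds on one core.

## Known limitations

* No death phase, no germination, no spatial structure, no stochastic
  (birth–death) variant, and no quorum-sensing dynamics beyond the
  self-limiting `f(E)`.
* Parameters are not fitted to data; the model is a qualitative
  instrument, and its headline percentages depend on the calibrated
  initial nutrient abundances documented above.
* `RF_C`'s vegetative reading is numerically delicate deep in
  stationary phase (see above); the lineage-inclusive variant is the
  robust choice when comparing against plate counts.
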