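# Methods

## The model

`nox1sim` models the Nox1 activation cycle in vascular smooth muscle
cells as a mass-action reaction network over eight species: the active
complex (X1), the membrane pool Nox1/p22phox (X2), and the three
cytosolic subunits in inactive/active form — p47phox (X3) /
phosphorylated p47phox (X4), Rac1_GDP (X5) / Rac1_GTP (X6), NoxA1 (X7)
/ NoxA1_P (X8). Sixteen fluxes connect them:

* `f1 = γ1·X2·X4·X6·X7` — assembly of the active complex from the
  membrane unit and the three activated subunits;
* `f2, f3, f4` — the recycling (disassembly) routes, first-order in X1.
  Each dissociates the complex into Nox1/p22phox plus the three
  subunits, returning exactly one of them in its *inactive* form:
  f2 → NoxA1_P, f3 → free p47phox, f4 → Rac1_GDP. The remaining two
  subunits re-emerge in the activated forms they entered with — the
  unique assignment consistent with the steady-state balances;
* `f5/f6`, `f7/f8`, `f9/f10` — reversible subunit
  activation/deactivation, with the dimensionless signals S1 (PKC-type,
  p47phox phosphorylation), S2 (GEF-type, Rac1 loading) and S3
  (PKA-type, NoxA1 phosphorylation) multiplying the forward rates;
* `f11, f12, f13, f15` — constant influxes of X2, X3, X5, X7;
* `f14 = γ14·X1` — proteolysis of the whole complex;
* `f16 = γ16·X8` — degradation of NoxA1_P (14-3-3-bound removal).

Signals sit at 1 under control conditions; a stimulus steps the
relevant signal(s) to 10 (AngII ≙ S1&S2, PMA ≙ S1 — the generic
intensity used whenever no quantitative dose information exists).
One model time unit is read as one minute, so the 30-minute and 4-hour
experimental readouts are t = 30 and t = 240.

## Steady-state flux-balance parameterization

The unstimulated system is assumed to sit at a stable steady state (the
Ready-to-Respond State). Setting all derivatives to zero gives eight
linear identities among the fluxes; the implementation hard-codes the
eight-flux basis `f2, f3, f4, f6, f8, f14, f16` + one of `{f9, f10}`
and completes it by

```
f1 = f2+f3+f4+f14   f5 = f3+f6+f14   f7 = f4+f8+f14
f11 = f12 = f13 = f14   f15 = f14+f16   f9 + f2 = f10 + f16
```

The p47 balance can be written with f11 or f12 as the influx term; at
steady state both readings coincide because f11 = f12 = f14, and the
code follows the network wiring (f11 → X2, f12 → X3, f13 → X5,
f15 → X7).

The eighth basis member is chosen by the relative sizes of f2 and f16:
f9 is sampled when f2 ≥ f16 and f10 otherwise, so the derived partner
equals the sampled value plus a non-negative offset and every draw is
feasible — no rejection is needed in the generic sampler. Rate
constants follow as γ_i = f_i / (mass-action monomial at the sampled
state with unit signals), making the sampled state an *exact* steady
state (verified to ≤1e-9 relative derivative for every emitted
parameterization).

The nominal complex pools are X1 = 10, X2 = 100 (configurable); the
subunit pair totals are fixed at 100. These normalizations enter all
reported quantities only through the fold change X1_new/X1_control.
The choice rescales γ1..γ4 and γ14 exactly (tested); in the fully open
regime (f14 > 0) the fold change is exactly invariant to it, while in
the proteolysis-free regime the conserved subunit pools tie the
stimulated steady state to the initial totals and the fold change
shifts by roughly 10–15% per doubling of X1_nominal. All comparative
results are reported at the single fixed normalization above.

## Sampling

* **Initial subunit distributions.** The active-form amounts X4, X6,
  X8 are drawn from clamped truncated Gaussians: "inactive dominant"
  (bit 0) ~ N(25, 5) clamped to [5, 50]; "active dominant" (bit 1)
  ~ N(75, 5) clamped to [50, 95] (σ = 5, read from the N(μ, 5)
  notation; clamping is applied as written and produces point masses at
  the interval ends). The bit triple (p47_P, Rac1_GTP, NoxA1_P) indexes
  the eight combination codes in binary order (1 = 000 … 8 = 111).
* **Fluxes.** Independent fluxes are i.i.d. 10^U(a,b): U(0, 2) for the
  responsiveness profile, U(−2, 2) for the experimental screens.
  The responsiveness profile pins f14 = 0 — the regime in which the
  system responds; with f14 sampled like the other fluxes the mean
  stimulated steady state stays ≈1 across all codes and signals
  (reproduced in the tests).
* **Rates.** γ6, γ8, γ9 ~ U(0, 1) ("slow") or U(10, 100) ("fast") in
  the module comparisons.
* **Seeding.** One root seed per experiment; per-sample generators are
  `SeedSequence.spawn` substreams, so ensembles are bit-reproducible
  and independent of execution order. Runs embed config hash and seed
  in their outputs.

The generator emulates the study's stated sampling conditions, not real
measurements: concentrations are arbitrary units, there is no cell-to-
cell variability structure, no measurement noise, and signals are ideal
steps. Passing tests therefore establish internal consistency of the
design analysis, not agreement with any particular dataset.

## Steady states, fold change and response times

The steady state reached from a given state under given signals is
computed by stiff integration (LSODA with analytic Jacobian, rtol 1e-6
/ atol 1e-9) in doubling time chunks until
`max_i |dX_i/dt| / max(X_i, 1e-6) < 1e-8`, capped at t_max = 1e4 with a
non-convergence flag. After each chunk the endpoint is polished by
algebraic root-finding; when rate constants leave conserved moieties
(the four subunit totals in the closed system; three of them whenever
f14 = 0) the root problem is degenerate, so the conservation
constraints of the *active* reaction set — computed as the left null
space of the stoichiometry restricted to reactions with nonzero γ —
are appended and the stacked system solved by Levenberg–Marquardt.
A polished root is accepted only when it is an exact steady state *and*
lies within 0.2% of the integration endpoint: these polynomial systems
can carry multiple nearby positive steady states (observed ~3% apart in
sampled fully-open parameterizations), and the dynamically reached
state is the quantity of interest.

Responsiveness is the fold change X1_new/X1_control. Response times
use a 2% relative settling band (configurable): the on(off)-time is the
linearly interpolated last entry into the band around the new (control)
steady X1, requiring the trailing quarter of the simulated record to
stay inside the band. The band tolerance is a declared operational
choice — no tolerance is inherent in "numerically reaches a new steady
state" — and all comparisons are run at the single fixed value.

## Experimental screens

A sampled parameterization passes the AngII/PMA screens if

1. after 240 min of S1&S2: |Δ(X1+X2)|/(X1+X2) ≤ 0.05 (in the closed
   system X1+X2 is a first integral and this holds exactly);
2. after 30 min of S1&S2: X1 is quasi-steady
   (|dX1/dt|·30/X1 < 0.05) *and* up-regulated (≥1.1-fold);
3. after 30 min of S1 alone: X1 ≥ 1.1-fold.

The ±5% stability band, the 1.1-fold up-regulation threshold and the
quasi-steady bound are implementation-declared (the source observations
are semi-quantitative) and configurable; all reported results use the
defaults. Screening uses initial-condition code 1, the experimentally
observed resting profile (free p47phox, Rac1_GDP, NoxA1 dominant).
Absolute retained counts depend on the pre-filter ensemble size and the
declared thresholds and are not comparable across implementations; the
robust surfaces are the retained-region geometry and the
recycling-vs-proteolysis flux separation.

## Module-design comparison

The seven designs are the nonempty subsets of {f2, f3, f4}
(1 = {f2}, 2 = {f3}, 3 = {f4}, 4 = {f2,f3}, 5 = {f2,f4}, 6 = {f3,f4},
7 = all three; the designs referenced in grouped claims — {2,3,6}
lacking f2, {6,7} containing f3 and f4 — are invariant to the
within-group order). Every cell fixes f1 = 100, f14 = 0 (hence
f11 = f12 = f13 = 0), initial code 1, and draws γ6, γ8, γ9 from the
rates regime; f6, f8, f9 follow from the sampled state. Design cells
share identical per-sample substreams (state and γ draws precede the
design-dependent apportionment), so differences between designs are
attributable to structure alone.

Open questions resolved as package choices:

* **Apportionment of f1 among present pathways.** Unspecified; the
  default is a flat Dirichlet split (seeded) so multi-pathway modules
  explore their whole apportionment simplex; an equal split mode exists
  for deterministic tests. A fixed split would understate
  multi-pathway variability.
* **f16 in open scenarios.** f16 is drawn log10-uniformly on the
  feasible interval implied by the NoxA1 balance f9 + f2 = f10 + f16:
  (max(f2, 0.01), f2 + f9) in scenario 1 (f9 > f10 ⇔ f16 > f2) and
  (0.01, f2) in scenario 2. This is the truncation of a generic
  log-uniform flux magnitude to the region where the scenario is
  realizable — a fixed [0.01, 100] range plus rejection would deadlock
  for designs whose f2 apportionment reaches 100.
* **Scenario 2 without f2.** For designs 2, 3 and 6 the steady balance
  forces f9 = f10 + f16 > f10 whenever f16 > 0, so scenario 2 is
  structurally infeasible; those draws run at the f9 = f10 boundary
  with f16 → 1e-6 and are flagged (`boundary`) in the output tables.

## Problem sizes and numerical defaults

Default ensemble sizes are 2,000 samples per cell for the
responsiveness profile and module grids and 10,000 for the screening
ensemble — the sizes at which the reported summaries are stable to well
under their between-seed spread. The test suite asserts the ensemble
claims at those sizes except the responsiveness-ordering and
rate-compression checks, which use 150–200 samples per cell: the
compared group means there differ by many standard errors, so the
reduced size leaves the orderings unambiguous while keeping the suite
quick. Integrator tolerances (rtol 1e-6, atol 1e-9), the steady-state
derivative criterion (1e-8), the settling band (2%) and the screen
thresholds are all configurable keyword arguments; halving the solver
tolerances moves final states by <1e-4 relative (tested).

## Known limitations

* The stoichiometry is the unique matrix consistent with the described
  pathway wiring and the steady-state identities; no independently
  published matrix was available to diff against.
* With small nonzero f14 the system becomes nearly degenerate: a
  quasi-steady plateau persists for times ~1/f14 before the true
  steady state is reached, and "the steady state the system reaches
  numerically" depends on the convergence criterion. The analyses
  avoid the ambiguity by using either f14 = 0 exactly or fixed-time
  (30/240 min) readouts.
* Reported folds depend weakly on the arbitrary X1 nominal pool in the
  proteolysis-free regime (see above).
* No spatial or compartmental structure, no downstream ROS chemistry,
  and no mechanistic kinase/GEF models — signals are ideal multiplier
  steps.
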