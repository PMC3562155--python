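# Methods

## The phosphorelay model

The state variables are the phosphorylated fractions of PtsP, PtsO,
PtsN and FruB.  Each transfer step follows reversible mass action,
`r_i = k_i (X^P·Y − K_i·X·Y^P)`, over the donor/acceptor pairs
(PEP, PtsP), (PtsP, PtsO), (PtsO, PtsN), (PEP, FruB) and (FruB, PtsN);
fructose uptake removes phosphoryl groups from FruB at an externally
imposed rate `r_fru`.  The ODEs are

```
d(PtsP^P)/dt = (r1 − r2)/PtsP0        d(PtsO^P)/dt = (r2 − r3)/PtsO0
d(PtsN^P)/dt = (r3 + r5)/PtsN0        d(FruB^P)/dt = (r4 − r5 − r_fru)/FruB0
```

with conservation `X0 = X + X^P` per protein.  Assumptions: a
pseudo-steady state on the growth timescale, spatially well-mixed
pools, no transcriptional dynamics (FruB induction is a binary flag),
and no explicit fructose/F1P metabolites — `r_fru` is an input.

**PEP/pyruvate pool convention.** Only the ratio `pp = PEP/Pyr` enters
every equilibrium relation, so the metabolite pool is normalised to
`PEP + Pyr = 1` (`PEP = pp/(1+pp)`); velocity constants absorb the true
pool size.  A `scaled()` utility likewise folds the protein totals into
the velocity constants; all printed quantities depend only on the
equilibrium constants and `pp`.

**Knockouts** remove every reaction of the deleted protein (rates
identically zero) rather than zeroing the total inside the rate laws,
which avoids 0/0 in scaled form.  **Uninduced FruB** (growth on
casamino acids alone) keeps the C-branch reactions but scales the FruB
pool to a configurable 0.02 of the induced level; because equilibrium
ratios are pool-size-independent, this choice only matters away from
detailed balance.

**Thermodynamic cycle.** The five reactions form a closed cycle, so a
consistent parameter set has `K1·K2·K3 = K4·K5` (checked to 1e−9).
When the constraint is deliberately violated the steady state carries a
circulating futile flux; mass balance forces it to satisfy
`r1 = r2 = r3 = −r5 = −r4` (the phosphoryl group runs up the relay
chain and returns through the cross talk and the C branch).

## Steady-state solving

With `r_fru = 0` and a closed (or knockout-broken) cycle the steady
state is detailed balance and is written in closed form by propagating
phosphorylation potentials `φ = x/(1−x)` from PEP through the active
reaction graph (`φ` divides by each traversed `K_i`); species
unreachable from PEP equilibrate internally subject to conservation of
their initial phosphoryl content (zero by default).  For the intact
strain under uptake the 4-dimensional problem reduces to a scalar one:
given the relay-chain flux `J`, all four fractions follow sequentially,
and the remaining condition `r5(J) + J = 0` is strictly monotone in
`J`, so the unique root is found by bracketing and Brent's method.  The
interval of admissible `J` can be extremely narrow when the C-branch
velocity constant is small, so its edges are located by bisection
rather than grid resolution.  All remaining cases (futile cycles,
knockouts under flux) go through a Powell-hybrid root find on the free
species, with long-time ODE integration (LSODA to t = 1e6) as a
fallback; a state is accepted only when `max |d/dt| < 1e−10`.  Unit-box
invariance holds for the mass-action right-hand side; with a constant
uptake rate it holds as long as the uptake does not exceed the
transferable flux, in which case the solver raises a convergence error
rather than returning an unphysical state.

## Parameter estimation

The cycle constraint is enforced exactly by parameterising the relay
with `Keq = K1K2K3` and `K5` (so `K4 = Keq/K5`).  Individual chain
constants are not identifiable from detailed-balance data, so
`K1 = K2 = K3 = Keq^(1/3)` is a documented convention (the split can be
changed; the fit on equilibrium cells is invariant under it).  Free
parameters: `Keq`, `K5`, one `pp` per non-reference condition (the
casamino-acid reference is fixed at 1.0 by convention), all in log
space with broad bounds.

**Velocity scale.** The flux-carrying cells respond to the combination
`K5·r_fru/k4` only: the responses to `log K5` and `log k4` are
numerically collinear (condition number ~1e4), so a free `k4` leaves
`K5` undetermined along a ridge.  The uptake rate is therefore treated
as a known design quantity (it is measured), and `k4` is fixed at the
flux-calibrated velocity scale by default; both can be freed as bounded
nuisance parameters (`k4_free=True`, `r_fru_free=True`) at the
documented cost.

**Objective.** Weighted least squares on the log-odds of predicted vs
measured fractions, with weight `2·rel_error` per cell — the scale on
which band-ratio measurements are homoscedastic (see noise model
below); a linear-scale residual is selectable.  Cells with measured or
predicted values of exactly 0 or 1 fall back to linear residuals.  The
optimiser is trust-region least squares with one heuristic start
(inverting the detailed-balance cells) plus eight log-uniform
multistarts under a fixed seed; the best final cost wins, and a
running-minimum cost log provides a monotone diagnostic.  Approximate
standard errors come from the Gauss–Newton covariance at the optimum.

Identifiability is checked before fitting: the reference condition
needs an intact-chain cell (wild type or ΔfruB), the fructose ratio
needs a detailed-balance fructose cell, and `K5` needs a relay-knockout
fructose cell; missing cells are listed in the error.

## The shipped calibration

The equilibrium constants (`Keq = 0.02`, `K5 = 654.6`) and
condition ratios (`pp = 1.0 / 0.49 / 0.05`) are the estimated values
the analysis reproduces.  The velocity constants are not separately
identifiable, so the default set fixes the relay and cross-talk
velocities at 1 (scaled time) and calibrates the remaining two degrees
of freedom — `k4` and the fructose uptake rate — so that (i) the
regulatory branch provides 78% of the phosphoryl groups consumed by
fructose uptake and (ii) a relay-knockout strain under fructose shows
mid-range (0.5) PtsN phosphorylation, the qualitative signature of the
cross talk.  This is a calibration that pins the unidentifiable
velocity scale to the documented flux split, not an independent
estimate; the solved values are `k4 ≈ 143.2`, `r_fru ≈ 0.0689` and the
share is 0.78 by construction, invariant under joint rescaling of all
velocities and the uptake rate (a time-unit change).

## Synthetic data

The generator emulates the strain × condition measurement grid
(4 strains × 3 conditions) by solving the forward model per cell and
adding per-cell relative noise in the experimentally reported 5–30%
band.  Three noise models are provided:

* **band** (default): the blot measures a phosphorylated to
  unphosphorylated intensity ratio, so noise is lognormal on the odds,
  `sd(log odds) = 2·rel_error`, which gives a mid-range fraction (1/2)
  exactly the nominal relative sd and makes near-saturated fractions
  proportionally more precise — as intensity ratios are.  The sample
  median equals the true fraction at every saturation level.
* **beta**: moment-matched beta noise; the mean is preserved exactly
  within [0, 1] (used where a mean-faithful bounded model is wanted).
* **gaussian**: multiplicative Gaussian truncated to [0, 1]; simplest,
  but truncation shifts the mean of near-saturated fractions (~6% at
  fraction 0.9 with 30% error), which is why it is not the default.

What passing recovery tests show: that the estimation pipeline is
correct and approximately median-unbiased *under the stated noise
model and the model's own forward map*.  They do not validate the
mass-action mechanism against real blots, nor the assumption that
replicate errors are independent across cells, nor condition effects
the model excludes (e.g. growth-stage dependence of phosphorylation).

The flux-table generator jitters a reference node-flux summary while
preserving the min ≤ nominal ≤ max envelope.  The toy central-carbon
network (16 reactions) mirrors the catabolic map around the
PEP/pyruvate hub — fructose enters through a PEP-consuming uptake
reaction, casamino acids at oxaloacetate, glucose via a lumped
Entner–Doudoroff route; pyruvate kinase and PEP synthase interconvert
the hubs; ATP closes over a maintenance (NGAM) drain and biomass.  It
is deliberately desk-scale: genome-scale flux values are out of its
reach, but every *procedure* (uptake minimisation, NGAM calibration,
virtual carbon, FVA) runs on it exactly as it would at genome scale.

## FBA/FVA choices

LPs are solved with HiGHS; mass balances and bounds are verified to
1e−9.  The NGAM reaction is a fixed *lower* bound (maintenance must be
paid, surplus ATP may be burned); calibration bisects the NGAM value
until the minimised uptake matches the measurement to 1e−6 relative,
and is monotone in the target.  The virtual-carbon feed adds one
pseudo-metabolite and one reaction per amino acid with carbon-count
stoichiometry, so minimising the carbon exchange minimises total
casamino-acid uptake on a common scale.  FVA fixes the objective at its
optimum (equality within 1e−9; no partial-optimum fraction) and
characterises alternate optima per reaction; degenerate optima are
reported through their ranges, with no lexicographic tie-breaking.
Relative ranges are `100·(max−min)/nominal`, rounded half-up to one
decimal in exact decimal arithmetic (so 2.69 → 2.7 and the tie
1.25 → 1.3); a zero nominal flux is flagged rather than divided by.

## The PEP/pyruvate node

The node is reduced to five lumped fluxes: input `ra` (oxaloacetate →
pyruvate), drain `rb`, pyruvate → PEP flux `rc` (PEP synthase) and
PEP → 2PG flux `rd`.  The printed fluxes do not balance the pyruvate
node exactly (minor drains to alanine and other compounds), so `rb` is
defined by closure, `rb = ra − rc`, which preserves the steady-state
relations `rc = rd = (1−k)·ra` exactly; the printed
pyruvate → acetyl-CoA flux remains available as a labelled alternative
drain (`mode="acetyl-coa"`).  The interpolation slope is
`k = Δrb/Δra ≈ 0.344` between the two conditions.

Power-law kinetics `rc = kc·Pyr^nc`, `rd = kd·PEP^nd` with the
normalisation `kc = nc = 1` (the analysis compares the two enzymes, not
absolute values) are fitted exactly through the two calibration points
(`rc`, `pp`) = (4.00, 1.0) and (2.93, 0.49), using the pyruvate → PEP
flux as `rc`.  The closed form gives `nd ≈ 0.304` (ratio 0.30) and `kd ≈ 2.63`.  Note
that `kd` is sensitive to the rounding of the calibration fluxes (a
fit through unrounded fluxes can shift it by a few percent, e.g. to
~2.7), so the package logs the value derived from the inputs it was
actually given and asserts nothing sharper about it.  The ratio law `pp = α^(1/nd)·(rc/kc)^{n′}` is increasing
in the input flux exactly when `nc/nd > 1`; the characteristic curve is
reported with an envelope over a slope band whose edges are themselves
valid curves.

Control coefficients are computed from the partitioned stoichiometry as
`ε dc/du = −N_u⁻¹ N_kn β` after a structural-rank screen of the
elasticity pattern (maximum bipartite matching), so pattern-level
singularities are reported distinctly from numeric ones.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run entirely on desk-scale
problems: 12-cell measurement grids, 25 seeded datasets for the
recovery protocol (median-based, 5% noise), toy networks of ≤ 16
reactions, and brute-force oracles (vertex enumeration, exhaustive
matching, long-time ODE integration) on the same scale.  Steady states
are accepted at `max |d/dt| < 1e−10`; ODE oracles agree to 1e−6;
detailed-balance identities to 1e−8 or better; the cycle constraint to
1e−9.

## Known limitations

* The genome-scale metabolic reconstruction is not bundled; networks
  load from a reaction-list TSV, and genome-scale flux values are not
  reproduced — only the node summaries and procedures.
* Velocity constants are identifiable only up to the calibrated scale;
  all conclusions that depend on them (the 78% share, the mid-range
  knockout phosphorylation) are conditional on that calibration.
* Glucose growth is modelled with zero fructose uptake by default; a
  residual-uptake mode exists but no data here distinguishes the two.
* Measurement noise is independent across cells; shared blot-level
  systematics are not modelled.
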