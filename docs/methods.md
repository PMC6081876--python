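# Methods

This note documents the models, the numerical and design choices behind
`zebratk`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Steady-state models

Both models assume a constant, homogeneously mixed aqueous exposure and
mass-action (first-order) chemical degradation, so the body reaches a
steady state that is linear in the exposure concentration `C_exp`. The BCF
is therefore scale-free: `C_body = BCF · C_exp` for any exposure, and
exposure reconstruction is the exact inverse `C_exp = C_body / BCF`.

All chemical specificity enters through `log10 Kow`. The blood–water
partition ratio is the log-linear regression `log10 P_bw = 0.78 · log10 Kow
− 0.82`; tissue–water partitioning uses the standard lipid-fraction closure
`P_tw = L_t · Kow + W_t` referred to blood, `P_tb = P_tw / P_bw`. This is
the conventional closure for fish PBTK models of this family; no
temperature, pH, ionization or protein-binding corrections are applied.
Whether published lipid/water "contents" are mass or volume fractions is
rarely stated; they are treated as volume fractions at unit tissue density
(1 g ≡ 1000 µL), which is exact for the concentration ratios computed here
up to a common density factor.

### One-compartment model

`BCF = P_bw / (1 + (V_t k_m / (F_gill P_t)) P_bw)` with the whole body as a
single reactor. It is strictly decreasing in `k_m`, bounded above by
`P_bw` (attained at `k_m = 0`), and equals 1 exactly when `k_m` equals
`(F_gill P_t / V_t)(1 − 1/P_bw)` — a bound that is negative for
`log10 Kow < 0.82/0.78 ≈ 1.05`, where no metabolism value can produce
`BCF > 1`.

### Seven-compartment model

Compartments: arterial blood, venous blood, brain, gonads, richly perfused
tissue (rpt), poorly perfused tissue (ppt), liver. Structure:

* Gill uptake into arterial blood at `α F_gill C_exp`; gill efflux
  `α F_gill C_ven / P_bw` is taken from the venous return. This efflux
  closure is the one consistent with net gill flux vanishing exactly at
  blood–water equilibrium, which yields the `k_m → 0` limit
  `C_ven = P_bw C_exp` and `C_i = P_tb,i · C_art` for every tissue.
* Flow-limited tissue exchange `Q_i (C_art − C_i/P_i)` with
  `Q_i = f_i · f_car`; flow fractions must sum to exactly 1 (blood is
  conserved), and configs violating this are rejected, never silently
  renormalised.
* Gonads and rpt drain through the liver; brain, ppt and liver drain to
  venous blood. The liver holds the only sink, `k_m V_liv C_liv`, acting on
  the liver concentration. There are no urinary/fecal elimination routes,
  no dietary uptake, and no growth dilution — the two sinks of the model
  are gill efflux and hepatic decomposition.
* Whole-body concentration is the volume-weighted mean over all seven
  compartments (blood included; excluding blood is available as an option).

The steady state is obtained by a direct dense linear solve of the 7×7
balance system (`numpy.linalg.solve`), not matrix inversion; a singular or
non-finite solve raises an error naming the offending parameter
combination. A fully vectorised closed-form evaluation of the same system
(tissues eliminated analytically) drives the calibration loops; its
agreement with the explicit solve is enforced by the test suite at 1e-10
relative.

**ODE oracle.** An independent validation path integrates the seven
time-dependent balances from zero initial conditions with the Radau stiff
solver (`rtol = 1e-12`, absolute tolerance scaled to `P_bw(1 + max P_tb)`),
out to 60 times the slowest eigen-time-constant of the system, and checks
convergence by requiring the state change over the final half-interval to
be below tolerance. Across 100 randomized draws of `(F_gill, k_m, Kow)`
spanning seven decades the linear solve and the integration agree to better
than 1e-8 relative; the packaged check requires 1e-6.

**Arterial volume.** The arterial/venous split of blood volume is not a
quantity the steady-state BCF depends on; it enters only the reported
influx rate `α F_gill / V_art`. The default arterial share is 1/3,
configurable.

**Assimilation efficiency α.** A pluggable rule mapping `log10 Kow` to
(0, 1]; default is the constant 1, because any multiplicative constant in
the uptake term is absorbed by the calibrated `F_gill`. α matters
independently only when reporting influx rates.

## Physiological parameters

The shipped adult-zebrafish configuration (`src/zebratk/data/*.yaml`)
carries per-entry provenance comments. The gill water flow
`F_gill = 9.167 µL/s` is the literature value for adult zebrafish; the
remaining entries (cardiac output, compartment mass fractions, tissue
lipid/water contents) are representative adult-zebrafish magnitudes entered
by the package authors, since a complete primary parameter table for this
compartment structure is not openly available. Users with a primary source
should supply their own YAML via `load_physiology_7c(path)` — every
workflow accepts a physiology argument. Quantities that depend on the
absolute location of the source/sink degeneracy curve (e.g. the fitted
`F_max` and `K` of the saturating curve, or influx-rate magnitudes)
therefore depend on this parameter choice and will differ between
parameterisations; the structural results (degeneracy, saturating median
curve, robustness to body-parameter uncertainty) do not.

## Particle swarm optimisation

Plain global-best PSO: velocity `v ← w v + c1 r1 (p_best − x) +
c2 r2 (g_best − x)`, position clamped to the bounds with the offending
velocity component zeroed. Coefficients default to the Clerc constriction
values `w = 0.72`, `c1 = c2 = 1.49` (configurable). Swarm defaults:
1000 particles, 500 iterations, early stop at an R² cutoff of 0.99; tests
and the acceptance script use smaller swarms (≈200 particles) and tighter
cutoffs chosen to resolve the quantities they check. Particles are
initialised log-uniformly because physiological parameters span orders of
magnitude; for the same reason the source/sink calibrations search in
log10-coordinates (uniform initialisation there is log-uniform in the raw
parameters), without which a swarm in linear coordinates cannot refine
values orders of magnitude below the box width. Objectives returning
non-finite scores have those particles scored `−inf` and counted; an
entirely non-finite initial swarm is an error. All randomness flows through
one seeded generator per run; identical seeds give bit-identical results.

Default source/sink search box: `F_gill ∈ (1e-7, 10) µL/s`,
`k_m ∈ (1e-6, 0.1) 1/s` — wide enough to contain both the literature
`F_gill` and the low-RMSE region, and matching the default grid-scan
ranges (100×100, log-spaced).

## Calibration workflows

* **Source/sink** (`SourceSinkModel.fit`): maximises the R² of predicted
  vs. observed log10 BCF against the identity line over `(F_gill, k_m)`,
  everything else fixed. Because only the source/sink balance is
  identified, noise-free data admit a 1-D curve of equivalent optima; the
  grid scan makes this degeneracy visible and the test suite verifies that
  the near-zero-RMSE region is a thin curve, not a blob.
* **All-parameter** (`AllParameterModel.fit`): optimises the 25 body
  parameters (everything except `F_gill` and `k_m`; the subset is
  configurable) under positivity with default bounds
  (literature/100, min(100 × literature, 1) for fractions). Flow fractions
  are treated as unnormalised weights renormalised to sum 1 inside the
  objective; candidate physiologies violating any invariant score `−inf`.
* **Per-chemical**: scores particles by the relative error
  `|obs − pred| / |obs|` on the log10 scale and stops below 1e-3. Records
  with `|log10 BCF| < 0.05` are refused — the score divides by the
  observed value and is ill-conditioned near BCF = 1. Observations above
  the model's equilibrium ceiling at their Kow (possible for noisy data)
  cannot reach the cutoff; such runs return their best error with a
  warning rather than failing.
* **Median curve and saturating fit**: pooled per-chemical optima are
  binned in 50 log-spaced `k_m` bins (enough to resolve the sigmoid
  without starving bins); per-bin medians of `F_gill` are fitted by
  nonlinear least squares to `F_max k/(K + k)` on the linear `F` scale,
  with initial guess `F_max = max F`, `K = median k_m`.

## Evaluation and uncertainty

Accuracy is RMSE on the log10 BCF scale. Systematic bias uses the exact
two-sided binomial test (sum of all outcomes with probability ≤ that of the
observed count) on strict under-predictions, ties excluded; an all-tie
dataset reports p = 1. Train/validation splits are seeded uniform halves
(odd sizes put the extra record in training). Cross-species comparisons use
per-species RMSEs, 0.2-wide histogram bins, and a two-sided Student's
t-test (unpaired by default, paired available).

Parameter uncertainty: each body parameter is resampled independently as
`log2(value) ~ Normal(log2(literature), 1)` — about 68% of draws within
half to twice the literature value — with `F_gill, k_m` held at the
calibrated pair; draws violating physiology invariants (e.g. lipid + water
> 1) are resampled and counted; perturbed flow fractions are renormalised.
A parameter is flagged significant when the baseline RMSE falls outside the
2.5–97.5 percentile band of the resampled RMSEs. Caveat: this flag detects
*direction*, not effect size. When the calibrated optimum leaves mean-zero
residuals and a parameter shifts all predictions monotonically, the
baseline sits at the sampled minimum and the flag can trigger at RMSE
differences of ~1e-5 — which is why the package also reports the maximum
97.5th-percentile RMSE inflation, the quantity that actually measures
robustness. No multiple-testing correction is applied across parameters.

## Synthetic data

The generator draws `log10 Kow` uniformly over (0.8, 8.48) — uniform rather
than the empirical distribution, to stress the whole domain — and computes
ground-truth log10 BCF from one of three truth models (the `P_bw`
regression; the 7C model at a known source/sink pair; or per-chemical
`k_m` drawn log-uniformly with `F_gill` on a saturating curve), plus
optional Gaussian noise in log10 units. The default 7C truth pair
`(F_gill, k_m) = (5.0 µL/s, 3e-6 1/s)` lies in the low-RMSE region of the
shipped physiology and was chosen once so that noise-free values span
roughly (−0.04, 5.2), matching the marginals of published adult-zebrafish
calibration data (−0.10 to 5.97). The adult-analogue dataset used by the
acceptance script draws observations from the regression truth with
sd 0.8 noise — the scatter scale of calibrated models on real data — so
that, as with real data, the literature body parameters are *not* the
data-generating truth.

What passing these tests shows: the solver stack is internally consistent,
the calibration recovers generating parameters (up to the structural
degeneracy) at zero noise, and the statistical machinery reproduces its
closed-form values. What it does not show: agreement with measured BCFs of
real chemicals, which depends on the published data tables and on a primary
body-parameter table; those checks activate when the tables are placed
under `data/supplementary/`.

## Numerical choices and degenerate inputs

* `F_gill = 0` with `k_m > 0` in the 1C model is a degenerate-input error
  (the correction term diverges); `F_gill = 0` with `k_m = 0` returns
  `P_bw`.
* `bcf_7c` at `C_exp = 0` computes the BCF from the unit-exposure solution
  so the ratio remains defined.
* Grid-scan cells whose model evaluation fails are recorded as NaN, not
  fatal.
* Exact floating-point ties in the under/over counts are excluded from the
  binomial n (measure-zero in practice).
* PSO bound intervals may be degenerate (lower = upper) to pin parameters.

## Problem sizes

Default test and acceptance runs use 76-chemical synthetic datasets,
200–300-particle swarms with a few hundred iterations, a 100×100 scan
grid, 100-draw oracle sweeps, 100-seed fit-recovery ensembles and
1000–2000-draw uncertainty resamples. These sizes resolve every reported
quantity well inside their tolerances; all entry points accept larger
swarms, grids and ensembles unchanged.

## Known limitations

* No time-resolved toxicokinetics beyond the validation oracle; constant
  exposure only.
* Flow-limited tissue exchange (no membrane limitation inside the body);
  the membrane-limitation question concerns the gill, where it is absorbed
  into `α F_gill`.
* Chemical structure handling (SMILES, Kow estimation) is out of scope:
  `log10 Kow` is always an input.
* The shipped body-parameter values are literature-informed but partly
  implementer-entered; curve-location quantities inherit that uncertainty.
* The embryo life stage has no dedicated physiology; applying the adult
  models across life stages or species is an evaluation exercise, not a
  claim of validity.
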