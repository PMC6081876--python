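# zebratk

Reverse-toxicokinetic (rTK) bioconcentration-factor modelling for adult
zebrafish (*Danio rerio*).

Environmental risk assessment needs to connect aqueous chemical exposures to
body burdens — and, inverted, to reconstruct the exposure concentration that
would explain a measured tissue concentration. `zebratk` implements two
steady-state toxicokinetic models of the adult zebrafish that need **only one
chemical-specific input**, the octanol–water partition ratio `log10 Kow`,
plus the calibration and evaluation machinery to fit their chemical-uptake
and elimination parameters to observed bioconcentration factor (BCF) data.
It is aimed at ecotoxicologists and modellers doing in-vitro-to-in-vivo
extrapolation, exposure reconstruction, or high-throughput chemical
screening.

## The models

The bioconcentration factor is the steady-state ratio of whole-body to
aqueous concentration, `BCF = C_body / C_exp`, so exposure reconstruction is
`C_exp = C_body / BCF`. Blood–water partitioning is regression-derived from
the octanol–water ratio:

    log10 P_bw = 0.78 · log10 Kow − 0.82

and tissue–blood ratios follow the lipid-fraction closure
`P_tb = (L_t · Kow + W_t) / P_bw`.

**One-compartment (1C) model** — the body as a single well-mixed reactor
with gill exchange (water flow `F_gill`, µL/s) and first-order metabolic
decomposition (`k_m`, 1/s):

    BCF = P_bw / (1 + (V_t · k_m / (F_gill · P_t)) · P_bw)

As `k_m → 0`, `BCF → P_bw`; for `BCF > 1` the decomposition rate must stay
below `(F_gill · P_t / V_t)(1 − 1/P_bw)`, which is negative for hydrophilic
chemicals (`log10 Kow < 1.05`) — no metabolism value can then raise the
prediction above 1.

**Seven-compartment (7C) model** — arterial and venous blood, brain, gonads,
richly and poorly perfused tissue, and liver. Chemical enters arterial blood
through the gills at rate `α·F_gill·C_exp`, tissues exchange flow-limited
with arterial blood, gonads and richly perfused tissue drain through the
liver (the only metabolic sink, `k_m·V_liv·C_liv`), and venous blood returns
through the gills where efflux `α·F_gill·C_ven/P_bw` closes the balance.
The steady state is a 7×7 linear solve, independently cross-checked by ODE
integration.

**Calibration** — a global-best particle swarm optimiser fits the uptake
"source" (`F_gill`) and elimination "sink" (`k_m`) to observed log10 BCF
data, scored by R² of predictions against the identity line. Because the
steady state constrains only the source/sink *balance*, noise-free data pin
the pair to a one-dimensional degeneracy curve rather than a point; pooling
per-chemical optima and taking binned medians exposes a saturating
relationship

    F_gill = F_max · k_m / (K + k_m)

which replaces chemical-specific metabolism measurements with a single
universal curve. Uncertainty in every other body parameter is assessed by
log2-normal resampling (most draws within half to twice the literature
value).

## Worked example

```python
import zebratk as z

# 1. a synthetic adult dataset with known 7C ground truth, no noise
data = z.generate_synthetic(z.SyntheticSpec(n_chemicals=40, seed=2024))

# 2. calibrate the source/sink pair
model = z.SourceSinkModel(data)
result = model.fit(z.PSOConfig(bounds=((1, 2),), n_particles=200,
                               max_iterations=400, score_cutoff=1 - 1e-9),
                   seed=11)
print(result.summary())
```

```
Source/sink calibration of the 7C bioconcentration model
==========================================================
No. observations:           40
F_gill (uL/s):              10
k_m (1/s):                  6.00681e-06
RMSE (log10 BCF):           0.0000
R^2 vs identity:            1.0000
Influx rate (1/s, alpha=1): 1.2
Iterations:                 15
Converged (score cutoff):   True
Seed:                       11
```

The data were generated at `(F_gill, k_m) = (5.0, 3e-6)`, yet the swarm
returns `(10.0, 6e-6)` with an essentially zero RMSE (4.3e-5): both pairs
lie on the same source/sink degeneracy curve, which is exactly why a single
"effective" decomposition rate paired with the saturating `F_gill(k_m)`
curve predicts BCFs across diverse chemicals. `result.predict([3.0])`
returns the calibrated log10 BCF for a new chemical with `log10 Kow = 3`,
and `z.predict_exposure(c_body, bcf)` inverts a measured body burden to an
exposure estimate.

A command-line interface mirrors the library
(`zebratk predict|calibrate|scan|eq4|evaluate|sensitivity|simulate`); every
run writes a JSON manifest with its seeds and input digests.

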