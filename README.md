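# hostresponse

Modeling the dose- and time-dependence of the host-mediated response to
chemotherapy.

A single injection of cytotoxic chemotherapy (here paclitaxel, 0–25 mg/kg in
mice) triggers a systemic *host response* — cytokine release and
mobilization of bone-marrow-derived cells — that can promote tumor-cell
migration, invasion and angiogenesis and thereby counteract the drug's
anti-tumor effect. This package implements, as a tested and reusable
library, the quantitative workflow for deciding *what drives that response*
and predicting it over the dose × duration plane, for three readouts:
circulating endothelial progenitor (CEP) levels, and migration/invasion of
tumor cells exposed to plasma from treated animals.

Two competing mechanisms are implemented as compartment-cascade models:

* **PK-based**: absorption → central → tissue concentrations
  (`dC0/dt = −k01·C0` with `C0(0) = D/Vd`, `dC1/dt = k01·C0 − k10·C1`,
  `dC2/dt = C1 − k20·C2`), with a Hill (Emax) effect link
  `E = ε + (Emax − ε)·C2^γ/(EC50^γ + C2^γ)`;
* **activation-based**: the *dose itself* seeds an effect cascade through
  `E00(D) = D^γ/(ED50^γ + D^γ)`, all rates equal to `k2`, and
  `E = ε_i + e_i·E2(t)` with the closed form
  `E2(t) = E00(D)·k2·t²/2·e^{−k2·t}` (peak at `t = 2/k2`).

A **global model** couples all three readouts: PK-driven Hill links for
migration and CEP (shared plasma kinetics, separate tissue compartments),
activation dynamics for invasion. Its four variants M1–M4 tie or free
(EC50, k20) between the migration and CEP sub-models and are compared by
pooled Gaussian maximum likelihood (shared σ, profiled analytically),
AIC/BIC (`AIC = −2l + 2P`, `BIC = −2l + P·log N_tot`, P counting σ) and
likelihood-ratio tests (`D = 2(l_alt − l_null)` ~ χ²(ΔP)).

The two families leave distinct fingerprints on the dose × duration plane:
the activation model's effect-minus-baseline factorizes into
(dose factor) × (time profile), so its onset dose threshold is the same at
every duration, while PK-driven effects have a drifting threshold and a
duration that grows with dose. `hostresponse.prediction` turns this into a
diagnostic.

Because the underlying per-animal data exist only as figure summaries, the
package ships a first-class synthetic-data module that emulates the study
design (doses {0, 5, 10, 25} mg/kg at 24 h; times {24, 48, 72, 96, 168} h at
25 mg/kg; 5 replicates/cell; Gaussian noise at 5% of each readout's dynamic
range) under a known model-3 ground truth, with the truth recorded in a
metadata sidecar so recovery experiments are self-contained. See
`docs/methods.md` for the model details and the generator's limitations.

## Worked example

Generate a synthetic study, fit the selected global variant, and predict a
held-out condition:

```
$ hostresponse generate --out data.csv --seed 1
wrote 120 measurements to data.csv

$ hostresponse fit --data data.csv --model global-M3 --starts 8 --seed 2 --out fit.json
loglik=-367.976 sigma=5.19414 -> fit.json
```

`fit.json` then contains the maximum-likelihood estimates (generating truth
in parentheses):

```
"theta": { "emax_m": 44.66 (45),  "emax_c": 259.88 (260),
           "ec50": 0.2544 (0.27), "k20_m": 0.0611 (0.06),
           "k20_c": 0.1237 (0.12), "ed50": 6.624 (7),
           "k2": 0.03964 (0.04),  "e_i": 3.694 (3.7) },
"sigma_hat": 5.194, "loglik": -367.98, "n_params": 9, "n_tot": 120
```

i.e. every kinetic and threshold parameter is recovered to within a few
percent from 120 noisy observations. Predicting the new condition
15 mg/kg / 72 h — a dose above the invasion threshold (ED50 ≈ 7 mg/kg) but a
time by which the PK-driven effects have washed out:

```
$ hostresponse predict --dose 15 --time 72
migration   10.09827147
cep         55.00000003
invasion    28.55913193
```

Migration and CEP sit at their baselines (10 and 55) while invasion is
elevated far above its baseline of 8 — the dose-triggered cascade is still
running at 72 h. `hostresponse validate` runs the same comparison against
simulated validation data with baselines re-anchored to the new controls.

Other subcommands: `select` (fit all four variants, rank by AIC),
`predict --surface` (dose × duration effect surface), `recover`,
`discriminate`, `calibrate-lrt` (the simulation studies).

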