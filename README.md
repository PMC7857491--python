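# efqokit

Quantitative analysis of **end-labeled fluorescence-quenched oligonucleotide
(EFQO)** acid 5′-exonuclease assays, with a built-in plate simulator.

## The problem

Lysosomal nucleases of the phospholipase-D family (PLD3, PLD4) degrade
single-stranded DNA exonucleolytically from the 5′ end at acidic pH. The EFQO
assay reads this activity out quantitatively: a 30-nt ssDNA substrate carries
a 5′-terminal FAM fluorophore and a 3′-terminal quencher, so the intact
oligonucleotide is dark; when the enzyme releases the 5′ fluorophore-coupled
nucleotide, FAM fluorescence (ex 485 nm / em 528 nm) appears in direct
proportion to the moles of substrate hydrolyzed. A 96-well plate is read every
5 min for 12 h at 37 °C after a 30-min preincubation, alongside a
substrate-only control (no lysate) and an enzyme-only control (no substrate).

`efqokit` implements the complete analysis for such data — and, because no
public plate exports exist for this assay, a forward simulator that generates
realistic synthetic plates with known ground truth, so every stage of the
pipeline can be validated by round-trip recovery.

## The method

**Drift correction.** With I_M(t) the measured sample intensity, I_M0 its
value at t = 0, and dI_S/dt, dI_E/dt the OLS drift slopes of the two controls:

```
I_C(t) = I_M(t) − I_M0 − (dI_S/dt + dI_E/dt) · t
```

**Calibration.** Substrate dilutions digested to completion by excess enzyme
give plateau intensities I_max; the OLS slope of I_max against substrate
amount is the fluorescence coefficient *k* (AU·mol⁻¹).

**Activity.** A = (dI_C/dt) · 1/k, with dI_C/dt estimated as the initial-rate
window slope (default: first 12 reads, i.e. 1 h, inside the substrate-excess
regime). Specific activity divides A by the lysate protein mass; integrated
activity is the trapezoidal AUC of I_C(t) divided by *k*.

**Downstream models.** Michaelis–Menten substrate dependence, four-parameter
logistic dose–response (IC50), Gaussian pH-optimum and descending-logistic
thermal-stability profiles — all scikit-learn-style estimators — plus group
statistics: fold-changes with bootstrap CIs, Dunnett's many-to-one comparison
(deterministic multivariate-t quadrature), and 5′-base preference ranking.

**Simulator.** Progress curves follow single-substrate irreversible
Michaelis–Menten kinetics, solved in closed form via the Wright omega
function; inhibitors (logistic in dose), activators (EDTA), pH, temperature
and substrate chemistry (5′-terminal base, phosphorothioate protection) act
as multiplicative factors on Vmax; wells carry linear background drifts and
seeded Gaussian read noise.

## Worked example

```python
import numpy as np
from efqokit import (standard_config, simulate_plate, quantify_plate,
                     fit_calibration, fold_change)
from efqokit.quantify import correct_trace, estimate_baseline, estimate_plateau
from efqokit.simulate import simulate_trace

# calibrate k from a fully digested dilution series
amounts, imaxs = [], []
for s0 in (0.25e-6, 0.5e-6, 1e-6, 2e-6):
    cfg = standard_config(noise_sd=0.0, S0=s0, Vmax=5e-8)
    tr = simulate_trace(cfg, "sample")
    corr = correct_trace(tr, estimate_baseline(tr),
                         cfg.drift_substrate, cfg.drift_enzyme)
    amounts.append(s0 * cfg.volume)
    imaxs.append(estimate_plateau(corr))
calib = fit_calibration(amounts, imaxs)
print(f"fluorescence coefficient k = {calib.k:.4g} AU/mol")

# a PLD3-vs-PLD4 plate: shared controls + triplicates at equal protein mass
design = [("A01", "substrate_control", {}), ("A02", "enzyme_control", {})]
design += [(f"B{i:02d}", "sample", {"condition": "PLD3", "replicate": i})
           for i in (1, 2, 3)]
design += [(f"C{i:02d}", "sample", {"condition": "PLD4", "replicate": i,
                                    "Vmax": 5e-10 / 300}) for i in (1, 2, 3)]
plate = simulate_plate(design, standard_config(noise_sd=0.0, Vmax=5e-10), seed=7)
results = quantify_plate(plate, calib)
pld3 = [r.specific_activity for r in results if r.condition == "PLD3"]
pld4 = [r.specific_activity for r in results if r.condition == "PLD4"]
fc = fold_change(pld3, pld4, "PLD3", "PLD4", seed=0)
print(f"PLD3/PLD4 specific-activity ratio: {fc.fold_change:.1f}-fold")
```

Output:

```
fluorescence coefficient k = 9.5e+12 AU/mol
PLD3/PLD4 specific-activity ratio: 299.0-fold
```

The fitted *k* is the generative coefficient (10¹³ AU/mol) times the quench
efficiency 0.95 — incomplete quenching scales the released-fluorophore signal
and the calibration identically, so molar activities are unaffected. The
recovered ratio matches the generative 300-fold rate difference between the
simulated PLD3 and PLD4 wells to 0.3%.

## Command line

```sh
efqo simulate  --config plate.yaml --seed 1 --out-dir run/
efqo calibrate --kinetics run/kinetics.csv --layout run/layout.csv --out k.csv
efqo quantify  --kinetics run/kinetics.csv --layout run/layout.csv \
               --calibration k.csv --out activities.csv
efqo fit       --model ic50 --in doses.csv --out fit.json
efqo report    --results activities.csv --layout run/layout.csv \
               --control untreated --out report.csv
efqo run       --config pipeline.yaml --seed 1 --out-dir run/
```

File formats (all delimited UTF-8 text, comma or tab auto-detected): kinetic
data in a *long* dialect (`well,time_min,rfu`) or *wide* dialect
(`time_min,<well>,…`); layouts as one row per well
(`well,role,condition,…`); results with units in the column names.

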