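# tacpredict

Predicting the [177Lu]Lu-DOTA-TATE time-activity curves (TACs) and
time-integrated activities (TIAs) of organs at risk and neuroendocrine
tumour lesions **from a single pre-therapy [68Ga]Ga-DOTA-TATE PET/CT
measurement**.

Peptide receptor radionuclide therapy (PRRT) delivers a fixed activity of
[177Lu]Lu-DOTA-TATE per cycle; individualising it requires the TIA — the
integral of each region's therapy TAC — which normally needs several
post-therapy imaging sessions.  `tacpredict` implements the alternative:
a whole-body physiologically based pharmacokinetic (PBPK) model of both
radioligands is fitted to the one diagnostic PET time point together with
population (Bayesian leave-one-out) information, and the fitted model
simulates the therapy phase.  Intended users are medical-physics and
pharmacometrics researchers studying single-time-point dosimetry.

The package covers, end to end:

* a two-administration whole-body PBPK model (SSTR2 receptor binding,
  internalization, endosomal sorting vs. recycling, lysosomal degradation,
  a kidney submodel with glomerular filtration, tubular reabsorption and
  collecting-duct transit), simulated as a stiff sparse ODE system;
* residual-error models with closed-form maximum-likelihood estimators,

  `b_model = sqrt(mean((y_i − f_i)² / f_i²))`,
  `b_data  = sqrt(mean((y_i − f_i)² / y_i²))`,

  split by phase (b_D, b_T) or phase × tissue class;
* MAP fitting of the 10 adjustable parameters (6 receptor densities,
  2 tumour flows, shared sorting and degradation rates) by damped
  Gauss–Newton on the extended-least-squares objective, with CV /
  correlation / AIC goodness-of-fit diagnostics;
* the iterative population workflow: per-patient b estimation, cohort
  medians, leave-one-out priors, reference (all-data) fits, and
  diagnostic-only therapy prediction (methods I/II/III);
* evaluation as RPE = (TIA_pred − TIA_ref)/TIA_ref with
  RMSE = sqrt(mean² + SD²) and MAPE summaries;
* a seeded virtual-patient generator reproducing the study's sampling
  design (8 diagnostic + 33 therapeutic values per patient), so everything
  is testable without clinical data.

## Worked example

```python
from tacpredict import (DEFAULT_CONSTANTS, FitParameters, PatientPhysiology,
                        build_model, simulate, study_dosing, tia, organ_activity)

phys = PatientPhysiology(
    weight_kg=76.5, height_cm=176.5, gfr_ml_min_1p73m2=70.0,
    volumes_l={"kidneys": 0.36, "spleen": 0.18, "liver": 1.80,
               "tumour1": 0.03, "tumour2": 0.03},
    total_tumour_volume_l=0.11,
)
model = build_model(phys, DEFAULT_CONSTANTS, FitParameters.default())
dosing = study_dosing()          # Ga-68 bolus at t=0; Lu-177 infusion day 7
traj = simulate(model, dosing, t_end=40000.0, dense=True)

pet = organ_activity(traj, "kidneys", 63.0, nuclide="ga68")
print(f"kidney activity at PET (63 min):   {pet:8.2f} MBq")
for region in ("kidneys", "tumour1"):
    t = tia(traj, region, window=(10080.0, 40000.0), nuclide="lu177")
    print(f"{region:8s} therapy TIA:           {t.tia_mbq_min:12.0f} MBq min")
print(f"mass-balance defect:               {traj.balance_error_max:.2e}")
```

prints

```
kidney activity at PET (63 min):       3.71 MBq
kidneys  therapy TIA:                  87468 MBq min
tumour1  therapy TIA:                  31761 MBq min
mass-balance defect:               1.12e-12
```

i.e. the population-median patient shows 3.7 MBq of Ga-68 in the kidneys
at the PET readout, a predicted kidney Lu-177 TIA of ~8.7e4 MBq·min over
the therapy window (infusion start to 40,000 min), and machine-precision
mass balance.

The cohort workflow runs from the command line:

```bash
tacpredict cohort make --n 12 --seed 42 --out cohort/
tacpredict estimate-b --manifest cohort/manifest.yaml --method I --out b_trace.json
tacpredict run --manifest cohort/manifest.yaml --method III --out report/
```

`run` writes the b-iteration trace, leave-one-out priors, per-patient
prediction JSONs, and an evaluation table (median [min, max], mean, SD,
RMSE, MAPE of the RPE per tissue class, tumours pooled).

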