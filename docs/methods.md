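# Methods

`tacpredict` predicts the therapeutic time-activity curves (TACs) and
time-integrated activities (TIAs) of [177Lu]Lu-DOTA-TATE in organs at risk
and neuroendocrine tumour lesions from a single pre-therapy
[68Ga]Ga-DOTA-TATE PET/CT measurement, by combining a whole-body
physiologically based pharmacokinetic (PBPK) model with population
information and an explicit residual-error model.  This note documents the
model, its assumptions, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Whole-body PBPK model

Ligand kinetics are described by a compartmental mass-balance system in
units of minutes / nmol / litres.  A central venous–arterial serum pool
connects all organs through their serum (plasma) flows.  Each organ has a
vascular and an interstitial space exchanging through a
permeability–surface-area (PS) product.  SSTR2-expressing organs — GI
tract, liver, spleen, muscle-with-fat, red marrow, prostate, adrenals,
rest-of-body, the kidneys, and four tumour compartments (two index lesions,
a lumped liver-lesion compartment, a lumped rest-of-body lesion
compartment) — additionally carry receptor-bound, endosomal and lysosomal
spaces.  Six organs (heart, bone, fat, lung, skin, brain) bind only
non-specifically and have vascular + interstitial spaces only.

Binding is bimolecular: free interstitial ligand associates with free
receptor at `kon` and dissociates at `kon * Kd`; both labelled and
unlabelled ligand compete for the same sites.  Bound ligand internalises at
a fixed (literature) rate into the endosomal space.  From there it either
moves to the lysosomal space at the *fitted sorting rate* or recycles back
to the interstitium at a fixed recycling rate; lysosomal ligand is degraded
at the *fitted degradation rate*, releasing its label into a systemic
metabolite pool that is cleared by glomerular filtration into urine.

The kidney submodel adds glomerular filtration of intact ligand
(GFR x arterial concentration), of which a fixed fraction is reabsorbed
into proximal-tubule cells (which sort like endosomes: lysosomal retention
at the fitted sorting rate versus basolateral return to serum at the
recycling rate) while the remainder transits the collecting ducts into
urine with a minutes-scale rate.  A small bidirectional non-specific
accumulation compartment completes the kidney.

**Why a recycling branch.**  In a chain `bound -> endosome -> lysosome`
confined to one readout region, moving material between the endosomal and
lysosomal pools does not change the region's summed activity, so a fitted
sorting rate would be almost unobservable in region-level TACs.  With an
endosomal recycling branch, the sorting rate determines the *retained
fraction* of internalised ligand — a directly observable property of every
specific organ's TAC, and the property a fitted sorting parameter must
control for fitting it to be meaningful.

**Species bookkeeping.**  Each administration event (the diagnostic bolus,
the therapeutic infusion) is simulated as one ODE species carrying its
*total* peptide.  Labelled and unlabelled ligand given together obey
identical kinetics, and the only nonlinearity (receptor competition)
couples species exclusively through total bound amount, so within one
administration the labelled amount stays exactly proportional to the total.
Labelled activity is recovered by the labelled-fraction and molar-activity
factors, and physical decay (half-lives 67.71 min for Ga-68, 9563 min for
Lu-177) is applied as a multiplicative readout factor with the decay clock
at the administration start.  This is an exact reformulation — chemistry is
decay-independent — and halves the state dimension (168 states for the
standard two-event timeline).  For a 36-min infusion of Lu-177 the
single-clock decay approximation is < 0.2%.

**Timeline.**  t = 0 at the diagnostic bolus; PET readout at 63 min;
therapeutic infusion starts on day 7 (10,080 min) with patient-specific
duration (~36 min); planar measurements at 1 h, 1 d, 4 d and 7 d after
infusion start, SPECT at 1 d; the simulation ends at 40,000 min (~day 28)
counted from the diagnostic injection, and TIAs integrate the therapy TAC
from the infusion start to that end point.  Both are configurable.

**Administered activity** is derived from the labelled amount and the
nuclide decay constant (A = lambda N), reproducing ~7.5 GBq for 10.28 nmol
of Lu-177 and ~0.18 GBq for 1.7e-3 nmol of Ga-68.

### Literature constants

The ten adjustable parameters are the receptor densities of the two index
tumours, kidneys, liver, spleen and muscle-with-fat, the serum flows of the
two index tumours (1/s, scaled by lesion volume), and one shared sorting
and one shared degradation rate.  The lumped lesion compartments use the
arithmetic mean of the two index tumours' density, flow and sorting.

Everything else is a fixed constant (editable JSON).  The kinetic defaults
were chosen once, within physiologically defensible ranges, to make the ten
fitted parameters jointly identifiable under the study's sampling design
(one 8-value PET time point plus 33 peri-therapy values) — an
experiment-design criterion evaluated with the expected Fisher information,
not with fitted results:

| constant | value | note |
|---|---|---|
| Kd | 1.5 nmol/L | mid-range of reported DOTA-TATE/SSTR2 affinities |
| kon | 8e-3 (nmol/L)^-1 s^-1 | ~8e6 M^-1 s^-1, fast peptide-GPCR association |
| internalization | 3e-3 s^-1 | agonist-driven, t1/2 ~ 4 min |
| endosomal recycling | 1e-2 s^-1 | competes with sorting (retained fraction 0.17–0.33 over the sorting range) |
| kidney reabsorbed fraction | 0.03 | low tubular retention of DOTA-TATE (~2 %ID kidney uptake) |
| collecting-duct transit | 5e-3 s^-1 | minutes-scale pelvis/ureter transit |
| tumour PS / tumour flow | 8e-3 | poorly permeable tumour microvasculature; see below |

The tumour PS/flow ratio places the diagnostic phase (low ligand
concentration, hungry receptors) in an extraction-limited regime where the
63-min uptake reads the *flow* parameter, while the therapeutic phase
(receptor-saturating peptide amount) is equilibrium-limited so the tumour
signal reads receptor *density*.  Organ volumes and serum flows for organs
not measured per patient are reference-adult values scaled linearly with
body weight; serum volume defaults to 43.5 mL/kg; GFR is normalised per
1.73 m^2 body surface area (DuBois) and converted to an absolute flow.

With the printed sorting/degradation ranges and renally cleared metabolite,
organ washout in this synthetic world is faster than clinical
[177Lu]Lu-DOTA-TATE retention (day-4/7 organ activities are small); all
package-level claims are therefore self-consistency claims about the
synthetic study, not reproductions of clinical TACs.

### Solver

The linear part of the right-hand side is assembled once per parameter
vector as a sparse matrix; the bilinear competition term and its Jacobian
entries are patched in analytically.  Dense-output runs (TIA quadrature,
diagnostics) use the implicit BDF method with the sparse analytic Jacobian
(rtol 1e-8, atol 1e-12 nmol); fitting runs use the LSODA driver with a
dense analytic Jacobian and relaxed tolerances (rtol 1e-6/1e-5), which
agrees with the tight solution to ~1e-4 relative at the measurement times.
Mass balance (all compartments + urine + metabolite vs. cumulative
administered) is tracked per species and stays below 1e-3 relative
(typically ~1e-12) on every simulation.  TIA uses adaptive quadrature on
the dense solver output with segment boundaries as breakpoints.

## Residual-error models

Measurement uncertainty is proportional: sigma_i = b f_i (model-based) or
sigma_i = b y_i (data-based); the combined form a + b f is fitted once in a
screening step and the additive term collapses to ~0 on proportional data.
The closed-form maximum-likelihood estimators

    b_model = sqrt(mean((y-f)^2 / f^2)),   b_data = sqrt(mean((y-f)^2 / y^2))

are the stationary points of the Gaussian negative log-likelihood
*including* the ln sigma term; that term is therefore kept in every fitted
objective.  The proportionality constant may be split by phase (b_D, b_T)
or by phase x tissue class (four-b partition), pooling residuals across
regions within a class.

A property worth knowing: when data are generated with noise proportional
to the *model* value (y = f (1 + b eps)), the data-based estimator, which
divides by the noisy y, is biased upward (~+27% at b = 0.2) and formally
has a divergent expectation because y has positive density near zero.
Consistency at the 3-standard-error level holds for each estimator under
its own noise model (y - f = b f eps, or y - f = b y eps); the tests check
exactly that, and a unit test documents the upward bias of the
cross-pairing.

## MAP estimation

The objective is the extended-least-squares form

    OF(p) = sum_i [(y_i - f_i)^2 / sigma_i^2 + ln sigma_i^2]
          + sum_j (ln p_j - ln mu_j)^2 / s*_j^2,

with the prior penalty on log-parameters (all ten are positive scale
quantities spanning the printed order-of-magnitude ranges);
s* = sqrt(ln(1 + cv^2)) is the log-sd induced by the prior mean/sd.  A
prior sd of zero pins the parameter.  Minimisation runs in log space with a
damped Gauss–Newton (Levenberg–Marquardt) iteration; sensitivities come
from one-sided finite differences (step 0.02 in log space) and are carried
across up to two accepted steps with Broyden rank-1 updates before a full
recompute.  Steps are clipped to a generous search box (population range
x/÷ 100) so that flat likelihood directions cannot drift to absurd scales.
Parameter CVs and the correlation matrix come from the Gauss–Newton
curvature at the optimum; AIC = 2k + OF_min.  Multi-start (log-uniform over
the population ranges, seeded) is available but defaults to a single start:
the population workflow warm-starts every fit from the previous iteration's
estimates, which makes restarts redundant and keeps the iterative loop
tractable.

The data-based weighting is markedly better conditioned than the
model-based one over this data's dynamic range (the ln f term of the
model-based objective rewards pushing small predictions down); the
workflow's bootstrap initialisation therefore always uses data-based
weighting, whatever family the method under study prescribes for the
subsequent fits.

## Population workflow

* **Iterative b estimation** (methods I/II: model-based with a two-b or
  four-b split; method III: data-based, four-b).  Bootstrap: one all-data
  fit per patient with uniform b = 0.2 and no prior (41 records > 10
  parameters), seeding the first leave-one-out priors and warm starts.
  Each iteration then runs, per patient, a diagnostic-only fit (per-class
  b_D from its residuals), a therapeutic-only fit (b_T), and an all-data
  fit whose estimates rebuild the next iteration's leave-one-out priors;
  cohort medians (lower-interpolated) of the per-patient b close the loop.
  Iteration stops when the therapeutic-median fluctuation drops below
  0.005, with a cap of 28 iterations for the two-b split; the four-b
  variants stop after one iteration by default (configurable).
* **Leave-one-out priors**: mean and sample sd (ddof 1) of the other
  patients' estimates, per parameter — the analysed patient never informs
  its own prior.
* **Reference fits**: all data + final error spec + LOO prior; therapy TAC
  simulated from the estimates, TIA per region.
* **Prediction**: only the 8 diagnostic values and the LOO prior reach the
  fit (an explicit therapeutic record raises a contamination error, and the
  result is bitwise invariant to edits of the held-out therapy data).
  Methods I/II fix all b at cohort medians; method III computes the
  diagnostic classes from the patient's own diagnostic residuals by a
  two-round self-consistent loop, while the therapeutic classes stay at
  cohort medians and enter only through the prior.

Evaluation: RPE = (TIA_pred - TIA_ref)/TIA_ref per region, pooled per
tissue class (the two index tumours together), summarised as median
[min, max], mean, population SD, RMSE = sqrt(mean^2 + SD^2) and
MAPE = mean|RPE|.  Report tables round half-away-from-zero to integer
percent; machine outputs keep full precision.

## Synthetic cohort

Virtual patients draw physiology and true parameters log-uniformly within
the printed population ranges (log-uniform to stress identifiability over
the full spread), use the study timeline, and get multiplicative Gaussian
noise y = f (1 + b_class eps) with class defaults (0.35, 0.27, 0.16, 0.39
for D-organ, D-tumour, T-organ, T-tumour) matching the data-based split
reported for the study; non-positive draws are redrawn.  The default
cohort size is 12.  All randomness flows from explicit seeds; identical
seeds give bitwise identical cohorts and pipeline outputs.

The generator emulates the sampling design and noise structure, not
image formation: no reconstruction or partial-volume effects, no organ
delineation error, no physiological drift between the diagnostic and
therapeutic phases (the LAR-analogue discrepancy is not modelled), and
faster-than-clinical late washout as noted above.  Passing tests
demonstrate internal consistency of estimation and prediction under the
stated design — not clinical accuracy.

## Known limitations and observed behaviour

* Tumour perfusion ("flow") is the weakest-identified parameter from a
  single pre-therapy time point: in the 20-patient recovery study the
  median relative errors of the two flow parameters sit near the 25%
  acceptance line (all eight other parameters are comfortably below it).
  This mirrors the wide printed population spread of the flow parameter
  (a factor ~38).
* Tumour-class RPE distributions are heavy-tailed: lesions whose true
  uptake parameters sit at the edges of the log-uniform population spread
  can have small reference TIAs, and the ratio metric then amplifies
  prediction misses into RPEs of several hundred percent.  Mean/SD/MAPE
  summaries of the tumour class at small cohort sizes are dominated by
  these tails (the medians stay moderate).
* The diagnostic-phase b constants estimated from 8 points per patient are
  biased low relative to the generative values: a 10-parameter fit can
  track 8 noisy values closely, shrinking the residuals that feed the
  closed-form estimator.  The therapeutic classes (33 points) are
  recovered much more faithfully — mirroring the reported observation that
  the diagnostic constants fluctuate far more than the therapeutic ones.
* The model-based extended-least-squares objective is poorly conditioned
  when predictions span many orders of magnitude; fits with it converge
  more slowly and can bias small predictions downward.  The data-based
  weighting does not have this pathology — consistent with the study's
  preference for the data-based error model.
* Problem sizes used by the shipped studies: recovery, 20 patients; the
  iterative b loop, the default 12 patients; the acceptance script's
  end-to-end demonstration, 6 patients with a 10-iteration cap and a
  single four-b iteration.
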