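# fddos

Non-invasive neuromonitoring during cardiopulmonary resuscitation, as a
reusable analysis pipeline.  `fddos` implements the full chain from raw
frequency-domain diffuse optical spectroscopy (FD-DOS) measurements to an
early, highly specific prediction of return of spontaneous circulation
(ROSC), and ships a seeded synthetic-cohort generator that reproduces the
statistical structure of a pediatric swine asphyxial cardiac-arrest study
(48 analyzable subjects, 37 ROSC / 11 No-ROSC, four CPR-strategy arms) so
the whole analysis can be exercised end to end without animal data.

It is written for researchers working on diffuse optics, resuscitation
physiology, or physiologic prediction during CPR.

## The analysis

**Optics.** A multi-distance FD-DOS probe measures AC amplitude and phase of
modulated near-infrared light at wavelengths λ = 690, 725, 785, 830 nm.  In
a semi-infinite homogeneous medium, ln(r²·AC) and phase are linear in
source-detector separation r with slopes

&nbsp;&nbsp;α = √{(3µₐµₛ′/2)·[√(1+(ω/vµₐ)²)+1]},&nbsp;&nbsp;
β = √{(3µₐµₛ′/2)·[√(1+(ω/vµₐ)²)−1]},

which invert in closed form to the absorption and reduced scattering
coefficients (µₐ, µₛ′) per wavelength.  Departure of the measured frames
from multi-distance linearity (low fit R²) is the quality-control signal for
motion artifact and light leakage.

**Spectroscopy.** The scattering spectrum is fit to the Mie power law
µₛ′(λ) = a·(λ/500 nm)^(−b), and the absorption spectrum is decomposed as

&nbsp;&nbsp;µₐ(λ) = ε_HbO₂(λ)[HbO₂] + ε_Hb(λ)[Hb] + 0.75·µₐ,H₂O(λ),

solved by least squares over the four wavelengths for the oxy- and
deoxy-hemoglobin concentrations; StO₂ = 100·[HbO₂]/([HbO₂]+[Hb]) and
THC = [HbO₂]+[Hb] follow.

**Epochs and prediction.** Each subject's series is reduced to window means
(baseline; final 15 s of asphyxia; 15 s after 1 min of CPR; 10th minute of
CPR) and the derived change family (Δ and relative forms versus baseline and
versus 1-min CPR).  The ROSC predictor for each candidate parameter is its
mean over CPR minutes 2–10; performance is scored by the weighted Youden
index

&nbsp;&nbsp;J_w = 2·(w·sensitivity + (1−w)·specificity) − 1,&nbsp;&nbsp; w = 0.1,

which emphasizes specificity (a predictor that predicts no one reaches
J_w = 0.8; a perfect one reaches 1).  Every observed value is scanned as a
decision threshold, discrimination is summarized by ROC AUC with a
stratified bootstrap CI, variability by outcome-stratified tenfold
cross-validation, and temporal stability by applying the global threshold to
held-out folds within each 1-min CPR bin.

## Worked example

Generate one calibrated cohort, run it through the optical forward model and
the chromophore solve, and score the Δ[HbO₂]-from-1-min-CPR predictor:

```python
import numpy as np
from fddos import (CohortConfig, ExtinctionTable, generate_cohort,
                   forward_to_optical, hemodynamics_series, optimal_threshold,
                   roc_and_auc)
from fddos.epochs import cpr_mean_predictor

ext = ExtinctionTable.default()
cohort = generate_cohort(CohortConfig(seed=7))

predictor, outcome = [], []
for subject in cohort.subjects:
    optical = forward_to_optical(subject, ext)           # 4-wavelength mua/musp
    hemo = hemodynamics_series(optical, ext, mie=False)  # [HbO2], [Hb], THC, StO2
    predictor.append(
        cpr_mean_predictor(hemo, subject.timeline, "hbo2", "delta_1min")
    )
    outcome.append(subject.rosc)

v, y = np.asarray(predictor), np.asarray(outcome)
best = optimal_threshold(v, y, w=0.1)
roc = roc_and_auc(v, y, n_boot=2000, seed=0)
print(f"cohort: {y.sum()}/{len(y)} ROSC")
print(f"max J_w = {best.j_w:.2f} at threshold {best.threshold:+.1f} umol/L "
      f"(sens {best.sensitivity:.2f}, spec {best.specificity:.2f})")
print(f"AUC = {roc['auc']:.2f} (95% CI {roc['auc_ci'][0]:.2f}-{roc['auc_ci'][1]:.2f})")
```

Output:

```
cohort: 37/48 ROSC
max J_w = 0.96 at threshold +0.6 umol/L (sens 0.81, spec 1.00)
AUC = 0.98 (95% CI 0.93-1.00)
```

A rise in cerebral oxy-hemoglobin of about a micromole per liter above its
1-min-CPR reference, averaged over CPR minutes 2–10, separates subjects who
will achieve ROSC with perfect specificity on this cohort: no subject that
failed to reach the threshold achieved ROSC.  The threshold itself varies
between cohorts (its across-replicate median is ≈ +1.2 µmol/L); J_w and AUC
are stable.

The same analysis is available from the shell:

```sh
fddos all runs/demo --seed 7          # simulate -> ... -> predict -> report
cat runs/demo/report.md
```

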