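# Methods

This note documents the models, the synthetic-cohort generator, the
numerical conventions, and the design choices behind `fddos`, in the order
the pipeline applies them.

## Photon-diffusion front end

The forward model is the semi-infinite homogeneous solution of the
frequency-domain photon diffusion equation.  For modulation angular
frequency ω = 2πf, tissue light speed v = c/n and optical properties
(µₐ, µₛ′) in 1/cm, the detected AC amplitude and phase at source-detector
separation r obey

    ln(r²·AC) = const − α·r        phase = φ₀ + β·r

with α² − β² = 3µₐµₛ′ and αβ = 3µₛ′ω/(2v).  Inversion fits unweighted
ordinary least-squares lines to ln(r²·AC) and (nearest-branch unwrapped)
phase across separations and applies the closed forms

    µₐ = (ω/2v)(α̂/β̂ − β̂/α̂)        µₛ′ = (α̂² − β̂²)/(3µₐ)

The second µₛ′ form, 2α̂β̂v/(3ω), is algebraically identical given the µₐ
formula; the first is primary and the equivalence is asserted in the tests.
Unweighted OLS is used because four separations leave nothing for robust
weighting to gain.  Defaults: separations {1.5, 2.0, 2.5, 3.0} cm,
modulation 110 MHz, refractive index 1.4 — standard values for this probe
class.

Assumptions: homogeneous semi-infinite tissue, no layered or curved-geometry
corrections, detectors in the diffusive regime.  Departures from
multi-distance linearity are treated as data-quality events, not modeling
targets.

### Quality control

A sample fails QC when the worst amplitude/phase fit R² across wavelengths
drops below `r2_min` (default 0.97) or the inversion is non-physical.  The
exact per-frame criteria used with the original instrument are not public;
0.97 is a documented, configurable stand-in chosen so that noise-free frames
pass with wide margin while injected light-leak and probe-shift artifacts of
plausible magnitude fail.  An epoch is unusable for a subject when more than
half of its window's samples fail; a subject is excluded from study-level
analyses when more than half of its CPR record fails.

## Spectroscopy

Scattering spectra are fit to µₛ′(λ) = a(λ/500 nm)^(−b) by nonlinear least
squares on the linear scale (Gauss-Newton, initialized from the log-log OLS
line; the two agree exactly on noise-free power-law spectra, and rows that
fail to converge fall back to the log-log estimate with a flag).  Adjusted
R² uses p = 2 free parameters, the usual convention even though the model is
nonlinear, and is reported as NaN with fewer than four wavelengths.

Hemoglobin concentrations solve the 4×2 linear system

    µₐ(λ) = ε_HbO₂(λ)[HbO₂] + ε_Hb(λ)[Hb] + 0.75·µₐ,H₂O(λ)

by ordinary least squares after subtracting the fixed 75%-water term
(`water_fraction` is configurable).  The packaged extinction table
(`fddos/data/extinction_table.csv`) pins ln-based specific absorption
coefficients in 1/(cm·µM), converted from the standard literature
compilation of molar log₁₀ extinction coefficients, plus pure-water
absorption; it is versioned with the package and swappable via
`ExtinctionTable.from_csv`.  Negative concentration solutions are reported
and flagged, never clipped: clipping would bias every downstream change
statistic.

## Epochs, derived parameters, prediction

All windows are half-open [start, end): baseline is the 120 s before
asphyxia onset; asphyxia end the final 15 s of asphyxia; 1-min CPR the 15 s
beginning at CPR t = 60 s; 10-min CPR the minute [540, 600) s of CPR; the
predictor window [120, 600) s; the time-resolved bins [2,3) … [9,10) min.
"Minute 10" and "2–10 min" are ambiguous in prose; the half-open convention
is applied uniformly so no sample lands in two windows.  A window mean is
missing unless at least half its samples pass QC; gaps are never
interpolated.

The candidate predictor set is the nine combinations of {[HbO₂], StO₂, THC}
× {absolute, Δ-from-1-min, relative-to-1-min}: deoxy-hemoglobin shows no
outcome association, and baseline-referenced forms are excluded because a
baseline is not measurable after arrest recognition.  The decision rule is
"predict ROSC when value ≥ θ" for every candidate (all nine are elevated in
ROSC); J_w ties during the threshold scan break toward higher specificity,
then toward the larger threshold, consistent with the specificity-first
intent of w = 0.1.  When no observed cut beats the degenerate predict-no-one
rule the reported threshold is +∞ with J_w = 2(1−w)−1.

AUC is the trapezoid area over all observed thresholds and equals the
tie-corrected Mann-Whitney U/(n₁n₀) identically; its 95% CI is a stratified
percentile bootstrap (2000 replicates, seeded) — the CI method is a
documented choice, as none is standard for this setting.  Cross-validation
uses outcome-stratified folds (scikit-learn `StratifiedKFold`, seeded);
stratification is by outcome only, since with 11 No-ROSC subjects outcome
balance is the binding constraint.  Fold counts cap automatically at the
minority-class size on small cohorts.

Two distinct out-of-sample procedures are provided and must not be
conflated: `kfold_cv` derives a threshold per training fold and scores it on
the held-out fold (threshold variability), while `time_resolved_performance`
applies one fixed global threshold to the held-out folds within each 1-min
bin (temporal stability).

## Statistics

Groups are summarized as median [IQR] with linear-interpolation quantiles.
Paired asphyxia effects use the Wilcoxon signed-rank test (zeros dropped;
exact null for n ≤ 25 without ties, else tie/continuity-corrected normal
approximation); group contrasts use the two-sided rank-sum test (exact for
small tie-free samples); the strategy × outcome table uses Fisher's exact
test.  The method actually used is recorded on every result, and no
multiple-testing correction is applied, matching the reporting convention of
the analyses this package mirrors.  Exactness is verified against full
enumeration oracles for n ≤ 8 and a hypergeometric tail-sum oracle.

## Synthetic cohort generator

The generator emulates the monitored cohort of a pediatric swine
asphyxial-arrest protocol: four CPR-strategy arms of 14/10/15/9 subjects
with 9/10/11/7 achieving ROSC (37/48 overall), 10 Hz sampling across a 2-min
baseline, 7 min of asphyxia and up to 20 min of CPR, ROSC times drawn from
the defibrillation-eligibility grid {600, 720, …, 1200} s of CPR.

**Latent state.** Each subject's truth is [HbO₂](t) and [Hb](t) plus
scattering truth (a, b, and a 785-nm perturbation δµₛ′).  THC and StO₂ are
derived, never drawn.

**Anchors.** Per-subject anchor values at baseline, asphyxia end, 1-min CPR
and (as changes from 1-min) 10-min CPR are drawn from quantile-matched
shifted log-normal distributions parameterized by each group's published
median and quartiles; the skew direction follows the printed quartile
asymmetry and the family degenerates to a normal for symmetric triplets.
The latent Gaussian is clipped at |z| ≤ 2 to keep the underdetermined far
tails physiologic (the matched quartiles move by under two percentile
points).  A Gaussian copula (ρ = 0.6) couples each subject's HbO₂ and Hb
change draws — a shared perfusion factor, so large combined losses co-occur;
ρ was fixed at this physiologic default after a scan showed no value in
[0, 0.9] dominates the match of the emergent ΔStO₂/ΔTHC medians to their
published counterparts.

The 1-min-CPR absolute levels are not published.  The HbO₂ medians follow
from the printed identity (absolute at 10 min minus the 1-min-referenced
change; the groups land within 0.3 µmol/L of each other, as expected before
hemodynamic divergence); the Hb level is given one common distribution for
both groups because no Hb form shows an outcome association.

**A structural limit worth knowing.** The published 10-min group medians of
Δ[HbO₂], ΔTHC and ΔStO₂ are mutually inconsistent with *any* two-chromophore
latent model: writing S = 100·H/T, the identity ΔS = 100·(H₁+ΔH)/(T₁+ΔT) −
100·H₁/T₁ becomes a quadratic in T₁ whose discriminant is negative at the
No-ROSC medians (ΔH = −3.6, ΔT = −5.4, ΔS = −3.9, H₁ ≈ 24.4 µM) — medians of
nonlinear per-subject quantities do not compose.  The generator therefore
calibrates the ([HbO₂], [Hb]) pair exactly and lets THC and StO₂ emerge.
The emergent ΔStO₂ medians (≈ +6.2 ROSC / −1.7 No-ROSC) and ΔTHC medians
(≈ +2.0 / −9 to −11) have the right ordering and discrimination for StO₂,
while the emergent ΔTHC distribution is more dispersed than the printed
IQRs, so ΔTHC separates the groups at p < 0.01 in roughly three quarters of
replicate cohorts rather than nearly all.  This is a property of the
published marginal summaries, not of the implementation, and the
corresponding directional test is expected to stay red at its stated 90%
bound.

**Trajectories.** Piecewise cubic-smoothstep templates run through the
anchors with holds over each analysis window, so the window means equal the
anchors exactly in the noise-free limit.  The CPR group divergence is
established between 1:15 and 4:00 of CPR (`divergence_end_s`, default
240 s), then plateaus at the 10-min anchor: the published time-resolved
results (AUC ≈ 0.8 already in the third minute; median fold J_w > 0.9 in
every bin from 2 min) rule out a divergence stretched uniformly to 10 min.
After minute 10, No-ROSC subjects continue their trend by a configurable
fraction (`post10_trend` = 0.6) while ROSC subjects hold until their ROSC
time.

**Noise.** Stationary AR(1) per chromophore (coefficient 0.95 at 10 Hz,
about a 2 s correlation time; marginal SD 1.0 µmol/L) plus a 0.3 µmol/L
pulsation at the compression rate (100/min) during CPR only, opposite in
sign between HbO₂ and Hb.  These magnitudes are stated defaults — the
within-subject noise of the original recordings is not published — chosen as
realistic for 10 Hz diffuse optical hemodynamics.

**Scattering.** a and b are per-subject constants (a with small AR(1)
wander); δµₛ′(785 nm) ramps to its asphyxia target during asphyxia and to
its group-specific CPR target during the divergence window, reproducing the
one scattering channel with a published outcome difference.

**Artifacts.** Frame-level corruption emulates motion events: a light leak
adds an r-independent amplitude floor (default five times the far-detector
signal), a probe shift rescales amplitude and offsets phase at the largest
separation; both break multi-distance linearity and are caught by the R²
rule, and the injector returns a truth mask for validating QC recall.  The
pipeline's `extra_artifact_subjects` option adds fully corrupted subjects to
reproduce a realistic feasibility denominator (e.g. 48/52).

**What the generator does not emulate.** No autoregulatory or compartment
physiology, no invasive pressures or ECG, no drug-dose events, no real
instrument systematics (detector nonlinearity, cross-talk, drift), and no
within-subject correlation between epochs beyond the anchor copula.  Tests
passing on these cohorts certify the analysis chain — inversion,
spectroscopy, epoching, statistics, prediction — under the study's marginal
statistical structure; they do not certify performance on real instrument
data.

## Reported reproduction quantities

`scripts/acceptance.py` reports, besides the closed-form identities and the
contingency-table p-value, replicate medians over 100 seeded cohorts of 48
subjects (the protocol calls for at least 25; 100 keeps the Monte-Carlo
error of the medians small at about a minute of CPU).  Typical values with
default calibration: Δ[HbO₂] max J_w ≈ 0.97, AUC ≈ 0.98, optimal threshold
≈ +1.2 µmol/L (per-cohort IQR roughly 0.7–1.6), ΔStO₂ max J_w ≈ 0.93, and a
per-bin across-fold median J_w of ≥ 0.9 in every CPR minute from 2 to 10.

## Known limitations

- The diffusion front end is semi-infinite and homogeneous; curved or
  layered geometries need a different forward model.
- The Mie fit's adjusted R² convention (p = 2) is reported for comparability,
  not as a rigorous nonlinear-model statistic.
- The quantile-matched anchor family fixes three quantiles; tails beyond the
  |z| ≤ 2 clip are a modeling convention.
- Exclusion rules (50% window coverage, 50% CPR coverage) are documented
  stand-ins for unpublished per-frame quality criteria.
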