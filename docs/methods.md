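# Methods

This note documents the statistical model behind `morphonorm`, the
defaults and why they were chosen, what the synthetic test-bed does and
does not emulate, and the numerical choices that matter when reproducing
results.

## Feature catalog

Each scan is reduced to 2,976 features. Surface-based morphometry
contributes (34 + 74) parcellations × 3 sides (left, right, asymmetry)
× 9 parameters = 2,916 features. The volume block contributes 60: 14
bilateral segmented structures (hippocampus, amygdala, thalamus, caudate,
putamen, pallidum, accumbens, ventral diencephalon, lateral and inferior
lateral ventricles, cerebellar cortex/white matter, cerebral cortex/white
matter) × {left, right, asymmetry}, plus 18 midline structures and
whole-brain partial volumes (3rd/4th ventricle, brainstem, CSF
segmentation, optic chiasm, five corpus-callosum subsegments, total
CSF/GM/WM, brain volume, intracranial volume, supratentorial volume,
subcortical grey volume, ventricle+choroid volume). Published catalogs of
this kind state the total (60) without enumerating the members; the list
above is this package's documented convention, chosen from the standard
segmentation outputs so that the total is exactly 60. Midline structures
carry a `global` side tag since neither hemisphere applies.

## Normalization

* **Head size.** `x ← x · (eTIV_ref/eTIV)^n` with exponents from
  dimensional analysis of isometric scaling: n = 1 volumes, 2/3 areas,
  1/3 thickness measures, −1/3 mean curvature (1/length), −2/3 Gaussian
  curvature (1/length²), 0 for the dimensionless curvature and folding
  indices. Multiplying by the reference ratio keeps physical units.
  `eTIV_ref` is the geometric mean of the normative eTIVs (stable under
  the power law).
* **Grey-white contrast** depends on sequence, not head size: values are
  rescaled so each (feature, scanner-sequence) group mean equals the
  grand normative mean. Scoring a scan from an unseen scanner group is an
  error (the caller must map to the closest group explicitly and flag the
  report) rather than a silent fallback.
* **Asymmetry index** AI = (R − L)/(R + L) ∈ [−1, +1]; −1 is extremely
  left-dominated, 0 symmetric. The (R−L)/(R+L) denominator convention is
  adopted because it produces exactly this range. AIs are computed from
  raw values (the eTIV factor cancels; the contrast group factor cancels
  too since both hemispheres share a scanner).

## Normative model and p-values

Per feature and variant (raw, eTIV-normalized; asymmetry features are
identical in both and belong to both 2,976-test families):

* **Age trend**: least-squares polynomial in a centered/scaled age basis,
  order 0–3 selected by BIC. BIC was chosen over a fixed "low order"
  because it is objective and reproducible; with ~300 controls it
  reliably finds quadratic trends of realistic size.
* **Outliers and artifact odds**: a robust rule (|median/MAD z| > 3.5)
  counts outliers; the artifact probability is Haldane-smoothed,
  p_art = (k + ½)/(n + 1), and odds_valid = (1 − p_art)/p_art is the
  per-feature weight used by the regional condensation. Exclusion from
  the trend/SD refit uses a wider fence (robust |z| > 5): trimming
  genuine ~3.5 σ observations would bias the scale estimate low and
  inflate the type-I rate by a few percent, while true segmentation
  failures are far outside either fence.
* **Error decomposition**: the control residual variance is
  σ²_resid = σ²_pop + σ²_meas. The measurement component is estimated
  from same-subject scan pairs within a three-year window as
  RMS(detrended pair differences)/√2 (zero mean known by construction);
  the stored population SD is the between-subject remainder
  √(σ²_resid − σ²_meas) (capped so σ²_meas ≤ 0.9 σ²_resid). The null
  width used at scoring, √(σ²_pop + σ²_meas), therefore reproduces the
  control residual spread exactly — adding the measurement error to the
  *full* residual SD would double-count it and roughly halve the
  empirical flag rate.
* **p-values**: z = r / (s·√(1 + h)) with s the null width and h the
  design leverage at the patient's age, referred to a Student-t with the
  feature's residual degrees of freedom. This is the exact prediction
  interval under Gaussian errors; with a 300-control cohort the Gaussian
  tail would overflag by ~5% at p = 0.01, which is visible when
  calibration is assessed over 6×10⁵ tests. The plain Gaussian identity
  (z = 2.5758 → p = 0.01) is available via `abnormality_p` with
  `df=None`. Ages outside the normative range are scored but the profile
  is flagged as extrapolated.
* **Two finite-sample refinements** keep the family-wide type-I rate at
  the nominal level:
  * *Asymmetry size-conditioning.* AI is a ratio; its null spread scales
    as 1/(L+R), so across subjects the AI distribution is a Gaussian
    scale mixture with excess kurtosis (≈ 12·CV² of the bilateral size),
    worth +10–15% flag-rate inflation at p = 0.01. Asymmetry residuals
    are therefore multiplied by s = (L+R)/S̄ (head-size-normalized
    values; S̄ the normative mean bilateral size, stored in the model)
    before standardization, which removes the size-induced
    heteroscedasticity. Larger-than-average structures get slightly
    tighter AI limits — the physically sensible direction.
  * *Contrast group-mean leverage.* A patient's contrast value is scaled
    by a group mean learned from n_g controls; the extra estimation
    variance enters as a 1/n_g leverage term.
* **Flags**: yellow = uncorrected p < α (default 0.01); red =
  Benjamini–Hochberg FDR-significant at q (default 0.01) within the
  scan's 2,976-test family of that variant. Red implies yellow.

## Fingerprints, condensation and detections

L = −log₁₀(p) with the sign of the residual (positive L = larger than
expected); p is floored at 10⁻¹⁶ before the log. Regional condensation is
the odds²-weighted RMS; each cortical hemisphere pools its 9 parameters
(weight 1) plus the region's 9 asymmetry scores (weight ½ — the asymmetry
"counts half for each hemisphere", so its total influence is one
region-equivalent). Bilateral volume structures pool volume + ½·asymmetry
so the detection rule is uniform across region kinds; midline volumes
stand alone. Detections are regions with L_r ≥ 2, ranked descending with
lexicographic tie-breaks. Detection uses the eTIV-normalized variant's
p-values (raw-variant scores are retained in reports); pooling raw and
normalized into one score is deliberately not done, to keep the two
families interpretable.

Note one consequence of half-weighted asymmetries: a purely
asymmetry-driven finding elevates both hemispheres' pools almost equally;
lateralization then comes from the hemisphere-specific contributors.

## Subtype-representative features

For a subtype's L-matrix (datasets × features): t_f = mean_f/sd_f
(unbiased SD; sd = 0 yields a capped ±10⁶ surrogate). *Reproducible* =
t_f outside Q1 − 1.5·IQR / Q3 + 1.5·IQR of the t distribution pooled over
all 2,976 features of that subtype. *Unique* = two-sided Welch t-test
p < 0.01 against **each** other subtype (the strict reading of "all other
subtypes"; a pooled comparison and a Mann-Whitney variant are options).
Selection = intersection. Importance = subtype-mean |L| over selected
features, normalized to sum 1 (the importance measure itself is a
package convention). On null data the Tukey exceedance of t_f is ~1%
(heavier than the 0.7% Gaussian benchmark because t_f is t-distributed at
small n), and the uniqueness intersection drives the null selection rate
well below 1%.

## Accuracy evaluation

A dataset is *sensitive* for a ground-truth source if **any** detection is
consistent with it, *specific* if one of the **top-3** detections is.
Consistency levels: sublobar (label identity within the annotated/resected
set, same hemisphere), lobar (static parcellation→lobe table shipped in
`accuracy.py`; assignments for labels straddling boundaries, e.g. the
central sulcus → frontal, are documented conventions), hemispheric. EEG
comparisons are hemispheric and only for focal (left/right)
lateralization; surgery comparisons require a resection with favorable
outcome (Engel I–II) and ≥ 6 months follow-up. Overall fractions are
means over evaluable datasets. Regional 2×2 tables yield
DOR = (TP·TN)/(FP·FN) with a +½ continuity correction on all cells when
any cell is zero (keeps log DOR finite), plus PPV/NPV. Randomization
tests permute group labels (default 10,000 resamples) with
p = (1 + #{|T*| ≥ |T|})/(N + 1), never zero. Sequential testing:
Kruskal-Wallis first; pairwise MWW only if p < 0.05; α = 0.01 with
0.01 ≤ p < 0.05 labeled a trend. The "exact test" is the standard
two-sided Fisher test; for the 5/5 vs 3/5 overlap table it gives
p = 0.44 (one-sided 0.22) — the reference study quotes p = 0.333 for the
same comparison, a variant we could not reconstruct and deliberately did
not reverse-engineer.

## Synthetic test-bed

The generator (see the `simulate` module docstring for the generative
equation) fixes the "population biology" — baselines, spreads, trend
shapes, scanner offsets, subtype templates — from a `population_seed`
(default 20170907), while cohort sampling uses `seed`; controls and
patients are thus drawn from one population. Key defaults, chosen once as
realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| controls / repeat pairs | 300 / 40 | mirrors a ~320-scan normative database at desk cost |
| ages | controls 7–79 y, patients 18–76 y | adult TLE cohort inside the normative range |
| between-subject CV | 4% (thickness) – 12% (curvature index) | typical morphometric spreads |
| σ_meas/σ_pop | 0.4 | scan–rescan error clearly smaller than biology |
| L/R subject-effect correlation | 0.9 | keeps AI spread realistically small (hippocampal AI SD ≈ 0.025) |
| scanner offsets | 0.1 σ additive; contrast ×e^N(0,0.05) | visible but subdominant site effects |
| eTIV | lognormal, sex-dependent (1550/1400 ml, 7%) | drives the isometric factor the pipeline must remove |
| artifact rate | 1% gross 6–12 σ outliers, clamped to physical values | segmentation-failure stand-in |
| MTLE-HS template | hippocampus −4, amygdala −1.5, pallidum −1, putamen −0.8 null-widths; mesiotemporal thinning −2 | unilateral hippocampal sclerosis pattern |
| LTLE template | lateral temporal thickness −4, GM volume −3.5, area −2.5 | lateral neocortical lesion strong enough to survive 9-parameter pooling |
| EEG discordance / surgery fraction / favorable | 0.1 / 0.4 / 0.8 | equivocal-case and surgery-subset analyses stay populated |

Calibration and recovery experiments use `artifact_rate=0`: an injected
gross outlier is a true abnormality by construction, so a type-I-rate
measurement on contaminated subjects would be answering a different
question. Null subjects are held-out draws from the control population.

What the generator does **not** emulate: skewed or bounded feature
distributions (everything is Gaussian before the head-size factor),
spatially correlated effects across neighboring parcellations,
age-by-disease interactions, scanner-by-region interactions beyond a
constant offset, and longitudinal disease progression in repeat scans.
Passing tests therefore demonstrate the statistical machinery under its
stated assumptions, not robustness to every property of real MRI-derived
data; with real data the Gaussian tails are an approximation and the
asymmetry/contrast corrections above address only the model-induced part
of the miscalibration.

## Numerical choices and degenerate inputs

* Age is centered/scaled before building Vandermonde designs
  (conditioning); stored coefficients live in that basis.
* BIC residual sums are floored relative to the data scale so exactly
  constant features select order 0 instead of a numerically noisy high
  order.
* p-values are clipped to (tiny, 1]; L scores floor p at 10⁻¹⁶.
* AI with L + R = 0, or with invalid (negative) inputs in a cohort table,
  becomes NaN rather than an exception; scalar `asymmetry_index` is
  strict.
* Ties in detection ranking break lexicographically by (region,
  hemisphere) — deterministic output ordering everywhere.
* Measurement SD is capped at 95% of the residual variance so the
  between-subject component stays positive under estimation noise.
* Sex can be included as an additive covariate in the trend fit
  (`include_sex=True`); by default sex enters only through eTIV, which the
  isometric normalization removes.

## Problem sizes used in the shipped experiments

Calibration: 300-control model, 200 held-out nulls (595,200 tests).
Recovery: 100 simulated MTLE-HS patients plus 50 nulls. Reproducibility:
four 10-patient subtype cohorts with 4 rescans each. These sizes give
binomial/rank-test resolution comfortably finer than the effects under
test while keeping a full run in minutes on one CPU.

## Known limitations

* Gaussian (t-corrected) tails cannot capture genuinely non-Gaussian
  real-world features; deep tail p-values (10⁻¹⁰ and beyond) should be
  read as "far outside the norm", not as literal probabilities.
* The artifact odds are feature-level (how often a feature fails in
  controls), not scan-level: a fresh artifact in a patient scan is not
  down-weighted.
* Asymmetry-driven detections do not by themselves lateralize (both
  hemisphere pools rise); interpretation needs the hemisphere-specific
  rows.
* The 60-volume catalog and the parcellation→lobe table are documented
  conventions; other sites may prefer different memberships, which
  changes sublobar/lobar matching.
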