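# Methods

## Study design being emulated

The package replicates, on synthetic data, a laboratory value-calibration of
a thigh-worn activity monitor (AP) against indirect calorimetry, with a
hip-worn accelerometer (AG) recorded concurrently. Thirty simulated
participants each complete, in order: 25 min rest lying, 5 min sitting,
5 min standing, 7 min slow walking, 7 min brisk walking and 7 min light
jogging. Devices report counts per 15 s epoch; VO₂ is epoch-averaged and
synchronized to the protocol start. Participants are split 15/15 into an
equation-development group and a cross-validation group by a seeded
permutation.

## Synthetic cohort generator

**What it emulates.** Per-activity AP counts, AG counts and MET scores with
the published development-group means and SDs:

| activity | AP counts/15 s | AG counts/15 s | MET |
|---|---|---|---|
| sitting | 5 (8) | 0 (1) | 1.1 (0.2) |
| standing | 15 (22) | 1 (2) | 1.1 (0.2) |
| slow walk | 3098 (858) | 632 (174) | 3.0 (0.7) |
| brisk walk | 5011 (869) | 940 (156) | 3.9 (0.8) |
| light jog | 11086 (1624) | 2368 (406) | 8.5 (1.9) |

Count marginals are Gaussian with these moments, clipped at zero (the
simplest distribution matching the printed moments; clipping is negligible
for locomotor activities, <1 % of draws, but material for near-zero count
profiles, whose realized means are the analytic clipped-normal moments). AP
and AG epoch counts share a bivariate-normal z-score at correlation 0.8
(default; not reported in the source study, exposed in
`GeneratorConfig.ap_ag_correlation`).

**Count→MET coupling.** Non-rest MET values follow a participant-varying
line applied to the AP counts:

    METᵢⱼ = (a + αᵢ) + (b + βᵢ)·countsᵢⱼ + εᵢⱼ

with the fixed line anchored so that it passes through (2997 counts/15 s,
3 MET) and (7428 counts/15 s, 6 MET) — b = 3/4431 ≈ 6.77×10⁻⁴ MET per
count, a ≈ 0.971 MET. These anchors are the two solved points of the
original calibration equation, which is the only form in which that
equation survives; the line is deliberately reverse-engineered from them
and nothing further is assumed about its source. The line also passes close
to the per-activity MET means in the table above (3.07 at the slow-walk
count mean, 8.48 at the jog mean), so drawing counts first and applying the
line honours the published MET summaries approximately; the brisk-walk mean
is the worst case (4.36 implied vs 3.9 tabulated), an internal tension of
the published summaries that the generator resolves in favour of the line.

Random effects are Gaussian: intercept SD 0.15 MET, slope SD 10 % of b
(plausible magnitudes; free parameters). The residual εᵢⱼ has total SD
`residual_met_sd` = 1.13 MET (one of the three SEE-like values reported for
the original fit — 1.13, 1.20 and 0.86 are all printed; they cannot
describe one fit, and 1.13 is used as the default epoch-level residual).
To give the configured within-activity count–MET correlation (default 0.7)
independent meaning, the residual is decomposed as
ε = s·(w·z_c + √(1−w²)·z⊥), where z_c is the count z-score and w is solved
per activity so that corr(counts, MET) hits the target where attainable
(for high-count activities the slope term alone already delivers ~0.7 and
w ≈ 0). Because E[ε | activity] = 0 regardless of w, activity-level means —
and hence the default calibration fit — are unbiased by this device.

MET values are floored at 0.1 so VO₂ stays positive; with a 1.13-MET
residual this floor lifts sedentary-activity means by ≈ 0.14 MET and shifts
the recovered moderate threshold a few percent below 2997, visible in the
replication medians.

**Rest.** Rest-bout MET is drawn N(1.0, 0.05) rather than from the count
line: the rest period defines the MET denominator, and a 1.13-MET residual
there would contaminate every MET score. Per-participant resting VO₂ is
uniform on 3.4–4.2 mL·kg⁻¹·min⁻¹ (consistent with a 4.2 mL·kg⁻¹·min⁻¹
sitting VO₂ at 1.1 MET; not reported directly).

**Posture streams.** The observer's record is exact per bout. The simulated
inclinometer lags bout transitions by `posture_transition_latency` epochs
(default 1, i.e. 15 s), carrying the previous bout's posture; corruption is
confined to that window. One lagged epoch never wins a 4-epoch minute
majority, so minute-level inclinometer agreement is 100 % at the default —
real inclinometers also misclassify within bouts, which this generator does
not emulate, so passing agreement tests bound the rule's structural
behaviour, not a real device's error rate.

**What the generator does not emulate.** Raw 10 Hz accelerations, VO₂
on-kinetics at bout starts (irrelevant: analysis uses final-2-min windows),
non-Gaussian count tails, device non-wear, and within-bout posture errors.
Conclusions from passing tests are about the statistical pipeline, not
about device hardware.

## Epoch processing

Breath-level VO₂ is averaged into half-open 15 s epochs aligned at protocol
start (empty epochs are omitted with a warning; a gap in a device epoch
stream is a hard error rather than being imputed — synthetic data never has
gaps, and silent imputation would mask generator bugs). Each non-rest bout
is summarized over its final 120 s (steady state); a shorter bout is an
error naming the bout. Resting VO₂ defaults to the session's stored value
and can be recomputed as the mean of the final 5 min of the 25 min rest
bout (`resting_vo2_from_rest_bout`) — the most settled portion; the exact
defining window is a free choice exposed as a parameter. Minutes are
non-overlapping 60 s bins aligned at protocol start, counts summed over
their four epochs, posture by majority with ties broken toward the earlier
epoch's label, partial trailing minutes dropped.

## Calibration model

Maximum-likelihood linear mixed model (statsmodels `MixedLM`): fixed
intercept and slope on counts, participant-level random intercept and slope
with a diagonal covariance (independence is the most parsimonious
structure; nothing in the design identifies the covariance well with 15
participants). ML rather than REML so nested-model comparisons (e.g.
covariate screening with age/height/weight) are valid. Counts are rescaled
by 10³ inside the fit for optimizer conditioning and transformed back.

Data granularity: the default fit uses per-activity steady-state means
(five points per participant), matching an analysis built on final-2-min
values; an epoch-level mode (every epoch in the steady-state windows) is
available. ROC analysis uses the same granularity as the fit.

Fit quality: Lin's CCC between observed MET and the fixed-effects
prediction, population-variance convention
2·cov(a,p)/(var(a)+var(p)+(ā−p̄)²); SEE = √(Σ(a−p)²/(n−2)) (regression
convention for the denominator). Thresholds: counts at which the fixed line
predicts 3 and 6 METs, reported exact and rounded; a non-positive slope is
a non-invertible calibration and an error.

Numerical notes: data lying exactly on one line put the variance components
on the boundary of the parameter space, where the mixed likelihood is
improper; this case is detected (max |residual| < 10⁻⁸ of the response
scale) and dispatched to pooled least squares with zero variance
components. Non-finite estimates raise with diagnostics rather than
returning silently.

## ROC thresholds and cross-validation

Candidate thresholds are midpoints between consecutive distinct scores plus
a sentinel below the minimum and above the maximum, so `score ≥ threshold`
treats observed values symmetrically. Sensitivity = fraction of positives
(MET ≥ anchor; the moderate positive class includes vigorous points, since
cut-points are cumulative) at or above the candidate; specificity =
fraction of negatives below it. AUC is the trapezoidal area over
(1−specificity, sensitivity), identical to the tie-adjusted
concordant-pair probability (verified exhaustively against a brute-force
oracle in the tests). The in-sample optimal threshold maximizes
sensitivity + specificity, ties broken by higher sensitivity then lower
threshold (the source analysis states no tie rule).

Cross-validation evaluates the two mixed-regression and two ROC-derived
thresholds on the held-out group. All candidates for one intensity share
the holdout's full-curve AUC, so selection ranks by AUC first (compared at
two decimals, the precision at which AUCs are reported) and then by the
sensitivity + specificity sum, reproducing the published selection logic.
The full ranked trail is retained in the report.

## Posture agreement

The comparison set is the sitting, standing and slow-walking bouts (the
region where a sedentary count rule is contested; brisk walking and jogging
are excluded). Observed and predicted minute categories form a 3×3
confusion matrix; overall agreement = 100·trace/total; sensitivity is
row-normalized, predictive value column-normalized. The identity
"overall = observed-count-weighted mean of sensitivities" is asserted on
every run. The AG rule maps a minute to sitting/lying when it accumulates
< 100 counts and to stepping otherwise — the only mapping consistent with
perfect sitting and walking detection alongside zero standing detection —
so its standing row is identically zero and its standing predictive value
is a 0/0 form, reported as 0 % with an explicit flag. Observation intervals
align with minute bins by construction here; for real logs a
majority-overlap snap is applied by the minute builder.

## Concurrent validity

Spearman correlation (mid-ranks for ties, scipy) between AP and AG
steady-state mean counts pooled over all participants and the five non-rest
activities (150 points at the default cohort size). The p-value uses the t
approximation and is reported, never used for gating.

## Problem sizes and determinism

Default cohorts are 30 participants × 224 epochs (~1 s to generate and
analyse end to end); replication medians use 20 seeded replicates, the
package's chosen desk-scale replication size. All randomness flows from
`GeneratorConfig.seed` through one `numpy` generator; identical configs
produce byte-identical cohorts and (timestamps aside) identical reports,
and the report's provenance block (config, hash, seed, granularity)
suffices to regenerate every number.

## Known limitations

- The fixed count→MET line is reconstructed from its two solved threshold
  points; intercept/slope uncertainty of the original equation is not
  propagated.
- Gaussian clipped-at-zero counts misstate the mean of near-zero count
  profiles (sitting/standing); all agreement results are insensitive to
  this, but sub-100-count dynamics are stylized.
- Published data-dependent values that depend on the real sample (CCC 0.93,
  holdout sensitivities of Table-3 type, SEE 1.20/0.86) are reproduced in
  structure and approximate magnitude only; the generator cannot and does
  not encode the original raw data.
- Free-living behaviour (wear time, bout fragmentation, posture errors
  within bouts) is out of scope.
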