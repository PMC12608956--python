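# Methods

## Setting

A health care professional (HCP) wearing several physical activity
trackers (PATs) walks 20 steps under each of 14 conditions that mimic the
low-impact gait of patients recovering from knee surgery (step size
25–100 % of normal; straight / 90°-turn / zigzag / 360°-circle paths;
forearm crutches; slippers).  After each walk the device count is compared
with the true (assistant-counted) number of steps.  The quantity of
interest is the **step count ratio** `observed / true`: near 1 when the
device detects the gait, near 0 when the gait is below the device's
detection limit, and unstable in between.  Each HCP performs the whole
protocol twice, so reproducibility can be assessed within raters
(round 1 vs round 2) and between raters.

The letter codes (S/T/Z/C/W/L) are never expanded by the protocol's
source materials; the mapping used here — S traight, T urn, Z igzag,
C ircle, W alking aid, L slippers — is inferred from the factor-level
ordering and the designation of S-75/S-40 as the two core conditions.
`parse_condition` accepts only the 14 protocol codes; `make_condition`
builds user-defined extensions (further conditions are an explicitly
invited use) but flags them as non-standard.

## Banded agreement and kappa

Ratios are not treated as fully quantitative.  Two ratios observed for the
same condition are compared through a banded weight with band edges at
0.2, 0.5 and 0.8:

| | low `[0,0.2)` | mid-low `[0.2,0.5)` | mid-high `[0.5,0.8]` | high `(0.8,∞)` |
|---|---|---|---|---|
| **low** | 1 | 1 | 0.5 | 0 |
| **mid-low** | 1 | 1 | 1 | 0.5 |
| **mid-high** | 0.5 | 1 | 1 | 1 |
| **high** | 0 | 0.5 | 1 | 1 |

The boundary convention (0.2 and 0.5 belong to the band above, 0.8 to
mid-high) is the unique assignment that turns the verbal weight clauses
into a partition without gaps or overlaps; for ratios that are multiples
of 1/20 only 0.5 and 0.8 ever land on an edge.

The *agreement rate* of a pair set is the mean weight.  It is
chance-corrected into `κ = (P_o − P_e) / (1 − P_e)` where `P_e` is the
expected weight under independent band draws.  By default `P_e` uses the
two pair-member marginal band distributions (Cohen's two-rater
convention); a pooled-marginal policy is available
(`chance_marginals="pooled"`) because the exact chance construction is
the main degree of freedom in this statistic — results for data near the
band edges can shift by a few hundredths between the policies.
Kappa reporting is suppressed when every ratio exceeds 0.5 (nothing but
detection left to agree on) or when the marginals are degenerate
(`P_e = 1`).  Verbal labels follow the conventional cut-offs 0.2 / 0.4 /
0.6 / 0.8 (poor ≤ 0 < slight ≤ 0.2 < fair ≤ 0.4 < moderate ≤ 0.6 <
substantial ≤ 0.8 < almost perfect).

**Pairing designs.**  Intra-rater: one pair per condition, round 1 vs
round 2 of the same participant (at most 12 pairs after cleaning).
Inter-rater: for every unordered participant pair and every round
combination — all four (1,1),(1,2),(2,1),(2,2) by default; a
cross-round-only toggle exists — a kappa is computed from the
condition-matched pairs and the headline value is the unweighted mean of
the non-suppressed kappas.  Averaging kappas (rather than pooling pairs)
keeps each rater pair's marginals intact; a suppressed combination is
excluded from the mean and counted, never imputed.

## Condition ICC

The quantitative companion models one pairing context's ratios as a
one-way random-effects layout with the conditions as random intercepts:
`ratio_cj = μ + b_c + e_cj`, `b_c ~ N(0, σ_c²)`, `e_cj ~ N(0, σ_r²)`;
`ICC = σ_c² / (σ_c² + σ_r²)`.  Components are estimated by REML,
maximising the restricted likelihood directly on the log-variance scale
(the compound-symmetric per-group covariance yields closed-form
determinants and quadratic forms; Nelder-Mead, tolerance 1e-8).  Negative
component estimates are truncated at zero at the REML boundary.  For
balanced designs with interior solutions the optimum coincides with the
classical one-way ANOVA estimator, which is also the fallback if the
optimiser fails; the equivalence is tested to 1e-6 and the fit is
cross-checked against an independent general mixed-model implementation.
Reporting is suppressed when the estimated condition SD is below 0.1 (no
meaningful condition signal).  The inter-rater ICC averages
per-participant-pair × round-combination fits (a pooled single fit is
available behind `pool=True`).

The ICC-recovery simulation uses 12 conditions × 4 replicates: with only
2 replicates per condition the zero-truncation inflates the mean ICC
estimate beyond ±0.1 of the truth at the smallest variance ratios, while
4 replicates keep the whole (σ_c, σ_r) ∈ {0.1, 0.3, 0.5}² grid within
that band.

## Condition effects: zero-inflated negative binomial

Device counts are modelled per PAT by a ZINB regression with the true
step count as exposure and the condition factor as the only covariate, in
both the count component (log link, `μ_c = true · exp(β₀ + β_c)`) and the
zero-inflation component (logit, `π_c`).  The two parts mirror the two
failure modes: a condition below the detection limit produces structural
zeros, a condition above it produces (possibly over-dispersed) miscounts.
Within-participant dependence — each rater contributes every condition
twice — is handled by a Huber-White sandwich covariance with participants
as clusters, not by random effects.

Numerical choices:

* estimation is staged — a negative-binomial fit on the positive counts
  provides starting values, Nelder-Mead finds the region, BFGS polishes —
  because the raw likelihood optimisation from default starts diverges
  (the dispersion runs negative when the data are nearly Poisson);
* a condition whose counts are *all zero* is a separable boundary
  component of the likelihood: its MLE is exactly π = 1, marginal mean 0.
  Such conditions are reported at the boundary (standard error 0) and
  excluded from the numerical fit rather than forced through the
  optimiser;
* perfectly separated inflation levels (conditions with no zeros at all)
  are left in the model; the sandwich bread uses a pseudo-inverse so the
  flat directions carry zero weight, which is harmless because the
  delta-method Jacobian of every reported quantity also vanishes there;
* if the data contain no zeros at all the model collapses to a plain
  negative binomial, flagged on the result;
* a global Wald test involving a boundary condition only uses the
  non-degenerate directions (rank-based degrees of freedom); in practice
  the remaining directions already carry the signal.

Reported quantities are **marginal means at 20 true steps**,
`E[count|c] = (1 − π_c) · 20 · exp(β₀ + β_c)`, with delta-method standard
errors from the cluster-robust covariance, plus: pairwise step-size
contrasts within each condition category, a joint equality test and a
linear step-size trend where a category has more than two levels (S),
category-vs-S contrasts at matched step sizes averaged over the sizes
present, and a global Wald test of equality of all condition means.
Large-sample normal / chi-square references are used throughout, the
usual practice for clustered sandwich inference; small-cluster
corrections are out of scope, so p-values at 14 clusters are approximate
(the simulation-based calibration of the global test is run at 100
clusters, where the rejection rate under the null is required to be
within [2.5 %, 8 %] at nominal 5 %).

## Synthetic data generator

The generator exists so every stage is testable by parameter recovery.
Each PAT × condition cell carries a `DetectionScenario` in one of the
three regimes the protocol aims to expose (detectable / near-limit /
undetectable), parameterised by zero-probability, mean ratio and NB2
dispersion.  On top of the zero-inflated count draw:

* a log-normal participant effect, shared across conditions within a PAT,
  models rater-level heterogeneity (per-PAT SD);
* occasional additive Poisson overcount bursts let ratios exceed 1.5 —
  the mechanism is invented, but some mechanism is needed because such
  ratios occur;
* `off_by_one` subtracts one step per walk (the sole sensor's half-step
  behaviour at start and end);
* the true step count jitters around 20 (19/21 with probability 0.05
  each) because raters cannot be forced to an exact count;
* near-perfect sensors use a binomial per-step detection model instead of
  the NB: an NB count can never be less variable than Poisson (SD ≈ 4.5
  steps at mean 20), which would contradict the tight ratio
  distributions these devices produce.  All recovery tests of the ZINB
  machinery use the NB regimes.

`preset_study_like()` encodes the study-sized configuration: 14
participants × 2 rounds × 14 conditions × 4 PATs; a near-perfect sole
sensor with the one-step undercount; a near-perfect knee sensor whose app
fails for 9 of 14 participants; a trouser-pocket sensor with strongly
step-size-dependent detection (undetectable at 25–40 %, near the limit at
75 %, crutches shifting detection further down); a wrist sensor with mild
condition effects but strong participant heterogeneity (effect SD 0.35);
an unusable first round for participant 1; slippers for only four
participants.  No distributional parameters for any sensor were ever
reported, so the preset values are illustrative choices that land in the
documented regimes — passing tests show that the *machinery* recovers
what the generator put in under study-like structure, not that these are
the true device characteristics.  Real data differ in ways the generator
does not model: gait-to-gait serial correlation, instructor effects,
condition-order (learning) effects, and miscounted ground truth.

## Cleaning rules

Slipper conditions are dropped entirely (too few participants brought
slippers); records with an empty device reading are dropped with a
per-tracker count (a recorded 0 is data, never missingness); ratios above
3.0 are flagged but retained (overcounting is a device behaviour);
cleaning is idempotent and every exclusion is logged.  Trackers whose
ratios show too little variation to support reproducibility analysis —
by default ≥ 95 % of ratios within [0.9, 1.1] — are excluded from the
kappa/ICC/ZINB stages with a logged reason; the threshold is a
configurable operationalisation of "very limited variation" chosen to
separate the near-perfect sensors from the others without naming devices.

## Problem sizes used in validation

Agreement-rate oracle equivalence: 1,000 random pair sets.  Kappa
calibration: 10,000 independent pairs.  ICC recovery: 200 datasets per
grid point, 12 × 4 design.  ZINB recovery: 200 participants; null
calibration of the global test: 400 simulated studies of 100
participants × 4 conditions.  The study-like pipeline runs at the study's
own size (14 participants).

## Known limitations

* The chance-agreement construction for the banded kappa follows Cohen's
  two-rater principle; other constructions are defensible and the policy
  toggle is the single biggest lever on inter-rater kappa values.
* ICC confidence intervals and kappa bootstrap intervals are not
  implemented (point estimates with suppression rules only).
* Sandwich inference at 14 clusters is approximate; no small-cluster
  degrees-of-freedom correction is applied.
* The generator's overcount mechanism and all preset magnitudes are
  illustrative; only the regime structure is anchored to observed
  behaviour.
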