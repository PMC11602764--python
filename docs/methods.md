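# Methods

## The screening model

`lqrscreen` implements a "passive" screening chain for cognitive
impairment built entirely from response-quality information in brief
Likert questionnaires.

**Graded response model.**  Each questionnaire scale is modelled as a
unidimensional Samejima GRM.  Item $i$ with $K_i$ ordered categories has a
discrimination $a_i>0$ and thresholds $b_{i1}<\dots<b_{i,K_i-1}$;
cumulative boundary probabilities are logistic in
$a_i(\theta-b_{ik})$, and category probabilities are their adjacent
differences.  Estimation is marginal maximum likelihood by EM: the E-step
computes posterior weights over a quadrature grid under a standard-normal
latent prior; the M-step maximises each item's expected complete-data
log-likelihood with L-BFGS on the $(\log a_i, b_{i1}, \log\text{gaps})$
parameterisation, which enforces positivity and threshold ordering by
construction.  The normal prior anchors the trait scale (no post-hoc
standardisation), and the marginal log-likelihood is non-decreasing across
iterations — asserted in the test suite to 1e-8.

Assumptions: unidimensionality within a scale, local independence given
$\theta$, missing-at-random skips (skipped items are simply dropped from
the likelihood).  One GRM is fitted per questionnaire; a respondent's
$\theta$ is always estimated from the same scale whose fit indices are
being computed.

**Quadrature.**  Default: 61 equally spaced nodes on $[-6, 6]$ with
trapezoid end-weights times the normal density.  Because the integrand
decays like the normal tail at the bounds, this rule is spectrally
accurate; EAP means and posterior SDs agree with a 10,001-node dense-grid
integration to better than 1e-6 (tested).  Gauss–Hermite is available as
an alternative scheme.

**Category coding.**  Categories are coded $0..K-1$ and the expected
response $E[X\mid\theta]=\sum_k k\,P_k(\theta)$ is computed on that
coding.  This matters: the squared-residual index scales quadratically
with the coding, so banks and responses must share it.

**LQR indices.**  Two per-item person-fit quantities, computed at the EAP
trait: the squared residual $s_{ij}=(x_{ij}-E[X_i\mid\theta_j])^2$ and the
observed-response probability $p_{ij}=P_{i,x_{ij}}(\theta_j)$.  By
default each item contributes both as separate predictors (12 columns for
a 6-item scale); per-scale aggregates (mean $s$, mean $\log p$) and a
log-probability transform sit behind flags.  Conditioning on $\theta$
removes content (a genuinely pessimistic respondent giving consistent
pessimistic answers is *not* flagged), isolating statistical misfit.

**Outcome labels.**  Cognition scores on the 0–27 scale map to dementia
(0–6), cognitively impaired without dementia (7–11) and normal (12–27);
the binary screening label collapses the first two bands.

**Imputation.**  Missing item responses are completed by regression-based
iterative (chained) imputation — each variable with missing entries
regressed on the rest, round-robin, initialised at column medians, default
max 10 rounds, tolerance 1e-3 — then rounded and clipped to the valid
category range.  Observed entries are never altered.  Imputation runs
before GRM fitting by default (`impute_target: responses`); imputing the
LQR features instead is supported because response-level imputation
attenuates the skipping signal.  This tension is inherent to the design:
a skipped item is itself an LQR act, but downstream classifiers need
complete predictor rows.

**Risk models.**  The primary classifier is a multilayer perceptron with
four ReLU hidden layers (default widths 64/32/16/8), batch normalisation
and dropout (0.2) after each hidden layer, and a sigmoid output whose bias
is initialised to the training-prevalence log-odds.  Training minimises
class-weighted binary cross-entropy (weights $n/(2n_c)$) with Adam
(initial step 1e-3), halves the learning rate after 3 epochs without
validation-AUC improvement, and stops after 10, restoring the best-epoch
weights.  Batch normalisation lets raw, unscaled features be fed directly.
The training regime repeats a stratified 80/20 train/validation split ten
times with fold seeds derived from one master seed; the fold with the best
validation AUC is retained, and the pooled validation predictions feed
threshold selection.  Baselines (logistic regression, decision tree,
histogram gradient-boosted trees, and a raw-response logistic model) are
grid-searched on cross-validated AUC and refitted.

The network is a compact numpy implementation — adequate for these
tabular problem sizes (d ≤ ~60, n ≤ ~10⁴ on one CPU) and exactly
serialisable to JSON.

**Threshold rule.**  Candidate thresholds are $\{0,1\}$ plus midpoints
between adjacent distinct scores; the rule minimises $r\cdot FN+FP$ and
breaks ties towards the largest threshold (fewest referrals).  Referral is
strict (`score > t`).  For calibrated scores the optimum approaches
$1/(1+r)$, which the tests verify within ±0.05; thresholds are
non-increasing and referral counts non-decreasing in $r$.  Thresholds are
tuned on pooled validation predictions, never on the held-out test
partition.

**Evaluation.**  AUC is the tie-aware Mann–Whitney probability.  The
efficiency curve sweeps the same candidate-threshold set as the decision
rule (so the two agree pointwise) and plots proportion referred against
proportion of impaired identified; rule-based strategies (age ≥ 65,
diabetes, high blood pressure, heart disease, stroke) are single points in
that plane.  Stratified reports repeat AUC and the referral proportions in
the decade age bins 50–59/60–69/70–79/80+; a single-class bin reports a
missing AUC rather than a placeholder.

## The synthetic cohort generator

The generator emulates the structure of a large community aging survey:
four brief well-being scales (optimism 6 items, hopelessness 7, purpose 7,
each 6-point; life satisfaction 5 items, 7-point), ~18% impairment
prevalence, ages 50+ in decade bins (shares 0.207/0.327/0.312/0.154),
roughly 1–2% item missingness, and disease indicators with realistic
prevalences for the rule-based comparators.  Item discriminations are
drawn from [0.8, 2.5] and thresholds span [-2.5, 2.5].  Each scale gets an
independent latent trait per respondent (impaired mean shifted by
`trait_impairment_shift`); responses are, per item, careless (uniform
category, or a straight-line repeat of the previous answer), skipped
(missing), or honest GRM draws.

Default study conditions:

| parameter | default | meaning |
|---|---|---|
| `prevalence` | 0.18 | impairment share |
| `careless_rate_normal` | 0.05 | per-item careless probability, normal |
| `careless_rate_impaired` | 0.45 | per-item careless probability, impaired |
| `skip_rate_normal` / `_impaired` | 0.01 / 0.03 | per-item skip probability |
| `straightline_fraction` | 0.25 | careless acts that repeat the previous category |
| `trait_impairment_shift` | −0.1 | mean trait offset for impaired |
| `age_impairment_log_or` | 0 | age–impairment association (off by default) |

The careless and trait defaults were calibrated so the synthetic cohorts
reproduce the qualitative signal structure this method is designed for:
questionnaire *content* is nearly uninformative about impairment (a
raw-response logistic baseline reaches only ~0.54–0.58 AUC), while
response *quality* carries the signal (LQR-feature models reach
~0.62–0.68 at n of a few thousand).  Two findings from that calibration
are worth recording.  First, straight-lining is largely invisible to
GRM person-fit indices: a straight-liner looks like a coherent respondent
with an extreme trait, so the indices mostly detect random/contradictory
answering — hence a modest default straight-line share.  Second, a large
trait shift hands content signal to the raw baseline and inverts the
ordering the method relies on, so the default shift is small.

What the generator does **not** emulate: real item wording and real item
parameter distributions, survey weights, proxy respondents,
"don't know" as a distinct category (it is treated as missing),
within-respondent correlation of carelessness over time, response-time
paradata, and any dependence of careless *style* on trait level.  Passing
tests therefore demonstrate internal validity of the method and its
implementation, not field performance on any particular survey.

The ten-year dementia-or-mortality secondary label is generated from a
logistic model (intercept −2.2, impairment +1.0, +0.6 per decade over 65)
chosen to give a plausible event rate; it is plumbing for workflows with a
longitudinal outcome, not a calibrated epidemiological model.

## Numerical and design choices

* EM convergence: relative log-likelihood change < 1e-6, max 500
  iterations.  Items whose observed responses collapse onto a single
  category raise an estimation error naming the item.
* EAP for an all-missing row returns the prior (θ=0, SD 1).
* Probability indices are floored at 1e-300, keeping them in (0, 1] so a
  log transform is always defined.
* Stratified splits allocate `round(n_stratum × fraction)` per stratum;
  single-member strata are warned into the training partition.
* Tie-break in threshold selection favours fewer referrals; the
  exhaustive-scan oracle in the tests enforces exact agreement.
* All stage seeds derive from one master seed via SHA-256, and artifacts
  are written with sorted keys and fixed float formatting, so identical
  configurations produce byte-identical outputs (hashed in the manifest).

## Problem sizes used in tests and the acceptance script

Parameter-recovery checks run at n=3000 (6 items, 6 categories); EAP
oracle checks at n=100 against a 10,001-node grid; the repeated-seed
validity and ordering checks run 20 seeds of an end-to-end pipeline at
n=1200 with a single 6-item scale and a logistic risk model — sizes at
which the checks are stable and the suite stays quick.  The acceptance
script runs the full four-scale pipeline at n=6000 with the ten-fold MLP
regime.

## Known limitations

* At these sample sizes the MLP holds no advantage over logistic
  regression on LQR features — deep models need more data and tuning to
  separate themselves; both are reported by the acceptance script.  The
  MLP remains the reference architecture of the deployed method.
* Per-bin AUCs in old-age strata are intrinsically lower when age itself
  predicts impairment (the within-bin signal is what remains after
  conditioning on age).
* GRM person-fit cannot detect straight-lining well (see above); a
  dedicated invariability index (e.g. within-respondent SD) would be the
  natural extension.
* Single imputation, not multiple; imputation-induced attenuation of the
  skip signal is unquantified.
* No differential item functioning, multidimensional traits, or survey
  weighting.
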