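# lqrscreen

Passive cognitive-impairment screening from **low-quality questionnaire
responding** (LQR).

Community health workers routinely administer brief well-being
questionnaires — optimism, hopelessness, purpose in life, life
satisfaction — whose content has nothing to do with cognition.  Yet *how*
older adults answer them carries signal: skipped items, contradictory or
random category choices, and straight-lined answers are all more common
among people with cognitive impairment.  `lqrscreen` turns that signal into
a screening instrument:

1. **Graded response model (GRM).**  For each questionnaire a Samejima GRM
   is fitted by marginal maximum likelihood.  With discrimination $a_i$ and
   ordered thresholds $b_{ik}$, the boundary curves are
   $P^*_{ik}(\theta)=\mathrm{logistic}\!\big(a_i(\theta-b_{ik})\big)$ and
   category probabilities are $P_{ik}=P^*_{ik}-P^*_{i,k+1}$.  Each
   respondent's latent trait $\theta_j$ is scored by its EAP posterior mean
   under a standard-normal prior, which strips questionnaire *content* out
   of the next step.
2. **LQR person-fit indices.**  Per respondent $j$ and item $i$:
   the squared residual $s_{ij}=(x_{ij}-E[X_i\mid\theta_j])^2$ and the
   observed-response probability $p_{ij}=P_{i,x_{ij}}(\theta_j)$.  Large
   $s_{ij}$ and small $p_{ij}$ flag statistically improbable answers
   irrespective of what the questions ask.
3. **Risk models.**  A class-weighted multilayer perceptron (four ReLU
   hidden layers, dropout, batch normalisation, prevalence-initialised
   sigmoid output, Adam with reduce-on-plateau, early stopping on
   validation AUC) plus logistic-regression, decision-tree,
   gradient-boosting and raw-response baselines, trained under a repeated
   stratified 80/20 cross-validation regime.
4. **Cost-ratio referral threshold.**  Predicted risks are cut at the
   threshold minimising $r\cdot FN + FP$, where $r$ (default 4) is the cost
   of underdiagnosis relative to one unnecessary follow-up assessment.
5. **Efficiency evaluation.**  Screening strategies are compared in the
   (proportion referred, proportion of impaired identified) plane against
   rule-based comparators such as "refer everyone aged 65+".

Because real cohort data of this kind are access-restricted, the package
ships a first-class synthetic-cohort generator with known item banks,
latent traits, impairment labels and injected LQR behaviours, so every
stage can be validated against ground truth.

## Worked example

```python
from lqrscreen.pipeline import RunConfig, run_pipeline

cfg = RunConfig.model_validate({
    "cohort": {"n_respondents": 2000, "age_impairment_log_or": 0.6},
    "features": {"scales": ["optimism"], "include_demographics": True},
    "model": {"kind": "mlp"},
    "seed": 7,
})
result = run_pipeline(cfg, "out/")
print(result.report.summary())
```

prints

```
Screening evaluation (mlp; features: optimism+demographics)
  AUC: 0.701
  cost ratio 4 -> threshold 0.3367
  referred: 130/600 (21.7%)   impaired identified: 50/112 (44.6%)
  by age group:
    50-59  n=  102  impaired=   8  AUC=0.626  referred=  0.0%  identified=  0.0%
    60-69  n=  200  impaired=  23  AUC=0.527  referred=  5.0%  identified= 13.0%
    70-79  n=  188  impaired=  43  AUC=0.649  referred= 25.5%  identified= 44.2%
    80+    n=  110  impaired=  38  AUC=0.614  referred= 65.5%  identified= 73.7%
```

Reading: on a simulated 2,000-person cohort (18% impairment prevalence,
age associated with impairment), the MLP trained on the optimism scale's
12 LQR features plus age and gender reaches test AUC 0.70.  At the default
cost ratio of 4 the tuned threshold refers 21.7% of the held-out cohort
for follow-up assessment and catches 44.6% of the impaired — with referral
concentrating, as it should, in the oldest age bins.

The same workflow is available from the shell:

```bash
lqrscreen run --config cfg.yaml --out out/
lqrscreen simulate --out sim/ --seed 1 --n 2000
lqrscreen fit-grm --responses sim/responses.csv --items optimism_1,...,optimism_6 --out bank.json
lqrscreen threshold --scores scores.csv --cost-ratio 4
```

Every run writes a manifest of seeds and artifact hashes; identical
configurations reproduce byte-identical outputs.

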