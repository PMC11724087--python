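# phenorisk

Phenome-wide disease-onset risk from binary medical-history records.

Routinely collected health records — diagnoses, prescriptions, procedures,
observations — carry substantial information about an individual's risk of
future disease across essentially every clinical specialty. `phenorisk`
implements a complete analysis pipeline for exploiting that information:

1. **Risk model.** A multi-task proportional-hazards neural network maps an
   individual's binary pre-recruitment record vector *x* ∈ {0,1}^C to one
   log partial hazard per disease endpoint ("risk state"),
   s_j(x) = f_j(x), trained with an adapted Cox partial-likelihood loss.
   Within each minibatch and endpoint *j*,

       L_j = −(1/E_j) Σ_{i: event} [ s_ij − log Σ_{k: t_k ≥ t_i} exp(s_kj) ],

   with Breslow handling of ties and in-batch risk sets; the total loss is
   Σ_j L_j. Endpoints with no in-batch events contribute zero. A linear
   variant serves as a baseline.
2. **Spatial validation.** Leave-one-center-out nested cross-validation:
   each recruitment center is held out once as a test partition, a random
   10% of the remaining data validates checkpoint selection, and every
   individual's risk state comes from the one model that never saw their
   center.
3. **Downstream Cox integration.** Per endpoint, Cox proportional-hazards
   models on covariate sets (age+sex; age+sex+risk state; optionally binary
   comorbidity indicators) convert the shift-invariant risk state into
   absolute 10-year risks via the Breslow baseline cumulative hazard,
   P(T ≤ h | x) = 1 − exp(−H₀(h) e^{x'β}). The *predisposition* of an
   individual is the ratio of their full-model 10-year risk to their
   age/sex-only estimate.
4. **Evaluation.** Percentile stratification with top/bottom-decile
   incident-event ratios, Harrell's C-index truncated at 10 years,
   paired-bootstrap model comparison with Bonferroni-adjusted percentile
   intervals, Kaplan–Meier cumulative event curves and phenome-wide
   summaries.
5. **Emerging threats.** Temporal-cutoff retraining (no record after the
   cutoff enters training or inference) and an unweighted composite
   severity score — the mean of standardised risk states for
   pneumonia-like, sepsis-like and all-cause-death endpoints — evaluated
   against age for a novel outcome.
6. **Attributions.** Permutation-sampling Shapley values per record concept
   and endpoint, with local (mean) and global (sum) aggregation.

Real population cohorts with linked health records are access-restricted,
so the package ships a first-class synthetic cohort generator
(`phenorisk.simulate`) that reproduces the statistical structure the
analysis assumes — sparse binary concepts with log-uniform prevalence,
latent-factor comorbidity linking records to multiple proportional-hazards
endpoints, age/sex effects, 22 recruitment centers with mild covariate
shift, administrative censoring, prior-event exclusions and a
distribution-shifted external cohort — together with the ground-truth log
hazards needed for recovery tests.

## Worked example

```python
import numpy as np
from phenorisk import (SimConfig, ModelConfig, MultitaskCoxPH, generate_cohort,
                       build_covariates, fit_cph, harrell_c, bootstrap_delta_c,
                       assign_percentiles, incident_event_ratio)

cfg = SimConfig(n_individuals=6000, n_concepts=150, n_endpoints=8,
                n_centers=4, seed=3)
cohort, vocab, matrix, events, truth = generate_cohort(cfg)
X = matrix.toarray()

model = MultitaskCoxPH(X[:4500], events.time[:4500], events.event[:4500],
                       config=ModelConfig(max_epochs=25, patience=3, seed=0))
res = model.fit()
print(res.summary())
```

```
Multi-task proportional-hazards network
=============================================
variant:           mlp
input concepts:    150
endpoints:         8
hidden layers:     3 x 128
parameters:        54,152
epochs run:        15
selected epoch:    11
init val loss:     49.9023
best val loss:     46.7302
```

Integrating the held-out risk state into a Cox model and comparing it with
an age+sex baseline:

```python
held = np.arange(4500, 6000)
risk = res.predict(X[held])
j = 1                                   # endpoint E001
ok = ~events.prior_event[held, j]       # eligibility: no prior event
age, sex = cohort.age_at_recruitment[held][ok], cohort.sex[held][ok]
t, e = events.time[held, j][ok], events.event[held, j][ok]
df_base, _ = build_covariates(age, sex)
df_full, _ = build_covariates(age, sex, risk[ok, j])
lp_base = fit_cph(df_base, t, e).linear_predictor(df_base)
lp_full = fit_cph(df_full, t, e).linear_predictor(df_full)
delta, ci, sig = bootstrap_delta_c(lp_full, lp_base, t, e, n_boot=200, seed=1)
bins = assign_percentiles(risk[:, j], ok)
r = incident_event_ratio(events.event[held, j] & ok, bins)
```

This prints (via the obvious f-strings):

```
E001: C(age+sex) = 0.588, C(age+sex+risk state) = 0.737
delta C = +0.148, 95% CI (0.094, 0.196), significant: True
incident events top decile: 28, bottom decile: 1, ratio 30.15
```

The risk state lifts the truncated C-index of this endpoint from 0.588 to
0.737 — a significant improvement over demography alone — and individuals
in the top decile of the risk state have ~30× the incident event count of
the bottom decile.

The full pipeline (simulate → leave-one-center-out training → Cox
integration → evaluation) runs from the command line:

```bash
phenorisk run-all --seed 17 --out my_run
```

and writes cohort files (TSV + MatrixMarket), the fold plan, per-endpoint
risk states, Cox fit summaries, an evaluation table and a Markdown report
into `my_run/`.

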