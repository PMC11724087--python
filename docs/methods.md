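# Methods

## The model

The core object is a multi-task proportional-hazards network. Each
individual is represented by a binary vector x ∈ {0,1}^C indicating which
clinical concepts (conditions, drugs, procedures, observations,
measurements, devices) were ever recorded before recruitment. The network
f: {0,1}^C → R^J outputs one score per endpoint, interpreted as the log
partial hazard of a Cox model: λ_j(t | x) = λ_{0j}(t) exp(f_j(x)). Scores
are shift-invariant per endpoint — only differences between individuals
matter — which is why every downstream use either ranks them (C-index,
percentiles) or re-anchors them through a Cox fit (absolute risk).

Architecture: a shared stack of fully connected layers (default 3), each
followed by layer normalisation, dropout and a leaky-ReLU activation, and a
linear head mapping the last shared representation to one score per
endpoint. The shared trunk acts as a regulariser: features must be useful
for many diseases at once. A `linear` variant (single linear map) is the
complexity baseline. The reference configuration uses 4096 hidden units;
the desk-scale default is 128 units, which preserves the architecture's
shape while keeping single-CPU runs in seconds to minutes.

### Loss

Per minibatch and endpoint j, the loss is the negative log partial
likelihood with in-batch risk sets, averaged over that endpoint's in-batch
events, and the per-endpoint losses are summed:

    L_j = −(1/E_j) Σ_{i∈batch: event} [ s_ij − log Σ_{k∈batch: t_kj ≥ t_ij} exp(s_kj) ],
    L   = Σ_j L_j.

Tied event times share the full tied risk set (Breslow convention),
matching the tie handling of the downstream Cox fits. Endpoints with no
in-batch event contribute exactly zero. Two deliberate choices here:

- **In-batch risk sets** approximate the full-cohort partial likelihood;
  the batch size (default 512) is the accuracy knob. This is the standard
  neural-Cox device and is what makes stochastic training possible.
- **Event-mean, then endpoint-sum.** Averaging each endpoint's event terms
  before summing makes rare and common endpoints contribute on comparable
  scales; the alternative (summing raw event terms) would let common
  endpoints dominate the gradient. The per-endpoint normalisation is the
  one genuinely ambiguous design point; the event-mean was chosen and is
  fixed throughout.

Training uses Adam (lr 6e-4) with decoupled weight decay (0.3) on the
weight matrices, seeded shuffling, and early stopping on a held-out
validation loss; the returned model is the checkpoint with minimum
validation loss. `patience = 0` trains exactly one epoch and returns that
checkpoint. Training deliberately uses all individuals regardless of
prior-event status (a masked-training flag exists); eligibility exclusions
apply to every *downstream* analysis instead.

The implementation is plain numpy with analytic gradients (the Cox-loss
gradient and layer-norm backprop are exact; both are verified against
finite differences in the test suite).

## Spatial validation

`make_fold_plan` builds one fold per recruitment center: that center is the
test partition, and a simple random 10% of the pooled remaining centers is
the validation set (seeded, recorded in provenance). `run_nested_cv` trains
one model per fold and assembles the out-of-fold risk-state matrix, so each
individual is scored by the single model that never saw their center;
provenance records the source fold. External transfer freezes the fold
models and scores a new cohort with the mean of their predictions; concepts
absent from the external vocabulary are zero-filled (the frozen-model
contract), and only the age+sex baseline is refit externally.

A property worth knowing: with the nonlinear variant trained for few
epochs, the *mean* of fold-model predictions systematically discriminates
slightly better than the single out-of-fold predictions (ensemble variance
reduction of noisy weights; paired-bootstrap ΔC ≈ +0.05 at desk scale).
The equivalence of transferred means and out-of-fold predictions — the
regime the transfer test asserts — holds when fold models are trained to
convergence, where they nearly coincide; the test uses the converged linear
variant for that reason.

## Downstream Cox integration

Per endpoint and covariate set (age+sex; age+sex+risk state; optional
binary comorbidity indicators), a Cox model is fitted on eligible
individuals (no prior event; sex compatible). Fitting is delegated to
lifelines' `CoxPHFitter` with an escalating step-size fallback
(0.5 → 0.1 → 0.01) for hard likelihoods; constant or collinear design
columns raise an explicit degeneracy error first. Continuous covariates
(age, risk state) are standardised with moments learned on training data
and frozen before any held-out application. The Breslow baseline cumulative
hazard at x = 0,

    H₀(t) = Σ_{t_i ≤ t} d_i / Σ_{k: t_k ≥ t_i} exp(x_k'β),

is computed directly from its defining sum (with β = 0 it reduces exactly
to the Nelson–Aalen estimator), giving absolute risk
1 − exp(−H₀(h) e^{x'β}) at horizon h (default 10 years). The
predisposition ratio divides an individual's full-model 10-year risk by
their own age/sex-only estimate; the high-risk flag requires ratio > 2
and absolute risk > 10%.

## Evaluation conventions

- **Truncated C-index.** Follow-up is clipped at the horizon (default 10
  years); events after the horizon count as censored at the horizon. A pair
  is comparable when the shorter time is an event and the times differ;
  tied scores count one half. This matches the standard estimator on
  tie-free data (cross-checked against lifelines).
- **Percentile bins** are assigned by ordinal rank with a stable tie-break
  on input order: sparse binary inputs produce heavy score ties, and a
  randomised break would cost reproducibility. Bin sizes differ by at most
  one.
- **Incident-event ratios** compare event *rates* between percentile bands
  (top 91–100 vs bottom 1–10 by default; a top-vs-median variant uses
  41–60), reducing to count ratios for equal band sizes. A zero-event
  bottom band reports +inf with counts preserved.
- **Model comparison** uses paired bootstrap resampling of individuals
  (default 1000 iterations; a 100-iteration fast mode exists for
  exploratory runs), a percentile CI at Bonferroni-adjusted level
  1 − α/m, and calls models different when the CI excludes zero. BCa was
  not used; the percentile interval is transparent and adequate at these
  resample counts.
- **Kaplan–Meier** curves and Greenwood CIs come from lifelines.

## The synthetic cohort generator

The generator is the package's study condition, not a demo. A K-dimensional
latent factor u_i ~ N(0, I) expresses comorbidity structure: concepts
activate with probability logistic(b_c + w_c·u_i + a_c·age_z), and
endpoint hazards follow η_ij = b_age_j·age_z + b_sex_j·sex + v_j·u_i with
exponential event times T ~ Exp(λ_{0j} e^{η_ij}) (Weibull optional) and
administrative censoring uniform over the follow-up range. Defaults:
20,000 individuals, 500 concepts, 20 endpoints, K = 5, 22 centers,
log-uniform concept prevalence in [2·10⁻⁴, 0.3] (many concepts below the
50-carrier rarity filter, mirroring the long rare tail of real
vocabularies), follow-up 11–14 years, per-endpoint target incidence
log-uniform in [0.02, 0.15], prior-event base rate 5%, ±2-year center
age shifts. Loadings are sparse — each concept on 1–2 latent factors, each
endpoint on 1–3 — giving clustered comorbidity without claiming semantic
realism.

Two calibrations keep the marginals honest: per-concept intercepts b_c are
bisected (on a subsample) so empirical prevalence matches the drawn p_c
despite the latent noise, and per-endpoint baseline rates λ_{0j} are
bisected so the mean cumulative incidence at the mean administrative
horizon hits the target within 1e-6. Prior events are drawn independently
of the incident-time mechanism except through the shared η (a documented
simplification); because the link is logistic in raw η, strong latent
signal concentrates prior events among high-hazard individuals — exactly
the selection effect real prior-event exclusions produce, and the reason
very strong `signal_strength` settings starve eligible analyses of events.
The external cohort shares all truth parameters and shifts only marginals:
prevalence odds (globally or per domain), mean age, and a shortened
follow-up window (~3 years), emulating transfer to a younger, more
recently recruited population.

What the generator does **not** emulate: real coding semantics and
care-pathway sequences, coding-practice drift over time, informative
censoring, competing risks, and measurement values (records are binary
presence indicators). Passing tests therefore demonstrate correctness of
the machinery and recoverability under the stated generative assumptions —
not clinical performance on any real population.

## Emerging-threat composite

Temporal-cutoff retraining converts the calendar cutoff to per-individual
"years before recruitment" windows and drops every record dated after it;
training keeps time zero unchanged and the threat outcome window begins
after the cutoff. The composite severity score is the unweighted mean of
per-component z-scores of the selected endpoint risk states
(pneumonia-like, sepsis-like, all-cause death by convention). Raw log
partial hazards are shift-invariant and live on incomparable scales across
endpoints, so per-component standardisation over the scored population is
required before equal weighting; a raw-mean option exists
(`standardize=False`). The median stratum for Kaplan–Meier display is
percentiles 48–52.

## Shapley attributions

Per individual, endpoint and concept, attributions use the
permutation-sampling estimator: each sample draws a feature permutation and
a background row, builds the C+1 prefix states, and credits each feature
its marginal model-output change; averaging over samples converges to the
exact Shapley value of v(S) = E_z[f(x_S, z_{S̄})], with Monte-Carlo SE
shrinking as 1/√n. The background set is a seeded random subsample of the
evaluation cohort (default 100 rows) — the reference distribution is a free
choice and this one matches "attribution relative to a typical individual".
Local attributions average over selected individuals (typically those
without prior events); global attributions sum. Top-k tables break ties by
concept id for reproducibility.

## Orchestration and determinism

A run is reconstructable from its YAML config and one global seed, fanned
out to stage seeds via CRC-32 of the stage name so stages can be rerun
independently. All randomness flows through `numpy.random.default_rng`
with explicit seed sequences; two runs with one seed produce byte-identical
evaluation tables. Artifacts (TSV tables, MatrixMarket record matrix,
fold plan, checkpoints, provenance JSON, Markdown report) live in one
directory per run.

## Problem sizes in the test and acceptance suites

The suites run at desk scale by design: the default 20,000 × 500 cohort
for signal-recovery checks; twenty 8,000-individual replicates (default
generator structure) for the discrimination-significance property, each
evaluated on the strongest-loading endpoint among those with ≥100 eligible
pre-horizon events in the held-out third (endpoints without events cannot
power a bootstrap comparison); a 6,000-individual 4-center cohort for
transfer; and a 2,000 × 100 smoke configuration for end-to-end
determinism. The held-out Spearman floor (0.25) asserted for endpoints
with ≥200 test events was fixed once from an oracle run at the pinned
seeds and left alone thereafter.

## Known limitations

- The network is trained on binary ever-recorded indicators; record
  recency enters only through ablation/cutoff operations, not as a model
  feature.
- In-batch risk sets bias the partial likelihood for very small batches;
  batch size 512 makes this negligible at desk scale but the approximation
  is inherent.
- The comorbidity covariate set is a configurable list of binary concept
  indicators, a structural stand-in for published comorbidity indices
  (whose weights are out of scope).
- Exact Shapley values are only computed for tiny feature counts (test
  oracles); production attributions are Monte-Carlo estimates with
  reported SEs.
- lifelines' Cox fitter can fail to converge on severely separated data
  even with the smallest step size; the error surfaces with diagnostics
  rather than being silently absorbed.
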