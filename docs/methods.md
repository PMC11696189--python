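# Methods

This note documents the models, procedures and numerical choices behind
`tildyn`, in the package's own terms: what is computed, under which
assumptions, and what the synthetic experiments do and do not show.

## 1. Daily TIL-Basic scoring

TIL-Basic for a calendar day is the maximum ICP-control class (0 none,
1 basic, 2 mild, 3 moderate, 4 extreme) over the treatments administered
that day.  Two conventions:

* **Carry-forward.** A decompressive craniectomy performed as a last
  resort for refractory intracranial hypertension scores 4 on the day of
  the operation and on every subsequent day of the stay.  Other
  intracranial operations (e.g. evacuation of a progressive mass lesion)
  score 4 on the day only.
* **WLST censoring.** Scores are removed on and after the day of a
  decision to withdraw life-sustaining therapies; model variables are
  likewise only taken before that day.

Temperature boundary: cooling for ICP control at ≥ 35 °C is moderate;
therapeutic hypothermia < 35 °C is extreme.  The weekly summary
TIL-Basic median is the median over available days 1–7, using the
*lower* median for an even number of days so the summary stays on the
ordinal scale.  The assessment schedule (days 1–7, 10, 14, 21, 28) is a
package constant; evaluation days are the days directly preceding an
assessment day (1–6, 9, 13, 20, 27).  The synthetic generator assesses
daily (a densified schedule), so all its evaluation days are consecutive.

## 2. Tokenisation

Fitted on the training partition only (bin edges never see test
patients):

* numeric → 19 interior quantile cut points (20 bins), half-open
  right-exclusive intervals, outer values clamped to the first/last bin;
  a value equal to a cut point goes to the higher bin; duplicate cut
  points from heavily tied distributions are merged (fewer effective
  bins, numbering preserved);
* categorical → `variable=value`;
* text → lower-case alphanumerics appended to the variable name; empty
  or whitespace-only text is missing;
* non-finite numerics are missing;
* each variable owns a `<NA>` (missing) token, emitted in every window
  in which the variable is unobserved — static variables once and then
  carried forward, dynamic variables per window — so models can learn
  patterns of missingness without imputation; and an `<UNK>` token for
  values unseen in training (out-of-vocabulary rule at test time).

A window is the *set* of unique token indices; duplicates collapse.
Every eligible variable contributes exactly one token per window, which
makes windows non-empty by construction and gives a fixed feature
universe for attribution.

## 3. Sequence model

Window vector: relevance-weighted average of token embeddings,
`v = Σ r_i e_i / Σ r_i`, with positivity of relevance weights enforced
through a softplus transform of free parameters.  The sequence of window
vectors feeds a GRU or LSTM; each hidden state is decoded by a softmax
layer into the 5-category distribution of next-day TIL-Basic.  Threshold
probabilities are derived partial sums, not separately parameterised
heads; change probabilities are sums relative to the last available
score; the expected score is the probability-weighted mean.

The network is written in NumPy with hand-derived backpropagation
(embedding bag, both recurrences, softmax cross-entropy); the gradients
are verified against central finite differences in the test suite
(relative error < 1e-4).  Training: Adam, per-labelled-day multinomial
cross-entropy with days lacking a next-day assessment masked, minibatches
of stays (padded by iteration, not by tensor), L2 weight decay on the
embedding, recurrent and output weights (not on the relevance
parameters), early stopping on internal-validation loss with the
learning rate halved mid-plateau, best-validation parameters restored.
Fixed seeds make runs bit-reproducible.

Defaults and why: embedding dimension 128 (the smallest of the searched
grid {128, 256, 512, 1024}; ample for synthetic vocabularies of a few
hundred tokens), hidden dimension 32, learning rate 1e-3, patience 5,
weight decay 1e-3.  The experiments in the tests use a more aggressive
recipe (hidden 16, learning rate 0.02, weight decay 3e-3, batch 16,
patience 20) chosen for small synthetic cohorts where stronger
regularisation plus a higher rate reaches the information ceiling in a
few seconds.  Hyperparameter tuning selects by internal-validation
ordinal concordance of the expected score, ties going to the first
listed candidate.

## 4. Synthetic cohort generator

The generator is the package's stand-in for the restricted clinical
cohort; the real data have no published generative model, so all
distributional choices here are explicit constructions.

* **Latent severity**: bounded AR(1) per patient,
  `s_t = clip(0.8 s_{t-1} + 0.6 ε, ±2.5)`.
* **Stay length**: minimum two days (every stay has at least two
  consecutive TIL-assessed days, mirroring the inclusion criterion),
  geometric discharge hazard (default 0.08/day) up to `max_day`; WLST is
  a per-day hazard from day 3, truncating both TIL scoring and
  observations.
* **Driver variables**: dynamic numeric variables listed in
  `driver_effects` load directly on severity (`x = s + 0.5 ε`); their
  per-day *recording* indicator is drawn first, because the treatment
  policy responds to recorded measurements — an unrecorded value cannot
  influence the decision.
* **TIL policy**: an ordered-logit step policy with a stasis spike.
  With escalation log-odds
  `η_t = Σ_v eff_v · x_{v,t}·recorded_{v,t} − drift·(t−1)`
  (falling back to `0.8 s_t` when no drivers are configured and
  `severity_drives_policy` is on), the day-to-day step is
  +1 with probability σ(η − a), −1 with probability σ(−η − a), else
  stay; boundary states keep only their feasible direction; a changing
  step doubles with probability 0.15 (occasional two-category jumps, as
  seen in real transition matrices).  The intercept `a` (and a separate
  day-1 intercept) is **calibrated by bisection on a seeded pilot
  simulation with common random numbers** so that the empirical marginal
  stasis matches `stasis_prob` (default 0.72, the observed 69–75 % range
  of unchanged day-to-day scores) and the day-1→2 change rate matches
  `1 − stasis_prob + day1_change_boost` (default boost 0.30; the first
  transition is by far the most changeable).  `stasis_prob = 1`
  short-circuits to a numerically change-free policy.
* **Treatments**: each day emits one treatment of the class equal to the
  policy's TIL (plus, half the time, one of the class below), so
  re-scoring the emitted treatments reproduces the latent TIL series
  exactly — a round-trip the tests assert.  The first dynamic
  treatment/impression variable in the manifest records the day's
  delivered intensity with 2 % missingness (daily TIL recording is
  near-complete in practice, ≤ 2.4 % missing), making the treatment
  trajectory visible to the full variable set and removable by the
  `no_treatment_impression` ablation.
* **Other variables**: static and non-driver dynamic variables are
  noise (normal, categorical levels, or phrases with punctuation/casing
  to exercise text normalisation) observed with probability
  `1 − missing_rate` (default 0.25, MCAR); an optional informative
  missingness switch links recording probability to severity.
* **Manifest**: `table_manifest()` reproduces the nine-category
  marginals of the motivating cohort exactly (1,029 static + 979
  dynamic = 2,008 variables, 205 treatment/impression);
  `small_manifest()` scales down for fast experiments.

What passing tests on these cohorts show: that the pipeline recovers
injected effects, honours censoring and leakage rules, and that its
metrics behave as designed.  What they do not show: performance on real
ICU data, whose missingness is informative in unmodelled ways, whose
variables are correlated, and whose treatment policies vary by centre.

## 5. Evaluation

* **Partitions**: repeats × folds (default 20 × 5 = 100) stratified by
  each patient's TIL-Basic median (the motivating analyses do not state
  their stratification; stratifying stabilises small folds), 15 % of
  each training set set aside as internal validation (floor convention).
* **AUC**: Mann–Whitney with ties counted one half; undefined on
  single-class samples (reported as missing, never imputed).
* **Calibration slope**: coefficient of logit(p) in a logistic refit of
  the outcome; < 1 indicates overfitting, > 1 underfitting.  Calibration
  curves: lowess smoother, span 0.75, **no robustness iterations**
  (robust reweighting is biased for binary outcomes), evaluated on a
  101-point grid restricted to the observed prediction range; the
  summary is the maximum absolute deviation from the diagonal; constant
  predictions degenerate to a flat curve at the outcome mean.
* **Somers' D_xy**: pair-counting over pairs with distinct observed
  outcomes, ties on the model output counted in the denominator,
  equal to 2·(c − 0.5).  The scalar model output for day-to-day change
  is the expected next-day score minus the last available score — the
  natural ordinal summary of the model's change prediction (the original
  operand is not public; this reconstruction is flagged).
* **Carry-forward reference**: point mass on the last available score,
  pushed through the same metric code as model predictions.
* **BBC-CV**: patient-level bootstrap over pooled out-of-fold
  predictions (all repeats pooled).  Each resample selects the best
  configuration on in-resample rows and evaluates it on out-of-resample
  rows; the point estimate is the mean of the out-of-resample
  distribution with a percentile 95 % CI.  With a single configuration
  this reduces to an ordinary patient-level percentile bootstrap with
  the pooled metric as point estimate.  Resamples on which a metric is
  undefined are redrawn up to a retry cap.

### The null-cohort check

Two subtleties make a naive "no-signal ⇒ change AUC = 0.5" check
ill-posed.  First, the change probabilities condition on the last
available score by definition, and the ordinal boundaries are
structurally informative: escalation from TIL 4 is impossible
(p_inc ≡ 0) and a change at TIL 0 can only be an escalation, so even an
information-free model separates boundary rows perfectly (measured
effect ≈ +0.07 AUC).  Second, a policy driven by latent severity leaks
real signal into the observed treatment trajectory.  The package's null
experiment therefore uses a fully exogenous policy
(`severity_drives_policy=False`, no drift, no day-1 boost) and computes
the change AUC over interior states (last score 1–3), where the event
probability is constant by construction.

## 6. Attribution

KernelSHAP over token-within-window features: Shapley values solve a
kernel-weighted least squares on binary coalition masks with weight
`(M−1)/(C(M,s)·s·(M−s))`, the efficiency constraint
`Σφ = f(observed) − f(baseline)` enforced exactly by variable
elimination.  All 2^M coalitions are enumerated for M ≤ 12 (the solution
is then the exact Shapley value, verified against a permutation-average
oracle); larger M uses paired (antithetic) size-weighted sampling with a
default budget of 2M + 2048 masks.

The explained output is the expected next-day score.  The **baseline**
replaces every token by its variable's missing token — the model's
native representation of "no information".  A consequence: missing-value
tokens are exact null players (masking them is a no-op), so their
Shapley values are identically zero and they are tabulated separately
from value tokens in the population ranking.  **Temporal pruning** scans
earliest-first for the longest contiguous prefix of windows whose joint
replacement by the baseline moves the output by less than the tolerance
(default 0.05 expected-score units); that prefix becomes a single
group feature.

**ΔTimeSHAP** for an observed change between days t−1 and t (only
changes after day two qualify, since two prior days are needed):
Δφ(token) = φ at day t−1 minus φ at day t−2, each taken for the token in
that day's own window, with φ = 0 when the token is absent from the
window.  Positive Δ associates the token with escalation, negative with
de-escalation.  Population ranking: records are first averaged per
(patient, transition, token) across CV partitions, then summarised per
variable by the median; the table lists the ten most-negative-median
variables and, among the remainder, the ten most-positive; median ties
break by record count, then name.

## 7. Problem sizes in the shipped experiments

The test suite's recovery experiments use cohorts of 300 train / 100
test patients (discrimination; the escalation AUC is reported as the
mean over five replicate cohorts, since a single 100-patient draw has a
sampling SD of about 0.03), twenty replicates of 200 train / 50 test
(ΔTimeSHAP sign recovery, 12 transitions per replicate, coalition
budget 192), fifty replicate null cohorts for BBC-CV coverage, and a
bundled demo pipeline profile of ~120 patients, one model
configuration and 3-fold CV.  These sizes are the package's chosen
experiment scale: large enough for the effects to dominate sampling
noise, small enough that the full suite runs on a single CPU in
minutes.

## 8. Known limitations

* The generator's variables are conditionally independent given
  severity; real clinical variables are strongly cross-correlated.
* Change probabilities derived by summation from the 5-class head trade
  a few points of change-discrimination against a direct binary change
  model — the price of a single coherent ordinal output.
* The all-missing baseline makes missingness itself unattributable by
  construction; an average-event baseline would attribute it but is not
  the model's natural "no information" point.
* The NumPy network is CPU-bound and sized for cohorts of hundreds to a
  few thousand patients, not for production-scale training.
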