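# tildyn

Dynamic, ordinal prediction of **next-day intracranial-pressure (ICP)
therapy intensity** for traumatic brain injury (TBI) patients in the ICU,
with bootstrap bias-corrected cross-validated evaluation and temporal
Shapley attribution of day-to-day treatment changes.

ICP management after severe TBI follows a stepwise escalation philosophy
whose overall intensity is summarised by the Therapy Intensity Level
scale; its condensed five-category daily form, **TIL<sup>Basic</sup> ∈
{0 … 4}** (none / basic / mild / moderate / extreme), is the highest
ICP-control class among all treatments given that calendar day.  `tildyn`
asks: *how well do the variables recorded up to today predict tomorrow's
treatment intensity — and which variables drive predicted escalations and
de-escalations?*

It is aimed at clinical-data scientists studying treatment-decision
dynamics in longitudinal ICU data.  Because the motivating cohort is
access-controlled, the package ships a synthetic-cohort generator with
the same statistical structure (mixed-type variable manifest, heavy
day-to-day stasis, withdrawal-of-care censoring) and *known* ground-truth
driver effects, so every stage of the pipeline is testable end to end.

## The model

Each patient's stay is cut into daily windows.  Every observation
becomes a discrete token: categorical values as `variable=value`,
numeric values by 20-quantile binning fitted on the training partition,
free text stripped to lower-case alphanumerics, and a dedicated
`variable=<NA>` token wherever a variable is unobserved (missingness is
modelled, never imputed).  A window is its set of unique tokens.

For window $t$ with tokens $i \in W_t$, the model computes a
relevance-weighted embedding average

$$v_t = \frac{\sum_{i\in W_t} r_i\,e_i}{\sum_{i\in W_t} r_i},\qquad
r_i = \mathrm{softplus}(\rho_i) > 0,$$

feeds the sequence $v_1,\dots,v_t$ to a gated RNN (GRU or LSTM), and
decodes each hidden state with a multinomial (softmax) layer into
$p = (p_0,\dots,p_4)$, the distribution of **tomorrow's**
TIL<sup>Basic</sup>.  Derived views: threshold probabilities
$\Pr(Y>k)=\sum_{j>k}p_j$; change probabilities relative to the last
available score $L$, $p_\downarrow=\sum_{j<L}p_j$, $p_{=}=p_L$,
$p_\uparrow=\sum_{j>L}p_j$; and the expected score
$\mathbb{E}[Y]=\sum_k k\,p_k$.

Evaluation uses repeated stratified cross-validation (20 repeats × 5
folds, 15 % internal validation) with **BBC-CV** (bootstrap
bias-corrected cross-validation) confidence intervals: each patient-level
bootstrap resample selects the best configuration on in-resample rows
and evaluates it out-of-resample.  Metrics: threshold AUC,
escalation/de-escalation AUC, logistic-recalibration calibration slope,
smoothed calibration curves, Somers' $D_{xy}$ of the expected-change
score against observed ordinal change, and a carry-forward reference
predictor.  Attribution uses kernel-weighted Shapley values over
token-within-window features with temporal coalition pruning
(TimeSHAP-style), and **ΔTimeSHAP** — the difference of a token's
Shapley value between the two days preceding an observed change — to
rank variables associated with escalation (positive Δ) or de-escalation
(negative Δ).

## Worked example

```python
from tildyn import NextDayTILModel, ModelConfig, CohortConfig, generate_cohort
from tildyn.simulate import small_manifest, manifest_frame

manifest = small_manifest(n_static=4, n_dynamic=8, driver_names=["icp_mean"])
cohort = generate_cohort(CohortConfig(
    n_patients=300, max_day=7,
    driver_effects={"icp_mean": 2.0},      # mean ICP raises escalation odds
    variable_manifest=manifest, seed=7,
))
model = NextDayTILModel(
    cohort, manifest_frame(manifest),
    ModelConfig(hidden_dim=16, learning_rate=0.02, weight_decay=3e-3,
                batch_size=16, max_epochs=150, patience=20, seed=0),
)
results = model.fit()
print(results.summary())
```

```
Next-day TIL-Basic sequence model
================================================
RNN type:        GRU
Embedding dim:   128
Hidden dim:      16
Variable set:    full
Vocabulary size: 193
Epochs run:      33 (best val loss 0.8817)

Internal-validation discrimination
------------------------------------------------
AUC  Pr(Y>0):   0.957
AUC  Pr(Y>1):   0.949
AUC  Pr(Y>2):   0.949
AUC  Pr(Y>3):   0.967
Somers' Dxy (change): 0.374
```

The threshold AUCs say the model separates patients above/below each
next-day intensity band 95 %+ of the time — mostly reflecting the strong
day-to-day stasis of treatment intensity.  Somers' $D_{xy}$ = 0.374
means about 37 % of the *ordinal variation in day-to-day changes* is
explained — changes, not levels, are the hard target.  Per-day
predictions with the change decomposition:

```python
print(results.predict().head(3).round(3))
```

```
patient_id  day  p_inc  p_same  p_dec  expected
    P00000    1  0.674   0.277  0.049     2.850
    P00000    2  0.636   0.290  0.074     3.556
    P00005    1  0.331   0.555  0.114     2.236
```

`results.attribute(stay, day)` returns the Shapley attribution of the
expected next-day score for one patient-day;
`tildyn.attribution.delta_timeshap` and `population_ranking` aggregate
ΔTimeSHAP records into the escalation/de-escalation variable table.

## Command line

```bash
tildyn simulate --out runs/demo/cohort --seed 1     # synthetic cohort CSVs
tildyn score-til --treatments t.csv --stays s.csv --out til.csv
tildyn run --config demo.yaml --out runs/demo --seed 1   # full pipeline
tildyn report --run runs/demo
```

`run` executes simulate → score → tokenise → train → evaluate →
attribute with shared CV partitions across the variable-set ablations
(`full`, `no_treatment_impression`, `static_only`), writing pooled
predictions, per-day BBC-CV metric tables, ΔTimeSHAP records and a
markdown report.  Omitting `--config` uses a bundled small demo profile.

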