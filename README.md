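# procat

A graded-response-model (GRM) computerized adaptive testing (CAT) engine for
ordinal patient-reported outcome measures (PROMs), built for instruments like
the hand-function questionnaires used in surgical registries: ~10 items, each
answered on an ordered multi-category (bipolar-adjective) scale.

Long questionnaires cost response rates; item response theory lets an adaptive
test ask only the most informative questions for each respondent while still
reporting a score on the full instrument's metric. `procat` covers the whole
workflow:

1. **Calibrate** a GRM item bank from a person × item ordinal response matrix
   (Bock–Aitkin marginal maximum likelihood EM).
2. **Score** any partial or complete response set by EAP (expected a
   posteriori) with a standard error of measurement (SEm), rescaled to a
   0–100 clinical scale.
3. **Administer** the instrument adaptively: start at the population average,
   repeatedly give the unadministered item with maximum Fisher information at
   the current estimate, and stop when SEm < 0.3 (PROMIS-style precision).
4. **Evaluate** the adaptive form against full-length scoring in a paired
   Monte Carlo simulation, with the standard agreement battery.

## The model

Each item i has a discrimination $a_i > 0$ and ordered thresholds
$b_{i1} < \dots < b_{i,K-1}$ (logits). Boundary probabilities follow the
logistic form

$$P(X_i \ge k \mid \theta) = \frac{1}{1 + e^{-a_i(\theta - b_{ik})}},$$

category probabilities are differences of adjacent boundaries, and the item's
Fisher information is $I_i(\theta) = \sum_k (\partial P_{ik}/\partial\theta)^2 / P_{ik}$.
Scoring is the posterior mean of $\theta$ under a standard-normal population
prior; its posterior SD is the SEm that drives the stopping rule. Scores are
reported both in logits and on a 0–100 scale via the bank's affine transform
(default: logit −4…+4 → 0…100).

## Worked example

No clinical data ships with the package; everything below runs on the
synthetic 10-item, 7-category fixture instrument.

```python
import procat as pc

bank = pc.make_fixture_bank()                      # synthetic 10-item, 7-category instrument
responses = {"Q1": 3, "Q2": 2, "Q3": 4, "Q4": 3, "Q5": 2,
             "Q6": 3, "Q7": 2, "Q8": 3, "Q9": 2, "Q10": 3}

full = pc.full_length_score(pc.ResponseVector(responses), bank)
print(f"full-length score: {full.score_0_100:.1f} (SEm {full.se_logit:.3f}, 10 items)")

result = pc.administer_cat(responses.__getitem__, bank)
for step in result.state.trace:
    est = step.estimate
    print(f"  {step.item_id} -> {step.response}: score {est.score_0_100:.1f} (SEm {est.se_logit:.3f})")
print(f"CAT score: {result.final.score_0_100:.1f} after "
      f"{result.final.n_items_used} items ({result.stop_reason})")

report = pc.agreement_report(pc.run_monte_carlo(bank, pc.SimulationConfig(n_respondents=200, seed=42)))
print(f"n=200 cohort: median items {report.items_median:.0f}, "
      f"median SEm {report.median_sem:.2f}, mean error {report.mean_error:.2f}, "
      f"r {report.pearson_r:.3f}, ICC {report.icc:.3f}")
```

Output:

```
full-length score: 42.9 (SEm 0.184, 10 items)
  Q8 -> 3: score 42.7 (SEm 0.405)
  Q2 -> 2: score 43.5 (SEm 0.292)
CAT score: 43.5 after 2 items (precision_met)
n=200 cohort: median items 3, median SEm 0.29, mean error 0.14, r 0.990, ICC 0.990
```

The adaptive session asked two of the ten questions: Q8 (the information
argmax at the population average — it opens every session), then Q2, at which
point the SEm fell below 0.3 and the test stopped within 0.6 score points of
the full-length value. Over a simulated cohort the CAT reproduces full-length
scores with a near-zero mean error and correlation ≈ 0.99.

Calibration exposes a sklearn-style estimator as well:

```python
data = pc.make_fixture_responses(bank, 1000, seed=11)   # person x item matrix
model = pc.GradedResponseModel().fit(data)              # MML-EM
model.item_bank_                                        # recovered parameters
theta = model.predict(data.values[:5])                  # EAP trait scores
```

## Command line

```bash
procat make-fixtures --seed 7 --bank-out bank.json --responses-out responses.csv
procat calibrate     --responses responses.csv --bank-out refit.json --report-out fit.json
procat simulate      --bank bank.json --n 1000 --seed 1 --results-out results.csv --report-out report.json
procat evaluate      --results results.csv --report-out report.json --plots-dir figures/
procat cat           --bank bank.json      # interactive console administration
```

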