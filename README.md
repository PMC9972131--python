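# scump

Detection of fully random (bot) responders in Likert-type questionnaire
data. The method fits per-class Gaussian feature distributions on a
labeled, *stratified* calibration sample (real or policed humans plus a
large generated bot sample), then estimates the target sample's
contamination rate by unsupervised maximum likelihood and classifies
each respondent with the Bayes rule. Because the class mix of a
stratified calibration sample carries no information about prevalence,
the contamination rate must come from the target sample itself; the
resulting classifier adapts its cutoff to the data at hand instead of
fixing a nominal specificity.

The package also ships:

- **Nonresponsivity indices (NRIs)**: squared Mahalanobis distance and
  person-total correlation relative to the calibration humans, plus
  optional factor-model coherence/reliability plugins, all with
  explicit suspicion orientations and a registry for custom indices.
- **Specificity-calibrated baselines**: the univariate 99th-percentile
  union rule and the feature-space Mahalanobis cutoff.
- **Closed-form two-normal theory**: specificity/sensitivity/accuracy
  of any cutoff, ROC area, and the accuracy-maximizing cutoff for a
  single index with normal class densities.
- **Simulation framework**: graded-response-model human generator (no
  downloads needed), uniform and middle-preferring bot generators, and
  a Monte Carlo replicate engine over fully crossed designs.

## Python API

```python
import numpy as np
from scump import (
    LabeledSample, ResponseMatrix, scump_pipeline,
    default_human_model, generate_humans, generate_bots, uniform_bot,
)

model = default_human_model()
humans = generate_humans(model, 200, seed=0)
bots = generate_bots(uniform_bot(), 2000, model.n_items, seed=1)
cal = LabeledSample(
    responses=ResponseMatrix(np.vstack([humans.values, bots.values])),
    labels=np.r_[np.zeros(200, int), np.ones(2000, int)])

target = generate_humans(model, 300, seed=2)      # any unlabeled sample
result = scump_pipeline(cal, target)
result.fit.lambda_hat        # estimated contamination rate
result.report.predicted      # 1 = flagged as bot
```

## Command line

```sh
scump make-fixtures --seed 0 --out fixtures/        # small demo CSVs
scump fit --calibration fixtures/calibration.csv --label-col label \
      --out model.json
scump predict --target fixtures/bots.csv --id-col row_id \
      --model model.json --out preds.csv
scump baseline --method mahalanobis --specificity 0.99 \
      --calibration fixtures/calibration.csv --label-col label \
      --target fixtures/bots.csv --id-col row_id --out base.csv
scump simulate --config design.yaml --out results/   # Monte Carlo design
scump theory table1                                  # closed-form table
```

Input format: delimited text with one header row of item names and one
row of integer responses (default categories 1..5) per respondent;
missing cells (`""`, `NA`, `NaN` by default) are imputed with the
middle category. Labels come from a `--label-col` column (0 = human,
1 = bot). Exit codes: 0 ok, 2 validation failure, 3 numerical failure.

## Notes

- The squared Mahalanobis form (no square root) is used throughout;
  it is monotone-equivalent for thresholding.
- All Gaussian densities are evaluated in log space and the mixture
  score from per-row density ratios; raw densities underflow for
  realistic feature counts and far outliers.
- Covariances use the maximum-likelihood divisor `n` everywhere.
  Singular covariances are a hard error by default; pass a ridge to
  opt into regularization.
- The graded-response-model human population is a synthetic stand-in
  (items skewed across the scale, four correlated factors), not a
  calibrated model of any real instrument.
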