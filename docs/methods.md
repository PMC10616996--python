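# Methods

## Model

`procat` implements Samejima's graded response model (GRM) for ordered
polytomous items. For item $i$ with $K_i$ categories, discrimination
$a_i > 0$ and strictly increasing thresholds $b_{i1} < \dots < b_{i,K_i-1}$:

$$P(X_i \ge k \mid \theta) = \operatorname{logit}^{-1}\!\big(a_i(\theta - b_{ik})\big),
\qquad P(X_i = k) = P(X_i \ge k) - P(X_i \ge k+1),$$

with the implicit anchors $P(X_i \ge 1) = 1$ and $P(X_i \ge K_i + 1) = 0$.
The pure logistic metric is used (scaling constant $D = 1$, no 1.7
normal-ogive correction), matching the convention of the dominant IRT
software; parameter files in a slope–intercept dialect
($c_k = -a\,b_k$) are converted on load. Item information is the expected
(Fisher) form $I_i(\theta) = \sum_k (P'_{ik})^2 / P_{ik}$ — the standard
choice for adaptive item selection — and test information is its sum over
items (local independence).

Assumptions inherited from the model: unidimensionality of the measured
trait, local independence of items given $\theta$, and a common logistic
response process across respondents. None of these are tested automatically;
the fit report's observed-vs-expected category tables are the provided
diagnostic surface.

## Calibration

Item parameters are estimated by Bock–Aitkin marginal maximum likelihood EM:

- **Latent density**: standard normal, fixed (the identification
  constraint). The empirical trait distribution of a target population is a
  simulation-stage concern, not a calibration one.
- **Quadrature**: 61 Gauss–Legendre nodes on $[-6, 6]$ logits, weighted by
  the prior density and normalized. Deterministic and reproducible; no
  adaptive quadrature.
- **E-step**: posterior node masses per person; expected response counts
  $r_{iqk}$ per item, node and category.
- **M-step**: per-item L-BFGS-B on $(\log a,\; b_1,\; \log(b_2-b_1), \dots)$
  with analytic gradients. The reparameterization keeps $a > 0$ and the
  thresholds strictly ordered at every step; bounds
  ($a \in [0.05, 20]$, gaps $\ge 10^{-3}$) fence off degenerate optima. If a
  quasi-Newton step fails to improve the expected complete-data objective the
  warm start is kept, which preserves EM's monotone marginal likelihood.
- **Convergence**: absolute change in marginal log-likelihood
  $< 10^{-5}$, cap 500 iterations; hitting the cap warns and returns
  `converged_ = False`, never silently.
- **Missing data** (coded 0 / blank) are dropped from each person's
  likelihood product (missing at random). A complete-case filter is
  available at the file-reading layer for analyses that require complete
  response sets.
- **Unobserved categories** are inestimable (their thresholds have no
  data); they are collapsed onto the nearest observed neighbour (ties
  downward), logged, and the original→collapsed map stored in the bank
  metadata so new data can be rescored consistently. An item with fewer than
  two observed categories is a hard error naming the item.
- **Identification guard**: calibration refuses matrices with no more
  observations than free parameters (e.g. 2 persons × 2 items) rather than
  returning an unidentified bank.

The public estimator is sklearn-style (`GradedResponseModel().fit(X)`,
`predict` = EAP scores), so it composes with sklearn tooling; `fit_grm` /
`marginal_loglik` / `fit_report` are functional wrappers. Person-level
`predict` uses a uniform 161-node grid rather than the Gauss–Legendre
calibration nodes, which are too sparse mid-interval for sharp individual
posteriors.

## Scoring

The trait estimator is EAP: posterior mean under the population prior, with
the posterior SD reported as the SEm. EAP (rather than ML/WLE) is the
natural choice for an adaptive test that must produce an estimate before any
item is answered — a fresh session starts exactly at the prior mean (score
50 under the default transform) with SEm 1 — and it is the convention of the
large PROM CAT systems whose precision threshold this engine borrows.
Posterior moments are computed on 161 equally spaced nodes on $[-6, 6]$ with
prior weights; against 100 001-point dense-grid integration the error is
below $10^{-6}$ logits (tested), far under reporting precision.

Scores are mapped to 0–100 by a strictly increasing affine transform, then
clipped; the SEm is scaled by the slope and never truncated. The default
transform (slope 12.5, offset 50, i.e. logit $[-4, 4] \to [0, 100]$) is bank
metadata, not a constant: a bank calibrated elsewhere carries its own
anchoring.

## Adaptive administration

The loop is select → ask → re-estimate → check:

- **Selection**: maximum Fisher information at the current EAP point
  estimate, ties to the lowest bank index. Because every session starts at
  the prior mean, the first item is a constant of the bank.
- **Stopping**: SEm $< 0.3$ (strict inequality, logit scale) after at least
  `min_items` (default 1) items; otherwise bank exhaustion or an optional
  item cap. The threshold is on the logit posterior SD — the standardized
  metric on which PROM precision conventions are defined — not on the 0–100
  scale.
- No exposure control or content balancing (out of scope).

With an unreachable threshold the CAT administers every item and reproduces
the full-length score exactly (identical arithmetic path; the item-wise
log-likelihood is summed in bank order precisely so that administration
order cannot perturb the floats).

## Simulation and agreement analysis

Each simulated respondent draws one complete response set from the GRM at
their true $\theta$; the same set is scored full-length and replayed through
the CAT (paired design — required for the paired agreement battery).

Respondent population default: 0–100 scores $\sim$ Normal(43.9, 18.7)
back-transformed through the bank transform, a parametric description of a
post-surgical hand-function cohort; a standard-normal and an empirical
resampling spec are available. Cohort size default 1000.

Metrics, with differences oriented CAT − full-length:

- mean error, mean absolute error, RMSE (0–100 scale);
- Pearson r; R², slope and intercept from regressing CAT on full-length;
- ICC(A,1) — two-way, absolute-agreement, single-measurement (McGraw &
  Wong), the standard variant for method-agreement designs
  (cross-checked against `pingouin` in the tests);
- Bland–Altman mean difference and 95% limits of agreement
  (mean ± 1.96 SD of differences);
- item-count median/IQR/range, median SEm, per-item usage percentages.

Zero variance in either arm marks the correlation-type metrics as undefined
(`None`) rather than propagating NaN.

## The synthetic instrument

No registry data is distributable, so tests and demonstrations run on a
generated fixture: 10 items × 7 categories, discriminations uniform on
[1.5, 4.5], threshold centres uniform on [−1, 1], gaps uniform on
[0.35, 0.85]. The steep upper range reflects what unidimensional
hand-function banks look like — a couple of items carry most of the
information, so an adaptive test plausibly stops after 2–4 items at
SEm < 0.3, which is exactly the regime the engine is designed for. All
generation is seed-reproducible; nothing is stored on disk.

What the fixture does *not* emulate: multidimensionality, local dependence
between similarly worded items, response styles (e.g. extreme responding),
informative missingness, or test–retest noise. Passing simulations therefore
demonstrate the engine's internal consistency and statistical behaviour
under a correctly specified GRM, not the clinical validity of any real
instrument.

## Problem sizes and numerics

Default analysis sizes: 1000 Monte Carlo respondents and 1000 calibration
persons (the acceptance script), with smaller cohorts (40–200) in unit
tests; at these sizes the full pipeline runs in seconds. Probabilities are
floored at $10^{-12}$ before logarithms. The fixed quadrature grids make
every estimate deterministic given inputs; all randomness flows through
explicit `numpy` generators seeded at the interface.

## Known limitations

- One latent dimension; no partial-credit/nominal models.
- The latent prior is normal by construction; strongly skewed populations
  are represented only through the score-scale simulation specs.
- Fit reporting is generic (observed vs expected category frequencies,
  standardized residuals); named item-fit indices (S-X², infit/outfit) are
  not implemented.
- CAT item selection is pointwise max-information; no posterior-weighted or
  exposure-controlled selection rules.
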