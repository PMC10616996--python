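"""Monte Carlo evaluation of the CAT against full-length scoring.

Each simulated respondent draws one complete GRM response set at their true
theta; that single set feeds both arms of a paired design — the full-length
EAP score and the adaptive session replayed against the same responses.
The agreement battery (mean error, MAE, RMSE, Pearson r, ICC(A,1), R^2 from
regressing CAT on full-length, Bland-Altman 95% limits of agreement) and the
per-item usage table summarize how faithfully the short adaptive form
reproduces the full-length score.

The default respondent-population spec draws 0-100 scores from
Normal(43.9, 18.7) and back-transforms them through the bank's scale
transform — a parametric stand-in for an empirical clinical score
distribution; an empirical resampling spec and a standard-normal spec are
also available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cat import CatConfig, CatResult, administer_cat
from .grm import ItemBank, ResponseVector, category_probabilities
from .scale import ScaleTransform
from .scoring import (
    NormalPrior,
    QuadratureGrid,
    ThetaEstimate,
    full_length_score,
)

UNDEFINED = None  # marker for metrics undefined under zero variance


@dataclass(frozen=True)
class ThetaDistribution:
    """Respondent latent-trait population spec.

    kind:
      * ``"standard_normal"`` — theta ~ N(0, 1) in logits.
      * ``"normal_score_scale"`` — 0-100 scores ~ N(mean, sd), mapped to
        logits through the (inverse, unclipped) scale transform.
      * ``"empirical"`` — resample supplied 0-100 scores with replacement,
        then back-transform.
    """

    kind: str = "normal_score_scale"
    mean: float = 43.9
    sd: float = 18.7
    scores: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in ("standard_normal", "normal_score_scale", "empirical"):
            raise ValueError(f"unknown theta distribution kind {self.kind!r}")
        if self.kind == "normal_score_scale" and not self.sd > 0:
            raise ValueError("sd must be positive")
        if self.kind == "empirical":
            if self.scores is None or len(self.scores) == 0:
                raise ValueError("empirical spec requires a non-empty scores sample")
            object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))


@dataclass(frozen=True)
class SimulationConfig:
    n_respondents: int = 1000
    theta_distribution: ThetaDistribution = field(default_factory=ThetaDistribution)
    seed: int = 0
    cat_config: CatConfig = field(default_factory=CatConfig)

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")


@dataclass(frozen=True)
class SimulationRecord:
    respondent_id: int
    theta_true_logit: float
    full_estimate: ThetaEstimate
    cat_result: CatResult


@dataclass
class AgreementReport:
    """The metric battery comparing CAT vs full-length 0-100 scores.

    Differences are oriented CAT minus full-length.  ``icc`` is the
    two-way, absolute-agreement, single-measurement variant ICC(A,1);
    ``r_squared``/``slope``/``intercept`` come from regressing the CAT score
    on the full-length score.  Correlation-type metrics are None when either
    arm has zero variance.
    """

    n: int
    mean_error: float
    mean_absolute_error: float
    rmse: float
    pearson_r: Optional[float]
    icc: Optional[float]
    r_squared: Optional[float]
    regression_slope: Optional[float]
    regression_intercept: Optional[float]
    bland_altman: Dict[str, float]
    cat_score_mean: float
    cat_score_sd: float
    full_score_mean: float
    full_score_sd: float
    items_median: float
    items_iqr: tuple
    items_range: tuple
    median_sem: float

    def to_dict(self) -> Dict:
        return {
            "n": self.n,
            "mean_error": self.mean_error,
            "mean_absolute_error": self.mean_absolute_error,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "icc": self.icc,
            "r_squared": self.r_squared,
            "regression_slope": self.regression_slope,
            "regression_intercept": self.regression_intercept,
            "bland_altman": dict(self.bland_altman),
            "cat_score_mean": self.cat_score_mean,
            "cat_score_sd": self.cat_score_sd,
            "full_score_mean": self.full_score_mean,
            "full_score_sd": self.full_score_sd,
            "items_median": self.items_median,
            "items_iqr": list(self.items_iqr),
            "items_range": list(self.items_range),
            "median_sem": self.median_sem,
        }


def generate_thetas(
    config: SimulationConfig,
    transform: Optional[ScaleTransform] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw n_respondents true latent traits (logits), reproducibly."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    dist = config.theta_distribution
    n = config.n_respondents
    if dist.kind == "standard_normal":
        return rng.standard_normal(n)
    transform = transform or ScaleTransform()
    if dist.kind == "normal_score_scale":
        scores = rng.normal(dist.mean, dist.sd, size=n)
    else:  # empirical
        scores = rng.choice(np.asarray(dist.scores, dtype=float), size=n, replace=True)
    return np.array([transform.inverse(s) for s in scores])


def simulate_full_responses(
    theta_true: float, bank: ItemBank, rng: np.random.Generator
) -> ResponseVector:
    """One complete response set drawn from the GRM category probabilities."""
    entries = {}
    for item in bank:
        p = category_probabilities(item, float(theta_true))
        p = p / p.sum()  # guard rounding
        entries[item.item_id] = int(rng.choice(item.n_categories, p=p)) + 1
    return ResponseVector(entries)


def run_monte_carlo(
    bank: ItemBank,
    config: SimulationConfig,
    prior: Optional[NormalPrior] = None,
    grid: Optional[QuadratureGrid] = None,
) -> List[SimulationRecord]:
    """Paired simulation: per respondent, one response set scored both ways."""
    rng = np.random.default_rng(config.seed)
    thetas = generate_thetas(config, bank.scale_transform, rng=rng)
    records: List[SimulationRecord] = []
    for i, theta in enumerate(thetas):
        responses = simulate_full_responses(theta, bank, rng)
        full = full_length_score(responses, bank, prior, grid)
        cat = administer_cat(
            responses.entries.__getitem__, bank, config.cat_config, prior, grid
        )
        records.append(
            SimulationRecord(
                respondent_id=i,
                theta_true_logit=float(theta),
                full_estimate=full,
                cat_result=cat,
            )
        )
    return records


def _icc_a1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(A,1): two-way, absolute agreement, single measurement.

    McGraw & Wong: (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    with k = 2 raters (the two scoring methods).
    """
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if msr == 0 else float("nan")
    return float((msr - mse) / denom)


def agreement_report(records_or_frame) -> AgreementReport:
    """Compute the full agreement battery from simulation records.

    Also accepts a DataFrame with columns ``cat_score``, ``full_score``,
    ``n_items`` and ``cat_se_logit`` (a written results table reloaded).
    """
    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame
        cat = df["cat_score"].to_numpy(dtype=float)
        full = df["full_score"].to_numpy(dtype=float)
        n_items = df["n_items"].to_numpy(dtype=float)
        sems = df["cat_se_logit"].to_numpy(dtype=float)
    else:
        records = list(records_or_frame)
        cat = np.array([r.cat_result.final.score_0_100 for r in records], dtype=float)
        full = np.array([r.full_estimate.score_0_100 for r in records], dtype=float)
        n_items = np.array(
            [len(r.cat_result.state.administered) for r in records], dtype=float
        )
        sems = np.array([r.cat_result.final.se_logit for r in records], dtype=float)
    n = len(cat)
    if n < 3:
        raise ValueError(f"agreement analysis needs >= 3 records, got {n}")

    diff = cat - full
    mean_error = float(diff.mean())
    mae = float(np.abs(diff).mean())
    rmse = float(math.sqrt(np.mean(diff**2)))
    sd_diff = float(diff.std(ddof=1))
    loa_half = 1.96 * sd_diff
    bland_altman = {
        "mean_difference": mean_error,
        "loa_lower": mean_error - loa_half,
        "loa_upper": mean_error + loa_half,
    }

    degenerate = cat.std() == 0 or full.std() == 0
    if degenerate:
        pearson_r = icc = r2 = slope = intercept = UNDEFINED
    else:
        pearson_r = float(stats.pearsonr(cat, full).statistic)
        icc = _icc_a1(cat, full)
        reg = stats.linregress(full, cat)  # CAT regressed on full-length
        slope = float(reg.slope)
        intercept = float(reg.intercept)
        r2 = float(reg.rvalue**2)

    return AgreementReport(
        n=n,
        mean_error=mean_error,
        mean_absolute_error=mae,
        rmse=rmse,
        pearson_r=pearson_r,
        icc=icc,
        r_squared=r2,
        regression_slope=slope,
        regression_intercept=intercept,
        bland_altman=bland_altman,
        cat_score_mean=float(cat.mean()),
        cat_score_sd=float(cat.std(ddof=1)),
        full_score_mean=float(full.mean()),
        full_score_sd=float(full.std(ddof=1)),
        items_median=float(np.median(n_items)),
        items_iqr=(float(np.percentile(n_items, 25)), float(np.percentile(n_items, 75))),
        items_range=(float(n_items.min()), float(n_items.max())),
        median_sem=float(np.median(sems)),
    )


def usage_table(records: Sequence[SimulationRecord], bank: ItemBank) -> pd.DataFrame:
    """Per-item administration counts and percentages over the cohort."""
    records = list(records)
    if not records:
        raise ValueError("usage_table needs at least one record")
    counts = {item_id: 0 for item_id in bank.item_ids}
    for r in records:
        for item_id in r.cat_result.state.administered:
            counts[item_id] += 1
    n = len(records)
    return pd.DataFrame(
        {
            "item_id": list(counts),
            "label": [bank.get(i).label for i in counts],
            "count": list(counts.values()),
            "percentage": [100.0 * c / n for c in counts.values()],
        }
    )


def records_frame(records: Sequence[SimulationRecord]) -> pd.DataFrame:
    """One row per simulated respondent (the results-CSV layout)."""
    rows = []
    for r in records:
        rows.append(
            {
                "respondent_id": r.respondent_id,
                "theta_true_logit": r.theta_true_logit,
                "full_theta_logit": r.full_estimate.theta_logit,
                "full_se_logit": r.full_estimate.se_logit,
                "full_score": r.full_estimate.score_0_100,
                "cat_theta_logit": r.cat_result.final.theta_logit,
                "cat_se_logit": r.cat_result.final.se_logit,
                "cat_score": r.cat_result.final.score_0_100,
                "n_items": len(r.cat_result.state.administered),
                "stop_reason": r.cat_result.stop_reason,
                "items_administered": ";".join(r.cat_result.state.administered),
            }
        )
    return pd.DataFrame(rows)
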