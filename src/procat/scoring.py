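"""Latent-trait scoring: EAP estimation with standard errors and rescaling.

The estimator is EAP (expected a posteriori): the posterior mean of theta
under a population prior, with the posterior standard deviation reported as
the standard error of measurement (SEm).  Before any item is answered the
posterior equals the prior, so a fresh session starts at the population
average with SE 1 under the standard-normal default — the behaviour an
adaptive test displays as its score trace unfolds.

The posterior is evaluated on a fixed equally spaced quadrature grid
(default 161 nodes on [-6, 6]) with prior-density weights; the grid is
deterministic and its error is far below reporting precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .grm import ItemBank, ResponseVector, response_loglik
from .scale import ScaleTransform


@dataclass(frozen=True)
class NormalPrior:
    """Normal latent-trait prior (standard normal by default)."""

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"prior sd must be positive, got {self.sd}")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mean) / self.sd
        return -0.5 * z * z - math.log(self.sd) - 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced theta nodes on a closed interval."""

    n: int = 161
    lower: float = -6.0
    upper: float = 6.0

    def __post_init__(self) -> None:
        if self.n < 11:
            raise ValueError(f"need at least 11 quadrature nodes, got {self.n}")
        if not self.lower < self.upper:
            raise ValueError("quadrature interval must be ordered")

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n)


@dataclass(frozen=True)
class ThetaEstimate:
    """A latent-trait point estimate with its uncertainty, on both scales.

    ``se_logit`` is the SEm used by the adaptive test's stopping rule;
    ``score_0_100`` / ``se_0_100`` are the rescaled clinical-scale values.
    """

    theta_logit: float
    se_logit: float
    score_0_100: Optional[float] = None
    se_0_100: Optional[float] = None
    n_items_used: int = 0


DEFAULT_PRIOR = NormalPrior()
DEFAULT_GRID = QuadratureGrid()


def rescale_theta(estimate: ThetaEstimate, transform: ScaleTransform) -> ThetaEstimate:
    """Populate the 0-100 score fields via the affine transform (then clip)."""
    return replace(
        estimate,
        score_0_100=transform.apply(estimate.theta_logit),
        se_0_100=transform.apply_se(estimate.se_logit),
    )


def eap_estimate(
    responses: ResponseVector,
    bank: ItemBank,
    prior: Optional[NormalPrior] = None,
    grid: Optional[QuadratureGrid] = None,
) -> ThetaEstimate:
    """Posterior mean and SD of theta given the (possibly empty) responses.

    Deterministic given inputs; the returned estimate carries 0-100 scores
    through the bank's scale transform.
    """
    prior = prior if prior is not None else DEFAULT_PRIOR
    grid = grid if grid is not None else DEFAULT_GRID
    responses.validate_against(bank)

    nodes = grid.nodes
    logw = prior.logpdf(nodes) + response_loglik(responses, bank, nodes)
    w = np.exp(logw - logsumexp(logw))
    mean = float(w @ nodes)
    var = float(w @ (nodes - mean) ** 2)
    est = ThetaEstimate(
        theta_logit=mean,
        se_logit=math.sqrt(max(var, 0.0)),
        n_items_used=len(responses),
    )
    return rescale_theta(est, bank.scale_transform)


def full_length_score(
    responses: ResponseVector,
    bank: ItemBank,
    prior: Optional[NormalPrior] = None,
    grid: Optional[QuadratureGrid] = None,
) -> ThetaEstimate:
    """EAP score from a complete response set — the full-length comparator.

    Raises if any bank item is unanswered; otherwise identical to
    :func:`eap_estimate` on the same inputs.
    """
    missing = set(bank.item_ids) - set(responses.entries)
    if missing:
        raise ValueError(f"full-length scoring requires all items; missing {sorted(missing)}")
    return eap_estimate(responses, bank, prior, grid)
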