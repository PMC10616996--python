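"""Samejima's graded response model (GRM) for polytomous ordinal items.

The GRM describes the probability that a respondent with latent trait
``theta`` (in logits) endorses category ``k`` of an ordered K-category item.
Each item carries a discrimination (slope) ``a > 0`` and K-1 strictly
increasing boundary thresholds ``b_1 < ... < b_{K-1}``.  The boundary
(cumulative) probabilities follow the two-parameter logistic form

    P(X >= k | theta) = 1 / (1 + exp(-a (theta - b_k)))

and category probabilities are the telescoping differences of adjacent
boundaries.  A pure logistic metric is used throughout (scaling constant
D = 1, no 1.7 normal-ogive correction), matching the convention of the
dominant GRM software.

All probability functions accept a scalar theta or an array of thetas and
broadcast over the trailing category axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
from scipy.special import expit

from .scale import ScaleTransform

#: floor applied to probabilities before logarithms; prevents -inf at extreme
#: theta without visibly perturbing test-level quantities
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ItemParameters:
    """GRM parameters for one ordinal item (slope-threshold parameterization).

    Parameters
    ----------
    item_id : str
        Short unique identifier (e.g. ``"Q7"``).
    discrimination : float
        Positive logit slope ``a``.
    thresholds : tuple of float
        Strictly increasing boundary locations ``b_1 .. b_{K-1}`` in logits;
        the number of response categories is ``len(thresholds) + 1``.
    label : str
        Free-text item wording, optional.
    """

    item_id: str
    discrimination: float
    thresholds: tuple
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(b) for b in self.thresholds))
        object.__setattr__(self, "discrimination", float(self.discrimination))
        if not self.item_id:
            raise ValueError("item_id must be a non-empty string")
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise ValueError(
                f"item {self.item_id!r}: discrimination must be positive, "
                f"got {self.discrimination}"
            )
        if len(self.thresholds) < 1:
            raise ValueError(f"item {self.item_id!r}: at least one threshold required (K >= 2)")
        b = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.isfinite(b)):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite")
        if np.any(np.diff(b) <= 0):
            raise ValueError(
                f"item {self.item_id!r}: thresholds must be strictly increasing, got {list(b)}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class ItemBank:
    """An ordered, calibrated collection of :class:`ItemParameters`.

    Carries the 0-100 scale transform as bank metadata so that scores from
    different banks are anchored by their own calibration, not a constant.
    """

    items: tuple
    scale_transform: ScaleTransform = field(default_factory=ScaleTransform)
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) == 0:
            raise ValueError("item bank must be non-empty")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids in bank: {dup}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __getitem__(self, index: int) -> ItemParameters:
        return self.items[index]

    @property
    def item_ids(self) -> list:
        return [it.item_id for it in self.items]

    def get(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"unknown item_id {item_id!r}; bank has {self.item_ids}")

    def index(self, item_id: str) -> int:
        for i, it in enumerate(self.items):
            if it.item_id == item_id:
                return i
        raise KeyError(f"unknown item_id {item_id!r}; bank has {self.item_ids}")


@dataclass(frozen=True)
class ResponseVector:
    """Observed 1-based category responses, keyed by item_id.

    May be partial (an adaptive session) or complete (full-length
    administration); validity against a bank is checked on demand.
    """

    entries: Mapping

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for item_id, cat in self.entries.items():
            if int(cat) != cat or cat < 1:
                raise ValueError(f"response to {item_id!r} must be a 1-based integer, got {cat}")

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, bank: ItemBank) -> None:
        for item_id, cat in self.entries.items():
            item = bank.get(item_id)  # raises KeyError for unknown items
            if not 1 <= cat <= item.n_categories:
                raise ValueError(
                    f"response {cat} to item {item_id!r} outside its "
                    f"1..{item.n_categories} category range"
                )

    def is_complete(self, bank: ItemBank) -> bool:
        return set(self.entries) == set(bank.item_ids)


def boundary_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """P(X >= k | theta) for k = 1..K-1, strictly decreasing in k.

    Returns shape ``theta.shape + (K-1,)`` (``(K-1,)`` for scalar theta).
    """
    th = np.asarray(theta, dtype=float)
    b = np.asarray(item.thresholds, dtype=float)
    return expit(item.discrimination * (th[..., None] - b))


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """P(X = k | theta) for k = 1..K as differences of adjacent boundaries.

    The implicit anchors P(X >= "category 1") = 1 and P(X >= K+1) = 0 make the
    probabilities telescope to exactly 1.
    """
    bp = boundary_probabilities(item, theta)
    shape = bp.shape[:-1] + (1,)
    cum = np.concatenate([np.ones(shape), bp, np.zeros(shape)], axis=-1)
    return -np.diff(cum, axis=-1)


def _boundary_derivatives(item: ItemParameters, theta) -> np.ndarray:
    """d P(X>=k) / d theta = a p (1-p), padded with zeros at both anchors."""
    bp = boundary_probabilities(item, theta)
    s = item.discrimination * bp * (1.0 - bp)
    shape = s.shape[:-1] + (1,)
    return np.concatenate([np.zeros(shape), s, np.zeros(shape)], axis=-1)


def item_information(item: ItemParameters, theta):
    """Expected (Fisher) information the item contributes at theta.

    I(theta) = sum_k (dP_k/dtheta)^2 / P_k; nonnegative and continuous.
    For K = 2 this reduces to the dichotomous closed form a^2 P (1 - P).
    """
    padded = _boundary_derivatives(item, theta)
    dP = -np.diff(padded, axis=-1)
    P = np.clip(category_probabilities(item, theta), PROB_FLOOR, None)
    info = np.sum(dP * dP / P, axis=-1)
    if np.ndim(theta) == 0:
        return float(info)
    return info


def test_information(items: Iterable[ItemParameters], theta):
    """Test information: the sum of item informations (local independence)."""
    items = list(items)
    if not items:
        raise ValueError("test_information requires a non-empty item subset")
    total = item_information(items[0], theta)
    for it in items[1:]:
        total = total + item_information(it, theta)
    return total


def response_loglik(responses: ResponseVector, bank: ItemBank, theta):
    """Log-likelihood sum_i log P(X_i = x_i | theta) over answered items.

    Empty response sets contribute 0 (the empty sum).  Probabilities are
    floored at ``PROB_FLOOR`` before the logarithm.
    """
    th = np.asarray(theta, dtype=float)
    total = np.zeros(th.shape)
    for item_id in responses.entries:
        bank.get(item_id)  # raise on unknown items before any arithmetic
    # iterate in bank order so the float summation path is independent of
    # the order responses were recorded in (CAT vs full-length identity)
    for item in bank:
        if item.item_id not in responses.entries:
            continue
        cat = responses.entries[item.item_id]
        if not 1 <= cat <= item.n_categories:
            raise ValueError(
                f"response {cat} to item {item.item_id!r} outside its "
                f"1..{item.n_categories} category range"
            )
        p = category_probabilities(item, th)[..., int(cat) - 1]
        total = total + np.log(np.clip(p, PROB_FLOOR, 1.0))
    if np.ndim(theta) == 0:
        return float(total)
    return total
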