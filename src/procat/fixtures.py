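"""Synthetic fixture generator: a PEM-shaped instrument and GRM responses.

The registry data behind hand-function questionnaires is not publicly
deposited, so every test and demonstration here runs on a synthetic
instrument: 10 ordinal items with 7 response categories (bipolar-adjective
scales), item discriminations varying enough that adaptive item ordering is
non-trivial, and thresholds spread around the centre of the trait range.
Discriminations span 1.5-4.5 logits — the steep slopes typical of a
unidimensional hand-function bank, where one or two items dominate the
information curve and an adaptive test can stop after very few questions.

Everything is reproducible from a seed; no files are shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .calibrate import MISSING, ResponseMatrix
from .grm import ItemBank, ItemParameters, category_probabilities
from .scale import ScaleTransform
from .simulate import SimulationConfig, ThetaDistribution, generate_thetas


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of the synthetic instrument (defaults mirror a 10-item,
    7-category hand-function questionnaire)."""

    n_items: int = 10
    n_categories: int = 7
    discrimination_range: Tuple[float, float] = (1.5, 4.5)
    threshold_center_range: Tuple[float, float] = (-1.0, 1.0)
    threshold_gap_range: Tuple[float, float] = (0.35, 0.85)
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        lo, hi = self.discrimination_range
        if not 0 < lo <= hi:
            raise ValueError("discrimination_range must be positive and ordered")
        glo, ghi = self.threshold_gap_range
        if not 0 < glo <= ghi:
            raise ValueError("threshold_gap_range must be positive and ordered")


def make_fixture_bank(spec: Optional[FixtureSpec] = None) -> ItemBank:
    """Generate a synthetic calibrated bank satisfying all item invariants."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    items = []
    for j in range(spec.n_items):
        a = float(rng.uniform(*spec.discrimination_range))
        center = float(rng.uniform(*spec.threshold_center_range))
        gaps = rng.uniform(*spec.threshold_gap_range, size=max(spec.n_categories - 2, 0))
        offsets = np.concatenate([[0.0], np.cumsum(gaps)])
        b = center - offsets[-1] / 2.0 + offsets
        items.append(
            ItemParameters(
                item_id=f"Q{j + 1}",
                label=f"Synthetic ordinal item {j + 1} ({spec.n_categories} categories)",
                discrimination=a,
                thresholds=tuple(b),
            )
        )
    return ItemBank(
        items=tuple(items),
        scale_transform=ScaleTransform(),
        metadata={"instrument": "synthetic-fixture", "generator_seed": spec.seed},
    )


def make_fixture_responses(
    bank: ItemBank,
    n: int,
    theta_spec: Optional[ThetaDistribution] = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Draw n complete GRM response sets from the bank.

    The calibration-sample default is a standard-normal trait distribution
    (the identification metric); pass a spec for other populations.
    """
    theta_spec = theta_spec or ThetaDistribution(kind="standard_normal")
    rng = np.random.default_rng(seed)
    config = SimulationConfig(n_respondents=n, theta_distribution=theta_spec, seed=seed)
    thetas = generate_thetas(config, bank.scale_transform, rng=rng)
    values = np.empty((n, len(bank)), dtype=int)
    for j, item in enumerate(bank):
        probs = category_probabilities(item, thetas)  # (n, K)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        values[:, j] = (u[:, None] > cum).sum(axis=1) + 1
    return ResponseMatrix(
        person_ids=tuple(f"S{i + 1}" for i in range(n)),
        item_ids=tuple(bank.item_ids),
        values=values,
    )
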