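"""The computerized adaptive testing (CAT) loop.

A session starts at the prior-only estimate (the population average), then
repeatedly (1) picks the unadministered item with maximum Fisher information
at the current theta estimate, (2) records the response, (3) re-estimates
theta by EAP, and (4) stops once the logit-scale SEm drops strictly below
the precision threshold (default 0.3, the PROMIS-style precision), the bank
is exhausted, or an item cap is hit.

Because item selection is evaluated at the current point estimate and every
session starts at the same prior mean, the first administered item is a
constant of the bank: the information argmax at the prior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

from .grm import ItemBank, ResponseVector, item_information
from .scoring import NormalPrior, QuadratureGrid, ThetaEstimate, eap_estimate

STOP_PRECISION = "precision_met"
STOP_EXHAUSTED = "bank_exhausted"
STOP_MAX_ITEMS = "max_items"


@dataclass(frozen=True)
class CatConfig:
    """Stopping and selection rules for an adaptive session.

    ``se_threshold`` is on the logit scale (posterior SD).  ``max_items``
    defaults to the bank size.  ``min_items`` = 1 means precision may stop
    the test after a single item if the bank supports it; any observed floor
    on item counts should emerge from information content.
    """

    se_threshold: float = 0.3
    min_items: int = 1
    max_items: Optional[int] = None
    item_selection: str = "max_info"
    tie_break: str = "bank_order"

    def __post_init__(self) -> None:
        if not self.se_threshold >= 0:
            raise ValueError("se_threshold must be nonnegative")
        if self.min_items < 1:
            raise ValueError("min_items must be >= 1")
        if self.max_items is not None and self.max_items < self.min_items:
            raise ValueError("max_items must be >= min_items")
        if self.item_selection != "max_info":
            raise ValueError(f"unknown item_selection rule {self.item_selection!r}")
        if self.tie_break != "bank_order":
            raise ValueError(f"unknown tie_break rule {self.tie_break!r}")

    def resolved_max_items(self, bank: ItemBank) -> int:
        if self.max_items is None:
            return len(bank)
        if self.max_items > len(bank):
            raise ValueError(f"max_items {self.max_items} exceeds bank size {len(bank)}")
        return self.max_items


@dataclass(frozen=True)
class CatStep:
    item_id: str
    response: int
    estimate: ThetaEstimate


@dataclass(frozen=True)
class CatState:
    """The evolving session: administered items, responses, score trace."""

    administered: tuple
    responses: ResponseVector
    current: ThetaEstimate
    trace: tuple

    def __post_init__(self) -> None:
        if len(self.trace) != len(self.administered):
            raise ValueError("trace and administered lengths differ")
        if len(set(self.administered)) != len(self.administered):
            raise ValueError("administered items must be unique")


@dataclass(frozen=True)
class CatResult:
    final: ThetaEstimate
    state: CatState
    stop_reason: str


def initialize_cat(
    bank: ItemBank,
    config: Optional[CatConfig] = None,
    prior: Optional[NormalPrior] = None,
    grid: Optional[QuadratureGrid] = None,
) -> CatState:
    """Fresh session: no items administered, estimate = prior-only posterior."""
    config = config or CatConfig()
    config.resolved_max_items(bank)  # validate against this bank
    current = eap_estimate(ResponseVector({}), bank, prior, grid)
    return CatState(administered=(), responses=ResponseVector({}), current=current, trace=())


def select_next_item(state: CatState, bank: ItemBank, config: Optional[CatConfig] = None) -> str:
    """Unadministered item with maximum information at the current estimate.

    Ties resolve to the lowest bank index (strict-improvement scan in bank
    order), so selection is deterministic.
    """
    theta = state.current.theta_logit
    best_id, best_info = None, -1.0
    administered = set(state.administered)
    for item in bank:
        if item.item_id in administered:
            continue
        info = item_information(item, theta)
        if info > best_info:
            best_id, best_info = item.item_id, info
    if best_id is None:
        raise ValueError("all bank items have been administered")
    return best_id


def record_response(
    state: CatState,
    item_id: str,
    category: int,
    bank: ItemBank,
    prior: Optional[NormalPrior] = None,
    grid: Optional[QuadratureGrid] = None,
) -> CatState:
    """Extend the session by one answered item and re-estimate theta."""
    if item_id in state.administered:
        raise ValueError(f"item {item_id!r} already administered")
    item = bank.get(item_id)
    if not 1 <= category <= item.n_categories:
        raise ValueError(
            f"response {category} to item {item_id!r} outside its "
            f"1..{item.n_categories} category range"
        )
    entries = dict(state.responses.entries)
    entries[item_id] = int(category)
    responses = ResponseVector(entries)
    current = eap_estimate(responses, bank, prior, grid)
    return CatState(
        administered=state.administered + (item_id,),
        responses=responses,
        current=current,
        trace=state.trace + (CatStep(item_id, int(category), current),),
    )


def should_stop(
    state: CatState, bank: ItemBank, config: Optional[CatConfig] = None
) -> Tuple[bool, Optional[str]]:
    """Stopping rule: SEm strictly below threshold (after min_items), bank
    exhaustion, or the item cap — in that order of precedence."""
    config = config or CatConfig()
    n = len(state.administered)
    if n >= config.min_items and state.current.se_logit < config.se_threshold:
        return True, STOP_PRECISION
    if n == len(bank):
        return True, STOP_EXHAUSTED
    if n >= config.resolved_max_items(bank):
        return True, STOP_MAX_ITEMS
    return False, None


def administer_cat(
    response_provider: Callable[[str], int],
    bank: ItemBank,
    config: Optional[CatConfig] = None,
    prior: Optional[NormalPrior] = None,
    grid: Optional[QuadratureGrid] = None,
) -> CatResult:
    """Run a full adaptive session against a response provider.

    The provider maps an item_id to a 1-based category, playing the role of
    the respondent.  With a provider that answers from a complete response
    set and an unreachable threshold, the final estimate equals the
    full-length score exactly (same likelihood, same arithmetic path).
    """
    config = config or CatConfig()
    state = initialize_cat(bank, config, prior, grid)
    while True:
        stop, reason = should_stop(state, bank, config)
        if stop:
            return CatResult(final=state.current, state=state, stop_reason=reason)
        item_id = select_next_item(state, bank, config)
        category = response_provider(item_id)
        try:
            state = record_response(state, item_id, category, bank, prior, grid)
        except ValueError as exc:
            raise ValueError(f"invalid response for item {item_id!r}: {exc}") from exc
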