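"""Affine logit -> 0-100 score rescaling.

Latent-trait estimates live on the logit scale; for clinical interpretation
they are mapped to a 0-100 score by a strictly increasing affine transform
followed by clipping.  The default maps logit [-4, +4] onto [0, 100]
(slope 12.5 points per logit, offset 50 at theta = 0); a calibrated bank may
carry its own anchoring as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScaleTransform:
    """score = clip(offset + slope * theta, *clip_range); SE scales by slope."""

    slope: float = 12.5
    offset: float = 50.0
    clip_range: tuple = (0.0, 100.0)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        lo, hi = self.clip_range
        if not lo < hi:
            raise ValueError(f"clip_range must be ordered, got {self.clip_range}")

    def apply(self, theta_logit: float) -> float:
        lo, hi = self.clip_range
        return float(min(max(self.offset + self.slope * theta_logit, lo), hi))

    def apply_se(self, se_logit: float) -> float:
        # pre-clip: the SE is scaled, never truncated
        return float(self.slope * se_logit)

    def inverse(self, score: float) -> float:
        """Logit corresponding to an (unclipped) 0-100 score."""
        return float((score - self.offset) / self.slope)
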