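"""Precision recommendations by expected-prevalence regime and study scale.

For mid-range prevalences (10-90%) a fixed precision band is sensible:
2-3 percentage points for large, well-funded studies, 4-5 for small
ones, and anything looser marks the study as preliminary.  For rare
(< 10%) or near-universal (> 90%) conditions, a fixed precision would
swamp the estimate, so the recommendation scales with the distance of
the expected prevalence (EP) from the nearer boundary: 0.25x for large
studies, 0.5x for small, looser than 0.5x for preliminary work.  In
every regime the precision must stay strictly below min(EP, 100 - EP),
or the anticipated Wald interval leaves the percentage scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = [
    "REGIMES",
    "SCALES",
    "PrecisionAdvice",
    "PrecisionVerdict",
    "classify_regime",
    "recommend_precision",
    "validate_precision",
]

REGIMES = ("mid", "low", "high")
SCALES = ("large", "small", "preliminary")


def classify_regime(ep_pct: float) -> str:
    """Assign an expected prevalence (percent) to its advisory regime.

    ``mid`` for 10% <= EP <= 90% (boundaries inclusive), ``low`` below,
    ``high`` above.
    """
    if not (isinstance(ep_pct, (int, float)) and math.isfinite(ep_pct)):
        raise ValueError(f"expected prevalence must be finite, got {ep_pct!r}")
    if not 0.0 < ep_pct < 100.0:
        raise ValueError(f"expected prevalence must be in (0, 100) percent, got {ep_pct}")
    if ep_pct < 10.0:
        return "low"
    if ep_pct > 90.0:
        return "high"
    return "mid"


@dataclass(frozen=True)
class PrecisionAdvice:
    """A recommended precision range for one (EP, study scale) pair.

    ``recommended_high is None`` marks an open-ended recommendation
    (preliminary studies accept any precision looser than
    ``recommended_low``), capped only by ``hard_upper_bound``, the
    exclusive validity limit min(EP, 100 - EP).  All values in percent.
    """

    ep_pct: float
    regime: str
    scale: str
    recommended_low: float
    recommended_high: float | None
    hard_upper_bound: float

    @property
    def open_ended(self) -> bool:
        return self.recommended_high is None

    def to_dict(self) -> dict:
        return {
            "ep_pct": self.ep_pct,
            "regime": self.regime,
            "scale": self.scale,
            "recommended_low_pct": self.recommended_low,
            "recommended_high_pct": self.recommended_high,
            "hard_upper_bound_pct": self.hard_upper_bound,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def describe(self) -> str:
        """One-paragraph human rendering for the terminal."""
        if self.recommended_high is None:
            band = (
                f"any precision looser than {self.recommended_low:g}% "
                f"(the study should then be framed as preliminary)"
            )
        elif self.recommended_low == self.recommended_high:
            band = f"a precision of {self.recommended_low:g}%"
        else:
            band = f"a precision of {self.recommended_low:g} to {self.recommended_high:g}%"
        return (
            f"For an expected prevalence of {self.ep_pct:g}% ({self.regime} "
            f"regime) and a {self.scale}-scale study, consider {band}. "
            f"Whatever you choose, the precision cannot be "
            f"{self.hard_upper_bound:g}% or larger, or the anticipated "
            f"interval would leave the 0-100% scale. The final choice is "
            f"the researcher's informed decision."
        )


def recommend_precision(ep_pct: float, scale: str) -> PrecisionAdvice:
    """Recommended precision (percent) for an expected prevalence and scale."""
    regime = classify_regime(ep_pct)
    if scale not in SCALES:
        raise ValueError(f"unknown study scale {scale!r}; expected one of {SCALES}")
    bound = min(ep_pct, 100.0 - ep_pct)
    if regime == "mid":
        bands = {"large": (2.0, 3.0), "small": (4.0, 5.0), "preliminary": (5.0, None)}
    else:
        base = ep_pct if regime == "low" else 100.0 - ep_pct
        bands = {
            "large": (0.25 * base, 0.25 * base),
            "small": (0.50 * base, 0.50 * base),
            "preliminary": (0.50 * base, None),
        }
    low, high = bands[scale]
    return PrecisionAdvice(
        ep_pct=ep_pct,
        regime=regime,
        scale=scale,
        recommended_low=low,
        recommended_high=high,
        hard_upper_bound=bound,
    )


@dataclass(frozen=True)
class PrecisionVerdict:
    """Outcome of checking a user-chosen precision against an EP."""

    ep_pct: float
    d_pct: float
    valid: bool
    reason: str
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "ep_pct": self.ep_pct,
            "d_pct": self.d_pct,
            "valid": self.valid,
            "reason": self.reason,
            "warning": self.warning,
        }


def validate_precision(ep_pct: float, d_pct: float) -> PrecisionVerdict:
    """Check a chosen precision (percent) against the hard validity bound.

    Invalid iff ``d >= EP`` or ``d >= 100 - EP``.  Valid verdicts carry a
    softness warning when the precision is looser than the preliminary
    threshold for the regime (i.e. the study should be called preliminary).
    """
    classify_regime(ep_pct)  # domain check on EP
    if not (isinstance(d_pct, (int, float)) and math.isfinite(d_pct) and d_pct > 0):
        raise ValueError(f"precision must be a positive finite percent, got {d_pct!r}")
    if d_pct >= ep_pct:
        return PrecisionVerdict(
            ep_pct, d_pct, False,
            f"precision {d_pct:g}% cannot be equal to the expected "
            f"prevalence ({ep_pct:g}%) or larger",
        )
    if d_pct >= 100.0 - ep_pct:
        return PrecisionVerdict(
            ep_pct, d_pct, False,
            f"precision {d_pct:g}% cannot be equal to 100% minus the "
            f"expected prevalence ({100.0 - ep_pct:g}%) or larger",
        )
    preliminary_threshold = recommend_precision(ep_pct, "preliminary").recommended_low
    warning = None
    if d_pct > preliminary_threshold:
        warning = (
            f"precision {d_pct:g}% exceeds {preliminary_threshold:g}%; a study "
            "this imprecise should be framed as a preliminary study"
        )
    return PrecisionVerdict(ep_pct, d_pct, True, "within the validity bound", warning)
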