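"""Closed-form sample-size engine for estimating a single prevalence.

The planning model is the normal-approximation (Wald) interval for a
binomial proportion.  To estimate a prevalence ``P`` with absolute
precision ``d`` (the half-width of the anticipated confidence interval)
at confidence level ``1 - alpha``, the required simple-random-sample
size is

    n = Z^2 * P * (1 - P) / d^2

rounded **up** to the next integer.  Two standard inflations follow:
a design-effect multiplier for non-simple sampling schemes, then
division by ``(1 - loss)`` to pre-compensate anticipated non-response
or attrition.  Each inflation is ceiled, in that order; see
``compute_sample_size``.

All functions in this module work in proportions on (0, 1).  Percent
conversion is an interface concern (see :mod:`prevsize.cli`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "StudyParameters",
    "SampleSizeResult",
    "InvalidPrecisionError",
    "PlanningWarning",
    "z_for_confidence",
    "compute_base_n",
    "apply_design_effect",
    "apply_loss",
    "anticipated_ci",
    "compute_sample_size",
]

#: The conventional confidence level for prevalence estimates in the
#: medical and health sciences; anything else is legal but warned about.
DEFAULT_CONFIDENCE = 0.95

#: Anticipated losses at or above this fraction compromise how
#: representative the recruited sample can be, inflation notwithstanding.
ACCEPTABLE_LOSS = 0.10


class InvalidPrecisionError(ValueError):
    """Requested precision is impossible for the expected prevalence.

    The Wald interval P +/- d leaves [0, 1] whenever d >= P or
    d >= 1 - P, so such precisions are rejected outright.
    """


class PlanningWarning(UserWarning):
    """A parameter choice is legal but questionable for planning."""


def _check_proportion(value: float, name: str) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValueError(f"{name} must be a finite number, got {value!r}")
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie strictly between 0 and 1, got {value}")


def z_for_confidence(confidence: float) -> float:
    """Two-sided standard-normal critical value for a confidence level.

    ``z_for_confidence(0.95)`` is 1.959964..., the familiar 1.96.
    """
    _check_proportion(confidence, "confidence")
    return float(norm.ppf(0.5 + confidence / 2.0))


def _check_precision_validity(p: float, d: float) -> None:
    # Round to 12 dp so binary noise (e.g. 1 - 0.95 = 0.0500...044) cannot
    # let a precision exactly at the bound slip past the check.
    if round(d, 12) >= round(p, 12) or round(d, 12) >= round(1.0 - p, 12):
        raise InvalidPrecisionError(
            f"precision {d:g} must be smaller than both the expected "
            f"prevalence ({p:g}) and its complement ({1.0 - p:g}); "
            "otherwise the anticipated Wald interval leaves [0, 1]"
        )


def compute_base_n(p: float, d: float, confidence: float = DEFAULT_CONFIDENCE) -> int:
    """Required sample size ``ceil(Z^2 p (1-p) / d^2)`` before inflation."""
    _check_proportion(p, "expected prevalence")
    _check_proportion(d, "precision")
    _check_precision_validity(p, d)
    z = z_for_confidence(confidence)
    n = math.ceil(z * z * p * (1.0 - p) / (d * d))
    return max(n, 1)


def apply_design_effect(n: int, deff: float) -> int:
    """Inflate ``n`` for a complex sampling design: ``ceil(n * deff)``."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if not (math.isfinite(deff) and deff > 0):
        raise ValueError(f"design effect must be a positive finite number, got {deff!r}")
    if deff < 1.0:
        warnings.warn(
            f"design effect {deff:g} < 1 shrinks the sample size; values "
            "below 1 are unusual outside of highly efficient stratified designs",
            PlanningWarning,
            stacklevel=2,
        )
    return max(math.ceil(n * deff), 1)


def apply_loss(n: int, loss: float) -> int:
    """Inflate ``n`` for anticipated loss: ``ceil(n / (1 - loss))``.

    Dividing by the retention fraction (rather than multiplying by
    ``1 + loss``) guarantees that the *retained* sample still meets the
    planned size when the anticipated fraction is indeed lost.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if not (math.isfinite(loss) and 0.0 <= loss < 1.0):
        raise ValueError(f"loss must be a fraction in [0, 1), got {loss!r}")
    if loss >= ACCEPTABLE_LOSS:
        warnings.warn(
            f"anticipated loss of {loss:.0%} is at or above the commonly "
            "acceptable 10%; inflation compensates the count but not the "
            "non-response bias",
            PlanningWarning,
            stacklevel=2,
        )
    return math.ceil(n / (1.0 - loss))


def anticipated_ci(p: float, d: float) -> tuple[float, float]:
    """Anticipated confidence interval, in percent: (100(p-d), 100(p+d)).

    This is the interval the study expects to report if the observed
    prevalence matches the planning value.  Bounds outside [0, 100] are
    rejected: the Wald interval can overshoot the probability scale, a
    known weakness the precision-validity rule exists to prevent.
    """
    _check_proportion(p, "expected prevalence")
    _check_proportion(d, "precision")
    # Round away float noise from the proportion->percent conversion so
    # bounds print cleanly and the width identity (width == 2d) is exact.
    low = round(100.0 * p - 100.0 * d, 10)
    high = round(100.0 * p + 100.0 * d, 10)
    if low < 0.0 or high > 100.0:
        raise InvalidPrecisionError(
            f"anticipated interval ({low:g}%, {high:g}%) leaves [0%, 100%]: "
            f"precision {100 * d:g}% is inappropriate for an expected "
            f"prevalence of {100 * p:g}%"
        )
    return (low, high)


@dataclass(frozen=True)
class StudyParameters:
    """The planning inputs for a prevalence study.

    expected_prevalence
        Anticipated proportion with the condition, from literature or a
        pilot study; strictly in (0, 1).
    precision
        Absolute margin of error d, the half-width of the anticipated
        interval, as a proportion; must satisfy d < P and d < 1 - P.
    loss
        Anticipated fraction of the sample lost to non-response,
        incomplete data or follow-up loss; in [0, 1).
    design_effect
        Multiplier for complex sampling designs; 1.0 for simple random,
        systematic, or proportionate-stratified sampling.
    confidence
        Coverage level of the interval estimate; 0.95 by convention.
    """

    expected_prevalence: float
    precision: float
    loss: float = 0.0
    design_effect: float = 1.0
    confidence: float = DEFAULT_CONFIDENCE

    def __post_init__(self) -> None:
        _check_proportion(self.expected_prevalence, "expected_prevalence")
        _check_proportion(self.precision, "precision")
        _check_proportion(self.confidence, "confidence")
        if not (math.isfinite(self.loss) and 0.0 <= self.loss < 1.0):
            raise ValueError(f"loss must be in [0, 1), got {self.loss!r}")
        if not (math.isfinite(self.design_effect) and self.design_effect > 0):
            raise ValueError(f"design_effect must be positive, got {self.design_effect!r}")
        _check_precision_validity(self.expected_prevalence, self.precision)
        if self.confidence != DEFAULT_CONFIDENCE:
            warnings.warn(
                f"confidence level {self.confidence:g} departs from the "
                "conventional 0.95 used for prevalence estimates",
                PlanningWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class SampleSizeResult:
    """Full output of one sample-size calculation.

    ``n_base <= n_deff <= n_adjusted`` always holds: the base closed-form
    size, after the design-effect multiplier, and after loss inflation.
    CI fields are in percent and ``ci_width == 2 * precision`` exactly.
    """

    n_base: int
    n_deff: int
    n_adjusted: int
    ci_low: float
    ci_high: float
    ci_width: float
    parameters: StudyParameters

    def to_dict(self) -> dict:
        """JSON-ready mapping; percent-scale keys for human consumption."""
        p = self.parameters
        return {
            "expected_prevalence_pct": round(100.0 * p.expected_prevalence, 10),
            "precision_pct": round(100.0 * p.precision, 10),
            "confidence_pct": round(100.0 * p.confidence, 10),
            "loss_pct": round(100.0 * p.loss, 10),
            "design_effect": p.design_effect,
            "n_base": self.n_base,
            "n_deff": self.n_deff,
            "n_adjusted": self.n_adjusted,
            "ci_low_pct": self.ci_low,
            "ci_high_pct": self.ci_high,
            "ci_width_pct": self.ci_width,
        }


def compute_sample_size(params: StudyParameters) -> SampleSizeResult:
    """Run the full pipeline: base n, design effect, loss, anticipated CI.

    The design-effect multiplier is applied before loss inflation, each
    step ceiled, so the recruited sample covers attrition of the
    *effective* design size.
    """
    n_base = compute_base_n(params.expected_prevalence, params.precision, params.confidence)
    n_deff = apply_design_effect(n_base, params.design_effect)
    n_adjusted = apply_loss(n_deff, params.loss)
    ci_low, ci_high = anticipated_ci(params.expected_prevalence, params.precision)
    return SampleSizeResult(
        n_base=n_base,
        n_deff=n_deff,
        n_adjusted=n_adjusted,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_width=round(ci_high - ci_low, 10),
        parameters=params,
    )
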