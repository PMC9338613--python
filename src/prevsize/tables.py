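"""Decision-support tables: sample size over a precision grid, and the
prevalence-versus-n curve.

The precision grid table lets a researcher see, for their expected
prevalence, how quickly the required sample grows as the anticipated
confidence interval narrows, and choose a precision their resources can
bear.  The prevalence curve shows why "assume 50%" is a poor shortcut:
50% maximises the required n only while a fixed precision applies
(10-90% prevalence); outside that band the regime-scaled precision
rules drive n far higher.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .advisor import classify_regime, recommend_precision, validate_precision
from .core import DEFAULT_CONFIDENCE, StudyParameters, compute_sample_size

__all__ = [
    "TableRow",
    "SampleSizeTable",
    "default_grid",
    "build_table",
    "prevalence_curve",
]

#: Default precision grid (percent) for mid-regime prevalences: spans the
#: large-scale (2-3%), small-scale (4-5%) and preliminary (>5%) bands at
#: half-point steps.
MID_REGIME_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 10.0)

#: For low/high regimes the grid scales with the validity bound
#: min(EP, 100-EP): these fractions bracket the large-scale (0.25x) and
#: small-scale (0.5x) rules and extend into preliminary territory.
BOUNDARY_REGIME_FRACTIONS = (0.125, 0.1875, 0.25, 0.3125, 0.375, 0.5, 0.625, 0.75)


def default_grid(ep_pct: float) -> list[float]:
    """Regime-appropriate default precision grid, in percent."""
    if classify_regime(ep_pct) == "mid":
        return list(MID_REGIME_GRID)
    bound = min(ep_pct, 100.0 - ep_pct)
    return [f * bound for f in BOUNDARY_REGIME_FRACTIONS]


@dataclass(frozen=True)
class TableRow:
    precision_pct: float
    n: int
    ci_low_pct: float
    ci_high_pct: float
    ci_width_pct: float


@dataclass(frozen=True)
class SampleSizeTable:
    """Sample sizes over a precision grid for one expected prevalence.

    ``rows`` are sorted by increasing precision (n non-increasing down
    the table).  Grid entries failing the validity bound are recorded in
    ``skipped`` with the reason, never silently dropped.
    """

    ep_pct: float
    loss: float
    design_effect: float
    confidence: float
    rows: tuple[TableRow, ...]
    skipped: tuple[tuple[float, str], ...] = field(default_factory=tuple)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.precision_pct, r.n, r.ci_low_pct, r.ci_high_pct, r.ci_width_pct)
                for r in self.rows
            ],
            columns=["precision_pct", "n", "ci_low_pct", "ci_high_pct", "ci_width_pct"],
        )

    def to_csv(self, path_or_buf=None, sep: str = ","):
        return self.to_dataframe().to_csv(path_or_buf, sep=sep, index=False)

    def to_text(self) -> str:
        """Aligned plain-text rendering for the terminal."""
        buf = io.StringIO()
        buf.write(
            f"Sample sizes for expected prevalence {self.ep_pct:g}% "
            f"(loss {100 * self.loss:g}%, design effect {self.design_effect:g}, "
            f"confidence {100 * self.confidence:g}%)\n"
        )
        buf.write(self.to_dataframe().to_string(index=False))
        for d, reason in self.skipped:
            buf.write(f"\n[skipped] precision {d:g}%: {reason}")
        return buf.getvalue()


def build_table(
    ep_pct: float,
    loss: float = 0.0,
    grid: list[float] | None = None,
    design_effect: float = 1.0,
    confidence: float = DEFAULT_CONFIDENCE,
) -> SampleSizeTable:
    """Build the precision-grid decision table for one expected prevalence.

    Each valid grid precision yields one row computed through the full
    pipeline (base n, design effect, loss).  Invalid precisions are
    retained as skipped entries.  Raises if no grid entry survives.
    """
    if grid is None:
        grid = default_grid(ep_pct)
    if not grid:
        raise ValueError("precision grid must be non-empty")
    rows: list[TableRow] = []
    skipped: list[tuple[float, str]] = []
    for d_pct in sorted(set(float(d) for d in grid)):
        verdict = validate_precision(ep_pct, d_pct)
        if not verdict.valid:
            skipped.append((d_pct, verdict.reason))
            continue
        result = compute_sample_size(
            StudyParameters(
                expected_prevalence=ep_pct / 100.0,
                precision=d_pct / 100.0,
                loss=loss,
                design_effect=design_effect,
                confidence=confidence,
            )
        )
        rows.append(
            TableRow(d_pct, result.n_adjusted, result.ci_low, result.ci_high, result.ci_width)
        )
    if not rows:
        bound = min(ep_pct, 100.0 - ep_pct)
        raise ValueError(
            f"no grid precision is valid for an expected prevalence of "
            f"{ep_pct:g}%: all entries reach the bound {bound:g}%. Use a "
            f"grid below {bound:g}%, e.g. fractions of the bound such as "
            f"{[round(f * bound, 4) for f in (0.25, 0.5, 0.75)]}"
        )
    return SampleSizeTable(
        ep_pct=ep_pct,
        loss=loss,
        design_effect=design_effect,
        confidence=confidence,
        rows=tuple(rows),
        skipped=tuple(skipped),
    )


def _curve_precision_pct(ep_pct: float, scale: str) -> float:
    """Per-EP precision under the advisory rule for a fixed study scale.

    Small scale (the conventional illustration): fixed 5% in the mid
    regime, 0.5*EP below 10%, 0.5*(100-EP) above 90%.  Large scale uses
    the tight ends: 3%, 0.25*EP, 0.25*(100-EP).
    """
    advice = recommend_precision(ep_pct, scale)
    if advice.recommended_high is None:
        raise ValueError(
            "the preliminary scale has no point precision rule; "
            "use 'large' or 'small' for the prevalence curve"
        )
    # Mid-regime bands are ranges; the curve uses the loose end (5% for
    # small, 3% for large). Boundary regimes give point values.
    return advice.recommended_high


def prevalence_curve(
    ep_grid: list[float],
    scale: str = "small",
    loss: float = 0.0,
    confidence: float = DEFAULT_CONFIDENCE,
) -> list[tuple[float, int]]:
    """Required n across expected prevalences, precision set per regime rule.

    Returns ``[(ep_pct, n), ...]`` in the order of ``ep_grid``.
    """
    curve: list[tuple[float, int]] = []
    for ep_pct in ep_grid:
        d_pct = _curve_precision_pct(ep_pct, scale)
        result = compute_sample_size(
            StudyParameters(
                expected_prevalence=ep_pct / 100.0,
                precision=d_pct / 100.0,
                loss=loss,
                confidence=confidence,
            )
        )
        curve.append((ep_pct, result.n_adjusted))
    return curve
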