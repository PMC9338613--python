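"""Publication-style sample-size paragraph.

A sample-size calculation is reproducible only if every parameter is
reported: the confidence level, the expected prevalence (and where it
came from), the precision, and the anticipated loss — plus the design
effect when one was applied, and the software used.  ``draft_report``
renders all of these into a paragraph a researcher can paste into a
methods section, together with a machine-readable echo of each field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .core import SampleSizeResult

__all__ = ["ReportDraft", "draft_report"]

SOFTWARE_CITATION_PLACEHOLDER = (
    "prevsize sample-size calculator [ADD VERSION AND REFERENCE]"
)


def _fmt(x: float) -> str:
    """Percent value with at most 2 decimals, trailing zeros stripped."""
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


@dataclass(frozen=True)
class ReportDraft:
    """A draft methods paragraph plus the exact values it echoes."""

    text: str
    fields_echoed: dict

    def to_json(self) -> str:
        return json.dumps(self.fields_echoed, sort_keys=True)


def draft_report(
    result: SampleSizeResult,
    source_note: str = "recent literature",
    software_note: str = SOFTWARE_CITATION_PLACEHOLDER,
) -> ReportDraft:
    """Render a deterministic methods paragraph from a calculation result.

    ``source_note`` states where the expected prevalence came from
    (literature, pilot study, ...).  Identical inputs yield byte-identical
    text.
    """
    p = result.parameters
    conf = _fmt(100.0 * p.confidence)
    ep = _fmt(100.0 * p.expected_prevalence)
    d = _fmt(100.0 * p.precision)
    loss = _fmt(100.0 * p.loss)
    deff = _fmt(p.design_effect)

    sentences = [
        "The sample size was calculated for estimating a single prevalence.",
        f"Based on an expected prevalence of {ep}% (from {source_note}), "
        f"a {conf}% confidence level and an absolute precision of {d}%, "
        f"the required sample size is {result.n_base}, giving an "
        f"anticipated {conf}% confidence interval of "
        f"({_fmt(result.ci_low)}%, {_fmt(result.ci_high)}%).",
    ]
    if p.design_effect != 1.0:
        sentences.append(
            f"Applying a design effect of {deff} for the sampling design "
            f"increases the sample size from {result.n_base} to {result.n_deff}."
        )
    if p.loss > 0.0:
        sentences.append(
            f"Allowing for an anticipated loss (non-response or attrition) "
            f"of {loss}%, the final sample size required is {result.n_adjusted}."
        )
    else:
        sentences.append(
            f"No loss to non-response or attrition was anticipated ({loss}%); "
            f"the final sample size required is {result.n_adjusted}."
        )
    sentences.append(f"The calculation was performed with {software_note}.")

    fields_echoed = {
        "confidence_pct": float(conf),
        "expected_prevalence_pct": float(ep),
        "expected_prevalence_source": source_note,
        "precision_pct": float(d),
        "loss_pct": float(loss),
        "design_effect": float(deff),
        "n_base": result.n_base,
        "n_deff": result.n_deff,
        "n_adjusted": result.n_adjusted,
        "software": software_note,
    }
    return ReportDraft(text=" ".join(sentences), fields_echoed=fields_echoed)
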