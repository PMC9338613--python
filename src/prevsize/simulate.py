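"""Monte-Carlo and exact verification of the planning guarantee.

The calculator promises that a study of the computed size, analysed
with the Wald interval p_hat +/- Z*sqrt(p_hat(1-p_hat)/n), will (a)
cover the true prevalence at roughly the nominal rate and (b) deliver
a half-width no wider than the planned precision.  This module makes
that promise testable two ways:

* ``simulate_precision`` draws binomial samples and measures empirical
  coverage and half-widths;
* ``exact_coverage`` enumerates all n+1 binomial outcomes and sums the
  probability of those whose Wald interval covers the truth — an exact,
  deterministic oracle the simulation must agree with.

Wald coverage is famously jagged in n and p (it can dip well below
nominal for small n or extreme p); the validator reports what the
chosen interval actually delivers rather than substituting a
better-behaved interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .core import DEFAULT_CONFIDENCE, z_for_confidence

__all__ = [
    "SimulationSummary",
    "simulate_precision",
    "exact_coverage",
    "monte_carlo_tolerance",
]


def _wald_covers(k: np.ndarray, n: int, true_p: float, z: float) -> np.ndarray:
    """Boolean mask: does the Wald interval at count k cover true_p?

    Degenerate outcomes (k = 0 or k = n) give zero-width intervals at 0
    or 1, which never cover an interior true_p.
    """
    phat = k / n
    half = z * np.sqrt(phat * (1.0 - phat) / n)
    return (phat - half <= true_p) & (true_p <= phat + half)


@dataclass(frozen=True)
class SimulationSummary:
    """Result of one Monte-Carlo precision/coverage experiment.

    ``frac_half_width_le_d`` is populated only when a planning precision
    was supplied.  ``n_degenerate`` counts replicates with p_hat of 0 or
    1, whose zero-width intervals are included in the coverage tally.
    """

    true_p: float
    n: int
    replicates: int
    seed: int
    confidence: float
    empirical_coverage: float
    mean_half_width: float
    frac_half_width_le_d: float | None
    planning_precision: float | None
    n_degenerate: int

    def to_dict(self) -> dict:
        return {
            "true_p": self.true_p,
            "n": self.n,
            "replicates": self.replicates,
            "seed": self.seed,
            "confidence": self.confidence,
            "empirical_coverage": self.empirical_coverage,
            "mean_half_width": self.mean_half_width,
            "frac_half_width_le_d": self.frac_half_width_le_d,
            "planning_precision": self.planning_precision,
            "n_degenerate": self.n_degenerate,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def simulate_precision(
    true_p: float,
    n: int,
    replicates: int,
    seed: int,
    confidence: float = DEFAULT_CONFIDENCE,
    planning_d: float | None = None,
) -> SimulationSummary:
    """Simulate repeated studies of size ``n`` at prevalence ``true_p``.

    Draws ``replicates`` binomial counts, forms each study's Wald
    interval, and summarises coverage of ``true_p``, the mean half-width,
    and (when ``planning_d`` is given) the fraction of half-widths at or
    below the planned precision.  Fixed seed implies a bit-identical
    summary.
    """
    if not (0.0 < true_p < 1.0):
        raise ValueError(f"true_p must be in (0, 1), got {true_p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    z = z_for_confidence(confidence)
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n, true_p, size=replicates)
    phat = counts / n
    half = z * np.sqrt(phat * (1.0 - phat) / n)
    covered = _wald_covers(counts, n, true_p, z)
    degenerate = int(np.count_nonzero((counts == 0) | (counts == n)))
    frac_le = None
    if planning_d is not None:
        if not (0.0 < planning_d < 1.0):
            raise ValueError(f"planning_d must be in (0, 1), got {planning_d}")
        frac_le = float(np.mean(half <= planning_d))
    return SimulationSummary(
        true_p=true_p,
        n=n,
        replicates=replicates,
        seed=seed,
        confidence=confidence,
        empirical_coverage=float(np.mean(covered)),
        mean_half_width=float(np.mean(half)),
        frac_half_width_le_d=frac_le,
        planning_precision=planning_d,
        n_degenerate=degenerate,
    )


def exact_coverage(true_p: float, n: int, confidence: float = DEFAULT_CONFIDENCE) -> float:
    """Exact Wald coverage probability by enumeration of all counts 0..n.

    Sums the binomial pmf over every count whose Wald interval covers
    ``true_p``.  Deterministic; the brute-force oracle for
    :func:`simulate_precision`.
    """
    if not (0.0 < true_p < 1.0):
        raise ValueError(f"true_p must be in (0, 1), got {true_p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    z = z_for_confidence(confidence)
    k = np.arange(n + 1)
    covered = _wald_covers(k, n, true_p, z)
    return float(binom.pmf(k[covered], n, true_p).sum())


def monte_carlo_tolerance(coverage: float, replicates: int, n_se: float = 3.0) -> float:
    """``n_se`` binomial standard errors for an empirical coverage estimate."""
    if not (0.0 <= coverage <= 1.0) or replicates < 1:
        raise ValueError("coverage must be in [0, 1] and replicates >= 1")
    return n_se * math.sqrt(coverage * (1.0 - coverage) / replicates)
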