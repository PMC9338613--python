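# Methods

## Planning model

The package plans studies whose estimand is a single population
proportion (a prevalence). The sampling model is binomial: a simple
random sample of size *n* from a large population in which a fraction
*P* has the condition. The analysis interval assumed throughout is the
Wald (normal-approximation) interval

    p̂ ± Z · √(p̂(1 − p̂)/n),

with *Z* the two-sided standard-normal critical value for the chosen
confidence level. Setting the interval's half-width at the planning
value *P* equal to the desired absolute precision *d* and solving for
*n* gives the closed form

    n = Z²·P·(1 − P)/d²,

rounded **up** to the next integer (a sample size is a count of people;
rounding up is the only direction that cannot under-deliver the
precision). All computation is done in proportions on (0, 1); percent
is an interface convention handled at the CLI boundary.

*Z* is computed as the exact normal quantile (1.959964… at 95%) rather
than the textbook 1.96; at the magnitudes involved in prevalence
planning the two produce identical integers after the ceiling.
Confidence is a parameter defaulting to 0.95 — the near-universal
convention for prevalence estimates in health research — and any other
level triggers a warning rather than an error, keeping the engine
general while steering non-statistician users toward the convention.

### Inflation steps and their order

Two inflations follow the base calculation, each ceiled:

1. **Design effect** (default 1.0): multiply by *deff* when the sampling
   scheme is not simple/systematic/proportionate-stratified random
   sampling. The package applies but does not estimate design effects;
   users should take them from comparable published studies. Values
   below 1 are accepted with a warning (they arise only in unusually
   efficient stratified designs).
2. **Anticipated loss** (default 0): divide by (1 − loss). Division by
   the retention fraction — not multiplication by (1 + loss) — is the
   form that guarantees the retained sample still meets the planned
   size when the anticipated fraction is lost. Losses of 10% or more
   warn: inflation restores the count, not the representativeness lost
   to non-response bias.

The order is base-n → ceiling → design effect → ceiling → loss →
ceiling. Applying the design effect before loss inflation was a
genuinely open choice; it is the conservative one (the reverse order
can only be smaller, and only by rounding), and it reads naturally:
inflate the effective-design sample for attrition.

### Precision validity

The anticipated interval is P ± d. If d ≥ P or d ≥ 1 − P, that interval
leaves the probability scale — the Wald interval's known weakness for
extreme proportions — so such precisions are rejected as errors rather
than warned about. The comparison is made after rounding both sides to
12 decimal places so that binary float noise (e.g. 1 − 0.95 =
0.0500…044) cannot let a precision exactly at the bound slip through.

## Precision advisor

Recommendations depend on the expected-prevalence regime and the study
scale:

| Regime | Large scale | Small scale | Preliminary |
|---|---|---|---|
| 10% ≤ EP ≤ 90% | 2–3% | 4–5% | > 5% |
| EP < 10% | 0.25·EP | 0.50·EP | > 0.50·EP |
| EP > 90% | 0.25·(100−EP) | 0.50·(100−EP) | > 0.50·(100−EP) |

Boundary prevalences of exactly 10% and 90% belong to the mid regime;
the scaled rules meet the fixed band continuously there (0.5 × 10 = 5).
The preliminary column is open-ended: the advisor reports the threshold
and the hard bound min(EP, 100 − EP) but never auto-selects a
precision — the final choice is the researcher's informed decision.
Scaled recommendations are not rounded (EP = 3% yields 0.75% as-is).
`validate_precision` enforces only the hard bound; precisions looser
than the preliminary threshold are valid but flagged, since a study
that imprecise should be framed as preliminary.

## Decision tables and the prevalence curve

`build_table` computes the full pipeline over a precision grid. The
default mid-regime grid is {1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5, 10}
percent: half-point steps spanning the large-scale and small-scale
bands plus one preliminary point. For low/high regimes a fixed grid
would be mostly invalid, so the default scales with the bound:
fractions {0.125, 0.1875, 0.25, 0.3125, 0.375, 0.5, 0.625, 0.75} of
min(EP, 100 − EP), bracketing the 0.25× and 0.5× advisory rules. Grid
entries failing the validity bound are recorded as skipped rows with
the reason — never silently dropped — so the table is honest about what
the bound excludes.

`prevalence_curve` shows why "assume P = 50%" is a poor shortcut. Under
a fixed precision, P(1 − P) and hence n peak at 50%; but the advisory
rules shrink d outside the 10–90% band, and there the required n rises
far above the 50% value (e.g. EP 2% at its small-scale rule d = 1%
needs n = 753, versus 385 at EP 50%, d = 5%). The curve uses the loose
end of the recommendation band (5% small / 3% large) in the mid regime
and the scaled point rules outside it; the preliminary scale has no
point rule and is rejected.

## Report

`draft_report` renders a deterministic methods paragraph from a result.
A sample-size calculation is reproducible only if every parameter is
reported, so the paragraph always states the confidence level, the
expected prevalence and its source, the precision, the anticipated loss
(explicitly zero-stated when absent), the design effect sentence when
deff ≠ 1, both the base and final n, and a software-citation
placeholder. The wording is this package's own; tests assert field
presence and determinism, not sentence prose. Percentages are rendered
with at most two decimals, n as integers, and every printed number
parses back exactly to the machine-readable `fields_echoed` mapping.

## Verification module

The calculator's implicit promise — that a study of the computed size,
analysed with the Wald interval, covers the true prevalence at roughly
the nominal rate with half-width at most d — is made testable two ways:

- `exact_coverage(p, n)` enumerates all n + 1 binomial outcomes and
  sums the pmf over those whose Wald interval covers p. Deterministic
  and exact; at desk scales (n in the thousands) this is a trivial
  vectorised computation.
- `simulate_precision(p, n, replicates, seed)` draws binomial counts
  from a seeded `numpy.random.default_rng` generator (no hidden global
  state; bit-identical summaries for identical seeds) and reports
  empirical coverage, mean half-width, and the fraction of half-widths
  within the planning precision.

Both routes share one coverage predicate so their agreement tests
Monte-Carlo error only. The test criterion is agreement within 3
binomial standard errors √(c(1−c)/R) at R = 10,000 replicates.
Degenerate outcomes (p̂ of 0 or 1) produce zero-width intervals that
never cover an interior truth; they are counted and reported, never
fatal. The Wald interval is used deliberately, matching the
calculator's own CI method: the validator tests the tool's actual
promise, not a better interval's. Wald coverage is known to oscillate
below nominal (at p = 0.30, n = 897 the exact coverage is ≈ 0.946);
the validator reports what is delivered rather than smoothing it.

### What the simulation does and does not show

The binomial draws emulate exactly the model the closed form assumes:
independent, identically distributed sampling from a large population
with a known true prevalence. Passing tests therefore show internal
consistency — the computed n delivers its promised width and coverage
*under the planning model*. They cannot show robustness to what real
surveys face: cluster correlation beyond a constant design effect,
informative non-response (inflation restores count, not
representativeness), or a planning prevalence far from the truth.

## Numerical choices

- Rounding of sample sizes is always ceiling; computed n is floored at
  1; prevalences of exactly 0 or 1 are rejected rather than returning 0.
- Percent-scale CI outputs are rounded to 10 decimal places to remove
  proportion→percent conversion noise, making identities such as
  ci_width = 2d exact; 10 dp is far below planning-relevant resolution.
- The precision-validity comparison rounds to 12 dp (see above).
- Simulation sizes: 10,000 replicates give a 3-SE coverage tolerance of
  about ±0.007 at 95% nominal — tight enough to detect an implementation
  error of one interval form vs another, loose enough to be stable
  across seeds — and run in well under a second at worked-example sizes.

## Limitations

- No finite population correction: the population is assumed unknown
  and large, the safer default when the later analysis will not use
  survey-weighted methods either.
- Wald-only planning: alternative intervals (Wilson, exact, logit) are
  out of scope; inappropriate precision choices are prevented by the
  validity bound instead.
- Not applicable to means, group comparisons, or regression objectives.
- Design effects are applied, never estimated.
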