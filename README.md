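# prevsize

Sample-size planning for prevalence (single-proportion) studies:
epidemiological surveys whose objective is to estimate what fraction of a
population has a condition — obesity, smoking, diabetes — to a chosen
margin of error. It is written for researchers planning such a study and
for methodologists reviewing one.

## The method

To estimate a prevalence *P* with a two-sided confidence level 1 − α and
an absolute precision *d* (the half-width of the anticipated confidence
interval), the required simple-random-sample size is

```
n = ⌈ Z²·P·(1 − P) / d² ⌉
```

where *Z* is the standard-normal critical value (1.96 for 95%
confidence). Two inflations follow, each rounded up: multiplication by a
design effect *deff* for complex sampling schemes, then division by
(1 − loss) so that the *retained* sample still meets the target after
anticipated non-response or attrition. The anticipated interval is the
Wald interval P ± d; choices of *d* at or beyond min(P, 1 − P) are
rejected because that interval would leave the 0–100% scale.

Beyond the closed form, the package provides:

- **Precision advice** by expected-prevalence regime: fixed 2–3% (large
  studies) or 4–5% (small studies) bands for prevalences between 10% and
  90%; scaled rules 0.25×EP / 0.5×EP for rare conditions and the mirror
  rules for near-universal ones. Looser precisions mark the study as
  preliminary.
- **Decision tables** of n across a precision grid, so the trade-off
  between interval width and cost is visible before committing.
- **A draft methods paragraph** echoing all four planning parameters
  (confidence, expected prevalence, precision, loss) plus the design
  effect and final n, so the calculation is reproducible from the report.
- **Verification**: exact enumeration of the Wald interval's coverage
  probability over all binomial outcomes, and a seeded Monte-Carlo
  simulation that must agree with it — a check that the computed n really
  delivers the promised precision and near-nominal coverage.

## Worked example

A study will estimate the prevalence of obesity among secondary-school
children. The literature suggests 30% prevalence; previous studies in
this population saw 10% non-response; a ±3% margin of error is
acceptable.

```
$ prevsize --quiet calc --percent -p 30 -d 3 --loss 10 --report
Required sample size: 997 (base 897, after design effect 897)
Anticipated 95% CI: (27%, 33%), width 6%

The sample size was calculated for estimating a single prevalence. Based on an
expected prevalence of 30% (from recent literature), a 95% confidence level and
an absolute precision of 3%, the required sample size is 897, giving an
anticipated 95% confidence interval of (27%, 33%). Allowing for an anticipated
loss (non-response or attrition) of 10%, the final sample size required is 997.
The calculation was performed with prevsize sample-size calculator [ADD VERSION
AND REFERENCE].
```

The base size 897 is ⌈1.96²·0.3·0.7/0.03²⌉; dividing by the 90% retention
and rounding up gives the 997 participants to recruit. The same study in
proportion units: `prevsize calc --proportion -p 0.3 -d 0.03 --loss 0.1`.

Before choosing the precision, inspect the trade-off:

```
$ prevsize table -p 25 --grid 2,5,10 -o csv
precision_pct,n,ci_low_pct,ci_high_pct,ci_width_pct
2.0,1801,23.0,27.0,4.0
5.0,289,20.0,30.0,10.0
10.0,73,15.0,35.0,20.0
```

and ask for regime-appropriate advice (here, a rare condition):

```
$ prevsize advise -p 4 --scale small
For an expected prevalence of 4% (low regime) and a small-scale study, consider
a precision of 2%. Whatever you choose, the precision cannot be 4% or larger,
or the anticipated interval would leave the 0-100% scale. The final choice is
the researcher's informed decision.
```

Finally, verify that the computed size keeps its promise:

```
$ prevsize --quiet verify --percent -p 30 -d 3 --seed 7
n = 897, true prevalence = 0.3, replicates = 10000, seed = 7
[PASS] empirical coverage 0.9440 vs exact 0.9461 (tolerance ±0.0068, 3 binomial SEs)
[PASS] mean half-width 0.02996 <= planning precision 0.03
```

Every subcommand is a thin wrapper over the library; the same results are
available from Python via `prevsize.compute_sample_size`,
`prevsize.build_table`, `prevsize.recommend_precision`,
`prevsize.draft_report` and `prevsize.simulate_precision`.

## Limitations

The method assumes a large, effectively infinite population (no finite
population correction) and plans for the Wald interval only; it is not
suitable for estimating means, comparing groups, or regression analyses.
See `docs/methods.md` for the full model description and design choices.
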