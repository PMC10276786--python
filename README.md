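# sbrkit

Structured benefit-risk (sBR) assessment for two-arm clinical programs:
value trees of Key Clinical Benefits and Key Safety Risks, ordinal and
anchor-100 Delphi weighting, NNT/NNH with properly inverted (possibly
disjoint) confidence regions, MCDA net clinical benefit with weight
sensitivity analysis, the context-table / effects-table / forest-plot
deliverables, a milestone-driven methodology recommender, and a linted
1–2 page Core Company BR position.

It is written for the people who assemble benefit-risk assessments in
pharmaceutical development — patient-safety physicians, epidemiologists
and biostatisticians — who need the quantitative pieces of an sBR
process to be computed correctly and reproducibly from raw event counts
rather than transcribed.

## The statistics at the core

For a two-arm comparison with event proportions `p_t` and `p_c`, the risk
difference is `rd = p_t − p_c` and the number needed to treat (or harm)
is `NNT = ⌈1/|rd|⌉`. The confidence region for the NNT comes from
inverting the risk-difference interval `(l, u)`:

- if the interval excludes 0, the region is the finite integer interval
  `(⌈1/u⌉, ⌈1/l⌉)` (for a positive `rd`);
- if the interval spans 0, inversion produces the **disjoint union of two
  half-infinite intervals** `(−∞, ⌈1/l⌉] ∪ [⌈1/u⌉, +∞)` — collapsing this
  into a single finite interval is a classic NNT reporting error, and
  `sbrkit` never does it.

The default risk-difference interval is the hybrid score (Newcombe)
method built from per-arm Wilson score bounds `(l_t,u_t)`, `(l_c,u_c)`:

```
lower = rd − √((p_t − l_t)² + (u_c − p_c)²)
upper = rd + √((u_t − p_t)² + (p_c − l_c)²)
```

which keeps near-nominal coverage at small event counts, where the Wald
interval does not. A Wald variant is available for comparison.

The MCDA score is linear: each node contributes
`normalized weight × frequency` per arm, benefits add and risks
subtract, and the net clinical benefit difference between arms is the
decision quantity. Weights come from an anchor-100 elicitation (the
single most important benefit fixed at 100, all other nodes scored
relative to it), aggregated across raters by the median of the final
Delphi round.

## Worked example

The bundled worked example is a drug-vs-placebo comparison with one
efficacy outcome (response: 143/177 vs 226/342) and one safety outcome
(discontinuation due to adverse events: 7/206 vs 10/432):

```
$ sbrkit nnt examples/counts.csv
response_rate: NNT 7 (5, 15)
discontinuation_ae: NNH 93 (-inf, -67] U [22, +inf)
```

Reading: 7 patients must be treated for one additional response
(per-arm rates 80.8% vs 66.1%); the NNT's 95% confidence interval runs
from 5 to 15 patients. The discontinuation excess is 1 per 93 patients,
but its risk-difference interval spans zero, so the NNH confidence
region is disjoint: values at or beyond 22 (harm) together with values
at or beyond −67 (i.e. NNT-to-benefit of 67 or more) are all compatible
with the data at the 95% level — the data do not rule out no harm at
all.

The same counts drive the semi-quantitative displays:

```
$ sbrkit recommend submission --br-complexity complex_or_borderline
category: fully_quantitative
methods:  nnt_nnh, mcda
```

and the library API mirrors every command (`sbrkit.nnt`,
`sbrkit.mcda_score`, `sbrkit.build_effects_table`,
`sbrkit.recommend`, `sbrkit.render_cbr`, …). See `docs/methods.md` for
the full model description and conventions.

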