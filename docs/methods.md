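# Methods

This note describes the models and conventions implemented in `sbrkit`,
the choices made where the design was genuinely open, and what the test
suite's synthetic data does and does not establish about real trials.

## Data model

The statistical atom is a two-arm comparison: event counts `n` of `N`
per arm for one outcome, tagged `favorable` (a clinical benefit — more
events are good) or `unfavorable` (a safety risk). Only pairwise
treatment-vs-comparator designs are supported; multi-arm files are
rejected rather than silently reduced. Percentages and proportions are
always derived from the counts — printed percentages in source tables
are display artifacts, not inputs. (In the bundled worked example the
safety row's transcribed percentage for 7/206 is internally inconsistent
with its own counts; the counts are authoritative and reproduce the
published NNH exactly, which is why the reader ignores percent columns
entirely.)

## Proportion and risk-difference intervals

Per-arm intervals use the Wilson score method (via
`statsmodels.stats.proportion.proportion_confint`), with the boundary
cases pinned exactly: zero events give a lower bound of exactly 0, all
events a upper bound of exactly 1. The Wilson interval is
symmetric-in-complement — the interval for `n − x` mirrors the interval
for `x` about 0.5 — and this is property-tested.

The default risk-difference interval is the hybrid score (Newcombe)
construction: the distance from `rd` to each bound is the quadrature sum
of the corresponding per-arm Wilson gaps. It was chosen as the default
because it is the standard score-based method with near-nominal coverage
at small event counts; a Monte-Carlo check at `n = 200` per arm and true
rates (0.10, 0.05) over 5,000 replicates keeps empirical coverage inside
[0.93, 0.97]. The Wald interval is provided for comparison only. Bounds
are clipped to [−1, 1].

## NNT/NNH inversion

- Point estimate: `⌈1/|rd|⌉` — the ceiling convention of the NNT
  literature (a "number of patients" is rounded up). `NNT = 1` exactly
  when `|rd| = 1`.
- Labeling: NNT when the treatment does better on the outcome (more of a
  favorable one, fewer of an unfavorable one), NNH otherwise. Swapping
  the arms negates `rd` and exchanges NNT↔NNH at the same magnitude.
- Interval: inverted risk-difference bounds, rounded with mathematical
  ceiling (`⌈21.3⌉ = 22`, `⌈−67.1⌉ = −67`). If the risk-difference
  interval excludes zero the result is a finite integer interval; if it
  spans zero the region is the disjoint union `(−∞, ⌈1/l⌉] ∪ [⌈1/u⌉, +∞)`
  with the negative branch read as "number needed to benefit". The
  branch condition (`l ≤ 0 ≤ u`) is exhaustively verified against a
  brute-force classifier on all small 2×2 tables up to `N = 8` per arm.
- `rd = 0` exactly: the point estimate is undefined (flagged, `point =
  None`); the region is still computed from the interval. The NNT/NNH
  label then carries no information about effect direction and defaults
  to the outcome's direction (NNT for favorable outcomes).
- For the worked example's efficacy row the ceiling convention yields an
  upper bound of 15 (1/0.0667 ≈ 14.98); published versions of that
  example print 14 without stating a rounding rule. The package applies
  one rule uniformly rather than special-casing a bound.
- JSON serialization spells infinite bounds as the strings `"-inf"` /
  `"+inf"` and carries an explicit `interval_type` of `finite` or
  `disjoint_union`.

Risk ratios use the log-ratio normal interval. The point estimate always
comes from the raw counts; when any cell of the 2×2 table is zero the
interval (only) is computed after adding 0.5 to all four cells
(Haldane–Anscombe) and the result is flagged `continuity_corrected` so a
report can say so.

## Value trees and weighting

A value tree is two ordered lists of nodes (benefits, risks) with
precise clinical definitions and optional links into a counts dataset.
Validation enforces what can be machine-checked: unique ids and labels
(errors), non-empty sides (errors), identical definition text on two
nodes (a double-counting warning), and the cardinality guidance — 2–3
benefits, 6–8 risks — as warnings, because the guidance is a target, not
a hard rule. Semantic overlap between clinical definitions cannot be
verified syntactically and is out of scope.

Ordinal weighting is a per-side permutation `1..k` of relative medical
importance; it rearranges the rendered tree and deliberately carries no
cardinal meaning (`normalize_weights` refuses ordinal sets). Event
frequencies play no part in weighting — importance is judged per single
occurrence of each benefit or risk.

Anchor-100 weighting fixes the single most important benefit at exactly
100 and scores all other nodes in (0, 100] relative to it. Multi-rater
elicitation is aggregated by the per-node **median of the final Delphi
round** — the median is robust to a single extreme rater, and the final
round is taken as the panel's settled view. Convergence (inter-rater
range per node against a facilitator-chosen threshold, default 20
points) is reported, never enforced. The scheme is intentionally a
minimal multi-round median process; richer feedback formats between
rounds are a facilitation concern, not a computational one.

## MCDA

Contribution of node `i` in arm `a`: `w̃_i · f_{i,a}`, where `w̃` are the
anchor-100 weights normalized to sum to one over all scored nodes and
`f` is the event frequency (observed or estimated, flagged as such).
Benefits add, risks subtract; the net clinical benefit of an arm is
benefit total minus risk total, and the decision quantity is
`net(treatment) − net(comparator)`, favorable iff positive. The value
function is deliberately linear in frequency; nonlinear partial-value
functions exist in the broader MCDA literature but are out of scope.
Chart records report each node's signed between-arm contribution
difference, ordered benefits-then-risks by descending magnitude; they
sum to the net difference exactly (additivity is tested at 1e−12).

Sensitivity analysis perturbs the weights (the subjective input): each
draw multiplies every non-anchor weight by an independent uniform factor
in `[1−h, 1+h]`, clips into (0, 100] to preserve the anchor semantics,
re-normalizes and re-scores. `sign_stability` is the fraction of draws
whose favorability verdict matches the baseline; `h = 0` gives exactly
1.0. The scheme string is recorded in the report so a reader knows
precisely what was varied. Frequencies are not perturbed — sampling
uncertainty in frequencies is visible in the interval estimates instead.

## Framework displays

- **Context table**: four fixed rows × (overview and evidence,
  uncertainties and implications); empty cells render as "not yet
  available" and a completeness score (filled/8) summarizes maturity.
- **Effects table**: favorable rows before unfavorable; per-arm cells
  recomputed from counts as percentages with one-decimal **half-up**
  rounding (80.8, 66.1); every row must carry uncertainties text —
  missing text on a linked node is an error, unlinked nodes get an
  auto-generated missing-data note. Externally computed effects (e.g. a
  hazard ratio from a time-to-event analysis) pass through as text;
  the package never computes survival statistics.
- **Forest data**: one record per node on the risk-ratio (log) or
  risk-difference (linear) scale; zero-cell outcomes are flagged, never
  dropped; ordering follows the weighted tree when weights are given.
  Rendering targets are CSV and an optional static matplotlib figure.

## Methodology recommender

A first-match rule table over (milestone, data maturity, BR complexity):
context table at first-time-in-human; value tree plus weighted value
tree at Phase IIb; effects table at Phase III with pivotal data, else
the weighted-value-tree fallback; at submission the semi-quantitative
base case (effects table / forest plot), fully quantitative (NNT/NNH for
one-benefit-vs-one-comparable-risk, MCDA for multiple disparate
criteria) for complex or borderline profiles, and a descriptive position
when data remain minimal. The table is shipped as editable YAML
(`sbrkit/data/selector_rules.yaml`, labeled reconstructed-from-text) so
an organization can refine it; rule loading validates that each rule's
category matches its methods' categories, and a totality test exercises
all 48 project states. The `accelerated` flag only appends an advisory
note — milestone boundaries blur on accelerated timelines.

## Core Company BR position

The CBR is rendered deterministically in a fixed section order (header,
benefits, risks, uncertainties, conclusion, version footer — a
documented convention, since no standard fixes the order). Lint rules
operationalize the five structural principles; "1–2 pages" is enforced
as a configurable ≤ 900-word body ceiling because pages are not a
machine-checkable unit. Every Key Safety Risk must carry a quantitative
estimate or an explicit uncertainty statement. Versioning is an
in-memory log: issuing changed content increments the version and marks
the prior position superseded; identical content is a no-op.

## Synthetic data and what the tests show

The trial simulator draws independent per-arm binomial counts at
specified true rates with one seeded generator per call (same seed and
spec → byte-identical files). It emulates the *shape* of two-arm binary
outcome data — it does not model dropout, correlated outcomes,
time-varying risk, or clustering, so passing tests demonstrate numerical
and structural correctness of the methods, not robustness to those
real-data features. Test problem sizes (5,000-replicate coverage runs,
1,000-table property sweeps, exhaustive grids to N = 8 per arm) were
chosen to make binomial Monte-Carlo error small relative to the asserted
bands while keeping the default suite fast.

## Numerical conventions

- Confidence level defaults to 0.95 everywhere, overridable per call.
- Weight normalization tolerance 1e−12; MCDA additivity asserted at
  1e−12.
- CSV is comma-separated UTF-8 with a mandatory header; floats are
  parsed round-trip-exactly.
- All randomness flows through explicit integer seeds; there is no
  global random state.
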