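# Methods

## Transaction model

A patient record becomes a *transaction*: the set of boolean items true
for that patient. Items are (attribute, category) indicators over ten
retained features (ST slope, age, chest pain type, cholesterol, exercise
angina, fasting blood sugar, max heart rate, oldpeak, sex, and the disease
class). Within each attribute group the items are mutually exclusive and
exhaustive, so every transaction carries exactly one item per group —
an invariant the encoder checks and the synthetic generator preserves.

Four continuous attributes are discretized with fixed, clinically
conventional edges:

| attribute       | edges                  | labels                          |
|-----------------|------------------------|---------------------------------|
| age (years)     | 0, 30, 60, ∞           | young, maged, elderly           |
| cholesterol (mg/dl) | −1, 200, 240, ∞    | lcol, ncol, hcol                |
| max heart rate (bpm) | 0, 100, 160, ∞    | hrlow, hrnoraml, hrhigh         |
| oldpeak (ST depression) | −∞, 1.0, 2.0, ∞ | peaklow, peakmoderate, peakhigh |

Intervals are left-open/right-closed `(a, b]`: a value exactly on an
interior edge falls in the lower bin (oldpeak 1.0 → `peaklow`), and the
cholesterol left edge of −1 exists precisely so that a recorded value of 0
lands in `lcol`. The convention is exposed as `BinningScheme.right_closed`.
Rows with the out-of-coding ST-slope value 0 are removed during cleaning;
rows are never reordered, so transaction index = cleaned row index.
Only categories that actually occur receive a column, so the encoded
dimension is data-dependent (27 for the cleaned combined heart dataset);
the run report records the realized dimension.

## Mining

FP-growth is implemented in-package (FP-tree with conditional pattern
bases; item order = descending global count, ties lexicographic — fully
deterministic and invariant to input item order). Rare mining is one
complete pass at `minRare` followed by partition at `minSup`; this is
output-equivalent to a dedicated rare-pattern traversal because both bands
are defined purely by support, and it guarantees the disjoint-union
identity `patterns(minRare) = frequent(minSup) ⊎ rare(minSup, minRare)`
by construction. Correctness is established against an exhaustive
enumerator (`brute_force_patterns`, capped at 20 items) on batches of
random datasets.

Support thresholds are compared on absolute counts by default:
`count ≥ ceil(minSup·m)`, with an epsilon guard against float fuzz. On
m = 1189 this gives count thresholds 12 (minSup = 0.01) and 2
(minRare = 0.001). Because the rounding rule at the band boundary is a
genuine free choice, a `threshold_mode="fraction"` option compares float
supports directly; the run report records which mode produced the counts.

## Rules

Every pattern with ≥ 2 items is split into all `2^|P| − 2` ordered
(antecedent, consequent) pairs; sub-itemset supports are read from the
union of both mined bands (every proper subset of a mined pattern is
itself mined, by anti-monotonicity) with a direct column-scan fallback.
`class_consequent_only=True` enumerates only the class-item consequents —
a speed switch that leaves every class-typed rule identical; the full
enumeration is the default for reproduction runs, since the published
global rule totals count all consequent sizes.

Metric conventions: conviction at confidence 1 is `+inf` (serialized as
the string `"inf"` in CSV exports) and passes the `conv > 1` filter; at
confidence 1 *and* `Supp(Y) = 1` the 0/0 form is resolved to 1. All
strong-rule thresholds are strict inequalities, so a rule at confidence
exactly 0.80 or lift exactly 1 is rejected. Band membership of a rule is
keyed on the support of `X ∪ Y` (the source pattern's band); the
antecedent's own support is stored separately on the rule. Duplicate
(X, Y) pairs arising from different source patterns are deduplicated.

## Interesting pairs

Pairing is rare⇒yes against frequent⇒no (the direction that flags
apparently healthy profiles at risk); the symmetric direction is available
but off by default. The similarity comparison is inclusive (`≥ simT`),
with a strict mode flag; at `simT = 0.80` the distinction is untestable on
the published examples, whose similarities (0.83, 0.857) clear either
form. Output order is total and documented — similarity descending, then
rare-rule support ascending, then lexicographic antecedents — so exports
are byte-stable across re-runs. Both the pair count and the distinct
rare-rule count are reported, since a rare rule may legitimately match
several frequent rules. Trigger attribution is exact set difference
(rare antecedent minus frequent antecedent); a pair with k triggers
contributes to k per-item tallies, so tallies may sum past the pair count
— the same overlap visible in the published per-factor totals.

## Synthetic data

The generator emulates the *encoded* data: it works at the item level
(one category per attribute group per row, plus a class item), not at the
raw continuous level. Background rows draw each group independently from
configurable category probabilities (defaults are round numbers shaped
like the clinical marginals — middle age dominant, ~75% male, oldpeak
mostly low — and a class balance of 0.53 "yes", documented as
approximate). Planted itemsets occupy exactly `floor(target_support · m)`
deterministically assigned rows, so band membership of a planted pattern
is never a sampling coin flip; a class item inside the planted itemset
(or a `consequent_class` on the planted pattern) forces the class on
those rows.
Background rows that would accidentally complete a planted itemset are
nudged off it by reassigning one non-forced group, so realized planted
support is exact whenever no plant is a subset of another; nested plants
(used deliberately to build contradiction pairs) overlap by construction
and the generation report records realized supports.

What the generator does **not** emulate: the real data's between-attribute
correlations (background groups are independent), source heterogeneity
across the five constituent cohorts, and any continuous-value structure.
Passing end-to-end tests on synthetic data therefore demonstrate that the
pipeline recovers contradiction structure that is present, not that such
structure exists in any particular clinical dataset.

## Problem sizes in the test suite

Oracle batteries run on 100 random datasets of up to 60 transactions over
up to 10 items (exhaustive enumeration stays cheap); end-to-end runs use
m = 1189 synthetic transactions over the full 27-item schema with
class-consequent enumeration, which keeps the candidate-rule space
proportional to the ~100k mined patterns. The full-split reproduction
path is exercised on the real combined dataset when the user supplies it
(see README); its stage counts are sensitive to the threshold-rounding
and enumeration conventions above, which is why the run report names the
conventions used.

## Known limitations

- The full-dataset stage counts cannot be verified without the third-party
  CSV, which is not redistributed; the dedicated test fails with a
  diagnostic rather than silently passing when the file is absent.
- Rule-space enumeration is exponential in pattern length in full-split
  mode; no closed/maximal condensation or top-k mining is provided.
- The interestingness stage is quadratic in the number of T4 × T1 rules,
  with only a length-ratio prefilter; adequate at the published scale
  (~10^4 × ~10^3) but not tuned beyond it.
- Statistical significance of individual rules is operationalized solely
  as the strong-rule metric thresholds; no hypothesis testing or
  multiplicity control is attempted.
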