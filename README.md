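# raremine

Rare association rule mining for clinical transaction data: find the rare,
disease-predicting rules that *contradict* well-supported healthy patterns,
and name the symptom that flips the outcome.

## The problem

Cardiovascular risk models built on frequent patterns recover what is
already well known: common symptom combinations with obvious outcomes.
The clinically interesting signal is often the opposite — a patient profile
that is frequent and benign (normal heart rate, no exercise-induced angina,
normal fasting blood sugar, ...) which becomes a *rare* but highly
confident predictor of heart disease the moment one extra finding appears,
such as a high exercise-induced ST depression (oldpeak) or a flat ST slope.
`raremine` mines both support bands of a boolean patient-transaction
dataset and isolates exactly those contradiction pairs.

## The method

Let `DB = {T_1, ..., T_m}` be transactions over items `I` (each item a
discretized (attribute, category) indicator, e.g. `peakhigh` = oldpeak >
2.0, plus a class pair `yes`/`no`). For an itemset `X`,
`Supp(X) = σ(X)/m`. The pipeline has three phases:

1. **Pattern mining.** FP-growth enumerates every itemset with
   `Supp ≥ minRare`; the result is partitioned into the *frequent* band
   (`Supp ≥ minSup`) and the *rare* band (`minRare ≤ Supp < minSup`).
   Defaults: `minSup = 0.01`, `minRare = 0.001`.
2. **Rule extraction.** Every split of a pattern `P` into non-empty
   `X → Y = P \ X` is scored with

   ```
   Conf(X→Y) = Supp(X∪Y)/Supp(X)
   lift(X→Y) = Supp(X∪Y)/(Supp(X)·Supp(Y))
   lev(X→Y)  = Supp(X∪Y) − Supp(X)·Supp(Y)
   conv(X→Y) = (1 − Supp(Y))/(1 − Conf(X→Y))      (+∞ at Conf = 1)
   ```

   A rule is *strong* if `Conf > 0.80`, `lift > 1`, `lev > 0`, `conv > 1`
   (strict), within its band's support window. Strong rules with a single
   class consequent are typed T1 (frequent ⇒ no), T2 (frequent ⇒ yes),
   T3 (rare ⇒ no), T4 (rare ⇒ yes).
3. **Interestingness.** Every rare disease rule (T4) is compared with every
   frequent healthy rule (T1) by antecedent Jaccard similarity
   `|X∩A|/|X∪A|`; pairs with similarity ≥ `simT = 0.80` and opposite class
   consequents are *interesting*, and the items `X \ A` are the **trigger
   factors** — the red-flag symptoms that flip the prediction.

## Worked example

`python examples/01_worked_rule_pairs.py` prints:

```
high-cholesterol female profile:
  frequent (=> no):  ['F', 'exangina0', 'fbsugar0', 'hcol', 'hrnoraml']
  rare     (=> yes): ['F', 'exangina0', 'fbsugar0', 'hcol', 'hrnoraml', 'peakhigh']
  trigger: ['peakhigh']   Jaccard = 0.833
...
rule-7 head-counts at m = 1189
  frequent support 0.06 -> ~71 healthy patients
  rare support     0.002 -> ~2 diseased patients
```

Read: a profile shared by roughly 71 healthy patients becomes a rare rule
covering about 2 diseased patients once `peakhigh` enters the antecedent;
the 0.83 similarity says the two profiles are nearly identical, which is
exactly what makes the contradiction clinically interesting.

`python examples/03_synthetic_pipeline.py` runs the whole pipeline on
synthetic transactions with one planted contradiction pair and prints the
per-stage counts plus the trigger tally that recovers it:

```
transactions: 1189 over 27 items
patterns: 22547 frequent, 78926 rare
strong class rules: T1=101 T2=34 T3=4307 T4=4325
interesting pairs: 12 (distinct rare rules: 12)
trigger tallies: {'fbsugar1': 1, 'peakhigh': 11}
```

## Library and CLI

The importable API is the primary interface (`raremine.mine_bands`,
`generate_rules`, `filter_strong`, `classify_rules`,
`find_interesting_pairs`, `summarize_triggers`, `run_pipeline`, ...).
A thin CLI wraps it:

```bash
raremine run   --input data.csv --min-sup 0.01 --min-rare 0.001 --sim-t 0.80 --out out/
raremine synth --config synth.yaml --seed 42 --out synth_out/
raremine pairs --rules out/rules.csv --sim-t 0.85 --out pairs85.csv
```

`run` writes `patterns_frequent.csv`, `patterns_rare.csv`, `rules.csv`,
`pairs.csv`, `pairs_coordinates.csv` (support/support/similarity triples
for plotting) and `report.json` / `report.txt`.

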