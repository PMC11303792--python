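"""Unexpected-rule discovery: pairing rare disease rules with frequent
healthy rules whose antecedents nearly coincide.

A rare rule X -> yes is *interesting* with respect to a frequent rule
A -> no when Jaccard(X, A) = |X n A| / |X u A| meets the similarity
threshold and the consequents are the two opposite class items.  The items
X \\ A are the *trigger factors* — the symptoms whose appearance flips a
benign, well-supported pattern into a rare disease-predicting one (e.g.
high oldpeak, a flat ST slope, asymptomatic chest pain).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .rules import AssociationRule

__all__ = [
    "InterestingRulePair",
    "TriggerSummary",
    "jaccard",
    "find_interesting_pairs",
    "summarize_triggers",
    "pairs_to_frame",
    "write_pairs_csv",
]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a n b| / |a u b| over item sets; raises on empty input."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("jaccard similarity requires non-empty item sets")
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class InterestingRulePair:
    rare_rule: AssociationRule
    frequent_rule: AssociationRule
    similarity: float
    trigger_items: frozenset[str]  # rare antecedent minus frequent antecedent
    reverse_items: frozenset[str]  # frequent antecedent minus rare antecedent

    def sort_key(self) -> tuple:
        return (
            -self.similarity,
            self.rare_rule.support,
            tuple(sorted(self.rare_rule.antecedent)),
            tuple(sorted(self.frequent_rule.antecedent)),
        )


def find_interesting_pairs(
    rare_yes: Sequence[AssociationRule],
    freq_no: Sequence[AssociationRule],
    sim_t: float,
    *,
    strict: bool = False,
) -> list[InterestingRulePair]:
    """All (rare, frequent) pairs with antecedent Jaccard >= sim_t.

    Inputs must already be strong-filtered and typed (T4 and T1); the
    consequents being opposite class items is what makes the pair
    contradictory.  ``strict`` switches the comparison to > sim_t.
    Output order: similarity descending, then rare-rule support ascending,
    then lexicographic antecedents.

    A size-ratio prefilter skips hopeless pairs: Jaccard(a, b) is at most
    min(|a|,|b|) / max(|a|,|b|).
    """
    pairs: list[InterestingRulePair] = []
    seen: set[tuple[frozenset[str], frozenset[str]]] = set()
    for rare in rare_yes:
        la = len(rare.antecedent)
        for freq in freq_no:
            lb = len(freq.antecedent)
            if min(la, lb) / max(la, lb) < sim_t:
                continue
            sim = jaccard(rare.antecedent, freq.antecedent)
            ok = sim > sim_t if strict else sim >= sim_t
            if not ok:
                continue
            key = (rare.antecedent, freq.antecedent)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                InterestingRulePair(
                    rare_rule=rare,
                    frequent_rule=freq,
                    similarity=sim,
                    trigger_items=rare.antecedent - freq.antecedent,
                    reverse_items=freq.antecedent - rare.antecedent,
                )
            )
    pairs.sort(key=InterestingRulePair.sort_key)
    return pairs


@dataclass
class TriggerSummary:
    """Per-item trigger tallies over the interesting pairs.

    A pair with k trigger items contributes to k tallies, so the column
    sums may exceed the pair count; identical-antecedent pairs (similarity
    exactly 1) land in the no-trigger bucket.
    """

    tallies: dict[str, int]
    total_pairs: int
    distinct_rare_rules: int
    no_trigger_pairs: int = 0

    def top(self, k: int = 10) -> list[tuple[str, int]]:
        return sorted(self.tallies.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def summarize_triggers(pairs: Sequence[InterestingRulePair]) -> TriggerSummary:
    tallies: Counter[str] = Counter()
    rare_seen: set[tuple] = set()
    no_trigger = 0
    for p in pairs:
        if p.trigger_items:
            tallies.update(p.trigger_items)
        else:
            no_trigger += 1
        rare_seen.add((p.rare_rule.antecedent, p.rare_rule.consequent))
    return TriggerSummary(
        tallies=dict(tallies),
        total_pairs=len(pairs),
        distinct_rare_rules=len(rare_seen),
        no_trigger_pairs=no_trigger,
    )


def pairs_to_frame(pairs: Sequence[InterestingRulePair]) -> pd.DataFrame:
    rows = [
        {
            "rare_antecedents": ";".join(sorted(p.rare_rule.antecedent)),
            "rare_consequent": ";".join(sorted(p.rare_rule.consequent)),
            "rare_support": p.rare_rule.support,
            "rare_confidence": p.rare_rule.confidence,
            "frequent_antecedents": ";".join(sorted(p.frequent_rule.antecedent)),
            "frequent_consequent": ";".join(sorted(p.frequent_rule.consequent)),
            "frequent_support": p.frequent_rule.support,
            "frequent_confidence": p.frequent_rule.confidence,
            "similarity": p.similarity,
            "trigger_items": ";".join(sorted(p.trigger_items)),
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rare_antecedents",
            "rare_consequent",
            "rare_support",
            "rare_confidence",
            "frequent_antecedents",
            "frequent_consequent",
            "frequent_support",
            "frequent_confidence",
            "similarity",
            "trigger_items",
        ],
    )


def write_pairs_csv(pairs: Sequence[InterestingRulePair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, index=False)
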