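"""Association rule generation, the five strength metrics, and rule typing.

A candidate rule X -> Y is produced for every ordered split of a mined
pattern P into non-empty disjoint X and Y = P \\ X.  Each rule carries:

    support    = supp(X u Y)
    confidence = supp(X u Y) / supp(X)
    lift       = supp(X u Y) / (supp(X) * supp(Y))
    leverage   = supp(X u Y) - supp(X) * supp(Y)
    conviction = (1 - supp(Y)) / (1 - confidence)   (+inf at confidence 1)

A *strong* rule clears confidence > 0.80, lift > 1, leverage > 0 and
conviction > 1 (strict), plus the support band of its source pattern.
Strong rules whose consequent is exactly the disease class item are typed:

    T1  frequent => no disease        T2  frequent => disease
    T3  rare     => no disease        T4  rare     => disease
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from .dataset_io import CLASS_ITEMS, TransactionDataset
from .mining import MiningConfig, PatternSet, count_threshold, support_of

__all__ = [
    "RuleMetrics",
    "AssociationRule",
    "RULE_TYPES",
    "compute_metrics",
    "generate_rules",
    "filter_strong",
    "classify_rules",
    "write_rules_csv",
]

RULE_TYPES = ("T1", "T2", "T3", "T4")


@dataclass(frozen=True)
class RuleMetrics:
    support: float
    confidence: float
    lift: float
    leverage: float
    conviction: float


def compute_metrics(supp_xy: float, supp_x: float, supp_y: float) -> RuleMetrics:
    """Evaluate all five metrics from the three supports.

    Conviction is +inf exactly when confidence = 1 and supp(Y) < 1; when
    both confidence and supp(Y) are 1 the 0/0 form is resolved to 1
    (the rule is vacuously as good as independence).
    """
    if not 0 < supp_x <= 1 or not 0 < supp_y <= 1:
        raise ValueError("supp_x and supp_y must lie in (0, 1]")
    if supp_xy < 0 or supp_xy > min(supp_x, supp_y) + 1e-12:
        raise ValueError(
            f"inconsistent supports: supp_xy={supp_xy} exceeds "
            f"min(supp_x={supp_x}, supp_y={supp_y})"
        )
    confidence = supp_xy / supp_x
    lift = supp_xy / (supp_x * supp_y)
    leverage = supp_xy - supp_x * supp_y
    if confidence >= 1.0:
        conviction = 1.0 if supp_y >= 1.0 else math.inf
    else:
        conviction = (1.0 - supp_y) / (1.0 - confidence)
    return RuleMetrics(supp_xy, confidence, lift, leverage, conviction)


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    metrics: RuleMetrics
    supp_antecedent: float
    supp_consequent: float
    band: Literal["frequent", "rare"]
    rule_type: str | None = None  # "T1".."T4" or None (untyped)

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def support(self) -> float:
        return self.metrics.support

    @property
    def confidence(self) -> float:
        return self.metrics.confidence

    def sort_key(self) -> tuple:
        return (
            tuple(sorted(self.antecedent)),
            tuple(sorted(self.consequent)),
        )

    def __str__(self) -> str:
        ante = ", ".join(sorted(self.antecedent))
        cons = ", ".join(sorted(self.consequent))
        return f"{{{ante}}} => {{{cons}}}"


def _support_lookup(
    counts: Mapping[frozenset[str], int],
    ds: TransactionDataset,
    items: frozenset[str],
) -> float:
    c = counts.get(items)
    if c is None:
        return support_of(ds, items).support
    return c / ds.m


def generate_rules(
    patterns: PatternSet,
    ds: TransactionDataset,
    *,
    class_consequent_only: bool = False,
    support_index: Mapping[frozenset[str], int] | None = None,
) -> list[AssociationRule]:
    """Every ordered split of every pattern with >= 2 items into X -> Y.

    Sub-itemset supports come from ``support_index`` (typically the union
    of both mined bands) and fall back to a direct column scan, so metrics
    are always exact.  ``class_consequent_only`` restricts consequents to
    the single class item — a speed switch; the full enumeration is the
    reproduction default.  Duplicate (X, Y) pairs are deduplicated.
    """
    counts = dict(support_index) if support_index is not None else patterns.as_dict()
    class_items = set(CLASS_ITEMS)
    seen: set[tuple[frozenset[str], frozenset[str]]] = set()
    rules: list[AssociationRule] = []
    for pattern in patterns:
        items = sorted(pattern.items)
        if len(items) < 2:
            continue
        supp_xy = pattern.count / pattern.m
        if class_consequent_only:
            splits: Iterable[tuple[str, ...]] = [
                (it,) for it in items if it in class_items
            ]
        else:
            splits = (
                cons
                for r in range(1, len(items))
                for cons in itertools.combinations(items, r)
            )
        for cons in splits:
            consequent = frozenset(cons)
            antecedent = pattern.items - consequent
            key = (antecedent, consequent)
            if key in seen:
                continue
            seen.add(key)
            supp_x = _support_lookup(counts, ds, antecedent)
            supp_y = _support_lookup(counts, ds, consequent)
            metrics = compute_metrics(supp_xy, supp_x, supp_y)
            rules.append(
                AssociationRule(
                    antecedent=antecedent,
                    consequent=consequent,
                    metrics=metrics,
                    supp_antecedent=supp_x,
                    supp_consequent=supp_y,
                    band=patterns.band if patterns.band != "all" else "frequent",
                )
            )
    rules.sort(key=AssociationRule.sort_key)
    return rules


def filter_strong(
    rules: Iterable[AssociationRule],
    config: MiningConfig,
    m: int | None = None,
) -> list[AssociationRule]:
    """Keep rules clearing every metric threshold strictly, in their band.

    Band support is checked on the rule's own support (the source pattern's
    band): frequent rules need supp >= minSup, rare rules need
    minRare <= supp < minSup.  With ``threshold_mode='count'`` and m given,
    band boundaries are evaluated on absolute counts.
    """
    out: list[AssociationRule] = []
    for rule in rules:
        met = rule.metrics
        if not (
            met.confidence > config.min_confidence
            and met.lift > config.min_lift
            and met.leverage > config.min_leverage
            and met.conviction > config.min_conviction
        ):
            continue
        if config.threshold_mode == "count" and m is not None:
            count = round(met.support * m)
            sup_c = count_threshold(config.min_sup, m)
            rare_c = count_threshold(config.min_rare, m)
            if rule.band == "frequent" and count < sup_c:
                continue
            if rule.band == "rare" and not (rare_c <= count < sup_c):
                continue
        else:
            if rule.band == "frequent" and met.support < config.min_sup:
                continue
            if rule.band == "rare" and not (config.min_rare <= met.support < config.min_sup):
                continue
        out.append(rule)
    return out


def classify_rules(
    rules: Iterable[AssociationRule],
) -> dict[str, list[AssociationRule]]:
    """Partition strong rules into T1-T4 by (band, class consequent).

    Rules whose consequent is not exactly one class item stay untyped and
    are excluded from the interestingness stage.
    """
    yes, no = CLASS_ITEMS
    buckets: dict[str, list[AssociationRule]] = {t: [] for t in RULE_TYPES}
    buckets["untyped"] = []
    for rule in rules:
        if len(rule.consequent) == 1 and next(iter(rule.consequent)) in (yes, no):
            cls = next(iter(rule.consequent))
            if rule.band == "frequent":
                rtype = "T1" if cls == no else "T2"
            else:
                rtype = "T3" if cls == no else "T4"
            typed = AssociationRule(
                antecedent=rule.antecedent,
                consequent=rule.consequent,
                metrics=rule.metrics,
                supp_antecedent=rule.supp_antecedent,
                supp_consequent=rule.supp_consequent,
                band=rule.band,
                rule_type=rtype,
            )
            buckets[rtype].append(typed)
        else:
            buckets["untyped"].append(rule)
    return buckets


def _fmt_conviction(v: float) -> str:
    return "inf" if math.isinf(v) else repr(v)


def rules_to_frame(rules: Iterable[AssociationRule]) -> pd.DataFrame:
    rows = [
        {
            "antecedents": ";".join(sorted(r.antecedent)),
            "consequents": ";".join(sorted(r.consequent)),
            "support": r.metrics.support,
            "confidence": r.metrics.confidence,
            "lift": r.metrics.lift,
            "leverage": r.metrics.leverage,
            "conviction": _fmt_conviction(r.metrics.conviction),
            "band": r.band,
            "type": r.rule_type or "",
        }
        for r in sorted(rules, key=AssociationRule.sort_key)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "antecedents",
            "consequents",
            "support",
            "confidence",
            "lift",
            "leverage",
            "conviction",
            "band",
            "type",
        ],
    )


def write_rules_csv(rules: Iterable[AssociationRule], path: str | Path) -> None:
    rules_to_frame(rules).to_csv(path, index=False)
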