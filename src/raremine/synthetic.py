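"""Synthetic boolean transaction data with the clinical schema's structure.

Generation happens at the item level (post-discretization): every
transaction gets exactly one category item per attribute group, a binary
class item, and — where requested — *planted* itemsets placed in an exact,
deterministically chosen number of rows so that their band membership
(frequent vs rare) is never a sampling coin flip.  Background rows draw
each group's category independently from configurable probabilities and
are perturbed away from accidentally completing a planted itemset, so a
planted pattern's realized support equals floor(target * m) / m whenever
no plant is a subset of another plant.

The module also bundles the published worked-example rule pairs (antecedent
sets, printed supports/confidences/similarities) as structured fixtures for
regression tests and desk-scale reproduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .dataset_io import ItemVocabulary, TransactionDataset

__all__ = [
    "PlantedPatternSpec",
    "SyntheticConfig",
    "heart_schema",
    "generate_transactions",
    "WorkedRule",
    "WorkedRulePair",
    "WorkedExampleBundle",
    "fixture_worked_examples",
]


@dataclass(frozen=True)
class PlantedPatternSpec:
    """An itemset to embed at an exact support, optionally forcing the class."""

    items: frozenset[str]
    target_support: float
    consequent_class: Literal["yes", "no", "none"] = "none"

    def __post_init__(self) -> None:
        if not 0 < self.target_support <= 1:
            raise ValueError("target_support must lie in (0, 1]")
        if not self.items:
            raise ValueError("planted itemset must be non-empty")


def heart_schema() -> dict[str, tuple[tuple[str, ...], tuple[float, ...]]]:
    """Attribute groups mirroring the encoded heart-disease vocabulary.

    Probabilities are round numbers loosely shaped like the real data's
    marginals (middle age dominant, upsloping/flat slopes common, oldpeak
    mostly low); they are background defaults, not estimates.
    """
    return {
        "age": (("young", "maged", "elderly"), (0.05, 0.70, 0.25)),
        "sex": (("F", "M"), (0.25, 0.75)),
        "chest_pain_type": (("tangina", "atangina", "napain", "asym"), (0.1, 0.15, 0.2, 0.55)),
        "cholesterol": (("lcol", "ncol", "hcol"), (0.35, 0.25, 0.40)),
        "fasting_blood_sugar": (("fbsugar0", "fbsugar1"), (0.78, 0.22)),
        "max_heart_rate": (("hrlow", "hrnoraml", "hrhigh"), (0.10, 0.55, 0.35)),
        "exercise_angina": (("exangina0", "exangina1"), (0.6, 0.4)),
        "oldpeak": (("peaklow", "peakmoderate", "peakhigh"), (0.65, 0.2, 0.15)),
        "st_slope": (("usloping", "flat", "dsloping"), (0.45, 0.48, 0.07)),
    }


@dataclass
class SyntheticConfig:
    """Everything a generation run needs; identical config + seed is
    bit-reproducible."""

    m: int = 1189
    groups: Mapping[str, tuple[tuple[str, ...], tuple[float, ...]]] = field(
        default_factory=heart_schema
    )
    planted: Sequence[PlantedPatternSpec] = ()
    class_yes_prob: float = 0.53  # approximate class balance of the real data
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("m must be positive")
        for attr, (cats, probs) in self.groups.items():
            if len(cats) != len(probs) or len(cats) < 2:
                raise ValueError(f"group {attr!r}: need >=2 categories with probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"group {attr!r}: probabilities must sum to 1")

    @property
    def item_to_group(self) -> dict[str, str]:
        out = {it: g for g, (cats, _) in self.groups.items() for it in cats}
        out["yes"] = "target"
        out["no"] = "target"
        return out

    def vocabulary(self) -> ItemVocabulary:
        items: list[str] = []
        groups: dict[str, tuple[str, ...]] = {}
        for attr, (cats, _) in self.groups.items():
            groups[attr] = tuple(cats)
            items.extend(cats)
        groups["target"] = ("yes", "no")
        items.extend(("yes", "no"))
        return ItemVocabulary(items=tuple(items), groups=groups)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SyntheticConfig":
        groups = {
            attr: (tuple(spec["categories"]), tuple(spec["probabilities"]))
            for attr, spec in doc.get("groups", {}).items()
        } or heart_schema()
        planted = [
            PlantedPatternSpec(
                items=frozenset(p["items"]),
                target_support=float(p["target_support"]),
                consequent_class=p.get("consequent_class", "none"),
            )
            for p in doc.get("planted", [])
        ]
        return cls(
            m=int(doc.get("m", 1189)),
            groups=groups,
            planted=planted,
            class_yes_prob=float(doc.get("class_yes_prob", 0.53)),
            seed=int(doc.get("seed", 0)),
        )


def _validate_plants(config: SyntheticConfig) -> list[int]:
    """Row-block sizes per plant; errors out before sampling if infeasible."""
    item_to_group = config.item_to_group
    sizes: list[int] = []
    for spec in config.planted:
        groups_used: set[str] = set()
        for it in spec.items:
            g = item_to_group.get(it)
            if g is None:
                raise ValueError(f"planted item {it!r} not in the schema vocabulary")
            if g in groups_used:
                raise ValueError(
                    f"planted itemset {sorted(spec.items)} uses attribute {g!r} twice"
                )
            groups_used.add(g)
        sizes.append(int(math.floor(spec.target_support * config.m)))
    if sum(sizes) > config.m:
        raise ValueError(
            f"planting demands {sum(sizes)} rows but only m={config.m} available"
        )
    return sizes


def generate_transactions(
    config: SyntheticConfig,
) -> tuple[TransactionDataset, dict[str, object]]:
    """Build the dataset; returns it with a realized-support report.

    Plants occupy disjoint leading row blocks (rows are then left in that
    deterministic order); each planted row has the plant's items forced and
    the remaining groups sampled.  Any row outside a plant's block that
    would contain the full planted itemset is nudged off it by reassigning
    one non-forced group, keeping realized supports exact.
    """
    sizes = _validate_plants(config)
    rng = np.random.default_rng(config.seed)
    item_to_group = config.item_to_group
    attrs = list(config.groups)

    # row -> attr -> category; class handled separately
    rows: list[dict[str, str]] = []
    owners: list[int] = []  # plant index owning the row, -1 for background
    cursor = 0
    for pi, (spec, size) in enumerate(zip(config.planted, sizes)):
        forced = {item_to_group[it]: it for it in spec.items if item_to_group[it] != "target"}
        for _ in range(size):
            row = {}
            for attr in attrs:
                cats, probs = config.groups[attr]
                row[attr] = forced.get(attr) or cats[rng.choice(len(cats), p=probs)]
            rows.append(row)
            owners.append(pi)
        cursor += size
    for _ in range(config.m - cursor):
        row = {}
        for attr in attrs:
            cats, probs = config.groups[attr]
            row[attr] = cats[rng.choice(len(cats), p=probs)]
        rows.append(row)
        owners.append(-1)

    # class assignment: a class item inside the planted itemset, or the
    # spec's consequent_class, forces the row's class; otherwise Bernoulli
    classes: list[str] = []
    for row, owner in zip(rows, owners):
        forced_class = None
        if owner >= 0:
            spec = config.planted[owner]
            in_items = spec.items & {"yes", "no"}
            if in_items:
                forced_class = next(iter(in_items))
            elif spec.consequent_class != "none":
                forced_class = spec.consequent_class
        classes.append(
            forced_class
            if forced_class is not None
            else ("yes" if rng.random() < config.class_yes_prob else "no")
        )

    # nudge rows off plants they were not assigned to (non-forced groups only)
    for i, (row, owner) in enumerate(zip(rows, owners)):
        forced_groups = (
            {item_to_group[it] for it in config.planted[owner].items}
            if owner >= 0
            else set()
        )
        for _ in range(10):  # fixpoint loop; plants are few
            hit = None
            for pi, spec in enumerate(config.planted):
                if pi == owner:
                    continue
                non_class = {it for it in spec.items if item_to_group[it] != "target"}
                class_part = spec.items - non_class
                contains = all(row[item_to_group[it]] == it for it in non_class) and all(
                    classes[i] == it for it in class_part
                )
                if contains:
                    hit = spec
                    break
            if hit is None:
                break
            moved = False
            for it in sorted(hit.items):
                g = item_to_group[it]
                if g == "target" or g in forced_groups:
                    continue
                cats, _ = config.groups[g]
                alternatives = [c for c in cats if c != row[g]]
                row[g] = alternatives[rng.choice(len(alternatives))]
                moved = True
                break
            if not moved:
                break  # plant nested inside forced groups: unavoidable overlap

    vocab = config.vocabulary()
    index = {it: j for j, it in enumerate(vocab.items)}
    matrix = np.zeros((config.m, len(vocab.items)), dtype=bool)
    for i, (row, cls) in enumerate(zip(rows, classes)):
        for attr in attrs:
            matrix[i, index[row[attr]]] = True
        matrix[i, index[cls]] = True
    ds = TransactionDataset(vocabulary=vocab, matrix=matrix)

    realized = {}
    for spec, size in zip(config.planted, sizes):
        idx = [index[it] for it in spec.items]
        realized[";".join(sorted(spec.items))] = {
            "target_support": spec.target_support,
            "planted_rows": size,
            "realized_support": float(matrix[:, idx].all(axis=1).mean()),
        }
    report = {"m": config.m, "n": len(vocab.items), "seed": config.seed, "planted": realized}
    return ds, report


# ---------------------------------------------------------------------------
# Published worked examples, as structured fixtures.


@dataclass(frozen=True)
class WorkedRule:
    """One printed example rule with its published metric values."""

    antecedent: frozenset[str]
    consequent: str  # "yes" | "no"
    support: float | None = None
    confidence: float | None = None
    lift: float | None = None
    leverage: float | None = None
    conviction: float | None = None  # math.inf for the confidence-1 examples


@dataclass(frozen=True)
class WorkedRulePair:
    """A printed (frequent healthy, rare disease) pair with its similarity."""

    frequent: WorkedRule
    rare: WorkedRule
    printed_similarity: float

    @property
    def trigger_items(self) -> frozenset[str]:
        return self.rare.antecedent - self.frequent.antecedent


@dataclass(frozen=True)
class WorkedExampleBundle:
    m: int
    pair_cholesterol: WorkedRulePair  # 5- vs 6-item antecedents, similarity 0.83
    pair_upsloping: WorkedRulePair  # 6- vs 7-item antecedents, similarity 0.857
    pair_rule7: WorkedRulePair  # supports 0.06 vs 0.002 on m = 1189
    pair_asymptomatic: WorkedRulePair  # the visualized asym example
    type_examples: dict[str, WorkedRule]  # one example per rule type T1-T4

    @property
    def pairs(self) -> tuple[WorkedRulePair, ...]:
        return (
            self.pair_cholesterol,
            self.pair_upsloping,
            self.pair_rule7,
            self.pair_asymptomatic,
        )


def fixture_worked_examples() -> WorkedExampleBundle:
    """The published worked-example rules, verbatim item sets and metrics."""
    f = frozenset
    pair_cholesterol = WorkedRulePair(
        frequent=WorkedRule(
            antecedent=f({"hrnoraml", "exangina0", "fbsugar0", "hcol", "F"}),
            consequent="no",
        ),
        rare=WorkedRule(
            antecedent=f({"hrnoraml", "peakhigh", "exangina0", "fbsugar0", "hcol", "F"}),
            consequent="yes",
        ),
        printed_similarity=0.83,
    )
    upsloping_base = {"maged", "M", "fbsugar0", "usloping", "napain", "exangina0"}
    pair_upsloping = WorkedRulePair(
        frequent=WorkedRule(
            antecedent=f(upsloping_base), consequent="no", support=0.048, confidence=0.89
        ),
        rare=WorkedRule(
            antecedent=f(upsloping_base | {"peakhigh"}),
            consequent="yes",
            support=0.003,
            confidence=1.0,
        ),
        printed_similarity=0.857,
    )
    rule7_base = {"maged", "hrhigh", "M", "fbsugar0", "usloping", "exangina0"}
    pair_rule7 = WorkedRulePair(
        frequent=WorkedRule(antecedent=f(rule7_base), consequent="no", support=0.06),
        rare=WorkedRule(
            antecedent=f(rule7_base | {"peakhigh"}), consequent="yes", support=0.002
        ),
        printed_similarity=0.857,
    )
    asym_base = {"peaklow", "maged", "hrhigh", "lcol", "fbsugar0"}
    pair_asymptomatic = WorkedRulePair(
        frequent=WorkedRule(
            antecedent=f(asym_base), consequent="no", support=0.02, confidence=0.82
        ),
        rare=WorkedRule(
            antecedent=f(asym_base | {"asym"}),
            consequent="yes",
            support=0.004,
            confidence=0.83,
        ),
        printed_similarity=round(5 / 6, 2),
    )
    type_examples = {
        "T1": WorkedRule(
            antecedent=f({"maged", "fbsugar0", "usloping", "peaklow"}),
            consequent="no",
            support=0.24,
            confidence=0.86,
            lift=1.81,
            leverage=0.11,
            conviction=3.73,
        ),
        "T2": WorkedRule(
            antecedent=f({"hrnoraml", "exangina1", "asym", "M"}),
            consequent="yes",
            support=0.21,
            confidence=0.92,
            lift=1.7,
            leverage=0.08,
            conviction=6.02,
        ),
        "T3": WorkedRule(
            antecedent=f({"fbsugar0", "tangina", "hrnoraml", "exangina0", "dsloping", "M"}),
            consequent="no",
            support=0.001,
            confidence=1.0,
            lift=2.11,
            leverage=0.0008,
            conviction=math.inf,
        ),
        "T4": WorkedRule(
            antecedent=f({"asym", "exangina1", "hrnoraml", "flat", "ncol", "elderly", "M"}),
            consequent="yes",
            support=0.009,
            confidence=1.0,
            lift=1.89,
            leverage=0.004,
            conviction=math.inf,
        ),
    }
    return WorkedExampleBundle(
        m=1189,
        pair_cholesterol=pair_cholesterol,
        pair_upsloping=pair_upsloping,
        pair_rule7=pair_rule7,
        pair_asymptomatic=pair_asymptomatic,
        type_examples=type_examples,
    )
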