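"""Frequent and rare itemset mining over boolean transaction datasets.

Frequent patterns (support >= minSup) are enumerated with FP-growth; rare
patterns are the band minRare <= support < minSup, obtained by complete
mining at minRare followed by partition — output-equivalent to a dedicated
rare-pattern traversal, since the band is defined purely by support.

Support thresholds can be compared on absolute counts (count >=
ceil(minSup * m), the default) or directly on fractions; the two differ
only when minSup * m is fractional and floating-point rounding matters at
the boundary.  A brute-force enumerator over all non-empty itemsets serves
as the verification oracle for small vocabularies.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .dataset_io import TransactionDataset

__all__ = [
    "Pattern",
    "PatternSet",
    "MiningConfig",
    "mine_frequent",
    "mine_rare",
    "mine_bands",
    "support_of",
    "brute_force_patterns",
    "count_threshold",
    "write_patterns_csv",
]

ThresholdMode = Literal["count", "fraction"]


@dataclass(frozen=True)
class Pattern:
    """An itemset with its absolute occurrence count and relative support."""

    items: frozenset[str]
    count: int
    m: int

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("pattern itemset must be non-empty")
        if not 0 < self.count <= self.m:
            raise ValueError("count must lie in (0, m]")

    @property
    def support(self) -> float:
        return self.count / self.m

    def sorted_items(self) -> tuple[str, ...]:
        return tuple(sorted(self.items))


@dataclass
class PatternSet:
    """A band of mined patterns plus the thresholds that produced it."""

    patterns: list[Pattern]
    band: Literal["frequent", "rare", "all"]
    min_sup: float
    min_rare: float | None = None

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def as_dict(self) -> dict[frozenset[str], int]:
        return {p.items: p.count for p in self.patterns}

    def sorted(self) -> list[Pattern]:
        return sorted(self.patterns, key=lambda p: (-p.count, len(p.items), p.sorted_items()))


@dataclass
class MiningConfig:
    """All thresholds of a mining run.

    min_sup / min_rare are support fractions; simT is the Jaccard threshold
    for pairing rare rules with frequent ones; the metric thresholds are the
    strict lower bounds a strong rule must clear.
    """

    min_sup: float = 0.01
    min_rare: float = 0.001
    sim_t: float = 0.80
    min_confidence: float = 0.80
    min_lift: float = 1.0
    min_leverage: float = 0.0
    min_conviction: float = 1.0
    threshold_mode: ThresholdMode = "count"
    class_consequent_only: bool = False
    strict_similarity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_rare < self.min_sup <= 1:
            raise ValueError("need 0 < min_rare < min_sup <= 1")
        if not 0 < self.sim_t <= 1:
            raise ValueError("need 0 < sim_t <= 1")


def count_threshold(min_sup: float, m: int) -> int:
    """Smallest count c with c/m >= min_sup (epsilon-guarded ceiling)."""
    return max(1, math.ceil(min_sup * m - 1e-9))


# ---------------------------------------------------------------------------
# FP-growth


class _FPNode:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: str | None, parent: "_FPNode | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _FPNode] = {}


def _build_tree(
    transactions: Iterable[tuple[tuple[str, ...], int]],
    item_counts: dict[str, int],
    min_count: int,
) -> tuple[_FPNode, dict[str, list[_FPNode]]]:
    # Global order: descending count, ties lexicographic — deterministic.
    rank = {
        item: i
        for i, (item, _) in enumerate(
            sorted(item_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        if item_counts[item] >= min_count
    }
    root = _FPNode(None, None)
    header: dict[str, list[_FPNode]] = defaultdict(list)
    for items, weight in transactions:
        filtered = sorted((it for it in items if it in rank), key=rank.__getitem__)
        node = root
        for it in filtered:
            child = node.children.get(it)
            if child is None:
                child = _FPNode(it, node)
                node.children[it] = child
                header[it].append(child)
            child.count += weight
            node = child
    return root, header


def _fpgrowth(
    transactions: list[tuple[tuple[str, ...], int]],
    min_count: int,
    suffix: frozenset[str],
    out: dict[frozenset[str], int],
) -> None:
    item_counts: Counter[str] = Counter()
    for items, weight in transactions:
        for it in items:
            item_counts[it] += weight
    root, header = _build_tree(transactions, dict(item_counts), min_count)
    # Process items in ascending frequency (reverse of tree order).
    order = sorted(header, key=lambda it: (item_counts[it], it))
    for item in order:
        nodes = header[item]
        count = sum(n.count for n in nodes)
        if count < min_count:
            continue
        new_suffix = suffix | {item}
        out[new_suffix] = count
        # Conditional pattern base: prefix paths of every node for `item`.
        conditional: list[tuple[tuple[str, ...], int]] = []
        for node in nodes:
            path: list[str] = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                conditional.append((tuple(path), node.count))
        if conditional:
            _fpgrowth(conditional, min_count, new_suffix, out)


def _mine_counts(ds: TransactionDataset, min_count: int) -> dict[frozenset[str], int]:
    transactions = [(tuple(t), 1) for t in ds.transactions()]
    out: dict[frozenset[str], int] = {}
    _fpgrowth(transactions, min_count, frozenset(), out)
    return out


def _min_count_for(min_sup: float, m: int, mode: ThresholdMode) -> int:
    if mode == "count":
        return count_threshold(min_sup, m)
    # fraction mode: mine at the equivalent floor count, then refilter on floats
    return max(1, math.ceil(min_sup * m - 1e-9))


def mine_frequent(
    ds: TransactionDataset, min_sup: float, mode: ThresholdMode = "count"
) -> PatternSet:
    """All itemsets with support >= min_sup, with exact counts.

    Complete and sound with respect to the threshold: verified against
    exhaustive enumeration in the test suite.
    """
    if not 0 < min_sup <= 1:
        raise ValueError("min_sup must lie in (0, 1]")
    counts = _mine_counts(ds, _min_count_for(min_sup, ds.m, mode))
    if mode == "fraction":
        counts = {k: c for k, c in counts.items() if c / ds.m >= min_sup}
    patterns = [Pattern(items, c, ds.m) for items, c in counts.items()]
    return PatternSet(patterns=patterns, band="frequent", min_sup=min_sup)


def mine_rare(
    ds: TransactionDataset,
    min_sup: float,
    min_rare: float,
    mode: ThresholdMode = "count",
) -> PatternSet:
    """All itemsets in the rare band min_rare <= support < min_sup."""
    if not 0 < min_rare < min_sup <= 1:
        raise ValueError("need 0 < min_rare < min_sup <= 1")
    _, rare = mine_bands(ds, min_sup, min_rare, mode)
    return rare


def mine_bands(
    ds: TransactionDataset,
    min_sup: float,
    min_rare: float,
    mode: ThresholdMode = "count",
) -> tuple[PatternSet, PatternSet]:
    """One complete mining pass at min_rare, partitioned into the two bands.

    Guarantees the disjoint-union identity: frequent(min_rare) =
    frequent(min_sup) + rare(min_sup, min_rare).
    """
    if not 0 < min_rare < min_sup <= 1:
        raise ValueError("need 0 < min_rare < min_sup <= 1")
    counts = _mine_counts(ds, _min_count_for(min_rare, ds.m, mode))
    if mode == "fraction":
        counts = {k: c for k, c in counts.items() if c / ds.m >= min_rare}
        is_frequent = lambda c: c / ds.m >= min_sup
    else:
        sup_count = count_threshold(min_sup, ds.m)
        is_frequent = lambda c: c >= sup_count
    freq = [Pattern(k, c, ds.m) for k, c in counts.items() if is_frequent(c)]
    rare = [Pattern(k, c, ds.m) for k, c in counts.items() if not is_frequent(c)]
    return (
        PatternSet(patterns=freq, band="frequent", min_sup=min_sup, min_rare=min_rare),
        PatternSet(patterns=rare, band="rare", min_sup=min_sup, min_rare=min_rare),
    )


def support_of(ds: TransactionDataset, items: Iterable[str]) -> Pattern:
    """Exact support of one itemset by direct column conjunction."""
    items = frozenset(items)
    if not items:
        raise ValueError("patterns are non-empty; cannot take support of {}")
    unknown = items - set(ds.vocabulary.items)
    if unknown:
        raise KeyError(f"unknown item name(s): {sorted(unknown)}")
    idx = [ds.vocabulary.index_of(it) for it in items]
    mask = ds.matrix[:, idx].all(axis=1)
    count = int(mask.sum())
    if count == 0:
        return _zero_pattern(items, ds.m)
    return Pattern(items=items, count=count, m=ds.m)


@dataclass(frozen=True)
class _ZeroSupport:
    """Stand-in for an itemset that never occurs (Pattern requires count>0)."""

    items: frozenset[str]
    count: int
    m: int

    @property
    def support(self) -> float:
        return 0.0

    def sorted_items(self) -> tuple[str, ...]:
        return tuple(sorted(self.items))


def _zero_pattern(items: frozenset[str], m: int) -> _ZeroSupport:
    return _ZeroSupport(items=items, count=0, m=m)


def brute_force_patterns(
    ds: TransactionDataset, min_count: int, max_vocab: int = 20
) -> PatternSet:
    """Exhaustive enumeration of every itemset with count >= min_count.

    Verification oracle only: refuses vocabularies larger than ``max_vocab``
    to guard against the 2^n blow-up.
    """
    n = ds.n
    if n > max_vocab:
        raise ValueError(
            f"brute force over {n} items would enumerate 2^{n} itemsets; "
            f"use mine_frequent, or raise max_vocab explicitly"
        )
    transactions = ds.transactions()
    items = list(ds.vocabulary.items)
    out: list[Pattern] = []
    for r in range(1, n + 1):
        for combo in itertools.combinations(items, r):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t)
            if count >= min_count:
                out.append(Pattern(items=s, count=count, m=ds.m))
    return PatternSet(patterns=out, band="all", min_sup=min_count / ds.m)


def write_patterns_csv(ps: PatternSet, path: str | Path) -> None:
    rows = [
        {
            "items": ";".join(p.sorted_items()),
            "count": p.count,
            "support": p.support,
            "band": ps.band,
        }
        for p in ps.sorted()
    ]
    pd.DataFrame(rows, columns=["items", "count", "support", "band"]).to_csv(
        path, index=False
    )
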