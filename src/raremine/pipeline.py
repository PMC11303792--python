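"""Three-phase pipeline orchestration and run reporting.

Phase 1 prepares the transaction dataset (load/clean/discretize/encode a
clinical CSV, or generate synthetic transactions).  Phase 2 mines both
support bands and extracts strong rules.  Phase 3 pairs rare disease rules
against frequent healthy rules by antecedent similarity and attributes the
trigger factors.  Every stage count lands in a RunReport, and all artifacts
(patterns.csv, rules.csv, pairs.csv, report.json) are written with fixed
sort orders so re-runs are byte-identical.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .dataset_io import (
    TransactionDataset,
    clean_records,
    discretize,
    encode_transactions,
    load_raw_records,
    write_transactions_csv,
)
from .interesting import (
    find_interesting_pairs,
    pairs_to_frame,
    summarize_triggers,
    write_pairs_csv,
)
from .mining import MiningConfig, PatternSet, mine_bands, write_patterns_csv
from .rules import classify_rules, filter_strong, generate_rules, write_rules_csv
from .synthetic import SyntheticConfig, generate_transactions

__all__ = ["RunReport", "run_pipeline", "export_report", "prepare_dataset"]


@dataclass
class RunReport:
    """Per-stage counts and settings of one pipeline run."""

    raw_rows: int
    cleaned_rows: int
    removed_rows: int
    item_dimension: int
    frequent_patterns: int
    rare_patterns: int
    total_patterns: int
    frequent_strong_rules: int
    rare_strong_rules: int
    type_counts: dict[str, int]
    interesting_pairs: int
    distinct_rare_rules: int
    trigger_tallies: dict[str, int]
    config: dict
    seed: int
    elapsed_seconds: float
    timestamp: str

    def validate(self) -> None:
        if self.total_patterns != self.frequent_patterns + self.rare_patterns:
            raise ValueError("pattern counts do not add up")
        if self.type_counts["T1"] + self.type_counts["T2"] > self.frequent_strong_rules:
            raise ValueError("frequent type counts exceed frequent strong rules")
        if self.type_counts["T3"] + self.type_counts["T4"] > self.rare_strong_rules:
            raise ValueError("rare type counts exceed rare strong rules")


def prepare_dataset(
    source: str | Path | SyntheticConfig | TransactionDataset,
) -> tuple[TransactionDataset, int, int]:
    """Phase 1: returns (dataset, raw_rows, removed_rows)."""
    if isinstance(source, TransactionDataset):
        return source, source.m, 0
    if isinstance(source, SyntheticConfig):
        ds, _ = generate_transactions(source)
        return ds, ds.m, 0
    table = load_raw_records(source)
    raw_rows = len(table)
    cleaned = clean_records(table)
    labeled = discretize(cleaned)
    ds = encode_transactions(labeled)
    return ds, raw_rows, cleaned.removed_rows


def run_pipeline(
    config: MiningConfig,
    source: str | Path | SyntheticConfig | TransactionDataset,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run all three phases; optionally export every artifact to ``out_dir``."""
    t0 = time.time()
    ds, raw_rows, removed = prepare_dataset(source)

    freq_patterns, rare_patterns = mine_bands(
        ds, config.min_sup, config.min_rare, config.threshold_mode
    )
    # one shared support index so sub-itemset lookups never rescan
    support_index = {**rare_patterns.as_dict(), **freq_patterns.as_dict()}
    freq_rules = filter_strong(
        generate_rules(
            freq_patterns,
            ds,
            class_consequent_only=config.class_consequent_only,
            support_index=support_index,
        ),
        config,
        ds.m,
    )
    rare_rules = filter_strong(
        generate_rules(
            rare_patterns,
            ds,
            class_consequent_only=config.class_consequent_only,
            support_index=support_index,
        ),
        config,
        ds.m,
    )
    buckets = classify_rules(freq_rules + rare_rules)

    pairs = find_interesting_pairs(
        buckets["T4"], buckets["T1"], config.sim_t, strict=config.strict_similarity
    )
    summary = summarize_triggers(pairs)

    report = RunReport(
        raw_rows=raw_rows,
        cleaned_rows=ds.m,
        removed_rows=removed,
        item_dimension=ds.n,
        frequent_patterns=len(freq_patterns),
        rare_patterns=len(rare_patterns),
        total_patterns=len(freq_patterns) + len(rare_patterns),
        frequent_strong_rules=len(freq_rules),
        rare_strong_rules=len(rare_rules),
        type_counts={t: len(buckets[t]) for t in ("T1", "T2", "T3", "T4")},
        interesting_pairs=summary.total_pairs,
        distinct_rare_rules=summary.distinct_rare_rules,
        trigger_tallies=dict(sorted(summary.tallies.items())),
        config={
            "min_sup": config.min_sup,
            "min_rare": config.min_rare,
            "sim_t": config.sim_t,
            "min_confidence": config.min_confidence,
            "min_lift": config.min_lift,
            "min_leverage": config.min_leverage,
            "min_conviction": config.min_conviction,
            "threshold_mode": config.threshold_mode,
            "class_consequent_only": config.class_consequent_only,
            "strict_similarity": config.strict_similarity,
        },
        seed=config.seed,
        elapsed_seconds=round(time.time() - t0, 3),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    report.validate()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_transactions_csv(ds, out / "transactions.csv")
        all_patterns = PatternSet(
            patterns=list(freq_patterns) + list(rare_patterns),
            band="all",
            min_sup=config.min_rare,
        )
        write_patterns_csv(freq_patterns, out / "patterns_frequent.csv")
        write_patterns_csv(rare_patterns, out / "patterns_rare.csv")
        write_rules_csv(
            [r for t in ("T1", "T2", "T3", "T4") for r in buckets[t]],
            out / "rules.csv",
        )
        write_pairs_csv(pairs, out / "pairs.csv")
        # Fig-8-style coordinate triples for external plotting
        coords = pairs_to_frame(pairs)[
            ["frequent_support", "rare_support", "similarity"]
        ]
        coords.to_csv(out / "pairs_coordinates.csv", index=False)
        export_report(report, out / "report.json", fmt="json")
        export_report(report, out / "report.txt", fmt="text")
    return report


def export_report(report: RunReport, path: str | Path, fmt: str = "json") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(asdict(report), indent=2) + "\n", encoding="utf-8")
    elif fmt == "text":
        tc = report.type_counts
        lines = [
            "pipeline run report",
            "===================",
            f"rows: raw={report.raw_rows} cleaned={report.cleaned_rows} removed={report.removed_rows}",
            f"item dimension: {report.item_dimension}",
            f"patterns: frequent={report.frequent_patterns} rare={report.rare_patterns} total={report.total_patterns}",
            f"strong rules: frequent={report.frequent_strong_rules} rare={report.rare_strong_rules}",
            f"rule types: T1={tc['T1']} T2={tc['T2']} T3={tc['T3']} T4={tc['T4']}",
            f"interesting pairs: {report.interesting_pairs} (distinct rare rules: {report.distinct_rare_rules})",
            "trigger tallies: "
            + ", ".join(f"{k}={v}" for k, v in report.trigger_tallies.items()),
            f"thresholds: {report.config}",
            f"seed: {report.seed}  elapsed: {report.elapsed_seconds}s",
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def load_report(path: str | Path) -> RunReport:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return RunReport(**doc)
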