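"""Reading, cleaning, discretizing and encoding the clinical records table.

The input is a 12-column CSV of per-patient cardiovascular measurements
(age, sex, chest pain type, resting blood pressure, cholesterol, fasting
blood sugar, resting ECG, max heart rate, exercise-induced angina, oldpeak,
ST slope, disease class).  The output is a boolean *transaction dataset*:
each row becomes the set of (attribute, category) indicator items that hold
for that patient, one item true per attribute group, ready for itemset
mining.

Four continuous attributes are discretized into clinically conventional
bins (e.g. age into young / middle-aged / elderly at 30 and 60 years);
categorical attributes map directly to items.  Item names use the field's
compact abbreviations (``peakhigh`` = oldpeak > 2.0, ``asym`` =
asymptomatic chest pain, ``yes``/``no`` = disease class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawRecordTable",
    "BinningScheme",
    "ItemVocabulary",
    "TransactionDataset",
    "REQUIRED_COLUMNS",
    "DEFAULT_FEATURES",
    "default_binning_scheme",
    "default_vocabulary",
    "load_raw_records",
    "clean_records",
    "discretize",
    "encode_transactions",
    "decode_transaction",
    "write_transactions_csv",
    "write_item_lists",
]

# Canonical column names; header matching is case/space/underscore-insensitive.
REQUIRED_COLUMNS = (
    "age",
    "sex",
    "chest_pain_type",
    "resting_bp",
    "cholesterol",
    "fasting_blood_sugar",
    "resting_ecg",
    "max_heart_rate",
    "exercise_angina",
    "oldpeak",
    "st_slope",
    "target",
)

# Alias table for the header dialects seen in circulating copies of the data.
_COLUMN_ALIASES: dict[str, str] = {
    "age": "age",
    "sex": "sex",
    "chestpaintype": "chest_pain_type",
    "chestpain": "chest_pain_type",
    "restingbp": "resting_bp",
    "restingbps": "resting_bp",
    "restingbloodpressure": "resting_bp",
    "cholesterol": "cholesterol",
    "serumcholesterol": "cholesterol",
    "chol": "cholesterol",
    "fastingbloodsugar": "fasting_blood_sugar",
    "fbs": "fasting_blood_sugar",
    "restingecg": "resting_ecg",
    "restingecgresults": "resting_ecg",
    "maxheartrate": "max_heart_rate",
    "maxheartrateachieved": "max_heart_rate",
    "thalach": "max_heart_rate",
    "exerciseangina": "exercise_angina",
    "exerciseinducedangina": "exercise_angina",
    "exang": "exercise_angina",
    "oldpeak": "oldpeak",
    "stslope": "st_slope",
    "slope": "st_slope",
    "slopeofthepeakexercisestsegment": "st_slope",
    "target": "target",
    "class": "target",
    "heartdisease": "target",
}

# The ten features retained for mining (union of the top picks of the five
# standard feature-selection procedures, taken as configuration).
DEFAULT_FEATURES = (
    "st_slope",
    "age",
    "chest_pain_type",
    "cholesterol",
    "exercise_angina",
    "fasting_blood_sugar",
    "max_heart_rate",
    "oldpeak",
    "sex",
    "target",
)

_CATEGORICAL_DOMAINS: dict[str, tuple[int, ...]] = {
    "sex": (0, 1),
    "chest_pain_type": (1, 2, 3, 4),
    "fasting_blood_sugar": (0, 1),
    "resting_ecg": (0, 1, 2),
    "exercise_angina": (0, 1),
    "st_slope": (0, 1, 2, 3),
    "target": (0, 1),
}

_CONTINUOUS_COLUMNS = ("age", "cholesterol", "max_heart_rate", "oldpeak")


@dataclass
class RawRecordTable:
    """The parsed clinical table with canonical column names."""

    frame: pd.DataFrame
    removed_rows: int = 0

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class BinningScheme:
    """Per-attribute bin edges and labels for the continuous columns.

    ``right_closed=True`` means intervals are (a, b] — a value exactly on an
    interior edge falls in the lower bin (oldpeak 1.0 -> "peaklow").  The
    cholesterol left edge of -1 exists so that a recorded value of 0 lands
    in the lowest bin.
    """

    edges: Mapping[str, tuple[float, ...]]
    labels: Mapping[str, tuple[str, ...]]
    right_closed: bool = True

    def __post_init__(self) -> None:
        for col, e in self.edges.items():
            if list(e) != sorted(set(e)):
                raise ValueError(f"bin edges for {col!r} must be strictly increasing")
            if len(self.labels[col]) != len(e) - 1:
                raise ValueError(f"{col!r}: need exactly {len(e) - 1} labels")

    def assign(self, column: str, values: pd.Series) -> pd.Series:
        edges = list(self.edges[column])
        labels = list(self.labels[column])
        out = pd.cut(
            values.astype(float),
            bins=edges,
            labels=labels,
            right=self.right_closed,
            include_lowest=False,
        )
        if out.isna().any():
            bad = values[out.isna()].iloc[0]
            raise ValueError(
                f"value {bad!r} in column {column!r} falls outside all bins {edges}"
            )
        return out.astype(str)


def default_binning_scheme() -> BinningScheme:
    """The study's discretization of the four continuous attributes."""
    return BinningScheme(
        edges={
            "age": (0.0, 30.0, 60.0, math.inf),
            "cholesterol": (-1.0, 200.0, 240.0, math.inf),
            "max_heart_rate": (0.0, 100.0, 160.0, math.inf),
            "oldpeak": (-math.inf, 1.0, 2.0, math.inf),
        },
        labels={
            "age": ("young", "maged", "elderly"),
            "cholesterol": ("lcol", "ncol", "hcol"),
            "max_heart_rate": ("hrlow", "hrnoraml", "hrhigh"),
            "oldpeak": ("peaklow", "peakmoderate", "peakhigh"),
        },
    )


# attribute -> {raw category value or bin label -> abbreviated item name}
_ITEM_NAMES: dict[str, dict[object, str]] = {
    "age": {"young": "young", "maged": "maged", "elderly": "elderly"},
    "sex": {0: "F", 1: "M"},
    "chest_pain_type": {1: "tangina", 2: "atangina", 3: "napain", 4: "asym"},
    "cholesterol": {"lcol": "lcol", "ncol": "ncol", "hcol": "hcol"},
    "fasting_blood_sugar": {0: "fbsugar0", 1: "fbsugar1"},
    "max_heart_rate": {"hrlow": "hrlow", "hrnoraml": "hrnoraml", "hrhigh": "hrhigh"},
    "exercise_angina": {0: "exangina0", 1: "exangina1"},
    "oldpeak": {"peaklow": "peaklow", "peakmoderate": "peakmoderate", "peakhigh": "peakhigh"},
    "st_slope": {1: "usloping", 2: "flat", 3: "dsloping", 0: "slope0"},
    "resting_ecg": {0: "ecgnormal", 1: "ecgst", 2: "ecglvh"},
    "target": {0: "no", 1: "yes"},
}

CLASS_ATTRIBUTE = "target"
CLASS_ITEMS = ("yes", "no")


@dataclass(frozen=True)
class ItemVocabulary:
    """Ordered item names plus the attribute group each item belongs to."""

    items: tuple[str, ...]
    groups: Mapping[str, tuple[str, ...]]  # attribute -> its items, mutually exclusive
    class_items: tuple[str, str] = CLASS_ITEMS

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("item names must be unique")

    @property
    def item_to_group(self) -> dict[str, str]:
        return {it: g for g, its in self.groups.items() for it in its}

    def index_of(self, item: str) -> int:
        return self.items.index(item)


def default_vocabulary(features: Sequence[str] = DEFAULT_FEATURES) -> ItemVocabulary:
    """Vocabulary over the selected features, in attribute-group order."""
    items: list[str] = []
    groups: dict[str, tuple[str, ...]] = {}
    for attr in features:
        names = tuple(_ITEM_NAMES[attr].values())
        groups[attr] = names
        items.extend(names)
    return ItemVocabulary(items=tuple(items), groups=groups)


@dataclass
class TransactionDataset:
    """Boolean item-occurrence matrix over a fixed item vocabulary.

    ``matrix`` is m x n (transactions x items), dtype bool.  Within each
    attribute group each transaction has exactly one true item.
    """

    vocabulary: ItemVocabulary
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[1] != len(self.vocabulary.items):
            raise ValueError("matrix width must equal vocabulary size")
        if self.matrix.shape[0] == 0:
            raise ValueError("transaction dataset must contain at least one transaction")

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.vocabulary.items))

    def transactions(self) -> list[frozenset[str]]:
        items = np.asarray(self.vocabulary.items, dtype=object)
        return [frozenset(items[row]) for row in self.matrix]


def _canonical(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def load_raw_records(path: str | Path) -> RawRecordTable:
    """Parse the clinical CSV into a table with canonical column names.

    Raises a descriptive error when a required column is missing or a cell
    fails numeric parsing (the message names the row and column).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input CSV not found: {path}")
    raw = pd.read_csv(path)
    rename: dict[str, str] = {}
    for col in raw.columns:
        canon = _COLUMN_ALIASES.get(_canonical(col))
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    frame = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"input CSV is missing required column(s): {', '.join(missing)}")
    frame = frame[list(REQUIRED_COLUMNS)].copy()
    for col in REQUIRED_COLUMNS:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"unparseable value {frame[col][row]!r} at row {row}, column {col!r}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ValueError(f"missing value at row {row}, column {col!r}")
        frame[col] = converted
    for col, domain in _CATEGORICAL_DOMAINS.items():
        vals = frame[col]
        outside = ~vals.isin(domain)
        if outside.any():
            row = int(outside.idxmax())
            raise ValueError(
                f"value {vals[row]!r} at row {row} outside domain {domain} for column {col!r}"
            )
    if (frame["age"] < 0).any():
        raise ValueError("negative age encountered")
    return RawRecordTable(frame=frame.reset_index(drop=True))


def clean_records(table: RawRecordTable) -> RawRecordTable:
    """Drop the degenerate ST-slope-0 rows; everything else is kept in order.

    An ST-slope code of 0 is outside the documented 1-3 coding and occurs
    once in the combined dataset; it contributes nothing to pattern
    generation and is removed (1190 rows -> 1189).
    """
    keep = table.frame["st_slope"] != 0
    removed = int((~keep).sum())
    return RawRecordTable(frame=table.frame[keep].reset_index(drop=True), removed_rows=removed)


def discretize(table: RawRecordTable, scheme: BinningScheme | None = None) -> pd.DataFrame:
    """Replace the four continuous columns by their bin labels.

    Re-applying to an already-labeled frame raises (labels are not numeric),
    so a second application can never silently corrupt.
    """
    scheme = scheme or default_binning_scheme()
    frame = table.frame.copy()
    for col in _CONTINUOUS_COLUMNS:
        if frame[col].dtype == object:
            raise TypeError(f"column {col!r} already discretized")
        frame[col] = scheme.assign(col, frame[col])
    return frame


def encode_transactions(
    labeled: pd.DataFrame,
    vocab: ItemVocabulary | None = None,
    selected_features: Sequence[str] = DEFAULT_FEATURES,
) -> TransactionDataset:
    """One-hot encode the labeled table into a boolean transaction matrix.

    Only items whose category actually occurs in the data get a column;
    the realized dimension is therefore data-dependent (27 for the cleaned
    combined heart dataset).
    """
    present_items: list[str] = []
    groups: dict[str, tuple[str, ...]] = {}
    columns: list[np.ndarray] = []
    full_vocab = vocab or default_vocabulary(selected_features)
    for attr in selected_features:
        mapping = _ITEM_NAMES[attr]
        values = labeled[attr]
        group_items: list[str] = []
        known = set(mapping) | {str(k) for k in mapping}
        unknown = values[~values.isin(list(known))]
        if len(unknown):
            raise ValueError(
                f"unknown category {unknown.iloc[0]!r} for attribute {attr!r}"
            )
        for cat, item in mapping.items():
            mask = (values == cat) | (values.astype(str) == str(cat))
            if mask.any() and item in full_vocab.items:
                group_items.append(item)
                columns.append(mask.to_numpy(dtype=bool))
        groups[attr] = tuple(group_items)
        present_items.extend(group_items)
    vocab_out = ItemVocabulary(items=tuple(present_items), groups=groups)
    matrix = np.column_stack(columns) if columns else np.zeros((len(labeled), 0), bool)
    ds = TransactionDataset(vocabulary=vocab_out, matrix=matrix)
    _check_one_hot(ds)
    return ds


def _check_one_hot(ds: TransactionDataset) -> None:
    frame = ds.to_frame()
    for attr, items in ds.vocabulary.groups.items():
        cols = [c for c in items if c in frame.columns]
        if not cols:
            continue
        per_row = frame[cols].sum(axis=1)
        if not (per_row == 1).all():
            raise ValueError(f"one-hot violation in attribute group {attr!r}")


def decode_transaction(ds: TransactionDataset, row: int) -> dict[str, str]:
    """Map one transaction back to attribute -> item-label pairs."""
    item_group = ds.vocabulary.item_to_group
    out: dict[str, str] = {}
    for j, flag in enumerate(ds.matrix[row]):
        if flag:
            item = ds.vocabulary.items[j]
            out[item_group[item]] = item
    return out


def write_transactions_csv(ds: TransactionDataset, path: str | Path) -> None:
    """0/1 matrix with item names as headers."""
    ds.to_frame().astype(int).to_csv(path, index=False)


def write_item_lists(ds: TransactionDataset, path: str | Path) -> None:
    """One transaction per line, items space-separated (basket interchange)."""
    items = np.asarray(ds.vocabulary.items, dtype=object)
    with open(path, "w", encoding="utf-8") as fh:
        for row in ds.matrix:
            fh.write(" ".join(items[row]) + "\n")
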