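import numpy as np
import pandas as pd
import pytest

from raremine import (
    ItemVocabulary,
    MiningConfig,
    PlantedPatternSpec,
    SyntheticConfig,
    TransactionDataset,
    fixture_worked_examples,
)


def random_dataset(rng: np.random.Generator, m: int, n: int, density: float) -> TransactionDataset:
    """Unstructured boolean dataset for mining oracles (no group constraint)."""
    matrix = rng.random((m, n)) < density
    # guarantee at least one true cell so the dataset is non-degenerate
    if not matrix.any():
        matrix[0, 0] = True
    items = tuple(f"i{k}" for k in range(n))
    vocab = ItemVocabulary(items=items, groups={"items": items})
    return TransactionDataset(vocabulary=vocab, matrix=matrix)


def dataset_from_transactions(transactions: list[set[str]]) -> TransactionDataset:
    items = tuple(sorted(set().union(*transactions)))
    vocab = ItemVocabulary(items=items, groups={"items": items})
    matrix = np.array([[it in t for it in items] for t in transactions], dtype=bool)
    return TransactionDataset(vocabulary=vocab, matrix=matrix)


@pytest.fixture(scope="session")
def worked_examples():
    return fixture_worked_examples()


@pytest.fixture
def rng():
    return np.random.default_rng(20240806)


@pytest.fixture
def five_transactions():
    """{ab, ab, ac, bc, a}: the hand-enumerable five-row example."""
    return dataset_from_transactions(
        [{"a", "b"}, {"a", "b"}, {"a", "c"}, {"b", "c"}, {"a"}]
    )


@pytest.fixture
def raw_clinical_frame():
    """A 12-column clinical table covering every category, incl. one
    degenerate ST-slope-0 row (synthetic; hand-written rows)."""
    rows = [
        # age sex cp bp chol fbs ecg hr exang oldpeak slope target
        [45, 1, 3, 130, 180, 0, 0, 170, 0, 0.5, 1, 0],
        [72, 0, 4, 140, 260, 1, 1, 95, 1, 2.5, 2, 1],
        [29, 1, 1, 120, 210, 0, 0, 150, 0, 1.0, 1, 0],
        [61, 0, 2, 150, 0, 0, 2, 165, 0, 1.5, 3, 1],
        [55, 1, 4, 135, 230, 1, 0, 120, 1, 3.1, 2, 1],
        [33, 0, 3, 110, 199, 0, 1, 185, 0, 0.0, 1, 0],
        [50, 1, 2, 125, 241, 0, 0, 160, 0, 2.0, 0, 1],  # st_slope == 0
    ]
    return pd.DataFrame(
        rows,
        columns=[
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
        ],
    )


@pytest.fixture
def clinical_csv(tmp_path, raw_clinical_frame):
    path = tmp_path / "clinical.csv"
    raw_clinical_frame.to_csv(path, index=False)
    return path


@pytest.fixture
def planted_pair_config():
    """One frequent healthy antecedent and its rare disease superset, with
    the class forced on planted rows so both rules reach confidence high
    enough to pass the strong filter."""
    antecedent = frozenset({"maged", "hrnoraml", "exangina0"})
    return SyntheticConfig(
        m=1189,
        planted=[
            PlantedPatternSpec(items=antecedent | {"usloping", "fbsugar0"},
                               target_support=0.05, consequent_class="no"),
            PlantedPatternSpec(items=antecedent | {"usloping", "fbsugar0", "peakhigh"},
                               target_support=0.004, consequent_class="yes"),
        ],
        seed=7,
    )


@pytest.fixture
def standard_thresholds():
    """The study's thresholds; class-consequent enumeration keeps the
    candidate-rule space proportional to the pattern count."""
    return MiningConfig(class_consequent_only=True)
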