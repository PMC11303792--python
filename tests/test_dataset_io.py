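"""Loading, cleaning, discretization and one-hot transaction encoding."""

import numpy as np
import pandas as pd
import pytest

from raremine import (
    RawRecordTable,
    clean_records,
    decode_transaction,
    default_binning_scheme,
    discretize,
    encode_transactions,
    load_raw_records,
)
from raremine.dataset_io import REQUIRED_COLUMNS, write_item_lists, write_transactions_csv


class TestLoad:
    def test_parses_all_rows_with_canonical_columns(self, clinical_csv):
        table = load_raw_records(clinical_csv)
        assert len(table) == 7
        assert list(table.frame.columns) == list(REQUIRED_COLUMNS)

    def test_header_dialects_are_normalized(self, tmp_path, raw_clinical_frame):
        frame = raw_clinical_frame.rename(
            columns={"st_slope": "ST slope", "max_heart_rate": "Max Heart Rate", "target": "class"}
        )
        path = tmp_path / "dialect.csv"
        frame.to_csv(path, index=False)
        table = load_raw_records(path)
        assert "st_slope" in table.frame.columns
        assert "max_heart_rate" in table.frame.columns

    def test_header_only_csv_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(REQUIRED_COLUMNS) + "\n")
        assert len(load_raw_records(path)) == 0

    def test_missing_column_error_names_it(self, tmp_path, raw_clinical_frame):
        path = tmp_path / "broken.csv"
        raw_clinical_frame.drop(columns=["oldpeak"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="oldpeak"):
            load_raw_records(path)

    def test_unparseable_cell_names_row_and_column(self, tmp_path, raw_clinical_frame):
        frame = raw_clinical_frame.copy()
        frame["cholesterol"] = frame["cholesterol"].astype(object)
        frame.loc[2, "cholesterol"] = "high"
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 2.*cholesterol"):
            load_raw_records(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_raw_records(tmp_path / "nope.csv")


class TestClean:
    def test_drops_exactly_the_slope_zero_rows(self, clinical_csv):
        table = load_raw_records(clinical_csv)
        cleaned = clean_records(table)
        assert len(cleaned) == len(table) - 1
        assert cleaned.removed_rows == 1
        assert (cleaned.frame["st_slope"] != 0).all()

    def test_identity_when_nothing_to_remove(self, clinical_csv):
        cleaned = clean_records(load_raw_records(clinical_csv))
        again = clean_records(cleaned)
        assert again.removed_rows == 0
        pd.testing.assert_frame_equal(again.frame, cleaned.frame)

    def test_row_count_conservation(self, clinical_csv):
        table = load_raw_records(clinical_csv)
        n_zero = int((table.frame["st_slope"] == 0).sum())
        cleaned = clean_records(table)
        assert len(cleaned) == len(table) - n_zero


class TestDiscretize:
    @pytest.mark.parametrize(
        "column,value,label",
        [
            ("age", 45, "maged"),
            ("age", 72, "elderly"),
            ("age", 30, "young"),  # right-closed: 30 stays in (0, 30]
            ("cholesterol", 0, "lcol"),  # left edge -1 admits 0
            ("cholesterol", 200, "lcol"),
            ("cholesterol", 241, "hcol"),
            ("max_heart_rate", 100, "hrlow"),
            ("max_heart_rate", 160, "hrnoraml"),
            ("oldpeak", 2.5, "peakhigh"),
            ("oldpeak", 1.0, "peaklow"),  # boundary falls in the lower bin
            ("oldpeak", -2.6, "peaklow"),
        ],
    )
    def test_bin_assignment(self, column, value, label):
        scheme = default_binning_scheme()
        out = scheme.assign(column, pd.Series([value]))
        assert out.iloc[0] == label

    def test_continuous_columns_replaced_others_untouched(self, clinical_csv):
        cleaned = clean_records(load_raw_records(clinical_csv))
        labeled = discretize(cleaned)
        for col in ("age", "cholesterol", "max_heart_rate", "oldpeak"):
            assert labeled[col].dtype == object
        pd.testing.assert_series_equal(labeled["sex"], cleaned.frame["sex"])

    def test_second_application_raises_never_corrupts(self, clinical_csv):
        cleaned = clean_records(load_raw_records(clinical_csv))
        labeled = discretize(cleaned)
        with pytest.raises(TypeError, match="already discretized"):
            discretize(RawRecordTable(frame=labeled))


class TestEncode:
    def test_one_hot_within_every_group(self, clinical_csv):
        cleaned = clean_records(load_raw_records(clinical_csv))
        ds = encode_transactions(discretize(cleaned))
        frame = ds.to_frame()
        for attr, items in ds.vocabulary.groups.items():
            assert (frame[list(items)].sum(axis=1) == 1).all(), attr

    def test_single_record_forced_encoding(self, raw_clinical_frame):
        one = RawRecordTable(frame=raw_clinical_frame.iloc[[0]].reset_index(drop=True))
        ds = encode_transactions(discretize(one), selected_features=("sex", "target"))
        assert ds.transactions() == [frozenset({"M", "no"})]

    def test_sex_locality(self, raw_clinical_frame):
        base = raw_clinical_frame.iloc[[0, 0]].reset_index(drop=True).copy()
        base.loc[1, "sex"] = 0
        ds = encode_transactions(discretize(RawRecordTable(frame=base)))
        frame = ds.to_frame()
        differing = [c for c in frame.columns if frame[c][0] != frame[c][1]]
        assert set(differing) == {"M", "F"}

    def test_unknown_category_named_in_error(self, raw_clinical_frame):
        labeled = discretize(RawRecordTable(frame=raw_clinical_frame.iloc[:2].copy()))
        labeled.loc[0, "chest_pain_type"] = 9
        with pytest.raises(ValueError, match="9"):
            encode_transactions(labeled)

    def test_decode_reencode_round_trip(self, clinical_csv):
        cleaned = clean_records(load_raw_records(clinical_csv))
        ds = encode_transactions(discretize(cleaned))
        for row in range(ds.m):
            decoded = decode_transaction(ds, row)
            rebuilt = np.zeros(ds.n, dtype=bool)
            for item in decoded.values():
                rebuilt[ds.vocabulary.index_of(item)] = True
            assert (rebuilt == ds.matrix[row]).all()

    def test_interchange_exports(self, clinical_csv, tmp_path):
        cleaned = clean_records(load_raw_records(clinical_csv))
        ds = encode_transactions(discretize(cleaned))
        write_transactions_csv(ds, tmp_path / "t.csv")
        back = pd.read_csv(tmp_path / "t.csv")
        assert (back.to_numpy(dtype=bool) == ds.matrix).all()
        write_item_lists(ds, tmp_path / "t.basket")
        lines = (tmp_path / "t.basket").read_text().splitlines()
        assert len(lines) == ds.m
        assert set(lines[0].split()) == set(ds.transactions()[0])
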