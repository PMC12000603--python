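"""Reaction record/dataset invariants, CSV round-trips, binarization and
splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxnproto.data import (
    ReactionDataset, ReactionRecord, RecordError, SchemaError,
    binarize_labels, impute_conditions, read_dataset, split_dataset,
    write_dataset,
)


def make_record(rid="r1", ee=90.0, **kw):
    base = dict(record_id=rid, olefin="C=CC", ligand="CP(C)C", solvent="CO",
                metal="Rh", additive_present=False, pressure=10.0,
                temperature=25.0, sc_ratio=100.0, ee=ee)
    base.update(kw)
    return ReactionRecord(**base)


class TestRecordValidation:
    def test_valid_record_passes(self):
        make_record().validate()

    @pytest.mark.parametrize("kw", [
        {"olefin": "C1CC"},              # unclosed ring
        {"ligand": "not-a-smiles"},
        {"metal": "Pd"},
        {"sc_ratio": -5.0},
        {"ee": 130.0},
    ])
    def test_invalid_record_raises(self, kw):
        with pytest.raises(RecordError):
            make_record(**kw).validate()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(RecordError):
            ReactionDataset([make_record("a"), make_record("a")])


class TestCsvRoundTrip:
    def test_round_trip_preserves_all_fields(self, tiny_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        write_dataset(tiny_dataset, path)
        back = read_dataset(path)
        assert back.record_ids == tiny_dataset.record_ids
        for a, b in zip(back.records, tiny_dataset.records):
            assert a == b
        np.testing.assert_array_equal(back.labels, tiny_dataset.labels)

    def test_three_row_csv(self, tmp_path):
        path = tmp_path / "three.csv"
        ds = ReactionDataset([make_record(f"id{i}") for i in range(3)])
        write_dataset(ds, path)
        back = read_dataset(path)
        assert len(back) == 3
        assert back.record_ids == ["id0", "id1", "id2"]

    def test_missing_column_names_the_column(self, tiny_dataset, tmp_path):
        import pandas as pd
        path = tmp_path / "bad.csv"
        df = tiny_dataset.to_frame().drop(columns=["metal"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="metal"):
            read_dataset(path)

    def test_bad_smiles_row_raises_with_id(self, tmp_path):
        ds = ReactionDataset([make_record("good"), make_record("bad")])
        df = ds.to_frame()
        df.loc[df.record_id == "bad", "olefin_smiles"] = "C1CC"
        path = tmp_path / "rows.csv"
        df.to_csv(path, index=False)
        with pytest.raises(RecordError, match="bad"):
            read_dataset(path)
        kept = read_dataset(path, on_bad_row="skip")
        assert kept.record_ids == ["good"]

    def test_schema_mapping_adapts_headers(self, tmp_path):
        ds = ReactionDataset([make_record()])
        df = ds.to_frame().rename(columns={"ee_percent": "ee"})
        path = tmp_path / "mapped.csv"
        df.to_csv(path, index=False)
        back = read_dataset(path, schema={"ee_percent": "ee"})
        assert back.records[0].ee == 90.0


class TestBinarize:
    @pytest.mark.parametrize("ee,threshold,expected", [
        (92.0, 80.0, 1),    # clearly selective
        (0.0, 80.0, 0),     # floor
        (80.0, 80.0, 0),    # boundary goes to the low class (strict >)
    ])
    def test_threshold_cases(self, ee, threshold, expected):
        ds = ReactionDataset([make_record(ee=ee)])
        out = binarize_labels(ds, threshold)
        assert out.labels[0] == expected

    def test_idempotent(self, tiny_dataset):
        once = binarize_labels(tiny_dataset, 80.0)
        twice = binarize_labels(once, 80.0)
        np.testing.assert_array_equal(once.labels, twice.labels)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone_in_threshold(self, lo, hi):
        """Raising the threshold never flips a low label to high."""
        lo, hi = min(lo, hi), max(lo, hi)
        ds = ReactionDataset([make_record(f"r{i}", ee=e)
                              for i, e in enumerate([0.0, 50.0, 80.0, 90.0, 100.0])])
        a = binarize_labels(ds, lo).labels
        b = binarize_labels(ds, hi).labels
        assert np.all(b <= a)


class TestSplit:
    def test_sizes_and_disjointness(self, medium):
        ds, _ = medium
        tr, te, va = split_dataset(ds, (400, 150, 50), seed=7)
        assert (len(tr), len(te), len(va)) == (400, 150, 50)
        ids = [set(s.record_ids) for s in (tr, te, va)]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
        assert (ids[0] | ids[1] | ids[2]) <= set(ds.record_ids)

    def test_deterministic(self, medium):
        ds, _ = medium
        a = split_dataset(ds, (70, 20, 10), seed=3)
        b = split_dataset(ds, (70, 20, 10), seed=3)
        for x, y in zip(a, b):
            assert x.record_ids == y.record_ids

    def test_oversized_request_raises(self, tiny_dataset):
        with pytest.raises(ValueError):
            split_dataset(tiny_dataset, (25, 5, 5), seed=0)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_disjoint_for_every_seed(self, medium, seed):
        ds, _ = medium
        tr, te, va = split_dataset(ds, (300, 200, 100), seed=seed)
        all_ids = tr.record_ids + te.record_ids + va.record_ids
        assert len(set(all_ids)) == len(all_ids)


def test_imputation_uses_training_medians():
    recs = [make_record(f"r{i}", pressure=p)
            for i, p in enumerate([10.0, 20.0, 30.0])]
    missing = make_record("rm", pressure=float("nan"))
    train = ReactionDataset(recs)
    _, medians = impute_conditions(train)
    assert medians["pressure"] == 20.0
    filled, _ = impute_conditions(ReactionDataset([missing]), medians)
    assert filled.records[0].pressure == 20.0
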