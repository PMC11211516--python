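"""Consensus labeling, deduplication and dataset assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combosyn.data import (
    EXCLUDED,
    NEGATIVE,
    POSITIVE,
    CombinationRecord,
    DatasetConfig,
    assemble_dataset,
    consensus_label,
    dedup_and_filter,
    read_combination_table,
    read_drug_table,
    read_expression_table,
)


class TestConsensusLabel:
    def test_all_positive(self):
        assert consensus_label((5.2, 3.1, 2.0, 7.7)) == POSITIVE

    def test_one_discordant_excluded(self):
        assert consensus_label((5.2, -3.1, 2.0, 7.7)) == EXCLUDED

    def test_all_negative(self):
        assert consensus_label((-1, -2, -0.5, -4)) == NEGATIVE

    def test_missing_score_excluded(self):
        assert consensus_label((1.0, float("nan"), 2.0, 3.0)) == EXCLUDED

    def test_exhaustive_sign_patterns(self):
        """Of the 16 sign quadruples, exactly one is positive, one negative."""
        labels = [
            consensus_label([2.0 * s for s in signs])
            for signs in itertools.product((1, -1), repeat=4)
        ]
        assert labels.count(POSITIVE) == 1
        assert labels.count(NEGATIVE) == 1
        assert labels.count(EXCLUDED) == 14

    def test_on_threshold_excluded(self):
        assert consensus_label((0.0, 1.0, 1.0, 1.0)) == EXCLUDED

    def test_custom_thresholds(self):
        assert consensus_label((5, 5, 5, 5), thresholds=(10, 10, 10, 10)) == NEGATIVE

    @given(
        scores=st.tuples(*[st.floats(-50, 50) for _ in range(4)]),
        bump=st.floats(0, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_monotonicity(self, scores, bump):
        """Raising all thresholds never turns a negative into a positive."""
        lo = consensus_label(scores, thresholds=(0, 0, 0, 0))
        hi = consensus_label(scores, thresholds=(bump,) * 4)
        assert not (lo == NEGATIVE and hi == POSITIVE)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            consensus_label((1.0, 2.0))


def rec(a, b, c, scores=(1, 1, 1, 1)):
    return CombinationRecord(a, b, c, tuple(float(s) for s in scores))


class TestDedup:
    def test_unordered_pair_collapsed(self):
        out = dedup_and_filter([rec("A", "B", "c"), rec("B", "A", "c")])
        assert len(out) == 1
        assert (out[0].drug_a_id, out[0].drug_b_id) == ("A", "B")

    def test_incomplete_dropped(self):
        out = dedup_and_filter(
            [rec("", "B", "c"), rec("A", "B", "c", (1, float("nan"), 1, 1)), rec("A", "B", "c")]
        )
        assert len(out) == 1

    def test_empty_input(self):
        assert dedup_and_filter([]) == []

    def test_idempotent(self):
        records = [rec("A", "B", "c1"), rec("B", "A", "c1"), rec("A", "C", "c2")]
        once = dedup_and_filter(records)
        assert dedup_and_filter(once) == once

    def test_distinct_cell_lines_kept(self):
        out = dedup_and_filter([rec("A", "B", "c1"), rec("A", "B", "c2")])
        assert len(out) == 2


def toy_tables():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(
        rng.normal(size=(3, 64)),
        index=pd.Index(["c1", "c2", "c3"], name="cell_line_id"),
        columns=[f"g{i}" for i in range(64)],
    )
    drugs = pd.DataFrame(
        {"smiles": ["CCO", "c1ccccc1", "CC(=O)O", "CCN"]},
        index=pd.Index(["d1", "d2", "d3", "d4"], name="drug_id"),
    )
    combos = pd.DataFrame(
        {
            "drug_a": ["d1", "d1", "d2", "d3", "d2", "d1"],
            "drug_b": ["d2", "d3", "d3", "d4", "d4", "d4"],
            "cell_line": ["c1", "c2", "c3", "c1", "c2", "c3"],
            "loewe": [5, -4, 3, 2, -1, 6],
            "bliss": [4, -2, 3, -2, -2, 5],
            "hsa": [6, -3, 1, 2, -3, 4],
            "zip": [2, -1, 2, 2, -4, 3],
        }
    )
    return expr, drugs, combos


class TestAssemble:
    def test_toy_join_counts(self):
        expr, drugs, combos = toy_tables()
        ds = assemble_dataset(expr, drugs, combos, DatasetConfig(grid_size=32))
        # one record is sign-discordant -> excluded
        assert len(ds) == 5
        assert ds.provenance["n_excluded"] == 1
        assert set(ds.tensors) <= {"c1", "c2", "c3"}
        assert all(t.channels.shape == (3, 32, 32) for t in ds.tensors.values())

    def test_unknown_drug_reported(self):
        expr, drugs, combos = toy_tables()
        combos.loc[0, "drug_a"] = "mystery"
        with pytest.raises(KeyError, match="mystery"):
            assemble_dataset(expr, drugs, combos, DatasetConfig(grid_size=32))

    def test_unknown_reference_droppable_by_flag(self):
        expr, drugs, combos = toy_tables()
        combos.loc[0, "drug_a"] = "mystery"
        ds = assemble_dataset(
            expr, drugs, combos, DatasetConfig(grid_size=32, drop_unresolvable=True)
        )
        assert all(a != "mystery" for (_, a, _, _, _) in ds.samples)

    def test_deterministic(self):
        expr, drugs, combos = toy_tables()
        ds1 = assemble_dataset(expr, drugs, combos, DatasetConfig(grid_size=32))
        ds2 = assemble_dataset(expr, drugs, combos, DatasetConfig(grid_size=32))
        assert ds1.samples == ds2.samples

    def test_sample_count_is_labeled_minus_excluded(self):
        expr, drugs, combos = toy_tables()
        ds = assemble_dataset(expr, drugs, combos, DatasetConfig(grid_size=32))
        assert len(ds) + ds.provenance["n_excluded"] == len(combos)


class TestReaders:
    def test_roundtrip(self, tmp_path):
        expr, drugs, combos = toy_tables()
        expr.to_csv(tmp_path / "e.tsv", sep="\t")
        drugs.to_csv(tmp_path / "d.tsv", sep="\t")
        combos.to_csv(tmp_path / "c.csv", index=False)
        e = read_expression_table(tmp_path / "e.tsv", normalize=False)
        pd.testing.assert_frame_equal(e, expr, check_names=False)
        d = read_drug_table(tmp_path / "d.tsv")
        assert list(d.index) == list(drugs.index)
        c = read_combination_table(tmp_path / "c.csv")
        assert len(c) == len(combos)

    def test_expression_zscore(self, tmp_path):
        expr, _, _ = toy_tables()
        expr.to_csv(tmp_path / "e.tsv", sep="\t")
        e = read_expression_table(tmp_path / "e.tsv", normalize=True)
        np.testing.assert_allclose(e.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(e.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_bad_drug_header_rejected(self, tmp_path):
        (tmp_path / "d.tsv").write_text("name\tstructure\nd1\tCCO\n")
        with pytest.raises(ValueError, match="drug_id"):
            read_drug_table(tmp_path / "d.tsv")

    def test_missing_combo_column_rejected(self, tmp_path):
        (tmp_path / "c.csv").write_text("drug_a,drug_b,cell_line,loewe\nd1,d2,c1,3\n")
        with pytest.raises(ValueError, match="missing"):
            read_combination_table(tmp_path / "c.csv")
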