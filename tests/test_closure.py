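"""The fixed-point derivation engine and its tabular I/O."""

import itertools
import logging

import pytest

import relframe as rf
from relframe import (
    DerivationLevel,
    DerivationRecord,
    DerivationTable,
    KUMode,
    Statement,
    Operator,
    dedup_relations,
    parse_statement,
    read_table,
    relation_train,
    summarize,
    write_table,
)
from conftest import TUTORIAL3_RELATIONS, relations


class TestSeedPass:
    def test_trained_then_mutual_order(self, table1):
        levels = [r.level for r in table1.records[:4]]
        assert levels == [
            DerivationLevel.DIRECT,
            DerivationLevel.MUTUAL,
            DerivationLevel.DIRECT,
            DerivationLevel.MUTUAL,
        ]

    def test_base_statement_not_shadowed_by_earlier_mutual_entailment(self):
        # B>A is A<B's mutual entailment but is itself trained: both stay DIRECT
        table = relation_train(["A<B", "B>A"])
        assert [(str(r.statement), r.level) for r in table.records] == [
            ("A < B", DerivationLevel.DIRECT),
            ("B > A", DerivationLevel.DIRECT),
        ]

    def test_duplicate_base_statement_dropped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="relframe.closure"):
            table = relation_train(["A=B", "A=B", "B=C"])
        assert len(table) == 6
        assert any("duplicate" in message for message in caplog.messages)

    def test_empty_base_rejected(self):
        with pytest.raises(ValueError):
            relation_train([])

    def test_parse_error_names_offending_statement(self):
        with pytest.raises(rf.ParseError, match="A\\?B"):
            relation_train(["A=B", "A?B"])


class TestWorkedExamples:
    @pytest.mark.parametrize("mode", list(KUMode))
    def test_equivalence_network(self, mode):
        """Two trained equivalences derive the full six-statement network in
        every KU mode (no indeterminate case can arise from equivalence)."""
        table = relation_train(["A=B", "B=C"], mode)
        expected = [
            ("A = B", DerivationLevel.DIRECT, "NA"),
            ("B = A", DerivationLevel.MUTUAL, "NA"),
            ("B = C", DerivationLevel.DIRECT, "NA"),
            ("C = B", DerivationLevel.MUTUAL, "NA"),
            ("A = C", DerivationLevel.COMBINATORIAL, "A = B,B = C"),
            ("C = A", DerivationLevel.COMBINATORIAL_MUTUAL, "A = B,B = C"),
        ]
        got = [
            (
                str(r.statement),
                r.level,
                ",".join(str(p) for p in r.parents) or "NA",
            )
            for r in table.records
        ]
        assert got == expected
        assert [r.color for r in table.records] == [
            "Blue", "Purple", "Blue", "Purple", "Orange", "Orange",
        ]

    def test_mixed_network_off(self, table2_off):
        assert [str(r.statement) for r in table2_off.records] == [
            "A > B", "B < A", "B = C", "C = B", "A > C", "C < A",
        ]

    def test_mixed_network_emit_adds_ku_pair(self, table2_emit):
        assert relations(table2_emit) == relations_off_plus_ku()

    def test_complex_network_statement_set(self, table3):
        assert len(table3) == 48
        assert relations(table3) == set(TUTORIAL3_RELATIONS)

    def test_complex_network_trained_records(self, table3):
        trained = {
            str(r.statement)
            for r in table3.records
            if r.level is DerivationLevel.DIRECT
        }
        assert trained == {
            "gkuj", "h < i", "i < k", "k < j", "l < o", "mkuk", "n = o", "p > o",
        }

    def test_contradictory_base_derives_both_directions(self):
        table = relation_train(["A>B", "B=C", "C>A"])
        names = relations(table)
        assert {"A < C", "A > C"} <= names

    def test_two_strict_chains_emit(self):
        table = relation_train(["A<B", "B<C"], KUMode.EMIT)
        assert relations(table) == {
            "A < B", "B > A", "B < C", "C > B", "A < C", "C > A",
            "AkuB", "BkuA", "BkuC", "CkuB",
        }
        assert len(table) == 10

    def test_provenance_parents_share_one_stimulus(self, table3):
        for record in table3.records:
            if record.parents:
                a, b = record.parents
                assert len(a.stimuli & b.stimuli) == 1
                assert a in table3.statement_set()
                assert b in table3.statement_set()


def relations_off_plus_ku():
    return {
        "A > B", "B < A", "B = C", "C = B", "A > C", "C < A", "BkuC", "CkuB",
    }


class TestClosureProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_statement_set_invariant_under_base_order(self, seed):
        import random

        base = rf.fixture("tutorial3")
        random.Random(seed).shuffle(base)
        assert relations(relation_train(base)) == set(TUTORIAL3_RELATIONS)

    @pytest.mark.parametrize("name", ["tutorial1", "tutorial2", "tutorial3",
                                      "contradiction"])
    def test_statement_set_fixed_point(self, name):
        first = relation_train(rf.fixture(name), KUMode.EMIT)
        again = relation_train([str(s) for s in first.statements()], KUMode.EMIT)
        assert again.statement_set() == first.statement_set()

    @pytest.mark.parametrize("seed", range(6))
    def test_termination_bound(self, seed):
        config = rf.GeneratorConfig(
            n_stimuli=5, n_statements=5, seed=seed,
            operator_weights={"<": 1, ">": 1, "=": 0.5, "ku": 0.5},
        )
        table = relation_train(rf.random_base_set(config))
        n = len(table.stimuli)
        assert len(table) <= 4 * n * (n - 1)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_equivalence_chain_yields_all_ordered_pairs(self, n):
        stimuli = "ABCDE"[:n]
        base = [f"{stimuli[i]}={stimuli[i + 1]}" for i in range(n - 1)]
        table = relation_train(base)
        assert len(table) == n * (n - 1)
        assert all(r.statement.op is Operator.EQ for r in table.records)

    def test_mutual_closure(self, table3):
        present = table3.statement_set()
        for s in present:
            assert rf.mutual_entail(s) in present

    def test_sorted_is_display_only(self, table3):
        shown = table3.sorted()
        assert shown.statement_set() == table3.statement_set()
        combinatorial_started = False
        for record in shown.records:
            if record.level.is_combinatorial:
                combinatorial_started = True
            else:
                assert not combinatorial_started


class TestDedup:
    def test_engine_output_passes_through(self, table1):
        assert dedup_relations(table1).records == table1.records

    def test_first_wins_and_idempotent(self):
        dup = DerivationRecord(
            parse_statement("A=C"),
            DerivationLevel.COMBINATORIAL,
            (parse_statement("A=B"), parse_statement("B=C")),
        )
        table = DerivationTable([dup, DerivationRecord(
            parse_statement("A=C"), DerivationLevel.MUTUAL)])
        deduped = dedup_relations(table)
        assert deduped.records == [dup]
        assert dedup_relations(deduped).records == deduped.records


class TestSummarize:
    def test_equivalence_network(self, table1):
        stats = summarize(table1)
        assert stats["by_level"] == {
            "Directly Trained": 2,
            "Mutually Entailed": 2,
            "Combinatorially Entailed": 1,
            "Combinatorially Mutually Entailed": 1,
        }
        assert stats["stimuli"] == 3
        assert stats["components"] == 1

    def test_complex_network(self, table3):
        stats = summarize(table3)
        assert stats["total"] == 48
        assert stats["stimuli"] == 10
        assert stats["components"] == 2

    def test_single_statement(self):
        stats = summarize(relation_train(["A<B"]))
        assert stats["trained"] == 1
        assert stats["derived"] == 1
        assert stats["by_level"]["Combinatorially Entailed"] == 0


class TestTableIO:
    def test_csv_schema_and_first_row(self, table1, tmp_path):
        path = tmp_path / "table1.csv"
        write_table(table1, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == (
            "From,To,Operator,Derivation_Level,Relation,Edge_color,Derived_from"
        )
        assert lines[1] == "A,B,=,Directly Trained,A = B,Blue,NA"
        assert len(lines) == 7
        assert '"A = B,B = C"' in lines[5]

    @pytest.mark.parametrize("name", ["tutorial1", "tutorial3", "contradiction"])
    def test_roundtrip(self, name, tmp_path):
        table = relation_train(rf.fixture(name))
        path = tmp_path / "t.csv"
        write_table(table, path)
        assert read_table(path).records == table.records

    def test_missing_edge_color_recomputed(self, table1, tmp_path):
        path = tmp_path / "t.csv"
        df = table1.to_dataframe().drop(columns=["Edge_color"])
        df.to_csv(path, index=False)
        loaded = read_table(path)
        assert [r.color for r in loaded.records] == [
            r.color for r in table1.records
        ]

    def test_missing_relation_column_rejected(self, table1, tmp_path):
        path = tmp_path / "t.csv"
        table1.to_dataframe().drop(columns=["Relation"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="Relation"):
            read_table(path)

    def test_unknown_level_rejected(self, table1, tmp_path):
        path = tmp_path / "t.csv"
        df = table1.to_dataframe()
        df.loc[0, "Derivation_Level"] = "Telepathically Entailed"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="Telepathically"):
            read_table(path)

    def test_loaded_duplicates_survive_until_dedup(self, table1, tmp_path):
        path = tmp_path / "t.csv"
        import pandas as pd

        df = table1.to_dataframe()
        df = pd.concat([df, df.iloc[[4]]], ignore_index=True)
        df.to_csv(path, index=False)
        loaded = read_table(path)
        assert len(loaded) == 7
        assert len(dedup_relations(loaded)) == 6
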