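"""Item normalization, the built-in corpus, orientations, and file I/O."""

import pytest

import herbbasket as hb
from herbbasket.errors import (
    EmptyDatabaseError,
    InvalidArgumentError,
    InvalidItemError,
    ParseError,
)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Tufulin ", "tufulin"),
        ("chuanxiong", "chuanxiong"),
        ("Dahuang", "dahuang"),  # capitalized and lowercase spellings are one item
        ("  XiXin\t", "xixin"),
    ],
)
def test_normalize_item(raw, expected):
    assert hb.normalize_item(raw) == expected
    assert hb.normalize_item(hb.normalize_item(raw)) == hb.normalize_item(raw)


@pytest.mark.parametrize("bad", ["", "   ", "\t\n"])
def test_normalize_rejects_blank(bad):
    with pytest.raises(InvalidItemError):
        hb.normalize_item(bad)


class TestBuiltinCorpus:
    def test_shape(self, paper_table):
        assert len(paper_table) == 17
        assert len(paper_table.all_herbs) == 43
        assert paper_table.max_len == 22

    def test_longest_formula_is_zhao_2011(self, paper_table):
        longest = max(paper_table.records, key=lambda r: len(r.herbs))
        assert longest.study_label == "Zhao, 2011"
        assert len(longest.herbs) == 22

    def test_all_herbs_resolve_in_lexicon(self, paper_table):
        lex = hb.builtin_paper_lexicon()
        assert len(lex) == 43
        assert all(h in lex for h in paper_table.all_herbs)

    def test_records_have_no_duplicates(self, paper_table):
        for rec in paper_table.records:
            assert len(set(rec.herbs)) == len(rec.herbs)


class TestOrientations:
    def test_by_formula_shape(self, paper_table, by_formula_db):
        assert by_formula_db.n == 17
        assert by_formula_db.universe == paper_table.all_herbs

    def test_by_rank_shape(self, by_rank_db):
        assert by_rank_db.n == 22

    def test_by_rank_single_column_transposes_to_singletons(self):
        table = hb.FormulaTable(
            (hb.FormulaRecord("only", ("a", "b", "c")),)
        )
        db = hb.to_transactions(table, "by_rank")
        assert [set(t) for t in db] == [{"a"}, {"b"}, {"c"}]

    def test_by_rank_transactions_cover_every_placement(self, paper_table, by_rank_db):
        # transaction r is exactly the SET of rank-r herbs: every placement
        # lands in its rank's transaction, repeats within a rank collapse
        assert sum(len(r.herbs) for r in paper_table.records) == 182
        for rank, tx in enumerate(by_rank_db):
            placed = {
                r.herbs[rank] for r in paper_table.records if len(r.herbs) > rank
            }
            assert tx == placed

    def test_by_formula_invariant_under_record_permutation(self, paper_table):
        reversed_table = hb.FormulaTable(tuple(reversed(paper_table.records)))
        a = hb.to_transactions(paper_table, "by_formula")
        b = hb.to_transactions(reversed_table, "by_formula")
        assert sorted(map(sorted, a)) == sorted(map(sorted, b))

    def test_unknown_orientation_rejected(self, paper_table):
        with pytest.raises(InvalidArgumentError):
            hb.to_transactions(paper_table, "sideways")


class TestBasketIO:
    def test_read_two_line_basket(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("a,b\nb,c\n")
        db = hb.read_basket(p)
        assert db.n == 2
        assert db.universe == {"a", "b", "c"}

    def test_round_trip_preserves_by_rank_db(self, tmp_path, by_rank_db):
        p = tmp_path / "rank.csv"
        hb.write_basket(by_rank_db, p)
        again = hb.read_basket(p)
        assert list(again) == list(by_rank_db.transactions)

    def test_duplicates_collapse_with_warning(self, tmp_path, caplog):
        p = tmp_path / "dup.csv"
        p.write_text("a,a,b\n")
        with caplog.at_level("WARNING"):
            db = hb.read_basket(p)
        assert list(db) == [frozenset({"a", "b"})]
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(EmptyDatabaseError):
            hb.read_basket(p)


class TestLongAndGridIO:
    def test_long_format_groups_by_id(self, tmp_path):
        p = tmp_path / "long.csv"
        p.write_text("transaction_id,item\nt1,a\nt1,b\nt2,c\n")
        db = hb.read_long(p)
        assert sorted(map(sorted, db)) == [["a", "b"], ["c"]]

    def test_long_format_bad_header(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,thing\nt1,a\n")
        with pytest.raises(ParseError):
            hb.read_long(p)

    def test_grid_round_trip_recovers_corpus(self, tmp_path, paper_table):
        from herbbasket.transactions import read_grid, write_grid

        p = tmp_path / "grid.csv"
        write_grid(paper_table, p)
        again = read_grid(p)
        assert [r.herbs for r in again.records] == [
            r.herbs for r in paper_table.records
        ]

    def test_grid_empty_cells_skip_deep_ranks(self, tmp_path):
        from herbbasket.transactions import read_grid

        p = tmp_path / "g.csv"
        p.write_text("f1,f2\na,x\nb,\n")
        table = read_grid(p)
        assert [r.herbs for r in table.records] == [("a", "b"), ("x",)]
        assert hb.to_transactions(table, "by_rank").n == 2
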