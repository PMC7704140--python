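"""Rule metrics, generation, sorting, and the published-rule replication."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import herbbasket as hb
from herbbasket.errors import InvalidRuleError, UndefinedConfidenceError

from test_apriori import small_dbs


class TestRuleMetrics:
    def test_chuanxiong_dahuang_pair(self, by_rank_db):
        r = hb.rule_metrics(by_rank_db, {"chuanxiong"}, {"dahuang"})
        assert math.isclose(r.support, 2 / 22)
        assert r.confidence == 1.0
        assert math.isclose(r.expected_confidence, 2 / 22)
        assert math.isclose(r.lift, 11.0)

    def test_jixueteng_danggui_pair(self, by_rank_db):
        r = hb.rule_metrics(by_rank_db, {"jixueteng"}, {"danggui"})
        assert math.isclose(r.support, 3 / 22)
        assert r.confidence == 1.0
        assert math.isclose(r.expected_confidence, 4 / 22)
        assert math.isclose(r.lift, 5.5)

    def test_independence_gives_lift_one(self):
        db = hb.make_db([{"a", "b"}, {"a"}])
        r = hb.rule_metrics(db, {"a"}, {"b"})
        assert (r.support, r.confidence, r.expected_confidence, r.lift) == (
            0.5, 0.5, 0.5, 1.0
        )

    def test_overlapping_sets_rejected(self, by_rank_db):
        with pytest.raises(InvalidRuleError):
            hb.rule_metrics(by_rank_db, {"kushen"}, {"kushen", "difuzi"})

    def test_absent_antecedent_rejected(self, by_rank_db):
        with pytest.raises(UndefinedConfidenceError):
            hb.rule_metrics(by_rank_db, {"not-a-herb"}, {"kushen"})

    def test_lift_identity_holds_exactly(self, paper_rules):
        for r in paper_rules:
            assert abs(r.lift * r.expected_confidence - r.confidence) < 1e-12


class TestGenerateRules:
    def test_hand_enumerated_three_transaction_db(self):
        db = hb.make_db([{"a", "b"}, {"a", "b"}, {"c"}])
        frequent = hb.mine_frequent(db, hb.MiningParams(0.5, 2))
        rules = hb.generate_rules(
            db, frequent, hb.RuleFilter(0.5, 0.9, antecedent_size=1)
        )
        assert {r.label() for r in rules} == {"{a} => {b}", "{b} => {a}"}

    def test_full_confidence_means_containment(self, by_rank_db):
        frequent = hb.mine_frequent(by_rank_db, hb.MiningParams(0.05, 2))
        rules = hb.generate_rules(by_rank_db, frequent, hb.RuleFilter(0.05, 1.0))
        for r in rules:
            ante_tx = [t for t in by_rank_db if r.antecedent <= t]
            assert all(r.consequent <= t for t in ante_tx)

    def test_rule_support_bounded_by_both_sides(self, by_rank_db, paper_rules):
        for r in paper_rules:
            assert r.joint_count <= r.antecedent_count
            assert r.joint_count <= r.consequent_count

    def test_invariant_under_frequent_list_permutation(self, by_rank_db):
        frequent = hb.mine_frequent(by_rank_db, hb.MiningParams(0.05, 2))
        f = hb.RuleFilter(0.05, 0.9, antecedent_size=1, consequent_size=1)
        a = hb.generate_rules(by_rank_db, frequent, f)
        b = hb.generate_rules(by_rank_db, list(reversed(frequent)), f)
        assert [r.label() for r in a] == [r.label() for r in b]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(db=small_dbs(), lo=st.integers(1, 10), hi=st.integers(0, 9))
    def test_raising_thresholds_never_adds_rules(self, db, lo, hi):
        frequent = hb.mine_frequent(db, hb.MiningParams(lo / 20, 3))
        loose = hb.generate_rules(db, frequent, hb.RuleFilter(lo / 20, 0.5))
        tight_conf = hb.generate_rules(
            db, frequent, hb.RuleFilter(lo / 20, min(1.0, 0.5 + hi / 10))
        )
        assert {r.label() for r in tight_conf} <= {r.label() for r in loose}

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(db=small_dbs())
    def test_lift_is_symmetric(self, db):
        frequent = hb.mine_frequent(db, hb.MiningParams(0.1, 2))
        rules = hb.generate_rules(db, frequent, hb.RuleFilter(0.1, 0.01))
        by_pair = {(r.antecedent, r.consequent): r.lift for r in rules}
        for (a, b), lift in by_pair.items():
            if (b, a) in by_pair:
                assert math.isclose(lift, by_pair[(b, a)])


class TestSortRules:
    def test_sorted_on_empty_and_idempotent(self, paper_rules):
        assert hb.sort_rules([]) == []
        once = hb.sort_rules(list(paper_rules))
        assert hb.sort_rules(list(reversed(once))) == once

    def test_higher_support_rules_come_first(self, paper_rules):
        supports = [r.support for r in paper_rules]
        assert supports == sorted(supports, reverse=True)
        assert all(math.isclose(s, 3 / 22) for s in supports[:3])
        assert all(math.isclose(s, 2 / 22) for s in supports[3:])


class TestReplication:
    def test_nineteen_rules_all_confidence_one(self, paper_rules):
        assert len(paper_rules) == 19
        assert all(r.confidence == 1.0 for r in paper_rules)

    def test_exactly_two_support_values(self, paper_rules):
        assert {round(r.support, 8) for r in paper_rules} == {
            round(3 / 22, 8), round(2 / 22, 8)
        }

    def test_heshouwu_fangfeng_lift(self, paper_rules):
        (r,) = [
            r for r in paper_rules
            if r.antecedent == {"heshouwu"} and r.consequent == {"fangfeng"}
        ]
        assert math.isclose(r.lift, 22 / 3)

    def test_tsv_and_json_exports(self, tmp_path, paper_rules):
        from herbbasket.rules import write_rules_json, write_rules_tsv

        tsv = tmp_path / "rules.tsv"
        write_rules_tsv(paper_rules, tsv)
        lines = tsv.read_text().splitlines()
        assert len(lines) == 20
        assert lines[1].split("\t")[1].startswith("{")

        import json

        jp = tmp_path / "rules.json"
        write_rules_json(paper_rules, jp)
        payload = json.loads(jp.read_text())
        assert len(payload) == 19
        assert all(row["n"] == 22 for row in payload)
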