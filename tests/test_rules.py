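"""Rule generation: bipartitions, the four validity regimes, and
agreement of every emitted measure with brute-force counting."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fisinfis.measures import Literal, SupportTable
from fisinfis.miner import MiningConfig, mine
from fisinfis.rules import (
    bipartitions,
    mine_all_rules,
    rules_from_frequent,
    rules_from_infrequent,
)

from conftest import brute_literal_count, make_db, random_db


def table_from(entries: dict) -> SupportTable:
    t = SupportTable(n_docs=0)
    for items, s in entries.items():
        t.set(items if isinstance(items, tuple) else (items,), s)
    return t


def rule_index(ruleset):
    return {r.key: r for r in ruleset}


class TestBipartitions:
    def test_pair(self):
        assert set(bipartitions(("a", "b"))) == {
            (("a",), ("b",)), (("b",), ("a",))
        }

    @pytest.mark.parametrize("n,count", [(2, 2), (3, 6), (4, 14)])
    def test_count_is_2_pow_n_minus_2(self, n, count):
        items = tuple(f"i{k}" for k in range(n))
        parts = bipartitions(items)
        assert len(parts) == count == 2**n - 2
        for a, b in parts:
            assert set(a) | set(b) == set(items)
            assert not set(a) & set(b)

    def test_singleton_empty(self):
        assert bipartitions(("a",)) == []


class TestRulesFromFrequent:
    """Worked frequent-itemset configuration: supp(A)=0.7, supp(B)=0.5,
    supp(A∪B)=0.25 — positively co-occurring often enough to be a
    frequent pair, yet negatively dependent (lift < 1)."""

    TABLE = table_from({"A": "0.7", "B": "0.5", ("A", "B"): "0.25"})
    CFG = MiningConfig(min_supp=0.2, min_conf=0.6)

    def test_positive_rule_rejected_negative_emitted(self):
        rules = rule_index(
            rules_from_frequent({("A", "B")}, self.TABLE, self.CFG)
        )
        assert (("A",), False, ("B",), False) not in rules  # conf .3571, lift .7143
        nar = rules[(("A",), False, ("B",), True)]
        assert nar.rule_class == "NAR-FIS"
        assert nar.support == Fraction("0.45")
        assert round(float(nar.confidence), 4) == 0.6429
        assert round(float(nar.lift), 4) == 1.2857

    def test_independent_pair_no_rules(self):
        t = table_from({"A": "0.5", "B": "0.5", ("A", "B"): "0.25"})
        assert len(rules_from_frequent({("A", "B")}, t, self.CFG)) == 0

    def test_perfect_implication_needs_nonuniversal_consequent(self):
        # supp(A∪B) == supp(A) == supp(B): conf 1, lift 1/supp(B)
        t = table_from({"A": "0.4", "B": "0.4", ("A", "B"): "0.4"})
        rules = rule_index(rules_from_frequent({("A", "B")}, t, self.CFG))
        assert (("A",), False, ("B",), False) in rules
        t_univ = table_from({"A": "1", "B": "1", ("A", "B"): "1"})
        assert (
            len(rules_from_frequent({("A", "B")}, t_univ, self.CFG)) == 0
        )

    def test_class_filter(self):
        cfg = MiningConfig(rule_classes=frozenset({"PAR-FIS"}))
        rules = rules_from_frequent({("A", "B")}, self.TABLE, cfg)
        assert all(
            not r.antecedent.negated and not r.consequent.negated
            for r in rules
        )


class TestRulesFromInfrequent:
    """Worked infrequent-itemset configuration (mole/cancer): the pair
    co-occurs in 5% of documents only, far below its expectation under
    independence — a strong negative dependence."""

    TABLE = table_from(
        {"mole": "0.4", "cancer": "0.6", ("cancer", "mole"): "0.05"}
    )
    CFG = MiningConfig(min_supp=0.2, min_conf=0.6)

    def test_mole_implies_not_cancer(self):
        rules = rule_index(
            rules_from_infrequent({("cancer", "mole")}, self.TABLE, self.CFG)
        )
        assert (("mole",), False, ("cancer",), False) not in rules  # conf 0.125
        nar = rules[(("mole",), False, ("cancer",), True)]
        assert nar.rule_class == "NAR-inFIS"
        assert nar.support == Fraction("0.35")
        assert nar.confidence == Fraction("0.875")
        assert nar.lift == Fraction("2.1875")

    def test_sole_rule_with_mole_antecedent(self):
        rules = rules_from_infrequent(
            {("cancer", "mole")}, self.TABLE, self.CFG
        )
        with_mole = [
            r for r in rules
            if r.antecedent == Literal(("mole",), False)
        ]
        assert len(with_mole) == 1
        assert with_mole[0].consequent == Literal(("cancer",), True)

    def test_infrequent_subitem_blocks_rules(self):
        t = table_from({"A": "0.8", "B": "0.2", ("A", "B"): "0.2"})
        cfg = MiningConfig(min_supp=0.3, min_conf=0.7)
        assert len(rules_from_infrequent({("A", "B")}, t, cfg)) == 0

    def test_positive_rule_from_infrequent_pair(self):
        """A rare co-occurrence that is a perfect implication: B always
        comes with A, so conf(B=>A)=1 and lift > 1."""
        t = table_from({"A": "0.8", "B": "0.2", ("A", "B"): "0.2"})
        cfg = MiningConfig(min_supp=0.2, min_conf=0.7)
        rules = rule_index(rules_from_infrequent({("A", "B")}, t, cfg))
        par = rules[(("B",), False, ("A",), False)]
        assert par.rule_class == "PAR-inFIS"
        assert par.confidence == 1
        assert par.lift == Fraction("1.25")  # 0.2 / (0.2 × 0.8)
        # A=>B: conf 0.25 < mc, rejected
        assert (("A",), False, ("B",), False) not in rules


class TestMineAllRules:
    def test_empty_inputs(self):
        cfg = MiningConfig()
        assert len(mine_all_rules(set(), set(), SupportTable(), cfg)) == 0

    def test_deterministic_sort_and_dedup(self):
        t = table_from(
            {"mole": "0.4", "cancer": "0.6", ("cancer", "mole"): "0.05"}
        )
        cfg = MiningConfig()
        rs1 = mine_all_rules(set(), {("cancer", "mole")}, t, cfg)
        rs2 = mine_all_rules(set(), {("cancer", "mole")}, t, cfg)
        assert [r.format() for r in rs1] == [r.format() for r in rs2]
        keys = [r.key for r in rs1]
        assert len(keys) == len(set(keys))
        lifts = [r.lift for r in rs1]
        assert lifts == sorted(lifts, reverse=True)

    def test_complementarity_when_mc_above_half(self, rng):
        """For mc > 0.5 at most one of A=>B, A=>¬B can pass."""
        db = random_db(rng)
        result = mine(db, MiningConfig(min_supp=0.25))
        rules = mine_all_rules(
            result.fis, result.infis, result.table,
            MiningConfig(min_supp=0.25, min_conf=0.6),
        )
        seen = set()
        for r in rules:
            flipped = (
                r.antecedent.base, r.antecedent.negated,
                r.consequent.base, not r.consequent.negated,
            )
            assert flipped not in seen
            seen.add(r.key)

    def test_class_soundness(self, rng):
        """FIS-stream rules have frequent unions; inFIS-stream rules have
        infrequent unions with frequent sides."""
        db = random_db(rng)
        cfg = MiningConfig(min_supp=0.3, min_conf=0.6)
        ms = cfg.min_supp_frac
        result = mine(db, cfg)
        for r in mine_all_rules(result.fis, result.infis, result.table, cfg):
            union = tuple(sorted(set(r.antecedent.base) | set(r.consequent.base)))
            union_supp = result.table.get(union)
            if r.rule_class.endswith("-FIS"):
                assert union_supp >= ms
            else:
                assert union_supp < ms
                assert result.table.get(r.antecedent.base) >= ms
                assert result.table.get(r.consequent.base) >= ms

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.sampled_from([0.2, 0.3, 0.4]),
    )
    def test_measures_match_brute_force(self, seed, ms):
        """Every emitted rule's measures equal direct transaction
        counting of its literal patterns."""
        rng = np.random.default_rng(seed)
        db = random_db(rng)
        cfg = MiningConfig(min_supp=ms, min_conf=0.5)
        result = mine(db, cfg)
        rules = mine_all_rules(result.fis, result.infis, result.table, cfg)
        n = db.n_docs
        for r in rules:
            joint = Fraction(
                brute_literal_count(
                    r.antecedent.base, r.antecedent.negated,
                    r.consequent.base, r.consequent.negated,
                    db.transactions,
                ),
                n,
            )
            ant = Fraction(
                brute_literal_count(
                    r.antecedent.base, r.antecedent.negated,
                    r.antecedent.base, r.antecedent.negated,
                    db.transactions,
                ),
                n,
            )
            cons = Fraction(
                brute_literal_count(
                    r.consequent.base, r.consequent.negated,
                    r.consequent.base, r.consequent.negated,
                    db.transactions,
                ),
                n,
            )
            assert r.support == joint
            assert r.confidence == joint / ant
            assert r.lift == joint / (ant * cons)
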