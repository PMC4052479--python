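"""Rule generation from frequent itemsets and the negative border.

Four rule streams are produced, named by polarity and provenance:

* PAR-FIS — positive rules A=>B from frequent itemsets; the classical
  Apriori output, valid when supp(A∪B) ≥ ms, conf ≥ mc, lift > min_lift.
* NAR-FIS — negative rules (A=>¬B, ¬A=>B, ¬A=>¬B) from frequent
  itemsets: co-occurring item groups whose sub-patterns are negatively
  dependent.
* PAR-inFIS — positive rules from infrequent itemsets of interest.
  supp(A∪B) < ms by construction, so the union-support condition is
  deliberately waived for this class; the sub-itemset supports (which
  are ≥ ms because the negative border has all proper subsets frequent)
  plus conf ≥ mc and lift > min_lift carry the validity burden.  A rare
  co-occurrence can still be a near-implication (e.g. conf(B=>A)=1).
* NAR-inFIS — negative rules from infrequent itemsets; the literal
  pattern's own support must reach ms (e.g. supp(A∪¬B) ≥ ms), which is
  what makes a negative rule from a rare co-occurrence statistically
  grounded.

For every parent itemset all ordered bipartitions (A, B) are tried, so
symmetric forms like B=>¬A arise without being listed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from json import dumps
from pathlib import Path
from typing import Any, Iterable, Mapping

from .measures import (
    AssociationRule,
    Itemset,
    Literal,
    SupportTable,
    canon,
    confidence,
    lift,
    literal_pattern_support,
    literal_support,
)
from .miner import MiningConfig

__all__ = [
    "RuleSet",
    "bipartitions",
    "rules_from_frequent",
    "rules_from_infrequent",
    "mine_all_rules",
    "write_rules_csv",
    "write_rules_json",
]

# The negative forms tried per ordered bipartition (A, B).
_NEGATIVE_FORMS = ((False, True), (True, False), (True, True))


@dataclass
class RuleSet:
    """Deduplicated, deterministically sorted collection of rules."""

    rules: list[AssociationRule] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def add(self, rule: AssociationRule) -> None:
        self.rules.append(rule)

    def finalize(self) -> "RuleSet":
        """Drop duplicate (antecedent, consequent, negation) rules and
        sort by lift desc, confidence desc, support desc, then rule text."""
        seen = {}
        for r in self.rules:
            seen.setdefault(r.key, r)
        self.rules = sorted(
            seen.values(),
            key=lambda r: (-r.lift, -r.confidence, -r.support, r.format()),
        )
        return self

    def by_class(self) -> dict[str, list[AssociationRule]]:
        out: dict[str, list[AssociationRule]] = {}
        for r in self.rules:
            out.setdefault(r.rule_class, []).append(r)
        return out


def bipartitions(itemset: Iterable[Any]) -> list[tuple[Itemset, Itemset]]:
    """All ordered pairs (A, B) of non-empty disjoint sub-itemsets with
    A ∪ B = itemset; 2^n − 2 pairs for n items, [] for a singleton."""
    items = canon(itemset)
    n = len(items)
    if n < 2:
        return []
    out = []
    for r in range(1, n):
        for a in combinations(items, r):
            b = tuple(i for i in items if i not in a)
            out.append((a, b))
    return out


def _try_rule(
    a: Literal,
    b: Literal,
    table: SupportTable,
    config: MiningConfig,
    rule_class: str,
    require_union_supp: bool,
) -> AssociationRule | None:
    """Apply the validity conditions to one literal pair; None if invalid.

    require_union_supp demands the joint literal-pattern support reach
    min_supp; it is waived only for PAR-inFIS (false by construction).
    Zero-support antecedents/consequents make conf or lift undefined and
    the rule is silently skipped.
    """
    supp = literal_pattern_support(a, b, table)
    if require_union_supp and supp < config.min_supp_frac:
        return None
    conf = confidence(a, b, table)
    if conf is None or conf < config.min_conf_frac:
        return None
    lft = lift(a, b, table)
    if lft is None or not lft > config.min_lift_frac:
        return None
    return AssociationRule(
        antecedent=a, consequent=b,
        support=supp, confidence=conf, lift=lft,
        rule_class=rule_class,
    )


def rules_from_frequent(
    fis: set[Itemset], table: SupportTable, config: MiningConfig
) -> RuleSet:
    """PAR-FIS and NAR-FIS rules from every frequent itemset of size ≥ 2.

    For frequent parents the sub-itemset supports supp(A), supp(B) are
    ≥ supp(A∪B) ≥ ms automatically (anti-monotonicity), so only the
    measure thresholds are tested per bipartition.
    """
    out = RuleSet()
    want_pos = "PAR-FIS" in config.rule_classes
    want_neg = "NAR-FIS" in config.rule_classes
    if not (want_pos or want_neg):
        return out
    for itemset in fis:
        for a_items, b_items in bipartitions(itemset):
            if want_pos:
                rule = _try_rule(
                    Literal(a_items), Literal(b_items), table, config,
                    "PAR-FIS", require_union_supp=True,
                )
                if rule:
                    out.add(rule)
            if want_neg:
                for neg_a, neg_b in _NEGATIVE_FORMS:
                    rule = _try_rule(
                        Literal(a_items, neg_a), Literal(b_items, neg_b),
                        table, config, "NAR-FIS", require_union_supp=True,
                    )
                    if rule:
                        out.add(rule)
    return out.finalize()


def rules_from_infrequent(
    infis: set[Itemset], table: SupportTable, config: MiningConfig
) -> RuleSet:
    """PAR-inFIS and NAR-inFIS rules from the negative border.

    Both sides of a bipartition must be individually frequent
    (supp(A) ≥ ms and supp(B) ≥ ms) — guaranteed when the input is a
    true negative border but re-checked here so the generator is safe
    on arbitrary itemset sets.
    """
    out = RuleSet()
    want_pos = "PAR-inFIS" in config.rule_classes
    want_neg = "NAR-inFIS" in config.rule_classes
    if not (want_pos or want_neg):
        return out
    ms = config.min_supp_frac
    for itemset in infis:
        for a_items, b_items in bipartitions(itemset):
            if table.get(a_items) < ms or table.get(b_items) < ms:
                continue
            if want_pos:
                rule = _try_rule(
                    Literal(a_items), Literal(b_items), table, config,
                    "PAR-inFIS", require_union_supp=False,
                )
                if rule:
                    out.add(rule)
            if want_neg:
                for neg_a, neg_b in _NEGATIVE_FORMS:
                    rule = _try_rule(
                        Literal(a_items, neg_a), Literal(b_items, neg_b),
                        table, config, "NAR-inFIS", require_union_supp=True,
                    )
                    if rule:
                        out.add(rule)
    return out.finalize()


def mine_all_rules(
    fis: set[Itemset],
    infis: set[Itemset],
    table: SupportTable,
    config: MiningConfig,
) -> RuleSet:
    """Union of the frequent and infrequent rule streams, restricted to
    ``config.rule_classes``, deduplicated and deterministically sorted."""
    combined = RuleSet()
    for rule in chain(
        rules_from_frequent(fis, table, config),
        rules_from_infrequent(infis, table, config),
    ):
        combined.add(rule)
    return combined.finalize()


def _rule_row(
    rule: AssociationRule, names: Mapping[Any, str] | None, n_docs: int
) -> dict[str, Any]:
    def fmt_items(items: Itemset) -> str:
        return "|".join(str(names[i]) if names else str(i) for i in items)

    return {
        "rule_class": rule.rule_class,
        "antecedent": fmt_items(rule.antecedent.base),
        "antecedent_negated": rule.antecedent.negated,
        "consequent": fmt_items(rule.consequent.base),
        "consequent_negated": rule.consequent.negated,
        "support": round(float(rule.support), 4),
        "confidence": round(float(rule.confidence), 4),
        "lift": round(float(rule.lift), 4),
        "support_count": int(rule.support * n_docs) if n_docs else None,
        "n_docs": n_docs or None,
    }


def write_rules_csv(
    path: str | Path,
    rules: RuleSet,
    names: Mapping[Any, str] | None = None,
    n_docs: int = 0,
) -> None:
    """CSV rule report (4-decimal floats, header row)."""
    import csv

    cols = [
        "rule_class", "antecedent", "antecedent_negated",
        "consequent", "consequent_negated", "support", "confidence", "lift",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
        writer.writeheader()
        for rule in rules:
            row = _rule_row(rule, names, n_docs)
            row["support"] = f"{row['support']:.4f}"
            row["confidence"] = f"{row['confidence']:.4f}"
            row["lift"] = f"{row['lift']:.4f}"
            writer.writerow(row)


def write_rules_json(
    path: str | Path,
    rules: RuleSet,
    names: Mapping[Any, str] | None = None,
    n_docs: int = 0,
) -> None:
    """JSON rule report: same fields as the CSV plus raw counts."""
    payload = [_rule_row(r, names, n_docs) for r in rules]
    Path(path).write_text(dumps(payload, indent=1) + "\n", encoding="utf-8")
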