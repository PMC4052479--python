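"""Support / confidence / lift algebra for positive and negated patterns.

A rule ``A => B`` ranges over literals: each side is an itemset ``X`` or
its negation ``¬X``, where ``¬X`` denotes the event "the transaction
does NOT contain the whole of X" (the complement of the co-occurrence
event).  With that semantics the joint supports of the four literal
combinations follow from three table entries by inclusion–exclusion:

    supp(¬X)      = 1 − supp(X)
    supp(X ∪ ¬Y)  = supp(X) − supp(X ∪ Y)
    supp(¬X ∪ Y)  = supp(Y) − supp(X ∪ Y)
    supp(¬X ∪ ¬Y) = 1 − supp(X) − supp(Y) + supp(X ∪ Y)

Confidence is the joint-pattern support over the antecedent-pattern
support, and lift divides further by the consequent-pattern support.
All arithmetic is exact (``fractions.Fraction``); floats appear only at
the reporting boundary.

The alternative negation reading, "contains none of X's items", breaks
the identities above for ``|X| > 1`` and is not used; for singleton
itemsets the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Any, Iterable, Mapping

from .corpus import TransactionDB

__all__ = [
    "Itemset",
    "canon",
    "Literal",
    "SupportTable",
    "AssociationRule",
    "RULE_CLASSES",
    "support",
    "support_count",
    "literal_support",
    "literal_pattern_support",
    "confidence",
    "lift",
]

# An itemset is a canonically ordered tuple of items (term ids or term
# strings); canonical order makes equal sets compare and hash equal.
Itemset = tuple[Any, ...]

RULE_CLASSES = ("PAR-FIS", "NAR-FIS", "PAR-inFIS", "NAR-inFIS")


def canon(items: Iterable[Any]) -> Itemset:
    """Canonical (sorted, duplicate-free) tuple form of an itemset."""
    out = tuple(sorted(set(items)))
    if not out:
        raise ValueError("itemset must be non-empty")
    return out


@dataclass(frozen=True)
class Literal:
    """An itemset with an optional negation flag."""

    base: Itemset
    negated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "base", canon(self.base))

    def format(self, names: Mapping[Any, str] | None = None) -> str:
        items = [str(names[i]) if names else str(i) for i in self.base]
        body = "{" + " ".join(items) + "}"
        return f"~{body}" if self.negated else body


def _as_fraction(x: Any) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(str(x))  # exact decimal reading of e.g. 0.4


@dataclass
class SupportTable:
    """Map from canonical itemset to its support fraction.

    Entries are exact rationals; ``n_docs`` records the transaction
    count behind them (0 for a table of stated probabilities, as in a
    planted-truth configuration).
    """

    entries: dict[Itemset, Fraction] = field(default_factory=dict)
    n_docs: int = 0

    def set(self, items: Iterable[Any], supp: Any) -> None:
        s = _as_fraction(supp)
        if not 0 <= s <= 1:
            raise ValueError(f"support out of [0, 1]: {s}")
        self.entries[canon(items)] = s

    def get(self, items: Iterable[Any]) -> Fraction:
        key = canon(items)
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"support table has no entry for itemset {key}") from None

    def __contains__(self, items: Iterable[Any]) -> bool:
        return canon(items) in self.entries

    @classmethod
    def from_db(cls, db: TransactionDB, itemsets: Iterable[Itemset]) -> "SupportTable":
        table = cls(n_docs=db.n_docs)
        for s in itemsets:
            table.set(s, support(s, db))
        return table


def support_count(itemset: Iterable[Any], db: TransactionDB) -> int:
    """Number of transactions containing ALL items of the itemset."""
    items = frozenset(itemset)
    if not items:
        raise ValueError("itemset must be non-empty")
    return sum(1 for t in db.transactions if items <= t)


def support(itemset: Iterable[Any], db: TransactionDB) -> Fraction:
    """Fraction of transactions containing all items of the itemset."""
    if db.n_docs == 0:
        raise ValueError("empty transaction database")
    return Fraction(support_count(itemset, db), db.n_docs)


def literal_support(lit: Literal, table: SupportTable) -> Fraction:
    """Marginal support of a literal: supp(X) or 1 − supp(X)."""
    s = table.get(lit.base)
    return 1 - s if lit.negated else s


def literal_pattern_support(a: Literal, b: Literal, table: SupportTable) -> Fraction:
    """Joint support of the pattern formed by two literals.

    Requires table entries for a.base, b.base and their union; raises
    KeyError naming the missing itemset otherwise.  The four sign
    combinations follow the inclusion–exclusion identities in the
    module docstring.
    """
    union = canon(tuple(a.base) + tuple(b.base))
    s_ab = table.get(union)
    if not a.negated and not b.negated:
        return s_ab
    if not a.negated and b.negated:
        return table.get(a.base) - s_ab
    if a.negated and not b.negated:
        return table.get(b.base) - s_ab
    return 1 - table.get(a.base) - table.get(b.base) + s_ab


def confidence(a: Literal, b: Literal, table: SupportTable) -> Fraction | None:
    """conf(a => b) = supp(joint pattern) / supp(antecedent pattern).

    Returns ``None`` (rule undefined, to be skipped) when the
    antecedent pattern has zero support; this is deliberately distinct
    from an exception, which signals a missing table entry.
    """
    denom = literal_support(a, table)
    if denom == 0:
        return None
    return literal_pattern_support(a, b, table) / denom


def lift(a: Literal, b: Literal, table: SupportTable) -> Fraction | None:
    """lift(a => b) = supp(joint) / (supp(antecedent) · supp(consequent)).

    Negated literals contribute their complement supports to the
    denominator.  Returns ``None`` when either marginal is zero.
    """
    sa = literal_support(a, table)
    sb = literal_support(b, table)
    if sa == 0 or sb == 0:
        return None
    return literal_pattern_support(a, b, table) / (sa * sb)


@dataclass(frozen=True)
class AssociationRule:
    """A validated rule with its measures and provenance class.

    ``rule_class`` records which stream produced the rule: positive or
    negative association rule (PAR/NAR) from frequent (FIS) or
    infrequent-of-interest (inFIS) itemsets.  Measures are stored
    exactly; ``format`` rounds to 4 decimals for reporting.
    """

    antecedent: Literal
    consequent: Literal
    support: Fraction
    confidence: Fraction
    lift: Fraction
    rule_class: str

    def __post_init__(self) -> None:
        if self.rule_class not in RULE_CLASSES:
            raise ValueError(f"unknown rule class: {self.rule_class}")
        if set(self.antecedent.base) & set(self.consequent.base):
            raise ValueError("antecedent and consequent itemsets must be disjoint")
        if not 0 <= self.confidence <= 1:
            raise ValueError(f"confidence out of [0, 1]: {self.confidence}")

    @property
    def key(self) -> tuple:
        return (
            self.antecedent.base,
            self.antecedent.negated,
            self.consequent.base,
            self.consequent.negated,
        )

    def format(self, names: Mapping[Any, str] | None = None) -> str:
        return (
            f"{self.antecedent.format(names)} => {self.consequent.format(names)}"
            f"  supp={float(self.support):.4f}"
            f"  conf={float(self.confidence):.4f}"
            f"  lift={float(self.lift):.4f}"
            f"  [{self.rule_class}]"
        )
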