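"""Level-wise Apriori mining of frequent itemsets and the negative border.

The FISinFIS pass structure is a classic Apriori sweep that keeps, at
every level k, BOTH outcomes of the support test: candidates at or
above ``min_supp`` enter the frequent set FIS, and counted candidates
that fall below it (but above zero) enter inFIS, the infrequent
itemsets *of interest*.  Because candidates at level k are joined only
from frequent (k−1)-itemsets, inFIS is exactly the negative border of
the itemset lattice: every infrequent itemset retained has all proper
subsets frequent — the precondition the rule generator needs for the
positive-rules-from-infrequent-itemsets stream.

Supports are exact rationals (count / n_docs), so threshold comparisons
never hinge on float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Iterable

from .corpus import TransactionDB
from .measures import Itemset, SupportTable, RULE_CLASSES, canon

__all__ = [
    "MiningConfig",
    "LevelResult",
    "MiningResult",
    "generate_level1",
    "generate_candidates",
    "mine",
    "write_itemset_report",
    "read_itemset_report",
]


@dataclass(frozen=True)
class MiningConfig:
    """All mining thresholds in one place.

    min_supp (ms): support threshold separating FIS from inFIS.
    min_conf (mc): confidence threshold for rule validity.
    max_k: largest itemset size mined (default 4).
    min_lift: lift must strictly exceed this for a rule to be valid;
        1.0 demands any positive dependence.
    top_idf_pct: percentage of IDF-ranked terms kept as items.
    log_base: base of the IDF logarithm (10 or e).
    rule_classes: which of the four rule streams to emit.
    seed: seed for any synthetic-data generation in the same run.
    """

    min_supp: float = 0.2
    min_conf: float = 0.6
    max_k: int = 4
    min_lift: float = 1.0
    top_idf_pct: float = 60.0
    log_base: float = 10.0
    rule_classes: frozenset[str] = frozenset(RULE_CLASSES)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_supp < 1:
            raise ValueError(f"min_supp must be in (0, 1), got {self.min_supp}")
        if not 0 < self.min_conf <= 1:
            raise ValueError(f"min_conf must be in (0, 1], got {self.min_conf}")
        if self.max_k < 1:
            raise ValueError(f"max_k must be >= 1, got {self.max_k}")
        unknown = set(self.rule_classes) - set(RULE_CLASSES)
        if unknown:
            raise ValueError(f"unknown rule classes: {sorted(unknown)}")
        object.__setattr__(self, "rule_classes", frozenset(self.rule_classes))

    @property
    def min_supp_frac(self) -> Fraction:
        return Fraction(str(self.min_supp))

    @property
    def min_conf_frac(self) -> Fraction:
        return Fraction(str(self.min_conf))

    @property
    def min_lift_frac(self) -> Fraction:
        return Fraction(str(self.min_lift))


@dataclass
class LevelResult:
    """Frequent and infrequent k-itemsets found at one level."""

    k: int
    fis_k: set[Itemset]
    infis_k: set[Itemset]


@dataclass
class MiningResult:
    fis: set[Itemset]
    infis: set[Itemset]
    table: SupportTable
    levels: list[LevelResult] = field(default_factory=list)


def _count_candidates(
    db: TransactionDB, candidates: Iterable[Itemset]
) -> dict[Itemset, int]:
    counts = {c: 0 for c in candidates}
    if not counts:
        return counts
    sets = {c: frozenset(c) for c in counts}
    for t in db.transactions:
        for c, cset in sets.items():
            if cset <= t:
                counts[c] += 1
    return counts


def generate_level1(db: TransactionDB, min_supp: float | Fraction) -> LevelResult:
    """Partition single terms into FIS_1 / inFIS_1 by support.

    Terms with zero support (possible after IDF projection) belong to
    neither: rules about never-occurring terms are vacuous.
    """
    ms = Fraction(str(min_supp)) if not isinstance(min_supp, Fraction) else min_supp
    counts = _count_candidates(db, [(i,) for i in range(len(db.vocabulary))])
    fis, infis = set(), set()
    for c, n in counts.items():
        supp = Fraction(n, db.n_docs)
        if supp >= ms:
            fis.add(c)
        elif supp > 0:
            infis.add(c)
    return LevelResult(k=1, fis_k=fis, infis_k=infis)


def generate_candidates(fis_prev: set[Itemset]) -> set[Itemset]:
    """Apriori join + prune.

    Join: two frequent (k−1)-itemsets sharing a (k−2)-prefix under
    canonical order.  Prune: keep a candidate only if ALL of its
    (k−1)-subsets are frequent.
    """
    if not fis_prev:
        return set()
    prev = sorted(fis_prev)
    k_minus_1 = len(prev[0])
    candidates = set()
    for i in range(len(prev)):
        for j in range(i + 1, len(prev)):
            a, b = prev[i], prev[j]
            if a[:-1] != b[:-1]:
                continue
            cand = canon(a + (b[-1],))
            if all(
                tuple(sub) in fis_prev
                for sub in combinations(cand, k_minus_1)
            ):
                candidates.add(cand)
    return candidates


def mine(db: TransactionDB, config: MiningConfig) -> MiningResult:
    """Run the full level-wise sweep up to ``config.max_k``.

    Every counted candidate — frequent or not — lands in the support
    table, so the rule generator can later look up any sub-support it
    needs without rescanning the corpus.
    """
    if db.n_docs == 0:
        raise ValueError("empty transaction database")
    ms = config.min_supp_frac
    table = SupportTable(n_docs=db.n_docs)

    level = generate_level1(db, ms)
    counts1 = _count_candidates(db, [(i,) for i in range(len(db.vocabulary))])
    for c, n in counts1.items():
        table.set(c, Fraction(n, db.n_docs))

    result = MiningResult(
        fis=set(level.fis_k), infis=set(level.infis_k), table=table,
        levels=[level],
    )
    fis_prev = level.fis_k
    k = 2
    while fis_prev and k <= config.max_k:
        candidates = generate_candidates(fis_prev)
        if not candidates:
            break
        counts = _count_candidates(db, candidates)
        fis_k, infis_k = set(), set()
        for c, n in counts.items():
            supp = Fraction(n, db.n_docs)
            table.set(c, supp)
            if supp >= ms:
                fis_k.add(c)
            elif supp > 0:
                infis_k.add(c)
        result.levels.append(LevelResult(k=k, fis_k=fis_k, infis_k=infis_k))
        result.fis |= fis_k
        result.infis |= infis_k
        fis_prev = fis_k
        k += 1
    return result


def write_itemset_report(
    path: str | Path, result: MiningResult, db: TransactionDB
) -> None:
    """TSV twin of the itemset summary: itemset, size, count, support, class."""
    lines = [f"# n_docs={db.n_docs}", "itemset\tsize\tcount\tsupport\tclass"]
    rows = []
    for cls, group in (("frequent", result.fis), ("infrequent", result.infis)):
        for itemset in group:
            terms = "|".join(db.vocabulary[i] for i in itemset)
            supp = result.table.get(itemset)
            count = int(supp * db.n_docs)
            rows.append((len(itemset), terms, count, float(supp), cls))
    rows.sort()
    for size, terms, count, supp, cls in rows:
        lines.append(f"{terms}\t{size}\t{count}\t{supp:.4f}\t{cls}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_itemset_report(
    path: str | Path,
) -> tuple[set[Itemset], set[Itemset], SupportTable]:
    """Rebuild (FIS, inFIS, SupportTable) from a saved itemset report.

    Itemsets are keyed by term string here (no vocabulary ids), which
    the rule generator accepts just the same.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("# n_docs="):
        raise ValueError(f"not an itemset report (missing n_docs header): {path}")
    n_docs = int(lines[0].split("=", 1)[1])
    fis: set[Itemset] = set()
    infis: set[Itemset] = set()
    table = SupportTable(n_docs=n_docs)
    for line in lines[1:]:
        if not line.strip() or line.startswith(("#", "itemset\t")):
            continue
        terms_s, _size, count_s, _supp, cls = line.split("\t")
        itemset = canon(terms_s.split("|"))
        table.set(itemset, Fraction(int(count_s), n_docs))
        (fis if cls == "frequent" else infis).add(itemset)
    return fis, infis, table
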