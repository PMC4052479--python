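"""Shared fixtures and independent brute-force oracles.

The oracles count transactions directly and enumerate the itemset
lattice exhaustively; they share no code with the level-wise miner or
the inclusion–exclusion measure algebra they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import settings

from fisinfis.corpus import TransactionDB

settings.register_profile("repro", derandomize=True, deadline=None, database=None)
settings.load_profile("repro")


def make_db(term_sets: list[set[str]]) -> TransactionDB:
    """TransactionDB from explicit term sets (keeps empty transactions)."""
    vocab = sorted(set().union(*term_sets)) if term_sets else []
    index = {t: i for i, t in enumerate(vocab)}
    return TransactionDB(
        transactions=[frozenset(index[t] for t in s) for s in term_sets],
        vocabulary=vocab,
        doc_ids=[f"d{i}" for i in range(len(term_sets))],
    )


def brute_count(itemset, transactions) -> int:
    items = frozenset(itemset)
    return sum(1 for t in transactions if items <= t)


def brute_literal_count(a_items, a_neg, b_items, b_neg, transactions) -> int:
    """Transactions satisfying both literals, counted directly.

    A negated literal is satisfied when the transaction does NOT
    contain the full base itemset.
    """
    a, b = frozenset(a_items), frozenset(b_items)
    n = 0
    for t in transactions:
        ok_a = (a <= t) != a_neg
        ok_b = (b <= t) != b_neg
        if ok_a and ok_b:
            n += 1
    return n


def exhaustive_fis(db: TransactionDB, min_supp: Fraction, max_k: int) -> set:
    """All itemsets of size <= max_k with supp >= min_supp, by full
    enumeration of the lattice."""
    n_items = len(db.vocabulary)
    out = set()
    for k in range(1, min(max_k, n_items) + 1):
        for combo in combinations(range(n_items), k):
            if Fraction(brute_count(combo, db.transactions), db.n_docs) >= min_supp:
                out.add(combo)
    return out


def exhaustive_negative_border(
    db: TransactionDB, min_supp: Fraction, max_k: int
) -> set:
    """Itemsets with 0 < supp < min_supp whose proper subsets are all
    frequent, up to size max_k (singletons qualify vacuously)."""
    fis = exhaustive_fis(db, min_supp, max_k)
    n_items = len(db.vocabulary)
    out = set()
    for k in range(1, min(max_k, n_items) + 1):
        for combo in combinations(range(n_items), k):
            supp = Fraction(brute_count(combo, db.transactions), db.n_docs)
            if not 0 < supp < min_supp:
                continue
            if all(
                sub in fis
                for r in range(1, k)
                for sub in combinations(combo, r)
            ):
                out.add(combo)
    return out


def random_db(rng: np.random.Generator, max_items: int = 8,
              max_trans: int = 25) -> TransactionDB:
    """A random small database; item inclusion probabilities vary per
    item so both frequent and rare items occur."""
    n_items = int(rng.integers(2, max_items + 1))
    n_trans = int(rng.integers(4, max_trans + 1))
    probs = rng.uniform(0.05, 0.9, size=n_items)
    incl = rng.random((n_trans, n_items)) < probs
    vocab = [f"t{i:02d}" for i in range(n_items)]
    return TransactionDB(
        transactions=[frozenset(np.flatnonzero(row)) for row in incl],
        vocabulary=vocab,
        doc_ids=[f"d{i}" for i in range(n_trans)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240518)


@pytest.fixture
def small_db() -> TransactionDB:
    """10 transactions over {x, y}: each in 6, jointly in 2."""
    sets = (
        [{"x", "y"}] * 2
        + [{"x"}] * 4
        + [{"y"}] * 4
    )
    return make_db(sets)
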