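"""IDF term weighting and top-N% vocabulary selection.

Raw text vocabularies are dominated by ubiquitous words whose supports
tell us nothing; inverse document frequency, ``idf(t) = log(D / df_t)``
with ``D`` the corpus size and ``df_t`` the number of documents
containing ``t``, up-weights terms concentrated in few documents.  The
item universe for mining is the top-N% of terms by IDF (N defaults to
60 elsewhere in the pipeline); transactions are re-projected onto the
retained vocabulary before any itemset counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .corpus import TransactionDB

__all__ = [
    "TermWeight",
    "document_frequencies",
    "idf_scores",
    "select_top_pct",
    "project_db",
    "write_term_report",
]


@dataclass(frozen=True)
class TermWeight:
    term: str
    df: int
    idf: float


def document_frequencies(db: TransactionDB) -> dict[str, int]:
    """Count, for every vocabulary term, the transactions containing it.

    Every vocabulary term gets an entry (possibly 0 for a term that
    appears in the vocabulary but no transaction, which cannot happen
    for a db built by ``to_transactions`` but can after projection).
    """
    if db.n_docs == 0:
        raise ValueError("empty transaction database")
    counts = [0] * len(db.vocabulary)
    for t in db.transactions:
        for i in t:
            counts[i] += 1
    return {term: counts[i] for i, term in enumerate(db.vocabulary)}


def idf_scores(
    dfs: dict[str, int], n_docs: int, log_base: float = 10.0
) -> list[TermWeight]:
    """IDF for every term, sorted descending by idf, ties lexicographic.

    ``idf = log_base(n_docs / df)``; a term in every document scores 0.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    weights = []
    for term, df in dfs.items():
        if df < 1:
            raise ValueError(f"term {term!r} has df={df} < 1")
        if df > n_docs:
            raise ValueError(
                f"corrupt counts: df({term!r})={df} exceeds n_docs={n_docs}"
            )
        idf = math.log(n_docs / df) / math.log(log_base)
        weights.append(TermWeight(term=term, df=df, idf=idf))
    weights.sort(key=lambda w: (-w.idf, w.term))
    return weights


def select_top_pct(
    weights: list[TermWeight], pct: float
) -> tuple[list[TermWeight], list[TermWeight]]:
    """Keep the first ceil(pct/100 * len) of the IDF-ranked terms.

    Returns (kept, discarded).  Ties at the cutoff boundary fall where
    the deterministic (idf desc, term asc) sort placed them; tied terms
    beyond the cutoff are discarded, not pulled in.
    """
    if not 0 < pct <= 100:
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    n_keep = math.ceil(pct / 100.0 * len(weights))
    return list(weights[:n_keep]), list(weights[n_keep:])


def project_db(db: TransactionDB, kept_terms: list[str]) -> TransactionDB:
    """Re-project transactions onto a retained vocabulary.

    Terms outside ``kept_terms`` are deleted from every transaction;
    transactions emptied by the projection are retained (they still
    count toward support denominators).
    """
    kept_sorted = sorted(set(kept_terms))
    new_index = {t: i for i, t in enumerate(kept_sorted)}
    old_to_new = {
        i: new_index[t]
        for i, t in enumerate(db.vocabulary)
        if t in new_index
    }
    transactions = [
        frozenset(old_to_new[i] for i in t if i in old_to_new)
        for t in db.transactions
    ]
    return TransactionDB(
        transactions=transactions,
        vocabulary=kept_sorted,
        doc_ids=list(db.doc_ids),
    )


def write_term_report(
    path: str | Path,
    kept: list[TermWeight],
    discarded: list[TermWeight],
    log_base: float = 10.0,
) -> None:
    """TSV report: term, df, idf, kept/discarded (idf to 4 decimals)."""
    lines = [f"# log_base={log_base:g}", "term\tdf\tidf\tstatus"]
    for status, group in (("kept", kept), ("discarded", discarded)):
        for w in group:
            lines.append(f"{w.term}\t{w.df}\t{w.idf:.4f}\t{status}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
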