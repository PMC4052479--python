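"""Corpus ingestion: raw text documents -> set-valued transactions.

A *transaction* is the set of distinct terms retained from one document;
support is counted over transactions, so within-document term repetition
carries no weight.  This mirrors the market-basket view of text in which
each document/blog is one basket of words.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "Document",
    "TransactionDB",
    "TokenizerConfig",
    "load_corpus",
    "load_stopwords",
    "tokenize",
    "to_transactions",
]

_TOKEN_RE = re.compile(r"[^0-9A-Za-z]+")


@dataclass(frozen=True)
class Document:
    """A raw document with an identifier unique within its corpus."""

    doc_id: str
    text: str


@dataclass
class TransactionDB:
    """A corpus as a transaction database.

    ``transactions`` holds one ``frozenset`` of integer term ids per
    document; ``vocabulary`` maps each id back to its term string
    (ids index the sorted vocabulary).  Empty transactions are legal:
    they still count toward the number of documents and therefore
    toward every support denominator.
    """

    transactions: list[frozenset[int]]
    vocabulary: list[str]
    doc_ids: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return len(self.transactions)

    def term_id(self, term: str) -> int:
        """Id of ``term`` in the vocabulary (raises KeyError if absent)."""
        try:
            return self._index()[term]
        except KeyError:
            raise KeyError(f"term not in vocabulary: {term!r}") from None

    def _index(self) -> dict[str, int]:
        idx = getattr(self, "_term_index", None)
        if idx is None or len(idx) != len(self.vocabulary):
            idx = {t: i for i, t in enumerate(self.vocabulary)}
            object.__setattr__(self, "_term_index", idx)
        return idx

    def terms_of(self, transaction: frozenset[int]) -> frozenset[str]:
        return frozenset(self.vocabulary[i] for i in transaction)


@dataclass(frozen=True)
class TokenizerConfig:
    """Text normalisation knobs.

    lowercase: fold case before stopword removal (default on; item
        matching is case-insensitive in spirit even when source text
        mixes cases).
    stopwords: removed after case folding.
    stemmer: optional callable applied last, token by token; ``None``
        disables stemming (the deterministic, dependency-free default).
    token_pattern: regex whose *complement* splits the text — tokens are
        the maximal runs not matching it.
    """

    lowercase: bool = True
    stopwords: frozenset[str] = frozenset()
    stemmer: Callable[[str], str] | None = None
    token_pattern: re.Pattern[str] = _TOKEN_RE


def load_corpus(source: str | Path) -> list[Document]:
    """Read documents from a directory of ``.txt`` files or a single file.

    A directory yields one document per ``*.txt`` file in lexicographic
    filename order; a plain file yields one document per non-blank line,
    in line order.  Raises ``ValueError("no documents")`` on an empty
    corpus and ``OSError`` naming the file on read failure.
    """
    source = Path(source)
    docs: list[Document] = []
    if source.is_dir():
        for path in sorted(source.glob("*.txt")):
            try:
                text = path.read_text(encoding="utf-8")
            except OSError as exc:
                raise OSError(f"cannot read corpus file {path}: {exc}") from exc
            if text.strip():
                docs.append(Document(doc_id=path.name, text=text))
    elif source.is_file():
        try:
            lines = source.read_text(encoding="utf-8").splitlines()
        except OSError as exc:
            raise OSError(f"cannot read corpus file {source}: {exc}") from exc
        for lineno, line in enumerate(lines, start=1):
            if line.strip():
                docs.append(Document(doc_id=f"line{lineno}", text=line))
    else:
        raise FileNotFoundError(f"corpus source does not exist: {source}")
    if not docs:
        raise ValueError("no documents")
    return docs


def load_stopwords(path: str | Path) -> frozenset[str]:
    """One stopword per line, UTF-8; blank lines and '#' comments ignored."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        word = line.strip()
        if word and not word.startswith("#"):
            words.add(word)
    return frozenset(words)


def tokenize(text: str, config: TokenizerConfig | None = None) -> list[str]:
    """Split ``text`` into terms: split on non-alphanumeric runs, fold
    case, drop stopwords, then stem.  Order is preserved and duplicates
    are kept (deduplication happens at transaction construction)."""
    config = config or TokenizerConfig()
    tokens = [t for t in config.token_pattern.split(text) if t]
    if config.lowercase:
        tokens = [t.lower() for t in tokens]
    if config.stopwords:
        tokens = [t for t in tokens if t not in config.stopwords]
    if config.stemmer is not None:
        tokens = [config.stemmer(t) for t in tokens]
    return tokens


def to_transactions(
    docs: Sequence[Document], config: TokenizerConfig | None = None
) -> TransactionDB:
    """Convert documents into a TransactionDB.

    Each document becomes the SET of its tokens; the vocabulary is the
    sorted union of all terms.  Documents whose token set is empty are
    kept as empty transactions.
    """
    if not docs:
        raise ValueError("no documents")
    seen = [frozenset(tokenize(d.text, config)) for d in docs]
    vocabulary = sorted(set().union(*seen)) if seen else []
    index = {t: i for i, t in enumerate(vocabulary)}
    transactions = [frozenset(index[t] for t in s) for s in seen]
    return TransactionDB(
        transactions=transactions,
        vocabulary=vocabulary,
        doc_ids=[d.doc_id for d in docs],
    )


def from_term_sets(term_sets: Iterable[Iterable[str]]) -> TransactionDB:
    """Build a TransactionDB directly from iterables of term strings.

    Convenience constructor for tests and synthetic data.
    """
    sets = [frozenset(s) for s in term_sets]
    if not sets:
        raise ValueError("no documents")
    vocabulary = sorted(set().union(*sets))
    index = {t: i for i, t in enumerate(vocabulary)}
    return TransactionDB(
        transactions=[frozenset(index[t] for t in s) for s in sets],
        vocabulary=vocabulary,
        doc_ids=[f"doc{i}" for i in range(len(sets))],
    )
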