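"""Synthetic transaction databases with planted associations.

Each planted pair (a, b) is drawn, per transaction, from the 2×2 joint
distribution fixed by its marginals and joint probability:

    P(a, b) = p_ab              P(a, ¬b) = p_a − p_ab
    P(¬a, b) = p_b − p_ab       P(¬a, ¬b) = 1 − p_a − p_b + p_ab

so the planted positive or negative dependence is exactly controlled
(lift of a=>b is p_ab / (p_a · p_b)).  Background items are sprinkled
independently to give the vocabulary realistic bulk.  Everything is
driven by a single integer seed through numpy's PCG64 generator, so a
fixture is reproducible bit-for-bit across runs and platforms.

``expected_measures`` evaluates the same support/confidence/lift
algebra on the *stated* probabilities (exactly, no sampling), giving
planted ground truth against which mined estimates can converge.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

from .corpus import TransactionDB, from_term_sets
from .measures import (
    Literal,
    SupportTable,
    confidence,
    lift,
    literal_pattern_support,
)

__all__ = [
    "PlantedPairSpec",
    "generate_planted",
    "expected_measures",
    "write_corpus_text",
]


@dataclass(frozen=True)
class PlantedPairSpec:
    """A pair of items with fixed marginal and joint probabilities.

    The joint must satisfy the Fréchet bounds
    max(0, p_a + p_b − 1) ≤ p_ab ≤ min(p_a, p_b); outside them no joint
    distribution with the stated marginals exists.
    """

    item_a: str
    item_b: str
    p_a: float
    p_b: float
    p_ab: float

    def __post_init__(self) -> None:
        if self.item_a == self.item_b:
            raise ValueError(f"planted pair items must differ: {self.item_a!r}")
        for name, p in (("p_a", self.p_a), ("p_b", self.p_b), ("p_ab", self.p_ab)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} out of [0, 1]: {p}")
        lo = max(0.0, self.p_a + self.p_b - 1.0)
        hi = min(self.p_a, self.p_b)
        if not lo <= self.p_ab <= hi:
            raise ValueError(
                f"joint probability p_ab={self.p_ab} violates Fréchet bounds "
                f"[{lo}, {hi}] for marginals p_a={self.p_a}, p_b={self.p_b} "
                f"({self.item_a!r}, {self.item_b!r})"
            )

    @property
    def cell_probs(self) -> tuple[float, float, float, float]:
        """(both, a only, b only, neither)."""
        return (
            self.p_ab,
            self.p_a - self.p_ab,
            self.p_b - self.p_ab,
            1.0 - self.p_a - self.p_b + self.p_ab,
        )


def generate_planted(
    specs: list[PlantedPairSpec],
    n: int,
    seed: int,
    background_items: int = 8,
    background_p: float = 0.7,
) -> TransactionDB:
    """Draw ``n`` transactions with every planted pair and background.

    Planted items must be distinct across specs.  Background items are
    named ``bg000 ...`` and included independently with probability
    ``background_p`` each; the default makes them *common* — they play
    the role of the ubiquitous filler vocabulary that IDF screening
    exists to rank below topical terms — and keeps empty transactions
    (blank lines in the text emission) vanishingly rare.
    """
    if n < 1:
        raise ValueError("no documents")
    planted_names: list[str] = []
    for spec in specs:
        planted_names.extend((spec.item_a, spec.item_b))
    if len(set(planted_names)) != len(planted_names):
        raise ValueError("planted items must be distinct across pair specs")
    bg_names = [f"bg{i:03d}" for i in range(background_items)]
    if set(bg_names) & set(planted_names):
        raise ValueError("background item names collide with planted items")

    rng = np.random.default_rng(seed)
    docs: list[list[str]] = [[] for _ in range(n)]
    for spec in specs:
        cells = rng.choice(4, size=n, p=np.asarray(spec.cell_probs))
        for t, cell in enumerate(cells):
            if cell == 0:
                docs[t] += [spec.item_a, spec.item_b]
            elif cell == 1:
                docs[t].append(spec.item_a)
            elif cell == 2:
                docs[t].append(spec.item_b)
    if background_items:
        draws = rng.random((n, background_items)) < background_p
        for t in range(n):
            docs[t] += [bg_names[i] for i in np.flatnonzero(draws[t])]
    return from_term_sets(docs)


def expected_measures(spec: PlantedPairSpec) -> dict[str, dict[str, Fraction]]:
    """Exact support/confidence/lift for all four literal-rule forms.

    Keys are 'a=>b', 'a=>~b', '~a=>b', '~a=>~b'; probabilities are read
    as exact decimals so every conservation identity holds exactly.
    A form whose antecedent or consequent has zero probability maps to
    an empty dict (measures undefined).
    """
    table = SupportTable(n_docs=0)
    table.set((spec.item_a,), Fraction(str(spec.p_a)))
    table.set((spec.item_b,), Fraction(str(spec.p_b)))
    table.set((spec.item_a, spec.item_b), Fraction(str(spec.p_ab)))
    out: dict[str, dict[str, Fraction]] = {}
    for neg_a in (False, True):
        for neg_b in (False, True):
            a = Literal((spec.item_a,), neg_a)
            b = Literal((spec.item_b,), neg_b)
            name = f"{'~' if neg_a else ''}a=>{'~' if neg_b else ''}b"
            conf = confidence(a, b, table)
            lft = lift(a, b, table)
            if conf is None or lft is None:
                out[name] = {}
            else:
                out[name] = {
                    "support": literal_pattern_support(a, b, table),
                    "confidence": conf,
                    "lift": lft,
                }
    return out


def write_corpus_text(db: TransactionDB, path: str | Path) -> None:
    """Emit one document per line, terms space-separated and sorted —
    the one-doc-per-line format the ingest module accepts, closing the
    loop for end-to-end pipeline tests."""
    lines = []
    for t in db.transactions:
        lines.append(" ".join(sorted(db.vocabulary[i] for i in t)))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
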