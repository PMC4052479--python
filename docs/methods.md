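# Methods

## Problem and model

Given a corpus of documents (e.g. patient-authored medical blogs), each
document is reduced to the **set** of its retained terms — a transaction in
the market-basket sense.  Over a database `D` of `n` transactions, for
itemsets `X, Y ⊆ I` with `X ∩ Y = ∅`:

* `supp(X)` — fraction of transactions containing every item of `X`;
* `conf(X ⇒ Y) = supp(X ∪ Y) / supp(X)`;
* `lift(X ⇒ Y) = supp(X ∪ Y) / (supp(X) · supp(Y))` — `> 1` positive
  dependence, `< 1` negative, `= 1` independence.

Rules range over **literals**: each side is `X` or `¬X`.  `¬X` is defined
as the *complement of the co-occurrence event* — "the transaction does not
contain the whole of X" — not "contains none of X's items".  Only the first
reading makes the inclusion–exclusion identities hold for `|X| > 1` (the
two coincide for singletons):

```
supp(¬X)      = 1 − supp(X)
supp(X ∪ ¬Y)  = supp(X) − supp(X ∪ Y)
supp(¬X ∪ Y)  = supp(Y) − supp(X ∪ Y)
supp(¬X ∪ ¬Y) = 1 − supp(X) − supp(Y) + supp(X ∪ Y)
```

All confidences and lifts for negated patterns are the plain definitions
applied to these literal-pattern supports.  Internally every support is an
exact rational (`fractions.Fraction` of a transaction count over `n`), so
threshold comparisons never hinge on float rounding; floats appear only in
reports, rounded to 4 decimals.

## Pipeline

1. **Ingest** — tokenize on maximal non-alphanumeric runs, fold case
   (default on), drop stopwords after folding, optionally stem (a built-in
   Porter stemmer; off by default for determinism and because stemmer
   choice is a corpus-preparation decision, not part of the model).  Each
   document becomes a term set; empty transactions are *retained* because
   they contribute to every support denominator.
2. **IDF screen** — `idf(t) = log(n / df_t)`; terms are ranked by IDF
   descending (ties broken lexicographically) and the top `N%` kept
   (`ceil(N/100 · |V|)` terms, default `N = 60`).  Transactions are then
   re-projected onto the kept vocabulary.  The log base is configurable
   (10 default, e selectable) and recorded in the term report; the choice
   only rescales scores and cannot change the ranking or the cutoff.
3. **FISinFIS mining** — a level-wise Apriori sweep that keeps both
   outcomes of the support test.  Level-k candidates are joined from
   frequent (k−1)-itemsets (shared (k−2)-prefix) and pruned unless every
   (k−1)-subset is frequent.  Counted candidates with `supp ≥ ms` enter
   FIS; those with `0 < supp < ms` enter inFIS.  inFIS is therefore the
   **negative border** of the lattice: every retained infrequent itemset
   has all proper subsets frequent — exactly the precondition the
   infrequent-rule stream needs.  Joining infrequent itemsets as well
   would be combinatorially hopeless on text and would produce rule
   candidates whose sides fail the frequency conditions anyway.
4. **Rule generation** — for every mined itemset of size ≥ 2 and every
   ordered bipartition `(A, B)` (all `2^k − 2` of them, so symmetric forms
   like `B ⇒ ¬A` need no separate listing), four streams:

   | class | parent | conditions |
   |---|---|---|
   | PAR-FIS | FIS | `supp(A∪B) ≥ ms`, `conf ≥ mc`, `lift > min_lift` |
   | NAR-FIS | FIS | literal-pattern supp ≥ ms, `conf ≥ mc`, `lift > min_lift`, forms `A⇒¬B, ¬A⇒B, ¬A⇒¬B` |
   | PAR-inFIS | inFIS | `supp(A) ≥ ms`, `supp(B) ≥ ms`, `conf ≥ mc`, `lift > min_lift` — union support **not** required |
   | NAR-inFIS | inFIS | as NAR-FIS plus `supp(A) ≥ ms`, `supp(B) ≥ ms` |

   Waiving the union-support condition for PAR-inFIS is deliberate: for a
   negative-border itemset `supp(A∪B) < ms` holds by construction, and the
   point of the stream is precisely that a rare co-occurrence can still be
   a near-implication (`conf(B⇒A) = 1` when B's occurrences are contained
   in A's).  The statistical grounding shifts to the sides' supports,
   which are ≥ ms because the border's proper subsets are frequent.  For a
   negative rule the *literal pattern's own* support must reach ms (e.g.
   `supp(A ∪ ¬B) ≥ ms`), which is what makes it well-supported evidence of
   absence rather than an artefact of rarity.

Rules are deduplicated on (antecedent itemset, negation, consequent
itemset, negation) and sorted by lift, confidence, support descending and
finally rule text, so all outputs are byte-reproducible.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `min_supp` (ms) | 0.2 | support threshold separating FIS from inFIS |
| `min_conf` (mc) | 0.6 | confidence threshold for rule validity (≥, inclusive) |
| `min_lift` | 1.0 | lift must **strictly** exceed this (no epsilon); independence never yields a rule |
| `max_k` | 4 | largest itemset mined; 4 covers the rule shapes of practical interest and bounds the lattice sweep on text |
| `top_idf_pct` | 60 | percentage of IDF-ranked terms kept as the item universe |
| `log_base` | 10 | IDF logarithm base (e selectable); ranking-invariant |

Confidence/support thresholds are inclusive (`≥`), the lift threshold is
strict (`>`): a rule exactly at independence carries no information.

## Numerical and degenerate-input choices

* Thresholds given as decimal floats are read as exact decimals
  (`Fraction(str(x))`), so `supp = 0.2` passes `ms = 0.2` exactly.
* A literal with zero pattern support in the antecedent (e.g. `¬A` when
  `supp(A) = 1`) makes confidence undefined; such rules are silently
  skipped — distinct from a missing support-table entry, which raises an
  error naming the itemset.
* Terms with zero support after IDF projection join neither FIS nor
  inFIS; rules about never-occurring terms are vacuous.  Itemsets whose
  counted support is zero are likewise dropped from inFIS at every level
  (the "infrequent itemsets of interest" must actually occur).
* The top-N% cutoff uses a ceiling; ties at the boundary fall where the
  deterministic (idf desc, term asc) order placed them — tied terms past
  the cutoff are discarded, not pulled in.
* One printed measure in the infrequent-itemset illustration that this
  package's worked examples derive from (a lift of 1.19 for marginals
  0.8/0.2 with joint 0.2) is arithmetically inconsistent with the lift
  definition, which gives 1.25; the implementation and its tests assert
  the definition, and only the confidences of that example are treated
  as reference values.

## Synthetic data: what it emulates and what it does not

`generate_planted` draws each transaction's planted pair from the 2×2
joint distribution fixed by `(p_a, p_b, p_ab)` (Fréchet bounds enforced),
plus independent background items.  Defaults: 8 background items at
inclusion probability 0.7 — background plays the role of the ubiquitous,
uninformative vocabulary that the IDF screen exists to rank *below*
topical terms, and it keeps empty transactions (blank lines, skipped on
re-ingest) vanishingly rare in text emissions.  `expected_measures`
evaluates the same measure algebra on the stated probabilities exactly,
giving planted ground truth for convergence tests (confidence within
0.05 at n = 2000).

The generator emulates controlled co-occurrence structure only.  It does
not model natural language: no word burstiness, no document-length
variation, no phrase structure, no correlated background terms.  A green
end-to-end test therefore establishes that the pipeline recovers planted
marginal/joint structure from set-valued transactions — not that any
particular real corpus yields particular rules.  Corpus-scale results on
the original blog collections are not reproducible (the corpora are not
public); the run report exposes the same statistics (vocabulary sizes
before/after screening, per-level itemset counts, per-class rule counts)
so the report *shape* carries over to any corpus.

## Known limitations

* Items are unigrams; multi-word medical phrases ("CT scan") are not
  reconstructed — no phrase-detection procedure is defined here.
* "Non-medical word" filtering is delegated entirely to the user-supplied
  stopword list; no built-in lexicon.
* Negation is set-absence within a document, with no linguistic negation
  handling ("no evidence of cancer" still contributes the term *cancer*).
* Term context/semantics are out of scope; rules are co-occurrence
  statements only.
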