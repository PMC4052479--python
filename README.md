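# fisinfis

Positive **and negative** association rule mining from text corpora, via
simultaneous frequent / infrequent itemset (FISinFIS) Apriori mining.

Classical association rule mining finds rules `A ⇒ B` among *frequently*
co-occurring terms.  In many domains — medical text above all — the
informative signal is often the other way around: a symptom that
*rules out* a disease, a treatment that rarely co-occurs with another.
This package mines, from a corpus of documents treated as term-set
transactions:

* **PAR-FIS** — positive rules `A ⇒ B` from frequent itemsets (classical
  Apriori output);
* **NAR-FIS** — negative rules `A ⇒ ¬B`, `¬A ⇒ B`, `¬A ⇒ ¬B` from frequent
  itemsets whose sub-patterns are negatively dependent;
* **PAR-inFIS** — positive rules from *infrequent* itemsets of interest
  (the negative border of the lattice): rare co-occurrences that are
  nonetheless near-implications;
* **NAR-inFIS** — negative rules from infrequent itemsets.

All rules are validated by the support–confidence–lift framework extended
to negated patterns, where `¬X` means "the transaction does not contain
all of X" and, e.g., `supp(X ∪ ¬Y) = supp(X) − supp(X ∪ Y)`:

```
supp(A ⇒ B) ≥ ms        conf(A ⇒ B) = supp(A∪B)/supp(A) ≥ mc
lift(A ⇒ B) = supp(A∪B)/(supp(A)·supp(B)) > 1
```

The vocabulary is screened by inverse document frequency
(`idf(t) = log(D/df_t)`, top-N% retained, N = 60 by default) before any
counting, so mining runs on the discriminative part of a text vocabulary.
See `docs/methods.md` for the full model, parameter table, and design
rationale.  Intended users: text/health-informatics researchers who want
negative-association structure out of document collections without
writing their own lattice code.

## Worked example

The canonical illustration: in a corpus where `supp(mole) = 0.4`,
`supp(cancer) = 0.6` but `supp(mole ∪ cancer) = 0.05`, the positive rule
is worthless — `conf(mole ⇒ cancer) = 0.05/0.4 = 0.125` — while the
*negative* rule is strong:

```
supp(mole ∪ ¬cancer) = 0.4 − 0.05          = 0.35   (≥ ms = 0.2)
conf(mole ⇒ ¬cancer) = 0.35 / 0.4          = 0.875  (≥ mc = 0.6)
lift(mole ⇒ ¬cancer) = 0.35 / (0.4 × 0.4)  = 2.1875 (> 1)
```

End to end, with a synthetic corpus that plants exactly that dependence
among common background vocabulary:

```
$ cat pairs.json
{"pairs": [{"item_a": "mole", "item_b": "cancer",
            "p_a": 0.4, "p_b": 0.6, "p_ab": 0.05}],
 "n": 2000, "background_items": 8, "background_p": 0.7}

$ fisinfis generate pairs.json corpus.txt --seed 7
wrote 2000 documents, 10 terms -> corpus.txt

$ fisinfis mine corpus.txt --out-dir out --min-supp 0.2 --min-conf 0.6
$ head -3 out/rules.csv
rule_class,antecedent,antecedent_negated,consequent,consequent_negated,support,confidence,lift
NAR-inFIS,mole,False,cancer,True,0.3585,0.8852,2.1803
NAR-inFIS,cancer,True,mole,False,0.3585,0.8830,2.1803
```

Reading the first row: the pair `{mole, cancer}` lands in the negative
border (each term frequent, the pair's support 0.05 ≪ ms), and the miner
emits `mole ⇒ ¬cancer` with empirical confidence 0.8852 and lift 2.1803 —
the sampled estimates of the planted 0.875 and 2.1875.  The run also
writes `out/terms.tsv` (df/IDF per term, kept or discarded),
`out/itemsets.tsv` (every counted itemset with its support and
frequent/infrequent class), `out/rules.json` (rules with raw counts) and
`out/report.json` (corpus statistics, per-level FIS/inFIS counts,
per-class rule counts).

Library use mirrors the CLI: `load_corpus`/`to_transactions` →
`idf_scores`/`select_top_pct`/`project_db` → `mine(db, MiningConfig(...))`
→ `mine_all_rules(fis, infis, table, config)`, or `run_pipeline(...)` for
the whole chain.

## Acceptance script

`scripts/acceptance.py` rebuilds the worked example above from scratch —
it constructs a 100-document corpus realising those supports exactly,
runs the FISinFIS miner on it, and evaluates the measure algebra on the
mined support table (conf of the rejected positive rule, the negative
pattern's support, and the confidence and lift of `mole ⇒ ¬cancer`):

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The seed shuffles document order only; support counting is order
invariant, so the emitted JSON is identical for every seed.
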