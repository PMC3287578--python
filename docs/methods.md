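# Methods

## Model overview

`lbdnet` treats a biological interaction network as a family of
subnetworks, one per combination of ≥2 distinct entity categories. A
subnetwork over categories `(C_1, …, C_n)` is a matrix whose cells are
entity tuples, one cluster representative per category. Cell status is
three-valued:

* **absent** — no evidence; the cell's level is 0 and never stored;
* **known** — the entities co-occur in ≥1 document; established at
  iteration 0 with a level aggregated from vector-space similarities;
* **new** — inferred by the transitive closure at iteration ≥1.

Status is stored explicitly rather than inferred from a nonzero level:
a known cell whose every entity is ubiquitous (idf 0) legitimately has
level 0 and must not be mistaken for an absent cell.

## Occurrence counting

Entity detection is dictionary-based exact phrase matching: no
stemming, no context handling. Matching is case-insensitive, requires
word boundaries (a match may not begin or end inside an alphanumeric
token) and, within one cluster, counts non-overlapping occurrences
scanned left to right with the longest synonym preferred — so a phrase
such as "diabetes mellitus type 2" is not additionally counted as
containing "type 2 diabetes". Synonym sets of distinct clusters must be
disjoint (validated case-insensitively at load), so every match maps to
one node. Whitespace inside a phrase matches any whitespace run.

## TFIDF and similarity

Weights use max-normalised term frequency times `log(N / n_x)` with no
smoothing; the log base is configurable (e, 2, 10; default natural log)
because only a common positive rescaling of all weights is affected and
cosine similarity cancels it. The document norm in the cosine runs over
all `t` network entities of the document, not only the query entities;
the query norm is `√|q|` since query weights are fixed at 1. Similarity
is computed only for conjunction-satisfying documents (every query
entity present), which guarantees a nonzero numerator except in the
degenerate all-idf-zero case; such zero-norm documents score 0 with a
warning rather than raising, keeping batch builds total. The cosine of
non-negative vectors lies in [0, 1]; a final clamp at 1.0 removes
floating-point overshoot of a few ulp.

Known levels aggregate the matching documents' similarities only — the
average is not diluted by the zero similarity of non-matching
documents. Three strategies are supported: arithmetic **average**,
**maximum**, and **sum**. Average and maximum keep levels in [0, 1];
the sum may exceed 1 and is stored unclamped (it is used for ranking,
where only order matters).

## Transitive closure

The rule — (x,y) ∧ (x,w) ∧ (z,y) ⇒ (z,w), with x,z in one category and
y,w in the complementary dimension(s) — is defined on a 2-D matrix; for
an n-dimensional subnetwork it is applied over every bipartition into a
pivot category (rows) and the composite of the remaining categories
(columns), and all bipartitions' candidates compete. Two bipartition
readings of the same three supporting cells are the same closure
instance; candidates are therefore de-duplicated on the supporting cell
*set*, and the candidate mean is summed in sorted-cell order so the two
readings produce bit-identical values.

Iterations are synchronous: iteration k uses only cells established at
iterations < k, so traversal order within an iteration cannot matter.
The level of a cell inferred at iteration k is `best_mean / k`,
penalising indirect chains; the supporting levels entering a mean are
the stored (already penalised) levels of the supporting cells. Ties
between equal candidate means break lexicographically on the sorted
supporting tuples; ranking ties break on subnetwork label then entity
tuple. Both rules exist purely for determinism. Iteration stops at a
fixpoint or a full matrix; a configurable cap (default 100) guards
against pathological cases and warns if reached.

Candidate targets of an iteration are generated from the established
structure (for each pivot, pairs of rows with a shared column) rather
than by scanning the full Cartesian product, so inference cost scales
with the evidence, not with the 10^5-cell matrices a realistic lexicon
implies.

## Temporal hold-out

Year slices are rebuilt from scratch on the date-filtered corpus
(inclusive of December 31), trading speed for correctness at the corpus
sizes involved; co-occurrence is monotone in the corpus, so known cells
are nested across years. A *confirmation* is an interaction new in the
slice of year y and known in the slice of year y+1, counted at
interaction granularity with the number of confirming documents
reported alongside. Its rank is its 1-based position in year y's
per-subnetwork new-interaction ranking. The confirmation set is
strategy-independent (statuses depend only on co-occurrence and closure
structure); only ranks differ across aggregation strategies, so the
strategy sweep reports three top-K columns over one confirmation set.
Consecutive-year confirmation is the default; any later slice can be
passed explicitly for multi-year confirmation.

## Synthetic corpora

The generator emulates what matters to the pipeline: synonym-clustered
vocabularies per category, documents mentioning a controlled entity
set 1–3 times each (exercising tf normalisation) through randomly
chosen synonyms (exercising clustering), filler text from a vocabulary
provably disjoint from all entity names, and issue dates uniform over a
year range except for confirmation documents planted in a later year.
Each document carries at most one planted tuple, so no unplanted
cross-category co-occurrence can arise and the expected known set is
exactly the planted tuples projected onto every subnetwork they cover.
The expected inferable set is the status-only closure fixpoint of those
knowns, computed by an independent generative fixpoint inside the
generator. Generation is a pure function of config + seed.

What the generator does **not** model: realistic document language,
ambiguous or polysemous entity names, entity mentions split across
clauses, or corpus-level frequency distributions. Passing tests
therefore demonstrate the correctness of counting, weighting, closure
and validation logic on controlled inputs — not entity-recognition
quality on real text, which is dictionary-limited by design.

Default condition sizes: the demo corpus uses two categories × 4
clusters, 15 documents over 2001–2003 with one planted closure; the
temporal demo uses 12 documents over 2002–2003 with the withheld pair
published in 2004; the published-scale config reproduces the published
lexicon shape (22/22/20/23 clusters, hence 11 subnetworks and 266,528
possible interactions) over a deliberately small corpus, since the
combinatorial quantities depend only on the lexicon.

## Numerical choices

* Floating-point comparisons in tests use absolute tolerance 1e-9;
  closure results are compared to the brute-force oracle exactly
  (bit-identical), which both sides achieve by evaluating the mean in
  the same canonical (sorted-support) order.
* `math.fsum` is used for weight norms, similarity numerators and
  aggregation sums.
* Degenerate inputs: empty documents are rejected at load; documents
  matching no entity contribute `max_freq = 0` and no weights; empty
  similarity lists cannot reach aggregation (a known cell requires ≥1
  matching document).

## Known limitations

* Entity recognition is exact dictionary matching; misspellings,
  abbreviations and context-dependent senses are out of scope.
* Co-occurrence is counted at document granularity; sentence- or
  paragraph-window proximity is not implemented.
* The sum strategy's unbounded levels make its absolute values
  incomparable across cells with very different support sizes; it is
  intended for ranking only.
* Slice rebuilding is quadratic in years × corpus; incremental updates
  would be needed for very large collections.
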