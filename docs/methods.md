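# Methods

This note records the models, conventions and defaults implemented in
`ontovocab`, and what the synthetic fixtures do and do not establish.

## Ontology loading

Ontologies are read from OBO 1.4 flat files (via `obonet`) and OWL RDF/XML
(via `rdflib`). Six annotation properties carry labelling metadata:
`rdfs:label` (the primary label), `skos:altLabel`,
`oboInOwl:hasExactSynonym` / `hasNarrowSynonym` / `hasBroadSynonym`, and
`IAO:0000118` (alternative term). Related-scope synonyms
(`hasRelatedSynonym`, OBO `RELATED`) are excluded throughout: their
synonymy is too loose for vocabulary expansion. OBO CURIEs are mapped onto
OBO PURLs so the same class carries the same IRI in every serialisation.

**First label.** Neither OWL nor OBO guarantees a stable label order across
parsers. When a class carries several primary-label values, the
lexicographically smallest is used; this is a determinism convention of the
package, not a property of the formats. A class with no labels is excluded
from lexical matching with a warning.

**Label normalisation.** "Exact" matching lowercases, collapses internal
whitespace and strips surrounding whitespace, because capitalisation
conventions differ across ontologies. A strict byte-equality mode
(`Repository(strict_labels=True)`) is retained for sensitivity checks.

**Equivalence.** The equivalence graph is the connected-component closure of
(i) same-IRI occurrences across documents and (ii) asserted named-class
equivalence axioms. Anonymous class expressions in equivalence position are
dropped (and counted): inferring equivalences from logical definitions would
need a DL reasoner, and the asserted subset is the sound conservative choice.
Obsolete classes (OBO `is_obsolete`, OWL `owl:deprecated`) are excluded from
the label index, the equivalence graph, and subclass queries.

## Expansion

Candidates from the two matching routes are pruned in a fixed order —
blocked ontology → identifier form → substring → pseudo-label — with the
first matching reason recorded per removed candidate. Conventions the
description leaves open, resolved here:

- Deduplication is by normalised string; the first-seen surface form is
  kept and provenance lists are merged.
- The input class's own labels and synonyms bypass pruning and always
  appear in the output: pruning is a filter on *candidates* from other
  classes.
- The substring check is case-insensitive on normalised strings.
- Pseudo-label filtering is exact-match against the configured list
  (default `europe pmc`, `kegg compound`); these strings are
  annotation-property names mis-indexed as labels, not genuine synonyms.
- Blocklists are configuration with defaults (GO-PLUS, MONDO, CCONT,
  phenX), overridable per run.
- `equivalency_only` mode skips lexical matching; it trades recall for the
  higher confidence of axiom-backed links and always produces a subset of
  the full-mode vocabulary.

`n_novel` counts unique accepted labels not among the input class's own
(normalised) labels and synonyms.

## Annotation

Text preprocessing replaces newlines and tabs with spaces
(length-preserving, so character offsets remain valid in the original),
splits sentences at `.`/`!`/`?` before whitespace, and tokenises words and
single punctuation marks with offsets. Lemmatisation is a small
ordered-suffix-rule stemmer with a short exception table, applied to both
the vocabulary and the text; both surface and lemma token sequences are
matched, so an imperfect lemma only costs recall when the two sides inflect
differently. The `-ches`/`-shes` plural is resolved by stripping the bare
`s` (headaches → headache) rather than `es`; the choice is applied
identically on both sides.

Matching is case-insensitive token-sequence lookup. Overlapping matches are
resolved longest-span-first, then leftmost; a winning span emits one
annotation per class when the vocabulary maps the same form to several
classes (ambiguity is preserved, never guessed away). Character spans are
half-open, 0-based, over the newline-normalised text.

Negation is a cue-window rule: an annotation is negated when a cue (default
`no, not, without, denies, denied, negative for, absence of, free of`) ends
at most 6 tokens before the match within the same sentence, with no scope
breaker (`;`, `but`, `however`) in between. Cue list, window and breakers
are configuration. This is a deliberately simple re-implementation of
cue-scope negation; it does not attempt uncertainty or hedging detection.

## Similarity

Information content is computed from the annotation corpus itself:
with propagation (default), every (entity, class) annotation counts toward
the class and all of its ancestors, `p(c) = count(c) / total` over all
(entity, class) pairs, and `IC(c) = −ln p(c)`. Classes never reached have
undefined IC and are absent from the table; annotations to classes missing
from the subclass graph are kept as root-attached leaves with a warning. A
no-propagation mode exists for sensitivity analysis, but the Resnik/MICA
framework needs ancestor probabilities defined, so propagation is the
default.

Resnik similarity is the maximal IC over common ancestors (a class is its
own ancestor, so `resnik(c, c) = IC(c)` and subsumption pairs score the
subsumer's IC); pairs whose only common ancestors have undefined IC score
0. Group similarity is the best-match average; empty sets score 0 against
everything, including themselves. Natural log is used throughout — the
rankings the evaluation consumes are invariant to the log base. The
similarity matrix orders entities by sorted id and is exactly symmetric by
construction.

On multi-parent DAGs, self-similarity is not guaranteed to dominate
cross-similarity in general; the identity-dominance property is only
asserted (and tested) on tree ontologies.

## Ranking evaluation

Neighbours are ranked by similarity descending with ties broken by entity
id ascending (determinism). Reciprocal rank is 1/rank of the first
neighbour sharing the query's primary code, 0 when none does. Average
precision at k = 10 is normalised by `min(k, R)` where R is the number of
relevant cohort members, so a query with fewer than k relevant members can
still reach 1; queries with R = 0 are excluded from MAP but contribute
RR = 0 to MRR. Both conventions are recorded in the evaluation report.

The two-scheme comparison pools, over all queries, the ranks at which
matching-diagnosis pairs appear, and applies a two-sided Wilcoxon rank-sum
test (exact enumeration for tie-free samples of at most 20 per group,
tie-corrected normal approximation otherwise, via
`scipy.stats.mannwhitneyu`). The reported statistic is the rank-sum of the
first sample, `W = U₁ + n₁(n₁+1)/2`.

Validation precision from manual count tables is `tp / (tp + fp)`; the
worst-case variant also counts non-English and uncertain judgements as
false positives.

## Synthetic fixtures

The generator emulates the structure of the real multi-ontology ecosystem,
not its content:

- **Repository** (defaults: 60 concepts, 4 ontologies, seed-deterministic
  down to bytes). The base ontology holds all concepts in a random tree
  (extra parents with probability 0.1 to exercise MICA search on DAGs,
  maximum depth 5). Carrier ontologies re-describe each concept with
  probability 0.9 via an identical first label and with probability 0.4 via
  an equivalence link (half shared IRI, half asserted axiom), each adding
  1–3 fresh synonyms. Distractor rates (identifier-form labels, substring
  labels, blocklisted-ontology presence) and the homonym rate default to 0;
  they are switched on in the tests that exercise pruning and the homonym
  failure mode specifically. All labels are drawn from a pronounceable
  synthetic word grammar with repository-wide uniqueness, which is what
  makes exact expected outcomes computable: per concept the ground truth
  lists exactly the novel synonyms the algorithm must accept.
- **Corpus** (defaults: 200 entities, 12 diagnosis codes with uneven
  prevalence, 4–8 mentions per entity, hidden-synonym fraction 0.5, negated
  fraction 0.15, noise-token rate 0.1, background-mention rate 0.25).
  Concepts are partitioned into per-code pools plus a shared background
  pool; each mention renders as one sentence with optional synthetic filler
  words and, when negated, a cue prefix. Half of the mentions use
  expansion-only synonyms, invisible to the unexpanded vocabulary — the
  mechanism by which expansion improves downstream ranking. Ground-truth
  spans are validated against the emitted text at generation time. When the
  hidden fraction is positive and not every mention is negated, at least
  one non-negated hidden mention is guaranteed so the expanded and
  unexpanded runs are never trivially identical.

What passing on these fixtures shows: the algorithmic contracts hold —
planted synonyms are recovered exactly, pruning is sound, equivalency-only
output is a subset, expansion strictly increases annotations and improves
MAP/MRR across seeds. What it does not show: performance on real clinical
language (abbreviations, misspellings, word-order variation), real ontology
quality problems (multilingual labels, near-synonymy, modelling
disagreements), or real ICD coding behaviour. The headline numbers of the
original experiments depend on a specific ontology-repository snapshot and
a credentialed clinical dataset and are out of scope here; the synthetic
replication establishes direction, not magnitude.

## Problem sizes

The test suite and the acceptance script run the full pipeline at reduced
scale, chosen as the package's own defaults: recovery checks use 15-concept
/ 3-ontology repositories over 20 seeds; the ranking replication uses the
default 60-concept repository with 200-entity corpora over 20 seeds
(roughly one second per seed). Oracle checks (Resnik, BMA, MRR/MAP,
rank-sum) enumerate exhaustively at 20–30 nodes/entities, where brute force
is exact and fast.
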