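# ontovocab

Inter-ontology synonym expansion and ontology-based characterisation of
clinical-style text.

Biomedical ontologies describe the same real-world entities — diseases,
phenotypes, findings — under different concepts in different ontologies, each
carrying its own labels and synonyms. `ontovocab` links those concepts and
pools their labelling metadata to build *expanded vocabularies* for text
mining, then evaluates the effect downstream: dictionary annotation of notes
with negation exclusion, Resnik/best-match-average semantic similarity between
entities (e.g. patient visits), and ranking evaluation against shared primary
diagnosis codes.

## The algorithm

For each input class with first label *ℓ* and IRI *i*:

1. **Lexical matching** — every class in any loaded ontology with a label or
   synonym exactly matching *ℓ* (case/whitespace-normalised) contributes all
   of its labels and synonyms as candidates. Only the first label of the input
   class is matched on; secondary labels match too many unrelated classes.
2. **Equivalency querying** — every class in the equivalence component of
   *(ontology, i)* contributes all of its labels and synonyms. The component
   is the transitive closure of shared-IRI identity across ontologies and
   asserted named-class equivalence axioms.
3. **Pruning** — candidates are discarded when they (a) come from a
   blocklisted ontology (default GO-PLUS, MONDO, CCONT, phenX), (b) contain
   `:` or `_` (identifier-form labels), (c) contain *ℓ* as a substring (the
   shorter string already matches, so the longer adds nothing to concept
   recognition), or (d) equal a mis-indexed pseudo-label such as
   `europe pmc`.

The accepted candidates, made unique, join the class's own labels to form its
expanded vocabulary.

Downstream, entity annotation sets *A*, *B* are compared with the
best-match average of Resnik pairwise similarities,

    sim(a, b)  = IC(MICA(a, b)),       IC(c) = −ln p(c),
    BMA(A, B)  = ½ [ 1/|A| Σ_a max_b sim(a,b) + 1/|B| Σ_b max_a sim(a,b) ]

where p(c) is the annotation probability of class *c* (propagated to
ancestors) in the corpus itself, and MICA is the most informative common
ancestor. Rankings induced by the similarity matrix are scored by mean
reciprocal rank (MRR) and mean average precision over the 10 most similar
entities (MAP@10), with relevance defined as sharing the query's primary
diagnosis code; two vocabularies are compared with a two-sided Wilcoxon
rank-sum test on the ranks of matching-diagnosis pairs.

Because the ontology snapshots and the clinical corpus behind the original
experiments are not redistributable, the package ships a synthetic-fixture
generator (`ontovocab.simulate`) that emits multi-ontology OBO repositories
and note corpora with complete ground truth, so every stage is testable
end-to-end offline.

## Worked example

```python
from ontovocab import expand_term
from ontovocab.simulate import hypertension_example

repo, record = hypertension_example()
vocab = expand_term(record, repo)
print(f"input class:      {vocab.input_first_label} ({vocab.input_iri})")
print(f"candidates:       {vocab.n_lexical} lexical + {vocab.n_equivalency} equivalency")
print(f"pruned:           {vocab.n_pruned}")
print(f"unique accepted:  {vocab.n_unique_accepted}")
print(f"novel synonyms:   {vocab.n_novel}")
print("sample:", ", ".join(vocab.novel_surface_forms()[:4]))
```

prints

```
input class:      hypertension (http://purl.obolibrary.org/obo/DOID_10763)
candidates:       66 lexical + 14 equivalency
pruned:           10
unique accepted:  28
novel synonyms:   25
sample: essential hyperpiesia, hyperpiesia, hyperpiesis, primary hyperpiesia
```

The input class asserts 3 labels and synonyms of its own; the matching steps
find 70 candidate synonyms beyond the input label itself (56 lexical, 14 via
equivalency — the 66 above includes the 10 carrier copies of "hypertension"
that pruning removes again). Deduplication leaves 28 unique accepted labels,
25 of which are new to the input class.

The same flow works from the shell on any OWL (RDF/XML) or OBO files:

```sh
ontovocab expand --ontology DOID:obo:doid.obo --ontology HP:obo:hp.obo \
    --root http://purl.obolibrary.org/obo/DOID_4 --out vocab.tsv
ontovocab annotate --lexicon vocab.tsv --corpus notes.tsv --out annotations.tsv
ontovocab similarity --ontology DOID:obo:doid.obo --annotations annotations.tsv \
    --out matrix.tsv
ontovocab evaluate --matrix matrix.tsv --diagnoses diagnoses.tsv --out report.json
```

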