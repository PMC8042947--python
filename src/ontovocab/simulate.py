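"""Seed-deterministic synthetic ontology repositories and note corpora.

The generator emulates the multi-ontology ecosystem the expansion
algorithm was designed for: several small ontologies describe the same
concepts, sharing them either verbatim (identical first labels), by IRI
reuse, or through asserted equivalence axioms, each contributing its own
extra synonyms.  Optional distractors plant the failure modes the
pruning stage exists for (identifier-form labels, substring labels,
blocklisted source ontologies, mis-indexed pseudo-labels) plus homonyms,
the algorithm's irreducible false-positive source.

Concept labels come from a pronounceable synthetic word grammar, never
real clinical terms, so nothing depends on English-specific lemmatiser
behaviour; every generated word is unique within a repository, which
makes the expected outcome of every pipeline stage computable at
generation time and recorded as ground truth.

The corpus generator emulates the patient-visit experimental design:
each entity (visit) carries one primary diagnosis code, its notes
mention concepts associated with that code plus background concepts,
a configurable fraction of mentions use only expansion-derived synonyms
(invisible to the unexpanded vocabulary), and a fraction are negated.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .ontology import (
    OntologyDocument,
    Repository,
    TermRecord,
    curie_to_iri,
)

__all__ = [
    "RepositoryBlueprint",
    "CorpusBlueprint",
    "ConceptTruth",
    "RepositoryTruth",
    "MentionTruth",
    "CorpusTruth",
    "GenerationError",
    "generate_repository",
    "generate_corpus",
    "hypertension_example",
]


class GenerationError(ValueError):
    """The blueprint cannot be realised."""


_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"


class WordPool:
    """Unique pronounceable synthetic words."""

    def __init__(self, rng: random.Random, reserved: set[str] | None = None):
        self._rng = rng
        self._used: set[str] = set(reserved or ())

    def word(self, syllables: int = 2) -> str:
        for _ in range(10000):
            w = "".join(
                self._rng.choice(_CONSONANTS) + self._rng.choice(_VOWELS)
                + (self._rng.choice(_CONSONANTS) if self._rng.random() < 0.3 else "")
                for _ in range(syllables)
            )
            if w not in self._used:
                self._used.add(w)
                return w
        raise GenerationError("word pool exhausted")

    def phrase(self, n_words: int = 2) -> str:
        return " ".join(self.word() for _ in range(n_words))

    @property
    def used(self) -> set[str]:
        return set(self._used)


@dataclass(frozen=True)
class RepositoryBlueprint:
    """Conditions for a synthetic multi-ontology repository."""

    n_concepts: int = 60
    n_ontologies: int = 4  # one base + (n-1) carrier ontologies
    synonyms_per_concept_per_ontology: tuple[int, int] = (1, 3)
    shared_first_label_rate: float = 0.9
    equivalence_axiom_rate: float = 0.4
    homonym_rate: float = 0.0
    identifier_label_rate: float = 0.0
    substring_label_rate: float = 0.0
    blocked_ontology_rate: float = 0.0
    dag_rate: float = 0.1
    max_depth: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.shared_first_label_rate,
            self.equivalence_axiom_rate,
            self.homonym_rate,
            self.identifier_label_rate,
            self.substring_label_rate,
            self.blocked_ontology_rate,
            self.dag_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise GenerationError("all blueprint rates must lie in [0, 1]")
        if self.n_concepts < 1 or self.n_ontologies < 1:
            raise GenerationError("need at least one concept and one ontology")
        if self.homonym_rate > 0 and self.n_concepts < 2:
            raise GenerationError("homonyms need at least two concepts")


@dataclass
class ConceptTruth:
    """Per-concept expected expansion outcome."""

    curie: str
    iri: str
    first_label: str
    original_labels: list[str]
    expected_novel: list[str]  # accepted novel synonyms the algorithm must find
    homonym_false_positives: list[str]  # planted via homonym classes
    distractors: list[str]  # planted strings the pruning stage must remove


@dataclass
class RepositoryTruth:
    blueprint: RepositoryBlueprint
    base_ontology_id: str
    root_curie: str
    concepts: dict[str, ConceptTruth]
    files: list[tuple[str, str, str]]  # (path, format, ontology_id)
    subclass_edges: list[tuple[str, str]]  # (child iri, parent iri), base ontology
    all_words: set[str] = field(default_factory=set)

    def load_repository(self) -> Repository:
        return Repository.load(self.files)

    def concept_iris(self) -> list[str]:
        return [c.iri for c in self.concepts.values()]


@dataclass
class _OboTerm:
    curie: str
    name: str
    synonyms: list[tuple[str, str]] = field(default_factory=list)  # (text, OBO scope)
    is_a: list[str] = field(default_factory=list)
    equivalent_to: list[str] = field(default_factory=list)
    obsolete: bool = False


def _write_obo(path: Path, ontology_id: str, terms: list[_OboTerm]) -> None:
    lines = ["format-version: 1.2", f"ontology: {ontology_id.lower()}", ""]
    for term in sorted(terms, key=lambda t: t.curie):
        lines.append("[Term]")
        lines.append(f"id: {term.curie}")
        lines.append(f"name: {term.name}")
        for text, scope in term.synonyms:
            lines.append(f'synonym: "{text}" {scope} []')
        for parent in term.is_a:
            lines.append(f"is_a: {parent}")
        for eq in term.equivalent_to:
            lines.append(f"equivalent_to: {eq}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    path.write_text("\n".join(lines))


def generate_repository(
    blueprint: RepositoryBlueprint, out_dir: str | Path
) -> RepositoryTruth:
    """Emit OBO files for a synthetic repository plus full ground truth.

    The base ontology ("BASE") holds every concept in a random tree
    (optional extra parents per ``dag_rate``); carrier ontologies
    re-describe concepts via shared first labels, shared IRIs, or
    equivalence axioms, each adding fresh synonyms.  Ground truth lists,
    per concept, exactly the novel synonyms the expansion algorithm is
    expected to accept, separately from planted distractors and homonym
    false positives.
    """
    bp = blueprint
    rng = random.Random(bp.seed)
    pool = WordPool(rng)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n = bp.n_concepts
    curies = [f"BASE:{i:07d}" for i in range(1, n + 1)]
    depth = {0: 0}
    parents: dict[int, list[int]] = {0: []}
    for i in range(1, n):
        eligible = [j for j in range(i) if depth[j] < bp.max_depth]
        p = rng.choice(eligible)
        parents[i] = [p]
        depth[i] = depth[p] + 1
        if rng.random() < bp.dag_rate:
            extra = [j for j in range(i) if j != p and depth[j] < bp.max_depth]
            if extra:
                parents[i].append(rng.choice(extra))

    concepts: dict[str, ConceptTruth] = {}
    base_terms: list[_OboTerm] = []
    carrier_ids = [f"EXT{k}" for k in range(1, bp.n_ontologies)]
    carrier_terms: dict[str, list[_OboTerm]] = {c: [] for c in carrier_ids}
    blocked_terms: list[_OboTerm] = []
    counters = {c: 0 for c in carrier_ids + ["MONDO"]}

    def fresh_curie(ont: str) -> str:
        counters[ont] += 1
        return f"{ont}:{counters[ont]:07d}"

    for i, curie in enumerate(curies):
        label = pool.phrase(2)
        own_syns = [pool.phrase(2) for _ in range(rng.randint(1, 2))]
        base_terms.append(
            _OboTerm(
                curie=curie,
                name=label,
                synonyms=[(s, "EXACT") for s in own_syns],
                is_a=[curies[p] for p in parents.get(i, [])],
            )
        )
        truth = ConceptTruth(
            curie=curie,
            iri=curie_to_iri(curie),
            first_label=label,
            original_labels=[label] + own_syns,
            expected_novel=[],
            homonym_false_positives=[],
            distractors=[],
        )

        lo, hi = bp.synonyms_per_concept_per_ontology
        for carrier in carrier_ids:
            planted_terms: list[_OboTerm] = []
            if rng.random() < bp.shared_first_label_rate:
                syns = [pool.phrase(2) for _ in range(rng.randint(lo, hi))]
                planted_terms.append(
                    _OboTerm(curie=fresh_curie(carrier), name=label,
                             synonyms=[(s, "EXACT") for s in syns])
                )
                truth.expected_novel.extend(syns)
            if rng.random() < bp.equivalence_axiom_rate:
                alt_label = pool.phrase(2)
                syns = [pool.phrase(2) for _ in range(rng.randint(lo, hi))]
                if rng.random() < 0.5:
                    # same IRI reused in the carrier ontology
                    term = _OboTerm(curie=curie, name=alt_label,
                                    synonyms=[(s, "EXACT") for s in syns])
                else:
                    term = _OboTerm(curie=fresh_curie(carrier), name=alt_label,
                                    synonyms=[(s, "EXACT") for s in syns],
                                    equivalent_to=[curie])
                planted_terms.append(term)
                truth.expected_novel.extend([alt_label] + syns)
            # distractors ride on the carrier classes that already exist
            for term in planted_terms:
                if rng.random() < bp.identifier_label_rate:
                    bad = rng.choice(
                        [f"{carrier}:{rng.randint(1, 10**6)}", f"{pool.word()}_{pool.word()}"]
                    )
                    term.synonyms.append((bad, "EXACT"))
                    truth.distractors.append(bad)
                if rng.random() < bp.identifier_label_rate:
                    pseudo = rng.choice(["europe pmc", "kegg compound"])
                    term.synonyms.append((pseudo, "EXACT"))
                    truth.distractors.append(pseudo)
                if rng.random() < bp.substring_label_rate:
                    bad = f"{label} {pool.word()}"
                    term.synonyms.append((bad, "EXACT"))
                    truth.distractors.append(bad)
            carrier_terms[carrier].extend(planted_terms)

        if rng.random() < bp.blocked_ontology_rate:
            syns = [pool.phrase(2) for _ in range(rng.randint(1, 2))]
            blocked_terms.append(
                _OboTerm(curie=fresh_curie("MONDO"), name=label,
                         synonyms=[(s, "EXACT") for s in syns])
            )
            truth.distractors.extend(syns)

        if rng.random() < bp.homonym_rate:
            carrier = rng.choice(carrier_ids) if carrier_ids else None
            if carrier is not None:
                syns = [pool.phrase(2) for _ in range(rng.randint(1, 2))]
                carrier_terms[carrier].append(
                    _OboTerm(curie=fresh_curie(carrier), name=label,
                             synonyms=[(s, "EXACT") for s in syns])
                )
                truth.homonym_false_positives.extend(syns)

        truth.expected_novel.sort()
        concepts[curie] = truth

    files: list[tuple[str, str, str]] = []
    base_path = out / "base.obo"
    _write_obo(base_path, "BASE", base_terms)
    files.append((str(base_path), "obo", "BASE"))
    for carrier in carrier_ids:
        p = out / f"{carrier.lower()}.obo"
        _write_obo(p, carrier, carrier_terms[carrier])
        files.append((str(p), "obo", carrier))
    if blocked_terms:
        p = out / "mondo.obo"
        _write_obo(p, "MONDO", blocked_terms)
        files.append((str(p), "obo", "MONDO"))

    edges = [
        (curie_to_iri(curies[i]), curie_to_iri(curies[p]))
        for i in range(1, n)
        for p in parents[i]
    ]
    truth_obj = RepositoryTruth(
        blueprint=bp,
        base_ontology_id="BASE",
        root_curie=curies[0],
        concepts=concepts,
        files=files,
        subclass_edges=edges,
        all_words=pool.used,
    )
    _dump_repository_truth(truth_obj, out / "repository_truth.json")
    return truth_obj


def _dump_repository_truth(truth: RepositoryTruth, path: Path) -> None:
    payload = {
        "blueprint": asdict(truth.blueprint),
        "base_ontology_id": truth.base_ontology_id,
        "root_curie": truth.root_curie,
        "files": truth.files,
        "concepts": {c: asdict(t) for c, t in sorted(truth.concepts.items())},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


_DEFAULT_CODES: tuple[tuple[str, float], ...] = tuple(
    (f"ICD:{i:03d}", w)
    for i, w in enumerate(
        [0.16, 0.13, 0.11, 0.10, 0.09, 0.08, 0.07, 0.07, 0.06, 0.05, 0.04, 0.04], 1
    )
)


@dataclass(frozen=True)
class CorpusBlueprint:
    """Conditions for a synthetic note corpus over a generated repository."""

    n_entities: int = 200
    codes: tuple[tuple[str, float], ...] = _DEFAULT_CODES
    mentions_per_entity: tuple[int, int] = (4, 8)
    hidden_synonym_fraction: float = 0.5
    negated_fraction: float = 0.15
    noise_token_rate: float = 0.1
    background_mention_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.codes:
            raise GenerationError("code list must be non-empty")
        for frac in (
            self.hidden_synonym_fraction,
            self.negated_fraction,
            self.noise_token_rate,
            self.background_mention_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise GenerationError("all corpus fractions must lie in [0, 1]")


@dataclass
class MentionTruth:
    entity_id: str
    doc_id: str
    start: int
    end: int
    surface: str
    curie: str
    iri: str
    hidden: bool
    negated: bool


@dataclass
class CorpusTruth:
    blueprint: CorpusBlueprint
    diagnoses: dict[str, str]  # entity → primary code
    code_concepts: dict[str, list[str]]  # code → concept curies
    background_concepts: list[str]
    mentions: list[MentionTruth]
    documents: list[tuple[str, str, str]]  # (entity_id, doc_id, text)

    def expected_entity_sets(self, expanded: bool) -> dict[str, set[str]]:
        """Non-negated annotation sets each vocabulary should recover."""
        out: dict[str, set[str]] = {e: set() for e in self.diagnoses}
        for m in self.mentions:
            if m.negated:
                continue
            if m.hidden and not expanded:
                continue
            out[m.entity_id].add(m.iri)
        return out


_NEGATION_TEMPLATES = ("no", "denies", "without")


def generate_corpus(
    blueprint: CorpusBlueprint,
    repository_truth: RepositoryTruth,
    out_dir: str | Path | None = None,
) -> CorpusTruth:
    """Generate a note corpus with known mentions and diagnoses.

    Concepts (minus the base root) are partitioned into per-code pools
    and a shared background pool; each entity's mentions are drawn from
    its own code's pool or the background, rendered one sentence per
    mention with synthetic filler words.  When ``hidden_synonym_fraction``
    is positive and any concept has expansion-only synonyms, at least one
    hidden mention is guaranteed so vocabulary expansion is observable.
    """
    bp = blueprint
    rng = random.Random(bp.seed + 1)
    pool = WordPool(rng, reserved=set(repository_truth.all_words))

    concepts = [
        t for c, t in sorted(repository_truth.concepts.items())
        if c != repository_truth.root_curie
    ]
    codes = [c for c, _ in bp.codes]
    weights = [w for _, w in bp.codes]
    n_background = max(2, len(concepts) // 6)
    per_code = (len(concepts) - n_background) // len(codes)
    if per_code < 2:
        raise GenerationError(
            f"{len(concepts)} concepts cannot support {len(codes)} codes "
            "(need at least 2 concepts per code after the background pool)"
        )
    shuffled = concepts[:]
    rng.shuffle(shuffled)
    code_concepts = {
        code: sorted(t.curie for t in shuffled[i * per_code : (i + 1) * per_code])
        for i, code in enumerate(codes)
    }
    background = sorted(t.curie for t in shuffled[len(codes) * per_code :])
    by_curie = repository_truth.concepts

    # phase 1: plan mentions
    plans: list[tuple[str, str, list[tuple[ConceptTruth, str, bool, bool]]]] = []
    diagnoses: dict[str, str] = {}
    any_hidden = False
    expandable = any(t.expected_novel for t in concepts)
    for i in range(bp.n_entities):
        entity = f"E{i + 1:05d}"
        code = rng.choices(codes, weights=weights)[0]
        diagnoses[entity] = code
        n_mentions = rng.randint(*bp.mentions_per_entity)
        mentions: list[tuple[ConceptTruth, str, bool, bool]] = []
        for _ in range(n_mentions):
            pool_curies = (
                background
                if background and rng.random() < bp.background_mention_rate
                else code_concepts[code]
            )
            concept = by_curie[rng.choice(pool_curies)]
            hidden = (
                rng.random() < bp.hidden_synonym_fraction
                and bool(concept.expected_novel)
            )
            surface = (
                rng.choice(concept.expected_novel)
                if hidden
                else rng.choice(concept.original_labels)
            )
            negated = rng.random() < bp.negated_fraction
            any_hidden = any_hidden or (hidden and not negated)
            mentions.append((concept, surface, hidden, negated))
        n_docs = 1 if n_mentions <= 4 or rng.random() < 0.5 else 2
        split = len(mentions) if n_docs == 1 else rng.randint(1, len(mentions) - 1)
        plans.append((entity, code, mentions[:split]))
        if n_docs == 2:
            plans.append((entity, code, mentions[split:]))

    if (
        bp.hidden_synonym_fraction > 0
        and bp.negated_fraction < 1.0
        and expandable
        and not any_hidden
    ):
        # guarantee the expansion has something to find
        entity, code, mentions = plans[0]
        concept = next(t for t in concepts if t.expected_novel)
        mentions[0] = (concept, concept.expected_novel[0], True, False)

    # phase 2: render documents, tracking spans
    mentions_truth: list[MentionTruth] = []
    documents: list[tuple[str, str, str]] = []
    doc_counter: dict[str, int] = {}
    for entity, code, mentions in plans:
        doc_counter[entity] = doc_counter.get(entity, 0) + 1
        doc_id = f"{entity}-N{doc_counter[entity]}"
        parts: list[str] = []
        length = 0
        for concept, surface, hidden, negated in mentions:
            tokens: list[str] = []
            if negated:
                tokens.append(rng.choice(_NEGATION_TEMPLATES))
            while rng.random() < bp.noise_token_rate and len(tokens) < 4:
                tokens.append(pool.word())
            prefix = " ".join(tokens)
            sep = "" if not parts else ("\n" if rng.random() < 0.2 else " ")
            head = sep + (prefix + " " if prefix else "")
            start = length + len(head)
            tail = ""
            while rng.random() < bp.noise_token_rate and len(tail.split()) < 3:
                tail += " " + pool.word()
            sentence = head + surface + tail + "."
            parts.append(sentence)
            length += len(sentence)
            mentions_truth.append(
                MentionTruth(
                    entity_id=entity,
                    doc_id=doc_id,
                    start=start,
                    end=start + len(surface),
                    surface=surface,
                    curie=concept.curie,
                    iri=concept.iri,
                    hidden=hidden,
                    negated=negated,
                )
            )
        documents.append((entity, doc_id, "".join(parts)))

    truth = CorpusTruth(
        blueprint=bp,
        diagnoses=diagnoses,
        code_concepts=code_concepts,
        background_concepts=background,
        mentions=mentions_truth,
        documents=documents,
    )
    _validate_corpus_truth(truth)
    if out_dir is not None:
        _write_corpus(truth, Path(out_dir))
    return truth


def _validate_corpus_truth(truth: CorpusTruth) -> None:
    """Cross-check that recorded spans slice to the mention surfaces."""
    texts = {(e, d): t for e, d, t in truth.documents}
    for m in truth.mentions:
        text = texts[(m.entity_id, m.doc_id)]
        if text[m.start : m.end] != m.surface:
            raise AssertionError(
                f"ground-truth span mismatch in {m.doc_id}: "
                f"{text[m.start:m.end]!r} != {m.surface!r}"
            )


def _write_corpus(truth: CorpusTruth, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "corpus.tsv", "w") as fh:
        fh.write("entity_id\tdoc_id\ttext\n")
        for entity, doc, text in truth.documents:
            fh.write(f"{entity}\t{doc}\t" + text.replace("\n", " ") + "\n")
    with open(out / "diagnoses.tsv", "w") as fh:
        fh.write("entity_id\tcode\n")
        for entity, code in sorted(truth.diagnoses.items()):
            fh.write(f"{entity}\t{code}\n")
    payload = {
        "blueprint": asdict(truth.blueprint),
        "diagnoses": truth.diagnoses,
        "code_concepts": truth.code_concepts,
        "background_concepts": truth.background_concepts,
        "mentions": [asdict(m) for m in truth.mentions],
    }
    (out / "corpus_truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Worked example: the hypertension expansion narrative
# ---------------------------------------------------------------------------

_HT_NOVEL = [
    "hypertensive disorder",
    "hypertensive disease",
    "hyperpiesia",
    "hyperpiesis",
    "hypertensive vascular disease",
    "hypertensive vascular disorder",
    "elevated blood pressure",
    "raised blood pressure",
    "increased blood pressure",
    "high blood pressure disorder",
    "blood pressure elevation",
    "high arterial pressure",
    "elevated arterial pressure",
    "raised arterial pressure",
    "increased arterial pressure",
    "arterial hypertensive disorder",
    "systemic arterial hypertensive disorder",
    "essential hyperpiesia",
    "primary hyperpiesia",
    "vascular hypertensive disorder",
    "systemic hypertensive disease",
    "arterial hypertensive disease",
    "chronic hypertensive disorder",
    "sustained elevated blood pressure",
    "persistent high blood pressure",
]

_HT_LEXICAL_CARRIERS: dict[str, list[str]] = {
    "GWAS_EFO_SKOS": _HT_NOVEL[4:6] + _HT_NOVEL[11:17] + _HT_NOVEL[19:23]
    + [_HT_NOVEL[24], "HTN", "high blood pressure", "elevated blood pressure"],
    "MESH": ["hypertensive vascular disease", "high arterial pressure", "HTN",
             "elevated blood pressure"],
    "CCTOO": ["hypertensive vascular disease", "hypertensive vascular disorder",
              "high arterial pressure", "elevated arterial pressure",
              "high blood pressure", "hypertensive disorder"],
    "NCIT": ["raised arterial pressure", "increased arterial pressure",
             "arterial hypertensive disorder", "HTN", "elevated blood pressure",
             "hypertensive disease"],
    "COSTART": ["systemic arterial hypertensive disorder", "vascular hypertensive disorder",
                "systemic hypertensive disease", "arterial hypertensive disease",
                "chronic hypertensive disorder", "raised blood pressure",
                "increased blood pressure"],
    "CRISP": ["HTN"],
    "CSSO": ["high blood pressure", "hypertensive vascular disease"],
    "ODAE": ["high arterial pressure", "essential hyperpiesia"],
    "HTN-ONT": ["HTN", "high blood pressure", "elevated blood pressure"],
    "EFO": ["arterial hypertensive disease", "chronic hypertensive disorder",
            "arterial hypertensive disorder", "systemic arterial hypertensive disorder",
            "vascular hypertensive disorder", "systemic hypertensive disease",
            "high blood pressure disorder", "blood pressure elevation",
            "primary hyperpiesia"],
}

_HT_EQ_CARRIERS: list[tuple[str, str | None, str, list[str]]] = [
    # (ontology, carrier curie or None for shared IRI, first label, synonyms)
    ("DTO", "DTO:0000001", "hypertensive disorder",
     ["elevated blood pressure", "raised blood pressure"]),
    ("ONTONEO", None, "hypertensive disease",
     ["increased blood pressure", "high blood pressure disorder",
      "blood pressure elevation", "HTN"]),
    ("BAO", "BAO:0000001", "hyperpiesia",
     ["essential hyperpiesia", "primary hyperpiesia", "hyperpiesis",
      "high blood pressure", "sustained elevated blood pressure"]),
]


def hypertension_example() -> tuple[Repository, TermRecord]:
    """In-memory repository reproducing the hypertension worked example.

    The input class asserts 3 labels and synonyms of its own; carrier
    ontologies contribute 70 candidate synonyms beyond the input label
    itself (56 via lexical matching, 14 via equivalency), which
    deduplicate to 28 unique accepted labels — 25 of them novel.
    """
    input_curie = "DOID:10763"
    input_iri = curie_to_iri(input_curie)
    docs: list[OntologyDocument] = []

    do_record = TermRecord(
        iri=input_iri,
        ontology_id="DO",
        labels=("hypertension",),
        synonyms=(("HTN", "exact"), ("high blood pressure", "exact")),
    )
    docs.append(
        OntologyDocument(ontology_id="DO", source_path="<builtin>",
                         classes={input_iri: do_record})
    )

    n_lexical = 0
    for k, (ont, syns) in enumerate(_HT_LEXICAL_CARRIERS.items(), start=1):
        iri = curie_to_iri(f"LEX{k}:{k:07d}")
        rec = TermRecord(
            iri=iri, ontology_id=ont, labels=("hypertension",),
            synonyms=tuple((s, "exact") for s in syns),
        )
        docs.append(OntologyDocument(ontology_id=ont, source_path="<builtin>",
                                     classes={iri: rec}))
        n_lexical += len(syns)

    n_equivalency = 0
    for ont, curie, label, syns in _HT_EQ_CARRIERS:
        iri = input_iri if curie is None else curie_to_iri(curie)
        rec = TermRecord(
            iri=iri, ontology_id=ont, labels=(label,),
            synonyms=tuple((s, "exact") for s in syns),
        )
        doc = OntologyDocument(ontology_id=ont, source_path="<builtin>",
                               classes={iri: rec})
        if curie is not None:
            doc.equivalence_axioms.append((iri, input_iri))
        docs.append(doc)
        n_equivalency += 1 + len(syns)

    # defensive cross-check of the fixture's arithmetic
    pool = set(_HT_NOVEL) | {"HTN", "high blood pressure"}
    seen = {s for syns in _HT_LEXICAL_CARRIERS.values() for s in syns}
    seen |= {label for _, _, label, _ in _HT_EQ_CARRIERS}
    seen |= {s for _, _, _, syns in _HT_EQ_CARRIERS for s in syns}
    if n_lexical != 56 or n_equivalency != 14 or seen != pool or len(pool) != 27:
        raise AssertionError(
            f"hypertension fixture drifted: lexical={n_lexical}, "
            f"equivalency={n_equivalency}, unique={len(seen)}"
        )
    return Repository(docs), do_record
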