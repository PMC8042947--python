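"""Inter-ontology synonym expansion.

For each input class the algorithm gathers candidate synonyms from two
matching routes and then prunes them:

1. *Lexical matching* — every class, in any loaded ontology, carrying a
   label or synonym that exactly matches (under normalisation) the input
   class's **first label** contributes all of its labels and synonyms.
   Only the first label is matched on: secondary labels and synonyms are
   far more likely to hit classes with different meanings.
2. *Equivalency querying* — every class in the input's equivalence
   component (shared IRI across ontologies, or asserted equivalence
   axioms, transitively closed) contributes all of its labels and
   synonyms.  This recovers synonyms from equivalent classes whose first
   label differs from the input's and which lexical matching therefore
   misses.
3. *Pruning* — candidates are discarded when they (a) come from an
   ontology known to produce incorrect synonyms, (b) look like term
   identifiers (contain ``:`` or ``_``), (c) contain the input class's
   first label as a substring (the shorter string would already match,
   making the longer one redundant for concept recognition), or
   (d) equal a known mis-indexed annotation-property name such as
   ``europe pmc``.

The accepted candidates, made unique, are merged with the input class's
own labels and synonyms into an :class:`ExpandedVocabulary`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .ontology import (
    Repository,
    TermRecord,
    UnlabelledClassError,
    extract_first_label,
    normalize_label,
)

__all__ = [
    "CandidateSynonym",
    "PruneConfig",
    "AcceptedSynonym",
    "ExpandedVocabulary",
    "ExpansionResult",
    "lexical_candidates",
    "equivalency_candidates",
    "prune",
    "expand_term",
    "expand_set",
    "write_vocabulary",
    "read_vocabulary",
]

Method = Literal["lexical", "equivalency"]

#: ontologies found to consistently produce incorrect synonyms
DEFAULT_BLOCKED_ONTOLOGIES = frozenset({"GO-PLUS", "MONDO", "CCONT", "phenX"})
#: annotation-property names mis-indexed as labels
DEFAULT_BLOCKED_PSEUDO_LABELS = frozenset({"europe pmc", "kegg compound"})
#: characters marking identifier-form labels
DEFAULT_IDENTIFIER_CHARS = frozenset({":", "_"})


@dataclass(frozen=True)
class CandidateSynonym:
    """A proposed label with its provenance."""

    text: str
    source_ontology: str
    source_iri: str
    method: Method
    scope: str  # 'label' or a synonym scope

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("candidate synonym text must be non-empty")


@dataclass(frozen=True)
class PruneConfig:
    blocked_ontologies: frozenset[str] = DEFAULT_BLOCKED_ONTOLOGIES
    blocked_pseudo_labels: frozenset[str] = DEFAULT_BLOCKED_PSEUDO_LABELS
    identifier_chars: frozenset[str] = DEFAULT_IDENTIFIER_CHARS


@dataclass(frozen=True)
class AcceptedSynonym:
    """A unique accepted vocabulary entry with merged provenance."""

    text: str  # first-seen surface form
    provenance: tuple[CandidateSynonym, ...]
    is_original: bool


@dataclass
class ExpandedVocabulary:
    """Expansion result for one input class."""

    input_iri: str
    input_ontology: str
    input_first_label: str
    original_labels: tuple[str, ...]
    accepted: list[AcceptedSynonym]
    removed: list[tuple[CandidateSynonym, str]]  # (candidate, reason)
    n_candidates_raw: int = 0
    n_lexical: int = 0
    n_equivalency: int = 0

    @property
    def n_pruned(self) -> int:
        return len(self.removed)

    @property
    def n_unique_accepted(self) -> int:
        return len(self.accepted)

    @property
    def n_novel(self) -> int:
        n_original = len({normalize_label(t) for t in self.original_labels})
        return self.n_unique_accepted - n_original

    def surface_forms(self) -> list[str]:
        return [a.text for a in self.accepted]

    def novel_surface_forms(self) -> list[str]:
        return [a.text for a in self.accepted if not a.is_original]


def lexical_candidates(record: TermRecord, repository: Repository) -> list[CandidateSynonym]:
    """Step 1: candidates from classes sharing the input's first label.

    Every class (in any loaded ontology, other than the input class
    itself) with a label *or* synonym matching the first label emits all
    of its labels and synonyms.  No sense disambiguation is attempted, so
    a homonym match contributes its — possibly unrelated — synonyms too.
    """
    try:
        first = extract_first_label(record)
    except UnlabelledClassError:
        warnings.warn(f"skipping unlabelled class {record.iri}")
        return []
    out: list[CandidateSynonym] = []
    for ont_id, iri in sorted(repository.label_index.lookup(first)):
        if (ont_id, iri) == (record.ontology_id, record.iri):
            continue
        out.extend(_emit_all(repository.record(ont_id, iri), "lexical"))
    return out


def equivalency_candidates(record: TermRecord, repository: Repository) -> list[CandidateSynonym]:
    """Step 2: candidates from the input's equivalence component."""
    members = repository.equivalence_graph.members(record.ontology_id, record.iri)
    out: list[CandidateSynonym] = []
    for ont_id, iri in sorted(members):
        if (ont_id, iri) == (record.ontology_id, record.iri):
            continue
        out.extend(_emit_all(repository.record(ont_id, iri), "equivalency"))
    return out


def _emit_all(source: TermRecord, method: Method) -> list[CandidateSynonym]:
    out = []
    for text in source.labels:
        out.append(CandidateSynonym(text, source.ontology_id, source.iri, method, "label"))
    for text, scope in source.synonyms:
        out.append(CandidateSynonym(text, source.ontology_id, source.iri, method, scope))
    return out


def prune(
    candidates: Sequence[CandidateSynonym],
    record: TermRecord,
    config: PruneConfig = PruneConfig(),
) -> tuple[list[CandidateSynonym], list[tuple[CandidateSynonym, str]]]:
    """Step 3: discard incorrect-by-form candidates, recording reasons.

    Checks run in order (first matching reason recorded):
    ``blocked_ontology`` → ``identifier`` → ``substring`` →
    ``pseudo_label``.
    """
    first_norm = normalize_label(extract_first_label(record))
    pseudo_norm = {normalize_label(p) for p in config.blocked_pseudo_labels}
    accepted: list[CandidateSynonym] = []
    removed: list[tuple[CandidateSynonym, str]] = []
    for cand in candidates:
        if cand.source_ontology in config.blocked_ontologies:
            removed.append((cand, "blocked_ontology"))
        elif any(ch in cand.text for ch in config.identifier_chars):
            removed.append((cand, "identifier"))
        elif first_norm and first_norm in normalize_label(cand.text):
            removed.append((cand, "substring"))
        elif normalize_label(cand.text) in pseudo_norm:
            removed.append((cand, "pseudo_label"))
        else:
            accepted.append(cand)
    return accepted, removed


def expand_term(
    record: TermRecord,
    repository: Repository,
    config: PruneConfig = PruneConfig(),
    mode: Literal["both", "equivalency_only"] = "both",
) -> ExpandedVocabulary:
    """Run the full expansion (match → prune → deduplicate) for one class.

    The input class's own labels and synonyms bypass pruning and always
    appear in the output vocabulary; deduplication is by normalised
    string, keeping the first-seen surface form and merging provenance.
    """
    first = extract_first_label(record)  # raises on unlabelled input
    lex = lexical_candidates(record, repository) if mode == "both" else []
    eq = equivalency_candidates(record, repository)
    candidates = sorted(
        lex + eq,
        key=lambda c: (c.method, c.source_ontology, c.source_iri, c.text, c.scope),
    )
    kept, removed = prune(candidates, record, config)

    originals = tuple(record.all_label_texts())
    original_norms = {normalize_label(t) for t in originals}

    by_norm: dict[str, dict] = {}
    order: list[str] = []
    for text in originals:
        key = normalize_label(text)
        if key not in by_norm:
            by_norm[key] = {"text": text, "prov": [], "original": True}
            order.append(key)
    for cand in kept:
        key = normalize_label(cand.text)
        if key not in by_norm:
            by_norm[key] = {"text": cand.text, "prov": [], "original": key in original_norms}
            order.append(key)
        by_norm[key]["prov"].append(cand)

    accepted = [
        AcceptedSynonym(
            text=by_norm[key]["text"],
            provenance=tuple(by_norm[key]["prov"]),
            is_original=by_norm[key]["original"],
        )
        for key in order
    ]
    return ExpandedVocabulary(
        input_iri=record.iri,
        input_ontology=record.ontology_id,
        input_first_label=first,
        original_labels=originals,
        accepted=accepted,
        removed=removed,
        n_candidates_raw=len(candidates),
        n_lexical=len(lex),
        n_equivalency=len(eq),
    )


@dataclass
class ExpansionResult:
    """Expansion of a set of input classes plus aggregate bookkeeping."""

    vocabularies: dict[str, ExpandedVocabulary] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (iri, reason)

    @property
    def n_labels_before(self) -> int:
        return sum(
            len({normalize_label(t) for t in v.original_labels})
            for v in self.vocabularies.values()
        )

    @property
    def n_labels_after(self) -> int:
        return sum(v.n_unique_accepted for v in self.vocabularies.values())

    def to_frame(self) -> pd.DataFrame:
        """One row per accepted vocabulary entry."""
        rows = []
        for iri in sorted(self.vocabularies):
            vocab = self.vocabularies[iri]
            for acc in vocab.accepted:
                methods = sorted({p.method for p in acc.provenance})
                sources = sorted({p.source_ontology for p in acc.provenance})
                src_iris = sorted({p.source_iri for p in acc.provenance})
                rows.append(
                    {
                        "iri": iri,
                        "first_label": vocab.input_first_label,
                        "synonym": acc.text,
                        "source_ontology": ";".join(sources) or vocab.input_ontology,
                        "source_iri": ";".join(src_iris) or iri,
                        "methods": ";".join(methods) or "original",
                        "is_original": acc.is_original,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "iri",
                "first_label",
                "synonym",
                "source_ontology",
                "source_iri",
                "methods",
                "is_original",
            ],
        )


def expand_set(
    iris: Iterable[str],
    repository: Repository,
    config: PruneConfig = PruneConfig(),
    mode: Literal["both", "equivalency_only"] = "both",
    input_ontology: str | None = None,
) -> ExpansionResult:
    """Expand every input IRI; unresolvable or unlabelled IRIs are skipped.

    ``input_ontology`` restricts which ontology's record is treated as the
    input class when an IRI is loaded in several documents; by default the
    first (sorted) occurrence is used.
    """
    result = ExpansionResult()
    for iri in iris:
        records = repository.find_by_iri(iri)
        if input_ontology is not None:
            records = [r for r in records if r.ontology_id == input_ontology]
        if not records:
            result.skipped.append((iri, "unresolvable"))
            continue
        record = records[0]
        try:
            result.vocabularies[iri] = expand_term(record, repository, config, mode)
        except UnlabelledClassError:
            result.skipped.append((iri, "unlabelled"))
    return result


def write_vocabulary(result: ExpansionResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)


def read_vocabulary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"iri": str, "synonym": str})
    missing = {"iri", "synonym"} - set(df.columns)
    if missing:
        raise ValueError(f"vocabulary file {path} lacks columns {sorted(missing)}")
    return df
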