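"""Dictionary-based concept recognition with negation flagging.

Vocabulary surface forms and their lemmatised forms are compiled into a
token-sequence lexicon; documents are matched case-insensitively on both
their surface and lemma token streams.  Overlapping matches are resolved
longest-first (then leftmost); a winning span may map to several classes
when the vocabulary is ambiguous, and all of them are emitted.

Negation is a cue-window rule: an annotation is flagged negated when a
negation cue ("no", "denies", "negative for", ...) ends within a small
token window before the match inside the same sentence, with no scope
breaker (``;``, "but", "however") in between.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .text import Sentence, lemmatize_phrase, normalize_text, preprocess

__all__ = [
    "Document",
    "LexiconEntry",
    "Lexicon",
    "Annotation",
    "NegationConfig",
    "compile_lexicon",
    "annotate",
    "flag_negation",
    "annotate_corpus",
    "entity_annotation_sets",
    "read_corpus",
    "write_annotations",
    "read_annotations",
]


@dataclass(frozen=True)
class Document:
    entity_id: str
    doc_id: str
    text: str


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    lemma_form: str
    iri: str


@dataclass(frozen=True)
class Annotation:
    entity_id: str
    doc_id: str
    sentence_index: int
    start: int  # half-open char span over the newline-normalised text
    end: int
    matched_text: str
    iri: str
    negated: bool = False


class Lexicon:
    """Token-sequence lookup compiled from vocabulary entries."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries = list(entries)
        self._forms: dict[tuple[str, ...], set[str]] = {}
        for entry in self.entries:
            for form in (entry.surface, entry.lemma_form):
                key = tuple(form.lower().split())
                if key:
                    self._forms.setdefault(key, set()).add(entry.iri)
        self.max_tokens = max((len(k) for k in self._forms), default=0)

    def lookup(self, tokens: tuple[str, ...]) -> set[str]:
        return self._forms.get(tokens, set())

    def __len__(self) -> int:
        return len(self.entries)


def compile_lexicon(vocabulary: pd.DataFrame | str | Path) -> Lexicon:
    """Build a lexicon from a vocabulary table (or its TSV path).

    Each (label, iri) pair yields both its surface and its lemmatised
    form; duplicate (form, iri) pairs collapse.  Rows with missing text
    or IRI are skipped with a warning count.
    """
    if not isinstance(vocabulary, pd.DataFrame):
        from .expansion import read_vocabulary

        vocabulary = read_vocabulary(vocabulary)
    entries: dict[tuple[str, str], LexiconEntry] = {}
    n_bad = 0
    for row in vocabulary.itertuples(index=False):
        text, iri = getattr(row, "synonym", None), getattr(row, "iri", None)
        if not isinstance(text, str) or not text.strip() or not isinstance(iri, str):
            n_bad += 1
            continue
        surface = " ".join(text.split())
        entries[(surface, iri)] = LexiconEntry(
            surface=surface, lemma_form=lemmatize_phrase(surface), iri=iri
        )
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed vocabulary rows")
    return Lexicon(entries.values())


def annotate(document: Document, lexicon: Lexicon) -> list[Annotation]:
    """Longest-match dictionary annotation of one document.

    All candidate token windows whose surface or lemma sequence is in the
    lexicon are collected, then filtered greedily by (longest span,
    leftmost start); annotations are emitted with ``negated=False``.
    """
    sentences = preprocess(document.text)
    norm_text = normalize_text(document.text)
    matches: list[tuple[int, int, int, frozenset[str]]] = []  # (start, end, sent_idx, iris)
    for sent in sentences:
        toks = sent.tokens
        n = len(toks)
        for i in range(n):
            for length in range(1, min(lexicon.max_tokens, n - i) + 1):
                window = toks[i : i + length]
                surf = tuple(t.surface.lower() for t in window)
                lem = tuple(t.lemma for t in window)
                iris = lexicon.lookup(surf) | lexicon.lookup(lem)
                if iris:
                    matches.append(
                        (window[0].start, window[-1].end, sent.index, frozenset(iris))
                    )
    # longest span wins; ties by leftmost start
    matches.sort(key=lambda m: (-(m[1] - m[0]), m[0]))
    accepted: list[tuple[int, int, int, frozenset[str]]] = []
    for m in matches:
        if all(m[1] <= a[0] or m[0] >= a[1] for a in accepted):
            accepted.append(m)
    out = [
        Annotation(
            entity_id=document.entity_id,
            doc_id=document.doc_id,
            sentence_index=sent_idx,
            start=start,
            end=end,
            matched_text=norm_text[start:end],
            iri=iri,
        )
        for start, end, sent_idx, iris in accepted
        for iri in sorted(iris)
    ]
    out.sort(key=lambda a: (a.start, a.end, a.iri))
    return out


DEFAULT_NEGATION_CUES = (
    "no",
    "not",
    "without",
    "denies",
    "denied",
    "negative for",
    "absence of",
    "free of",
)
DEFAULT_SCOPE_BREAKERS = frozenset({";", "but", "however"})


@dataclass(frozen=True)
class NegationConfig:
    cues: tuple[str, ...] = DEFAULT_NEGATION_CUES
    window: int = 6  # max tokens between cue end and match start
    scope_breakers: frozenset[str] = DEFAULT_SCOPE_BREAKERS


def flag_negation(
    annotations: Iterable[Annotation],
    sentences: list[Sentence],
    config: NegationConfig = NegationConfig(),
) -> list[Annotation]:
    """Return annotations with ``negated`` set by the cue-window rule."""
    cue_seqs = [tuple(c.lower().split()) for c in config.cues]
    by_index = {s.index: s for s in sentences}
    out: list[Annotation] = []
    for ann in annotations:
        sent = by_index.get(ann.sentence_index)
        negated = sent is not None and _is_negated(ann, sent, cue_seqs, config)
        out.append(
            Annotation(
                entity_id=ann.entity_id,
                doc_id=ann.doc_id,
                sentence_index=ann.sentence_index,
                start=ann.start,
                end=ann.end,
                matched_text=ann.matched_text,
                iri=ann.iri,
                negated=negated,
            )
        )
    return out


def _is_negated(
    ann: Annotation,
    sent: Sentence,
    cue_seqs: list[tuple[str, ...]],
    config: NegationConfig,
) -> bool:
    before = [t for t in sent.tokens if t.end <= ann.start]
    lowered = [t.surface.lower() for t in before]
    n = len(lowered)
    for cue in cue_seqs:
        L = len(cue)
        for j in range(n - L + 1):
            if tuple(lowered[j : j + L]) != cue:
                continue
            gap = lowered[j + L :]
            if len(gap) > config.window:
                continue
            if any(tok in config.scope_breakers for tok in gap):
                continue
            return True
    return False


def annotate_corpus(
    documents: Iterable[Document],
    lexicon: Lexicon,
    negation: NegationConfig = NegationConfig(),
) -> list[Annotation]:
    """Annotate many documents, with negation flags set."""
    out: list[Annotation] = []
    for doc in documents:
        anns = annotate(doc, lexicon)
        if anns:
            anns = flag_negation(anns, preprocess(doc.text), negation)
        out.extend(anns)
    return out


def entity_annotation_sets(
    annotations: Iterable[Annotation], drop_negated: bool = True
) -> dict[str, set[str]]:
    """Deduplicated class set per entity, excluding negated matches."""
    sets: dict[str, set[str]] = {}
    for ann in annotations:
        if drop_negated and ann.negated:
            continue
        sets.setdefault(ann.entity_id, set()).add(ann.iri)
    return sets


def read_corpus(path: str | Path) -> list[Document]:
    """Read a corpus TSV with columns entity_id, doc_id, text."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"entity_id", "doc_id", "text"} - set(df.columns)
    if missing:
        raise ValueError(f"corpus file {path} lacks columns {sorted(missing)}")
    return [Document(r.entity_id, r.doc_id, r.text) for r in df.itertuples(index=False)]


ANNOTATION_COLUMNS = [
    "entity_id",
    "doc_id",
    "sentence_index",
    "start",
    "end",
    "matched_text",
    "iri",
    "negated",
]


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            writer.writerow(
                [a.entity_id, a.doc_id, a.sentence_index, a.start, a.end,
                 a.matched_text, a.iri, int(a.negated)]
            )


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "doc_id": str, "iri": str})
    return [
        Annotation(
            entity_id=r.entity_id,
            doc_id=r.doc_id,
            sentence_index=int(r.sentence_index),
            start=int(r.start),
            end=int(r.end),
            matched_text=str(r.matched_text),
            iri=r.iri,
            negated=bool(r.negated),
        )
        for r in df.itertuples(index=False)
    ]
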