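"""Text preprocessing: newline normalisation, sentence splitting,
tokenisation with character offsets, and rule-based lemmatisation.

The lemmatiser is a deliberately small ordered-suffix-rule stemmer (plus
a short exception table) tuned for the noun-phrase vocabulary that
dictionary annotation works on ("headaches" → "headache", "decreased
heart rates" → "decrease heart rate").  It is not a general English
lemmatiser; both surface and lemma forms are matched at annotation time,
so imperfect lemmas cost recall only when text and vocabulary inflect
the same word differently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Token", "Sentence", "lemmatize", "lemmatize_phrase", "preprocess"]


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    start: int  # char offset into the newline-normalised text
    end: int    # half-open


@dataclass(frozen=True)
class Sentence:
    index: int
    start: int
    end: int
    tokens: tuple[Token, ...]


_EXCEPTIONS = {
    "denies": "deny",
    "denied": "deny",
    "has": "have",
    "had": "have",
    "is": "be",
    "are": "be",
    "was": "be",
    "were": "be",
    "feet": "foot",
    "teeth": "tooth",
    "men": "man",
    "women": "woman",
    "children": "child",
}

_VOWELS = set("aeiou")
# after stripping -ed/-ing these endings take back a final 'e'
_E_RESTORE = ("s", "c", "v", "u", "z", "g")


def _fix_stem(stem: str) -> str:
    if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "lsz":
        return stem[:-1]  # stopped → stop
    if stem and stem[-1] in _E_RESTORE:
        return stem + "e"  # decreas → decrease
    return stem


def lemmatize(token: str) -> str:
    """Lemma of a single lowercase-insensitive token."""
    w = token.lower()
    if not w.isalpha():
        return w
    if w in _EXCEPTIONS:
        return _EXCEPTIONS[w]
    if len(w) <= 3:
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("ied") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith(("xes", "zes")):
        return w[:-2]
    # -ches/-shes is ambiguous (match+es vs headache+s); stripping the bare
    # 's' keeps noun plurals right and stays consistent across vocabulary
    # and text, which is what token matching needs
    if w.endswith(("ches", "shes")):
        return w[:-1]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    if w.endswith("ing") and len(w) > 5:
        return _fix_stem(w[:-3])
    if w.endswith("ed") and len(w) > 4:
        return _fix_stem(w[:-2])
    return w


def lemmatize_phrase(phrase: str) -> str:
    """Lemmatise a whitespace-separated phrase token by token."""
    return " ".join(lemmatize(t) for t in phrase.split())


_NEWLINES = re.compile(r"[\r\n\t]")
# word tokens (letters/digits, internal apostrophes/hyphens) or single
# punctuation marks; punctuation must surface as tokens so that negation
# scope breakers like ';' are visible
_TOKEN = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-]*|[^\sA-Za-z0-9]")
_SENTENCE_END = re.compile(r"[.!?]+(?=\s|$)")


def normalize_text(text: str) -> str:
    """Replace newlines/tabs with spaces (length-preserving)."""
    return _NEWLINES.sub(" ", text)


def preprocess(text: str) -> list[Sentence]:
    """Newline-normalise, split into sentences, tokenise and lemmatise.

    Character offsets index the newline-normalised text, which has the
    same length as the input.
    """
    norm = normalize_text(text)
    bounds: list[tuple[int, int]] = []
    start = 0
    for m in _SENTENCE_END.finditer(norm):
        bounds.append((start, m.end()))
        start = m.end()
    if norm[start:].strip():
        bounds.append((start, len(norm)))

    sentences: list[Sentence] = []
    for idx, (s, e) in enumerate(bounds):
        tokens = tuple(
            Token(
                surface=m.group(),
                lemma=lemmatize(m.group()),
                start=s + m.start(),
                end=s + m.end(),
            )
            for m in _TOKEN.finditer(norm[s:e])
        )
        if tokens:
            sentences.append(Sentence(index=len(sentences), start=s, end=e, tokens=tokens))
    return sentences
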