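"""Sentence splitting and tokenization for titles and abstracts.

A document is processed zone by zone (``title`` and ``abstract`` are
independent coordinate spaces).  Sentences break only at a dot followed by
whitespace; dot-terminated abbreviations (``e.g.``, ``i.v.`` ...) never end a
sentence.  Tokens are whitespace-delimited, with two deliberate refinements:

* a trailing comma or semicolon is detached into a punctuation token of its
  own, so downstream clause rules (linkage stop, negation scope) can see it;
* the sentence-final period is stripped from the last token.

Every token carries its character span in the zone text, 0-based half-open,
so that ``zone_text[start:end] == surface`` always holds.  The same tokenizer
is applied to dictionary entries, which keeps lexicon matching aligned with
document tokenization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

TITLE = "title"
ABSTRACT = "abstract"

#: Dot-terminated forms (lowercase) that never end a sentence.  Extendable
#: through the resources manifest.
DEFAULT_ABBREVIATIONS = frozenset(
    {"e.g.", "i.e.", "i.v.", "et al.", "vs.", "approx.", "fig.", "spp."}
)

_TRAILING_PUNCT = {",", ";"}


@dataclass(frozen=True)
class Document:
    """A corpus item: PubMed identifier plus title and abstract text."""

    pmid: str
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("Document requires a non-empty pmid")


@dataclass(frozen=True)
class Token:
    surface: str
    norm: str
    start: int  # char offset in the zone text
    end: int
    is_punct_comma: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("token span must be non-empty")


@dataclass
class Sentence:
    zone: str
    index: int
    text: str
    start: int  # char offset of ``text`` within the zone
    tokens: list[Token] = field(default_factory=list)

    @property
    def norms(self) -> list[str]:
        return [t.norm for t in self.tokens]


def _is_abbreviation(text: str, dot: int, abbreviations: frozenset[str]) -> bool:
    """True when the dot at ``dot`` terminates a known abbreviation."""
    j = dot
    while j > 0 and not text[j - 1].isspace():
        j -= 1
    chunk = text[j:dot + 1].lower()
    if chunk in abbreviations:
        return True
    # multiword forms such as "et al."
    k = j
    while k > 0 and text[k - 1].isspace():
        k -= 1
    m = k
    while m > 0 and not text[m - 1].isspace():
        m -= 1
    if m < k:
        two = (text[m:k] + " " + chunk).lower()
        if two in abbreviations:
            return True
    return False


def split_sentences(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[tuple[str, int]]:
    """Split ``text`` into ``(sentence_text, start_offset)`` pairs.

    Boundaries occur only at a dot immediately followed by whitespace, unless
    the dot terminates an abbreviation or sits between two digits.  Trailing
    text without a final dot forms a last sentence.
    """
    out: list[tuple[str, int]] = []
    n = len(text)

    def emit(raw_start: int, raw_end: int) -> None:
        seg = text[raw_start:raw_end]
        stripped = seg.strip()
        if stripped:
            out.append((stripped, raw_start + (len(seg) - len(seg.lstrip()))))

    start = 0
    i = 0
    while i < n:
        if text[i] == "." and i + 1 < n and text[i + 1].isspace():
            inside_number = (
                0 < i < n - 1 and text[i - 1].isdigit() and text[i + 1].isdigit()
            )
            if inside_number or _is_abbreviation(text, i, abbreviations):
                i += 1
                continue
            emit(start, i + 1)
            i += 1
            while i < n and text[i].isspace():
                i += 1
            start = i
            continue
        i += 1
    emit(start, n)
    return out


def tokenize(text: str, base: int = 0) -> list[Token]:
    """Tokenize one sentence; spans are offset by ``base`` (zone coordinates)."""
    chunks: list[tuple[str, int]] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace():
            j += 1
        chunks.append((text[i:j], i))
        i = j
    if not chunks:
        return []

    # strip the sentence-final period from the last chunk
    last, last_off = chunks[-1]
    if last.endswith(".") and len(last) > 1:
        chunks[-1] = (last[:-1], last_off)
    elif last == ".":
        chunks.pop()
        if not chunks:
            return []

    tokens: list[Token] = []
    for chunk, off in chunks:
        trail: list[str] = []
        word = chunk
        while word and word[-1] in _TRAILING_PUNCT:
            trail.append(word[-1])
            word = word[:-1]
        pos = off
        if word:
            tokens.append(
                Token(word, word.lower(), base + pos, base + pos + len(word))
            )
            pos += len(word)
        for ch in reversed(trail):
            tokens.append(
                Token(ch, ch, base + pos, base + pos + 1, is_punct_comma=(ch == ","))
            )
            pos += 1
    return tokens


def preprocess_document(
    doc: Document, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[Sentence]:
    """Split a document into tokenized sentences, title zone first."""
    sentences: list[Sentence] = []
    for zone, text in ((TITLE, doc.title), (ABSTRACT, doc.abstract)):
        for idx, (sent_text, off) in enumerate(split_sentences(text, abbreviations)):
            sentences.append(
                Sentence(
                    zone=zone,
                    index=idx,
                    text=sent_text,
                    start=off,
                    tokens=tokenize(sent_text, base=off),
                )
            )
    return sentences
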