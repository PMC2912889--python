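"""Entity tagging, number/unit recognition and negation filtering.

Tagging is a single left-to-right greedy pass over each sentence: at every
token position the trie returns the longest dictionary phrase starting
there; matches never overlap and punctuation tokens never start one.

Numbers are recognized only in sentences that already contain a kinetic
expression (this gate is what keeps whole-corpus runs cheap: most sentences
never reach the number grammar).  The grammar covers plain decimals,
scientific notation in the dialects common in abstracts (``1.5 x 10(-3)``,
``10^-3``, ``5e-4``), ``+/-`` error terms and hyphenated ranges.  A number
directly followed by a recognized unit is fused with it; a number whose unit
is incompatible with every kinetic category mentioned in the sentence is
discarded outright (temperature units are exempt: they identify the number
as a temperature by themselves).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from collections.abc import Iterable, Mapping, Sequence

from .lexicon import (
    BARE_NUMBER_CATEGORIES,
    Category,
    KINETIC_CATEGORIES,
    LexiconEntry,
    TokenTrie,
)
from .preprocess import Sentence

#: Which kinetic categories each unit dictionary vouches for.  The
#: concentration list is shared by every concentration-valued parameter.
UNIT_CATEGORY_MAP: dict[Category, frozenset[Category]] = {
    Category.UNIT_CONCENTRATION: frozenset(
        {
            Category.KM,
            Category.KI,
            Category.KD,
            Category.IC50,
            Category.S_HALF,
            Category.KA,
        }
    ),
    Category.UNIT_KCAT: frozenset({Category.KCAT}),
    Category.UNIT_KCAT_OVER_KM: frozenset({Category.KCAT_OVER_KM}),
    Category.UNIT_T_HALF: frozenset({Category.T_HALF}),
    Category.UNIT_VMAX: frozenset({Category.VMAX}),
    Category.UNIT_SPECIFIC_ACTIVITY: frozenset({Category.SPECIFIC_ACTIVITY}),
    Category.UNIT_VMAX_OVER_KM: frozenset({Category.VMAX_OVER_KM}),
    Category.UNIT_KA: frozenset({Category.KA}),
    Category.UNIT_TEMPERATURE: frozenset({Category.TEMPERATURE}),
    Category.UNIT_OTHER: frozenset(),
}


@dataclass(frozen=True)
class Mention:
    """A tagged occurrence of a dictionary phrase."""

    category: Category
    zone: str
    sentence_index: int
    token_span: tuple[int, int]  # half-open token indices
    char_span: tuple[int, int]  # half-open char offsets in the zone text
    surface: str
    canonical: str


@dataclass(frozen=True)
class NumericMention:
    """A recognized number, optionally fused with a following unit."""

    value: float
    error: float | None
    range_high: float | None
    unit_surface: str  # "" for bare numbers
    unit_categories: frozenset[Category]
    zone: str
    sentence_index: int
    token_span: tuple[int, int]
    char_span: tuple[int, int]
    tagged_as: Category | None = None  # set to PH/TEMPERATURE once identified


class UnitTable:
    """Longest-match table from unit token sequences to kinetic categories."""

    def __init__(self, mapping: Mapping[tuple[str, ...], frozenset[Category]]):
        self._map = dict(mapping)
        self._maxlen = max((len(k) for k in self._map), default=0)

    @classmethod
    def from_entries(cls, entries: Iterable[LexiconEntry]) -> "UnitTable":
        mapping: dict[tuple[str, ...], frozenset[Category]] = {}
        for e in entries:
            if e.category.group != "unit":
                continue
            cats = UNIT_CATEGORY_MAP[e.category]
            mapping[e.tokens] = mapping.get(e.tokens, frozenset()) | cats
        return cls(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def match(
        self, norms: Sequence[str], start: int
    ) -> tuple[int, frozenset[Category]] | None:
        limit = min(self._maxlen, len(norms) - start)
        for length in range(limit, 0, -1):
            key = tuple(norms[start:start + length])
            if key in self._map:
                return length, self._map[key]
        return None


def _slice(sentence: Sentence, tok_start: int, tok_end: int) -> tuple[str, tuple[int, int]]:
    a = sentence.tokens[tok_start].start
    b = sentence.tokens[tok_end - 1].end
    return sentence.text[a - sentence.start : b - sentence.start], (a, b)


def tag_entities(sentence: Sentence, trie: TokenTrie) -> list[Mention]:
    """Greedy non-overlapping longest-match scan over one sentence."""
    norms = sentence.norms
    mentions: list[Mention] = []
    i = 0
    n = len(norms)
    while i < n:
        if sentence.tokens[i].surface in (",", ";"):
            i += 1
            continue
        match = trie.lookup_longest(norms, i)
        if match is None:
            i += 1
            continue
        surface, char_span = _slice(sentence, i, i + match.length)
        mentions.append(
            Mention(
                category=match.category,
                zone=sentence.zone,
                sentence_index=sentence.index,
                token_span=(i, i + match.length),
                char_span=char_span,
                surface=surface,
                canonical=match.canonical,
            )
        )
        i += match.length
    return mentions


_RE_PLAIN = re.compile(r"^[+-]?(?:\d+(?:\.\d+)?|\.\d+)$")
_RE_SCI = re.compile(r"^[+-]?\d+(?:\.\d+)?e[+-]?\d+$")
_RE_POW = re.compile(r"^10(?:\^\(?([+-]?\d+)\)?|\(([+-]?\d+)\))$")
_RE_RANGE = re.compile(r"^(\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)$")
_PLUSMINUS = {"+/-", "+-", "±"}
_MULT = {"x", "×", "*"}


def _pow_exponent(norm: str) -> int | None:
    m = _RE_POW.match(norm)
    if not m:
        return None
    return int(m.group(1) if m.group(1) is not None else m.group(2))


def _parse_number(norms: Sequence[str], i: int) -> tuple[float, float | None, float | None, int] | None:
    """Parse a numeric phrase at token ``i``; returns (value, error, high, consumed)."""
    tok = norms[i]
    m = _RE_RANGE.match(tok)
    if m:
        return float(m.group(1)), None, float(m.group(2)), 1
    value: float | None = None
    consumed = 0
    if _RE_PLAIN.match(tok) or _RE_SCI.match(tok):
        value = float(tok)
        consumed = 1
        if (
            i + 2 < len(norms)
            and norms[i + 1] in _MULT
            and _pow_exponent(norms[i + 2]) is not None
        ):
            value *= 10.0 ** _pow_exponent(norms[i + 2])
            consumed = 3
    else:
        exp = _pow_exponent(tok)
        if exp is not None:
            value = 10.0 ** exp
            consumed = 1
    if value is None:
        return None
    error: float | None = None
    j = i + consumed
    if (
        j + 1 < len(norms)
        and norms[j] in _PLUSMINUS
        and (_RE_PLAIN.match(norms[j + 1]) or _RE_SCI.match(norms[j + 1]))
    ):
        error = float(norms[j + 1])
        consumed += 2
    return value, error, None, consumed


def recognize_numbers(
    sentence: Sentence, mentions: Sequence[Mention], units: UnitTable
) -> list[NumericMention]:
    """Recognize numbers (with units) in a sentence holding a kinetic mention."""
    norms = sentence.norms
    covered: set[int] = set()
    for m in mentions:
        covered.update(range(*m.token_span))
    sentence_kinetic = {m.category for m in mentions if m.category in KINETIC_CATEGORIES}

    numbers: list[NumericMention] = []
    i = 0
    n = len(norms)
    while i < n:
        if i in covered or sentence.tokens[i].surface in (",", ";"):
            i += 1
            continue
        parsed = _parse_number(norms, i)
        if parsed is None:
            i += 1
            continue
        value, error, range_high, consumed = parsed
        j = i + consumed
        unit_len = 0
        unit_cats: frozenset[Category] | None = None
        hit = units.match(norms, j)
        if hit is not None and not any(k in covered for k in range(j, j + hit[0])):
            unit_len, unit_cats = hit
        if unit_cats is not None:
            end = j + unit_len
            # incompatible-unit removal; temperature units identify themselves
            if Category.TEMPERATURE not in unit_cats and not (
                unit_cats & sentence_kinetic
            ):
                i = end
                continue
            surface, char_span = _slice(sentence, i, end)
            unit_surface, _ = _slice(sentence, j, end)
            numbers.append(
                NumericMention(
                    value=value,
                    error=error,
                    range_high=range_high,
                    unit_surface=unit_surface,
                    unit_categories=unit_cats,
                    zone=sentence.zone,
                    sentence_index=sentence.index,
                    token_span=(i, end),
                    char_span=char_span,
                )
            )
            i = end
        else:
            surface, char_span = _slice(sentence, i, j)
            numbers.append(
                NumericMention(
                    value=value,
                    error=error,
                    range_high=range_high,
                    unit_surface="",
                    unit_categories=BARE_NUMBER_CATEGORIES,
                    zone=sentence.zone,
                    sentence_index=sentence.index,
                    token_span=(i, j),
                    char_span=char_span,
                )
            )
            i = j
    return numbers


def detect_ph_temperature(
    sentence: Sentence,
    mentions: Sequence[Mention],
    numbers: Sequence[NumericMention],
    ph_bounds: tuple[float, float] = (0.0, 14.0),
    temperature_bounds: tuple[float, float] = (-80.0, 150.0),
) -> list[NumericMention]:
    """Tag numbers as pH or temperature values; out-of-range ones stay bare.

    A bare number immediately after a pH (temperature) expression becomes a
    pH (temperature) value; a number fused with a temperature unit is a
    temperature value regardless of nearby expressions.
    """
    expr_end: dict[int, Category] = {}
    for m in mentions:
        if m.category in (Category.PH, Category.TEMPERATURE):
            expr_end[m.token_span[1]] = m.category

    out: list[NumericMention] = []
    for num in numbers:
        tagged = num
        if Category.TEMPERATURE in num.unit_categories and num.unit_surface:
            if temperature_bounds[0] <= num.value <= temperature_bounds[1]:
                tagged = replace(num, tagged_as=Category.TEMPERATURE)
        elif not num.unit_surface:
            cat = expr_end.get(num.token_span[0])
            if cat is Category.PH and ph_bounds[0] <= num.value <= ph_bounds[1]:
                tagged = replace(num, tagged_as=Category.PH)
            elif (
                cat is Category.TEMPERATURE
                and temperature_bounds[0] <= num.value <= temperature_bounds[1]
            ):
                tagged = replace(num, tagged_as=Category.TEMPERATURE)
        out.append(tagged)
    return out


def filter_negated(sentence: Sentence, mentions: Sequence[Mention]) -> list[Mention]:
    """Drop ligand mentions inside a negated clause.

    The clause window opens right after a negation phrase and closes at the
    next comma token or at the sentence end.  Only ligands are affected.
    """
    windows: list[tuple[int, int]] = []
    n = len(sentence.tokens)
    for m in mentions:
        if m.category is not Category.NEGATION_PHRASE:
            continue
        start = m.token_span[1]
        end = n
        for k in range(start, n):
            if sentence.tokens[k].is_punct_comma:
                end = k
                break
        windows.append((start, end))
    if not windows:
        return list(mentions)
    return [
        m
        for m in mentions
        if not (
            m.category is Category.LIGAND
            and any(a <= m.token_span[0] < b for a, b in windows)
        )
    ]


@dataclass
class TaggedSentence:
    sentence: Sentence
    mentions: list[Mention]
    numbers: list[NumericMention]

    def has_kinetic(self) -> bool:
        return any(m.category in KINETIC_CATEGORIES for m in self.mentions)


def tag_document(
    sentences: Sequence[Sentence],
    trie: TokenTrie,
    units: UnitTable,
    ph_bounds: tuple[float, float] = (0.0, 14.0),
    temperature_bounds: tuple[float, float] = (-80.0, 150.0),
    apply_negation_filter: bool = True,
) -> list[TaggedSentence]:
    """Tag every sentence; numbers only where a kinetic expression occurs."""
    tagged: list[TaggedSentence] = []
    for sentence in sentences:
        mentions = tag_entities(sentence, trie)
        numbers: list[NumericMention] = []
        if any(m.category in KINETIC_CATEGORIES for m in mentions):
            numbers = recognize_numbers(sentence, mentions, units)
            numbers = detect_ph_temperature(
                sentence, mentions, numbers, ph_bounds, temperature_bounds
            )
        if apply_negation_filter:
            mentions = filter_negated(sentence, mentions)
        tagged.append(TaggedSentence(sentence, list(mentions), numbers))
    return tagged
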