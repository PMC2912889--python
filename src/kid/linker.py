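"""Assembly of kinetic records from tagged sentences.

Each kinetic-parameter mention anchors one record.  Linking proceeds in four
stages, mirroring how the information is usually laid out in an abstract:

1. **direct linkage** — scan rightward from the anchor (the natural reading
   direction), hopping across binding phrases ("of", "for", "was" ...) and
   chaining from each newly linked entity; then run the mirrored scan to the
   left.  The scan stops at the sentence boundary, at a comma not followed by
   a continuation keyword, at a negation phrase, at another kinetic anchor,
   or as soon as a token is neither a binding phrase nor a linkable item.
2. **enumerations** — "A, B and C" runs of one entity category are itemized
   into one record per member; when several equally-largest runs of
   different categories coexist they pair element-wise in textual order.
3. **indirect linkage** — an empty slot is filled when its category has
   exactly one distinct candidate in the sentence, else in the abstract,
   else in the title.  pH, temperature and the numeric value only ever fill
   at sentence level, where the presence/absence of a unit disambiguates
   them from unrelated numbers.
4. **enzyme/EC completion** — a local name<->EC mapping fills whichever of
   the two identifiers is missing, when the mapping is unambiguous.

Every filled slot records how it was filled (its linkage type) and where the
supporting text sits, so each record is auditable down to token spans.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from .lexicon import (
    Category,
    ENTITY_CATEGORIES,
    KINETIC_PARAMETERS,
    normalize_term,
)
from .tagger import Mention, NumericMention, TaggedSentence

DEFAULT_CONTINUATION_KEYWORDS = frozenset({"which", "that"})


class LinkageType(str, Enum):
    DIRECT = "direct"
    INDIRECT_SENTENCE = "indirect_sentence"
    INDIRECT_ABSTRACT = "indirect_abstract"
    INDIRECT_TITLE = "indirect_title"
    LISTING = "listing"
    COMPLETED_LOOKUP = "completed_lookup"


#: entity category -> record attribute
SLOT_OF_CATEGORY: dict[Category, str] = {
    Category.ENZYME_NAME: "enzyme_name",
    Category.EC_NUMBER: "ec_number",
    Category.LIGAND: "ligand",
    Category.ORGANISM: "organism",
    Category.LOCALISATION: "localisation",
}
ENTITY_SLOTS = tuple(SLOT_OF_CATEGORY.values())


@dataclass(frozen=True)
class Slot:
    """A filled entity slot: canonical form, provenance, linkage type."""

    canonical: str
    linkage: LinkageType
    mention: Mention | None = None  # None for completed_lookup


@dataclass(frozen=True)
class NumericSlot:
    number: NumericMention
    linkage: LinkageType


@dataclass
class KineticRecord:
    pmid: str
    kinetic_category: Category
    anchor: Mention
    value: NumericSlot | None = None
    enzyme_name: Slot | None = None
    ec_number: Slot | None = None
    ligand: Slot | None = None
    organism: Slot | None = None
    localisation: Slot | None = None
    ph: NumericSlot | None = None
    temperature: NumericSlot | None = None

    def __post_init__(self) -> None:
        if self.kinetic_category not in KINETIC_PARAMETERS:
            raise ValueError(
                f"{self.kinetic_category} cannot anchor a record"
            )

    def entity_slot(self, category: Category) -> Slot | None:
        return getattr(self, SLOT_OF_CATEGORY[category])


@dataclass(frozen=True)
class EnumerationGroup:
    category: Category
    members: tuple[Mention, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an enumeration needs at least two members")


class EcMap:
    """Bidirectional enzyme-name <-> EC-number mapping from a local TSV."""

    def __init__(self, name_to_ec: Mapping[str, set[str]], ec_to_name: Mapping[str, set[str]]):
        self._name_to_ec = {k: set(v) for k, v in name_to_ec.items()}
        self._ec_to_name = {k: set(v) for k, v in ec_to_name.items()}

    @classmethod
    def load(cls, path: str | Path) -> "EcMap":
        name_to_ec: dict[str, set[str]] = {}
        ec_to_name: dict[str, set[str]] = {}
        text = Path(path).read_text(encoding="utf-8")
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed mapping line {line!r}")
            name = " ".join(normalize_term(parts[0]))
            ec = parts[1].strip().lower()
            name_to_ec.setdefault(name, set()).add(ec)
            ec_to_name.setdefault(ec, set()).add(name)
        return cls(name_to_ec, ec_to_name)

    def ecs_for(self, name: str) -> set[str]:
        return set(self._name_to_ec.get(name, set()))

    def names_for(self, ec: str) -> set[str]:
        return set(self._ec_to_name.get(ec, set()))


def detect_enumerations(ts: TaggedSentence) -> list[EnumerationGroup]:
    """Find comma/conjunction-separated runs of same-category entities."""
    tokens = ts.sentence.tokens
    by_cat: dict[Category, list[Mention]] = {}
    for m in ts.mentions:
        if m.category in ENTITY_CATEGORIES:
            by_cat.setdefault(m.category, []).append(m)

    def gap_ok(a: Mention, b: Mention) -> tuple[bool, bool]:
        """(separator-only gap, gap contains a conjunction)."""
        gap = tokens[a.token_span[1] : b.token_span[0]]
        if not gap:
            return False, False
        norms = {t.norm for t in gap}
        return norms <= {",", "and", "or"}, bool(norms & {"and", "or"})

    groups: list[EnumerationGroup] = []
    for cat, mentions in by_cat.items():
        mentions.sort(key=lambda m: m.token_span)
        run: list[Mention] = []
        runs: list[list[Mention]] = []
        for m in mentions:
            if run:
                ok, _ = gap_ok(run[-1], m)
                if not ok:
                    runs.append(run)
                    run = []
            run.append(m)
        if run:
            runs.append(run)
        for r in runs:
            # the conjunction must sit before the last member kept
            while len(r) >= 2 and not gap_ok(r[-2], r[-1])[1]:
                r.pop()
            if len(r) >= 2:
                groups.append(EnumerationGroup(cat, tuple(r)))
    groups.sort(key=lambda g: g.members[0].token_span)
    return groups


def _item_maps(ts: TaggedSentence):
    """Index mentions/numbers by start and end token position."""
    start: dict[int, object] = {}
    end: dict[int, object] = {}
    for m in ts.mentions:
        start[m.token_span[0]] = m
        end[m.token_span[1]] = m
    for n in ts.numbers:
        start.setdefault(n.token_span[0], n)
        end.setdefault(n.token_span[1], n)
    return start, end


def _fill_number(record: KineticRecord, num: NumericMention, linkage: LinkageType) -> bool:
    if num.tagged_as is Category.PH:
        if record.ph is None:
            record.ph = NumericSlot(num, linkage)
            return True
    elif num.tagged_as is Category.TEMPERATURE:
        if record.temperature is None:
            record.temperature = NumericSlot(num, linkage)
            return True
    elif record.kinetic_category in num.unit_categories and record.value is None:
        record.value = NumericSlot(num, linkage)
        return True
    return False


def link_direct(
    anchor: Mention,
    ts: TaggedSentence,
    continuation_keywords: frozenset[str] = DEFAULT_CONTINUATION_KEYWORDS,
) -> KineticRecord:
    """Right-then-left direct linkage around one kinetic anchor."""
    record = KineticRecord(
        pmid="", kinetic_category=anchor.category, anchor=anchor
    )
    tokens = ts.sentence.tokens
    n = len(tokens)
    start_map, end_map = _item_maps(ts)

    def handle_item(item, direction: int) -> int | None:
        """Link or skip an item; return the next scan position, None to stop."""
        if isinstance(item, Mention):
            span = item.token_span
            nxt = span[1] if direction > 0 else span[0] - 1
            if item.category is Category.BINDING_PHRASE:
                return nxt
            if item.category is Category.NEGATION_PHRASE:
                return None
            if item.category in (Category.PH, Category.TEMPERATURE):
                # the expression's number sits to its right in either scan
                num = start_map.get(span[1])
                if (
                    isinstance(num, NumericMention)
                    and num.tagged_as is item.category
                    and _fill_number(record, num, LinkageType.DIRECT)
                ):
                    return num.token_span[1] if direction > 0 else span[0] - 1
                return nxt  # nothing to link here; skip past
            if item.category in KINETIC_PARAMETERS:
                return None if item is not anchor else nxt
            slot_name = SLOT_OF_CATEGORY[item.category]
            if getattr(record, slot_name) is None:
                setattr(
                    record,
                    slot_name,
                    Slot(item.canonical, LinkageType.DIRECT, item),
                )
            return nxt  # chain from the entity whether linked or skipped
        if isinstance(item, NumericMention):
            _fill_number(record, item, LinkageType.DIRECT)
            return item.token_span[1] if direction > 0 else item.token_span[0] - 1
        return None

    # rightward scan
    pos = anchor.token_span[1]
    while pos < n:
        if tokens[pos].is_punct_comma:
            if pos + 1 < n and tokens[pos + 1].norm in continuation_keywords:
                pos += 2  # step over the comma and its continuation keyword
                continue
            break
        item = start_map.get(pos)
        if item is None:
            break
        nxt = handle_item(item, direction=+1)
        if nxt is None:
            break
        pos = nxt

    # mirrored leftward scan
    pos = anchor.token_span[0] - 1
    while pos >= 0:
        if tokens[pos].is_punct_comma:
            if pos - 1 >= 0 and tokens[pos - 1].norm in continuation_keywords:
                pos -= 2  # mirrored: step over the comma and its keyword
                continue
            break
        item = end_map.get(pos + 1)
        if item is None:
            break
        nxt = handle_item(item, direction=-1)
        if nxt is None:
            break
        pos = nxt

    return record


def link_enumerations(
    record: KineticRecord,
    groups: Sequence[EnumerationGroup],
) -> list[KineticRecord]:
    """Itemize enumerations into one record per member.

    The equally-largest groups pair element-wise in textual order; slots
    filled from single mentions are broadcast unchanged to every itemized
    record.  Entity categories only — kinetic expressions never enumerate.
    """
    if not groups:
        return [record]
    largest = max(len(g.members) for g in groups)
    if largest < 2:
        return [record]
    paired = [g for g in groups if len(g.members) == largest]
    out: list[KineticRecord] = []
    for i in range(largest):
        item = replace(record)
        for g in paired:
            member = g.members[i]
            setattr(
                item,
                SLOT_OF_CATEGORY[g.category],
                Slot(member.canonical, LinkageType.LISTING, member),
            )
        out.append(item)
    return out


def _distinct_candidates(pool: Iterable[Mention], category: Category) -> dict[str, Mention]:
    cands: dict[str, Mention] = {}
    for m in pool:
        if m.category is category and m.canonical not in cands:
            cands[m.canonical] = m
    return cands


def link_indirect(
    record: KineticRecord,
    ts: TaggedSentence,
    abstract_pool: Sequence[Mention],
    title_pool: Sequence[Mention],
) -> KineticRecord:
    """Fill empty slots from the unique candidate at sentence/abstract/title.

    Entity slots walk all three levels; the numeric value, pH and temperature
    are sentence-only (a number outside the anchor sentence cannot be told
    apart from unrelated numbers).
    """
    levels = (
        (ts.mentions, LinkageType.INDIRECT_SENTENCE),
        (abstract_pool, LinkageType.INDIRECT_ABSTRACT),
        (title_pool, LinkageType.INDIRECT_TITLE),
    )
    for category, slot_name in SLOT_OF_CATEGORY.items():
        if getattr(record, slot_name) is not None:
            continue
        for pool, linkage in levels:
            cands = _distinct_candidates(pool, category)
            if len(cands) == 1:
                canonical, mention = next(iter(cands.items()))
                setattr(record, slot_name, Slot(canonical, linkage, mention))
                break

    if record.value is None:
        cands_v = [
            num
            for num in ts.numbers
            if num.tagged_as is None and record.kinetic_category in num.unit_categories
        ]
        if len(cands_v) == 1:
            record.value = NumericSlot(cands_v[0], LinkageType.INDIRECT_SENTENCE)
    if record.ph is None:
        cands_p = [num for num in ts.numbers if num.tagged_as is Category.PH]
        if len(cands_p) == 1:
            record.ph = NumericSlot(cands_p[0], LinkageType.INDIRECT_SENTENCE)
    if record.temperature is None:
        cands_t = [
            num for num in ts.numbers if num.tagged_as is Category.TEMPERATURE
        ]
        if len(cands_t) == 1:
            record.temperature = NumericSlot(cands_t[0], LinkageType.INDIRECT_SENTENCE)
    return record


def complete_enzyme_ec(record: KineticRecord, ec_map: EcMap | None) -> KineticRecord:
    """Fill the missing one of enzyme name / EC number from the local map."""
    if ec_map is None:
        return record
    if record.enzyme_name is not None and record.ec_number is None:
        ecs = ec_map.ecs_for(record.enzyme_name.canonical)
        if len(ecs) == 1:
            record.ec_number = Slot(next(iter(ecs)), LinkageType.COMPLETED_LOOKUP)
    elif record.ec_number is not None and record.enzyme_name is None:
        names = ec_map.names_for(record.ec_number.canonical)
        if len(names) == 1:
            record.enzyme_name = Slot(next(iter(names)), LinkageType.COMPLETED_LOOKUP)
    return record


def link_document(
    pmid: str,
    tagged: Sequence[TaggedSentence],
    ec_map: EcMap | None = None,
    continuation_keywords: frozenset[str] = DEFAULT_CONTINUATION_KEYWORDS,
    enable_indirect: bool = True,
) -> list[KineticRecord]:
    """Run the full linkage cascade over every anchor, in document order."""
    from .preprocess import ABSTRACT, TITLE

    abstract_pool = [m for ts in tagged if ts.sentence.zone == ABSTRACT for m in ts.mentions]
    title_pool = [m for ts in tagged if ts.sentence.zone == TITLE for m in ts.mentions]

    records: list[KineticRecord] = []
    for ts in tagged:
        groups = detect_enumerations(ts)
        anchors = [m for m in ts.mentions if m.category in KINETIC_PARAMETERS]
        for anchor in anchors:
            base = link_direct(anchor, ts, continuation_keywords)
            base.pmid = pmid
            for rec in link_enumerations(base, groups):
                rec.pmid = pmid
                if enable_indirect:
                    rec = link_indirect(rec, ts, abstract_pool, title_pool)
                rec = complete_enzyme_ec(rec, ec_map)
                records.append(rec)
    return records


def check_indirect_uniqueness(
    tagged: Sequence[TaggedSentence], records: Sequence[KineticRecord]
) -> bool:
    """Re-verify that every indirectly filled slot had a unique candidate.

    Recomputes the candidate pools from the tagged sentences; returns True
    when the uniqueness-soundness invariant holds for every record.
    """
    from .preprocess import ABSTRACT, TITLE

    abstract_pool = [m for ts in tagged if ts.sentence.zone == ABSTRACT for m in ts.mentions]
    title_pool = [m for ts in tagged if ts.sentence.zone == TITLE for m in ts.mentions]
    by_ref = {(ts.sentence.zone, ts.sentence.index): ts for ts in tagged}

    for rec in records:
        ts = by_ref[(rec.anchor.zone, rec.anchor.sentence_index)]
        pools = {
            LinkageType.INDIRECT_SENTENCE: ts.mentions,
            LinkageType.INDIRECT_ABSTRACT: abstract_pool,
            LinkageType.INDIRECT_TITLE: title_pool,
        }
        for category, slot_name in SLOT_OF_CATEGORY.items():
            slot: Slot | None = getattr(rec, slot_name)
            if slot is None or slot.linkage not in pools:
                continue
            if len(_distinct_candidates(pools[slot.linkage], category)) != 1:
                return False
        for numeric, pred in (
            (rec.value, lambda n: n.tagged_as is None
             and rec.kinetic_category in n.unit_categories),
            (rec.ph, lambda n: n.tagged_as is Category.PH),
            (rec.temperature, lambda n: n.tagged_as is Category.TEMPERATURE),
        ):
            if numeric is not None and numeric.linkage is LinkageType.INDIRECT_SENTENCE:
                if sum(1 for n in ts.numbers if pred(n)) != 1:
                    return False
    return True
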