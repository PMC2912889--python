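"""Corpus readers, record serialization and debug rendering.

Supported inputs are MEDLINE/PubMed ``PubmedArticleSet`` XML (plain or
gzipped) and a one-object-per-line JSONL of ``{pmid, title, abstract}``.
Records serialize to JSONL (lossless round trip) or a flat TSV; both writers
are deterministic given the same record stream.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from collections.abc import Iterable, Iterator, Sequence
from pathlib import Path

from lxml import etree

from .lexicon import Category
from .linker import (
    ENTITY_SLOTS,
    KineticRecord,
    LinkageType,
    NumericSlot,
    Slot,
)
from .preprocess import ABSTRACT, Document, TITLE
from .tagger import Mention, NumericMention

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# corpus readers

def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rb")
    return open(path, "rb")


def read_medline_xml(path: str | Path) -> Iterator[Document]:
    """Stream documents out of a PubmedArticleSet XML file."""
    with _open_maybe_gzip(path) as fh:
        for _, elem in etree.iterparse(fh, tag="PubmedArticle"):
            pmid = elem.findtext(".//MedlineCitation/PMID") or elem.findtext(".//PMID")
            title = elem.findtext(".//ArticleTitle") or ""
            parts = []
            for node in elem.iterfind(".//Abstract/AbstractText"):
                text = "".join(node.itertext()).strip()
                if text:
                    parts.append(text)
            abstract = ". ".join(parts)
            if pmid is None or not pmid.strip():
                logger.warning("article at line %d has no PMID; skipped", elem.sourceline or -1)
            else:
                yield Document(pmid=pmid.strip(), title=title.strip(), abstract=abstract)
            elem.clear(keep_tail=True)


def read_jsonl(path: str | Path) -> Iterator[Document]:
    """Stream documents from JSONL; malformed lines name their line number."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                yield Document(
                    pmid=str(obj["pmid"]),
                    title=obj.get("title", "") or "",
                    abstract=obj.get("abstract", "") or "",
                )
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: bad JSONL at line {lineno}: {exc}") from exc


def write_jsonl_documents(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {"pmid": doc.pmid, "title": doc.title, "abstract": doc.abstract},
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# record serialization

def _mention_to_dict(m: Mention | None) -> dict | None:
    if m is None:
        return None
    return {
        "category": m.category.value,
        "zone": m.zone,
        "sentence_index": m.sentence_index,
        "token_span": list(m.token_span),
        "char_span": list(m.char_span),
        "surface": m.surface,
        "canonical": m.canonical,
    }


def _mention_from_dict(d: dict | None) -> Mention | None:
    if d is None:
        return None
    return Mention(
        category=Category(d["category"]),
        zone=d["zone"],
        sentence_index=d["sentence_index"],
        token_span=tuple(d["token_span"]),
        char_span=tuple(d["char_span"]),
        surface=d["surface"],
        canonical=d["canonical"],
    )


def _number_to_dict(n: NumericMention) -> dict:
    return {
        "value": n.value,
        "error": n.error,
        "range_high": n.range_high,
        "unit_surface": n.unit_surface,
        "unit_categories": sorted(c.value for c in n.unit_categories),
        "zone": n.zone,
        "sentence_index": n.sentence_index,
        "token_span": list(n.token_span),
        "char_span": list(n.char_span),
        "tagged_as": n.tagged_as.value if n.tagged_as else None,
    }


def _number_from_dict(d: dict) -> NumericMention:
    return NumericMention(
        value=d["value"],
        error=d["error"],
        range_high=d["range_high"],
        unit_surface=d["unit_surface"],
        unit_categories=frozenset(Category(c) for c in d["unit_categories"]),
        zone=d["zone"],
        sentence_index=d["sentence_index"],
        token_span=tuple(d["token_span"]),
        char_span=tuple(d["char_span"]),
        tagged_as=Category(d["tagged_as"]) if d["tagged_as"] else None,
    )


def record_to_dict(rec: KineticRecord) -> dict:
    out: dict = {
        "pmid": rec.pmid,
        "kinetic_category": rec.kinetic_category.value,
        "anchor": _mention_to_dict(rec.anchor),
    }
    for name in ("value", "ph", "temperature"):
        slot: NumericSlot | None = getattr(rec, name)
        out[name] = (
            None
            if slot is None
            else {"number": _number_to_dict(slot.number), "linkage": slot.linkage.value}
        )
    for name in ENTITY_SLOTS:
        slot: Slot | None = getattr(rec, name)
        out[name] = (
            None
            if slot is None
            else {
                "canonical": slot.canonical,
                "linkage": slot.linkage.value,
                "mention": _mention_to_dict(slot.mention),
            }
        )
    return out


def record_from_dict(d: dict) -> KineticRecord:
    rec = KineticRecord(
        pmid=d["pmid"],
        kinetic_category=Category(d["kinetic_category"]),
        anchor=_mention_from_dict(d["anchor"]),
    )
    for name in ("value", "ph", "temperature"):
        v = d.get(name)
        if v is not None:
            setattr(
                rec,
                name,
                NumericSlot(_number_from_dict(v["number"]), LinkageType(v["linkage"])),
            )
    for name in ENTITY_SLOTS:
        v = d.get(name)
        if v is not None:
            setattr(
                rec,
                name,
                Slot(
                    v["canonical"],
                    LinkageType(v["linkage"]),
                    _mention_from_dict(v.get("mention")),
                ),
            )
    return rec


def record_to_flat(rec: KineticRecord) -> dict:
    """Flatten a record to the slot-level schema used by TSV and evaluation."""
    flat: dict = {
        "pmid": rec.pmid,
        "kinetic_category": rec.kinetic_category.value,
        "value": None,
        "error": None,
        "range_high": None,
        "unit": None,
        "value_linkage": None,
        "ph": None,
        "ph_linkage": None,
        "temperature": None,
        "temperature_linkage": None,
    }
    if rec.value is not None:
        flat["value"] = rec.value.number.value
        flat["error"] = rec.value.number.error
        flat["range_high"] = rec.value.number.range_high
        flat["unit"] = rec.value.number.unit_surface.lower() or None
        flat["value_linkage"] = rec.value.linkage.value
    for name in ("ph", "temperature"):
        slot: NumericSlot | None = getattr(rec, name)
        if slot is not None:
            flat[name] = slot.number.value
            flat[f"{name}_linkage"] = slot.linkage.value
    for name in ENTITY_SLOTS:
        slot: Slot | None = getattr(rec, name)
        flat[name] = slot.canonical if slot else None
        flat[f"{name}_linkage"] = slot.linkage.value if slot else None
    return flat


TSV_COLUMNS: tuple[str, ...] = (
    "pmid",
    "kinetic_category",
    "value",
    "error",
    "range_high",
    "unit",
    "value_linkage",
    "enzyme_name",
    "enzyme_name_linkage",
    "ec_number",
    "ec_number_linkage",
    "ligand",
    "ligand_linkage",
    "organism",
    "organism_linkage",
    "localisation",
    "localisation_linkage",
    "ph",
    "ph_linkage",
    "temperature",
    "temperature_linkage",
    "anchor_source",
    "enzyme_name_source",
    "ec_number_source",
    "ligand_source",
    "organism_source",
    "localisation_source",
    "value_source",
    "ph_source",
    "temperature_source",
)


def _source_str(obj) -> str:
    if obj is None:
        return ""
    return f"{obj.zone}:{obj.sentence_index}:{obj.token_span[0]}-{obj.token_span[1]}"


def _tsv_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_records(
    records: Sequence[KineticRecord], path: str | Path, format: str = "jsonl"
) -> None:
    """Write records as JSONL (lossless) or flat TSV (fixed column order)."""
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(record_to_dict(rec), ensure_ascii=False) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown record format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rec in records:
            flat = record_to_flat(rec)
            flat["anchor_source"] = _source_str(rec.anchor)
            for name in ENTITY_SLOTS:
                slot = getattr(rec, name)
                flat[f"{name}_source"] = _source_str(slot.mention if slot else None)
            for name in ("value", "ph", "temperature"):
                slot = getattr(rec, name)
                flat[f"{name}_source"] = _source_str(slot.number if slot else None)
            fh.write("\t".join(_tsv_cell(flat.get(c)) for c in TSV_COLUMNS) + "\n")


def read_records(path: str | Path) -> list[KineticRecord]:
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(record_from_dict(json.loads(line)))
    return records


# ---------------------------------------------------------------------------
# annotated-text rendering

def render_annotated(doc: Document, records: Sequence[KineticRecord]) -> str:
    """Plain-text rendering with bracket tags around every linked span.

    Spans are labelled ``[label:surface]``; overlapping spans nest
    innermost-first.  A per-record legend follows the text.
    """
    spans: set[tuple[str, int, int, str]] = set()

    def add(zone: str, char_span: tuple[int, int], label: str) -> None:
        spans.add((zone, char_span[0], char_span[1], label))

    for rec in records:
        add(rec.anchor.zone, rec.anchor.char_span, rec.kinetic_category.value)
        for name in ENTITY_SLOTS:
            slot: Slot | None = getattr(rec, name)
            if slot is not None and slot.mention is not None:
                add(slot.mention.zone, slot.mention.char_span, name)
        for name in ("value", "ph", "temperature"):
            nslot: NumericSlot | None = getattr(rec, name)
            if nslot is not None:
                add(nslot.number.zone, nslot.number.char_span, name)

    def mark_zone(zone: str, text: str) -> str:
        markers: list[tuple[int, int, int, str]] = []
        for z, start, end, label in spans:
            if z != zone:
                continue
            markers.append((start, 1, -end, f"[{label}:"))
            markers.append((end, 0, -start, "]"))
        markers.sort()
        out = io.StringIO()
        last = 0
        for pos, _prio, _tie, s in markers:
            out.write(text[last:pos])
            out.write(s)
            last = pos
        out.write(text[last:])
        return out.getvalue()

    lines = [mark_zone(TITLE, doc.title), "", mark_zone(ABSTRACT, doc.abstract)]
    if records:
        lines.append("")
        for i, rec in enumerate(records):
            flat = record_to_flat(rec)
            parts = [f"{rec.kinetic_category.value}"]
            for name in ("value", *ENTITY_SLOTS, "ph", "temperature"):
                if flat.get(name) is not None:
                    parts.append(f"{name}={flat[name]} ({flat[name + '_linkage']})")
            lines.append(f"# record {i}: " + "; ".join(parts))
    return "\n".join(lines)
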