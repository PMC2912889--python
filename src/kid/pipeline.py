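"""End-to-end extraction: preprocess -> tag -> link."""

from __future__ import annotations

from collections.abc import Iterable, Iterator

from .linker import KineticRecord, link_document
from .preprocess import Document, preprocess_document
from .resources import Resources, default_resources
from .tagger import TaggedSentence, tag_document


def analyze_document(
    doc: Document,
    resources: Resources,
    apply_negation_filter: bool = True,
    enable_indirect: bool = True,
) -> tuple[list[TaggedSentence], list[KineticRecord]]:
    """Run the full pipeline on one document, keeping the tagging stage.

    The ablation switches exist for evaluation experiments: disabling the
    negation filter or the indirect linkage shows what each rule buys.
    """
    sentences = preprocess_document(doc, resources.abbreviations)
    tagged = tag_document(
        sentences,
        resources.trie,
        resources.units,
        ph_bounds=resources.ph_bounds,
        temperature_bounds=resources.temperature_bounds,
        apply_negation_filter=apply_negation_filter,
    )
    records = link_document(
        doc.pmid,
        tagged,
        ec_map=resources.ec_map,
        continuation_keywords=resources.continuation_keywords,
        enable_indirect=enable_indirect,
    )
    return tagged, records


def mine_document(doc: Document, resources: Resources | None = None) -> list[KineticRecord]:
    resources = resources if resources is not None else default_resources()
    return analyze_document(doc, resources)[1]


def mine_corpus(
    docs: Iterable[Document], resources: Resources | None = None
) -> Iterator[tuple[Document, list[KineticRecord]]]:
    """Stream extraction over a corpus; one document resident at a time."""
    resources = resources if resources is not None else default_resources()
    for doc in docs:
        yield doc, analyze_document(doc, resources)[1]
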