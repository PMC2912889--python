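"""Direct linkage, enumerations, indirect linkage and EC completion."""

from __future__ import annotations

import pytest

from kid import Document, analyze_document
from kid.corpus_io import record_to_flat
from kid.linker import EcMap


def test_direct_chain_links_value_ligand_enzyme(extract_flat):
    recs = extract_flat("The K(m) of hexokinase for glucose was 0.05 mM.")
    assert len(recs) == 1
    r = recs[0]
    assert r["kinetic_category"] == "K_M"
    assert (r["value"], r["unit"], r["value_linkage"]) == (0.05, "mm", "direct")
    assert (r["enzyme_name"], r["enzyme_name_linkage"]) == ("hexokinase", "direct")
    assert (r["ligand"], r["ligand_linkage"]) == ("glucose", "direct")


def test_comma_stops_direct_scan(extract_flat):
    # urease sits behind a comma without a continuation keyword: only the
    # sentence-level indirect mechanism may still reach it
    recs = extract_flat("The K(m) was 0.05 mM, and urease was present.")
    assert recs[0]["enzyme_name_linkage"] == "indirect_sentence"


def test_continuation_keyword_lets_scan_cross_comma(extract_flat):
    recs = extract_flat("The K(m) of hexokinase, which for glucose was 0.05 mM.")
    r = recs[0]
    assert r["ligand"] == "glucose"
    assert r["ligand_linkage"] == "direct"


def test_anchor_at_sentence_end_links_nothing_rightward(extract_flat):
    recs = extract_flat("Our study reports a Michaelis constant.")
    r = recs[0]
    assert r["value"] is None and r["ligand"] is None


def test_enumeration_pairs_equally_largest_groups(extract_flat):
    recs = extract_flat(
        "The k(m) was determined for enzyme a and enzyme b "
        "with ligand c and ligand d."
    )
    pairs = [(r["enzyme_name"], r["ligand"], r["ligand_linkage"]) for r in recs]
    assert pairs == [
        ("enzyme a", "ligand c", "listing"),
        ("enzyme b", "ligand d", "listing"),
    ]


def test_itemization_broadcasts_singletons(extract_flat):
    recs = extract_flat(
        "The k(m) of hexokinase for ATP, GTP and CTP was measured."
    )
    assert [(r["enzyme_name"], r["enzyme_name_linkage"]) for r in recs] == [
        ("hexokinase", "direct")
    ] * 3
    assert [(r["ligand"], r["ligand_linkage"]) for r in recs] == [
        ("atp", "listing"),
        ("gtp", "listing"),
        ("ctp", "listing"),
    ]


def test_plain_pair_without_conjunction_is_not_an_enumeration(extract_flat):
    recs = extract_flat("The k(m) of hexokinase for ATP was 1 mM.")
    assert len(recs) == 1


def test_indirect_levels_sentence_abstract_title(extract_flat):
    # sentence level: unique enzyme behind a comma
    recs = extract_flat("The K(i) was 2 mM, a value typical of trypsin.")
    assert (recs[0]["enzyme_name"], recs[0]["enzyme_name_linkage"]) == (
        "trypsin",
        "indirect_sentence",
    )
    # abstract level: enzyme in another sentence
    recs = extract_flat("The K(i) was 2 mM. Purified trypsin was used throughout.")
    assert recs[0]["enzyme_name_linkage"] == "indirect_abstract"
    # title level: organism only in the title
    recs = extract_flat(
        "The K(i) of trypsin was 2 mM.", title="Kinetic studies in rat."
    )
    assert (recs[0]["organism"], recs[0]["organism_linkage"]) == (
        "rat",
        "indirect_title",
    )


def test_two_abstract_level_organisms_leave_slot_unfilled(extract_flat):
    recs = extract_flat(
        "The K(m) of hexokinase was 0.05 mM. "
        "Material came from escherichia coli and from xenopus.",
        title="Enzyme kinetics.",
    )
    assert recs[0]["organism"] is None


def test_repeated_identical_candidate_still_counts_as_unique(extract_flat):
    recs = extract_flat(
        "The K(m) of hexokinase was 0.05 mM. "
        "Samples of rat tissue were compared with further rat material."
    )
    assert (recs[0]["organism"], recs[0]["organism_linkage"]) == (
        "rat",
        "indirect_abstract",
    )


def test_ph_temperature_sentence_level_only(extract_flat):
    recs = extract_flat(
        "The K(m) of hexokinase was 0.05 mM. Buffers were adjusted at pH 7.4."
    )
    assert recs[0]["ph"] is None  # pH in another sentence never links
    recs = extract_flat("The K(m) of hexokinase was 0.05 mM at pH 7.4.")
    assert (recs[0]["ph"], recs[0]["ph_linkage"]) == (7.4, "direct")


def test_value_indirect_within_sentence(extract_flat):
    recs = extract_flat("The K(m) for hexokinase equalled exactly 0.05 mM overall.")
    assert (recs[0]["value"], recs[0]["value_linkage"]) == (0.05, "indirect_sentence")


def test_ec_completion_unique_and_ambiguous(extract_flat):
    r = extract_flat("The K(m) of hexokinase was 0.05 mM.")[0]
    assert (r["ec_number"], r["ec_number_linkage"]) == ("2.7.1.1", "completed_lookup")
    r = extract_flat("The K(m) of amylase was 0.05 mM.")[0]
    assert r["ec_number"] is None  # amylase maps to two EC numbers


def test_ec_to_name_completion(extract_flat):
    r = extract_flat("The K(m) of 2.7.1.1 was 0.05 mM.")[0]
    assert (r["enzyme_name"], r["enzyme_name_linkage"]) == (
        "hexokinase",
        "completed_lookup",
    )
    assert r["ec_number"] == "2.7.1.1"


def test_malformed_ec_map_is_hard_error(tmp_path):
    bad = tmp_path / "map.tsv"
    bad.write_text("hexokinase\t2.7.1.1\nbroken-line-without-tab\n")
    with pytest.raises(ValueError, match="map.tsv:2"):
        EcMap.load(bad)


def test_record_count_at_least_anchor_count(extract, resources):
    tagged, recs = extract(
        "The K(m) of hexokinase was 0.05 mM. The K(i) for ATP was 2 mM."
    )
    from kid.lexicon import KINETIC_PARAMETERS

    anchors = sum(
        1
        for ts in tagged
        for m in ts.mentions
        if m.category in KINETIC_PARAMETERS
    )
    assert anchors == 2
    assert len(recs) >= anchors


def test_no_kinetic_expression_no_records(extract):
    _, recs = extract("Cells were grown overnight in rich medium.")
    assert recs == []


def test_monotonicity_extra_organism_only_removes_or_keeps(resources):
    base = Document(
        pmid="1",
        title="Enzyme kinetics.",
        abstract="The K(m) of hexokinase was 0.05 mM. The enzyme came from rat.",
    )
    _, recs = analyze_document(base, resources)
    before = record_to_flat(recs[0])["organism"]
    assert before == "rat"
    extended = Document(
        pmid="1",
        title=base.title,
        abstract=base.abstract + " Comparable data exist for xenopus.",
    )
    _, recs2 = analyze_document(extended, resources)
    after = record_to_flat(recs2[0])["organism"]
    assert after in (before, None)
    assert after is None  # two abstract-level organisms -> unfilled


def test_determinism_byte_identical_record_stream(resources, tmp_path):
    from kid.corpus_io import write_records

    doc = Document(
        pmid="1",
        title="Characterization of hexokinase.",
        abstract="The K(m) of hexokinase for ATP, GTP and CTP was 0.05 mM at pH 7.0.",
    )
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    write_records(analyze_document(doc, resources)[1], p1)
    write_records(analyze_document(doc, resources)[1], p2)
    assert p1.read_bytes() == p2.read_bytes()
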