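"""Dictionary loading, ambiguity resolution and the token trie."""

from __future__ import annotations

import random

import pytest

from kid.lexicon import (
    AmbiguityPolicy,
    Category,
    LexiconEntry,
    build_trie,
    load_lexicon,
    normalize_term,
)

from conftest import (
    brute_force_leftmost_longest,
    random_dictionary,
    random_token_sequence,
)


@pytest.mark.parametrize(
    "surface,tokens",
    [
        ("Michaelis constant", ("michaelis", "constant")),
        ("K(m)", ("k(m)",)),
        ("Glucose 6- Phosphate", ("glucose", "6-", "phosphate")),
    ],
)
def test_normalize_term(surface, tokens):
    assert normalize_term(surface) == tokens


@pytest.mark.parametrize("surface", ["", "   ", "\t"])
def test_blank_terms_normalize_to_empty(surface):
    assert normalize_term(surface) == ()


def _write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return p


def test_load_lexicon_excludes_cross_category_acronym(tmp_path):
    """A term in the exclusion list vanishes from every category."""
    paths = {
        Category.ENZYME_NAME: _write(tmp_path, "e.txt", ["IPP", "hexokinase"]),
        Category.LIGAND: _write(tmp_path, "l.txt", ["IPP", "atp"]),
    }
    entries = load_lexicon(paths, AmbiguityPolicy())
    surfaces = {(e.category, " ".join(e.tokens)) for e in entries}
    assert (Category.ENZYME_NAME, "ipp") not in surfaces
    assert (Category.LIGAND, "ipp") not in surfaces
    assert (Category.LIGAND, "atp") in surfaces


def test_load_lexicon_priority_keeps_one_category(tmp_path):
    paths = {
        Category.ORGANISM: _write(tmp_path, "o.txt", ["chicken"]),
        Category.LOCALISATION: _write(tmp_path, "t.txt", ["chicken", "liver"]),
    }
    entries = load_lexicon(paths, AmbiguityPolicy())
    cats = {e.category for e in entries if e.tokens == ("chicken",)}
    assert cats == {Category.ORGANISM}  # organism outranks localisation
    assert any(e.tokens == ("liver",) for e in entries)


def test_load_lexicon_deduplicates_and_keeps_canonical(tmp_path):
    paths = {
        Category.LIGAND: _write(
            tmp_path, "l.txt", ["ATP\tadenosine triphosphate", "ATP", "# comment", ""]
        )
    }
    entries = load_lexicon(paths, AmbiguityPolicy())
    assert len(entries) == 1
    assert entries[0].canonical == "adenosine triphosphate"


def test_load_lexicon_missing_file_is_hard_error(tmp_path):
    with pytest.raises(OSError, match="nowhere.txt"):
        load_lexicon({Category.LIGAND: tmp_path / "nowhere.txt"}, AmbiguityPolicy())


def _entry(surface, category):
    tokens = normalize_term(surface)
    return LexiconEntry(surface, tokens, category, " ".join(tokens))


def test_trie_shared_prefix_with_distinct_flags():
    trie = build_trie(
        [
            _entry("glucose phosphatase", Category.ENZYME_NAME),
            _entry("glucose 6- phosphate", Category.LIGAND),
        ]
    )
    assert trie.lookup_longest(["glucose", "6-", "phosphate"], 0) == (
        3,
        Category.LIGAND,
        "glucose 6- phosphate",
    )
    assert trie.lookup_longest(["glucose", "phosphatase"], 0)[:2] == (
        2,
        Category.ENZYME_NAME,
    )


def test_trie_falls_back_to_last_flagged_prefix():
    trie = build_trie(
        [
            _entry("glucose", Category.LIGAND),
            _entry("glucose phosphatase", Category.ENZYME_NAME),
        ]
    )
    # the walk continues to "kinase-like" territory and must fall back
    hit = trie.lookup_longest(["glucose", "kinase-like", "domain"], 0)
    assert hit == (1, Category.LIGAND, "glucose")


def test_trie_no_match_and_bad_start():
    trie = build_trie([_entry("atp", Category.LIGAND)])
    assert trie.lookup_longest(["gdp", "atp"], 0) is None
    with pytest.raises(IndexError):
        trie.lookup_longest(["atp"], 5)


def test_trie_roundtrip_and_order_independence():
    rng = random.Random(42)
    entries = random_dictionary(rng, max_entries=50)
    trie = build_trie(entries)
    shuffled = entries[:]
    rng.shuffle(shuffled)
    trie2 = build_trie(shuffled)
    for e in entries:
        for t in (trie, trie2):
            hit = t.lookup_longest(list(e.tokens), 0)
            assert hit is not None
            assert hit.length >= len(e.tokens) or (
                hit.length == len(e.tokens) and hit.category is e.category
            )
            # inside a sentence consisting only of the entry, the full entry
            # is retrieved with its own category
            exact = t.lookup_longest(list(e.tokens), 0)
            assert exact.length == len(e.tokens)
            assert exact.category is e.category


def test_one_category_invariant_after_load(tmp_path):
    paths = {
        Category.ENZYME_NAME: _write(tmp_path, "e.txt", ["alpha beta", "gamma"]),
        Category.LIGAND: _write(tmp_path, "l.txt", ["alpha beta", "delta"]),
        Category.ORGANISM: _write(tmp_path, "o.txt", ["gamma", "delta gamma"]),
    }
    entries = load_lexicon(paths, AmbiguityPolicy())
    by_tokens: dict[tuple, set] = {}
    for e in entries:
        by_tokens.setdefault(e.tokens, set()).add(e.category)
    assert all(len(cats) == 1 for cats in by_tokens.values())


def test_greedy_scan_matches_brute_force_oracle():
    """Greedy trie tagging equals leftmost-longest non-overlapping matching."""
    rng = random.Random(2024)
    for _ in range(300):
        entries = random_dictionary(rng)
        tokens = random_token_sequence(rng)
        trie = build_trie(entries)
        greedy = []
        i = 0
        while i < len(tokens):
            hit = trie.lookup_longest(tokens, i) if tokens else None
            if hit is None:
                i += 1
                continue
            greedy.append((i, hit.length, hit.category))
            i += hit.length
        assert greedy == brute_force_leftmost_longest(entries, tokens)
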