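"""Shared fixtures: default resources, tiny lexicons, brute-force oracle."""

from __future__ import annotations

import random

import pytest

from kid import Category, Document, LexiconEntry, analyze_document, default_resources
from kid.corpus_io import record_to_flat


@pytest.fixture(scope="session")
def resources():
    return default_resources()


@pytest.fixture()
def extract(resources):
    """Run the pipeline on title/abstract text, returning (tagged, records)."""

    def _run(abstract: str, title: str = "Untitled study.", **kwargs):
        doc = Document(pmid="1", title=title, abstract=abstract)
        return analyze_document(doc, resources, **kwargs)

    return _run


@pytest.fixture()
def extract_flat(extract):
    def _run(abstract: str, title: str = "Untitled study.", **kwargs):
        _, recs = extract(abstract, title, **kwargs)
        return [record_to_flat(r) for r in recs]

    return _run


# ---------------------------------------------------------------------------
# independent oracle for longest-match tagging

_ALPHABET = ("alpha", "beta", "gamma", "delta", "eps", "zeta")
_CATEGORIES = (
    Category.ENZYME_NAME,
    Category.LIGAND,
    Category.ORGANISM,
    Category.LOCALISATION,
)


def random_dictionary(rng: random.Random, max_entries: int = 50, max_len: int = 5):
    """Random one-category-per-sequence dictionary over a tiny token alphabet."""
    seen: dict[tuple[str, ...], Category] = {}
    for _ in range(rng.randint(1, max_entries)):
        tokens = tuple(
            rng.choice(_ALPHABET) for _ in range(rng.randint(1, max_len))
        )
        if tokens not in seen:
            seen[tokens] = rng.choice(_CATEGORIES)
    return [
        LexiconEntry(
            surface=" ".join(tokens), tokens=tokens, category=cat,
            canonical=" ".join(tokens),
        )
        for tokens, cat in seen.items()
    ]


def random_token_sequence(rng: random.Random, max_len: int = 60) -> list[str]:
    return [rng.choice(_ALPHABET) for _ in range(rng.randint(0, max_len))]


def brute_force_leftmost_longest(entries, tokens):
    """Enumerate all (start, entry) matches; select leftmost-longest greedily.

    Deliberately independent of the trie: a quadratic scan over every entry
    at every start position.
    """
    matches = []
    for start in range(len(tokens)):
        for e in entries:
            L = len(e.tokens)
            if tuple(tokens[start:start + L]) == e.tokens:
                matches.append((start, L, e.category))
    chosen = []
    cursor = 0
    while True:
        viable = [m for m in matches if m[0] >= cursor]
        if not viable:
            break
        s = min(m[0] for m in viable)
        best = max((m for m in viable if m[0] == s), key=lambda m: m[1])
        chosen.append(best)
        cursor = s + best[1]
    return chosen
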