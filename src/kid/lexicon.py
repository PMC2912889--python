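"""Category dictionaries and the longest-match token trie.

Dictionaries are plain-text term lists, one per category.  Every entry is
lowercased and tokenized with the shared document tokenizer, then indexed in
a token-keyed trie whose terminal nodes carry category flags: tagging walks
the trie token by token and accepts the longest prefix that ends on a
flagged node, falling back to the last flagged node seen when the walk runs
past it.

Because one surface form can belong to exactly one category, cross-category
duplicates are resolved by an explicit, deterministic :class:`AmbiguityPolicy`
(a priority ordering plus an exclusion list of forms dropped outright).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import NamedTuple

from .preprocess import tokenize

logger = logging.getLogger(__name__)


class Category(str, Enum):
    """Every dictionary category, grouped into entity/kinetic/unit/control."""

    ENZYME_NAME = "enzyme_name"
    EC_NUMBER = "ec_number"
    LIGAND = "ligand"
    ORGANISM = "organism"
    LOCALISATION = "localisation"

    KM = "K_M"
    KI = "K_i"
    KCAT = "k_cat"
    KCAT_OVER_KM = "k_cat/K_M"
    VMAX = "V_max"
    IC50 = "IC_50"
    S_HALF = "S_0.5"
    KD = "K_d"
    KA = "K_a"
    T_HALF = "t_1/2"
    PI = "pI"
    N_H = "n_H"
    SPECIFIC_ACTIVITY = "specific_activity"
    VMAX_OVER_KM = "V_max/K_M"
    PH = "pH"
    TEMPERATURE = "temperature"

    UNIT_CONCENTRATION = "unit_concentration"
    UNIT_KCAT = "unit_k_cat"
    UNIT_KCAT_OVER_KM = "unit_k_cat/K_M"
    UNIT_T_HALF = "unit_t_1/2"
    UNIT_VMAX = "unit_V_max"
    UNIT_SPECIFIC_ACTIVITY = "unit_specific_activity"
    UNIT_VMAX_OVER_KM = "unit_V_max/K_M"
    UNIT_KA = "unit_K_a"
    UNIT_TEMPERATURE = "unit_temperature"
    UNIT_OTHER = "unit_other"

    BINDING_PHRASE = "binding_phrase"
    NEGATION_PHRASE = "negation_phrase"

    @property
    def group(self) -> str:
        if self in ENTITY_CATEGORIES:
            return "entity"
        if self in KINETIC_CATEGORIES:
            return "kinetic"
        if self in CONTROL_CATEGORIES:
            return "control"
        return "unit"


ENTITY_CATEGORIES = frozenset(
    {
        Category.ENZYME_NAME,
        Category.EC_NUMBER,
        Category.LIGAND,
        Category.ORGANISM,
        Category.LOCALISATION,
    }
)

#: The fourteen kinetic parameter categories that anchor record assembly.
KINETIC_PARAMETERS = frozenset(
    {
        Category.KM,
        Category.KI,
        Category.KCAT,
        Category.KCAT_OVER_KM,
        Category.VMAX,
        Category.IC50,
        Category.S_HALF,
        Category.KD,
        Category.KA,
        Category.T_HALF,
        Category.PI,
        Category.N_H,
        Category.SPECIFIC_ACTIVITY,
        Category.VMAX_OVER_KM,
    }
)

#: pH and temperature are context-number categories: their expressions gate
#: number recognition like any kinetic expression, but they fill context
#: slots rather than anchoring records.
KINETIC_CATEGORIES = KINETIC_PARAMETERS | {Category.PH, Category.TEMPERATURE}

CONTROL_CATEGORIES = frozenset({Category.BINDING_PHRASE, Category.NEGATION_PHRASE})

#: Categories a unit-less number may belong to.
BARE_NUMBER_CATEGORIES = frozenset(
    {Category.PH, Category.TEMPERATURE, Category.PI, Category.N_H}
)


def normalize_term(surface: str) -> tuple[str, ...]:
    """Lowercase and tokenize a dictionary term with the shared tokenizer.

    Returns an empty tuple for blank input (the caller rejects such entries).
    """
    if not surface or not surface.strip():
        return ()
    return tuple(t.norm for t in tokenize(surface))


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    tokens: tuple[str, ...]
    category: Category
    canonical: str

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("LexiconEntry requires a non-empty token sequence")


_DEFAULT_PRIORITY: tuple[Category, ...] = (
    # kinetic expressions first: a term written as a parameter symbol is
    # almost always meant as one
    Category.KM,
    Category.KI,
    Category.KCAT,
    Category.KCAT_OVER_KM,
    Category.VMAX,
    Category.IC50,
    Category.S_HALF,
    Category.KD,
    Category.KA,
    Category.T_HALF,
    Category.PI,
    Category.N_H,
    Category.SPECIFIC_ACTIVITY,
    Category.VMAX_OVER_KM,
    Category.PH,
    Category.TEMPERATURE,
    Category.EC_NUMBER,
    Category.ENZYME_NAME,
    Category.LIGAND,
    Category.ORGANISM,
    Category.LOCALISATION,
    Category.UNIT_CONCENTRATION,
    Category.UNIT_KCAT,
    Category.UNIT_KCAT_OVER_KM,
    Category.UNIT_T_HALF,
    Category.UNIT_VMAX,
    Category.UNIT_SPECIFIC_ACTIVITY,
    Category.UNIT_VMAX_OVER_KM,
    Category.UNIT_KA,
    Category.UNIT_TEMPERATURE,
    Category.UNIT_OTHER,
    Category.NEGATION_PHRASE,
    Category.BINDING_PHRASE,
)

#: Acronyms too ambiguous to keep at all: an enzyme/ligand homonym, two
#: parameter symbols doubling as compound acronyms, and a parameter symbol
#: used as a rat-strain name.
DEFAULT_EXCLUSIONS = frozenset({("ipp",), ("ka",), ("ki",), ("km",)})


@dataclass(frozen=True)
class AmbiguityPolicy:
    """Deterministic one-term-one-category resolution."""

    priority: tuple[Category, ...] = _DEFAULT_PRIORITY
    exclusions: frozenset[tuple[str, ...]] = DEFAULT_EXCLUSIONS

    def resolve(
        self, tokens: tuple[str, ...], categories: Iterable[Category]
    ) -> Category | None:
        """Pick the single surviving category for ``tokens``, or None to drop."""
        if tokens in self.exclusions:
            return None
        cats = set(categories)
        for cat in self.priority:
            if cat in cats:
                return cat
        # categories outside the priority list: deterministic fallback
        return min(cats, key=lambda c: c.value) if cats else None


class TrieMatch(NamedTuple):
    length: int
    category: Category
    canonical: str


class _Node:
    __slots__ = ("children", "entries")

    def __init__(self) -> None:
        self.children: dict[str, _Node] = {}
        self.entries: dict[Category, str] = {}  # category -> canonical form

    @property
    def flags(self) -> set[Category]:
        return set(self.entries)


class TokenTrie:
    """Token-keyed trie with category flags on terminal nodes."""

    def __init__(self) -> None:
        self._root = _Node()
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def insert(self, entry: LexiconEntry) -> None:
        node = self._root
        for tok in entry.tokens:
            node = node.children.setdefault(tok, _Node())
        if entry.category not in node.entries:
            self._size += 1
        node.entries[entry.category] = entry.canonical

    def categories_for(self, tokens: Sequence[str]) -> set[Category]:
        node = self._root
        for tok in tokens:
            nxt = node.children.get(tok)
            if nxt is None:
                return set()
            node = nxt
        return node.flags

    def lookup_longest(self, tokens: Sequence[str], start: int) -> TrieMatch | None:
        """Longest flagged prefix of ``tokens[start:]``.

        The walk may run beyond the last flagged node (e.g. into a longer
        dictionary phrase that is not completed in the text); in that case
        the longest flagged prefix seen along the walk is returned.
        """
        if not 0 <= start < len(tokens):
            raise IndexError(f"start {start} out of range for {len(tokens)} tokens")
        node = self._root
        best: TrieMatch | None = None
        depth = 0
        for i in range(start, len(tokens)):
            nxt = node.children.get(tokens[i])
            if nxt is None:
                break
            node = nxt
            depth += 1
            if node.entries:
                if len(node.entries) == 1:
                    cat, canon = next(iter(node.entries.items()))
                else:  # pre-resolution tries: deterministic pick
                    cat = min(node.entries, key=lambda c: c.value)
                    canon = node.entries[cat]
                best = TrieMatch(depth, cat, canon)
        return best


def build_trie(entries: Iterable[LexiconEntry]) -> TokenTrie:
    """Index ambiguity-resolved entries; insertion order is irrelevant."""
    trie = TokenTrie()
    for entry in sorted(entries, key=lambda e: (e.tokens, e.category.value)):
        trie.insert(entry)
    return trie


def _parse_lexicon_file(path: Path, category: Category) -> list[LexiconEntry]:
    entries: list[LexiconEntry] = []
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot read lexicon file {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        surface = parts[0].strip()
        canonical = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
        tokens = normalize_term(surface)
        if not tokens:
            logger.warning("%s:%d: empty term rejected", path, lineno)
            continue
        entries.append(
            LexiconEntry(
                surface=surface,
                tokens=tokens,
                category=category,
                canonical=canonical if canonical is not None else " ".join(tokens),
            )
        )
    return entries


def load_lexicon(
    paths: Mapping[Category, Sequence[str | Path] | str | Path],
    policy: AmbiguityPolicy | None = None,
) -> list[LexiconEntry]:
    """Load per-category term files and apply the one-category rule.

    ``paths`` maps each category to one file or a list of files.  Duplicates
    within a category are silently deduplicated (count logged); token
    sequences found in more than one category keep exactly the category the
    policy selects, or vanish entirely when excluded.
    """
    policy = policy or AmbiguityPolicy()
    per_seq: dict[tuple[str, ...], dict[Category, LexiconEntry]] = {}
    for category, spec in paths.items():
        files = [spec] if isinstance(spec, (str, Path)) else list(spec)
        dupes = 0
        for f in files:
            for entry in _parse_lexicon_file(Path(f), category):
                bucket = per_seq.setdefault(entry.tokens, {})
                if category in bucket:
                    dupes += 1
                else:
                    bucket[category] = entry
        if dupes:
            logger.info("%s: %d duplicate terms deduplicated", category.value, dupes)

    resolved: list[LexiconEntry] = []
    dropped = 0
    for tokens, bucket in per_seq.items():
        keep = policy.resolve(tokens, bucket.keys())
        if keep is None or keep not in bucket:
            dropped += 1
            continue
        if len(bucket) > 1:
            logger.info(
                "ambiguous term %r kept as %s (candidates: %s)",
                " ".join(tokens),
                keep.value,
                ",".join(sorted(c.value for c in bucket)),
            )
        resolved.append(bucket[keep])
    if dropped:
        logger.info("%d ambiguous/excluded terms dropped", dropped)
    counts: dict[str, int] = {}
    for e in resolved:
        counts[e.category.value] = counts.get(e.category.value, 0) + 1
    logger.info("lexicon loaded: %s", counts)
    return sorted(resolved, key=lambda e: (e.category.value, e.tokens))
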