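"""Loading of dictionaries, units and settings from a manifest file.

A manifest is a single TOML file naming one term file per category plus the
tunable settings (abbreviation list, continuation keywords, pH/temperature
plausibility bounds, optional enzyme<->EC mapping).  ``default_resources``
loads the toy lexicons shipped with the package.

Trie categories (entities, kinetic expressions, control phrases) pass
through the one-term-one-category ambiguity resolution.  Unit lists are
loaded directly into the :class:`~kid.tagger.UnitTable` instead: a unit may
legitimately vouch for several kinetic categories (the same rate unit
serves V_max and specific activity), so the exclusivity rule that governs
tagging flags does not apply to them.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

from .lexicon import (
    AmbiguityPolicy,
    Category,
    DEFAULT_EXCLUSIONS,
    LexiconEntry,
    TokenTrie,
    _parse_lexicon_file,
    build_trie,
    load_lexicon,
    normalize_term,
)
from .linker import DEFAULT_CONTINUATION_KEYWORDS, EcMap
from .preprocess import DEFAULT_ABBREVIATIONS
from .tagger import UnitTable


@dataclass
class Resources:
    """Everything the pipeline needs besides the documents themselves."""

    entries: list[LexiconEntry]
    trie: TokenTrie
    units: UnitTable
    policy: AmbiguityPolicy = field(default_factory=AmbiguityPolicy)
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
    continuation_keywords: frozenset[str] = DEFAULT_CONTINUATION_KEYWORDS
    ph_bounds: tuple[float, float] = (0.0, 14.0)
    temperature_bounds: tuple[float, float] = (-80.0, 150.0)
    ec_map: EcMap | None = None

    def entries_for(self, category: Category) -> list[LexiconEntry]:
        return [e for e in self.entries if e.category is category]


def _category(key: str) -> Category:
    try:
        return Category(key)
    except ValueError as exc:
        raise ValueError(f"unknown lexicon category {key!r} in manifest") from exc


def load_manifest(path: str | Path) -> Resources:
    """Build :class:`Resources` from a manifest TOML file."""
    path = Path(path)
    with path.open("rb") as fh:
        cfg = tomllib.load(fh)
    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    ambiguity = cfg.get("ambiguity", {})
    exclusions = frozenset(
        normalize_term(t) for t in ambiguity.get("exclusions", [])
    ) or DEFAULT_EXCLUSIONS
    if "priority" in ambiguity:
        priority = tuple(_category(c) for c in ambiguity["priority"])
    else:
        priority = AmbiguityPolicy().priority
    policy = AmbiguityPolicy(priority=priority, exclusions=frozenset(exclusions))

    lex_paths = {
        _category(k): resolve(v) for k, v in cfg.get("lexicons", {}).items()
    }
    entries = load_lexicon(lex_paths, policy)
    trie = build_trie(entries)

    unit_entries: list[LexiconEntry] = []
    for k, v in cfg.get("units", {}).items():
        unit_entries.extend(_parse_lexicon_file(resolve(v), _category(k)))
    units = UnitTable.from_entries(unit_entries)

    settings = cfg.get("settings", {})
    abbreviations = frozenset(
        a.lower() for a in settings.get("abbreviations", DEFAULT_ABBREVIATIONS)
    )
    continuation = frozenset(
        settings.get("continuation_keywords", DEFAULT_CONTINUATION_KEYWORDS)
    )
    ph_bounds = tuple(settings.get("ph_bounds", (0.0, 14.0)))
    temperature_bounds = tuple(settings.get("temperature_bounds", (-80.0, 150.0)))
    ec_map = None
    if settings.get("ec_map"):
        ec_map = EcMap.load(resolve(settings["ec_map"]))

    return Resources(
        entries=entries,
        trie=trie,
        units=units,
        policy=policy,
        abbreviations=abbreviations,
        continuation_keywords=continuation,
        ph_bounds=ph_bounds,  # type: ignore[arg-type]
        temperature_bounds=temperature_bounds,  # type: ignore[arg-type]
        ec_map=ec_map,
    )


def default_manifest_path() -> Path:
    return Path(str(importlib_resources.files("kid") / "data" / "manifest.toml"))


def default_resources() -> Resources:
    """Resources built from the fixture lexicons shipped with the package."""
    return load_manifest(default_manifest_path())
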