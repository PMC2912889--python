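"""Synthetic gold-annotated corpora and precision/recall scoring.

The generator emits abstracts built from the sentence shapes the extraction
rules target: direct chains of binding phrases, enumerations, facts spread
over sentence/abstract/title levels, negated ligand clauses, distractor
sentences, and ambiguous-acronym traps (a dictionary homonym used in the
text with its other meaning, the classic false-positive source of
dictionary-based tagging).  Every document carries the records a perfect
extractor should emit, including the linkage type of each slot, so the
whole pipeline can be scored without any external annotation.

Scoring is slot-level: records are aligned by (pmid, kinetic category,
document order) and each slot contributes TP/FP/FN to its own category,
mirroring per-category precision/recall evaluation.  Precision with zero
predictions is reported as 1.0 with an explicit ``vacuous`` flag rather
than NaN.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

from .corpus_io import record_to_flat
from .lexicon import Category, KINETIC_PARAMETERS
from .linker import LinkageType, check_indirect_uniqueness
from .pipeline import analyze_document
from .preprocess import Document
from .resources import Resources, default_resources

SLOT_CATEGORIES = (
    "value",
    "enzyme_name",
    "ec_number",
    "ligand",
    "organism",
    "localisation",
    "ph",
    "temperature",
)

_NUMERIC_SLOTS = {"value", "ph", "temperature"}

PATTERNS = (
    "direct_chain",
    "enumeration",
    "indirect_only",
    "negation",
    "distractor",
    "ambiguous_acronym",
)

#: unit surfaces the generator prints, per kinetic category (None = bare value)
_UNITS_FOR: dict[Category, tuple[str, ...] | None] = {
    Category.KM: ("mM", "microM", "nM"),
    Category.KI: ("mM", "microM", "nM"),
    Category.KD: ("nM", "microM"),
    Category.IC50: ("microM", "nM"),
    Category.S_HALF: ("mM",),
    Category.KA: ("mM", "microM"),
    Category.KCAT: ("s(-1)", "min(-1)"),
    Category.KCAT_OVER_KM: ("mM(-1)s(-1)",),
    Category.T_HALF: ("min", "hours", "s"),
    Category.VMAX: ("micromol/min/mg", "nmol/min/mg"),
    Category.SPECIFIC_ACTIVITY: ("U/mg", "units/mg"),
    Category.VMAX_OVER_KM: ("ml/min/mg",),
    Category.PI: None,
    Category.N_H: None,
}

_TRAP_LIGAND_SURFACE = "TPA"
_PLACEHOLDER_SURFACES = {"enzyme a", "enzyme b", "ligand c", "ligand d"}


@dataclass(frozen=True)
class GeneratorProfile:
    """Study conditions for the synthetic corpus.

    Pattern probabilities must sum to one; ``seed`` makes the corpus fully
    reproducible.
    """

    n_documents: int = 100
    seed: int = 0
    direct_chain: float = 0.35
    enumeration: float = 0.20
    indirect_only: float = 0.20
    negation: float = 0.15
    distractor: float = 0.10
    ambiguous_acronym: float = 0.00
    sci_value_rate: float = 0.15
    error_value_rate: float = 0.15
    range_value_rate: float = 0.10
    ph_clause_rate: float = 0.60
    localisation_rate: float = 0.40
    value_log10_range: tuple[float, float] = (-2.5, 2.0)

    @property
    def pattern_weights(self) -> tuple[float, ...]:
        return tuple(getattr(self, p) for p in PATTERNS)

    def validate(self) -> None:
        total = sum(self.pattern_weights)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern probabilities sum to {total}, expected 1")
        if any(w < 0 for w in self.pattern_weights):
            raise ValueError("pattern probabilities must be non-negative")

    def with_pattern_rates(self, **rates: float) -> "GeneratorProfile":
        """Set some pattern rates, rescaling the others to keep the sum at 1."""
        unknown = set(rates) - set(PATTERNS)
        if unknown:
            raise ValueError(f"unknown patterns: {sorted(unknown)}")
        fixed = sum(rates.values())
        if fixed > 1 + 1e-9:
            raise ValueError("fixed pattern rates exceed 1")
        rest = [p for p in PATTERNS if p not in rates]
        rest_total = sum(getattr(self, p) for p in rest)
        scale = (1.0 - fixed) / rest_total if rest_total > 0 else 0.0
        updates = dict(rates)
        for p in rest:
            updates[p] = getattr(self, p) * scale
        return dc_replace(self, **updates)


@dataclass
class GoldDocument:
    document: Document
    gold: list[dict] = field(default_factory=list)


def _fmt(v: float) -> str:
    s = f"{v:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _gold(pmid: str, category: Category, **slots) -> dict:
    rec: dict = {
        "pmid": pmid,
        "kinetic_category": category.value,
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
    for name in ("enzyme_name", "ec_number", "ligand", "organism", "localisation"):
        rec[name] = None
        rec[f"{name}_linkage"] = None
    rec.update(slots)
    return rec


class _CorpusBuilder:
    """Single-seed corpus assembly over the fixture lexicons."""

    def __init__(self, profile: GeneratorProfile, resources: Resources):
        self.profile = profile
        self.res = resources
        self.rng = random.Random(profile.seed)
        self.enzymes = [
            e
            for e in resources.entries_for(Category.ENZYME_NAME)
            if e.surface.lower() not in _PLACEHOLDER_SURFACES
        ]
        self.ligands = [
            e
            for e in resources.entries_for(Category.LIGAND)
            if e.surface.lower() not in _PLACEHOLDER_SURFACES
            and e.surface != _TRAP_LIGAND_SURFACE
        ]
        self.organisms = resources.entries_for(Category.ORGANISM)
        self.tissues = resources.entries_for(Category.LOCALISATION)
        self.expressions = {
            cat: [
                e
                for e in resources.entries_for(cat)
                if "," not in e.surface
            ]
            for cat in KINETIC_PARAMETERS
        }
        self.categories = sorted(KINETIC_PARAMETERS, key=lambda c: c.value)

    # -- small sampling helpers -------------------------------------------
    def pick(self, pool):
        return pool[self.rng.randrange(len(pool))]

    def pick_n(self, pool, n):
        idx = self.rng.sample(range(len(pool)), n)
        return [pool[i] for i in idx]

    def gold_ec(self, enzyme_canonical: str) -> str | None:
        if self.res.ec_map is None:
            return None
        ecs = self.res.ec_map.ecs_for(enzyme_canonical)
        return next(iter(ecs)) if len(ecs) == 1 else None

    def value_clause(self, category: Category) -> tuple[str, dict]:
        """Printed value text plus the gold value fields."""
        rng = self.rng
        units = _UNITS_FOR[category]
        fields: dict = {"value_linkage": LinkageType.DIRECT.value}
        if units is None:  # pI / Hill coefficient: bare numbers
            v = round(rng.uniform(1.0, 9.5), 1)
            fields["value"] = float(_fmt(v))
            return _fmt(v), fields
        unit = self.pick(units)
        fields["unit"] = unit.lower()
        form = rng.random()
        lo, hi = self.profile.value_log10_range
        v = round(10 ** rng.uniform(lo, hi), 4)
        if form < self.profile.sci_value_rate:
            mantissa = round(rng.uniform(1.0, 9.99), 2)
            exp = rng.randint(-6, -1)
            text = f"{_fmt(mantissa)} x 10({exp})"
            fields["value"] = float(_fmt(mantissa)) * 10.0 ** exp
        elif form < self.profile.sci_value_rate + self.profile.error_value_rate:
            err = round(v * rng.uniform(0.05, 0.3), 4)
            text = f"{_fmt(v)} +/- {_fmt(err)}"
            fields["value"] = float(_fmt(v))
            fields["error"] = float(_fmt(err))
        elif form < (
            self.profile.sci_value_rate
            + self.profile.error_value_rate
            + self.profile.range_value_rate
        ):
            high = round(v * rng.uniform(1.5, 3.0), 4)
            text = f"{_fmt(v)}-{_fmt(high)}"
            fields["value"] = float(_fmt(v))
            fields["range_high"] = float(_fmt(high))
        else:
            text = _fmt(v)
            fields["value"] = float(_fmt(v))
        return f"{text} {unit}", fields

    def organism_sentence(self, org) -> str:
        return f"The enzyme was purified from {org.surface}."

    # -- document patterns -------------------------------------------------
    def direct_chain(self, pmid: str, with_distractor: bool = False) -> GoldDocument:
        rng = self.rng
        cat = self.pick(self.categories)
        kx = self.pick(self.expressions[cat])
        enzyme = self.pick(self.enzymes)
        org = self.pick(self.organisms)
        bare = _UNITS_FOR[cat] is None
        with_ligand = cat is not Category.PI
        ligand = self.pick(self.ligands) if with_ligand else None
        val_text, val_fields = self.value_clause(cat)

        org_mode = (
            "sentence"
            if with_distractor
            else self.pick(("sentence", "abstract", "title", "none"))
        )
        ph_clause = (not bare) and rng.random() < self.profile.ph_clause_rate
        with_loc = rng.random() < self.profile.localisation_rate
        loc = self.pick(self.tissues) if with_loc else None

        s1 = f"The {kx.surface} of {enzyme.surface}"
        if ligand is not None:
            s1 += f" for {ligand.surface}"
        if org_mode == "sentence":
            s1 += f" from {org.surface}"
        s1 += f" was {val_text}"
        ph_val = temp_val = None
        if ph_clause:
            ph_val = round(rng.uniform(5.0, 9.0), 1)
            temp_val = float(rng.randint(20, 42))
            s1 += f" at pH {_fmt(ph_val)} and {_fmt(temp_val)} degrees C"
        s1 += "."

        abstract_sentences = [s1]
        if org_mode == "abstract":
            abstract_sentences.append(self.organism_sentence(org))
        if loc is not None:
            abstract_sentences.append(f"The enzyme is located in the {loc.surface}.")
        if with_distractor:
            org2 = self.pick([o for o in self.organisms if o.canonical != org.canonical])
            abstract_sentences.append(f"Cells of {org2.surface} were grown in rich medium.")
            abstract_sentences.append("Samples were stored for 3 days before the assay.")

        title = (
            f"Kinetic studies in {org.surface}."
            if org_mode == "title"
            else f"Characterization of {enzyme.surface}."
        )

        slots = dict(val_fields)
        slots["enzyme_name"] = enzyme.canonical
        slots["enzyme_name_linkage"] = LinkageType.DIRECT.value
        ec = self.gold_ec(enzyme.canonical)
        if ec is not None:
            slots["ec_number"] = ec
            slots["ec_number_linkage"] = LinkageType.COMPLETED_LOOKUP.value
        if ligand is not None:
            slots["ligand"] = ligand.canonical
            slots["ligand_linkage"] = LinkageType.DIRECT.value
        if org_mode != "none":
            slots["organism"] = org.canonical
            slots["organism_linkage"] = {
                "sentence": LinkageType.DIRECT,
                "abstract": LinkageType.INDIRECT_ABSTRACT,
                "title": LinkageType.INDIRECT_TITLE,
            }[org_mode].value
        if loc is not None:
            slots["localisation"] = loc.canonical
            slots["localisation_linkage"] = LinkageType.INDIRECT_ABSTRACT.value
        if ph_clause:
            slots["ph"] = float(_fmt(ph_val))
            slots["ph_linkage"] = LinkageType.DIRECT.value
            slots["temperature"] = float(_fmt(temp_val))
            slots["temperature_linkage"] = LinkageType.INDIRECT_SENTENCE.value

        doc = Document(pmid=pmid, title=title, abstract=" ".join(abstract_sentences))
        return GoldDocument(doc, [_gold(pmid, cat, **slots)])

    def enumeration(self, pmid: str) -> GoldDocument:
        rng = self.rng
        cat = self.pick(self.categories)
        kx = self.pick(self.expressions[cat])
        with_org = rng.random() < 0.5
        org = self.pick(self.organisms) if with_org else None
        title = "Comparative kinetic measurements."
        golds: list[dict] = []

        if rng.random() < 0.5:  # two equally-sized groups pair element-wise
            e1, e2 = self.pick_n(self.enzymes, 2)
            l1, l2 = self.pick_n(self.ligands, 2)
            s1 = (
                f"The {kx.surface} was determined for {e1.surface} and "
                f"{e2.surface} with {l1.surface} and {l2.surface}."
            )
            for enz, lig in ((e1, l1), (e2, l2)):
                slots = {
                    "enzyme_name": enz.canonical,
                    "enzyme_name_linkage": LinkageType.LISTING.value,
                    "ligand": lig.canonical,
                    "ligand_linkage": LinkageType.LISTING.value,
                }
                ec = self.gold_ec(enz.canonical)
                if ec is not None:
                    slots["ec_number"] = ec
                    slots["ec_number_linkage"] = LinkageType.COMPLETED_LOOKUP.value
                if org is not None:
                    slots["organism"] = org.canonical
                    slots["organism_linkage"] = LinkageType.INDIRECT_ABSTRACT.value
                golds.append(_gold(pmid, cat, **slots))
        else:  # single group itemized, singleton enzyme broadcast
            enzyme = self.pick(self.enzymes)
            l1, l2, l3 = self.pick_n(self.ligands, 3)
            s1 = (
                f"The {kx.surface} of {enzyme.surface} for {l1.surface}, "
                f"{l2.surface} and {l3.surface} was measured."
            )
            ec = self.gold_ec(enzyme.canonical)
            for lig in (l1, l2, l3):
                slots = {
                    "enzyme_name": enzyme.canonical,
                    "enzyme_name_linkage": LinkageType.DIRECT.value,
                    "ligand": lig.canonical,
                    "ligand_linkage": LinkageType.LISTING.value,
                }
                if ec is not None:
                    slots["ec_number"] = ec
                    slots["ec_number_linkage"] = LinkageType.COMPLETED_LOOKUP.value
                if org is not None:
                    slots["organism"] = org.canonical
                    slots["organism_linkage"] = LinkageType.INDIRECT_ABSTRACT.value
                golds.append(_gold(pmid, cat, **slots))

        abstract = s1 if org is None else f"{s1} {self.organism_sentence(org)}"
        return GoldDocument(Document(pmid=pmid, title=title, abstract=abstract), golds)

    def indirect_only(self, pmid: str) -> GoldDocument:
        rng = self.rng
        cat = self.pick(self.categories)
        kx = self.pick(self.expressions[cat])
        enzyme = self.pick(self.enzymes)
        org = self.pick(self.organisms)
        val_text, val_fields = self.value_clause(cat)
        enzyme_mode = self.pick(("abstract", "sentence"))
        org_mode = self.pick(("abstract", "title"))
        with_loc = rng.random() < self.profile.localisation_rate
        loc = self.pick(self.tissues) if with_loc else None
        with_ligand = rng.random() < 0.5
        ligand = self.pick(self.ligands) if with_ligand else None

        s1 = f"A {kx.surface} of {val_text} was determined"
        if enzyme_mode == "sentence":
            s1 += f", as reported for {enzyme.surface}"
        s1 += "."
        sentences = [s1]

        if enzyme_mode == "abstract":
            s2 = enzyme.surface[0].upper() + enzyme.surface[1:] + " was purified"
        else:
            s2 = "The protein was purified"
        tail = []
        if org_mode == "abstract":
            tail.append(org.surface)
        if loc is not None:
            tail.append(loc.surface)
        s2 += f" from {' '.join(tail)}" if tail else " to homogeneity"
        s2 += "."
        sentences.append(s2)
        if ligand is not None:
            sentences.append(f"The assay mixture contained {ligand.surface} as substrate.")

        title = (
            f"Kinetic studies in {org.surface}."
            if org_mode == "title"
            else "Kinetic properties of a purified enzyme."
        )

        slots = dict(val_fields)
        slots["enzyme_name"] = enzyme.canonical
        slots["enzyme_name_linkage"] = (
            LinkageType.INDIRECT_SENTENCE.value
            if enzyme_mode == "sentence"
            else LinkageType.INDIRECT_ABSTRACT.value
        )
        ec = self.gold_ec(enzyme.canonical)
        if ec is not None:
            slots["ec_number"] = ec
            slots["ec_number_linkage"] = LinkageType.COMPLETED_LOOKUP.value
        slots["organism"] = org.canonical
        slots["organism_linkage"] = (
            LinkageType.INDIRECT_TITLE.value
            if org_mode == "title"
            else LinkageType.INDIRECT_ABSTRACT.value
        )
        if loc is not None:
            slots["localisation"] = loc.canonical
            slots["localisation_linkage"] = LinkageType.INDIRECT_ABSTRACT.value
        if ligand is not None:
            slots["ligand"] = ligand.canonical
            slots["ligand_linkage"] = LinkageType.INDIRECT_ABSTRACT.value

        doc = Document(pmid=pmid, title=title, abstract=" ".join(sentences))
        return GoldDocument(doc, [_gold(pmid, cat, **slots)])

    def negation(self, pmid: str) -> GoldDocument:
        rng = self.rng
        cat = self.pick([c for c in self.categories if _UNITS_FOR[c] is not None])
        kx = self.pick(self.expressions[cat])
        enzyme = self.pick(self.enzymes)
        with_true_ligand = rng.random() < 0.5
        lig, lig2 = self.pick_n(self.ligands, 2)
        val_text, val_fields = self.value_clause(cat)
        with_org = rng.random() < 0.5
        org = self.pick(self.organisms) if with_org else None

        s1 = f"The {kx.surface} of {enzyme.surface}"
        if with_true_ligand:
            s1 += f" for {lig.surface}"
        s1 += f" was {val_text} in the absence of {lig2.surface}."
        sentences = [s1]
        if org is not None:
            sentences.append(self.organism_sentence(org))

        slots = dict(val_fields)
        slots["enzyme_name"] = enzyme.canonical
        slots["enzyme_name_linkage"] = LinkageType.DIRECT.value
        ec = self.gold_ec(enzyme.canonical)
        if ec is not None:
            slots["ec_number"] = ec
            slots["ec_number_linkage"] = LinkageType.COMPLETED_LOOKUP.value
        if with_true_ligand:
            slots["ligand"] = lig.canonical
            slots["ligand_linkage"] = LinkageType.DIRECT.value
        if org is not None:
            slots["organism"] = org.canonical
            slots["organism_linkage"] = LinkageType.INDIRECT_ABSTRACT.value

        doc = Document(
            pmid=pmid,
            title=f"Characterization of {enzyme.surface}.",
            abstract=" ".join(sentences),
        )
        return GoldDocument(doc, [_gold(pmid, cat, **slots)])

    def ambiguous_acronym(self, pmid: str) -> GoldDocument:
        """A dictionary homonym used with its non-ligand meaning.

        The gold ligand slot stays empty; a dictionary-based extractor will
        tag the acronym as a ligand and link it, producing a false positive.
        """
        rng = self.rng
        cat = self.pick([c for c in self.categories if _UNITS_FOR[c] is not None])
        kx = self.pick(self.expressions[cat])
        enzyme = self.pick(self.enzymes)
        val_text, val_fields = self.value_clause(cat)
        with_org = rng.random() < 0.5
        org = self.pick(self.organisms) if with_org else None

        s1 = (
            f"The {kx.surface} of {enzyme.surface} was {val_text} after "
            f"stimulation with {_TRAP_LIGAND_SURFACE}."
        )
        sentences = [s1]
        if org is not None:
            sentences.append(self.organism_sentence(org))

        slots = dict(val_fields)
        slots["enzyme_name"] = enzyme.canonical
        slots["enzyme_name_linkage"] = LinkageType.DIRECT.value
        ec = self.gold_ec(enzyme.canonical)
        if ec is not None:
            slots["ec_number"] = ec
            slots["ec_number_linkage"] = LinkageType.COMPLETED_LOOKUP.value
        if org is not None:
            slots["organism"] = org.canonical
            slots["organism_linkage"] = LinkageType.INDIRECT_ABSTRACT.value

        doc = Document(
            pmid=pmid,
            title=f"Characterization of {enzyme.surface}.",
            abstract=" ".join(sentences),
        )
        return GoldDocument(doc, [_gold(pmid, cat, **slots)])

    def build(self) -> list[GoldDocument]:
        out: list[GoldDocument] = []
        for i in range(self.profile.n_documents):
            pmid = str(9000000 + i)
            pattern = self.rng.choices(PATTERNS, weights=self.profile.pattern_weights)[0]
            if pattern == "direct_chain":
                out.append(self.direct_chain(pmid))
            elif pattern == "enumeration":
                out.append(self.enumeration(pmid))
            elif pattern == "indirect_only":
                out.append(self.indirect_only(pmid))
            elif pattern == "negation":
                out.append(self.negation(pmid))
            elif pattern == "distractor":
                out.append(self.direct_chain(pmid, with_distractor=True))
            else:
                out.append(self.ambiguous_acronym(pmid))
        return out


def generate_corpus(
    profile: GeneratorProfile, resources: Resources | None = None
) -> list[GoldDocument]:
    """Generate a seeded gold-annotated corpus from the fixture lexicons."""
    profile.validate()
    resources = resources if resources is not None else default_resources()
    return _CorpusBuilder(profile, resources).build()


# ---------------------------------------------------------------------------
# scoring

def _num_eq(a, b) -> bool:
    if a is None and b is None:
        return True
    if a is None or b is None:
        return False
    return abs(a - b) <= 1e-9 * max(1.0, abs(a), abs(b))


def _slot_eq(name: str, p: dict, g: dict) -> bool:
    if name == "value":
        return (
            _num_eq(p["value"], g["value"])
            and _num_eq(p["error"], g["error"])
            and _num_eq(p["range_high"], g["range_high"])
            and (p["unit"] or None) == (g["unit"] or None)
        )
    if name in _NUMERIC_SLOTS:
        return _num_eq(p[name], g[name])
    return p[name] == g[name]


def match_records(
    predicted: Sequence[dict], gold: Sequence[dict]
) -> list[tuple[dict | None, dict | None]]:
    """Align record streams by (pmid, kinetic category) in document order."""
    groups: dict[tuple[str, str], list[list]] = {}
    for p in predicted:
        groups.setdefault((p["pmid"], p["kinetic_category"]), [[], []])[0].append(p)
    for g in gold:
        groups.setdefault((g["pmid"], g["kinetic_category"]), [[], []])[1].append(g)
    pairs: list[tuple[dict | None, dict | None]] = []
    for key in sorted(groups):
        preds, golds = groups[key]
        for i in range(max(len(preds), len(golds))):
            pairs.append(
                (preds[i] if i < len(preds) else None, golds[i] if i < len(golds) else None)
            )
    return pairs


ERROR_CLASSES = (
    "none_in_abstract",
    "correct",
    "wrong_with_right_available",
    "wrong_no_right",
    "incomplete_not_incorrect",
    "missing",
)


@dataclass
class CategoryScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def vacuous_precision(self) -> bool:
        return (self.tp + self.fp) == 0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def vacuous_recall(self) -> bool:
        return (self.tp + self.fn) == 0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "vacuous_precision": self.vacuous_precision,
            "vacuous_recall": self.vacuous_recall,
        }


@dataclass
class EvalReport:
    per_category: dict[str, CategoryScore]
    overall: CategoryScore
    precision_by_linkage: dict[str, CategoryScore]
    recall_by_gold_linkage: dict[str, CategoryScore]
    error_classes: Counter

    def to_dict(self) -> dict:
        return {
            "per_category": {k: v.to_dict() for k, v in self.per_category.items()},
            "overall": self.overall.to_dict(),
            "precision_by_linkage": {
                k: v.to_dict() for k, v in sorted(self.precision_by_linkage.items())
            },
            "recall_by_gold_linkage": {
                k: v.to_dict() for k, v in sorted(self.recall_by_gold_linkage.items())
            },
            "error_classes": {c: self.error_classes.get(c, 0) for c in ERROR_CLASSES},
        }


def evaluate(predicted: Sequence[dict], gold: Sequence[dict]) -> EvalReport:
    """Slot-level precision/recall with linkage-type and error breakdowns."""
    per_cat = {name: CategoryScore() for name in SLOT_CATEGORIES}
    overall = CategoryScore()
    by_linkage: dict[str, CategoryScore] = {}
    by_gold_linkage: dict[str, CategoryScore] = {}
    classes: Counter = Counter()

    empty = _gold("", Category.KM)  # stand-in for a missing record side

    for pred, gld in match_records(predicted, gold):
        p = pred if pred is not None else empty
        g = gld if gld is not None else empty
        for name in SLOT_CATEGORIES:
            filled_p = p[name] is not None
            filled_g = g[name] is not None
            pl = p.get(f"{name}_linkage") if name != "value" else p.get("value_linkage")
            gl = g.get(f"{name}_linkage") if name != "value" else g.get("value_linkage")
            lp = by_linkage.setdefault(pl, CategoryScore()) if pl else None
            lg = by_gold_linkage.setdefault(gl, CategoryScore()) if gl else None
            if not filled_p and not filled_g:
                classes["none_in_abstract"] += 1
                continue
            if filled_p and filled_g and _slot_eq(name, p, g):
                per_cat[name].tp += 1
                overall.tp += 1
                if lp:
                    lp.tp += 1
                if lg:
                    lg.tp += 1
                classes["correct"] += 1
            elif filled_p and filled_g:
                per_cat[name].fp += 1
                per_cat[name].fn += 1
                overall.fp += 1
                overall.fn += 1
                if lp:
                    lp.fp += 1
                if lg:
                    lg.fn += 1
                if (
                    name not in _NUMERIC_SLOTS
                    and isinstance(p[name], str)
                    and isinstance(g[name], str)
                    and p[name] in g[name]
                ):
                    classes["incomplete_not_incorrect"] += 1
                else:
                    classes["wrong_with_right_available"] += 1
            elif filled_p:
                per_cat[name].fp += 1
                overall.fp += 1
                if lp:
                    lp.fp += 1
                classes["wrong_no_right"] += 1
            else:
                per_cat[name].fn += 1
                overall.fn += 1
                if lg:
                    lg.fn += 1
                classes["missing"] += 1

    return EvalReport(
        per_category=per_cat,
        overall=overall,
        precision_by_linkage=by_linkage,
        recall_by_gold_linkage=by_gold_linkage,
        error_classes=classes,
    )


# ---------------------------------------------------------------------------
# convenience: run the extractor over a gold corpus

def run_extractor(
    gold_docs: Iterable[GoldDocument],
    resources: Resources | None = None,
    apply_negation_filter: bool = True,
    enable_indirect: bool = True,
    check_soundness: bool = False,
) -> list[dict]:
    """Extract flat records from every gold document, in corpus order."""
    resources = resources if resources is not None else default_resources()
    flats: list[dict] = []
    for gd in gold_docs:
        tagged, records = analyze_document(
            gd.document,
            resources,
            apply_negation_filter=apply_negation_filter,
            enable_indirect=enable_indirect,
        )
        if check_soundness and not check_indirect_uniqueness(tagged, records):
            raise AssertionError(
                f"indirect-uniqueness violated in document {gd.document.pmid}"
            )
        flats.extend(record_to_flat(r) for r in records)
    return flats


def write_gold(gold_docs: Sequence[GoldDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gd in gold_docs:
            for rec in gd.gold:
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_gold(path: str | Path) -> list[dict]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(json.loads(line))
    return out
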