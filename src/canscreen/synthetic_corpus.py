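"""Seeded synthetic data: pediatric-note corpora with gold annotations,
expert-survey rounds, and separable sentence datasets.

The corpus generator emulates the statistical structure the screening
pipeline assumes: a multi-note-type pediatric corpus in which a small
fraction of notes carry planted CAN mentions, some planted mentions are
negated, and five categories of false-positive "trap" sentences imitate the
recurring real-note failure modes (third-party subjects, template legends,
first-aid boilerplate, section-header fragments, abbreviation expansions).
All templates are synthetic well-child boilerplate written for this package;
gold records every plant with its exact character span.

Defaults reproduce the observed study conditions: note-type weights follow
the development-sample distribution, ~2.9% of notes are CAN positive, and
the subtype mixture is SERVICE-heavy (0.67 / 0.22 / 0.06 / 0.05 / 0.00).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .corpus_io import ClinicalNote
from .lexicon import SUBTYPES, LexiconTerm, SurveyRound

__all__ = [
    "SynthSpec",
    "GoldAnnotation",
    "CorpusStats",
    "generate",
    "corpus_stats",
    "gold_positive_sentences",
    "load_spec",
    "save_spec",
    "generate_survey_round",
    "generate_suggestions",
    "generate_sentence_dataset",
    "TRAP_KINDS",
    "NOTE_TYPE_WEIGHTS",
]

#: Development-sample note-type counts (22 types, 14,397 notes) used as
#: default sampling weights.
NOTE_TYPE_WEIGHTS = {
    "Plan of Care": 333,
    "Not Specified": 1813,
    "Nursing": 134,
    "Emergency Department Notes": 518,
    "Patient Instructions": 1149,
    "ED AVS Snapshot": 472,
    "Telephone Encounter": 2051,
    "MR AVS Snapshot": 1571,
    "Letter": 127,
    "Medical Student": 60,
    "Discharge Instructions - Other Orders": 58,
    "Sticky Note": 27,
    "Emergency Department Provider Notes": 281,
    "Progress Notes": 3859,
    "IP AVS Snapshot": 66,
    "Discharge Summaries": 788,
    "H&P": 677,
    "Lactation Note": 192,
    "Consults": 45,
    "Consult NW": 11,
    "Social Worker/Case Management": 51,
    "Treatment Plan": 5,
}

TRAP_KINDS = ("r1", "r2", "r3", "r4", "r5")

#: Observed entity-frequency prior: "child protective services" dominates,
#: followed by the other placement/agency terms.
_TERM_WEIGHTS = {
    "child protective services": 6.0,
    "foster care": 4.0,
    "foster care support clinic": 3.0,
    "abuse": 3.0,
    "physical abuse": 2.5,
    "child abuse pediatrics": 2.0,
    "child advocacy center": 2.0,
    "neglect": 2.0,
    "foster parents": 2.0,
}

_DEFAULT_SUBTYPE_MIX = {
    "SERVICE": 0.67,
    "ABUSE": 0.22,
    "SEXUAL_ABUSE": 0.06,
    "PHYSICAL_INDICATION": 0.05,
    "EMOTIONAL_INDICATION": 0.00,
}


@dataclass
class SynthSpec:
    """Generator parameters; every rate lies in [0, 1] and the probability
    vectors sum to 1."""

    seed: int = 0
    n_patients: int = 153
    notes_per_patient: tuple[int, int] = (60, 120)
    note_type_mix: dict = field(default_factory=lambda: dict(NOTE_TYPE_WEIGHTS))
    sentence_count: tuple[int, int] = (4, 12)
    positive_note_rate: float = 0.029
    subtype_mix: dict = field(default_factory=lambda: dict(_DEFAULT_SUBTYPE_MIX))
    negation_rate: float = 0.2
    trap_rates: dict = field(
        default_factory=lambda: {k: 0.005 for k in TRAP_KINDS}
    )
    duplicate_rate: float = 0.05
    plants_per_positive_note: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    plants_weights: tuple[float, ...] = (0.15, 0.15, 0.2, 0.2, 0.15, 0.15)

    def __post_init__(self) -> None:
        for name, rate in (
            ("positive_note_rate", self.positive_note_rate),
            ("negation_rate", self.negation_rate),
            ("duplicate_rate", self.duplicate_rate),
            *((f"trap_rate[{k}]", v) for k, v in self.trap_rates.items()),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        mass = sum(self.subtype_mix.values())
        if abs(mass - 1.0) > 1e-9:
            raise ValueError(f"subtype_mix sums to {mass}, expected 1")
        if unknown := set(self.subtype_mix) - set(SUBTYPES):
            raise ValueError(f"unknown subtypes in subtype_mix: {sorted(unknown)}")
        if unknown := set(self.trap_rates) - set(TRAP_KINDS):
            raise ValueError(f"unknown trap kinds: {sorted(unknown)}")


@dataclass(frozen=True)
class GoldAnnotation:
    """One planted surface: where it is and why it was planted.

    ``planted_kind`` "positive" marks a gold-positive sentence; "negated"
    and "trap_r1".."trap_r5" sentences are gold-negative.
    """

    note_id: str
    sentence_index: int
    begin: int
    end: int
    subtype: str
    surface: str
    planted_kind: str

    @property
    def gold_positive(self) -> bool:
        return self.planted_kind == "positive"


# --- sentence templates (synthetic well-child boilerplate) -----------------

_FILLERS = (
    "Growth parameters tracked along expected percentile curves.",
    "Immunizations reviewed and updated per schedule.",
    "Diet and sleep habits discussed with the family.",
    "Vision and hearing screening completed without concern.",
    "Developmental milestones appropriate for age.",
    "Lungs clear and heart sounds regular on exam.",
    "School attendance and activity level reviewed.",
    "Medication list reconciled at this encounter.",
    "Anticipatory guidance provided for the next interval.",
    "Follow up scheduled with the primary care team.",
    "Hydration and nutrition adequate by report.",
)

# (prefix, suffix) carriers; the planted surface sits between them.
_POSITIVE_CARRIERS = (
    ("Patient discloses ", " during the visit."),
    ("Caregiver described ", " involving a neighbor."),
    ("Chart documents ", " from a prior encounter."),
    ("Plan updated because of ", " concerns raised today."),
    ("Referred for ", " follow up this week."),
)

_NEGATED_CARRIERS = (
    ("Patient denies ", " at home."),
    ("No ", " reported by caregiver."),
    ("There was no evidence of ", " today."),
)


def _trap_sentence(kind: str, rng: random.Random):
    """Build one trap sentence; returns (text, surface, rel_begin, subtype)."""
    if kind == "r1":
        kin1, kin2 = rng.choice(
            [("grandparents", "mother"), ("aunt", "mother"), ("grandmother", "father")]
        )
        surface = rng.choice(["date rape", "sexual assault"])
        prefix = f"Per the {kin1} the {kin2} reported one "
        return prefix + surface + " years ago.", surface, len(prefix), "SEXUAL_ABUSE"
    if kind == "r2":
        prefix = "Abbreviations used in this note: AV = "
        return (
            prefix + "alleged victim, AO = alleged offender.",
            "alleged",
            len(prefix),
            "ABUSE",
        )
    if kind == "r3":
        prefix = "First Aid: "
        surface = "Burns"
        return (
            prefix + surface + " Call 911 immediately if the victim has trouble breathing.",
            surface,
            len(prefix),
            "PHYSICAL_INDICATION",
        )
    if kind == "r4":
        surface = "sexual abuse"
        return (
            surface + " health since last visit: No concerns were reported today.",
            surface,
            0,
            "SEXUAL_ABUSE",
        )
    if kind == "r5":
        prefix = "Labs reviewed for "
        surface = "STD"
        return (
            prefix + surface + " (sexually transmitted disease) exposure.",
            surface,
            len(prefix),
            "SEXUAL_ABUSE",
        )
    raise ValueError(f"unknown trap kind {kind!r}")


def _plantable_terms(lexicon: Sequence[LexiconTerm]) -> dict[str, list[LexiconTerm]]:
    """Standard-specificity terms per subtype (low-specificity terms are
    never planted as gold positives: uncorroborated they are, by design,
    suppressed by the pipeline)."""
    pool: dict[str, list[LexiconTerm]] = {s: [] for s in SUBTYPES}
    for t in lexicon:
        if t.specificity == "standard":
            pool[t.subtype].append(t)
    return pool


def generate(
    spec: SynthSpec, lexicon: Sequence[LexiconTerm]
) -> tuple[list[ClinicalNote], list[GoldAnnotation]]:
    """Generate a corpus and its gold annotations, fully determined by
    ``spec.seed``.

    Notes are template-based filler sentences interleaved with planted
    sentences; sentences are joined with blank lines so each template is
    exactly one detector sentence. Duplicated notes (same patient, type and
    text, later date) are planted at ``duplicate_rate``.
    """
    rng = random.Random(spec.seed)
    pool = _plantable_terms(lexicon)
    for subtype, mass in spec.subtype_mix.items():
        if mass > 0 and not pool[subtype]:
            raise ValueError(
                f"subtype_mix places mass on {subtype} but the lexicon has no "
                f"standard-specificity terms for it"
            )
    subtype_names = [s for s in SUBTYPES if spec.subtype_mix.get(s, 0) > 0]
    subtype_weights = [spec.subtype_mix[s] for s in subtype_names]
    type_names = list(spec.note_type_mix)
    type_weights = [spec.note_type_mix[t] for t in type_names]

    notes: list[ClinicalNote] = []
    gold: list[GoldAnnotation] = []
    note_seq = 0
    day = 0
    for p in range(spec.n_patients):
        patient_id = f"P{p:05d}"
        n_notes = rng.randint(*spec.notes_per_patient)
        patient_notes: list[tuple[ClinicalNote, list[GoldAnnotation]]] = []
        for _ in range(n_notes):
            note_seq += 1
            day += 1
            date = _iso_date(day)
            note_id = f"N{note_seq:07d}"
            note_type = rng.choices(type_names, weights=type_weights)[0]
            n_sent = rng.randint(*spec.sentence_count)
            # opener makes every note's text unique, so the only duplicate
            # texts are the deliberately planted ones
            sentences: list[tuple[str, Optional[tuple]]] = [
                (f"Routine visit number {note_seq} documented on {date}.", None)
            ]
            for _ in range(n_sent - 1):
                sentences.append((rng.choice(_FILLERS), None))
            if rng.random() < spec.positive_note_rate:
                n_plants = rng.choices(
                    spec.plants_per_positive_note, weights=spec.plants_weights
                )[0]
                for _ in range(n_plants):
                    subtype = rng.choices(subtype_names, weights=subtype_weights)[0]
                    terms = pool[subtype]
                    term = rng.choices(
                        terms,
                        weights=[_TERM_WEIGHTS.get(t.surface, 1.0) for t in terms],
                    )[0]
                    surface = term.surface
                    if rng.random() < spec.negation_rate:
                        prefix, suffix = rng.choice(_NEGATED_CARRIERS)
                        kind = "negated"
                    else:
                        prefix, suffix = rng.choice(_POSITIVE_CARRIERS)
                        kind = "positive"
                    text = prefix + surface + suffix
                    slot = rng.randint(1, len(sentences))
                    sentences.insert(
                        slot, (text, (len(prefix), surface, subtype, kind))
                    )
            for trap_kind in TRAP_KINDS:
                if rng.random() < spec.trap_rates.get(trap_kind, 0.0):
                    text, surface, rel, subtype = _trap_sentence(trap_kind, rng)
                    slot = rng.randint(1, len(sentences))
                    sentences.insert(
                        slot, (text, (rel, surface, subtype, f"trap_{trap_kind}"))
                    )
            note_text_parts: list[str] = []
            note_gold: list[GoldAnnotation] = []
            offset = 0
            for idx, (text, plant) in enumerate(sentences):
                if plant is not None:
                    rel, surface, subtype, kind = plant
                    note_gold.append(
                        GoldAnnotation(
                            note_id=note_id,
                            sentence_index=idx,
                            begin=offset + rel,
                            end=offset + rel + len(surface),
                            subtype=subtype,
                            surface=surface,
                            planted_kind=kind,
                        )
                    )
                note_text_parts.append(text)
                offset += len(text) + 2  # "\n\n" separator
            note = ClinicalNote(
                note_id=note_id,
                patient_id=patient_id,
                note_type=note_type,
                provider_category=rng.choice(
                    ["physician", "nurse", "social_worker", "other"]
                ),
                date=date,
                text="\n\n".join(note_text_parts),
            )
            patient_notes.append((note, note_gold))
        for note, note_gold in list(patient_notes):
            if rng.random() < spec.duplicate_rate:
                note_seq += 1
                day += 1
                dup_id = f"N{note_seq:07d}"
                dup = ClinicalNote(
                    note_id=dup_id,
                    patient_id=note.patient_id,
                    note_type=note.note_type,
                    provider_category=note.provider_category,
                    date=_iso_date(day),
                    text=note.text,
                )
                patient_notes.append(
                    (
                        dup,
                        [
                            GoldAnnotation(
                                dup_id, g.sentence_index, g.begin, g.end,
                                g.subtype, g.surface, g.planted_kind,
                            )
                            for g in note_gold
                        ],
                    )
                )
        for note, note_gold in patient_notes:
            notes.append(note)
            gold.extend(note_gold)
    return notes, gold


def _iso_date(day: int) -> str:
    # a simple 30-day-month calendar starting 2012-01-01; monotone in `day`
    year = 2012 + day // 360
    month = (day % 360) // 30 + 1
    dom = day % 30 + 1
    return f"{year:04d}-{month:02d}-{dom:02d}"


def gold_positive_sentences(gold: Sequence[GoldAnnotation]) -> set[tuple[str, int]]:
    """(note_id, sentence_index) units that are gold CAN-positive."""
    return {(g.note_id, g.sentence_index) for g in gold if g.gold_positive}


@dataclass(frozen=True)
class CorpusStats:
    n_notes: int
    n_patients: int
    notes_per_type: dict
    plants_per_kind: dict
    n_gold_positive_sentences: int
    n_duplicate_notes: int
    positive_note_rate: float


def corpus_stats(
    notes: Sequence[ClinicalNote], gold: Sequence[GoldAnnotation]
) -> CorpusStats:
    """Exact bookkeeping over a generated corpus; orphan gold is an error."""
    ids = {n.note_id for n in notes}
    for g in gold:
        if g.note_id not in ids:
            raise ValueError(f"gold record references unknown note {g.note_id!r}")
    per_type: dict[str, int] = {}
    for n in notes:
        per_type[n.note_type] = per_type.get(n.note_type, 0) + 1
    per_kind: dict[str, int] = {}
    for g in gold:
        per_kind[g.planted_kind] = per_kind.get(g.planted_kind, 0) + 1
    pos_docs = {g.note_id for g in gold if g.gold_positive}
    n_dupes = len(notes) - len({(n.patient_id, n.note_type, n.text) for n in notes})
    return CorpusStats(
        n_notes=len(notes),
        n_patients=len({n.patient_id for n in notes}),
        notes_per_type=per_type,
        plants_per_kind=per_kind,
        n_gold_positive_sentences=len(gold_positive_sentences(gold)),
        n_duplicate_notes=n_dupes,
        positive_note_rate=len(pos_docs) / len(notes) if notes else 0.0,
    )


def load_spec(path) -> SynthSpec:
    """Read a SynthSpec from YAML."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    for key in ("notes_per_patient", "sentence_count", "plants_per_positive_note", "plants_weights"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return SynthSpec(**doc)


def save_spec(spec: SynthSpec, path) -> None:
    doc = {
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "notes_per_patient": list(spec.notes_per_patient),
        "note_type_mix": dict(spec.note_type_mix),
        "sentence_count": list(spec.sentence_count),
        "positive_note_rate": spec.positive_note_rate,
        "subtype_mix": dict(spec.subtype_mix),
        "negation_rate": spec.negation_rate,
        "trap_rates": dict(spec.trap_rates),
        "duplicate_rate": spec.duplicate_rate,
        "plants_per_positive_note": list(spec.plants_per_positive_note),
        "plants_weights": list(spec.plants_weights),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Survey synthesis
# ---------------------------------------------------------------------------


def generate_survey_round(
    terms: Sequence[str],
    n_raters: int,
    target_mean: float = 2.58,
    n_fail: int = 0,
    seed: int = 0,
    round_id: str = "round1",
    suggestions: Optional[dict] = None,
) -> SurveyRound:
    """Construct a rating round with a controlled grand mean and failure count.

    Passing terms receive rating multisets whose pooled mean hits
    ``target_mean`` to within 1/(terms x raters) (ones and threes are dealt
    round-robin across terms so no passing term drops below the 80%
    retention bar); ``n_fail`` randomly chosen terms instead get ratings
    with fewer than 80% at 2 or above.
    """
    rng = random.Random(seed)
    terms = list(terms)
    respondents = tuple(f"R{i:03d}" for i in range(n_raters))
    fail_set = set(rng.sample(range(len(terms)), n_fail)) if n_fail else set()
    pass_terms = [t for i, t in enumerate(terms) if i not in fail_set]

    per_term: dict[str, list[int]] = {}
    if pass_terms:
        total = len(pass_terms) * n_raters
        target_sum = round(target_mean * total)
        n_ones = round(0.05 * total)
        n_threes = (target_sum - 2 * total) + n_ones
        if n_threes < 0:
            n_ones -= -n_threes  # low targets: trade ones for twos
            n_threes = 0
        if n_ones + n_threes > total:
            raise ValueError("target_mean infeasible for {1,2,3} ratings")
        ratings = {t: [2] * n_raters for t in pass_terms}
        max_ones_per_term = max(1, n_raters - int(0.8 * n_raters) - 1)
        slot = {t: 0 for t in pass_terms}
        for j in range(n_ones):
            t = pass_terms[j % len(pass_terms)]
            if slot[t] >= max_ones_per_term:  # keep every passing term above the bar
                t = min(slot, key=slot.get)
            ratings[t][slot[t]] = 1
            slot[t] += 1
        pos = {t: n_raters - 1 for t in pass_terms}
        for j in range(n_threes):
            t = pass_terms[j % len(pass_terms)]
            while ratings[t][pos[t]] != 2:
                pos[t] -= 1
            ratings[t][pos[t]] = 3
            pos[t] -= 1
        per_term.update(ratings)
    for i in fail_set:
        # 80% bar missed: ceil(0.8*n)-? -> give just under 80% at >= 2
        n_low = int(n_raters * 0.2) + 1
        per_term[terms[i]] = [1] * n_low + [2] * (n_raters - n_low)

    rating_map: dict[tuple[str, str], int] = {}
    for term in terms:
        values = per_term[term][:]
        rng.shuffle(values)
        for resp, value in zip(respondents, values):
            rating_map[(resp, term)] = value
    return SurveyRound(
        round_id=round_id,
        terms=tuple(terms),
        respondents=respondents,
        ratings=rating_map,
        suggestions=suggestions or {},
    )


def generate_suggestions(
    candidate_terms: Sequence[str],
    respondents: Sequence[str],
    noise_terms: Sequence[str] = (),
    min_endorsers: int = 3,
    seed: int = 0,
) -> dict[str, tuple[str, ...]]:
    """Free-text suggestion lists in which each candidate term is endorsed by
    at least ``min_endorsers`` distinct respondents and each noise term by
    fewer, so exactly the candidates clear a 10% endorsement threshold."""
    rng = random.Random(seed)
    respondents = list(respondents)
    per_resp: dict[str, list[str]] = {r: [] for r in respondents}
    for term in candidate_terms:
        extra = rng.randint(0, max(0, len(respondents) // 4 - min_endorsers))
        for r in rng.sample(respondents, min_endorsers + extra):
            per_resp[r].append(term)
    for term in noise_terms:
        for r in rng.sample(respondents, max(1, min_endorsers - 1)):
            per_resp[r].append(term)
    return {r: tuple(v) for r, v in per_resp.items() if v}


# ---------------------------------------------------------------------------
# Separable sentence data for the SVM classifier
# ---------------------------------------------------------------------------

_SVM_POSITIVE_SEEDS = (
    "abuse", "neglect", "child protective services", "foster care",
    "physical abuse", "sexual abuse",
)
_SVM_FILLER_WORDS = (
    "patient", "seen", "today", "clinic", "well", "visit", "normal", "exam",
    "growth", "diet", "sleep", "school", "plan", "return", "weeks", "stable",
    "review", "family", "caregiver", "immunizations",
)


def generate_sentence_dataset(
    n: int, positive_frac: float = 0.714, seed: int = 0
) -> "SentenceDataset":
    """Linearly separable labeled sentences: every positive contains a CAN
    seed phrase, no negative ever does. Class balance defaults to the
    71.4/28.6 split of the labeled review data."""
    from .svm_classifier import SentenceDataset

    rng = random.Random(seed)
    n_pos = round(n * positive_frac)
    sentences: list[str] = []
    labels: list[int] = []
    for i in range(n):
        words = rng.choices(_SVM_FILLER_WORDS, k=rng.randint(5, 10))
        if i < n_pos:
            words.insert(rng.randint(0, len(words)), rng.choice(_SVM_POSITIVE_SEEDS))
            labels.append(1)
        else:
            labels.append(0)
        sentences.append(" ".join(words))
    order = list(range(n))
    rng.shuffle(order)
    return SentenceDataset(
        tuple(sentences[i] for i in order),
        tuple(labels[i] for i in order),
        partition="synthetic",
    )
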