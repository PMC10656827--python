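"""CAN lexicon curation and compilation.

Builds the child-abuse-and-neglect (CAN) term dictionary from investigator
seed terms and multi-round expert survey ratings, and compiles it into a
token-boundary matcher used by the annotator.

The curation workflow mirrors expert-consensus practice: a seed list is
rated on a 3-point importance scale (1 = not important, 2 = somewhat
important, 3 = critical for inclusion); a term is retained when at least 80%
of its raters score it 2 or higher; free-text suggestions endorsed by at
least 10% of respondents roll into the next round.
"""

from __future__ import annotations

import csv
from collections import OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._text import normalize_phrase, phrase_words

__all__ = [
    "SUBTYPES",
    "SUBTYPE_PRIORITY",
    "LexiconError",
    "LexiconTerm",
    "SurveyRound",
    "RatingSummary",
    "RatingAggregate",
    "aggregate_ratings",
    "retain_terms",
    "collect_suggestions",
    "load_lexicon",
    "save_lexicon",
    "starter_lexicon",
    "compile_matcher",
    "LexiconMatcher",
]

#: The five CAN mention subtypes.
SUBTYPES = (
    "ABUSE",
    "SEXUAL_ABUSE",
    "PHYSICAL_INDICATION",
    "EMOTIONAL_INDICATION",
    "SERVICE",
)

#: Tie-break priority for equal-span matches: prefer the clinically more
#: specific label. Lower value wins.
SUBTYPE_PRIORITY = {
    "SEXUAL_ABUSE": 0,
    "PHYSICAL_INDICATION": 1,
    "EMOTIONAL_INDICATION": 2,
    "ABUSE": 3,
    "SERVICE": 4,
}

SPECIFICITIES = ("standard", "low")
SOURCES = ("investigator", "expert_round1", "expert_round2")

#: An all-uppercase variant this short (e.g. "SA", "CPS", "PTSD") is matched
#: case-sensitively to avoid clashing with ordinary lowercase words.
MAX_CASED_ABBREV_LEN = 4


class LexiconError(ValueError):
    """Raised for invalid lexicon rows or inconsistent term definitions."""


@dataclass(frozen=True)
class LexiconTerm:
    """One dictionary entry.

    ``surface`` is the lowercase canonical phrase (1..8 tokens); ``variants``
    are alternative surfaces, e.g. the abbreviation "SA" for "sexual abuse".
    ``specificity`` "low" marks terms (e.g. "police") that only indicate CAN
    when corroborated by a stronger mention nearby in the note.
    """

    surface: str
    subtype: str
    variants: tuple[str, ...] = ()
    specificity: str = "standard"
    source: str = "investigator"
    mean_rating: Optional[float] = None
    prop_at_least_2: Optional[float] = None

    def __post_init__(self) -> None:
        norm = normalize_phrase(self.surface)
        if not norm:
            raise LexiconError(f"term surface {self.surface!r} is empty after normalization")
        if not 1 <= len(norm.split()) <= 8:
            raise LexiconError(f"term surface {norm!r} must have 1..8 tokens")
        object.__setattr__(self, "surface", norm)
        if self.subtype not in SUBTYPES:
            raise LexiconError(
                f"unknown subtype {self.subtype!r}; allowed: {', '.join(SUBTYPES)}"
            )
        if self.specificity not in SPECIFICITIES:
            raise LexiconError(
                f"unknown specificity {self.specificity!r}; allowed: {', '.join(SPECIFICITIES)}"
            )
        if self.source not in SOURCES:
            raise LexiconError(
                f"unknown source {self.source!r}; allowed: {', '.join(SOURCES)}"
            )
        if self.mean_rating is not None:
            if not 1.0 <= self.mean_rating <= 3.0:
                raise LexiconError("mean_rating must lie in [1, 3]")
            if self.prop_at_least_2 is None:
                raise LexiconError("mean_rating present requires prop_at_least_2")
        if self.prop_at_least_2 is not None and not 0.0 <= self.prop_at_least_2 <= 1.0:
            raise LexiconError("prop_at_least_2 must lie in [0, 1]")

    @property
    def all_surfaces(self) -> tuple[str, ...]:
        return (self.surface,) + self.variants


@dataclass(frozen=True)
class SurveyRound:
    """Ratings and free-text suggestions from one expert survey round."""

    round_id: str
    terms: tuple[str, ...]
    respondents: tuple[str, ...]
    ratings: Mapping[tuple[str, str], int]  # (respondent, term) -> 1|2|3
    suggestions: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        term_set = set(self.terms)
        resp_set = set(self.respondents)
        for (resp, term), rating in self.ratings.items():
            if rating not in (1, 2, 3):
                raise ValueError(f"rating {rating!r} for {term!r} not in {{1,2,3}}")
            if term not in term_set:
                raise ValueError(f"rating for {term!r} which was not presented")
            if resp not in resp_set:
                raise ValueError(f"rating from unknown respondent {resp!r}")


@dataclass(frozen=True)
class RatingSummary:
    term: str
    n_raters: int
    mean_rating: float
    prop_at_least_2: float


@dataclass(frozen=True)
class RatingAggregate:
    """Per-term summaries plus the terms nobody rated (excluded downstream)."""

    summaries: tuple[RatingSummary, ...]
    unrated: tuple[str, ...]

    @property
    def grand_mean(self) -> float:
        total = sum(s.mean_rating * s.n_raters for s in self.summaries)
        n = sum(s.n_raters for s in self.summaries)
        return total / n


def aggregate_ratings(survey_round: SurveyRound) -> RatingAggregate:
    """Summarize a round: per-term rater count, mean, and share of ratings >= 2.

    Terms presented but never rated are reported as ``unrated`` and take no
    part in retention decisions. Presentation order is preserved.
    """
    by_term: dict[str, list[int]] = {t: [] for t in survey_round.terms}
    for (_, term), rating in survey_round.ratings.items():
        by_term[term].append(rating)
    summaries = []
    unrated = []
    for term in survey_round.terms:
        ratings = by_term[term]
        if not ratings:
            unrated.append(term)
            continue
        summaries.append(
            RatingSummary(
                term=term,
                n_raters=len(ratings),
                mean_rating=sum(ratings) / len(ratings),
                prop_at_least_2=sum(r >= 2 for r in ratings) / len(ratings),
            )
        )
    return RatingAggregate(tuple(summaries), tuple(unrated))


def retain_terms(
    aggregate: RatingAggregate | Sequence[RatingSummary],
    min_prop: float = 0.80,
) -> list[str]:
    """Retention rule: keep a term iff at least ``min_prop`` of its raters
    scored it 2 or higher. A share of exactly ``min_prop`` is retained
    ("at least 80%"). Order is preserved; deterministic."""
    summaries = aggregate.summaries if isinstance(aggregate, RatingAggregate) else aggregate
    return [s.term for s in summaries if s.prop_at_least_2 >= min_prop]


def collect_suggestions(survey_round: SurveyRound, min_frac: float = 0.10) -> list[str]:
    """Candidate terms for the next round: normalized free-text suggestions
    endorsed by at least ``min_frac`` of the round's respondents.

    Endorsers are counted as distinct respondents after normalization merges
    typographic duplicates; empty suggestions are ignored. Candidates come
    back in first-appearance order.
    """
    n_resp = len(survey_round.respondents)
    endorsers: "OrderedDict[str, set[str]]" = OrderedDict()
    for resp in survey_round.respondents:
        for raw in survey_round.suggestions.get(resp, ()):
            term = normalize_phrase(raw)
            if not term:
                continue
            endorsers.setdefault(term, set()).add(resp)
    return [t for t, who in endorsers.items() if len(who) / n_resp >= min_frac]


# ---------------------------------------------------------------------------
# TSV persistence
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "term",
    "variants",
    "subtype",
    "specificity",
    "source",
    "mean_rating",
    "prop_at_least_2",
)


def load_lexicon(path: str | Path) -> list[LexiconTerm]:
    """Load a lexicon TSV (UTF-8, header row, variants '|'-separated).

    Unknown subtypes and duplicate (surface, subtype) pairs are hard errors
    naming the offending row.
    """
    terms: list[LexiconTerm] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or reader.fieldnames[0] != "term":
            raise LexiconError(f"{path}: missing or malformed header row")
        for row_no, row in enumerate(reader, start=2):
            try:
                term = _term_from_row(row)
            except LexiconError as exc:
                raise LexiconError(f"{path}: row {row_no}: {exc}") from None
            key = (term.surface, term.subtype)
            if key in seen:
                raise LexiconError(
                    f"{path}: row {row_no}: duplicate (surface, subtype) pair {key!r}"
                )
            seen.add(key)
            terms.append(term)
    return terms


def _term_from_row(row: Mapping[str, Optional[str]]) -> LexiconTerm:
    def get(col: str) -> str:
        value = row.get(col)
        return value.strip() if value else ""

    variants = tuple(v.strip() for v in get("variants").split("|") if v.strip())
    mean_rating = float(get("mean_rating")) if get("mean_rating") else None
    prop = float(get("prop_at_least_2")) if get("prop_at_least_2") else None
    return LexiconTerm(
        surface=get("term"),
        variants=variants,
        subtype=get("subtype"),
        specificity=get("specificity") or "standard",
        source=get("source") or "investigator",
        mean_rating=mean_rating,
        prop_at_least_2=prop,
    )


def save_lexicon(terms: Iterable[LexiconTerm], path: str | Path) -> None:
    """Write a lexicon TSV; ``load_lexicon`` of the result round-trips."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for t in terms:
            writer.writerow(
                [
                    t.surface,
                    "|".join(t.variants),
                    t.subtype,
                    t.specificity,
                    t.source,
                    "" if t.mean_rating is None else repr(t.mean_rating),
                    "" if t.prop_at_least_2 is None else repr(t.prop_at_least_2),
                ]
            )


def starter_lexicon() -> list[LexiconTerm]:
    """The bundled starter lexicon: the published CAN terms, subtyped.

    The full expert-validated pool is not public; this ships the recoverable
    union (seed examples, top entities, and the five low-specificity terms)
    and the TSV format is the extension point.
    """
    with resources.as_file(
        resources.files("canscreen.data").joinpath("starter_lexicon.tsv")
    ) as p:
        return load_lexicon(p)


# ---------------------------------------------------------------------------
# Matcher compilation
# ---------------------------------------------------------------------------


def _is_cased_abbrev(surface: str) -> bool:
    return surface.isalpha() and surface.isupper() and len(surface) <= MAX_CASED_ABBREV_LEN


@dataclass
class _Entry:
    term: LexiconTerm
    lexicon_surface: str  # canonical surface the hit maps back to


class LexiconMatcher:
    """Token-boundary dictionary matcher.

    Ordinary surfaces match case-insensitively on word-token sequences;
    all-uppercase variants of length <= 4 match case-sensitively ("SA"
    matches "SA" but not "sa"). ``lookup`` returns the longest match at a
    token position; equal-length candidates are resolved by subtype
    priority (most specific first).
    """

    def __init__(self, terms: Sequence[LexiconTerm]):
        if not terms:
            raise LexiconError("cannot compile an empty lexicon")
        self.terms = list(terms)
        self._ci: dict[tuple[str, ...], list[_Entry]] = {}
        self._cs: dict[tuple[str, ...], list[_Entry]] = {}
        self.max_len = 1
        for term in terms:
            for surf in term.all_surfaces:
                entry = _Entry(term, term.surface)
                if _is_cased_abbrev(surf):
                    self._cs.setdefault((surf,), []).append(entry)
                else:
                    key = tuple(phrase_words(surf))
                    if not key:
                        continue
                    self.max_len = max(self.max_len, len(key))
                    self._ci.setdefault(key, []).append(entry)

    def lookup(self, words: Sequence, i: int) -> Optional[tuple[int, LexiconTerm, str]]:
        """Longest match starting at word position ``i``.

        ``words`` is a sequence of word tokens (objects with ``.text``).
        Returns (length_in_tokens, term, lexicon_surface) or None.
        """
        limit = min(self.max_len, len(words) - i)
        for length in range(limit, 0, -1):
            exact = tuple(w.text for w in words[i : i + length])
            candidates = list(self._cs.get(exact, ()))
            candidates += self._ci.get(tuple(s.lower() for s in exact), ())
            if candidates:
                best = min(candidates, key=lambda e: SUBTYPE_PRIORITY[e.term.subtype])
                return length, best.term, best.lexicon_surface
        return None


def compile_matcher(terms: Sequence[LexiconTerm]) -> LexiconMatcher:
    """Compile a lexicon into a :class:`LexiconMatcher`."""
    return LexiconMatcher(terms)
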