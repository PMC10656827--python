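"""Rule-based CAN annotation pipeline.

Stages, in the order they run on each note:

1. sentence detection (rule-based; periods, !, ?, blank lines, list markers);
2. tokenization (shared convention from :mod:`canscreen._text`);
3. dictionary named-entity recognition against a compiled CAN lexicon
   (leftmost-longest, non-overlapping, token-boundary matching);
4. negation detection (NegEx-style pre/post triggers with a token scope and
   scope-terminating conjunctions);
5. exclusion rules r1..r5 for the recurring false-positive patterns
   (non-patient subjects, template legends, first-aid boilerplate,
   section-header fragments, abbreviation expansions);
6. corroboration of low-specificity terms ("police", "case manager", ...)
   which only count when a standard-specificity mention occurs within a
   sentence window in the same note;
7. sentence classification (positive iff >= 1 surviving mention) and
   document classification (positive iff >= 1 positive sentence).

All character offsets are 0-based, half-open, in note coordinates.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from ._text import Token, tokenize_text, word_tokens
from .corpus_io import ClinicalNote
from .lexicon import SUBTYPES, LexiconMatcher

__all__ = [
    "Sentence",
    "EntityMention",
    "SentenceLabel",
    "DocumentLabel",
    "NegationRule",
    "ExclusionRule",
    "AnnotatorConfig",
    "DocumentAnnotation",
    "RuleConfigError",
    "split_sentences",
    "tokenize",
    "match_entities",
    "detect_negation",
    "apply_exclusions",
    "corroborate_low_specificity",
    "classify_sentence",
    "classify_document",
    "annotate_note",
    "annotate_corpus",
    "default_negation_rules",
    "default_exclusion_rules",
    "load_rules",
    "annotations_to_jsonl",
    "write_brat",
]


class RuleConfigError(ValueError):
    """Raised when a rule file contains an unknown rule kind or bad params."""


# ---------------------------------------------------------------------------
# Sentence detection
# ---------------------------------------------------------------------------

#: Period is suppressed after these abbreviations (lowercased, incl. the dot).
ABBREVIATIONS = (
    "dr.", "mr.", "mrs.", "ms.", "vs.", "e.g.", "i.e.", "mg.", "kg.", "yo.",
)

_LIST_MARKER_RE = re.compile(r"(?:[-*•]|\d{1,2}[.)])\s")


@dataclass(frozen=True)
class Sentence:
    """A sentence span in note coordinates; ``text`` equals the note slice."""

    note_id: str
    index: int
    begin: int
    end: int
    text: str


def _protected_period(text: str, i: int) -> bool:
    nxt = text[i + 1] if i + 1 < len(text) else ""
    prev = text[i - 1] if i > 0 else ""
    if prev.isdigit() and nxt.isdigit():
        return True  # decimal number
    if nxt.isalnum():
        return True  # internal period (e.g. the first dot of "e.g.")
    window = text[max(0, i - 4) : i + 1].lower()
    for abbr in ABBREVIATIONS:
        if window.endswith(abbr):
            before = text[i - len(abbr)] if i - len(abbr) >= 0 else " "
            if not before.isalnum():
                return True
    return False


def split_sentences(note: ClinicalNote | str, note_id: str = "") -> list[Sentence]:
    """Rule-based sentence detector.

    Boundaries occur at sentence-final punctuation (. ! ?), runs of two or
    more newlines, and before list-item markers at the start of a line.
    Periods after bundled abbreviations, inside decimals, and glued to a
    following alphanumeric do not split. Colons never split — clinical
    headers run into their content. Empty text yields zero sentences.
    """
    if isinstance(note, ClinicalNote):
        text, note_id = note.text, note.note_id
    else:
        text = note
    n = len(text)
    bounds: list[int] = []
    i = 0
    while i < n:
        c = text[i]
        if c in ".!?":
            if c == "." and _protected_period(text, i):
                i += 1
                continue
            j = i + 1
            while j < n and text[j] in ".!?\"')]":
                j += 1
            bounds.append(j)
            i = j
        elif c == "\n":
            j = i + 1
            while j < n and text[j] in " \t\n":
                j += 1
            run = text[i:j].count("\n")
            if run >= 2 or _LIST_MARKER_RE.match(text, j):
                bounds.append(i)
                i = j
            else:
                i += 1
        else:
            i += 1
    bounds.append(n)
    sentences: list[Sentence] = []
    start = 0
    for b in bounds:
        begin, end = start, b
        while begin < end and text[begin].isspace():
            begin += 1
        while end > begin and text[end - 1].isspace():
            end -= 1
        if begin < end:
            sentences.append(
                Sentence(note_id, len(sentences), begin, end, text[begin:end])
            )
        start = b
    return sentences


def tokenize(sentence: Sentence) -> list[Token]:
    """Tokenize a sentence; token spans are in note coordinates."""
    return tokenize_text(sentence.text, offset=sentence.begin)


# ---------------------------------------------------------------------------
# Dictionary NER
# ---------------------------------------------------------------------------


@dataclass
class EntityMention:
    """A dictionary hit with its assertion flags.

    ``span`` fields are note coordinates; ``matched_surface`` is the exact
    note slice, ``lexicon_surface`` the canonical dictionary phrase.
    """

    note_id: str
    sentence_index: int
    begin: int
    end: int
    matched_surface: str
    lexicon_surface: str
    subtype: str
    specificity: str
    negated: bool = False
    excluded: bool = False
    exclusion_rule_id: Optional[str] = None

    @property
    def qualifying(self) -> bool:
        return not self.negated and not self.excluded


def match_entities(
    sentence: Sentence, tokens: Sequence[Token], matcher: LexiconMatcher
) -> list[EntityMention]:
    """Leftmost-longest non-overlapping dictionary matching over word tokens.

    Case rules follow the compiled matcher: ordinary phrases are
    case-insensitive, short all-caps abbreviations case-sensitive. Mentions
    never span sentence boundaries (matching is per sentence).
    """
    words = word_tokens(list(tokens))
    mentions: list[EntityMention] = []
    i = 0
    while i < len(words):
        hit = matcher.lookup(words, i)
        if hit is None:
            i += 1
            continue
        length, term, lexicon_surface = hit
        begin = words[i].begin
        end = words[i + length - 1].end
        mentions.append(
            EntityMention(
                note_id=sentence.note_id,
                sentence_index=sentence.index,
                begin=begin,
                end=end,
                matched_surface=sentence.text[begin - sentence.begin : end - sentence.begin],
                lexicon_surface=lexicon_surface,
                subtype=term.subtype,
                specificity=term.specificity,
            )
        )
        i += length
    return mentions


# ---------------------------------------------------------------------------
# Negation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NegationRule:
    """A NegEx-style trigger with direction and token scope."""

    trigger: str
    direction: str = "pre"  # or "post"
    scope_tokens: int = 6
    terminators: tuple[str, ...] = ("but", "however", "although", "except")

    def __post_init__(self) -> None:
        if self.direction not in ("pre", "post"):
            raise RuleConfigError(f"negation direction must be pre/post, got {self.direction!r}")
        if self.scope_tokens < 1:
            raise RuleConfigError("scope_tokens must be >= 1")


DEFAULT_NEGATION_TRIGGERS = (
    "no", "not", "denies", "deny", "denied", "without",
    "negative for", "no evidence of", "no signs of", "never",
)


def default_negation_rules() -> list[NegationRule]:
    return [NegationRule(t) for t in DEFAULT_NEGATION_TRIGGERS]


def _token_index_at(tokens: Sequence[Token], begin: int) -> int:
    for idx, t in enumerate(tokens):
        if t.begin >= begin:
            return idx
    return len(tokens)


def detect_negation(
    mentions: Sequence[EntityMention],
    tokens: Sequence[Token],
    rules: Optional[Sequence[NegationRule]] = None,
) -> list[EntityMention]:
    """Set ``negated`` flags in place (and return the mentions).

    A mention is negated iff a pre-trigger ends within ``scope_tokens``
    tokens before its first token (or a post-trigger starts within scope
    after its last token) with no terminator between trigger and mention.
    Scope is counted over all tokens, punctuation included.
    """
    if rules is None:
        rules = default_negation_rules()
    lowered = [t.text.lower() for t in tokens]
    for m in mentions:
        first = _token_index_at(tokens, m.begin)
        last = _token_index_at(tokens, m.end) - 1
        for rule in rules:
            trig = rule.trigger.lower().split()
            k = len(trig)
            if rule.direction == "pre":
                lo = max(0, first - rule.scope_tokens - k + 1)
                for p in range(lo, first - k + 1):
                    if lowered[p : p + k] != trig:
                        continue
                    between = lowered[p + k : first]
                    if not any(t in rule.terminators for t in between):
                        m.negated = True
                        break
            else:
                hi = min(len(tokens), last + 1 + rule.scope_tokens)
                for p in range(last + 1, hi - k + 1):
                    if lowered[p : p + k] != trig:
                        continue
                    between = lowered[last + 1 : p]
                    if not any(t in rule.terminators for t in between):
                        m.negated = True
                        break
            if m.negated:
                break
    return list(mentions)


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------

_EXCLUSION_KINDS = (
    "phrase_blacklist",
    "template_pattern",
    "section_header",
    "non_patient_subject",
)


@dataclass(frozen=True)
class ExclusionRule:
    """A configurable false-positive suppressor; see data/default_rules.yaml."""

    rule_id: str
    kind: str
    params: dict = field(default_factory=dict)
    scope: str = "sentence"

    def __post_init__(self) -> None:
        if self.kind not in _EXCLUSION_KINDS:
            raise RuleConfigError(
                f"unknown exclusion rule kind {self.kind!r}; allowed: "
                + ", ".join(_EXCLUSION_KINDS)
            )
        if self.scope not in ("sentence", "note"):
            raise RuleConfigError(f"rule scope must be sentence/note, got {self.scope!r}")


@lru_cache(maxsize=1)
def _load_default_rule_file() -> tuple:
    with resources.files("canscreen.data").joinpath("default_rules.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return _parse_rule_doc(yaml.safe_load(fh))


def load_rules(path: str | Path) -> tuple[list[NegationRule], list[ExclusionRule]]:
    """Load negation and exclusion rules from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _parse_rule_doc(doc)


def _parse_rule_doc(doc: dict) -> tuple[list[NegationRule], list[ExclusionRule]]:
    neg = doc.get("negation", {}) or {}
    scope = int(neg.get("scope_tokens", 6))
    terminators = tuple(neg.get("terminators", ("but", "however", "although", "except")))
    negation_rules = [
        NegationRule(t, "pre", scope, terminators)
        for t in neg.get("triggers", DEFAULT_NEGATION_TRIGGERS)
    ]
    exclusion_rules = []
    seen_ids: set[str] = set()
    for raw in doc.get("exclusions", ()) or ():
        rule = ExclusionRule(
            rule_id=str(raw["rule_id"]),
            kind=str(raw["kind"]),
            params=dict(raw.get("params", {}) or {}),
            scope=str(raw.get("scope", "sentence")),
        )
        if rule.rule_id in seen_ids:
            raise RuleConfigError(f"duplicate exclusion rule_id {rule.rule_id!r}")
        seen_ids.add(rule.rule_id)
        exclusion_rules.append(rule)
    return negation_rules, exclusion_rules


def default_exclusion_rules() -> list[ExclusionRule]:
    return list(_load_default_rule_file()[1])


def _fires_non_patient_subject(
    rule: ExclusionRule, m: EntityMention, sentence: Sentence, tokens: Sequence[Token]
) -> bool:
    kin = {k.lower() for k in rule.params.get("kin_tokens", ())}
    markers = {k.lower() for k in rule.params.get("history_markers", ())}
    window = int(rule.params.get("window_tokens", 6))
    words = word_tokens(list(tokens))
    lowered = [w.text.lower() for w in words]
    first = 0
    for idx, w in enumerate(words):
        if w.begin >= m.begin:
            first = idx
            break
    else:
        first = len(words)
    before = lowered[max(0, first - window) : first]
    return bool(kin & set(before)) and bool(markers & set(lowered))


def _fires_template_pattern(
    rule: ExclusionRule, m: EntityMention, sentence: Sentence, tokens: Sequence[Token]
) -> bool:
    for pat in rule.params.get("patterns", ()):
        if re.search(pat, sentence.text):
            return True
    if rule.params.get("paren_definition"):
        # "STD (sexually transmitted disease" style artifacts: a mention
        # immediately followed by an opening parenthesis, or sitting inside
        # one that follows an all-caps abbreviation.
        idx_first = _token_index_at(tokens, m.begin)
        idx_last = _token_index_at(tokens, m.end) - 1
        if idx_last + 1 < len(tokens) and tokens[idx_last + 1].text == "(":
            return True
        if idx_first >= 2 and tokens[idx_first - 1].text == "(":
            prev = tokens[idx_first - 2].text
            return prev.isalpha() and prev.isupper()
    return False


def _fires_phrase_blacklist(
    rule: ExclusionRule, m: EntityMention, sentence: Sentence, tokens: Sequence[Token]
) -> bool:
    low = sentence.text.lower()
    if any(low.startswith(p.lower()) for p in rule.params.get("starts_with", ())):
        return True
    return any(p.lower() in low for p in rule.params.get("contains", ()))


def _fires_section_header(
    rule: ExclusionRule, m: EntityMention, sentence: Sentence, tokens: Sequence[Token]
) -> bool:
    verbs = {v.lower() for v in rule.params.get("verbs", ())}
    colon = sentence.text.find(":", m.end - sentence.begin)
    if colon < 0:
        return False
    header = sentence.text[:colon]
    header_words = {w.lower() for w in re.findall(r"[A-Za-z0-9]+", header)}
    return not (header_words & verbs)


_RULE_DISPATCH = {
    "non_patient_subject": _fires_non_patient_subject,
    "template_pattern": _fires_template_pattern,
    "phrase_blacklist": _fires_phrase_blacklist,
    "section_header": _fires_section_header,
}


def apply_exclusions(
    mentions: Sequence[EntityMention],
    sentence: Sentence,
    tokens: Sequence[Token],
    rules: Optional[Sequence[ExclusionRule]] = None,
) -> list[EntityMention]:
    """Set ``excluded`` flags (first firing rule wins, in rule order)."""
    if rules is None:
        rules = default_exclusion_rules()
    for m in mentions:
        if m.excluded:
            continue
        for rule in rules:
            if _RULE_DISPATCH[rule.kind](rule, m, sentence, tokens):
                m.excluded = True
                m.exclusion_rule_id = rule.rule_id
                break
    return list(mentions)


def corroborate_low_specificity(
    mentions: Sequence[EntityMention], window_sentences: int = 3
) -> list[EntityMention]:
    """Document-level corroboration of low-specificity terms.

    A low-specificity mention is excluded unless a standard-specificity,
    non-negated, non-excluded mention occurs within ``window_sentences``
    sentences in the same note. ``mentions`` must be the full document set.
    """
    anchors = [
        m.sentence_index
        for m in mentions
        if m.specificity == "standard" and m.qualifying
    ]
    for m in mentions:
        if m.specificity != "low" or not m.qualifying:
            continue
        if not any(abs(a - m.sentence_index) <= window_sentences for a in anchors):
            m.excluded = True
            m.exclusion_rule_id = "low_specificity"
    return list(mentions)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SentenceLabel:
    """Sentence-level CAN decision with its supporting mentions."""

    note_id: str
    sentence_index: int
    positive: bool
    active_subtypes: frozenset[str]
    supporting: tuple[int, ...]  # indices into the document mention list


@dataclass(frozen=True)
class DocumentLabel:
    """Note-level decision: positive iff any sentence is positive."""

    note_id: str
    positive: bool
    n_positive_sentences: int
    subtype_counts: dict


def classify_sentence(
    note_id: str,
    sentence_index: int,
    mentions: Sequence[EntityMention],
    mention_offset: int = 0,
) -> SentenceLabel:
    """Positive iff at least one mention survives negation and exclusion."""
    supporting = tuple(
        mention_offset + i for i, m in enumerate(mentions) if m.qualifying
    )
    subtypes = frozenset(m.subtype for m in mentions if m.qualifying)
    return SentenceLabel(note_id, sentence_index, bool(supporting), subtypes, supporting)


def classify_document(
    note_id: str,
    sentence_labels: Sequence[SentenceLabel],
    mentions: Sequence[EntityMention] = (),
) -> DocumentLabel:
    """Any note with >= 1 positive sentence is a positive CAN note."""
    n_pos = sum(1 for s in sentence_labels if s.positive)
    counts = {s: 0 for s in SUBTYPES}
    for m in mentions:
        if m.qualifying:
            counts[m.subtype] += 1
    return DocumentLabel(note_id, n_pos >= 1, n_pos, counts)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnnotatorConfig:
    """Pipeline toggles; defaults are the full rule set, window 3."""

    negation_rules: Optional[list[NegationRule]] = None
    exclusion_rules: Optional[list[ExclusionRule]] = None
    negation_enabled: bool = True
    exclusions_enabled: bool = True
    corroboration_window: int = 3

    def resolved_negation(self) -> list[NegationRule]:
        return self.negation_rules if self.negation_rules is not None else default_negation_rules()

    def resolved_exclusions(self) -> list[ExclusionRule]:
        return self.exclusion_rules if self.exclusion_rules is not None else default_exclusion_rules()


@dataclass
class DocumentAnnotation:
    """All pipeline outputs for one note."""

    note_id: str
    sentences: list[Sentence]
    mentions: list[EntityMention]
    sentence_labels: list[SentenceLabel]
    document_label: DocumentLabel


def annotate_note(
    note: ClinicalNote,
    matcher: LexiconMatcher,
    config: Optional[AnnotatorConfig] = None,
) -> DocumentAnnotation:
    """Run the full pipeline on one note."""
    config = config or AnnotatorConfig()
    negation_rules = config.resolved_negation()
    exclusion_rules = config.resolved_exclusions()
    sentences = split_sentences(note)
    all_mentions: list[EntityMention] = []
    per_sentence: list[list[EntityMention]] = []
    for sent in sentences:
        tokens = tokenize(sent)
        mentions = match_entities(sent, tokens, matcher)
        if mentions:
            if config.negation_enabled:
                detect_negation(mentions, tokens, negation_rules)
            if config.exclusions_enabled:
                apply_exclusions(mentions, sent, tokens, exclusion_rules)
        per_sentence.append(mentions)
        all_mentions.extend(mentions)
    if config.exclusions_enabled:
        corroborate_low_specificity(all_mentions, config.corroboration_window)
    labels: list[SentenceLabel] = []
    offset = 0
    for sent, mentions in zip(sentences, per_sentence):
        labels.append(classify_sentence(note.note_id, sent.index, mentions, offset))
        offset += len(mentions)
    doc_label = classify_document(note.note_id, labels, all_mentions)
    return DocumentAnnotation(note.note_id, sentences, all_mentions, labels, doc_label)


def annotate_corpus(
    notes: Iterable[ClinicalNote],
    matcher: LexiconMatcher,
    config: Optional[AnnotatorConfig] = None,
) -> list[DocumentAnnotation]:
    config = config or AnnotatorConfig()
    return [annotate_note(n, matcher, config) for n in notes]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def annotations_to_jsonl(annotations: Iterable[DocumentAnnotation], path: str | Path) -> None:
    """One JSON record per note: mentions, sentence labels, document label."""
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            record = {
                "note_id": ann.note_id,
                "mentions": [asdict(m) for m in ann.mentions],
                "sentence_labels": [
                    {
                        "note_id": s.note_id,
                        "sentence_index": s.sentence_index,
                        "positive": s.positive,
                        "active_subtypes": sorted(s.active_subtypes),
                        "supporting": list(s.supporting),
                    }
                    for s in ann.sentence_labels
                ],
                "document_label": asdict(ann.document_label),
            }
            fh.write(json.dumps(record, ensure_ascii=False))
            fh.write("\n")


def write_brat(annotation: DocumentAnnotation, directory: str | Path) -> Path:
    """Write BRAT-style standoff for one note: T lines with the subtype and
    span, A lines for Negated/Excluded attributes. Returns the .ann path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{annotation.note_id}.ann"
    lines = []
    attr = 0
    for i, m in enumerate(annotation.mentions, start=1):
        text = m.matched_surface.replace("\n", " ")
        lines.append(f"T{i}\t{m.subtype} {m.begin} {m.end}\t{text}")
        if m.negated:
            attr += 1
            lines.append(f"A{attr}\tNegated T{i}")
        if m.excluded:
            attr += 1
            rule = m.exclusion_rule_id or ""
            lines.append(f"A{attr}\tExcluded T{i} {rule}".rstrip())
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path
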