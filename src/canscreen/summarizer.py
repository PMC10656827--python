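"""Descriptive outputs: note-type positivity tables, subtype distributions,
top-entity rankings, and highlighted-note renderings for reviewer display."""

from __future__ import annotations

import html
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotator import DocumentAnnotation, DocumentLabel, EntityMention
from .corpus_io import ClinicalNote
from .lexicon import SUBTYPES

__all__ = [
    "NoteTypeRow",
    "note_type_table",
    "table_to_dataframe",
    "subtype_distribution",
    "top_entities",
    "render_highlights",
    "strip_highlights",
    "summary_markdown",
]


def _pct_2dp(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals (table formatting)."""
    value = Decimal(numerator * 100) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class NoteTypeRow:
    note_type: str
    n_notes: int
    n_positive: int
    positive_pct: float


def note_type_table(
    document_labels: Sequence[DocumentLabel], notes: Sequence[ClinicalNote]
) -> list[NoteTypeRow]:
    """Per-note-type positivity, sorted ascending by positive percentage.

    Every label must join to a note; ties in percentage break alphabetically.
    """
    by_id = {n.note_id: n for n in notes}
    totals: dict[str, int] = {}
    positives: dict[str, int] = {}
    for n in notes:
        totals[n.note_type] = totals.get(n.note_type, 0) + 1
        positives.setdefault(n.note_type, 0)
    for label in document_labels:
        note = by_id.get(label.note_id)
        if note is None:
            raise ValueError(f"document label {label.note_id!r} has no matching note")
        if label.positive:
            positives[note.note_type] += 1
    rows = [
        NoteTypeRow(t, totals[t], positives[t], _pct_2dp(positives[t], totals[t]))
        for t in totals
    ]
    rows.sort(key=lambda r: (r.positive_pct, r.note_type))
    return rows


def table_to_dataframe(rows: Sequence[NoteTypeRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "note_type": r.note_type,
                "n_notes": r.n_notes,
                "n_positive": r.n_positive,
                "positive_pct": r.positive_pct,
            }
            for r in rows
        ]
    )


def _qualifying(mentions: Iterable[EntityMention]) -> list[EntityMention]:
    return [m for m in mentions if m.qualifying]


def subtype_distribution(mentions: Sequence[EntityMention]) -> dict[str, float]:
    """Proportion of qualifying mentions ("hits") per subtype.

    All five subtypes are reported, zeros included, and the proportions sum
    to 1. Zero qualifying mentions yields an empty dict (flagged upstream),
    never a division error.
    """
    hits = _qualifying(mentions)
    if not hits:
        return {}
    counts = {s: 0 for s in SUBTYPES}
    for m in hits:
        counts[m.subtype] += 1
    total = len(hits)
    return {s: counts[s] / total for s in SUBTYPES}


def top_entities(mentions: Sequence[EntityMention], k: int) -> list[tuple[str, int]]:
    """Top ``k`` canonical lexicon surfaces among qualifying mentions,
    descending by count, ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for m in _qualifying(mentions):
        counts[m.lexicon_surface] = counts.get(m.lexicon_surface, 0) + 1
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


_SUBTYPE_ANSI = {
    "ABUSE": "31",
    "SEXUAL_ABUSE": "35",
    "PHYSICAL_INDICATION": "33",
    "EMOTIONAL_INDICATION": "36",
    "SERVICE": "32",
}

_HTML_SPAN_RE = re.compile(r"</?span[^>]*>")
_ANSI_RE = re.compile(r"\x1b\[[0-9;]*m")


def render_highlights(
    note: ClinicalNote,
    mentions: Sequence[EntityMention],
    format: str = "html",
) -> str:
    """Mark up qualifying mentions in the note body.

    HTML output wraps each mention in a subtype-classed ``<span>`` (the rest
    of the text HTML-escaped); "ansi" uses terminal colors. Stripping the
    markup with :func:`strip_highlights` reproduces the original text.
    """
    spans = sorted(
        ((m.begin, m.end, m.subtype) for m in mentions if m.qualifying),
        key=lambda s: s[0],
    )
    for begin, end, _ in spans:
        if begin < 0 or end > len(note.text) or begin >= end:
            raise ValueError(f"mention span ({begin}, {end}) outside note {note.note_id!r}")
    out: list[str] = []
    pos = 0
    if format == "html":
        for begin, end, subtype in spans:
            out.append(html.escape(note.text[pos:begin]))
            out.append(
                f'<span class="can-mention can-{subtype.lower()}" '
                f'data-subtype="{subtype}">{html.escape(note.text[begin:end])}</span>'
            )
            pos = end
        out.append(html.escape(note.text[pos:]))
    elif format == "ansi":
        for begin, end, subtype in spans:
            out.append(note.text[pos:begin])
            out.append(f"\x1b[{_SUBTYPE_ANSI[subtype]}m{note.text[begin:end]}\x1b[0m")
            pos = end
        out.append(note.text[pos:])
    else:
        raise ValueError(f"unknown highlight format {format!r}")
    return "".join(out)


def strip_highlights(markup: str, format: str = "html") -> str:
    """Inverse of :func:`render_highlights`."""
    if format == "html":
        return html.unescape(_HTML_SPAN_RE.sub("", markup))
    if format == "ansi":
        return _ANSI_RE.sub("", markup)
    raise ValueError(f"unknown highlight format {format!r}")


def summary_markdown(
    rows: Sequence[NoteTypeRow],
    distribution: dict[str, float],
    top: Sequence[tuple[str, int]],
) -> str:
    """A compact Markdown report of the three descriptive summaries."""
    lines = ["# CAN screening summary", "", "## CAN-positive notes by note type", ""]
    lines.append("| Note type | Notes | CAN positive | Positive % |")
    lines.append("|---|---:|---:|---:|")
    for r in rows:
        lines.append(f"| {r.note_type} | {r.n_notes} | {r.n_positive} | {r.positive_pct:.2f} |")
    lines += ["", "## Subtype distribution of qualifying hits", ""]
    if distribution:
        for s in SUBTYPES:
            lines.append(f"- {s}: {distribution[s] * 100:.1f}%")
    else:
        lines.append("- no qualifying mentions")
    lines += ["", "## Top entities", ""]
    for surface, count in top:
        lines.append(f"- {surface}: {count}")
    lines.append("")
    return "\n".join(lines)
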