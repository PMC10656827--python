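"""Precision-oriented evaluation with two-reviewer adjudication.

Real-data performance review in this setting is precision-only: reviewers
confirm or reject each NLP-identified unit, disagreements are adjudicated
(a third reviewer breaks ties), and precision = confirmed / identified at
sentence and document level. Recall and F1 are additionally computable on
synthetic corpora where gold annotations exist.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotator import DocumentAnnotation
from .corpus_io import ClinicalNote

__all__ = [
    "ReviewRecord",
    "EvalCounts",
    "adjudicate",
    "precision",
    "format_proportion",
    "format_precision",
    "EvalReport",
    "evaluate_against_gold",
    "sample_for_review",
]

_VERDICTS = ("confirm", "reject", "unsure")
_FINALS = ("true_positive", "false_positive", "unresolved")


@dataclass(frozen=True)
class ReviewRecord:
    """One NLP-positive unit with reviewer verdicts."""

    unit_id: str
    reviewer1: str
    reviewer2: str
    reviewer3: Optional[str] = None
    nlp_positive: bool = True
    final: Optional[str] = None

    def __post_init__(self) -> None:
        for who in ("reviewer1", "reviewer2"):
            if getattr(self, who) not in _VERDICTS:
                raise ValueError(f"{who} verdict must be one of {_VERDICTS}")
        if self.reviewer3 is not None and self.reviewer3 not in _VERDICTS:
            raise ValueError(f"reviewer3 verdict must be one of {_VERDICTS}")
        if self.final is not None and self.final not in _FINALS:
            raise ValueError(f"final must be one of {_FINALS}")


_VERDICT_TO_FINAL = {"confirm": "true_positive", "reject": "false_positive"}


def adjudicate(records: Iterable[ReviewRecord]) -> list[ReviewRecord]:
    """Resolve reviewer verdicts to final labels.

    Agreement on confirm/reject yields that label; any disagreement
    ("unsure" counts as disagreement) defers to reviewer3 when present;
    otherwise the unit is unresolved and blocked from precision computation.
    """
    out = []
    for r in records:
        if r.reviewer1 == r.reviewer2 and r.reviewer1 in _VERDICT_TO_FINAL:
            final = _VERDICT_TO_FINAL[r.reviewer1]
        elif r.reviewer3 in _VERDICT_TO_FINAL:
            final = _VERDICT_TO_FINAL[r.reviewer3]
        else:
            final = "unresolved"
        out.append(replace(r, final=final))
    return out


def precision(n_identified: int, n_confirmed: int) -> Optional[float]:
    """Confirmed / identified; ``None`` (not-available) when nothing was
    identified — never zero, never a division error."""
    if n_identified < 0 or n_confirmed < 0:
        raise ValueError("counts must be non-negative")
    if n_confirmed > n_identified:
        raise ValueError("n_confirmed cannot exceed n_identified")
    if n_identified == 0:
        return None
    return n_confirmed / n_identified


def format_proportion(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Exact half-up percentage formatting, e.g. (396, 422) -> '93.8%'."""
    if denominator == 0:
        return "n/a"
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator * 100) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return f"{value}%"


def format_precision(n_identified: int, n_confirmed: int, decimals: int = 1) -> str:
    """Precision as a 1-decimal percentage string; 'n/a' when undefined."""
    if precision(n_identified, n_confirmed) is None:
        return "n/a"
    return format_proportion(n_confirmed, n_identified, decimals)


@dataclass(frozen=True)
class EvalCounts:
    """Identified vs. review-confirmed counts at one level."""

    level: str  # "sentence" | "document"
    n_sample: int
    n_identified: int
    n_confirmed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_confirmed <= self.n_identified <= self.n_sample:
            raise ValueError("need n_confirmed <= n_identified <= n_sample")

    @property
    def precision(self) -> Optional[float]:
        return precision(self.n_identified, self.n_confirmed)


def _prf(tp: int, fp: int, fn: int) -> tuple[Optional[float], Optional[float], Optional[float]]:
    p = tp / (tp + fp) if tp + fp else None
    r = tp / (tp + fn) if tp + fn else None
    f1 = None
    if p is not None and r is not None and (p + r):
        f1 = 2 * p * r / (p + r)
    return p, r, f1


@dataclass(frozen=True)
class EvalReport:
    sentence_precision: Optional[float]
    sentence_recall: Optional[float]
    sentence_f1: Optional[float]
    document_precision: Optional[float]
    document_recall: Optional[float]
    document_f1: Optional[float]
    n_sentences: int
    n_documents: int


def evaluate_against_gold(
    annotations: Sequence[DocumentAnnotation],
    gold_positive_sentences: set[tuple[str, int]],
) -> EvalReport:
    """Precision/recall/F1 at sentence and document level against gold.

    ``gold_positive_sentences`` holds (note_id, sentence_index) units; every
    gold unit must exist in the predicted universe (unit mismatch is an
    error). Document gold = notes with at least one gold-positive sentence,
    consistent with the document classification rule.
    """
    universe: set[tuple[str, int]] = set()
    pred_pos: set[tuple[str, int]] = set()
    doc_ids: set[str] = set()
    pred_pos_docs: set[str] = set()
    for ann in annotations:
        doc_ids.add(ann.note_id)
        for label in ann.sentence_labels:
            unit = (label.note_id, label.sentence_index)
            universe.add(unit)
            if label.positive:
                pred_pos.add(unit)
        if ann.document_label.positive:
            pred_pos_docs.add(ann.note_id)
    stray = gold_positive_sentences - universe
    if stray:
        raise ValueError(f"gold units outside the predicted universe: {sorted(stray)[:5]}")
    gold_docs = {note_id for note_id, _ in gold_positive_sentences}

    tp_s = len(pred_pos & gold_positive_sentences)
    fp_s = len(pred_pos - gold_positive_sentences)
    fn_s = len(gold_positive_sentences - pred_pos)
    tp_d = len(pred_pos_docs & gold_docs)
    fp_d = len(pred_pos_docs - gold_docs)
    fn_d = len(gold_docs - pred_pos_docs)
    ps, rs, fs = _prf(tp_s, fp_s, fn_s)
    pd_, rd, fd = _prf(tp_d, fp_d, fn_d)
    return EvalReport(ps, rs, fs, pd_, rd, fd, len(universe), len(doc_ids))


def sample_for_review(
    annotations: Sequence[DocumentAnnotation],
    notes: Sequence[ClinicalNote],
    n_patients: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded patient-level review worksheet.

    Samples ``n_patients`` patients and lists every NLP-positive sentence of
    their notes with a +/-1-sentence context window and empty reviewer
    columns, ready for two-reviewer adjudication.
    """
    note_by_id = {n.note_id: n for n in notes}
    patients = sorted({n.patient_id for n in notes})
    if n_patients > len(patients):
        raise ValueError(f"cannot sample {n_patients} of {len(patients)} patients")
    chosen = set(random.Random(seed).sample(patients, n_patients))
    rows = []
    for ann in annotations:
        note = note_by_id.get(ann.note_id)
        if note is None or note.patient_id not in chosen:
            continue
        texts = [s.text for s in ann.sentences]
        for label in ann.sentence_labels:
            if not label.positive:
                continue
            i = label.sentence_index
            rows.append(
                {
                    "patient_id": note.patient_id,
                    "note_id": ann.note_id,
                    "note_type": note.note_type,
                    "sentence_index": i,
                    "context_before": texts[i - 1] if i > 0 else "",
                    "sentence_text": texts[i],
                    "context_after": texts[i + 1] if i + 1 < len(texts) else "",
                    "active_subtypes": "|".join(sorted(label.active_subtypes)),
                    "reviewer1": "",
                    "reviewer2": "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "note_id", "note_type", "sentence_index",
            "context_before", "sentence_text", "context_after",
            "active_subtypes", "reviewer1", "reviewer2",
        ],
    )
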