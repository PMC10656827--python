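# canscreen

Rule-based screening of clinical notes for child abuse and neglect (CAN).

Child abuse and neglect is prevalent, under-documented, and frequently
missed in pediatric primary care. Electronic health records hold the
evidence — referrals to child protective services, disclosures, injury
patterns — but scattered across thousands of notes that no provider has
time to read. `canscreen` implements the lexicon-plus-NLP approach to this
problem as a reusable toolkit, for health-informatics researchers and
clinical-NLP practitioners who want to build, refine, and evaluate CAN
screening pipelines without shipping protected health data:

- **lexicon** — expert-consensus dictionary curation: 3-point importance
  ratings aggregated per term, the "≥ 80% of raters scored ≥ 2" retention
  rule, 10%-endorsement collection of free-text suggestions, TSV
  persistence, and compilation into a token-boundary matcher. A starter
  lexicon of published CAN terms in five subtypes (ABUSE, SEXUAL_ABUSE,
  PHYSICAL_INDICATION, EMOTIONAL_INDICATION, SERVICE) is bundled.
- **annotator** — the core pipeline: sentence detection, tokenization,
  leftmost-longest dictionary NER, NegEx-style negation (trigger + 6-token
  scope + terminators), five configurable exclusion rules for recurring
  false-positive patterns, corroboration of low-specificity terms
  ("police", "case manager", …), and sentence/document classification:
  a sentence is CAN-positive iff it holds a mention that survives negation
  and exclusion; a note is positive iff any sentence is.
- **corpus_io / summarizer** — JSONL/CSV corpora with validation,
  deduplication and seeded patient-level splits; note-type positivity
  tables, subtype distributions, top-entity rankings, and highlighted-note
  HTML for reviewer display.
- **svm_classifier** — the machine-learning comparator: binary
  unigram/bigram/trigram features and a linear-kernel SVM over sentences,
  with per-class predictive value, sensitivity and specificity reporting.
- **evaluation** — precision-oriented review: two-reviewer adjudication
  with a third-reviewer tiebreak, precision = confirmed / identified with
  exact half-up percentage formatting, and full precision/recall/F1 against
  gold on synthetic corpora.
- **synthetic_corpus** — a seeded generator of pediatric-note corpora with
  gold annotations: planted mentions, negated mentions, five categories of
  false-positive trap sentences, duplicates, and survey-round synthesis,
  so every module is testable end to end.

## Worked example

```python
import canscreen as cs

matcher = cs.compile_matcher(cs.starter_lexicon())
note = cs.ClinicalNote(
    note_id="N001", patient_id="P01", note_type="Progress Notes",
    provider_category="physician", date="2016-03-02",
    text=("Pt seen for follow up today. Denies abuse at home.\n\n"
          "Caregiver reports prior referral to child protective services.\n\n"
          "police were involved per chart."),
)
ann = cs.annotate_note(note, matcher)
for m in ann.mentions:
    flag = ("negated" if m.negated
            else "excluded:" + m.exclusion_rule_id if m.excluded
            else "qualifying")
    print(f"[{m.begin:3d},{m.end:3d}) {m.matched_surface!r:35} {m.subtype:12} {flag}")
print("positive sentences:", [s.sentence_index for s in ann.sentence_labels if s.positive])
print("document positive:", ann.document_label.positive)
```

prints

```
[ 36, 41) 'abuse'                             ABUSE        negated
[ 88,113) 'child protective services'         SERVICE      qualifying
[116,122) 'police'                            SERVICE      qualifying
positive sentences: [2, 3]
document positive: True
```

"abuse" sits in the scope of "Denies", so it is negated and does not count.
"child protective services" is a clean SERVICE mention, which makes its
sentence — and therefore the note — CAN-positive. "police" is a
low-specificity term that would be suppressed on its own, but it is
corroborated by the child-protective-services mention two sentences
earlier (default window: 3 sentences), so it qualifies too.

The same workflow is available from the shell:

```bash
canscreen simulate --out runs/sim --seed 1
canscreen annotate --corpus runs/sim/corpus.jsonl --out runs/ann
canscreen summarize --corpus runs/sim/corpus.jsonl \
    --annotations runs/ann/annotations.jsonl --out runs/summary
canscreen eval --corpus runs/sim/corpus.jsonl \
    --annotations runs/ann/annotations.jsonl \
    --gold runs/sim/gold.jsonl --out runs/eval
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the default
parameters and why they were chosen, what the synthetic generator does and
does not emulate, and known limitations.
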