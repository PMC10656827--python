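# Methods

## The screening model

`canscreen` treats CAN screening as dictionary-based named-entity
recognition followed by rule-based assertion resolution. The unit of
evidence is the *mention*: a lexicon phrase matched at token boundaries
inside one sentence. A sentence is CAN-positive iff at least one of its
mentions survives three filters — negation, exclusion rules, and
low-specificity corroboration — and a note is CAN-positive iff at least
one of its sentences is. The model is deliberately shallow: no parsing, no
statistical NER, no coreference. Its assumptions are that CAN evidence is
lexicalized (a curated phrase appears in the text), sentence-local (a
mention's assertion status is decidable from its sentence, plus a small
sentence window for corroboration), and precision-critical (the intended
use is flagging notes for clinician review, where false positives cost
trust; recall on real data is unmeasurable without exhaustive chart
review, which is why the evaluation design is precision-oriented).

## Lexicon curation

Terms carry one of five subtypes (ABUSE, SEXUAL_ABUSE,
PHYSICAL_INDICATION, EMOTIONAL_INDICATION, SERVICE) and a specificity
class. Curation follows the expert-consensus workflow: raters score each
term 1–3 (not important / somewhat important / critical); a term is
retained when at least 80% of its raters scored it ≥ 2 (a share of exactly
80% is retained — the rule is "at least"); free-text suggestions endorsed
by ≥ 10% of respondents, after normalization, feed the next round.
Normalization is lowercase, punctuation-stripped, whitespace-collapsed,
hyphen-as-separator; suggestion merging is exact string match after
normalization, with no stemming, so distinct clinical concepts are never
silently conflated. The bundled starter lexicon contains the published CAN
terms (42 entries); the full expert-validated pool is not public, so the
TSV format is the extension point and retention arithmetic is exercised on
synthesized survey rounds.

## Matching

The compiled matcher performs leftmost-longest, non-overlapping lookup
over word tokens (maximal alphanumeric runs; hyphens and slashes split).
Ordinary surfaces match case-insensitively. All-uppercase variants of
length ≤ 4 ("SA", "CPS", "STD", "PTSD", "FCSC") match case-sensitively:
clinical text is full of short lowercase words ("sa") that would otherwise
collide with abbreviations. When equal-length candidates compete, the
clinically more specific subtype wins (SEXUAL_ABUSE > PHYSICAL_INDICATION
> EMOTIONAL_INDICATION > ABUSE > SERVICE). Mentions never cross sentence
boundaries. The matcher is verified against a brute-force
"try every phrase at every position" oracle on hundreds of fuzzed
lexicon/text pairs.

## Sentence detection and tokenization

The sentence detector is rule-based: boundaries at `.`, `!`, `?`, runs of
two or more newlines, and list-item markers at line start. Periods are
protected inside decimals, when glued to a following alphanumeric, and
after a bundled abbreviation list (Dr., Mr., Mrs., Ms., vs., e.g., i.e.,
mg., kg., yo.). Colons never split: clinical headers habitually run into
their content ("sexual abuse health since last visit: No illnesses …"),
and splitting there would detach the header fragment the exclusion rules
need to see. Sentence spans are 0-based half-open character offsets in
note coordinates (the single convention used everywhere, BRAT-compatible),
and sentence texts always equal their note slices.

## Negation

NegEx-style: a pre-trigger ("no", "not", "denies", "denied", "without",
"negative for", "no evidence of", "no signs of", "never", …) negates a
mention when it ends within `scope_tokens` tokens before the mention's
first token, unless a scope terminator ("but", "however", "although",
"except") intervenes. The scope default is 6 tokens — the published NegEx
community convention; the original toolkit's exact trigger inventory is
not public, so this re-implementation is behavior-compatible by
specification rather than bit-compatible. Post-direction triggers are
supported by the rule schema but none ship by default. Rules live in YAML
(`canscreen/data/default_rules.yaml`) and are user-replaceable.

## Exclusion rules

Five default rules approximate the recurring false-positive patterns in
real notes. They are data, not code — each has a kind with parameters, and
the refinement loop the workflow assumes (reviewers label false positives,
rules are added) happens in the YAML file:

- **r1 non_patient_subject** — a kin token (mother, grandmother, aunt, …)
  within 6 word-tokens before the mention plus a history marker (per,
  history, reports, …) anywhere in the sentence: the subject is a third
  party, not the patient.
- **r2 template_pattern** — legend boilerplate such as
  "AV = alleged victim, AO = alleged offender".
- **r3 phrase_blacklist** — first-aid / patient-instruction templates
  ("First Aid: …", "Call 911").
- **r4 section_header** — the mention sits in a header fragment before a
  colon with no verb: a form label, not an assertion.
- **r5 template_pattern (paren_definition)** — abbreviation-expansion
  artifacts ("STD (sexually transmitted disease").

The first firing rule wins, in rule order. Adding rules can only suppress
mentions, so the positive-sentence count is monotonically non-increasing
in the rule list — a property the tests check. The taxonomy's
"patient was the perpetrator" pattern has no dedicated rule; it requires
semantic-role reasoning outside this rule vocabulary and is a known
limitation.

## Low-specificity corroboration

Five terms (police, law enforcement, case worker, case manager,
incarcerated) are valid CAN vocabulary but not specific enough on their
own. A low-specificity mention is excluded unless a standard-specificity,
non-negated, non-excluded mention occurs within `window_sentences`
(default 3) sentences of it in the same note. Window 0 means same-sentence
corroboration only. The default of 3 sentences operationalizes "clear
supportive information nearby within the note" at roughly
paragraph scale; it is a pipeline toggle.

## The SVM comparator

The sentence-topic classifier uses binary presence features over
unigrams, bigrams and trigrams of lowercased tokens (binary rather than
counts — standard for short sentences, and configurable), built from the
training partition only with first-occurrence column ordering for
determinism. The model is a linear-kernel SVM with C = 1.0 (libsvm-backed
via scikit-learn; the hyperparameters are exposed because only the library
choice, not its settings, is part of the original design). Decisions
threshold the hyperplane distance at 0. Models serialize to a portable
JSON bundle (vocabulary + weights + bias + config). The published 92%/100%
performance figures equal the per-class predictive values TP/(TP+FP) and
TN/(TN+FN) on the held-out confusion, not sensitivity/specificity; the
report emits all four metrics so either reading is checkable, and
undefined ratios are reported as not-available, never zero.

## Evaluation

Real-data evaluation is precision-only: each NLP-positive unit is reviewed
by two experts; agreement decides, disagreement (including "unsure")
defers to an optional third reviewer, and otherwise the unit stays
unresolved and blocked from precision computation. Precision is always
computed as confirmed/identified and formatted half-up to one decimal;
where published tables disagree with their own ratios, the computed ratio
is reported. On synthetic corpora with gold annotations the harness
additionally reports recall and F1 at sentence and document level.

## The synthetic generator

The generator emulates the statistical shape of the study corpus, not its
language. Defaults are the observed study conditions: 153 patients with
60–120 notes each (the development sample averaged ~94 notes/patient over
14,397 notes), note types drawn with the development-sample weights across
22 types, positive-note rate 0.029 (422/14,397), a SERVICE-heavy subtype
mixture (0.67/0.22/0.06/0.05/0.00), and 1–6 planted sentences per positive
note (mean 3.5, matching 1,486 sentences over 422 notes). Values the study
does not quantify were fixed once at realistic levels and documented here:
negation_rate 0.2 (negated mentions are common in well-child screening
language), trap rate 0.005 per category per note, duplicate_rate 0.05.
Within-subtype term sampling is weighted so "child protective services"
and the other placement/agency terms dominate, mirroring the observed
top-entity ranking.

Planted positive sentences embed a standard-specificity lexicon surface in
a disclosure carrier; negated plants use a negation-trigger carrier; trap
sentences instantiate the five false-positive patterns. Gold records every
plant with exact character spans. Three contracts tie generator and
pipeline together: with negation and traps off, pipeline predictions equal
gold exactly; every negated plant is flagged negated; and enabling the
default exclusion rules strictly improves precision on trap-bearing
corpora. Positive plants deliberately avoid low-specificity terms — an
uncorroborated "police" plant would be suppressed by design, which would
break the exactness contract; corroboration behavior is exercised by
dedicated unit tests instead.

What the generator does **not** emulate: real clinical language
(templates are a small fixed pool of synthetic well-child boilerplate),
misspellings and OCR noise, lexical variety beyond the lexicon, section
structure, or inter-note narrative. Passing the end-to-end suites
therefore demonstrates that the pipeline implements its rules exactly and
that the rules behave as designed on the failure modes they target — not
that real-data precision would reach any particular level.

Survey synthesis builds rating rounds with an exact grand mean (ratings
are dealt as counts of 1s/2s/3s summing to the target, round-robin across
terms so every passing term stays above the 80% bar) and a requested
number of failing terms, plus suggestion pools in which exactly the
intended candidates clear the 10% endorsement threshold.

## Numerical and formatting choices

- Percentages use decimal half-up rounding: two decimals in note-type
  tables, one decimal for precision, zero for per-class predictive values —
  matching the published table formats exactly.
- All randomness flows through explicit integer seeds (`random.Random` /
  seeded sampling); there is no global random state, and identical inputs
  produce byte-identical outputs.
- Duplicate collapse keys on exact (patient_id, note_type, text); the
  earliest-dated copy wins, ties broken by note_id.
- Patient-level splits assign ⌈train_frac · P⌉ shuffled patients to
  training; stratified sentence splits use largest-remainder allocation.
- Degenerate inputs are explicit: empty text yields zero sentences; zero
  identified units yields not-available precision; zero qualifying
  mentions yields an empty (flagged) subtype distribution; single-class
  training sets and infeasible stratifications are errors.

## Problem sizes

The end-to-end suites run on 200-patient corpora (~18,000 notes, ~150,000
sentences), large enough that the 2.9% positive rate yields hundreds of
positive notes and every trap category appears; matcher fuzzing uses 500
random lexicon/text pairs; SVM recovery uses n = 300 sentences across 20
seeds. The full test suite completes in well under a minute on one CPU.

## Known limitations

- Dictionary NER cannot find what the lexicon lacks; the starter lexicon
  is the published subset, not the full validated pool.
- Assertion handling is negation-only; temporality ("history of"),
  hypotheticals, and experiencer resolution beyond rule r1 are out of
  scope.
- The perpetrator-patient false-positive pattern has no rule (see above).
- The sentence detector is rule-based and will mis-segment prose outside
  its boundary rules (unusual abbreviations, tables).
- Synthetic-corpus results bound implementation correctness, not clinical
  performance.
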