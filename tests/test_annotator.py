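"""The rule-based pipeline: sentence detection, tokenization, dictionary NER,
negation scope, exclusion rules, corroboration, and classification."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canscreen._text import tokenize_text, word_tokens
from canscreen.annotator import (
    AnnotatorConfig,
    RuleConfigError,
    annotate_corpus,
    annotate_note,
    annotations_to_jsonl,
    apply_exclusions,
    classify_document,
    classify_sentence,
    corroborate_low_specificity,
    default_exclusion_rules,
    detect_negation,
    match_entities,
    split_sentences,
    tokenize,
    write_brat,
    ExclusionRule,
)
from canscreen.corpus_io import ClinicalNote
from canscreen.lexicon import LexiconTerm, compile_matcher
from tests.test_lexicon import brute_force_leftmost_longest


def annotate_text(text, matcher, config=None):
    return annotate_note(ClinicalNote("n", "p", text=text), matcher, config)


def sentence_mentions(text, matcher):
    sents = split_sentences(text)
    out = []
    for s in sents:
        toks = tokenize(s)
        out.append((s, toks, match_entities(s, toks, matcher)))
    return out


class TestSplitSentences:
    def test_period_splits(self):
        assert [s.text for s in split_sentences("Pt doing well. Denies abuse.")] == [
            "Pt doing well.",
            "Denies abuse.",
        ]

    def test_empty_text_zero_sentences(self):
        assert split_sentences("") == []

    def test_colon_does_not_split_agrammatical_header(self):
        text = "sexual abuse health since last visit: No illnesses, ER visits, or hospitalizations"
        assert len(split_sentences(text)) == 1

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Seen by Dr. Smith today.", 1),
            ("Temp was 98.6 at triage.", 1),
            ("Dose was 5 mg. at bedtime", 1),
            ("Weight checked today. Follow up in 2 weeks.", 2),
            ("First line\n\nSecond line", 2),
            ("One item\n- second item\n- third item", 3),
            ("No abuse!  Confirmed twice?", 2),
        ],
    )
    def test_boundary_rules(self, text, expected):
        assert len(split_sentences(text)) == expected

    @given(st.text(alphabet=" \n.!?abcdeA:;-\t", max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_spans_reconstruct_note(self, text):
        """Sentence texts equal their note slices; spans are ordered and
        non-overlapping, so text + separators reconstructs the note."""
        sents = split_sentences(text)
        prev_end = 0
        for s in sents:
            assert text[s.begin : s.end] == s.text
            assert s.begin >= prev_end
            assert text[prev_end : s.begin].strip() == ""
            prev_end = s.end
        assert text[prev_end:].strip() == ""


class TestTokenize:
    def test_multiword_phrase_token_count(self):
        toks = tokenize_text("child protective services")
        assert [t.text for t in toks] == ["child", "protective", "services"]

    def test_hyphen_splits(self):
        toks = tokenize_text("2nd-degree burn")
        assert [t.text for t in toks] == ["2nd", "-", "degree", "burn"]

    @given(st.text(max_size=120))
    @settings(max_examples=200, deadline=None)
    def test_token_spans_slice_back_to_token_strings(self, text):
        for t in tokenize_text(text):
            assert text[t.begin : t.end] == t.text


class TestMatchEntities:
    def test_service_mention_found_in_context(self, matcher):
        [(s, toks, mentions)] = sentence_mentions(
            "referred to child protective services today", matcher
        )
        assert len(mentions) == 1
        m = mentions[0]
        assert m.subtype == "SERVICE"
        assert m.matched_surface == "child protective services"
        assert s.text[m.begin - s.begin : m.end - s.begin] == m.matched_surface

    def test_leftmost_longest_prefers_multiword_term(self):
        matcher = compile_matcher(
            [LexiconTerm("abuse", "ABUSE"), LexiconTerm("physical abuse", "ABUSE")]
        )
        [(_, _, mentions)] = sentence_mentions("history of physical abuse", matcher)
        assert [m.lexicon_surface for m in mentions] == ["physical abuse"]

    def test_no_lexicon_tokens_empty(self, matcher):
        [(_, _, mentions)] = sentence_mentions("well child exam today", matcher)
        assert mentions == []

    def test_fuzzed_agreement_with_brute_force_oracle(self):
        """500 fuzzed (lexicon, sentence) pairs against the enumerate-all
        oracle."""
        rng = random.Random(7)
        pool = ["abuse", "child", "services", "protective", "neglect", "foster",
                "care", "rape", "burn", "pt", "ER", "CPS", "sa", "the", "of"]
        for _ in range(500):
            terms = []
            seen = set()
            for _ in range(rng.randint(1, 6)):
                surf = " ".join(
                    rng.sample([w for w in pool if w.islower()], rng.randint(1, 3))
                )
                subtype = rng.choice(
                    ("ABUSE", "SERVICE", "SEXUAL_ABUSE", "PHYSICAL_INDICATION")
                )
                if (surf, subtype) in seen:
                    continue
                seen.add((surf, subtype))
                variants = ("CPS",) if rng.random() < 0.25 else ()
                terms.append(LexiconTerm(surf, subtype, variants=variants))
            matcher = compile_matcher(terms)
            text = " ".join(rng.choices(pool, k=rng.randint(1, 20)))
            [(sent, toks, mentions)] = sentence_mentions(text, matcher) or [
                (None, None, [])
            ]
            words = word_tokens(tokenize_text(text))
            expected = brute_force_leftmost_longest(words, terms)
            got = [
                (next(i for i, w in enumerate(words) if w.begin == m.begin),
                 len([w for w in words if m.begin <= w.begin < m.end]),
                 m.subtype)
                for m in mentions
            ]
            assert got == expected


class TestNegation:
    @pytest.mark.parametrize(
        "text,negated",
        [
            ("denies any abuse at home", True),
            ("no signs of neglect", True),
            ("denies pain but reports abuse by stepfather", False),
            ("never experienced violence before", True),
            ("reports abuse by stepfather", False),
        ],
    )
    def test_scope_and_terminators(self, matcher, text, negated):
        [(s, toks, mentions)] = sentence_mentions(text, matcher)
        detect_negation(mentions, toks)
        assert mentions[0].negated is negated

    def test_trigger_beyond_scope_does_not_negate(self, matcher):
        text = "denies one two three four five six seven abuse"
        [(s, toks, mentions)] = sentence_mentions(text, matcher)
        detect_negation(mentions, toks)
        assert mentions[0].negated is False

    def test_planting_denies_flips_sentence_label(self, matcher):
        """Negation-flip property on fuzzed positive sentences."""
        rng = random.Random(13)
        carriers = [
            "patient reports {} at school",
            "chart documents {} last year",
            "{} observed on exam",
        ]
        surfaces = ["abuse", "neglect", "violence", "bruise", "child abuse"]
        for _ in range(50):
            base = rng.choice(carriers).format(rng.choice(surfaces))
            pos = annotate_text(base, matcher)
            neg = annotate_text("denies " + base, matcher)
            assert pos.sentence_labels[0].positive
            assert not neg.sentence_labels[0].positive


class TestExclusions:
    def test_template_legend_excluded_r2(self, matcher):
        ann = annotate_text(
            "Abbreviations: AV = alleged victim, AO = alleged offender", matcher
        )
        assert ann.mentions and all(m.exclusion_rule_id == "r2" for m in ann.mentions)

    def test_first_aid_boilerplate_excluded_r3(self, matcher):
        ann = annotate_text(
            "First Aid: Burns Call 911 immediately if the victim has symptoms of shock",
            matcher,
        )
        assert ann.mentions and all(m.exclusion_rule_id == "r3" for m in ann.mentions)

    def test_non_patient_kin_history_excluded_r1(self, matcher):
        ann = annotate_text(
            "Per the grandparents the mother reported one date rape at about age 15",
            matcher,
        )
        assert ann.mentions and ann.mentions[0].exclusion_rule_id == "r1"

    def test_header_fragment_excluded_r4(self, matcher):
        ann = annotate_text(
            "sexual abuse health since last visit: No illnesses, ER visits, or hospitalizations",
            matcher,
        )
        assert ann.mentions and ann.mentions[0].exclusion_rule_id == "r4"

    def test_parenthetical_expansion_excluded_r5(self, matcher):
        ann = annotate_text("Labs reviewed for STD (sexually transmitted disease) exposure", matcher)
        assert len(ann.mentions) == 2
        assert all(m.exclusion_rule_id == "r5" for m in ann.mentions)

    def test_plain_disclosure_not_excluded(self, matcher):
        ann = annotate_text("pt discloses abuse by neighbor", matcher)
        assert ann.mentions[0].qualifying

    def test_unknown_rule_kind_is_config_error(self):
        with pytest.raises(RuleConfigError, match="unknown exclusion rule kind"):
            ExclusionRule("rx", "regexp_blacklist")

    def test_adding_rules_never_increases_positive_sentences(self, matcher, trap_corpus):
        """Monotonicity: each prefix of the rule list yields <= positives of
        the previous prefix."""
        notes, _ = trap_corpus
        notes = notes[:300]
        rules = default_exclusion_rules()
        prev = None
        for k in range(len(rules) + 1):
            config = AnnotatorConfig(exclusion_rules=rules[:k])
            n_pos = sum(
                s.positive
                for a in annotate_corpus(notes, matcher, config)
                for s in a.sentence_labels
            )
            if prev is not None:
                assert n_pos <= prev
            prev = n_pos


class TestCorroboration:
    def test_lone_low_specificity_mention_suppressed(self, matcher):
        ann = annotate_text("police were called to the home", matcher)
        assert ann.mentions[0].exclusion_rule_id == "low_specificity"
        assert not ann.document_label.positive

    def test_low_specificity_retained_near_standard_mention(self, matcher):
        text = "police were called to the home.\n\nreferred to child protective services."
        ann = annotate_text(text, matcher)
        low = [m for m in ann.mentions if m.specificity == "low"]
        assert low and low[0].qualifying

    def test_window_zero_requires_same_sentence(self, matcher):
        text = "police were called to the home.\n\nreferred to child protective services."
        ann = annotate_text(text, matcher, AnnotatorConfig(corroboration_window=0))
        low = [m for m in ann.mentions if m.specificity == "low"]
        assert low and not low[0].qualifying
        same = annotate_text(
            "police escorted pt to child protective services",
            matcher,
            AnnotatorConfig(corroboration_window=0),
        )
        low_same = [m for m in same.mentions if m.specificity == "low"]
        assert low_same and low_same[0].qualifying

    def test_negated_standard_mention_does_not_corroborate(self, matcher):
        text = "police were called to the home.\n\ndenies abuse."
        ann = annotate_text(text, matcher)
        low = [m for m in ann.mentions if m.specificity == "low"]
        assert low and not low[0].qualifying


class TestClassification:
    def test_clean_mention_positive_with_subtype(self, matcher):
        ann = annotate_text("referred to child protective services today", matcher)
        label = ann.sentence_labels[0]
        assert label.positive and label.active_subtypes == frozenset({"SERVICE"})

    def test_only_negated_mention_negative(self, matcher):
        ann = annotate_text("denies abuse", matcher)
        assert not ann.sentence_labels[0].positive

    def test_document_positive_iff_any_sentence_positive(self, matcher):
        filler = "Routine well child exam today.\n\n" * 39
        ann = annotate_text(filler + "pt discloses abuse by neighbor", matcher)
        assert ann.document_label.positive
        assert ann.document_label.n_positive_sentences == 1
        neg = annotate_text(filler, matcher)
        assert not neg.document_label.positive
        empty = annotate_text("", matcher)
        assert not empty.document_label.positive
        assert classify_document("x", []).positive is False


class TestDeterminismAndSerialization:
    def test_identical_inputs_byte_identical_output(self, matcher, trap_corpus, tmp_path):
        notes, _ = trap_corpus
        notes = notes[:100]
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        annotations_to_jsonl(annotate_corpus(notes, matcher), p1)
        annotations_to_jsonl(annotate_corpus(notes, matcher), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_brat_standoff_spans_slice_note_text(self, matcher, tmp_path):
        note = ClinicalNote(
            "n1", "p1",
            text="Pt denies abuse.\n\nreferred to child protective services today.",
        )
        ann = annotate_note(note, matcher)
        path = write_brat(ann, tmp_path)
        lines = path.read_text().splitlines()
        t_lines = [l for l in lines if l.startswith("T")]
        assert len(t_lines) == 2
        for line in t_lines:
            _, meta, surface = line.split("\t")
            _, b, e = meta.split()
            assert note.text[int(b) : int(e)] == surface
        assert any(l.startswith("A") and "Negated" in l for l in lines)
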