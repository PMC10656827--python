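import pytest

from canscreen import compile_matcher, starter_lexicon
from canscreen.synthetic_corpus import SynthSpec, TRAP_KINDS, generate


@pytest.fixture(scope="session")
def lexicon():
    return starter_lexicon()


@pytest.fixture(scope="session")
def matcher(lexicon):
    return compile_matcher(lexicon)


@pytest.fixture(scope="session")
def clean_corpus(lexicon):
    """Small corpus with no negations, traps, or duplicates."""
    spec = SynthSpec(
        seed=11,
        n_patients=30,
        notes_per_patient=(10, 20),
        positive_note_rate=0.15,
        negation_rate=0.0,
        trap_rates={k: 0.0 for k in TRAP_KINDS},
        duplicate_rate=0.0,
    )
    return generate(spec, lexicon)


@pytest.fixture(scope="session")
def trap_corpus(lexicon):
    """Small corpus with traps and negations enabled."""
    spec = SynthSpec(
        seed=12,
        n_patients=30,
        notes_per_patient=(10, 20),
        positive_note_rate=0.15,
        negation_rate=0.3,
        trap_rates={k: 0.05 for k in TRAP_KINDS},
        duplicate_rate=0.0,
    )
    return generate(spec, lexicon)
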