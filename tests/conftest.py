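import numpy as np
import pytest

from picdesc.corpus_io import Token, Transcript, Utterance
from picdesc.simulate import SyntheticCohortConfig, simulate_cohort


def make_timed_transcript(intervals, filler_intervals=(), sample_id="t", duration=None):
    """Transcript with one utterance of plain words at the given (onset, offset)
    intervals, plus optional filler tokens."""
    tokens = [
        Token(surface=f"w{i}", lemma=f"w{i}", pos="NN", onset=s, offset=e)
        for i, (s, e) in enumerate(intervals)
    ]
    tokens += [
        Token(surface="um", lemma="um", pos="UH", onset=s, offset=e, is_filler=True)
        for s, e in filler_intervals
    ]
    tokens.sort(key=lambda t: t.onset)
    return Transcript(
        sample_id=sample_id,
        utterances=(Utterance(speaker="PAR", tokens=tuple(tokens)),),
        duration=duration,
    )


def make_word_transcript(utterance_words, pos=None, sample_id="t"):
    """Transcript from lists of words (one list per utterance), no timing."""
    utts = []
    for words in utterance_words:
        tokens = tuple(
            Token(surface=w, lemma=w.lower(), pos=(pos or {}).get(w, "NN"))
            for w in words
        )
        utts.append(Utterance(speaker="PAR", tokens=tokens))
    return Transcript(sample_id=sample_id, utterances=tuple(utts))


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared by read-only tests."""
    return simulate_cohort(SyntheticCohortConfig(), seed=1)
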