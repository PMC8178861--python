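"""Synthetic picture-description cohorts with severity-linked structure.

The generator emulates a three-group study (healthy controls, MCI, AD; 10
per group) of ~1-minute Cookie-Theft-style descriptions. Each sample draws
a latent severity in [0, 3] per rated characteristic from its group's
distribution, and the severities drive the generators monotonically:

* word-finding difficulty — longer inter-word gaps (exponential, severity-
  scaled mean), longer word durations, and substitution of content nouns by
  the generic "thing" (raising mean word frequency, as word-finding
  impairment does);
* incoherence — higher probability of off-picture, past-tense utterances
  built from late-acquired, negative-valence words;
* perseveration — higher probability of repeating an earlier utterance
  verbatim, and a shrinking pool of sentence templates (reduced vocabulary
  richness);
* errors in speech — higher probability of subordinate-clause fragment
  constructions.

Transcripts use a closed vocabulary with synthetic psycholinguistic norms
and embeddings, so the norm/embedding lookup code paths are exercised
without shipping third-party norm datasets. Waveforms are noise bursts
during word intervals and exact silence in gaps — sufficient for
zero-crossing, energy, and pause properties, not a speech synthesizer.
Rater panels add Gaussian noise to the latent severity, then round and clip
to the 0-3 scale. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .corpus_io import (
    AudioSignal,
    EmbeddingTable,
    NormEntry,
    NormsTable,
    RatingPanel,
    Token,
    Transcript,
    Utterance,
)
from .linguistic import ContentLexicon, load_content_lexicon

__all__ = [
    "CHARACTERISTICS",
    "SyntheticCohortConfig",
    "SimulatedCohort",
    "FactorModelSpec",
    "simulate_cohort",
    "simulate_waveform",
    "simulate_rating_panel",
    "simulate_factor_model",
    "synthetic_norms",
    "synthetic_embeddings",
]

CHARACTERISTICS = ("word_finding", "incoherence", "perseveration", "speech_errors")

GROUP_ORDER = ("HC", "MCI", "AD")


# ---------------------------------------------------------------------------
# Closed vocabulary: sentence templates with parses, and synthetic norms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Template:
    words: tuple[tuple[str, str, str], ...]  # (surface, lemma, POS)
    parse: str


def _t(*words: str) -> tuple[tuple[str, str, str], ...]:
    """Each word is 'surface/lemma/POS' (lemma omitted => lower surface)."""
    out = []
    for w in words:
        parts = w.split("/")
        if len(parts) == 2:
            surface, pos = parts
            lemma = surface.lower()
        else:
            surface, lemma, pos = parts
        out.append((surface, lemma, pos))
    return tuple(out)


SCENE_TEMPLATES: tuple[_Template, ...] = (
    _Template(
        _t("the/DT", "boy/NN", "is/be/VBZ", "on/IN", "the/DT", "stool/NN"),
        "(S (NP (DT the) (NN boy)) (VP (VBZ is) (PP (IN on) (NP (DT the) (NN stool)))))",
    ),
    _Template(
        _t("the/DT", "girl/NN", "reaches/reach/VBZ", "for/IN", "a/DT", "cookie/NN"),
        "(S (NP (DT the) (NN girl)) (VP (VBZ reaches) (PP (IN for) (NP (DT a) (NN cookie)))))",
    ),
    _Template(
        _t("the/DT", "water/NN", "is/be/VBZ", "running/run/VBG", "over/IN", "the/DT", "sink/NN"),
        "(S (NP (DT the) (NN water)) (VP (VBZ is) (VP (VBG running) "
        "(PP (IN over) (NP (DT the) (NN sink))))))",
    ),
    _Template(
        _t("the/DT", "mother/NN", "is/be/VBZ", "drying/dry/VBG", "the/DT", "dishes/dish/NNS"),
        "(S (NP (DT the) (NN mother)) (VP (VBZ is) (VP (VBG drying) (NP (DT the) (NNS dishes)))))",
    ),
    _Template(
        _t("the/DT", "boy/NN", "takes/take/VBZ", "a/DT", "cookie/NN", "from/IN", "the/DT", "jar/NN"),
        "(S (NP (DT the) (NN boy)) (VP (VBZ takes) (NP (DT a) (NN cookie)) "
        "(PP (IN from) (NP (DT the) (NN jar)))))",
    ),
    _Template(
        _t("the/DT", "stool/NN", "is/be/VBZ", "falling/fall/VBG", "over/RP"),
        "(S (NP (DT the) (NN stool)) (VP (VBZ is) (VP (VBG falling) (PRT (RP over)))))",
    ),
    _Template(
        _t("the/DT", "mother/NN", "stands/stand/VBZ", "at/IN", "the/DT", "sink/NN"),
        "(S (NP (DT the) (NN mother)) (VP (VBZ stands) (PP (IN at) (NP (DT the) (NN sink)))))",
    ),
    _Template(
        _t("the/DT", "curtains/curtain/NNS", "are/be/VBP", "open/JJ",
           "and/CC", "the/DT", "window/NN", "is/be/VBZ", "open/JJ"),
        "(S (S (NP (DT the) (NNS curtains)) (VP (VBP are) (ADJP (JJ open)))) (CC and) "
        "(S (NP (DT the) (NN window)) (VP (VBZ is) (ADJP (JJ open)))))",
    ),
    _Template(
        _t("the/DT", "boy/NN", "and/CC", "the/DT", "girl/NN", "want/VBP", "cookies/cookie/NNS"),
        "(S (NP (NP (DT the) (NN boy)) (CC and) (NP (DT the) (NN girl))) "
        "(VP (VBP want) (NP (NNS cookies))))",
    ),
    _Template(
        _t("this/DT", "is/be/VBZ", "a/DT", "kitchen/NN"),
        "(S (NP (DT this)) (VP (VBZ is) (NP (DT a) (NN kitchen))))",
    ),
    _Template(
        _t("that/DT", "jar/NN", "is/be/VBZ", "in/IN", "the/DT", "cupboard/NN"),
        "(S (NP (DT that) (NN jar)) (VP (VBZ is) (PP (IN in) (NP (DT the) (NN cupboard)))))",
    ),
    _Template(
        _t("she/PRP", "wants/want/VBZ", "a/DT", "bigger/big/JJR", "plate/NN"),
        "(S (NP (PRP she)) (VP (VBZ wants) (NP (DT a) (JJR bigger) (NN plate))))",
    ),
    _Template(
        _t("the/DT", "girl/NN", "asks/ask/VBZ", "for/IN", "a/DT", "cookie/NN",
           "because/IN", "she/PRP", "is/be/VBZ", "hungry/JJ"),
        "(S (NP (DT the) (NN girl)) (VP (VBZ asks) (PP (IN for) (NP (DT a) (NN cookie))) "
        "(SBAR (IN because) (S (NP (PRP she)) (VP (VBZ is) (ADJP (JJ hungry)))))))",
    ),
)

OFFTOPIC_TEMPLATES: tuple[_Template, ...] = (
    _Template(
        _t("she/PRP", "remembered/remember/VBD", "a/DT", "dreary/JJ", "sorrow/NN"),
        "(S (NP (PRP she)) (VP (VBD remembered) (NP (DT a) (JJ dreary) (NN sorrow))))",
    ),
    _Template(
        _t("the/DT", "gloomy/JJ", "weather/NN", "ruined/ruin/VBD", "the/DT", "afternoon/NN"),
        "(S (NP (DT the) (JJ gloomy) (NN weather)) (VP (VBD ruined) (NP (DT the) (NN afternoon))))",
    ),
    _Template(
        _t("he/PRP", "pondered/ponder/VBD", "a/DT", "melancholy/JJ", "notion/NN"),
        "(S (NP (PRP he)) (VP (VBD pondered) (NP (DT a) (JJ melancholy) (NN notion))))",
    ),
    _Template(
        _t("they/PRP", "lamented/lament/VBD", "the/DT", "dismal/JJ", "tragedy/NN"),
        "(S (NP (PRP they)) (VP (VBD lamented) (NP (DT the) (JJ dismal) (NN tragedy))))",
    ),
    _Template(
        _t("it/PRP", "was/be/VBD", "a/DT", "bleak/JJ", "memory/NN"),
        "(S (NP (PRP it)) (VP (VBD was) (NP (DT a) (JJ bleak) (NN memory))))",
    ),
)

FRAGMENT_TEMPLATES: tuple[_Template, ...] = (
    _Template(
        _t("she/PRP", "seems/seem/VBZ", "to/TO", "think/VB", "that/IN",
           "it/PRP", "fell/fall/VBD"),
        "(S (NP (PRP she)) (VP (VBZ seems) (S (VP (TO to) (VP (VB think) "
        "(SBAR (IN that) (S (NP (PRP it)) (VP (VBD fell)))))))))",
    ),
    _Template(
        _t("he/PRP", "says/say/VBZ", "that/IN", "the/DT", "thing/NN",
           "is/be/VBZ", "there/RB"),
        "(S (NP (PRP he)) (VP (VBZ says) (SBAR (IN that) (S (NP (DT the) (NN thing)) "
        "(VP (VBZ is) (ADVP (RB there)))))))",
    ),
)

# zipf, aoa (years), valence, arousal, dominance (1-9). Scene words are
# early-acquired and neutral-to-positive; off-topic words late-acquired,
# negative, and rarer. "thing" is the high-frequency generic substitute.
_CONTENT_NORMS: dict[str, tuple[float, float, float, float, float]] = {
    "boy": (5.4, 3.0, 6.2, 4.0, 5.5),
    "girl": (5.5, 3.0, 6.4, 4.1, 5.4),
    "mother": (5.6, 2.8, 6.9, 4.2, 5.8),
    "cookie": (4.6, 3.2, 7.2, 4.6, 5.6),
    "stool": (3.8, 5.0, 5.2, 3.2, 5.1),
    "sink": (4.3, 4.2, 5.0, 3.1, 5.2),
    "water": (5.9, 2.6, 6.3, 3.6, 5.9),
    "dish": (4.5, 3.8, 5.4, 3.0, 5.3),
    "jar": (4.1, 4.4, 5.3, 3.0, 5.2),
    "window": (5.2, 3.4, 5.6, 3.2, 5.4),
    "curtain": (4.0, 4.8, 5.1, 2.9, 5.1),
    "cupboard": (3.7, 5.2, 5.2, 2.8, 5.1),
    "kitchen": (5.1, 3.3, 6.0, 3.4, 5.6),
    "plate": (4.6, 3.6, 5.5, 3.0, 5.3),
    "reach": (5.0, 5.4, 5.4, 4.2, 5.4),
    "run": (5.7, 3.5, 5.8, 5.5, 5.6),
    "dry": (4.9, 4.0, 5.1, 3.2, 5.2),
    "take": (6.3, 3.1, 5.5, 4.0, 5.7),
    "fall": (5.5, 3.2, 4.1, 5.0, 4.4),
    "stand": (5.6, 3.4, 5.4, 3.6, 5.5),
    "want": (6.4, 2.9, 5.7, 4.4, 5.5),
    "ask": (6.0, 3.3, 5.4, 3.9, 5.3),
    "open": (5.8, 3.4, 5.9, 3.8, 5.6),
    "hungry": (4.8, 3.0, 3.9, 5.2, 4.4),
    "big": (6.2, 2.8, 6.0, 4.3, 5.9),
    "thing": (6.6, 3.0, 5.4, 3.7, 5.4),
    "remember": (5.6, 5.2, 5.6, 4.0, 5.3),
    "sorrow": (3.0, 10.8, 2.2, 4.6, 3.6),
    "dreary": (2.6, 11.5, 2.8, 3.2, 3.9),
    "gloomy": (3.0, 9.8, 2.9, 3.4, 3.9),
    "weather": (5.3, 5.0, 5.2, 3.5, 5.0),
    "ruin": (4.0, 9.0, 2.6, 5.0, 3.7),
    "afternoon": (5.2, 5.4, 5.8, 3.0, 5.4),
    "ponder": (2.8, 11.8, 5.0, 3.2, 5.0),
    "melancholy": (2.5, 12.6, 2.7, 3.5, 3.8),
    "notion": (3.9, 10.9, 5.1, 3.4, 5.0),
    "lament": (2.4, 12.2, 2.4, 4.2, 3.6),
    "dismal": (2.7, 11.9, 2.5, 3.6, 3.7),
    "tragedy": (3.7, 9.6, 1.9, 5.6, 3.3),
    "bleak": (2.9, 11.2, 2.6, 3.6, 3.7),
    "memory": (5.0, 6.0, 5.9, 4.0, 5.2),
    "seem": (5.9, 6.2, 5.2, 3.2, 5.1),
    "think": (6.5, 3.6, 5.6, 3.8, 5.6),
    "say": (6.8, 2.9, 5.4, 3.7, 5.4),
}

_FUNCTION_WORDS = (
    "the", "a", "this", "that", "these", "those", "is", "be", "are", "was",
    "on", "for", "over", "from", "at", "in", "and", "because", "she", "he",
    "it", "they", "to", "there", "um", "uh",
)


def synthetic_norms() -> NormsTable:
    """Deterministic norms table covering the closed vocabulary."""
    entries = {w: NormEntry(*vals) for w, vals in _CONTENT_NORMS.items()}
    for w in _FUNCTION_WORDS:
        entries.setdefault(w, NormEntry(zipf=7.0, aoa=2.5, valence=5.5,
                                        arousal=3.5, dominance=5.5))
    # surface inflections share the lemma's norms
    for template in SCENE_TEMPLATES + OFFTOPIC_TEMPLATES + FRAGMENT_TEMPLATES:
        for surface, lemma, _pos in template.words:
            if lemma in entries:
                entries.setdefault(surface.lower(), entries[lemma])
    entries.setdefault("things", entries["thing"])
    return NormsTable(entries)


def synthetic_embeddings(seed: int = 0, dim: int = 50,
                         lexicon: ContentLexicon | None = None) -> EmbeddingTable:
    """Random unit vectors for every vocabulary word, lemma, inflection, and
    picture key word; deterministic per seed."""
    lexicon = lexicon or load_content_lexicon()
    words: set[str] = set(_CONTENT_NORMS) | set(_FUNCTION_WORDS) | {"things"}
    for template in SCENE_TEMPLATES + OFFTOPIC_TEMPLATES + FRAGMENT_TEMPLATES:
        for surface, lemma, _pos in template.words:
            words |= {surface.lower(), lemma}
    for kw in lexicon.key_words:
        words |= lexicon.forms(kw)
    rng = np.random.default_rng([int(seed) % (2**31), 90001])
    vectors = {}
    for w in sorted(words):
        v = rng.standard_normal(dim)
        vectors[w] = v / np.linalg.norm(v)
    return EmbeddingTable(vectors)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

def _affine(intercept: float, slope: float, s: float) -> float:
    return intercept + slope * s


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for the synthetic cohort.

    Severity maps are (intercept, slope) pairs applied to the latent
    severity s in [0, 3]; slope signs are validated so every map is monotone
    in the documented direction.
    """

    n_per_group: tuple[int, int, int] = (10, 10, 10)  # HC, MCI, AD
    severity_means: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "word_finding": (0.2, 1.5, 2.6),
        "incoherence": (0.2, 1.3, 2.3),
        "perseveration": (0.1, 0.6, 2.1),
        "speech_errors": (0.2, 0.8, 2.0),
    })
    severity_sd: dict[str, float] = field(default_factory=lambda: {
        "word_finding": 0.45, "incoherence": 0.45,
        "perseveration": 0.50, "speech_errors": 0.55,
    })
    # severity -> generator parameter maps (intercept, slope)
    gap_scale: tuple[float, float] = (0.06, 0.10)       # s: mean inter-word gap
    word_duration: tuple[float, float] = (0.22, 0.06)   # s: median word duration
    generic_prob: tuple[float, float] = (0.04, 0.10)    # noun -> "thing"
    offtopic_prob: tuple[float, float] = (0.05, 0.22)
    fragment_prob: tuple[float, float] = (0.03, 0.15)
    repeat_prob: tuple[float, float] = (0.05, 0.10)     # utterance perseveration
    filler_prob: tuple[float, float] = (0.01, 0.03)     # um/uh insertion
    scene_pool_drop: float = 2.0                        # templates lost per severity unit
    word_duration_sigma: float = 0.15                   # lognormal shape
    words_range: tuple[int, int] = (70, 110)
    n_raters: int = 5
    rater_sd: float = 0.35
    embed_dim: int = 50
    sample_rate: int = 16000

    def __post_init__(self) -> None:
        for name in ("gap_scale", "word_duration", "generic_prob", "offtopic_prob",
                     "fragment_prob", "repeat_prob", "filler_prob"):
            intercept, slope = getattr(self, name)
            if intercept < 0 or slope < 0:
                raise ValueError(
                    f"severity map {name!r} must be non-decreasing with non-negative "
                    f"intercept, got ({intercept}, {slope})"
                )
        if self.scene_pool_drop < 0:
            raise ValueError("scene_pool_drop must be >= 0 (vocabulary shrinks with severity)")
        if self.rater_sd < 0:
            raise ValueError("rater_sd must be >= 0")
        if set(self.severity_means) != set(CHARACTERISTICS):
            raise ValueError(f"severity_means must cover {CHARACTERISTICS}")


@dataclass(frozen=True)
class SimulatedCohort:
    transcripts: tuple[Transcript, ...]
    labels: pd.Series                 # sample_id -> group
    true_severities: pd.DataFrame     # samples x characteristics
    norms: NormsTable
    embeddings: EmbeddingTable
    lexicon: ContentLexicon
    config: SyntheticCohortConfig


# ---------------------------------------------------------------------------
# Transcript generation
# ---------------------------------------------------------------------------

def _emit_utterance(
    words: tuple[tuple[str, str, str], ...],
    parse: str,
    t_cursor: float,
    sev: dict[str, float],
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> tuple[Utterance, float]:
    s_wf = sev["word_finding"]
    gap_scale = _affine(*cfg.gap_scale, s_wf)
    dur_med = _affine(*cfg.word_duration, s_wf)
    p_fill = _affine(*cfg.filler_prob, s_wf)

    tokens: list[Token] = []
    t = t_cursor
    for i, (surface, lemma, pos) in enumerate(words):
        gap = float(rng.exponential(gap_scale)) if (tokens or i > 0) else 0.05
        if rng.random() < p_fill and gap < 0.6:
            # hesitation bridging (part of) the gap
            fill_dur = 0.25
            t += gap * 0.3
            tokens.append(Token("um", "um", "UH", onset=t, offset=t + fill_dur, is_filler=True))
            t += fill_dur + gap * 0.3
        else:
            t += gap
        dur = float(rng.lognormal(np.log(dur_med), cfg.word_duration_sigma))
        tokens.append(Token(surface, lemma, pos, onset=t, offset=t + dur))
        t += dur
    utt = Utterance(
        speaker="PAR", tokens=tuple(tokens), parse=parse,
        start=tokens[0].onset, end=tokens[-1].offset,
    )
    return utt, t


def _substitute_generic(
    template: _Template, p: float, rng: np.random.Generator
) -> tuple[tuple[tuple[str, str, str], ...], str]:
    """Replace content nouns by generic 'thing(s)' with probability p,
    rewriting the parse leaves to match."""
    words = []
    parse = template.parse
    for surface, lemma, pos in template.words:
        if pos in ("NN", "NNS") and lemma != "thing" and rng.random() < p:
            new_surface = "thing" if pos == "NN" else "things"
            parse = parse.replace(f"({pos} {surface})", f"({pos} {new_surface})", 1)
            words.append((new_surface, "thing", pos))
        else:
            words.append((surface, lemma, pos))
    return tuple(words), parse


def _simulate_transcript(
    sample_id: str,
    sev: dict[str, float],
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> Transcript:
    n_scene = len(SCENE_TEMPLATES)
    pool_size = max(3, n_scene - int(round(cfg.scene_pool_drop * sev["perseveration"])))
    scene_pool = SCENE_TEMPLATES[:pool_size]
    p_off = min(_affine(*cfg.offtopic_prob, sev["incoherence"]), 0.85)
    p_frag = min(_affine(*cfg.fragment_prob, sev["speech_errors"]), 0.60)
    p_rep = min(_affine(*cfg.repeat_prob, sev["perseveration"]), 0.70)
    p_gen = min(_affine(*cfg.generic_prob, sev["word_finding"]), 0.80)

    n_target = int(rng.integers(cfg.words_range[0], cfg.words_range[1] + 1))
    utterances: list[Utterance] = []
    emitted: list[tuple[tuple[tuple[str, str, str], ...], str]] = []
    t_cursor = 0.5
    n_words = 0
    while n_words < n_target:
        if emitted and rng.random() < p_rep:
            words, parse = emitted[int(rng.integers(len(emitted)))]
        else:
            u = rng.random()
            if u < p_off:
                template = OFFTOPIC_TEMPLATES[int(rng.integers(len(OFFTOPIC_TEMPLATES)))]
            elif u < p_off + p_frag:
                template = FRAGMENT_TEMPLATES[int(rng.integers(len(FRAGMENT_TEMPLATES)))]
            else:
                template = scene_pool[int(rng.integers(len(scene_pool)))]
            words, parse = _substitute_generic(template, p_gen, rng)
        emitted.append((words, parse))
        utt, t_cursor = _emit_utterance(words, parse, t_cursor, sev, cfg, rng)
        utterances.append(utt)
        n_words += len(utt.content_tokens())
        t_cursor += float(rng.exponential(_affine(*cfg.gap_scale, sev["word_finding"])))
    return Transcript(
        sample_id=sample_id,
        utterances=tuple(utterances),
        duration=t_cursor + 0.5,
    )


def simulate_cohort(
    config: SyntheticCohortConfig | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Generate a full synthetic cohort: transcripts with timing, POS, and
    parses; group labels; latent severities; norms; embeddings."""
    cfg = config or SyntheticCohortConfig()
    base = int(seed) % (2**31)
    transcripts: list[Transcript] = []
    labels = {}
    severities = {}
    idx = 0
    for group, n in zip(GROUP_ORDER, cfg.n_per_group):
        gi = GROUP_ORDER.index(group)
        for _ in range(n):
            sample_id = f"S{idx + 1:03d}"
            rng = np.random.default_rng([base, idx])
            sev = {
                ch: float(np.clip(rng.normal(cfg.severity_means[ch][gi], cfg.severity_sd[ch]), 0.0, 3.0))
                for ch in CHARACTERISTICS
            }
            transcripts.append(_simulate_transcript(sample_id, sev, cfg, rng))
            labels[sample_id] = group
            severities[sample_id] = sev
            idx += 1
    sev_df = pd.DataFrame(severities).T[list(CHARACTERISTICS)]
    sev_df.index.name = "sample_id"
    return SimulatedCohort(
        transcripts=tuple(transcripts),
        labels=pd.Series(labels, name="group"),
        true_severities=sev_df,
        norms=synthetic_norms(),
        embeddings=synthetic_embeddings(seed=base, dim=cfg.embed_dim),
        lexicon=load_content_lexicon(),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Waveform
# ---------------------------------------------------------------------------

def simulate_waveform(
    transcript: Transcript,
    seed: int = 0,
    rate: int = 16000,
    amplitude: float = 0.3,
) -> AudioSignal:
    """Band-limited noise bursts during token intervals, exact silence in
    gaps; the signal length equals the transcript duration (+-1 sample)."""
    duration = transcript.elapsed_duration()
    if duration is None:
        raise ValueError("simulate_waveform requires transcript timing")
    total = transcript.duration if transcript.duration is not None else duration
    n = int(round(total * rate))
    x = np.zeros(n)
    rng = np.random.default_rng([int(seed) % (2**31), 77001])
    sos = scipy.signal.butter(2, [300, 3000], btype="bandpass", fs=rate, output="sos")
    for tok in transcript.tokens(include_fillers=True):
        if tok.onset is None or tok.offset is None:
            raise ValueError(f"token {tok.surface!r} lacks timing")
        i0, i1 = int(round(tok.onset * rate)), int(round(tok.offset * rate))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        burst = scipy.signal.sosfilt(sos, rng.standard_normal(i1 - i0))
        ramp = min(32, (i1 - i0) // 4)
        if ramp > 0:
            env = np.ones(i1 - i0)
            ramp_curve = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
            env[:ramp] = ramp_curve
            env[-ramp:] = ramp_curve[::-1]
            burst = burst * env
        peak = np.max(np.abs(burst))
        if peak > 0:
            burst = burst / peak * amplitude
        x[i0:i1] = burst
    return AudioSignal(samples=x, rate=rate)


# ---------------------------------------------------------------------------
# Rating panels
# ---------------------------------------------------------------------------

def simulate_rating_panel(
    true_severities: pd.DataFrame,
    n_raters: int = 5,
    rater_sd: float = 0.35,
    seed: int = 0,
    rater_bias_sd: float = 0.0,
) -> RatingPanel:
    """Each rater perceives severity plus Gaussian noise (and an optional
    rater-specific bias), rounded and clipped to the 0-3 scale."""
    if rater_sd < 0 or rater_bias_sd < 0:
        raise ValueError("rater_sd and rater_bias_sd must be >= 0")
    rng = np.random.default_rng([int(seed) % (2**31), 55001])
    raters = [f"R{j + 1}" for j in range(n_raters)]
    biases = rng.normal(0.0, rater_bias_sd, size=n_raters) if rater_bias_sd > 0 else np.zeros(n_raters)
    rows = {}
    for sample_id, sev_row in true_severities.iterrows():
        for ch in true_severities.columns:
            noise = rng.normal(0.0, rater_sd, size=n_raters) if rater_sd > 0 else np.zeros(n_raters)
            ratings = np.clip(np.round(sev_row[ch] + biases + noise), 0, 3).astype(int)
            rows[(sample_id, ch)] = ratings
    table = pd.DataFrame.from_dict(rows, orient="index", columns=raters)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["sample_id", "characteristic"])
    return RatingPanel(table)


# ---------------------------------------------------------------------------
# Factor-model data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorModelSpec:
    """Common-factor generative model: X = F L' + E with F ~ N(0, Phi)."""

    loadings: np.ndarray                  # p x k
    phi: np.ndarray | None = None         # k x k, default identity
    uniquenesses: np.ndarray | None = None  # p, default 1 - diag(L Phi L')
    n: int = 500

    def resolve(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lam = np.asarray(self.loadings, dtype=float)
        k = lam.shape[1]
        phi = np.eye(k) if self.phi is None else np.asarray(self.phi, dtype=float)
        common = lam @ phi @ lam.T
        psi = (1.0 - np.diag(common) if self.uniquenesses is None
               else np.asarray(self.uniquenesses, dtype=float))
        if np.any(psi < 0):
            raise ValueError("implied uniquenesses are negative: loadings too large")
        sigma = common + np.diag(psi)
        if np.min(np.linalg.eigvalsh(sigma)) < -1e-10:
            raise ValueError("implied correlation matrix is not positive semi-definite")
        if np.min(np.linalg.eigvalsh(phi)) < -1e-10:
            raise ValueError("factor correlation matrix is not positive semi-definite")
        return lam, phi, psi


def simulate_factor_model(spec: FactorModelSpec, seed: int = 0) -> np.ndarray:
    """Draw an n x p data matrix from the common-factor model and z-score
    the columns."""
    lam, phi, psi = spec.resolve()
    p, k = lam.shape
    rng = np.random.default_rng([int(seed) % (2**31), 33001])
    chol = np.linalg.cholesky(phi + 1e-12 * np.eye(k))
    f = rng.standard_normal((spec.n, k)) @ chol.T
    e = rng.standard_normal((spec.n, p)) * np.sqrt(psi)
    x = f @ lam.T + e
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x
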