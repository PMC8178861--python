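"""Lexical, syntactic, semantic, and discourse-graph variables from
annotated transcripts.

All counts exclude hesitation fillers (um/uh); "use of X" variables are
normalised per 100 words, since a raw count scales with how much the
speaker says. Lexical norm averages (frequency, age of acquisition,
valence/arousal/dominance) are taken over the covered tokens only, with the
coverage fraction reported alongside, never imputing zero for absent words.
Utterance repetitiveness and the speech graph work at the lemma level, so
inflectional variation is not mistaken for lexical novelty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO

import networkx as nx
import numpy as np

from .acoustic import (
    FrameConfig,
    MissingTimingError,
    PauseConfig,
    detect_pauses,
    mfcc_stats,
    pause_features,
    timing_feature_dict,
    zcr_stats,
)
from .corpus_io import AudioSignal, EmbeddingTable, NormsTable, Transcript
from .trees import ParseFormatError, TreeNode, parse_tree

__all__ = [
    "ContentLexicon",
    "load_content_lexicon",
    "lexical_stats",
    "vocabulary_richness",
    "syntactic_rates",
    "utterance_repetitiveness",
    "picture_similarity",
    "speech_graph_metrics",
    "extract_all",
    "feature_manifest",
    "write_feature_manifest",
]

NOUN_TAGS = frozenset({"NN", "NNS", "NNP", "NNPS"})
PAST_TAGS = frozenset({"VBD", "VBN"})
DEMONSTRATIVES = frozenset({"this", "that", "these", "those"})
SUBORDINATORS = frozenset({
    "because", "although", "though", "since", "while", "if", "that", "when",
    "after", "before", "unless", "until", "whereas", "so",
})


def _lemma(token) -> str:
    return (token.lemma or token.surface).lower()


def _content_lemmas(transcript: Transcript) -> list[str]:
    return [_lemma(t) for t in transcript.tokens(include_fillers=False)]


# ---------------------------------------------------------------------------
# Content lexicon (picture key words)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContentLexicon:
    """Key words of the picture stimulus with roles and synonym lists.

    ``roles`` maps word -> role (subject/object/place/action); ``synonyms``
    maps word -> acceptable alternates. The default lexicon describes the
    Cookie Theft scene (boy, girl, mother, cookie jar, overflowing sink ...).
    """

    roles: dict[str, str]
    synonyms: dict[str, tuple[str, ...]]

    @property
    def key_words(self) -> tuple[str, ...]:
        return tuple(self.roles)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(w for w, r in self.roles.items() if r == "subject")

    def forms(self, word: str) -> frozenset[str]:
        """The word and its listed synonyms, lower-cased."""
        return frozenset({word.lower(), *map(str.lower, self.synonyms.get(word, ()))})


def load_content_lexicon(source: IO[str] | str | Path | None = None) -> ContentLexicon:
    """Load a content lexicon TSV (word, role, |-separated synonyms); the
    bundled Cookie Theft lexicon is the default."""
    if source is None:
        text = (resources.files("picdesc") / "data" / "cookie_theft_lexicon.tsv").read_text()
    elif isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[0].strip().lower() != "word":
        raise ValueError("content lexicon must have header word<TAB>role<TAB>synonyms")
    roles: dict[str, str] = {}
    synonyms: dict[str, tuple[str, ...]] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        word = parts[0].strip().lower()
        roles[word] = parts[1].strip().lower() if len(parts) > 1 else "object"
        syns = parts[2].strip() if len(parts) > 2 else ""
        synonyms[word] = tuple(s.strip().lower() for s in syns.split("|") if s.strip())
    return ContentLexicon(roles=roles, synonyms=synonyms)


# ---------------------------------------------------------------------------
# Lexical profile
# ---------------------------------------------------------------------------

def lexical_stats(transcript: Transcript, norms: NormsTable | None = None) -> dict[str, float | None]:
    """Word-level rates and norm averages (Penn-Treebank POS tags required
    for the noun/verb subsets)."""
    tokens = transcript.tokens(include_fillers=False)
    n = len(tokens)
    out: dict[str, float | None] = {
        "lexical.n_words": float(n) if n else None,
        "lexical.avg_word_length": None,
        "lexical.avg_zipf": None,
        "lexical.avg_aoa.all": None,
        "lexical.avg_aoa.nouns": None,
        "lexical.avg_valence.all": None,
        "lexical.avg_valence.nouns": None,
        "lexical.avg_arousal.nouns": None,
        "lexical.avg_dominance.all": None,
        "lexical.avg_dominance.nouns": None,
        "lexical.norm_coverage": None,
        "lexical.rate_past_tense": None,
        "lexical.rate_demonstratives": None,
        "lexical.rate_comparative_adj": None,
        "lexical.ratio_sub_coord": None,
    }
    if n == 0:
        return out

    out["lexical.avg_word_length"] = float(np.mean([len(t.surface) for t in tokens]))
    per100 = 100.0 / n
    out["lexical.rate_past_tense"] = per100 * sum(1 for t in tokens if t.pos in PAST_TAGS)
    out["lexical.rate_demonstratives"] = per100 * sum(
        1 for t in tokens if t.pos == "DT" and t.surface.lower() in DEMONSTRATIVES
    )
    out["lexical.rate_comparative_adj"] = per100 * sum(1 for t in tokens if t.pos == "JJR")
    n_sub = sum(
        1 for t in tokens if t.pos == "IN" and t.surface.lower() in SUBORDINATORS
    )
    n_coord = sum(1 for t in tokens if t.pos == "CC")
    out["lexical.ratio_sub_coord"] = (n_sub / n_coord) if n_coord else None

    if norms is not None:
        is_noun = [t.pos in NOUN_TAGS for t in tokens]
        covered = 0
        fields = {
            "zipf": ("lexical.avg_zipf", None),
            "aoa": ("lexical.avg_aoa.all", "lexical.avg_aoa.nouns"),
            "valence": ("lexical.avg_valence.all", "lexical.avg_valence.nouns"),
            "arousal": (None, "lexical.avg_arousal.nouns"),
            "dominance": ("lexical.avg_dominance.all", "lexical.avg_dominance.nouns"),
        }
        collected: dict[str, list[float]] = {k: [] for k in out}
        for tok, noun in zip(tokens, is_noun):
            entry = norms.get(_lemma(tok)) or norms.get(tok.surface)
            if entry is None:
                continue
            covered += 1
            for field, (all_key, noun_key) in fields.items():
                value = getattr(entry, field)
                if value is None:
                    continue
                if all_key:
                    collected[all_key].append(value)
                if noun_key and noun:
                    collected[noun_key].append(value)
        for key, values in collected.items():
            if values:
                out[key] = float(np.mean(values))
        out["lexical.norm_coverage"] = covered / n
    return out


# ---------------------------------------------------------------------------
# Vocabulary richness
# ---------------------------------------------------------------------------

def vocabulary_richness(transcript: Transcript, mattr_window: int = 10) -> dict[str, float | None]:
    """Lexical-diversity statistics on lemmas: type-token ratio, moving-average
    TTR (window 10), Brunet's W = N^(V^-0.165) and Honoré's R =
    100·log N / (1 - V1/V) with V1 the hapax count (undefined when V1 = V)."""
    lemmas = _content_lemmas(transcript)
    n = len(lemmas)
    out: dict[str, float | None] = {
        "richness.ttr": None,
        "richness.mattr_w10": None,
        "richness.brunet_w": None,
        "richness.honore_r": None,
    }
    if n == 0:
        return out
    types = set(lemmas)
    v = len(types)
    out["richness.ttr"] = v / n
    out["richness.brunet_w"] = float(n ** (v ** -0.165))
    counts: dict[str, int] = {}
    for lem in lemmas:
        counts[lem] = counts.get(lem, 0) + 1
    v1 = sum(1 for c in counts.values() if c == 1)
    if v1 < v:
        out["richness.honore_r"] = 100.0 * math.log(n) / (1.0 - v1 / v)
    if n >= mattr_window:
        windows = [
            len(set(lemmas[i: i + mattr_window])) / mattr_window
            for i in range(n - mattr_window + 1)
        ]
        out["richness.mattr_w10"] = float(np.mean(windows))
    return out


# ---------------------------------------------------------------------------
# Syntactic production rates
# ---------------------------------------------------------------------------

def _count_patterns(tree: TreeNode) -> dict[str, int]:
    c = {
        "np_dt_nn": 0,        # NP whose children are exactly DT NN
        "vp_vbd_np": 0,       # past-tense VP with NP object
        "vp_vbz_pp": 0,       # 3rd-sing present VP containing a PP
        "vp_sbar": 0,         # VP dominating a subordinate clause
        "coord_phrase": 0,    # CC flanked by same-category siblings
        "adjp": 0,
        "conj_vp": 0,         # VP with a CC child
        "clauses": 0,         # S and SBAR nodes
    }
    for node in tree.walk():
        labels = [ch.label for ch in node.children]
        if node.label in ("S", "SBAR"):
            c["clauses"] += 1
        if node.label == "ADJP":
            c["adjp"] += 1
        if node.label == "NP" and labels == ["DT", "NN"]:
            c["np_dt_nn"] += 1
        if node.label == "VP":
            if labels == ["VBD", "NP"]:
                c["vp_vbd_np"] += 1
            if "VBZ" in labels and "PP" in labels:
                c["vp_vbz_pp"] += 1
            if "CC" in labels:
                c["conj_vp"] += 1
            if any(d.label == "SBAR" for ch in node.children for d in ch.walk()):
                c["vp_sbar"] += 1
        for i in range(1, len(labels) - 1):
            if labels[i] == "CC" and labels[i - 1] == labels[i + 1]:
                c["coord_phrase"] += 1
    return c


def syntactic_rates(transcript: Transcript) -> dict[str, float | None]:
    """Production rates per 100 words over parsed utterances (utterances
    without a bracketed parse are excluded from numerator and denominator)."""
    totals = {k: 0 for k in (
        "np_dt_nn", "vp_vbd_np", "vp_vbz_pp", "vp_sbar",
        "coord_phrase", "adjp", "conj_vp", "clauses",
    )}
    n_words = 0
    any_parse = False
    for i, utt in enumerate(transcript.utterances):
        if not utt.parse:
            continue
        any_parse = True
        try:
            tree = parse_tree(utt.parse)
        except ParseFormatError as exc:
            raise ParseFormatError(f"utterance {i}: {exc}") from exc
        counts = _count_patterns(tree)
        for k in totals:
            totals[k] += counts[k]
        n_words += len(utt.content_tokens())
    keys = {
        "syntax.np_dt_nn.rate": "np_dt_nn",
        "syntax.vp_vbd_np.rate": "vp_vbd_np",
        "syntax.vp_vbz_pp.rate": "vp_vbz_pp",
        "syntax.vp_sbar.rate": "vp_sbar",
        "syntax.coord_phrase.rate": "coord_phrase",
        "syntax.adjp.rate": "adjp",
        "syntax.conj_vp.rate": "conj_vp",
    }
    out: dict[str, float | None] = {k: None for k in keys}
    out["syntax.coord_per_clause"] = None
    if not any_parse or n_words == 0:
        return out
    for key, pat in keys.items():
        out[key] = 100.0 * totals[pat] / n_words
    if totals["clauses"] > 0:
        out["syntax.coord_per_clause"] = totals["coord_phrase"] / totals["clauses"]
    return out


# ---------------------------------------------------------------------------
# Semantic variables
# ---------------------------------------------------------------------------

def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    return 1.0 - float(u @ v) / (nu * nv)


def utterance_repetitiveness(transcript: Transcript, pairs: str = "all") -> dict[str, float | None]:
    """Cosine distances between bag-of-lemma count vectors of utterances.

    Low mean distance means the same words recur across utterances
    (repetitive speech); disjoint vocabularies give distance 1. ``pairs`` is
    ``"all"`` (every unordered pair, default) or ``"consecutive"``.
    """
    bags: list[dict[str, int]] = []
    for utt in transcript.utterances:
        lemmas = [_lemma(t) for t in utt.content_tokens()]
        if lemmas:
            bag: dict[str, int] = {}
            for lem in lemmas:
                bag[lem] = bag.get(lem, 0) + 1
            bags.append(bag)
    out: dict[str, float | None] = {
        "semantic.utt_cosdist.mean": None,
        "semantic.utt_cosdist.min": None,
        "semantic.utt_cosdist.max": None,
    }
    if len(bags) < 2:
        return out
    vocab = sorted(set().union(*bags))
    index = {w: i for i, w in enumerate(vocab)}
    mat = np.zeros((len(bags), len(vocab)))
    for i, bag in enumerate(bags):
        for w, cnt in bag.items():
            mat[i, index[w]] = cnt
    if pairs == "consecutive":
        pair_idx = [(i, i + 1) for i in range(len(bags) - 1)]
    else:
        pair_idx = [(i, j) for i in range(len(bags)) for j in range(i + 1, len(bags))]
    dists = [_cosine_distance(mat[i], mat[j]) for i, j in pair_idx]
    out["semantic.utt_cosdist.mean"] = float(np.mean(dists))
    out["semantic.utt_cosdist.min"] = float(np.min(dists))
    out["semantic.utt_cosdist.max"] = float(np.max(dists))
    return out


def picture_similarity(
    transcript: Transcript,
    embeddings: EmbeddingTable,
    lexicon: ContentLexicon,
) -> dict[str, float | None]:
    """Embedding distance of the description to the picture content.

    Per utterance: mean embedding of covered lemmas, then the minimum cosine
    distance to any key-word vector (how close the utterance gets to *some*
    picture item); the reported value is the maximum over utterances — the
    most off-picture utterance. Also reports the fraction of picture subjects
    mentioned (synonyms count) and the fraction of tokens that are
    subject words.
    """
    out: dict[str, float | None] = {
        "semantic.pic_sim_max_cosdist": None,
        "semantic.prop_subjects_mentioned": None,
        "semantic.prop_subject_words": None,
    }
    key_vecs = {}
    for kw in lexicon.key_words:
        vec = embeddings.get(kw)
        if vec is not None:
            key_vecs[kw] = vec
    utt_dists: list[float] = []
    for utt in transcript.utterances:
        vecs = [embeddings.get(_lemma(t)) for t in utt.content_tokens()]
        vecs = [v for v in vecs if v is not None]
        if not vecs or not key_vecs:
            continue
        centroid = np.mean(vecs, axis=0)
        if not np.any(centroid):
            continue
        utt_dists.append(min(_cosine_distance(centroid, kv) for kv in key_vecs.values()))
    if utt_dists:
        out["semantic.pic_sim_max_cosdist"] = float(np.max(utt_dists))

    lemmas = set(_content_lemmas(transcript))
    subjects = lexicon.subjects
    if subjects:
        mentioned = sum(1 for s in subjects if lexicon.forms(s) & lemmas)
        out["semantic.prop_subjects_mentioned"] = mentioned / len(subjects)
        subject_forms = frozenset().union(*(lexicon.forms(s) for s in subjects))
        all_lemmas = _content_lemmas(transcript)
        if all_lemmas:
            out["semantic.prop_subject_words"] = (
                sum(1 for lem in all_lemmas if lem in subject_forms) / len(all_lemmas)
            )
    return out


# ---------------------------------------------------------------------------
# Speech graph
# ---------------------------------------------------------------------------

def speech_graph_metrics(transcript: Transcript) -> dict[str, float | None]:
    """Topology of the word-adjacency multigraph: nodes are lemma types,
    directed edges connect consecutive tokens within an utterance. Repetitive,
    poorly organised speech shows fewer nodes, more repeated edges and
    self-loops, and higher density."""
    g = nx.MultiDiGraph()
    for utt in transcript.utterances:
        lemmas = [_lemma(t) for t in utt.content_tokens()]
        g.add_nodes_from(lemmas)
        g.add_edges_from(zip(lemmas, lemmas[1:]))
    out: dict[str, float | None] = {
        "graph.n_nodes": None,
        "graph.n_edges": None,
        "graph.repeated_edges": None,
        "graph.self_loops": None,
        "graph.lcc": None,
        "graph.density": None,
    }
    n = g.number_of_nodes()
    if n == 0:
        return out
    out["graph.n_nodes"] = float(n)
    out["graph.n_edges"] = float(g.number_of_edges())
    multiplicity: dict[tuple[str, str], int] = {}
    for u, v in g.edges():
        multiplicity[(u, v)] = multiplicity.get((u, v), 0) + 1
    out["graph.repeated_edges"] = float(sum(1 for c in multiplicity.values() if c >= 2))
    out["graph.self_loops"] = float(sum(c for (u, v), c in multiplicity.items() if u == v))
    out["graph.lcc"] = float(max(len(c) for c in nx.weakly_connected_components(g)))
    distinct = sum(1 for (u, v) in multiplicity if u != v)
    out["graph.density"] = distinct / (n * (n - 1)) if n > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# Full extraction and manifest
# ---------------------------------------------------------------------------

def _spectral_channel_names(config: FrameConfig) -> list[str]:
    names = [f"mfcc{i}" for i in range(1, config.n_mfcc + 1)] + ["log_energy"]
    out = []
    for name in names:
        out.extend([name, f"{name}.d1", f"{name}.d2"])
    return out


_STATS = ("mean", "variance", "skewness", "kurtosis")


def feature_manifest(config: FrameConfig | None = None) -> list[tuple[str, str, str]]:
    """Every emitted feature name with its family and a one-line definition."""
    config = config or FrameConfig()
    rows: list[tuple[str, str, str]] = [
        ("acoustic.pause.unfilled_count", "acoustic", "number of unfilled (silent) pauses >= 0.25 s"),
        ("acoustic.pause.short_count", "acoustic", "number of short pauses (< 1.0 s)"),
        ("acoustic.pause.long_count", "acoustic", "number of long pauses (>= 1.0 s)"),
        ("acoustic.pause.total_short_dur", "acoustic", "total duration of short pauses (s)"),
        ("acoustic.pause.total_long_dur", "acoustic", "total duration of long pauses (s)"),
        ("acoustic.pause.mean_dur", "acoustic", "mean unfilled-pause duration (s)"),
        ("acoustic.speech_rate", "acoustic", "non-filler words per minute of elapsed time (pauses included)"),
        ("acoustic.avg_word_duration", "acoustic", "mean word duration (s), fillers excluded"),
        ("acoustic.total_duration", "acoustic", "elapsed sample duration (s)"),
    ]
    for stat in _STATS:
        rows.append((f"acoustic.zcr.{stat}", "acoustic", f"{stat} of per-frame zero-crossing counts"))
    for chan in _spectral_channel_names(config):
        for stat in _STATS:
            rows.append((f"acoustic.{chan}.{stat}", "acoustic", f"{stat} of framewise {chan}"))
    rows += [
        ("lexical.n_words", "lexical", "number of non-filler words"),
        ("lexical.avg_word_length", "lexical", "mean word length in characters"),
        ("lexical.avg_zipf", "lexical", "mean Zipf word frequency over covered words"),
        ("lexical.avg_aoa.all", "lexical", "mean age of acquisition, all covered words (years)"),
        ("lexical.avg_aoa.nouns", "lexical", "mean age of acquisition, covered nouns (years)"),
        ("lexical.avg_valence.all", "lexical", "mean valence (1-9), all covered words"),
        ("lexical.avg_valence.nouns", "lexical", "mean valence (1-9), covered nouns"),
        ("lexical.avg_arousal.nouns", "lexical", "mean arousal (1-9), covered nouns"),
        ("lexical.avg_dominance.all", "lexical", "mean dominance (1-9), all covered words"),
        ("lexical.avg_dominance.nouns", "lexical", "mean dominance (1-9), covered nouns"),
        ("lexical.norm_coverage", "lexical", "fraction of words found in the norms table"),
        ("lexical.rate_past_tense", "lexical", "VBD/VBN tokens per 100 words"),
        ("lexical.rate_demonstratives", "lexical", "demonstrative determiners per 100 words"),
        ("lexical.rate_comparative_adj", "lexical", "comparative adjectives (JJR) per 100 words"),
        ("lexical.ratio_sub_coord", "lexical", "subordinating / coordinating conjunction ratio"),
        ("richness.ttr", "lexical", "type-token ratio on lemmas"),
        ("richness.mattr_w10", "lexical", "moving-average TTR, window 10"),
        ("richness.brunet_w", "lexical", "Brunet's W = N^(V^-0.165)"),
        ("richness.honore_r", "lexical", "Honore's R = 100 log N / (1 - V1/V)"),
        ("syntax.np_dt_nn.rate", "syntactic", "NP -> DT NN productions per 100 words"),
        ("syntax.vp_vbd_np.rate", "syntactic", "past-tense VP with NP object per 100 words"),
        ("syntax.vp_vbz_pp.rate", "syntactic", "3rd-sing present VP with PP per 100 words"),
        ("syntax.vp_sbar.rate", "syntactic", "VP dominating a subordinate clause per 100 words"),
        ("syntax.coord_phrase.rate", "syntactic", "coordinate phrases per 100 words"),
        ("syntax.adjp.rate", "syntactic", "adjective phrases per 100 words"),
        ("syntax.conj_vp.rate", "syntactic", "VPs with a coordinating conjunction per 100 words"),
        ("syntax.coord_per_clause", "syntactic", "coordinate phrases per clause (S/SBAR)"),
        ("semantic.utt_cosdist.mean", "semantic", "mean pairwise utterance cosine distance (bag of lemmas)"),
        ("semantic.utt_cosdist.min", "semantic", "min pairwise utterance cosine distance"),
        ("semantic.utt_cosdist.max", "semantic", "max pairwise utterance cosine distance"),
        ("semantic.pic_sim_max_cosdist", "semantic", "max over utterances of min cosine distance to a picture key word"),
        ("semantic.prop_subjects_mentioned", "semantic", "fraction of picture subjects mentioned"),
        ("semantic.prop_subject_words", "semantic", "fraction of tokens that are subject words"),
        ("graph.n_nodes", "graph", "lemma types in the word-adjacency graph"),
        ("graph.n_edges", "graph", "token transitions (multi-edges)"),
        ("graph.repeated_edges", "graph", "distinct transitions occurring more than once"),
        ("graph.self_loops", "graph", "immediate word repetitions"),
        ("graph.lcc", "graph", "largest weakly connected component size"),
        ("graph.density", "graph", "distinct transitions / n(n-1)"),
    ]
    return rows


def write_feature_manifest(path: str | Path, config: FrameConfig | None = None) -> None:
    lines = ["feature\tfamily\tdefinition"]
    lines += [f"{n}\t{f}\t{d}" for n, f, d in feature_manifest(config)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def extract_all(
    transcript: Transcript,
    audio: AudioSignal | None = None,
    norms: NormsTable | None = None,
    embeddings: EmbeddingTable | None = None,
    lexicon: ContentLexicon | None = None,
    pause_config: PauseConfig | None = None,
    frame_config: FrameConfig | None = None,
) -> dict[str, float | None]:
    """Compute every feature in the manifest for one sample.

    The result always contains the full manifest key set; a feature whose
    inputs are unavailable (no audio, no timing, no norms/embeddings) is
    explicitly None, never silently dropped. Deterministic.
    """
    frame_config = frame_config or FrameConfig()
    features: dict[str, float | None] = {name: None for name, _, _ in feature_manifest(frame_config)}

    try:
        features.update(pause_features(detect_pauses(transcript, pause_config)))
        features.update(timing_feature_dict(transcript))
    except (MissingTimingError, ValueError):
        pass  # untimed transcript: timing-family features stay missing

    if audio is not None:
        features.update(zcr_stats(audio, frame_config).flat())
        features.update(mfcc_stats(audio, frame_config).flat())

    features.update(lexical_stats(transcript, norms))
    features.update(vocabulary_richness(transcript))
    try:
        features.update(syntactic_rates(transcript))
    except ParseFormatError:
        raise
    features.update(utterance_repetitiveness(transcript))
    if embeddings is not None:
        features.update(picture_similarity(transcript, embeddings, lexicon or load_content_lexicon()))
    features.update(speech_graph_metrics(transcript))
    return features
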