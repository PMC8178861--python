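import numpy as np
import pytest

from _reference import count_tree_patterns, random_toy_tree
from conftest import make_word_transcript
from picdesc.corpus_io import EmbeddingTable, NormEntry, NormsTable, Token, Transcript, Utterance
from picdesc.linguistic import (
    ContentLexicon,
    extract_all,
    feature_manifest,
    lexical_stats,
    load_content_lexicon,
    picture_similarity,
    speech_graph_metrics,
    syntactic_rates,
    utterance_repetitiveness,
    vocabulary_richness,
)
from picdesc.trees import ParseFormatError, parse_tree


def _transcript_with_pos(spec, parse=None):
    """spec: list of (surface, pos) pairs for one utterance."""
    tokens = tuple(Token(surface=s, lemma=s.lower(), pos=p) for s, p in spec)
    return Transcript("t", (Utterance("PAR", tokens, parse=parse),))


class TestLexical:
    def test_average_word_length(self):
        t = _transcript_with_pos([("the", "DT"), ("boy", "NN"), ("runs", "VBZ")])
        out = lexical_stats(t)
        assert out["lexical.avg_word_length"] == pytest.approx(10 / 3)

    def test_norm_mean_over_covered_words_with_coverage(self):
        norms = NormsTable({"the": NormEntry(aoa=4.0), "boy": NormEntry(aoa=6.0)})
        t = _transcript_with_pos([("the", "DT"), ("boy", "NN"), ("runs", "VBZ")])
        out = lexical_stats(t, norms)
        assert out["lexical.avg_aoa.all"] == pytest.approx(5.0)
        assert out["lexical.norm_coverage"] == pytest.approx(2 / 3)

    def test_pos_based_rates(self):
        t = _transcript_with_pos([
            ("that", "DT"), ("boy", "NN"), ("jumped", "VBD"),
            ("and", "CC"), ("ran", "VBD"), ("because", "IN"), ("bigger", "JJR"),
        ])
        out = lexical_stats(t)
        assert out["lexical.rate_past_tense"] == pytest.approx(200 / 7)
        assert out["lexical.rate_demonstratives"] == pytest.approx(100 / 7)
        assert out["lexical.rate_comparative_adj"] == pytest.approx(100 / 7)
        assert out["lexical.ratio_sub_coord"] == pytest.approx(1.0)

    def test_zero_coordinators_gives_missing_ratio(self):
        t = _transcript_with_pos([("boy", "NN")])
        assert lexical_stats(t)["lexical.ratio_sub_coord"] is None

    def test_empty_transcript_all_missing(self):
        t = Transcript("t", ())
        assert all(v is None for v in lexical_stats(t).values())


class TestRichness:
    def test_ttr_on_repeated_word(self):
        t = make_word_transcript([["a", "a", "a", "a"]])
        assert vocabulary_richness(t)["richness.ttr"] == pytest.approx(0.25)

    def test_all_distinct_tokens(self):
        t = make_word_transcript([[f"w{i}" for i in range(10)]])
        out = vocabulary_richness(t)
        assert out["richness.ttr"] == 1.0
        assert out["richness.mattr_w10"] == 1.0

    def test_honore_statistic_closed_form(self):
        # N=100 tokens, V=50 types, V1=20 hapaxes
        words = [f"h{i}" for i in range(20)]          # 20 hapaxes
        for i in range(29):                            # 29 doubletons = 58 tokens
            words += [f"d{i}"] * 2
        words += ["filler_type"] * 22                  # 1 type with 22 tokens
        t = make_word_transcript([words])
        out = vocabulary_richness(t)
        assert out["richness.honore_r"] == pytest.approx(100 * np.log(100) / (1 - 20 / 50))
        assert out["richness.brunet_w"] == pytest.approx(100 ** (50 ** -0.165))

    def test_hapax_only_vocabulary_makes_honore_undefined(self):
        t = make_word_transcript([["a", "b", "c"]])
        assert vocabulary_richness(t)["richness.honore_r"] is None

    def test_brunet_decreases_with_more_types_at_fixed_n(self):
        def brunet(v):
            words = [f"w{i}" for i in range(v)] + ["w0"] * (60 - v)
            return vocabulary_richness(make_word_transcript([words]))["richness.brunet_w"]

        values = [brunet(v) for v in (10, 20, 30, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSyntax:
    def test_simple_clause_counts(self):
        parse = "(S (NP (DT the) (NN boy)) (VP (VBZ runs)))"
        t = _transcript_with_pos(
            [("the", "DT"), ("boy", "NN"), ("runs", "VBZ")], parse=parse)
        out = syntactic_rates(t)
        assert out["syntax.np_dt_nn.rate"] == pytest.approx(100 / 3)
        assert out["syntax.coord_per_clause"] == pytest.approx(0.0)

    def test_coordinate_noun_phrase(self):
        parse = "(NP (NP (NN cat)) (CC and) (NP (NN dog)))"
        t = _transcript_with_pos(
            [("cat", "NN"), ("and", "CC"), ("dog", "NN")], parse=parse)
        assert syntactic_rates(t)["syntax.coord_phrase.rate"] == pytest.approx(100 / 3)

    def test_unbalanced_parse_names_utterance(self):
        t = _transcript_with_pos([("boy", "NN")], parse="(S (NP (NN boy)")
        with pytest.raises(ParseFormatError, match="utterance 0"):
            syntactic_rates(t)

    def test_pattern_counts_match_brute_force_on_random_trees(self):
        from picdesc.linguistic import _count_patterns

        rng = np.random.default_rng(99)
        for _ in range(100):
            tree = random_toy_tree(rng)
            assert _count_patterns(tree) == count_tree_patterns(tree)


class TestRepetitiveness:
    def test_identical_utterances_distance_zero(self):
        t = make_word_transcript([["the", "boy"], ["the", "boy"]])
        out = utterance_repetitiveness(t)
        assert out["semantic.utt_cosdist.mean"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_vocabulary_distance_one(self):
        t = make_word_transcript([["a", "b"], ["c", "d"]])
        assert utterance_repetitiveness(t)["semantic.utt_cosdist.mean"] == pytest.approx(1.0)

    def test_three_utterances_hand_computed_mean(self):
        # bags: u1={a:2}, u2={a:1,b:1}, u3={b:1}
        t = make_word_transcript([["a", "a"], ["a", "b"], ["b"]])
        d12 = 1 - 1 / np.sqrt(2)
        d13 = 1.0
        d23 = 1 - 1 / np.sqrt(2)
        out = utterance_repetitiveness(t)
        assert out["semantic.utt_cosdist.mean"] == pytest.approx((d12 + d13 + d23) / 3)
        assert out["semantic.utt_cosdist.min"] == pytest.approx(d12)
        assert out["semantic.utt_cosdist.max"] == pytest.approx(1.0)

    def test_single_utterance_is_missing(self):
        t = make_word_transcript([["a", "b"]])
        assert utterance_repetitiveness(t)["semantic.utt_cosdist.mean"] is None


class TestPictureSimilarity:
    lexicon = ContentLexicon(
        roles={"boy": "subject", "girl": "subject", "mother": "subject", "sink": "object"},
        synonyms={"mother": ("woman",)},
    )

    def test_key_word_utterance_has_zero_distance(self):
        emb = EmbeddingTable({"boy": [1.0, 0.0], "sink": [0.0, 1.0]})
        t = make_word_transcript([["boy"]])
        out = picture_similarity(t, emb, self.lexicon)
        assert out["semantic.pic_sim_max_cosdist"] == pytest.approx(0.0, abs=1e-12)

    def test_proportion_of_subjects_with_synonyms(self):
        emb = EmbeddingTable({"boy": [1.0, 0.0]})
        t = make_word_transcript([["woman", "saw", "it"]])
        out = picture_similarity(t, emb, self.lexicon)
        assert out["semantic.prop_subjects_mentioned"] == pytest.approx(1 / 3)
        assert out["semantic.prop_subject_words"] == pytest.approx(1 / 3)

    def test_orthogonal_embeddings_give_distance_one(self):
        emb = EmbeddingTable({
            "boy": [1.0, 0.0, 0.0], "sink": [0.0, 1.0, 0.0], "tree": [0.0, 0.0, 1.0],
        })
        t = make_word_transcript([["tree"]])
        out = picture_similarity(t, emb, self.lexicon)
        assert out["semantic.pic_sim_max_cosdist"] == pytest.approx(1.0)

    def test_no_covered_lemma_is_missing(self):
        emb = EmbeddingTable({"boy": [1.0, 0.0]})
        t = make_word_transcript([["zzz"]])
        assert picture_similarity(t, emb, self.lexicon)["semantic.pic_sim_max_cosdist"] is None


class TestSpeechGraph:
    def test_alternating_pair(self):
        t = make_word_transcript([["a", "b", "a", "b"]])
        out = speech_graph_metrics(t)
        assert out["graph.n_nodes"] == 2
        assert out["graph.n_edges"] == 3
        assert out["graph.repeated_edges"] >= 1

    def test_identical_tokens_self_loops(self):
        t = make_word_transcript([["a"] * 6])
        out = speech_graph_metrics(t)
        assert out["graph.n_nodes"] == 1
        assert out["graph.self_loops"] == 5

    def test_disconnected_utterances(self):
        t = make_word_transcript([["a", "b"], ["c", "d"]])
        out = speech_graph_metrics(t)
        assert out["graph.lcc"] < out["graph.n_nodes"]

    def test_density_bounds(self):
        t = make_word_transcript([["a", "b", "c", "a", "c", "b"]])
        assert 0.0 <= speech_graph_metrics(t)["graph.density"] <= 1.0


class TestExtractAll:
    def test_manifest_size_and_explicit_missingness(self, cohort):
        t = cohort.transcripts[0]
        feats = extract_all(t, norms=cohort.norms, embeddings=cohort.embeddings,
                            lexicon=cohort.lexicon)
        manifest_names = [n for n, _, _ in feature_manifest()]
        assert len(manifest_names) >= 60
        assert set(feats) == set(manifest_names)
        for name, value in feats.items():
            assert value is None or np.isfinite(value), name

    def test_transcript_only_marks_spectral_features_missing(self, cohort):
        feats = extract_all(cohort.transcripts[0], norms=cohort.norms)
        assert feats["acoustic.mfcc4.d2.kurtosis"] is None
        assert feats["acoustic.zcr.mean"] is None
        assert feats["acoustic.pause.unfilled_count"] is not None  # timing-based

    def test_repeated_call_is_identical(self, cohort):
        t = cohort.transcripts[3]
        a = extract_all(t, norms=cohort.norms, embeddings=cohort.embeddings)
        b = extract_all(t, norms=cohort.norms, embeddings=cohort.embeddings)
        assert a == b

    def test_rates_invariant_to_utterance_order(self, cohort):
        t = cohort.transcripts[5]
        reordered = Transcript(t.sample_id, tuple(reversed(t.utterances)),
                               duration=t.duration)
        for fn in (utterance_repetitiveness, speech_graph_metrics):
            assert fn(t) == fn(reordered)
        assert syntactic_rates(t) == syntactic_rates(reordered)
        a, b = vocabulary_richness(t), vocabulary_richness(reordered)
        a.pop("richness.mattr_w10")  # MATTR slides over the token stream: order-defined
        b.pop("richness.mattr_w10")
        assert a == b


def test_default_lexicon_loads_with_subjects():
    lex = load_content_lexicon()
    assert {"boy", "girl", "mother"} <= set(lex.subjects)
    assert "woman" in lex.forms("mother")


def test_parse_tree_round_trip():
    s = "(S (NP (DT the) (NN boy)) (VP (VBZ runs)))"
    assert str(parse_tree(s)) == s
    assert parse_tree(s).leaves() == ["the", "boy", "runs"]
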