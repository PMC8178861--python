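import io

import numpy as np
import pytest
from scipy.io import wavfile

from picdesc.corpus_io import (
    CorpusFormatError,
    Token,
    read_chat_transcript,
    read_embeddings,
    read_labels_csv,
    read_norms_table,
    read_ratings_csv,
    read_transcript_json,
    read_wav,
    write_transcript_json,
)
from picdesc.simulate import simulate_cohort


class TestChatReader:
    def test_single_participant_tier(self):
        t = read_chat_transcript(io.StringIO("*PAR:\tthe boy is on the stool ."))
        assert len(t.utterances) == 1
        assert [tok.surface for tok in t.utterances[0].tokens] == [
            "the", "boy", "is", "on", "the", "stool",
        ]

    def test_investigator_tier_skipped(self):
        t = read_chat_transcript(io.StringIO("*INV:\tokay .\n*PAR:\tthe sink ."))
        assert len(t.utterances) == 1
        surfaces = {tok.surface for u in t.utterances for tok in u.tokens}
        assert "okay" not in surfaces

    def test_codes_fragments_continuations(self):
        text = (
            "@Begin\n"
            "*PAR:\tthe boy [//] the girl falls .\n"
            "*PAR:\t&-um the water &sp runs\n"
            "\tover the sink .\n"
            "%mor:\tignored tier\n"
            "*PAR:\tthe mother .\n"
            "@End\n"
        )
        t = read_chat_transcript(io.StringIO(text))
        assert len(t.utterances) == 3
        all_tokens = [tok.surface for u in t.utterances for tok in u.tokens]
        assert "[//]" not in all_tokens and "&sp" not in all_tokens
        # continuation line joined into utterance 2
        assert [tok.surface for tok in t.utterances[1].tokens] == [
            "um", "the", "water", "runs", "over", "the", "sink",
        ]
        assert t.utterances[1].tokens[0].is_filler

    def test_no_participant_tier_is_error(self):
        with pytest.raises(CorpusFormatError, match="participant"):
            read_chat_transcript(io.StringIO("*INV:\thello .\n"))

    def test_missing_header_warns_not_fatal(self):
        with pytest.warns(UserWarning, match="header"):
            t = read_chat_transcript(io.StringIO("*PAR:\tthe sink ."))
        assert len(t.utterances) == 1


class TestTranscriptJson:
    def test_minimal_document(self):
        doc = '{"sample_id": "x", "utterances": [{"speaker": "PAR", "tokens": [{"surface": "boy"}]}]}'
        t = read_transcript_json(io.StringIO(doc))
        assert len(t.utterances) == 1
        assert t.utterances[0].tokens[0].surface == "boy"

    def test_timing_preserved_to_ms(self):
        doc = ('{"sample_id": "x", "utterances": [{"speaker": "PAR", '
               '"tokens": [{"surface": "boy", "onset": 0.123, "offset": 0.456}]}]}')
        tok = read_transcript_json(io.StringIO(doc)).utterances[0].tokens[0]
        assert tok.onset == pytest.approx(0.123, abs=1e-9)
        assert tok.offset == pytest.approx(0.456, abs=1e-9)

    def test_round_trip_of_simulated_transcript(self):
        cohort = simulate_cohort(seed=3)
        original = cohort.transcripts[0]
        assert read_transcript_json(io.StringIO(write_transcript_json(original))) == original

    def test_schema_violation_names_field(self):
        with pytest.raises(CorpusFormatError, match="speaker"):
            read_transcript_json(io.StringIO('{"sample_id": "x", "utterances": [{"tokens": []}]}'))
        with pytest.raises(CorpusFormatError, match="surface"):
            read_transcript_json(io.StringIO(
                '{"sample_id": "x", "utterances": [{"speaker": "PAR", "tokens": [{"pos": "NN"}]}]}'
            ))


NORMS_TSV = (
    "word\tzipf\taoa\tvalence\tarousal\tdominance\n"
    "Boy\t5.4\t3.0\t6.2\t4.0\t5.5\n"
    "jar\t4.1\t\t5.3\t3.0\t5.2\n"
)


class TestNormsTable:
    def test_case_folded_lookup(self):
        norms = read_norms_table(io.StringIO(NORMS_TSV))
        assert norms.get("Boy").zipf == pytest.approx(5.4)
        assert norms.get("BOY").aoa == pytest.approx(3.0)

    def test_absent_word_reports_absence(self):
        norms = read_norms_table(io.StringIO(NORMS_TSV))
        assert norms.get("cookie") is None
        assert "cookie" not in norms

    def test_blank_cell_is_missing_not_zero(self):
        entry = read_norms_table(io.StringIO(NORMS_TSV)).get("jar")
        assert entry.aoa is None
        assert entry.valence == pytest.approx(5.3)

    def test_duplicate_word_last_wins_with_warning(self):
        tsv = NORMS_TSV + "boy\t6.0\t4.0\t6.0\t4.0\t5.0\n"
        with pytest.warns(UserWarning, match="duplicate"):
            norms = read_norms_table(io.StringIO(tsv))
        assert norms.get("boy").zipf == pytest.approx(6.0)

    def test_missing_header_is_error(self):
        with pytest.raises(CorpusFormatError, match="header"):
            read_norms_table(io.StringIO("boy\t5.4\t3.0\t6.2\t4.0\t5.5\n"))


class TestEmbeddings:
    def test_small_table(self):
        table = read_embeddings(io.StringIO("a 1 0 0 0\nb 0 1 0 0\nc 0 0 1 0\n"))
        assert len(table) == 3 and table.dim == 4
        assert np.allclose(table.get("b"), [0, 1, 0, 0])

    def test_inconsistent_dimension_is_error(self):
        with pytest.raises(CorpusFormatError, match="dimension"):
            read_embeddings(io.StringIO("a 1 0 0 0\nb 0 1 0\n"))

    def test_non_numeric_component_names_line(self):
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_embeddings(io.StringIO("a 1 0\nb x 1\n"))

    def test_zero_vector_disallowed(self):
        with pytest.raises(CorpusFormatError, match="zero"):
            read_embeddings(io.StringIO("a 0 0 0\n"))


class TestWavAndRatings:
    def test_silence_wav(self, tmp_path):
        path = tmp_path / "silence.wav"
        wavfile.write(path, 16000, np.zeros(16000, dtype=np.int16))
        audio = read_wav(path)
        assert audio.rate == 16000
        assert audio.samples.size == 16000
        assert np.all(audio.samples == 0)

    def test_stereo_downmix_and_scaling(self, tmp_path):
        path = tmp_path / "stereo.wav"
        data = np.column_stack([
            np.full(100, 16384, dtype=np.int16),
            np.full(100, -16384, dtype=np.int16),
        ])
        wavfile.write(path, 8000, data)
        audio = read_wav(path)
        assert np.allclose(audio.samples, 0.0)
        assert np.all(np.abs(audio.samples) <= 1.0)

    def _ratings_csv(self, n_samples=30, n_raters=5, n_chars=4):
        lines = ["sample_id,characteristic,rater_id,rating"]
        for i in range(n_samples):
            for c in range(n_chars):
                for r in range(n_raters):
                    lines.append(f"S{i},char{c},R{r},{(i + r) % 4}")
        return "\n".join(lines)

    def test_panel_shape(self):
        panel = read_ratings_csv(io.StringIO(self._ratings_csv()))
        assert panel.table.shape == (30 * 4, 5)
        assert panel.table.notna().sum().sum() == 600

    def test_out_of_range_rating_names_cell(self):
        csv = ("sample_id,characteristic,rater_id,rating\n"
               "S1,wf,R1,2\nS1,wf,R2,5\n")
        with pytest.raises(CorpusFormatError, match=r"R2"):
            read_ratings_csv(io.StringIO(csv))

    def test_labels_reader_validates_groups(self):
        labels = read_labels_csv(io.StringIO("sample_id,group\nS1,HC\nS2,AD\n"))
        assert labels["S2"] == "AD"
        with pytest.raises(CorpusFormatError, match="group"):
            read_labels_csv(io.StringIO("sample_id,group\nS1,XX\n"))


def test_token_invariants():
    with pytest.raises(ValueError):
        Token(surface="")
    with pytest.raises(ValueError):
        Token(surface="boy", onset=1.0, offset=0.5)
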