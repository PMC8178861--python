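"""Data model and readers/writers for picture-description corpora.

The unit of analysis is a ~1-minute "Cookie Theft" style picture description:
a transcript of timed, POS-tagged tokens grouped into utterances, optionally
paired with a mono waveform, plus the side tables the feature extractors need
(psycholinguistic norms, word embeddings) and the clinician rating panels.

Times are seconds (float); a token occupies the half-open interval
``[onset, offset)``. Norm and embedding lookup is case-folded; surface forms
are preserved everywhere else. Missing norm values stay missing — they are
never imputed as zero, since a zero age-of-acquisition or valence would bias
the per-transcript means.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Token",
    "Utterance",
    "Transcript",
    "AudioSignal",
    "NormsTable",
    "NormEntry",
    "EmbeddingTable",
    "RatingPanel",
    "CorpusFormatError",
    "read_chat_transcript",
    "read_transcript_json",
    "write_transcript_json",
    "read_norms_table",
    "read_embeddings",
    "read_wav",
    "read_ratings_csv",
    "read_labels_csv",
]

FILLER_SURFACES = frozenset({"um", "uh", "er", "ah", "em", "hm", "mhm"})

GROUPS = ("HC", "MCI", "AD")


class CorpusFormatError(ValueError):
    """An external file violated the expected format."""


@dataclass(frozen=True)
class Token:
    """One spoken word (or hesitation marker) with optional timing.

    ``pos`` is a Penn-Treebank tag; ``is_filler`` marks um/uh-class
    hesitations, which are excluded from lexical counts but participate in
    pause logic (a gap bridged by a filler is a filled pause).
    """

    surface: str
    lemma: str | None = None
    pos: str | None = None
    onset: float | None = None
    offset: float | None = None
    is_filler: bool = False

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("Token surface must be non-empty")
        if self.onset is not None and self.offset is not None:
            if not self.offset > self.onset:
                raise ValueError(
                    f"Token {self.surface!r}: offset {self.offset} must exceed "
                    f"onset {self.onset}"
                )

    @property
    def duration(self) -> float | None:
        if self.onset is None or self.offset is None:
            return None
        return self.offset - self.onset


@dataclass(frozen=True)
class Utterance:
    speaker: str
    tokens: tuple[Token, ...]
    parse: str | None = None
    start: float | None = None
    end: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        prev = None
        for tok in self.tokens:
            if tok.onset is not None:
                if prev is not None and tok.onset < prev:
                    raise ValueError("token onsets must be nondecreasing")
                prev = tok.onset if tok.offset is None else tok.offset
            if self.start is not None and tok.onset is not None and tok.onset < self.start:
                raise ValueError("token onset before utterance start")
            if self.end is not None and tok.offset is not None and tok.offset > self.end:
                raise ValueError("token offset after utterance end")

    def content_tokens(self) -> tuple[Token, ...]:
        """Tokens excluding fillers."""
        return tuple(t for t in self.tokens if not t.is_filler)


@dataclass(frozen=True)
class Transcript:
    sample_id: str
    utterances: tuple[Utterance, ...]
    audio_path: str | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "utterances", tuple(self.utterances))

    def tokens(self, include_fillers: bool = False) -> tuple[Token, ...]:
        out: list[Token] = []
        for utt in self.utterances:
            out.extend(utt.tokens if include_fillers else utt.content_tokens())
        return tuple(out)

    def elapsed_duration(self) -> float | None:
        """Stated duration, else span from first onset to last offset."""
        if self.duration is not None:
            return self.duration
        onsets = [t.onset for t in self.tokens(include_fillers=True) if t.onset is not None]
        offsets = [t.offset for t in self.tokens(include_fillers=True) if t.offset is not None]
        if not onsets or not offsets:
            return None
        return max(offsets) - min(onsets)


@dataclass(frozen=True)
class AudioSignal:
    """Mono waveform, amplitudes in [-1, 1]."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("AudioSignal requires a 1-D, non-empty sample array")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class NormEntry:
    """Psycholinguistic norms for one word; any field may be missing (None)."""

    zipf: float | None = None
    aoa: float | None = None
    valence: float | None = None
    arousal: float | None = None
    dominance: float | None = None


class NormsTable:
    """Case-folded word -> norms lookup. Absent words report absence."""

    def __init__(self, entries: Mapping[str, NormEntry]):
        self._entries = {w.lower(): e for w, e in entries.items()}

    def get(self, word: str) -> NormEntry | None:
        return self._entries.get(word.lower())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def words(self) -> Iterable[str]:
        return self._entries.keys()


class EmbeddingTable:
    """Case-folded word -> dense vector of fixed dimension."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        self._vectors: dict[str, np.ndarray] = {}
        self.dim: int | None = None
        for word, vec in vectors.items():
            v = np.asarray(vec, dtype=np.float64)
            if self.dim is None:
                self.dim = v.size
            elif v.size != self.dim:
                raise CorpusFormatError(
                    f"embedding for {word!r} has dimension {v.size}, expected {self.dim}"
                )
            if not np.any(v):
                raise CorpusFormatError(f"zero embedding vector for {word!r}")
            self._vectors[word.lower()] = v

    def get(self, word: str) -> np.ndarray | None:
        return self._vectors.get(word.lower())

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)


class RatingPanel:
    """Ordinal 0-3 ratings, items (sample, characteristic) x raters.

    Stored as a DataFrame indexed by (sample_id, characteristic) with one
    column per rater; missing ratings are NaN.
    """

    VALID = frozenset({0, 1, 2, 3})

    def __init__(self, table: pd.DataFrame):
        bad = []
        values = table.to_numpy(dtype=float)
        for (i, j), v in np.ndenumerate(values):
            if not np.isnan(v) and v not in self.VALID:
                bad.append((table.index[i], table.columns[j], v))
        if bad:
            item, rater, v = bad[0]
            raise CorpusFormatError(
                f"invalid rating {v!r} for item {item}, rater {rater!r} "
                f"({len(bad)} invalid cell(s) total); ratings must be in 0..3"
            )
        self.table = table.sort_index()

    @property
    def raters(self) -> list[str]:
        return list(self.table.columns)

    @property
    def items(self) -> list[tuple[str, str]]:
        return list(self.table.index)

    def characteristic(self, name: str) -> pd.DataFrame:
        """Items x raters sub-panel for one rated characteristic."""
        sub = self.table.xs(name, level="characteristic")
        if sub.empty:
            raise KeyError(name)
        return sub

    def characteristics(self) -> list[str]:
        return sorted(set(self.table.index.get_level_values("characteristic")))


# ---------------------------------------------------------------------------
# CHAT (.cha) minimal dialect
# ---------------------------------------------------------------------------

def _clean_chat_token(raw: str) -> Token | None:
    """Map one whitespace token of a CHAT main tier to a Token, or drop it."""
    raw = raw.strip()
    if not raw:
        return None
    if raw.startswith("[") and raw.endswith("]"):
        return None  # CHAT code, e.g. [//]
    if raw in {".", "?", "!", "+...", "+..?", "+/.", "+//."}:
        return None  # utterance terminators
    if raw.startswith("&-"):
        surface = raw[2:].strip(".,?!")
        if not surface:
            return None
        if surface.lower() in FILLER_SURFACES:
            return Token(surface=surface, lemma=surface.lower(), is_filler=True)
        return None
    if raw.startswith("&"):
        return None  # phonological fragment
    surface = raw.strip(".,?!")
    if not surface:
        return None
    return Token(surface=surface, lemma=surface.lower(),
                 is_filler=surface.lower() in FILLER_SURFACES)


def read_chat_transcript(
    stream: IO[str] | str | Path,
    sample_id: str | None = None,
    participant_prefix: str = "*PAR:",
) -> Transcript:
    """Read a minimal-dialect CHAT (.cha) file: participant main tiers only.

    One Utterance per participant tier line (continuation lines joined);
    bracketed codes, ``&``-prefixed fragments and terminators are stripped;
    ``&-um``/``&-uh`` hesitations are kept as filler tokens. Dependent tiers
    (``%...``) and other speakers are skipped. No timing or POS is attached —
    annotation happens downstream.
    """
    if isinstance(stream, (str, Path)):
        path = Path(stream)
        text = path.read_text(encoding="utf-8")
        if sample_id is None:
            sample_id = path.stem
    else:
        text = stream.read()
    if sample_id is None:
        sample_id = "chat"

    lines = text.splitlines()
    if lines and not lines[0].startswith("@"):
        warnings.warn("CHAT stream does not start with an @ header line", stacklevel=2)

    # join continuation lines (leading tab/space) onto the current tier
    tiers: list[str] = []
    for line in lines:
        if line.startswith(("@", "*", "%")):
            tiers.append(line)
        elif line.startswith(("\t", " ")) and tiers:
            tiers[-1] += " " + line.strip()

    speaker = participant_prefix.strip("*:").strip()
    utterances: list[Utterance] = []
    saw_participant_tier = False
    for tier in tiers:
        if not tier.startswith(participant_prefix):
            continue
        saw_participant_tier = True
        body = tier[len(participant_prefix):].strip()
        tokens = [t for t in (_clean_chat_token(w) for w in body.split()) if t is not None]
        if tokens:
            utterances.append(Utterance(speaker=speaker, tokens=tuple(tokens)))
    if not saw_participant_tier:
        raise CorpusFormatError(
            f"no participant tiers ({participant_prefix!r}) found: empty transcript"
        )
    return Transcript(sample_id=sample_id, utterances=tuple(utterances))


# ---------------------------------------------------------------------------
# Transcript JSON
# ---------------------------------------------------------------------------

def _token_to_dict(t: Token) -> dict:
    return {
        "surface": t.surface,
        "lemma": t.lemma,
        "pos": t.pos,
        "onset": t.onset,
        "offset": t.offset,
        "is_filler": t.is_filler,
    }


def _token_from_dict(d: Mapping, where: str) -> Token:
    if "surface" not in d:
        raise CorpusFormatError(f"{where}: token missing required field 'surface'")
    try:
        return Token(
            surface=d["surface"],
            lemma=d.get("lemma"),
            pos=d.get("pos"),
            onset=d.get("onset"),
            offset=d.get("offset"),
            is_filler=bool(d.get("is_filler", False)),
        )
    except (TypeError, ValueError) as exc:
        raise CorpusFormatError(f"{where}: invalid token: {exc}") from exc


def write_transcript_json(transcript: Transcript, stream: IO[str] | str | Path | None = None) -> str:
    """Serialise a Transcript to the canonical JSON document (lossless)."""
    doc = {
        "sample_id": transcript.sample_id,
        "duration": transcript.duration,
        "audio_path": transcript.audio_path,
        "utterances": [
            {
                "speaker": u.speaker,
                "start": u.start,
                "end": u.end,
                "parse": u.parse,
                "tokens": [_token_to_dict(t) for t in u.tokens],
            }
            for u in transcript.utterances
        ],
    }
    text = json.dumps(doc, indent=1, sort_keys=True)
    if stream is not None:
        if isinstance(stream, (str, Path)):
            Path(stream).write_text(text, encoding="utf-8")
        else:
            stream.write(text)
    return text


def read_transcript_json(stream: IO[str] | str | Path) -> Transcript:
    """Read the canonical Transcript JSON document (round-trip inverse)."""
    if isinstance(stream, (str, Path)):
        text = Path(stream).read_text(encoding="utf-8")
    else:
        text = stream.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"invalid transcript JSON: {exc}") from exc
    if "sample_id" not in doc:
        raise CorpusFormatError("transcript document missing required field 'sample_id'")
    utterances = []
    for i, u in enumerate(doc.get("utterances", [])):
        where = f"utterance {i}"
        if "speaker" not in u:
            raise CorpusFormatError(f"{where}: missing required field 'speaker'")
        tokens = tuple(
            _token_from_dict(t, f"{where}, token {j}") for j, t in enumerate(u.get("tokens", []))
        )
        try:
            utterances.append(
                Utterance(
                    speaker=u["speaker"],
                    tokens=tokens,
                    parse=u.get("parse"),
                    start=u.get("start"),
                    end=u.get("end"),
                )
            )
        except ValueError as exc:
            raise CorpusFormatError(f"{where}: {exc}") from exc
    return Transcript(
        sample_id=doc["sample_id"],
        utterances=tuple(utterances),
        audio_path=doc.get("audio_path"),
        duration=doc.get("duration"),
    )


# ---------------------------------------------------------------------------
# Norms, embeddings, WAV, ratings, labels
# ---------------------------------------------------------------------------

_NORM_COLUMNS = ("word", "zipf", "aoa", "valence", "arousal", "dominance")


def read_norms_table(stream: IO[str] | str | Path) -> NormsTable:
    """Read a TSV of psycholinguistic norms (zipf frequency, AoA years,
    valence/arousal/dominance on 1-9). Blank cells are missing; keys are
    case-folded; duplicate words keep the last row (with a warning)."""
    if isinstance(stream, (str, Path)):
        stream = io.StringIO(Path(stream).read_text(encoding="utf-8"))
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise CorpusFormatError("norms table is empty: missing header") from None
    header = [h.strip().lower() for h in header]
    if tuple(header[: len(_NORM_COLUMNS)]) != _NORM_COLUMNS:
        raise CorpusFormatError(
            f"norms table header must be {list(_NORM_COLUMNS)}, got {header}"
        )
    entries: dict[str, NormEntry] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or not row[0].strip():
            continue
        word = row[0].strip().lower()
        vals: list[float | None] = []
        for j, name in enumerate(_NORM_COLUMNS[1:], start=1):
            cell = row[j].strip() if j < len(row) else ""
            if not cell:
                vals.append(None)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise CorpusFormatError(
                    f"norms table line {lineno}: non-numeric {name} value {cell!r}"
                ) from None
        if word in entries:
            warnings.warn(f"duplicate norms row for {word!r}: last row wins", stacklevel=2)
        entries[word] = NormEntry(*vals)
    return NormsTable(entries)


def read_embeddings(stream: IO[str] | str | Path) -> EmbeddingTable:
    """Read a GloVe-style whitespace text embedding table; the dimension is
    inferred from the first line and enforced thereafter."""
    if isinstance(stream, (str, Path)):
        stream = io.StringIO(Path(stream).read_text(encoding="utf-8"))
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    for lineno, line in enumerate(stream, start=1):
        parts = line.split()
        if not parts:
            continue
        word, comps = parts[0], parts[1:]
        if dim is None:
            dim = len(comps)
            if dim == 0:
                raise CorpusFormatError(f"embeddings line {lineno}: no vector components")
        elif len(comps) != dim:
            raise CorpusFormatError(
                f"embeddings line {lineno}: dimension {len(comps)} != {dim}"
            )
        try:
            vec = np.array([float(c) for c in comps])
        except ValueError:
            raise CorpusFormatError(
                f"embeddings line {lineno}: non-numeric vector component"
            ) from None
        vectors[word] = vec
    if not vectors:
        raise CorpusFormatError("embedding table is empty")
    return EmbeddingTable(vectors)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file as mono float64 in [-1, 1] (stereo is downmixed
    by channel mean)."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioSignal(samples=data, rate=int(rate))


def read_ratings_csv(stream: IO[str] | str | Path) -> RatingPanel:
    """Read long-format ratings (sample_id, characteristic, rater_id, rating)
    into a validated items x raters panel."""
    df = pd.read_csv(stream, dtype={"sample_id": str, "rater_id": str})
    required = {"sample_id", "characteristic", "rater_id", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusFormatError(f"ratings CSV missing columns: {sorted(missing)}")
    wide = df.pivot_table(
        index=["sample_id", "characteristic"],
        columns="rater_id",
        values="rating",
        aggfunc="last",
    )
    wide.index.names = ["sample_id", "characteristic"]
    wide.columns.name = None
    return RatingPanel(wide)


def read_labels_csv(stream: IO[str] | str | Path) -> pd.Series:
    """Read diagnosis labels (sample_id, group in {HC, MCI, AD})."""
    df = pd.read_csv(stream, dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise CorpusFormatError("labels CSV must have columns sample_id, group")
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise CorpusFormatError(f"unknown group labels {bad}; expected {GROUPS}")
    return df.set_index("sample_id")["group"]
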