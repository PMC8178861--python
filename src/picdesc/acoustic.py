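"""Acoustic variables: pauses, speech rate, word duration, and framewise
spectral statistics (zero-crossing counts, MFCCs, log energy and their
derivatives).

Pauses are computed from word-level timing annotations, not from waveform
energy: a pause is a silent gap between consecutive non-filler words, and a
gap bridged by a hesitation marker (um/uh) is a *filled* pause and is
excluded. Thresholds are configurable; the defaults (0.25 s to count a gap
as an unfilled pause, 1.0 s to call it long) are conventional values for
connected-speech analysis.

Framewise statistics use 25 ms Hamming windows with a 10 ms hop. Skewness
and kurtosis are Pearson moment ratios (kurtosis is *not* excess-corrected:
a normal channel scores 3); a zero-variance channel reports missing skew and
kurtosis rather than a 0/0 artefact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.stats

from .corpus_io import AudioSignal, Transcript

__all__ = [
    "PauseConfig",
    "PauseSet",
    "FrameConfig",
    "FrameStats",
    "detect_pauses",
    "timing_features",
    "zcr_stats",
    "mfcc_stats",
    "frame_count",
    "pause_features",
    "timing_feature_dict",
]


class MissingTimingError(ValueError):
    """Raised when an operation requires word-level timing that is absent.

    Real corpora get timing from manual alignment; for synthetic cohorts use
    the simulated timing attached by the cohort generator.
    """


# ---------------------------------------------------------------------------
# Pauses and timing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PauseConfig:
    unfilled_min: float = 0.25  # s; shorter gaps are articulatory, not pauses
    long_min: float = 1.0      # s; boundary between short and long pauses


@dataclass(frozen=True)
class PauseSet:
    pauses: tuple[tuple[float, float], ...]  # (start, end) of unfilled pauses
    short: tuple[tuple[float, float], ...]
    long: tuple[tuple[float, float], ...]

    @property
    def unfilled_count(self) -> int:
        return len(self.pauses)

    @property
    def short_count(self) -> int:
        return len(self.short)

    @property
    def long_count(self) -> int:
        return len(self.long)

    @property
    def total_short_dur(self) -> float:
        return float(sum(e - s for s, e in self.short))

    @property
    def total_long_dur(self) -> float:
        return float(sum(e - s for s, e in self.long))

    @property
    def mean_dur(self) -> float | None:
        if not self.pauses:
            return None
        return float(sum(e - s for s, e in self.pauses) / len(self.pauses))


def _timed_intervals(transcript: Transcript, fillers: bool) -> list[tuple[float, float]]:
    out = []
    for utt in transcript.utterances:
        for tok in utt.tokens:
            if tok.is_filler is not fillers:
                continue
            if tok.onset is None or tok.offset is None:
                raise MissingTimingError(
                    f"token {tok.surface!r} in {transcript.sample_id!r} lacks timing; "
                    "supply aligned timing or use simulated timing"
                )
            out.append((tok.onset, tok.offset))
    out.sort()
    return out


def detect_pauses(transcript: Transcript, config: PauseConfig | None = None) -> PauseSet:
    """Find unfilled (silent) pauses between consecutive non-filler words.

    Gaps are taken across utterance boundaries within the sample. A gap of at
    least ``unfilled_min`` counts as an unfilled pause; pauses shorter than
    ``long_min`` are short, the rest long. If any filler token overlaps the
    gap it is a filled pause and is excluded from every count.
    """
    config = config or PauseConfig()
    words = _timed_intervals(transcript, fillers=False)
    fillers = _timed_intervals(transcript, fillers=True)

    pauses: list[tuple[float, float]] = []
    for (s0, e0), (s1, e1) in zip(words, words[1:]):
        gap_start, gap_end = e0, s1
        if gap_end - gap_start < config.unfilled_min:
            continue
        bridged = any(fs < gap_end and fe > gap_start for fs, fe in fillers)
        if bridged:
            continue
        pauses.append((gap_start, gap_end))

    short = tuple(p for p in pauses if (p[1] - p[0]) < config.long_min)
    long = tuple(p for p in pauses if (p[1] - p[0]) >= config.long_min)
    return PauseSet(pauses=tuple(pauses), short=short, long=long)


def timing_features(transcript: Transcript) -> dict[str, float]:
    """Speech rate (words/min over elapsed time, pauses included), mean word
    duration (s), and total elapsed duration (s); fillers excluded."""
    words = _timed_intervals(transcript, fillers=False)
    duration = transcript.elapsed_duration()
    if duration is None or duration <= 0:
        raise ValueError(f"transcript {transcript.sample_id!r} has nonpositive duration")
    durations = [e - s for s, e in words]
    return {
        "speech_rate": len(words) / duration * 60.0,
        "avg_word_duration": float(np.mean(durations)) if durations else float("nan"),
        "total_duration": float(duration),
    }


# ---------------------------------------------------------------------------
# Framewise statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameConfig:
    frame_len: float = 0.025   # s
    hop_len: float = 0.010     # s
    n_mfcc: int = 13           # c1..c13 (c0 replaced by a log-energy channel)
    n_mels: int = 26
    preemphasis: float = 0.0   # off by default; standard value 0.97 if wanted
    delta_width: int = 2       # +-N-frame regression deltas


def frame_count(n_samples: int, win: int, hop: int) -> int:
    """Number of full analysis frames: floor((N - win)/hop) + 1 (0 if N < win)."""
    if n_samples < win:
        return 0
    return (n_samples - win) // hop + 1


def _frame_signal(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    n = frame_count(x.size, win, hop)
    if n == 0:
        raise ValueError(f"signal of {x.size} samples is shorter than one frame ({win})")
    idx = np.arange(win)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _moment_stats(channel: np.ndarray) -> dict[str, float | None]:
    """Mean/variance/skewness/kurtosis (Pearson, non-excess) over frames.

    Zero-variance channels report skew/kurt as missing (None).
    """
    mean = float(np.mean(channel))
    var = float(np.var(channel))
    if var <= 0:
        return {"mean": mean, "variance": var, "skewness": None, "kurtosis": None}
    with warnings.catch_warnings():
        # near-constant channels trip scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = float(scipy.stats.skew(channel, bias=True))
        kurt = float(scipy.stats.kurtosis(channel, bias=True, fisher=False))
    return {"mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt}


@dataclass(frozen=True)
class FrameStats:
    """Per-channel moment statistics over analysis frames.

    ``channels`` maps a channel name (e.g. ``"zcr"``, ``"mfcc4"``,
    ``"mfcc4.d2"``, ``"log_energy.d1"``) to its mean/variance/skewness/
    kurtosis dict.
    """

    channels: dict[str, dict[str, float | None]] = field(default_factory=dict)
    n_frames: int = 0

    def flat(self, prefix: str = "acoustic") -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for chan, stats in self.channels.items():
            for stat, value in stats.items():
                out[f"{prefix}.{chan}.{stat}"] = value
        return out


def zcr_stats(audio: AudioSignal, config: FrameConfig | None = None) -> FrameStats:
    """Framewise zero-crossing counts and their moment statistics.

    A crossing is a strict sign change between consecutive samples; zeros are
    treated as positive, so the statistics are invariant to amplitude scaling.
    """
    config = config or FrameConfig()
    win = int(round(config.frame_len * audio.rate))
    hop = int(round(config.hop_len * audio.rate))
    frames = _frame_signal(audio.samples, win, hop)
    signs = frames >= 0
    counts = np.sum(signs[:, 1:] != signs[:, :-1], axis=1).astype(float)
    return FrameStats(channels={"zcr": _moment_stats(counts)}, n_frames=frames.shape[0])


def _mel(hz: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(hz, dtype=float) / 700.0)


def _mel_inv(mel: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(mel, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, n_fft: int, rate: int) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), n_mels x (n_fft//2 + 1)."""
    mel_pts = np.linspace(_mel(0.0), _mel(rate / 2.0), n_mels + 2)
    hz_pts = np.asarray(_mel_inv(mel_pts))
    bins = np.floor((n_fft + 1) * hz_pts / rate).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for m in range(1, n_mels + 1):
        lo, mid, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, mid):
            if mid > lo:
                fb[m - 1, k] = (k - lo) / (mid - lo)
        for k in range(mid, hi):
            if hi > mid:
                fb[m - 1, k] = (hi - k) / (hi - mid)
    return fb


def _delta(x: np.ndarray, width: int) -> np.ndarray:
    """Regression delta over +-width frames (edge frames replicate-padded)."""
    n = np.arange(1, width + 1)
    denom = 2.0 * np.sum(n**2)
    padded = np.pad(x, ((width, width), (0, 0)), mode="edge")
    out = np.zeros_like(x, dtype=float)
    for k in n:
        out += k * (padded[width + k: width + k + x.shape[0]]
                    - padded[width - k: width - k + x.shape[0]])
    return out / denom


def mfcc_stats(audio: AudioSignal, config: FrameConfig | None = None) -> FrameStats:
    """MFCC (c1..c13), log-energy, and their first/second derivative channels,
    each summarised by framewise mean/variance/skewness/kurtosis.

    Pipeline: optional pre-emphasis, 25 ms Hamming frames at 10 ms hop, power
    spectrum via FFT, 26 triangular mel filters, log, orthonormal DCT-II;
    coefficient indexing is 1-based ("4th MFCC" = c4). Log energy is the
    natural log of per-frame power (pre-window), kept as its own channel.
    Derivatives are +-2-frame regression deltas.
    """
    config = config or FrameConfig()
    x = audio.samples
    if config.preemphasis > 0:
        x = np.append(x[0], x[1:] - config.preemphasis * x[:-1])
    win = int(round(config.frame_len * audio.rate))
    hop = int(round(config.hop_len * audio.rate))
    frames = _frame_signal(x, win, hop)

    eps = np.finfo(np.float64).tiny
    log_energy = np.log(np.maximum(np.sum(frames**2, axis=1), eps))

    n_fft = 1 << (win - 1).bit_length()
    window = np.hamming(win)
    spectrum = np.abs(np.fft.rfft(frames * window, n=n_fft)) ** 2
    fb = _mel_filterbank(config.n_mels, n_fft, audio.rate)
    mel_energy = np.log(np.maximum(spectrum @ fb.T, eps))
    cepstra = scipy.fft.dct(mel_energy, type=2, axis=1, norm="ortho")
    mfcc = cepstra[:, 1: config.n_mfcc + 1]  # c1..c13; c0 dropped

    base = np.column_stack([mfcc, log_energy])
    d1 = _delta(base, config.delta_width)
    d2 = _delta(d1, config.delta_width)

    names = [f"mfcc{i}" for i in range(1, config.n_mfcc + 1)] + ["log_energy"]
    channels: dict[str, dict[str, float | None]] = {}
    for j, name in enumerate(names):
        channels[name] = _moment_stats(base[:, j])
        channels[f"{name}.d1"] = _moment_stats(d1[:, j])
        channels[f"{name}.d2"] = _moment_stats(d2[:, j])
    return FrameStats(channels=channels, n_frames=frames.shape[0])


# ---------------------------------------------------------------------------
# Canonical feature dictionaries
# ---------------------------------------------------------------------------

def pause_features(pauses: PauseSet) -> dict[str, float | None]:
    return {
        "acoustic.pause.unfilled_count": float(pauses.unfilled_count),
        "acoustic.pause.short_count": float(pauses.short_count),
        "acoustic.pause.long_count": float(pauses.long_count),
        "acoustic.pause.total_short_dur": pauses.total_short_dur,
        "acoustic.pause.total_long_dur": pauses.total_long_dur,
        "acoustic.pause.mean_dur": pauses.mean_dur,
    }


def timing_feature_dict(transcript: Transcript) -> dict[str, float]:
    t = timing_features(transcript)
    return {
        "acoustic.speech_rate": t["speech_rate"],
        "acoustic.avg_word_duration": t["avg_word_duration"],
        "acoustic.total_duration": t["total_duration"],
    }
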