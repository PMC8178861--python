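"""Independent, literal-formula reference implementations used as oracles.

Everything here is written directly from the textbook definitions (explicit
loops, explicit cosine transforms) so it shares no code path with the
package implementations it checks.
"""

import numpy as np


def reference_mfcc_logenergy(x, rate, frame_len=0.025, hop_len=0.010,
                             n_mels=26, n_mfcc=13):
    """Frames x (n_mfcc + 1) matrix of [c1..c13, log-energy] per frame."""
    win = int(round(frame_len * rate))
    hop = int(round(hop_len * rate))
    n_frames = (len(x) - win) // hop + 1

    # Hamming window, explicit formula
    n = np.arange(win)
    window = 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (win - 1))

    nfft = 1
    while nfft < win:
        nfft *= 2

    # triangular mel filterbank from the HTK mel formula
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    mel_points = np.linspace(hz_to_mel(0.0), hz_to_mel(rate / 2.0), n_mels + 2)
    bin_points = np.floor((nfft + 1) * mel_to_hz(mel_points) / rate).astype(int)
    fbank = np.zeros((n_mels, nfft // 2 + 1))
    for m in range(1, n_mels + 1):
        f_lo, f_mid, f_hi = bin_points[m - 1], bin_points[m], bin_points[m + 1]
        for k in range(f_lo, f_mid):
            if f_mid != f_lo:
                fbank[m - 1, k] = (k - f_lo) / (f_mid - f_lo)
        for k in range(f_mid, f_hi):
            if f_hi != f_mid:
                fbank[m - 1, k] = (f_hi - k) / (f_hi - f_mid)

    # orthonormal DCT-II matrix, explicit cosines
    dct = np.zeros((n_mels, n_mels))
    for k in range(n_mels):
        scale = np.sqrt(1.0 / n_mels) if k == 0 else np.sqrt(2.0 / n_mels)
        for j in range(n_mels):
            dct[k, j] = scale * np.cos(np.pi * k * (j + 0.5) / n_mels)

    tiny = np.finfo(np.float64).tiny
    out = np.zeros((n_frames, n_mfcc + 1))
    for i in range(n_frames):
        frame = np.asarray(x[i * hop: i * hop + win], dtype=float)
        out[i, n_mfcc] = np.log(max(np.sum(frame * frame), tiny))
        spec = np.abs(np.fft.rfft(frame * window, nfft)) ** 2
        mel_e = np.log(np.maximum(fbank @ spec, tiny))
        cep = dct @ mel_e
        out[i, :n_mfcc] = cep[1: n_mfcc + 1]
    return out


def reference_delta(channels, width=2):
    """Regression delta, explicit loop with replicated edges."""
    n_frames, n_chan = channels.shape
    denom = 2.0 * sum(k * k for k in range(1, width + 1))
    out = np.zeros_like(channels)
    for t in range(n_frames):
        for k in range(1, width + 1):
            fwd = channels[min(t + k, n_frames - 1)]
            bwd = channels[max(t - k, 0)]
            out[t] += k * (fwd - bwd)
    return out / denom


def reference_moments(channel):
    """Mean, variance, skewness, kurtosis (Pearson, biased) by the raw
    moment definitions."""
    channel = np.asarray(channel, dtype=float)
    m = channel.mean()
    centered = channel - m
    m2 = np.mean(centered**2)
    m3 = np.mean(centered**3)
    m4 = np.mean(centered**4)
    return m, m2, m3 / m2**1.5, m4 / m2**2


def count_tree_patterns(node):
    """Brute-force pattern counts by enumerating every node independently
    of the package's single-pass walker."""
    def all_nodes(n):
        nodes = [n]
        for child in n.children:
            nodes.extend(all_nodes(child))
        return nodes

    def dominates(n, label):
        return any(d.label == label for c in n.children for d in all_nodes(c))

    counts = dict(np_dt_nn=0, vp_vbd_np=0, vp_vbz_pp=0, vp_sbar=0,
                  coord_phrase=0, adjp=0, conj_vp=0, clauses=0)
    for n in all_nodes(node):
        kids = [c.label for c in n.children]
        counts["clauses"] += n.label in ("S", "SBAR")
        counts["adjp"] += n.label == "ADJP"
        counts["np_dt_nn"] += n.label == "NP" and kids == ["DT", "NN"]
        if n.label == "VP":
            counts["vp_vbd_np"] += kids == ["VBD", "NP"]
            counts["vp_vbz_pp"] += ("VBZ" in kids) and ("PP" in kids)
            counts["conj_vp"] += "CC" in kids
            counts["vp_sbar"] += dominates(n, "SBAR")
        counts["coord_phrase"] += sum(
            1 for i in range(1, len(kids) - 1)
            if kids[i] == "CC" and kids[i - 1] == kids[i + 1]
        )
    return counts


def random_toy_tree(rng, depth=0):
    """Random small constituency tree over a toy grammar."""
    labels = ["S", "NP", "VP", "PP", "SBAR", "ADJP"]
    pres = ["DT", "NN", "VBD", "VBZ", "CC", "IN", "JJ"]
    words = ["the", "boy", "ran", "runs", "and", "on", "big"]
    from picdesc.trees import TreeNode

    if depth >= 3 or rng.random() < 0.4:
        i = int(rng.integers(len(pres)))
        return TreeNode(label=pres[i], leaf=words[i])
    label = labels[int(rng.integers(len(labels)))]
    n_children = int(rng.integers(1, 4))
    return TreeNode(
        label=label,
        children=tuple(random_toy_tree(rng, depth + 1) for _ in range(n_children)),
    )
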