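"""Per-event acoustic features of the musical stimuli.

Summarizes each composer-defined event window by standard music-
information descriptors: dynamics (frame RMS), articulation (log-slope
of the amplitude-envelope attack), pitch content (12-bin chroma and its
centroid), harmony (6-d tonal-centroid / tonnetz motion between frames),
and spectral shape (centroid, spread, roll-off, novelty).  These are the
covariates regressed out of aligned brain features when asking whether
event-transition effects survive low-level acoustics.

Built directly on scipy.signal STFT primitives; frames default to
2048 samples with a 512-sample hop at a 22.05 kHz working rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .timeline import EventTimeline

__all__ = ["extract_acoustic_features", "feature_rating_correlations"]

TARGET_SR = 22050
FRAME = 2048
HOP = 512

#: Table row order of the feature schema.
FEATURE_COLUMNS = [
    "rms_mean",
    "rms_sd",
    "attack_log_slope",
    "tonnetz_max",
    "tonnetz_sd",
    "chroma_centroid_mean",
    "chroma_centroid_sd",
    "chroma_max",
    "spectral_centroid",
    "spectral_spread",
    "spectral_rolloff",
    "spectral_novelty",
]


def _resample(y: np.ndarray, sr: int, target: int) -> np.ndarray:
    if sr == target:
        return y
    g = np.gcd(int(sr), int(target))
    return sps.resample_poly(y, target // g, sr // g)


def _stft_mag(y: np.ndarray, sr: int, n_fft: int = FRAME, hop: int = HOP):
    f, _, z = sps.stft(
        y, fs=sr, nperseg=n_fft, noverlap=n_fft - hop, window="hann",
        boundary=None, padded=False,
    )
    return f, np.abs(z)


def _chroma(freqs: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """12-bin chroma: fold FFT-bin magnitudes onto pitch classes (C = 0)."""
    valid = freqs > 20
    midi = 69 + 12 * np.log2(freqs[valid] / 440.0)
    pc = np.mod(np.round(midi), 12).astype(int)
    chroma = np.zeros((12, mag.shape[1]))
    np.add.at(chroma, pc, mag[valid])
    norm = chroma.sum(axis=0)
    norm[norm == 0] = 1.0
    return chroma / norm


_TONNETZ_BASIS = None


def _tonnetz(chroma: np.ndarray) -> np.ndarray:
    """6-d tonal centroid per frame (fifths, minor-third, major-third circles)."""
    global _TONNETZ_BASIS
    if _TONNETZ_BASIS is None:
        pc = np.arange(12)
        basis = np.stack(
            [
                np.sin(pc * 7 * np.pi / 6), np.cos(pc * 7 * np.pi / 6),
                np.sin(pc * 3 * np.pi / 2), np.cos(pc * 3 * np.pi / 2),
                0.5 * np.sin(pc * 2 * np.pi / 3), 0.5 * np.cos(pc * 2 * np.pi / 3),
            ]
        )
        _TONNETZ_BASIS = basis
    return _TONNETZ_BASIS @ chroma


def _frame_rms(y: np.ndarray, frame: int = FRAME, hop: int = HOP) -> np.ndarray:
    n = 1 + max(len(y) - frame, 0) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return np.sqrt(np.mean(y[idx] ** 2, axis=1))


def _attack_log_slope(y: np.ndarray, sr: int) -> float:
    """Mean log-slope of the 10%-90% envelope rise before each onset peak."""
    env = np.abs(sps.hilbert(y))
    smooth = max(int(0.02 * sr), 1)
    env = np.convolve(env, np.ones(smooth) / smooth, mode="same")
    peaks, _ = sps.find_peaks(env, height=0.3 * env.max(), distance=int(0.2 * sr))
    slopes = []
    for p in peaks:
        hi, lo = 0.9 * env[p], 0.1 * env[p]
        t_hi = t_lo = None
        for t in range(p, max(p - sr, 0), -1):
            if t_hi is None and env[t] <= hi:
                t_hi = t
            if env[t] <= lo:
                t_lo = t
                break
        if t_hi is not None and t_lo is not None and t_hi > t_lo:
            slopes.append((np.log(hi) - np.log(max(lo, 1e-12))) / ((t_hi - t_lo) / sr))
    return float(np.mean(slopes)) if slopes else 0.0


def _spectral_shape(freqs: np.ndarray, mag: np.ndarray, rolloff: float = 0.85):
    tot = mag.sum(axis=0)
    tot[tot == 0] = 1.0
    centroid = (freqs[:, None] * mag).sum(axis=0) / tot
    spread = np.sqrt(
        (((freqs[:, None] - centroid[None, :]) ** 2) * mag).sum(axis=0) / tot
    )
    cum = np.cumsum(mag, axis=0) / tot
    roll = freqs[np.argmax(cum >= rolloff, axis=0)]
    flux = np.sqrt((np.clip(np.diff(mag, axis=1), 0, None) ** 2).sum(axis=0))
    novelty = np.concatenate([[0.0], flux])
    return centroid, spread, roll, novelty


def extract_acoustic_features(
    waveform: np.ndarray,
    sr: int,
    tl: EventTimeline,
    frame: int = FRAME,
    hop: int = HOP,
    target_sr: int = TARGET_SR,
) -> pd.DataFrame:
    """Per-event feature table for one mono waveform of a piece version.

    Deterministic given the frame parameters; input is resampled to the
    working rate (22.05 kHz by default) first so results are sample-rate
    invariant.  Raises if an event window is shorter than one frame.
    """
    y = np.asarray(waveform, dtype=float)
    if y.ndim != 1:
        raise ValueError("waveform must be mono")
    y = _resample(y, sr, target_sr)
    rows = []
    for e in tl.events:
        a, b = int(e.onset_s * target_sr), int(e.offset_s * target_sr)
        seg = y[a: min(b, len(y))]
        if len(seg) < frame:
            raise ValueError(
                f"event {e.index} window shorter than one frame ({len(seg)} samples)"
            )
        freqs, mag = _stft_mag(seg, target_sr, frame, hop)
        rms = _frame_rms(seg, frame, hop)
        chroma = _chroma(freqs, mag)
        centroid_pc = np.arange(12) @ chroma
        tonnetz = _tonnetz(chroma)
        hc = np.linalg.norm(np.diff(tonnetz, axis=1), axis=0)
        sc, spd, roll, novelty = _spectral_shape(freqs, mag)
        rows.append(
            {
                "piece": e.piece,
                "version": e.version,
                "emotion": e.emotion.value,
                "exemplar_no": e.exemplar_no,
                "rms_mean": float(rms.mean()),
                "rms_sd": float(rms.std()),
                "attack_log_slope": _attack_log_slope(seg, target_sr),
                "tonnetz_max": float(np.abs(tonnetz).max()),
                "tonnetz_sd": float(hc.std()) if hc.size else 0.0,
                "chroma_centroid_mean": float(centroid_pc.mean()),
                "chroma_centroid_sd": float(centroid_pc.std()),
                "chroma_max": float(chroma.max()),
                "spectral_centroid": float(sc.mean()),
                "spectral_spread": float(spd.mean()),
                "spectral_rolloff": float(roll.mean()),
                "spectral_novelty": float(novelty.mean()),
            }
        )
    return pd.DataFrame(rows)


def feature_rating_correlations(
    event_features: pd.DataFrame,
    event_ratings: pd.DataFrame,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r between each acoustic feature and each emotion's mean rating.

    Both frames must be indexed/aligned by event (one row per unique
    event; 32 in the full design).  Constant columns yield r = 0 with a
    warning rather than NaN.
    """
    import warnings

    if len(event_features) < 3:
        raise ValueError("need at least 3 events to correlate")
    if len(event_features) != len(event_ratings):
        raise ValueError("feature and rating tables must align by event")
    feature_cols = feature_cols or [
        c for c in FEATURE_COLUMNS if c in event_features.columns
    ]
    out = pd.DataFrame(index=feature_cols, columns=event_ratings.columns, dtype=float)
    for f in feature_cols:
        x = event_features[f].to_numpy(dtype=float)
        for emo in event_ratings.columns:
            y = event_ratings[emo].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"constant column in ({f}, {emo}); r set to 0",
                              stacklevel=2)
                out.loc[f, emo] = 0.0
            else:
                out.loc[f, emo] = float(np.corrcoef(x, y)[0, 1])
    return out
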