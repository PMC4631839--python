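"""Raw single-lead ECG -> fixed-width beat matrix.

Pipeline: Savitzky-Golay smoothing, R-peak detection (band-pass /
differentiate / square / integrate with an adaptive threshold), beat
segmentation taking 1/3 of the reference RR interval left of each R
peak and 2/3 to the right, and linear resampling of every beat to a
fixed width (200 samples by default).  The pipeline is deterministic —
no randomness anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt, savgol_filter

logger = logging.getLogger(__name__)

BEAT_WIDTH = 200

__all__ = [
    "BEAT_WIDTH",
    "ECGSignal",
    "BeatMatrix",
    "denoise",
    "default_savgol_window",
    "detect_r_peaks",
    "segment_beats",
    "resample_beat",
    "build_beat_matrix",
]


@dataclass
class ECGSignal:
    """A sampled single-lead trace (amplitude in mV)."""

    samples: np.ndarray
    fs: float
    lead: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class BeatMatrix:
    """n beats x fixed width, with optional per-beat class labels."""

    beats: np.ndarray
    labels: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=float)
        if self.beats.ndim != 2:
            raise ValueError("beat matrix must be 2-D")
        if not np.all(np.isfinite(self.beats)):
            raise ValueError("beat matrix must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.beats.shape[0]:
                raise ValueError("labels length must match beat count")

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]

    @property
    def width(self) -> int:
        return self.beats.shape[1]


def default_savgol_window(fs: float) -> int:
    """Nearest odd window to 25 ms of samples (minimum 5)."""
    w = int(round(0.025 * fs))
    if w % 2 == 0:
        w += 1
    return max(w, 5)


def denoise(
    signal: ECGSignal,
    window: int | None = None,
    polyorder: int = 3,
) -> ECGSignal:
    """Savitzky-Golay least-squares polynomial smoothing."""
    if window is None:
        window = default_savgol_window(signal.fs)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(signal):
        raise ValueError("window exceeds signal length")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    smoothed = savgol_filter(signal.samples, window, polyorder)
    return ECGSignal(samples=smoothed, fs=signal.fs, lead=signal.lead)


def _qrs_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    # band-pass 5-15 Hz isolates QRS energy from P/T waves and drift
    nyq = fs / 2.0
    hi = min(15.0 / nyq, 0.99)
    lo = min(5.0 / nyq, hi * 0.5)
    b, a = butter(2, [lo, hi], btype="band")
    filtered = filtfilt(b, a, x)
    deriv = np.gradient(filtered)
    squared = deriv**2
    win = max(int(round(0.15 * fs)), 1)
    return np.convolve(squared, np.ones(win) / win, mode="same")


def detect_r_peaks(
    signal: ECGSignal,
    refractory_s: float = 0.2,
    threshold_frac: float = 0.3,
    polarity: str = "auto",
) -> np.ndarray:
    """Strictly increasing R-peak sample indices.

    An energy envelope locates candidate QRS regions; each peak is then
    refined to the dominant deflection of the smoothed trace within
    +/-75 ms.  ``polarity`` may be "auto", "up" or "down"; auto picks
    whichever deflection direction dominates across candidates.  A
    refractory gap of ``refractory_s`` seconds is enforced.  An empty
    array (with a warning) is returned when nothing crosses threshold.
    """
    if len(signal) < 2 * signal.fs:
        raise ValueError("signal must be at least 2 s long")
    x = signal.samples
    fs = signal.fs
    env = _qrs_envelope(x, fs)
    peak_env = float(np.max(env))
    if peak_env <= 0:
        warnings.warn("no R peaks found (flat signal)", stacklevel=2)
        return np.array([], dtype=int)

    from scipy.signal import find_peaks

    gap = max(int(round(refractory_s * fs)), 1)
    rough, _ = find_peaks(env, height=threshold_frac * peak_env, distance=gap)
    if len(rough) == 0:
        warnings.warn("no R peaks found (below threshold)", stacklevel=2)
        return np.array([], dtype=int)

    half = int(round(0.075 * fs))
    if polarity == "auto":
        ups, downs = [], []
        for p in rough:
            seg = x[max(p - half, 0) : p + half + 1]
            ups.append(np.max(seg))
            downs.append(-np.min(seg))
        sign = 1.0 if np.mean(ups) >= np.mean(downs) else -1.0
    elif polarity == "up":
        sign = 1.0
    elif polarity == "down":
        sign = -1.0
    else:
        raise ValueError("polarity must be 'auto', 'up' or 'down'")

    refined = []
    for p in rough:
        start = max(p - half, 0)
        seg = sign * x[start : p + half + 1]
        refined.append(start + int(np.argmax(seg)))

    # refinement can merge neighbours; keep the stronger of any pair
    # closer than the refractory gap
    out: list[int] = []
    for idx in refined:
        if out and idx - out[-1] < gap:
            if sign * x[idx] > sign * x[out[-1]]:
                out[-1] = idx
        elif not out or idx > out[-1]:
            out.append(idx)
    return np.asarray(out, dtype=int)


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def segment_beats(
    signal: ECGSignal, r_peaks: Sequence[int]
) -> list[np.ndarray]:
    """Cut one variable-length beat per R peak.

    The reference RR for each peak is the preceding RR interval; the
    first peak borrows the following one.  The window is the half-open
    range [R - round(RR/3), R + round(2*RR/3)); beats whose window falls
    outside the record are dropped.
    """
    r = np.asarray(r_peaks, dtype=int)
    if len(r) < 2:
        warnings.warn("need at least two R peaks to segment", stacklevel=2)
        return []
    rr = np.diff(r)
    beats = []
    n = len(signal.samples)
    for i, peak in enumerate(r):
        ref_rr = int(rr[i - 1]) if i > 0 else int(rr[0])
        left = _round_half_up(ref_rr / 3.0)
        right = _round_half_up(2.0 * ref_rr / 3.0)
        start, stop = peak - left, peak + right
        if start < 0 or stop > n:
            continue
        beats.append(signal.samples[start:stop].copy())
    return beats


def resample_beat(beat: Sequence[float], n: int = BEAT_WIDTH) -> np.ndarray:
    """Linear interpolation onto n equally spaced points across the beat."""
    arr = np.asarray(beat, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("beat must be a vector of length >= 2")
    grid = np.linspace(0.0, len(arr) - 1.0, n)
    return np.interp(grid, np.arange(len(arr)), arr)


def build_beat_matrix(
    records: Sequence[tuple[ECGSignal, str]],
    width: int = BEAT_WIDTH,
    savgol_window: int | None = None,
    savgol_polyorder: int = 3,
) -> BeatMatrix:
    """Full denoise -> detect -> segment -> resample pipeline per record.

    Records that fail are logged and skipped; an empty total is an error.
    """
    if len(records) == 0:
        raise ValueError("no records given")
    rows: list[np.ndarray] = []
    labels: list[str] = []
    provenance: list[str] = []
    for i, (signal, label) in enumerate(records):
        rec_id = signal.lead or f"record{i}"
        try:
            clean = denoise(signal, window=savgol_window, polyorder=savgol_polyorder)
            peaks = detect_r_peaks(clean)
            beats = segment_beats(clean, peaks)
        except ValueError as exc:
            logger.warning("skipping %s: %s", rec_id, exc)
            continue
        logger.info("%s: %d peaks, %d beats", rec_id, len(peaks), len(beats))
        for beat in beats:
            rows.append(resample_beat(beat, width))
            labels.append(label)
            provenance.append(rec_id)
    if not rows:
        raise ValueError("no beats extracted from any record")
    return BeatMatrix(
        beats=np.vstack(rows), labels=np.asarray(labels), provenance=provenance
    )
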