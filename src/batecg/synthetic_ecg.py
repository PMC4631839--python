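"""Synthetic single-lead ECG with known ground truth.

Beats are sums of five Gaussians (P, Q, R, S, T) on a unit-interval
grid, with an optional rectangular ST-segment offset.  The "mi" preset
raises the ST segment and attenuates the R wave relative to the
"normal" preset, so the class-discriminative sample window is known by
construction.  Records concatenate per-beat templates stretched to
jittered RR intervals, with exact R-sample ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .ecg_preprocess import BEAT_WIDTH, BeatMatrix, ECGSignal

__all__ = [
    "WaveParams",
    "BeatTemplateParams",
    "SynthDataset",
    "normal_params",
    "mi_params",
    "make_beat_template",
    "synth_record",
    "synth_dataset",
    "noise_sd_for_snr",
]

# R centred at 1/3 so the 1/3-left / 2/3-right segmentation reproduces
# this layout; ST window [0.60, 0.80) maps to resampled indices [120, 160)
_R_CENTER = 1.0 / 3.0
_ST_WINDOW = (0.60, 0.80)

MI_ST_OFFSET = 0.2  # mV, full-separation ST elevation
MI_R_SCALE = 0.6  # full-separation R-wave attenuation factor


@dataclass(frozen=True)
class WaveParams:
    amplitude: float  # mV
    center: float  # fraction of the beat in [0, 1)
    width: float  # Gaussian sigma as a fraction of the beat


@dataclass(frozen=True)
class BeatTemplateParams:
    """Gaussian parameters for the five waves plus the ST-segment offset."""

    p: WaveParams
    q: WaveParams
    r: WaveParams
    s: WaveParams
    t: WaveParams
    st_offset: float = 0.0
    st_window: tuple[float, float] = _ST_WINDOW
    label: str = "normal"

    def __post_init__(self) -> None:
        waves = (self.p, self.q, self.r, self.s, self.t)
        centers = [w.center for w in waves]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be strictly ordered P<Q<R<S<T")
        if any(w.width <= 0 for w in waves):
            raise ValueError("wave widths must be > 0")
        others = [abs(w.amplitude) for w in (self.p, self.q, self.s, self.t)]
        if any(a > 0 for a in others) and abs(self.r.amplitude) <= max(others):
            raise ValueError("R amplitude must dominate for detectability")

    def waves(self) -> tuple[WaveParams, ...]:
        return (self.p, self.q, self.r, self.s, self.t)


def normal_params() -> BeatTemplateParams:
    return BeatTemplateParams(
        p=WaveParams(0.12, 0.15, 0.030),
        q=WaveParams(-0.12, 0.30, 0.010),
        r=WaveParams(1.00, _R_CENTER, 0.012),
        s=WaveParams(-0.20, 0.38, 0.012),
        t=WaveParams(0.30, 0.88, 0.040),
        st_offset=0.0,
        label="normal",
    )


def mi_params(separation: float = 1.0) -> BeatTemplateParams:
    """ST-elevation / attenuated-R preset; separation in [0, 1] scales both."""
    if not (0.0 <= separation <= 1.0):
        raise ValueError("separation must lie in [0, 1]")
    base = normal_params()
    r_scale = 1.0 - (1.0 - MI_R_SCALE) * separation
    return replace(
        base,
        r=replace(base.r, amplitude=base.r.amplitude * r_scale),
        st_offset=MI_ST_OFFSET * separation,
        label="mi",
    )


def _render(
    waves: Sequence[WaveParams],
    st_offset: float,
    st_window: tuple[float, float],
    n: int,
) -> np.ndarray:
    t = np.arange(n) / n
    out = np.zeros(n)
    for w in waves:
        out += w.amplitude * np.exp(-((t - w.center) ** 2) / (2.0 * w.width**2))
    lo, hi = st_window
    out[(t >= lo) & (t < hi)] += st_offset
    return out


def make_beat_template(params: BeatTemplateParams, n: int = BEAT_WIDTH) -> np.ndarray:
    """Render the Gaussian-sum beat on an n-point grid over [0, 1)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return _render(params.waves(), params.st_offset, params.st_window, n)


def st_window_indices(n: int = BEAT_WIDTH) -> np.ndarray:
    lo, hi = _ST_WINDOW
    return np.arange(int(round(lo * n)), int(round(hi * n)))


def noise_sd_for_snr(clean: np.ndarray, snr_db: float) -> float:
    """White-noise sigma giving the requested SNR against ``clean``."""
    rms = float(np.sqrt(np.mean(np.asarray(clean, dtype=float) ** 2)))
    return rms / (10.0 ** (snr_db / 20.0))


def synth_record(
    beat_class: str = "normal",
    n_beats: int = 10,
    fs: float = 1000.0,
    heart_rate_bpm: float = 70.0,
    rr_jitter: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    separation: float = 1.0,
    pad_frac: float = 0.4,
) -> tuple[ECGSignal, np.ndarray]:
    """Concatenated jittered beats plus exact R-sample ground truth.

    ``pad_frac`` nominal RR intervals of baseline are prepended and
    appended so that boundary beats survive downstream segmentation.
    Draw order: all RR jitters first, then the additive noise, so a
    noise-free call with the same seed yields identical R positions.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    params = mi_params(separation) if beat_class == "mi" else normal_params()
    if beat_class not in ("normal", "mi"):
        raise ValueError("beat_class must be 'normal' or 'mi'")
    rng = np.random.default_rng(seed)
    rr_nominal = fs * 60.0 / heart_rate_bpm
    jit = rng.uniform(-rr_jitter, rr_jitter, size=n_beats)
    lengths = np.maximum(np.round(rr_nominal * (1.0 + jit)).astype(int), 8)

    pad = int(round(pad_frac * rr_nominal))
    pieces = [np.zeros(pad)] if pad else []
    r_indices = []
    offset = pad
    for length in lengths:
        beat = make_beat_template(params, n=int(length))
        r_indices.append(offset + int(np.argmax(beat)))
        pieces.append(beat)
        offset += int(length)
    if pad:
        pieces.append(np.zeros(pad))
    samples = np.concatenate(pieces)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=len(samples))
    return (
        ECGSignal(samples=samples, fs=fs, lead=f"synth-{beat_class}"),
        np.asarray(r_indices, dtype=int),
    )


def expected_beat(
    params: BeatTemplateParams, center_jitter: float, n: int = BEAT_WIDTH
) -> np.ndarray:
    """Class-mean beat under Gaussian per-beat wave-centre jitter.

    Amplitude jitter has unit mean so only the centre jitter matters:
    each Gaussian wave widens to sqrt(w^2 + cj^2) with its area
    preserved, and the rectangular ST window acquires erf-shaped edges.
    """
    from scipy.special import ndtr

    t = np.arange(n) / n
    out = np.zeros(n)
    cj2 = center_jitter**2
    for w in params.waves():
        var = w.width**2 + cj2
        out += (
            w.amplitude
            * (w.width / np.sqrt(var))
            * np.exp(-((t - w.center) ** 2) / (2.0 * var))
        )
    lo, hi = params.st_window
    if center_jitter > 0:
        out += params.st_offset * (
            ndtr((hi - t) / center_jitter) - ndtr((lo - t) / center_jitter)
        )
    else:
        out[(t >= lo) & (t < hi)] += params.st_offset
    return out


@dataclass
class SynthDataset:
    """A labelled beat matrix with its known discriminative sample sets."""

    matrix: BeatMatrix
    informative_indices: np.ndarray  # all columns where class means differ
    st_window: np.ndarray  # the ST-offset columns only
    seed: int
    separation: float
    noise_sd: float
    amp_jitter: float = 0.0
    center_jitter: float = 0.0

    @property
    def beats(self) -> np.ndarray:
        return self.matrix.beats

    @property
    def labels(self) -> np.ndarray:
        return self.matrix.labels


def synth_dataset(
    n_normal: int = 200,
    n_mi: int = 200,
    separation: float = 1.0,
    noise_sd: float = 0.12,
    seed: int = 0,
    n: int = BEAT_WIDTH,
    amp_jitter: float = 0.15,
    center_jitter: float = 0.03,
) -> SynthDataset:
    """Directly sampled beat matrix with per-beat parameter perturbations.

    Each beat scales every wave amplitude and the ST offset by
    independent factors (1 + N(0, amp_jitter)), shifts all wave centres
    jointly by N(0, center_jitter) — beat-alignment variability that
    blurs narrow-wave features while leaving the ST plateau reliable —
    then adds white noise.  ``separation`` scales the class difference;
    0 makes the class distributions identical.
    """
    if n_normal < 1 or n_mi < 1:
        raise ValueError("class counts must be >= 1")
    rng = np.random.default_rng(seed)
    presets = [(normal_params(), n_normal), (mi_params(separation), n_mi)]
    rows, labels = [], []
    for params, count in presets:
        for _ in range(count):
            factors = 1.0 + rng.normal(0.0, amp_jitter, size=6)
            shift = rng.normal(0.0, center_jitter)
            waves = tuple(
                replace(w, amplitude=w.amplitude * f, center=w.center + shift)
                for w, f in zip(params.waves(), factors)
            )
            beat = _render(waves, params.st_offset * factors[5], params.st_window, n)
            beat = beat + rng.normal(0.0, noise_sd, size=n)
            rows.append(beat)
            labels.append(params.label)
    diff = np.abs(
        expected_beat(mi_params(separation), center_jitter, n=n)
        - expected_beat(normal_params(), center_jitter, n=n)
    )
    informative = np.flatnonzero(diff > 1e-3)
    matrix = BeatMatrix(
        beats=np.vstack(rows),
        labels=np.asarray(labels),
        provenance=["synth_dataset"] * len(rows),
    )
    return SynthDataset(
        matrix=matrix,
        informative_indices=informative,
        st_window=st_window_indices(n),
        seed=seed,
        separation=separation,
        noise_sd=noise_sd,
        amp_jitter=amp_jitter,
        center_jitter=center_jitter,
    )
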