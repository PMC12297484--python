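"""Waveform preprocessing and beat detection.

Preprocessing follows the standard wearable pipeline: resample to a target
rate, zero-phase band-pass filter, fix the window length, per-channel
z-normalize.  Beat detection is an energy-based detector in the
Pan-Tompkins tradition: band-limit, square, moving-window integrate, then
pick peaks above an adaptive threshold with a refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .data import SignalSegment, ValidationError

__all__ = ["PreprocessSpec", "preprocess", "preprocess_dataset", "detect_beats"]


@dataclass
class PreprocessSpec:
    """Preprocessing parameters.

    band : (low, high) Hz or None
        Pass band of a zero-phase 4th-order Butterworth filter; must satisfy
        0 < low < high < target_fs / 2.
    """

    target_fs: float = 100.0
    band: tuple[float, float] | None = None
    window_s: float = 10.0
    znorm_signal: bool = True

    def __post_init__(self) -> None:
        if self.target_fs <= 0 or self.window_s <= 0:
            raise ValidationError("target_fs and window_s must be positive")
        if self.band is not None:
            low, high = self.band
            if not (0 < low < high < self.target_fs / 2):
                raise ValidationError(
                    f"band {self.band} infeasible at target_fs={self.target_fs}"
                )


# Named presets mirroring common wearable protocols (band Hz, window s, rate Hz).
PRESETS: dict[str, PreprocessSpec] = {
    "ecg": PreprocessSpec(target_fs=125.0, band=(0.5, 40.0), window_s=10.0),
    "eeg": PreprocessSpec(target_fs=100.0, band=(0.4, 30.0), window_s=30.0),
    "imu": PreprocessSpec(target_fs=100.0, band=None, window_s=10.0),
    "ppg": PreprocessSpec(target_fs=50.0, band=(0.5, 20.0), window_s=10.0),
}


def _resample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    if abs(fs - target_fs) < 1e-12:
        return x
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def preprocess(segment: SignalSegment, spec: PreprocessSpec) -> SignalSegment:
    """Resample, band-pass (zero-phase), trim/pad, and z-normalize a segment.

    Output length is exactly ``round(target_fs * window_s)``; the signal is
    right-trimmed or zero-padded to that length after resampling.
    """
    x = _resample(segment.x, segment.fs, spec.target_fs)
    if spec.band is not None:
        sos = sps.butter(4, spec.band, btype="bandpass", fs=spec.target_fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=-1)
    n_out = int(round(spec.target_fs * spec.window_s))
    if x.shape[-1] >= n_out:
        x = x[:, :n_out]
    else:
        x = np.pad(x, ((0, 0), (0, n_out - x.shape[-1])))
    if spec.znorm_signal:
        mu = x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, keepdims=True)
        x = (x - mu) / np.where(sd < 1e-12, 1.0, sd)
    return replace(segment, x=np.ascontiguousarray(x), fs=spec.target_fs,
                   meta={**segment.meta, "preprocessed": True})


def preprocess_dataset(dataset, spec: PreprocessSpec):
    """Apply :func:`preprocess` to every segment, keeping split tags."""
    from .data import SegmentDataset

    return SegmentDataset(segments=[preprocess(s, spec) for s in dataset],
                          split_tags=None if dataset.split_tags is None
                          else list(dataset.split_tags))


def detect_beats(segment: SignalSegment, channel: int = 0,
                 refractory_s: float = 0.2,
                 integrate_s: float = 0.15,
                 threshold_frac: float = 0.4) -> np.ndarray:
    """Detect dominant periodic peaks on one reference channel.

    Energy pipeline: band-limit (0.5 Hz – min(18, Nyquist·0.9) Hz), square,
    moving-window integrate over ``integrate_s``, adaptive threshold at
    ``threshold_frac`` of the integrated envelope's robust maximum, with a
    ``refractory_s`` minimum gap.  Each envelope peak is refined to the local
    maximum of the band-limited signal within ±``integrate_s``.

    Returns strictly increasing sample indices; empty for flat or too-short
    segments (not an error).
    """
    fs = segment.fs
    x = segment.x[channel].astype(np.float64)
    if len(x) < int(refractory_s * fs) + 2 or np.ptp(x) < 1e-12:
        return np.array([], dtype=np.int64)

    high = min(18.0, 0.9 * fs / 2)
    sos = sps.butter(2, [0.5, high], btype="bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, x)
    energy = xb ** 2
    win = max(1, int(round(integrate_s * fs)))
    env = np.convolve(energy, np.ones(win) / win, mode="same")

    # robust ceiling: 98th percentile guards against one spiky artifact
    ceiling = np.percentile(env, 98)
    if ceiling < 1e-24:
        return np.array([], dtype=np.int64)
    peaks, _ = sps.find_peaks(env, height=threshold_frac * ceiling,
                              distance=max(1, int(round(refractory_s * fs))))
    if len(peaks) == 0:
        return np.array([], dtype=np.int64)

    # refine each envelope peak to the nearby maximum of the filtered signal
    half = win
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(xb), p + half + 1)
        refined.append(lo + int(np.argmax(xb[lo:hi])))
    refined = np.unique(np.array(refined, dtype=np.int64))

    # enforce refractory after refinement (keep the larger peak of a close pair)
    keep: list[int] = []
    min_gap = int(round(refractory_s * fs))
    for r in refined:
        if keep and r - keep[-1] < min_gap:
            if xb[r] > xb[keep[-1]]:
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    return np.array(keep, dtype=np.int64)
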