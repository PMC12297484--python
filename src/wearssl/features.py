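"""Handcrafted domain feature banks.

These are the "old-school" descriptors that guide contrastive training:
rhythm and morphology statistics around detected beats (heart-rate
variability: SDNN, RMSSD, pNN50-style proportions, plus amplitude and
beat-template-similarity quality indices), spectral band powers from an
averaged periodogram, and temporal/spectral/angular movement descriptors for
tri-axial accelerometry.

Conventions chosen for exact testability: SDNN and RMSSD use population
normalization; interval features for segments with fewer than two beats are
set to the NaN sentinel and mean-imputed at matrix level; z-normalization
maps constant columns to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data import SegmentDataset, SignalSegment, ValidationError
from .preprocessing import detect_beats

__all__ = [
    "DomainFeatureMatrix",
    "rhythm_morphology_features",
    "bandpower_features",
    "motion_features",
    "znormalize_features",
    "extract_feature_matrix",
    "RHYTHM_FEATURE_NAMES",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0))

RHYTHM_FEATURE_NAMES: tuple[str, ...] = (
    "ibi_mean_s", "ibi_median_s", "ibi_min_s", "ibi_max_s",
    "sdnn_s", "rmssd_s", "pnn50", "rate_bpm",
    "peak_amp_mean", "peak_amp_std", "peak_amp_max",
    "beat_template_corr", "beat_coverage",
)


@dataclass
class DomainFeatureMatrix:
    """Per-segment domain feature vectors with normalization statistics."""

    values: np.ndarray                      # (segments, features)
    feature_names: list[str]
    norm_mean: np.ndarray | None = None     # set after z-normalization
    norm_std: np.ndarray | None = None
    modality: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValidationError("values shape inconsistent with feature_names")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def rows(self, idx: np.ndarray) -> "DomainFeatureMatrix":
        return DomainFeatureMatrix(self.values[idx], list(self.feature_names),
                                   self.norm_mean, self.norm_std, self.modality)


def rhythm_morphology_features(segment: SignalSegment, beats: np.ndarray,
                               channel: int = 0) -> np.ndarray:
    """Rhythm, amplitude and beat-similarity features from detected beats.

    Fixed length and ordering per :data:`RHYTHM_FEATURE_NAMES`.  With fewer
    than two beats, interval-based entries are NaN (imputed later at matrix
    level); amplitude entries use whatever beats exist, or NaN with none.
    """
    x = segment.x[channel]
    fs = segment.fs
    T = len(x)
    nan = float("nan")
    out = dict.fromkeys(RHYTHM_FEATURE_NAMES, nan)

    if len(beats) >= 1:
        amps = x[beats]
        out["peak_amp_mean"] = float(np.mean(amps))
        out["peak_amp_std"] = float(np.std(amps))
        out["peak_amp_max"] = float(np.max(amps))
        out["beat_coverage"] = float((beats.max() - beats.min()) / T) if len(beats) > 1 else 0.0

    if len(beats) >= 2:
        ibi = np.diff(beats) / fs
        out["ibi_mean_s"] = float(np.mean(ibi))
        out["ibi_median_s"] = float(np.median(ibi))
        out["ibi_min_s"] = float(np.min(ibi))
        out["ibi_max_s"] = float(np.max(ibi))
        out["sdnn_s"] = float(np.std(ibi))            # population sigma
        succ = np.diff(ibi)
        out["rmssd_s"] = float(np.sqrt(np.mean(succ ** 2))) if len(succ) else 0.0
        out["pnn50"] = float(np.mean(np.abs(succ) > 0.05)) if len(succ) else 0.0
        out["rate_bpm"] = float(60.0 / np.mean(ibi))

        # beat-template correlation: mean pairwise Pearson r of beat-centred
        # windows (half-width = 40% of the median interval), a quality index
        half = max(2, int(round(0.4 * np.median(ibi) * fs)))
        wins = [x[b - half:b + half + 1] for b in beats
                if b - half >= 0 and b + half + 1 <= T]
        wins = [w for w in wins if np.std(w) > 1e-12]
        if len(wins) >= 2:
            W = np.array(wins)
            W = (W - W.mean(axis=1, keepdims=True)) / W.std(axis=1, keepdims=True)
            R = (W @ W.T) / W.shape[1]
            iu = np.triu_indices(len(wins), k=1)
            out["beat_template_corr"] = float(np.mean(R[iu]))

    return np.array([out[k] for k in RHYTHM_FEATURE_NAMES])


def bandpower_names(n_channels: int, bands=DEFAULT_BANDS) -> list[str]:
    names = []
    for ch in range(n_channels):
        for lo, hi in bands:
            names.append(f"ch{ch}_abs_{lo:g}_{hi:g}Hz")
        for lo, hi in bands:
            names.append(f"ch{ch}_rel_{lo:g}_{hi:g}Hz")
    return names


def bandpower_features(segment: SignalSegment,
                       bands=DEFAULT_BANDS) -> np.ndarray:
    """Absolute and relative band powers per channel from Welch's method.

    Averaged modified periodogram: Hann window, ``nperseg = min(T, 256)``,
    50% overlap.  Relative powers per channel sum to 1 over the band set
    (defined as 0 for an all-zero channel).
    """
    if len(bands) == 0:
        raise ValidationError("empty band list")
    nyq = segment.fs / 2
    for lo, hi in bands:
        if not (0 <= lo < hi <= nyq):
            raise ValidationError(f"band ({lo}, {hi}) outside Nyquist range")
    nperseg = min(segment.n_timesteps, 256)
    f, psd = sps.welch(segment.x, fs=segment.fs, window="hann",
                       nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
    df = f[1] - f[0]
    feats = []
    for ch in range(segment.n_channels):
        absp = []
        for lo, hi in bands:
            sel = (f >= lo) & (f < hi)
            absp.append(float(psd[ch, sel].sum() * df))
        total = sum(absp)
        rel = [a / total for a in absp] if total > 1e-30 else [0.0] * len(absp)
        feats.extend(absp)
        feats.extend(rel)
    return np.array(feats)


MOTION_FEATURE_NAMES: tuple[str, ...] = (
    "x_mean", "x_std", "x_range", "y_mean", "y_std", "y_range",
    "z_mean", "z_std", "z_range", "mag_mean", "mag_std",
    "dom_freq_hz", "dom_freq_power", "spectral_entropy",
    "roll_deg", "pitch_deg",
)


def motion_features(segment: SignalSegment) -> np.ndarray:
    """Temporal/spectral/angular descriptors of a tri-axial acceleration window.

    Angle convention: gravity is the per-axis mean vector (gx, gy, gz);
    pitch = atan2(gx, sqrt(gy^2 + gz^2)), roll = atan2(gy, gz), in degrees —
    a gravity-aligned (0, 0, 1) window has roll = pitch = 0 and a (1, 0, 0)
    window has pitch = 90.  Dominant frequency is the argmax of the
    DC-removed per-axis periodograms summed across axes.
    """
    if segment.n_channels != 3:
        raise ValidationError(f"motion features need 3 channels, got {segment.n_channels}")
    x = segment.x
    out = []
    for ax in range(3):
        out.extend([float(x[ax].mean()), float(x[ax].std()), float(np.ptp(x[ax]))])
    mag = np.sqrt((x ** 2).sum(axis=0))
    out.extend([float(mag.mean()), float(mag.std())])

    f, psd = sps.periodogram(x - x.mean(axis=-1, keepdims=True), fs=segment.fs, axis=-1)
    psd_sum = psd.sum(axis=0)[1:]           # drop DC
    f = f[1:]
    if psd_sum.sum() > 1e-30:
        k = int(np.argmax(psd_sum))
        p = psd_sum / psd_sum.sum()
        ent = float(-(p[p > 0] * np.log(p[p > 0])).sum() / np.log(len(p)))
        out.extend([float(f[k]), float(psd_sum[k]), ent])
    else:
        out.extend([0.0, 0.0, 0.0])

    gx, gy, gz = x.mean(axis=-1)
    out.append(float(np.degrees(np.arctan2(gy, gz))))
    out.append(float(np.degrees(np.arctan2(gx, np.hypot(gy, gz)))))
    return np.array(out)


def znormalize_features(matrix: DomainFeatureMatrix,
                        stats: tuple[np.ndarray, np.ndarray] | None = None
                        ) -> DomainFeatureMatrix:
    """Z-normalize each feature column (population sigma).

    NaNs are mean-imputed per column first (using ``stats`` means when
    supplied, e.g. train-split statistics applied to a held-out split).
    Constant columns (sigma < 1e-12) map to 0.  An all-NaN column with no
    provided statistics is an error naming the column.
    """
    V = matrix.values.copy()
    if stats is None:
        for j in range(V.shape[1]):
            col = V[:, j]
            if np.isnan(col).all():
                raise ValidationError(f"feature {matrix.feature_names[j]!r} is all-NaN")
        mean = np.nanmean(V, axis=0)
        # impute, then population std of the imputed column
        idx = np.where(np.isnan(V))
        V[idx] = mean[idx[1]]
        std = V.std(axis=0)
    else:
        mean, std = stats
        if mean.shape != (V.shape[1],) or std.shape != (V.shape[1],):
            raise ValidationError("stats dimensions do not match feature count")
        idx = np.where(np.isnan(V))
        V[idx] = mean[idx[1]]
    safe = np.where(std < 1e-12, 1.0, std)
    Z = (V - mean) / safe
    Z[:, std < 1e-12] = 0.0
    return DomainFeatureMatrix(Z, list(matrix.feature_names), mean.copy(), std.copy(),
                               matrix.modality)


def extract_feature_matrix(dataset: SegmentDataset, modality: str = "cardiac",
                           bands=DEFAULT_BANDS, channel: int = 0) -> DomainFeatureMatrix:
    """Extract the per-modality feature bank for every segment (unnormalized).

    ``"cardiac"`` (ECG/PPG-like): rhythm/morphology features on the reference
    channel plus per-channel band powers.  ``"motion"`` (tri-axial IMU):
    movement descriptors plus band powers.  ``"spectral"`` (EEG-like): band
    powers only.
    """
    rows = []
    n_ch = dataset[0].n_channels if len(dataset) else 1
    if modality == "cardiac":
        names = list(RHYTHM_FEATURE_NAMES) + bandpower_names(n_ch, bands)
        for seg in dataset:
            beats = detect_beats(seg, channel=channel)
            rows.append(np.concatenate([
                rhythm_morphology_features(seg, beats, channel=channel),
                bandpower_features(seg, bands),
            ]))
    elif modality == "motion":
        names = list(MOTION_FEATURE_NAMES) + bandpower_names(n_ch, bands)
        for seg in dataset:
            rows.append(np.concatenate([motion_features(seg), bandpower_features(seg, bands)]))
    elif modality == "spectral":
        names = bandpower_names(n_ch, bands)
        for seg in dataset:
            rows.append(bandpower_features(seg, bands))
    else:
        raise ValidationError(f"unknown modality {modality!r}")
    return DomainFeatureMatrix(np.array(rows), names, modality=modality)
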