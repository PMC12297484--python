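"""Synthetic quasi-periodic waveform generator with subject structure.

The generator emulates the statistical skeleton of wearable datasets used
for contrastive pretraining: each segment is a class-dependent quasi-periodic
component (impulse-like "beats" at the class rhythm rate convolved with a
class morphology template) plus subject-dependent nuisance (multiplicative
gain, additive baseline, Gaussian noise).  By construction, handcrafted
rhythm/morphology features carry the class signal while raw amplitude and
offset carry the subject signal — the failure mode where instance-level
contrastive learning latches onto subject identity is therefore reproducible
and controllable.

Nothing here attempts physiological fidelity (no dynamical ECG model); the
point is controllable class/subject structure with known ground truth.
"""

from __future__ import annotations

import numpy as np

from .data import SegmentDataset, SignalSegment, SynthConfig, ValidationError

__all__ = ["generate_dataset", "make_splits", "class_parameters", "generating_parameters"]


def class_parameters(config: SynthConfig) -> list[dict]:
    """Per-class generating parameters (rhythm rate, bump width, secondary bump).

    ``class_sep`` linearly scales every between-class deviation, so at
    ``class_sep=0`` all classes share identical parameters.
    """
    C = config.n_classes
    params = []
    for c in range(C):
        dev = c - (C - 1) / 2.0                     # centred, unit steps
        u = (2 * c - (C - 1)) / max(C - 1, 1)       # centred, in [-1, 1]
        u_alt = u * (1.0 if c % 2 == 0 else -1.0)   # decorrelated from width
        params.append(
            {
                "rate_bpm": config.base_rate_bpm + config.class_sep * config.rate_spread_bpm * dev,
                "width_s": float(
                    np.clip(config.base_width_s + config.class_sep * config.width_spread_s * u,
                            0.015, 0.15)
                ),
                # secondary bump (T-wave-like) weight; class-coupled only when sep > 0
                "secondary": 0.3 + config.class_sep * config.secondary_bump_spread * u_alt,
            }
        )
    return params


def _morphology_kernel(width_s: float, secondary: float, period_s: float, fs: float) -> tuple[np.ndarray, int]:
    """Beat template: a narrow primary bump plus a broader delayed bump.

    Returns the kernel and the index of the primary bump's centre within it.
    """
    lag_s = 0.3 * period_s
    half_s = max(4 * width_s, lag_s + 8 * width_s)
    n_half = int(np.ceil(half_s * fs))
    t = np.arange(-n_half, n_half + 1) / fs
    kern = np.exp(-0.5 * (t / width_s) ** 2)
    kern += secondary * np.exp(-0.5 * ((t - lag_s) / (2.5 * width_s)) ** 2)
    return kern, n_half


def _synthesize_segment(rng: np.random.Generator, config: SynthConfig,
                        cls: dict, subj: dict) -> tuple[np.ndarray, np.ndarray]:
    """One clean-class-component + nuisance segment; returns (x, beat_indices)."""
    T = config.n_timesteps
    fs = config.fs
    period_s = 60.0 / cls["rate_bpm"]

    # quasi-periodic beat times: jittered inter-beat intervals
    times = [float(rng.uniform(0, period_s))]
    while times[-1] < config.window_s:
        iv = period_s * (1.0 + config.interval_jitter_frac * rng.standard_normal())
        times.append(times[-1] + max(iv, 0.4 * period_s))
    beat_idx = np.array([int(round(t * fs)) for t in times if round(t * fs) < T], dtype=np.int64)

    kern, n_half = _morphology_kernel(cls["width_s"], cls["secondary"], period_s, fs)
    clean = np.zeros(T + 2 * n_half + len(kern))
    for b in beat_idx:
        clean[b:b + len(kern)] += kern
    # impulse at index b contributes kernel centred at b + n_half in the
    # padded buffer; crop so centres align with beat indices
    clean = clean[n_half:n_half + T]

    chan_scale = 1.0 / (1.0 + 0.4 * np.arange(config.channels))
    x = np.empty((config.channels, T))
    for ch in range(config.channels):
        noise = subj["noise_sd"] * rng.standard_normal(T)
        x[ch] = subj["gain"] * chan_scale[ch] * clean + subj["baseline"] + noise
    return x, beat_idx


def generate_dataset(config: SynthConfig) -> SegmentDataset:
    """Generate a labeled, subject-structured synthetic dataset.

    Every subject receives segments cycling through all classes (shuffled
    per subject).  Ground-truth beat sample indices and generating parameters
    are kept in each segment's ``meta``.  Identical configs (including seed)
    yield bit-identical datasets; all randomness flows through one seeded
    generator.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    cls_params = class_parameters(config)

    subjects = []
    for s in range(config.n_subjects):
        subjects.append(
            {
                "gain": float(rng.uniform(*config.gain_range)),
                "baseline": float(config.baseline_sd * rng.standard_normal()),
                "noise_sd": float(rng.uniform(*config.noise_sd_range)),
            }
        )

    segments = []
    for s in range(config.n_subjects):
        reps = int(np.ceil(config.segments_per_subject / config.n_classes))
        labels = np.tile(np.arange(config.n_classes), reps)[: config.segments_per_subject]
        labels = rng.permutation(labels)
        for j, lab in enumerate(labels):
            cls = cls_params[int(lab)]
            x, beats = _synthesize_segment(rng, config, cls, subjects[s])
            segments.append(
                SignalSegment(
                    x=x,
                    fs=config.fs,
                    subject_id=f"S{s:03d}",
                    label=int(lab),
                    segment_id=f"S{s:03d}_seg{j:03d}",
                    meta={
                        "beat_indices": beats.tolist(),
                        "rate_bpm": cls["rate_bpm"],
                        "width_s": cls["width_s"],
                        "secondary": cls["secondary"],
                        "gain": subjects[s]["gain"],
                        "baseline": subjects[s]["baseline"],
                        "noise_sd": subjects[s]["noise_sd"],
                    },
                )
            )
    return SegmentDataset(segments=segments)


def generating_parameters(dataset: SegmentDataset) -> np.ndarray:
    """Ground-truth class-generating parameters per segment, (N, 3).

    Columns: rhythm rate (bpm), primary bump width (s), secondary bump weight.
    """
    return np.array([[s.meta["rate_bpm"], s.meta["width_s"], s.meta["secondary"]]
                     for s in dataset])


def make_splits(dataset: SegmentDataset, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                seed: int = 0) -> SegmentDataset:
    """Subject-level random train/val/test partition at the given ratios.

    Subject counts are rounded to nearest with the total preserved (largest
    remainder); no subject spans two splits.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError(f"ratios must sum to 1, got {sum(ratios)}")
    subjects = sorted(set(dataset.subject_ids))
    n = len(subjects)
    if n < 3:
        raise ValidationError("need at least 3 subjects to split")
    nonempty = sum(r > 0 for r in ratios)
    if n < nonempty:
        raise ValidationError(f"{n} subjects cannot fill {nonempty} non-empty splits")

    quotas = np.array([r * n for r in ratios])
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for k in np.argsort(-rem)[: n - counts.sum()]:
        counts[k] += 1
    # every non-empty ratio gets at least one subject
    for k in range(3):
        if ratios[k] > 0 and counts[k] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[k] += 1

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(n)
    tags_by_subject: dict[str, str] = {}
    names = ("train", "val", "test")
    pos = 0
    for k, name in enumerate(names):
        for i in order[pos:pos + counts[k]]:
            tags_by_subject[subjects[i]] = name
        pos += counts[k]

    return dataset.with_splits([tags_by_subject[s.subject_id] for s in dataset])
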