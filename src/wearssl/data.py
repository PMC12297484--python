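"""Core data containers: windowed signal segments and segment collections.

A :class:`SignalSegment` is one fixed-length multichannel window of a
physiological waveform (ECG-like, EEG-like, tri-axial accelerometry ...)
together with its sampling rate, the wearer it came from, and an optional
class label.  A :class:`SegmentDataset` is an ordered collection of segments,
optionally tagged with subject-disjoint train/val/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["SignalSegment", "SegmentDataset", "SynthConfig", "ValidationError"]


class ValidationError(ValueError):
    """An input violated a documented container invariant."""


@dataclass
class SignalSegment:
    """One windowed multichannel waveform.

    Parameters
    ----------
    x : ndarray, shape (channels, timesteps)
        The waveform, arbitrary units.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Identifier of the wearer the segment was recorded from.
    label : int or None
        Class index; ``None`` when unlabeled.
    segment_id : str
        Unique identifier within a dataset.
    meta : dict
        Free-form metadata (e.g. ground-truth beat sample indices for
        synthetic segments, preprocessing digests).
    """

    x: np.ndarray
    fs: float
    subject_id: str
    label: int | None = None
    segment_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim != 2:
            raise ValidationError(f"x must be 2-D (channels, timesteps), got {self.x.ndim}-D")
        c, t = self.x.shape
        if c < 1 or t < 2:
            raise ValidationError(f"need channels >= 1 and timesteps >= 2, got {self.x.shape}")
        if not np.isfinite(self.x).all():
            raise ValidationError("segment contains NaN/Inf")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.x.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.x.shape[1]

    @property
    def duration_s(self) -> float:
        return self.x.shape[1] / self.fs


@dataclass
class SegmentDataset:
    """Ordered collection of segments with optional subject-disjoint splits.

    ``split_tags`` (parallel to ``segments``) holds one of ``"train"``,
    ``"val"``, ``"test"`` per segment; when present, no subject may appear in
    more than one split.
    """

    segments: list[SignalSegment]
    split_tags: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValidationError("segment_ids are not unique")
        if self.split_tags is not None:
            if len(self.split_tags) != len(self.segments):
                raise ValidationError("split_tags length mismatch")
            self._check_subject_disjoint()

    def _check_subject_disjoint(self) -> None:
        seen: dict[str, str] = {}
        for seg, tag in zip(self.segments, self.split_tags):
            prev = seen.setdefault(seg.subject_id, tag)
            if prev != tag:
                raise ValidationError(
                    f"subject {seg.subject_id!r} appears in splits {prev!r} and {tag!r}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[SignalSegment]:
        return iter(self.segments)

    def __getitem__(self, i: int) -> SignalSegment:
        return self.segments[i]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.segments]

    @property
    def labels(self) -> np.ndarray:
        """Labels as an int array, -1 where missing."""
        return np.array([-1 if s.label is None else s.label for s in self.segments])

    def signal_array(self) -> np.ndarray:
        """Stack all segments into one (N, C, T) array (shapes must agree)."""
        return np.stack([s.x for s in self.segments])

    def subset(self, split: str) -> "SegmentDataset":
        """Segments of one split, as a new dataset without split tags."""
        if self.split_tags is None:
            raise ValidationError("dataset has no split tags")
        segs = [s for s, t in zip(self.segments, self.split_tags) if t == split]
        return SegmentDataset(segments=segs)

    def indices_of(self, split: str) -> np.ndarray:
        if self.split_tags is None:
            raise ValidationError("dataset has no split tags")
        return np.flatnonzero(np.array(self.split_tags) == split)

    def with_splits(self, split_tags: Sequence[str]) -> "SegmentDataset":
        return SegmentDataset(segments=list(self.segments), split_tags=list(split_tags))


@dataclass
class SynthConfig:
    """Configuration of the synthetic quasi-periodic waveform generator.

    Classes differ in rhythm (beats per minute) and beat morphology; subjects
    contribute nuisance structure (multiplicative gain, baseline offset,
    noise level) that is deliberately unrelated to class.  ``class_sep``
    scales the between-class spread of the rhythm/morphology parameters:
    0 makes all classes statistically identical, larger values spread them out.
    """

    n_classes: int = 4
    n_subjects: int = 12
    segments_per_subject: int = 10
    channels: int = 1
    fs: float = 100.0
    window_s: float = 10.0
    class_sep: float = 1.0
    seed: int = 0
    # per-class rhythm: base rate and per-step spread, beats/min
    base_rate_bpm: float = 72.0
    rate_spread_bpm: float = 12.0
    # per-class morphology: Gaussian bump width (s) and secondary-bump weight
    base_width_s: float = 0.045
    width_spread_s: float = 0.012
    secondary_bump_spread: float = 0.35
    # subject nuisance ranges
    gain_range: tuple[float, float] = (0.5, 2.0)
    baseline_sd: float = 0.5
    noise_sd_range: tuple[float, float] = (0.05, 0.25)
    # quasi-periodicity: sd of beat-interval jitter as a fraction of the period
    interval_jitter_frac: float = 0.03

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.n_subjects < 3:
            raise ValidationError("n_subjects must be >= 3")
        if self.segments_per_subject < 1 or self.channels < 1:
            raise ValidationError("counts must be positive")
        if self.fs < 20:
            raise ValidationError("fs must be >= 20 Hz")
        if self.class_sep < 0:
            raise ValidationError("class_sep must be >= 0")
        slowest_period = 60.0 / max(
            1e-9, self.base_rate_bpm - self.class_sep * self.rate_spread_bpm * (self.n_classes - 1) / 2
        )
        if self.window_s < slowest_period:
            raise ValidationError(
                f"window ({self.window_s} s) shorter than one beat period ({slowest_period:.2f} s)"
            )

    @property
    def n_timesteps(self) -> int:
        return int(round(self.fs * self.window_s))

    @property
    def n_segments(self) -> int:
        return self.n_subjects * self.segments_per_subject
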