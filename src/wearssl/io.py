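"""Dataset container and artifact serialization.

The on-disk dataset is a single HDF5 file: datasets ``X`` (N, C, T, gzip),
``y`` (N, int, -1 for unlabeled), ``subject`` (N, strings), optional
``split`` (N, strings), and scalar attrs ``fs``, ``schema_version`` plus
free-form metadata.  Domain feature tables round-trip as CSV with a header
of feature names; normalization statistics and ground-truth metadata as
JSON.  Every artifact embeds the configuration digest and seed that
produced it, so runs are exactly repeatable.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .data import SegmentDataset, SignalSegment, ValidationError
from .features import DomainFeatureMatrix

__all__ = [
    "read_container", "write_container", "write_features", "read_features",
    "write_truth", "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def write_container(dataset: SegmentDataset, path: str, fs: float | None = None,
                    attrs: dict | None = None) -> None:
    """Write a dataset to the HDF5 container (X compressed)."""
    if len(dataset) == 0:
        raise ValidationError("refusing to write an empty dataset")
    X = dataset.signal_array()
    y = dataset.labels
    subj = np.array(dataset.subject_ids, dtype="S")
    seg_ids = np.array([s.segment_id for s in dataset], dtype="S")
    fs = fs if fs is not None else dataset[0].fs
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=X, compression="gzip", compression_opts=4)
        f.create_dataset("y", data=y.astype(np.int64))
        f.create_dataset("subject", data=subj)
        f.create_dataset("segment_id", data=seg_ids)
        if dataset.split_tags is not None:
            f.create_dataset("split", data=np.array(dataset.split_tags, dtype="S"))
        f.attrs["fs"] = float(fs)
        f.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def read_container(path: str) -> SegmentDataset:
    """Load and validate a dataset container written by :func:`write_container`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValidationError(f"unrecognized container schema version {version}")
        X = f["X"][...]
        y = f["y"][...]
        subj = [s.decode() for s in f["subject"][...]]
        seg_ids = [s.decode() for s in f["segment_id"][...]]
        split = [s.decode() for s in f["split"][...]] if "split" in f else None
        fs = float(f.attrs["fs"])
    n = X.shape[0]
    if not (len(y) == len(subj) == len(seg_ids) == n):
        raise ValidationError("container arrays have inconsistent lengths (field: y/subject/segment_id)")
    if fs <= 0:
        raise ValidationError("container invariant violated (field: fs must be > 0)")
    if np.any(y < -1):
        raise ValidationError("container invariant violated (field: y must be >= -1)")
    segments = [
        SignalSegment(x=X[i], fs=fs, subject_id=subj[i],
                      label=None if y[i] < 0 else int(y[i]), segment_id=seg_ids[i])
        for i in range(n)
    ]
    return SegmentDataset(segments=segments, split_tags=split)


def write_features(matrix: DomainFeatureMatrix, csv_path: str,
                   stats_path: str | None = None) -> None:
    """Feature table as CSV (header = feature names); stats as JSON sidecar."""
    pd.DataFrame(matrix.values, columns=matrix.feature_names).to_csv(csv_path, index=False)
    if stats_path is not None:
        stats = {
            "modality": matrix.modality,
            "feature_names": list(matrix.feature_names),
            "norm_mean": None if matrix.norm_mean is None else matrix.norm_mean.tolist(),
            "norm_std": None if matrix.norm_std is None else matrix.norm_std.tolist(),
        }
        with open(stats_path, "w") as fh:
            json.dump(stats, fh, indent=2)


def read_features(csv_path: str, stats_path: str | None = None) -> DomainFeatureMatrix:
    df = pd.read_csv(csv_path)
    mean = std = None
    modality = "generic"
    if stats_path is not None:
        with open(stats_path) as fh:
            stats = json.load(fh)
        if stats["feature_names"] != list(df.columns):
            raise ValidationError("stats feature names do not match CSV header")
        mean = None if stats["norm_mean"] is None else np.array(stats["norm_mean"])
        std = None if stats["norm_std"] is None else np.array(stats["norm_std"])
        modality = stats.get("modality", "generic")
    return DomainFeatureMatrix(df.to_numpy(dtype=np.float64), list(df.columns),
                               mean, std, modality)


def write_truth(dataset: SegmentDataset, path: str, seed: int | None = None,
                config: dict | None = None) -> None:
    """Ground-truth sidecar JSON: per-segment generator metadata."""
    payload = {
        "seed": seed,
        "config": config,
        "segments": {
            s.segment_id: {"subject_id": s.subject_id, "label": s.label, **s.meta}
            for s in dataset
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
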