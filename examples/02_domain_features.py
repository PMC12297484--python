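"""Extract the handcrafted domain feature bank and see what it knows.

Heart-rate-variability statistics (mean inter-beat interval, SDNN, RMSSD),
beat amplitude/similarity indices and spectral band powers are computed per
segment, z-normalized with train-split statistics, and probed with a
10-nearest-neighbour classifier — the "old-school" baseline whose knowledge
later guides contrastive pretraining.
"""

import numpy as np
from sklearn.metrics import f1_score
from sklearn.neighbors import KNeighborsClassifier

from wearssl import (SynthConfig, extract_feature_matrix, generate_dataset,
                     make_splits, znormalize_features)

ds = make_splits(generate_dataset(SynthConfig(seed=7)), seed=7)
raw = extract_feature_matrix(ds, modality="cardiac")
train_idx = ds.indices_of("train")
fitted = znormalize_features(raw.rows(train_idx))
feats = znormalize_features(raw, stats=(fitted.norm_mean, fitted.norm_std))

seg = ds[0]
row = dict(zip(raw.feature_names, raw.values[0]))
print(f"segment {seg.segment_id} (class {seg.label}, {seg.meta['rate_bpm']:.0f} bpm):")
for name in ("ibi_mean_s", "sdnn_s", "rmssd_s", "rate_bpm", "beat_template_corr"):
    print(f"  {name:>20s} = {row[name]:.4f}")
# ibi_mean tracks 60/rate; sdnn/rmssd reflect the generator's interval jitter.

test_idx = ds.indices_of("test")
y = ds.labels
clf = KNeighborsClassifier(n_neighbors=10).fit(feats.values[train_idx], y[train_idx])
f1 = f1_score(y[test_idx], clf.predict(feats.values[test_idx]), average="macro")
print(f"\n10-NN probe on domain features: test macro-F1 = {f1:.3f} (chance 0.25)")
# Well above chance: the feature bank carries the class signal that will
# steer positive-pair selection and prototype clustering.
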