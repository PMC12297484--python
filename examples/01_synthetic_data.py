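"""Generate a subject-structured synthetic wearable dataset.

Each segment is a quasi-periodic waveform whose rhythm and beat morphology
depend on its class, overlaid with subject-specific gain, baseline and
noise.  The generator keeps the true beat locations, so detectors and
rhythm features can be validated exactly.
"""

import numpy as np

from wearssl import SynthConfig, detect_beats, generate_dataset, make_splits

cfg = SynthConfig(seed=7)                  # 4 classes x 12 subjects x 10 segments
ds = make_splits(generate_dataset(cfg), seed=7)

print(f"{len(ds)} segments of shape {ds[0].x.shape} at {ds[0].fs:g} Hz")
for split in ("train", "val", "test"):
    sub = ds.subset(split)
    print(f"  {split}: {len(sub)} segments from {len(set(sub.subject_ids))} subjects")

seg = ds[0]
truth = np.array(seg.meta["beat_indices"])
det = detect_beats(seg)
err_ms = np.abs(det - truth).max() / seg.fs * 1000 if len(det) == len(truth) else float("nan")
print(f"\nsegment {seg.segment_id}: class {seg.label}, "
      f"{seg.meta['rate_bpm']:.0f} bpm, subject gain {seg.meta['gain']:.2f}")
print(f"beat detector found {len(det)}/{len(truth)} beats, max error {err_ms:.0f} ms")
# The detector recovers the generator's impulse train to within a few
# milliseconds, which is what makes the rhythm feature bank trustworthy.
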