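"""Canned end-to-end experiments on the synthetic preset.

These are the package's own study protocols, shared by the examples, the
test suite and the reproduction script: build the synthetic dataset with
strong subject nuisance, preprocess and extract/normalize domain features
(train-split statistics only), pretrain under each condition, and evaluate
with frozen-representation probes or semi-supervised fine-tuning.

The pretraining length for the comparison protocols is 60 epochs: with
~70 training segments and batch 32 an epoch is only two optimization steps,
and the comparison between pretraining conditions needs the optimizer to
approach its plateau to measure representation quality rather than
initialization noise.  The determinism/runtime checks elsewhere use the
20-epoch desk preset.
"""

from __future__ import annotations

import numpy as np

from .data import SegmentDataset, SynthConfig
from .evaluation import (FineTuneConfig, encode_representations, fine_tune,
                         knn_probe, linear_probe)
from .features import DomainFeatureMatrix, extract_feature_matrix, znormalize_features
from .nn import build_encoder
from .preprocessing import PreprocessSpec, preprocess_dataset
from .synthetic import generate_dataset, make_splits
from .training import TrainConfig, desk_config, pretrain

__all__ = ["standard_pipeline", "pretraining_comparison", "label_efficiency_comparison"]

COMPARISON_EPOCHS = 60


def standard_pipeline(seed: int, synth: SynthConfig | None = None,
                      modality: str = "cardiac") -> tuple[SegmentDataset, DomainFeatureMatrix]:
    """Generate, split, preprocess and feature-ize the synthetic preset.

    Signals are per-channel z-normalized; domain features are z-normalized
    with train-split statistics applied to all splits (leak-free).
    """
    cfg = synth if synth is not None else SynthConfig(seed=seed)
    ds = make_splits(generate_dataset(cfg), seed=seed)
    ds = preprocess_dataset(ds, PreprocessSpec(target_fs=cfg.fs, band=None,
                                               window_s=cfg.window_s, znorm_signal=True))
    raw = extract_feature_matrix(ds, modality)
    fitted = znormalize_features(raw.rows(ds.indices_of("train")))
    feats = znormalize_features(raw, stats=(fitted.norm_mean, fitted.norm_std))
    return ds, feats


def _probe_both(model, ds: SegmentDataset, k: int = 10) -> dict:
    train, test = ds.subset("train"), ds.subset("test")
    h_tr = encode_representations(model, train.signal_array())
    h_te = encode_representations(model, test.signal_array())
    return {
        "linear_f1": linear_probe(h_tr, train.labels, h_te, test.labels).macro_f1,
        "knn_f1": knn_probe(h_tr, train.labels, h_te, test.labels, k=k).macro_f1,
    }


def pretraining_comparison(seeds=(0, 1, 2), epochs: int = COMPARISON_EPOCHS) -> dict:
    """Probe quality of domain-guided vs instance-only vs untrained encoders.

    Returns per-seed and mean macro-F1 for the linear and KNN probes under
    three conditions sharing architecture and data: ``guided`` (neighbour
    positives + prototype contrast), ``instance`` (plain one-positive
    contrast), ``random`` (no pretraining).
    """
    conditions = {
        "guided": dict(n_neighbors=2, use_prototypes=True),
        "instance": dict(n_neighbors=0, use_prototypes=False),
        "random": None,
    }
    out: dict = {name: {"linear_f1": [], "knn_f1": []} for name in conditions}
    for seed in seeds:
        ds, feats = standard_pipeline(seed)
        for name, kw in conditions.items():
            if kw is None:
                model = build_encoder(desk_config().encoder,
                                      np.random.default_rng(np.random.SeedSequence([seed, 0])))
            else:
                model = pretrain(ds, feats, desk_config(seed=seed, epochs=epochs, **kw)).model
            probes = _probe_both(model, ds)
            for key, v in probes.items():
                out[name][key].append(v)
    for name in conditions:
        for key in ("linear_f1", "knn_f1"):
            out[name][f"mean_{key}"] = float(np.mean(out[name][key]))
    return out


def label_efficiency_comparison(seeds=(0, 1, 2), fraction: float = 0.1,
                                epochs: int = COMPARISON_EPOCHS,
                                ft_epochs: int = 20) -> dict:
    """Fine-tune from a domain-guided checkpoint vs from random init.

    Both start from the same architecture and see the same stratified
    ``fraction`` of train labels; reports test macro-F1 per seed and means.
    """
    out = {"pretrained": [], "random_init": []}
    for seed in seeds:
        ds, feats = standard_pipeline(seed)
        pre = pretrain(ds, feats, desk_config(seed=seed, epochs=epochs)).model
        rnd = build_encoder(desk_config().encoder,
                            np.random.default_rng(np.random.SeedSequence([seed, 0])))
        ft_cfg = FineTuneConfig(epochs=ft_epochs, seed=seed)
        for name, model in [("pretrained", pre), ("random_init", rnd)]:
            _, _, rep = fine_tune(model, ds, label_fraction=fraction, cfg=ft_cfg)
            out[name].append(rep.macro_f1)
    out["mean_pretrained"] = float(np.mean(out["pretrained"]))
    out["mean_random_init"] = float(np.mean(out["random_init"]))
    return out
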