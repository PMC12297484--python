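"""End-to-end self-supervised pretraining.

One run executes: offline k-means on the (z-normalized) domain features of
the training split — exactly once; then per batch, two augmented views per
segment are encoded and projected, the domain-guided multi-positive
instance loss is computed, prototypes are EMA-updated and the prototype
loss evaluated, and the encoder is optimized under the ramped total loss

    L = L_instance + min(max((T - T0) / Tmax, 0), 1) * L_prototype,

with per-cluster temperatures refreshed at each epoch end.  The prototype
term phases in because early prototypes are poor: epochs with ramp weight 0
serve as a warm-up during which member projections are collected, and the
prototypes are initialized from those means when the ramp activates.

Randomness is hierarchical: one master seed derives independent, named
streams for weight init, k-means, and each epoch's shuffling/augmentation,
so runs are bit-reproducible and a checkpointed run resumes on the exact
trajectory of an uninterrupted one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .augment import AugmentationSpec, sample_view_pair
from .data import SegmentDataset, ValidationError
from .features import DomainFeatureMatrix
from .losses import EmbeddingBatch, build_pair_assignment, instance_loss_and_grad
from .nn import Adam, EncoderProjector, EncoderSpec, build_encoder
from .prototypes import (PrototypeBank, ema_update, kmeans_assign,
                         prototype_loss_and_grad, update_temperatures)

__all__ = [
    "LossSchedule", "TrainConfig", "ramp_weight", "total_loss",
    "pretrain", "PretrainResult", "save_checkpoint", "load_checkpoint",
    "desk_config", "fullscale_config", "TrainingError",
]

# named sub-stream ids for the master seed
_STREAM_INIT, _STREAM_KMEANS, _STREAM_EPOCH = 0, 1, 2


class TrainingError(RuntimeError):
    pass


@dataclass
class LossSchedule:
    """Prototype-term ramp: start epoch T0, total epochs Tmax, current epoch T."""

    t0: int
    t_max: int
    t: int = 0

    def __post_init__(self) -> None:
        if self.t0 < 0 or self.t_max < 1:
            raise ValidationError("need t0 >= 0 and t_max >= 1")


def ramp_weight(T: int, T0: int, Tmax: int, denominator: str = "tmax") -> float:
    """min(max((T - T0)/D, 0), 1) with D = Tmax (default) or Tmax - T0."""
    if Tmax <= 0:
        raise ValidationError("Tmax must be > 0")
    D = Tmax if denominator == "tmax" else max(Tmax - T0, 1)
    return float(min(max((T - T0) / D, 0.0), 1.0))


def total_loss(instance: float, proto: float, schedule: LossSchedule,
               denominator: str = "tmax") -> float:
    """instance + ramp_weight * proto at the schedule's current epoch.

    Non-finite inputs are a training error (with both values in the message).
    """
    if not (np.isfinite(instance) and np.isfinite(proto)):
        raise TrainingError(f"non-finite loss: instance={instance}, proto={proto}")
    return instance + ramp_weight(schedule.t, schedule.t0, schedule.t_max, denominator) * proto


@dataclass
class TrainConfig:
    """Pretraining hyperparameters.

    The defaults are the desk-scale preset; :func:`fullscale_config` mirrors the
    GPU-scale protocol (1000 epochs, batch 1024, K=128) for users with the
    hardware to run it.  ``t0=None`` means 10% of the epoch count.
    ``n_neighbors=0`` together with ``use_prototypes=False`` recovers plain
    instance-discrimination pretraining (the SimCLR-style baseline).
    """

    batch_size: int = 32
    epochs: int = 20
    lr: float = 1e-3
    warmup_epochs: int = 5
    tau: float = 0.1
    K: int = 4                              # ~batch_size/8 members per cluster per batch
    alpha: float = 0.5
    m: int = 10
    t0: int | None = None
    n_neighbors: int = 2
    use_prototypes: bool = True
    normalize_prototypes: bool = True
    ramp_denominator: str = "tmax"          # or "tmax_minus_t0"
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 2 or self.epochs < 1:
            raise ValidationError("need batch_size >= 2 and epochs >= 1")
        if self.ramp_denominator not in ("tmax", "tmax_minus_t0"):
            raise ValidationError(f"unknown ramp denominator {self.ramp_denominator!r}")

    @property
    def t0_effective(self) -> int:
        return int(round(0.1 * self.epochs)) if self.t0 is None else self.t0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["augmentation"] = self.augmentation.to_dict()
        d["encoder"] = self.encoder.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        aug = d.pop("augmentation", {})
        enc = d.pop("encoder", {})
        return cls(augmentation=AugmentationSpec(**aug) if not isinstance(aug, AugmentationSpec) else aug,
                   encoder=EncoderSpec.from_dict(enc) if not isinstance(enc, EncoderSpec) else enc,
                   **d)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def desk_config(**overrides) -> TrainConfig:
    """CPU-friendly preset used throughout the tests and examples."""
    return TrainConfig(**overrides)


def fullscale_config(**overrides) -> TrainConfig:
    """GPU-scale protocol: 1000 epochs, batch 1024, K=128, warm-up 5 epochs."""
    base = dict(batch_size=1024, epochs=1000, lr=1e-3, warmup_epochs=5, K=128)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class PretrainResult:
    model: EncoderProjector
    bank: PrototypeBank
    history: list[dict]
    config: TrainConfig

    def epoch_mean(self, key: str) -> np.ndarray:
        """Per-epoch mean of a logged step quantity."""
        epochs = sorted({r["epoch"] for r in self.history})
        return np.array([np.mean([r[key] for r in self.history if r["epoch"] == e])
                         for e in epochs])


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM_EPOCH, epoch]))


def _build_views(dataset: SegmentDataset, train_idx: np.ndarray, order: np.ndarray,
                 cfg: TrainConfig, rng: np.random.Generator,
                 feat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Augmented view tensor (2B, C, T), view->source positions, feature rows."""
    X, src, drows = [], [], []
    for pos in order:
        seg = dataset[int(train_idx[pos])]
        v1, v2 = sample_view_pair(seg, cfg.augmentation, rng)
        X += [v1, v2]
        src += [int(pos)] * 2
        drows += [feat[pos], feat[pos]]
    return np.stack(X), np.array(src), np.stack(drows)


def pretrain(dataset: SegmentDataset, features: DomainFeatureMatrix,
             cfg: TrainConfig, checkpoint_path: str | None = None,
             stop_after_epoch: int | None = None,
             resume_from: str | None = None) -> PretrainResult:
    """Run domain-guided self-supervised pretraining.

    ``features`` must be aligned to ``dataset`` row-for-row (z-normalized
    domain features); when the dataset carries split tags only the train
    split is used, with feature rows subset accordingly.  Incomplete final
    batches are dropped so neighbour pools and cluster counts are comparable
    across steps.

    ``stop_after_epoch``/``resume_from`` implement checkpointed runs: a run
    stopped after epoch E and resumed from its checkpoint reproduces the
    uninterrupted run's remaining epochs exactly.
    """
    if features.n_segments != len(dataset):
        raise ValidationError("features not aligned to dataset")
    if dataset.split_tags is not None:
        train_idx = dataset.indices_of("train")
    else:
        train_idx = np.arange(len(dataset))
    n_train = len(train_idx)
    if cfg.batch_size > n_train:
        raise ValidationError(f"batch_size {cfg.batch_size} exceeds train set size {n_train}")
    feat = features.values[train_idx]
    schedule = LossSchedule(t0=cfg.t0_effective, t_max=cfg.epochs)

    if resume_from is not None:
        state = load_checkpoint(resume_from)
        if state["config_digest"] != cfg.digest():
            raise ValidationError("checkpoint was produced by a different configuration")
        model = build_encoder(cfg.encoder, np.random.default_rng(0))
        model.load_state_dict(state["model"])
        opt = Adam(model.params(), lr=cfg.lr)
        opt.load_state_dict(state["opt"])
        bank = state["bank"]
        history = state["history"]
        start_epoch = state["next_epoch"]
    else:
        init_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_INIT]))
        model = build_encoder(cfg.encoder, init_rng)
        opt = Adam(model.params(), lr=cfg.lr)
        km_seed = int(np.random.SeedSequence([cfg.seed, _STREAM_KMEANS]).generate_state(1)[0] % (2 ** 31))
        assignments, _ = kmeans_assign(feat, cfg.K, seed=km_seed)
        bank = PrototypeBank(K=min(cfg.K, n_train),
                             dim=cfg.encoder.proj_dim, base_tau=cfg.tau,
                             alpha=cfg.alpha, m=cfg.m,
                             normalize_prototypes=cfg.normalize_prototypes,
                             assignments=assignments)
        history = []
        start_epoch = 0

    n_batches = n_train // cfg.batch_size
    for epoch in range(start_epoch, cfg.epochs):
        rng = _epoch_rng(cfg.seed, epoch)
        schedule.t = epoch
        w = ramp_weight(epoch, schedule.t0, schedule.t_max, cfg.ramp_denominator)
        lr_scale = min(1.0, (epoch + 1) / cfg.warmup_epochs) if cfg.warmup_epochs > 0 else 1.0
        perm = rng.permutation(n_train)
        warm_sum = np.zeros((bank.K, bank.dim))
        warm_cnt = np.zeros(bank.K, dtype=np.int64)

        for b in range(n_batches):
            order = perm[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            X, src, drows = _build_views(dataset, train_idx, order, cfg, rng, feat)
            z = model.forward_proj(X)
            batch = EmbeddingBatch(z=z, view_to_source=src, d=drows)
            pairs = build_pair_assignment(batch, cfg.n_neighbors)
            L_ins, dz = instance_loss_and_grad(batch, pairs, cfg.tau)

            L_pro = 0.0
            if cfg.use_prototypes:
                if w > 0 and bank.initialized:
                    ema_update(bank, batch)
                    L_pro, dz_pro = prototype_loss_and_grad(batch, bank)
                    dz = dz + w * dz_pro
                else:
                    ks = bank.view_clusters(batch)
                    np.add.at(warm_sum, ks, z)
                    np.add.at(warm_cnt, ks, 1)

            L_tot = total_loss(L_ins, L_pro, schedule, cfg.ramp_denominator)
            model.zero_grad()
            model.backward_from_proj(dz)
            opt.step(model.grads(), lr_scale=lr_scale)
            history.append({"epoch": epoch, "step": b, "instance_loss": float(L_ins),
                            "proto_loss": float(L_pro), "ramp": w,
                            "total_loss": float(L_tot), "lr_scale": lr_scale})

        # epoch end: initialize prototypes during warm-up, refresh temperatures after
        if cfg.use_prototypes:
            if w == 0:
                seen = warm_cnt > 0
                if seen.any():
                    c = np.where(seen[:, None], warm_sum / np.maximum(warm_cnt, 1)[:, None],
                                 warm_sum.sum(axis=0) / max(warm_cnt.sum(), 1))
                    if cfg.normalize_prototypes:
                        c /= np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-12)
                    bank.c = c
            elif bank.initialized and bank.n_k.sum() > 0:
                update_temperatures(bank)

        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, model, bank, opt, epoch + 1, cfg, history)
        if stop_after_epoch is not None and epoch >= stop_after_epoch:
            break

    return PretrainResult(model=model, bank=bank, history=history, config=cfg)


def save_checkpoint(path: str, model: EncoderProjector, bank: PrototypeBank,
                    opt: Adam, next_epoch: int, cfg: TrainConfig,
                    history: list[dict]) -> None:
    """Serialize model/optimizer/prototype state with the config digest and seed."""
    arrays = {f"model.{k}": v for k, v in model.state_dict().items()}
    arrays.update({f"opt.{k}": v for k, v in opt.state_dict().items() if k != "t"})
    arrays["opt.t"] = np.array(opt.t)
    arrays["bank.assignments"] = bank.assignments
    arrays["bank.tau_k"] = bank.tau_k
    arrays["bank.dist_sum"] = bank.dist_sum
    arrays["bank.n_k"] = bank.n_k
    if bank.c is not None:
        arrays["bank.c"] = bank.c
    meta = {"next_epoch": next_epoch, "config": cfg.to_dict(),
            "config_digest": cfg.digest(), "seed": cfg.seed,
            "bank": {"K": bank.K, "dim": bank.dim, "base_tau": bank.base_tau,
                     "alpha": bank.alpha, "m": bank.m,
                     "normalize_prototypes": bank.normalize_prototypes,
                     "initialized": bank.initialized},
            "history": history}
    arrays["meta_json"] = np.array(json.dumps(meta))
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> dict:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with np.load(path, allow_pickle=False) as f:
        data = {k: f[k] for k in f.files}
    meta = json.loads(str(data.pop("meta_json")))
    model_state = {k[len("model."):]: v for k, v in data.items() if k.startswith("model.")}
    opt_state = {k[len("opt."):]: v for k, v in data.items() if k.startswith("opt.")}
    opt_state["t"] = int(opt_state["t"])
    b = meta["bank"]
    bank = PrototypeBank(K=b["K"], dim=b["dim"], base_tau=b["base_tau"], alpha=b["alpha"],
                         m=b["m"], normalize_prototypes=b["normalize_prototypes"],
                         assignments=data["bank.assignments"],
                         c=data.get("bank.c"), tau_k=data["bank.tau_k"],
                         dist_sum=data["bank.dist_sum"], n_k=data["bank.n_k"])
    return {"model": model_state, "opt": opt_state, "bank": bank,
            "next_epoch": int(meta["next_epoch"]), "config": meta["config"],
            "config_digest": meta["config_digest"], "history": meta["history"]}
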