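"""Residual 1-D convolutional encoder with a nonlinear projection head.

The encoder maps a (N, C, T) batch of waveform views to backbone
representations h (N, repr_dim) via strided conv stages with residual
blocks and global average pooling.  A two-layer projector maps h to
l2-normalized projections z used for all contrastive similarity
calculations; probing and fine-tuning consume h, the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Conv1d, Dense, GlobalAvgPool, ReLU, Residual, Sequential

__all__ = ["EncoderSpec", "EncoderProjector", "build_encoder"]


@dataclass
class EncoderSpec:
    """Depth/width configuration of the conv encoder and projector."""

    in_channels: int = 1
    widths: tuple[int, ...] = (8, 16, 32)
    kernels: tuple[int, ...] = (7, 5, 3)
    strides: tuple[int, ...] = (2, 2, 2)
    residual: bool = True
    proj_hidden: int = 32
    proj_dim: int = 16

    @property
    def repr_dim(self) -> int:
        return self.widths[-1]

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels, "widths": list(self.widths),
            "kernels": list(self.kernels), "strides": list(self.strides),
            "residual": self.residual, "proj_hidden": self.proj_hidden,
            "proj_dim": self.proj_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderSpec":
        return cls(in_channels=int(d["in_channels"]), widths=tuple(d["widths"]),
                   kernels=tuple(d["kernels"]), strides=tuple(d["strides"]),
                   residual=bool(d["residual"]), proj_hidden=int(d["proj_hidden"]),
                   proj_dim=int(d["proj_dim"]))


def build_encoder(spec: EncoderSpec, rng: np.random.Generator) -> "EncoderProjector":
    layers: list = []
    prev = spec.in_channels
    for w, k, s in zip(spec.widths, spec.kernels, spec.strides):
        layers += [Conv1d(prev, w, k, stride=s, rng=rng), ReLU()]
        if spec.residual:
            layers.append(Residual(Sequential([
                Conv1d(w, w, 3, rng=rng), ReLU(), Conv1d(w, w, 3, rng=rng),
            ])))
        prev = w
    layers.append(GlobalAvgPool())
    backbone = Sequential(layers)
    projector = Sequential([
        Dense(spec.repr_dim, spec.proj_hidden, rng=rng), ReLU(),
        Dense(spec.proj_hidden, spec.proj_dim, rng=rng),
    ])
    return EncoderProjector(spec, backbone, projector)


class EncoderProjector:
    """Backbone + projector with explicit backward passes."""

    def __init__(self, spec: EncoderSpec, backbone: Sequential, projector: Sequential):
        self.spec = spec
        self.backbone = backbone
        self.projector = projector

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> dict[str, np.ndarray]:
        out = {f"backbone.{k}": v for k, v in self.backbone.params().items()}
        out.update({f"projector.{k}": v for k, v in self.projector.params().items()})
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {f"backbone.{k}": v for k, v in self.backbone.grads().items()}
        out.update({f"projector.{k}": v for k, v in self.projector.grads().items()})
        return out

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch: {sorted(missing)}")
        for k, v in params.items():
            v[...] = state[k]

    def copy(self) -> "EncoderProjector":
        clone = build_encoder(self.spec, np.random.default_rng(0))
        clone.load_state_dict(self.state_dict())
        return clone

    # -- forward / backward -------------------------------------------------
    def forward_repr(self, x: np.ndarray) -> np.ndarray:
        """Backbone representations h, (N, repr_dim)."""
        return self.backbone.forward(np.asarray(x, dtype=np.float64))

    def forward_proj(self, x: np.ndarray) -> np.ndarray:
        """l2-normalized projections z, (N, proj_dim)."""
        h = self.forward_repr(x)
        u = self.projector.forward(h)
        self._norms = np.linalg.norm(u, axis=1, keepdims=True)
        self._norms = np.maximum(self._norms, 1e-12)
        self._z = u / self._norms
        return self._z

    def backward_from_proj(self, dz: np.ndarray) -> None:
        """Backprop d(loss)/dz through normalization, projector, backbone."""
        z, nrm = self._z, self._norms
        du = (dz - (dz * z).sum(axis=1, keepdims=True) * z) / nrm
        dh = self.projector.backward(du)
        self.backbone.backward(dh)

    def backward_from_repr(self, dh: np.ndarray) -> None:
        """Backprop d(loss)/dh through the backbone only (fine-tuning path)."""
        self.backbone.backward(dh)
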