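"""Stochastic view generation for contrastive training.

A deliberately modality-agnostic pipeline: temporal jittering (circular
shift), per-channel scaling, magnitude warping by a smooth random curve,
additive Gaussian noise, and cutout.  Two independently sampled transform
chains applied to one segment yield a positive view pair; both views inherit
the source segment's identity and domain feature vector.

The transform order is fixed (jitter -> scaling -> magnitude_warp -> noise
-> cutout) so a single RNG stream makes the chain deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import CubicSpline

from .data import SignalSegment, ValidationError

__all__ = ["AugmentationSpec", "apply_transform", "sample_view_pair", "TRANSFORM_ORDER"]

TRANSFORM_ORDER = ("jitter", "scaling", "magnitude_warp", "gaussian_noise", "cutout")


@dataclass
class AugmentationSpec:
    """Per-transform parameters and application probabilities."""

    jitter_max_shift: int = 50          # samples, circular
    scaling_sigma: float = 0.2          # multiplicative factor ~ N(1, sigma^2) per channel
    warp_knots: int = 4
    warp_sigma: float = 0.2
    noise_sigma: float = 0.05
    cutout_frac: float = 0.1            # fraction of the window zeroed
    apply_prob: dict = field(default_factory=lambda: {
        "jitter": 0.5, "scaling": 0.5, "magnitude_warp": 0.5,
        "gaussian_noise": 1.0, "cutout": 0.5,
    })

    def __post_init__(self) -> None:
        if min(self.scaling_sigma, self.warp_sigma, self.noise_sigma) < 0:
            raise ValidationError("sigmas must be >= 0")
        if not (0 <= self.cutout_frac < 1):
            raise ValidationError("cutout_frac must be in [0, 1)")
        if self.warp_knots < 2:
            raise ValidationError("warp_knots must be >= 2")
        for k in self.apply_prob:
            if k not in TRANSFORM_ORDER:
                raise ValidationError(f"unknown transform {k!r} in apply_prob")

    def params_for(self, kind: str) -> dict:
        return {
            "jitter": {"max_shift": self.jitter_max_shift},
            "scaling": {"sigma": self.scaling_sigma},
            "magnitude_warp": {"knots": self.warp_knots, "sigma": self.warp_sigma},
            "gaussian_noise": {"sigma": self.noise_sigma},
            "cutout": {"frac": self.cutout_frac},
        }[kind]

    def to_dict(self) -> dict:
        return asdict(self)


def apply_transform(x: np.ndarray, kind: str, params: dict,
                    rng: np.random.Generator) -> np.ndarray:
    """Apply one named transform to a (channels, timesteps) array.

    Output shape always equals input shape.
    """
    x = np.asarray(x, dtype=np.float64)
    C, T = x.shape
    if kind == "jitter":
        shift = int(rng.integers(-params["max_shift"], params["max_shift"] + 1))
        return np.roll(x, shift, axis=-1)
    if kind == "scaling":
        factors = 1.0 + params["sigma"] * rng.standard_normal((C, 1))
        return x * factors
    if kind == "magnitude_warp":
        knots = params["knots"]
        t_knots = np.linspace(0, T - 1, knots)
        out = np.empty_like(x)
        for c in range(C):
            vals = 1.0 + params["sigma"] * rng.standard_normal(knots)
            out[c] = x[c] * CubicSpline(t_knots, vals)(np.arange(T))
        return out
    if kind == "gaussian_noise":
        return x + params["sigma"] * rng.standard_normal((C, T))
    if kind == "cutout":
        n_cut = int(round(params["frac"] * T))
        out = x.copy()
        if n_cut > 0:
            start = int(rng.integers(0, T - n_cut + 1))
            out[:, start:start + n_cut] = 0.0
        return out
    raise ValidationError(f"unknown transform {kind!r}")


def _one_view(x: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator) -> np.ndarray:
    out = x
    for kind in TRANSFORM_ORDER:
        # always draw the gate so the stream advances identically per chain
        gate = rng.uniform() < spec.apply_prob.get(kind, 0.0)
        if gate:
            out = apply_transform(out, kind, spec.params_for(kind), rng)
    return out


def sample_view_pair(segment: SignalSegment, spec: AugmentationSpec,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of one segment.

    The views share the source segment's identity and domain feature vector;
    that pairing contract is what lets sibling views reuse one feature row
    during neighbour selection.
    """
    return _one_view(segment.x, spec, rng), _one_view(segment.x, spec, rng)
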