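"""Adam optimizer over flat name->array parameter dicts."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        out = {"t": self.t}
        for k in self.params:
            out[f"m.{k}"] = self.m[k].copy()
            out[f"v.{k}"] = self.v[k].copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for k in self.params:
            self.m[k][...] = state[f"m.{k}"]
            self.v[k][...] = state[f"v.{k}"]
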