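"""AdamW optimizer (decoupled weight decay) over autodiff parameters."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class AdamW:
    """Adam with decoupled weight decay.

    Defaults follow the optimizer's conventional settings: betas (0.9, 0.999),
    eps 1e-8, weight decay 1e-2.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * g * g
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            p.data = p.data - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {"t": np.array(self.t)}
        for i in range(len(self.params)):
            state[f"m{i}"] = self.m[i]
            state[f"v{i}"] = self.v[i]
        return state

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(state[f"m{i}"]) for i in range(len(self.params))]
        self.v = [np.asarray(state[f"v{i}"]) for i in range(len(self.params))]
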