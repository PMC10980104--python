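"""Sequential container with save/load support."""

from __future__ import annotations

import json

import numpy as np

from .layers import BatchNorm2d, Layer


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        """Yield (key, param_array, grad_array) triples in a stable order."""
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"{i}.{name}", p, layer.grads[name]

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.copy() for k, p, _ in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p, _ in self.parameters():
            p[...] = state[k]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def save_meta(path, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
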