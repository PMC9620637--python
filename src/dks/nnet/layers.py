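"""Layer/module abstractions over the autodiff core.

Modules own :class:`~dks.nnet.autograd.Parameter` tensors and compose into a
tree; ``parameters()`` walks the tree, ``state_dict`` / ``load_state_dict``
serialize it by dotted path.  Weight initialization is He-normal and takes an
explicit ``numpy`` Generator so model builds are reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = ["Module", "Conv2d", "Linear", "ResBlock"]

DTYPE = np.float32


class Module:
    """Base class: submodules and parameters are discovered by attribute walk."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            yield from _walk_params(value, f"{prefix}{name}")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError(
                f"state dict mismatch: missing {set(own) - set(state)}, "
                f"unexpected {set(state) - set(own)}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _walk_params(value, path: str) -> Iterator[tuple[str, "Parameter"]]:
    """Recursively discover parameters in modules, lists and dicts."""
    if isinstance(value, Parameter):
        yield path, value
    elif isinstance(value, Module):
        yield from value.named_parameters(f"{path}.")
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _walk_params(item, f"{path}.{i}")
    elif isinstance(value, dict):
        for k, item in value.items():
            yield from _walk_params(item, f"{path}.{k}")


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2d(Module):
    """3x3 or 1x1 same-padding convolution.

    ``init_scale`` shrinks the He-normal weights; output heads use a small
    scale so the untrained network emits near-zero maps (stable early
    optimization instead of chaotic random-head gradients).
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        rng: np.random.Generator,
        init_scale: float = 1.0,
    ):
        self.w = Parameter(init_scale * he_normal(rng, (cout, cin, k, k), cin * k * k))
        self.b = Parameter(np.zeros(cout, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        self.w = Parameter(he_normal(rng, (din, dout), din))
        self.b = Parameter(np.zeros(dout, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.w, self.b)


class ResBlock(Module):
    """conv3-relu-conv3 with an (optionally projected) identity shortcut."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.proj = Conv2d(cin, cout, 1, rng) if cin != cout else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(ag.relu(self.conv1(x)))
        shortcut = self.proj(x) if self.proj is not None else x
        return ag.relu(y + shortcut)
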