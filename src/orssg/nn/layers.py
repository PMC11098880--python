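"""Parameterized layers built on the autograd engine."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autograd import Tensor, concat, gather_rows

__all__ = ["Linear", "MLP", "Conv2d", "Module"]


class Module:
    """Base class exposing a flat parameter list."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, arrays):
            p.data = np.asarray(arr, dtype=np.float64).reshape(p.data.shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.weight = Tensor(rng.normal(0.0, scale, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros((1, d_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Linear stack with ReLU between layers (none after the last)."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Conv2d(Module):
    """Valid convolution over channels-last images, implemented via im2col."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        self.kernel = kernel
        self.stride = stride
        self.c_in = c_in
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.weight = Tensor(
            rng.normal(0.0, scale, (kernel * kernel * c_in, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros((1, c_out)), requires_grad=True)
        self._index_cache: dict[tuple[int, int], tuple[np.ndarray, int, int]] = {}

    def _indices(self, h: int, w: int) -> tuple[np.ndarray, int, int]:
        key = (h, w)
        if key not in self._index_cache:
            k, s = self.kernel, self.stride
            h_out = (h - k) // s + 1
            w_out = (w - k) // s + 1
            rows = (np.arange(h_out) * s)[:, None] + np.arange(k)[None, :]  # (h_out, k)
            cols = (np.arange(w_out) * s)[:, None] + np.arange(k)[None, :]
            # flat index into (h, w, c_in) for every (patch, element)
            idx = (
                rows[:, None, :, None, None] * (w * self.c_in)
                + cols[None, :, None, :, None] * self.c_in
                + np.arange(self.c_in)[None, None, None, None, :]
            )
            self._index_cache[key] = (
                idx.reshape(h_out * w_out, k * k * self.c_in),
                h_out,
                w_out,
            )
        return self._index_cache[key]

    def __call__(self, image: Tensor) -> Tensor:
        """image: (H, W, C_in) -> (H_out, W_out, C_out)."""
        h, w, c = image.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        idx, h_out, w_out = self._indices(h, w)
        flat = image.reshape(h * w * c, 1)
        cols = gather_rows(flat, idx.ravel()).reshape(len(idx), idx.shape[1])
        out = cols @ self.weight + self.bias
        return out.reshape(h_out, w_out, out.shape[-1])
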