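"""Neural-network building blocks: modules, linear/layer-norm, self-attention."""

from __future__ import annotations

import hashlib
from typing import Dict, List

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "state_checksum",
]


class Module:
    """Base class with recursive parameter discovery and state (de)serialization."""

    training: bool = False

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
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

    def named_state(self, prefix: str = "") -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data
            elif isinstance(value, Module):
                state.update(value.named_state(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.named_state(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        state[f"{key}.{i}"] = item.data
        return state

    def load_state(self, state: Dict[str, np.ndarray], prefix: str = "") -> None:
        own = self.named_state(prefix=prefix)
        missing = sorted(set(own) - set(state))
        if missing:
            raise KeyError(f"checkpoint missing parameters: {missing[:5]}")
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                if value.data.shape != state[key].shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{value.data.shape} vs {state[key].shape}"
                    )
                value.data = np.asarray(state[key], dtype=np.float32).copy()
            elif isinstance(value, Module):
                value.load_state(state, prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def state_checksum(module: Module) -> str:
    """SHA-256 over all parameter bytes, used to assert a backbone stayed frozen."""
    h = hashlib.sha256()
    for name in sorted(module.named_state()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(module.named_state()[name]).tobytes())
    return h.hexdigest()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (d_in + d_out)), size=(d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps) ** 0.5 * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard multi-head self-attention; stores the last attention maps.

    The per-head softmax matrices of the most recent forward pass are kept
    (detached) in ``last_attention`` with shape (B, heads, T, T) so that the
    caller can build attention-rollout saliency maps.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 qk_norm: bool = True):
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by {heads} heads")
        self.dim = dim
        self.heads = heads
        self.qk_norm = qk_norm
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None

    @staticmethod
    def _rms_normalize(x: Tensor) -> Tensor:
        # parameter-free RMS norm over the head dimension; keeps query/key
        # magnitudes bounded so attention logits cannot blow up mid-training
        return x * ((x * x).mean(axis=-1, keepdims=True) + 1e-6) ** -0.5

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, dh = self.heads, self.dim // self.heads
        qkv = self.qkv(x)                                   # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                    # (B, h, T, dh)
        if self.qk_norm:
            q = self._rms_normalize(q)
            k = self._rms_normalize(k)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)                      # rows sum to 1
        self.last_attention = attn.data.copy()
        out = attn @ v                                      # (B, h, T, dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer block (LN -> MHSA -> residual, LN -> MLP -> residual)."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(round(dim * mlp_ratio))
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(self.fc1(self.norm2(x)).gelu())
        return x
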