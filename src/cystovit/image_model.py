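"""Image-level multitask vision transformer.

One encoder, two output routes:

* the **class token** drives four independent classification heads — bladder
  abnormality (2-way), urethral abnormality (2-way), left and right
  vesicoureteral-reflux grade (6-way each);
* the **patch tokens** drive a 4-class segmentation head (background,
  bladder, ureter, urethra).  Per-layer attention maps are chained into an
  attention-rollout saliency map whose values additively bias the foreground
  logits (strength ``lambda_att``), steering the mask toward regions the
  classifier already attends to.  The per-pixel maximum class probability is
  exported as a confidence map and also weights the segmentation loss.

Two geometry presets exist: ``tiny`` (64 px images, 8 px patches, 64-dim
embedding, 4 layers, 4 heads) for desk-scale training from random init, and
``base`` matching ViT-Base geometry (224/16/768/12/12) for loading external
pretrained weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .nn import LayerNorm, Linear, Module, Tensor, TransformerBlock, concat, no_grad
from .utils import substream

__all__ = [
    "TASKS",
    "TASK_CLASSES",
    "EncoderConfig",
    "TaskProbs",
    "ImagePrediction",
    "ImageModel",
    "attention_rollout",
    "predict_image",
    "save_checkpoint",
    "load_checkpoint",
]

TASKS: Tuple[str, ...] = ("bladder", "urethra", "lvur", "rvur")
TASK_CLASSES: Dict[str, int] = {"bladder": 2, "urethra": 2, "lvur": 6, "rvur": 6}

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class EncoderConfig:
    image_size: int = 64
    patch_size: int = 8
    embed_dim: int = 64
    depth: int = 4
    heads: int = 4
    mlp_ratio: float = 2.0
    dropout: float = 0.0
    lambda_att: float = 1.0

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError(
                f"image_size {self.image_size} not divisible by "
                f"patch_size {self.patch_size}"
            )
        if self.embed_dim % self.heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by heads {self.heads}"
            )

    @classmethod
    def tiny(cls, **over) -> "EncoderConfig":
        return cls(**{**dict(image_size=64, patch_size=8, embed_dim=64,
                             depth=4, heads=4, mlp_ratio=2.0), **over})

    @classmethod
    def base(cls, **over) -> "EncoderConfig":
        return cls(**{**dict(image_size=224, patch_size=16, embed_dim=768,
                             depth=12, heads=12, mlp_ratio=4.0), **over})

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid ** 2


@dataclass
class TaskProbs:
    bladder: np.ndarray
    urethra: np.ndarray
    lvur: np.ndarray
    rvur: np.ndarray

    def __post_init__(self):
        for task in TASKS:
            v = np.asarray(getattr(self, task), dtype=np.float64)
            if v.shape != (TASK_CLASSES[task],):
                raise ValueError(f"{task}: expected {TASK_CLASSES[task]} classes, "
                                 f"got shape {v.shape}")
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-6:
                raise ValueError(f"{task}: not a probability distribution: {v}")
            setattr(self, task, v)

    def argmax(self) -> Dict[str, int]:
        return {task: int(np.argmax(getattr(self, task))) for task in TASKS}


@dataclass
class ImagePrediction:
    probs: TaskProbs
    mask: np.ndarray          # H x W in {0,1,2,3}
    saliency: np.ndarray      # H x W in [0,1]
    confidence: np.ndarray    # H x W, per-pixel max class probability
    feature: np.ndarray       # class-token representation, length embed_dim


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image min-max to [0,1], then fixed standardization (mean .5, sd .5)."""
    x = np.asarray(image, dtype=np.float32)
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        x = (x - lo) / (hi - lo)
    else:
        x = np.zeros_like(x)
    return (x - 0.5) / 0.5


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B,H,W) -> (B, n_patches, patch_size**2), row-major patch order."""
    B, H, W = images.shape
    gh, gw = H // patch_size, W // patch_size
    x = images.reshape(B, gh, patch_size, gw, patch_size)
    return x.transpose(0, 1, 3, 2, 4).reshape(B, gh * gw, patch_size * patch_size)


@lru_cache(maxsize=8)
def _bilinear_matrix(grid: int, size: int) -> np.ndarray:
    """(size*size, grid*grid) matrix performing bilinear upsampling of a
    patch-grid map to pixel resolution (patch centers as sample points)."""
    ps = size / grid
    U = np.zeros((size * size, grid * grid), dtype=np.float32)
    coords = (np.arange(size) + 0.5) / ps - 0.5
    coords = np.clip(coords, 0.0, grid - 1.0)
    i0 = np.floor(coords).astype(int)
    i1 = np.minimum(i0 + 1, grid - 1)
    frac = coords - i0
    for r in range(size):
        for c in range(size):
            p = r * size + c
            for gi, wi in ((i0[r], 1 - frac[r]), (i1[r], frac[r])):
                for gj, wj in ((i0[c], 1 - frac[c]), (i1[c], frac[c])):
                    U[p, gi * grid + gj] += wi * wj
    return U


def attention_rollout(attentions: List[np.ndarray]) -> np.ndarray:
    """Chain per-layer attention into a class-token saliency map.

    Heads are averaged within each layer, the identity is added (residual
    mixing) and rows renormalized, then the matrices are multiplied across
    layers.  The class-token row, restricted to patch positions, is min-max
    scaled to [0,1].  Returns (B, grid, grid); a constant rollout row maps to
    an all-zero map (scaling guard).
    """
    if not attentions:
        raise ValueError("empty attention stack")
    B, _, T, _ = attentions[0].shape
    rollout = np.broadcast_to(np.eye(T, dtype=np.float64), (B, T, T)).copy()
    eye = np.eye(T, dtype=np.float64)
    for layer in attentions:
        A = layer.astype(np.float64).mean(axis=1) + eye
        A /= A.sum(axis=-1, keepdims=True)
        rollout = A @ rollout
    cls_row = rollout[:, 0, 1:]                       # (B, n_patches)
    lo = cls_row.min(axis=1, keepdims=True)
    hi = cls_row.max(axis=1, keepdims=True)
    span = hi - lo
    scaled = np.where(span > 1e-12, (cls_row - lo) / np.where(span > 0, span, 1.0), 0.0)
    grid = int(round(np.sqrt(cls_row.shape[1])))
    return scaled.reshape(B, grid, grid).astype(np.float32)


class ImageModel(Module):
    """Unified transformer for joint classification and segmentation."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = substream(seed, "init/image_model")
        D = config.embed_dim
        self.patch_proj = Linear(config.patch_size ** 2, D, rng)
        self.cls_token = Tensor(np.zeros((1, 1, D)), requires_grad=True)
        self.pos_embed = Tensor(
            rng.normal(0.0, 0.02, size=(1, config.n_patches + 1, D)),
            requires_grad=True,
        )
        self.blocks = [TransformerBlock(D, config.heads, config.mlp_ratio, rng)
                       for _ in range(config.depth)]
        self.norm = LayerNorm(D)
        # heads start at zero so an untrained model emits uniform distributions
        self.heads = {t: Linear(D, TASK_CLASSES[t], rng, zero_init=True)
                      for t in TASKS}
        self.head_bladder = self.heads["bladder"]
        self.head_urethra = self.heads["urethra"]
        self.head_lvur = self.heads["lvur"]
        self.head_rvur = self.heads["rvur"]
        self.seg_head = Linear(D, 4, rng, zero_init=True)
        self._drop_rng = substream(seed, "dropout/image_model")

    # -- pipeline stages ---------------------------------------------------

    def patch_embed(self, images: np.ndarray) -> Tensor:
        """(B,H,W) grayscale batch -> (B, n_patches+1, D) token sequence."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        S = self.config.image_size
        if images.shape[1:] != (S, S):
            raise ValueError(
                f"image batch shape {images.shape[1:]} does not match "
                f"configured size {(S, S)}"
            )
        patches = patchify(images, self.config.patch_size)
        tok = self.patch_proj(Tensor(patches))                  # (B, N, D)
        B = patches.shape[0]
        cls = concat([self.cls_token] * B, axis=0) if B > 1 else self.cls_token
        tokens = concat([cls, tok], axis=1)
        return tokens + self.pos_embed

    def encode(self, tokens: Tensor) -> Tuple[Tensor, Tensor, List[np.ndarray]]:
        """Run the transformer; returns class feature, patch features and the
        per-layer attention maps of this forward pass."""
        x = tokens
        attns: List[np.ndarray] = []
        for i, blk in enumerate(self.blocks):
            x = blk(x)
            if not np.isfinite(x.data).all():
                raise FloatingPointError(f"non-finite activations at layer {i}")
            attns.append(blk.attn.last_attention)
            if self.training and self.config.dropout > 0:
                keep = 1.0 - self.config.dropout
                mask = (self._drop_rng.random(x.shape) < keep) / keep
                x = x * Tensor(mask.astype(np.float32))
        x = self.norm(x)
        return x[:, 0, :], x[:, 1:, :], attns

    def classify(self, cls_feat: Tensor) -> Dict[str, Tensor]:
        """Four independent linear heads over the class-token feature -> logits."""
        if cls_feat.shape[-1] != self.config.embed_dim:
            raise ValueError(
                f"feature dim {cls_feat.shape[-1]} != embed_dim {self.config.embed_dim}"
            )
        return {t: self.heads[t](cls_feat) for t in TASKS}

    def segment(self, patch_feats: Tensor, saliency: np.ndarray,
                lambda_att: float | None = None) -> Tensor:
        """Per-patch 4-class logits, bilinearly upsampled to pixels, with
        foreground logits additively biased by the saliency map.

        Returns pixel logits with shape (B, H*W, 4).
        """
        lam = self.config.lambda_att if lambda_att is None else lambda_att
        cfg = self.config
        logits = self.seg_head(patch_feats)                     # (B, N, 4)
        U = Tensor(_bilinear_matrix(cfg.grid, cfg.image_size)[None])
        pixel_logits = U @ logits                               # (B, HW, 4)
        if lam != 0.0:
            sal = saliency.reshape(saliency.shape[0], -1)
            sal_pix = (_bilinear_matrix(cfg.grid, cfg.image_size) @ sal.T).T
            bias = np.zeros(pixel_logits.shape, dtype=np.float32)
            bias[:, :, 1:] = lam * sal_pix[:, :, None]
            pixel_logits = pixel_logits + Tensor(bias)
        return pixel_logits

    def forward(self, images: np.ndarray) -> Dict[str, object]:
        """Full pass: normalized images -> logits for every output route."""
        tokens = self.patch_embed(images)
        cls_feat, patch_feats, attns = self.encode(tokens)
        saliency = attention_rollout(attns)                     # detached by design
        pixel_logits = self.segment(patch_feats, saliency)
        return dict(
            cls_feat=cls_feat,
            task_logits=self.classify(cls_feat),
            pixel_logits=pixel_logits,
            saliency=saliency,
            attentions=attns,
        )


def predict_image(model: ImageModel, image: np.ndarray) -> ImagePrediction:
    """Inference on a single raw image (normalization applied here)."""
    model.eval()
    S = model.config.image_size
    with no_grad():
        out = model.forward(normalize_image(image)[None])
    task_probs = {t: _softmax_np(out["task_logits"][t].data[0]) for t in TASKS}
    pixel_logits = out["pixel_logits"].data[0]                  # (HW, 4)
    pixel_probs = _softmax_np(pixel_logits)
    mask = pixel_probs.argmax(axis=-1).reshape(S, S).astype(np.uint8)
    confidence = pixel_probs.max(axis=-1).reshape(S, S)
    sal_pix = (_bilinear_matrix(model.config.grid, S)
               @ out["saliency"][0].reshape(-1)).reshape(S, S)
    return ImagePrediction(
        probs=TaskProbs(**task_probs),
        mask=mask,
        saliency=np.clip(sal_pix, 0.0, 1.0),
        confidence=confidence,
        feature=out["cls_feat"].data[0].copy(),
    )


def _softmax_np(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: Module, path, config: dict | None = None,
                    extra: dict | None = None) -> None:
    """Single-file .npz checkpoint: weights + JSON-encoded config/provenance."""
    meta = dict(version=CHECKPOINT_VERSION,
                model_class=type(model).__name__,
                config=config or {},
                extra=extra or {})
    state = model.named_state()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8), **state)


def load_checkpoint(path) -> Tuple[dict, Dict[str, np.ndarray]]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode("utf-8"))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    return meta, state


def load_image_model(path) -> ImageModel:
    meta, state = load_checkpoint(path)
    if meta["model_class"] != "ImageModel":
        raise ValueError(f"not an image-model checkpoint: {meta['model_class']}")
    model = ImageModel(EncoderConfig(**meta["config"]))
    model.load_state(state)
    return model
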