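"""Patient-level aggregation by disease-specific attention pooling.

An examination yields one class-token feature per image from the *frozen*
image-level encoder.  For each of the four diagnostic tasks a learnable
category embedding q_t scores every image through scaled dot-product
attention over projected keys,

    w_{t,i} = softmax_i( q_t · k_i / sqrt(d) ),   k_i = W_K^{(t)} f_i,

and the patient representation for task t is the attention-weighted sum of
projected values v_i = W_V^{(t)} f_i.  A linear head per task maps the
pooled vector to patient-level probabilities.  The 4 × n_images matrix of
attention weights is the exported image weight map: each row is a
probability distribution stating how much each image contributed to that
task's diagnosis.

The pooling is orderless: permuting the images permutes the weight-map
columns and leaves the diagnosis unchanged; duplicating every image halves
the weights and leaves the diagnosis unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .image_model import (
    TASKS,
    ImageModel,
    TaskProbs,
    load_checkpoint,
    normalize_image,
)
from .nn import Linear, Module, Tensor, no_grad, state_checksum
from .phantoms import ExamBundle
from .utils import substream

__all__ = [
    "ExamFeatures",
    "PatientNet",
    "PatientPrediction",
    "WeightMap",
    "attention_pool",
    "extract_features",
    "predict_patient",
    "export_weight_map",
    "load_patient_model",
]


@dataclass
class ExamFeatures:
    matrix: np.ndarray            # n_images x d
    image_ids: List[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError(f"need a (n_images>=1, d) matrix, got {self.matrix.shape}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite feature rows")
        if len(self.image_ids) != self.matrix.shape[0]:
            raise ValueError("image_ids length must match feature rows")


@dataclass
class WeightMap:
    """tasks x images attention weights; task order (bladder, urethra, lvur, rvur)."""
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != len(TASKS):
            raise ValueError(f"expected ({len(TASKS)}, n_images), got {w.shape}")
        if (w < 0).any() or np.abs(w.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("weight-map rows must be probability distributions")
        self.weights = w

    def row(self, task: str) -> np.ndarray:
        return self.weights[TASKS.index(task)]


@dataclass
class PatientPrediction:
    probs: TaskProbs
    labels: Dict[str, int]
    weight_map: WeightMap
    n_images: int
    image_ids: List[str] = field(default_factory=list)
    patient_id: str = ""


class PatientNet(Module):
    """Category-embedding bank + per-task key/value projections + linear heads.

    These are the only trainable patient-level parameters; the image encoder
    stays frozen throughout stage-2 training.
    """

    def __init__(self, embed_dim: int, seed: int = 0, identity_proj: bool = False):
        rng = substream(seed, "init/patient_model")
        d = self.embed_dim = embed_dim
        self.queries = Tensor(rng.normal(0.0, 0.2, size=(len(TASKS), d)),
                              requires_grad=True)
        eye = np.eye(d)
        if identity_proj:
            wk = np.repeat(eye[None], len(TASKS), axis=0)
            wv = wk.copy()
        else:
            noise = 0.05
            wk = eye[None] + rng.normal(0, noise, size=(len(TASKS), d, d))
            wv = eye[None] + rng.normal(0, noise, size=(len(TASKS), d, d))
        self.key_proj = Tensor(wk, requires_grad=True)
        self.value_proj = Tensor(wv, requires_grad=True)
        self.head_bladder = Linear(d, 2, rng, zero_init=True)
        self.head_urethra = Linear(d, 2, rng, zero_init=True)
        self.head_lvur = Linear(d, 6, rng, zero_init=True)
        self.head_rvur = Linear(d, 6, rng, zero_init=True)
        self.heads = {"bladder": self.head_bladder, "urethra": self.head_urethra,
                      "lvur": self.head_lvur, "rvur": self.head_rvur}

    def pool(self, features: Tensor) -> Tuple[Tensor, Tensor]:
        """(n, d) features -> pooled (tasks, d) and weights (tasks, n)."""
        n, d = features.shape
        keys = Tensor._lift(features) @ self.key_proj        # (tasks, n, d)
        values = Tensor._lift(features) @ self.value_proj    # (tasks, n, d)
        q = self.queries.reshape(len(TASKS), 1, d)
        scores = (keys @ q.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))  # (tasks, n, 1)
        weights = scores.transpose(0, 2, 1).softmax(axis=-1)         # (tasks, 1, n)
        pooled = (weights @ values).reshape(len(TASKS), d)
        return pooled, weights.reshape(len(TASKS), n)

    def forward(self, features: Tensor) -> Tuple[Dict[str, Tensor], Tensor]:
        pooled, weights = self.pool(features)
        logits = {t: self.heads[t](pooled[i: i + 1, :])[0, :]
                  for i, t in enumerate(TASKS)}
        return logits, weights


def attention_pool(features: ExamFeatures | np.ndarray,
                   bank: PatientNet) -> Tuple[np.ndarray, WeightMap]:
    """Pool an exam's feature matrix; returns (tasks x d pooled, WeightMap)."""
    matrix = features.matrix if isinstance(features, ExamFeatures) else np.asarray(features)
    if matrix.shape[0] == 0:
        raise ValueError("cannot pool an exam with zero images")
    if matrix.shape[1] != bank.embed_dim:
        raise ValueError(f"feature dim {matrix.shape[1]} != bank dim {bank.embed_dim}")
    with no_grad():
        pooled, weights = bank.pool(Tensor(matrix))
    return pooled.data.copy(), WeightMap(weights.data.astype(np.float64))


def extract_features(exam: ExamBundle, image_model: ImageModel) -> ExamFeatures:
    """Class-token feature per image from the frozen encoder (eval mode).

    The encoder is checksummed before and after to certify it was not
    modified by extraction.
    """
    if not exam.images:
        raise ValueError(f"exam {exam.patient_truth.patient_id} has no images")
    before = state_checksum(image_model)
    image_model.eval()
    batch = np.stack([normalize_image(r.image) for r in exam.images])
    with no_grad():
        tokens = image_model.patch_embed(batch)
        cls_feat, _, _ = image_model.encode(tokens)
    after = state_checksum(image_model)
    if before != after:
        raise RuntimeError("image model was modified during feature extraction")
    ids = [f"{exam.patient_truth.patient_id}_{j:02d}" for j in range(len(exam.images))]
    return ExamFeatures(matrix=cls_feat.data.copy(), image_ids=ids)


def predict_patient(exam: ExamBundle, image_model: ImageModel,
                    patient_net: PatientNet) -> PatientPrediction:
    """Frozen feature extraction -> attention pooling -> per-task heads."""
    feats = extract_features(exam, image_model)
    with no_grad():
        logits, weights = patient_net.forward(Tensor(feats.matrix))
    probs = {t: _softmax_np(logits[t].data) for t in TASKS}
    tp = TaskProbs(**probs)
    return PatientPrediction(
        probs=tp,
        labels=tp.argmax(),
        weight_map=WeightMap(weights.data.astype(np.float64)),
        n_images=len(exam.images),
        image_ids=feats.image_ids,
        patient_id=exam.patient_truth.patient_id,
    )


def export_weight_map(prediction: PatientPrediction, out_path,
                      heatmap: bool = False) -> pd.DataFrame:
    """Serialize the image weight map as CSV (+ JSON mirror, optional heatmap).

    Rows are renormalized after rounding to 6 decimals so the serialized
    rows still sum to 1; a note records this.
    """
    w = prediction.weight_map.weights
    cols = prediction.image_ids or [f"img{j}" for j in range(prediction.n_images)]
    rounded = np.round(w, 6)
    rounded = rounded / rounded.sum(axis=1, keepdims=True)
    df = pd.DataFrame(rounded, index=list(TASKS), columns=cols)
    df.index.name = "task"
    out_path = Path(out_path)
    df.to_csv(out_path, float_format="%.6f", lineterminator="\n")
    payload = dict(
        patient_id=prediction.patient_id,
        tasks=list(TASKS),
        image_ids=cols,
        weights=rounded.tolist(),
        note="rows renormalized after rounding to 6 decimals",
    )
    out_path.with_suffix(".json").write_text(json.dumps(payload, indent=1) + "\n",
                                             encoding="utf-8")
    if heatmap:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(1 + 0.6 * len(cols), 2.4))
        im = ax.imshow(w, cmap="viridis", vmin=0, vmax=w.max())
        ax.set_yticks(range(len(TASKS)), TASKS)
        ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(out_path.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return df


def _softmax_np(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def load_patient_model(path) -> PatientNet:
    meta, state = load_checkpoint(path)
    if meta["model_class"] != "PatientNet":
        raise ValueError(f"not a patient-model checkpoint: {meta['model_class']}")
    net = PatientNet(embed_dim=int(meta["config"]["embed_dim"]))
    net.load_state(state)
    return net
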