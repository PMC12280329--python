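"""Losses, patient-level splitting and the two seeded training stages.

Stage 1 trains the image-level transformer on single images with a summed
multitask objective: one cross-entropy per classification task (optionally
inverse-frequency class-weighted, since grade 0 dominates real cohorts) plus
a segmentation term combining confidence-weighted pixel cross-entropy and a
soft Dice loss over the four classes.  Stage 2 freezes the image model and
trains only the patient-level attention bank and heads on exam-level labels.

Design notes: the optimizer is AdamW with cosine decay; horizontal-flip
augmentation is deliberately absent because flipping swaps the left/right
reflux labels.  Splitting is at the patient level — no patient contributes
images to both partitions — with size round(ratio*N) (half-up).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .image_model import (
    TASKS,
    TASK_CLASSES,
    EncoderConfig,
    ImageModel,
    normalize_image,
)
from .nn import AdamW, Tensor, cosine_lr, no_grad, state_checksum
from .patient_model import PatientNet, extract_features
from .phantoms import ExamBundle
from .utils import substream

__all__ = [
    "TrainConfig",
    "SplitResult",
    "split_patients",
    "multitask_loss",
    "inverse_frequency_weights",
    "train_image_model",
    "train_patient_model",
]


@dataclass(frozen=True)
class TrainConfig:
    stage: str = "image"                 # "image" | "patient"
    epochs: int = 30
    batch_size: int = 16
    lr: float = 3e-3
    weight_decay: float = 1e-4
    lambda_task: Tuple[float, float, float, float] = (4.0, 2.0, 2.0, 2.0)
    lambda_seg: float = 1.2
    seg_warmup_epochs: int = 4   # classification-only epochs before the seg
                                 # loss switches on (stabilizes the trunk)
    class_weighting: str = "inverse-frequency"   # or "none"
    aug_translate: int = 0       # max |shift| in px for train-time translation
    label_smoothing: float = 0.1
    ema_decay: float = 0.99      # 0 disables weight averaging
    clip_norm: float = 1.0       # 0 disables gradient clipping
    adam_betas: Tuple[float, float] = (0.9, 0.95)
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.stage not in ("image", "patient"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.lambda_seg < 0 or any(l < 0 for l in self.lambda_task):
            raise ValueError("loss weights must be nonnegative")
        if self.class_weighting not in ("none", "inverse-frequency"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


@dataclass(frozen=True)
class SplitResult:
    train_ids: frozenset
    val_ids: frozenset
    ratio: float
    seed: int


def split_patients(patient_ids: Sequence[str], ratio: float = 0.7,
                   seed: int = 0) -> SplitResult:
    """Uniform random patient-level partition; sizes (round(ratio*N), rest)."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes[:5]}")
    if len(ids) < 2:
        raise ValueError("need at least two patients to split")
    rng = substream(seed, "split_patients")
    order = rng.permutation(len(ids))
    n_train = int(np.floor(ratio * len(ids) + 0.5))      # half-up
    train = frozenset(ids[i] for i in order[:n_train])
    val = frozenset(ids[i] for i in order[n_train:])
    return SplitResult(train_ids=train, val_ids=val, ratio=ratio, seed=seed)


def inverse_frequency_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class weights proportional to 1/frequency, mean 1 over present
    classes; absent classes get weight 0 (they cannot contribute loss)."""
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=n_classes).astype(float)
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = 1.0 / counts[present]
    w[present] /= w[present].mean()
    return w


def _weighted_ce(logits: Tensor, targets: np.ndarray,
                 sample_weights: np.ndarray,
                 label_smoothing: float = 0.0) -> Tensor:
    """Weighted-mean cross-entropy over a batch; weights need not sum to 1.

    With label smoothing eps the target distribution is
    (1-eps)*one_hot + eps*uniform.
    """
    targets = np.asarray(targets, dtype=int)
    n, c = logits.shape
    if targets.min() < 0 or targets.max() >= c:
        raise ValueError(f"label outside [0,{c - 1}]: {targets.min()}..{targets.max()}")
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(n), targets]
    w = np.asarray(sample_weights, dtype=np.float32)
    denom = float(w.sum())
    if denom <= 0:
        return Tensor(0.0)
    nll = -(picked * Tensor(w)).sum() * (1.0 / denom)
    if label_smoothing > 0:
        uniform = -(logp.mean(axis=-1) * Tensor(w)).sum() * (1.0 / denom)
        nll = nll * (1.0 - label_smoothing) + uniform * label_smoothing
    return nll


def soft_dice_loss(pixel_probs: Tensor, mask_targets: np.ndarray,
                   eps: float = 1e-6) -> Tensor:
    """1 - mean soft Dice over the 4 classes.

    Dice is computed per image and per class, then averaged over the classes
    present in each image's reference mask (background is always present).
    Per-image averaging keeps the gradient for thin, rare structures (the
    urethra occupies ~1% of pixels on a voiding image and none elsewhere)
    from being diluted by images where the class is absent.
    """
    B, P, C = pixel_probs.shape
    flat = np.asarray(mask_targets, dtype=int).reshape(B, P)
    onehot = np.zeros((B, P, C), dtype=np.float32)
    for c in range(C):
        onehot[:, :, c] = flat == c
    t = Tensor(onehot)
    inter = (pixel_probs * t).sum(axis=1)                    # (B, C)
    total = pixel_probs.sum(axis=1) + Tensor(onehot.sum(axis=1))
    dice = (inter * 2.0 + eps) / (total + eps)               # (B, C)
    present = (onehot.sum(axis=1) > 0).astype(np.float32)    # (B, C)
    n_present = float(present.sum())
    return 1.0 - (dice * Tensor(present)).sum() * (1.0 / max(n_present, 1.0))


def multitask_loss(task_logits: Dict[str, Tensor],
                   targets: Dict[str, np.ndarray],
                   config: TrainConfig,
                   pixel_logits: Optional[Tensor] = None,
                   mask_targets: Optional[np.ndarray] = None,
                   class_weights: Optional[Dict[str, np.ndarray]] = None,
                   ) -> Tuple[Tensor, Dict[str, float]]:
    """Total training objective with a per-term breakdown.

    total = sum_t lambda_t * CE_t  +  lambda_seg * (conf-weighted pixel CE + soft Dice)

    The breakdown reports each weighted term; the reported terms sum to the
    total within 1e-6.
    """
    terms: Dict[str, float] = {}
    total = Tensor(0.0)
    for lam, task in zip(config.lambda_task, TASKS):
        y = np.asarray(targets[task], dtype=int)
        if class_weights and task in class_weights:
            sw = class_weights[task][y]
        else:
            sw = np.ones(len(y))
        ce = _weighted_ce(task_logits[task], y, sw,
                          label_smoothing=config.label_smoothing) * lam
        terms[f"ce_{task}"] = float(ce.data)
        total = total + ce
    if pixel_logits is not None and config.lambda_seg > 0:
        if mask_targets is None:
            raise ValueError("mask_targets required when lambda_seg > 0")
        B, P, C = pixel_logits.shape
        probs = pixel_logits.softmax(axis=-1)
        conf = probs.data.max(axis=-1).reshape(-1)            # detached confidence
        flat_logits = pixel_logits.reshape(B * P, C)
        flat_targets = np.asarray(mask_targets, dtype=int).reshape(-1)
        # balance the foreground classes: background outnumbers the urethra
        # by ~100:1, so unweighted pixel CE never learns thin structures
        pix_w = conf
        if class_weights and "pixels" in class_weights:
            pix_w = conf * class_weights["pixels"][flat_targets]
        seg_ce = _weighted_ce(flat_logits, flat_targets, pix_w) * config.lambda_seg
        dice = soft_dice_loss(probs, mask_targets) * config.lambda_seg
        terms["seg_ce"] = float(seg_ce.data)
        terms["seg_dice"] = float(dice.data)
        total = total + seg_ce + dice
    terms["total"] = float(total.data)
    return total, terms


# --------------------------------------------------------------------------
# stage 1: image-level model

def _flatten_images(exams: Iterable[ExamBundle]):
    images, masks, labels = [], [], {t: [] for t in TASKS}
    for exam in exams:
        for rec in exam.images:
            images.append(normalize_image(rec.image))
            masks.append(rec.mask)
            b, u, lv, rv = rec.image_labels
            labels["bladder"].append(b)
            labels["urethra"].append(u)
            labels["lvur"].append(lv)
            labels["rvur"].append(rv)
    return (np.stack(images), np.stack(masks),
            {t: np.asarray(v, dtype=int) for t, v in labels.items()})


def _translate(images: np.ndarray, masks: np.ndarray, shifts: np.ndarray
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Shift each image of a batch by its own (dy, dx), filling exposed
    borders with background.

    Translation keeps every label valid; horizontal flips would not (they
    swap the lateralized reflux labels) and are deliberately not offered.
    """
    out_i = np.full_like(images, images.min())
    out_m = np.zeros_like(masks)
    H, W = images.shape[1:]
    for b, (dy, dx) in enumerate(shifts):
        dy, dx = int(dy), int(dx)
        ys = slice(max(dy, 0), H + min(dy, 0))
        xs = slice(max(dx, 0), W + min(dx, 0))
        ys_src = slice(max(-dy, 0), H + min(-dy, 0))
        xs_src = slice(max(-dx, 0), W + min(-dx, 0))
        out_i[b, ys, xs] = images[b, ys_src, xs_src]
        out_m[b, ys, xs] = masks[b, ys_src, xs_src]
    return out_i, out_m


def train_image_model(exams: Sequence[ExamBundle], encoder_config: EncoderConfig,
                      config: TrainConfig,
                      val_exams: Optional[Sequence[ExamBundle]] = None,
                      ) -> Tuple[ImageModel, List[dict]]:
    """Seeded stage-1 training; returns the model and per-epoch history."""
    model = ImageModel(encoder_config, seed=config.seed)
    images, masks, labels = _flatten_images(exams)
    n = len(images)
    class_weights = None
    if config.class_weighting == "inverse-frequency":
        class_weights = {t: inverse_frequency_weights(labels[t], TASK_CLASSES[t])
                         for t in TASKS}
        # tempered (square-root) balance for pixels: full inverse-frequency
        # over-rewards recall on thin classes and widens their masks
        pix = np.sqrt(inverse_frequency_weights(masks.reshape(-1), 4))
        class_weights["pixels"] = pix / pix[pix > 0].mean()
    params = model.parameters()
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay,
                betas=config.adam_betas, clip_norm=config.clip_norm)
    ema = [p.data.copy() for p in params] if config.ema_decay > 0 else None
    shuffle_rng = substream(config.seed, "train/image/shuffle")
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    history: List[dict] = []
    model.train()
    step = 0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_terms: Dict[str, float] = {}
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            batch_images, batch_masks = images[idx], masks[idx]
            if config.aug_translate > 0:
                shifts = shuffle_rng.integers(-config.aug_translate,
                                              config.aug_translate + 1,
                                              size=(len(idx), 2))
                batch_images, batch_masks = _translate(batch_images, batch_masks,
                                                       shifts)
            out = model.forward(batch_images)
            step_config = config
            if epoch < config.seg_warmup_epochs:
                step_config = replace(config, lambda_seg=0.0)
            total, terms = multitask_loss(
                out["task_logits"], {t: labels[t][idx] for t in TASKS},
                step_config, pixel_logits=out["pixel_logits"],
                mask_targets=batch_masks, class_weights=class_weights,
            )
            if not np.isfinite(total.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch} step {step}")
            opt.lr = cosine_lr(config.lr, step, total_steps, warmup=steps_per_epoch)
            opt.zero_grad()
            total.backward()
            opt.step()
            if ema is not None:
                d = config.ema_decay
                for s, p in zip(ema, params):
                    s *= d
                    s += (1.0 - d) * p.data
            step += 1
            for k, v in terms.items():
                epoch_terms[k] = epoch_terms.get(k, 0.0) + v / steps_per_epoch
        row = dict(epoch=epoch, lr=opt.lr, **epoch_terms)
        if val_exams is not None:
            row.update(_quick_image_val(model, val_exams))
            model.train()
        history.append(row)
    if ema is not None:   # adopt the averaged weights for the final model
        for s, p in zip(ema, params):
            p.data = s.astype(np.float32)
    model.eval()
    if val_exams is not None:
        history[-1].update(_quick_image_val(model, val_exams))
    return model, history


def _quick_image_val(model: ImageModel, exams: Sequence[ExamBundle]) -> dict:
    from .metrics import macro_ovr_auc, roc_auc
    images, _, labels = _flatten_images(exams)
    model.eval()
    probs = {t: [] for t in TASKS}
    with no_grad():
        for start in range(0, len(images), 64):
            out = model.forward(images[start: start + 64])
            for t in TASKS:
                z = out["task_logits"][t].data
                e = np.exp(z - z.max(axis=1, keepdims=True))
                probs[t].append(e / e.sum(axis=1, keepdims=True))
    result = {}
    for t in TASKS:
        p = np.concatenate(probs[t])
        y = labels[t]
        try:
            if TASK_CLASSES[t] == 2:
                result[f"val_auc_{t}"] = roc_auc(p[:, 1], y)
            else:
                result[f"val_auc_{t}"] = macro_ovr_auc(p, y)
        except ValueError:
            result[f"val_auc_{t}"] = float("nan")
    return result


# --------------------------------------------------------------------------
# stage 2: patient-level model

def train_patient_model(exams: Sequence[ExamBundle], image_model: ImageModel,
                        config: TrainConfig) -> Tuple[PatientNet, List[dict]]:
    """Stage-2 training of the category bank and patient heads only.

    The image model is frozen: a checksum asserts its weights are identical
    before and after training.
    """
    backbone_before = state_checksum(image_model)
    feats = [extract_features(exam, image_model).matrix for exam in exams]
    targets = {t: np.array([getattr(e.patient_truth, a) for e in exams], dtype=int)
               for t, a in zip(TASKS, ("bladder_abnormal", "urethra_abnormal",
                                       "lvur_grade", "rvur_grade"))}
    net = PatientNet(embed_dim=image_model.config.embed_dim, seed=config.seed)
    class_weights = None
    if config.class_weighting == "inverse-frequency":
        class_weights = {t: inverse_frequency_weights(targets[t], TASK_CLASSES[t])
                         for t in TASKS}
    opt = AdamW(net.parameters(), lr=config.lr, weight_decay=config.weight_decay,
                betas=config.adam_betas, clip_norm=config.clip_norm)
    shuffle_rng = substream(config.seed, "train/patient/shuffle")
    n = len(exams)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    history: List[dict] = []
    net.train()
    step = 0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for i in idx:
                logits, _ = net.forward(Tensor(feats[i]))
                per_task = {t: logits[t].reshape(1, TASK_CLASSES[t]) for t in TASKS}
                tgt = {t: targets[t][i: i + 1] for t in TASKS}
                total, _ = multitask_loss(per_task, tgt, config,
                                          class_weights=class_weights)
                total = total * (1.0 / len(idx))
                total.backward()
                batch_loss += float(total.data)
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch} step {step}")
            opt.lr = cosine_lr(config.lr, step, total_steps, warmup=steps_per_epoch)
            opt.step()
            step += 1
            epoch_loss += batch_loss / steps_per_epoch
        history.append(dict(epoch=epoch, lr=opt.lr, loss=epoch_loss))
    net.eval()
    if state_checksum(image_model) != backbone_before:
        raise RuntimeError("backbone changed during stage-2 training")
    return net, history
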