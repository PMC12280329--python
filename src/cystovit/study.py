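"""Desk-scale end-to-end study: train both stages on phantoms and evaluate.

This module fixes the study conditions used by the package's own validation
(and by ``scripts/acceptance.py``): a stage-1 training set of ~300 phantom
images, a 400-image held-out set for image-level AUROC and Dice, a stage-2
training set of 200 exams and 100 held-out exams for patient-level AUROC,
plus the constructed-exam weighting probe and a bootstrap-coverage
calibration.  Everything is driven by one integer seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .image_model import (
    TASKS,
    TASK_CLASSES,
    EncoderConfig,
    ImageModel,
    predict_image,
)
from .metrics import bootstrap_auc_ci, macro_ovr_auc, roc_auc
from .patient_model import PatientNet, predict_patient
from .phantoms import (
    ExamBundle,
    PatientTruth,
    PhantomConfig,
    generate_exams,
    render_image,
)
from .train import TrainConfig, train_image_model, train_patient_model
from .utils import substream

__all__ = [
    "StudyResult",
    "train_study_models",
    "evaluate_image_level",
    "evaluate_patient_level",
    "weighting_probe",
    "run_learnability_study",
    "bootstrap_coverage",
]

_TRUTH_ATTR = dict(bladder="bladder_abnormal", urethra="urethra_abnormal",
                   lvur="lvur_grade", rvur="rvur_grade")

# study sizes: chosen for a single-CPU desk-scale run of a few minutes
N_IMAGE_TRAIN = 300          # stage-1 training images (exams taken until reached)
N_IMAGE_VAL_PATIENTS = 100   # held-out patients for image-level metrics (~400 images)
N_PATIENT_TRAIN = 200        # stage-2 training exams
N_PATIENT_VAL = 100          # held-out exams for patient-level metrics
N_DICE_EXAMS = 60            # held-out exams scored for segmentation Dice
N_PROBE_EXAMS = 20           # constructed exams for the weighting probe


@dataclass
class StudyResult:
    image_auc: Dict[str, float]
    dice: Dict[str, float]                 # per class name
    patient_auc: Dict[str, float]
    probe_hits: int
    probe_total: int
    n_train_images: int
    n_val_images: int
    seconds: float


def _take_images(exams: List[ExamBundle], n_images: int) -> List[ExamBundle]:
    out, count = [], 0
    for e in exams:
        out.append(e)
        count += len(e.images)
        if count >= n_images:
            break
    return out


def train_study_models(seed: int) -> Tuple[ImageModel, PatientNet, dict]:
    """Train both stages under the fixed study conditions."""
    t0 = time.time()
    pool = generate_exams(PhantomConfig(n_patients=90, seed=seed + 1000))
    stage1 = _take_images(pool, N_IMAGE_TRAIN)
    image_cfg = TrainConfig(stage="image", epochs=30, batch_size=16, lr=3e-3,
                            seed=seed)
    image_model, hist1 = train_image_model(stage1, EncoderConfig.tiny(), image_cfg)

    stage2 = generate_exams(PhantomConfig(n_patients=N_PATIENT_TRAIN,
                                          seed=seed + 3000))
    patient_cfg = TrainConfig(stage="patient", epochs=120, batch_size=16, lr=5e-3,
                              lambda_task=(1.0, 1.0, 1.0, 1.0), seed=seed)
    patient_net, hist2 = train_patient_model(stage2, image_model, patient_cfg)
    info = dict(n_train_images=sum(len(e.images) for e in stage1),
                n_train_exams=len(stage2),
                history_image=hist1, history_patient=hist2,
                seconds=time.time() - t0)
    return image_model, patient_net, info


def evaluate_image_level(image_model: ImageModel, seed: int
                         ) -> Tuple[Dict[str, float], Dict[str, float], int]:
    """Held-out image-level macro AUROC per task and per-class Dice.

    Dice for a class is averaged over held-out images whose reference mask
    contains that class.
    """
    val = generate_exams(PhantomConfig(n_patients=N_IMAGE_VAL_PATIENTS,
                                       seed=seed + 2000))
    probs = {t: [] for t in TASKS}
    truth = {t: [] for t in TASKS}
    dice_acc: Dict[int, List[float]] = {c: [] for c in range(4)}
    n_images = 0
    for i, exam in enumerate(val):
        for rec in exam.images:
            pred = predict_image(image_model, rec.image)
            n_images += 1
            b, u, lv, rv = rec.image_labels
            for t, y in zip(TASKS, (b, u, lv, rv)):
                probs[t].append(getattr(pred.probs, t))
                truth[t].append(y)
            if i < N_DICE_EXAMS:
                for c in range(4):
                    ref = rec.mask == c
                    if ref.sum() == 0:
                        continue
                    hyp = pred.mask == c
                    dice_acc[c].append(
                        2.0 * (hyp & ref).sum() / max(hyp.sum() + ref.sum(), 1))
    aucs = {}
    for t in TASKS:
        p, y = np.array(probs[t]), np.array(truth[t])
        aucs[t] = (roc_auc(p[:, 1], y) if TASK_CLASSES[t] == 2
                   else macro_ovr_auc(p, y))
    class_names = ("background", "bladder", "ureter", "urethra")
    dice = {name: float(np.mean(dice_acc[c])) if dice_acc[c] else float("nan")
            for c, name in enumerate(class_names)}
    return aucs, dice, n_images


def evaluate_patient_level(image_model: ImageModel, patient_net: PatientNet,
                           seed: int) -> Dict[str, float]:
    """Held-out patient-level AUROC per task (macro one-vs-rest for grades)."""
    val = generate_exams(PhantomConfig(n_patients=N_PATIENT_VAL, seed=seed + 4000))
    probs = {t: [] for t in TASKS}
    truth = {t: [] for t in TASKS}
    for exam in val:
        pred = predict_patient(exam, image_model, patient_net)
        for t in TASKS:
            probs[t].append(getattr(pred.probs, t))
            truth[t].append(int(getattr(exam.patient_truth, _TRUTH_ATTR[t])))
    aucs = {}
    for t in TASKS:
        p, y = np.array(probs[t]), np.array(truth[t])
        aucs[t] = (roc_auc(p[:, 1], y) if TASK_CLASSES[t] == 2
                   else macro_ovr_auc(p, y))
    return aucs


def weighting_probe(image_model: ImageModel, patient_net: PatientNet,
                    seed: int, n_exams: int = N_PROBE_EXAMS,
                    grade: int = 4) -> Tuple[int, int]:
    """Constructed exams where exactly one image shows left reflux.

    Returns (hits, total): a hit means the left-VUR weight-map row peaks on
    the image that actually shows the reflux.
    """
    cfg = PhantomConfig(seed=seed)
    hits = 0
    for i in range(n_exams):
        stream = substream(seed, f"probe/{i}")
        truth = PatientTruth(f"PR{i:02d}", grade, 0, False, None, False, None)
        show = int(stream.integers(0, 4))
        records = []
        for j in range(4):
            records.append(render_image(
                truth, "voiding" if j % 2 else "filling", cfg, stream,
                force_visible=dict(left=(j == show), right=False,
                                   bladder=False, urethra=False)))
        exam = ExamBundle(patient_truth=truth, images=records)
        pred = predict_patient(exam, image_model, patient_net)
        hits += int(int(np.argmax(pred.weight_map.row("lvur"))) == show)
    return hits, n_exams


def run_learnability_study(seed: int) -> StudyResult:
    """Full stage-1 + stage-2 study; the package's headline self-validation."""
    t0 = time.time()
    image_model, patient_net, info = train_study_models(seed)
    image_auc, dice, n_val = evaluate_image_level(image_model, seed)
    patient_auc = evaluate_patient_level(image_model, patient_net, seed)
    hits, total = weighting_probe(image_model, patient_net, seed)
    return StudyResult(
        image_auc=image_auc, dice=dice, patient_auc=patient_auc,
        probe_hits=hits, probe_total=total,
        n_train_images=info["n_train_images"], n_val_images=n_val,
        seconds=time.time() - t0,
    )


def bootstrap_coverage(seed: int, n_subjects: int = 200, replications: int = 500,
                       B: int = 2000, true_auc_target: float = 0.8,
                       level: float = 0.95) -> float:
    """Empirical coverage of the percentile-bootstrap AUROC interval.

    Binary labels are balanced Bernoulli(0.5); positive scores are shifted
    normal so the population AUROC is ``true_auc_target`` (binormal model:
    AUC = Phi(mu / sqrt(2))).  Returns the fraction of replications whose
    95% interval contains the true AUROC.
    """
    from scipy.stats import norm
    mu = norm.ppf(true_auc_target) * np.sqrt(2.0)
    rng = substream(seed, "coverage")
    covered = 0
    for rep in range(replications):
        labels = rng.integers(0, 2, size=n_subjects)
        while labels.min() == labels.max():      # need both classes
            labels = rng.integers(0, 2, size=n_subjects)
        scores = rng.normal(0.0, 1.0, size=n_subjects) + mu * labels
        lo, hi = bootstrap_auc_ci(scores, labels, B=B,
                                  seed=int(rng.integers(0, 2 ** 31)), level=level)
        covered += int(lo <= true_auc_target <= hi)
    return covered / replications
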