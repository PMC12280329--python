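"""Procedural generator of multi-image cystourethrogram-like phantom exams.

Real voiding-cystourethrography (VCUG) studies are private clinical data, so
the package ships a phantom generator whose *statistical* structure matches
what the two-stage model assumes:

* an examination is an ordered set of 2–6 grayscale images taken during the
  filling and voiding phases;
* a patient carries ground-truth labels for four tasks — bladder abnormality
  (binary), urethral abnormality (binary), and left/right vesicoureteral
  reflux (VUR) grade 0–5 — with grade 0 strongly dominant, mirroring the
  skew of real cohorts;
* a lesion only renders on a given image with probability ``visibility``,
  so most images of a refluxing patient look normal and per-image labels
  are set to normal whenever the lesion did not render: patient-level truth
  is the maximum over what the images *could* show, which is exactly the
  image-vs-patient label gap the attention aggregator has to bridge.

Morphology follows the International Reflux Society grading qualitatively:
grade 1 reaches the distal ureter only; grade 2 and above reach the renal
pelvis; ureteral width and tortuosity grow with grade; grades 4–5 add
blunted-calyx lobes.  The rendering recipe itself (ellipse bladder, tube
urethra, parametric ureter curve) is a deliberate stand-in whose only
contract is label–appearance consistency and grade monotonicity.

Coordinate convention: row-major arrays, origin top-left; the *left* side of
a patient is the left half of the array (columns < width/2).  This is an
image-coordinate convention, not the radiological one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as cio
from .utils import substream

__all__ = [
    "PhantomConfig",
    "PatientTruth",
    "ImageRecord",
    "ExamBundle",
    "sample_patient_truth",
    "render_image",
    "sample_exam",
    "generate_exams",
    "generate_dataset",
    "load_exams",
    "BLADDER_SUBTYPES",
    "URETHRA_SUBTYPES",
]

BLADDER_SUBTYPES = ("diverticulum", "trabeculation")
URETHRA_SUBTYPES = ("posterior_valve_dilation", "stenosis")

# default grade distribution: grade 0 dominant, as in clinical cohorts
_DEFAULT_GRADE_PROBS = (0.70, 0.05, 0.05, 0.10, 0.06, 0.04)


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 64
    n_patients: int = 30
    images_per_exam: Tuple[int, int] = (2, 6)
    grade_probs: Tuple[float, ...] = _DEFAULT_GRADE_PROBS
    p_bladder_abnormal: float = 0.30
    p_urethra_abnormal: float = 0.25
    visibility: float = 0.85
    noise_sd: float = 0.05
    blur_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        lo, hi = self.images_per_exam
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid images_per_exam range {self.images_per_exam}")
        gp = np.asarray(self.grade_probs, dtype=float)
        if gp.shape != (6,) or (gp < 0).any() or abs(gp.sum() - 1.0) > 1e-9:
            raise ValueError("grade_probs must be 6 nonnegative values summing to 1")
        for name in ("p_bladder_abnormal", "p_urethra_abnormal", "visibility"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class PatientTruth:
    patient_id: str
    lvur_grade: int
    rvur_grade: int
    bladder_abnormal: bool
    bladder_subtype: Optional[str]
    urethra_abnormal: bool
    urethra_subtype: Optional[str]

    def __post_init__(self):
        for g in (self.lvur_grade, self.rvur_grade):
            if g not in range(6):
                raise ValueError(f"VUR grade {g} outside 0..5")
        if self.bladder_abnormal != (self.bladder_subtype is not None):
            raise ValueError("bladder subtype present iff flag set")
        if self.urethra_abnormal != (self.urethra_subtype is not None):
            raise ValueError("urethra subtype present iff flag set")

    @property
    def labels(self) -> Tuple[int, int, int, int]:
        return (int(self.bladder_abnormal), int(self.urethra_abnormal),
                self.lvur_grade, self.rvur_grade)


@dataclass
class ImageRecord:
    image: np.ndarray          # float32 in [0,1], H x W
    mask: np.ndarray           # uint8 in {0 bg, 1 bladder, 2 ureter, 3 urethra}
    phase: str                 # "filling" | "voiding"
    image_labels: Tuple[int, int, int, int]   # (bladder, urethra, lvur, rvur)


@dataclass
class ExamBundle:
    patient_truth: PatientTruth
    images: List[ImageRecord] = field(default_factory=list)


# --------------------------------------------------------------------------
# truth sampling

def sample_patient_truth(config: PhantomConfig, stream: np.random.Generator,
                         patient_id: str = "P0000") -> PatientTruth:
    """Draw one patient's ground truth; grades independent per side."""
    gp = np.asarray(config.grade_probs)
    lv = int(stream.choice(6, p=gp))
    rv = int(stream.choice(6, p=gp))
    b = bool(stream.random() < config.p_bladder_abnormal)
    u = bool(stream.random() < config.p_urethra_abnormal)
    return PatientTruth(
        patient_id=patient_id,
        lvur_grade=lv, rvur_grade=rv,
        bladder_abnormal=b,
        bladder_subtype=str(stream.choice(BLADDER_SUBTYPES)) if b else None,
        urethra_abnormal=u,
        urethra_subtype=str(stream.choice(URETHRA_SUBTYPES)) if u else None,
    )


# --------------------------------------------------------------------------
# rasterization helpers (all coordinates in units of a 64-px frame, scaled)

def _paint_disks(shape, xs, ys, radii) -> np.ndarray:
    """Union of disks along a sampled path; returns a boolean canvas."""
    H, W = shape
    canvas = np.zeros(shape, dtype=bool)
    for x, y, r in zip(xs, ys, radii):
        r = max(float(r), 0.5)
        x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
        y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, W), min(y1, H)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        canvas[y0:y1, x0:x1] |= (xx - x) ** 2 + (yy - y) ** 2 <= r * r
    return canvas


def _bladder_region(size: int, truth: PatientTruth, show_abnormal: bool,
                    stream: np.random.Generator) -> np.ndarray:
    s = size / 64.0
    cx = (32.0 + stream.uniform(-1.5, 1.5)) * s
    cy = (40.0 + stream.uniform(-1.5, 1.5)) * s
    rx = (13.0 + stream.uniform(-1.5, 1.5)) * s
    ry = (9.5 + stream.uniform(-1.5, 1.5)) * s
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = (xx - cx) / rx, (yy - cy) / ry
    rho = np.sqrt(dx ** 2 + dy ** 2)
    limit = np.ones_like(rho)
    if show_abnormal and truth.bladder_subtype == "trabeculation":
        theta = np.arctan2(dy, dx)
        phi = stream.uniform(0, 2 * np.pi)
        limit = 1.0 + 0.24 * np.sin(8.0 * theta + phi)  # wavy trabeculated wall
    region = rho <= limit
    if show_abnormal and truth.bladder_subtype == "diverticulum":
        ang = stream.uniform(0.25, 1.2) * stream.choice([-1.0, 1.0])
        bx = cx + (rx + 3.0 * s) * np.cos(ang)
        by = cy - (ry + 3.0 * s) * np.sin(abs(ang))
        region |= _paint_disks((size, size), [bx], [by], [5.0 * s])
    return region


def _urethra_region(size: int, truth: PatientTruth, show_abnormal: bool,
                    stream: np.random.Generator) -> np.ndarray:
    s = size / 64.0
    t = np.linspace(0.0, 1.0, 80)
    y0, y1 = 46.0 * s, (size - 1.0)
    ys = y0 + t * (y1 - y0)
    xs = 32.0 * s + 1.2 * s * np.sin(2.5 * t + stream.uniform(0, 1.0))
    width = np.full_like(t, 1.5 * s)
    if show_abnormal:
        if truth.urethra_subtype == "posterior_valve_dilation":
            # widened proximal (posterior) segment above an obstructing valve
            width = width * (1.0 + 3.2 * np.exp(-((t - 0.18) / 0.18) ** 2))
        elif truth.urethra_subtype == "stenosis":
            # focal narrowing with upstream dilation of the obstructed segment
            width = width * (1.0 + 2.0 * np.exp(-((t - 0.25) / 0.16) ** 2)
                             - 0.85 * np.exp(-((t - 0.60) / 0.10) ** 2))
            width = np.maximum(width, 0.3 * s)
    return _paint_disks((size, size), xs, ys, width)


def _ureter_region(size: int, side: str, grade: int,
                   stream: np.random.Generator) -> np.ndarray:
    """Reflux column for one side; empty for grade 0.

    Extent, width, tortuosity and pelvic/calyceal features are all
    nondecreasing in grade, so the rendered area grows with severity.
    """
    if grade <= 0:
        return np.zeros((size, size), dtype=bool)
    s = size / 64.0
    sign = -1.0 if side == "left" else 1.0
    x0, y0 = 32.0 + sign * 9.0, 38.0          # ureterovesical junction
    x1, y1 = 32.0 + sign * 21.0, 8.0          # renal pelvis
    extent = 0.55 if grade == 1 else 1.0
    n = 120
    t = np.linspace(0.0, extent, n)
    xs = x0 + (x1 - x0) * t + stream.uniform(-1.0, 1.0)
    ys = y0 + (y1 - y0) * t
    # tortuosity: sinusoidal displacement perpendicular to the chord
    amp = 0.35 * grade
    phase = stream.uniform(0, 2 * np.pi)
    xs = xs + amp * np.sin(2.0 * np.pi * 1.3 * t / max(extent, 1e-9) + phase)
    width = (1.0 + 0.45 * (grade - 1)) * np.ones(n)
    region = _paint_disks((size, size), xs * s, ys * s, width * s)
    if grade >= 2:  # contrast reaches the pelvis
        pr = 2.0 + 0.8 * (grade - 2)
        region |= _paint_disks((size, size), [xs[-1] * s], [ys[-1] * s], [pr * s])
        if grade >= 4:  # blunted calyces fanning off the pelvis
            for ang in (-0.9, 0.0, 0.9):
                cxa = xs[-1] + (pr + 1.2) * np.sin(ang) + sign * 1.0
                cya = ys[-1] - (pr + 1.2) * np.cos(ang) * 0.8 - 1.0
                region |= _paint_disks(
                    (size, size), [cxa * s], [cya * s], [(1.3 + 0.3 * (grade - 4)) * s]
                )
    # clip to the correct half so left/right never bleed across the midline
    half = np.zeros((size, size), dtype=bool)
    if side == "left":
        half[:, : size // 2] = True
    else:
        half[:, size // 2:] = True
    return region & half


# --------------------------------------------------------------------------
# image rendering

def render_image(truth: PatientTruth, phase: str, config: PhantomConfig,
                 stream: np.random.Generator,
                 force_visible: Optional[dict] = None) -> ImageRecord:
    """Render one phantom image of a patient in the given phase.

    ``force_visible`` overrides the per-lesion Bernoulli(visibility) draws
    (keys ``bladder``, ``urethra``, ``left``, ``right``); it exists so tests
    and demonstrations can construct exams where a lesion appears on exactly
    one chosen image.  Per-image labels always reflect what was actually
    rendered: an invisible lesion yields a normal label for that task.
    """
    if phase not in ("filling", "voiding"):
        raise ValueError(f"unknown phase {phase!r}")
    size = config.image_size
    force_visible = force_visible or {}

    def visible(key: str) -> bool:
        if key in force_visible:
            return bool(force_visible[key])
        return bool(stream.random() < config.visibility)

    show_bladder_abn = truth.bladder_abnormal and visible("bladder")
    show_urethra_abn = (phase == "voiding" and truth.urethra_abnormal
                        and visible("urethra"))
    show_left = truth.lvur_grade > 0 and visible("left")
    show_right = truth.rvur_grade > 0 and visible("right")

    mask = np.zeros((size, size), dtype=np.uint8)
    bladder = _bladder_region(size, truth, show_bladder_abn, stream)
    mask[bladder] = 1
    if phase == "voiding":
        urethra = _urethra_region(size, truth, show_urethra_abn, stream)
        mask[urethra & (mask == 0)] = 3
    lvur_label = rvur_label = 0
    if show_left:
        left = _ureter_region(size, "left", truth.lvur_grade, stream)
        region = left & (mask == 0)
        if region.any():
            mask[region] = 2
            lvur_label = truth.lvur_grade
    if show_right:
        right = _ureter_region(size, "right", truth.rvur_grade, stream)
        region = right & (mask == 0)
        if region.any():
            mask[region] = 2
            rvur_label = truth.rvur_grade

    intensity = np.full((size, size), 0.08, dtype=np.float64)
    intensity[mask == 1] = 0.88
    intensity[mask == 3] = 0.80
    intensity[mask == 2] = 0.72
    if config.blur_sigma > 0:
        intensity = gaussian_filter(intensity, sigma=config.blur_sigma)
    if config.noise_sd > 0:
        intensity = intensity + stream.normal(0.0, config.noise_sd, intensity.shape)
    image = np.clip(intensity, 0.0, 1.0).astype(np.float32)

    labels = (int(show_bladder_abn), int(show_urethra_abn), lvur_label, rvur_label)
    return ImageRecord(image=image, mask=mask, phase=phase, image_labels=labels)


def _exam_phases(k: int, stream: np.random.Generator) -> List[str]:
    """Phase assignment guaranteeing at least one voiding image per exam
    (and at least one filling image when the exam has >= 2 images)."""
    if k == 1:
        return ["voiding"]
    n_fill = int(stream.integers(1, k))   # 1..k-1 filling images
    phases = ["filling"] * n_fill + ["voiding"] * (k - n_fill)
    return [phases[i] for i in stream.permutation(k)]


def sample_exam(truth: PatientTruth, config: PhantomConfig,
                stream: np.random.Generator) -> ExamBundle:
    lo, hi = config.images_per_exam
    k = int(stream.integers(lo, hi + 1))
    records = [render_image(truth, ph, config, stream)
               for ph in _exam_phases(k, stream)]
    return ExamBundle(patient_truth=truth, images=records)


def generate_exams(config: PhantomConfig) -> List[ExamBundle]:
    """Generate ``config.n_patients`` in-memory exam bundles, deterministically."""
    exams = []
    for i in range(config.n_patients):
        stream = substream(config.seed, f"phantom/patient/{i}")
        truth = sample_patient_truth(config, stream, patient_id=f"P{i:04d}")
        exams.append(sample_exam(truth, config, stream))
    return exams


# --------------------------------------------------------------------------
# on-disk dataset

def generate_dataset(config: PhantomConfig, out_dir) -> pd.DataFrame:
    """Write a full phantom dataset (PNGs + CSV/JSON manifest) to ``out_dir``.

    Regeneration with the same config and seed reproduces identical files.
    Synthetic demographics (sex, age in months) are attached per patient so
    cohort summaries have something to count.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, exam in enumerate(generate_exams(config)):
        truth = exam.patient_truth
        demo = substream(config.seed, f"phantom/demographics/{i}")
        sex = "M" if demo.random() < 0.614 else "F"
        age = round(float(np.clip(demo.gamma(1.3, 32.0), 1.0, 216.0)), 1)
        pb, pu, plv, prv = truth.labels
        for j, rec in enumerate(exam.images):
            image_id = f"{truth.patient_id}_{j:02d}"
            img_rel = f"images/{image_id}.png"
            msk_rel = f"masks/{image_id}.png"
            cio.write_image(rec.image, out / img_rel)
            cio.write_mask(rec.mask, out / msk_rel)
            b, u, lv, rv = rec.image_labels
            rows.append(dict(
                patient_id=truth.patient_id, image_id=image_id,
                image_path=img_rel, mask_path=msk_rel, phase=rec.phase,
                bladder=b, urethra=u, lvur=lv, rvur=rv,
                p_bladder=pb, p_urethra=pu, p_lvur=plv, p_rvur=prv,
                sex=sex, age_months=age, cohort="",
            ))
    df = pd.DataFrame(rows, columns=cio.MANIFEST_COLUMNS)
    cio.write_manifest(df, out / "manifest.csv")
    return df


def load_exams(manifest: pd.DataFrame, root) -> List[ExamBundle]:
    """Rehydrate ExamBundles from a manifest written by :func:`generate_dataset`."""
    root = Path(root)
    exams = []
    for pid, grp in manifest.groupby("patient_id", sort=True):
        first = grp.iloc[0]
        plv, prv = int(first["p_lvur"]), int(first["p_rvur"])
        pb, pu = int(first["p_bladder"]), int(first["p_urethra"])
        truth = PatientTruth(
            patient_id=str(pid), lvur_grade=plv, rvur_grade=prv,
            bladder_abnormal=bool(pb),
            bladder_subtype=BLADDER_SUBTYPES[0] if pb else None,
            urethra_abnormal=bool(pu),
            urethra_subtype=URETHRA_SUBTYPES[0] if pu else None,
        )
        records = []
        for _, row in grp.iterrows():
            records.append(ImageRecord(
                image=cio.read_image(root / row["image_path"]),
                mask=cio.read_mask(root / row["mask_path"]),
                phase=str(row["phase"]),
                image_labels=(int(row["bladder"]), int(row["urethra"]),
                              int(row["lvur"]), int(row["rvur"])),
            ))
        exams.append(ExamBundle(patient_truth=truth, images=records))
    return exams
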