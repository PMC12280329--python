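"""Image, mask and manifest serialization.

Images are 8-bit grayscale PNG.  Segmentation masks are indexed PNG with the
fixed palette 0=black (background), 1=red (bladder), 2=yellow (ureter),
3=green (urethra).  Exam manifests are written as CSV with a JSON mirror;
both carry per-image labels and the patient-level label block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "MASK_PALETTE",
    "MANIFEST_COLUMNS",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_manifest",
    "read_manifest",
]

# class index -> RGB; fixed display convention for overlays and indexed PNGs
MASK_PALETTE = {0: (0, 0, 0), 1: (255, 0, 0), 2: (255, 255, 0), 3: (0, 255, 0)}

MANIFEST_COLUMNS = [
    "patient_id", "image_id", "image_path", "mask_path", "phase",
    "bladder", "urethra", "lvur", "rvur",
    "p_bladder", "p_urethra", "p_lvur", "p_rvur",
    "sex", "age_months", "cohort",
]

_LABEL_RANGES = {"bladder": 1, "urethra": 1, "lvur": 5, "rvur": 5,
                 "p_bladder": 1, "p_urethra": 1, "p_lvur": 5, "p_rvur": 5}
_PHASES = {"filling", "voiding"}


def write_image(image: np.ndarray, path) -> None:
    """Write a grayscale image (float in [0,1] or uint8) as 8-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_image(path) -> np.ndarray:
    """Read a PNG as float array scaled to [0,1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("I")).astype(np.float64)
    peak = 65535.0 if arr.max() > 255 else 255.0
    return (arr / peak).astype(np.float32)


def write_mask(mask: np.ndarray, path) -> None:
    arr = np.asarray(mask)
    bad = np.setdiff1d(np.unique(arr), list(MASK_PALETTE))
    if bad.size:
        raise ValueError(f"mask contains labels outside {{0..3}}: {bad.tolist()}")
    im = Image.fromarray(arr.astype(np.uint8), mode="P")
    palette = []
    for idx in range(256):
        palette.extend(MASK_PALETTE.get(idx, (0, 0, 0)))
    im.putpalette(palette)
    im.save(path)


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode != "P":
            raise ValueError(f"{path}: expected an indexed (palette) PNG, got {im.mode}")
        arr = np.asarray(im).astype(np.uint8)
    bad = np.setdiff1d(np.unique(arr), list(MASK_PALETTE))
    if bad.size:
        raise ValueError(f"{path}: mask labels outside {{0..3}}: {bad.tolist()}")
    return arr


def _validate_manifest(df: pd.DataFrame, root: Path | None, check_paths: bool) -> None:
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    errors = []
    for i, row in df.iterrows():
        for col, hi in _LABEL_RANGES.items():
            v = row[col]
            if not (0 <= int(v) <= hi):
                errors.append(f"row {i}: {col}={v} outside [0,{hi}]")
        if row["phase"] not in _PHASES:
            errors.append(f"row {i}: unknown phase {row['phase']!r}")
        if check_paths and root is not None:
            for col in ("image_path", "mask_path"):
                p = root / str(row[col])
                if not p.exists():
                    errors.append(f"row {i}: missing file {p}")
    if errors:
        raise ValueError("manifest validation failed:\n" + "\n".join(errors[:20]))


def write_manifest(df: pd.DataFrame, path) -> None:
    """Write manifest as CSV plus a JSON mirror (same stem, .json suffix)."""
    path = Path(path)
    out = df[MANIFEST_COLUMNS]
    out.to_csv(path, index=False, lineterminator="\n")
    records = out.to_dict(orient="records")
    path.with_suffix(".json").write_text(
        json.dumps(records, indent=1) + "\n", encoding="utf-8"
    )


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    else:
        df = pd.read_csv(path, keep_default_na=False)
    for col in ("bladder", "urethra", "lvur", "rvur",
                "p_bladder", "p_urethra", "p_lvur", "p_rvur"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    _validate_manifest(df, path.parent, check_paths)
    return df
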