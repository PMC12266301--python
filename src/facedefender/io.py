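"""File formats: PNG images, 16-bit mask PNGs, landmark CSV + group
sidecar JSON, cohort CSV, rater tables and benchmark JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .diagnostics import EyeMeasurements, X_ASYM, Y_ASYM
from .geometry import LandmarkError, LandmarkSet

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "cohort_to_dataframe",
    "dataframe_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "read_rater_table",
]


def read_image(path) -> np.ndarray:
    """Read an RGB image (PNG or JPEG input; alpha discarded)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(img: np.ndarray, path) -> None:
    """Write a lossless 8-bit RGB PNG."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValueError("images are written as lossless PNG only")
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path, format="PNG")


def write_mask(mask: np.ndarray, path) -> None:
    """Persist an alpha mask as single-channel 16-bit PNG scaled to
    [0, 65535]."""
    arr = np.asarray(mask, dtype=float)
    scaled = np.rint(np.clip(arr, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(scaled).save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64)
    return arr / 65535.0


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".groups.json")


def write_landmarks(lm: LandmarkSet, csv_path, groups_path=None) -> None:
    """Landmark CSV (columns index,x,y) plus a JSON sidecar naming the
    group index lists and image size."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {"index": np.arange(len(lm.points)), "x": lm.points[:, 0], "y": lm.points[:, 1]}
    )
    df.to_csv(csv_path, index=False)
    sidecar = Path(groups_path) if groups_path else _sidecar_path(csv_path)
    meta = {
        "image_size": list(lm.image_size),
        "groups": {k: np.asarray(v).tolist() for k, v in lm.groups.items()},
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_landmarks(csv_path, groups_path=None) -> LandmarkSet:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("index", "x", "y"):
        if col not in df.columns:
            raise LandmarkError(f"landmark CSV missing column {col!r}")
    df = df.sort_values("index")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    sidecar = Path(groups_path) if groups_path else _sidecar_path(csv_path)
    if not sidecar.exists():
        raise LandmarkError(f"missing landmark group sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    groups = {k: np.asarray(v, dtype=int) for k, v in meta["groups"].items()}
    return LandmarkSet(pts, groups, tuple(meta["image_size"]))


def cohort_to_dataframe(
    cohort: Sequence[EyeMeasurements], labels: Sequence[dict] | None = None
) -> pd.DataFrame:
    df = pd.DataFrame([m.as_dict() for m in cohort])
    if labels is not None:
        df["label_left"] = [l["left"] for l in labels]
        df["label_right"] = [l["right"] for l in labels]
    return df


def dataframe_to_cohort(df: pd.DataFrame) -> list[EyeMeasurements]:
    measure_cols = [
        c for c in df.columns if c not in (X_ASYM, Y_ASYM, "label_left", "label_right")
    ]
    out = []
    for _, row in df.iterrows():
        out.append(
            EyeMeasurements(
                values={c: float(row[c]) for c in measure_cols},
                x_asymmetry=float(row[X_ASYM]),
                y_asymmetry=float(row[Y_ASYM]),
            )
        )
    return out


def write_cohort_csv(cohort, path, labels=None) -> None:
    cohort_to_dataframe(cohort, labels).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_rater_table(path) -> np.ndarray:
    """Square rater1×rater2 contingency table from CSV (first column may
    hold row labels)."""
    df = pd.read_csv(path)
    if df.shape[1] and not np.issubdtype(df.dtypes.iloc[0], np.number):
        df = df.set_index(df.columns[0])
    return df.to_numpy(dtype=float)
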