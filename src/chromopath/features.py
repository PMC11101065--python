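"""Per-image predictors: channel means, grayscale conversion, histogram entropy.

The unit record of the analysis is one whole-slide snapshot reduced to four
numbers: the arithmetic means of the red, green and blue channels (intensity
units, 0-255) and the Shannon entropy of the 256-bin grayscale histogram
(bits).  On H&E-stained tissue the eosin (pink) and hematoxylin (purple)
balance shifts these channel statistics between benign and malignant
morphology, and malignant slides show a more dispersed gray-level
distribution (higher entropy).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "FeatureVector",
    "to_grayscale",
    "channel_means",
    "gray_histogram",
    "gray_entropy",
    "image_features",
    "extract_features",
    "read_rgb_image",
]

#: ITU-R BT.601 luma weights; they sum to 1, so adding a constant to all
#: three channels shifts the gray level by that constant exactly.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class FeatureVector:
    """One image reduced to the model's predictors."""

    avg_r: float
    avg_g: float
    avg_b: float
    entropy: float
    image_id: str | None = None
    label: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.avg_r, self.avg_g, self.avg_b, self.entropy])


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an HxWx3 RGB array, got shape {arr.shape}"
        )
    if arr.shape[0] * arr.shape[1] == 0:
        raise ValueError("empty image: zero pixels")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"expected 8-bit integer pixels, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("pixel intensities must lie in [0, 255]")
    return arr


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB array to 8-bit gray via BT.601 luma.

    Per pixel: ``round(0.299 R + 0.587 G + 0.114 B)`` with round-half-away-
    from-zero, the convention of mainstream imaging libraries.  Output is
    uint8 in [0, 255].
    """
    arr = _validate_rgb(image).astype(np.float64)
    wr, wg, wb = LUMA_WEIGHTS
    luma = wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]
    # np.round is banker's rounding; floor(x+0.5) is half-away-from-zero
    # for the non-negative values a luma combination can take.
    return np.floor(luma + 0.5).astype(np.uint8)


def channel_means(image: np.ndarray) -> tuple[float, float, float]:
    """Exact arithmetic mean of each channel: avg_R, avg_G, avg_B."""
    arr = _validate_rgb(image)
    means = arr.reshape(-1, 3).mean(axis=0, dtype=np.float64)
    return float(means[0]), float(means[1]), float(means[2])


def gray_histogram(gray: np.ndarray) -> np.ndarray:
    """256-bin count histogram of an 8-bit gray image."""
    arr = np.asarray(gray)
    if arr.size == 0:
        raise ValueError("empty image: zero pixels")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"expected integer gray levels, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("gray levels must lie in [0, 255]")
    return np.bincount(arr.ravel().astype(np.int64), minlength=256)


def gray_entropy(gray: np.ndarray) -> float:
    """Shannon entropy (bits) of the gray-level histogram.

    H = -sum_i P_i log2 P_i over the 256 integer gray levels, with
    0*log(0) = 0; empty bins contribute nothing.  H lies in [0, 8], reaching
    8 only when all 256 levels are equifrequent.
    """
    counts = gray_histogram(gray)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def image_features(
    image: np.ndarray, image_id: str | None = None, label: str | None = None
) -> FeatureVector:
    """All four predictors of one RGB image."""
    r, g, b = channel_means(image)
    h = gray_entropy(to_grayscale(image))
    return FeatureVector(r, g, b, h, image_id=image_id, label=label)


def read_rgb_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit image file as an HxWx3 uint8 array.

    Palette and RGBA images are converted to RGB explicitly; 16-bit or
    floating-point inputs are rejected rather than silently rescaled.
    """
    with Image.open(path) as img:
        if img.mode in ("I", "I;16", "I;16B", "F"):
            raise ValueError(
                f"{path}: mode {img.mode!r} is not 8-bit; refusing to coerce"
            )
        if img.mode != "RGB":
            img = img.convert("RGB")
        return np.asarray(img, dtype=np.uint8)


def extract_features(
    manifest: pd.DataFrame,
    root: str | Path | None = None,
    gray_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Batch feature extraction over a manifest of image files.

    Parameters
    ----------
    manifest : DataFrame with columns ``image_id``, ``path`` and optionally
        ``label``.  Paths are resolved relative to *root* when given.
    gray_dir : if given, the grayscale conversion of each image is written
        there as PNG for audit.

    Returns
    -------
    (features, failures) : a FeatureTable DataFrame with columns
        ``image_id, label, avg_r, avg_g, avg_b, entropy`` (one row per
        successfully read manifest row, order preserved) and a list of
        row-level error records ``{"image_id", "path", "error"}``.
        Unreadable files are recorded and skipped; the batch continues.
    """
    required = {"image_id", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")

    gray_dir = Path(gray_dir) if gray_dir is not None else None
    if gray_dir is not None:
        gray_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    failures: list[dict] = []
    for rec in manifest.itertuples(index=False):
        path = Path(rec.path)
        if root is not None and not path.is_absolute():
            path = Path(root) / path
        try:
            arr = read_rgb_image(path)
            fv = image_features(arr)
        except (OSError, ValueError) as exc:
            failures.append(
                {"image_id": rec.image_id, "path": str(path), "error": str(exc)}
            )
            continue
        if gray_dir is not None:
            gray = to_grayscale(arr)
            Image.fromarray(gray, mode="L").save(
                gray_dir / f"{rec.image_id}_gray.png"
            )
        rows.append(
            {
                "image_id": rec.image_id,
                "label": getattr(rec, "label", None),
                "avg_r": fv.avg_r,
                "avg_g": fv.avg_g,
                "avg_b": fv.avg_b,
                "entropy": fv.entropy,
            }
        )
    columns = ["image_id", "label", "avg_r", "avg_g", "avg_b", "entropy"]
    return pd.DataFrame(rows, columns=columns), failures


def feature_matrix(table: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    """Numeric design matrix for the listed feature columns."""
    return table.loc[:, list(features)].to_numpy(dtype=np.float64)
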