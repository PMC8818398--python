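"""Grayscale image I/O, intensity histograms, and threshold-based labelling.

This module is the shared substrate of the two thresholding objectives: it
loads 8-bit (or rescaled 16-bit) grayscale rasters, computes normalized
intensity histograms, and turns a vector of k ordered thresholds into a
(k+1)-class label map and a binary vessel mask.

Class-boundary convention (used consistently everywhere in the package):
with thresholds t_1 < t_2 < ... < t_k, class 0 is the inclusive intensity
range [0, t_1], class j (1 <= j < k) is [t_j + 1, t_{j+1}], and class k is
[t_k + 1, L-1].  A pixel exactly equal to a threshold therefore joins the
*lower* class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

DEFAULT_LEVELS = 256

__all__ = [
    "DEFAULT_LEVELS",
    "Histogram",
    "read_gray_image",
    "compute_histogram",
    "as_thresholds",
    "apply_thresholds",
    "binarize_labels",
    "class_edges",
]


@dataclass(frozen=True)
class Histogram:
    """Per-gray-level pixel counts of an image with ``levels`` intensity bins.

    ``counts[i]`` is the number of pixels of intensity ``i``; ``normalized``
    is the relative frequency h(i) = counts[i] / N, which sums to 1.
    """

    counts: np.ndarray
    levels: int = field(default=DEFAULT_LEVELS)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.shape[0] != self.levels:
            raise ValueError(
                f"counts must be a 1-D array of length levels={self.levels}, "
                f"got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("histogram must contain at least one pixel")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        """Total pixel count N."""
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        """Relative frequencies h(i) = counts[i] / N (sum to 1)."""
        return self.counts / self.n


def read_gray_image(path: str | Path, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Load a raster image as a 2-D integer grayscale array in [0, levels-1].

    Multi-channel inputs are reduced by averaging the channels and rounding
    half up.  16-bit inputs requested at 256 levels are rescaled by
    ``floor(v / 257)`` (the exact 65535 -> 255 mapping).

    Raises
    ------
    IOError
        If the file cannot be read or decoded.
    ValueError
        If pixel values exceed ``levels - 1`` after conversion.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = np.floor(arr.astype(np.float64).mean(axis=2) + 0.5)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape} from {path}")

    arr = arr.astype(np.int64)
    if np.asarray(raw).dtype == np.uint16 and levels == 256:
        arr = arr // 257
    if arr.min() < 0 or arr.max() > levels - 1:
        raise ValueError(
            f"pixel values in {path} fall outside [0, {levels - 1}] "
            f"after conversion (range {arr.min()}..{arr.max()})"
        )
    return arr


def compute_histogram(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> Histogram:
    """Histogram of a grayscale image: counts f_i and frequencies h(i) = f_i/N."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must contain at least one pixel")
    flat = image.reshape(-1).astype(np.int64)
    if flat.min() < 0 or flat.max() > levels - 1:
        raise ValueError(f"pixel values outside [0, {levels - 1}]")
    counts = np.bincount(flat, minlength=levels)
    return Histogram(counts=counts, levels=levels)


def as_thresholds(values, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Validate a threshold vector: strictly increasing integers in [1, levels-2]."""
    th = np.asarray(values)
    if th.ndim != 1 or th.size < 1:
        raise ValueError("threshold vector must be 1-D with k >= 1")
    if not np.issubdtype(th.dtype, np.integer):
        rounded = np.rint(th)
        if not np.allclose(th, rounded):
            raise ValueError("thresholds must be integers")
        th = rounded
    th = th.astype(np.int64)
    if th.min() < 1 or th.max() > levels - 2:
        raise ValueError(f"thresholds must lie in [1, {levels - 2}], got {th.tolist()}")
    if (np.diff(th) <= 0).any():
        raise ValueError(f"thresholds must be strictly increasing, got {th.tolist()}")
    return th


def class_edges(thresholds: np.ndarray, levels: int = DEFAULT_LEVELS) -> list[tuple[int, int]]:
    """Inclusive intensity range (lo, hi) of each of the k+1 classes."""
    th = as_thresholds(thresholds, levels)
    bounds = [0, *[int(t) + 1 for t in th], levels]
    return [(bounds[j], bounds[j + 1] - 1) for j in range(len(th) + 1)]


def apply_thresholds(
    image: np.ndarray, thresholds, levels: int = DEFAULT_LEVELS
) -> np.ndarray:
    """Label each pixel with its class index under the k thresholds.

    A pixel of intensity v gets label c = #{ t_j : v > t_j }, i.e. a pixel
    equal to a threshold joins the lower class.
    """
    th = as_thresholds(thresholds, levels)
    image = np.asarray(image)
    return np.searchsorted(th, image.reshape(-1), side="left").reshape(image.shape)


def binarize_labels(
    labels: np.ndarray, k: int, vessel_labels=None
) -> np.ndarray:
    """Binary vessel mask from a label map.

    Default rule is "top-class": a pixel is vessel iff its label is k (the
    brightest class).  Pass an explicit iterable of class indices in
    ``vessel_labels`` to mark several classes as vessel.
    """
    labels = np.asarray(labels)
    if vessel_labels is None:
        vessel_labels = {int(k)}
    vessel_labels = set(int(v) for v in vessel_labels)
    if not vessel_labels:
        raise ValueError("vessel label set must not be empty")
    if any(v < 0 or v > k for v in vessel_labels):
        raise ValueError(f"vessel labels must lie in [0, {k}]")
    return np.isin(labels, sorted(vessel_labels))
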