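"""Synthetic vessel phantoms and histogram fixtures with exact ground truth.

Real photoacoustic vessel images are bright, roughly tubular absorbers on a
darker, noisy tissue background.  :func:`generate_phantom` emulates exactly
that structure at desk scale: each vessel is a smooth curvilinear centerline
(a bounded-turning random walk) dilated to a tube of random width, composited
at ``vessel_intensity`` over ``background_intensity``, with clipped additive
Gaussian noise.  The ground-truth mask is the exact pre-noise tube support,
so segmentation scores against it are free of annotation error.

:func:`sample_histogram` draws a histogram directly from a Gaussian mixture —
the multimodal shape both thresholding objectives assume — for tests whose
optimal thresholds are known from the mode layout.

Deliberately *not* modelled: light transport, limited-view reconstruction
artifacts, speckle, 3-D geometry.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .histogram import DEFAULT_LEVELS, Histogram

__all__ = ["PhantomConfig", "HistogramSpec", "generate_phantom", "sample_histogram", "write_phantom"]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the tube-phantom generator.

    ``curvature`` is the half-width (radians) of the uniform per-step turning
    angle of each vessel centerline; 0 gives straight vessels.
    """

    shape: tuple[int, int] = (64, 64)
    n_vessels: int = 3
    width_range: tuple[float, float] = (2.0, 5.0)
    vessel_intensity: int = 200
    background_intensity: int = 60
    noise_sigma: float = 20.0
    curvature: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise ValueError("need at least one vessel")
        if not (0 <= self.background_intensity < self.vessel_intensity <= 255):
            raise ValueError(
                "intensities must satisfy 0 <= background < vessel <= 255"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.width_range
        if not 0 < lo <= hi:
            raise ValueError("width_range must be 0 < min <= max")
        if hi >= min(self.shape):
            raise ValueError("vessel width must be smaller than the image extent")


def _centerline(
    rng: np.random.Generator, shape: tuple[int, int], curvature: float
) -> np.ndarray:
    """Boolean grid of one bounded-turning random-walk centerline.

    The walk starts on a random border pixel heading inward and advances in
    half-pixel steps until it leaves the image, so every vessel spans from
    one border into (usually across) the field.
    """
    rows, cols = shape
    side = int(rng.integers(4))
    if side == 0:  # top edge, heading down
        pos = np.array([0.0, float(rng.uniform(0, cols - 1))])
        angle = float(rng.uniform(np.pi / 4, 3 * np.pi / 4))
    elif side == 1:  # bottom edge, heading up
        pos = np.array([rows - 1.0, float(rng.uniform(0, cols - 1))])
        angle = float(rng.uniform(-3 * np.pi / 4, -np.pi / 4))
    elif side == 2:  # left edge, heading right
        pos = np.array([float(rng.uniform(0, rows - 1)), 0.0])
        angle = float(rng.uniform(-np.pi / 4, np.pi / 4))
    else:  # right edge, heading left
        pos = np.array([float(rng.uniform(0, rows - 1)), cols - 1.0])
        angle = float(rng.uniform(3 * np.pi / 4, 5 * np.pi / 4))

    grid = np.zeros(shape, dtype=bool)
    max_steps = 4 * (rows + cols)
    for _ in range(max_steps):
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < rows and 0 <= c < cols):
            break
        grid[r, c] = True
        angle += float(rng.uniform(-curvature, curvature))
        pos += 0.5 * np.array([np.sin(angle), np.cos(angle)])
    return grid


def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic-per-seed vessel phantom.

    Returns
    -------
    image : 2-D int array in [0, 255]
        Vessel tubes at ``vessel_intensity`` on ``background_intensity``,
        plus clipped Gaussian noise.
    mask : 2-D bool array
        Exact pre-noise tube support (True = vessel).
    """
    rng = np.random.default_rng(config.seed)
    mask = np.zeros(config.shape, dtype=bool)
    for _ in range(config.n_vessels):
        line = _centerline(rng, config.shape, config.curvature)
        width = float(rng.uniform(*config.width_range))
        if not line.any():  # pragma: no cover - walk always marks its start
            continue
        dist = ndimage.distance_transform_edt(~line)
        mask |= dist <= width / 2.0

    image = np.where(mask, config.vessel_intensity, config.background_intensity).astype(
        np.float64
    )
    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, size=config.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.int64)
    return image, mask


@dataclass(frozen=True)
class HistogramSpec:
    """Gaussian-mixture histogram: modes are (center, weight, spread) triples."""

    modes: tuple[tuple[float, float, float], ...] = ((60.0, 0.7, 10.0), (200.0, 0.3, 10.0))
    levels: int = DEFAULT_LEVELS
    n_samples: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        modes = tuple(tuple(float(x) for x in m) for m in self.modes)
        object.__setattr__(self, "modes", modes)
        weights = [w for _, w, _ in modes]
        if any(w <= 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mode weights must be positive and sum to 1")
        if any(not 0 <= c <= self.levels - 1 for c, _, _ in modes):
            raise ValueError(f"mode centers must lie in [0, {self.levels - 1}]")
        if any(s < 0 for _, _, s in modes):
            raise ValueError("mode spreads must be >= 0")


def sample_histogram(spec: HistogramSpec) -> Histogram:
    """Draw ``n_samples`` intensities from the mixture, clip, bin."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for _, w, _ in spec.modes])
    per_mode = rng.multinomial(spec.n_samples, weights)
    draws = []
    for (center, _, spread), count in zip(spec.modes, per_mode):
        if count == 0:
            continue
        draws.append(rng.normal(center, spread, size=count) if spread > 0 else np.full(count, center))
    values = np.clip(np.rint(np.concatenate(draws)), 0, spec.levels - 1).astype(np.int64)
    counts = np.bincount(values, minlength=spec.levels)
    return Histogram(counts=counts, levels=spec.levels)


def write_phantom(
    out_dir: str | Path, image: np.ndarray, mask: np.ndarray, config: PhantomConfig
) -> dict[str, Path]:
    """Write phantom PNG, 0/255 mask PNG, and a JSON sidecar echoing the config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / "phantom.png",
        "mask": out_dir / "mask.png",
        "config": out_dir / "phantom.json",
    }
    iio.imwrite(paths["image"], image.astype(np.uint8))
    iio.imwrite(paths["mask"], np.where(mask, 255, 0).astype(np.uint8))
    paths["config"].write_text(json.dumps(asdict(config), indent=2) + "\n")
    return paths
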