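"""Volume enhancement chain for speckle-dominated OCT intensity data.

The chain standardizes intensity against a reference histogram, stretches
contrast, stabilizes the Poisson speckle variance with a square-root
transform, sharpens organoid edges by unsharp masking, removes residual
noise with a cubic median filter, inverts the stabilization by squaring and
finally quantizes to 8 bits:

    normalize -> stretch -> sqrt -> unsharp -> median -> square -> uint8

Sharpening and median filtering act in the stabilized (approximately
Gaussian-noise) domain, which is the point of the square-root transform;
the squaring step undoes it after the last filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
from scipy import ndimage

from .volumes import RawVolume

logger = logging.getLogger("octrack.preprocess")


@dataclass
class PreprocessConfig:
    """Tunable parameters of the enhancement chain.

    p_norm
        Percentile used for reference-histogram intensity normalization.
    p_lo, p_hi
        Contrast-stretch percentiles; voxels below/above map to 0/1.
    b
        Unsharp weight in (0.5, 1]; the output is
        ``b/(2b-1) * V - (1-b)/(2b-1) * U`` with ``U`` a Gaussian blur.
        The default 2/3 gives the classical ``2V - U``.
    sigma
        Gaussian blur width in voxels.
    median_kernel
        Edge length of the cubic median-filter kernel (odd).
    """

    p_norm: float = 95.0
    p_lo: float = 1.0
    p_hi: float = 99.0
    b: float = 2.0 / 3.0
    sigma: float = 3.0
    median_kernel: int = 7

    def __post_init__(self) -> None:
        if not (0 < self.p_lo < self.p_hi <= 100):
            raise ValueError("need 0 < p_lo < p_hi <= 100")
        if not (0 < self.p_norm <= 100):
            raise ValueError("p_norm must be in (0, 100]")
        if not (0.5 < self.b <= 1.0):
            raise ValueError("b must lie in (0.5, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")


def histogram_percentile(counts: np.ndarray, p: float) -> int:
    """Smallest intensity at which the cumulative histogram mass exceeds
    p percent of the total (an intensity exactly at the boundary rounds up,
    so 100 voxels valued 0..99 give a 95th percentile of 95)."""
    counts = np.asarray(counts, dtype=np.int64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    cum = np.cumsum(counts)
    target = p / 100.0 * total
    return int(min(np.searchsorted(cum, target, side="right"), len(counts) - 1))


@dataclass
class ReferenceHistogram:
    """Summed luminance histogram of a set of reference (training) volumes.

    ``counts[i]`` is the number of voxels with integer intensity ``i``
    across all reference volumes; ``p95_ref`` is the ``p_norm``-th
    percentile of that summed histogram, used as the normalization anchor.
    """

    counts: np.ndarray
    p_norm: float = 95.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or np.any(self.counts < 0):
            raise ValueError("counts must be a 1-D non-negative array")

    @property
    def p95_ref(self) -> int:
        return histogram_percentile(self.counts, self.p_norm)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {"counts": self.counts.tolist(), "p_norm": self.p_norm, "p95_ref": self.p95_ref}
            )
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ReferenceHistogram":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["counts"], dtype=np.int64), float(d.get("p_norm", 95.0)))


def build_reference_histogram(
    volumes: Sequence[RawVolume], p_norm: float = 95.0
) -> ReferenceHistogram:
    """Sum the per-volume luminance histograms of integer-valued volumes."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one reference volume")
    counts: np.ndarray | None = None
    for vol in volumes:
        if not np.issubdtype(vol.data.dtype, np.integer):
            raise ValueError("reference volumes must have integer intensities")
        h = np.bincount(vol.data.ravel().astype(np.int64))
        if counts is None:
            counts = h
        else:
            n = max(len(counts), len(h))
            counts = np.pad(counts, (0, n - len(counts))) + np.pad(h, (0, n - len(h)))
    ref = ReferenceHistogram(counts, p_norm)
    logger.info("reference histogram from %d volumes, p%g = %d", len(volumes), p_norm, ref.p95_ref)
    return ref


def _volume_percentile(data: np.ndarray, p: float) -> float:
    """Percentile matching the histogram rule for integer data."""
    if np.issubdtype(data.dtype, np.integer):
        return float(histogram_percentile(np.bincount(data.ravel().astype(np.int64)), p))
    return float(np.quantile(data, p / 100.0))


def normalize_intensity(vol: RawVolume, ref: ReferenceHistogram) -> RawVolume:
    """Scale intensities so the volume's p_norm percentile hits the reference.

    Every voxel is multiplied by ``p95_ref / p95(vol)``; output intensities
    are real-valued.
    """
    p95 = _volume_percentile(vol.data, ref.p_norm)
    if p95 <= 0:
        raise ValueError("volume percentile is zero; cannot normalize an (almost) empty volume")
    scale = ref.p95_ref / p95
    logger.info("normalize: p%g=%g -> %d (scale %.4f)", ref.p_norm, p95, ref.p95_ref, scale)
    return vol.with_data(vol.data.astype(np.float64) * scale)


def stretch_contrast(vol: RawVolume, p_lo: float = 1.0, p_hi: float = 99.0) -> RawVolume:
    """Affine map sending the p_lo/p_hi percentiles to 0/1, clipped to [0, 1]."""
    lo = np.percentile(vol.data, p_lo)
    hi = np.percentile(vol.data, p_hi)
    if hi <= lo:
        raise ValueError(f"degenerate percentiles (p{p_lo}={lo}, p{p_hi}={hi})")
    out = (vol.data.astype(np.float64) - lo) / (hi - lo)
    return vol.with_data(np.clip(out, 0.0, 1.0))


def stabilize_variance(vol: RawVolume) -> RawVolume:
    """Square-root transform: Poisson-like noise becomes near-Gaussian with
    variance ~1/4, independent of the local mean."""
    if vol.data.min() < 0:
        raise ValueError("negative intensities cannot be square-rooted")
    return vol.with_data(np.sqrt(vol.data.astype(np.float64)))


def invert_stabilization(vol: RawVolume) -> RawVolume:
    """Elementwise square; exact inverse of :func:`stabilize_variance`."""
    if vol.data.min() < 0:
        raise ValueError("negative intensities are invalid in the stabilized domain")
    d = vol.data.astype(np.float64)
    return vol.with_data(d * d)


def gaussian_smooth(data: np.ndarray, sigma: float) -> np.ndarray:
    """Normalized discrete Gaussian, truncated at 4*sigma, reflective borders."""
    return ndimage.gaussian_filter(
        data.astype(np.float64), sigma=sigma, mode="reflect", truncate=4.0
    )


def unsharp_coefficients(b: float) -> tuple[float, float]:
    """Weights (on the volume, on its blur) of the unsharp combination."""
    if not (0.5 < b <= 1.0):
        raise ValueError("b must lie in (0.5, 1]")
    return b / (2 * b - 1), (1 - b) / (2 * b - 1)


def unsharp_sharpen(
    vol: RawVolume, b: float = 2.0 / 3.0, sigma: float = 3.0, clip: bool = True
) -> RawVolume:
    """Edge enhancement by subtracting a Gaussian-blurred copy.

    Output is ``a1*V - a2*U`` with ``(a1, a2) = (b/(2b-1), (1-b)/(2b-1))``;
    the coefficients satisfy ``a1 - a2 = 1`` so constants are fixed points.
    With the default ``b = 2/3`` this is ``2V - U``. When ``clip`` is true
    (unit-interval data) the result is clipped back to [0, 1].
    """
    a1, a2 = unsharp_coefficients(b)
    blurred = gaussian_smooth(vol.data, sigma)
    out = a1 * vol.data.astype(np.float64) - a2 * blurred
    # negative undershoot is always clipped: intensities must stay >= 0
    out = np.clip(out, 0.0, 1.0) if clip else np.maximum(out, 0.0)
    return vol.with_data(out)


def median_denoise(vol: RawVolume, kernel: int = 7) -> RawVolume:
    """Cubic median filter with reflective boundary handling."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 1")
    return vol.with_data(ndimage.median_filter(vol.data, size=kernel, mode="reflect"))


def to_uint8(data: np.ndarray) -> np.ndarray:
    """Scale [0, 1] to 0..255 with round-half-up quantization."""
    return np.clip(np.floor(data * 255.0 + 0.5), 0, 255).astype(np.uint8)


def preprocess_volume(
    vol: RawVolume, ref: ReferenceHistogram, config: PreprocessConfig | None = None
) -> RawVolume:
    """Run the full enhancement chain; returns an 8-bit volume.

    A constant (organoid-free, noise-free) volume has no contrast to
    stretch; such degenerate inputs yield an all-zero volume with a warning
    instead of failing mid-pipeline.
    """
    cfg = config or PreprocessConfig()
    logger.info("preprocess: shape=%s params=%s", vol.shape, cfg)
    v = normalize_intensity(vol, ref)
    try:
        v = stretch_contrast(v, cfg.p_lo, cfg.p_hi)
    except ValueError:
        logger.warning("constant volume: contrast stretch degenerate, returning zeros")
        return vol.with_data(np.zeros(vol.shape, dtype=np.uint8))
    v = stabilize_variance(v)
    v = unsharp_sharpen(v, cfg.b, cfg.sigma, clip=True)
    v = median_denoise(v, cfg.median_kernel)
    v = invert_stabilization(v)
    return vol.with_data(to_uint8(v.data))
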