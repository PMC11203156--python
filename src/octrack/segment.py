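"""Binary organoid masks: ingestion of external per-slice CNN predictions,
plus a classical baseline segmenter for self-contained testing.

The deep segmentation network itself is out of scope here; the module
boundary is the binary mask volume. `baseline_segment` is a deliberately
simple global-threshold stand-in (documented as a test harness, not a claim
of CNN-equivalent accuracy) so the downstream postprocessing and tracking
stages can be exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from skimage import filters, morphology

from .volumes import DEFAULT_SPACING, BinaryVolume, RawVolume, Spacing

logger = logging.getLogger("octrack.segment")


@dataclass
class SegmentConfig:
    """Baseline segmenter settings.

    threshold_mode is "otsu" or "percentile"; in percentile mode the
    threshold is the `threshold_percentile`-th intensity percentile.
    open_radius is the radius (voxels) of the ball used for morphological
    opening; 0 disables opening.
    """

    mode: str = "baseline"  # "baseline" | "ingest"
    threshold_mode: str = "otsu"
    threshold_percentile: float = 99.0
    open_radius: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("baseline", "ingest"):
            raise ValueError("mode must be 'baseline' or 'ingest'")
        if self.threshold_mode not in ("otsu", "percentile"):
            raise ValueError("threshold_mode must be 'otsu' or 'percentile'")
        if not (0 < self.threshold_percentile < 100):
            raise ValueError("threshold_percentile must lie in (0, 100)")
        if self.open_radius < 0:
            raise ValueError("open_radius must be >= 0")


def load_mask_volume(
    path: Union[str, Path],
    spacing: Spacing = DEFAULT_SPACING,
    expected_shape: Optional[Tuple[int, int, int]] = None,
    timepoint_day: Optional[int] = None,
) -> BinaryVolume:
    """Read a TIFF stack of {0, nonzero} slices as a boolean mask volume."""
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ValueError(f"mask shape {arr.shape} does not match declared geometry {expected_shape}")
    return BinaryVolume(arr != 0, spacing, timepoint_day)


def write_mask_volume(mask: BinaryVolume, path: Union[str, Path]) -> None:
    """Write a mask as an 8-bit TIFF stack with foreground = 255."""
    import tifffile

    tifffile.imwrite(str(path), mask.mask.astype(np.uint8) * 255, photometric="minisblack")


def baseline_segment(
    vol: RawVolume,
    threshold_mode: str = "otsu",
    open_radius: int = 1,
    threshold_percentile: float = 99.0,
) -> BinaryVolume:
    """Global threshold followed by morphological opening with a ball.

    Deterministic for a fixed input. In Otsu mode the threshold is floored
    at median + 6 * (1.4826 * MAD): Otsu always splits a histogram, even a
    unimodal object-free one, and the robust floor keeps an all-background
    volume from being segmented as half foreground while staying inert for
    volumes holding genuinely bright organoids (the median/MAD of the
    background are unaffected by sparse foreground). Otsu mode fails on
    constant volumes (no threshold separates one class).
    """
    data = vol.data
    if threshold_mode == "otsu":
        if data.max() == data.min():
            raise ValueError("Otsu threshold undefined on a constant volume")
        med = float(np.median(data))
        mad = float(np.median(np.abs(data.astype(np.float64) - med)))
        thr = max(float(filters.threshold_otsu(data.ravel())), med + 6.0 * 1.4826 * mad)
    elif threshold_mode == "percentile":
        thr = np.percentile(data, threshold_percentile)
    else:
        raise ValueError("threshold_mode must be 'otsu' or 'percentile'")
    fg = data > thr
    if open_radius > 0:
        fg = morphology.opening(fg, morphology.ball(open_radius))
    logger.info(
        "baseline_segment: mode=%s thr=%.4g foreground=%d voxels",
        threshold_mode,
        float(thr),
        int(fg.sum()),
    )
    return BinaryVolume(fg, vol.spacing, vol.timepoint_day)
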