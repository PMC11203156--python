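"""Mask postprocessing: connected-component labeling and the minimum-size
sphere filter.

Per-slice detections are stitched into 3-D objects by connected-component
labeling (26-neighbor adjacency by default, so diagonal contacts across
slices connect). Objects whose physical volume is below that of a reference
sphere of 25 um diameter — smaller than any plausible organoid at the
imaging resolution — are removed as noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .volumes import BinaryVolume, LabelVolume

logger = logging.getLogger("octrack.postprocess")

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # neighbor count -> skimage rank


@dataclass
class PostfilterConfig:
    min_diameter: float = 25.0  # um
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.min_diameter <= 0:
            raise ValueError("min_diameter must be positive")
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError("connectivity must be one of 6, 18, 26")


def reference_sphere_volume(diameter: float) -> float:
    """Volume (um^3) of a sphere with the given diameter: (pi/6) d^3."""
    return math.pi / 6.0 * diameter**3


def label_components(mask: BinaryVolume, connectivity: int = 26) -> LabelVolume:
    """Label maximal connected foreground components 1..K.

    Labels are assigned deterministically in order of each component's
    first-encountered voxel in (z, y, x) scan order.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    lab = measure.label(mask.mask, connectivity=_CONNECTIVITY[connectivity])
    # enforce scan-order label numbering regardless of the labeling backend
    flat = lab.ravel()
    fg = np.flatnonzero(flat)
    if fg.size:
        first = {}
        old = flat[fg]
        for pos, l in zip(fg.tolist(), old.tolist()):
            if l not in first:
                first[l] = pos
        order = sorted(first, key=first.get)
        remap = np.zeros(lab.max() + 1, dtype=lab.dtype)
        for new, l in enumerate(order, start=1):
            remap[l] = new
        lab = remap[lab]
    n = int(lab.max())
    logger.info("label_components: %d components (connectivity %d)", n, connectivity)
    return LabelVolume(lab, mask.spacing, mask.timepoint_day)


def min_volume_filter(labels: LabelVolume, config: PostfilterConfig | None = None) -> LabelVolume:
    """Remove components whose physical volume is below the reference sphere.

    A component's volume is its voxel count times the voxel volume; it is
    removed iff strictly smaller than (pi/6) * min_diameter^3 (a component
    exactly at the threshold survives). Surviving components keep their
    labels.
    """
    cfg = config or PostfilterConfig()
    threshold = reference_sphere_volume(cfg.min_diameter)
    voxvol = labels.voxel_volume
    counts = np.bincount(labels.labels.ravel())
    small = np.flatnonzero(counts * voxvol < threshold)
    small = small[small > 0]
    out = labels.labels.copy()
    if small.size:
        out[np.isin(out, small)] = 0
    kept = np.unique(out).size - (1 if (out == 0).any() else 0)
    logger.info(
        "min_volume_filter: threshold %.2f um^3 (%d voxels at %.2f um^3/voxel); removed %d, kept %d",
        threshold,
        int(math.floor(threshold / voxvol)),
        voxvol,
        small.size,
        kept,
    )
    return LabelVolume(out, labels.spacing, labels.timepoint_day)
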