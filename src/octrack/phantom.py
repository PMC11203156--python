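"""Synthetic OCT-like time series with known organoid trajectories.

The phantom emulates the features the pipeline depends on: a Poisson
speckle background, brighter quasi-spherical organoids growing over ~7
timepoints at 2-day intervals, a small rigid misregistration between
timepoints, and optional fusion events. Each organoid's voxel set on a
given day is the ``n`` grid voxels nearest its (drifted) center, with ``n``
chosen so the voxelized volume matches the analytic growth schedule to
within half a voxel — so ground-truth volumes follow the programmed growth
law almost exactly and tracking/growth analytics can be validated against
it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .volumes import DEFAULT_SPACING, LabelVolume, RawVolume, Spacing

logger = logging.getLogger("octrack.phantom")


@dataclass
class PhantomConfig:
    """Study conditions of the synthetic time series.

    shape, spacing
        Grid size in voxels and (dz, dy, dx) in um; the default grid is a
        desk-scale stand-in for a full acquisition, with the acquisition's
        voxel spacing.
    days
        Imaging days (2-day intervals over ~13 days by default).
    diameter_range
        Initial organoid diameters in um, sampled uniformly.
    growth_rate
        Volume-linear growth in um^3/day ("volume_linear" mode) or the
        daily radial multiplication factor ("radial_factor" mode).
    drift_per_day
        Magnitude of the rigid inter-timepoint misregistration, in um per
        day; the shift between consecutive timepoints is this times the day
        gap, in a seeded random direction.
    lambda_bg, lambda_org
        Poisson intensity means of background speckle and organoid
        interiors (lambda_org > lambda_bg).
    fusion
        When true, organoids whose voxel sets come to overlap merge into
        the lower id from that day on (label merging only).
    """

    shape: Tuple[int, int, int] = (96, 160, 160)
    spacing: Spacing = DEFAULT_SPACING
    n_organoids: int = 10
    days: Tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13)
    diameter_range: Tuple[float, float] = (30.0, 45.0)
    growth_mode: str = "volume_linear"
    growth_rate: float = 1500.0
    drift_per_day: float = 5.0
    lambda_bg: float = 20.0
    lambda_org: float = 80.0
    fusion: bool = False
    min_separation: float = 5.0  # extra clearance between organoid surfaces, um
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.days = tuple(int(d) for d in self.days)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.diameter_range = tuple(float(d) for d in self.diameter_range)
        if not (self.lambda_org > self.lambda_bg >= 0):
            raise ValueError("need lambda_org > lambda_bg >= 0")
        if min(self.diameter_range) <= 0 or self.diameter_range[0] > self.diameter_range[1]:
            raise ValueError("diameter_range must be positive and ordered")
        if self.drift_per_day < 0:
            raise ValueError("drift_per_day must be >= 0")
        if self.growth_mode not in ("volume_linear", "radial_factor"):
            raise ValueError("growth_mode must be 'volume_linear' or 'radial_factor'")
        if self.n_organoids < 0:
            raise ValueError("n_organoids must be >= 0")
        if len(self.days) < 1 or list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")


@dataclass
class SyntheticTimeSeries:
    """Volumes, ground-truth labels, trajectories and events of one scene."""

    volumes: Dict[int, RawVolume]
    labels: Dict[int, LabelVolume]
    trajectories: pd.DataFrame  # id, day, centroid_z, centroid_y, centroid_x, volume_um3
    events: List[dict]
    config: PhantomConfig


def simulate_speckle(
    shape: Tuple[int, int, int],
    lam: float,
    seed: int,
    spacing: Spacing = DEFAULT_SPACING,
) -> RawVolume:
    """Independent Poisson(lam) intensities on the grid."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    rng = np.random.default_rng(seed)
    return RawVolume(rng.poisson(lam, size=shape).astype(np.uint16), spacing)


def _volume_schedule(cfg: PhantomConfig, v0: float, day: int) -> float:
    dt = day - cfg.days[0]
    if cfg.growth_mode == "volume_linear":
        return v0 + cfg.growth_rate * dt
    r0 = (3.0 * v0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    r = r0 * cfg.growth_rate**dt
    return 4.0 / 3.0 * math.pi * r**3


def _nearest_voxels(
    center: np.ndarray, n: int, shape: Tuple[int, int, int], spacing: Spacing
) -> np.ndarray:
    """Flat indices of the n voxel centers nearest a physical point."""
    spacing = np.asarray(spacing)
    # generous bounding box: radius of a ball holding n voxels, plus margin
    voxvol = float(np.prod(spacing))
    r = (3.0 * n * voxvol / (4.0 * math.pi)) ** (1.0 / 3.0) + 2.0 * spacing.max()
    lo = np.maximum(np.floor((center - r) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + r) / spacing).astype(int) + 1, np.asarray(shape))
    axes = [np.arange(lo[a], hi[a]) for a in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    d2 = ((coords * spacing - center) ** 2).sum(axis=1)
    if coords.shape[0] < n:
        raise ValueError("organoid does not fit inside the grid")
    flat = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), shape)
    order = np.lexsort((flat, d2))[:n]
    return np.sort(flat[order])


def generate_scene(cfg: PhantomConfig) -> SyntheticTimeSeries:
    """Deterministically generate one synthetic time series from its seed.

    Organoids are placed by rejection sampling with enough clearance that,
    without fusion, they never overlap over the whole growth schedule; with
    fusion enabled the clearance covers only the initial day, so growth may
    merge neighbors (merged into the lower id, logged as an event).
    """
    rng = np.random.default_rng(cfg.seed)
    spacing = np.asarray(cfg.spacing)
    extent = (np.asarray(cfg.shape) - 1) * spacing
    voxvol = float(np.prod(spacing))
    t0, t_end = cfg.days[0], cfg.days[-1]

    # cumulative rigid drift per day (random direction per step)
    shifts = {t0: np.zeros(3)}
    acc = np.zeros(3)
    for d_prev, d_next in zip(cfg.days, cfg.days[1:]):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        acc = acc + direction * cfg.drift_per_day * (d_next - d_prev)
        shifts[d_next] = acc.copy()
    max_shift = max(float(np.abs(s).max()) for s in shifts.values())

    # initial sizes and final radii (for clearance)
    d0 = rng.uniform(*cfg.diameter_range, size=cfg.n_organoids)
    v0 = math.pi / 6.0 * d0**3
    r_final = np.array(
        [(3.0 * _volume_schedule(cfg, v, t_end) / (4.0 * math.pi)) ** (1 / 3) for v in v0]
    )
    r_init = d0 / 2.0
    r_clear = r_init if cfg.fusion else r_final

    centers0 = np.zeros((cfg.n_organoids, 3))
    margin = r_final + max_shift + 2.0 * spacing.max()
    for i in range(cfg.n_organoids):
        lo = margin[i]
        hi = extent - margin[i]
        if np.any(hi <= lo):
            raise ValueError("grid too small for the requested organoids")
        ok = False
        for _ in range(10000):
            c = rng.uniform(lo, hi)
            if all(
                np.linalg.norm(c - centers0[j]) >= r_clear[i] + r_clear[j] + cfg.min_separation
                for j in range(i)
            ):
                ok = True
                break
        if not ok:
            raise ValueError("could not place organoids without overlap; enlarge the grid")
        centers0[i] = c

    volumes: Dict[int, RawVolume] = {}
    labels: Dict[int, LabelVolume] = {}
    events: List[dict] = [
        {"type": "birth", "id": i + 1, "day": t0} for i in range(cfg.n_organoids)
    ]
    merged_into: Dict[int, int] = {}  # id -> surviving lower id
    rows = []
    for day in cfg.days:
        vox_of: Dict[int, np.ndarray] = {}
        for i in range(cfg.n_organoids):
            oid = i + 1
            if oid in merged_into:
                continue
            v_t = _volume_schedule(cfg, v0[i], day)
            n_t = max(1, round(v_t / voxvol))
            center = centers0[i] + shifts[day]
            vox_of[oid] = _nearest_voxels(center, n_t, cfg.shape, spacing)
        if cfg.fusion:
            ids = sorted(vox_of)
            changed = True
            while changed:
                changed = False
                ids = sorted(vox_of)
                for a in ids:
                    for b in ids:
                        if b <= a or a not in vox_of or b not in vox_of:
                            continue
                        if np.intersect1d(vox_of[a], vox_of[b], assume_unique=True).size:
                            vox_of[a] = np.union1d(vox_of[a], vox_of[b])
                            del vox_of[b]
                            merged_into[b] = a
                            events.append({"type": "fusion", "day": int(day), "into": a, "from": b})
                            changed = True
        lab = np.zeros(cfg.shape, dtype=np.int32)
        for oid, vox in sorted(vox_of.items()):
            lab.ravel()[vox] = oid
        vol = rng.poisson(cfg.lambda_bg, size=cfg.shape).astype(np.uint16)
        fg = np.flatnonzero(lab.ravel())
        vol.ravel()[fg] = rng.poisson(cfg.lambda_org, size=fg.size)
        volumes[day] = RawVolume(vol, cfg.spacing, timepoint_day=int(day))
        labels[day] = LabelVolume(lab, cfg.spacing, timepoint_day=int(day))
        for oid, vox in sorted(vox_of.items()):
            coords = np.column_stack(np.unravel_index(vox, cfg.shape)) * spacing
            cz, cy, cx = coords.mean(axis=0)
            rows.append(
                {
                    "id": oid,
                    "label": oid,  # ground-truth label volumes use the persistent id
                    "day": int(day),
                    "centroid_z": float(cz),
                    "centroid_y": float(cy),
                    "centroid_x": float(cx),
                    "volume_um3": float(vox.size * voxvol),
                }
            )
    traj = pd.DataFrame(
        rows,
        columns=["id", "label", "day", "centroid_z", "centroid_y", "centroid_x", "volume_um3"],
    )
    logger.info(
        "phantom: %d organoids, %d days, grid %s, %d fusion events",
        cfg.n_organoids,
        len(cfg.days),
        cfg.shape,
        sum(1 for e in events if e["type"] == "fusion"),
    )
    return SyntheticTimeSeries(
        volumes=volumes, labels=labels, trajectories=traj, events=events, config=cfg
    )
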