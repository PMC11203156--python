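"""Reading and writing volumes, label stacks, masks and track tables.

TIFF stacks (multi-page, or a directory of equally sized 2-D slice images)
are the interchange format for volumes; tables are CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .features import OrganoidRecord
from .tracking import TrackSet
from .volumes import AXIS_NAMES, DEFAULT_SPACING, LabelVolume, RawVolume, Spacing

logger = logging.getLogger("octrack.io")

_TIFF_SUFFIXES = {".tif", ".tiff"}

TRACK_TABLE_COLUMNS = [
    "track_id",
    "day",
    "label",
    "centroid_z",
    "centroid_y",
    "centroid_x",
    "volume_um3",
    "match_probability",
]


def _read_slice(path: Path) -> np.ndarray:
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"slice {path.name} is not a 2-D image (shape {arr.shape})")
    return arr


def read_volume(
    path: Union[str, Path],
    spacing: Spacing = DEFAULT_SPACING,
    timepoint_day: Optional[int] = None,
) -> RawVolume:
    """Read a multi-page TIFF, or a directory of slice images sorted by name.

    Slices are ordered by page index (TIFF stack) or by filename
    (directory); integer intensities are preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        names = sorted(p for p in path.iterdir() if p.is_file())
        if not names:
            raise ValueError(f"directory {path} holds no slice images")
        slices = [_read_slice(p) for p in names]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(slices)
    else:
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
    logger.info("read volume %s: shape %s dtype %s", path, data.shape, data.dtype)
    return RawVolume(data, spacing, timepoint_day)


def write_volume(vol: RawVolume, path: Union[str, Path]) -> None:
    """Write the volume as a multi-page TIFF, dtype preserved."""
    tifffile.imwrite(str(path), np.asarray(vol.data), photometric="minisblack")


def read_label_volume(
    path: Union[str, Path],
    spacing: Spacing = DEFAULT_SPACING,
    timepoint_day: Optional[int] = None,
) -> LabelVolume:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelVolume(arr.astype(np.int32), spacing, timepoint_day)


def write_label_volume(labels: LabelVolume, path: Union[str, Path]) -> None:
    """Write labels as a 16-bit TIFF stack."""
    if labels.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed the 16-bit range")
    tifffile.imwrite(str(path), labels.labels.astype(np.uint16), photometric="minisblack")


def render_mip(vol: RawVolume, axis: str = "z") -> np.ndarray:
    """Maximum intensity projection along a named axis ('z', 'y' or 'x')."""
    if axis not in AXIS_NAMES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(AXIS_NAMES)}")
    return np.asarray(vol.data).max(axis=AXIS_NAMES[axis])


def write_track_table(
    tracks: TrackSet,
    records_by_day: Mapping[int, Sequence[OrganoidRecord]],
    path: Union[str, Path],
) -> None:
    """CSV with one row per (track, timepoint) observation.

    Centroids and volumes are looked up from the per-day records the
    tracker consumed.
    """
    rec_of = {(day, r.label): r for day, recs in records_by_day.items() for r in recs}
    rows = []
    for tid in sorted(tracks.tracks):
        for o in sorted(tracks.tracks[tid], key=lambda o: o.day):
            r = rec_of.get((o.day, o.label))
            rows.append(
                {
                    "track_id": tid,
                    "day": o.day,
                    "label": o.label,
                    "centroid_z": r.centroid[0] if r else np.nan,
                    "centroid_y": r.centroid[1] if r else np.nan,
                    "centroid_x": r.centroid[2] if r else np.nan,
                    "volume_um3": r.volume if r else np.nan,
                    "match_probability": o.p,
                }
            )
    pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS).to_csv(path, index=False)
    logger.info("wrote %d track rows to %s", len(rows), path)


def read_track_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns {sorted(missing)}")
    return df
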