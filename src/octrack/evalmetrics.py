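"""Segmentation metrics, tracking-quality metrics against known
trajectories, and growth-curve analytics.

Segmentation scores are voxel-pooled per volume (Dice, accuracy,
sensitivity, precision from the confusion counts). Tracking quality is
judged at the level of links — a link is the assertion that a label on day
t and a label on day t+1 are the same organoid — after mapping detected
labels to ground-truth identities by majority voxel overlap. The growth
curve reports the per-day mean and standard error of tracked organoid
volumes in mm^3 and the least-squares slope of mean volume versus day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import OrganoidRecord
from .tracking import TrackSet
from .volumes import BinaryVolume, LabelVolume

logger = logging.getLogger("octrack.evalmetrics")

UM3_PER_MM3 = 1e9


@dataclass
class SegScores:
    dice: float
    accuracy: float
    sensitivity: float
    precision: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "dice": self.dice,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
        }


def _safe_ratio(num: float, den: float, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def segmentation_metrics(pred: BinaryVolume, gt: BinaryVolume) -> SegScores:
    """Voxel-confusion scores between a predicted and a reference mask."""
    if pred.shape != gt.shape:
        raise ValueError(f"geometry mismatch: {pred.shape} vs {gt.shape}")
    p = pred.mask
    g = gt.mask
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    both_empty = (tp + fp == 0) and (tp + fn == 0)
    return SegScores(
        dice=_safe_ratio(2 * tp, 2 * tp + fp + fn, both_empty),
        accuracy=(tp + tn) / p.size,
        sensitivity=_safe_ratio(tp, tp + fn, both_empty),
        precision=_safe_ratio(tp, tp + fp, both_empty),
    )


def map_labels_to_truth(
    found: Mapping[int, LabelVolume], truth: Mapping[int, LabelVolume]
) -> Dict[Tuple[int, int], int]:
    """Map (day, detected label) -> ground-truth id by majority voxel overlap.

    A detected label maps to the truth id covering the largest share of its
    voxels; labels whose majority overlap is background are unmapped.
    """
    mapping: Dict[Tuple[int, int], int] = {}
    for day, lv in found.items():
        if day not in truth:
            raise ValueError(f"day {day} missing from ground truth")
        det = lv.labels.ravel()
        tru = truth[day].labels.ravel()
        if det.shape != tru.shape:
            raise ValueError("label volumes disagree in shape")
        fg = np.flatnonzero(det)
        if fg.size == 0:
            continue
        pairs = det[fg].astype(np.int64) * (int(tru.max()) + 1) + tru[fg].astype(np.int64)
        uniq, counts = np.unique(pairs, return_counts=True)
        base = int(tru.max()) + 1
        per_label: Dict[int, Tuple[int, int]] = {}
        for code, c in zip(uniq.tolist(), counts.tolist()):
            lab, tid = divmod(code, base)
            best = per_label.get(lab)
            if best is None or c > best[0]:
                per_label[lab] = (c, tid)
        for lab, (_, tid) in per_label.items():
            if tid > 0:
                mapping[(day, lab)] = tid
    return mapping


def tracking_metrics(
    found: TrackSet,
    truth: pd.DataFrame,
    label_map: Optional[Mapping[Tuple[int, int], int]] = None,
) -> Dict[str, float]:
    """Link precision/recall, full-track recall, and the fraction of
    reference-day organoids tracked across the entire series.

    `truth` needs columns (id, day, label) with persistent ids per day.
    When `label_map` is omitted, detected labels are matched to truth ids
    through the truth table's own (day, label) pairs — appropriate when
    tracking was run on the ground-truth label volumes themselves.
    """
    if not {"id", "day", "label"} <= set(truth.columns):
        raise ValueError("truth table needs columns id, day, label")
    if label_map is None:
        label_map = {
            (int(r.day), int(r.label)): int(r.id) for r in truth.itertuples(index=False)
        }
    truth_days = sorted(truth["day"].unique().tolist())
    found_days = sorted({o.day for obs in found.tracks.values() for o in obs})
    if not set(found_days) <= set(truth_days):
        raise ValueError("found tracks contain days absent from the truth table")

    truth_links = set()
    truth_ids = sorted(truth["id"].unique().tolist())
    days_of_id: Dict[int, List[int]] = {}
    for tid in truth_ids:
        ds = sorted(truth.loc[truth["id"] == tid, "day"].tolist())
        days_of_id[tid] = ds
        for d1, d2 in zip(ds, ds[1:]):
            truth_links.add((tid, d1, d2))

    found_links: List[Tuple[Optional[int], int, int]] = []
    links_of_track: Dict[int, set] = {}
    for fid, obs in found.tracks.items():
        obs = sorted(obs, key=lambda o: o.day)
        links = set()
        for a, b in zip(obs, obs[1:]):
            t1 = label_map.get((a.day, a.label))
            t2 = label_map.get((b.day, b.label))
            tid = t1 if (t1 is not None and t1 == t2) else None
            found_links.append((tid, a.day, b.day))
            if tid is not None and (tid, a.day, b.day) in truth_links:
                links.add((tid, a.day, b.day))
        links_of_track[fid] = links

    correct = [l for l in found_links if l[0] is not None and l in truth_links]
    link_precision = len(correct) / len(found_links) if found_links else 1.0
    recovered = set(correct)
    link_recall = len(recovered) / len(truth_links) if truth_links else 1.0

    full = 0
    for tid in truth_ids:
        need = {(tid, d1, d2) for d1, d2 in zip(days_of_id[tid], days_of_id[tid][1:])}
        if need and any(need <= links for links in links_of_track.values()):
            full += 1
        elif not need:  # single-day trajectory: found iff some track observes it
            if any(
                label_map.get((o.day, o.label)) == tid
                for obs in found.tracks.values()
                for o in obs
            ):
                full += 1
    full_track_recall = full / len(truth_ids) if truth_ids else 1.0

    ref_tracks = [
        obs for obs in found.tracks.values() if found.reference_day in {o.day for o in obs}
    ]
    spanning = [obs for obs in ref_tracks if {o.day for o in obs} >= set(truth_days)]
    frac_ref = len(spanning) / len(ref_tracks) if ref_tracks else 0.0

    report = {
        "link_precision": link_precision,
        "link_recall": link_recall,
        "full_track_recall": full_track_recall,
        "fraction_reference_tracked": frac_ref,
        "n_found_tracks": float(len(found.tracks)),
        "n_truth_tracks": float(len(truth_ids)),
    }
    logger.info("tracking metrics: %s", report)
    return report


@dataclass
class GrowthCurve:
    """Per-day mean tracked organoid volume (mm^3) and its linear trend."""

    table: pd.DataFrame  # columns: day, mean_volume_mm3, sem_mm3, n
    rate: float  # least-squares slope, mm^3/day


def growth_curve(
    tracks: TrackSet,
    records_by_day: Mapping[int, Sequence[OrganoidRecord]],
) -> GrowthCurve:
    """Mean tracked volume per day with standard errors, and its slope."""
    vol_of: Dict[Tuple[int, int], float] = {
        (day, r.label): r.volume for day, recs in records_by_day.items() for r in recs
    }
    per_day: Dict[int, List[float]] = {}
    for obs in tracks.tracks.values():
        for o in obs:
            v = vol_of.get((o.day, o.label))
            if v is not None:
                per_day.setdefault(o.day, []).append(v / UM3_PER_MM3)
    days = sorted(per_day)
    if len(days) < 2:
        raise ValueError("growth curve needs tracked organoids on at least two days")
    rows = []
    for d in days:
        vols = np.asarray(per_day[d])
        sem = float(vols.std(ddof=1) / np.sqrt(vols.size)) if vols.size > 1 else 0.0
        rows.append(
            {"day": d, "mean_volume_mm3": float(vols.mean()), "sem_mm3": sem, "n": vols.size}
        )
    table = pd.DataFrame(rows)
    rate = float(np.polyfit(table["day"], table["mean_volume_mm3"], 1)[0])
    logger.info("growth rate %.4g mm^3/day over %d days", rate, len(days))
    return GrowthCurve(table=table, rate=rate)
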