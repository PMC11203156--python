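"""Dual-branch probabilistic multi-timepoint tracking.

A reference timepoint anchors the series and splits it into an ascending
branch (forward in time) and a descending branch (backward). At each step,
candidate pairs between the current reference records and the evaluation
day are hard-gated on centroid displacement and on biologically implausible
volume change (shrinkage beyond tolerance when ascending, growth beyond
tolerance when descending). Surviving pairs receive a composite similarity
score

    S = w_c (1 - D_c) + w_v (1 - D_v) + w_p (1 - D_p) + w_iou * IoU

with D_c the centroid distance scaled by the gate radius and clipped at 1,
D_v the volume difference relative to the larger volume, D_p the mean
absolute shape-descriptor difference, all in [0, 1]. The match probability
is the logistic transform P = 1 / (1 + exp(-S)); gated pairs get P = 0.
Matches are drawn greedily from the probability matrix (global maximum
above the acceptance threshold, then exclusion of its row and column), so
assignment is injective both ways. Matched evaluation records become the
references for the next step; unmatched evaluation records found mid-branch
start new tracks extended only in that branch's direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .features import OrganoidRecord, iou as voxel_iou

logger = logging.getLogger("octrack.tracking")

ASCENDING = "ascending"
DESCENDING = "descending"


@dataclass
class MatchConfig:
    """Weights, gates and thresholds of the matcher.

    w_c, w_v, w_p, w_iou
        Relative importance (each in [0, 1]) of centroid, volume, shape and
        IoU similarity in the composite score. Defaults follow the tuned
        configuration 0.9 / 0.6 / 0 / 1; shape similarity is off by default
        but supported.
    theta_c
        Centroid gate in um; candidate pairs farther apart are excluded
        outright. Sensible values span roughly 20-40 um.
    vol_tol
        Fractional volume-oscillation tolerance (roughly 0.05-0.15):
        ascending, a decrease beyond it gates the pair; descending, an
        increase beyond it does.
    p_min
        Acceptance threshold on the match probability.
    reference_day
        Anchor day of the dual-branch analysis, or "auto" to choose it by
        the tuning objective.
    """

    w_c: float = 0.9
    w_v: float = 0.6
    w_p: float = 0.0
    w_iou: float = 1.0
    theta_c: float = 30.0
    vol_tol: float = 0.10
    p_min: float = 0.5
    reference_day: Union[int, str] = "auto"

    def __post_init__(self) -> None:
        for name in ("w_c", "w_v", "w_p", "w_iou"):
            w = getattr(self, name)
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.theta_c <= 0:
            raise ValueError("theta_c must be positive")
        if not (0.0 < self.vol_tol < 1.0):
            raise ValueError("vol_tol must be in (0, 1)")
        if not (0.0 < self.p_min < 1.0):
            raise ValueError("p_min must be in (0, 1)")
        if self.reference_day != "auto" and not isinstance(self.reference_day, int):
            raise ValueError("reference_day must be an int or 'auto'")


@dataclass
class MatchScore:
    """Decomposition of one candidate pairing."""

    d_c: float
    d_v: float
    d_p: float
    iou: float
    s: float
    p: float
    gated: bool


@dataclass
class Observation:
    day: int
    label: int
    p: float  # probability of the link that added this observation (1 for seeds)
    seed: bool = False  # True for the observation that started the track


@dataclass
class TrackSet:
    """Global organoid identities mapped to per-timepoint observations."""

    tracks: Dict[int, List[Observation]] = field(default_factory=dict)
    reference_day: int = 0

    def days(self, track_id: int) -> List[int]:
        return [o.day for o in self.tracks[track_id]]

    def spanning(self, all_days: Sequence[int]) -> List[int]:
        """Track ids observed on every day of the series."""
        need = set(all_days)
        return [tid for tid, obs in self.tracks.items() if {o.day for o in obs} >= need]

    def n_tracks(self) -> int:
        return len(self.tracks)

    def link_probabilities(self) -> List[float]:
        """Probabilities of matcher-created links (seed observations excluded)."""
        return [o.p for obs in self.tracks.values() for o in obs if not o.seed]


def centroid_distance(a: OrganoidRecord, b: OrganoidRecord) -> float:
    return float(np.linalg.norm(np.subtract(a.centroid, b.centroid)))


def gate(ref: OrganoidRecord, ev: OrganoidRecord, branch: str, cfg: MatchConfig) -> bool:
    """True iff the pair is excluded before scoring.

    Exclusion triggers on centroid distance beyond theta_c, or on a volume
    decrease beyond tolerance in the ascending branch (any increase is
    expected growth), or symmetrically an increase beyond tolerance in the
    descending branch.
    """
    if ref.day is not None and ref.day == ev.day:
        raise ValueError("gate expects records from distinct days")
    if branch not in (ASCENDING, DESCENDING):
        raise ValueError(f"unknown branch {branch!r}")
    if centroid_distance(ref, ev) > cfg.theta_c:
        return True
    if branch == ASCENDING and ev.volume < ref.volume * (1.0 - cfg.vol_tol):
        return True
    if branch == DESCENDING and ev.volume > ref.volume * (1.0 + cfg.vol_tol):
        return True
    return False


def match_score(
    ref: OrganoidRecord,
    ev: OrganoidRecord,
    cfg: MatchConfig,
    branch: str = ASCENDING,
) -> MatchScore:
    """Composite similarity score and logistic match probability."""
    gated = gate(ref, ev, branch, cfg)
    dist = centroid_distance(ref, ev)
    d_c = min(dist / cfg.theta_c, 1.0)
    d_v = abs(ev.volume - ref.volume) / max(ev.volume, ref.volume)
    d_p = float(np.abs(np.asarray(ref.shape) - np.asarray(ev.shape)).mean())
    ov = voxel_iou(ref, ev)
    s = (
        cfg.w_c * (1.0 - d_c)
        + cfg.w_v * (1.0 - d_v)
        + cfg.w_p * (1.0 - d_p)
        + cfg.w_iou * ov
    )
    p = 0.0 if gated else 1.0 / (1.0 + math.exp(-s))
    return MatchScore(d_c=d_c, d_v=d_v, d_p=d_p, iou=ov, s=s, p=p, gated=gated)


def build_probability_matrix(
    refs: Sequence[OrganoidRecord],
    evals: Sequence[OrganoidRecord],
    branch: str,
    cfg: MatchConfig,
) -> np.ndarray:
    """Matrix of match probabilities, shape (len(refs), len(evals))."""
    mat = np.zeros((len(refs), len(evals)), dtype=np.float64)
    for i, r in enumerate(refs):
        for j, e in enumerate(evals):
            mat[i, j] = match_score(r, e, cfg, branch).p
    return mat


def assign_matches(matrix: np.ndarray, p_min: float = 0.5) -> List[Tuple[int, int, float]]:
    """Greedy exclusive assignment from a probability matrix.

    Repeatedly selects the global maximum entry strictly above p_min,
    records the pair, and zeroes its row and column, so each reference and
    evaluation record is used at most once. Ties resolve to the smallest
    (ref, eval) index pair. Output is sorted by descending probability.
    """
    m = np.array(matrix, dtype=np.float64, copy=True)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if m.size and not np.all(np.isfinite(m)):
        raise ValueError("matrix entries must be finite")
    out: List[Tuple[int, int, float]] = []
    while m.size:
        flat = int(np.argmax(m))
        i, j = np.unravel_index(flat, m.shape)
        p = float(m[i, j])
        if p <= p_min:
            break
        out.append((int(i), int(j), p))
        m[i, :] = 0.0
        m[:, j] = 0.0
    return out


def _match_step(
    refs: List[Tuple[int, OrganoidRecord]],
    evals: Sequence[OrganoidRecord],
    branch: str,
    cfg: MatchConfig,
    tracks: Dict[int, List[Observation]],
    next_id: int,
) -> Tuple[List[Tuple[int, OrganoidRecord]], int]:
    """One branch step: match current references against an evaluation day.

    Returns the references for the next step (matched evaluation records
    plus freshly born ones) and the updated id counter.
    """
    matrix = build_probability_matrix([r for _, r in refs], evals, branch, cfg)
    matches = assign_matches(matrix, cfg.p_min)
    matched_evals = set()
    new_refs: List[Tuple[int, OrganoidRecord]] = []
    for i, j, p in matches:
        tid = refs[i][0]
        ev = evals[j]
        tracks[tid].append(Observation(day=ev.day, label=ev.label, p=p))
        matched_evals.add(j)
        new_refs.append((tid, ev))
    matched_ref_ids = {refs[i][0] for i, _, _ in matches}
    for tid, _ in refs:
        if tid not in matched_ref_ids:
            logger.info("track %d terminates before day %s (%s branch)", tid, evals[0].day if evals else "?", branch)
    for j, ev in enumerate(evals):
        if j not in matched_evals:
            tracks[next_id] = [Observation(day=ev.day, label=ev.label, p=1.0, seed=True)]
            new_refs.append((next_id, ev))
            next_id += 1
    return new_refs, next_id


def track_timeseries(
    records_by_day: Mapping[int, Sequence[OrganoidRecord]],
    cfg: MatchConfig | None = None,
) -> TrackSet:
    """Dual-branch tracking over a multi-day series of organoid records.

    Reference-day organoids seed the global identities; the ascending
    branch chains matches day by day forward, the descending branch
    backward. A track ends at its first failed match (no gap bridging);
    fusion collapses to a single surviving identity because assignment is
    exclusive.
    """
    cfg = cfg or MatchConfig()
    days = sorted(records_by_day)
    if len(days) < 2:
        raise ValueError("need at least two days of records")
    if cfg.reference_day == "auto":
        grid = [replace(cfg, reference_day=d) for d in days]
        best, _ = tune_parameters(records_by_day, grid)
        cfg = best
    if cfg.reference_day not in records_by_day:
        raise ValueError(f"reference day {cfg.reference_day} absent from the series")
    ref_day = int(cfg.reference_day)

    tracks: Dict[int, List[Observation]] = {}
    seeds: List[Tuple[int, OrganoidRecord]] = []
    next_id = 1
    for rec in records_by_day[ref_day]:
        tracks[next_id] = [Observation(day=ref_day, label=rec.label, p=1.0, seed=True)]
        seeds.append((next_id, rec))
        next_id += 1

    refs = list(seeds)
    for day in [d for d in days if d > ref_day]:
        refs, next_id = _match_step(refs, list(records_by_day[day]), ASCENDING, cfg, tracks, next_id)
    refs = list(seeds)
    for day in [d for d in days if d < ref_day][::-1]:
        refs, next_id = _match_step(refs, list(records_by_day[day]), DESCENDING, cfg, tracks, next_id)

    for obs in tracks.values():
        obs.sort(key=lambda o: o.day)
    ts = TrackSet(tracks=tracks, reference_day=ref_day)
    logger.info(
        "tracked %d identities over %d days (reference day %d); %d span the full series",
        ts.n_tracks(),
        len(days),
        ref_day,
        len(ts.spanning(days)),
    )
    return ts


def tune_parameters(
    records_by_day: Mapping[int, Sequence[OrganoidRecord]],
    grid: Sequence[MatchConfig],
) -> Tuple[MatchConfig, pd.DataFrame]:
    """Exhaustive configuration search.

    The objective is the number of tracks spanning the full series; ties
    break to the higher mean link probability, then to the smaller centroid
    gate. Returns the winning configuration and a per-configuration
    diagnostics table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty configuration grid")
    days = sorted(records_by_day)
    expanded: List[MatchConfig] = []
    for cfg in grid:
        if cfg.reference_day == "auto":
            expanded.extend(replace(cfg, reference_day=d) for d in days)
        else:
            expanded.append(cfg)
    rows = []
    results: List[Tuple[float, float, float, int, MatchConfig]] = []
    for k, cfg in enumerate(expanded):
        ts = track_timeseries(records_by_day, cfg)
        link_ps = ts.link_probabilities()
        full = len(ts.spanning(days))
        mean_p = float(np.mean(link_ps)) if link_ps else 0.0
        rows.append(
            {
                "reference_day": cfg.reference_day,
                "theta_c": cfg.theta_c,
                "vol_tol": cfg.vol_tol,
                "w_c": cfg.w_c,
                "w_v": cfg.w_v,
                "w_p": cfg.w_p,
                "w_iou": cfg.w_iou,
                "p_min": cfg.p_min,
                "n_tracks": ts.n_tracks(),
                "n_full_tracks": full,
                "mean_link_p": mean_p,
            }
        )
        results.append((full, mean_p, -cfg.theta_c, -k, cfg))
    best = max(results)[-1]
    return best, pd.DataFrame(rows)
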