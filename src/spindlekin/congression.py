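"""Polar/aligned classification, alignment events and congression kinematics.

This module implements the live-cell analytics of the congression assay:

* classification of every sister-kinetochore pair as *polar* (lingering
  nearer a spindle pole than the spindle centre, and further than 3 µm from
  the equatorial plane) or *aligned*;
* detection of the alignment event — the first frame at which the pair
  midpoint comes within 2 µm of the equatorial plane;
* congression velocity over the last minutes before that crossing;
* residence time of polar chromosomes at poles (bipolarization → alignment,
  right-censored at anaphase onset), polar-chromosome counts per cell and
  per pole, and mitosis duration (NEBD → one frame before anaphase onset);
* the initiation-likelihood proxy: time-to-alignment regressed on the
  pair's initial distance from the nearest centrosome.

Tracks are 2D maximum-projection trajectories on a shared, constant-interval
time base. Frames where a sister could not be tracked are carried as NaN;
gaps up to ``AnalysisConfig.max_gap_frames_interpolated`` frames are closed
by per-sister linear interpolation, longer gaps simply restrict the usable
window of each metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import SpindleFrame, build_frame, pair_geometry
from .stats import OlsResult, ols_slope_test

__all__ = [
    "AnalysisConfig",
    "PairTrack",
    "PoleTrack",
    "CellRecord",
    "AlignmentEvent",
    "VelocityEstimate",
    "PairResult",
    "PolarCount",
    "classify_pair",
    "fill_gaps",
    "cell_frames",
    "detect_alignment_event",
    "congression_velocity",
    "residence_time",
    "polar_count_at_time",
    "mitosis_duration",
    "initiation_vs_distance",
    "analyze_cell",
    "analyze_cohort",
]

POLAR = "polar"
ALIGNED = "aligned"


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis constants, in µm and minutes.

    Defaults encode the assay conventions: a pair is aligned once either
    sister is within 3 µm of the equatorial plane; the alignment event is
    the midpoint first crossing within 2 µm; congression velocity is taken
    over the last 6 min before that crossing; polar chromosomes are counted
    5 min after spindle bipolarization; kinetochores within 1 µm of a
    centrosome are excluded from intensity analysis.
    """

    aligned_dist_threshold: float = 3.0
    alignment_cross_threshold: float = 2.0
    velocity_window: float = 6.0
    count_delay_after_bipolarization: float = 5.0
    pole_exclusion_radius: float = 1.0
    min_velocity_window: float = 3.0
    max_gap_frames_interpolated: int = 2

    def __post_init__(self) -> None:
        for name in (
            "aligned_dist_threshold",
            "alignment_cross_threshold",
            "velocity_window",
            "count_delay_after_bipolarization",
            "min_velocity_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # radius 0 disables the exclusion entirely (all measured d are > 0)
        if self.pole_exclusion_radius < 0:
            raise ValueError("pole_exclusion_radius must be >= 0")
        if self.alignment_cross_threshold > self.aligned_dist_threshold:
            raise ValueError(
                "alignment_cross_threshold must not exceed aligned_dist_threshold"
            )
        if self.max_gap_frames_interpolated < 0:
            raise ValueError("max_gap_frames_interpolated must be >= 0")


def _check_time_base(frame_index: np.ndarray, time_min: np.ndarray, what: str) -> None:
    if frame_index.ndim != 1 or frame_index.size == 0:
        raise ValueError(f"{what}: empty track")
    if np.any(np.diff(frame_index) <= 0):
        raise ValueError(f"{what}: frame_index must be strictly increasing")
    dt = np.diff(time_min)
    if time_min.size > 1:
        if np.any(dt <= 0):
            raise ValueError(f"{what}: time_min must be strictly increasing")
        # constant frame interval, allowing for skipped frame indices
        per_frame = dt / np.diff(frame_index)
        if not np.allclose(per_frame, per_frame[0], rtol=0, atol=1e-9):
            raise ValueError(f"{what}: frame interval must be constant")


@dataclass
class PairTrack:
    """2D trajectory of one sister-kinetochore pair (NaN rows = untracked)."""

    cell_id: str
    pair_id: str
    frame_index: np.ndarray
    time_min: np.ndarray
    sister1: np.ndarray  # (n, 2)
    sister2: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.sister1 = np.asarray(self.sister1, dtype=float).reshape(-1, 2)
        self.sister2 = np.asarray(self.sister2, dtype=float).reshape(-1, 2)
        _check_time_base(self.frame_index, self.time_min,
                         f"pair {self.cell_id}/{self.pair_id}")
        if not np.any(self.valid):
            raise ValueError(
                f"pair {self.cell_id}/{self.pair_id}: no frame with both sisters"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of frames where both sisters were tracked."""
        return (
            np.all(np.isfinite(self.sister1), axis=1)
            & np.all(np.isfinite(self.sister2), axis=1)
        )

    @property
    def midpoint(self) -> np.ndarray:
        mid = (self.sister1 + self.sister2) / 2.0
        mid[~self.valid] = np.nan
        return mid


@dataclass
class PoleTrack:
    """2D trajectory of one spindle pole with its (constant) centriole count."""

    pole_id: str
    centriole_count: int
    frame_index: np.ndarray
    time_min: np.ndarray
    position: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.position = np.asarray(self.position, dtype=float).reshape(-1, 2)
        if self.centriole_count not in (0, 1, 2):
            raise ValueError(f"pole {self.pole_id}: centriole_count must be 0, 1 or 2")
        _check_time_base(self.frame_index, self.time_min, f"pole {self.pole_id}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"pole {self.pole_id}: pole positions must be complete")


@dataclass
class CellRecord:
    """All tracks and event annotations of one mitotic cell."""

    cell_id: str
    condition_label: str
    pole_tracks: Sequence[PoleTrack]
    pair_tracks: Sequence[PairTrack]
    t_nebd: float
    t_bipolarization: float
    t_anaphase_onset: float | None = None

    def __post_init__(self) -> None:
        if len(self.pole_tracks) != 2:
            raise ValueError(f"cell {self.cell_id}: exactly 2 pole tracks required")
        if len(self.pair_tracks) < 1:
            raise ValueError(f"cell {self.cell_id}: at least one pair track required")
        if self.t_nebd > self.t_bipolarization:
            raise ValueError(f"cell {self.cell_id}: t_nebd must precede bipolarization")
        if self.t_anaphase_onset is not None and (
            self.t_bipolarization > self.t_anaphase_onset
        ):
            raise ValueError(
                f"cell {self.cell_id}: bipolarization must precede anaphase onset"
            )

    @property
    def frame_interval(self) -> float:
        t = self.pole_tracks[0].time_min
        if t.size < 2:
            raise ValueError(f"cell {self.cell_id}: cannot infer frame interval")
        return float(t[1] - t[0])

    @property
    def time_span(self) -> tuple[float, float]:
        t = self.pole_tracks[0].time_min
        return float(t[0]), float(t[-1])


@dataclass(frozen=True)
class AlignmentEvent:
    """Outcome of alignment-event detection for one pair."""

    t_alignment: float | None
    censored_reason: str | None = None  # "end_of_track" or "anaphase"

    @property
    def censored(self) -> bool:
        return self.t_alignment is None


@dataclass(frozen=True)
class VelocityEstimate:
    """Congression velocity over the pre-crossing window."""

    velocity: float           # µm/min, net midpoint displacement / window
    window_used: float        # minutes actually available
    partial_window: bool      # True if shorter than the configured window
    path_velocity: float      # summed frame-to-frame path / window (variant)


@dataclass
class PairResult:
    """Per-pair analysis results for one cell."""

    cell_id: str
    pair_id: str
    classification_at_reference_time: str | None
    t_alignment: float | None
    alignment_censored_reason: str | None
    residence_time: float | None
    residence_censored: bool
    congression_velocity: float | None
    velocity_partial_window: bool
    initial_dist_to_nearest_centrosome: float | None
    nearest_pole_id: str | None
    interkinetochore_distance_series: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class PolarCount:
    """Polar-pair count of one cell at one time, total and per pole."""

    total: int
    per_pole: dict
    n_pairs_evaluated: int
    time_used: float


# ---------------------------------------------------------------------------
# track utilities

def fill_gaps(track: PairTrack, max_gap: int) -> PairTrack:
    """Linearly interpolate per-sister gaps of at most ``max_gap`` frames.

    Longer gaps are left missing, which splits the usable window of any
    metric computed downstream. Leading/trailing missing frames are never
    extrapolated.
    """
    if max_gap <= 0:
        return track

    def _fill(sisters: np.ndarray) -> np.ndarray:
        out = sisters.copy()
        ok = np.all(np.isfinite(sisters), axis=1)
        idx = np.flatnonzero(ok)
        if idx.size < 2:
            return out
        for lo, hi in zip(idx[:-1], idx[1:]):
            gap = hi - lo - 1
            if 0 < gap <= max_gap:
                w = (np.arange(lo + 1, hi) - lo) / (hi - lo)
                out[lo + 1:hi] = (1 - w[:, None]) * sisters[lo] + w[:, None] * sisters[hi]
        return out

    return replace(track, sister1=_fill(track.sister1), sister2=_fill(track.sister2))


def cell_frames(cell: CellRecord) -> dict[int, SpindleFrame]:
    """Build the per-frame spindle coordinate frame from the two pole tracks."""
    pa, pb = cell.pole_tracks
    common, ia, ib = np.intersect1d(pa.frame_index, pb.frame_index,
                                    return_indices=True)
    frames: dict[int, SpindleFrame] = {}
    for k, fidx in enumerate(common):
        frames[int(fidx)] = build_frame(
            pa.position[ia[k]], pb.position[ib[k]], int(fidx),
            pole_a_id=pa.pole_id, pole_b_id=pb.pole_id,
        )
    return frames


def _pair_geometries(track: PairTrack, frames: Mapping[int, SpindleFrame]):
    """Yield (row, time, PairFrameGeometry) for usable frames in time order."""
    valid = track.valid
    for i, fidx in enumerate(track.frame_index):
        if valid[i] and int(fidx) in frames:
            yield i, float(track.time_min[i]), pair_geometry(
                frames[int(fidx)], track.sister1[i], track.sister2[i]
            )


# ---------------------------------------------------------------------------
# classification and events

def classify_pair(geom, cfg: AnalysisConfig) -> str:
    """Classify one pair-frame as ``"polar"`` or ``"aligned"``.

    A pair is aligned if either sister lies within the plate margin
    (3 µm from the equatorial plane by default) *or* its midpoint is at
    least as close to the spindle centre as to the nearest pole; it is
    polar otherwise. The two aligned rules are combined as a union, so a
    pair on the plane is always aligned.
    """
    if geom.sister_dist_plane_min <= cfg.aligned_dist_threshold:
        return ALIGNED
    if geom.dist_pole_near >= geom.dist_center:
        return ALIGNED
    return POLAR


def detect_alignment_event(
    track: PairTrack,
    frames: Mapping[int, SpindleFrame],
    cfg: AnalysisConfig,
    t_anaphase_onset: float | None = None,
) -> AlignmentEvent:
    """Find the first frame at which the pair midpoint crosses within the
    alignment threshold (2 µm) of the equatorial plane.

    Returns a censored event (reason ``"anaphase"`` or ``"end_of_track"``)
    if the midpoint never crosses within the observed window.
    """
    filled = fill_gaps(track, cfg.max_gap_frames_interpolated)
    seen = False
    for _, t, geom in _pair_geometries(filled, frames):
        if t_anaphase_onset is not None and t >= t_anaphase_onset:
            break
        seen = True
        if geom.dist_plane <= cfg.alignment_cross_threshold:
            return AlignmentEvent(t_alignment=t)
    if not seen:
        raise ValueError(
            f"pair {track.cell_id}/{track.pair_id}: no overlap between track "
            "and spindle frames"
        )
    reason = "anaphase" if t_anaphase_onset is not None else "end_of_track"
    return AlignmentEvent(t_alignment=None, censored_reason=reason)


def congression_velocity(
    track: PairTrack,
    frames: Mapping[int, SpindleFrame],
    t_alignment: float,
    cfg: AnalysisConfig,
) -> VelocityEstimate | None:
    """Net midpoint speed over the last ``velocity_window`` minutes before
    the alignment crossing.

    The estimate is the net Euclidean displacement of the pair midpoint
    between ``t_alignment - velocity_window`` and ``t_alignment``, divided
    by the window. If the tracked coverage before the crossing is shorter
    than the window but at least ``min_velocity_window``, the available
    window is used and flagged; below that the velocity is undefined
    (``None``). The summed frame-to-frame path-length variant is reported
    alongside.
    """
    filled = fill_gaps(track, cfg.max_gap_frames_interpolated)
    pts = [(t, geom.midpoint) for _, t, geom in _pair_geometries(filled, frames)
           if t <= t_alignment + 1e-9]
    if not pts or abs(pts[-1][0] - t_alignment) > 1e-9:
        return None  # midpoint not observed at the crossing frame

    t_end, p_end = pts[-1]
    t_start_target = t_alignment - cfg.velocity_window
    # last contiguous stretch of observed frames ending at the crossing
    if track.time_min.size > 1:
        interval = float(
            (track.time_min[1] - track.time_min[0])
            / (track.frame_index[1] - track.frame_index[0])
        )
    else:
        interval = cfg.velocity_window
    window_pts = [pts[-1]]
    for t0, p0 in reversed(pts[:-1]):
        if (window_pts[0][0] - t0) - interval > 1e-9:
            break  # gap longer than one frame: usable window is split here
        window_pts.insert(0, (t0, p0))
        if t0 <= t_start_target + 1e-9:
            break

    t_first = window_pts[0][0]
    coverage = t_end - t_first
    if coverage + 1e-9 < cfg.min_velocity_window:
        return None
    # trim to exactly the configured window when coverage allows
    start_t = max(t_first, t_start_target)
    trimmed = [(t, p) for t, p in window_pts if t >= start_t - 1e-9]
    t0, p0 = trimmed[0]
    window_used = t_end - t0
    if window_used <= 0:
        return None
    net = float(np.hypot(*(p_end - p0)))
    path = float(sum(np.hypot(*(b[1] - a[1])) for a, b in zip(trimmed[:-1], trimmed[1:])))
    return VelocityEstimate(
        velocity=net / window_used,
        window_used=window_used,
        partial_window=window_used + 1e-9 < cfg.velocity_window,
        path_velocity=path / window_used,
    )


def residence_time(
    t_bipolarization: float,
    t_alignment: float | None,
    t_anaphase_onset: float | None = None,
    t_last_observed: float | None = None,
) -> tuple[float, bool]:
    """Time a polar chromosome spends at the pole, right-censored.

    Uncensored pairs: alignment time minus bipolarization. Pairs that never
    align are censored at anaphase onset (or at the last observed time when
    anaphase was not reached). Alignment annotated before bipolarization is
    clamped to 0 with a warning.
    """
    if t_alignment is not None:
        value = t_alignment - t_bipolarization
        if value < 0:
            warnings.warn(
                "alignment precedes bipolarization; residence time clamped to 0",
                stacklevel=2,
            )
            value = 0.0
        return float(value), False
    t_censor = t_anaphase_onset if t_anaphase_onset is not None else t_last_observed
    if t_censor is None:
        raise ValueError("censored pair needs t_anaphase_onset or t_last_observed")
    return float(max(t_censor - t_bipolarization, 0.0)), True


def polar_count_at_time(
    cell: CellRecord, t: float, cfg: AnalysisConfig
) -> PolarCount:
    """Number of polar pairs in ``cell`` at the frame nearest to time ``t``,
    with the per-pole breakdown (keyed by nearest-pole id)."""
    lo, hi = cell.time_span
    if not (lo - 1e-9 <= t <= hi + 1e-9):
        raise ValueError(
            f"cell {cell.cell_id}: time {t} outside imaging span [{lo}, {hi}]"
        )
    pa, pb = cell.pole_tracks
    k = int(np.argmin(np.abs(pa.time_min - t)))
    fidx = int(pa.frame_index[k])
    kb = int(np.flatnonzero(pb.frame_index == fidx)[0])
    frame = build_frame(pa.position[k], pb.position[kb], fidx,
                        pole_a_id=pa.pole_id, pole_b_id=pb.pole_id)
    time_used = float(pa.time_min[k])

    per_pole = {p.pole_id: 0 for p in cell.pole_tracks}
    total = 0
    evaluated = 0
    for track in cell.pair_tracks:
        filled = fill_gaps(track, cfg.max_gap_frames_interpolated)
        where = np.flatnonzero(filled.frame_index == fidx)
        if where.size == 0 or not filled.valid[where[0]]:
            continue  # pair not observed at the counting frame
        i = int(where[0])
        geom = pair_geometry(frame, filled.sister1[i], filled.sister2[i])
        evaluated += 1
        if classify_pair(geom, cfg) == POLAR:
            total += 1
            per_pole[geom.nearest_pole_id] += 1
    return PolarCount(total=total, per_pole=per_pole,
                      n_pairs_evaluated=evaluated, time_used=time_used)


def mitosis_duration(cell: CellRecord) -> tuple[float, bool]:
    """Duration of mitosis: NEBD to one frame before visible anaphase onset.

    Returns ``(minutes, censored)``; cells that never reach anaphase within
    the observation window are censored at the last observed frame.
    """
    if cell.t_anaphase_onset is None:
        return float(cell.time_span[1] - cell.t_nebd), True
    return float((cell.t_anaphase_onset - cell.frame_interval) - cell.t_nebd), False


# ---------------------------------------------------------------------------
# per-cell and cohort analysis

def analyze_cell(cell: CellRecord, cfg: AnalysisConfig) -> list[PairResult]:
    """Run classification, event detection and kinematics for every pair."""
    frames = cell_frames(cell)
    t_ref = cell.t_bipolarization + cfg.count_delay_after_bipolarization
    results: list[PairResult] = []
    for track in cell.pair_tracks:
        filled = fill_gaps(track, cfg.max_gap_frames_interpolated)
        geoms = list(_pair_geometries(filled, frames))
        if not geoms:
            continue
        # classification at the reference time (bipolarization + delay)
        near = min(geoms, key=lambda g: abs(g[1] - t_ref))
        cls = (classify_pair(near[2], cfg)
               if abs(near[1] - t_ref) <= cell.frame_interval / 2 + 1e-9 else None)

        event = detect_alignment_event(track, frames, cfg,
                                       t_anaphase_onset=cell.t_anaphase_onset)
        res_t, res_cens = residence_time(
            cell.t_bipolarization, event.t_alignment,
            t_anaphase_onset=cell.t_anaphase_onset,
            t_last_observed=cell.time_span[1],
        )
        vel = (congression_velocity(track, frames, event.t_alignment, cfg)
               if event.t_alignment is not None else None)
        first_t, first_geom = geoms[0][1], geoms[0][2]
        results.append(PairResult(
            cell_id=cell.cell_id,
            pair_id=track.pair_id,
            classification_at_reference_time=cls,
            t_alignment=event.t_alignment,
            alignment_censored_reason=event.censored_reason,
            residence_time=res_t,
            residence_censored=res_cens,
            congression_velocity=None if vel is None else vel.velocity,
            velocity_partial_window=False if vel is None else vel.partial_window,
            initial_dist_to_nearest_centrosome=first_geom.dist_pole_near,
            nearest_pole_id=first_geom.nearest_pole_id,
            interkinetochore_distance_series=np.array(
                [g.interkinetochore_distance for _, _, g in geoms]
            ),
        ))
    return results


def initiation_vs_distance(
    cells: Sequence[CellRecord], cfg: AnalysisConfig
) -> tuple[pd.DataFrame, OlsResult | None]:
    """Duration of congression as a proxy for initiation likelihood, per
    pair, against the pair's initial distance from the nearest centrosome.

    Censored pairs (never aligned within the window) are listed in the
    table but excluded from the OLS fit. The fit is ``None`` when fewer
    than three uncensored pairs are available.
    """
    rows = []
    for cell in cells:
        frames = cell_frames(cell)
        for track in cell.pair_tracks:
            filled = fill_gaps(track, cfg.max_gap_frames_interpolated)
            geoms = list(_pair_geometries(filled, frames))
            if not geoms:
                continue
            t_first, g_first = geoms[0][1], geoms[0][2]
            event = detect_alignment_event(
                track, frames, cfg, t_anaphase_onset=cell.t_anaphase_onset)
            duration = (event.t_alignment - t_first
                        if event.t_alignment is not None else geoms[-1][1] - t_first)
            rows.append({
                "cell_id": cell.cell_id,
                "pair_id": track.pair_id,
                "initial_dist_to_nearest_centrosome": g_first.dist_pole_near,
                "time_to_alignment": duration,
                "censored": event.censored,
            })
    table = pd.DataFrame(rows)
    fit = None
    if len(table) and (~table["censored"]).sum() >= 3:
        sub = table[~table["censored"]]
        x = sub["initial_dist_to_nearest_centrosome"].to_numpy()
        if np.var(x) > 0:
            fit = ols_slope_test(x, sub["time_to_alignment"].to_numpy())
    return table, fit


def analyze_cohort(
    cells: Sequence[CellRecord], cfg: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair and per-cell result tables for a cohort of cells."""
    pair_rows, cell_rows = [], []
    for cell in cells:
        results = analyze_cell(cell, cfg)
        t_count = cell.t_bipolarization + cfg.count_delay_after_bipolarization
        lo, hi = cell.time_span
        count = polar_count_at_time(cell, min(max(t_count, lo), hi), cfg)
        count_end = polar_count_at_time(cell, hi, cfg)
        dur, dur_cens = mitosis_duration(cell)
        cell_rows.append({
            "cell_id": cell.cell_id,
            "condition_label": cell.condition_label,
            "polar_count": count.total,
            **{f"polar_count_pole_{pid}": n for pid, n in count.per_pole.items()},
            "count_time_min": count.time_used,
            "polar_count_end": count_end.total,
            "end_time_min": count_end.time_used,
            "mitosis_duration_min": dur,
            "mitosis_duration_censored": dur_cens,
        })
        for r in results:
            pair_rows.append({
                "cell_id": r.cell_id,
                "pair_id": r.pair_id,
                "condition_label": cell.condition_label,
                "classification_at_reference_time": r.classification_at_reference_time,
                "t_alignment_min": r.t_alignment,
                "alignment_censored_reason": r.alignment_censored_reason,
                "residence_time_min": r.residence_time,
                "residence_censored": r.residence_censored,
                "congression_velocity_um_per_min": r.congression_velocity,
                "velocity_partial_window": r.velocity_partial_window,
                "initial_dist_to_nearest_centrosome_um":
                    r.initial_dist_to_nearest_centrosome,
                "nearest_pole_id": r.nearest_pole_id,
                "mean_interkinetochore_distance_um":
                    float(np.nanmean(r.interkinetochore_distance_series)),
            })
    return pd.DataFrame(pair_rows), pd.DataFrame(cell_rows)
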