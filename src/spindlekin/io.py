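"""CSV/JSON schemas for tracks, events and intensity tables.

All tables are comma-separated UTF-8 with a header row and "." decimals;
floats are written with 6 significant digits so identical runs produce
byte-identical files. Coordinates are µm, times minutes, frame indices
0-based. Pair tracks carry one row per sister per frame (``sister`` 1/2);
untracked frames have empty coordinates. Pole rows leave ``sister`` blank
and carry the pole's centriole count. Event annotations (NEBD,
bipolarization, anaphase onset) live in a separate per-cell events table,
mirroring how they are annotated manually.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .congression import AnalysisConfig, CellRecord, PairTrack, PoleTrack
from .intensity import IntensitySample

__all__ = [
    "SchemaError",
    "TRACK_COLUMNS",
    "EVENT_COLUMNS",
    "INTENSITY_COLUMNS",
    "RunConfig",
    "write_tracks",
    "read_tracks",
    "write_events",
    "read_events",
    "assemble_cells",
    "write_intensities",
    "read_intensities",
]

FLOAT_FORMAT = "%.6g"

TRACK_COLUMNS = ["cell_id", "track_kind", "track_id", "frame_index", "time_min",
                 "x_um", "y_um", "sister", "centriole_count"]
EVENT_COLUMNS = ["cell_id", "condition_label", "t_nebd", "t_bipolarization",
                 "t_anaphase_onset"]
INTENSITY_COLUMNS = ["cell_id", "roi_id", "channel_label", "roi_kind",
                     "mean_signal", "background_mean", "reference_mean",
                     "n_z_planes", "location_class", "dist_to_nearest_pole_um",
                     "dist_to_plane_um", "is_integrated"]


class SchemaError(ValueError):
    """A file violates the documented table schema."""


@dataclass
class RunConfig:
    """Serializable analysis run configuration (JSON round-trip)."""

    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    tracks_path: str | None = None
    events_path: str | None = None
    intensities_path: str | None = None
    output_dir: str = "results"
    root_seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["analysis"] = AnalysisConfig(**d.get("analysis", {}))
        return cls(**d)


# ---------------------------------------------------------------------------
# tracks

def _tracks_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for cell in cells:
        for pt in cell.pole_tracks:
            for k in range(pt.frame_index.size):
                rows.append((cell.cell_id, "pole", pt.pole_id,
                             int(pt.frame_index[k]), pt.time_min[k],
                             FLOAT_FORMAT % pt.position[k, 0],
                             FLOAT_FORMAT % pt.position[k, 1],
                             "", pt.centriole_count))
        for tr in cell.pair_tracks:
            for sister, arr in ((1, tr.sister1), (2, tr.sister2)):
                for k in range(tr.frame_index.size):
                    x, y = arr[k]
                    # mixed with blanks for untracked frames, so pandas
                    # float_format does not apply: format here
                    rows.append((cell.cell_id, "pair", tr.pair_id,
                                 int(tr.frame_index[k]), tr.time_min[k],
                                 "" if not np.isfinite(x) else FLOAT_FORMAT % x,
                                 "" if not np.isfinite(y) else FLOAT_FORMAT % y,
                                 sister, ""))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(cells: Sequence[CellRecord], path) -> None:
    _tracks_frame(cells).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_tracks(path) -> dict:
    """Read and validate a tracks table.

    Returns ``{cell_id: {"poles": [PoleTrack, PoleTrack], "pairs":
    [PairTrack, ...]}}``. Raises :class:`SchemaError` listing every
    violating row for duplicate keys, and rejects 1-based frame files.
    """
    df = pd.read_csv(path, dtype={"sister": "string"})
    if df.empty:
        raise SchemaError(f"{path}: empty tracks file")
    _require_columns(df, TRACK_COLUMNS, path)

    bad_kind = df.loc[~df["track_kind"].isin(["pair", "pole"])]
    if len(bad_kind):
        raise SchemaError(
            f"{path}: unknown track_kind in rows {bad_kind.index.tolist()}"
        )
    key = ["cell_id", "track_kind", "track_id", "frame_index", "sister"]
    norm = df.assign(sister=df["sister"].fillna(""))
    dup = norm.duplicated(subset=key, keep=False)
    if dup.any():
        rows = norm.index[dup].tolist()
        raise SchemaError(
            f"{path}: duplicated (cell_id, track_kind, track_id, frame_index, "
            f"sister) keys at rows {rows[:20]}"
        )
    if int(df["frame_index"].min()) >= 1:
        raise SchemaError(
            f"{path}: frame_index starts at {int(df['frame_index'].min())}; "
            "the schema is 0-based (first frame of each recording must be 0)"
        )

    out: dict = {}
    for (cell_id, kind, track_id), sub in df.groupby(
            ["cell_id", "track_kind", "track_id"], sort=True):
        entry = out.setdefault(str(cell_id), {"poles": [], "pairs": []})
        if kind == "pole":
            sub = sub.sort_values("frame_index")
            if sub["frame_index"].duplicated().any():
                raise SchemaError(f"{path}: duplicate pole frames for "
                                  f"{cell_id}/{track_id}")
            cc = sub["centriole_count"].dropna().unique()
            if len(cc) != 1:
                raise SchemaError(
                    f"{path}: pole {cell_id}/{track_id} needs one constant "
                    "centriole_count"
                )
            entry["poles"].append(PoleTrack(
                pole_id=str(track_id), centriole_count=int(cc[0]),
                frame_index=sub["frame_index"].to_numpy(int),
                time_min=sub["time_min"].to_numpy(float),
                position=sub[["x_um", "y_um"]].to_numpy(float),
            ))
        else:
            sisters = {}
            for s in ("1", "2"):
                ssub = sub.loc[sub["sister"] == s].sort_values("frame_index")
                sisters[s] = ssub
            if len(sisters["1"]) == 0 or len(sisters["2"]) == 0:
                raise SchemaError(
                    f"{path}: pair {cell_id}/{track_id} must have rows for "
                    "both sisters"
                )
            f1 = sisters["1"]["frame_index"].to_numpy(int)
            f2 = sisters["2"]["frame_index"].to_numpy(int)
            if not np.array_equal(f1, f2):
                raise SchemaError(
                    f"{path}: pair {cell_id}/{track_id}: sisters must share "
                    "the same frame list"
                )
            entry["pairs"].append(PairTrack(
                cell_id=str(cell_id), pair_id=str(track_id),
                frame_index=f1,
                time_min=sisters["1"]["time_min"].to_numpy(float),
                sister1=sisters["1"][["x_um", "y_um"]].to_numpy(float),
                sister2=sisters["2"][["x_um", "y_um"]].to_numpy(float),
            ))
    return out


# ---------------------------------------------------------------------------
# events

def write_events(cells: Sequence[CellRecord], path) -> None:
    rows = [{
        "cell_id": c.cell_id, "condition_label": c.condition_label,
        "t_nebd": c.t_nebd, "t_bipolarization": c.t_bipolarization,
        "t_anaphase_onset": ("" if c.t_anaphase_onset is None
                             else FLOAT_FORMAT % c.t_anaphase_onset),
    } for c in cells]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)
    if df["cell_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated cell_id in events table")
    return df


def assemble_cells(tracks_path, events_path) -> list[CellRecord]:
    """Join the tracks and events tables into validated cell records."""
    tracks = read_tracks(tracks_path)
    events = read_events(events_path).set_index("cell_id")
    cells = []
    for cell_id, entry in tracks.items():
        if cell_id not in events.index:
            raise SchemaError(f"cell {cell_id} has tracks but no event row")
        ev = events.loc[cell_id]
        t_ana = ev["t_anaphase_onset"]
        cells.append(CellRecord(
            cell_id=cell_id,
            condition_label=str(ev["condition_label"]),
            pole_tracks=entry["poles"],
            pair_tracks=entry["pairs"],
            t_nebd=float(ev["t_nebd"]),
            t_bipolarization=float(ev["t_bipolarization"]),
            t_anaphase_onset=None if pd.isna(t_ana) else float(t_ana),
        ))
    return cells


# ---------------------------------------------------------------------------
# intensities

def write_intensities(samples: Iterable[IntensitySample], path) -> None:
    rows = [{
        "cell_id": s.cell_id, "roi_id": s.roi_id,
        "channel_label": s.channel_label, "roi_kind": s.roi_kind,
        "mean_signal": s.mean_signal, "background_mean": s.background_mean,
        # mixed with blanks, so pandas float_format does not apply: format here
        "reference_mean": ("" if s.reference_mean is None
                           else FLOAT_FORMAT % s.reference_mean),
        "n_z_planes": s.n_z_planes, "location_class": s.location_class,
        "dist_to_nearest_pole_um": s.dist_to_nearest_pole,
        "dist_to_plane_um": s.dist_to_plane,
        "is_integrated": s.is_integrated,
    } for s in samples]
    pd.DataFrame(rows, columns=INTENSITY_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_intensities(path) -> list[IntensitySample]:
    df = pd.read_csv(path)
    _require_columns(df, INTENSITY_COLUMNS, path)
    samples = []
    for _, r in df.iterrows():
        samples.append(IntensitySample(
            cell_id=str(r["cell_id"]), roi_id=str(r["roi_id"]),
            channel_label=str(r["channel_label"]), roi_kind=str(r["roi_kind"]),
            mean_signal=float(r["mean_signal"]),
            background_mean=float(r["background_mean"]),
            reference_mean=(None if pd.isna(r["reference_mean"])
                            else float(r["reference_mean"])),
            n_z_planes=int(r["n_z_planes"]),
            location_class=str(r["location_class"]),
            dist_to_nearest_pole=float(r["dist_to_nearest_pole_um"]),
            dist_to_plane=float(r["dist_to_plane_um"]),
            is_integrated=bool(r["is_integrated"]),
        ))
    return samples
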