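import numpy as np
import pytest

from spindlekin.congression import AnalysisConfig, CellRecord, PairTrack, PoleTrack


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


def make_static_cell(
    pair_midpoints,
    pole_a=(0.0, 0.0),
    pole_b=(12.0, 0.0),
    n_frames=21,
    frame_interval=1.0,
    t_nebd=0.0,
    t_bipolarization=5.0,
    t_anaphase_onset=None,
    sister_offset=(0.4, 0.0),
    cell_id="cell",
    condition="fixture",
    centrioles=(2, 2),
) -> CellRecord:
    """A cell whose poles and pair midpoints never move: the simplest
    geometry for exercising classification and counting."""
    fi = np.arange(n_frames)
    t = fi * frame_interval
    off = np.asarray(sister_offset, float)
    poles = [
        PoleTrack("A", centrioles[0], fi, t, np.tile(pole_a, (n_frames, 1))),
        PoleTrack("B", centrioles[1], fi, t, np.tile(pole_b, (n_frames, 1))),
    ]
    pairs = []
    for k, mid in enumerate(pair_midpoints):
        mid = np.asarray(mid, float)
        pairs.append(PairTrack(
            cell_id, f"p{k}", fi, t,
            np.tile(mid + off, (n_frames, 1)),
            np.tile(mid - off, (n_frames, 1)),
        ))
    return CellRecord(cell_id, condition, poles, pairs,
                      t_nebd, t_bipolarization, t_anaphase_onset)


def make_moving_pair(
    x_of_t,
    n_frames,
    cell_id="cell",
    pair_id="p0",
    frame_interval=1.0,
    y=0.0,
    sister_dy=0.1,
) -> PairTrack:
    """A pair whose midpoint moves along the spindle axis as x(t)."""
    fi = np.arange(n_frames)
    t = fi * frame_interval
    xs = np.array([x_of_t(tt) for tt in t], float)
    mid = np.column_stack([xs, np.full(n_frames, y)])
    off = np.array([0.0, sister_dy])
    return PairTrack(cell_id, pair_id, fi, t, mid + off, mid - off)
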