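"""Synthetic spindle generator with known ground truth.

The generator encodes the working model of congression control: Aurora A
activity forms a pole-centred spatial gradient (Gaussian in distance,
SD 1.5 µm, hence negligible beyond ~3 µm) whose amplitude scales with the
centriole content of the pole (acentriolar poles carry ~4-fold less
activity). When CENP-E is inactive, a kinetochore pair's probability of
*initiating* congression per unit time is suppressed wherever local Aurora
activity exceeds a threshold; with CENP-E active, initiation proceeds at
the full rate everywhere. After initiation a pair moves toward the
metaphase plate at a constant drawn speed.

Cells are simulated in 3D on a fixed frame interval and projected to the
2D plane before emission (small z scatter, discarded at projection), so
the 2D analysis assumptions of :mod:`spindlekin.geometry` hold by
construction. Positions are emitted with isotropic Gaussian localization
noise. A matching intensity model emits pole (pAurA) and kinetochore
phospho-channel ROI samples whose amplitudes follow the same gradient,
plus CENP-A reference and cytoplasmic background values, so the full
intensity pipeline can be exercised end to end.

Everything is deterministic in (preset, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .congression import CellRecord, PairTrack, PoleTrack
from .geometry import build_frame, pair_geometry
from .congression import AnalysisConfig, classify_pair

__all__ = [
    "Preset",
    "GroundTruth",
    "Cohort",
    "PRESET_NAMES",
    "get_preset",
    "aurora_activity",
    "initiation_hazard",
    "simulate_cell",
    "simulate_intensities",
    "simulate_experiment",
]


@dataclass(frozen=True)
class Preset:
    """Generator parameter set for one experimental condition.

    All rates are per minute, lengths in µm, times in minutes,
    intensities in arbitrary units. ``aurora_attenuation`` < 1 models an
    acute Aurora A inhibitor: the attenuation is applied from the drug
    addition time (``drug_delay_after_bipolarization`` after
    bipolarization) and the cell is fixed (simulation snapshot ends)
    ``t_fixation_after_drug`` minutes later.
    """

    name: str
    centriole_config: tuple[int, int] = (2, 2)
    cenpe_active: bool = True
    aurora_attenuation: float = 1.0     # alpha, 1.0 = untreated
    n_pairs_total: int = 23             # kinetochore pairs resolvable per projection
    lambda_polar_per_pole: float = 4.0  # Poisson mean of initially-polar pairs
    gradient_sd_um: float = 1.5         # sigma of the Aurora A gradient
    pole_amplitude: float = 1.0         # A0, centriolar pole activity
    acentriolar_factor: float = 0.25    # rho, acentriolar amplitude = rho * A0
    hazard_threshold: float = 0.4       # A_thr, activity above this blocks initiation
    h_max_per_min: float = 0.55         # maximal initiation hazard
    congression_speed_mean: float = 1.5
    congression_speed_sd: float = 0.3
    frame_interval_min: float = 1.0
    position_noise_sd_um: float = 0.05
    spindle_length_um: float = 12.0
    initial_polar_distance_um: tuple[float, float] = (0.5, 2.0)
    plate_lateral_radius_um: float = 3.0
    plate_axial_sd_um: float = 0.75
    interkinetochore_distance_um: float = 0.8
    z_scatter_sd_um: float = 0.5
    # intensity model
    kappa_pole: float = 1000.0          # pole channel gain
    i_base: float = 50.0                # kinetochore channel baseline
    beta_kinetochore: float = 500.0     # kinetochore channel gradient gain
    reference_mean: float = 200.0       # CENP-A reference
    reference_sd: float = 20.0
    background_mean: float = 30.0
    background_sd: float = 5.0
    noise_cv_pole: float = 0.05
    noise_cv_kinetochore: float = 0.10
    # timeline
    t_nebd: float = 0.0
    t_bipolarization: float = 10.0
    t_anaphase_control: float = 60.0
    t_window_max: float = 120.0
    drug_delay_after_bipolarization: float = 5.0
    t_fixation_after_drug: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 < self.aurora_attenuation <= 1.0):
            raise ValueError("aurora_attenuation must be in (0, 1]")
        if not (0.0 < self.acentriolar_factor <= 1.0):
            raise ValueError("acentriolar_factor must be in (0, 1]")
        for nm in ("gradient_sd_um", "pole_amplitude", "hazard_threshold",
                   "h_max_per_min", "congression_speed_mean",
                   "frame_interval_min", "spindle_length_um", "kappa_pole"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if any(c not in (0, 1, 2) for c in self.centriole_config):
            raise ValueError("centriole_config entries must be 0, 1 or 2")
        lo, hi = self.initial_polar_distance_um
        if not (0 < lo < hi):
            raise ValueError("initial_polar_distance_um must be an increasing "
                             "positive range")

    @property
    def aurora_drug(self) -> bool:
        """True for acute Aurora-A-inhibitor (fixed-cell snapshot) presets."""
        return self.aurora_attenuation < 1.0

    @property
    def t_drug(self) -> float:
        return self.t_bipolarization + self.drug_delay_after_bipolarization

    @property
    def t_snapshot(self) -> float:
        """Fixed-cell readout time: fixation for drug presets, the standard
        counting time (bipolarization + 5 min) otherwise."""
        if self.aurora_drug:
            return self.t_drug + self.t_fixation_after_drug
        return self.t_bipolarization + 5.0

    def zero_noise(self) -> "Preset":
        """Variant with all intensity noise terms switched off."""
        return dataclasses.replace(
            self, noise_cv_pole=0.0, noise_cv_kinetochore=0.0,
            reference_sd=0.0, background_sd=0.0,
        )


def _presets() -> dict[str, Preset]:
    base = dict()
    out = {}
    out["control_2v2"] = Preset(name="control_2v2", centriole_config=(2, 2),
                                cenpe_active=True, **base)
    out["control_1v0"] = Preset(name="control_1v0", centriole_config=(1, 0),
                                cenpe_active=True, **base)
    for cfg in [(2, 2), (1, 1), (1, 0), (0, 0)]:
        nm = f"cenpe_inhibited_{cfg[0]}v{cfg[1]}"
        out[nm] = Preset(name=nm, centriole_config=cfg, cenpe_active=False, **base)
    out["cenpe_inhibited_2v2_auroraA_inhibited"] = Preset(
        name="cenpe_inhibited_2v2_auroraA_inhibited",
        centriole_config=(2, 2), cenpe_active=False, aurora_attenuation=0.5,
    )
    return out


_PRESETS = _presets()
PRESET_NAMES = tuple(sorted(_PRESETS))


def get_preset(name: str, **overrides) -> Preset:
    """Look up a named preset, optionally overriding parameters."""
    try:
        p = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return dataclasses.replace(p, **overrides) if overrides else p


def aurora_activity(d, a_pole: float, sigma: float):
    """Aurora A activity at distance ``d`` (µm) from a pole of amplitude
    ``a_pole``: a Gaussian gradient A(d) = A_pole * exp(-d² / (2 σ²))."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = a_pole * np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def initiation_hazard(
    d, preset: Preset, pole_centriolar: bool, alpha: float | None = None
):
    """Per-minute congression-initiation hazard at distance ``d`` from the
    nearest pole.

    With CENP-E active the hazard is ``h_max`` everywhere. Without CENP-E
    it is ``h_max * max(0, 1 - alpha * A(d) / A_thr)``: fully suppressed
    wherever attenuated Aurora activity exceeds the threshold, recovering
    smoothly with distance.
    """
    if alpha is None:
        alpha = preset.aurora_attenuation
    d = np.asarray(d, dtype=float)
    if preset.cenpe_active:
        out = np.full_like(d, preset.h_max_per_min)
    else:
        a_pole = preset.pole_amplitude * (
            1.0 if pole_centriolar else preset.acentriolar_factor
        )
        act = aurora_activity(d, a_pole, preset.gradient_sd_um)
        out = preset.h_max_per_min * np.maximum(
            0.0, 1.0 - alpha * np.asarray(act) / preset.hazard_threshold
        )
    return float(out) if out.ndim == 0 else out


@dataclass
class GroundTruth:
    """Generative truth for one simulated cell."""

    preset_name: str
    seed: int
    t_nebd: float
    t_bipolarization: float
    t_anaphase_onset: float | None
    t_snapshot: float
    pairs: pd.DataFrame = field(repr=False)


@dataclass
class Cohort:
    """A simulated experiment: cells, intensities, truth and provenance."""

    preset: Preset
    cells: list
    intensities: list
    ground_truth: pd.DataFrame = field(repr=False)
    manifest: dict = field(repr=False)


# ---------------------------------------------------------------------------

def _pole_separation(t: np.ndarray, preset: Preset) -> np.ndarray:
    """Pole-to-pole distance over time: linear prometaphase elongation from
    1 µm at NEBD to full length at bipolarization, constant afterwards."""
    frac = np.clip((t - preset.t_nebd)
                   / max(preset.t_bipolarization - preset.t_nebd, 1e-9), 0, 1)
    return 1.0 + frac * (preset.spindle_length_um - 1.0)


def simulate_cell(
    preset: Preset, seed: int, cell_id: str | None = None
) -> tuple[CellRecord, GroundTruth]:
    """Simulate one cell; identical (preset, seed) gives identical output.

    Initially-polar pairs are drawn per pole (Poisson, capped so the total
    stays within ``n_pairs_total``), placed at U(0.5, 2) µm in-plane from
    their pole with a small z offset; the initiation clock runs from
    bipolarization with the frame-piecewise-constant hazard evaluated at
    the pair's true 3D pole distance. Initiated pairs move in a straight
    line toward a drawn point on the plate at a drawn constant speed.
    Remaining pairs start aligned near the plate and stay there. Control
    cells enter anaphase at 60 min provided every pair has reached the
    plate; otherwise the cell is followed to the 120-min window end with
    anaphase absent. Aurora-drug presets are fixed (emission stops) 8 min
    after drug addition.
    """
    rng = np.random.default_rng(seed)
    cid = cell_id or f"{preset.name}_s{seed}"
    dt = preset.frame_interval_min
    half = preset.spindle_length_um / 2.0

    # --- initially-polar pairs per pole, capped
    n_polar = rng.poisson(preset.lambda_polar_per_pole, size=2)
    while n_polar.sum() > preset.n_pairs_total:
        n_polar[int(np.argmax(n_polar))] -= 1
    n_aligned = preset.n_pairs_total - int(n_polar.sum())

    pole_centriolar = [c > 0 for c in preset.centriole_config]

    # --- per-pair static draws
    pairs = []  # dicts of generative state
    lo, hi = preset.initial_polar_distance_um
    for pole_idx in (0, 1):
        for j in range(n_polar[pole_idx]):
            # pair midpoint on a sphere of radius d around the pole, biased
            # toward the spindle interior, with small out-of-plane elevation
            d = rng.uniform(lo, hi)
            theta = rng.uniform(-np.pi / 4, np.pi / 4)
            psi = rng.normal(0.0, 0.25)  # elevation (rad); z = d*sin(psi)
            interior = 1.0 if pole_idx == 0 else -1.0
            offset = d * np.array([interior * np.cos(psi) * np.cos(theta),
                                   np.cos(psi) * np.sin(theta),
                                   np.sin(psi)])
            target = np.array([0.0,
                               rng.uniform(0, 1.5) * np.cos(rng.uniform(0, 2 * np.pi)),
                               rng.normal(0.0, 0.3)])
            pairs.append(dict(polar=True, pole_idx=pole_idx, d_pole=d,
                              offset=offset, target=target,
                              speed=max(rng.normal(preset.congression_speed_mean,
                                                   preset.congression_speed_sd), 0.2)))
    for j in range(n_aligned):
        x = np.clip(rng.normal(0.0, preset.plate_axial_sd_um), -2.0, 2.0)
        r = rng.uniform(0, preset.plate_lateral_radius_um)
        phi = rng.uniform(0, 2 * np.pi)
        pos = np.array([x, r * np.cos(phi),
                        0.3 * r * np.sin(phi)
                        + rng.normal(0.0, preset.z_scatter_sd_um / 2)])
        pairs.append(dict(polar=False, pole_idx=int(np.argmin(
            [abs(pos[0] + half), abs(pos[0] - half)])), offset=pos,
            target=pos, speed=0.0, d_pole=np.nan))

    # --- initiation times: exact exponential clock from bipolarization,
    # hazard piecewise-constant per frame (cumulative-hazard inversion)
    t_stop = preset.t_snapshot if preset.aurora_drug else preset.t_window_max
    for p in pairs:
        p["t_init"] = np.nan
        if not p["polar"]:
            continue
        d_true = float(p["d_pole"])
        e_target = rng.exponential(1.0)
        cum = 0.0
        t = preset.t_bipolarization
        while t < t_stop:
            alpha = 1.0
            if preset.aurora_drug and t >= preset.t_drug - 1e-9:
                alpha = preset.aurora_attenuation
            h = initiation_hazard(d_true, preset,
                                  pole_centriolar[p["pole_idx"]], alpha=alpha)
            if h > 0 and cum + h * dt >= e_target:
                p["t_init"] = t + (e_target - cum) / h
                break
            cum += h * dt
            t += dt

    # --- event times and emission window
    if preset.aurora_drug:
        t_ana = None
        t_end = preset.t_snapshot
    else:
        done = []
        for p in pairs:
            if not p["polar"]:
                continue
            if np.isnan(p["t_init"]):
                done.append(np.inf)
            else:
                start = _pole_position3d(p, np.array([p["t_init"]]), preset)[0]
                done.append(p["t_init"]
                            + float(np.linalg.norm(p["target"] - start))
                            / p["speed"])
        if all(d <= preset.t_anaphase_control - 2 * dt for d in done):
            t_ana = preset.t_anaphase_control
            t_end = t_ana
        else:
            t_ana = None
            t_end = preset.t_window_max

    times = np.arange(preset.t_nebd, t_end + dt / 2, dt)
    n_frames = times.size
    frame_idx = np.arange(n_frames)
    sep = _pole_separation(times, preset)
    pole_a = np.column_stack([-sep / 2, np.zeros(n_frames), np.zeros(n_frames)])
    pole_b = np.column_stack([sep / 2, np.zeros(n_frames), np.zeros(n_frames)])

    # --- trajectories; kinetochore tracks start at bipolarization (the
    # polar/aligned geometry is only meaningful on the bipolar spindle),
    # pole tracks span the whole recording
    emit = times >= preset.t_bipolarization - 1e-9
    pair_tracks = []
    gt_rows = []
    for idx, p in enumerate(pairs):
        pid = f"pair{idx:02d}"
        pole_pos = pole_a if p["pole_idx"] == 0 else pole_b
        if p["polar"]:
            mid = pole_pos + p["offset"][None, :]
        else:
            mid = np.tile(p["offset"], (n_frames, 1))
        if p["polar"] and not np.isnan(p["t_init"]):
            moving = times >= p["t_init"]
            start = mid[moving][0] if moving.any() else None
            if start is not None:
                vec = p["target"] - start
                dist = float(np.linalg.norm(vec))
                u = vec / dist if dist > 0 else np.zeros(3)
                travelled = np.minimum((times[moving] - p["t_init"]) * p["speed"],
                                       dist)
                mid = mid.copy()
                mid[moving] = start[None, :] + travelled[:, None] * u[None, :]
        # sisters along the spindle axis, constant separation
        s_off = np.array([preset.interkinetochore_distance_um / 2, 0.0, 0.0])
        s1 = mid + s_off
        s2 = mid - s_off
        noise = rng.normal(0.0, preset.position_noise_sd_um, size=(2, n_frames, 3))
        pair_tracks.append(PairTrack(
            cell_id=cid, pair_id=pid,
            frame_index=frame_idx[emit], time_min=times[emit],
            sister1=(s1 + noise[0])[emit][:, :2],
            sister2=(s2 + noise[1])[emit][:, :2],
        ))
        k0 = int(np.flatnonzero(emit)[0])
        d0_a = float(np.linalg.norm(mid[k0] - pole_a[k0]))
        d0_b = float(np.linalg.norm(mid[k0] - pole_b[k0]))
        gt_rows.append({
            "cell_id": cid, "pair_id": pid,
            "initially_polar": p["polar"],
            "pole_id": "A" if p["pole_idx"] == 0 else "B",
            "pole_centriolar": pole_centriolar[p["pole_idx"]],
            "initial_dist_pole_um": p["d_pole"],
            "initial_dist_pole_a_um": d0_a,
            "initial_dist_pole_b_um": d0_b,
            "t_initiation_min": p["t_init"],
            "true_speed_um_per_min": p["speed"] if p["polar"] else np.nan,
        })

    pole_noise = rng.normal(0.0, preset.position_noise_sd_um, size=(2, n_frames, 3))
    pole_tracks = [
        PoleTrack(pole_id="A", centriole_count=preset.centriole_config[0],
                  frame_index=frame_idx, time_min=times,
                  position=(pole_a + pole_noise[0])[:, :2]),
        PoleTrack(pole_id="B", centriole_count=preset.centriole_config[1],
                  frame_index=frame_idx, time_min=times,
                  position=(pole_b + pole_noise[1])[:, :2]),
    ]

    cell = CellRecord(
        cell_id=cid, condition_label=preset.name,
        pole_tracks=pole_tracks, pair_tracks=pair_tracks,
        t_nebd=preset.t_nebd, t_bipolarization=preset.t_bipolarization,
        t_anaphase_onset=t_ana,
    )
    gt = GroundTruth(
        preset_name=preset.name, seed=int(seed),
        t_nebd=preset.t_nebd, t_bipolarization=preset.t_bipolarization,
        t_anaphase_onset=t_ana, t_snapshot=preset.t_snapshot,
        pairs=pd.DataFrame(gt_rows),
    )
    return cell, gt


def _pole_position3d(p: dict, t: np.ndarray, preset: Preset) -> np.ndarray:
    """True 3D midpoint of a polar pair while attached to its pole."""
    sep = _pole_separation(t, preset)
    sign = -1.0 if p["pole_idx"] == 0 else 1.0
    pole = np.column_stack([sign * sep / 2, np.zeros(t.size), np.zeros(t.size)])
    return pole + p["offset"][None, :]


def simulate_intensities(
    preset: Preset,
    cell: CellRecord,
    seed: int,
    channel: str = "pAurB",
    cfg: AnalysisConfig | None = None,
) -> list:
    """Emit fixed-cell intensity samples for one simulated cell.

    The snapshot is taken at the preset's fixation/readout time. Pole ROIs
    (channel pAurA) have true mean ``kappa_pole * A_pole``; kinetochore
    ROIs have true mean ``i_base + beta * alpha * A(d)`` with ``d`` the
    pair's measured distance to its nearest pole and ``A`` the gradient of
    that pole. Cytoplasmic background and the CENP-A reference are drawn
    per ROI; the drawn background enters both the signal and the recorded
    background field, so correction is unbiased. Location classes come
    from the same geometry classifier the analysis uses.
    """
    from .intensity import IntensitySample  # local import: avoid cycle

    rng = np.random.default_rng([int(seed), 0xF1])
    cfg = cfg or AnalysisConfig()
    t_snap = preset.t_snapshot
    alpha = preset.aurora_attenuation

    pa, pb = cell.pole_tracks
    k = int(np.argmin(np.abs(pa.time_min - t_snap)))
    frame = build_frame(pa.position[k], pb.position[k], int(pa.frame_index[k]),
                        pole_a_id=pa.pole_id, pole_b_id=pb.pole_id)

    def _bg() -> float:
        return float(max(rng.normal(preset.background_mean,
                                    preset.background_sd), 0.0))

    samples = []
    amp = {
        pa.pole_id: preset.pole_amplitude * (1.0 if pa.centriole_count > 0
                                             else preset.acentriolar_factor),
        pb.pole_id: preset.pole_amplitude * (1.0 if pb.centriole_count > 0
                                             else preset.acentriolar_factor),
    }
    for pt in (pa, pb):
        b = _bg()
        eps = rng.normal(0.0, preset.noise_cv_pole)
        true = preset.kappa_pole * amp[pt.pole_id]
        samples.append(IntensitySample(
            cell_id=cell.cell_id, roi_id=f"pole_{pt.pole_id}",
            channel_label="pAurA", roi_kind="pole",
            mean_signal=max(true * (1.0 + eps) + b, 0.0),
            background_mean=b, reference_mean=None, n_z_planes=32,
            location_class=("pole_centriolar" if pt.centriole_count > 0
                            else "pole_acentriolar"),
            dist_to_nearest_pole=0.0,
            dist_to_plane=frame.spindle_length / 2.0,
        ))

    for track in cell.pair_tracks:
        i = int(np.argmin(np.abs(track.time_min - t_snap)))
        if not track.valid[i]:
            continue
        geom = pair_geometry(frame, track.sister1[i], track.sister2[i])
        a_pole = amp[geom.nearest_pole_id]
        act = aurora_activity(geom.dist_pole_near, a_pole, preset.gradient_sd_um)
        true = preset.i_base + preset.beta_kinetochore * alpha * act
        b = _bg()
        eps = rng.normal(0.0, preset.noise_cv_kinetochore)
        ref = max(rng.normal(preset.reference_mean, preset.reference_sd), 1.0)
        samples.append(IntensitySample(
            cell_id=cell.cell_id, roi_id=f"kc_{track.pair_id}",
            channel_label=channel, roi_kind="kinetochore_pair",
            mean_signal=max(true * (1.0 + eps) + b, 0.0),
            background_mean=b, reference_mean=ref + b, n_z_planes=32,
            location_class=classify_pair(geom, cfg),
            dist_to_nearest_pole=geom.dist_pole_near,
            dist_to_plane=geom.dist_plane,
        ))
    return samples


def simulate_experiment(
    preset: Preset,
    n_cells: int,
    root_seed: int,
    with_intensities: bool = True,
    channel: str = "pAurB",
) -> Cohort:
    """Simulate a cohort of cells with per-cell seeds derived from
    ``root_seed`` (deterministic; two cohorts with the same root seed are
    identical)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    child_seeds = np.random.SeedSequence(int(root_seed)).generate_state(n_cells)
    cells, gts, intensities = [], [], []
    for i, cs in enumerate(child_seeds):
        cid = f"{preset.name}_c{i:03d}"
        cell, gt = simulate_cell(preset, int(cs), cell_id=cid)
        cells.append(cell)
        gts.append(gt.pairs.assign(seed=int(cs)))
        if with_intensities:
            intensities.extend(
                simulate_intensities(preset, cell, int(cs), channel=channel))
    manifest = {
        "preset": dataclasses.asdict(preset),
        "root_seed": int(root_seed),
        "n_cells": int(n_cells),
        "child_seeds": [int(s) for s in child_seeds],
        "channel": channel,
    }
    return Cohort(
        preset=preset, cells=cells, intensities=intensities,
        ground_truth=pd.concat(gts, ignore_index=True), manifest=manifest,
    )
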