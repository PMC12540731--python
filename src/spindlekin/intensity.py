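"""Background-corrected, reference-normalized immunofluorescence quantities.

Workflow mirrored here: each ROI mean (kinetochore pair or spindle pole) is
corrected by subtracting the cytoplasmic background measured in the same
cell; integrated sum-projection values are first divided by the number of
z-planes. Kinetochore signals are normalized to the CENP-A reference of the
same ROI. Kinetochore pairs lying inside the circular pole signal (within
~1 µm of the centrosome) are excluded to avoid the non-specific pole
staining of phospho-antibodies. From the corrected/normalized values the
module computes the per-cell pole ratio (centriolar vs acentriolar pAurA),
the polar-vs-aligned kinetochore ratio, and the intensity-vs-distance
gradient regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .congression import AnalysisConfig
from .stats import OlsResult, ols_slope_test

__all__ = [
    "IntensitySample",
    "CorrectedIntensity",
    "PoleRatio",
    "corrected_intensity",
    "normalize_to_reference",
    "normalized_value",
    "pole_exclusion_filter",
    "pole_ratio",
    "polar_vs_aligned_ratio",
    "gradient_regression",
    "samples_to_frame",
]

log = logging.getLogger(__name__)

KINETOCHORE_PAIR = "kinetochore_pair"
POLE = "pole"
LOCATION_CLASSES = ("polar", "aligned", "pole_centriolar", "pole_acentriolar")


@dataclass(frozen=True)
class IntensitySample:
    """One ROI measurement (arbitrary units, distances in µm).

    ``mean_signal`` and ``background_mean`` are per-plane means unless
    ``is_integrated`` is set, in which case ``mean_signal`` is an
    integrated sum-projection value that must be divided by ``n_z_planes``
    before background subtraction. ``reference_mean`` carries the CENP-A
    signal of the same ROI for kinetochore samples (absent for poles).
    """

    cell_id: str
    roi_id: str
    channel_label: str
    roi_kind: str  # "kinetochore_pair" | "pole"
    mean_signal: float
    background_mean: float
    reference_mean: float | None
    n_z_planes: int
    location_class: str
    dist_to_nearest_pole: float
    dist_to_plane: float
    is_integrated: bool = False

    def __post_init__(self) -> None:
        if self.roi_kind not in (KINETOCHORE_PAIR, POLE):
            raise ValueError(f"ROI {self.roi_id}: unknown roi_kind {self.roi_kind!r}")
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(
                f"ROI {self.roi_id}: unknown location_class {self.location_class!r}"
            )
        if self.mean_signal < 0 or self.background_mean < 0:
            raise ValueError(f"ROI {self.roi_id}: negative intensity input")
        if self.n_z_planes < 1:
            raise ValueError(f"ROI {self.roi_id}: n_z_planes must be >= 1")


class CorrectedIntensity(NamedTuple):
    value: float
    clipped: bool


class PoleRatio(NamedTuple):
    value: float
    symmetric_pair: bool  # True when both poles share a class (max/min readout)


def corrected_intensity(sample: IntensitySample) -> CorrectedIntensity:
    """Background-subtracted ROI intensity, clamped at 0 with a flag.

    Integrated sum-projection inputs are divided by the number of z-planes
    first, so the subtraction is always per-plane mean minus per-plane
    cytoplasmic background.
    """
    signal = sample.mean_signal
    if sample.is_integrated:
        signal = signal / sample.n_z_planes
    value = signal - sample.background_mean
    if value < 0:
        return CorrectedIntensity(0.0, True)
    return CorrectedIntensity(float(value), False)


def normalize_to_reference(corrected: float, reference_corrected: float) -> float:
    """Ratio of a corrected signal to its corrected CENP-A reference."""
    if reference_corrected <= 0:
        raise ValueError("reference intensity must be > 0 after correction")
    return float(corrected / reference_corrected)


def normalized_value(sample: IntensitySample) -> float:
    """Corrected signal normalized to the sample's own corrected reference."""
    if sample.reference_mean is None:
        raise ValueError(f"ROI {sample.roi_id}: no reference channel recorded")
    corr = corrected_intensity(sample).value
    ref = sample.reference_mean
    if sample.is_integrated:
        ref = ref / sample.n_z_planes
    ref_corr = ref - sample.background_mean
    if ref_corr <= 0:
        raise ValueError(
            f"ROI {sample.roi_id}: corrected reference is not positive"
        )
    return normalize_to_reference(corr, ref_corr)


def pole_exclusion_filter(
    samples: Iterable[IntensitySample], cfg: AnalysisConfig
) -> tuple[list[IntensitySample], int]:
    """Drop kinetochore-pair samples inside the circular pole signal.

    A sample is removed when its distance to the nearest centrosome is
    less than or equal to the exclusion radius ("outside" is read
    strictly, so the boundary itself is excluded). Pole samples are never
    filtered. Returns the kept samples and the number removed.
    """
    kept, removed = [], 0
    for s in samples:
        if s.roi_kind == KINETOCHORE_PAIR and (
            s.dist_to_nearest_pole <= cfg.pole_exclusion_radius
        ):
            removed += 1
        else:
            kept.append(s)
    return kept, removed


def pole_ratio(cell_samples: Sequence[IntensitySample]) -> PoleRatio:
    """Per-cell ratio of corrected pole intensity, centriolar / acentriolar.

    For cells whose two poles are of the same class (e.g. 1:1 spindles,
    both centriolar) the maximum-difference readout max/min is returned
    with the ``symmetric_pair`` flag set.
    """
    poles = [s for s in cell_samples if s.roi_kind == POLE]
    cent = [corrected_intensity(s).value for s in poles
            if s.location_class == "pole_centriolar"]
    acent = [corrected_intensity(s).value for s in poles
             if s.location_class == "pole_acentriolar"]
    if cent and acent:
        num, den = float(np.mean(cent)), float(np.mean(acent))
        symmetric = False
    elif len(cent) >= 2 or len(acent) >= 2:
        vals = cent if cent else acent
        num, den = max(vals), min(vals)
        symmetric = True
    else:
        raise ValueError("pole_ratio needs a pole sample of each class "
                         "(or two of the same class)")
    if den <= 0:
        raise ValueError("denominator pole intensity is 0 after correction")
    return PoleRatio(num / den, symmetric)


def polar_vs_aligned_ratio(
    cell_samples: Sequence[IntensitySample],
) -> float | None:
    """Per-cell ratio: mean normalized polar kinetochore signal over mean
    normalized aligned signal. ``None`` (with a log entry) when the cell
    lacks one of the classes."""
    kc = [s for s in cell_samples if s.roi_kind == KINETOCHORE_PAIR]
    polar = [normalized_value(s) for s in kc if s.location_class == "polar"]
    aligned = [normalized_value(s) for s in kc if s.location_class == "aligned"]
    if not polar or not aligned:
        cell = cell_samples[0].cell_id if cell_samples else "?"
        log.info("cell %s skipped: needs >=1 polar and >=1 aligned kinetochore "
                 "sample (got %d polar, %d aligned)", cell, len(polar), len(aligned))
        return None
    return float(np.mean(polar) / np.mean(aligned))


def gradient_regression(
    samples: Sequence[IntensitySample], cfg: AnalysisConfig | None = None
) -> OlsResult:
    """OLS of normalized kinetochore intensity on distance to the nearest
    pole, after applying the pole-exclusion filter.

    A negative slope quantifies the pole-centred phospho-gradient (signal
    inversely correlated with distance from the centrosome).
    """
    cfg = cfg or AnalysisConfig()
    kc = [s for s in samples if s.roi_kind == KINETOCHORE_PAIR]
    kept, _ = pole_exclusion_filter(kc, cfg)
    if len(kept) < 3:
        raise ValueError(
            f"gradient regression needs >= 3 kinetochore samples outside the "
            f"pole exclusion radius (got {len(kept)})"
        )
    x = np.array([s.dist_to_nearest_pole for s in kept])
    y = np.array([normalized_value(s) for s in kept])
    return ols_slope_test(x, y)


def samples_to_frame(samples: Iterable[IntensitySample]) -> pd.DataFrame:
    """Tabulate samples with their corrected (and normalized, if possible)
    values for reporting."""
    rows = []
    for s in samples:
        corr = corrected_intensity(s)
        row = {
            "cell_id": s.cell_id, "roi_id": s.roi_id,
            "channel_label": s.channel_label, "roi_kind": s.roi_kind,
            "location_class": s.location_class,
            "mean_signal": s.mean_signal, "background_mean": s.background_mean,
            "reference_mean": s.reference_mean, "n_z_planes": s.n_z_planes,
            "dist_to_nearest_pole_um": s.dist_to_nearest_pole,
            "dist_to_plane_um": s.dist_to_plane,
            "corrected": corr.value, "clipped": corr.clipped,
        }
        try:
            row["normalized"] = normalized_value(s)
        except ValueError:
            row["normalized"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
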