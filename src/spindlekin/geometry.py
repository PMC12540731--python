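"""Per-frame spindle coordinate frame and distance/angle primitives.

All live-cell quantities in this package are computed in the 2D maximum-
projection plane. Each frame defines a spindle coordinate system from the
two pole positions: the spindle axis is the pole-to-pole line, and the
equatorial (metaphase) plane is the line through the midpoint of that
segment, perpendicular to it. Every classification and kinematic metric in
:mod:`spindlekin.congression` is built from the primitives here.

Units are micrometres for lengths and degrees for angles throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateFrameError",
    "SpindleFrame",
    "PairFrameGeometry",
    "build_frame",
    "pair_geometry",
]

#: Poles closer than this are treated as coincident (degenerate frame).
_COINCIDENT_TOL = 1e-12


class DegenerateFrameError(ValueError):
    """Raised when the two spindle poles coincide and no axis exists."""


@dataclass(frozen=True)
class SpindleFrame:
    """Spindle geometry of a single time frame.

    Attributes
    ----------
    frame_index : int
        0-based index of the time frame.
    pole_a, pole_b : ndarray, shape (2,)
        Pole positions (µm) in the projection plane.
    midpoint : ndarray, shape (2,)
        Midpoint of the pole-to-pole segment; the equatorial plane passes
        through this point, perpendicular to ``axis_unit``.
    axis_unit : ndarray, shape (2,)
        Unit vector from ``pole_a`` to ``pole_b``.
    spindle_length : float
        Pole-to-pole distance (µm).
    pole_a_id, pole_b_id : str
        Identifiers used to report the nearest pole of a kinetochore pair.
    """

    frame_index: int
    pole_a: np.ndarray
    pole_b: np.ndarray
    midpoint: np.ndarray
    axis_unit: np.ndarray
    spindle_length: float
    pole_a_id: str = "A"
    pole_b_id: str = "B"


@dataclass(frozen=True)
class PairFrameGeometry:
    """All per-frame scalar geometry of one sister-kinetochore pair.

    ``dist_plane`` is the distance of the pair midpoint to the equatorial
    plane (absolute projection onto the spindle axis), ``dist_pole_near``
    the distance to the nearest pole centre and ``dist_center`` the distance
    to the spindle midpoint. ``sister_dist_plane_min`` is the smaller of the
    two sisters' own distances to the plane; the aligned/polar classifier
    uses it so that a pair counts as aligned as soon as either sister is
    within the plate margin. ``angle_to_axis`` is the angle, at the nearest
    pole, between the pole-to-pole line and the line from that pole to the
    pair midpoint, in degrees in [0, 180].
    """

    midpoint: np.ndarray
    dist_plane: float
    dist_pole_near: float
    dist_center: float
    sister_dist_plane_min: float
    interkinetochore_distance: float
    angle_to_axis: float
    nearest_pole_id: str


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinates: {a}")
    return a


def build_frame(
    pole_a,
    pole_b,
    frame_index: int,
    pole_a_id: str = "A",
    pole_b_id: str = "B",
) -> SpindleFrame:
    """Construct the spindle coordinate frame for one time frame.

    Parameters
    ----------
    pole_a, pole_b
        2D pole positions in µm. Must not coincide.
    frame_index
        0-based frame index, carried through for error reporting.

    Raises
    ------
    DegenerateFrameError
        If the poles coincide (no spindle axis can be defined).
    """
    a = _as_point(pole_a)
    b = _as_point(pole_b)
    delta = b - a
    length = float(np.hypot(*delta))
    if length <= _COINCIDENT_TOL:
        raise DegenerateFrameError(
            f"coincident spindle poles at frame {frame_index}: {a.tolist()}"
        )
    return SpindleFrame(
        frame_index=int(frame_index),
        pole_a=a,
        pole_b=b,
        midpoint=(a + b) / 2.0,
        axis_unit=delta / length,
        spindle_length=length,
        pole_a_id=pole_a_id,
        pole_b_id=pole_b_id,
    )


def _dist_plane(frame: SpindleFrame, point: np.ndarray) -> float:
    """Distance of ``point`` to the equatorial plane (line) of ``frame``."""
    return float(abs(np.dot(point - frame.midpoint, frame.axis_unit)))


def pair_geometry(frame: SpindleFrame, sister1, sister2) -> PairFrameGeometry:
    """Compute all scalar geometry of a sister pair in one frame.

    The pair is represented by the midpoint between the sister-kinetochore
    centres; distances to the nearest pole, the spindle midpoint and the
    equatorial plane are measured from that midpoint. Exact nearest-pole
    ties are broken toward the lexicographically smaller pole identifier.
    """
    s1 = _as_point(sister1)
    s2 = _as_point(sister2)
    mid = (s1 + s2) / 2.0

    d_a = float(np.hypot(*(mid - frame.pole_a)))
    d_b = float(np.hypot(*(mid - frame.pole_b)))
    if d_a < d_b:
        near_id, near_pole, d_near = frame.pole_a_id, frame.pole_a, d_a
    elif d_b < d_a:
        near_id, near_pole, d_near = frame.pole_b_id, frame.pole_b, d_b
    else:  # exact tie: deterministic, documented tie-break
        if frame.pole_a_id <= frame.pole_b_id:
            near_id, near_pole, d_near = frame.pole_a_id, frame.pole_a, d_a
        else:
            near_id, near_pole, d_near = frame.pole_b_id, frame.pole_b, d_b

    # Angle at the nearest pole between the pole->pole line and the
    # pole->pair-midpoint line. Undefined if the midpoint sits exactly on
    # the pole; reported as 0 in that degenerate case.
    to_other = (frame.pole_b if near_id == frame.pole_a_id else frame.pole_a) - near_pole
    to_pair = mid - near_pole
    norm_pair = np.hypot(*to_pair)
    if norm_pair <= _COINCIDENT_TOL:
        angle = 0.0
    else:
        cosang = np.dot(to_other, to_pair) / (np.hypot(*to_other) * norm_pair)
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    return PairFrameGeometry(
        midpoint=mid,
        dist_plane=_dist_plane(frame, mid),
        dist_pole_near=d_near,
        dist_center=float(np.hypot(*(mid - frame.midpoint))),
        sister_dist_plane_min=min(_dist_plane(frame, s1), _dist_plane(frame, s2)),
        interkinetochore_distance=float(np.hypot(*(s1 - s2))),
        angle_to_axis=angle,
        nearest_pole_id=near_id,
    )
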