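"""MAPSE measurement from per-volume 3D mitral-annulus landmark detections.

This module implements the post-detection half of an automatic MAPSE
pipeline.  The input is a :class:`DetectionStream`: for every 3D volume of a
multi-cycle recording, a set of candidate annulus points with azimuth labels,
plus ECG R-wave times.  The processing chain is

1. long-axis estimation (or a user-supplied axis),
2. view slicing at 60 degree rotations from the LAX azimuth,
3. centre-of-mass aggregation of all candidates inside a +/-15 degree arc
   around each wall azimuth, with an artifact guard on stray candidates,
4. rotation correction — projecting each wall point onto the long axis so
   only the longitudinal component of annular motion is measured,
5. per-volume artifact filtering (a point that moved more than 5 mm from its
   preceding volume is rejected),
6. per-cycle filtering (a cycle with the annulus detected in less than 60 %
   of its volumes is discarded),
7. per-cycle MAPSE as max - min of the longitudinal position, and
8. the recording measurement as the unweighted mean of all feasible
   (wall, cycle) sub-measurements.

A recording is feasible when at least one wall in one cycle survives the
filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .views import ViewSet, WALL_ORDER, circular_delta_deg, slice_views

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeFrame",
    "DetectionStream",
    "LongAxis",
    "FilterConfig",
    "WallTrajectory",
    "RecordingMeasurement",
    "estimate_long_axis",
    "aggregate_arc",
    "filter_candidates",
    "rotation_correct",
    "filter_volumes",
    "filter_cycles",
    "cycle_windows",
    "mapse_per_cycle",
    "aggregate_recording",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class VolumeFrame:
    """Candidate annulus detections of one 3D volume.

    ``azimuth_deg`` has shape (n,), ``positions`` (n, 3) in mm, and
    ``confidence`` is optional with values in [0, 1].
    """

    t: float
    azimuth_deg: np.ndarray
    positions: np.ndarray
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        az = np.atleast_1d(np.asarray(self.azimuth_deg, dtype=float))
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if az.shape[0] != pos.shape[0]:
            raise ValueError("azimuth_deg and positions must have the same length")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if np.any((az < 0) | (az >= 360.0)):
            raise ValueError("azimuths must lie in [0, 360)")
        object.__setattr__(self, "azimuth_deg", az)
        object.__setattr__(self, "positions", pos)
        if self.confidence is not None:
            conf = np.atleast_1d(np.asarray(self.confidence, dtype=float))
            if conf.shape[0] != az.shape[0]:
                raise ValueError("confidence must match the number of points")
            object.__setattr__(self, "confidence", conf)

    @property
    def n_points(self) -> int:
        return int(self.azimuth_deg.shape[0])


@dataclass(frozen=True)
class DetectionStream:
    """Ordered volumes of candidate detections with ECG gating."""

    volumes: tuple[VolumeFrame, ...]
    r_times: np.ndarray
    volume_rate: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "volumes", tuple(self.volumes))
        r = np.atleast_1d(np.asarray(self.r_times, dtype=float))
        if self.volume_rate <= 0:
            raise ValueError("volume_rate must be positive")
        t = np.array([v.t for v in self.volumes], dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("volume timestamps must be strictly increasing")
        if r.size < 2:
            raise ValueError("r_times must span at least one full cardiac cycle")
        if np.any(np.diff(r) <= 0):
            raise ValueError("r_times must be strictly increasing")
        object.__setattr__(self, "r_times", r)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def times(self) -> np.ndarray:
        return np.array([v.t for v in self.volumes], dtype=float)

    @property
    def n_volumes(self) -> int:
        return len(self.volumes)


@dataclass(frozen=True)
class LongAxis:
    """LV long axis as an oriented line; direction points apex -> base."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector (within 1e-9)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class FilterConfig:
    """Artifact-filter thresholds.

    ``max_jump_mm``: a wall point moving *more than* this distance from its
    preceding valid detection is rejected (strict inequality).
    ``max_neighbour_dist_mm``: a candidate farther than this from the body of
    its concurrently detected neighbours is rejected.
    ``min_cycle_detection_frac``: a cycle is kept when at least this fraction
    of its volumes carries a valid detection (inclusive threshold).
    ``neighbour_scope``: "candidate" applies the neighbour rule to raw
    candidates inside each arc (robust to single stray detections);
    "wall" applies it between concurrently detected aggregated wall points.
    """

    max_jump_mm: float = 5.0
    max_neighbour_dist_mm: float = 5.0
    min_cycle_detection_frac: float = 0.60
    neighbour_scope: str = "candidate"

    def __post_init__(self) -> None:
        if self.max_jump_mm <= 0 or self.max_neighbour_dist_mm <= 0:
            raise ValueError("distance thresholds must be positive")
        if not (0.0 < self.min_cycle_detection_frac <= 1.0):
            raise ValueError("min_cycle_detection_frac must lie in (0, 1]")
        if self.neighbour_scope not in ("candidate", "wall"):
            raise ValueError("neighbour_scope must be 'candidate' or 'wall'")


@dataclass
class WallTrajectory:
    """Per-wall longitudinal-position time series with one slot per volume."""

    wall: str
    t: np.ndarray
    positions: np.ndarray        # (n, 3); NaN rows where no detection
    longitudinal_mm: np.ndarray  # (n,);   NaN where invalid
    valid: np.ndarray            # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.valid) == n == len(self.longitudinal_mm) == self.positions.shape[0]):
            raise ValueError("trajectory arrays must share one slot per volume")


@dataclass
class RecordingMeasurement:
    """Recording-level MAPSE with per-(wall, cycle) sub-measurements."""

    sub_measurements: pd.DataFrame  # columns: wall, cycle, value_mm, feasible
    mapse_mm: float | None
    n_walls_contributing: int
    n_cycles_contributing: int
    feasible: bool
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def estimate_long_axis(stream: DetectionStream, supplied: LongAxis | None = None) -> LongAxis:
    """Estimate the LV long axis from the annulus centroid motion.

    A supplied axis is returned unchanged.  Otherwise the axis is the line
    through the time-averaged annulus centroid along the first principal
    direction of the centroid's displacement over time.  The sign is chosen
    so that the end-diastolic (R-wave) position is maximal, i.e. systole is a
    descent toward the apex.  When the centroid does not move, the axis falls
    back to the annulus-plane normal (least-variance direction of all
    points), a degenerate case that still defines a longitudinal direction.
    """
    if supplied is not None:
        return supplied
    centroids = []
    times = []
    all_points = []
    for v in stream.volumes:
        if v.n_points:
            centroids.append(v.positions.mean(axis=0))
            times.append(v.t)
            all_points.append(v.positions)
    if len(centroids) < 2:
        raise ValueError("long axis inestimable: fewer than 2 volumes with detections")
    C = np.asarray(centroids)
    times = np.asarray(times)
    origin = C.mean(axis=0)
    X = C - origin
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    # motion below 1e-6 mm RMS: no usable displacement -> annulus-plane normal
    if s[0] / np.sqrt(len(C)) < 1e-6:
        P = np.concatenate(all_points, axis=0)
        P = P - P.mean(axis=0)
        _, _, vt_p = np.linalg.svd(P, full_matrices=False)
        direction = vt_p[-1]
        logger.warning("stationary annulus centroid: falling back to annulus-plane normal")
    else:
        direction = vt[0]
    direction = direction / np.linalg.norm(direction)
    # orient apex->base: end-diastolic (R-wave) longitudinal position maximal
    proj = X @ direction
    ed_idx = np.unique(np.abs(times[:, None] - stream.r_times[None, :]).argmin(axis=0))
    if proj[ed_idx].mean() < 0.0:
        direction = -direction
    return LongAxis(origin=origin, direction=direction)


def aggregate_arc(frame: VolumeFrame, wall_azimuth_deg: float, halfwidth_deg: float) -> np.ndarray | None:
    """Centre of mass of the candidates inside a circular azimuth arc.

    Membership is inclusive on both edges and wraps around 360 degrees.
    Returns ``None`` when the arc holds no candidate (absence is a value).
    """
    if halfwidth_deg <= 0:
        raise ValueError("halfwidth_deg must be positive")
    if frame.n_points == 0:
        return None
    inside = np.abs(circular_delta_deg(frame.azimuth_deg, wall_azimuth_deg)) <= halfwidth_deg
    if not inside.any():
        return None
    return frame.positions[inside].mean(axis=0)


def filter_candidates(
    frame: VolumeFrame, views: ViewSet, config: FilterConfig
) -> tuple[VolumeFrame, np.ndarray]:
    """Reject candidates stranded far from their concurrently detected arc.

    For every candidate inside a wall arc, the distance to the median
    position of the *other* candidates of the same arc is computed; a
    candidate more than ``max_neighbour_dist_mm`` away is rejected before
    centre-of-mass aggregation.  The median makes the reference robust when
    the arc itself contains an artifact.  Candidates with no concurrent arc
    companion are exempt.  Returns the cleaned frame and a boolean keep-mask
    aligned with the input candidate order.
    """
    keep = np.ones(frame.n_points, dtype=bool)
    for wall, az in views.wall_azimuths.items():
        idx = np.flatnonzero(
            np.abs(circular_delta_deg(frame.azimuth_deg, az)) <= views.arc_halfwidth_deg
        )
        if idx.size < 2:
            continue  # no concurrent neighbour: exempt
        pos = frame.positions[idx]
        for j, i in enumerate(idx):
            others = np.delete(pos, j, axis=0)
            ref = np.median(others, axis=0)
            if np.linalg.norm(pos[j] - ref) > config.max_neighbour_dist_mm:
                keep[i] = False
    if keep.all():
        return frame, keep
    cleaned = VolumeFrame(
        t=frame.t,
        azimuth_deg=frame.azimuth_deg[keep],
        positions=frame.positions[keep],
        confidence=None if frame.confidence is None else frame.confidence[keep],
    )
    return cleaned, keep


def rotation_correct(
    t: np.ndarray, points: np.ndarray, axis: LongAxis, wall: str = ""
) -> WallTrajectory:
    """Project wall points onto the long axis, discarding transverse motion.

    ``points`` has shape (n, 3) with NaN rows for volumes without a
    detection.  The longitudinal position is ``(p - origin) . direction``.
    """
    t = np.asarray(t, dtype=float)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    longitudinal = (points - axis.origin) @ axis.direction
    valid = np.isfinite(longitudinal)
    return WallTrajectory(
        wall=wall, t=t, positions=points, longitudinal_mm=longitudinal, valid=valid
    )


def filter_volumes(
    traj: WallTrajectory,
    neighbours: Sequence[np.ndarray | None] | None,
    config: FilterConfig,
) -> WallTrajectory:
    """Per-volume artifact rejection on an aggregated wall trajectory.

    Rule (a): a sample whose 3D distance to the same wall's valid sample in
    the immediately preceding volume exceeds ``max_jump_mm`` (strictly) is
    invalidated.  When the preceding volume holds no valid sample the rule
    is inapplicable and the sample is exempt — genuine annular motion
    accumulated across a detection gap must not be mistaken for a jump.

    Rule (b) (only with ``neighbour_scope='wall'``): a sample farther than
    ``max_neighbour_dist_mm`` from its nearest concurrently detected wall
    point is invalidated; samples with no concurrent neighbour are exempt.
    ``neighbours`` supplies, per volume, an (m, 3) array of the other walls'
    concurrently detected points (or None).
    """
    valid = traj.valid.copy()
    n = len(valid)
    if config.neighbour_scope == "wall" and neighbours is not None:
        for i in range(n):
            if not valid[i]:
                continue
            nb = neighbours[i]
            if nb is None or len(nb) == 0:
                continue
            d = np.linalg.norm(np.asarray(nb) - traj.positions[i], axis=1)
            if d.min() > config.max_neighbour_dist_mm:
                valid[i] = False
    # rule (a): jump check against the preceding volume's surviving sample
    for i in range(1, n):
        if not valid[i] or not valid[i - 1]:
            continue
        jump = np.linalg.norm(traj.positions[i] - traj.positions[i - 1])
        if jump > config.max_jump_mm:
            valid[i] = False
    longitudinal = np.where(valid, traj.longitudinal_mm, np.nan)
    return WallTrajectory(
        wall=traj.wall,
        t=traj.t,
        positions=traj.positions,
        longitudinal_mm=longitudinal,
        valid=valid,
    )


def cycle_windows(r_times: np.ndarray) -> list[tuple[float, float]]:
    """ECG-defined cardiac cycles as half-open windows [R_i, R_{i+1})."""
    r = np.asarray(r_times, dtype=float)
    return [(float(r[i]), float(r[i + 1])) for i in range(len(r) - 1)]


def filter_cycles(
    traj: WallTrajectory, r_times: np.ndarray, config: FilterConfig
) -> tuple[list[tuple[float, float]], np.ndarray, np.ndarray]:
    """Per-cycle validity: detection in at least 60 % of the cycle's volumes.

    Returns the cycle windows, a boolean validity array, and the detected
    fraction per cycle.  A cycle containing no volumes at all is invalid.
    """
    windows = cycle_windows(r_times)
    valid = np.zeros(len(windows), dtype=bool)
    frac = np.zeros(len(windows), dtype=float)
    for k, (t0, t1) in enumerate(windows):
        in_cycle = (traj.t >= t0) & (traj.t < t1)
        n_vol = int(in_cycle.sum())
        if n_vol == 0:
            logger.warning("cycle [%.3f, %.3f) holds no volumes; discarded", t0, t1)
            continue
        frac[k] = traj.valid[in_cycle].sum() / n_vol
        valid[k] = frac[k] >= config.min_cycle_detection_frac
    return windows, valid, frac


def mapse_per_cycle(traj: WallTrajectory, window: tuple[float, float]) -> float | None:
    """Excursion over one cycle: highest minus lowest longitudinal position.

    Requires at least two valid samples inside the window; otherwise the
    sub-measurement is infeasible and ``None`` is returned.
    """
    t0, t1 = window
    sel = (traj.t >= t0) & (traj.t < t1) & traj.valid
    if sel.sum() < 2:
        return None
    x = traj.longitudinal_mm[sel]
    return float(x.max() - x.min())


def aggregate_recording(subs: pd.DataFrame) -> RecordingMeasurement:
    """Recording MAPSE as the unweighted mean of feasible sub-measurements.

    ``subs`` has columns wall, cycle, value_mm, feasible.  When no
    sub-measurement is feasible the recording is infeasible and carries no
    value.
    """
    if len(subs) == 0:
        subs = pd.DataFrame(columns=["wall", "cycle", "value_mm", "feasible"])
    ok = subs[subs["feasible"].astype(bool)]
    feasible = len(ok) > 0
    return RecordingMeasurement(
        sub_measurements=subs.reset_index(drop=True),
        mapse_mm=float(ok["value_mm"].mean()) if feasible else None,
        n_walls_contributing=int(ok["wall"].nunique()) if feasible else 0,
        n_cycles_contributing=int(ok["cycle"].nunique()) if feasible else 0,
        feasible=feasible,
    )


def run_pipeline(
    stream: DetectionStream,
    axis: LongAxis | None = None,
    views: ViewSet | None = None,
    config: FilterConfig | None = None,
) -> RecordingMeasurement:
    """Full chain from a detection stream to a recording measurement.

    An empty stream is an error; an artifact-saturated stream yields a
    measurement with ``feasible=False`` (absence of a value, not an error).
    Diagnostics record, per wall, the detection/filter counts and which
    candidate points entered the wall aggregates (as (volume, point) index
    pairs into the input stream).
    """
    if stream.n_volumes == 0:
        raise ValueError("empty detection stream")
    config = config or FilterConfig()
    if views is None:
        lax = float(stream.metadata.get("lax_angle_deg", 0.0))
        views = slice_views(lax)
    axis = estimate_long_axis(stream, axis)

    times = stream.times
    n_vol = stream.n_volumes
    walls = list(WALL_ORDER)

    # candidate-level neighbour guard, then per-wall arc aggregation
    used: list[tuple[int, int]] = []
    n_candidates = 0
    n_candidates_removed = 0
    wall_points: dict[str, np.ndarray] = {w: np.full((n_vol, 3), np.nan) for w in walls}
    for i, frame in enumerate(stream.volumes):
        n_candidates += frame.n_points
        if config.neighbour_scope == "candidate":
            cleaned, keep = filter_candidates(frame, views, config)
        else:
            cleaned, keep = frame, np.ones(frame.n_points, dtype=bool)
        n_candidates_removed += int((~keep).sum())
        orig_idx = np.flatnonzero(keep)
        for wall in walls:
            az = views.wall_azimuths[wall]
            if cleaned.n_points == 0:
                continue
            inside = (
                np.abs(circular_delta_deg(cleaned.azimuth_deg, az)) <= views.arc_halfwidth_deg
            )
            if inside.any():
                wall_points[wall][i] = cleaned.positions[inside].mean(axis=0)
                used.extend((i, int(j)) for j in orig_idx[inside])

    # rotation correction and per-volume / per-cycle filtering per wall
    per_wall: dict[str, dict] = {}
    rows = []
    for wall in walls:
        traj = rotation_correct(times, wall_points[wall], axis, wall=wall)
        n_detected = int(traj.valid.sum())
        if config.neighbour_scope == "wall":
            neighbours = []
            for i in range(n_vol):
                nb = [wall_points[w][i] for w in walls if w != wall]
                nb = np.array([p for p in nb if np.all(np.isfinite(p))])
                neighbours.append(nb if len(nb) else None)
        else:
            neighbours = None
        traj = filter_volumes(traj, neighbours, config)
        n_jump_rejected = n_detected - int(traj.valid.sum())
        windows, cyc_valid, frac = filter_cycles(traj, stream.r_times, config)
        for k, (win, ok) in enumerate(zip(windows, cyc_valid)):
            value = mapse_per_cycle(traj, win) if ok else None
            rows.append(
                {
                    "wall": wall,
                    "cycle": k,
                    "value_mm": np.nan if value is None else value,
                    "feasible": value is not None,
                }
            )
        per_wall[wall] = {
            "n_volumes": n_vol,
            "n_detected": n_detected,
            "n_jump_rejected": n_jump_rejected,
            "cycles_valid": cyc_valid.tolist(),
            "cycle_detection_frac": frac.tolist(),
        }

    subs = pd.DataFrame(rows, columns=["wall", "cycle", "value_mm", "feasible"])
    result = aggregate_recording(subs)
    result.diagnostics = {
        "axis_origin": axis.origin.tolist(),
        "axis_direction": axis.direction.tolist(),
        "lax_angle_deg": views.lax_angle_deg,
        "n_candidates": n_candidates,
        "n_candidates_removed": n_candidates_removed,
        "candidates_used": used,
        "per_wall": per_wall,
        "n_cycles": len(cycle_windows(stream.r_times)),
    }
    n_cyc_discarded = sum(
        sum(not v for v in d["cycles_valid"]) for d in per_wall.values()
    )
    logger.info(
        "pipeline: %d candidates (%d removed), %d/%d wall-cycles discarded, feasible=%s",
        n_candidates,
        n_candidates_removed,
        n_cyc_discarded,
        len(walls) * result.diagnostics["n_cycles"],
        result.feasible,
    )
    return result
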