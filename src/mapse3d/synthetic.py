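"""Synthetic annulus-motion, test-retest, and monitoring-series generators.

These generators stand in for the detector front-end and the patient cohort:
they produce detection streams, replicate measurement tables, and monitoring
series with the statistical structure the measurement pipeline and the
agreement statistics assume, together with the ground truth needed for
parameter-recovery and filter-soundness tests.

The annulus is modelled as a planar ring of radius ~15 mm whose plane is
tilted a few degrees to the long-axis normal.  Each wall of the ring
translates along the long axis following a raised-cosine waveform from
end-diastole to end-systole (single excursion extremum at mid-cycle, known
analytic amplitude); a smaller transverse translation and a rigid in-plane
rotation, both following a zero-mean sine waveform, emulate the non-
longitudinal annular motion that rotation correction must remove.  Detection
noise is isotropic Gaussian; dropout removes a wall's detections for a whole
volume (the landmark detector failing for that view); outliers displace
single candidates far from the annulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .pipeline import DetectionStream, LongAxis, VolumeFrame
from .stats import MonitoringSeries
from .views import WALL_LABELS, WALL_ORDER, slice_views

__all__ = [
    "AnnulusMotionParams",
    "GroundTruth",
    "simulate_recording",
    "TestRetestParams",
    "simulate_test_retest",
    "simulate_monitoring_series",
    "DEFAULT_WALL_EXCURSION",
]

#: Annulus ring radius (mm) and tilt of the ring plane to the axis normal.
ANNULUS_RADIUS_MM = 15.0
ANNULUS_TILT_DEG = 5.0
#: Candidate detections emitted per wall arc per volume.
POINTS_PER_ARC = 5

#: Default per-wall longitudinal excursions (mm): septal walls lower than
#: lateral ones, as observed clinically after cardiac surgery.
DEFAULT_WALL_EXCURSION: dict[str, float] = {
    "anterior": 6.2,
    "inferior": 6.5,
    "anterolateral": 8.7,
    "inferoseptal": 6.3,
    "anteroseptal": 5.3,
    "inferolateral": 7.0,
}


@dataclass(frozen=True)
class AnnulusMotionParams:
    """Parameters of one simulated multi-cycle 3D recording.

    Defaults emulate hands-free single-beat full-volume 3D acquisition in a
    postoperative cohort: ~19 volumes/s, heart rate 75/min, 10 cycles per
    recording, sub-millimetre detection noise, occasional whole-wall
    dropout, and rare large outlier artifacts that the filters must catch.
    """

    per_wall_excursion: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WALL_EXCURSION)
    )
    transverse_amplitude: float = 2.0
    rotation_amplitude_deg: float = 3.0
    heart_rate: float = 75.0
    volume_rate: float = 19.4
    n_cycles: int = 10
    noise_sd: float = 0.5
    dropout_prob: float = 0.10
    outlier_prob: float = 0.02
    outlier_magnitude: float = 15.0
    lax_angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.per_wall_excursion) != WALL_LABELS:
            raise ValueError(f"per_wall_excursion must map exactly {sorted(WALL_LABELS)}")
        if any(v < 0 for v in self.per_wall_excursion.values()):
            raise ValueError("excursions must be non-negative")
        if self.volume_rate <= 0 or self.heart_rate <= 0:
            raise ValueError("volume_rate and heart_rate must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        for name in ("dropout_prob", "outlier_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.transverse_amplitude < 0:
            raise ValueError("noise_sd and transverse_amplitude must be non-negative")
        if self.outlier_magnitude <= 0:
            raise ValueError("outlier_magnitude must be positive")
        object.__setattr__(self, "per_wall_excursion", dict(self.per_wall_excursion))


@dataclass(frozen=True)
class GroundTruth:
    """Ground truth emitted alongside a simulated stream, for testing.

    ``outliers`` and ``dropouts`` index into the emitted stream:
    outliers as (volume index, point index within the volume's arrays),
    dropouts as (volume index, wall label).
    """

    axis: LongAxis
    per_wall_excursion: dict[str, float]
    wall_azimuths: dict[str, float]
    mean_excursion: float
    outliers: tuple[tuple[int, int], ...]
    dropouts: tuple[tuple[int, str], ...]

    def to_dict(self) -> dict:
        return {
            "axis": {
                "origin": self.axis.origin.tolist(),
                "direction": self.axis.direction.tolist(),
            },
            "per_wall_excursion": dict(self.per_wall_excursion),
            "wall_azimuths": dict(self.wall_azimuths),
            "mean_excursion": self.mean_excursion,
            "outliers": [list(o) for o in self.outliers],
            "dropouts": [list(d) for d in self.dropouts],
        }


def _raised_cosine(phase: np.ndarray) -> np.ndarray:
    """Longitudinal waveform: 0 at end-diastole, 1 at mid-cycle end-systole."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


def simulate_recording(params: AnnulusMotionParams) -> tuple[DetectionStream, GroundTruth]:
    """Simulate one multi-cycle recording of annulus candidate detections.

    Volumes are sampled at ``volume_rate`` over ``n_cycles`` ECG-defined
    cycles (``ceil(volume_rate * 60 / heart_rate)`` volumes per cycle);
    R-wave times mark exact cycle boundaries.  Each volume carries candidate
    points at azimuths covering the six wall arcs.  Deterministic given the
    seed: all sub-generators derive child streams from one seed sequence.
    """
    T = 60.0 / params.heart_rate
    vpc = math.ceil(params.volume_rate * T)
    n_vol = params.n_cycles * vpc
    times = np.arange(n_vol) / params.volume_rate
    r_times = np.arange(params.n_cycles + 1) * T

    children = np.random.SeedSequence(params.seed).spawn(4)
    rng_noise = np.random.default_rng(children[0])
    rng_dropout = np.random.default_rng(children[1])
    rng_outlier = np.random.default_rng(children[2])
    rng_conf = np.random.default_rng(children[3])

    views = slice_views(params.lax_angle_deg)
    walls = list(WALL_ORDER)
    wall_az = views.wall_azimuths
    excursion = np.array([params.per_wall_excursion[w] for w in walls])

    # tilted ring basis: normal within ANNULUS_TILT_DEG of the long axis (z)
    tilt = math.radians(ANNULUS_TILT_DEG)
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, math.cos(tilt), math.sin(tilt)])

    # candidate material azimuths per wall, spread inside the +/-15 deg arc
    arc_offsets = np.linspace(-12.0, 12.0, POINTS_PER_ARC)

    phase = (times / T) % 1.0
    w_long = _raised_cosine(phase)                      # longitudinal waveform
    w_osc = np.sin(2.0 * np.pi * phase)                 # transverse / rotation waveform

    volumes: list[VolumeFrame] = []
    outliers: list[tuple[int, int]] = []
    dropouts: list[tuple[int, str]] = []
    for i in range(n_vol):
        rot = math.radians(params.rotation_amplitude_deg * w_osc[i])
        trans = np.array([params.transverse_amplitude * w_osc[i], 0.0, 0.0])
        pos_rows = []
        outlier_rows = []
        for k, wall in enumerate(walls):
            dropped = rng_dropout.random() < params.dropout_prob
            psi = np.radians(wall_az[wall] + arc_offsets) + rot
            ring = (
                ANNULUS_RADIUS_MM * np.cos(psi)[:, None] * u
                + ANNULUS_RADIUS_MM * np.sin(psi)[:, None] * v
            )
            pts = ring + trans - excursion[k] * w_long[i] * np.array([0.0, 0.0, 1.0])
            if params.noise_sd > 0:
                pts = pts + rng_noise.normal(0.0, params.noise_sd, size=pts.shape)
            else:
                rng_noise.normal(0.0, 1.0, size=pts.shape)  # keep child stream aligned
            u_out = rng_outlier.random(POINTS_PER_ARC)
            dirs = rng_outlier.normal(size=(POINTS_PER_ARC, 3))
            if dropped:
                dropouts.append((i, wall))
                continue
            is_out = u_out < params.outlier_prob
            if is_out.any():
                dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
                pts[is_out] = pts[is_out] + params.outlier_magnitude * dirs[is_out]
            for p, o in zip(pts, is_out):
                pos_rows.append(p)
                outlier_rows.append(bool(o))
        if pos_rows:
            pos = np.asarray(pos_rows)
            az = np.degrees(np.arctan2(pos[:, 1], pos[:, 0])) % 360.0
            conf = rng_conf.uniform(0.8, 1.0, size=len(pos))
            volumes.append(VolumeFrame(t=times[i], azimuth_deg=az, positions=pos, confidence=conf))
            outliers.extend((i, j) for j, o in enumerate(outlier_rows) if o)
        else:
            volumes.append(
                VolumeFrame(
                    t=times[i], azimuth_deg=np.empty(0), positions=np.empty((0, 3))
                )
            )

    stream = DetectionStream(
        volumes=tuple(volumes),
        r_times=r_times,
        volume_rate=params.volume_rate,
        metadata={
            "lax_angle_deg": params.lax_angle_deg,
            "heart_rate": params.heart_rate,
            "n_cycles": params.n_cycles,
            "seed": params.seed,
        },
    )
    truth = GroundTruth(
        axis=LongAxis(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0])),
        per_wall_excursion=dict(params.per_wall_excursion),
        wall_azimuths=dict(wall_az),
        mean_excursion=float(excursion.mean()),
        outliers=tuple(outliers),
        dropouts=tuple(dropouts),
    )
    return stream, truth


@dataclass(frozen=True)
class TestRetestParams:
    """Parameters of a simulated linked test-retest comparison.

    Each subject is measured by two methods in ``replicates_per_subject``
    linked replicates: value = subject effect + shared replicate effect +
    method offset + method-specific residual.  ``method_bias`` is the
    expected difference method A minus method B.  ``interaction_sd`` adds an
    optional method-by-subject interaction (zero by default).  Defaults
    emulate triplicate postoperative MAPSE recordings: population mean
    5.2 +/- 1.7 mm, residual SDs backed out of single-measurement least
    significant changes of 1.6 mm (automatic) and 0.9 mm (manual), and a
    -1.4 mm automatic-minus-manual offset.
    """

    n_subjects: int = 50
    true_mapse_mean: float = 5.2
    true_mapse_sd: float = 1.7
    within_subject_sd: float = 0.5
    method_bias: float = -1.4
    method_sd_a: float = 1.6 / (2 * 1.96)
    method_sd_b: float = 0.9 / (2 * 1.96)
    replicates_per_subject: int = 3
    interaction_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sds = (
            self.true_mapse_sd,
            self.within_subject_sd,
            self.method_sd_a,
            self.method_sd_b,
            self.interaction_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be non-negative")
        if self.replicates_per_subject < 2:
            raise ValueError("replicates_per_subject must be at least 2")
        if self.n_subjects < 2:
            raise ValueError("variance components unidentifiable with fewer than 2 subjects")


def simulate_test_retest(params: TestRetestParams):
    """Simulate a balanced linked replicate table for two methods.

    Returns a long-format table (columns subject, method, replicate,
    value_mm) and a ground-truth dict with the generating components.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    I, R = params.n_subjects, params.replicates_per_subject
    mu = rng.normal(params.true_mapse_mean, params.true_mapse_sd, size=I)
    a = rng.normal(0.0, params.within_subject_sd, size=(I, R))
    c = rng.normal(0.0, params.interaction_sd, size=(I, 2))
    e_a = rng.normal(0.0, params.method_sd_a, size=(I, R))
    e_b = rng.normal(0.0, params.method_sd_b, size=(I, R))
    y_a = mu[:, None] + a + c[:, [0]] + params.method_bias + e_a
    y_b = mu[:, None] + a + c[:, [1]] + e_b

    rows = []
    for i in range(I):
        for r in range(R):
            rows.append({"subject": i, "method": "A", "replicate": r, "value_mm": y_a[i, r]})
            rows.append({"subject": i, "method": "B", "replicate": r, "value_mm": y_b[i, r]})
    table = pd.DataFrame(rows)
    truth = {
        "bias": params.method_bias,
        "subject_effects": mu,
        "replicate_effects": a,
        "interaction_effects": c,
        "resid_sd": {"A": params.method_sd_a, "B": params.method_sd_b},
        "within_subject_sd": params.within_subject_sd,
    }
    return table, truth


def simulate_monitoring_series(
    trend: Sequence[tuple[float, float]],
    interval_min: float = 5.0,
    duration_min: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MonitoringSeries:
    """Sample a piecewise-linear mm-vs-minute trend at a fixed interval.

    Timestamps run 0, interval, ... up to and including ``duration_min``;
    values are the interpolated trend plus Gaussian noise.  The trend is a
    sequence of (minute, mm) breakpoints, held constant beyond its ends.
    """
    if duration_min <= 0 or interval_min <= 0:
        raise ValueError("duration_min and interval_min must be positive")
    trend = list(trend)
    if not trend:
        raise ValueError("trend must contain at least one (minute, mm) breakpoint")
    tb = np.array([p[0] for p in trend], dtype=float)
    vb = np.array([p[1] for p in trend], dtype=float)
    if np.any(np.diff(tb) < 0):
        raise ValueError("trend breakpoints must be time-ordered")
    t = np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)
    t = t[t <= duration_min]
    values = np.interp(t, tb, vb)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        values = values + rng.normal(0.0, noise_sd, size=len(t))
    return MonitoringSeries(t_min=t, value_mm=values)
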