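"""Driving-simulator vehicle-control metrics and the in-cab detection task.

Telemetry is a uniformly sampled (60 Hz by default) record of vehicle speed,
steering-wheel angle, and lateral/longitudinal acceleration during a drive on
a straight two-lane rural road (3.6 m lanes, 88.5 km/h ≈ 55 mph speed limit).
The derived outcome measures — mean/max velocity, velocity variability,
fraction of the drive over the 55 and 60 mph limits, and steering-wheel /
lateral / longitudinal acceleration variability — are the standard
speed-control and lane-maintenance proxies.  "Variability" is the sample
standard deviation over the full drive.

The driving-simulator visual field (DSVF) task flashes stimuli over a
60°×20° grid, four presentations per location; a location passes when its
detection rate strictly exceeds 50%.  A simulator-based VFI (DS-VFI) scores
the pass map with the same five-ring eccentricity weighting used for the
clinical OU-VFI, with rings scaled to the flat DSVF grid.

Acceleration channels are unit-agnostic: the simulator's native units are
carried through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binocular import weighted_vfi
from .geometry import DEFAULT_RING_BOUNDARIES, RING_WEIGHTS, ring_of

__all__ = [
    "TelemetryError",
    "TelemetryTrace",
    "DriveMetrics",
    "DSVFResult",
    "MPS_PER_MPH",
    "LIMIT_55_MPS",
    "LIMIT_60_MPS",
    "speed_to_mps",
    "compute_drive_metrics",
    "dsvf_grid",
    "score_dsvf",
    "simulate_telemetry",
]

MPS_PER_MPH: float = 0.44704
LIMIT_55_MPS: float = 55 * MPS_PER_MPH  # 24.5872 m/s
LIMIT_60_MPS: float = 60 * MPS_PER_MPH  # 26.8224 m/s

_UNIT_TO_MPS = {"mps": 1.0, "m/s": 1.0, "mph": MPS_PER_MPH, "kmh": 1 / 3.6, "km/h": 1 / 3.6}


class TelemetryError(ValueError):
    """Raised for malformed telemetry or response records."""


def speed_to_mps(value, unit: str):
    """Convert a speed from mph / km/h / m/s to m/s (exact factors)."""
    try:
        factor = _UNIT_TO_MPS[unit.lower()]
    except KeyError:
        raise TelemetryError(f"unknown speed unit {unit!r}; use mps, mph or kmh") from None
    return np.asarray(value, dtype=float) * factor


@dataclass(frozen=True)
class TelemetryTrace:
    """Uniformly sampled vehicle state for one drive.

    Speeds are m/s, steering angles degrees; acceleration channels keep the
    simulator's native units (recorded in ``accel_units`` as metadata).
    """

    t: np.ndarray
    speed: np.ndarray
    steering_angle: np.ndarray
    lat_accel: np.ndarray
    long_accel: np.ndarray
    sample_rate: float
    accel_units: str = "simulator"

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "speed", "steering_angle", "lat_accel", "long_accel"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arrays[name] = arr
        n = arrays["t"].size
        if n == 0:
            raise TelemetryError("telemetry trace is empty")
        for name, arr in arrays.items():
            if arr.shape != (n,):
                raise TelemetryError(f"channel {name} must be 1-D with {n} samples")
            object.__setattr__(self, name, arr)
        if self.sample_rate <= 0:
            raise TelemetryError("sample rate must be positive")
        dt = np.diff(arrays["t"])
        if n > 1 and not np.allclose(dt, 1.0 / self.sample_rate, atol=1e-6, rtol=0):
            raise TelemetryError("timestamps must be strictly increasing with spacing 1/sample_rate")
        if np.any(arrays["speed"] < 0):
            raise TelemetryError("speed must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "speed_mps": self.speed,
                "steer_deg": self.steering_angle,
                "lat_acc": self.lat_accel,
                "long_acc": self.long_accel,
            }
        )


@dataclass(frozen=True)
class DriveMetrics:
    """Vehicle-control outcome measures for one drive."""

    mean_velocity: float
    velocity_sd: float
    max_velocity: float
    pct_over_55: float
    pct_over_60: float
    steering_sd: float
    lat_accel_sd: float
    long_accel_sd: float

    def as_dict(self) -> dict:
        return {
            "mean_velocity": self.mean_velocity,
            "velocity_sd": self.velocity_sd,
            "max_velocity": self.max_velocity,
            "pct_over_55": self.pct_over_55,
            "pct_over_60": self.pct_over_60,
            "steering_sd": self.steering_sd,
            "lat_accel_sd": self.lat_accel_sd,
            "long_accel_sd": self.long_accel_sd,
        }


def compute_drive_metrics(
    trace: TelemetryTrace,
    limit_55: float = LIMIT_55_MPS,
    limit_60: float = LIMIT_60_MPS,
) -> DriveMetrics:
    """Derive the vehicle-control outcomes from one telemetry trace.

    Variabilities are sample standard deviations (ddof=1) over the full
    drive; over-limit fractions use a strict ``speed > limit`` comparison.
    At least two samples are required for the SDs to exist.
    """
    if trace.n_samples < 2:
        raise TelemetryError("at least 2 samples are required for variability metrics")
    sd = lambda x: float(np.std(x, ddof=1))
    return DriveMetrics(
        mean_velocity=float(np.mean(trace.speed)),
        velocity_sd=sd(trace.speed),
        max_velocity=float(np.max(trace.speed)),
        pct_over_55=float(np.mean(trace.speed > limit_55)),
        pct_over_60=float(np.mean(trace.speed > limit_60)),
        steering_sd=sd(trace.steering_angle),
        lat_accel_sd=sd(trace.lat_accel),
        long_accel_sd=sd(trace.long_accel),
    )


# --- DSVF detection task ---------------------------------------------------

#: Vertical half-extent of the DSVF grid is a third of the horizontal one;
#: eccentricity is scaled accordingly before ring lookup.
DSVF_VERTICAL_SCALE: float = 3.0


def dsvf_grid() -> pd.DataFrame:
    """Default DSVF stimulus lattice spanning 60°×20° of visual angle.

    Locations at x ∈ ±{3,9,15,21,27}, y ∈ ±{3,9} (40 locations), mirroring
    the 6°-spaced offset convention of clinical perimetry on a flat grid.
    """
    xs = [x for x in range(-27, 28, 6)]
    ys = [-9, -3, 3, 9]
    rows = [(float(x), float(y)) for y in sorted(ys, reverse=True) for x in xs]
    return pd.DataFrame(rows, columns=["x_deg", "y_deg"])


def _dsvf_weight(x: float, y: float, ring_boundaries, ring_weights) -> float:
    scaled_ecc = float(np.hypot(x, DSVF_VERTICAL_SCALE * y))
    return float(ring_weights[ring_of(scaled_ecc, ring_boundaries) - 1])


@dataclass(frozen=True)
class DSVFResult:
    """Per-location detection outcomes and the simulator-based VFI."""

    locations: pd.DataFrame  # x_deg, y_deg, presentations, hits, detection_rate, passed
    ds_vfi: float

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def pass_fraction(self) -> float:
        return float(self.locations["passed"].mean())


def score_dsvf(
    responses: pd.DataFrame,
    ring_boundaries=DEFAULT_RING_BOUNDARIES,
    ring_weights=RING_WEIGHTS,
) -> DSVFResult:
    """Score the DSVF detection task from per-location presentation records.

    ``responses`` needs columns x_deg, y_deg, presentations, hits (one row
    per location).  A location passes when hits/presentations is strictly
    greater than 0.5.  DS-VFI applies the five-ring weighting to the binary
    pass map (pass → S=100, fail → S=0).
    """
    required = {"x_deg", "y_deg", "presentations", "hits"}
    missing = required - set(responses.columns)
    if missing:
        raise TelemetryError(f"response table missing columns: {sorted(missing)}")
    table = responses.copy()
    if (table["presentations"] < 1).any():
        raise TelemetryError("every tested location needs at least one presentation")
    if (table["hits"] > table["presentations"]).any():
        raise TelemetryError("hits cannot exceed presentations")
    if (table["hits"] < 0).any():
        raise TelemetryError("hits must be non-negative")
    if table.duplicated(["x_deg", "y_deg"]).any():
        raise TelemetryError("duplicate DSVF locations in response table")
    table["detection_rate"] = table["hits"] / table["presentations"]
    table["passed"] = table["detection_rate"] > 0.5
    table = table.sort_values(["y_deg", "x_deg"], ascending=[False, True]).reset_index(drop=True)
    s = np.where(table["passed"], 100.0, 0.0)
    w = np.array(
        [
            _dsvf_weight(x, y, ring_boundaries, ring_weights)
            for x, y in zip(table["x_deg"], table["y_deg"])
        ]
    )
    return DSVFResult(locations=table, ds_vfi=weighted_vfi(s, w))


# --- Telemetry synthesis ----------------------------------------------------


def _ar1(rng: np.random.Generator, n: int, marginal_sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with the requested marginal SD."""
    if marginal_sd < 0:
        raise TelemetryError("noise SDs must be non-negative")
    if marginal_sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_sd)
    innov_sd = marginal_sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def simulate_telemetry(
    duration: float,
    sample_rate: float = 60.0,
    target_speed: float = LIMIT_55_MPS,
    speed_sd: float = 1.5,
    steering_sd: float = 0.5,
    lat_accel_sd: float = 0.003,
    long_accel_sd: float = 0.02,
    ar_coef: float = 0.98,
    seed: int | np.random.SeedSequence | None = 0,
) -> TelemetryTrace:
    """Generate a synthetic straight-road drive with controllable variability.

    Each channel is the target value plus stationary AR(1) perturbations
    (autocorrelation ``ar_coef`` per sample) whose marginal SD equals the
    requested value, emulating the slow wander of real lane-keeping rather
    than white sensor noise.  Speed is clipped at 0.  Reproducible by seed.
    """
    if duration <= 0 or sample_rate <= 0:
        raise TelemetryError("duration and sample_rate must be positive")
    for name, value in (
        ("speed_sd", speed_sd),
        ("steering_sd", steering_sd),
        ("lat_accel_sd", lat_accel_sd),
        ("long_accel_sd", long_accel_sd),
    ):
        if value < 0:
            raise TelemetryError(f"{name} must be non-negative")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sample_rate
    speed = np.clip(target_speed + _ar1(rng, n, speed_sd, ar_coef), 0.0, None)
    steering = _ar1(rng, n, steering_sd, ar_coef)
    lat = _ar1(rng, n, lat_accel_sd, ar_coef)
    long = _ar1(rng, n, long_accel_sd, ar_coef)
    return TelemetryTrace(
        t=t,
        speed=speed,
        steering_angle=steering,
        lat_accel=lat,
        long_accel=long,
        sample_rate=sample_rate,
    )
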