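"""Synthetic jump-trial generator.

Emulates the data a wearable-sensor jump study produces: six body-worn
tri-axial accelerometers (thoracic spine, sacrum, bilateral thigh and shin)
sampled at 100 Hz, and a force platform sampled at 2000 Hz, recorded while a
subject performs countermovement jumps with unilateral or bilateral landings.

The vertical ground-reaction-force (GRF) waveform is a piecewise composition:
quiet stance at 1 BW, a half-sine countermovement dip, a push-off burst, an
exact-zero flight window, a sharp half-sine landing impact whose peak is drawn
from a landing-type-specific truncated normal, and a damped-cosine settle back
to stance.  The sacrum vertical acceleration is coupled to the GRF as
``a_vert = grf_bw - 1`` (so free fall reads -1 g); the remaining sensors are
amplitude-scaled, lag-shifted, noisier transforms of the sacrum signal with a
small limb-swing component during flight.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

GRAVITY = 9.81  # m/s^2, N <-> BW conversion

SENSOR_LOCATIONS = ("thoracic", "sacrum", "thigh_l", "thigh_r", "shin_l", "shin_r")

#: per-location (amplitude scale, lag in sensor samples, extra noise SD in g,
#: flight-swing amplitude in g) applied to the sacrum reference signal
SENSOR_TRANSFORMS = {
    "thoracic": (0.90, 1, 0.02, 0.05),
    "sacrum": (1.00, 0, 0.00, 0.00),
    "thigh_l": (1.30, -1, 0.05, 0.30),
    "thigh_r": (1.30, -1, 0.05, 0.30),
    "shin_l": (1.60, -2, 0.08, 0.40),
    "shin_r": (1.60, -2, 0.08, 0.40),
}

#: cross-axis couplings: x and y carry scaled copies of the vertical channel
AXIS_SCALES = (0.20, 0.10, 1.00)  # (x, y, z); z is vertical

GROUND_CLAMP_BW = 0.05  # ground-phase GRF never drops below the labeling rule


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters of the synthetic jump protocol.

    Defaults mirror the measured cohort: landing peaks of 2.35 (SD 0.38) BW
    for unilateral and 3.13 (SD 0.72) BW for bilateral landings, subject mass
    54.7 (SD 3.3) kg, sensors at 100 Hz and the force plate at 2000 Hz.
    """

    n_subjects: int = 14
    jumps_per_type: int = 3
    landing_types: tuple[str, ...] = ("unilateral", "bilateral")
    sample_rate_sensor: float = 100.0
    sample_rate_plate: float = 2000.0
    peak_mean_unilateral: float = 2.35
    peak_sd_unilateral: float = 0.38
    peak_mean_bilateral: float = 3.13
    peak_sd_bilateral: float = 0.72
    peak_floor: float = 1.2
    flight_duration: tuple[float, float] = (0.30, 0.50)
    noise_sd_per_sensor: float = 0.05
    clock_offset_range: tuple[float, float] = (0.0, 0.0)
    mass_mean: float = 54.7
    mass_sd: float = 3.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.jumps_per_type < 1:
            raise ValueError("n_subjects and jumps_per_type must be >= 1")
        for name in ("sample_rate_sensor", "sample_rate_plate", "mass_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("peak_sd_unilateral", "peak_sd_bilateral", "mass_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.peak_mean_unilateral <= 1.0 or self.peak_mean_bilateral <= 1.0:
            raise ValueError("peak means must exceed 1 BW")
        lo, hi = self.flight_duration
        if not (0 < lo <= hi):
            raise ValueError("flight_duration must be a positive (low, high) range")
        if self.noise_sd_per_sensor < 0:
            raise ValueError("noise_sd_per_sensor must be non-negative")
        unknown = set(self.landing_types) - {"unilateral", "bilateral"}
        if unknown:
            raise ValueError(f"unknown landing types: {sorted(unknown)}")

    def peak_distribution(self, landing_type: str) -> tuple[float, float]:
        if landing_type == "unilateral":
            return self.peak_mean_unilateral, self.peak_sd_unilateral
        if landing_type == "bilateral":
            return self.peak_mean_bilateral, self.peak_sd_bilateral
        raise ValueError(f"unknown landing type: {landing_type!r}")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject draws: identifier and body mass in kg."""

    subject_id: str
    mass: float


@dataclass
class GroundTruthTrial:
    """One simulated jump with its noiseless GRF truth.

    ``grf_bw`` is the plate-rate series; ``grf_bw_sensor`` is the same
    waveform evaluated on the 100 Hz sensor grid (the grid every model
    operates on).  ``phase`` holds 'ground'/'flight' per sensor sample and is,
    by construction, exactly the 0.05 BW rule applied to the noiseless GRF.
    """

    grf_bw: np.ndarray
    grf_bw_sensor: np.ndarray
    sensor_accel: dict[str, np.ndarray]
    phase: np.ndarray
    landing_type: str
    subject_mass: float
    sample_rate_sensor: float
    sample_rate_plate: float
    peak_bw: float = float("nan")

    @property
    def time_sensor(self) -> np.ndarray:
        return np.arange(len(self.grf_bw_sensor)) / self.sample_rate_sensor

    @property
    def time_plate(self) -> np.ndarray:
        return np.arange(len(self.grf_bw)) / self.sample_rate_plate


@dataclass
class SubjectDataset:
    """All trials recorded for one subject."""

    subject_id: str
    mass: float
    trials: list[GroundTruthTrial] = field(default_factory=list)

    def trials_of(self, landing_type: str) -> list[GroundTruthTrial]:
        return [t for t in self.trials if t.landing_type == landing_type]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float) -> float:
    """Rejection-sample Normal(mean, sd) conditioned on >= lower."""
    if sd == 0:
        if mean < lower:
            raise ValueError("degenerate peak distribution below truncation point")
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def _grf_waveform(t: np.ndarray, peak_bw: float, push_amp: float,
                  flight_dur: float, timings: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the piecewise GRF model (BW) on time grid ``t``.

    Returns (grf, is_flight).  Ground-phase values are clamped at 0.05 BW and
    flight values are exactly zero, so thresholding at 0.05 BW recovers the
    flight window sample-for-sample.
    """
    t_stance = timings["stance"]
    t_dip = timings["dip"]
    t_push = timings["push"]
    t_rise = timings["impact_rise"]
    t_fall = timings["impact_fall"]
    t_settle = timings["settle"]

    t0 = t_stance
    t1 = t0 + t_dip          # dip ends
    t_to = t1 + t_push       # takeoff
    t_land = t_to + flight_dur
    t2 = t_land + t_rise     # impact peak
    t3 = t2 + t_fall         # back at ~1 BW
    t4 = t3 + t_settle
    # segment boundaries are multiples of the sensor period; nudge comparisons
    # so float jitter in the time grid cannot misassign a boundary sample
    eps = 1e-9
    t0, t1, t_to, t_land, t2, t3, t4 = (
        x - eps for x in (t0, t1, t_to, t_land, t2, t3, t4))

    w = np.ones_like(t)

    m = (t >= t0) & (t < t1)
    u = (t[m] - t0) / t_dip
    w[m] = 1.0 - 0.35 * np.sin(np.pi * u)

    # push-off: blend of a decaying stance load and a half-sine burst; ends at 0
    m = (t >= t1) & (t < t_to)
    u = (t[m] - t1) / t_push
    w[m] = (1.0 - u) + push_amp * np.sin(np.pi * u)

    is_flight = (t >= t_to) & (t < t_land)
    w[is_flight] = 0.0

    m = (t >= t_land) & (t < t2)
    u = (t[m] - t_land) / t_rise
    w[m] = peak_bw * np.sin(0.5 * np.pi * u)

    m = (t >= t2) & (t < t3)
    u = (t[m] - t2) / t_fall
    w[m] = 1.0 + (peak_bw - 1.0) * np.cos(0.5 * np.pi * u)

    m = (t >= t3) & (t < t4)
    u = (t[m] - t3) / t_settle
    w[m] = 1.0 + 0.12 * (peak_bw - 1.0) * np.exp(-5.0 * u) * np.cos(2 * np.pi * 2.5 * u)

    grf = np.where(is_flight, 0.0, np.maximum(w, GROUND_CLAMP_BW))
    return grf, is_flight


def simulate_trial(config: SimulationConfig, landing_type: str,
                   subject_params: SubjectParams,
                   seed: int | np.random.Generator = 0) -> GroundTruthTrial:
    """Simulate one jump trial for a subject.

    The landing peak is drawn from the landing-type's normal distribution,
    truncated below at ``config.peak_floor`` BW.  Acceleration noise is
    independent Gaussian per axis with SD ``config.noise_sd_per_sensor`` plus a
    per-location extra term.
    """
    if landing_type not in config.landing_types:
        raise ValueError(f"landing type {landing_type!r} not in config.landing_types")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mean, sd = config.peak_distribution(landing_type)
    peak_bw = _truncated_normal(rng, mean, sd, config.peak_floor)
    push_amp = float(rng.uniform(0.50, 0.65))  # push-off stays below peak_floor
    # snap the flight window to the sensor grid so phase boundaries (and the
    # impact-peak instant) fall on exact samples at both rates
    fs_snap = config.sample_rate_sensor
    flight_dur = round(rng.uniform(*config.flight_duration) * fs_snap) / fs_snap

    timings = {"stance": 1.0, "dip": 0.40, "push": 0.30,
               "impact_rise": 0.05, "impact_fall": 0.10, "settle": 0.60}
    total = sum(timings.values()) + flight_dur + 0.5  # trailing stance pad

    fs, fp = config.sample_rate_sensor, config.sample_rate_plate
    t_sensor = np.arange(int(round(total * fs))) / fs
    t_plate = np.arange(int(round(total * fp))) / fp

    grf_plate, _ = _grf_waveform(t_plate, peak_bw, push_amp, flight_dur, timings)
    grf_sensor, flight_sensor = _grf_waveform(t_sensor, peak_bw, push_amp,
                                              flight_dur, timings)
    phase = np.where(flight_sensor, "flight", "ground")

    # sacrum vertical acceleration (g): grf - 1 on the ground, -1 in free fall
    a_ref = grf_sensor - 1.0

    sensor_accel: dict[str, np.ndarray] = {}
    for loc in SENSOR_LOCATIONS:
        scale, lag, extra_sd, swing_amp = SENSOR_TRANSFORMS[loc]
        if landing_type == "unilateral":
            # asymmetric load: the landing limb carries more
            if loc.endswith("_l"):
                scale *= 1.15
            elif loc.endswith("_r"):
                scale *= 0.85
        a_z = scale * np.roll(a_ref, lag)
        if lag > 0:
            a_z[:lag] = a_z[lag]
        elif lag < 0:
            a_z[lag:] = a_z[lag - 1]
        swing = np.zeros_like(a_z)
        if swing_amp > 0:
            swing[flight_sensor] = swing_amp * np.sin(
                2 * np.pi * 4.0 * t_sensor[flight_sensor])
        a_z = a_z + swing
        clean = np.column_stack([AXIS_SCALES[0] * a_z,
                                 AXIS_SCALES[1] * a_z,
                                 a_z])
        noise_sd = config.noise_sd_per_sensor + extra_sd
        noise = rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else 0.0
        sensor_accel[loc] = clean + noise

    return GroundTruthTrial(
        grf_bw=grf_plate, grf_bw_sensor=grf_sensor, sensor_accel=sensor_accel,
        phase=phase, landing_type=landing_type, subject_mass=subject_params.mass,
        sample_rate_sensor=fs, sample_rate_plate=fp, peak_bw=peak_bw,
    )


def simulate_study(config: SimulationConfig) -> list[SubjectDataset]:
    """Simulate the full cohort: ``n_subjects`` subjects, ``jumps_per_type``
    trials per landing type each, deterministic under ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    datasets = []
    for i, ss in enumerate(root.spawn(config.n_subjects)):
        rng = np.random.default_rng(ss)
        mass = float(abs(rng.normal(config.mass_mean, config.mass_sd)))
        subject = SubjectParams(subject_id=f"S{i + 1:02d}", mass=mass)
        trials = []
        for landing_type in config.landing_types:
            for _ in range(config.jumps_per_type):
                trials.append(simulate_trial(config, landing_type, subject, rng))
        datasets.append(SubjectDataset(subject.subject_id, mass, trials))
    return datasets


def _write_csv(path: Path, header: list[str], t0: datetime,
               times: np.ndarray, values: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        values = np.atleast_2d(values.T).T
        for t, row in zip(times, values):
            stamp = (t0 + timedelta(seconds=float(t))).isoformat(timespec="microseconds")
            writer.writerow([stamp] + [f"{v:.6f}" for v in np.atleast_1d(row)])


def export_raw_fixture(trial: GroundTruthTrial, directory: str | Path,
                       clock_offsets: dict[str, float] | None = None,
                       start_time: datetime | None = None,
                       sensors: tuple[str, ...] | None = None) -> dict[str, Path]:
    """Write the trial as the raw per-device CSV files a recording session
    yields: one file per sensor (timestamp + 3 accel columns in g, 100 Hz) and
    ``forceplate.csv`` (timestamp + force in N, 2000 Hz).

    ``clock_offsets`` shifts individual sensor timestamps, emulating the
    between-sensor clock fault of the original hardware.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    clock_offsets = clock_offsets or {}
    t0 = start_time or datetime(2020, 1, 1, 12, 0, 0)
    written: dict[str, Path] = {}

    force_n = trial.grf_bw * trial.subject_mass * GRAVITY
    path = directory / "forceplate.csv"
    _write_csv(path, ["timestamp", "force_n"], t0, trial.time_plate, force_n)
    written["forceplate"] = path

    for loc in (sensors or tuple(trial.sensor_accel)):
        accel = trial.sensor_accel[loc]
        times = trial.time_sensor + clock_offsets.get(loc, 0.0)
        path = directory / f"{loc}.csv"
        _write_csv(path, ["timestamp", "accel_x", "accel_y", "accel_z"],
                   t0, times, accel)
        written[loc] = path
    return written


def with_noise(config: SimulationConfig, noise_sd: float) -> SimulationConfig:
    """Convenience: same protocol at a different sensor noise level."""
    return replace(config, noise_sd_per_sensor=noise_sd)
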