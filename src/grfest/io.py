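"""Raw-file ingest: read per-sensor and force-plate CSVs, downsample the
plate record to the sensor rate, normalise force to body weights, estimate
per-sensor clock offsets against the plate, and collate everything into a
single time-aligned :class:`Trial`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import GRAVITY, SENSOR_LOCATIONS

SENSOR_RATE_HZ = 100.0


class UnsynchronizableError(RuntimeError):
    """Raised when no credible lag aligns a sensor with the force plate."""


@dataclass
class SensorTrace:
    """A single sensor's tri-axial acceleration stream, in g, at 100 Hz."""

    location: str
    timestamps: np.ndarray  # seconds, uniform
    accel: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must be (n, 3)")
        if len(self.timestamps) != len(self.accel) or len(self.accel) < 1:
            raise ValueError("timestamps and accel must be equal length >= 1")
        if not np.all(np.isfinite(self.accel)):
            raise ValueError("non-finite acceleration values")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.ptp(dt) > 1e-6:
                raise ValueError("non-uniform sampling")

    @property
    def rate(self) -> float:
        if len(self.timestamps) < 2:
            return SENSOR_RATE_HZ
        return 1.0 / float(np.mean(np.diff(self.timestamps)))

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the tri-axial sample, in g (no gravity removal)."""
        return np.linalg.norm(self.accel, axis=1)


@dataclass
class ForceRecord:
    """Force-plate record; newtons natively, body weights once normalised."""

    timestamps: np.ndarray
    force: np.ndarray
    rate: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.force = np.asarray(self.force, dtype=float)


@dataclass
class Trial:
    """A collated, synchronised jump trial on the common 100 Hz grid."""

    sensors: dict[str, SensorTrace]
    grf_bw: np.ndarray
    landing_type: str
    subject_mass: float
    phase_labels: np.ndarray | None = None
    sync_offsets: dict[str, float] = field(default_factory=dict)
    time: np.ndarray | None = None

    @property
    def sensor_accel(self) -> dict[str, np.ndarray]:
        return {loc: tr.accel for loc, tr in self.sensors.items()}


def _find_header(path: Path) -> int:
    """Locate the CSV header row, skipping an ActiLife-style preamble block."""
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.lower().lstrip().startswith("timestamp"):
                return i
            if i > 50:
                break
    raise ValueError(f"{path}: no 'timestamp' header found")


def _read_timestamped_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, skiprows=_find_header(Path(path)))
    df.columns = [c.strip().lower() for c in df.columns]
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def _seconds(stamps: pd.Series) -> np.ndarray:
    """Seconds since midnight of the recording day.

    A day-relative base keeps float64 resolution well below a microsecond
    (epoch-absolute seconds would not) while preserving offsets between files
    recorded in the same session.
    """
    ns = stamps.astype("int64").to_numpy()
    day_ns = 86_400_000_000_000
    return (ns - (ns[0] // day_ns) * day_ns) / 1e9


def read_sensor_csv(path: str | Path, location: str | None = None) -> SensorTrace:
    path = Path(path)
    df = _read_timestamped_csv(path)
    cols = [c for c in df.columns if c.startswith("accel")]
    if len(cols) != 3:
        raise ValueError(f"{path}: expected 3 accel columns, found {cols}")
    return SensorTrace(location=location or path.stem,
                       timestamps=_seconds(df["timestamp"]),
                       accel=df[cols].to_numpy())


def read_force_csv(path: str | Path, rate: float = 2000.0) -> ForceRecord:
    df = _read_timestamped_csv(Path(path))
    col = "force_n" if "force_n" in df.columns else df.columns[1]
    return ForceRecord(timestamps=_seconds(df["timestamp"]),
                       force=df[col].to_numpy(), rate=rate)


def downsample_force(record: ForceRecord, target_rate: float = SENSOR_RATE_HZ) -> ForceRecord:
    """Anti-alias filter and decimate the plate record down to ``target_rate``.

    The native rate must be an integer multiple of the target; a zero-phase
    FIR decimator avoids both aliasing of the broadband landing impact and
    phase distortion that would shift the impact peak in time.
    """
    q = record.rate / target_rate
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValueError(f"rate {record.rate} not an integer multiple of {target_rate}")
    q = int(round(q))
    if q == 1:
        return ForceRecord(record.timestamps.copy(), record.force.copy(),
                           target_rate, record.normalized)
    # polyphase FIR decimation; line padding keeps the quiet-stance plateau
    # flat at the record edges instead of ringing against zero-padding
    force = sps.resample_poly(record.force, 1, q, padtype="line")
    n = len(record.force) // q
    return ForceRecord(timestamps=record.timestamps[::q][:n], force=force[:n],
                       rate=target_rate, normalized=record.normalized)


def normalize(record: ForceRecord, mass: float) -> ForceRecord:
    """Convert newtons to body weights: force / (mass * g)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if record.normalized:
        raise ValueError("record already normalized")
    return ForceRecord(record.timestamps.copy(),
                       record.force / (mass * GRAVITY), record.rate, True)


def denormalize(record: ForceRecord, mass: float) -> ForceRecord:
    if not record.normalized:
        raise ValueError("record is not normalized")
    return ForceRecord(record.timestamps.copy(),
                       record.force * (mass * GRAVITY), record.rate, False)


@dataclass
class SyncResult:
    offset_s: float
    residual: float  # sum of squared residuals at the optimum lag
    peak_correlation: float
    low_confidence: bool


def estimate_sync_offset(sensor: SensorTrace, grf: ForceRecord,
                         max_lag: float = 5.0,
                         confidence_ratio: float = 2.0,
                         full: bool = False) -> float | SyncResult:
    """Estimate the sensor clock offset relative to the force plate.

    The acceleration a body segment experiences beyond gravity is
    (GRF - BW)/m, so the sensor magnitude tracks ``|grf_bw - 1|``: flat in
    quiet stance, ~1 g in flight, spiking with the landing impact.  The
    offset is the lag maximising the demeaned cross-correlation between the
    magnitude and that reference over a bounded window — equivalently, the
    lag minimising the sum of squared residuals between the mean-matched
    signals.  Returns the offset in seconds: subtract it from the sensor's
    timestamps to put them on the plate clock.
    """
    mag = sensor.magnitude()
    g = np.asarray(grf.force, dtype=float)
    if np.std(mag) < 1e-12 or np.std(g) < 1e-12:
        raise UnsynchronizableError("flat input: no structure to align on")
    if abs(grf.rate - sensor.rate) > 1e-3:
        raise ValueError("sensor and GRF must share a rate before sync")
    rate = grf.rate
    ref = np.abs(g - 1.0) if grf.normalized else np.abs(g - np.median(g))

    a = mag - mag.mean()
    b = ref - ref.mean()
    corr = sps.correlate(a, b, mode="full")
    lags = sps.correlation_lags(len(a), len(b), mode="full")
    # lag k: sensor sample i matches plate sample i - k on the local grids
    start_shift = sensor.timestamps[0] - grf.timestamps[0]
    offsets = lags / rate + start_shift

    window = np.abs(offsets) <= max_lag
    if not np.any(window):
        raise UnsynchronizableError("lag window excludes all candidate offsets")
    gbest = float(offsets[int(np.argmax(corr))])
    if abs(gbest) > max_lag:
        raise UnsynchronizableError(
            f"best alignment at {gbest:+.2f} s, outside the +/-{max_lag:g} s "
            "lag window; true offset likely exceeds max_lag")
    corr_w, offsets_w = corr[window], offsets[window]
    best = int(np.argmax(corr_w))

    offset = float(offsets_w[best])
    others = np.delete(np.abs(corr_w), best)
    background = float(np.percentile(others, 95)) if len(others) else 0.0
    low_confidence = corr_w[best] < confidence_ratio * max(background, 1e-30)

    k = int(lags[window][best])
    if k >= 0:
        n = min(len(a) - k, len(b))
        resid = float(np.sum((mag[k:k + n] - ref[:n]) ** 2))
    else:
        n = min(len(a), len(b) + k)
        resid = float(np.sum((mag[:n] - ref[-k:-k + n]) ** 2))

    result = SyncResult(offset, resid, float(corr_w[best]), bool(low_confidence))
    return result if full else result.offset_s


def load_and_collate(directory: str | Path, mass: float, landing_type: str,
                     allow_missing: bool = False, max_lag: float = 5.0,
                     manual_offsets: dict[str, float] | None = None) -> Trial:
    """Run the full ingest chain on a raw-fixture directory.

    Reads ``forceplate.csv`` and the six per-sensor CSVs, downsamples the
    plate to 100 Hz, normalises to BW, estimates each sensor's clock offset
    (``manual_offsets`` overrides the estimate), shifts sensors onto the plate
    clock and trims all streams to their common support.  The sacrum sensor is
    mandatory — it anchors synchronisation quality control; other missing
    sensors are tolerated only with ``allow_missing``.
    """
    directory = Path(directory)
    manual_offsets = manual_offsets or {}

    force_path = directory / "forceplate.csv"
    if not force_path.exists():
        raise FileNotFoundError(force_path)
    grf = normalize(downsample_force(read_force_csv(force_path)), mass)

    traces: dict[str, SensorTrace] = {}
    for loc in SENSOR_LOCATIONS:
        path = directory / f"{loc}.csv"
        if not path.exists():
            if loc == "sacrum":
                raise FileNotFoundError(
                    f"{path}: the sacrum sensor anchors synchronisation and is required")
            if not allow_missing:
                raise FileNotFoundError(f"{path} (pass allow_missing=True to proceed)")
            warnings.warn(f"missing sensor file {path.name}; proceeding without it")
            continue
        traces[loc] = read_sensor_csv(path, loc)

    rate = grf.rate
    offsets: dict[str, float] = {}
    aligned: dict[str, SensorTrace] = {}
    for loc, tr in traces.items():
        off = manual_offsets.get(loc)
        if off is None:
            off = estimate_sync_offset(tr, grf, max_lag=max_lag)
        offsets[loc] = float(off)
        aligned[loc] = SensorTrace(loc, tr.timestamps - off, tr.accel)

    t_start = max([grf.timestamps[0]] + [a.timestamps[0] for a in aligned.values()])
    t_end = min([grf.timestamps[-1]] + [a.timestamps[-1] for a in aligned.values()])
    if t_end <= t_start:
        raise UnsynchronizableError("no common time support after alignment")

    n = int(np.floor((t_end - t_start) * rate)) + 1
    grid = t_start + np.arange(n) / rate

    def snap(ts: np.ndarray, values: np.ndarray) -> np.ndarray:
        idx = np.round((grid - ts[0]) * rate).astype(int)
        idx = np.clip(idx, 0, len(values) - 1)
        return values[idx]

    sensors = {loc: SensorTrace(loc, grid, snap(a.timestamps, a.accel))
               for loc, a in aligned.items()}
    grf_bw = snap(grf.timestamps, grf.force)

    from .phase import label_phases  # cyclic at module load otherwise
    return Trial(sensors=sensors, grf_bw=grf_bw, landing_type=landing_type,
                 subject_mass=mass, phase_labels=label_phases(grf_bw),
                 sync_offsets=offsets,
                 # time is referenced to the plate record's start so collated
                 # samples can be mapped back onto the plate timeline
                 time=grid - grf.timestamps[0])
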