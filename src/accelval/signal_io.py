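"""Raw triaxial acceleration streams and between-device agreement.

This module owns the per-second RMS summary used to compare two
simultaneously worn accelerometers: reading/writing raw streams as
delimited text, trimming protocol boundary segments, collapsing each
axis to one RMS value per second, and Pearson agreement between the
two devices' RMS series.

Conventions
-----------
* Acceleration is in gravitational units (g); time in seconds.
* RMS seconds are anchored to the recording's first sample: second k
  covers samples with time offsets in [k, k+1) from the start. This is
  deterministic without any wall-clock synchronisation.
* Agreement between devices with different native rates is always
  computed on the 1-second RMS series, never on raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    DataError,
    FormatError,
    InsufficientDataError,
    ProfileError,
    UndefinedStatisticError,
)

AXES = ("x", "y", "z")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def _rotation_matrix(misalignment) -> np.ndarray:
    """Coerce a misalignment spec into a proper 3-D rotation matrix.

    Accepts None (identity), a 3-tuple of intrinsic x/y/z Euler angles in
    degrees, or a ready 3x3 matrix.
    """
    if misalignment is None:
        return np.eye(3)
    arr = np.asarray(misalignment, dtype=float)
    if arr.shape == (3,):
        return Rotation.from_euler("xyz", arr, degrees=True).as_matrix()
    if arr.shape == (3, 3):
        if not np.allclose(arr @ arr.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(arr), 1.0, atol=1e-8
        ):
            raise ValueError("misalignment matrix is not a proper rotation")
        return arr
    raise ValueError("misalignment must be Euler angles (deg) or a 3x3 matrix")


@dataclass(frozen=True)
class DeviceProfile:
    """Recording-device characteristics.

    Parameters
    ----------
    name : str
        Device identifier (e.g. ``"smartwatch"``, ``"actigraph"``).
    sampling_rate : float
        Samples per second, > 0.
    dynamic_range : float
        Symmetric saturation bound in g (samples clip to ±dynamic_range).
    gain : float
        Unitless scale the device applies to true acceleration.
    misalignment : tuple or ndarray, optional
        Small rotation of the device axes relative to the reference frame;
        Euler angles in degrees or a 3x3 proper rotation matrix.
    noise_sd : float
        Additive white measurement noise SD in g.
    """

    name: str
    sampling_rate: float
    dynamic_range: float
    gain: float = 1.0
    misalignment: tuple = None
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        _rotation_matrix(self.misalignment)  # validates

    @property
    def rotation(self) -> np.ndarray:
        return _rotation_matrix(self.misalignment)


@dataclass
class AccelRecording:
    """A uniformly sampled triaxial acceleration stream.

    samples is an (n, 3) float array in g, ordered x, y, z; times are
    implicit: sample i is at ``start_time + i / sampling_rate``.
    """

    device_id: str
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0
    profile: DeviceProfile | None = field(default=None, repr=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError("samples must be an (n, 3) array")
        if self.samples.shape[0] == 0:
            raise DataError("recording must be non-empty")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples must be finite")
        if self.profile is not None:
            bound = self.profile.dynamic_range * (1 + 1e-12)
            if np.max(np.abs(self.samples)) > bound:
                raise DataError(
                    f"samples exceed the ±{self.profile.dynamic_range} g "
                    f"dynamic range of profile {self.profile.name!r}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording span in seconds (n / rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def axis(self, name: str) -> np.ndarray:
        return self.samples[:, _AXIS_INDEX[name]]


@dataclass
class RmsSeries:
    """One RMS value per whole second for a single axis, in g."""

    axis: str
    values: np.ndarray
    start_second: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise DataError("RMS values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def seconds(self) -> np.ndarray:
        return self.start_second + np.arange(len(self.values))


def read_accel_csv(path, profile: DeviceProfile | None = None) -> AccelRecording:
    """Read a raw acceleration stream from delimited text.

    The file must have a header with columns ``timestamp,x,y,z``
    (timestamp in seconds, acceleration in g) and strictly increasing
    timestamps. The sampling rate is inferred from the median timestamp
    spacing and, if a profile is given, must match its rate within 1%.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["timestamp", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    ts = df["timestamp"].to_numpy(dtype=float)
    if len(ts) == 0:
        raise DataError(f"{path}: empty recording")
    if len(ts) > 1:
        dt = np.diff(ts)
        if np.any(dt <= 0):
            raise DataError(f"{path}: timestamps must be strictly increasing")
        rate = 1.0 / float(np.median(dt))
    elif profile is not None:
        rate = profile.sampling_rate
    else:
        raise DataError(f"{path}: cannot infer sampling rate from one sample")
    if profile is not None and abs(rate - profile.sampling_rate) > 0.01 * profile.sampling_rate:
        raise ProfileError(
            f"{path}: inferred rate {rate:.3g} Hz does not match profile "
            f"{profile.name!r} rate {profile.sampling_rate:.3g} Hz within 1%"
        )
    return AccelRecording(
        device_id=profile.name if profile is not None else path.stem,
        sampling_rate=profile.sampling_rate if profile is not None else rate,
        samples=df[["x", "y", "z"]].to_numpy(dtype=float),
        start_time=float(ts[0]),
        profile=profile,
    )


def write_accel_csv(rec: AccelRecording, path) -> None:
    """Write a recording in the ``timestamp,x,y,z`` text format."""
    df = pd.DataFrame(
        {
            "timestamp": rec.times,
            "x": rec.samples[:, 0],
            "y": rec.samples[:, 1],
            "z": rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False)


def rms_per_second(rec: AccelRecording, axis: str) -> RmsSeries:
    """1-second RMS of one axis: sqrt(mean of squared samples per second).

    Seconds are anchored to the first sample; the trailing partial second
    is dropped.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of {AXES}")
    n_sec = int(np.floor(rec.n_samples / rec.sampling_rate))
    if n_sec < 1:
        raise InsufficientDataError("recording shorter than 1 second")
    x = rec.axis(axis)
    # second index of each sample, anchored to the first sample
    sec = np.floor(np.arange(rec.n_samples) / rec.sampling_rate).astype(int)
    keep = sec < n_sec
    sums = np.bincount(sec[keep], weights=x[keep] ** 2, minlength=n_sec)
    counts = np.bincount(sec[keep], minlength=n_sec)
    values = np.sqrt(sums / counts)
    return RmsSeries(axis=axis, values=values, start_second=int(round(rec.start_time)))


def trim_middle(rec: AccelRecording, keep_duration: float) -> AccelRecording:
    """Keep the centered ``keep_duration`` seconds, dropping both ends equally.

    The retained interval is half-open: a 180 s recording trimmed to 120 s
    keeps samples with time offsets in [30, 150).
    """
    if keep_duration > rec.duration + 1e-9:
        raise ValueError(
            f"keep_duration {keep_duration} s exceeds recording duration {rec.duration:.6g} s"
        )
    n_keep = int(round(keep_duration * rec.sampling_rate))
    offset = (rec.n_samples - n_keep) // 2
    return AccelRecording(
        device_id=rec.device_id,
        sampling_rate=rec.sampling_rate,
        samples=rec.samples[offset : offset + n_keep],
        start_time=rec.start_time + offset / rec.sampling_rate,
        profile=rec.profile,
    )


def _overlap(a: RmsSeries, b: RmsSeries) -> tuple[np.ndarray, np.ndarray]:
    lo = max(a.start_second, b.start_second)
    hi = min(a.start_second + len(a), b.start_second + len(b))
    if hi - lo < 1:
        return np.empty(0), np.empty(0)
    return (
        a.values[lo - a.start_second : hi - a.start_second],
        b.values[lo - b.start_second : hi - b.start_second],
    )


def axis_agreement(a: RmsSeries, b: RmsSeries) -> float:
    """Pearson correlation between two RMS series on their overlapping seconds."""
    va, vb = _overlap(a, b)
    return paired_correlation(va, vb)


def paired_correlation(va: np.ndarray, vb: np.ndarray) -> float:
    """Pearson r of two aligned value arrays, with the agreement contracts."""
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    if len(va) != len(vb):
        raise ValueError("paired series must have equal length")
    if len(va) < 3:
        raise InsufficientDataError(
            f"need >= 3 overlapping seconds, got {len(va)}"
        )
    if np.std(va) == 0 or np.std(vb) == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance series")
    return float(np.corrcoef(va, vb)[0, 1])


def find_lag(
    pairs: Iterable[tuple[RmsSeries, RmsSeries]], max_lag: int = 5
) -> int:
    """Integer-second lag of the second series maximizing mean correlation.

    Optional synchronisation aid (off by default everywhere): scans lags in
    [-max_lag, max_lag], shifting every ``b`` series by the candidate lag,
    and returns the lag with the highest mean Pearson r across pairs.
    """
    pairs = list(pairs)
    best_lag, best_r = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        rs = []
        for a, b in pairs:
            shifted = RmsSeries(b.axis, b.values, b.start_second + lag)
            try:
                rs.append(axis_agreement(a, shifted))
            except (InsufficientDataError, UndefinedStatisticError):
                continue
        if rs and np.mean(rs) > best_r:
            best_r, best_lag = float(np.mean(rs)), lag
    return best_lag


def agreement_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble agreement rows into the standard table layout."""
    return pd.DataFrame(rows, columns=["activity", "axis", "r", "n_seconds"])
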