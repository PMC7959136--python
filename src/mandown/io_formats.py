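"""Reading and writing IMU recordings.

Two on-disk dialects are supported:

* a SisFall-compatible raw-count text format: one sample per line, integer
  counts, comma separated, accelerometer channels first then gyroscope
  channels.  Counts are converted to physical units with the linear rule
  ``value = count * (2 * full_scale) / 2**bits``; rotational speed is stored
  in deg/s on disk and converted to rad/s in memory.
* the toolkit's native labelled format: a CSV with a header row naming the
  columns ``t, ax, ay, az, wx, wy, wz`` plus a YAML sidecar carrying the
  sampling rate, the scenario label and optional ground-truth state
  intervals.

Internal units are fixed: acceleration in g, rotational speed in rad/s.
Degrees appear only at I/O boundaries.  Timestamps are reconstructed from
the sampling rate (``index / fs``) because the raw dialect carries none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import AlignmentError, EmptyInputError, ParseError, RangeError

DEG2RAD = math.pi / 180.0

#: Sensor pairing used by the reference corpus: a 14-bit +/-8 g accelerometer
#: and a 16-bit +/-2000 deg/s gyroscope sampled at 200 Hz.
SISFALL_SENSOR = None  # assigned after SensorSpec is defined


@dataclass(frozen=True)
class SensorSpec:
    """Bit widths and full-scale ranges of a raw-count recording.

    Parameters
    ----------
    accel_bits, gyro_bits
        Signed resolution of each sensor in bits.
    accel_range_g
        Accelerometer full scale (counts span +/- this many g).
    gyro_range_dps
        Gyroscope full scale in deg/s.
    fs
        Sampling rate in Hz.
    """

    accel_bits: int = 14
    accel_range_g: float = 8.0
    gyro_bits: int = 16
    gyro_range_dps: float = 2000.0
    fs: float = 200.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def accel_scale(self) -> float:
        """Physical value of one accelerometer count, in g."""
        return 2.0 * self.accel_range_g / 2 ** self.accel_bits

    @property
    def gyro_scale_dps(self) -> float:
        """Physical value of one gyroscope count, in deg/s."""
        return 2.0 * self.gyro_range_dps / 2 ** self.gyro_bits


SISFALL_SENSOR = SensorSpec()


@dataclass
class ImuRecording:
    """A uniformly sampled 6-DOF inertial recording.

    Attributes
    ----------
    a : (n, 3) ndarray
        Tri-axial acceleration in g.
    w : (n, 3) ndarray
        Tri-axial rotational speed in rad/s.
    fs : float
        Sampling rate in Hz.
    label : str
        Scenario tag (an ADL class, a fall class, or an MDS sub-type).
    ground_truth : dict
        Optional mapping from critical-state tag (``"F"``, ``"I"``, ``"D"``)
        to a list of ``(start_s, end_s)`` intervals during which the state
        truly holds.
    is_mds : bool or None
        Scenario-level man-down label; ``None`` when unknown.
    rec_id : str
        Identifier used in verdict/interval tables.
    """

    a: np.ndarray
    w: np.ndarray
    fs: float
    label: str = ""
    ground_truth: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    is_mds: bool | None = None
    rec_id: str = ""

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError("a must be an (n, 3) array")
        if self.w.shape != self.a.shape:
            raise AlignmentError(
                f"acceleration and rotational speed differ in shape: "
                f"{self.a.shape} vs {self.w.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.a.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds, reconstructed as ``index / fs``."""
        return np.arange(len(self)) / self.fs

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def has_state(self, state: str) -> bool:
        """Whether the ground truth marks any interval of *state*."""
        return bool(self.ground_truth.get(state))

    def copy(self) -> "ImuRecording":
        return replace(
            self,
            a=self.a.copy(),
            w=self.w.copy(),
            ground_truth={k: list(v) for k, v in self.ground_truth.items()},
        )


def _check_counts(counts: np.ndarray, bits: int, name: str, line0: int) -> None:
    limit = 2 ** (bits - 1)
    bad = np.abs(counts) >= limit
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise RangeError(
            f"{name} count {counts[i, j]} at line {line0 + int(i)} exceeds the "
            f"{bits}-bit range (|count| < {limit})"
        )


def read_raw_counts(path: str | Path, sensor: SensorSpec = SISFALL_SENSOR,
                    label: str = "") -> ImuRecording:
    """Read a SisFall-dialect raw-count file into physical units.

    Each line holds one sample: three accelerometer counts then three
    gyroscope counts, comma separated.  Extra trailing columns (e.g. a
    second accelerometer) are ignored.  Counts convert linearly,
    ``count * 2 * range / 2**bits``; gyroscope values are then converted
    from deg/s to rad/s.

    Raises
    ------
    ParseError
        On a malformed row (message carries the 1-based line number).
    RangeError
        When a count exceeds the representable signed bit range.
    """
    path = Path(path)
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip().rstrip(";")
            if not text:
                continue
            parts = [p for p in text.split(",") if p.strip()]
            if len(parts) < 6:
                raise ParseError(
                    f"expected at least 6 comma-separated integers, got {len(parts)}",
                    line=lineno,
                )
            try:
                rows.append([int(p) for p in parts[:6]])
            except ValueError as exc:
                raise ParseError(f"non-integer field ({exc})", line=lineno) from None
    if not rows:
        raise EmptyInputError(f"{path} holds no samples")
    counts = np.asarray(rows, dtype=np.int64)
    _check_counts(counts[:, :3], sensor.accel_bits, "accelerometer", 1)
    _check_counts(counts[:, 3:], sensor.gyro_bits, "gyroscope", 1)
    a = counts[:, :3] * sensor.accel_scale
    w = counts[:, 3:] * sensor.gyro_scale_dps * DEG2RAD
    return ImuRecording(a=a, w=w, fs=sensor.fs, label=label, rec_id=path.stem)


def write_raw_counts(rec: ImuRecording, path: str | Path,
                     sensor: SensorSpec = SISFALL_SENSOR) -> None:
    """Write a recording as SisFall-dialect raw counts (round to nearest)."""
    if len(rec) == 0:
        raise EmptyInputError("refusing to write an empty recording")
    ac = np.rint(rec.a / sensor.accel_scale).astype(np.int64)
    wc = np.rint(rec.w / DEG2RAD / sensor.gyro_scale_dps).astype(np.int64)
    lim_a = 2 ** (sensor.accel_bits - 1) - 1
    lim_w = 2 ** (sensor.gyro_bits - 1) - 1
    ac = np.clip(ac, -lim_a, lim_a)
    wc = np.clip(wc, -lim_w, lim_w)
    counts = np.hstack([ac, wc])
    np.savetxt(path, counts, fmt="%d", delimiter=",")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording in the native CSV + YAML-sidecar format.

    The CSV stores ``t, ax, ay, az, wx, wy, wz`` at 12 significant digits so
    that a round trip reproduces every sample to well under 1e-9 relative
    error.  Metadata (fs, label, MDS flag, ground-truth intervals) goes into
    a sidecar with the same stem and a ``.yaml`` suffix.
    """
    if len(rec) == 0:
        raise EmptyInputError("refusing to write an empty recording")
    path = Path(path)
    data = np.column_stack([rec.t, rec.a, rec.w])
    header = "t,ax,ay,az,wx,wy,wz"
    np.savetxt(path, data, fmt="%.12g", delimiter=",", header=header, comments="")
    meta = {
        "fs": float(rec.fs),
        "label": rec.label,
        "is_mds": rec.is_mds,
        "rec_id": rec.rec_id or path.stem,
        "ground_truth": {
            k: [[float(s), float(e)] for s, e in v]
            for k, v in rec.ground_truth.items()
        },
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_recording(path: str | Path) -> ImuRecording:
    """Read a native-format recording (CSV + YAML sidecar)."""
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"malformed native CSV {path}: {exc}") from None
    if data.size == 0:
        raise EmptyInputError(f"{path} holds no samples")
    if data.shape[1] != 7:
        raise ParseError(f"expected 7 columns in {path}, found {data.shape[1]}")
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    fs = float(meta.get("fs") or round(1.0 / np.median(np.diff(data[:, 0])), 6))
    gt = {
        k: [tuple(iv) for iv in v]
        for k, v in (meta.get("ground_truth") or {}).items()
    }
    return ImuRecording(
        a=data[:, 1:4],
        w=data[:, 4:7],
        fs=fs,
        label=meta.get("label", ""),
        ground_truth=gt,
        is_mds=meta.get("is_mds"),
        rec_id=meta.get("rec_id", path.stem),
    )
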