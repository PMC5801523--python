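"""Trial-recording and study-manifest I/O.

A trial file is comma-delimited plain text: a header row
``timestamp_ms,ax,ay,az`` (optionally followed by ``,gx,gy,gz``; gyroscope
columns are parsed and dropped — they are recorded by the devices but never
analyzed), then one row per sample.  Acceleration is stored in milli-g
(mG, 1 mG = g/1000 with g = 9.80665 m/s²); timestamps are elapsed
milliseconds from trial start.  The dialect is fixed: ``,`` separator,
``.`` decimal, UTF-8, no quoting, full round-trip float precision.

A study manifest is a CSV with one row per trial file, carrying the
(subject, device, condition, attempt) key, the failure flag and reason.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .protocol import FailureReason

STANDARD_GRAVITY = 9.80665  # m/s² per g

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}
_TRIAL_HEADER = ("timestamp_ms", "ax", "ay", "az")
_GYRO_HEADER = ("gx", "gy", "gz")


def _parse_signed_axis(token: str) -> tuple[int, float]:
    sign = 1.0
    axis = token
    if token[0] in "+-":
        sign = -1.0 if token[0] == "-" else 1.0
        axis = token[1:]
    if axis not in _AXIS_INDEX:
        raise ValidationError(f"unknown axis specifier {token!r}")
    return _AXIS_INDEX[axis], sign


@dataclass(frozen=True)
class AxisConvention:
    """Mapping from sensor axes (x, y, z with sign) to body axes.

    ``ap`` is anterior-posterior (front-back), ``ml`` mediolateral,
    ``vertical`` the gravity-aligned axis.  The three sensor axes must be
    a permutation of {x, y, z}.
    """

    device: str
    ap: str = "+z"
    ml: str = "+x"
    vertical: str = "+y"

    def __post_init__(self) -> None:
        if self.device not in ("head", "waist"):
            raise ValidationError(f"device must be 'head' or 'waist', got {self.device!r}")
        axes = [_parse_signed_axis(t)[0] for t in (self.ap, self.ml, self.vertical)]
        if sorted(axes) != [0, 1, 2]:
            raise ValidationError(
                f"axis convention must use each of x,y,z exactly once: "
                f"ap={self.ap} ml={self.ml} vertical={self.vertical}"
            )

    def _extract(self, acc: np.ndarray, token: str) -> np.ndarray:
        idx, sign = _parse_signed_axis(token)
        return sign * acc[..., idx]

    def ap_signal(self, acc: np.ndarray) -> np.ndarray:
        return self._extract(acc, self.ap)

    def ml_signal(self, acc: np.ndarray) -> np.ndarray:
        return self._extract(acc, self.ml)

    def vertical_signal(self, acc: np.ndarray) -> np.ndarray:
        return self._extract(acc, self.vertical)


#: Default sensor-to-body mappings.  The waist phone is worn upright with
#: the screen facing away (screen normal z = AP, long axis y = vertical);
#: the head device is assumed to share the same effective mapping.
DEFAULT_CONVENTIONS: dict[str, AxisConvention] = {
    "waist": AxisConvention("waist", ap="+z", ml="+x", vertical="+y"),
    "head": AxisConvention("head", ap="+z", ml="+x", vertical="+y"),
}


@dataclass
class TrialRecording:
    """One 60 s, 3-axis accelerometer recording for a (subject, device,
    condition, attempt) cell, in mG."""

    subject_id: str
    device: str
    condition: int
    attempt: int
    sample_rate_hz: float
    timestamps_ms: np.ndarray
    acc_mg: np.ndarray
    failed: bool = False
    failure_reason: FailureReason | None = None

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.acc_mg = np.asarray(self.acc_mg, dtype=float)
        if self.device not in ("head", "waist"):
            raise ValidationError(f"device must be 'head' or 'waist', got {self.device!r}")
        if not 1 <= int(self.condition) <= 6:
            raise ValidationError(f"condition must be in 1..6, got {self.condition}")
        if not 1 <= int(self.attempt) <= 2:
            raise ValidationError(f"attempt must be in 1..2, got {self.attempt}")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.timestamps_ms.ndim != 1:
            raise ValidationError("timestamps must be 1-D")
        if self.acc_mg.shape != (self.timestamps_ms.size, 3):
            raise ValidationError(
                f"acc must be (n, 3) matching {self.timestamps_ms.size} timestamps, "
                f"got {self.acc_mg.shape}"
            )
        if self.timestamps_ms.size and np.any(np.diff(self.timestamps_ms) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.acc_mg)):
            raise ValidationError("acceleration values must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps_ms.size)

    @property
    def duration_s(self) -> float:
        """Analyzed span: first-to-last sample plus one sample period."""
        if self.n_samples < 2:
            return 0.0
        span = (self.timestamps_ms[-1] - self.timestamps_ms[0]) / 1000.0
        return float(span + 1.0 / self.sample_rate_hz)

    def with_data(self, timestamps_ms: np.ndarray, acc_mg: np.ndarray,
                  sample_rate_hz: float | None = None) -> "TrialRecording":
        """Copy of this recording with new samples, metadata preserved."""
        return replace(
            self,
            timestamps_ms=np.asarray(timestamps_ms, dtype=float),
            acc_mg=np.asarray(acc_mg, dtype=float),
            sample_rate_hz=self.sample_rate_hz if sample_rate_hz is None else sample_rate_hz,
        )


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject_id: str
    device: str
    condition: int
    attempt: int
    failed: bool = False
    failure_reason: FailureReason | None = None

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.subject_id, self.device, self.condition, self.attempt)


@dataclass
class StudyManifest:
    """Index of all trial files in a study; (subject, device, condition,
    attempt) keys must be unique."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate manifest keys: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, subject_id: str, device: str, condition: int,
               attempt: int) -> ManifestEntry | None:
        key = (subject_id, device, condition, attempt)
        for e in self.entries:
            if e.key == key:
                return e
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [e.path for e in self.entries],
                "subject_id": [e.subject_id for e in self.entries],
                "device": [e.device for e in self.entries],
                "condition": [e.condition for e in self.entries],
                "attempt": [e.attempt for e in self.entries],
                "failed": [e.failed for e in self.entries],
                "failure_reason": [
                    e.failure_reason.value if e.failure_reason else "" for e in self.entries
                ],
            }
        )

    def save_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | os.PathLike, check_files: bool = True) -> "StudyManifest":
        df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False)
        required = {"path", "subject_id", "device", "condition", "attempt", "failed"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"manifest {path} missing columns: {sorted(missing)}")
        base = os.path.dirname(os.fspath(path))
        entries = []
        for row in df.itertuples(index=False):
            fpath = row.path
            if not os.path.isabs(fpath):
                fpath = os.path.join(base, fpath)
            reason = getattr(row, "failure_reason", "")
            failed = row.failed in (True, "True", "true", 1, "1")
            entries.append(
                ManifestEntry(
                    path=fpath,
                    subject_id=str(row.subject_id),
                    device=str(row.device),
                    condition=int(row.condition),
                    attempt=int(row.attempt),
                    failed=failed,
                    failure_reason=FailureReason(reason) if reason else None,
                )
            )
        manifest = cls(entries=entries)
        if check_files:
            for e in manifest.entries:
                if not os.path.exists(e.path):
                    raise ValidationError(f"manifest references missing file: {e.path}")
        return manifest


def read_trial_csv(
    path: str | os.PathLike,
    convention: AxisConvention | None = None,
    meta: ManifestEntry | None = None,
) -> TrialRecording:
    """Read a comma-delimited trial file into a :class:`TrialRecording`.

    Metadata (subject, device, condition, attempt, failure flag) comes from
    ``meta`` when given; otherwise placeholder metadata is attached.
    ``convention`` is accepted for symmetry with the analysis chain but the
    raw axes are stored unmapped.  Errors name the offending 1-based line.
    """
    del convention  # mapping to body axes happens at metric time
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header = tuple(h.strip() for h in lines[0].split(","))
    if header[:4] != _TRIAL_HEADER or header[4:] not in ((), _GYRO_HEADER):
        raise ParseError(f"{path}: line 1: unrecognized header {lines[0]!r}")
    n_cols = len(header)
    ts, acc = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(",")
        if len(fields) != n_cols:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_cols} fields, got {len(fields)}"
            )
        try:
            values = [float(f) for f in fields[:4]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric field ({exc})") from None
        ts.append(values[0])
        acc.append(values[1:4])
    if not ts:
        raise ValidationError(f"{path}: no data rows")
    timestamps = np.asarray(ts, dtype=float)
    if np.any(np.diff(timestamps) <= 0):
        bad = int(np.argmax(np.diff(timestamps) <= 0))
        raise ValidationError(
            f"{path}: line {bad + 3}: timestamps not strictly increasing"
        )
    if len(ts) >= 2:
        rate = 1000.0 / float(np.median(np.diff(timestamps)))
    else:
        rate = 50.0
    if meta is None:
        meta = ManifestEntry(
            path=os.fspath(path), subject_id="", device="waist", condition=1, attempt=1
        )
    return TrialRecording(
        subject_id=meta.subject_id,
        device=meta.device,
        condition=meta.condition,
        attempt=meta.attempt,
        sample_rate_hz=rate,
        timestamps_ms=timestamps,
        acc_mg=np.asarray(acc, dtype=float),
        failed=meta.failed,
        failure_reason=meta.failure_reason,
    )


def write_trial_csv(trial: TrialRecording, path: str | os.PathLike) -> None:
    """Write ``trial`` in the dialect :func:`read_trial_csv` accepts.

    Floats are written with shortest round-trip precision, so
    write → read is the identity and repeated writes are byte-identical.
    """
    if trial.n_samples == 0:
        raise ValidationError("refusing to write a trial with 0 samples")
    rows = ["timestamp_ms,ax,ay,az"]
    for t, (x, y, z) in zip(trial.timestamps_ms, trial.acc_mg):
        rows.append(f"{float(t)!r},{float(x)!r},{float(y)!r},{float(z)!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(rows) + "\n")


def convert_to_milli_g(values: np.ndarray | float) -> np.ndarray | float:
    """Convert acceleration from m/s² to milli-g (out = in / 9.80665 × 1000)."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("acceleration values must be finite")
    out = arr / STANDARD_GRAVITY * 1000.0
    return float(out) if np.isscalar(values) or arr.ndim == 0 else out


def convert_from_milli_g(values: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`convert_to_milli_g` (mG → m/s²)."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("acceleration values must be finite")
    out = arr * STANDARD_GRAVITY / 1000.0
    return float(out) if np.isscalar(values) or arr.ndim == 0 else out


def regularize_sampling(trial: TrialRecording, target_hz: float) -> TrialRecording:
    """Resample onto a uniform grid at ``target_hz`` by linear interpolation.

    The grid spans [first, last] timestamp.  Real capture stamps jitter;
    the analysis assumes a uniform grid, so this is offered as an optional
    pre-step.  Affine signals are reproduced exactly.
    """
    if target_hz <= 0:
        raise ValidationError("target_hz must be positive")
    if trial.n_samples < 2:
        raise ValidationError("need at least 2 samples to resample")
    t0, t1 = trial.timestamps_ms[0], trial.timestamps_ms[-1]
    step = 1000.0 / target_hz
    n = int(np.floor((t1 - t0) / step)) + 1
    if n < 2:
        raise ValidationError("span shorter than 2 samples at target rate")
    grid = t0 + step * np.arange(n)
    acc = np.column_stack(
        [np.interp(grid, trial.timestamps_ms, trial.acc_mg[:, j]) for j in range(3)]
    )
    return trial.with_data(grid, acc, sample_rate_hz=target_hz)
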