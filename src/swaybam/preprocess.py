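"""Trim and low-pass filtering of accelerometer trials.

The analysis chain discards the first 10 s of each 60 s stance (postural
settling) and low-pass filters each axis with a fourth-order Butterworth
at 1.25 Hz, isolating the slow postural-sway band from sensor noise and
tremor.  Filtering defaults to a single causal pass; a zero-phase
(forward-backward) option exists but doubles the effective order and is
off by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, ValidationError
from .trial_io import TrialRecording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification.

    The digital design uses the bilinear transform with cutoff prewarping,
    so the −3 dB point of the realized filter sits exactly at ``cutoff_hz``.
    """

    order: int = 4
    cutoff_hz: float = 1.25
    zero_phase: bool = False
    family: str = "butterworth"
    kind: str = "lowpass"

    def __post_init__(self) -> None:
        if self.family != "butterworth" or self.kind != "lowpass":
            raise ConfigurationError("only low-pass Butterworth filters are supported")
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ConfigurationError("cutoff_hz must be positive")

    def design(self, fs: float) -> tuple[np.ndarray, np.ndarray]:
        if self.cutoff_hz >= fs / 2.0:
            raise ConfigurationError(
                f"cutoff {self.cutoff_hz} Hz must be below Nyquist ({fs / 2.0} Hz)"
            )
        b, a = signal.butter(self.order, self.cutoff_hz, btype="lowpass", fs=fs)
        return b, a


@dataclass(frozen=True)
class TrimSpec:
    """Initial-transient trim: drop the first ``discard_seconds`` of data."""

    discard_seconds: float = 10.0
    expected_trial_seconds: float = 60.0

    def __post_init__(self) -> None:
        if self.discard_seconds < 0:
            raise ConfigurationError("discard_seconds must be non-negative")
        if self.expected_trial_seconds <= self.discard_seconds:
            raise ConfigurationError("expected_trial_seconds must exceed discard_seconds")


def trim_initial(trial: TrialRecording, spec: TrimSpec = TrimSpec()) -> TrialRecording:
    """Drop all samples with elapsed time < ``discard_seconds``.

    Trimming is by elapsed time (not sample count) so jittered capture is
    tolerated.  Sample values are never altered, only membership.
    """
    if trial.n_samples == 0:
        raise ValidationError("no analyzable data: empty trial")
    elapsed_ms = trial.timestamps_ms - trial.timestamps_ms[0]
    keep = elapsed_ms >= spec.discard_seconds * 1000.0
    if keep.sum() < 2:
        raise ValidationError(
            f"no analyzable data: trial spans {elapsed_ms[-1] / 1000.0:.2f} s "
            f"<= discard window {spec.discard_seconds} s"
        )
    out = trial.with_data(trial.timestamps_ms[keep], trial.acc_mg[keep])
    expected = spec.expected_trial_seconds - spec.discard_seconds
    if out.duration_s < expected - 0.5 / trial.sample_rate_hz:
        log.warning(
            "trial %s/%s c%d a%d: only %.2f s retained after trim (expected %.2f s)",
            trial.subject_id, trial.device, trial.condition, trial.attempt,
            out.duration_s, expected,
        )
    return out


def lowpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the specified low-pass Butterworth along axis 0.

    Accepts a 1-D series or an (n, k) array filtered column-wise.  Output
    has the input's length; DC gain is unity.  The causal pass starts from
    steady-state conditions at the first sample, so a constant input (the
    gravity offset) passes through unchanged instead of exciting a startup
    transient; no padding or truncation is performed.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 3 * spec.order:
        raise ValidationError(
            f"signal too short to filter: {n} samples < 3×order ({3 * spec.order})"
        )
    b, a = spec.design(fs)
    if spec.zero_phase:
        return signal.filtfilt(b, a, x, axis=0)
    zi = signal.lfilter_zi(b, a)
    if x.ndim == 1:
        y, _ = signal.lfilter(b, a, x, zi=zi * x[0])
        return y
    y, _ = signal.lfilter(b, a, x, axis=0, zi=zi[:, None] * x[0][None, :])
    return y


def preprocess_trial(
    trial: TrialRecording,
    trim: TrimSpec = TrimSpec(),
    filt: FilterSpec = FilterSpec(),
) -> TrialRecording:
    """Trim then filter (each axis independently); metadata preserved."""
    trimmed = trim_initial(trial, trim)
    acc = lowpass_filter(trimmed.acc_mg, trimmed.sample_rate_hz, filt)
    return trimmed.with_data(trimmed.timestamps_ms, acc)
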