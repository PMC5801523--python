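"""Synthetic two-device balance-study generator.

Produces head- and waist-mounted accelerometer trials with the statistical
structure the downstream analysis assumes, so every stage has a known
ground truth:

* a latent log sway amplitude per (subject, condition, attempt),
  L = μ + log g_c + u_j + e_{jct}, with subject random effect
  u_j ~ N(0, σ_b²) and attempt-level noise e ~ N(0, σ_w²) — this drives
  the test-retest ICC σ_b²/(σ_b²+σ_w²) on the log scale;
* condition gains g₁ < … < g₆ encoding the harder-stance / eyes-closed
  sway increase;
* cross-device coupling: the head's latent amplitude and sway waveform
  share a common component with the waist's, sized so the *pooled*
  (across-condition) correlation of latent log amplitudes equals
  ``device_coupling``;
* sway waveforms modeled as band-limited Gaussian processes (white noise
  shaped by a 2nd-order low-pass at ``sway_bandwidth_hz``, normalized to
  unit RMS, then scaled to exp(L)) — not a biomechanical model, but the
  analysis consumes only second-order signal properties;
* a constant gravity offset on the vertical axis, attenuated ML/vertical
  sway components, white sensor noise, and per-condition Bernoulli
  facilitator-failure flags.

All randomness flows from a single seed through one generator, consumed
in a fixed documented order, so artifacts are bit-reproducible.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .protocol import BAM_PROTOCOL, FailureReason, ProtocolDefinition
from .trial_io import (
    DEFAULT_CONVENTIONS,
    AxisConvention,
    ManifestEntry,
    StudyManifest,
    TrialRecording,
    _parse_signed_axis,
    write_trial_csv,
)

GRAVITY_MG = 1000.0


@dataclass(frozen=True)
class SimulationConfig:
    """Variance components, condition gains, device coupling and noise
    for one simulated study.  Defaults emulate a 42-subject, 6-condition,
    2-attempt, 2-device protocol run."""

    n_subjects: int = 42
    protocol: ProtocolDefinition = field(default_factory=lambda: BAM_PROTOCOL)
    n_attempts: int = 2
    sample_rate_hz: float = 50.0
    trial_seconds: float = 60.0
    baseline_log_amplitude: float = math.log(2.0)  # log mG RMS, easiest stance
    condition_gains: tuple[float, ...] = (1.0, 1.5, 2.0, 3.2, 4.0, 7.0)
    subject_sd: float = 0.45  # σ_b on log amplitude
    attempt_sd: float = 0.19  # σ_w on log amplitude
    head_gain: float = 1.3  # κ: head sway amplification vs waist
    device_coupling: float = 0.9  # target pooled corr of latent log amplitudes
    sway_bandwidth_hz: float = 0.5
    sensor_noise_sd_mg: float = 2.0
    ml_ratio: float = 0.5
    vertical_ratio: float = 0.3
    failure_prob: tuple[float, ...] = (0.0, 0.0, 0.0, 0.06, 0.012, 0.155)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_attempts < 1:
            raise ConfigurationError("n_subjects and n_attempts must be >= 1")
        if len(self.condition_gains) != self.protocol.n_conditions:
            raise ConfigurationError("need one gain per condition")
        if any(g <= 0 for g in self.condition_gains):
            raise ConfigurationError("condition gains must be positive")
        if self.subject_sd < 0 or self.attempt_sd < 0 or self.sensor_noise_sd_mg < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if not 0.0 <= self.device_coupling <= 1.0:
            raise ConfigurationError("device_coupling must be in [0, 1]")
        if len(self.failure_prob) != self.protocol.n_conditions:
            raise ConfigurationError("need one failure probability per condition")
        if any(not 0.0 <= p <= 1.0 for p in self.failure_prob):
            raise ConfigurationError("failure probabilities must be in [0, 1]")
        if self.head_gain <= 0:
            raise ConfigurationError("head_gain must be positive")
        if self.sample_rate_hz <= 0 or self.trial_seconds <= 0:
            raise ConfigurationError("sample_rate_hz and trial_seconds must be positive")
        if self.sway_bandwidth_hz <= 0 or self.sway_bandwidth_hz >= self.sample_rate_hz / 2:
            raise ConfigurationError("sway_bandwidth_hz must be in (0, Nyquist)")
        if self.ml_ratio < 0 or self.vertical_ratio < 0:
            raise ConfigurationError("axis ratios must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("condition_gains", "failure_prob"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class ConditionOrdering(NamedTuple):
    order: tuple[int, ...]  # condition indices, ascending designed sway
    tied: bool


def expected_condition_ordering(config: SimulationConfig) -> ConditionOrdering:
    """Conditions sorted by designed gain; ground truth for recovery tests."""
    gains = np.asarray(config.condition_gains, dtype=float)
    order = tuple(int(i) + 1 for i in np.argsort(gains, kind="stable"))
    tied = len(set(config.condition_gains)) != len(config.condition_gains)
    return ConditionOrdering(order=order, tied=tied)


def latent_coupling_correlation(config: SimulationConfig) -> float:
    """Within-cell random-effect correlation implied by the pooled target.

    ``device_coupling`` targets the pooled correlation of latent log
    amplitudes across conditions; the between-condition gain variance is
    common to both devices, so the subject/attempt components need
    correlation ρ_z = (ρ*(V_g+σ²) − V_g)/σ² (clipped into [0, 1]).
    """
    sigma2 = config.subject_sd**2 + config.attempt_sd**2
    if sigma2 == 0:
        return 1.0
    v_g = float(np.var(np.log(config.condition_gains)))
    rho_z = (config.device_coupling * (v_g + sigma2) - v_g) / sigma2
    return float(min(1.0, max(0.0, rho_z)))


def simulate_latent_log_amplitudes(
    config: SimulationConfig,
    n_subjects: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Draw latent log sway amplitudes, shape (subjects, conditions, attempts).

    Returns waist and head latents plus the subject effects; cheap enough
    for large-n variance-component and coverage studies.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_sub = config.n_subjects if n_subjects is None else n_subjects
    n_cond = config.protocol.n_conditions
    n_att = config.n_attempts
    rho_z = latent_coupling_correlation(config)

    def correlated(shape: tuple[int, ...], sd: float) -> tuple[np.ndarray, np.ndarray]:
        z1 = rng.standard_normal(shape)
        z2 = rng.standard_normal(shape)
        a = sd * z1
        b = sd * (rho_z * z1 + math.sqrt(max(0.0, 1.0 - rho_z**2)) * z2)
        return a, b

    u_w, u_h = correlated((n_sub,), config.subject_sd)
    e_w, e_h = correlated((n_sub, n_cond, n_att), config.attempt_sd)
    log_g = np.log(config.condition_gains)
    base = config.baseline_log_amplitude + log_g[None, :, None]
    l_w = base + u_w[:, None, None] + e_w
    l_h = base + math.log(config.head_gain) + u_h[:, None, None] + e_h
    return {
        "waist": l_w,
        "head": l_h,
        "subject_effect_waist": u_w,
        "subject_effect_head": u_h,
        "coupling_rho_z": rho_z,
    }


def _band_limited_unit_rms(
    rng: np.random.Generator, n_rows: int, n_samples: int, fs: float, bandwidth_hz: float
) -> np.ndarray:
    """Rows of unit-RMS, zero-mean band-limited Gaussian noise."""
    from scipy import signal

    lead = int(round(10 * fs))  # discard shaping-filter transient
    white = rng.standard_normal((n_rows, n_samples + lead))
    b, a = signal.butter(2, bandwidth_hz, btype="lowpass", fs=fs)
    shaped = signal.lfilter(b, a, white, axis=1)[:, lead:]
    shaped = shaped - shaped.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    return shaped / rms


def _renormalize(rows: np.ndarray) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    return rows / np.sqrt(np.mean(rows**2, axis=1, keepdims=True))


def simulate_study(
    config: SimulationConfig,
    conventions: dict[str, AxisConvention] | None = None,
) -> tuple[list[TrialRecording], StudyManifest, pd.DataFrame]:
    """Generate a full two-device study.

    Returns all trial recordings (both devices), the matching manifest
    (synthetic in-memory paths), and a truth table holding every latent
    value and failure flag.  Same config (incl. seed) ⇒ identical output.
    """
    conv = conventions or DEFAULT_CONVENTIONS
    rng = np.random.default_rng(config.seed)
    n_sub, n_cond, n_att = (
        config.n_subjects,
        config.protocol.n_conditions,
        config.n_attempts,
    )
    n_cells = n_sub * n_cond * n_att
    fs = config.sample_rate_hz
    n_samples = int(round(config.trial_seconds * fs))
    latents = simulate_latent_log_amplitudes(config, rng=rng)
    amp_w = np.exp(latents["waist"]).reshape(n_cells)
    amp_h = np.exp(latents["head"]).reshape(n_cells)

    w = config.device_coupling
    axis_ratios = {"ap": 1.0, "ml": config.ml_ratio, "vertical": config.vertical_ratio}
    sway: dict[tuple[str, str], np.ndarray] = {}
    for body_axis, ratio in axis_ratios.items():
        shared = _band_limited_unit_rms(rng, n_cells, n_samples, fs, config.sway_bandwidth_hz)
        head_ind = _band_limited_unit_rms(rng, n_cells, n_samples, fs, config.sway_bandwidth_hz)
        head_shape = _renormalize(
            math.sqrt(w) * shared + math.sqrt(1.0 - w) * head_ind
        ) if w < 1.0 else shared
        sway[("waist", body_axis)] = ratio * amp_w[:, None] * shared
        sway[("head", body_axis)] = ratio * amp_h[:, None] * head_shape

    # facilitator failures, shared across devices
    probs = np.asarray(config.failure_prob)[None, :, None]
    failed = rng.random((n_sub, n_cond, n_att)) < probs
    observed = [FailureReason.FEET_MOVED, FailureReason.ARMS_OFF_CHEST]
    reason_pick = rng.integers(0, len(observed), size=(n_sub, n_cond, n_att))

    timestamps = (1000.0 / fs) * np.arange(n_samples)
    trials: list[TrialRecording] = []
    entries: list[ManifestEntry] = []
    truth_rows = []
    for device in ("waist", "head"):
        convention = conv[device]
        acc = np.zeros((n_cells, n_samples, 3))
        for body_axis in ("ap", "ml", "vertical"):
            token = getattr(convention, "vertical" if body_axis == "vertical" else body_axis)
            idx, sign = _parse_signed_axis(token)
            body = sway[(device, body_axis)]
            if body_axis == "vertical":
                body = body + GRAVITY_MG
            acc[:, :, idx] = sign * body
        if config.sensor_noise_sd_mg > 0:
            acc = acc + config.sensor_noise_sd_mg * rng.standard_normal(acc.shape)

        cell = 0
        for s in range(n_sub):
            subject_id = f"S{s + 1:03d}"
            for c in range(n_cond):
                for t in range(n_att):
                    is_failed = bool(failed[s, c, t])
                    reason = observed[reason_pick[s, c, t]] if is_failed else None
                    rec = TrialRecording(
                        subject_id=subject_id,
                        device=device,
                        condition=c + 1,
                        attempt=t + 1,
                        sample_rate_hz=fs,
                        timestamps_ms=timestamps,
                        acc_mg=acc[cell],
                        failed=is_failed,
                        failure_reason=reason,
                    )
                    trials.append(rec)
                    entries.append(
                        ManifestEntry(
                            path=f"{subject_id}_{device}_c{c + 1}_a{t + 1}.csv",
                            subject_id=subject_id,
                            device=device,
                            condition=c + 1,
                            attempt=t + 1,
                            failed=is_failed,
                            failure_reason=reason,
                        )
                    )
                    if device == "waist":
                        truth_rows.append(
                            {
                                "subject_id": subject_id,
                                "condition": c + 1,
                                "attempt": t + 1,
                                "log_amplitude_waist": latents["waist"][s, c, t],
                                "log_amplitude_head": latents["head"][s, c, t],
                                "failed": is_failed,
                                "failure_reason": reason.value if reason else "",
                            }
                        )
                    cell += 1

    truth = pd.DataFrame(truth_rows)
    truth.attrs["coupling_rho_z"] = latents["coupling_rho_z"]
    truth.attrs["config"] = config
    return trials, StudyManifest(entries=entries), truth


def make_fixture_study(
    size: str,
    seed: int,
    out_dir: str | os.PathLike,
    config: SimulationConfig | None = None,
) -> str:
    """Write a simulated study to disk (trial CSVs + ``manifest.csv``).

    ``size`` is ``tiny`` (4 subjects, fast tests) or ``paper_scale``
    (42 subjects).  Returns the manifest path.
    """
    if size not in ("tiny", "paper_scale"):
        raise ConfigurationError("size must be 'tiny' or 'paper_scale'")
    base = config or SimulationConfig()
    n_subjects = 4 if size == "tiny" else 42
    cfg = replace(base, n_subjects=n_subjects, seed=seed)
    trials, manifest, truth = simulate_study(cfg)
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    for trial, entry in zip(trials, manifest.entries):
        write_trial_csv(trial, os.path.join(out, entry.path))
    manifest_path = os.path.join(out, "manifest.csv")
    manifest.save_csv(manifest_path)
    truth.to_csv(os.path.join(out, "truth.csv"), index=False)
    return manifest_path
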