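"""Postural-sway metrics: normalized path length, standardized scores,
composite score, and per-condition geometric-mean summaries.

Normalized path length (NPL, mG/sec) is the cumulative absolute change of
the filtered acceleration divided by the analyzed duration; higher values
indicate more sway.  The per-axis form sums |x_i − x_{i−1}|; the "total"
form over all three axes defaults to the 3-D path length
Σ‖a_i − a_{i−1}‖₂ / T, which is invariant to the constant gravity offset.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .preprocess import FilterSpec, TrimSpec, preprocess_trial
from .trial_io import AxisConvention, TrialRecording

log = logging.getLogger(__name__)


class TotalNplVariant(str, Enum):
    """Reading of "NPL from the combined acceleration magnitude".

    PATH_3D (default): per-step Euclidean norm of the 3-axis difference
    vector — a genuine 3-D path length, translation-invariant w.r.t. the
    gravity offset.  MAGNITUDE_SERIES: NPL of the scalar series ‖a_i‖
    (gravity-offset sensitive).  NORM_OF_AXIS_NPLS: Euclidean norm of the
    three per-axis NPLs.  All three are provided for cross-comparison.
    """

    PATH_3D = "path_3d"
    MAGNITUDE_SERIES = "magnitude_series"
    NORM_OF_AXIS_NPLS = "norm_of_axis_npls"


@dataclass(frozen=True)
class NplResult:
    subject_id: str
    device: str
    condition: int
    attempt: int
    npl_ap: float
    npl_total: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.npl_ap < 0 or self.npl_total < 0:
            raise ValidationError("NPL values must be non-negative")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")


@dataclass(frozen=True)
class NormativeReference:
    """Per-condition location/scale used to standardize NPL.

    ``log_scale=True`` standardizes log(NPL) instead of raw NPL.  The
    packaged default reference is synthetic (computed from this package's
    own simulator defaults) and is **not** a normative clinical table.
    """

    location: dict[int, float]
    scale: dict[int, float]
    log_scale: bool = False

    def __post_init__(self) -> None:
        for c, s in self.scale.items():
            if s <= 0:
                raise ConfigurationError(f"scale for condition {c} must be > 0")


@dataclass(frozen=True)
class CompositeScore:
    """Sum of standardized NPL over the 6 conditions for one subject-attempt.

    ``value`` is None (with ``reason``) when any condition is missing or
    failed — partial composites are refused rather than rescaled.
    """

    subject_id: str
    attempt: int
    value: float | None
    contributing_conditions: frozenset[int] = field(default_factory=frozenset)
    reason: str | None = None


def normalized_path_length(x: np.ndarray, duration_s: float) -> float:
    """NPL of a 1-D series: Σ|x_i − x_{i−1}| / duration_s (mG/sec)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("need a 1-D series with at least 2 samples")
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    return float(np.sum(np.abs(np.diff(x))) / duration_s)


def total_npl(
    acc: np.ndarray,
    duration_s: float,
    variant: TotalNplVariant = TotalNplVariant.PATH_3D,
) -> float:
    """Total NPL over a 3-axis series (mG/sec); see :class:`TotalNplVariant`."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3 or acc.shape[0] < 2:
        raise ValidationError("need an (n, 3) series with at least 2 samples")
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    if variant is TotalNplVariant.PATH_3D:
        steps = np.linalg.norm(np.diff(acc, axis=0), axis=1)
        return float(np.sum(steps) / duration_s)
    if variant is TotalNplVariant.MAGNITUDE_SERIES:
        return normalized_path_length(np.linalg.norm(acc, axis=1), duration_s)
    per_axis = [normalized_path_length(acc[:, j], duration_s) for j in range(3)]
    return float(np.linalg.norm(per_axis))


def trial_npl(
    trial: TrialRecording,
    convention: AxisConvention,
    trim: TrimSpec = TrimSpec(),
    filt: FilterSpec = FilterSpec(),
    variant: TotalNplVariant = TotalNplVariant.PATH_3D,
) -> NplResult:
    """Full metric chain for one trial: trim → filter → AP and total NPL.

    Failed trials must be excluded upstream; passing one is a contract
    error.
    """
    if trial.failed:
        raise ValidationError(
            f"trial {trial.subject_id}/{trial.device} c{trial.condition} "
            f"a{trial.attempt} is flagged failed; exclude before computing metrics"
        )
    clean = preprocess_trial(trial, trim, filt)
    duration = clean.duration_s
    ap = normalized_path_length(convention.ap_signal(clean.acc_mg), duration)
    total = total_npl(clean.acc_mg, duration, variant)
    return NplResult(
        subject_id=trial.subject_id,
        device=trial.device,
        condition=trial.condition,
        attempt=trial.attempt,
        npl_ap=ap,
        npl_total=total,
        duration_s=duration,
    )


def standardize_npl(value: float, condition: int, ref: NormativeReference) -> float:
    """Standardize one NPL value against the per-condition reference."""
    if condition not in ref.location or condition not in ref.scale:
        raise ConfigurationError(f"reference has no entry for condition {condition}")
    v = math.log(value) if ref.log_scale else value
    return (v - ref.location[condition]) / ref.scale[condition]


def composite_score(
    standardized: dict[int, float],
    subject_id: str = "",
    attempt: int = 1,
) -> CompositeScore:
    """Sum standardized values across all 6 conditions for one attempt.

    Defined only when all 6 conditions contribute; otherwise returns an
    absent score with a reason.
    """
    present = frozenset(standardized)
    if present != frozenset(range(1, 7)):
        missing = sorted(set(range(1, 7)) - present)
        return CompositeScore(
            subject_id=subject_id,
            attempt=attempt,
            value=None,
            contributing_conditions=present,
            reason=f"incomplete conditions (missing {missing})",
        )
    return CompositeScore(
        subject_id=subject_id,
        attempt=attempt,
        value=float(sum(standardized.values())),
        contributing_conditions=present,
    )


def geometric_mean_ci(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[float, float | None, float | None]:
    """Geometric mean with a t-based CI on the log scale.

    Returns (gm, ci_low, ci_high); the CI is None for n = 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("need at least one value")
    if np.any(values <= 0):
        raise ValidationError("geometric mean requires strictly positive values")
    logs = np.log(values)
    gm = float(np.exp(np.mean(logs)))
    n = values.size
    if n == 1:
        return gm, None, None
    sem = float(np.std(logs, ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    return gm, float(np.exp(np.mean(logs) - tcrit * sem)), float(np.exp(np.mean(logs) + tcrit * sem))


#: Synthetic reference table: per-condition mean/SD of retained waist AP
#: NPL (mG/sec) from one simulator-default study (seed 12345).  Frozen for
#: reproducibility; non-normative — supply a study-appropriate table for
#: real analyses.
DEFAULT_SYNTHETIC_REFERENCE = NormativeReference(
    location={1: 5.06, 2: 7.42, 3: 9.62, 4: 15.00, 5: 18.26, 6: 33.48},
    scale={1: 2.73, 2: 3.89, 3: 5.15, 4: 9.17, 5: 9.37, 6: 19.88},
    log_scale=False,
)
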