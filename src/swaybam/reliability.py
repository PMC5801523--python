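"""Validation statistics for two-device balance studies.

Covers failure exclusion / pass accounting, Spearman rank correlation,
the two-way random-effects single-measure intraclass correlation
ICC(2,1) with its 95% CI, the Fisher z comparison of two correlations,
the Kruskal-Wallis rank test, and an Anderson-Darling normality check.

ICC(2,1) and its F-based confidence interval are implemented from the
ANOVA definitions (Shrout & Fleiss; McGraw & Wong formulation):

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E)/n)

with MS_R/MS_C/MS_E the row (subject), column (measurement) and residual
mean squares of the complete n×k two-way layout.  The CI inverts F bounds
with Satterthwaite degrees of freedom for the lower/upper limits.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .metrics import NplResult
from .trial_io import StudyManifest

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReliabilityEstimate:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_measurements: int
    ms_rows: float
    ms_cols: float
    ms_error: float

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.k_measurements < 2:
            raise ValidationError("ICC requires n >= 2 rows and k >= 2 columns")
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValidationError("CI must bracket the point estimate")


@dataclass(frozen=True)
class CorrelationComparison:
    rho_1: float
    rho_2: float
    n_1: int
    n_2: int
    z_statistic: float
    p_value: float


@dataclass(frozen=True)
class PassFailTally:
    """Per-condition counts of subjects passing both attempts, plus the
    count passing everything."""

    n_total: int
    passed_both_by_condition: dict[int, int]
    n_passed_all_conditions: int
    failure_reasons: list[tuple[str, int, int, str]] = field(default_factory=list)


def exclude_failures(
    results: list[NplResult], manifest: StudyManifest
) -> tuple[list[NplResult], PassFailTally]:
    """Drop facilitator-flagged failures and tally the pass pattern.

    A (subject, condition, attempt) counts as failed if any device's
    manifest entry for it is flagged; failure is a property of the stance
    attempt, not of one sensor.
    """
    by_key = {e.key: e for e in manifest.entries}
    # attempt-level failure across devices
    attempt_failed: dict[tuple[str, int, int], bool] = {}
    reasons: list[tuple[str, int, int, str]] = []
    for e in manifest.entries:
        akey = (e.subject_id, e.condition, e.attempt)
        attempt_failed[akey] = attempt_failed.get(akey, False) or e.failed
        if e.failed and e.failure_reason is not None:
            tag = (e.subject_id, e.condition, e.attempt, e.failure_reason.value)
            if tag not in reasons:
                reasons.append(tag)

    retained = []
    for r in results:
        key = (r.subject_id, r.device, r.condition, r.attempt)
        if key not in by_key:
            raise ValidationError(f"result {key} has no manifest entry")
        if not attempt_failed[(r.subject_id, r.condition, r.attempt)]:
            retained.append(r)
    if results and not retained:
        log.warning("all %d trials flagged failed; nothing retained", len(results))

    subjects = sorted({e.subject_id for e in manifest.entries})
    conditions = sorted({e.condition for e in manifest.entries})
    attempts = sorted({e.attempt for e in manifest.entries})
    passed_both = {}
    for c in conditions:
        passed_both[c] = sum(
            all(not attempt_failed.get((s, c, a), True) for a in attempts)
            for s in subjects
        )
    n_all = sum(
        all(
            not attempt_failed.get((s, c, a), True)
            for c in conditions
            for a in attempts
        )
        for s in subjects
    )
    tally = PassFailTally(
        n_total=len(subjects),
        passed_both_by_condition=passed_both,
        n_passed_all_conditions=n_all,
        failure_reasons=reasons,
    )
    return retained, tally


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float | None:
    """Spearman rank correlation (Pearson on midranks); None if undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite (drop missing pairs upstream)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("Spearman undefined for a constant sequence")
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def icc_2_1(data: np.ndarray, alpha: float = 0.05) -> ReliabilityEstimate | None:
    """ICC(2,1) with a 95% (1−alpha) CI from a complete n×k matrix.

    Rows are subjects, columns repeated measurements.  Returns None when
    the matrix has zero total variance (ICC undefined).  No imputation:
    missing cells are a validation error.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data must be a 2-D matrix (subjects × measurements)")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValidationError("need n >= 2 subjects and k >= 2 measurements")
    if not np.all(np.isfinite(data)):
        raise ValidationError("matrix contains missing/non-finite cells; no imputation")
    if np.ptp(data) == 0:
        log.warning("zero total variance: ICC undefined")
        return None

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI (Shrout-Fleiss / McGraw-Wong): Satterthwaite df for the
    # between-columns + error composite.
    if mse > 0:
        fj = msc / mse
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
        del a
    else:  # perfect agreement: degenerate CI
        lower = upper = icc
    lower = min(lower, icc)
    upper = max(upper, icc)
    return ReliabilityEstimate(
        icc=float(icc),
        ci_low=float(lower),
        ci_high=float(upper),
        n_subjects=n,
        k_measurements=k,
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
    )


def compare_correlations_fisher(
    rho_1: float, n_1: int, rho_2: float, n_2: int
) -> CorrelationComparison:
    """Compare two independent correlations via the Fisher z transform.

    z = (atanh ρ₁ − atanh ρ₂) / √(1/(n₁−3) + 1/(n₂−3)); two-sided normal p.
    """
    for rho in (rho_1, rho_2):
        if abs(rho) >= 1.0:
            raise ValidationError("|rho| must be < 1 (Fisher transform diverges)")
    if n_1 < 4 or n_2 < 4:
        raise ValidationError("need n >= 4 in each sample")
    se = math.sqrt(1.0 / (n_1 - 3) + 1.0 / (n_2 - 3))
    z = (math.atanh(rho_1) - math.atanh(rho_2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(
        rho_1=rho_1, rho_2=rho_2, n_1=n_1, n_2=n_2,
        z_statistic=float(z), p_value=float(p),
    )


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p across groups.

    All-identical observations give H = 0, p = 1 (tie-correction divisor
    would vanish).
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def anderson_darling_normal(values: np.ndarray, alpha: float = 0.05) -> tuple[float, bool]:
    """Anderson-Darling A² against a normal with estimated mean/variance.

    Returns (A², reject-at-alpha).  Estimated-parameter ("case 3")
    critical values are used; the statistic is location-scale invariant.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValidationError("need at least 8 observations")
    if np.ptp(values) == 0:
        raise ValidationError("Anderson-Darling undefined for constant input")
    with warnings.catch_warnings():
        # scipy >= 1.17 warns about a future p-value API; we use the
        # classic critical-value table deliberately.
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(values, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float)
    idx = int(np.argmin(np.abs(levels - alpha * 100.0)))
    crit = float(res.critical_values[idx])
    return float(res.statistic), bool(res.statistic > crit)
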