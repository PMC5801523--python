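"""End-to-end study analysis: manifest → sway metrics → validation report.

Composes the I/O, preprocessing, metric and reliability layers into one
deterministic pipeline whose surface mirrors a two-device balance study's
result tables: per-condition geometric means, pooled inter-device
correlations with a Fisher-z contrast, ICC(2,1) per device × metric,
Kruskal-Wallis condition contrasts, composite scores and the pass/fail
tally.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .metrics import (
    DEFAULT_SYNTHETIC_REFERENCE,
    NormativeReference,
    NplResult,
    TotalNplVariant,
    composite_score,
    geometric_mean_ci,
    standardize_npl,
    trial_npl,
)
from .preprocess import FilterSpec, TrimSpec
from .protocol import BAM_PROTOCOL, ProtocolDefinition
from .reliability import (
    CorrelationComparison,
    PassFailTally,
    ReliabilityEstimate,
    anderson_darling_normal,
    compare_correlations_fisher,
    exclude_failures,
    icc_2_1,
    kruskal_wallis,
    spearman_rho,
)
from .trial_io import (
    DEFAULT_CONVENTIONS,
    AxisConvention,
    StudyManifest,
    TrialRecording,
    read_trial_csv,
)

log = logging.getLogger(__name__)

_METRICS = ("npl_ap", "npl_total")


@dataclass
class PipelineConfig:
    trim: TrimSpec = field(default_factory=TrimSpec)
    filt: FilterSpec = field(default_factory=FilterSpec)
    conventions: dict[str, AxisConvention] = field(
        default_factory=lambda: dict(DEFAULT_CONVENTIONS)
    )
    total_variant: TotalNplVariant = TotalNplVariant.PATH_3D
    reference: NormativeReference = field(
        default_factory=lambda: DEFAULT_SYNTHETIC_REFERENCE
    )
    protocol: ProtocolDefinition = field(default_factory=lambda: BAM_PROTOCOL)
    alpha: float = 0.05
    per_condition_icc: bool = True

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "trim" in raw:
            kwargs["trim"] = TrimSpec(**raw["trim"])
        if "filter" in raw:
            kwargs["filt"] = FilterSpec(**raw["filter"])
        if "total_variant" in raw:
            kwargs["total_variant"] = TotalNplVariant(raw["total_variant"])
        if "alpha" in raw:
            kwargs["alpha"] = float(raw["alpha"])
        if "conventions" in raw:
            kwargs["conventions"] = {
                dev: AxisConvention(device=dev, **spec)
                for dev, spec in raw["conventions"].items()
            }
        if "reference" in raw:
            ref = raw["reference"]
            kwargs["reference"] = NormativeReference(
                location={int(k): float(v) for k, v in ref["location"].items()},
                scale={int(k): float(v) for k, v in ref["scale"].items()},
                log_scale=bool(ref.get("log_scale", False)),
            )
        return cls(**kwargs)


@dataclass
class StudyReport:
    npl_table: pd.DataFrame
    condition_summary: pd.DataFrame
    pooled_spearman: dict[str, tuple[float | None, int]]
    fisher_comparison: CorrelationComparison | None
    icc: dict[tuple[str, str], ReliabilityEstimate | None]
    icc_per_condition: dict[tuple[str, str, int], ReliabilityEstimate | None]
    condition_effects: pd.DataFrame
    normality: pd.DataFrame
    composites: pd.DataFrame
    composite_mean: float | None
    composite_sd: float | None
    tally: PassFailTally
    n_trials_manifest: int
    n_trials_retained: int

    def to_markdown(self) -> str:
        lines = ["# Balance study report", ""]
        lines.append(
            f"Trials in manifest: {self.n_trials_manifest}; retained after "
            f"failure exclusion: {self.n_trials_retained}."
        )
        lines.append("")
        lines.append("## Pass/fail tally")
        for c in sorted(self.tally.passed_both_by_condition):
            lines.append(
                f"- condition {c}: {self.tally.passed_both_by_condition[c]}"
                f"/{self.tally.n_total} subjects passed both attempts"
            )
        lines.append(
            f"- all conditions: {self.tally.n_passed_all_conditions}"
            f"/{self.tally.n_total} subjects passed everything"
        )
        lines.append("")
        lines.append("## Pooled inter-device Spearman correlation")
        for metric, (rho, n) in self.pooled_spearman.items():
            shown = "undefined" if rho is None else f"{rho:.3f}"
            lines.append(f"- {metric}: rho = {shown} (n = {n} trial pairs)")
        if self.fisher_comparison is not None:
            fc = self.fisher_comparison
            lines.append(
                f"- Fisher z comparison (total vs AP): z = {fc.z_statistic:.3f}, "
                f"p = {fc.p_value:.4g}"
            )
        lines.append("")
        lines.append("## Test-retest reliability, ICC(2,1)")
        for (device, metric), est in sorted(self.icc.items()):
            if est is None:
                lines.append(f"- {device} {metric}: undefined")
            else:
                lines.append(
                    f"- {device} {metric}: ICC = {est.icc:.3f} "
                    f"(95% CI {est.ci_low:.3f}-{est.ci_high:.3f}, "
                    f"n = {est.n_subjects} rows × {est.k_measurements} attempts)"
                )
        lines.append("")
        lines.append("## Condition contrasts (Kruskal-Wallis)")
        for row in self.condition_effects.itertuples(index=False):
            lines.append(
                f"- {row.device} {row.metric} c{row.condition_a} vs "
                f"c{row.condition_b} ({row.contrast}): H = {row.h_statistic:.2f}, "
                f"p = {row.p_value:.3g} (n = {row.n_a}+{row.n_b})"
            )
        lines.append("")
        if self.composite_mean is not None:
            lines.append(
                f"## Composite score\n\nmean (SD) = {self.composite_mean:.1f} "
                f"({self.composite_sd:.1f}) over {len(self.composites)} "
                "subject-attempts with all 6 conditions."
            )
        lines.append("")
        return "\n".join(lines)

    def write(self, out_dir: str | os.PathLike) -> None:
        out = os.fspath(out_dir)
        os.makedirs(out, exist_ok=True)
        self.npl_table.to_csv(os.path.join(out, "npl_results.csv"), index=False)
        self.condition_summary.to_csv(
            os.path.join(out, "condition_summary.csv"), index=False
        )
        self.condition_effects.to_csv(os.path.join(out, "contrasts.csv"), index=False)
        self.normality.to_csv(os.path.join(out, "normality.csv"), index=False)
        self.composites.to_csv(os.path.join(out, "composites.csv"), index=False)
        flat = []
        for metric, (rho, n) in self.pooled_spearman.items():
            flat.append(("spearman_" + metric, rho, n, "", ""))
        if self.fisher_comparison is not None:
            fc = self.fisher_comparison
            flat.append(("fisher_z_total_vs_ap", fc.z_statistic, fc.n_1, fc.p_value, ""))
        for (device, metric), est in sorted(self.icc.items()):
            if est is not None:
                flat.append(
                    (f"icc_{device}_{metric}", est.icc, est.n_subjects,
                     est.ci_low, est.ci_high)
                )
        if self.composite_mean is not None:
            flat.append(("composite_mean", self.composite_mean, len(self.composites), "", ""))
            flat.append(("composite_sd", self.composite_sd, len(self.composites), "", ""))
        pd.DataFrame(
            flat, columns=["statistic", "value", "n", "extra_low", "extra_high"]
        ).to_csv(os.path.join(out, "statistics.csv"), index=False)
        with open(os.path.join(out, "report.md"), "w", encoding="utf-8") as fh:
            fh.write(self.to_markdown())


def _npl_frame(results: list[NplResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "device": [r.device for r in results],
            "condition": [r.condition for r in results],
            "attempt": [r.attempt for r in results],
            "npl_ap": [r.npl_ap for r in results],
            "npl_total": [r.npl_total for r in results],
            "duration_s": [r.duration_s for r in results],
        }
    )


def report_condition_effects(
    npl: pd.DataFrame,
    protocol: ProtocolDefinition = BAM_PROTOCOL,
    metrics: tuple[str, ...] = _METRICS,
) -> pd.DataFrame:
    """Kruskal-Wallis contrasts per device: each eyes-open vs eyes-closed
    pair, plus easiest stance (condition 1) vs the foam and tandem
    eyes-open conditions.  Empty conditions are skipped and logged."""
    contrasts = [(a, b, "eyes_open_vs_closed") for a, b in protocol.eyes_pairs()]
    contrasts += [(1, 3, "firm_vs_foam"), (1, 5, "feet_together_vs_tandem")]
    rows = []
    for device in sorted(npl["device"].unique()):
        sub = npl[npl["device"] == device]
        for metric in metrics:
            for cond_a, cond_b, label in contrasts:
                ga = sub.loc[sub["condition"] == cond_a, metric].to_numpy()
                gb = sub.loc[sub["condition"] == cond_b, metric].to_numpy()
                if ga.size < 2 or gb.size < 2:
                    log.warning(
                        "skipping contrast c%d vs c%d (%s, %s): too few trials",
                        cond_a, cond_b, device, metric,
                    )
                    continue
                h, p = kruskal_wallis([ga, gb])
                rows.append(
                    {
                        "device": device,
                        "metric": metric,
                        "condition_a": cond_a,
                        "condition_b": cond_b,
                        "contrast": label,
                        "h_statistic": h,
                        "p_value": p,
                        "n_a": ga.size,
                        "n_b": gb.size,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "device", "metric", "condition_a", "condition_b", "contrast",
            "h_statistic", "p_value", "n_a", "n_b",
        ],
    )


def _icc_matrix(sub: pd.DataFrame, metric: str, per_condition: int | None) -> np.ndarray:
    """Rows = (subject[, condition]) with both attempts retained; cols = attempts."""
    if per_condition is not None:
        sub = sub[sub["condition"] == per_condition]
    wide = sub.pivot_table(
        index=["subject_id", "condition"], columns="attempt", values=metric
    )
    wide = wide.dropna()
    return wide.to_numpy()


def analyze_trials(
    trials: list[TrialRecording],
    manifest: StudyManifest,
    config: PipelineConfig | None = None,
) -> StudyReport:
    """Run the full analysis on in-memory trials."""
    cfg = config or PipelineConfig()
    results = []
    for trial in trials:
        if trial.failed:
            log.info(
                "excluding failed trial %s/%s c%d a%d (%s)",
                trial.subject_id, trial.device, trial.condition, trial.attempt,
                trial.failure_reason.value if trial.failure_reason else "unspecified",
            )
            continue
        results.append(
            trial_npl(
                trial,
                cfg.conventions[trial.device],
                trim=cfg.trim,
                filt=cfg.filt,
                variant=cfg.total_variant,
            )
        )
    retained, tally = exclude_failures(results, manifest)
    npl = _npl_frame(retained).sort_values(
        ["device", "subject_id", "condition", "attempt"], ignore_index=True
    )

    # per-condition geometric means
    summary_rows = []
    for (device, condition), group in npl.groupby(["device", "condition"]):
        for metric in _METRICS:
            vals = group[metric].to_numpy()
            vals = vals[vals > 0]
            if vals.size == 0:
                continue
            gm, lo, hi = geometric_mean_ci(vals, cfg.alpha)
            summary_rows.append(
                {
                    "device": device, "condition": condition, "metric": metric,
                    "geometric_mean": gm, "ci_low": lo, "ci_high": hi, "n": vals.size,
                }
            )
    condition_summary = pd.DataFrame(
        summary_rows,
        columns=["device", "condition", "metric", "geometric_mean", "ci_low", "ci_high", "n"],
    )

    # pooled inter-device correlation, one point per retained trial
    head = npl[npl["device"] == "head"]
    waist = npl[npl["device"] == "waist"]
    paired = head.merge(
        waist, on=["subject_id", "condition", "attempt"], suffixes=("_head", "_waist")
    )
    pooled: dict[str, tuple[float | None, int]] = {}
    for metric in _METRICS:
        n_pairs = len(paired)
        rho = (
            spearman_rho(paired[metric + "_head"], paired[metric + "_waist"])
            if n_pairs >= 3
            else None
        )
        pooled[metric] = (rho, n_pairs)
    fisher = None
    rho_ap, n_ap = pooled["npl_ap"]
    rho_tot, n_tot = pooled["npl_total"]
    if rho_ap is not None and rho_tot is not None and min(n_ap, n_tot) >= 4:
        try:
            fisher = compare_correlations_fisher(rho_tot, n_tot, rho_ap, n_ap)
        except ValidationError:
            log.warning("Fisher comparison undefined (|rho| = 1)")

    # ICC(2,1) per device × metric: all retained (subject, condition) rows
    # with both attempts, stacked jointly; plus per-condition panels.
    icc: dict[tuple[str, str], ReliabilityEstimate | None] = {}
    icc_cond: dict[tuple[str, str, int], ReliabilityEstimate | None] = {}
    for device in sorted(npl["device"].unique()):
        sub = npl[npl["device"] == device]
        for metric in _METRICS:
            mat = _icc_matrix(sub, metric, None)
            icc[(device, metric)] = icc_2_1(mat, cfg.alpha) if mat.shape[0] >= 2 and mat.shape[1] >= 2 else None
            if cfg.per_condition_icc:
                for c in sorted(sub["condition"].unique()):
                    mc = _icc_matrix(sub, metric, int(c))
                    icc_cond[(device, metric, int(c))] = (
                        icc_2_1(mc, cfg.alpha) if mc.shape[0] >= 2 and mc.shape[1] >= 2 else None
                    )

    effects = report_condition_effects(npl, cfg.protocol)

    # within-condition normality of NPL
    norm_rows = []
    for (device, condition), group in npl.groupby(["device", "condition"]):
        vals = group["npl_ap"].to_numpy()
        if vals.size >= 8 and np.ptp(vals) > 0:
            a2, reject = anderson_darling_normal(vals, cfg.alpha)
            norm_rows.append(
                {
                    "device": device, "condition": condition,
                    "a_squared": a2, "reject_normality": reject, "n": vals.size,
                }
            )
    normality = pd.DataFrame(
        norm_rows, columns=["device", "condition", "a_squared", "reject_normality", "n"]
    )

    # composite score from waist AP NPL
    comp_rows = []
    for (subject, attempt), group in waist.groupby(["subject_id", "attempt"]):
        standardized = {
            int(row.condition): standardize_npl(row.npl_ap, int(row.condition), cfg.reference)
            for row in group.itertuples(index=False)
        }
        score = composite_score(standardized, subject_id=subject, attempt=int(attempt))
        if score.value is not None:
            comp_rows.append(
                {"subject_id": subject, "attempt": attempt, "composite": score.value}
            )
        else:
            log.info("composite absent for %s attempt %s: %s", subject, attempt, score.reason)
    composites = pd.DataFrame(comp_rows, columns=["subject_id", "attempt", "composite"])
    comp_mean = float(composites["composite"].mean()) if len(composites) else None
    comp_sd = (
        float(composites["composite"].std(ddof=1)) if len(composites) > 1 else None
    )

    return StudyReport(
        npl_table=npl,
        condition_summary=condition_summary,
        pooled_spearman=pooled,
        fisher_comparison=fisher,
        icc=icc,
        icc_per_condition=icc_cond,
        condition_effects=effects,
        normality=normality,
        composites=composites,
        composite_mean=comp_mean,
        composite_sd=comp_sd,
        tally=tally,
        n_trials_manifest=len(manifest),
        n_trials_retained=len(retained),
    )


def run_pipeline(
    manifest_path: str | os.PathLike,
    config: PipelineConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> StudyReport:
    """Load a study from disk, analyze it, optionally write result files.

    Deterministic given inputs and config; every exclusion is logged.
    """
    cfg = config or PipelineConfig()
    manifest = StudyManifest.load_csv(manifest_path)
    trials = [
        read_trial_csv(e.path, cfg.conventions.get(e.device), meta=e)
        for e in manifest.entries
    ]
    report = analyze_trials(trials, manifest, cfg)
    if out_dir is not None:
        report.write(out_dir)
    return report
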