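"""Validation statistics: exclusion tallies, Spearman, ICC(2,1),
Fisher z, Kruskal-Wallis, Anderson-Darling."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import swaybam as sb


def make_manifest(n_subjects=42, failing=None):
    """Two-device manifest; ``failing`` maps (subject_idx, condition) to
    the list of failed attempts."""
    failing = failing or {}
    entries = []
    for s in range(n_subjects):
        sid = f"S{s + 1:03d}"
        for device in ("head", "waist"):
            for c in range(1, 7):
                for a in (1, 2):
                    failed = a in failing.get((s, c), [])
                    entries.append(
                        sb.ManifestEntry(
                            path=f"{sid}_{device}_{c}_{a}.csv",
                            subject_id=sid, device=device, condition=c, attempt=a,
                            failed=failed,
                            failure_reason=sb.FailureReason.FEET_MOVED if failed else None,
                        )
                    )
    return sb.StudyManifest(entries=entries)


def results_for(manifest):
    return [
        sb.NplResult(e.subject_id, e.device, e.condition, e.attempt, 1.0, 2.0, 50.0)
        for e in manifest.entries
    ]


class TestExcludeFailures:
    def test_no_failures_retains_everything(self):
        manifest = make_manifest(n_subjects=5)
        results = results_for(manifest)
        retained, tally = sb.exclude_failures(results, manifest)
        assert len(retained) == len(results)
        assert tally.passed_both_by_condition == {c: 5 for c in range(1, 7)}
        assert tally.n_passed_all_conditions == 5

    def test_constructed_condition4_failures_tally_37(self):
        failing = {(s, 4): [1] for s in range(5)}  # 5 subjects fail one attempt
        manifest = make_manifest(n_subjects=42, failing=failing)
        retained, tally = sb.exclude_failures(results_for(manifest), manifest)
        assert tally.n_total == 42
        assert tally.passed_both_by_condition[4] == 37
        assert tally.passed_both_by_condition[1] == 42
        assert tally.n_passed_all_conditions == 37
        # failed trials dropped on both devices
        assert len(retained) == (42 * 6 * 2 - 5) * 2

    def test_all_failed_returns_empty_with_warning(self, caplog):
        failing = {(s, c): [1, 2] for s in range(2) for c in range(1, 7)}
        manifest = make_manifest(n_subjects=2, failing=failing)
        with caplog.at_level("WARNING"):
            retained, tally = sb.exclude_failures(results_for(manifest), manifest)
        assert retained == []
        assert tally.n_passed_all_conditions == 0
        assert any("nothing retained" in r.message for r in caplog.records)

    def test_result_without_manifest_entry_rejected(self):
        manifest = make_manifest(n_subjects=1)
        orphan = sb.NplResult("S999", "waist", 1, 1, 1.0, 2.0, 50.0)
        with pytest.raises(sb.ValidationError, match="no manifest entry"):
            sb.exclude_failures([orphan], manifest)


def spearman_oracle(x, y):
    """Brute-force midrank Spearman: Pearson correlation of average ranks."""

    def midranks(v):
        v = list(v)
        ranks = []
        for vi in v:
            less = sum(1 for u in v if u < vi)
            equal = sum(1 for u in v if u == vi)
            ranks.append(less + (equal + 1) / 2.0)
        return np.asarray(ranks)

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert sb.spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert sb.spearman_rho(x, -(x**3)) == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        assert sb.spearman_rho(x, y) == pytest.approx(spearman_oracle(x, y), rel=1e-12)

    @given(seed=st.integers(0, 2**16), n=st.integers(4, 30))
    def test_matches_midrank_oracle_with_random_ties(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=n).astype(float)
        y = rng.integers(0, 5, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            assert sb.spearman_rho(x, y) is None
        else:
            assert sb.spearman_rho(x, y) == pytest.approx(
                spearman_oracle(x, y), rel=1e-9
            )

    def test_constant_sequence_is_undefined(self):
        assert sb.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None


def icc_anova_oracle(data):
    """From-scratch two-way ANOVA decomposition by explicit loops."""
    n, k = data.shape
    grand = sum(data[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(data[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_err = sum(
        (data[i][j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc21:
    def test_identical_columns_give_one(self):
        col = np.array([1.0, 4.0, 2.0, 9.0])
        est = sb.icc_2_1(np.column_stack([col, col]))
        assert est.icc == pytest.approx(1.0)

    @given(seed=st.integers(0, 2**16))
    def test_small_matrices_match_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(4, 2))
        est = sb.icc_2_1(data)
        assert est.icc == pytest.approx(icc_anova_oracle(data), rel=1e-9)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        data = rng.normal(size=(20, 3)) + rng.normal(size=(20, 1)) * 2.0
        est = sb.icc_2_1(data)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 3),
                "rater": np.tile(np.arange(3), 20),
                "score": data.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        row = ref.loc["ICC(A,1)"]  # two-way random, single measure, agreement
        assert est.icc == pytest.approx(row["ICC"], abs=1e-6)
        lo, hi = row["CI95"]
        assert est.ci_low == pytest.approx(lo, abs=6e-3)  # pingouin rounds CI
        assert est.ci_high == pytest.approx(hi, abs=6e-3)

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(9)
        n = 500
        rows = rng.normal(scale=math.sqrt(3.0), size=(n, 1))
        data = rows + rng.normal(scale=1.0, size=(n, 2))
        est = sb.icc_2_1(data)
        assert est.icc == pytest.approx(0.75, abs=0.05)
        assert est.ci_low < 0.75 < est.ci_high

    @given(
        a=st.floats(0.1, 50, allow_nan=False),
        b=st.floats(-100, 100, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_invariant_under_affine_transform(self, a, b, seed):
        data = np.random.default_rng(seed).normal(size=(8, 2))
        est = sb.icc_2_1(data)
        est2 = sb.icc_2_1(a * data + b)
        assert est2.icc == pytest.approx(est.icc, rel=1e-6, abs=1e-9)

    def test_zero_variance_is_undefined(self):
        assert sb.icc_2_1(np.full((4, 2), 3.0)) is None

    def test_missing_cells_rejected(self):
        data = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(sb.ValidationError):
            sb.icc_2_1(data)


class TestFisherComparison:
    def test_equal_correlations_give_zero(self):
        cmp = sb.compare_correlations_fisher(0.7, 50, 0.7, 80)
        assert cmp.z_statistic == 0.0
        assert cmp.p_value == pytest.approx(1.0)

    def test_antisymmetric_in_arguments(self):
        c1 = sb.compare_correlations_fisher(0.9, 100, 0.5, 60)
        c2 = sb.compare_correlations_fisher(0.5, 60, 0.9, 100)
        assert c1.z_statistic == pytest.approx(-c2.z_statistic)
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_closed_form_example(self):
        cmp = sb.compare_correlations_fisher(0.9, 100, 0.5, 100)
        expected = (math.atanh(0.9) - math.atanh(0.5)) / math.sqrt(2.0 / 97.0)
        assert cmp.z_statistic == pytest.approx(expected, rel=1e-12)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(sb.ValidationError):
            sb.compare_correlations_fisher(1.0, 100, 0.5, 100)


class TestKruskalWallis:
    def test_hand_computed_three_group_example(self):
        h, p = sb.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_identical_groups_give_zero(self):
        h, p = sb.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0
        assert p == 1.0

    def test_invariant_to_shuffling_within_groups(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(size=8), rng.normal(size=12) + 1.0]
        h1, _ = sb.kruskal_wallis(groups)
        h2, _ = sb.kruskal_wallis([rng.permutation(g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_single_group_rejected(self):
        with pytest.raises(sb.ValidationError):
            sb.kruskal_wallis([[1.0, 2.0]])


class TestAndersonDarling:
    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            sb.anderson_darling_normal(rng.standard_normal(5000))[1]
            for _ in range(200)
        )
        assert rejections <= 12  # >= 94% non-rejection at the 5% level

    def test_detects_exponential(self):
        rng = np.random.default_rng(12)
        a2, reject = sb.anderson_darling_normal(rng.exponential(size=5000))
        assert reject

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(500)
        a1, _ = sb.anderson_darling_normal(x)
        a2, _ = sb.anderson_darling_normal(3.5 * x - 11.0)
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(sb.ValidationError):
            sb.anderson_darling_normal(np.full(20, 1.0))
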