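import numpy as np
import pytest

from coroplaque.agreement_stats import (
    bland_altman,
    icc_agreement,
    lap_presence_analysis,
    paired_t,
    pearson_with_fit,
)


def mann_whitney_auc(labels, scores):
    """Brute-force AUC oracle: P(score+ > score-) + 0.5 P(tie) over all pairs."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestPearsonWithFit:
    def test_exact_line(self):
        x = np.array([1.0, 2, 3, 4])
        r, p, slope, intercept = pearson_with_fit(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # x=[1,2,3], y=[1,3,2]: cov 0.5, SDs 1 -> r = 0.5
        r, _, _, _ = pearson_with_fit([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson_with_fit([1, 2, 3], [5, 5, 5])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, 30)
        y = 1.7 * x + rng.normal(0, 1, 30)
        r1, _, s1, _ = pearson_with_fit(x, y)
        r2, _, s2, _ = pearson_with_fit(3.0 * x, y)
        assert r2 == pytest.approx(r1)
        assert s2 == pytest.approx(s1 / 3.0)


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2, 3])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2, 3])
        mean, sd, lo, hi = bland_altman(x, x + 2)
        assert (mean, sd) == (2.0, 0.0)

    def test_hand_computed_limits(self):
        mean, sd, lo, hi = bland_altman([1, 2, 3], [2, 2, 2])
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(1.0)
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)

    def test_limit_width_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 3, 40)
        y = x + rng.normal(0.5, 1.2, 40)
        _, sd, lo, hi = bland_altman(x, y)
        assert hi - lo == pytest.approx(2 * 1.96 * sd)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([3.0, 7, 11, 2, 9])
        assert icc_agreement(x, x) == pytest.approx(1.0)

    def test_bias_penalized_below_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 1, 30)
        y = x + 8.0 + rng.normal(0, 0.2, 30)  # large offset, small spread
        r, *_ = pearson_with_fit(x, y)
        assert icc_agreement(x, y) < r - 0.3

    def test_matches_pingouin_on_fixed_table(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = np.array([9.0, 6, 8, 7, 10, 6])
        y = np.array([2.0, 1, 4, 1, 5, 2])
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(6), 2),
                "raters": np.tile(["a", "b"], 6),
                "ratings": np.column_stack([x, y]).ravel(),
            }
        )
        res = pingouin.intraclass_corr(df, "targets", "raters", "ratings")
        # two-way random, absolute agreement, single measure (label varies
        # across pingouin versions: "ICC2" or "ICC(A,1)")
        row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
        expect = float(row["ICC"].iloc[0])
        assert icc_agreement(x, y) == pytest.approx(expect, abs=1e-10)


class TestPairedT:
    def test_null_simulation_false_positive_rate(self):
        rng = np.random.default_rng(10)
        rejections = 0
        for _ in range(100):
            x = rng.normal(10, 2, 100)
            y = x + rng.normal(0, 1, 100)
            _, p = paired_t(x, y)
            rejections += p <= 0.05
        assert rejections <= 10  # ~5% expected under the null

    def test_zero_sd_differences_error(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [3, 4, 5])

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0.3, 0.5, 20)
        t1, _ = paired_t(x, y)
        t2, _ = paired_t(y, x)
        assert t1 == pytest.approx(-t2)


class TestLapPresence:
    def test_perfect_separation(self):
        ivus = np.array([0.0] * 10 + [10.0] * 10)
        ccta = np.array([0.5] * 10 + [9.0] * 10)
        (res,) = lap_presence_analysis(ivus, ccta, thresholds=(8.0,))
        assert res.auc == pytest.approx(1.0)
        assert res.youden.sensitivity_pct == 100.0
        assert res.youden.specificity_pct == 100.0

    def test_two_case_roc(self):
        (res,) = lap_presence_analysis([10.0, 1.0], [5.0, 0.0], thresholds=(8.0,))
        assert res.auc == pytest.approx(1.0)

    def test_auc_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(10, 50))
            ivus = rng.uniform(0, 15, n)
            ccta = rng.uniform(0, 15, n)
            labels = ivus >= 4.0
            if labels.all() or not labels.any():
                continue
            (res,) = lap_presence_analysis(ivus, ccta, thresholds=(4.0,))
            assert res.auc == pytest.approx(mann_whitney_auc(labels, ccta), abs=1e-12)

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(2023)
        n = 500
        ivus = (rng.random(n) < 0.5) * 10.0  # labels independent of scores
        ccta = rng.uniform(0, 10, n)
        (res,) = lap_presence_analysis(ivus, ccta, thresholds=(8.0,))
        assert 0.45 <= res.auc <= 0.55

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            lap_presence_analysis([10.0, 12.0], [1.0, 2.0], thresholds=(8.0,))

    def test_metric_ranges(self):
        rng = np.random.default_rng(5)
        ivus = rng.uniform(0, 20, 60)
        ccta = ivus * 0.8 + rng.normal(0, 3, 60)
        for res in lap_presence_analysis(ivus, np.clip(ccta, 0, None)):
            assert 0.0 <= res.auc <= 1.0
            for op in (res.youden, res.ccta_positive):
                for v in (op.sensitivity_pct, op.specificity_pct, op.accuracy_pct):
                    assert 0.0 <= v <= 100.0
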