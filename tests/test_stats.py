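"""Dose-response fitting, regression, ROC and assay arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import srscell as sc
from srscell.stats import four_pl, seahorse_metrics, seahorse_reduction


class TestFitDoseResponse:
    DOSES = np.geomspace(0.33, 33.0, 8)

    def test_noise_free_recovery_to_machine_precision(self):
        df = sc.generate_dose_response(
            3.3, 1.0, 100.0, 0.0, self.DOSES, noise_sd=0.0, replicates=6
        )
        fit = sc.fit_dose_response(df.dose_uM, df.viability_pct, ci=False)
        assert fit.converged
        assert fit.ic50 == pytest.approx(3.3, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_ic50_is_half_effect_dose(self):
        df = sc.generate_dose_response(
            2.0, 1.7, 105.0, 5.0, self.DOSES, noise_sd=0.0, replicates=3
        )
        fit = sc.fit_dose_response(df.dose_uM, df.viability_pct, ci=False)
        half = (fit.top + fit.bottom) / 2.0
        assert fit.predict(fit.ic50) == pytest.approx(half, rel=1e-6)

    def test_flat_viability_does_not_converge(self):
        doses = np.repeat(self.DOSES, 3)
        fit = sc.fit_dose_response(doses, np.full(doses.size, 100.0))
        assert not fit.converged

    def test_noisy_ci_contains_truth(self):
        hits = 0
        for seed in range(5):
            df = sc.generate_dose_response(
                3.3, 1.0, 100.0, 0.0, self.DOSES, noise_sd=5.0, replicates=6,
                seed=seed,
            )
            fit = sc.fit_dose_response(
                df.dose_uM, df.viability_pct, n_boot=100, seed=seed
            )
            assert fit.converged and fit.ci_ic50 is not None
            if fit.ci_ic50[0] <= 3.3 <= fit.ci_ic50[1]:
                hits += 1
        assert hits >= 4

    def test_input_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            sc.fit_dose_response([1, 1, 2, 2], [90, 91, 50, 49])
        with pytest.raises(ValueError, match="> 0"):
            sc.fit_dose_response([0, 1, 2, 3, 4], [100, 90, 50, 20, 10])

    def test_rising_viability_warns(self):
        doses = self.DOSES
        v = four_pl(doses, 100, 0, np.log10(3.3), 1.0)[::-1]  # reversed: rising
        with pytest.warns(UserWarning, match="rises"):
            sc.fit_dose_response(doses, v, ci=False)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = sc.linear_fit(x, 2.0 * x + 1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_computed_three_points(self):
        res = sc.linear_fit([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0 / 3.0)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_convention(self):
        res = sc.linear_fit([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert res.slope == 0.0 and res.r_squared == 0.0 and res.constant_y

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sc.linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_closed_form_ols_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 12)
            x = rng.normal(size=n)
            if np.ptp(x) < 1e-9:
                continue
            y = rng.normal(size=n)
            res = sc.linear_fit(x, y)
            X = np.column_stack([x, np.ones(n)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert res.slope == pytest.approx(beta[0], abs=1e-12)
            assert res.intercept == pytest.approx(beta[1], abs=1e-12)


def _brute_force_auc(scores, labels, positive="resistant"):
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    credit = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return credit / (len(pos) * len(neg))


class TestRocAnalysis:
    def test_worked_example(self):
        res = sc.roc_analysis(
            [0.1, 0.35, 0.3, 0.4],
            ["sensitive", "sensitive", "resistant", "resistant"],
        )
        assert res.auc == pytest.approx(0.75)

    def test_all_ties_gives_half(self):
        res = sc.roc_analysis([0.2] * 6, ["sensitive"] * 3 + ["resistant"] * 3)
        assert res.auc == pytest.approx(0.5)

    def test_separated_groups_perfect(self):
        scores = [0.1, 0.2, 0.25, 0.5, 0.6]
        labels = ["sensitive"] * 3 + ["resistant"] * 2
        res = sc.roc_analysis(scores, labels)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 0.25 < res.threshold < 0.5  # midpoint between adjacent scores
        assert res.threshold == pytest.approx(0.375)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sc.roc_analysis([1.0, 2.0], ["resistant", "resistant"])

    def test_auc_equals_brute_force_pair_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 13))
            n_pos = int(rng.integers(1, n))
            labels = ["resistant"] * n_pos + ["sensitive"] * (n - n_pos)
            scores = rng.integers(0, 5, n) / 4.0  # coarse grid -> frequent ties
            res = sc.roc_analysis(scores, labels)
            assert res.auc == pytest.approx(_brute_force_auc(scores, labels))

    def test_matches_sklearn_on_tied_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.integers(0, 4, 30) / 3.0
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1  # both classes present
        labels = np.where(y == 1, "resistant", "sensitive")
        res = sc.roc_analysis(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(y, scores))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        scores = rng.random(n)
        labels = np.array(["sensitive"] * 6 + ["resistant"] * 6)
        rng.shuffle(labels)
        if len(set(labels)) < 2:
            return
        a1 = sc.roc_analysis(scores, labels).auc
        a2 = sc.roc_analysis(np.exp(3.0 * scores) + 1.0, labels).auc
        assert a1 == pytest.approx(a2)


class TestAssayArithmetic:
    def test_ocr_slope(self):
        t = np.arange(10.0)
        assert sc.ocr_slope(t, 10.0 * t, n_cells=5) == pytest.approx(2.0)
        assert sc.ocr_slope(t, np.full(10, 7.0), n_cells=3) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            sc.ocr_slope([0, 1], [1, 2], n_cells=5)
        with pytest.raises(ValueError):
            sc.ocr_slope(t, 10 * t, n_cells=0)

    def test_fao_rate(self):
        assert sc.fao_rate(10.0, 4.0) == 6.0
        assert sc.fao_rate(4.0, 4.0) == 0.0
        with pytest.warns(UserWarning, match="negative FAO"):
            assert sc.fao_rate(3.0, 4.0) == -1.0

    @pytest.mark.parametrize(
        "target,control,expected", [(18, 20, 2.0), (20, 20, 0.0), (22, 20, -2.0)]
    )
    def test_delta_ct(self, target, control, expected):
        assert sc.delta_ct(target, control) == expected

    def test_tumor_volume(self):
        assert sc.tumor_volume(2.0, 1.0) == 1.0
        assert sc.tumor_volume(4.0, 3.0) == 18.0
        assert sc.tumor_volume(0.0, 0.0) == 0.0
        with pytest.warns(UserWarning, match="swapping"):
            assert sc.tumor_volume(1.0, 2.0) == 1.0  # swapped to (2, 1)
        with pytest.raises(ValueError):
            sc.tumor_volume(-1.0, 1.0)

    def test_group_test(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = sc.group_test(a, a.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, 20)
        t2, p2 = sc.group_test(x + 100.0, x)
        assert p2 < 1e-6
        with pytest.raises(ValueError):
            sc.group_test([1.0], [1.0, 2.0])

    def test_seahorse_worked_example(self):
        trace = [10, 10, 10, 4, 4, 14, 14, 2, 2]
        m = seahorse_metrics(trace, (3, 5, 7))
        assert m.non_mito == 2.0
        assert m.basal == 8.0
        assert m.atp_linked == 6.0
        assert m.maximal == 12.0

    def test_seahorse_constant_trace_and_reduction(self):
        m = seahorse_metrics([5.0] * 8, (2, 4, 6))
        assert (m.basal, m.atp_linked, m.maximal, m.non_mito) == (0, 0, 0, 5.0)
        ctrl = seahorse_metrics([10, 10, 10, 4, 4, 14, 14, 2, 2], (3, 5, 7))
        eto = seahorse_metrics([8, 8, 8, 4, 4, 10, 10, 2, 2], (3, 5, 7))
        red = seahorse_reduction(ctrl, eto)
        assert red.basal == 2.0 and red.maximal == 4.0

    def test_seahorse_missing_segment_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            seahorse_metrics([1, 2, 3, 4], (2, 2, 3))
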