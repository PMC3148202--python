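"""Agreement statistics: CV, ICC, pixel confusion, consensus, outliers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ad3ri.evaluate import (
    area_cv,
    compare_to_truth,
    consensus_truth,
    confusion_metrics,
    expert_vs_experts,
    icc_agreement,
    outlier_filter,
    pixel_confusion,
)
from ad3ri.io import GradingMask


def icc2_anova_oracle(table: np.ndarray) -> float:
    """Brute-force two-way random, absolute agreement, single-measure ICC."""
    n, k = table.shape
    grand = table.mean()
    row_m = table.mean(axis=1)
    col_m = table.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    sse = np.sum((table - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestAreaCv:
    @pytest.mark.parametrize(
        "areas,expected",
        [
            ([5.9, 5.5, 6.7, 6.1, 6.7, 6.6, 8.3, 7.2], 13.0),
            ([8.3, 4.4, 5.8, 7.8, 6.9, 4.3, 6.1, 7.1], 23.2),
        ],
    )
    def test_published_expert_rows(self, areas, expected):
        assert area_cv(areas) == pytest.approx(expected, abs=0.05)

    def test_equal_values_zero(self):
        assert area_cv([4.2] * 5) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        areas=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=10),
        k=st.floats(0.01, 50.0),
    )
    def test_scale_invariance(self, areas, k):
        assert area_cv(np.array(areas) * k) == pytest.approx(
            area_cv(areas), rel=1e-9, abs=1e-9
        )

    def test_zero_mean_flagged(self):
        with pytest.raises(ValueError):
            area_cv([0.0, 0.0])


class TestIcc:
    def test_identical_columns_give_one(self):
        t = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc_agreement(t) == 1.0

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(1000, 2))
        assert abs(icc_agreement(t)) < 0.1

    def test_matches_anova_oracle_on_small_table(self):
        table = np.array([[9.0, 2.0], [45.0, 12.0], [8.0, 20.0], [4.0, 10.0]])
        assert icc_agreement(table) == pytest.approx(icc2_anova_oracle(table),
                                                     abs=1e-9)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            table = rng.uniform(0, 30, size=(8, 3))
            assert icc_agreement(table) == pytest.approx(
                icc2_anova_oracle(table), abs=1e-9)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement(np.array([[1.0, 2.0]]))


class TestPixelConfusion:
    def _mask(self, a):
        return GradingMask(np.asarray(a, dtype=np.uint8))

    def test_perfect_agreement(self):
        m = self._mask(np.eye(8, dtype=int))
        assert pixel_confusion(m, m) == (1.0, 1.0, 1.0)

    def test_complement_has_zero_sens_and_spec(self):
        t = self._mask(np.eye(8, dtype=int))
        inv = self._mask(1 - np.eye(8, dtype=int))
        sens, spec, _ = pixel_confusion(inv, t)
        assert sens == 0.0 and spec == 0.0

    def test_closed_form_on_hand_built_table(self):
        # TP=30 FN=20 FP=10 TN=940: sens 0.6, spec 0.989..., kappa via po/pe
        sens, spec, kappa = confusion_metrics(tp=30, fp=10, fn=20, tn=940)
        assert sens == pytest.approx(0.6)
        assert spec == pytest.approx(940 / 950)
        po = 970 / 1000
        pe = (40 * 50 + 960 * 950) / 1000**2
        assert kappa == pytest.approx((po - pe) / (1 - pe))

    def test_matches_independent_contingency_computation(self):
        rng = np.random.default_rng(1)
        a = rng.random((40, 40)) > 0.7
        b = rng.random((40, 40)) > 0.6
        _, _, kappa = pixel_confusion(
            GradingMask(a.astype(np.uint8)), GradingMask(b.astype(np.uint8)))
        from sklearn.metrics import cohen_kappa_score

        assert kappa == pytest.approx(
            cohen_kappa_score(a.ravel(), b.ravel()), abs=1e-12)

    def test_kappa_one_only_for_identical_masks(self):
        rng = np.random.default_rng(2)
        a = rng.random((20, 20)) > 0.5
        b = a.copy()
        b[0, 0] = ~b[0, 0]
        _, _, kappa = pixel_confusion(
            GradingMask(a.astype(np.uint8)), GradingMask(b.astype(np.uint8)))
        assert kappa < 1.0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_confusion(self._mask(np.zeros((4, 4))),
                            self._mask(np.zeros((5, 5))))

    def test_roi_restriction(self):
        t = np.zeros((10, 10), dtype=np.uint8)
        t[:5] = 1
        pred = np.zeros_like(t)
        pred[:5, :5] = 1
        roi = np.zeros((10, 10), dtype=bool)
        roi[:, :5] = True  # inside the ROI the masks agree everywhere
        sens, spec, kappa = pixel_confusion(
            GradingMask(pred), GradingMask(t), roi)
        assert (sens, spec, kappa) == (1.0, 1.0, 1.0)


class TestConsensusTruth:
    def _m(self, a):
        return GradingMask(np.asarray(a, dtype=np.uint8))

    def test_identical_masks_returned(self):
        m = self._m(np.eye(6, dtype=int))
        for n in (1, 3, 8):
            out = consensus_truth([m] * n)
            assert np.array_equal(out.pixels, m.pixels)

    def test_majority_and_tie_rules(self):
        marked = self._m(np.ones((2, 2), dtype=int))
        empty = self._m(np.zeros((2, 2), dtype=int))
        # 4 of 8 experts mark: tie -> marked
        out = consensus_truth([marked] * 4 + [empty] * 4)
        assert out.pixels.all()
        # 3 of 8: unmarked
        out = consensus_truth([marked] * 3 + [empty] * 5)
        assert not out.pixels.any()


class TestOutlierFilter:
    def test_high_cv_row_flagged(self):
        rows = [
            [10.1, 3.3, 0.1, 4.5, 3.6, 3.0, 2.2, 9.5],  # CV 77% -> outlier
            [5.9, 5.5, 6.7, 6.1, 6.7, 6.6, 8.3, 7.2],   # CV 13% -> retained
            [4.0] * 8,                                   # CV 0 -> retained
        ]
        retained, outliers = outlier_filter(rows, image_ids=[8, 12, 99])
        assert outliers == [8]
        assert retained == [12, 99]

    def test_all_zero_row_treated_as_outlier(self):
        retained, outliers = outlier_filter([[0.0, 0.0], [1.0, 1.0]])
        assert outliers == [1] and retained == [2]


class TestExpertVsExperts:
    def _random_mask(self, rng, shape=(48, 48), p=0.25):
        return GradingMask((rng.random(shape) < p).astype(np.uint8))

    def test_identical_experts_score_perfectly(self):
        rng = np.random.default_rng(0)
        base = [self._random_mask(rng) for _ in range(4)]
        masks_per_image = [[m, m, m] for m in base]
        reports = expert_vs_experts(masks_per_image)
        for rep in reports:
            assert rep.sensitivity == 1.0
            assert rep.specificity == 1.0
            assert rep.kappa == 1.0
            assert rep.cv_percent == 0.0

    def test_kappa_decreases_with_expert_noise(self):
        rng = np.random.default_rng(1)
        shape = (64, 64)
        truth = (rng.random(shape) < 0.3)
        flip_rates = [0.0, 0.10, 0.30]
        masks_per_image = []
        for _ in range(5):
            row = []
            for rate in flip_rates + [0.0]:  # 4th clean expert anchors consensus
                flips = rng.random(shape) < rate
                row.append(GradingMask(
                    np.where(flips, ~truth, truth).astype(np.uint8)))
            masks_per_image.append(row)
        reports = expert_vs_experts(masks_per_image)
        kappas = [r.kappa for r in reports[:3]]
        assert kappas[0] > kappas[1] > kappas[2]

    def test_fewer_than_three_experts_rejected(self):
        m = GradingMask(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            expert_vs_experts([[m, m]])


class TestCompareToTruth:
    def test_per_image_table_and_headline_averages(self):
        rng = np.random.default_rng(4)
        truths, tests = [], []
        for _ in range(4):
            t = rng.random((32, 32)) < 0.3
            noisy = np.where(rng.random((32, 32)) < 0.05, ~t, t)
            truths.append(GradingMask(t.astype(np.uint8)))
            tests.append(GradingMask(noisy.astype(np.uint8)))
        rep = compare_to_truth(tests, truths, resolution_um=12.5)
        assert len(rep.per_image) == 4
        assert 0.0 < rep.kappa < 1.0
        assert rep.sensitivity == pytest.approx(
            rep.per_image["sensitivity"].mean())
        assert -1.0 <= rep.icc <= 1.0
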