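"""Effect sizes, mutual information, permutation tests, and importance."""

import numpy as np
import pytest

from deltaspike import a_w, compare_cc_groups, mutual_information
from deltaspike.stats import (
    fold_attributions,
    group_tests,
    importance_with_null,
    kruskal_with_tukey,
    mann_whitney,
    wilcoxon_signed_rank,
)
from deltaspike.registry import BASE_FEATURES


class TestAw:
    def test_disjoint_samples_give_one(self, rng):
        a = rng.uniform(0, 1, 20)
        b = rng.uniform(10, 11, 15)
        assert a_w(a, b).a_w == 1.0

    def test_identical_samples_give_half(self):
        x = np.arange(10.0)
        assert a_w(x, x).a_w == pytest.approx(0.5)

    def test_worked_example_with_interleaving(self):
        """{1,3,5} vs {2,4}: 3 of 6 pairs favor a -> folded to 0.5."""
        res = a_w([1, 3, 5], [2, 4])
        assert res.a_w == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(30):
            a = rng.integers(0, 6, rng.integers(2, 12)).astype(float)
            b = rng.integers(0, 6, rng.integers(2, 12)).astype(float)
            wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            p_hat = wins / (a.size * b.size)
            assert a_w(a, b).a_w == pytest.approx(max(p_hat, 1 - p_hat))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            a_w([], [1.0])


class TestMutualInformation:
    def test_self_information_hits_log2_bins_cap(self, rng):
        x = rng.normal(size=1000)
        mi, _ = mutual_information(x, x, n_perm=50, rng=0)
        assert mi == pytest.approx(np.log2(10), abs=1e-9)

    def test_two_category_diagonal_is_one_bit(self):
        x = np.array([0] * 5 + [1] * 5, dtype=float)
        mi, _ = mutual_information(x, x, n_perm=50, rng=0)
        assert mi == pytest.approx(1.0)

    def test_independent_variables_not_significant(self, rng):
        hits = 0
        for k in range(20):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            _, p = mutual_information(x, y, n_perm=200, rng=k)
            hits += p > 0.05
        assert hits >= 18  # >= 90% of null trials non-significant

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=500)
        y = rng.normal(size=500) + 0.8 * x
        mi1, _ = mutual_information(x, y, n_perm=10, rng=0)
        mi2, _ = mutual_information(np.exp(x), y**3 + 5 * y, n_perm=10, rng=0)
        assert mi1 == pytest.approx(mi2, abs=1e-9)

    def test_matches_brute_force_contingency(self, rng):
        """Plug-in MI on the binned contingency, recomputed longhand."""
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        mi, _ = mutual_information(x, y, n_perm=10, rng=0)
        bx = np.empty(200, int)
        bx[np.argsort(x, kind="stable")] = np.arange(200) * 10 // 200
        by = np.empty(200, int)
        by[np.argsort(y, kind="stable")] = np.arange(200) * 10 // 200
        expected = 0.0
        for i in range(10):
            for j in range(10):
                pij = np.mean((bx == i) & (by == j))
                if pij > 0:
                    expected += pij * np.log2(
                        pij / (np.mean(bx == i) * np.mean(by == j))
                    )
        assert mi == pytest.approx(expected)


class TestPermutationTests:
    def test_identical_groups_rarely_significant(self, rng):
        hits = 0
        for k in range(20):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            hits += compare_cc_groups(a, b, n_perm=200, rng=k) > 0.05
        assert hits >= 16

    def test_separated_groups_significant(self, rng):
        a = rng.normal(10.0, 1.0, 20)
        b = rng.normal(0.0, 1.0, 20)
        assert compare_cc_groups(a, b, n_perm=1000, rng=0) <= 0.05

    def test_degenerate_single_members(self):
        p = compare_cc_groups([1.0], [1.0], n_perm=50, rng=0)
        assert 0 < p <= 1.0

    def test_p_values_roughly_uniform_under_null(self, rng):
        from scipy import stats as sps

        ps = [
            compare_cc_groups(rng.normal(size=10), rng.normal(size=10),
                              n_perm=200, rng=k)
            for k in range(60)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestGroupTests:
    def test_identical_groups_u_test(self, rng):
        x = rng.normal(size=30)
        res = group_tests({"a": x, "b": x.copy()})
        assert res["p_value"] > 0.05

    def test_tied_data_degenerate(self):
        with pytest.warns(UserWarning):
            _, p = mann_whitney(np.ones(5), np.ones(5))
        assert p == 1.0
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank(np.ones(5), np.ones(5))
        assert p == 1.0

    def test_planted_shift_flagged_only_for_that_pair(self, rng):
        groups = {
            "a": rng.normal(0, 1, 25),
            "b": rng.normal(0, 1, 25),
            "c": rng.normal(10, 1, 25),
        }
        res = kruskal_with_tukey(groups)
        assert res["p_value"] <= 0.05
        assert res["pairwise"][("a", "c")] <= 0.05
        assert res["pairwise"][("b", "c")] <= 0.05
        assert res["pairwise"][("a", "b")] > 0.05


class TestImportance:
    @staticmethod
    def _fake_run(attr, shuffled=False):
        from deltaspike.pipeline import ModelRun

        return ModelRun(
            partition=0, params={}, unit_ids=[], y_true=np.array([]),
            scores=np.array([]), auc=0.5, shuffled=shuffled, attributions=attr,
        )

    def test_chunk_statistics_fold_into_base(self):
        attr = {name: 0.0 for name in BASE_FEATURES}
        attr["FWHM"] = 0.1
        attr["FWHM_sd"] = 0.2
        attr["FWHM_q75"] = 0.3
        folded = fold_attributions(attr)
        assert len(folded) == 34
        assert folded["FWHM"] == pytest.approx(0.6)

    def test_planted_signal_detected_against_null(self, rng):
        real, null = [], []
        for _ in range(10):
            attr = {n: abs(rng.normal(0, 0.01)) for n in BASE_FEATURES}
            attr["TTP-duration"] = 0.5 + rng.normal(0, 0.01)
            real.append(self._fake_run(attr))
        for _ in range(99):
            attr = {n: abs(rng.normal(0, 0.01)) for n in BASE_FEATURES}
            null.append(self._fake_run(attr, shuffled=True))
        report = importance_with_null(real, null)
        assert report.shape[0] == 34
        assert report["importance"].idxmax() == "TTP-duration"
        assert report.loc["TTP-duration", "p_value"] <= 0.01
        # uninformative features are not flagged
        assert report["p_value"].drop("TTP-duration").median() > 0.2

    def test_mismatched_feature_sets_rejected(self):
        real = [self._fake_run({n: 0.1 for n in BASE_FEATURES})]
        with pytest.raises(ValueError):
            importance_with_null(real, [self._fake_run(None)])
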