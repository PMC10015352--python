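"""Statistics tests: unit conversion, Pearson, Bland-Altman, ROC/Youden,
Kruskal-Wallis + Dunn, recruitment accounting, cohort validation report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bilicam import biostat as bs
from bilicam.forward_model import BilicamError


class TestUnitConversion:
    @pytest.mark.parametrize("umol, mgdl, dp", [
        (250.0, 14.6, 1), (214.0, 12.5, 1), (166.0, 9.71, 2),
        (186.6, 10.9, 1), (178.2, 10.4, 1), (0.0, 0.0, 1)])
    def test_printed_conversion_pairs(self, umol, mgdl, dp):
        assert round(bs.umol_to_mgdl(umol), dp) == mgdl

    def test_negative_rejected(self):
        with pytest.raises(BilicamError):
            bs.umol_to_mgdl(-1.0)
        with pytest.raises(BilicamError):
            bs.mgdl_to_umol(-0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1e4))
    def test_round_trip_exact(self, x):
        assert bs.mgdl_to_umol(bs.umol_to_mgdl(x)) == pytest.approx(x, rel=1e-12, abs=1e-12)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert bs.pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert bs.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        x = np.array([3.1, 4.5, 2.2, 7.8, 5.0, 6.1, 1.9, 8.4, 3.3, 5.5])
        y = np.array([2.0, 5.1, 1.8, 6.9, 4.2, 6.6, 2.5, 7.0, 2.9, 4.8])
        r, _ = bs.pearson(x, y)
        direct = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(BilicamError, match="zero variance"):
            bs.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.array([1.0, 2.0, 3.0])
        st_, _ = bs.bland_altman(x, x)
        assert (st_.bias, st_.loa_lower, st_.loa_upper) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        y = np.array([10.0, 20.0, 30.0])
        st_, _ = bs.bland_altman(y + 5.0, y)
        assert st_.bias == pytest.approx(5.0)
        assert st_.loa_lower == pytest.approx(5.0)
        assert st_.loa_upper == pytest.approx(5.0)

    def test_recovers_simulated_bias(self):
        # differences drawn around a bias of -9.7 with the sd implied by
        # limits of agreement spanning -89.9 to 70.6 at n = 201
        rng = np.random.default_rng(201)
        y = rng.uniform(50, 350, 201)
        d = rng.normal(-9.7, 40.9, 201)
        st_, plot = bs.bland_altman(y + d, y)
        se = 40.9 / np.sqrt(201)
        assert st_.bias == pytest.approx(-9.7, abs=3 * se)
        assert len(plot) == 201
        inside = ((plot["difference"] >= st_.loa_lower)
                  & (plot["difference"] <= st_.loa_upper)).mean()
        assert inside == pytest.approx(0.95, abs=0.04)

    def test_limits_ordering_invariant(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        st_, _ = bs.bland_altman(x, y)
        assert st_.loa_lower <= st_.bias <= st_.loa_upper

    def test_single_pair_rejected(self):
        with pytest.raises(BilicamError):
            bs.bland_altman([1.0], [2.0])


class TestRoc:
    def test_perfect_separation(self):
        stats = bs.roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert stats.auc == 1.0
        assert stats.sensitivity == 1.0 and stats.specificity == 1.0

    def test_all_scores_identical_gives_half(self):
        stats = bs.roc([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert stats.auc == pytest.approx(0.5)

    def test_hand_listed_pairs_match_pair_counting(self):
        scores = [1.0, 2.0, 2.0, 3.0, 4.0, 4.5, 5.0, 6.0]
        labels = [0, 0, 1, 0, 1, 0, 1, 1]
        stats = bs.roc(scores, labels)
        assert stats.auc == pytest.approx(bs.auc_pair_counting(scores, labels),
                                          abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 9))
    def test_trapezoid_equals_pair_counting_and_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.normal(size=n), 1)  # coarse: force ties
        labels = rng.integers(0, 2, n)
        if labels.all() or not labels.any():
            labels[0], labels[-1] = 0, 1
        stats = bs.roc(scores, labels)
        assert stats.auc == pytest.approx(bs.auc_pair_counting(scores, labels),
                                          abs=1e-12)
        from sklearn.metrics import roc_auc_score
        assert stats.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_youden_tie_break_deterministic(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 0, 1, 1]
        once = bs.roc(scores, labels)
        doubled = bs.roc(scores * 2, labels * 2)
        assert once.youden_cutoff == doubled.youden_cutoff

    def test_single_class_rejected(self):
        with pytest.raises(BilicamError):
            bs.roc([1, 2, 3], [1, 1, 1])


class TestSensSpec:
    def test_extreme_cutoffs(self):
        scores, labels = [1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1]
        assert bs.sens_spec_at(scores, labels, 0.0) == (1.0, 0.0)
        assert bs.sens_spec_at(scores, labels, 10.0) == (0.0, 1.0)

    def test_hand_counted_two_by_two(self):
        # TP 16, FN 1, TN 29, FP 12 under score > 0.5
        scores = [1.0] * 16 + [0.0] * 1 + [0.0] * 29 + [1.0] * 12
        labels = [1] * 17 + [0] * 41
        sens, spec = bs.sens_spec_at(scores, labels, 0.5)
        assert sens == pytest.approx(16 / 17)
        assert spec == pytest.approx(29 / 41)


class TestKruskalDunn:
    def test_identical_observations_degenerate(self):
        H, p, table = bs.kruskal_dunn([[2.0, 2.0], [2.0, 2.0], [2.0]])
        assert H == 0.0 and p == 1.0
        assert len(table) == 3

    def test_hand_computed_h_without_ties(self):
        # ranks 1..6; H = 12/(N(N+1)) sum n_i (Rbar_i - (N+1)/2)^2 = 32/7
        H, _, _ = bs.kruskal_dunn([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert H == pytest.approx(32.0 / 7.0, abs=1e-12)

    def test_label_permutation_leaves_h_unchanged(self):
        g = [[1.0, 5.0, 3.0], [2.0, 8.0], [9.0, 4.0, 7.0]]
        H1, _, _ = bs.kruskal_dunn(g)
        H2, _, _ = bs.kruskal_dunn([g[2], g[0], g[1]])
        assert H1 == pytest.approx(H2)

    def test_dunn_adjusted_p_bounded(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1.0, 12) for loc in (0.0, 0.5, 2.0)]
        _, _, table = bs.kruskal_dunn(groups)
        assert ((table["p_adjusted"] >= table["p_raw"] - 1e-15)
                & (table["p_adjusted"] <= 1.0)).all()
        # the widely separated pair is the most significant
        assert table.loc[table["p_adjusted"].idxmin()].tolist()[:2] == [0, 2]


class TestAccounting:
    @pytest.mark.parametrize("recruited, exclusions, remaining, percent, dp", [
        (181, [36, 10, 34], 101, 55.8, 1),
        (248, [47], 201, 81, 0),
        (161, [3], 158, 98.1, 1),
        (10, [], 10, 100.0, 1)])
    def test_printed_accounting_rows(self, recruited, exclusions, remaining,
                                     percent, dp):
        got_n, got_pct = bs.cohort_accounting(recruited, exclusions, decimals=dp)
        assert got_n == remaining
        assert got_pct == percent

    def test_over_exclusion_rejected(self):
        with pytest.raises(BilicamError):
            bs.cohort_accounting(10, [6, 6])


class TestValidateCohort:
    def _frames(self, truth, estimates):
        ids = [f"S{i}" for i in range(len(truth))]
        manifest = pd.DataFrame({"subject_id": ids, "true_tsb_umol_L": truth})
        results = pd.DataFrame({"subject_id": ids, "estimate_umol_L": estimates})
        return manifest, results

    def test_near_perfect_estimates_give_high_r(self):
        rng = np.random.default_rng(7)
        truth = rng.uniform(20, 350, 60)
        report = bs.validate_cohort(*self._frames(truth, truth + rng.normal(0, 2, 60)))
        assert report["agreement"].pearson_r >= 0.99
        assert report["screening"].auc >= 0.95

    def test_disjoint_ids_is_explicit_error(self):
        manifest, results = self._frames([100.0] * 3, [100.0] * 3)
        results["subject_id"] = ["X0", "X1", "X2"]
        with pytest.raises(BilicamError, match="join failures"):
            bs.validate_cohort(manifest, results)

    def test_rejected_sets_dropped_from_pairs(self):
        manifest, results = self._frames([100.0, 200.0, 300.0, 260.0],
                                         [105.0, 190.0, np.nan, 255.0])
        report = bs.validate_cohort(manifest, results)
        assert report["n_pairs"] == 3
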