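import itertools

import numpy as np
import pytest

from lipodisc import (
    Biomarker,
    CohortConfig,
    CvConfig,
    aggregate_ranks_borda,
    generate_cohort,
    pca_confirmation,
    permutation_test,
    preprocess_table,
    rank_features,
    select_best_model,
    validation_curve,
)
from lipodisc.feature_selection import FeatureSubset, make_ensemble, refine_subsets
from lipodisc.resampling import CvEnsemble
from lipodisc.evaluation import MetricRecord


PLANTED = [5, 30, 60, 90, 120, 150]


def planted_cohort(seed, effects=(0.4, 0.44, 0.48, 0.52, 0.56, 0.6)):
    bms = [Biomarker(i, e) for i, e in zip(PLANTED, effects)]
    table, truth = generate_cohort(CohortConfig(seed=seed, biomarkers=bms))
    return preprocess_table(table), truth


class TestBorda:
    def test_unanimous_rankings_preserved(self):
        r = np.array([2, 0, 1])
        out = aggregate_ranks_borda([r, r, r])
        assert np.array_equal(out.order, r)

    def test_reversed_pair_falls_back_to_vip_tiebreak(self):
        a = np.array([0, 1, 2])
        out = aggregate_ranks_borda([a, a[::-1]], mean_vip=np.array([0.5, 2.0, 1.0]))
        assert np.unique(out.borda_score).size == 1
        assert np.array_equal(out.order, [1, 2, 0])

    def test_hand_enumerated_scores(self):
        # features A=0, B=1, C=2 with rankings (A,B,C), (A,C,B), (B,A,C)
        out = aggregate_ranks_borda(
            [np.array([0, 1, 2]), np.array([0, 2, 1]), np.array([1, 0, 2])]
        )
        assert out.borda_score.tolist() == [5.0, 3.0, 1.0]
        assert np.array_equal(out.order, [0, 1, 2])

    def test_matches_exhaustive_oracle_on_all_permutation_triples(self):
        perms = [np.array(p) for p in itertools.permutations(range(3))]
        for voters in itertools.combinations_with_replacement(perms, 3):
            out = aggregate_ranks_borda(list(voters))
            expected = np.zeros(3)
            for r in voters:
                for pos, feat in enumerate(r):
                    expected[feat] += 2 - pos  # points = features ranked below
            assert np.allclose(out.borda_score, expected)

    def test_inconsistent_feature_sets_rejected(self):
        with pytest.raises(ValueError, match="permutations"):
            aggregate_ranks_borda([np.array([0, 1, 2]), np.array([0, 0, 2])])


@pytest.fixture(scope="module")
def ranked_cohort():
    pt, truth = planted_cohort(31)
    cv = CvConfig(n_models=40, seed=2)
    ranked, _ = rank_features(pt, cv)
    return pt, truth, cv, ranked


class TestRankingAndCurve:
    def test_planted_features_dominate_ranking(self, ranked_cohort):
        _, truth, _, ranked = ranked_cohort
        assert len(set(ranked.order[:10]) & truth.biomarker_indices) >= 4

    def test_first_evaluated_size_is_lv_plus_one(self, ranked_cohort):
        pt, _, cv, ranked = ranked_cohort
        curve = validation_curve(pt, ranked, cv, n_models_per_point=10, sizes=range(2, 8))
        assert curve.subset_sizes[0] == 4  # total LV = 3 → first size 4

    def test_signal_region_outperforms_minimal_prefix(self, ranked_cohort):
        pt, _, cv, ranked = ranked_cohort
        curve = validation_curve(
            pt, ranked, cv, n_models_per_point=30, sizes=[4, 8, 30, 90, 183]
        )
        full_signal = curve.mean_auroc[curve.subset_sizes == 8][0]
        assert full_signal >= curve.mean_auroc[0] - 0.02
        # appending noise features beyond the signal gains almost nothing
        assert curve.mean_auroc[-1] <= full_signal + 0.02


class TestRefine:
    def test_null_data_terminates_and_selection_does_not_transfer(self):
        """On pure-noise data the procedure terminates, and the features it
        picks — whose within-cohort CV metrics are inflated by ranking
        outside the CV loop — carry no signal into a fresh null cohort."""
        table, _ = generate_cohort(CohortConfig(seed=33))
        pt = preprocess_table(table)
        cv = CvConfig(n_models=20, seed=3)
        ranked, _ = rank_features(pt, cv)
        _, subsets = refine_subsets(pt, ranked, cv, n_models_per_point=20, max_passes=1)
        assert subsets
        sizes = [len(s.member_indices) for s in subsets]
        assert sizes == sorted(sizes, reverse=True)
        # transfer check: same selected features, independent null cohort
        fresh, _ = generate_cohort(CohortConfig(seed=34))
        fresh_pt = preprocess_table(fresh)
        ens = make_ensemble(
            fresh_pt, CvConfig(n_models=20, seed=4),
            feature_subset=subsets[-1].member_indices,
        )
        assert abs(np.median(ens.metric_values("auroc")) - 0.5) < 0.15

    def test_collinear_duplicate_biomarker_not_kept_twice(self):
        pt, truth = planted_cohort(35)
        # make feature 7 an exact copy of planted feature 60
        vals = pt.intensities.copy()
        vals[:, 7] = vals[:, 60]
        dup = pt.with_values(vals)
        cv = CvConfig(n_models=30, seed=4)
        ranked, _ = rank_features(dup, cv)
        _, subsets = refine_subsets(dup, ranked, cv, n_models_per_point=30, max_passes=2)
        smallest = set(int(j) for j in subsets[-1].member_indices)
        assert not ({7, 60} <= smallest)

    def test_smallest_subset_recovers_planted_features(self):
        pt, truth = planted_cohort(36)
        cv = CvConfig(n_models=50, seed=5)
        ranked, _ = rank_features(pt, cv)
        _, subsets = refine_subsets(pt, ranked, cv, n_models_per_point=50)
        smallest = set(int(j) for j in subsets[-1].member_indices)
        assert len(smallest & truth.biomarker_indices) >= 4
        assert len(smallest - truth.biomarker_indices) <= 5


def fake_ensemble(acc, sens, spec, auc):
    n = len(acc)
    records = [
        MetricRecord(accuracy=a, sensitivity=s, specificity=p, class_error=0.0, auroc=u)
        for a, s, p, u in zip(acc, sens, spec, auc)
    ]
    return CvEnsemble(records, np.empty((n, 0)), np.empty((n, 0)), [], None, 0)


class TestBestModel:
    def test_dominating_model_selected(self):
        ens = fake_ensemble(
            acc=[0.8, 0.8, 0.8, 0.95],
            sens=[0.8, 0.8, 0.8, 0.95],
            spec=[0.8, 0.8, 0.8, 0.95],
            auc=[0.85, 0.85, 0.85, 0.99],
        )
        # modal bins hold the three 0.8 models; best AUROC among them wins
        idx, rec = select_best_model(ens)
        assert idx == 0

    def test_intersection_of_modal_bins(self):
        rng = np.random.default_rng(6)
        acc = rng.uniform(0.7, 0.9, 200)
        sens = rng.uniform(0.7, 0.9, 200)
        spec = rng.uniform(0.7, 0.9, 200)
        auc = rng.uniform(0.8, 1.0, 200)
        ens = fake_ensemble(acc, sens, spec, auc)
        idx, rec = select_best_model(ens, bin_width=0.02)
        # the chosen model lies in the modal bin of at least one metric and
        # maximizes AUROC among equally-qualified candidates
        hits = 0
        for v, x in ((acc, rec.accuracy), (sens, rec.sensitivity), (spec, rec.specificity)):
            edges = np.arange(0.0, 1.04, 0.02)
            which = np.digitize(v, edges) - 1
            modal = np.argmax(np.bincount(which))
            hits += which[idx] == modal
        assert hits >= 1

    def test_auroc_tie_breaks_to_lowest_index(self):
        ens = fake_ensemble(
            acc=[0.8, 0.8, 0.8], sens=[0.8, 0.8, 0.8], spec=[0.8, 0.8, 0.8],
            auc=[0.9, 0.9, 0.9],
        )
        idx, _ = select_best_model(ens)
        assert idx == 0


class TestPermutation:
    def test_strong_signal_minimal_p(self):
        pt, truth = planted_cohort(37, effects=(0.5,) * 6)
        res = permutation_test(
            pt, subset=sorted(truth.biomarker_indices), n_perm=99,
            cv=CvConfig(n_models=4), seed=1,
        )
        assert res["p_value"] == pytest.approx(1 / 100)
        assert res["q2_observed"] > np.max(res["q2_permuted"])

    def test_deterministic_given_seed(self):
        table, _ = generate_cohort(CohortConfig(seed=38))
        pt = preprocess_table(table)
        r1 = permutation_test(pt, n_perm=20, cv=CvConfig(n_models=2), seed=9)
        r2 = permutation_test(pt, n_perm=20, cv=CvConfig(n_models=2), seed=9)
        assert r1["q2_observed"] == r2["q2_observed"]
        assert np.allclose(r1["q2_permuted"], r2["q2_permuted"])
        assert r1["p_value"] == r2["p_value"]

    def test_tiny_n_perm_rejected(self):
        table, _ = generate_cohort(CohortConfig(seed=39))
        pt = preprocess_table(table)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(pt, n_perm=5)


class TestPcaConfirmation:
    def test_subset_sharpens_class_separation(self):
        pt, truth = planted_cohort(40)
        res = pca_confirmation(pt, subset=sorted(truth.biomarker_indices))
        assert res["standardized_difference"].max() > (
            res["standardized_difference_all_features"].max()
        )

    def test_full_subset_identical_to_plain_pca(self):
        pt, _ = planted_cohort(41)
        res = pca_confirmation(pt, subset=np.arange(pt.n_feat))
        assert np.allclose(
            res["standardized_difference"],
            res["standardized_difference_all_features"],
        )

    def test_separation_invariant_to_score_sign(self):
        pt, truth = planted_cohort(42)
        res = pca_confirmation(pt, subset=sorted(truth.biomarker_indices))
        # the statistic uses |mean difference|, so flipping a component's
        # sign (equivalent loading convention) cannot change it
        assert (res["standardized_difference"] >= 0).all()
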