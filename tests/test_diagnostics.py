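import numpy as np
import pytest
from scipy import stats

from conftest import make_matrix
from dhgomics.diagnostics import (DiagnosticsError, assemble_panel,
                                  evaluate_validation, fit_panel_model,
                                  mccv_combined_roc, per_marker_auc,
                                  rf_importance, roc_single, svm_importance)


def candidate_matrix(rng, n_feat=6, n_per_group=15, strong=None, effect=3.0,
                     noise_sd=0.3):
    """Log2-scale candidate matrix; features in ``strong`` carry the effect."""
    n = 2 * n_per_group
    X = rng.normal(0, noise_sd, size=(n_feat, n))
    for j in strong or []:
        X[j, :n_per_group] += effect
    return make_matrix(X, ["case"] * n_per_group + ["control"] * n_per_group)


class TestRocSingle:
    def test_hand_counted_concordance(self):
        # cases (0.9, 0.4), controls (0.6, 0.1): 3 of 4 pairs concordant
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        groups = np.array(["case", "case", "control", "control"])
        auc, ci, direction = roc_single(scores, groups)
        assert auc == pytest.approx(0.75)
        assert ci[0] <= auc <= ci[1]
        assert direction == ">"

    def test_perfect_separation(self):
        scores = np.array([5.0, 6.0, 1.0, 2.0])
        groups = np.array(["case", "case", "control", "control"])
        assert roc_single(scores, groups)[0] == 1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        groups = np.array(["case"] * 15 + ["control"] * 15)
        a1, _, _ = roc_single(scores, groups)
        a2, _, _ = roc_single(np.exp(scores * 3), groups)
        assert a1 == pytest.approx(a2)

    def test_constant_scores_warn(self):
        with pytest.warns(UserWarning, match="constant"):
            auc, ci, _ = roc_single(np.ones(6),
                                    np.array(["case"] * 3 + ["control"] * 3))
        assert (auc, ci) == (0.5, (0.5, 0.5))

    def test_auc_equals_normalized_mannwhitney_u(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            case = rng.normal(1, 1, size=12)
            ctrl = rng.normal(0, 1, size=9)
            scores = np.concatenate([case, ctrl])
            groups = np.array(["case"] * 12 + ["control"] * 9)
            auc, _, _ = roc_single(scores, groups, orient=False)
            u = stats.mannwhitneyu(case, ctrl, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (12 * 9))


class TestRfImportance:
    def test_strong_feature_has_largest_mda(self):
        m = candidate_matrix(np.random.default_rng(2), strong=[2])
        res = rf_importance(m, n_trees=200, seed=0)
        assert max(res.rf_mda, key=res.rf_mda.get) == "F2"
        assert res.rf_mda["F2"] > 14

    def test_pure_noise_importance_near_zero(self):
        vals = []
        for rep in range(10):
            m = candidate_matrix(np.random.default_rng(40 + rep), strong=[0],
                                 n_feat=5)
            res = rf_importance(m, n_trees=150, seed=rep)
            vals.extend(res.rf_mda[f] for f in ("F3", "F4"))
        assert abs(float(np.mean(vals))) < 2.0  # percentage points

    def test_seed_determinism(self):
        m = candidate_matrix(np.random.default_rng(3), strong=[0])
        a = rf_importance(m, n_trees=50, seed=9)
        b = rf_importance(m, n_trees=50, seed=9)
        assert a.rf_mda == b.rf_mda

    def test_single_feature_rejected(self):
        m = candidate_matrix(np.random.default_rng(4), n_feat=1)
        with pytest.raises(DiagnosticsError):
            rf_importance(m)


class TestSvmImportance:
    def test_separating_feature_dominates(self):
        m = candidate_matrix(np.random.default_rng(5), strong=[1])
        res = svm_importance(m, n_subsamples=30, seed=0)
        assert max(res.svm_importance, key=res.svm_importance.get) == "F1"

    def test_importances_normalised(self):
        m = candidate_matrix(np.random.default_rng(6), strong=[0, 1])
        res = svm_importance(m, n_subsamples=20, seed=1)
        assert sum(res.svm_importance.values()) == pytest.approx(1.0, abs=1e-8)
        assert all(v >= 0 for v in res.svm_importance.values())

    def test_label_shuffle_levels_importances(self):
        # under shuffled labels no feature should dominate systematically
        per_feature = {f"F{j}": [] for j in range(5)}
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            m = candidate_matrix(rng, n_feat=5, strong=[0], n_per_group=12)
            shuffled = m.samples.copy()
            shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
            from dhgomics.matrix import IntensityMatrix
            ms = IntensityMatrix(m.values, shuffled)
            res = svm_importance(ms, n_subsamples=10, seed=rep)
            for f, v in res.svm_importance.items():
                per_feature[f].append(v)
        h = stats.kruskal(*per_feature.values())
        assert h.pvalue > 0.01


class TestAssemblePanel:
    def make_results(self):
        from dhgomics.diagnostics import ImportanceResult
        ids = ["A", "B", "C", "D"]
        rf = ImportanceResult(ids, rf_mda={"A": 20.0, "B": 5.0, "C": 16.0,
                                           "D": 1.0})
        svm = ImportanceResult(ids, svm_importance={"A": 0.4, "B": 0.3,
                                                    "C": 0.005, "D": 0.002})
        return rf, svm

    def test_union_with_provenance(self):
        rf, svm = self.make_results()
        panel = assemble_panel(rf, svm, crucial_members={"A", "B", "C", "D"})
        assert panel.marker_ids == ["A", "B", "C"]
        assert panel.provenance["A"] == ["rf_mda", "svm_importance"]
        assert panel.provenance["B"] == ["svm_importance"]
        assert panel.provenance["C"] == ["rf_mda"]

    def test_outside_crucial_pathways_excluded(self):
        rf, svm = self.make_results()
        panel = assemble_panel(rf, svm, crucial_members={"B", "C"})
        assert panel.marker_ids == ["B", "C"]

    def test_empty_panel_warns_not_raises(self):
        rf, svm = self.make_results()
        with pytest.warns(UserWarning, match="empty"):
            panel = assemble_panel(rf, svm, crucial_members=set())
        assert panel.empty_warning and panel.marker_ids == []

    def test_lowering_thresholds_never_removes_markers(self):
        rf, svm = self.make_results()
        crucial = {"A", "B", "C", "D"}
        tight = set(assemble_panel(rf, svm, crucial, 18, 0.35).marker_ids)
        mid = set(assemble_panel(rf, svm, crucial, 14, 0.01).marker_ids)
        loose = set(assemble_panel(rf, svm, crucial, 0.5, 0.001).marker_ids)
        assert tight <= mid <= loose


class TestMccv:
    def test_seed_reproducible_and_order_invariant(self):
        m = candidate_matrix(np.random.default_rng(7), strong=[0, 1])
        a = mccv_combined_roc(m, "LR", n_iter=20, seed=5)
        b = mccv_combined_roc(m, "LR", n_iter=20, seed=5)
        assert a.auc == b.auc

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(8)
        m = candidate_matrix(rng, n_feat=4, n_per_group=20, strong=[0],
                             effect=2.5)
        shuffled = m.samples.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        from dhgomics.matrix import IntensityMatrix
        ms = IntensityMatrix(m.values, shuffled)
        res = mccv_combined_roc(ms, "LR", n_iter=50, seed=0)
        assert abs(res.auc - 0.5) <= 0.1

    def test_too_small_test_split_rejected(self):
        m = candidate_matrix(np.random.default_rng(9), n_per_group=4)
        with pytest.raises(DiagnosticsError):
            mccv_combined_roc(m, "LR", train_fraction=0.95)

    def test_unknown_model_kind(self):
        m = candidate_matrix(np.random.default_rng(10))
        with pytest.raises(DiagnosticsError):
            mccv_combined_roc(m, "XGB")


class TestValidation:
    def test_frozen_model_generalises_to_same_process(self):
        rng = np.random.default_rng(11)
        disc = candidate_matrix(rng, strong=[0, 1], n_per_group=20)
        val = candidate_matrix(rng, strong=[0, 1], n_per_group=12)
        fitted = fit_panel_model(disc, "LR", seed=0)
        res = evaluate_validation(fitted, val)
        disc_auc = mccv_combined_roc(disc, "LR", n_iter=30, seed=0).auc
        assert res.cohort == "validation"
        assert abs(res.auc - disc_auc) < 0.1

    def test_shuffled_validation_labels_are_chance(self):
        rng = np.random.default_rng(12)
        disc = candidate_matrix(rng, strong=[0, 1], n_per_group=20)
        val = candidate_matrix(rng, strong=[0, 1], n_per_group=15)
        shuffled = val.samples.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        from dhgomics.matrix import IntensityMatrix
        val_s = IntensityMatrix(val.values, shuffled)
        res = evaluate_validation(fit_panel_model(disc, "LR", seed=0), val_s)
        assert abs(res.auc - 0.5) < 0.2

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(13)
        disc = candidate_matrix(rng, n_feat=4)
        val = candidate_matrix(rng, n_feat=3)
        with pytest.raises(DiagnosticsError, match="match"):
            evaluate_validation(fit_panel_model(disc, "LR", seed=0), val)

    def test_per_marker_auc_strong_feature_wins(self):
        m = candidate_matrix(np.random.default_rng(14), strong=[2],
                             n_per_group=20)
        res = per_marker_auc(m)
        assert max(res, key=lambda f: res[f][0]) == "F2"
        for auc, lo, hi in res.values():
            assert lo <= auc <= hi
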