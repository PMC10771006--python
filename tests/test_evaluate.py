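import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbpp import evaluate, model as model_mod, synthetic
from dbpp.evaluate import (
    ConfusionCounts,
    confusion_metrics,
    endpoint_attribution,
    external_validate,
    gamma_sweep,
    kfold_cv,
    pu_noise_analysis,
    roc_auc,
    score_distributions,
)


def _auc_oracle(scores, labels):
    """Exhaustive pair counting over all positive/negative pairs, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(ConfusionCounts(tp=90, tn=80, fp=20, fn=10))
        assert m.accuracy == pytest.approx(0.85)
        assert m.recall == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)
        assert m.precision == pytest.approx(0.8182, abs=1e-4)
        assert m.f1 == pytest.approx(2 * 0.9 * (90 / 110) / (0.9 + 90 / 110))

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (m.accuracy, m.recall, m.specificity, m.precision, m.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_denominator_is_undefined_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m.precision is None
        assert m.recall == 0.0

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_independent_arithmetic_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 100, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            if tp + fn:
                assert m.recall == pytest.approx(tp / (tp + fn))
            else:
                assert m.recall is None
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))
            else:
                assert m.specificity is None
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            else:
                assert m.precision is None

    @given(
        tp=st.integers(0, 500), tn=st.integers(0, 500),
        fp=st.integers(0, 500), fn=st.integers(0, 500),
    )
    @settings(derandomize=True, max_examples=100)
    def test_accuracy_is_prevalence_weighted_recall_specificity(self, tp, tn, fp, fn):
        p, n = tp + fn, tn + fp
        if p < 1 or n < 1:
            return
        m = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert m.accuracy == pytest.approx(
            (m.recall * p + m.specificity * n) / (p + n)
        )


class TestRocAuc:
    def test_perfect_and_antiperfect(self):
        labels = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels) == 0.0

    def test_tie_across_classes_counted_half(self):
        scores = [0.1, 0.5, 0.5, 0.9, 0.2, 0.7]
        labels = [0, 0, 1, 1, 0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_oracle(scores, labels)
        )

    def test_matches_pair_counting_on_short_tied_vectors(self):
        # every labeling and every score draw from a coarse tied grid, n <= 8
        rng = np.random.default_rng(7)
        grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        for n in range(2, 9):
            for _ in range(40):
                labels = rng.integers(0, 2, size=n)
                if labels.min() == labels.max():
                    continue
                scores = rng.choice(grid, size=n)
                assert roc_auc(scores, labels) == pytest.approx(
                    _auc_oracle(scores, labels)
                )

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        base = roc_auc(scores, labels)
        for transform in (np.exp, np.tanh, lambda s: 3 * s + 2):
            assert roc_auc(transform(scores), labels) == pytest.approx(base)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestKFoldCV:
    @pytest.fixture(scope="class")
    def data(self):
        tab = synthetic.generate_profiles(
            synthetic.ProfileGeneratorConfig(
                n_per_class=100, admet_effect=np.full(20, 2.0), seed=9
            )
        )
        return tab.stacked(), tab.y

    def test_folds_partition_dataset(self, data):
        X, y = data
        res = kfold_cv(X, y, model_mod.make_builder(algo="lr", tune=False),
                       k=10, seed=0)
        sizes = [len(idx) for idx in res.fold_indices]
        assert sizes == [20] * 10
        all_idx = np.concatenate(res.fold_indices)
        assert len(all_idx) == len(set(all_idx)) == len(y)

    def test_summary_matches_hand_computed_mean_sd(self, data):
        X, y = data
        res = kfold_cv(X, y, model_mod.make_builder(algo="lr", tune=False),
                       k=5, seed=0)
        accs = [m.accuracy for m in res.fold_metrics]
        s = res.summary()
        assert s.loc["accuracy", "mean"] == pytest.approx(np.mean(accs))
        assert s.loc["accuracy", "sd"] == pytest.approx(np.std(accs, ddof=1))

    def test_same_seed_same_folds(self, data):
        X, y = data
        a = kfold_cv(X, y, model_mod.make_builder(algo="lr", tune=False), k=5, seed=4)
        b = kfold_cv(X, y, model_mod.make_builder(algo="lr", tune=False), k=5, seed=4)
        for ia, ib in zip(a.fold_indices, b.fold_indices):
            np.testing.assert_array_equal(ia, ib)

    def test_class_smaller_than_k_raises(self):
        X = np.random.default_rng(0).normal(size=(12, 26))
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ValueError, match="class"):
            kfold_cv(X, y, model_mod.make_builder(algo="lr", tune=False), k=5)

    def test_leave_one_out_agrees_with_explicit_loop(self):
        tab = synthetic.generate_profiles(
            synthetic.ProfileGeneratorConfig(
                n_per_class=5, admet_effect=np.full(20, 3.0), seed=2
            )
        )
        X, y = tab.stacked(), tab.y
        builder = model_mod.make_builder(algo="lr", tune=False)
        res = kfold_cv(X, y, builder, k=len(y), seed=0)
        # explicit loop oracle
        scores = np.empty(len(y))
        for i in range(len(y)):
            train = np.delete(np.arange(len(y)), i)
            m = builder(X[train], y[train])
            scores[i] = m.predict_proba_matrix(X[i : i + 1])[0]
        m_oracle = evaluate.metrics_from_scores(scores, y)
        assert res.fold_metrics[0].accuracy == pytest.approx(m_oracle.accuracy)
        assert res.fold_metrics[0].auc == pytest.approx(m_oracle.auc)


class TestGammaSweep:
    def test_singleton_grid(self, strong_profiles):
        tab = strong_profiles
        sel = np.r_[0:100, 300:400]  # both classes
        res = gamma_sweep(
            tab.pc.to_numpy()[sel], tab.admet.to_numpy()[sel], tab.y[sel],
            lambda g: model_mod.make_builder(algo="lr", gamma=g, tune=False),
            grid=[0.6], k=3, seed=0,
        )
        assert res.selected_gamma == 0.6

    def test_invalid_grid_raises(self, strong_profiles):
        tab = strong_profiles
        with pytest.raises(ValueError, match="grid"):
            gamma_sweep(
                tab.pc.to_numpy(), tab.admet.to_numpy(), tab.y,
                lambda g: model_mod.make_builder(algo="lr", gamma=g, tune=False),
                grid=[1.5],
            )

    def test_admet_signal_pushes_gamma_up(self):
        tab = synthetic.generate_profiles(
            synthetic.ProfileGeneratorConfig(
                n_per_class=150, admet_effect=np.full(20, 0.75), seed=21
            )
        )
        res = gamma_sweep(
            tab.pc.to_numpy(), tab.admet.to_numpy(), tab.y,
            lambda g: model_mod.make_builder(algo="lr", gamma=g, tune=False),
            grid=[0.0, 0.25, 0.5, 0.75, 1.0], k=3, seed=21,
        )
        assert res.selected_gamma >= 0.5

    def test_pc_signal_pushes_gamma_down(self):
        tab = synthetic.generate_profiles(
            synthetic.ProfileGeneratorConfig(
                n_per_class=150, pc_effect=np.full(6, 0.75), seed=22
            )
        )
        res = gamma_sweep(
            tab.pc.to_numpy(), tab.admet.to_numpy(), tab.y,
            lambda g: model_mod.make_builder(algo="lr", gamma=g, tune=False),
            grid=[0.0, 0.25, 0.5, 0.75, 1.0], k=3, seed=22,
        )
        assert res.selected_gamma <= 0.5


class TestExternalValidate:
    def test_self_evaluation_consistency(self, strong_profiles):
        tab = strong_profiles
        m = model_mod.fit_profile_classifier(
            tab.pc.to_numpy(), tab.admet.to_numpy(), tab.y,
            algo="lr", tune=False, seed=0,
        )
        table = external_validate(m, {"train": (tab.stacked(), tab.y)})
        scores = m.predict_proba_matrix(tab.stacked())
        self_m = evaluate.metrics_from_scores(scores, tab.y)
        assert table.loc["train", "auc"] == pytest.approx(self_m.auc)
        assert table.loc["train", "accuracy"] == pytest.approx(self_m.accuracy)

    def test_iid_external_set_generalizes(self):
        cfg = dict(n_per_class=250, admet_effect=np.full(20, 2.0))
        train = synthetic.generate_profiles(
            synthetic.ProfileGeneratorConfig(**cfg, seed=31)
        )
        m = model_mod.fit_profile_classifier(
            train.pc.to_numpy(), train.admet.to_numpy(), train.y,
            algo="lgbm", tune=False, seed=0,
        )
        cv = kfold_cv(
            train.stacked(), train.y,
            model_mod.make_builder(algo="lgbm", tune=False), k=5, seed=31,
        )
        ext_aucs = []
        for seed in range(32, 37):
            ext = synthetic.generate_profiles(
                synthetic.ProfileGeneratorConfig(**cfg, seed=seed)
            )
            ext_aucs.append(
                external_validate(m, {"ext": (ext.stacked(), ext.y)}).loc["ext", "auc"]
            )
        assert abs(np.mean(ext_aucs) - cv.mean("auc")) < 0.05

    def test_covariate_shift_still_well_formed(self, strong_profiles):
        tab = strong_profiles
        m = model_mod.fit_profile_classifier(
            tab.pc.to_numpy(), tab.admet.to_numpy(), tab.y,
            algo="lr", tune=False, seed=0,
        )
        shifted = synthetic.generate_profiles(
            synthetic.ProfileGeneratorConfig(
                n_per_class=200, admet_effect=np.full(20, 0.5),
                pc_effect=np.full(6, 2.0), seed=44,
            )
        )
        table = external_validate(
            m,
            {
                "iid": (tab.stacked(), tab.y),
                "shifted": (shifted.stacked(), shifted.y),
            },
        )
        assert set(table.columns) >= {"accuracy", "auc", "n"}
        assert table.loc["shifted", "auc"] <= table.loc["iid", "auc"]


class TestScoreDistributions:
    def test_identical_sets_show_no_location_difference(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=200)
        rep = score_distributions({"a": s, "b": s.copy()})
        assert rep.pairwise_tests.loc[0, "p_value"] > 0.9

    def test_disjoint_ranges_give_max_u(self):
        rep = score_distributions(
            {"low": np.linspace(0.0, 0.2, 30), "high": np.linspace(0.8, 1.0, 40)}
        )
        row = rep.pairwise_tests.iloc[0]
        assert max(row["u_statistic"], 30 * 40 - row["u_statistic"]) == 30 * 40
        assert row["p_value"] < 1e-6

    def test_reported_mean_matches_vectors(self):
        rng = np.random.default_rng(5)
        sets = {f"s{i}": rng.uniform(size=50 + i) for i in range(3)}
        rep = score_distributions(sets)
        for name, vec in sets.items():
            assert rep.per_set.loc[name, "mean"] == pytest.approx(vec.mean())
            assert rep.per_set.loc[name, "n"] == len(vec)
        assert len(rep.pairwise_tests) == 3

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            score_distributions({})


class TestPUNoise:
    def test_unlabeled_from_positive_process_scores_high(self):
        cfg = dict(n_per_class=250, admet_effect=np.full(20, 1.0))
        a = synthetic.generate_profiles(synthetic.ProfileGeneratorConfig(**cfg, seed=1))
        b = synthetic.generate_profiles(synthetic.ProfileGeneratorConfig(**cfg, seed=2))
        res = pu_noise_analysis(
            a.stacked()[a.y == 1], b.stacked()[b.y == 1], seed=0, n_replicates=3
        )
        assert res["likely_positive_fraction"] >= 0.8

    def test_fully_separated_unlabeled_scores_low(self):
        tab = synthetic.generate_profiles(
            synthetic.ProfileGeneratorConfig(
                n_per_class=250, admet_effect=np.full(20, 4.0), seed=3
            )
        )
        res = pu_noise_analysis(
            tab.stacked()[tab.y == 1], tab.stacked()[tab.y == 0],
            seed=0, n_replicates=3,
        )
        assert res["likely_positive_fraction"] <= 0.1

    def test_deterministic_for_fixed_seed(self, strong_profiles):
        tab = strong_profiles
        P, U = tab.stacked()[tab.y == 1], tab.stacked()[tab.y == 0]
        r1 = pu_noise_analysis(P, U, spy_fraction=0.5, seed=9, n_replicates=2)
        r2 = pu_noise_analysis(P, U, spy_fraction=0.5, seed=9, n_replicates=2)
        assert r1["per_replicate"] == r2["per_replicate"]

    def test_invalid_inputs_raise(self, strong_profiles):
        tab = strong_profiles
        P = tab.stacked()[tab.y == 1]
        with pytest.raises(ValueError):
            pu_noise_analysis(P, np.empty((0, 26)))
        with pytest.raises(ValueError):
            pu_noise_analysis(P, P, spy_fraction=1.5)


class TestAttribution:
    def test_constant_feature_gets_zero_credit(self, strong_profiles):
        tab = strong_profiles
        X = tab.stacked().copy()
        X[:, 3] = 1.23  # pin one feature
        from lightgbm import LGBMClassifier

        clf = LGBMClassifier(n_estimators=50, verbose=-1, n_jobs=1,
                             random_state=0).fit(X, tab.y)
        att = endpoint_attribution(clf, X[:50])
        np.testing.assert_allclose(att.contributions[:, 3], 0.0)

    def test_tree_local_accuracy(self, strong_profiles):
        tab = strong_profiles
        m = model_mod.fit_profile_classifier(
            tab.pc.to_numpy(), tab.admet.to_numpy(), tab.y,
            algo="lgbm", tune=False, seed=0,
        )
        feats = model_mod.weight_profile_matrix(
            m.pc_scaler.transform(tab.pc.to_numpy()[:50]),
            tab.admet.to_numpy()[:50], m.gamma,
        )
        att = endpoint_attribution(m, feats)
        margin = m.classifier.predict(feats, raw_score=True)
        assert np.abs(att.reconstruct_margin() - margin).max() < 1e-6

    def test_linear_ranking_matches_weight_times_sd(self, strong_profiles):
        tab = strong_profiles
        m = model_mod.fit_profile_classifier(
            tab.pc.to_numpy(), tab.admet.to_numpy(), tab.y,
            algo="lr", tune=False, seed=0,
        )
        feats = model_mod.weight_profile_matrix(
            m.pc_scaler.transform(tab.pc.to_numpy()),
            tab.admet.to_numpy(), m.gamma,
        )
        names = [f"pc_{j}" for j in range(6)] + [f"adm_{j}" for j in range(20)]
        att = endpoint_attribution(m, feats, feature_names=names)
        w = np.asarray(m.classifier.coef_).ravel()
        # exact closed form: mean |w_j (x_j - mu_j)| per feature
        expected = np.abs(w[None, :] * (feats - feats.mean(axis=0))).mean(axis=0)
        for j, name in enumerate(names):
            assert att.importance[name] == pytest.approx(expected[j])
        # the ranking agrees with the |w_j| * dispersion_j ordering; with the
        # mean-absolute-deviation dispersion the match is exact, against
        # sd it holds up to sampling noise on near-ties (rank correlation)
        mad = np.abs(feats - feats.mean(axis=0)).mean(axis=0)
        rank_mad = [names[j] for j in np.argsort(-np.abs(w) * mad)]
        assert list(att.importance.index) == rank_mad
        from scipy.stats import spearmanr

        order = {n: i for i, n in enumerate(att.importance.index)}
        rho = spearmanr(
            [order[n] for n in names],
            np.argsort(np.argsort(-np.abs(w) * feats.std(axis=0))),
        ).statistic
        assert rho > 0.95

    def test_unsupported_model_raises(self):
        with pytest.raises(TypeError):
            endpoint_attribution(object(), np.zeros((3, 4)))
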