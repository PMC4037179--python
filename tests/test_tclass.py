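"""Base learners, LOOCV forward selection, stability index and the
majority-vote ensemble."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from conftest import make_two_class_table
from metapanel import (
    PanelDefinition,
    SampleTable,
    build_ensemble,
    classify,
    ensemble_predict,
    forward_select,
    load_printed_model,
    loocv_accuracy,
    stability_index,
    train_fisher,
    train_naive_bayes,
)
from metapanel.groups import HEALTHY, NON_ELS_MDD
from metapanel.tclass import EnsembleModel, Tclass, TrainedClassifier

COMP = (HEALTHY, NON_ELS_MDD)


def _table_1d(x0, x1):
    n0, n1 = len(x0), len(x1)
    ids = [f"a{i:03d}" for i in range(n0)] + [f"b{i:03d}" for i in range(n1)]
    labels = dict(zip(ids, [HEALTHY] * n0 + [NON_ELS_MDD] * n1))
    return SampleTable(ids, ["m0"], np.asarray(x0 + x1, dtype=float)[:, None], labels)


PANEL1 = PanelDefinition(COMP, "tclass", ("m0",))


# ---------------------------------------------------------------------------
# learners vs Bayes-rule oracles
# ---------------------------------------------------------------------------


class TestFisher:
    def test_symmetric_1d_boundary_at_midpoint(self):
        t = _table_1d([-1.0, 0.0, 1.0], [9.0, 10.0, 11.0])
        clf = train_fisher(t, PANEL1, COMP)
        assert classify(clf, [5.0 - 1e-6])[0] == HEALTHY
        assert classify(clf, [5.0 + 1e-6])[0] == NON_ELS_MDD
        # the boundary itself is within 1e-9 of 5: scores cross there
        lo, hi = clf.linear.scores([5.0 - 1e-9]), clf.linear.scores([5.0 + 1e-9])
        assert lo[0] >= lo[1] and hi[1] > hi[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_shared_covariance_bayes_oracle(self, seed):
        """Independent oracle: equal-prior Gaussian Bayes rule with the
        pooled within-class covariance, via scipy's multivariate normal."""
        rng = np.random.default_rng(seed)
        t = make_two_class_table(rng, n_per_class=15, p=3, shift=1.0)
        panel = PanelDefinition(COMP, "tclass", ("m0", "m1", "m2"))
        clf = train_fisher(t, panel, COMP)
        X, y, _ = t.comparison_arrays(COMP)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        d0, d1 = X[y == 0] - mu0, X[y == 1] - mu1
        S = (d0.T @ d0 + d1.T @ d1) / (len(X) - 2)
        pts = rng.normal(0.5, 1.5, size=(30, 3))
        oracle = (
            multivariate_normal.logpdf(pts, mu1, S)
            > multivariate_normal.logpdf(pts, mu0, S)
        )
        ours = np.array([classify(clf, x)[0] == NON_ELS_MDD for x in pts])
        assert (oracle == ours).all()

    def test_identical_class_means_tie_to_control(self):
        t = _table_1d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        clf = train_fisher(t, PANEL1, COMP)
        label, (s0, s1) = classify(clf, [2.0])
        assert s0 == pytest.approx(s1)
        assert label == HEALTHY

    def test_collinear_panel_ridge_path(self, rng):
        t = make_two_class_table(rng, n_per_class=10, p=1, shift=2.0)
        dup = SampleTable(
            t.sample_ids, ["m0", "m1"], np.column_stack([t.values, t.values]), t.labels
        )
        panel = PanelDefinition(COMP, "tclass", ("m0", "m1"))
        clf = train_fisher(dup, panel, COMP)  # singular pooled covariance
        X, y, _ = dup.comparison_arrays(COMP)
        assert np.mean(clf.predict01(X) == y) > 0.8


class TestNaiveBayes:
    def test_matches_factorized_log_density_oracle(self):
        """Per-class Gaussian log-density with class-specific variances
        (quadratic rule), computed independently via scipy.stats.norm."""
        rng = np.random.default_rng(2)
        x0 = list(rng.normal(0, 1, 6))
        x1 = list(rng.normal(1.5, 3, 6))
        t = _table_1d(x0, x1)
        clf = train_naive_bayes(t, PANEL1, COMP)
        mu0, s0 = np.mean(x0), np.std(x0, ddof=1)
        mu1, s1 = np.mean(x1), np.std(x1, ddof=1)
        for x in rng.normal(0.8, 2, size=10):
            oracle = norm.logpdf(x, mu1, s1) > norm.logpdf(x, mu0, s0)
            assert (classify(clf, [x])[0] == NON_ELS_MDD) == oracle

    def test_duplicated_features_scale_log_posterior_gap(self, rng):
        t = make_two_class_table(rng, n_per_class=8, p=1, shift=1.0)
        k = 3
        rep = SampleTable(
            t.sample_ids,
            [f"m{j}" for j in range(k)],
            np.repeat(t.values, k, axis=1),
            t.labels,
        )
        clf1 = train_naive_bayes(t, PANEL1, COMP)
        panelk = PanelDefinition(COMP, "tclass", tuple(f"m{j}" for j in range(k)))
        clfk = train_naive_bayes(rep, panelk, COMP)
        x = rng.normal(0.5, 1.0)
        s1 = clf1.score_matrix([[x]])[0]
        sk = clfk.score_matrix([[x] * k])[0]
        assert (sk[1] - sk[0]) == pytest.approx(k * (s1[1] - s1[0]), rel=1e-9)

    def test_equal_class_conditionals_tie_to_control(self):
        t = _table_1d([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        clf = train_naive_bayes(t, PANEL1, COMP)
        assert classify(clf, [1.0])[0] == HEALTHY

    def test_agrees_with_sklearn_gaussian_nb_on_clear_points(self, rng):
        from sklearn.naive_bayes import GaussianNB

        t = make_two_class_table(rng, n_per_class=20, p=2, shift=2.0)
        panel = PanelDefinition(COMP, "tclass", ("m0", "m1"))
        clf = train_naive_bayes(t, panel, COMP)
        X, y, _ = t.comparison_arrays(COMP)
        ref = GaussianNB(priors=[0.5, 0.5]).fit(X, y)
        pts = rng.normal(1.0, 2.0, size=(40, 2))
        agree = np.mean(ref.predict(pts) == clf.predict01(pts))
        assert agree >= 0.95  # variance conventions differ slightly at the margin


class TestPrintedClassifier:
    def test_printed_scores_at_healthy_means(self):
        """Brute-force evaluation of the two published affine forms at the
        catalog's healthy-group mean RPA vector."""
        from metapanel import catalog_entry

        pair, panel = load_printed_model()
        x = np.array([catalog_entry(m).moments(HEALTHY)[0] for m in panel.metabolites])
        ctrl = pair.control_intercept + float(np.dot(pair.control_coefficients, x))
        case = pair.case_intercept + float(np.dot(pair.case_coefficients, x))
        assert ctrl == pytest.approx(192.900322735, abs=1e-6)
        assert case == pytest.approx(185.443423693, abs=1e-6)
        clf = TrainedClassifier(
            learner="fisher", class_labels=tuple(pair.class_labels),
            panel=panel, linear=pair,
        )
        # control score exceeds the case score there: a healthy call
        assert classify(clf, x)[0] == "HEALTHY"


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------


class TestLoocv:
    def test_perfectly_separated_data(self):
        t = _table_1d([0, 0.1, 0.2, 0.3, 0.4], [10, 10.1, 10.2, 10.3, 10.4])
        assert loocv_accuracy(t, PANEL1, COMP, "fisher") == 1.0
        assert loocv_accuracy(t, PANEL1, COMP, "naive_bayes") == 1.0

    @pytest.mark.parametrize("learner", ["fisher", "naive_bayes"])
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_explicit_fold_loop_oracle(self, learner, seed):
        rng = np.random.default_rng(seed)
        t = make_two_class_table(rng, n_per_class=8, p=2, shift=0.8)
        panel = PanelDefinition(COMP, "tclass", ("m0", "m1"))
        got = loocv_accuracy(t, panel, COMP, learner)
        # oracle: rebuild each training fold as its own SampleTable
        train = train_fisher if learner == "fisher" else train_naive_bayes
        X, y, ids = t.comparison_arrays(COMP, metabolites=panel.metabolites)
        correct = 0
        for i in range(len(ids)):
            keep = [j for j in range(len(ids)) if j != i]
            fold = SampleTable(
                [ids[j] for j in keep], list(panel.metabolites), X[keep],
                {ids[j]: t.labels[ids[j]] for j in keep},
            )
            clf = train(fold, panel, COMP)
            pred = classify(clf, X[i])[0]
            truth = t.labels[ids[i]]
            correct += pred == truth
        assert got == pytest.approx(correct / len(ids), abs=1e-12)

    def test_contradictory_twins_bound_accuracy(self):
        """Two identical samples with opposite labels can never both be
        right; with 8 separable companions the LOOCV accuracy is 0.8."""
        x0 = [0.0, 0.1, 0.2, 0.3, 5.0]
        x1 = [10.0, 10.1, 10.2, 10.3, 5.0]
        t = _table_1d(x0, x1)
        assert loocv_accuracy(t, PANEL1, COMP, "fisher") == pytest.approx(0.8)

    def test_needs_three_samples(self):
        t = _table_1d([0.0], [1.0])
        with pytest.raises(ValueError):
            loocv_accuracy(t, PANEL1, COMP, "fisher")


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------


class TestForwardSelect:
    def test_informative_feature_found_first(self, rng):
        y = np.r_[np.zeros(8), np.ones(8)]
        X = np.column_stack([rng.normal(size=16), y * 8 + rng.normal(0, 0.1, 16), rng.normal(size=16)])
        ids = [f"s{i:03d}" for i in range(16)]
        labels = dict(zip(ids, [HEALTHY] * 8 + [NON_ELS_MDD] * 8))
        t = SampleTable(ids, ["m0", "m1", "m2"], X, labels)
        trace = forward_select(t, COMP, "fisher", k_max=3)
        assert trace.steps[0].added == "m1"
        # exhaustive step-1 scan oracle
        accs = {
            m: loocv_accuracy(t, PanelDefinition(COMP, "tclass", (m,)), COMP, "fisher")
            for m in ("m0", "m1", "m2")
        }
        assert trace.steps[0].loocv_accuracy == max(accs.values())

    def test_k_max_one(self, rng):
        t = make_two_class_table(rng, n_per_class=8, p=4, shift=1.0)
        trace = forward_select(t, COMP, "naive_bayes", k_max=1)
        assert len(trace.steps) == 1

    def test_panels_grow_as_prefixes_and_chosen_is_smallest_max(self, rng):
        t = make_two_class_table(rng, n_per_class=10, p=6, shift=0.8)
        trace = forward_select(t, COMP, "naive_bayes", k_max=6)
        for a, b in zip(trace.steps, trace.steps[1:]):
            assert b.panel[: len(a.panel)] == a.panel
        accs = trace.accuracies
        first_max = int(np.argmax(accs))
        assert trace.chosen.metabolites == trace.steps[first_max].panel

    def test_stops_at_perfect_accuracy(self):
        t = _table_1d([0, 0.1, 0.2, 0.3, 0.4], [9, 9.1, 9.2, 9.3, 9.4])
        trace = forward_select(t, COMP, "fisher", k_max=1)
        assert trace.steps[-1].loocv_accuracy == 1.0


# ---------------------------------------------------------------------------
# stability index and ensemble
# ---------------------------------------------------------------------------


class TestStability:
    def test_injected_perfect_classifier_gives_one(self, rng):
        t = make_two_class_table(rng, n_per_class=10, p=1)
        memory = {tuple(np.round(row, 12)): lab for row, lab in zip(t.values, (t.labels[s] != HEALTHY for s in t.sample_ids))}

        def perfect_trainer(X_train, y_train):
            return lambda X: np.array([memory[tuple(np.round(r, 12))] for r in X], dtype=int)

        res = stability_index(t, PANEL1, COMP, "fisher", n_splits=50, seed=1, _trainer=perfect_trainer)
        assert res.stability_index == 1.0

    def test_index_is_mean_of_split_accuracies(self, rng):
        t = make_two_class_table(rng, n_per_class=10, p=1, shift=1.0)
        res = stability_index(t, PANEL1, COMP, "naive_bayes", n_splits=100, seed=2)
        assert res.stability_index == pytest.approx(np.mean(res.split_accuracies), abs=1e-12)
        assert len(res.split_accuracies) == 100

    def test_sample_order_invariance(self, rng):
        t = make_two_class_table(rng, n_per_class=10, p=2, shift=1.0)
        perm = rng.permutation(t.n_samples)
        t2 = SampleTable(
            [t.sample_ids[i] for i in perm], t.metabolite_names, t.values[perm], t.labels
        )
        panel = PanelDefinition(COMP, "tclass", ("m0", "m1"))
        r1 = stability_index(t, panel, COMP, "fisher", n_splits=50, seed=7)
        r2 = stability_index(t2, panel, COMP, "fisher", n_splits=50, seed=7)
        assert np.allclose(r1.split_accuracies, r2.split_accuracies)

    def test_tiny_class_rejected(self):
        t = _table_1d([0.0, 1.0, 2.0], [5.0])
        with pytest.raises(ValueError, match="too small"):
            stability_index(t, PANEL1, COMP, "fisher", n_splits=10, seed=0)

    def test_monotone_in_effect_size(self):
        """Mean stability index over seeds is non-decreasing in the planted
        standardized effect size."""
        means = []
        for d in (0.0, 1.0, 2.0, 4.0):
            vals = []
            for seed in range(20):
                t = make_two_class_table(np.random.default_rng(seed), n_per_class=12, p=1, shift=d)
                vals.append(
                    stability_index(t, PANEL1, COMP, "naive_bayes", n_splits=100, seed=seed).stability_index
                )
            means.append(np.mean(vals))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


class TestEnsemble:
    def test_size_and_determinism(self, rng):
        t = make_two_class_table(rng, n_per_class=10, p=1, shift=2.0)
        m1 = build_ensemble(t, PANEL1, COMP, "fisher", n_splits=10, seed=4)
        m2 = build_ensemble(t, PANEL1, COMP, "fisher", n_splits=10, seed=4)
        assert m1.n_splits == 10
        for a, b in zip(m1.classifiers, m2.classifiers):
            assert a.linear.control_coefficients == b.linear.control_coefficients
            assert a.linear.case_intercept == b.linear.case_intercept

    def test_shares_split_stream_with_stability(self, rng):
        """Under one seed the ensemble's classifiers reproduce the stability
        run's per-split test accuracies."""
        t = make_two_class_table(rng, n_per_class=10, p=1, shift=1.0)
        seed = 9
        stab = stability_index(t, PANEL1, COMP, "naive_bayes", n_splits=20, seed=seed)
        ens = build_ensemble(t, PANEL1, COMP, "naive_bayes", n_splits=20, seed=seed)
        from metapanel.tclass import _iter_splits, _stratified_split_setup

        X, y, ids = t.comparison_arrays(COMP, metabolites=PANEL1.metabolites)
        idx0, idx1, k0, k1 = _stratified_split_setup(X, y, ids, 0.85)
        rng2 = np.random.default_rng(seed)
        for clf, (train, test) in zip(
            ens.classifiers, _iter_splits(rng2, idx0, idx1, k0, k1, 20)
        ):
            acc = float(np.mean(clf.predict01(X[test]) == y[test]))
            assert acc in stab.split_accuracies  # same stream, same order
        accs = [
            float(np.mean(clf.predict01(X[test]) == y[test]))
            for clf, (train, test) in zip(
                ens.classifiers,
                _iter_splits(np.random.default_rng(seed), idx0, idx1, k0, k1, 20),
            )
        ]
        assert np.allclose(accs, stab.split_accuracies)

    def test_separated_training_samples_all_predicted(self, rng):
        t = make_two_class_table(rng, n_per_class=10, p=1, shift=10.0)
        ens = build_ensemble(t, PANEL1, COMP, "fisher", n_splits=30, seed=0)
        X, y, _ = t.comparison_arrays(COMP, metabolites=PANEL1.metabolites)
        for x, truth in zip(X, y):
            pred = ensemble_predict(ens, x)
            assert pred.vote_fraction == (1.0 if truth else 0.0)
            assert (pred.predicted_label == NON_ELS_MDD) == bool(truth)

    def test_vote_threshold_is_strict(self):
        """Exactly half the classifiers voting the case is a control call."""
        panel = PanelDefinition(COMP, "tclass", ("m0",))

        def constant_clf(case_wins):
            from metapanel.sample_table import LinearClassifierPair

            hi, lo = (1.0, -1.0)
            return TrainedClassifier(
                learner="fisher", class_labels=COMP, panel=panel,
                linear=LinearClassifierPair(
                    class_labels=COMP, feature_names=("m0",),
                    control_intercept=lo if case_wins else hi,
                    case_intercept=hi if case_wins else lo,
                    control_coefficients=(0.0,), case_coefficients=(0.0,),
                ),
            )

        for n_case, expect_p, expect_label in [
            (600, 0.6, NON_ELS_MDD),
            (500, 0.5, HEALTHY),
            (0, 0.0, HEALTHY),
        ]:
            model = EnsembleModel(
                classifiers=[constant_clf(True)] * n_case + [constant_clf(False)] * (1000 - n_case),
                panel=panel, class_labels=COMP, train_fraction=0.85, seed=0,
            )
            pred = ensemble_predict(model, [0.0])
            assert pred.vote_fraction == pytest.approx(expect_p)
            assert pred.predicted_label == expect_label

    def test_feature_mismatch_rejected(self, rng):
        t = make_two_class_table(rng, n_per_class=10, p=1, shift=1.0)
        ens = build_ensemble(t, PANEL1, COMP, "fisher", n_splits=5, seed=0)
        with pytest.raises(ValueError):
            ensemble_predict(ens, [0.0, 1.0])


def test_tclass_results_surface(small_cohort):
    res = Tclass(small_cohort, COMP, "naive_bayes", k_max=3).fit(n_splits=100, seed=0)
    text = res.summary()
    assert "stability index" in text and "LOOCV" in text
    assert res.panel.method == "tclass"
    assert 0.0 <= res.stability_index <= 1.0
    import matplotlib

    matplotlib.use("Agg")
    ax = res.plot_selection()
    assert ax.get_xlabel() == "panel size"
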