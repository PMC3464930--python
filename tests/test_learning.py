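import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import log_softmax

from oracles import naive_posteriors, random_tree_model
from drem2.learning import (
    LearnConfig,
    em_fit,
    fit_weighted_multiclass_logistic,
    split_times,
    structure_search,
    viterbi_assign,
)
from drem2.model_core import DremModel, SplitClassifier, StateNode, chain_model
from drem2.regulators import feature_matrices
from drem2.synthetic import SimScenario, recovery_report, simulate


class TestWeightedLogistic:
    def test_no_signal_recovers_marginal_frequencies(self, rng):
        X = rng.normal(size=(300, 3))
        M = np.tile([0.3, 0.7], (300, 1))  # labels carry no feature signal
        clf = fit_weighted_multiclass_logistic(X, M, l2_penalty=1.0)
        assert np.abs(clf.weights).max() < 1e-3
        p = clf.probs(np.zeros((1, 3)))[0]
        assert p[1] == pytest.approx(0.7, abs=1e-3)

    def test_separable_labels_recover_weight_sign_and_optimum(self, rng):
        n = 200
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] > 0).astype(float)
        M = np.column_stack([1 - y, y])
        lam = 0.01
        clf = fit_weighted_multiclass_logistic(X, M, l2_penalty=lam)
        assert clf.weights[1, 0] > 0

        # independent generic-optimizer oracle: BFGS with numerical gradient
        def neg_obj(theta):
            w, b = theta[:2], theta[2]
            logits = np.column_stack([np.zeros(n), X @ w + b])
            return -(np.sum(M * log_softmax(logits, axis=1)) - lam * np.dot(w, w))

        res = minimize(neg_obj, np.zeros(3), method="BFGS",
                       options={"gtol": 1e-8, "maxiter": 2000})
        ours = neg_obj(np.append(clf.weights[1], clf.intercepts[1]))
        assert ours == pytest.approx(res.fun, abs=1e-6)

    def test_infinite_penalty_shrinks_weights_to_zero(self, rng):
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(float)
        M = np.column_stack([1 - y, y])
        clf = fit_weighted_multiclass_logistic(X, M, l2_penalty=1e8)
        assert np.abs(clf.weights).max() < 1e-3

    def test_soft_labels_and_sample_weights_respected(self, rng):
        # duplicating a gene equals doubling its mass
        X = rng.normal(size=(50, 2))
        M = rng.random((50, 2))
        c1 = fit_weighted_multiclass_logistic(
            np.vstack([X, X[:10]]), np.vstack([M, M[:10]]), 0.5
        )
        M2 = M.copy()
        M2[:10] *= 2
        c2 = fit_weighted_multiclass_logistic(X, M2, 0.5)
        np.testing.assert_allclose(c1.weights, c2.weights, atol=1e-4)


class TestEmFit:
    def test_chain_em_closes_to_per_timepoint_moments(self, rng):
        X = rng.normal(1.0, 2.0, size=(200, 4))
        m = chain_model([0.0] * 4, [1.0] * 4)
        m, _ = em_fit(m, X, None, LearnConfig())
        for t, node in enumerate(m.states()):
            assert node.mean == pytest.approx(X[:, t].mean(), abs=1e-9)
            assert node.var == pytest.approx(X[:, t].var(), abs=1e-9)

    def test_empty_gene_set_rejected(self):
        m = chain_model([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="empty"):
            em_fit(m, np.empty((0, 2)), None, LearnConfig())

    def test_posteriors_match_enumeration_oracle(self, rng):
        from scipy.special import softmax

        m = random_tree_model(rng, n_times=4, n_tfs=2)
        n = 30
        X = rng.normal(size=(n, 4))
        feats = {t: rng.normal(size=(2, n)) for t in range(1, 4)}
        L = m.path_loglik(X, feats)
        np.testing.assert_allclose(
            softmax(L, axis=1), naive_posteriors(m, X, feats), atol=1e-10
        )

    def test_em_runs_are_deterministic(self, default_sim):
        sim = default_sim
        cfg = LearnConfig(seed=7)

        def run():
            means = [float(np.mean(sim["X"][:, t])) for t in range(5)]
            vs = [float(np.var(sim["X"][:, t])) for t in range(5)]
            m = chain_model(means, vs, sim["dyn"].tf_ids)
            return em_fit(m, sim["X"], sim["features"], cfg)

        m1, t1 = run()
        m2, t2 = run()
        assert t1.logliks == t2.logliks

    def test_parameter_recovery_on_planted_two_leaf_model(self, default_sim):
        """EM on the true structure recovers means within 0.1 and the
        planted TF's positive classifier weight."""
        sim = default_sim
        truth = sim["truth"]
        import copy

        model = copy.deepcopy(truth["model"])
        # perturb parameters away from truth, keep the structure
        for node in model.states():
            node.mean += 0.5 if node.t % 2 else -0.5
            node.var = 1.0
        for s in model.splits():
            s.classifier = SplitClassifier(
                np.zeros_like(s.classifier.weights),
                np.zeros_like(s.classifier.intercepts),
            )
        model, trace = em_fit(model, sim["X"], sim["features"], LearnConfig())
        rep_model_means = sorted(n.mean for n in model.states() if n.t == 4)
        true_means = sorted(n.mean for n in truth["model"].states() if n.t == 4)
        np.testing.assert_allclose(rep_model_means, true_means, atol=0.1)
        sig = model.tf_ids.index(truth["signal_tf_id"])
        split = model.splits()[0]
        up = int(np.argmax([c.mean for c in split.children]))
        w = split.classifier.weights[:, sig]
        assert w[up] - np.mean(np.delete(w, up)) > 0

    def test_monotone_penalized_loglik(self, rng):
        for seed in range(5):
            scn = SimScenario(seed=seed + 100, n_genes=120)
            table, dyn, truth = simulate(scn)
            X = table.values[: scn.n_genes]
            feats = feature_matrices(dyn, scn.n_times)
            import copy

            model = copy.deepcopy(truth["model"])
            _, trace = em_fit(model, X, feats, LearnConfig(em_tol=1e-6))
            diffs = np.diff(trace.logliks)
            assert diffs.min() > -1e-8


class TestViterbi:
    def test_single_path_model_takes_everyone(self, rng):
        m = chain_model([0.0, 0.0], [1.0, 1.0])
        a = viterbi_assign(m, rng.normal(size=(10, 2)), None)
        assert set(a.leaf_indices) == {0}

    def test_exact_tie_goes_to_lower_leaf_index(self):
        left = StateNode(1, 1.0, 1.0)
        right = StateNode(1, 1.0, 1.0)
        root = StateNode(0, 0.0, 1.0, [left, right])
        root.classifier = SplitClassifier(np.zeros((2, 0)), np.zeros(2))
        m = DremModel(root=root, n_times=2)
        a = viterbi_assign(m, np.array([[0.0, 1.0]]), None)
        assert a.leaf_indices[0] == 0

    def test_matches_argmax_of_enumeration_oracle(self, rng):
        from oracles import naive_path_loglik

        m = random_tree_model(rng, n_times=4, n_tfs=2)
        n = 25
        X = rng.normal(size=(n, 4))
        feats = {t: rng.normal(size=(2, n)) for t in range(1, 4)}
        a = viterbi_assign(m, X, feats)
        np.testing.assert_array_equal(
            a.leaf_indices, np.argmax(naive_path_loglik(m, X, feats), axis=1)
        )


class TestStructureSearch:
    def test_infinite_penalty_returns_chain(self, default_sim):
        sim = default_sim
        cfg = LearnConfig(structure_penalty=1e12)
        model, _ = structure_search(
            sim["X"], sim["features"], cfg, tf_ids=sim["dyn"].tf_ids
        )
        assert split_times(model) == []
        assert len(model.leaves()) == 1

    def test_chain_data_yields_chain(self):
        scn = SimScenario(seed=5, split_time=None, n_genes=300)
        table, dyn, truth = simulate(scn)
        X = table.values[: scn.n_genes]
        feats = feature_matrices(dyn, scn.n_times)
        model, _ = structure_search(X, feats, LearnConfig(seed=5), tf_ids=dyn.tf_ids)
        assert split_times(model) == []

    def test_recovers_planted_single_split(self, trained_default):
        model = trained_default["model"]
        truth = trained_default["truth"]
        assignment = trained_default["assignment"]
        rep = recovery_report(truth, model, assignment)
        assert rep["split_time_exact"]
        assert rep["ari"] >= 0.9
        assert rep["max_mean_error"] <= 0.1
        assert rep["signal_weight_positive"]

    def test_config_echoed_into_model(self, trained_default):
        cfg = trained_default["model"].config
        assert cfg["seed"] == 1 and cfg["k_max"] == 3
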