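import numpy as np
import pytest
from scipy.optimize import linprog, minimize

from neurotrace.branch_merging import MergeCluster, MergeScenario, TerminalPoint
from neurotrace.learning import (
    DEFAULT_G,
    ClusterWeightedSVM,
    SignConstrainedPerceptron,
    active_learning_loop,
    confidence,
    generalization_error,
    loocv,
    predict_scenario,
    training_deltas,
)
from neurotrace.synthetic import planted_clusters, truth_oracle, DEFAULT_W_STAR

N = 9


def feature_cluster(features, label=None):
    """A cluster whose scenarios are defined directly by feature vectors."""
    n = 2
    cl = MergeCluster([TerminalPoint(i, np.zeros(3), np.array([1.0, 0, 0]))
                       for i in range(n)])
    cl.scenarios = [MergeScenario(((0,), (1,)), features=np.asarray(f, dtype=float))
                    for f in features]
    cl.label = label
    return cl


def lp_separable(X, g, kappa):
    """LP feasibility oracle for the sign-constrained margin system."""
    m, n = X.shape
    # variables w; maximize 0 subject to X w >= kappa, sign constraints
    A_ub = [-X[i] for i in range(m)]
    b_ub = [-kappa] * m
    bounds = []
    for k in range(n):
        if g[k] > 0:
            bounds.append((0, None))
        elif g[k] < 0:
            bounds.append((None, 0))
        else:
            bounds.append((None, None))
    res = linprog(np.zeros(n), A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=bounds, method="highs")
    return res.status == 0


class TestPerceptron:
    def test_single_example_converges_with_margin(self):
        X = np.zeros((1, N))
        X[0, 0] = 1.0
        clf = SignConstrainedPerceptron(kappa=1.0).fit(X)
        assert clf.converged_
        assert clf.w_[0] >= 1.0
        assert (X @ clf.w_ >= 1.0).all()

    def test_sign_conflict_flags_non_separable(self):
        # only satisfiable with w_0 < 0 while g_0 = +1
        X = np.zeros((1, N))
        X[0, 0] = -1.0
        clf = SignConstrainedPerceptron(kappa=1.0, max_updates=2000).fit(X)
        assert not clf.converged_

    def test_sign_constraints_hold_after_training(self, rng):
        X = rng.normal(size=(40, N))
        X[:, 0] = np.abs(X[:, 0]) + 0.5  # separable respecting g
        clf = SignConstrainedPerceptron().fit(X)
        assert (clf.w_ * DEFAULT_G >= 0).all()

    def test_agreement_with_lp_feasibility_oracle(self, rng):
        # 50 random separable sets with margin >= kappa and free signs
        g = np.zeros(N)
        for trial in range(50):
            w_true = rng.normal(size=N)
            w_true /= np.linalg.norm(w_true)
            X = rng.normal(size=(20, N))
            margins = X @ w_true
            X[margins < 0] *= -1  # flip to make separable
            X += np.outer(np.sign(X @ w_true), w_true)  # widen margin
            clf = SignConstrainedPerceptron(kappa=1.0, g=g,
                                            random_state=trial).fit(X)
            assert lp_separable(X, g, 1.0)
            assert clf.converged_
            assert (X @ clf.w_ > 0).all()

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            SignConstrainedPerceptron(kappa=-1).fit(np.ones((1, N)))


class TestSVM:
    def test_single_example_closed_form(self):
        # 1-D dual: L = a/m - a^2 |dx|^2 / (2 N m^2) with m = 1;
        # optimum a* = N / |dx|^2, w = a* dx
        dx = np.zeros(N)
        dx[0] = 2.0
        clf = ClusterWeightedSVM(C=1e6).fit(dx[None, :])
        a_star = N / 4.0
        assert clf.alpha_[0] == pytest.approx(a_star, rel=1e-6)
        np.testing.assert_allclose(clf.w_, a_star * dx, rtol=1e-6)

    def test_separable_set_satisfies_all_inequalities(self, rng):
        X = rng.normal(size=(30, N)) + 1.0
        clf = ClusterWeightedSVM().fit(X)
        assert (X @ clf.w_ > 0).all()
        assert clf.kkt_residual_ < 1e-6

    def test_doubling_c_inactive_when_box_unconstrained(self, rng):
        X = rng.normal(size=(15, N)) + 1.5
        w1 = ClusterWeightedSVM(C=2.0**20).fit(X).w_
        w2 = ClusterWeightedSVM(C=2.0**21).fit(X).w_
        np.testing.assert_allclose(w1, w2, atol=1e-4)

    def test_against_dense_qp_oracle(self, rng):
        # <= 10 examples: compare dual objective with scipy SLSQP
        X = rng.normal(size=(8, N)) + 0.8
        m = len(X)
        C = 100.0
        clf = ClusterWeightedSVM(C=C).fit(X)
        K = X @ X.T

        def neg_dual(a):
            return -(a.sum() / m - a @ K @ a / (2 * N * m * m))

        res = minimize(neg_dual, np.zeros(m), method="SLSQP",
                       bounds=[(0, C)] * m,
                       options={"maxiter": 1000, "ftol": 1e-12})
        assert clf.dual_objective_ == pytest.approx(-res.fun, abs=1e-4)

    def test_cluster_weights_scale_the_box(self):
        dx = np.ones((1, N))
        # tiny C so the box binds: alpha = C * Q
        clf1 = ClusterWeightedSVM(C=1e-3).fit(dx, sample_weight=[1.0])
        clf2 = ClusterWeightedSVM(C=1e-3).fit(dx, sample_weight=[2.0])
        assert clf2.alpha_[0] == pytest.approx(2 * clf1.alpha_[0])


class TestConfidence:
    def test_single_scenario_full_confidence(self):
        cl = feature_cluster([np.zeros(N)])
        assert confidence(cl, np.ones(N)) == pytest.approx(1.0)

    def test_two_equal_scores_give_half(self):
        cl = feature_cluster([np.zeros(N), np.zeros(N)])
        assert confidence(cl, np.ones(N)) == pytest.approx(0.5)

    def test_three_scenarios_direct_evaluation(self):
        f = [np.zeros(N), np.zeros(N), np.zeros(N)]
        f[1] = np.eye(N)[0] * 10
        f[2] = np.eye(N)[0] * 10
        cl = feature_cluster(f)
        w = np.eye(N)[0]
        expected = 1.0 / (1.0 + 2 * np.exp(-10))
        assert confidence(cl, w, T=1.0) == pytest.approx(expected, rel=1e-9)

    def test_temperature_never_reorders_pairwise_margins(self, rng):
        # two-scenario clusters: confidence is monotone in the score gap
        # for every T, so the ranking across clusters is T-invariant
        from scipy.stats import spearmanr

        clusters = [feature_cluster([np.zeros(N), rng.exponential(1, N)])
                    for _ in range(20)]
        w = np.abs(rng.normal(size=N))
        ranks = []
        for T in (0.5, 1.0, 2.0):
            ranks.append([confidence(cl, w, T) for cl in clusters])
        assert spearmanr(ranks[0], ranks[1]).statistic == pytest.approx(1.0)
        assert spearmanr(ranks[1], ranks[2]).statistic == pytest.approx(1.0)

    def test_invalid_temperature_rejected(self):
        cl = feature_cluster([np.zeros(N)])
        with pytest.raises(ValueError):
            confidence(cl, np.ones(N), T=0.0)


class TestLoocv:
    def test_two_identical_separable_clusters(self):
        a = feature_cluster([np.zeros(N), np.ones(N)], label=0)
        b = feature_cluster([np.zeros(N), np.ones(N)], label=0)
        assert loocv([a, b]) == 0.0

    def test_random_labels_approach_chance_error(self, rng):
        # labels drawn uniformly over B(3) = 5 scenarios carry no signal:
        # expected error ~ 1 - 1/5
        errs = []
        for trial in range(30):
            clusters = []
            for _ in range(6):
                feats = rng.exponential(1.0, size=(5, N))
                cl = feature_cluster(list(feats))
                cl.label = int(rng.integers(5))
                clusters.append(cl)
            errs.append(loocv(clusters, lambda: SignConstrainedPerceptron(max_updates=2000)))
        assert np.mean(errs) > 0.5  # far from separable performance

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError):
            loocv([feature_cluster([np.zeros(N)], label=0)])


class TestPlantedModel:
    def test_planted_weight_recovery(self):
        pool = planted_clusters(100, rng_seed=3)
        X, Q = training_deltas(pool)
        for make in (SignConstrainedPerceptron, ClusterWeightedSVM):
            w = make().fit(X, sample_weight=Q).w_
            cos = w @ DEFAULT_W_STAR / (np.linalg.norm(w) * np.linalg.norm(DEFAULT_W_STAR))
            assert cos >= 0.9

    def test_perceptron_and_svm_agree_on_planted_clusters(self):
        train = planted_clusters(100, rng_seed=5)
        test = planted_clusters(100, rng_seed=6)
        X, Q = training_deltas(train)
        wp = SignConstrainedPerceptron().fit(X, sample_weight=Q).w_
        ws = ClusterWeightedSVM().fit(X, sample_weight=Q).w_
        agree = np.mean([predict_scenario(c, wp) == predict_scenario(c, ws)
                         for c in test])
        assert agree >= 0.95

    def test_noiseless_pool_is_separable(self):
        pool = planted_clusters(50, noise=0.0, rng_seed=2)
        X, Q = training_deltas(pool)
        clf = SignConstrainedPerceptron().fit(X, sample_weight=Q)
        assert clf.converged_
        assert generalization_error(pool, clf.w_) == 0.0


class TestActiveLearning:
    def test_budget_zero_leaves_weights_unchanged(self):
        pool = planted_clusters(20, rng_seed=0)
        clf, history = active_learning_loop(pool, truth_oracle(pool), budget=0)
        assert history == []
        assert not hasattr(clf, "w_")

    def test_active_reaches_low_error_within_forty_labels(self):
        pool = planted_clusters(200, rng_seed=11)
        clf, history = active_learning_loop(pool, truth_oracle(pool),
                                            batch=10, budget=40, rng_seed=11)
        assert history[-1][0] <= 40
        assert history[-1][1] < 0.05

    def test_active_not_worse_than_random_on_average(self):
        # small paired comparison; the full 100-seed version runs in the
        # acceptance suite
        act, rnd = [], []
        for seed in range(5):
            pa = planted_clusters(200, rng_seed=seed)
            pr = planted_clusters(200, rng_seed=seed)
            _, ha = active_learning_loop(pa, truth_oracle(pa), batch=10,
                                         budget=40, rng_seed=seed)
            _, hr = active_learning_loop(pr, truth_oracle(pr), batch=10,
                                         budget=40, random_query=True,
                                         rng_seed=seed)
            act.append([e for _, e in ha])
            rnd.append([e for _, e in hr])
        act, rnd = np.mean(act, axis=0), np.mean(rnd, axis=0)
        assert (act <= rnd + 1e-12).all()

    def test_declined_queries_are_skipped_permanently(self):
        pool = planted_clusters(20, rng_seed=1)
        asked = []

        def oracle(cl):
            asked.append(id(cl))
            return None  # decline everything

        clf, history = active_learning_loop(pool, oracle, batch=5, budget=10)
        assert len(asked) == len(set(asked)) == 20  # each asked exactly once
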