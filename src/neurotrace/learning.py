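"""Learning the branch-merging rule: sign-constrained perceptron,
cluster-weighted SVM, confidence-driven active learning, and
leave-one-out cross-validation.

Both classifiers learn a weight vector ``w`` over the 9 scenario features
such that within every labeled cluster

    w . x_erroneous > w . x_correct        for all erroneous scenarios,

i.e. lower score ``w . x`` means a better scenario and the predicted
topology is the score argmin. Training uses the subtractively normalized
differences ``dx = x_erroneous - x_correct`` (one inequality
``w . dx > 0`` per erroneous scenario), so the number of training
inequalities m is the total number of scenarios minus the number of
labeled clusters.

The perceptron enforces a priori sign constraints ``w_k g_k >= 0``
(g_k = +-1 fixes the sign of weight k, 0 leaves it free; the default
g = (1,1,1,0,0,0,0,0,1) constrains distance, overrun, offset, and
free-terminal-count weights to be positive) and a robustness margin kappa
(analogous to the SVM margin). The SVM maximizes a box-constrained dual
with per-example cluster weights Q.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from neurotrace.branch_merging import (
    MergeCluster,
    N_FEATURES,
    compute_cluster_features,
    normalize_within_cluster,
)

DEFAULT_G = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1], dtype=float)


def _stack_deltas(deltas, weights):
    X = np.asarray(deltas, dtype=float)
    if X.ndim != 2:
        raise ValueError("deltas must be a 2D array of feature differences")
    if weights is None:
        weights = np.ones(len(X))
    w = np.asarray(weights, dtype=float)
    if len(w) != len(X):
        raise ValueError("weights length must match number of examples")
    return X, w


class SignConstrainedPerceptron(BaseEstimator):
    """Perceptron with fixed weight signs and a robustness margin.

    Weights are updated asynchronously on examples mu drawn with
    probability proportional to their cluster weights Q_mu: if
    ``(1/N) w . dx < kappa/N`` then ``w <- w + dx/N``; after every update,
    weights violating their sign constraint are set to zero. Training stops
    when a full pass over all examples produces no update (all margins
    satisfied), or at ``max_updates``.

    Parameters
    ----------
    kappa : float
        Robustness (margin) parameter; 0 gives the plain perceptron.
    g : array-like of {-1, 0, 1}, length 9
        Sign constraints; None uses the default (1,1,1,0,0,0,0,0,1).
    max_updates : int
        Cap on weight updates before flagging non-separability.
    random_state : int
        Seed for the example-sampling order.

    Attributes
    ----------
    w_ : ndarray
        Learned weight vector.
    converged_ : bool
        False if the cap was reached without achieving all margins.
    n_updates_ : int
    """

    def __init__(self, kappa: float = 1.0, g=None, max_updates: int = 50_000,
                 random_state: int = 0):
        self.kappa = kappa
        self.g = g
        self.max_updates = max_updates
        self.random_state = random_state

    def _g(self, n_features):
        g = DEFAULT_G if self.g is None else np.asarray(self.g, dtype=float)
        if len(g) != n_features:
            raise ValueError(f"g has length {len(g)}, expected {n_features}")
        return g

    def fit(self, X, y=None, sample_weight=None):
        """Learn w from feature differences X (rows dx; target w.dx > kappa)."""
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        X, Q = _stack_deltas(X, sample_weight)
        m, N = X.shape
        g = self._g(N)
        rng = np.random.default_rng(self.random_state)
        w = g.astype(float).copy()  # feasible start: signs trivially satisfied
        prob = Q / Q.sum()

        self.n_updates_ = 0
        self.converged_ = False
        while self.n_updates_ < self.max_updates:
            margins = X @ w / N
            violated = margins < self.kappa / N
            if not violated.any():
                self.converged_ = True
                break
            p = prob * violated
            mu = rng.choice(m, p=p / p.sum())
            w = w + X[mu] / N
            bad = w * g < 0
            w[bad] = 0.0
            self.n_updates_ += 1
        self.w_ = w
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.w_

    def predict(self, X):
        """+1 where w.dx > 0 (the inequality holds), else -1."""
        return np.where(self.decision_function(X) > 0, 1, -1)


class ClusterWeightedSVM(BaseEstimator):
    """Linear SVM on feature differences with per-example box weights.

    Maximizes the dual

        L(a) = (1/m) sum_i a_i - 1/(2 N m^2) sum_ij (dx_i . dx_j) a_i a_j
        subject to 0 <= a_i <= C Q_i,

    and sets ``w = (1/m) sum_i a_i dx_i``. Because the dual has no equality
    constraint, exact single-coordinate (projected Newton) ascent applies;
    iteration stops when the largest KKT violation drops below ``tol``.

    Parameters
    ----------
    C : float
        Box parameter (default 2**20; effectively hard-margin).
    tol : float
        KKT residual tolerance.

    Attributes
    ----------
    w_ : ndarray
    alpha_ : ndarray
        Dual variables.
    dual_objective_ : float
    """

    def __init__(self, C: float = 2.0**20, tol: float = 1e-6, max_updates: int = 50_000):
        self.C = C
        self.tol = tol
        self.max_updates = max_updates

    def fit(self, X, y=None, sample_weight=None):
        if self.C <= 0:
            raise ValueError("C must be positive")
        X, Q = _stack_deltas(X, sample_weight)
        m, N = X.shape
        K_diag = np.einsum("ij,ij->i", X, X)
        alpha = np.zeros(m)
        wt = np.zeros(N)  # sum_j alpha_j dx_j
        s = np.zeros(m)  # X @ wt, maintained incrementally
        upper = self.C * Q
        denom = N * m * m

        self.n_updates_ = 0
        self.kkt_residual_ = np.inf
        while self.n_updates_ < self.max_updates:
            grad = 1.0 / m - s / denom
            viol = np.where(
                alpha <= 0, np.maximum(grad, 0.0),
                np.where(alpha >= upper, np.maximum(-grad, 0.0), np.abs(grad)),
            )
            viol[K_diag <= 0] = 0.0
            i = int(np.argmax(viol))
            self.kkt_residual_ = float(viol[i])
            if self.kkt_residual_ < self.tol:
                break
            new = min(max(alpha[i] + grad[i] * denom / K_diag[i], 0.0), upper[i])
            d = new - alpha[i]
            if d == 0.0:
                break
            wt += d * X[i]
            s += d * (X @ X[i])
            alpha[i] = new
            self.n_updates_ += 1
        self.alpha_ = alpha
        self.w_ = wt / m
        self.dual_objective_ = float(alpha.sum() / m - wt @ wt / (2 * denom))
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.w_

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, 1, -1)


# -- scoring, confidence, evaluation ---------------------------------------

def cluster_scores(cluster: MergeCluster, w: np.ndarray) -> np.ndarray:
    """Scores w.x of all scenarios in a cluster (lower = better)."""
    if not cluster.scenarios or any(s.features is None for s in cluster.scenarios):
        compute_cluster_features(cluster)
    return np.array([s.features @ w for s in cluster.scenarios])


def predict_scenario(cluster: MergeCluster, w: np.ndarray) -> int:
    """Index of the best (argmin-score) scenario."""
    return int(np.argmin(cluster_scores(cluster, w)))


def confidence(cluster: MergeCluster, w: np.ndarray, T: float = 1.0) -> float:
    """Softmax confidence of the best scenario within a cluster.

        conf = exp(-w.x_best / T) / sum_i exp(-w.x_i / T)

    Values lie in (0, 1]; the temperature T changes the spread but never
    the ordering of confidences across clusters with the same best margin
    structure.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    s = cluster_scores(cluster, w)
    if s.size == 0:
        raise ValueError("cluster has no scenarios")
    z = -(s - s.min()) / T
    e = np.exp(z)
    return float(e.max() / e.sum())


def training_deltas(clusters, repeat_weights=True):
    """Stack subtractive-normalized examples of all labeled clusters.

    Returns (X, Q) where each erroneous scenario contributes one row and
    carries its cluster's weight.
    """
    xs, qs = [], []
    for cl in clusters:
        dx = normalize_within_cluster(cl)
        xs.append(dx)
        qs.append(np.full(len(dx), cl.weight if repeat_weights else 1.0))
    if not xs:
        return np.zeros((0, N_FEATURES)), np.zeros(0)
    return np.vstack(xs), np.concatenate(qs)


def generalization_error(clusters, w: np.ndarray) -> float:
    """Fraction of clusters whose argmin-scored scenario differs from the label."""
    labeled = [cl for cl in clusters if cl.label is not None]
    if not labeled:
        return 0.0
    wrong = sum(predict_scenario(cl, w) != cl.label for cl in labeled)
    return wrong / len(labeled)


def loocv(clusters, make_classifier=None) -> float:
    """Leave-one-out cross-validated cluster error rate.

    Each labeled cluster is held out once; the classifier is trained on the
    rest and errs if its argmin scenario on the held-out cluster is not the
    label.
    """
    labeled = [cl for cl in clusters if cl.label is not None]
    if len(labeled) < 2:
        raise ValueError("need at least 2 labeled clusters")
    if make_classifier is None:
        make_classifier = SignConstrainedPerceptron
    errors = 0
    for i, held in enumerate(labeled):
        rest = labeled[:i] + labeled[i + 1:]
        X, Q = training_deltas(rest)
        clf = make_classifier().fit(X, sample_weight=Q)
        if predict_scenario(held, clf.w_) != held.label:
            errors += 1
    return errors / len(labeled)


def active_learning_loop(
    pool: list[MergeCluster],
    oracle,
    batch: int = 5,
    budget: int = 40,
    make_classifier=None,
    eval_clusters: list[MergeCluster] | None = None,
    T: float = 1.0,
    random_query: bool = False,
    rng_seed: int = 0,
):
    """Pool-based active learning of the branch-merging rule.

    Repeatedly scores the unlabeled pool with the current weights, queries
    the ``batch`` lowest-confidence clusters through ``oracle(cluster)``
    (which returns the correct scenario index, or None to skip the cluster
    permanently), retrains on all collected labels, and records the
    cluster-level generalization error on ``eval_clusters`` (default: the
    not-yet-queried labeled part of the pool).

    With ``random_query=True`` queries are drawn uniformly instead —
    the baseline against which active selection is measured.

    Returns ``(classifier, history)`` where history is a list of
    ``(n_labeled, error)`` pairs.
    """
    if not pool:
        raise ValueError("pool is empty")
    if make_classifier is None:
        make_classifier = SignConstrainedPerceptron
    rng = np.random.default_rng(rng_seed)
    for cl in pool:
        compute_cluster_features(cl)

    clf = make_classifier()
    w = DEFAULT_G.copy()
    labeled: list[MergeCluster] = []
    skipped: set[int] = set()
    queried: set[int] = set()
    history: list[tuple[int, float]] = []

    def _eval(w_now):
        targets = eval_clusters if eval_clusters is not None else [
            cl for i, cl in enumerate(pool) if i not in queried and cl.label is not None
        ]
        return generalization_error(targets, w_now)

    while len(labeled) < budget:
        avail = [i for i in range(len(pool)) if i not in queried and i not in skipped]
        if not avail:
            break
        if random_query:
            picks = list(rng.choice(avail, size=min(batch, len(avail)), replace=False))
        else:
            confs = [confidence(pool[i], w, T) for i in avail]
            order = np.argsort(confs, kind="stable")
            picks = [avail[j] for j in order[: min(batch, len(avail))]]
        for i in picks:
            queried.add(i)
            ans = oracle(pool[i])
            if ans is None:
                skipped.add(i)
                continue
            pool[i].label = int(ans)
            labeled.append(pool[i])
            if len(labeled) >= budget:
                break
        if labeled:
            X, Q = training_deltas(labeled)
            clf = make_classifier().fit(X, sample_weight=Q)
            w = clf.w_
        history.append((len(labeled), _eval(w)))
    return clf, history
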