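"""Boosting core tests: stump oracles, one-iteration hand checks, projections."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trioboost import boosting as B


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def brute_force_best_stump_error(X, y, w):
    """Exhaustive enumeration over all (feature, threshold, leaf labels)."""
    best = min(w[y != 1].sum(), w[y != -1].sum())  # constant learners
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for t in 0.5 * (values[:-1] + values[1:]):
            left = X[:, j] <= t
            for ll, rl in itertools.product((-1.0, 1.0), repeat=2):
                pred = np.where(left, ll, rl)
                best = min(best, w[pred != y].sum())
    return best


def brute_force_best_stump_sse(X, z, w):
    left_all = (w @ z) / w.sum()
    best = float(w @ (z - left_all) ** 2)
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for t in 0.5 * (values[:-1] + values[1:]):
            left = X[:, j] <= t
            if left.all() or not left.any():
                continue
            lv = (w[left] @ z[left]) / w[left].sum()
            rv = (w[~left] @ z[~left]) / w[~left].sum()
            pred = np.where(left, lv, rv)
            best = min(best, float(w @ (z - pred) ** 2))
    return best


# ---------------------------------------------------------------------------
# Stump fitting
# ---------------------------------------------------------------------------


def test_classifier_stump_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n, p = 6, 2
        X = rng.normal(size=(n, p)).round(1)
        y = rng.choice([-1.0, 1.0], n)
        w = rng.random(n)
        w /= w.sum()
        stump = B.fit_stump_classifier(X, y, w)
        err = w[stump.predict(X) != y].sum()
        assert err == pytest.approx(brute_force_best_stump_error(X, y, w), abs=1e-12)


def test_binary_feature_stump_matches_exhaustive_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n, p = 10, 4
        X = rng.integers(0, 2, (n, p)).astype(float)
        y = rng.choice([-1.0, 1.0], n)
        w = rng.random(n)
        w /= w.sum()
        stump = B.fit_stump_classifier(X, y, w)
        err = w[stump.predict(X) != y].sum()
        assert err == pytest.approx(brute_force_best_stump_error(X, y, w), abs=1e-12)


def test_separable_feature_gives_zero_error():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([-1.0, -1.0, 1.0, 1.0])
    stump = B.fit_stump_classifier(X, y, np.full(4, 0.25))
    assert np.all(stump.predict(X) == y)


def test_uniform_weights_equal_unweighted_best():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(12, 3))
    y = rng.choice([-1.0, 1.0], 12)
    uni = B.fit_stump_classifier(X, y, np.full(12, 1 / 12))
    miss_uni = (uni.predict(X) != y).sum()
    # unweighted brute force counts misclassifications
    best = min(
        (np.where(X[:, j] <= t, ll, rl) != y).sum()
        for j in range(3)
        for t in np.unique(X[:, j])
        for ll, rl in itertools.product((-1.0, 1.0), repeat=2)
    )
    assert miss_uni == best


def test_all_identical_labels_returns_constant():
    X = np.array([[0.0], [1.0], [2.0]])
    stump = B.fit_stump_classifier(X, np.ones(3), np.full(3, 1 / 3))
    assert stump.feature == -1 and stump.left == 1.0


def test_regression_stump_constant_response():
    X = np.array([[0.0], [1.0], [2.0]])
    stump = B.fit_stump_regressor(X, np.full(3, 2.5), np.full(3, 1 / 3))
    assert stump.left == pytest.approx(2.5) and stump.right == pytest.approx(2.5)


def test_regression_stump_two_clusters_weighted_means():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    z = np.array([1.0, 2.0, 10.0, 14.0])
    w = np.array([0.3, 0.1, 0.2, 0.4])
    stump = B.fit_stump_regressor(X, z, w)
    assert stump.feature == 0
    assert stump.left == pytest.approx((0.3 * 1 + 0.1 * 2) / 0.4)
    assert stump.right == pytest.approx((0.2 * 10 + 0.4 * 14) / 0.6)


def test_regression_stump_matches_exhaustive_sse():
    rng = np.random.default_rng(3)
    for _ in range(30):
        X = rng.normal(size=(8, 2)).round(1)
        z = rng.normal(size=8)
        w = rng.random(8)
        stump = B.fit_stump_regressor(X, z, w)
        wn = w / w.sum()
        sse = float(wn @ (z - stump.predict(X)) ** 2)
        assert sse == pytest.approx(brute_force_best_stump_sse(X, z, wn), abs=1e-10)


def test_regression_stump_zero_weight_error():
    with pytest.raises(ValueError, match="degenerate"):
        B.fit_stump_regressor(np.zeros((3, 1)), np.ones(3), np.zeros(3))


@settings(derandomize=True, max_examples=50)
@given(st.data())
def test_stump_never_worse_than_constant(data):
    n = data.draw(st.integers(3, 12))
    X = np.array(
        data.draw(
            st.lists(
                st.lists(st.integers(0, 1), min_size=2, max_size=2),
                min_size=n,
                max_size=n,
            )
        ),
        dtype=float,
    )
    y = np.array(data.draw(st.lists(st.sampled_from([-1.0, 1.0]), min_size=n, max_size=n)))
    w = np.full(n, 1.0 / n)
    stump = B.fit_stump_classifier(X, y, w)
    err = w[stump.predict(X) != y].sum()
    assert err <= min(w[y != 1].sum(), w[y != -1].sum()) + 1e-12


# ---------------------------------------------------------------------------
# AdaBoost
# ---------------------------------------------------------------------------

# fixed 4-sample problem: stump splits feature 0 at 0.5; the third sample is
# then the single misclassification, giving weighted error 1/4
X4 = np.array([[0.0], [0.0], [0.0], [1.0]])
Y4 = np.array([1.0, 1.0, -1.0, -1.0])


def test_adaboost_first_stage_matches_hand_computation():
    """Stage 1 on the fixed 4-sample set: err = 1/4, alpha = 0.5 ln 3,
    reweighted distribution (1/6, 1/6, 1/2, 1/6)."""
    model = B.fit_adaboost(X4, Y4, M=1)
    learner, alpha = model.stages[0]
    assert alpha == pytest.approx(0.5 * np.log(3.0), abs=1e-10)
    assert model.diagnostics["weighted_errors"][0] == pytest.approx(0.25, abs=1e-12)
    # recompute the weight update by hand
    h = learner.predict(X4)
    w = np.full(4, 0.25) * np.exp(-alpha * Y4 * h)
    w /= w.sum()
    np.testing.assert_allclose(w, [1 / 6, 1 / 6, 1 / 2, 1 / 6], atol=1e-10)


def test_adaboost_single_stage_separable_is_perfect():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([-1.0, -1.0, 1.0, 1.0])
    model = B.fit_adaboost(X, y, M=1)
    labels, _ = B.predict_ensemble(model, X)
    np.testing.assert_array_equal(labels, y)


def test_adaboost_exponential_loss_decreases_to_separation():
    """The exponential loss (AdaBoost's monotone surrogate) shrinks each
    stage and the separable toy ends perfectly classified."""
    rng = np.random.default_rng(5)
    X = rng.integers(0, 2, (40, 6)).astype(float)
    y = np.where(X[:, 0] + X[:, 3] >= 1, 1.0, -1.0)
    model = B.fit_adaboost(X, y, M=20)
    losses = []
    score = np.zeros(40)
    for learner, alpha in model.stages:
        score += alpha * learner.predict(X)
        losses.append(np.mean(np.exp(-y * score)))
    assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))
    assert np.all(np.where(score >= 0, 1.0, -1.0) == y)


def test_adaboost_literal_update_variant_runs():
    model = B.fit_adaboost(X4, Y4, M=5, weight_update="literal")
    assert model.n_stages >= 1


def test_adaboost_rejects_tiny_input():
    with pytest.raises(ValueError):
        B.fit_adaboost(np.zeros((1, 1)), np.array([1.0]), M=1)


# ---------------------------------------------------------------------------
# LogitBoost
# ---------------------------------------------------------------------------


def test_logitboost_one_iteration_matches_hand_computation():
    """Initial P = 1/2, w = 1/N; z = +-2; the fitted stump has leaves
    (2/3, -2) and the updated probabilities are sigma(2H)."""
    model = B.fit_logitboost(X4, Y4, M=1)
    learner, coef = model.stages[0]
    assert coef == 0.5
    assert learner.feature == 0
    assert learner.left == pytest.approx(2 / 3, abs=1e-10)
    assert learner.right == pytest.approx(-2.0, abs=1e-10)
    H = 0.5 * learner.predict(X4)
    P = 1 / (1 + np.exp(-2 * H))
    expected = [1 / (1 + np.exp(-2 / 3))] * 3 + [1 / (1 + np.exp(2.0))]
    np.testing.assert_allclose(P, expected, atol=1e-10)


def test_logitboost_loss_decreases_and_probabilities_valid():
    rng = np.random.default_rng(6)
    X = rng.integers(0, 2, (30, 5)).astype(float)
    y = np.where(X[:, 1] > 0, 1.0, -1.0)
    y[:3] *= -1  # label noise
    model = B.fit_logitboost(X, y, M=25)
    losses = model.diagnostics["logistic_loss"]
    assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))
    H = model.scores(X)
    P = 1 / (1 + np.exp(-2 * H))
    assert np.all((P > 0) & (P < 1))


# ---------------------------------------------------------------------------
# TotalBoost and the entropy projection
# ---------------------------------------------------------------------------


def test_entropy_projection_single_constraint_vs_grid_search():
    """KL projection with one constraint, checked against a simplex grid."""
    U = np.array([[1.0, 1.0, -1.0]])
    cap = 0.2
    w, duals = B.entropy_project(U, cap)
    # dense grid over the 2-simplex
    best, best_kl = None, np.inf
    n = 400
    for i in range(n + 1):
        for j in range(n + 1 - i):
            g = np.array([i, j, n - i - j]) / n
            if (U @ g)[0] <= cap + 1e-12:
                gp = np.maximum(g, 1e-12)
                kl = float(np.sum(gp * np.log(gp * 3)))
                if kl < best_kl:
                    best, best_kl = g, kl
    np.testing.assert_allclose(w, best, atol=5e-3)
    assert duals[0] > 0


def test_entropy_projection_matches_convex_oracle():
    """<= 8-sample systems against an SLSQP primal solve."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(7)
    for _ in range(10):
        q, n = rng.integers(1, 4), 8
        U = rng.choice([-1.0, 1.0], (q, n))
        cap = rng.uniform(0.0, 0.5)
        try:
            w, _ = B.entropy_project(U, cap)
        except B.InfeasibleError:
            continue
        cons = [{"type": "ineq", "fun": lambda w, k=k: cap - U[k] @ w} for k in range(q)]
        cons.append({"type": "eq", "fun": lambda w: w.sum() - 1})
        res = minimize(
            lambda w: np.sum(w * np.log(np.maximum(w, 1e-300) * n)),
            np.full(n, 1 / n),
            constraints=cons,
            bounds=[(1e-12, 1)] * n,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        np.testing.assert_allclose(w, res.x, atol=1e-4)


def test_entropy_projection_detects_infeasibility():
    U = np.ones((1, 4))
    with pytest.raises(B.InfeasibleError):
        B.entropy_project(U, 0.5)


def test_totalboost_edge_constraints_hold_after_training():
    rng = np.random.default_rng(8)
    X = rng.integers(0, 2, (60, 6)).astype(float)
    logit = 1.2 * X[:, 0] - 0.9 * X[:, 4] + 0.3
    y = np.where(rng.random(60) < 1 / (1 + np.exp(-logit)), 1.0, -1.0)
    model = B.fit_totalboost(X, y, M=30, nu=0.05)
    w = model.diagnostics["final_weights"]
    gamma = model.diagnostics["gamma_hat"]
    U = np.array([y * learner.predict(X) for learner, _ in model.stages])
    assert np.all(U @ w <= gamma - 0.05 + 1e-6)


def test_totalboost_margin_approaches_lp_optimum():
    """On a separable toy, the normalized margin is near the LP optimum."""
    from scipy.optimize import linprog

    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [0, 0], [1, 1]], dtype=float)
    y = np.array([-1.0, -1.0, 1.0, 1.0, -1.0, 1.0])
    nu = 0.05
    model = B.fit_totalboost(X, y, M=50, nu=nu)
    coefs = np.array([c for _, c in model.stages])
    preds = np.array([learner.predict(X) for learner, _ in model.stages])
    margin = np.min(y * (coefs @ preds)) / coefs.sum()
    # LP over the full stump pool on these binary features
    pool = []
    for j in range(2):
        for ll, rl in itertools.product((-1.0, 1.0), repeat=2):
            pool.append(np.where(X[:, j] <= 0.5, ll, rl))
    A = np.array(pool).T * y[:, None]  # margins per sample x hypothesis
    # max rho s.t. A alpha >= rho, sum alpha = 1, alpha >= 0
    nh = A.shape[1]
    res = linprog(
        c=np.concatenate([np.zeros(nh), [-1.0]]),
        A_ub=np.hstack([-A, np.ones((len(y), 1))]),
        b_ub=np.zeros(len(y)),
        A_eq=np.concatenate([np.ones(nh), [0.0]])[None, :],
        b_eq=[1.0],
        bounds=[(0, None)] * nh + [(None, None)],
    )
    rho_star = -res.fun
    assert margin >= rho_star - 2 * nu - 1e-6


def test_totalboost_kl_from_uniform_nondecreasing():
    rng = np.random.default_rng(9)
    X = rng.integers(0, 2, (40, 5)).astype(float)
    logit = 0.8 * X[:, 1] - 0.8 * X[:, 3]
    y = np.where(rng.random(40) < 1 / (1 + np.exp(-logit)), 1.0, -1.0)
    # track the KL divergence of successive projections
    N = len(y)
    w = np.full(N, 1 / N)
    U_rows, gamma = [], np.inf
    kls = [0.0]
    for _ in range(10):
        learner = B.fit_tree_classifier(X, y, w, 1)
        u = y * learner.predict(X)
        if any(np.array_equal(u, r) for r in U_rows):
            break
        edge = float(w @ u)
        if edge <= 0:
            break
        U_rows.append(u)
        gamma = min(gamma, edge)
        try:
            w, _ = B.entropy_project(np.array(U_rows), gamma - 0.05)
        except B.InfeasibleError:
            break
        kls.append(float(np.sum(w * np.log(np.maximum(w, 1e-300) * N))))
    assert all(b >= a - 1e-9 for a, b in zip(kls, kls[1:]))


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def test_single_stage_model_predicts_like_its_learner():
    stump = B.DecisionStump(0, 0.5, -1.0, 1.0)
    model = B.BoostModel("AB", [(stump, 2.0)], tie_label=1.0, n_features=1)
    X = np.array([[0.0], [1.0]])
    labels, scores = B.predict_ensemble(model, X)
    np.testing.assert_array_equal(labels, stump.predict(X))
    np.testing.assert_allclose(scores, 2.0 * stump.predict(X))


def test_ensemble_scores_match_brute_force_stage_sum():
    rng = np.random.default_rng(10)
    X = rng.integers(0, 2, (30, 4)).astype(float)
    y = np.where(X[:, 0] + X[:, 2] + rng.normal(0, 0.4, 30) > 1, 1.0, -1.0)
    model = B.fit_adaboost(X, y, M=15)
    Xtest = rng.integers(0, 2, (20, 4)).astype(float)
    _, scores = B.predict_ensemble(model, Xtest)
    brute = sum(c * learner.predict(Xtest) for learner, c in model.stages)
    np.testing.assert_allclose(scores, brute, atol=1e-12)


def test_zero_score_tie_breaks_to_majority_label():
    stump = B.DecisionStump(-1, 0.0, 1.0, 1.0)
    model = B.BoostModel("AB", [(stump, 0.0)], tie_label=-1.0, n_features=1)
    labels, scores = B.predict_ensemble(model, np.array([[0.0]]))
    assert scores[0] == 0.0 and labels[0] == -1.0


def test_feature_arity_mismatch_raises():
    model = B.fit_adaboost(X4, Y4, M=1)
    with pytest.raises(ValueError, match="features"):
        B.predict_ensemble(model, np.zeros((2, 3)))


def test_fitters_are_deterministic():
    rng = np.random.default_rng(11)
    X = rng.integers(0, 2, (25, 5)).astype(float)
    y = np.where(X[:, 2] > 0, 1.0, -1.0)
    y[:4] *= -1
    for fit in (B.fit_adaboost, B.fit_logitboost, B.fit_totalboost):
        a, b = fit(X, y, M=10), fit(X, y, M=10)
        _, sa = B.predict_ensemble(a, X)
        _, sb = B.predict_ensemble(b, X)
        np.testing.assert_array_equal(sa, sb)
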