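"""Boosting classifiers over decision-tree weak learners.

Three binary boosting schemes are implemented from first principles:

* **AdaBoost** (discrete): stagewise exponential reweighting of
  misclassified samples, stage coefficient ``alpha = 0.5*ln((1-err)/err)``.
* **LogitBoost**: Newton steps on the binomial log-likelihood; each stage
  fits a regression tree to the working response ``z = (y* - P)/(P(1-P))``
  with weights ``w = P(1-P)`` and adds half of it to the additive score
  ``H``, with ``P = exp(H)/(exp(H)+exp(-H))``.
* **TotalBoost**: totally corrective; after each stage the sample weights are
  re-solved as the minimum-relative-entropy distribution (against uniform)
  whose edge on *every* past hypothesis is at most ``gamma_hat - nu``, where
  ``gamma_hat`` is the running minimum of observed edges and ``nu`` a slack.
  Stage coefficients are the (normalized) dual multipliers of the final
  projection.

Labels are ``{-1, +1}`` (minor allele -> +1).  Weak learners are weighted
decision trees (default: depth-1 stumps) fit by exhaustive search, so all
three fitters are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import logging

import numpy as np
from scipy.optimize import brentq

log = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "DecisionStump",
    "TreeNode",
    "BoostModel",
    "fit_stump_classifier",
    "fit_stump_regressor",
    "fit_tree_classifier",
    "fit_tree_regressor",
    "fit_adaboost",
    "fit_logitboost",
    "fit_totalboost",
    "predict_ensemble",
    "InfeasibleError",
    "SolverError",
]

_EPS = 1e-10


class InfeasibleError(RuntimeError):
    """The edge-constraint system admits no probability distribution."""


class SolverError(RuntimeError):
    """Projection solver failed to converge."""

    def __init__(self, msg: str, iterations: int):
        super().__init__(f"{msg} (after {iterations} iterations)")
        self.iterations = iterations


@dataclass
class TrainingSet:
    """Labeled, weighted samples for one boosting fit.

    ``y`` must be in {-1, +1}; weights are nonnegative and sum to one.
    """

    X: np.ndarray
    y: np.ndarray
    w: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be (N, p) with matching y")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 training samples")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("labels must be in {-1, +1}")
        if np.isnan(self.X).any():
            raise ValueError("X contains unknowns")
        if self.w is None:
            self.w = np.full(len(self.y), 1.0 / len(self.y))
        else:
            self.w = np.asarray(self.w, dtype=np.float64)
            if np.any(self.w < 0):
                raise ValueError("weights must be nonnegative")
            s = self.w.sum()
            if s <= 0:
                raise ValueError("degenerate weights: total weight is zero")
            self.w = self.w / s


# ---------------------------------------------------------------------------
# Weak learners
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecisionStump:
    """Single-split tree: value ``left`` where x[feature] <= threshold, else ``right``.

    ``feature == -1`` encodes a constant learner.
    """

    feature: int
    threshold: float
    left: float
    right: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.feature < 0:
            return np.full(X.shape[0], self.left)
        return np.where(X[:, self.feature] <= self.threshold, self.left, self.right)

    @property
    def n_features_min(self) -> int:
        return self.feature + 1


@dataclass(frozen=True)
class TreeNode:
    """Internal node of a depth-limited decision tree."""

    feature: int
    threshold: float
    left: object  # TreeNode | float leaf
    right: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0])
        go_left = X[:, self.feature] <= self.threshold
        for side, sel in ((self.left, go_left), (self.right, ~go_left)):
            if isinstance(side, TreeNode):
                out[sel] = side.predict(X[sel])
            else:
                out[sel] = side
        return out


def _leaf_label(wp: float, wn: float) -> float:
    """Weighted-majority leaf label; ties go to +1."""
    return 1.0 if wp >= wn else -1.0


def _is_binary(X: np.ndarray) -> bool:
    return bool(np.isin(X, (0.0, 1.0)).all())


def _binary_stump_classifier(X, y, w, wp_tot, wn_tot) -> DecisionStump:
    """Exact fast path for 0/1 features: the only split is at 0.5.

    Per-leaf class weights for every feature come from two matrix-vector
    products, which reproduces the exhaustive search result (including its
    lowest-feature-index tie-break) at a fraction of the cost.
    """
    wp = np.where(y > 0, w, 0.0)
    wn = w - wp
    rp = wp @ X  # class weight with x == 1 (right leaf), per feature
    rn = wn @ X
    lp, ln = wp_tot - rp, wn_tot - rn
    err = np.minimum(lp, ln) + np.minimum(rp, rn)
    splittable = (lp + ln > 0) & (rp + rn > 0)
    err = np.where(splittable, err, np.inf)
    j = int(np.argmin(err))  # first minimum -> lowest feature index
    base_err = min(wp_tot, wn_tot)
    if not splittable[j] or err[j] >= base_err - 1e-15:
        lab = _leaf_label(wp_tot, wn_tot)
        return DecisionStump(-1, 0.0, lab, lab)
    return DecisionStump(
        j, 0.5, _leaf_label(lp[j], ln[j]), _leaf_label(rp[j], rn[j])
    )


def fit_stump_classifier(X, y, w) -> DecisionStump:
    """Best depth-1 classification tree by exhaustive weighted-error search.

    Every feature and every midpoint between consecutive distinct values is
    scored; each leaf takes its weighted-majority label.  Ties break to the
    lowest feature index, then the lowest threshold.  If all labels agree the
    constant learner carrying that label is returned.
    """
    ts = TrainingSet(X, y, w)
    X, y, w = ts.X, ts.y, ts.w
    wp_tot = float(w[y > 0].sum())
    wn_tot = float(w[y < 0].sum())
    if wp_tot == 0.0 or wn_tot == 0.0:
        lab = _leaf_label(wp_tot, wn_tot)
        return DecisionStump(-1, 0.0, lab, lab)
    if _is_binary(X):
        return _binary_stump_classifier(X, y, w, wp_tot, wn_tot)
    best_err = min(wp_tot, wn_tot)
    best_stump = DecisionStump(-1, 0.0, _leaf_label(wp_tot, wn_tot), _leaf_label(wp_tot, wn_tot))
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        wp = np.cumsum(np.where(y[order] > 0, w[order], 0.0))
        wn = np.cumsum(np.where(y[order] < 0, w[order], 0.0))
        cut = np.flatnonzero(np.diff(xs) > 0)  # split after sorted position i
        if len(cut) == 0:
            continue
        lp, ln = wp[cut], wn[cut]
        rp, rn = wp_tot - lp, wn_tot - ln
        err = np.minimum(lp, ln) + np.minimum(rp, rn)
        i = int(np.argmin(err))  # first minimum -> lowest threshold
        if err[i] < best_err - 1e-15:
            best_err = float(err[i])
            c = cut[i]
            thr = 0.5 * (xs[c] + xs[c + 1])
            best_stump = DecisionStump(
                j, float(thr), _leaf_label(lp[i], ln[i]), _leaf_label(rp[i], rn[i])
            )
    return best_stump


def fit_stump_regressor(X, z, w) -> DecisionStump:
    """Best depth-1 regression tree under weighted least squares.

    Leaf values are the weighted means of their side; the split minimizes
    weighted SSE over all features and midpoints.  A constant learner (the
    global weighted mean) is returned when no split improves on it.
    """
    X = np.asarray(X, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if w.sum() <= 0:
        raise ValueError("degenerate weights: total weight is zero")
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(w))):
        raise ValueError("working responses and weights must be finite")
    w = w / w.sum()
    mean = float(w @ z)
    if _is_binary(X):
        return _binary_stump_regressor(X, z, w, mean)
    best_gain = 0.0
    best_stump = DecisionStump(-1, 0.0, mean, mean)
    for j in range(X.shape[1]):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        cw = np.cumsum(w[order])
        cwz = np.cumsum((w * z)[order])
        cut = np.flatnonzero(np.diff(xs) > 0)
        if len(cut) == 0:
            continue
        lw, lz = cw[cut], cwz[cut]
        rw, rz = cw[-1] - lw, cwz[-1] - lz
        ok = (lw > 0) & (rw > 0)
        if not ok.any():
            continue
        # SSE reduction relative to the constant fit
        gain = np.where(ok, lz**2 / np.maximum(lw, _EPS) + rz**2 / np.maximum(rw, _EPS), -np.inf)
        i = int(np.argmax(gain))
        g = float(gain[i]) - mean**2 * cw[-1]
        if g > best_gain + 1e-15:
            best_gain = g
            c = cut[i]
            best_stump = DecisionStump(
                j,
                float(0.5 * (xs[c] + xs[c + 1])),
                float(lz[i] / lw[i]),
                float(rz[i] / rw[i]),
            )
    return best_stump


def _binary_stump_regressor(X, z, w, mean) -> DecisionStump:
    """Exact fast path of the weighted-least-squares stump for 0/1 features."""
    rw = w @ X
    rz = (w * z) @ X
    lw, lz = 1.0 - rw, (w @ z) - rz
    ok = (lw > 0) & (rw > 0)
    gain = np.where(
        ok, lz**2 / np.maximum(lw, _EPS) + rz**2 / np.maximum(rw, _EPS), -np.inf
    ) - mean**2
    j = int(np.argmax(gain))
    if not ok[j] or gain[j] <= 1e-15:
        return DecisionStump(-1, 0.0, mean, mean)
    return DecisionStump(j, 0.5, float(lz[j] / lw[j]), float(rz[j] / rw[j]))


def fit_tree_classifier(X, y, w, depth: int = 1):
    """Depth-limited weighted classification tree (greedy stump recursion)."""
    stump = fit_stump_classifier(X, y, w)
    if depth <= 1 or stump.feature < 0:
        return stump
    X = np.asarray(X, dtype=float)
    go_left = X[:, stump.feature] <= stump.threshold
    sides = []
    for sel, leaf in ((go_left, stump.left), (~go_left, stump.right)):
        if sel.sum() >= 2 and len(np.unique(y[sel])) > 1:
            sides.append(fit_tree_classifier(X[sel], y[sel], w[sel], depth - 1))
        else:
            sides.append(leaf)
    return TreeNode(stump.feature, stump.threshold, sides[0], sides[1])


def fit_tree_regressor(X, z, w, depth: int = 1):
    """Depth-limited weighted regression tree (greedy stump recursion)."""
    stump = fit_stump_regressor(X, z, w)
    if depth <= 1 or stump.feature < 0:
        return stump
    X = np.asarray(X, dtype=float)
    go_left = X[:, stump.feature] <= stump.threshold
    sides = []
    for sel, leaf in ((go_left, stump.left), (~go_left, stump.right)):
        if sel.sum() >= 2:
            sides.append(fit_tree_regressor(X[sel], z[sel], w[sel], depth - 1))
        else:
            sides.append(leaf)
    return TreeNode(stump.feature, stump.threshold, sides[0], sides[1])


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class BoostModel:
    """Ordered weak learners with stage coefficients.

    ``method`` is one of ``"AB"``, ``"LB"``, ``"TB"``.  ``tie_label`` is the
    majority training label, used when the ensemble score is exactly zero.
    """

    method: str
    stages: List[Tuple[object, float]] = field(default_factory=list)
    tie_label: float = 1.0
    n_features: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        s = np.zeros(X.shape[0])
        for learner, coef in self.stages:
            s += coef * learner.predict(X)
        return s


def predict_ensemble(model: BoostModel, X) -> Tuple[np.ndarray, np.ndarray]:
    """Weighted-majority vote: ``(labels, scores)``.

    The score is the coefficient-weighted sum of stage predictions (for
    LogitBoost this equals the additive logit H(x)); labels are its sign with
    exact zeros resolved to the majority training label.
    """
    scores = model.scores(X)
    labels = np.where(scores > 0, 1.0, np.where(scores < 0, -1.0, model.tie_label))
    return labels, scores


def _majority(y: np.ndarray) -> float:
    return 1.0 if (y > 0).sum() >= (y < 0).sum() else -1.0


def fit_adaboost(
    X,
    y,
    M: int = 100,
    depth: int = 1,
    weight_update: str = "standard",
) -> BoostModel:
    """Discrete AdaBoost with weighted decision trees.

    Weights start uniform; after each stage, misclassified samples are
    up-weighted by ``exp(alpha)`` and the weights renormalized to sum to one.
    A stage with weighted error 0 receives a large capped coefficient and
    training stops; a stage with error >= 0.5 is not added and training
    stops.  ``weight_update="literal"`` switches to the variant
    ``w_i <- w_i * exp(-w_i * alpha * h(x_i))`` for comparison.
    """
    ts = TrainingSet(X, y)
    X, y = ts.X, ts.y
    if M < 1:
        raise ValueError("M must be >= 1")
    N = len(y)
    w = np.full(N, 1.0 / N)
    model = BoostModel("AB", tie_label=_majority(y), n_features=X.shape[1])
    errors = []
    for _ in range(M):
        learner = fit_tree_classifier(X, y, w, depth)
        h = learner.predict(X) if hasattr(learner, "predict") else np.full(N, learner)
        miss = h != y
        err = float(w[miss].sum())
        errors.append(err)
        if err >= 0.5:
            break
        if err <= 0.0:
            alpha = 0.5 * np.log((1 - _EPS) / _EPS)
            model.stages.append((learner, alpha))
            break
        alpha = 0.5 * np.log((1 - err) / err)
        model.stages.append((learner, alpha))
        if weight_update == "literal":
            w = w * np.exp(-w * alpha * h)
        else:
            w = w * np.exp(-alpha * y * h)
        w = w / w.sum()
    if not model.stages:  # first stage already no better than chance
        const = DecisionStump(-1, 0.0, model.tie_label, model.tie_label)
        model.stages.append((const, 1.0))
    model.diagnostics["weighted_errors"] = errors
    return model


def fit_logitboost(X, y, M: int = 100, depth: int = 1) -> BoostModel:
    """Two-class LogitBoost (Newton steps on the binomial log-likelihood).

    Probabilities start at 0.5 (H = 0).  Each stage computes the working
    response ``z = (y* - P) / (P (1 - P))`` (``y*`` in {0,1}) and weights
    ``P (1 - P)``, fits a weighted regression tree, and adds half of it to
    H; then ``P = exp(H) / (exp(H) + exp(-H))``.  Numerical guards: P is
    clamped to [1e-5, 1-1e-5] and z to [-4, 4].  Stops at M stages or when
    the fitted tree is identically zero.
    """
    ts = TrainingSet(X, y)
    X, y = ts.X, ts.y
    if M < 1:
        raise ValueError("M must be >= 1")
    ystar = (y + 1) / 2
    N = len(y)
    H = np.zeros(N)
    model = BoostModel("LB", tie_label=_majority(y), n_features=X.shape[1])
    losses = []
    for _ in range(M):
        P = 1.0 / (1.0 + np.exp(-2.0 * H))
        P = np.clip(P, 1e-5, 1 - 1e-5)
        wgt = P * (1 - P)
        z = np.clip((ystar - P) / wgt, -4.0, 4.0)
        learner = fit_tree_regressor(X, z, wgt, depth)
        f = learner.predict(X) if hasattr(learner, "predict") else np.full(N, learner)
        if np.max(np.abs(f)) < 1e-12:
            break
        model.stages.append((learner, 0.5))
        H = H + 0.5 * f
        losses.append(float(np.mean(np.log1p(np.exp(-2.0 * y * H)))))
    if not model.stages:
        const = DecisionStump(-1, 0.0, model.tie_label, model.tie_label)
        model.stages.append((const, 0.0))
    model.diagnostics["logistic_loss"] = losses
    return model


# -- TotalBoost ------------------------------------------------------------


def _tilt_edge(w: np.ndarray, u: np.ndarray, lam: float) -> float:
    """Edge of ``u`` under the exponentially tilted distribution."""
    t = w * np.exp(-lam * (u - u.mean()))  # centring for numerical range
    return float((t @ u) / t.sum())


def _solve_lambda(w, u, target, lam_max=500.0):
    """Smallest lambda >= 0 with tilted edge == target (edge decreasing in lambda)."""
    lo, hi = 0.0, 1.0
    e_hi = _tilt_edge(w, u, hi)
    while e_hi > target:
        hi *= 2.0
        if hi > lam_max:
            raise InfeasibleError("edge constraint unreachable by tilting")
        e_hi = _tilt_edge(w, u, hi)
    return brentq(lambda l: _tilt_edge(w, u, l) - target, lo, hi, xtol=1e-12)


def entropy_project(U: np.ndarray, cap: float, tol: float = 1e-8, max_iter: int = 2000):
    """KL projection of the uniform distribution onto the edge polytope.

    Minimizes ``KL(w || uniform)`` subject to ``U @ w <= cap`` with ``w`` on
    the simplex.  Solved in the dual: the optimum has the exponential-family
    form ``w_i proportional to exp(-sum_q lam_q U[q, i])`` with multipliers
    ``lam >= 0`` minimizing the smooth convex function

        g(lam) = log mean_i exp(-(lam @ U)_i) + cap * sum(lam),

    which L-BFGS-B handles directly.  Returns ``(w, duals)``.

    Raises :class:`InfeasibleError` when the polytope is empty (the dual is
    unbounded below, detected by diverging multipliers with residual
    violation) and :class:`SolverError` on non-convergence.
    """
    from scipy.optimize import minimize

    q, N = U.shape
    if np.any(U.min(axis=1) > cap + tol):
        raise InfeasibleError("a single edge constraint is unsatisfiable")

    def dual(lam):
        a = -(lam @ U)
        amax = a.max()
        e = np.exp(a - amax)
        s = e.sum()
        g = amax + np.log(s / N) + cap * lam.sum()
        w = e / s
        grad = cap - U @ w
        return g, grad

    lam_cap = 1e4
    res = minimize(
        dual,
        np.zeros(q),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, lam_cap)] * q,
        options={"maxiter": max_iter, "ftol": 1e-18, "gtol": 1e-14},
    )
    lam = res.x.copy()
    a = -(lam @ U)
    w = np.exp(a - a.max())
    w /= w.sum()
    violation = float(np.max(U @ w - cap))
    # polish: exact one-dimensional tilts on any residually violated
    # constraint (L-BFGS-B stalls at machine precision near the optimum)
    for _ in range(50):
        if violation <= tol:
            break
        for k in np.flatnonzero(U @ w > cap + tol / 2):
            if float(U[k] @ w) <= cap:  # already fixed by a prior tilt
                continue
            try:
                dl = _solve_lambda(w, U[k], cap)
            except InfeasibleError:
                raise InfeasibleError("edge constraints are jointly infeasible")
            lam[k] += dl
            w = w * np.exp(-dl * (U[k] - U[k].mean()))
            w /= w.sum()
        violation = float(np.max(U @ w - cap))
    if violation > tol:
        if lam.max() > 0.99 * lam_cap or lam.sum() > 100.0:
            raise InfeasibleError("edge constraints are jointly infeasible")
        raise SolverError("entropy projection did not converge", res.nit)
    return w, lam


def fit_totalboost(X, y, M: int = 100, nu: float = 0.05, depth: int = 1) -> BoostModel:
    """Totally corrective boosting with adaptive edge caps.

    Each stage fits a tree on the current weights and records its edge
    ``sum_i w_i y_i h(x_i)``; the cap ``gamma_hat`` is the running minimum of
    observed edges.  The weights are then re-solved as the KL projection of
    the uniform distribution onto ``{w : edge_q(w) <= gamma_hat - nu}`` over
    all past hypotheses q.  Training stops when the polytope becomes
    infeasible, when the new hypothesis duplicates an earlier one (the
    constraint set, hence the weight vector, can no longer change), or at M
    stages.  Stage coefficients are the final projection's dual multipliers,
    renormalized to sum to one.
    """
    ts = TrainingSet(X, y)
    X, y = ts.X, ts.y
    if M < 1:
        raise ValueError("M must be >= 1")
    if not (0 < nu < 1):
        raise ValueError("nu must be in (0, 1)")
    N = len(y)
    w = np.full(N, 1.0 / N)
    model = BoostModel("TB", tie_label=_majority(y), n_features=X.shape[1])
    learners = []
    U_rows = []
    edges = []
    gamma_hat = np.inf
    duals = np.zeros(0)
    for _ in range(M):
        learner = fit_tree_classifier(X, y, w, depth)
        h = learner.predict(X) if hasattr(learner, "predict") else np.full(N, learner)
        u = y * h
        if any(np.array_equal(u, r) for r in U_rows):
            break  # fixed point: constraint set unchanged
        edge = float(w @ u)
        if edge <= 0:
            break  # no better than random under current weights
        learners.append(learner)
        U_rows.append(u)
        edges.append(edge)
        gamma_hat = min(gamma_hat, edge)
        U = np.array(U_rows)
        try:
            w, duals = entropy_project(U, gamma_hat - nu)
        except InfeasibleError:
            # polytope collapsed (e.g. a near-perfect hypothesis): keep the
            # stage but stop; it enters with zero dual, and if no dual is
            # positive the coefficients fall back to uniform below
            break
        except SolverError as exc:
            log.warning("stopping TotalBoost early: %s", exc)
            break
    if not learners:
        const = DecisionStump(-1, 0.0, model.tie_label, model.tie_label)
        model.stages.append((const, 1.0))
        model.diagnostics["edges"] = []
        return model
    if len(duals) < len(learners):
        duals = np.concatenate([duals, np.zeros(len(learners) - len(duals))])
    total = duals[: len(learners)].sum()
    if total > 0:
        coefs = duals[: len(learners)] / total
    else:
        coefs = np.full(len(learners), 1.0 / len(learners))
    model.stages = list(zip(learners, coefs))
    model.diagnostics["edges"] = edges
    model.diagnostics["gamma_hat"] = gamma_hat if np.isfinite(gamma_hat) else None
    model.diagnostics["final_weights"] = w
    return model
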