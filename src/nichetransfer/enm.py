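"""Presence-background maximum-entropy niche model.

The model places a Gibbs distribution q_lambda(x) proportional to
exp(sum_j lambda_j f_j(x)) over the background cells and chooses the
weights to minimize the L1-penalized negative log likelihood of the
presences:

    phi(lambda) = -(1/m) sum_presences lambda . f(x)
                  + log sum_background exp(lambda . f(b))
                  + sum_j beta_j |lambda_j|

This objective is convex; at beta = 0 its stationary point matches the
presence mean of every feature to its expectation under q (the maximum
entropy moment conditions). Features are the classic maxent classes over
climate variables scaled to [0, 1] by their training range: linear,
quadratic, pairwise product, and hinge at evenly spaced knots. The
L-BFGS-B optimizer works on the positive/negative split of lambda, which
turns the L1 term into a smooth bound-constrained problem.

Projection onto another decade's climate clamps covariates to their
training range and renormalizes the suitability over the target extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator

from .climate import ClimateStack

__all__ = [
    "FeatureSet",
    "MaxEntNicheModel",
    "ProjectionRecord",
    "select_feature_classes",
    "project_model",
    "default_beta",
]

# sample-size-interpolated default regularization per feature class
# (columns: n_presences, multiplier)
_REG_TABLE = {
    "l": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "q": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "p": ([0, 10, 17, 30, 100], [2.6, 1.6, 0.9, 0.55, 0.05]),
    "h": ([0, 100], [0.5, 0.5]),
}


def select_feature_classes(n_presences: int) -> str:
    """Feature classes enabled by default at a given presence count.

    Mirrors the default maxent behaviour of growing model complexity
    with sample size: < 10 linear only; < 15 adds quadratic; < 80 adds
    hinge; >= 80 all classes (adds products).
    """
    if n_presences < 3:
        raise ValueError("need at least 3 presences")
    if n_presences < 10:
        return "l"
    if n_presences < 15:
        return "lq"
    if n_presences < 80:
        return "lqh"
    return "lqph"


@dataclass
class FeatureSet:
    """Feature expansion over climate variables with training ranges.

    Stores per-variable training min/max used both for [0, 1] scaling
    and for clamping when projecting outside the training range.
    """

    variables: list[str]
    classes: str
    v_min: np.ndarray
    v_max: np.ndarray
    n_hinge_knots: int = 50
    names: list[str] = field(default_factory=list)
    var_of_feature: list[int] = field(default_factory=list)

    @classmethod
    def from_training(cls, X: np.ndarray, variables: list[str],
                      classes: str, n_hinge_knots: int = 50) -> "FeatureSet":
        X = np.asarray(X, dtype=float)
        fs = cls(variables=list(variables), classes=classes,
                 v_min=X.min(axis=0), v_max=X.max(axis=0),
                 n_hinge_knots=n_hinge_knots)
        fs._build_names()
        return fs

    def _build_names(self) -> None:
        k = len(self.variables)
        names: list[str] = []
        varof: list[int] = []
        if "l" in self.classes:
            names += [f"l:{v}" for v in self.variables]
            varof += list(range(k))
        if "q" in self.classes:
            names += [f"q:{v}" for v in self.variables]
            varof += list(range(k))
        if "p" in self.classes:
            for i in range(k):
                for j in range(i + 1, k):
                    names.append(f"p:{self.variables[i]}*{self.variables[j]}")
                    varof.append(i)  # attribution to first member
        if "h" in self.classes:
            knots = self._knots()
            for i, v in enumerate(self.variables):
                for t in knots:
                    names.append(f"h:{v}@{t:.3f}")
                    varof.append(i)
        self.names = names
        self.var_of_feature = varof

    def _knots(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_hinge_knots + 2)[1:-1]

    @property
    def n_features(self) -> int:
        return len(self.names)

    def scale(self, X: np.ndarray, clamp: bool) -> tuple[np.ndarray, np.ndarray]:
        """Scale raw values to the training [0, 1] box.

        Returns (scaled, clamped_mask) where clamped_mask flags samples
        with at least one covariate outside the training range.
        """
        X = np.asarray(X, dtype=float)
        span = np.where(self.v_max > self.v_min, self.v_max - self.v_min, 1.0)
        s = (X - self.v_min) / span
        outside = (s < 0.0) | (s > 1.0)
        if clamp:
            s = np.clip(s, 0.0, 1.0)
        return s, outside.any(axis=1)

    def transform(self, X: np.ndarray, clamp: bool = True,
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix for raw climate values X (n x n_vars)."""
        s, clamped = self.scale(X, clamp=clamp)
        k = s.shape[1]
        if k != len(self.variables):
            raise ValueError(
                f"expected {len(self.variables)} variables, got {k}")
        blocks = []
        if "l" in self.classes:
            blocks.append(s)
        if "q" in self.classes:
            blocks.append(s ** 2)
        if "p" in self.classes:
            prods = [s[:, i] * s[:, j]
                     for i in range(k) for j in range(i + 1, k)]
            if prods:
                blocks.append(np.column_stack(prods))
        if "h" in self.classes:
            knots = self._knots()
            hinge = np.maximum(0.0, s[:, :, None] - knots[None, None, :])
            hinge /= (1.0 - knots)[None, None, :]
            blocks.append(hinge.reshape(len(s), k * len(knots)))
        return np.column_stack(blocks), clamped


def default_beta(features_presence: np.ndarray, classes: str,
                 names: list[str]) -> np.ndarray:
    """Per-feature L1 multipliers from the sample-size tables.

    beta_j = reg_class(m) * sd_j / sqrt(m), with sd_j the feature's
    standard deviation over the m presences (floored at 0.01 so
    presence-constant features are still penalized).
    """
    m = len(features_presence)
    sd = features_presence.std(axis=0)
    sd = np.maximum(sd, 0.01)
    beta = np.empty(len(names))
    for j, name in enumerate(names):
        cls = name[0]
        xs, ys = _REG_TABLE[cls]
        beta[j] = np.interp(m, xs, ys) * sd[j] / np.sqrt(m)
    return beta


class MaxEntNicheModel(BaseEstimator):
    """L1-regularized presence-background maxent niche model.

    Parameters
    ----------
    feature_classes : str or "auto"
        Subset of "lqph" (linear, quadratic, product, hinge); "auto"
        selects by presence count.
    beta : None, float or array
        None uses the default per-feature-class sample-size tables; a
        scalar applies one multiplier to every feature.
    n_hinge_knots : int
        Hinge knots per variable, evenly spaced over the training range.
    max_iter, tol : optimizer budget and objective tolerance.
    random_state : seed for the optimizer's random start.

    Attributes (after fit)
    ----------------------
    lambda_ : fitted feature weights.
    feature_set_ : FeatureSet with training ranges (used for clamping).
    beta_ : per-feature multipliers actually used.
    n_iter_, converged_, objective_ : convergence record.
    """

    def __init__(self, feature_classes: str = "auto",
                 beta: float | np.ndarray | None = None,
                 n_hinge_knots: int = 50, max_iter: int = 500,
                 tol: float = 1e-8, random_state: int | None = None):
        self.feature_classes = feature_classes
        self.beta = beta
        self.n_hinge_knots = n_hinge_knots
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- sklearn plumbing --------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            variables: list[str] | None = None) -> "MaxEntNicheModel":
        """Fit from a stacked design: rows with y=1 are presences, y=0
        background. X holds raw climate values (n_samples x n_vars)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        pres = X[y == 1]
        bg = X[y == 0]
        if len(pres) < 3:
            raise ValueError("need at least 3 presences")
        if len(bg) == 0:
            raise ValueError("background is empty")

        classes = (select_feature_classes(len(pres))
                   if self.feature_classes == "auto" else self.feature_classes)
        varnames = variables or [f"v{i + 1}" for i in range(X.shape[1])]
        fs = FeatureSet.from_training(np.vstack([pres, bg]), varnames,
                                      classes, self.n_hinge_knots)
        Fp, _ = fs.transform(pres, clamp=False)
        Fb, _ = fs.transform(bg, clamp=False)

        if self.beta is None:
            beta = default_beta(Fp, classes, fs.names)
        else:
            beta = np.broadcast_to(np.asarray(self.beta, dtype=float),
                                   (fs.n_features,)).copy()
        if np.any(beta < 0):
            raise ValueError("beta must be non-negative")

        p_mean = Fp.mean(axis=0)
        n_feat = fs.n_features

        def objective(ab: np.ndarray) -> tuple[float, np.ndarray]:
            lam = ab[:n_feat] - ab[n_feat:]
            scores = Fb @ lam
            lse = logsumexp(scores)
            w = softmax(scores)
            e_q = w @ Fb
            val = -p_mean @ lam + lse + beta @ (ab[:n_feat] + ab[n_feat:])
            g_lam = -p_mean + e_q
            grad = np.concatenate([g_lam + beta, -g_lam + beta])
            return val, grad

        rng = np.random.default_rng(self.random_state)
        x0 = np.abs(rng.normal(0.0, 1e-3, size=2 * n_feat))
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * n_feat),
            options={"maxiter": self.max_iter, "ftol": self.tol,
                     "gtol": 1e-9})
        self.lambda_ = res.x[:n_feat] - res.x[n_feat:]
        self.feature_set_ = fs
        self.beta_ = beta
        self.n_iter_ = int(res.nit)
        self.objective_ = float(res.fun)
        self.converged_ = bool(res.success or res.nit < self.max_iter)
        if not self.converged_:
            warnings.warn("maxent optimizer hit max_iter without converging")
        self.n_features_in_ = X.shape[1]
        return self

    def score_samples(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Log relative suitability lambda . f(x) (unnormalized)."""
        F, _ = self.feature_set_.transform(np.asarray(X, float), clamp=clamp)
        return F @ self.lambda_

    decision_function = score_samples

    def predict(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Raw-output suitability normalized to sum to 1 over X."""
        return softmax(self.score_samples(X, clamp=clamp))

    def predict_logistic(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Logistic display transform of the raw output (rank-preserving)."""
        s = self.score_samples(X, clamp=clamp)
        return 1.0 / (1.0 + np.exp(-(s - s.mean())))

    def variable_weights(self) -> dict[str, float]:
        """Total |lambda| attributed to each climate variable."""
        out = {v: 0.0 for v in self.feature_set_.variables}
        for j, vi in enumerate(self.feature_set_.var_of_feature):
            out[self.feature_set_.variables[vi]] += abs(self.lambda_[j])
        return out


@dataclass
class ProjectionRecord:
    """A fitted model applied to a (possibly different) decade's climate."""

    model: MaxEntNicheModel
    source_decade: str
    target_decade: str
    suitability: np.ndarray          # normalized to sum 1 over the extent
    log_score: np.ndarray            # lambda . f(x), rank-equivalent
    clamp_mask: np.ndarray           # cells where any covariate was clamped
    mess: np.ndarray | None = None

    def scores_at(self, cells: np.ndarray) -> np.ndarray:
        cells = np.asarray(cells)
        return self.log_score[cells[:, 0], cells[:, 1]]


def project_model(model: MaxEntNicheModel, stack: ClimateStack,
                  source_decade: str = "", clamp: bool = True,
                  ) -> ProjectionRecord:
    """Project a fitted model onto a climate stack.

    Covariates are clamped to the model's training range when ``clamp``
    is true; the clamp mask records where clamping fired. Suitability is
    the raw (exponential) output renormalized over the target extent.
    """
    missing = [v for v in model.feature_set_.variables
               if v not in stack.grids]
    if missing:
        raise ValueError(f"target stack missing variables {missing}")
    geom = stack.geometry
    vals = stack.as_array(model.feature_set_.variables)
    X = vals.reshape(len(model.feature_set_.variables), -1).T
    F, clamped = model.feature_set_.transform(X, clamp=clamp)
    scores = F @ model.lambda_
    suit = softmax(scores)
    return ProjectionRecord(
        model=model, source_decade=source_decade, target_decade=stack.decade,
        suitability=suit.reshape(geom.rows, geom.cols),
        log_score=scores.reshape(geom.rows, geom.cols),
        clamp_mask=(clamped if clamp else np.zeros(len(X), bool)
                    ).reshape(geom.rows, geom.cols))
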