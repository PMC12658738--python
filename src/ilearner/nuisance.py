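"""Nuisance estimation: propensity scores and treated-arm outcome regressions.

The meta-learners need two nuisance functions: the propensity score
g(L) = P(A=1|L) and the treated-arm outcome regression Q(L) = E(Y|A=1,L).
Both are estimated with pluggable learners — a random forest, a stacked
super learner over a small library (main-effects GLM, all-pairs interaction
GLM, forward stepwise regression, random forest, smooth additive model), or
any user object with a fit/predict contract — and consumed out-of-fold via
K-fold cross-fitting, so every observation's nuisance predictions come from
models trained without it.

Propensity predictions are clipped to [clip_lo, 1-clip_lo] (default 1%,
mirroring the positivity assumption g > sigma); logistic-link outcome
predictions are clipped to [1e-3, 1-1e-3] so logit offsets in the targeting
step stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize, nnls
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer

from .data import ObservationTable

__all__ = [
    "LearnerSpec",
    "NuisanceFit",
    "assign_folds",
    "fit_propensity",
    "fit_outcome_treated",
    "super_learner_combine",
    "crossfit_nuisances",
    "nuisance_from_functions",
    "CLIP_LO_DEFAULT",
    "Q_CLIP_DEFAULT",
]

CLIP_LO_DEFAULT = 0.01
Q_CLIP_DEFAULT = 1e-3

SUPER_LEARNER_LIBRARY = (
    "linear_main_effects",
    "linear_interactions",
    "stepwise",
    "random_forest",
    "additive_smooth",
)


@dataclass
class LearnerSpec:
    """Specification of a nuisance learner.

    kind: "random_forest", "super_learner", or "custom" (supply ``model``
    implementing fit(X, y) and predict(X) on the mean scale).
    """

    kind: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    base_library: tuple = SUPER_LEARNER_LIBRARY
    model: object = None

    def __post_init__(self):
        if self.kind not in ("random_forest", "super_learner", "custom"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if self.kind == "super_learner" and not self.base_library:
            raise ValueError("super_learner requires a non-empty base library")
        if self.kind == "custom" and self.model is None and "factory" not in self.hyperparameters:
            raise ValueError("custom learner needs a model or a factory")


# --- base learners ----------------------------------------------------------


class _ConstantModel:
    def __init__(self, value):
        self.value = float(value)

    def predict(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.value)


class _BaseLearner:
    """fit/predict wrapper producing mean-scale predictions for either link."""

    def __init__(self, link):
        self.link = link
        self._model = None

    def _build(self, X, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            self._model = _ConstantModel(y[0])
            return self
        self._model = self._build(np.asarray(X, dtype=float), y)
        return self

    def _mean(self, model, X):
        if self.link == "logistic" and hasattr(model, "predict_proba"):
            return model.predict_proba(X)[:, 1]
        return model.predict(X)

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.asarray(self._mean(self._model, self._transform(X)), dtype=float)

    def _transform(self, X):
        return X


def _is_binary(y):
    return np.isin(y, (0.0, 1.0)).all()


class _LinearMainEffects(_BaseLearner):
    def _build(self, X, y):
        if self.link == "logistic" and _is_binary(y):
            return LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
        return LinearRegression().fit(X, y)


class _LinearInteractions(_BaseLearner):
    def _transform(self, X):
        return self._poly.transform(X)

    def _build(self, X, y):
        self._poly = PolynomialFeatures(degree=2, interaction_only=True, include_bias=False)
        Xt = self._poly.fit_transform(X)
        if self.link == "logistic" and _is_binary(y):
            # plain (unregularized) all-pairs GLM; on small training sets it is
            # close to separable and produces fitted probabilities near 0/1 —
            # the instability that stacked nuisances are known to show here
            return LogisticRegression(C=np.inf, max_iter=500).fit(Xt, y)
        return Ridge(alpha=1e-6).fit(Xt, y)


class _Stepwise(_BaseLearner):
    """Forward covariate selection by AIC on a GLM."""

    max_terms = 10

    def _glm(self, y, X):
        family = sm.families.Binomial() if self.link == "logistic" and _is_binary(y) else sm.families.Gaussian()
        return sm.GLM(y, X, family=family)

    def _build(self, X, y):
        n, d = X.shape
        selected: list[int] = []
        const = np.ones((n, 1))
        best_aic = self._glm(y, const).fit().aic
        remaining = list(range(d))
        while remaining and len(selected) < min(d, self.max_terms):
            trial = [
                (self._glm(y, np.column_stack([const, X[:, selected + [j]]])).fit().aic, j)
                for j in remaining
            ]
            aic, j = min(trial)
            if aic >= best_aic - 1e-9:
                break
            best_aic = aic
            selected.append(j)
            remaining.remove(j)
        self._selected = selected
        res = self._glm(y, np.column_stack([const, X[:, selected]])).fit()
        self._res = res
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if isinstance(self._model, _ConstantModel):
            return self._model.predict(X)
        design = np.column_stack([np.ones(X.shape[0]), X[:, self._selected]])
        return np.asarray(self._res.predict(design), dtype=float)


class _RandomForest(_BaseLearner):
    """Regression forest with the classical regression-forest defaults
    (500 trees, minimum leaf size 5, a third of the features per split).

    Binary responses are treated on the mean scale — leaf averages of 0/1
    outcomes are probabilities — which smooths far more than a
    classification forest grown to purity.
    """

    def __init__(self, link, n_estimators=500, seed=0, min_samples_leaf=5,
                 max_features=1 / 3, **kw):
        super().__init__(link)
        self.n_estimators = n_estimators
        self.seed = seed
        self.kw = dict(min_samples_leaf=min_samples_leaf, max_features=max_features, **kw)

    def _build(self, X, y):
        est = RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=self.seed, **self.kw
        )
        return est.fit(X, y)


class _AdditiveSmooth(_BaseLearner):
    """Penalized additive model: per-covariate cubic splines with ridge shrinkage."""

    def _transform(self, X):
        return self._spline.transform(X)

    def _build(self, X, y):
        n_knots = max(3, min(5, X.shape[0] // 10))
        self._spline = SplineTransformer(n_knots=n_knots, degree=3, include_bias=False)
        Xt = self._spline.fit_transform(X)
        if self.link == "logistic" and _is_binary(y):
            return LogisticRegression(C=1.0, max_iter=2000).fit(Xt, y)
        return Ridge(alpha=1.0).fit(Xt, y)


_BASE_FACTORY = {
    "linear_main_effects": _LinearMainEffects,
    "linear_interactions": _LinearInteractions,
    "stepwise": _Stepwise,
    "random_forest": _RandomForest,
    "additive_smooth": _AdditiveSmooth,
}


def assign_folds(n: int, K: int, seed: int) -> np.ndarray:
    """Seeded random partition into K folds whose sizes differ by at most 1."""
    if not 2 <= K <= n:
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    fold[rng.permutation(n)] = np.arange(n) % K
    return fold


def _cv_loss(pred, y, link):
    if link == "logistic":
        p = np.clip(pred, 1e-9, 1 - 1e-9)
        return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
    return float(np.mean((y - pred) ** 2))


def super_learner_combine(cv_predictions: np.ndarray, y: np.ndarray, link: str) -> np.ndarray:
    """Convex stacking weights minimizing cross-validated loss.

    Identity link: least squares on the simplex (NNLS-initialized); logistic
    link: log-loss on the simplex.  The returned weights never do worse than
    the best single base learner on the same out-of-fold predictions.
    """
    P = np.asarray(cv_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = P.shape

    def loss(w):
        return _cv_loss(np.clip(P @ w, 1e-9, 1 - 1e-9) if link == "logistic" else P @ w, y, link)

    candidates = [np.full(m, 1.0 / m)]
    candidates.extend(np.eye(m))
    w0 = np.full(m, 1.0 / m)
    if link == "identity":
        w_nnls, _ = nnls(P, y)
        if w_nnls.sum() <= 0:
            warnings.warn("degenerate all-zero stacking solution; using uniform weights")
        else:
            w0 = w_nnls / w_nnls.sum()
            candidates.append(w0)
    res = minimize(
        loss, w0, method="SLSQP", bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 300, "ftol": 1e-12},
    )
    if res.success and res.x.sum() > 0:
        candidates.append(np.clip(res.x, 0, None) / np.clip(res.x, 0, None).sum())
    best = min(candidates, key=loss)
    return best / best.sum()


class SuperLearner:
    """Cross-validated convex stack of the base-learner library."""

    def __init__(self, link, library=SUPER_LEARNER_LIBRARY, n_folds=5, seed=0):
        if not library:
            raise ValueError("empty super learner library")
        self.link = link
        self.library = tuple(library)
        self.n_folds = n_folds
        self.seed = seed

    def _make(self, name, seed):
        cls = _BASE_FACTORY[name]
        if name == "random_forest":
            return cls(self.link, seed=seed)
        return cls(self.link)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        m = len(self.library)
        if m == 1:
            self.weights_ = np.array([1.0])
            self.models_ = [self._make(self.library[0], self.seed).fit(X, y)]
            return self
        K = min(self.n_folds, max(2, n // 20), n)
        fold = assign_folds(n, K, self.seed)
        cv_pred = np.zeros((n, m))
        for k in range(K):
            tr, te = fold != k, fold == k
            for j, name in enumerate(self.library):
                mdl = self._make(name, self.seed + 1000 * k + j).fit(X[tr], y[tr])
                cv_pred[te, j] = mdl.predict(X[te])
        if self.link == "logistic":
            cv_pred = np.clip(cv_pred, 0.0, 1.0)
        self.cv_predictions_ = cv_pred
        self.weights_ = super_learner_combine(cv_pred, y, self.link)
        self.models_ = [self._make(name, self.seed + j).fit(X, y) for j, name in enumerate(self.library)]
        return self

    def predict(self, X):
        preds = np.column_stack([m.predict(X) for m in self.models_])
        if self.link == "logistic":
            preds = np.clip(preds, 0.0, 1.0)
        return preds @ self.weights_


def _make_learner(spec: LearnerSpec, link: str, seed: int):
    if spec.kind == "random_forest":
        return _RandomForest(link, seed=seed, **spec.hyperparameters)
    if spec.kind == "super_learner":
        return SuperLearner(link, library=spec.base_library, seed=seed,
                            **{k: v for k, v in spec.hyperparameters.items() if k == "n_folds"})
    factory = spec.hyperparameters.get("factory")
    return factory(link=link, seed=seed) if factory is not None else spec.model


class _ClippedPredictor:
    """Wraps a fitted model with mean-scale clipping bounds."""

    def __init__(self, model, lo=None, hi=None):
        self.model = model
        self.lo, self.hi = lo, hi

    def predict(self, X):
        p = np.asarray(self.model.predict(X), dtype=float)
        if self.lo is not None:
            p = np.clip(p, self.lo, self.hi)
        return p

    __call__ = predict


class _FunctionPredictor:
    def __init__(self, fn, lo=None, hi=None):
        self.fn = fn
        self.lo, self.hi = lo, hi

    def predict(self, X):
        p = np.asarray(self.fn(np.atleast_2d(np.asarray(X, dtype=float))), dtype=float)
        if self.lo is not None:
            p = np.clip(p, self.lo, self.hi)
        return p

    __call__ = predict


def fit_propensity(L, A, spec: LearnerSpec, clip_lo: float = CLIP_LO_DEFAULT, seed: int = 0):
    """Fit g(L) = P(A=1|L); predictions are clipped to [clip_lo, 1-clip_lo]."""
    L = np.asarray(L, dtype=float)
    A = np.asarray(A)
    if len(np.unique(A)) < 2:
        raise ValueError("propensity fitting requires both treatment arms in the training data")
    model = _make_learner(spec, "logistic", seed).fit(L, A.astype(float))
    return _ClippedPredictor(model, clip_lo, 1.0 - clip_lo)


def fit_outcome_treated(L, A, Y, spec: LearnerSpec, link: str = "identity",
                        seed: int = 0, q_clip: float = Q_CLIP_DEFAULT, min_treated: int = 10):
    """Fit Q(L) = E(Y|A=1,L) on the treated rows only."""
    L = np.asarray(L, dtype=float)
    A = np.asarray(A)
    Y = np.asarray(Y, dtype=float)
    treated = A == 1
    if treated.sum() < min_treated:
        raise ValueError(f"need at least {min_treated} treated rows, got {int(treated.sum())}")
    model = _make_learner(spec, link, seed).fit(L[treated], Y[treated])
    if link == "logistic":
        return _ClippedPredictor(model, q_clip, 1.0 - q_clip)
    return _ClippedPredictor(model)


@dataclass
class NuisanceFit:
    """Out-of-fold nuisance predictions with fold provenance.

    ``ghat[i]`` and ``qhat0[i]`` come from models trained without fold
    ``fold_id[i]``; the per-fold fitted predictors are kept so the targeting
    step can be run on each fold's training complement.
    """

    ghat: np.ndarray
    qhat0: np.ndarray
    fold_id: np.ndarray
    clip_lo: float
    q_clip: float
    link: str
    g_models: list = field(default_factory=list, repr=False)
    q_models: list = field(default_factory=list, repr=False)
    g_spec: LearnerSpec | None = None
    q_spec: LearnerSpec | None = None

    @property
    def K(self) -> int:
        return int(self.fold_id.max()) + 1


def crossfit_nuisances(data: ObservationTable, K: int, g_spec: LearnerSpec,
                       q_spec: LearnerSpec, seed: int = 0, link: str = "identity",
                       clip_lo: float = CLIP_LO_DEFAULT, q_clip: float = Q_CLIP_DEFAULT,
                       min_treated: int = 10) -> NuisanceFit:
    """K-fold cross-fitting of g and Q: fold k is predicted by models trained
    on the other K-1 folds."""
    n = data.n
    if K < 2:
        raise ValueError("cross-fitting requires K >= 2")
    fold = assign_folds(n, K, seed)
    L, A, Y = data.L, data.A, data.Y
    ghat = np.empty(n)
    qhat0 = np.empty(n)
    g_models, q_models = [], []
    for k in range(K):
        tr = fold != k
        try:
            g_k = fit_propensity(L[tr], A[tr], g_spec, clip_lo=clip_lo, seed=seed + 17 * k)
            q_k = fit_outcome_treated(L[tr], A[tr], Y[tr], q_spec, link=link,
                                      seed=seed + 17 * k + 7, q_clip=q_clip,
                                      min_treated=min_treated)
        except ValueError as err:
            raise ValueError(f"fold {k}: {err}") from err
        te = fold == k
        ghat[te] = g_k.predict(L[te])
        qhat0[te] = q_k.predict(L[te])
        g_models.append(g_k)
        q_models.append(q_k)
    return NuisanceFit(ghat=ghat, qhat0=qhat0, fold_id=fold, clip_lo=clip_lo,
                       q_clip=q_clip, link=link, g_models=g_models,
                       q_models=q_models, g_spec=g_spec, q_spec=q_spec)


def nuisance_from_functions(data: ObservationTable, g_fn, q_fn, K: int = 2,
                            seed: int = 0, link: str = "identity",
                            clip_lo: float = CLIP_LO_DEFAULT,
                            q_clip: float = Q_CLIP_DEFAULT) -> NuisanceFit:
    """NuisanceFit built from known nuisance functions of L (oracle nuisances)."""
    fold = assign_folds(data.n, K, seed)
    g = _FunctionPredictor(g_fn, clip_lo, 1.0 - clip_lo)
    if link == "logistic":
        q = _FunctionPredictor(q_fn, q_clip, 1.0 - q_clip)
    else:
        q = _FunctionPredictor(q_fn)
    L = data.L
    return NuisanceFit(ghat=g.predict(L), qhat0=q.predict(L), fold_id=fold,
                       clip_lo=clip_lo, q_clip=q_clip, link=link,
                       g_models=[g] * K, q_models=[q] * K)
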