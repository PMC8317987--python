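"""Elastic-net feature selection and the Enet-subset hybrid extension.

``ElasticNetSelector`` fits an elastic-net-penalized logistic regression
over a (lambda, alpha) grid — lambda the penalty strength, alpha the
lasso/ridge mixing weight — choosing the grid point by cross-validated AUC
and keeping the features with nonzero coefficients.

``EnetSubsetSelector`` extends this with an optimal-subset wrapper: the
nonzero-coefficient features are ranked by |coefficient| and growing
top-k subsets (k = step, 2*step, ..., capped at the nonzero count, with
the full nonzero set always evaluated) are scored by nested stratified
cross-validated AUC of a linear SVM; the best-scoring subset is kept, ties
resolved toward the smaller subset. The wrapper removes variables the
elastic net keeps but the downstream classifier does not benefit from.

Both classes are scikit-learn transformers (SelectorMixin) and compose
with Pipelines and model selection. Selection statistics are always
computed from the rows passed to ``fit`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "EnetConfig",
    "SelectionResult",
    "ElasticNetSelector",
    "EnetSubsetSelector",
    "enet_select",
    "enet_subset_select",
]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))
DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.0001, 0.0011, 0.0021, 0.0031, 0.0041)


@dataclass(frozen=True)
class EnetConfig:
    """Grid and fold configuration for elastic-net selection.

    lambda_grid : penalty strengths (glmnet-style; mapped internally to
        sklearn C = 1 / (n_samples * lambda)).
    alpha_grid : l1-ratio mixing weights. The defaults are near-ridge —
        small enough that correlated features are kept as groups rather
        than arbitrarily dropped, while still producing exact zeros.
    cv_folds : folds of the stratified CV used to pick the grid winner.
    """

    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    cv_folds: int = 4

    def __post_init__(self) -> None:
        if not self.lambda_grid or not self.alpha_grid:
            raise ValueError("grids must be non-empty")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda values must be positive")
        if any(not 0 <= a <= 1 for a in self.alpha_grid):
            raise ValueError("alpha (l1 ratio) values must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    coefficients : per-feature coefficient of the winning elastic-net fit
        (zeros included), indexed like the input columns.
    selected : feature indices ordered by descending |coefficient|.
    subset_trace : subset size -> nested-CV AUC (enet_subset only).
    method : "enet" or "enet_subset".
    """

    coefficients: np.ndarray
    selected: np.ndarray
    method: str
    subset_trace: dict[int, float] = field(default_factory=dict)
    chosen_lambda: float | None = None
    chosen_alpha: float | None = None
    cv_auc: float | None = None


class ElasticNetSelector(SelectorMixin, BaseEstimator):
    """Select features via elastic-net-penalized logistic regression.

    Parameters
    ----------
    lambda_grid, alpha_grid, cv : see :class:`EnetConfig`.
    random_state : seeds the CV fold shuffling.
    max_iter, tol : saga solver controls.

    Attributes
    ----------
    coef_ : ndarray (n_features,), coefficients of the winning fit.
    ranking_ : indices of nonzero-coefficient features, |coef| descending.
    lambda_, alpha_ : winning grid point (ties -> larger lambda, then
        smaller alpha, favoring parsimony).
    cv_auc_ : cross-validated AUC of the winner (None when the grid has a
        single point, for which no model competition is needed).
    """

    def __init__(
        self,
        lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
        alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        cv: int = 4,
        random_state: int | None = None,
        max_iter: int = 2000,
        tol: float = 1e-4,
    ):
        self.lambda_grid = lambda_grid
        self.alpha_grid = alpha_grid
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ---------------------------------------------------------

    def _logistic(self, lam: float, alpha: float, n: int) -> LogisticRegression:
        # a float l1_ratio selects the elastic-net penalty (sklearn >= 1.8)
        return LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            C=1.0 / (n * lam),
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,  # saga shuffles samples
        )

    def _cv_auc(self, X: np.ndarray, y: np.ndarray, lam: float, alpha: float) -> float:
        folds = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        aucs = []
        for tr, va in folds.split(X, y):
            scaler = StandardScaler().fit(X[tr])
            model = self._logistic(lam, alpha, len(tr)).fit(
                scaler.transform(X[tr]), y[tr]
            )
            scores = model.decision_function(scaler.transform(X[va]))
            if len(np.unique(y[va])) < 2:
                continue
            aucs.append(roc_auc_score(y[va], scores))
        return float(np.mean(aucs)) if aucs else 0.5

    def _fit_enet(self, X: np.ndarray, y: np.ndarray) -> None:
        cfg = EnetConfig(tuple(self.lambda_grid), tuple(self.alpha_grid), self.cv)
        grid = [(lam, alpha) for lam in cfg.lambda_grid for alpha in cfg.alpha_grid]
        if len(grid) == 1:
            best_lam, best_alpha = grid[0]
            best_auc = None
        else:
            best_auc, best_lam, best_alpha = -np.inf, None, None
            for lam, alpha in grid:
                auc = self._cv_auc(X, y, lam, alpha)
                better = auc > best_auc + 1e-12
                tie = abs(auc - best_auc) <= 1e-12 and (
                    lam > best_lam or (lam == best_lam and alpha < best_alpha)
                )
                if better or tie:
                    best_auc, best_lam, best_alpha = auc, lam, alpha
        self.scaler_ = StandardScaler().fit(X)
        model = self._logistic(best_lam, best_alpha, len(y)).fit(
            self.scaler_.transform(X), y
        )
        self.coef_ = model.coef_.ravel().copy()
        self.lambda_, self.alpha_ = best_lam, best_alpha
        self.cv_auc_ = best_auc
        nonzero = np.flatnonzero(self.coef_)
        if nonzero.size == 0:
            raise ValueError(
                "elastic net zeroed every coefficient at every grid point; "
                "decrease lambda or the l1 mixing weight"
            )
        # |coef| descending, ties by ascending feature index
        order = np.lexsort((nonzero, -np.abs(self.coef_[nonzero])))
        self.ranking_ = nonzero[order]

    def _validate(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("selection requires exactly two classes")
        if counts.min() < 2:
            raise ValueError("each class needs >= 2 training subjects")
        self.classes_ = classes
        return X, (y == classes[1]).astype(int)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X, y01 = self._validate(X, y)
        self._fit_enet(X, y01)
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.ranking_] = True
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            coefficients=self.coef_.copy(),
            selected=self.ranking_.copy(),
            method="enet",
            chosen_lambda=self.lambda_,
            chosen_alpha=self.alpha_,
            cv_auc=self.cv_auc_,
        )


class EnetSubsetSelector(ElasticNetSelector):
    """Elastic-net selection followed by optimal top-k subset search.

    Additional parameters
    ---------------------
    step : subset-size increment (default 25, i.e. subsets 25, 50, ...).
    subset_C : cost of the linear SVM used to score candidate subsets.

    Additional attributes
    ---------------------
    subset_trace_ : dict, subset size -> nested-CV AUC.
    best_size_ : chosen subset size (smallest among AUC ties).
    """

    def __init__(
        self,
        lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
        alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        cv: int = 4,
        random_state: int | None = None,
        max_iter: int = 2000,
        tol: float = 1e-4,
        step: int = 25,
        subset_C: float = 1.0,
    ):
        super().__init__(lambda_grid, alpha_grid, cv, random_state, max_iter, tol)
        self.step = step
        self.subset_C = subset_C

    def _subset_auc(self, X: np.ndarray, y: np.ndarray, cols: np.ndarray) -> float:
        folds = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        aucs = []
        for tr, va in folds.split(X, y):
            scaler = StandardScaler().fit(X[np.ix_(tr, cols)])
            model = SVC(kernel="linear", C=self.subset_C).fit(
                scaler.transform(X[np.ix_(tr, cols)]), y[tr]
            )
            if len(np.unique(y[va])) < 2:
                continue
            scores = model.decision_function(scaler.transform(X[np.ix_(va, cols)]))
            aucs.append(roc_auc_score(y[va], scores))
        return float(np.mean(aucs)) if aucs else 0.5

    def fit(self, X, y):
        if self.step < 1:
            raise ValueError("step must be >= 1")
        X, y01 = self._validate(X, y)
        self._fit_enet(X, y01)
        n_nonzero = self.ranking_.size
        sizes = list(range(self.step, n_nonzero, self.step)) + [n_nonzero]
        self.subset_trace_ = {}
        best_size, best_auc = None, -np.inf
        for size in sizes:
            auc = self._subset_auc(X, y01, self.ranking_[:size])
            self.subset_trace_[size] = auc
            if auc > best_auc + 1e-12:  # ties keep the earlier, smaller subset
                best_auc, best_size = auc, size
        self.best_size_ = best_size
        self.subset_auc_ = best_auc
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.ranking_[: self.best_size_]] = True
        return self

    def result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            coefficients=self.coef_.copy(),
            selected=self.ranking_[: self.best_size_].copy(),
            method="enet_subset",
            subset_trace=dict(self.subset_trace_),
            chosen_lambda=self.lambda_,
            chosen_alpha=self.alpha_,
            cv_auc=self.cv_auc_,
        )


def enet_select(
    X: np.ndarray, y: np.ndarray, cfg: EnetConfig = EnetConfig(), random_state: int | None = None
) -> SelectionResult:
    """Functional wrapper over :class:`ElasticNetSelector`."""
    sel = ElasticNetSelector(
        lambda_grid=cfg.lambda_grid,
        alpha_grid=cfg.alpha_grid,
        cv=cfg.cv_folds,
        random_state=random_state,
    ).fit(X, y)
    return sel.result()


def enet_subset_select(
    X: np.ndarray,
    y: np.ndarray,
    cfg: EnetConfig = EnetConfig(),
    step: int = 25,
    random_state: int | None = None,
) -> SelectionResult:
    """Functional wrapper over :class:`EnetSubsetSelector`."""
    sel = EnetSubsetSelector(
        lambda_grid=cfg.lambda_grid,
        alpha_grid=cfg.alpha_grid,
        cv=cfg.cv_folds,
        random_state=random_state,
        step=step,
    ).fit(X, y)
    return sel.result()
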