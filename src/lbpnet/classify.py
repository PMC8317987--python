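"""Repeated stratified train/test SVM evaluation protocol.

Each iteration: stratified 70/30 split -> feature selection on the training
rows only -> linear SVM with the cost grid tuned by repeated stratified
cross-validation -> confusion-matrix metrics and rank-based AUC on the held
out rows. Iterations are repeated (default 100) with derived seeds and the
per-iteration metrics are arithmetically averaged; per-feature selection
counts across iterations support frequency ranking of parcels.

Healthy controls are the positive class by convention, so sensitivity is
the fraction of controls recognized as controls and specificity the
fraction of patients recognized as patients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import EnetConfig, ElasticNetSelector, EnetSubsetSelector

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "IterationResult",
    "EvaluationReport",
    "stratified_split",
    "train_svm",
    "evaluate",
    "run_protocol",
]


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation-protocol settings.

    split_ratio : training fraction of each class (0.70 -> 19 of 27
        controls and 17 of 24 patients in training at the study sizes).
    n_iterations : number of independent split/select/train/test rounds.
    cost_grid : SVM cost values searched (C = 1..10).
    cv_folds, cv_repeats : folds and repeats of the stratified CV used to
        pick the cost (4-fold, repeated 5 times).
    cv_metric : criterion inside the cost search, "accuracy" or "auc".
    positive_class : label treated as positive in the confusion matrix.
    seed : base seed; iteration i uses seed + i.
    """

    split_ratio: float = 0.70
    n_iterations: int = 100
    cost_grid: tuple[float, ...] = tuple(range(1, 11))
    cv_folds: int = 4
    cv_repeats: int = 5
    cv_metric: str = "accuracy"
    positive_class: str = "HC"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if not self.cost_grid:
            raise ValueError("cost_grid must be non-empty")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.cv_metric not in ("accuracy", "auc"):
            raise ValueError("cv_metric must be 'accuracy' or 'auc'")


@dataclass
class IterationResult:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    chosen_cost: float
    selected_features: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvaluationReport:
    per_iteration: list[IterationResult]
    selection_counts: pd.Series

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.per_iteration]))

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean([r.auc for r in self.per_iteration]))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([r.sensitivity for r in self.per_iteration]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([r.specificity for r in self.per_iteration]))

    @property
    def mean_feature_count(self) -> float:
        return float(np.mean([len(r.selected_features) for r in self.per_iteration]))

    def summary(self) -> dict:
        return {
            "n_iterations": len(self.per_iteration),
            "mean_accuracy": self.mean_accuracy,
            "mean_auc": self.mean_auc,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "mean_feature_count": self.mean_feature_count,
        }

    def top_features(self, k: int = 60) -> pd.Series:
        """The k most frequently selected features across iterations."""
        return self.selection_counts.sort_values(ascending=False).head(k)


def stratified_split(
    y: np.ndarray, ratio: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class deterministic split: round(ratio * class size) rows of each
    class go to training. Returns (train_idx, test_idx)."""
    y = np.asarray(y)
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = int(np.floor(ratio * idx.size + 0.5))
        if n_train == 0 or n_train == idx.size:
            raise ValueError(
                f"split ratio {ratio} leaves class {cls!r} empty in one partition"
            )
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    features: np.ndarray,
    cfg: EvalConfig,
    cv_seed: int = 0,
) -> tuple[Pipeline, float]:
    """Tune the cost on the training rows and fit the final linear SVM.

    Features are standardized with training statistics (inside the returned
    Pipeline, so test transformation reuses them). Zero-variance features
    are dropped with a warning. Cost ties resolve toward the smaller C.
    """
    features = np.asarray(features)
    if features.size == 0:
        raise ValueError("feature list is empty")
    Xf = np.asarray(X, dtype=float)[:, features]
    keep = Xf.std(axis=0) > 0
    if not keep.all():
        dropped = features[~keep]
        logger.warning("dropping %d zero-variance feature(s): %s", dropped.size, dropped.tolist())
        warnings.warn(f"dropped zero-variance features {dropped.tolist()}")
        Xf = Xf[:, keep]
    if Xf.shape[1] == 0:
        raise ValueError("all features have zero variance on the training set")

    costs = sorted(cfg.cost_grid)
    if len(costs) == 1:
        best_c = costs[0]
    else:
        cv = RepeatedStratifiedKFold(
            n_splits=cfg.cv_folds, n_repeats=cfg.cv_repeats, random_state=cv_seed
        )
        splits = list(cv.split(Xf, y))
        best_c, best_score = None, -np.inf
        for c in costs:
            scores = []
            for tr, va in splits:
                scaler = StandardScaler().fit(Xf[tr])
                model = SVC(kernel="linear", C=c).fit(scaler.transform(Xf[tr]), y[tr])
                if cfg.cv_metric == "accuracy":
                    scores.append(model.score(scaler.transform(Xf[va]), y[va]))
                else:
                    if len(np.unique(y[va])) < 2:
                        continue
                    dv = model.decision_function(scaler.transform(Xf[va]))
                    scores.append(roc_auc_score(y[va] == model.classes_[1], dv))
            mean = float(np.mean(scores)) if scores else 0.0
            if mean > best_score + 1e-12:  # strict: ties keep the smaller C
                best_score, best_c = mean, c
    model = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=best_c))]
    ).fit(Xf, y)
    model.feature_indices_ = features[keep]
    return model, float(best_c)


def evaluate(
    model: Pipeline, X: np.ndarray, y: np.ndarray, positive_class: str, chosen_cost: float = np.nan
) -> IterationResult:
    """Confusion-matrix metrics and rank-statistic AUC on a test set."""
    if len(y) == 0:
        raise ValueError("test set is empty")
    Xf = np.asarray(X, dtype=float)[:, model.feature_indices_]
    pred = model.predict(Xf)
    pos = np.asarray(y) == positive_class
    pred_pos = pred == positive_class
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    if pos.all() or (~pos).all():
        auc = np.nan  # undefined on a one-class test set
    else:
        dv = model.decision_function(Xf)
        # decision_function is signed toward classes_[1]
        if model.named_steps["svm"].classes_[1] != positive_class:
            dv = -dv
        auc = float(roc_auc_score(pos, dv))
    return IterationResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        auc=auc,
        chosen_cost=chosen_cost,
    )


def _make_selector(method: str, enet_cfg: EnetConfig, step: int, seed: int | None):
    if method == "enet":
        return ElasticNetSelector(
            lambda_grid=enet_cfg.lambda_grid,
            alpha_grid=enet_cfg.alpha_grid,
            cv=enet_cfg.cv_folds,
            random_state=seed,
        )
    if method == "enet_subset":
        return EnetSubsetSelector(
            lambda_grid=enet_cfg.lambda_grid,
            alpha_grid=enet_cfg.alpha_grid,
            cv=enet_cfg.cv_folds,
            random_state=seed,
            step=step,
        )
    if method == "none":
        return None
    raise ValueError(f"unknown selection method {method!r}")


def run_protocol(
    X: np.ndarray,
    y: np.ndarray,
    cfg: EvalConfig = EvalConfig(),
    selector: str = "enet_subset",
    enet_cfg: EnetConfig = EnetConfig(),
    subset_step: int = 25,
) -> EvaluationReport:
    """Run the full repeated split/select/train/test protocol.

    ``selector`` is "enet", "enet_subset", or "none" (use all features).
    The report aggregates per-iteration metrics and per-feature selection
    counts; any iteration failure aborts with its index for auditability.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    counts = np.zeros(n_features, dtype=int)
    results: list[IterationResult] = []
    for i in range(cfg.n_iterations):
        it_seed = cfg.seed + i
        try:
            tr, te = stratified_split(y, cfg.split_ratio, seed=it_seed)
            sel = _make_selector(selector, enet_cfg, subset_step, seed=it_seed)
            if sel is None:
                features = np.arange(n_features)
            else:
                sel.fit(X[tr], y[tr])
                features = sel.result().selected
            model, cost = train_svm(X[tr], y[tr], features, cfg, cv_seed=it_seed)
            res = evaluate(model, X[te], y[te], cfg.positive_class, chosen_cost=cost)
            res.selected_features = np.asarray(features).tolist()
            counts[features] += 1
            results.append(res)
        except Exception as exc:
            raise RuntimeError(f"iteration {i} failed: {exc}") from exc
    return EvaluationReport(
        per_iteration=results,
        selection_counts=pd.Series(counts, index=pd.RangeIndex(n_features, name="feature")),
    )
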