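"""Assemble subjects-by-features tables from connectivity matrices.

Feature columns are (metric, node_id) pairs; concatenating metric blocks
gives N features per metric (e.g. BC+CC+DC on a 360-parcel atlas is 1,080
features).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .connectivity import FCMatrix, compute_fc
from .graph import DEFAULT_DENSITIES, METRIC_NAMES, metrics_across_densities
from .simulate import SyntheticCohort

__all__ = ["GraphMetricExtractor", "feature_table", "cohort_feature_table"]


class GraphMetricExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping stacked FC matrices to density-averaged metrics.

    Input ``X`` is an array of shape (n_subjects, n_nodes, n_nodes); output
    is (n_subjects, n_nodes * len(metrics)) with metric blocks concatenated
    in the order given. Stateless (fit only records shape), so it composes
    with sklearn pipelines.
    """

    def __init__(
        self,
        metrics: tuple[str, ...] = METRIC_NAMES,
        densities: tuple[float, ...] = DEFAULT_DENSITIES,
    ):
        self.metrics = metrics
        self.densities = densities

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be (n_subjects, n_nodes, n_nodes)")
        self.n_features_in_ = X.shape[1] * X.shape[2]
        self.n_nodes_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_nodes_")
        X = np.asarray(X, dtype=float)
        rows = [
            np.concatenate(
                [
                    metrics_across_densities(fc, self.densities, (m,))[m].to_numpy()
                    for m in self.metrics
                ]
            )
            for fc in X
        ]
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "n_nodes_")
        return np.array(
            [f"{m}_{i}" for m in self.metrics for i in range(self.n_nodes_)]
        )


def feature_table(
    fcs: list[FCMatrix],
    metrics: tuple[str, ...] = METRIC_NAMES,
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
) -> pd.DataFrame:
    """Subjects x (metric, node) table of density-averaged graph metrics."""
    if not metrics:
        raise ValueError("metric set must be non-empty")
    rows, index = [], []
    columns = None
    for fc in fcs:
        tab = metrics_across_densities(fc, densities, metrics)
        if columns is None:
            columns = pd.MultiIndex.from_tuples(
                [(m, n) for m in metrics for n in tab.index],
                names=["metric", "node_id"],
            )
        rows.append(
            np.concatenate([tab[m].to_numpy() for m in metrics])
        )
        index.append(fc.subject_id)
    return pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="subject_id"), columns=columns)


def cohort_feature_table(
    cohort: SyntheticCohort,
    metrics: tuple[str, ...] = METRIC_NAMES,
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Compute FC and graph metrics for every cohort subject.

    Returns the feature table and the aligned group-label Series.
    """
    fcs = []
    for sub in cohort.subjects:
        if sub.fc is None:
            sub.fc = compute_fc(sub.series, subject_id=sub.subject_id)
        fcs.append(sub.fc)
    X = feature_table(fcs, metrics, densities)
    y = pd.Series(cohort.labels(), index=X.index, name="group")
    return X, y
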