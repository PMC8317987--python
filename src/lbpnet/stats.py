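"""Group statistics: rank-sum screening with FDR control, permutation
significance for classifier performance, and metric-disability correlation."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import EvalConfig, EvaluationReport, run_protocol
from .selection import EnetConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationNull",
    "wilcoxon_by_node",
    "bh_adjust",
    "permutation_test",
    "correlate_with_disability",
]


@dataclass
class PermutationNull:
    """Permutation-test outcome with the add-one p-value
    p = (1 + #{null >= observed}) / (1 + n_perm), which can never be 0."""

    observed: float
    null_values: np.ndarray
    statistic: str

    @property
    def n_perm(self) -> int:
        return len(self.null_values)

    @property
    def p_value(self) -> float:
        return (1 + int(np.sum(self.null_values >= self.observed))) / (1 + self.n_perm)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value: exact enumeration for small untied
    samples, midrank normal approximation otherwise."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all values tied; rank-sum p set to 1")
        return 0.0, 1.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) < 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_by_node(
    X: pd.DataFrame, labels: np.ndarray, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Unpaired two-sample rank-sum test per feature column, with BH
    adjustment applied jointly across all (node, metric) columns.

    Parameters
    ----------
    X : subjects x features table (columns identify node/metric).
    labels : group label per row; exactly two groups, each with >= 2 rows.

    Returns
    -------
    DataFrame indexed like ``X.columns`` with columns ``statistic``, ``p``,
    ``q`` and ``significant`` (q < ``q_threshold``).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    ga, gb = (labels == groups[0]), (labels == groups[1])
    if ga.sum() < 2 or gb.sum() < 2:
        raise ValueError("each group needs >= 2 subjects")
    stats_, ps = [], []
    values = np.asarray(X, dtype=float)
    for j in range(values.shape[1]):
        s, p = _ranksum_p(values[ga, j], values[gb, j])
        stats_.append(s)
        ps.append(p)
    q = bh_adjust(np.array(ps))
    return pd.DataFrame(
        {"statistic": stats_, "p": ps, "q": q, "significant": q < q_threshold},
        index=X.columns if isinstance(X, pd.DataFrame) else None,
    )


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    cfg: EvalConfig = EvalConfig(),
    n_perm: int = 1000,
    statistic: str = "accuracy",
    selector: str = "enet_subset",
    enet_cfg: EnetConfig = EnetConfig(),
    n_iterations_perm: int | None = None,
    seed: int | None = None,
    observed_report: EvaluationReport | None = None,
) -> PermutationNull:
    """Label-permutation significance of classifier performance.

    Each permutation shuffles the group labels once for the whole dataset
    and re-runs the complete protocol — including feature selection, which
    must sit inside the null to avoid optimistic bias. ``n_iterations_perm``
    (default: same as ``cfg.n_iterations``) allows a cheaper per-permutation
    protocol; the reduction is logged.

    ``statistic`` names any mean metric of the report: "accuracy", "auc",
    "sensitivity" or "specificity".
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives too coarse a p-value resolution")
    attr = f"mean_{statistic}"
    if not hasattr(EvaluationReport, attr):
        raise ValueError(f"unknown statistic {statistic!r}")
    if observed_report is None:
        observed_report = run_protocol(X, y, cfg, selector=selector, enet_cfg=enet_cfg)
    observed = getattr(observed_report, attr)

    n_it = cfg.n_iterations if n_iterations_perm is None else n_iterations_perm
    if n_it != cfg.n_iterations:
        logger.info(
            "permutation null uses %d iteration(s) per permutation "
            "(observed statistic used %d)", n_it, cfg.n_iterations,
        )
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    y = np.asarray(y)
    nulls = np.empty(n_perm)
    from dataclasses import replace

    for b in range(n_perm):
        y_perm = rng.permutation(y)
        cfg_b = replace(cfg, n_iterations=n_it, seed=base_seed + 1 + b)
        rep = run_protocol(X, y_perm, cfg_b, selector=selector, enet_cfg=enet_cfg)
        nulls[b] = getattr(rep, attr)
    return PermutationNull(observed=float(observed), null_values=nulls, statistic=statistic)


def correlate_with_disability(
    X: pd.DataFrame, scores: np.ndarray, features=None
) -> pd.DataFrame:
    """Pearson correlation of each (node, metric) feature with the
    disability score, restricted to ``features`` when given (e.g. the top
    60 most frequently selected). Zero-variance inputs yield NaN r with a
    ``degenerate`` flag."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(X):
        raise ValueError("scores must align with table rows")
    if len(scores) < 3:
        raise ValueError("need >= 3 paired observations")
    cols = list(X.columns) if features is None else list(features)
    rows = []
    for c in cols:
        v = np.asarray(X[c], dtype=float)
        if v.std() == 0 or scores.std() == 0:
            rows.append((np.nan, np.nan, True))
            continue
        r, p = sps.pearsonr(v, scores)
        rows.append((float(r), float(p), False))
    idx = pd.Index(cols)  # tuple feature ids become a MultiIndex
    if not isinstance(idx, pd.MultiIndex):
        idx.name = "feature"
    return pd.DataFrame(rows, columns=["r", "p", "degenerate"], index=idx)
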