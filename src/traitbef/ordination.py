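"""Standardized PCA of trait and community matrices, with group comparisons.

Standardized (correlation-matrix) PCA puts every variable on the same
footing, which matters for mixed-unit trait tables.  PCA axis signs are
arbitrary; loading vectors are oriented so their largest-magnitude element is
positive, making outputs deterministic across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["PcaResult", "standardized_pca", "group_scores_test", "GroupScoresTest"]


@dataclass
class PcaResult:
    """Explained-variance fractions, orthonormal loadings and entity scores."""

    explained_fraction: np.ndarray
    loadings: pd.DataFrame  # variable x axis
    scores: pd.DataFrame  # entity x axis

    @property
    def n_axes(self) -> int:
        return len(self.explained_fraction)


def standardized_pca(matrix: pd.DataFrame | np.ndarray) -> PcaResult:
    """PCA on the correlation matrix of an entity x variable table.

    Scores are projections of the column-standardized data onto the
    orthonormal eigenvectors; explained fractions are the (non-negative)
    eigenvalues normalized to sum 1.  A constant column has no correlation
    structure and is rejected by name.
    """
    df = pd.DataFrame(matrix).copy()
    n, p = df.shape
    if n < 2 or p < 2:
        raise ValueError("standardized_pca requires >= 2 entities and >= 2 variables")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    constant = [str(c) for c, s in zip(df.columns, sd) if not s > 0]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # orient: largest-|.| element of each loading vector positive
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] *= -1.0
    explained = eigvals / eigvals.sum()
    axes = [f"PC{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(eigvecs, index=df.columns, columns=axes)
    scores = pd.DataFrame(Z @ eigvecs, index=df.index, columns=axes)
    return PcaResult(explained_fraction=explained, loadings=loadings, scores=scores)


class GroupScoresTest(NamedTuple):
    F: float
    df: tuple[int, int]
    p_value: float
    pairwise: pd.DataFrame


def group_scores_test(
    scores: Sequence[float] | np.ndarray | pd.Series,
    groups: Sequence[str],
) -> GroupScoresTest:
    """One-way ANOVA of an axis score across groups, plus Tukey HSD pairs.

    Groups with a single member carry no within-group variance and are
    excluded with a warning.  Returns the F statistic with df (g-1, n-g) and
    a pairwise table with Tukey-adjusted p-values from the studentized-range
    distribution at the ANOVA residual df.
    """
    y = np.asarray(scores, dtype=float)
    g = pd.Series(list(groups))
    if len(y) != len(g):
        raise ValueError("scores and groups differ in length")
    counts = g.value_counts()
    singles = sorted(counts.index[counts < 2])
    if singles:
        warnings.warn(f"excluding singleton group(s): {singles}", stacklevel=2)
        keep = ~g.isin(singles).to_numpy()
        y, g = y[keep], g[keep].reset_index(drop=True)
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ValueError("group_scores_test requires >= 2 groups with >= 2 members")
    samples = [y[(g == lv).to_numpy()] for lv in levels]
    F, p = stats.f_oneway(*samples)
    df = (len(levels) - 1, len(y) - len(levels))
    tukey = pairwise_tukeyhsd(y, g.to_numpy())
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return GroupScoresTest(F=float(F), df=df, p_value=float(p), pairwise=pairwise)
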