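"""Reproducibility analysis and heuristic subtype-representative features.

Fingerprint vectors (signed log-p scores, one per scan) are compared by
their pairwise Pearson correlation: repeated scans of the same patient
correlate strongly, scans of different patients weakly, and restricting to
subtype-representative features sharpens the block structure between
epilepsy subtypes.

A feature represents a subtype when it is both

* *reproducible*: the absolute subtype-wise mean in units of the SD,
  t_f = mean_f / sd_f over the subtype's datasets, is extraordinarily
  large relative to the population of all features -- outside the Tukey
  fences Q1 - 1.5 IQR / Q3 + 1.5 IQR of the t_f distribution; and
* *unique*: its mean differs from every other subtype (pairwise two-sided
  Welch t-test, all p < 0.01; a pooled-comparison alternative and a
  Mann-Whitney option are configurable).

The selection is the intersection of both sets. Relative feature
importances are the subtype-mean |L| over the selected features,
normalized to sum to one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

TUKEY_FACTOR = 1.5
UNIQUENESS_ALPHA = 0.01
T_CAP = 1e6  # surrogate for infinite t_f when sd_f == 0


def correlation_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of fingerprint vectors (rows = datasets).

    Zero-variance vectors produce NaN rows/columns (flagged by a warning);
    the diagonal is exactly 1 for well-defined vectors.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    X = vectors.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance fingerprint vector; correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=vectors.index, columns=vectors.index)


@dataclass
class MedianComparison:
    median_a: float
    median_b: float
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    mww_p: float


def group_median_compare(within_values, between_values) -> MedianComparison:
    """Medians, 2.5-97.5 element-percentile intervals and two-sided MWW p.

    The intervals are percentile ranges of the elements themselves (the
    spread of individual correlation coefficients), not bootstrap CIs of
    the median.
    """
    a = np.asarray(within_values, dtype=float)
    b = np.asarray(between_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both element sets must be non-empty")
    if np.array_equal(a, b) and np.all(a == a[0]):
        p = 1.0
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return MedianComparison(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        interval_a=(float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5))),
        interval_b=(float(np.percentile(b, 2.5)), float(np.percentile(b, 97.5))),
        mww_p=p,
    )


def reproducibility_scores(L_matrix: pd.DataFrame) -> pd.Series:
    """t_f = mean_f / sd_f per feature over a subtype's datasets.

    Uses the unbiased (ddof=1) SD; sd = 0 yields a capped signed surrogate
    for infinity (and a warning) so the feature lands outside any fence.
    """
    if len(L_matrix) < 3:
        raise ValueError("need at least three datasets in the subtype")
    mean = L_matrix.mean(axis=0)
    sd = L_matrix.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} features with zero SD; t capped")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / sd
    t[zero] = np.sign(mean[zero]) * T_CAP
    t[zero & (mean == 0)] = 0.0
    return t


def tukey_fences(values, factor: float = TUKEY_FACTOR) -> tuple[float, float]:
    q1, q3 = np.nanpercentile(np.asarray(values, dtype=float), [25, 75])
    iqr = q3 - q1
    return q1 - factor * iqr, q3 + factor * iqr


def select_reproducible(L_matrix: pd.DataFrame, factor: float = TUKEY_FACTOR) -> set[str]:
    """Features whose t_f falls outside the Tukey fences of the pooled
    t distribution over all features of the subtype."""
    t = reproducibility_scores(L_matrix)
    lo, hi = tukey_fences(t, factor)
    return set(t.index[(t < lo) | (t > hi)])


def select_unique(
    L_by_subtype: Mapping[str, pd.DataFrame],
    subtype_of_interest: str,
    alpha: float = UNIQUENESS_ALPHA,
    comparison: str = "pairwise",
    test: str = "welch",
) -> set[str]:
    """Features whose mean differs from all other subtypes (all p < alpha).

    ``comparison='pairwise'`` tests the subtype of interest against every
    other subtype separately (the stricter reading of "all other
    subtypes"); ``'pooled'`` tests against all other subtypes pooled.
    ``test`` selects Welch's t-test (default) or Mann-Whitney ('mww').
    """
    if subtype_of_interest not in L_by_subtype:
        raise KeyError(subtype_of_interest)
    target = L_by_subtype[subtype_of_interest]
    others = {}
    for name, mat in L_by_subtype.items():
        if name == subtype_of_interest:
            continue
        if len(mat) < 2:
            logger.warning("subtype %s has < 2 datasets; excluded from uniqueness test", name)
            continue
        others[name] = mat
    if not others:
        raise ValueError("need at least one other subtype with >= 2 datasets")
    if comparison == "pooled":
        others = {"pooled": pd.concat(others.values(), axis=0)}

    selected = pd.Series(True, index=target.columns)
    X = target.to_numpy(dtype=float)
    for mat in others.values():
        Y = mat.to_numpy(dtype=float)
        if test == "welch":
            with np.errstate(invalid="ignore", divide="ignore"):
                res = sps.ttest_ind(X, Y, axis=0, equal_var=False)
            p = np.nan_to_num(res.pvalue, nan=1.0)
        elif test == "mww":
            p = np.array(
                [sps.mannwhitneyu(X[:, j], Y[:, j], alternative="two-sided").pvalue
                 for j in range(X.shape[1])]
            )
        else:
            raise ValueError(f"unknown test {test!r}")
        selected &= pd.Series(p < alpha, index=target.columns)
    return set(selected.index[selected])


def feature_importance(selected, L_matrix: pd.DataFrame) -> pd.Series:
    """Relative importances: subtype-mean |L| over the selected features,
    normalized so all values add up to one."""
    selected = sorted(selected)
    if not selected:
        raise ValueError("selected feature set is empty")
    weights = L_matrix[selected].abs().mean(axis=0)
    total = weights.sum()
    if total == 0:
        return pd.Series(1.0 / len(selected), index=selected)
    return weights / total


@dataclass
class SelectionResult:
    """Representative features of one subtype."""

    subtype: str
    reproducible_set: frozenset[str]
    unique_set: frozenset[str]
    importance: pd.Series  # over selected features; sums to 1

    @property
    def selected_set(self) -> frozenset[str]:
        return self.reproducible_set & self.unique_set


def select_subtype_features(
    L_by_subtype: Mapping[str, pd.DataFrame],
    subtype_of_interest: str,
    factor: float = TUKEY_FACTOR,
    alpha: float = UNIQUENESS_ALPHA,
    comparison: str = "pairwise",
    test: str = "welch",
) -> SelectionResult:
    """Intersection of the reproducible and unique feature sets, with
    normalized importances."""
    reproducible = frozenset(select_reproducible(L_by_subtype[subtype_of_interest], factor))
    unique = frozenset(select_unique(L_by_subtype, subtype_of_interest, alpha, comparison, test))
    selected = reproducible & unique
    if selected:
        importance = feature_importance(selected, L_by_subtype[subtype_of_interest])
    else:
        importance = pd.Series(dtype=float)
    return SelectionResult(
        subtype=subtype_of_interest,
        reproducible_set=reproducible,
        unique_set=unique,
        importance=importance,
    )
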