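"""Reference rankers for the comparison harness.

Only what the comparisons need: the classical Welch t-test (optionally on
stabilized variances, for threshold-equivalence checks) and the naive
absolute log-fold-change ranker. External methods are compared by importing
their score vectors from TSV (see :mod:`dfctest.io`).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

from .core_stats import ExpressionDataset, FeatureSummaries, stabilized_variance, summarize_features

__all__ = ["WelchResult", "welch_t_test", "fold_change_ranker"]


class WelchResult(NamedTuple):
    t: np.ndarray
    p: np.ndarray
    df: np.ndarray
    degenerate: np.ndarray  # True where both class variances are zero


def welch_t_test(dataset: ExpressionDataset, v_bar_ee=None) -> WelchResult:
    """Per-feature Welch t statistic with two-sided p-value.

    With ``v_bar_ee`` (scalar or per-feature array) the class variances are
    first shrunk toward it, giving the stabilized-variance variant used by
    the expression-dependent p-value-threshold equivalence. Features with
    zero variance in both classes are degenerate: t and p are NaN.
    """
    summ = summarize_features(dataset)
    n1, n2 = summ.n1, summ.n2
    if v_bar_ee is None:
        vs1, vs2 = summ.var1, summ.var2
    else:
        vs1 = stabilized_variance(summ.var1, n1, v_bar_ee)
        vs2 = stabilized_variance(summ.var2, n2, v_bar_ee)

    a1, a2 = vs1 / n1, vs2 / n2
    vsd = a1 + a2
    degenerate = vsd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degenerate, summ.d / np.sqrt(np.where(degenerate, 1.0, vsd)), np.nan)
        denom = a1**2 / (n1 - 1) + a2**2 / (n2 - 1)
        df = np.where(~degenerate, vsd**2 / np.where(degenerate, 1.0, denom), np.nan)
        p = np.where(~degenerate, 2.0 * stats.t.sf(np.abs(t), df), np.nan)
    return WelchResult(t=t, p=p, df=df, degenerate=degenerate)


def fold_change_ranker(summaries: FeatureSummaries) -> np.ndarray:
    """Naive baseline score ``|d|`` (no associated confidence level)."""
    return np.abs(summaries.d)
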