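"""Expression-dependent significance/power thresholds, selection and ranking.

A feature passes selection when its absolute log fold change clears both an
expression-dependent significance threshold ``delta1 = sigma0(mu) * Phi^-1(1
- alpha/2)`` and a power threshold ``delta2 = s * T^-1(1 - beta_th, df)``
(and, optionally, the total-variance filter ``LV > LV_Th(mu)``). Ranking of
all features is by descending ``|Z_d|`` — equivalently by the two-sided
normal p-value of the DFC score — with stable tie-breaking by input order.

The same rule can be expressed through the conditional Type II error
``beta(d | alpha) = 1 - T((|d| - delta1)/s, df) < beta_th``; both routes are
implemented and must select identical sets. Every selected feature's
(stabilized) t-test p-value is bounded by the expression-dependent
``p_threshold(alpha, beta_th, sigma0, s, df)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import FeatureSummaries, stabilized_variance, variance_of_d
from .exceptions import DomainError, ParameterError
from .null_model import NullModel, classify_null_features

__all__ = [
    "DfcParameters",
    "DfcResult",
    "delta1_threshold",
    "delta2_threshold",
    "conditional_type2_error",
    "p_threshold",
    "select_and_rank",
    "select_by_power",
]


@dataclass(frozen=True)
class DfcParameters:
    """Selection parameters.

    ``alpha`` in (0, 1] controls the significance threshold delta1 (alpha=1
    disables it); ``beta_th`` in (0, 0.5] the power threshold delta2
    (beta_th=0.5 disables it). ``variance_filter`` additionally requires
    ``LV > LV_Th(mu)`` — switch it off for full-list ranking / ROC work.
    ``use_null_variance=False`` drops the v0 term from the score denominator
    and ``stabilize=False`` uses raw unbiased class variances; with both off
    the score is exactly the Welch t statistic.
    """

    alpha: float = 0.05
    beta_th: float = 0.2
    variance_filter: bool = True
    use_null_variance: bool = True
    stabilize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0.0 < self.beta_th <= 0.5:
            raise ParameterError(f"beta_th must be in (0, 0.5], got {self.beta_th}")


def delta1_threshold(alpha: float, sigma0):
    """Significance threshold on |logFC|: ``sigma0 * Phi^-1(1 - alpha/2)``.

    Exactly 0 at ``alpha = 1``; strictly decreasing in alpha.
    """
    if not 0.0 < alpha <= 1.0:
        raise ParameterError(
            f"alpha must be in (0, 1] (alpha=0 gives an infinite threshold), got {alpha}"
        )
    sigma0 = np.asarray(sigma0, dtype=float)
    if np.any(sigma0 <= 0):
        raise ParameterError("sigma0 must be positive")
    out = sigma0 * stats.norm.ppf(1.0 - alpha / 2.0)
    return float(out) if out.ndim == 0 else out


def delta2_threshold(beta_th: float, s, df):
    """Power threshold on |logFC|: ``s * T^-1(1 - beta_th, df)``.

    Exactly 0 at ``beta_th = 0.5`` (selection degenerates to the
    significance-only 'unusual ratio' rule).
    """
    if not 0.0 < beta_th <= 0.5:
        raise ParameterError(f"beta_th must be in (0, 0.5], got {beta_th}")
    s = np.asarray(s, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(s <= 0) or np.any(~(df > 0)):
        raise ParameterError("s and df must be positive")
    out = s * stats.t.ppf(1.0 - beta_th, df)
    return float(out) if out.ndim == 0 else out


def conditional_type2_error(d, delta1, s, df):
    """Type II error of a feature given the significance threshold.

    ``beta(d | alpha) = 1 - T((|d| - delta1)/s, df)``; only defined for
    ``|d| > delta1`` (raises :class:`DomainError` otherwise). Power is
    ``1 - beta``.
    """
    d = np.asarray(d, dtype=float)
    delta1 = np.asarray(delta1, dtype=float)
    s = np.asarray(s, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(s <= 0):
        raise ParameterError("s must be positive")
    excess = np.abs(d) - delta1
    if np.any(excess <= 0):
        raise DomainError("conditional Type II error is defined only for |d| > delta1")
    out = stats.t.sf(excess / s, df)
    return float(out) if np.ndim(out) == 0 else out


def p_threshold(alpha: float, beta_th: float, sigma0, s, df):
    """Expression-dependent bound on the (stabilized) t-test p-value.

    ``2 * (1 - T(sigma0/s * Phi^-1(1 - alpha/2) + T^-1(1 - beta_th, df), df))``.
    Reduces to ``2 * beta_th`` at ``alpha = 1``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    if not 0.0 < beta_th <= 0.5:
        raise ParameterError(f"beta_th must be in (0, 0.5], got {beta_th}")
    sigma0 = np.asarray(sigma0, dtype=float)
    s = np.asarray(s, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(sigma0 <= 0) or np.any(s <= 0) or np.any(~(df > 0)):
        raise ParameterError("sigma0, s and df must be positive")
    arg = sigma0 / s * stats.norm.ppf(1.0 - alpha / 2.0) + stats.t.ppf(1.0 - beta_th, df)
    out = 2.0 * stats.t.sf(arg, df)
    return float(out) if out.ndim == 0 else out


@dataclass
class DfcResult:
    """Per-feature DFC outcome: score, p-value, thresholds, flags, rank."""

    feature_ids: np.ndarray
    z_score: np.ndarray
    p_value: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    type2_error: np.ndarray
    p_th: np.ndarray
    is_null: np.ndarray
    passes_selection: np.ndarray
    rank: np.ndarray
    params: DfcParameters

    def to_frame(self, summaries: FeatureSummaries) -> pd.DataFrame:
        """Ranked-results table (input order; sort on ``rank`` to list top hits)."""
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "mu": summaries.mu,
                "d": summaries.d,
                "fc": summaries.fc,
                "v_total": summaries.v_total,
                "lv": summaries.lv,
                "z_score": self.z_score,
                "p_value": self.p_value,
                "delta1": self.delta1,
                "delta2": self.delta2,
                "type2_error": self.type2_error,
                "p_th": self.p_th,
                "is_null": self.is_null,
                "passes_selection": self.passes_selection,
                "rank": self.rank,
            }
        )


def _score_ingredients(summaries: FeatureSummaries, model: NullModel, params: DfcParameters):
    """Shared per-feature quantities: curves, stabilized s/df, z, delta1/2."""
    curves = model.evaluate(summaries.mu)
    n1, n2 = summaries.n1, summaries.n2
    if params.stabilize:
        vs1 = stabilized_variance(summaries.var1, n1, curves.v_bar_ee)
        vs2 = stabilized_variance(summaries.var2, n2, curves.v_bar_ee)
    else:
        vs1, vs2 = summaries.var1, summaries.var2
    vsd, s, df = variance_of_d(vs1, vs2, n1, n2)
    v0 = curves.sigma0**2 if params.use_null_variance else np.zeros(len(summaries))
    d0 = curves.d0_center

    denom = np.sqrt(vsd + v0)
    centered = summaries.d - d0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, centered / np.where(denom > 0, denom, 1.0), 0.0)
    # positive d with an exactly-zero denominator: infinite evidence
    z = np.where((denom == 0) & (centered != 0), np.sign(centered) * np.inf, z)

    delta1 = curves.sigma0 * stats.norm.ppf(1.0 - params.alpha / 2.0)
    with np.errstate(invalid="ignore"):
        t_q = stats.t.ppf(1.0 - params.beta_th, df)
    delta2 = np.where((s > 0) & np.isfinite(t_q), s * np.where(np.isfinite(t_q), t_q, 0.0), 0.0)
    return curves, vsd, s, df, z, delta1, delta2


def select_and_rank(
    summaries: FeatureSummaries, model: NullModel, params: DfcParameters | None = None
) -> DfcResult:
    """Score, test and rank every feature.

    Selection: ``|d| > delta1 + delta2`` (strict), intersected with
    ``LV > LV_Th(mu)`` when the variance filter is on. All features are
    ranked by descending ``|Z_d|`` regardless of the selection flags; ties
    keep input order.
    """
    params = params or DfcParameters()
    curves, vsd, s, df, z, delta1, delta2 = _score_ingredients(summaries, model, params)

    p_value = 2.0 * stats.norm.sf(np.abs(z))

    excess = np.abs(summaries.d) - delta1
    with np.errstate(invalid="ignore", divide="ignore"):
        type2 = np.where(
            (excess > 0) & (s > 0),
            stats.t.sf(np.where(s > 0, excess / np.where(s > 0, s, 1.0), 0.0), df),
            np.nan,
        )
        type2 = np.where((excess > 0) & (s == 0), 0.0, type2)  # limit of the t tail
        pth = np.where(
            (s > 0) & (df > 0),
            2.0
            * stats.t.sf(
                curves.sigma0 / np.where(s > 0, s, 1.0) * stats.norm.ppf(1.0 - params.alpha / 2.0)
                + stats.t.ppf(1.0 - params.beta_th, df),
                df,
            ),
            np.nan,
        )

    passes = np.abs(summaries.d) > delta1 + delta2
    is_null = classify_null_features(summaries, model)
    if params.variance_filter:
        passes &= summaries.lv > curves.lv_th

    order = np.argsort(-np.abs(z), kind="stable")
    rank = np.empty(len(summaries), dtype=int)
    rank[order] = np.arange(1, len(summaries) + 1)

    return DfcResult(
        feature_ids=summaries.feature_ids.copy(),
        z_score=z,
        p_value=p_value,
        delta1=delta1,
        delta2=delta2,
        type2_error=type2,
        p_th=pth,
        is_null=is_null,
        passes_selection=passes,
        rank=rank,
        params=params,
    )


def select_by_power(
    summaries: FeatureSummaries, model: NullModel, params: DfcParameters | None = None
) -> np.ndarray:
    """Selection mask via the conditional-power route.

    ``beta(d|alpha) < beta_th`` and ``|d| > delta1`` (and the variance filter
    when enabled). Must coincide with :func:`select_and_rank`'s
    ``passes_selection`` on every dataset.
    """
    params = params or DfcParameters()
    curves, vsd, s, df, z, delta1, _ = _score_ingredients(summaries, model, params)
    excess = np.abs(summaries.d) - delta1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_d = np.where(
            (excess > 0) & (s > 0),
            stats.t.sf(np.where(s > 0, excess / np.where(s > 0, s, 1.0), 0.0), df),
            np.inf,  # undefined or no excess: cannot pass
        )
    # s == 0 with positive excess: infinite evidence, beta -> 0
    beta_d = np.where((excess > 0) & (s == 0), 0.0, beta_d)
    passes = (beta_d < params.beta_th) & (excess > 0)
    if params.variance_filter:
        passes &= summaries.lv > curves.lv_th
    return passes
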