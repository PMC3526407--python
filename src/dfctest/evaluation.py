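"""ROC construction and comparison metrics.

ROC curves are built by sweeping the score threshold over all distinct
values; tied scores enter together, producing diagonal segments, so the
trapezoidal AUC equals the probability that a random positive outranks a
random negative with ties counted 1/2 (Mann-Whitney identity).

The standardized partial area ``SPA(eta) = pAUC(eta) / eta`` normalizes the
partial area by the ideal receiver's (``pAUC_ideal(eta) = eta``); SPA(1) is
the AUC. The Youden index is ``max(tau - eta)`` over curve points, reported
with the selected fraction ``nu`` at which it is attained. ``nu`` relates to
the rates through ``nu = eta * (1 - N_T/N_p) + tau * N_T/N_p``.

AUC comparisons across datasets follow the paired design: one-sided Wilcoxon
signed-rank on raw AUCs, one-sided paired t on logit-transformed AUCs
``LTA = 0.5 * ln(AUC / (1 - AUC))``, and Pearson (or Spearman) correlation
of LTAs between two preprocessing conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataValidationError, DomainError, ParameterError

__all__ = [
    "LabeledScores",
    "RocCurve",
    "roc_curve",
    "auc",
    "spa",
    "youden_index",
    "YoudenResult",
    "logit_auc",
    "paired_auc_tests",
    "logit_auc_correlation",
    "compare_aucs",
    "average_curves",
]


@dataclass
class LabeledScores:
    """Per-feature ranking scores (higher = more likely DE) with truth flags."""

    scores: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.scores.shape != self.truth.shape or self.scores.ndim != 1:
            raise DataValidationError("scores and truth must be 1-D and equal length")
        if not np.all(np.isfinite(self.scores)):
            raise DataValidationError("scores must be finite")
        if self.n_true < 1:
            raise DataValidationError("need at least one true positive feature")
        if self.n_true >= self.n_total:
            raise DataValidationError("need at least one negative feature")

    @property
    def n_true(self) -> int:
        return int(self.truth.sum())

    @property
    def n_total(self) -> int:
        return len(self.truth)


@dataclass
class RocCurve:
    """Stepwise ROC curve: FPR ``eta``, TPR ``tau``, selected fraction ``nu``."""

    eta: np.ndarray
    tau: np.ndarray
    nu: np.ndarray
    n_true: int
    n_total: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"eta": self.eta, "tau": self.tau, "nu": self.nu})


def roc_curve(ls: LabeledScores) -> RocCurve:
    """Build the ROC curve over all score thresholds (ties grouped).

    The curve includes the endpoints (0, 0) and (1, 1). If every score is
    identical the curve is the single diagonal segment and is flagged
    ``degenerate``.
    """
    n_pos = ls.n_true
    n_neg = ls.n_total - n_pos

    order = np.argsort(-ls.scores, kind="stable")
    s_sorted = ls.scores[order]
    t_sorted = ls.truth[order]

    # indices of the last member of each tie group
    ends = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.append(ends, len(s_sorted) - 1)

    cum_tp = np.cumsum(t_sorted)[ends]
    n_sel = ends + 1
    cum_fp = n_sel - cum_tp

    eta = np.concatenate([[0.0], cum_fp / n_neg])
    tau = np.concatenate([[0.0], cum_tp / n_pos])
    nu = np.concatenate([[0.0], n_sel / ls.n_total])

    return RocCurve(
        eta=eta,
        tau=tau,
        nu=nu,
        n_true=n_pos,
        n_total=ls.n_total,
        degenerate=len(ends) == 1,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tau, curve.eta))


def spa(curve: RocCurve, eta_max: float = 1.0) -> float:
    """Standardized partial area: ``(1/eta_max) * integral_0^eta_max tau d(eta)``.

    ``spa(curve, 1.0)`` equals :func:`auc`. ``eta_max`` must be in (0, 1].
    """
    if not 0.0 < eta_max <= 1.0:
        raise DomainError(f"eta_max must be in (0, 1], got {eta_max}")
    eta, tau = curve.eta, curve.tau
    j = int(np.searchsorted(eta, eta_max, side="right")) - 1
    if eta[j] >= eta_max or j == len(eta) - 1:
        eta_c, tau_c = eta[: j + 1], tau[: j + 1]
    else:
        # interpolate the boundary point inside the segment [j, j+1]
        frac = (eta_max - eta[j]) / (eta[j + 1] - eta[j])
        tau_b = tau[j] + frac * (tau[j + 1] - tau[j])
        eta_c = np.append(eta[: j + 1], eta_max)
        tau_c = np.append(tau[: j + 1], tau_b)
    pauc = float(np.trapezoid(tau_c, eta_c))
    return pauc / eta_max


class YoudenResult(NamedTuple):
    yi: float
    nu_max: float


def youden_index(curve: RocCurve) -> YoudenResult:
    """Maximum of ``tau - eta`` over curve points and the ``nu`` attaining it.

    Ties are resolved to the first (smallest ``nu``) maximizer.
    """
    diff = curve.tau - curve.eta
    i = int(np.argmax(diff))
    return YoudenResult(yi=float(diff[i]), nu_max=float(curve.nu[i]))


def logit_auc(value):
    """Logit transform ``0.5 * ln(AUC / (1 - AUC))``; AUC must be in (0, 1)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError("logit transform requires AUC strictly inside (0, 1)")
    out = 0.5 * np.log(arr / (1.0 - arr))
    return float(out) if out.ndim == 0 else out


def paired_auc_tests(auc_a: Sequence[float], auc_b: Sequence[float]) -> dict:
    """One-sided paired tests of H1: method *a* has larger AUC than *b*.

    Returns the Wilcoxon signed-rank p-value on raw AUCs and the paired
    t-test p-value on logit-transformed AUCs, with the mean differences.
    Requires at least 5 pairs.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired AUC vectors must be 1-D and equal length")
    if len(a) < 5:
        raise ParameterError(f"need >= 5 paired AUC values, got {len(a)}")
    lta_a, lta_b = logit_auc(a), logit_auc(b)
    wilcoxon = stats.wilcoxon(a, b, alternative="greater")
    ttest = stats.ttest_rel(lta_a, lta_b, alternative="greater")
    return {
        "n": len(a),
        "wilcoxon_p": float(wilcoxon.pvalue),
        "t_logit_p": float(ttest.pvalue),
        "mean_auc_diff": float(np.mean(a - b)),
        "mean_lta_diff": float(np.mean(lta_a - lta_b)),
    }


def logit_auc_correlation(
    auc_a: Sequence[float], auc_b: Sequence[float], method: str = "pearson"
) -> float:
    """Correlation of logit-transformed AUCs between two conditions."""
    lta_a = logit_auc(np.asarray(auc_a, dtype=float))
    lta_b = logit_auc(np.asarray(auc_b, dtype=float))
    if method == "pearson":
        return float(stats.pearsonr(lta_a, lta_b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(lta_a, lta_b).statistic)
    raise ParameterError(f"unknown correlation method {method!r}")


def compare_aucs(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Compare a reference method's AUCs against every other column.

    ``table``: rows = datasets, columns = methods, values = AUCs. Returns a
    report with one row per non-reference method.
    """
    if reference not in table.columns:
        raise ParameterError(f"reference method {reference!r} not in table columns")
    rows = []
    for method in table.columns:
        if method == reference:
            continue
        res = paired_auc_tests(table[reference].to_numpy(), table[method].to_numpy())
        res["method"] = method
        rows.append(res)
    report = pd.DataFrame(rows)
    return report[["method", "n", "mean_auc_diff", "mean_lta_diff", "wilcoxon_p", "t_logit_p"]]


def average_curves(curves: Sequence[RocCurve], nu_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Average TPR across datasets at fixed selected fraction ``nu``.

    Returns a frame with ``nu``, ``mean_tau``, ``se_tau`` (and the same for
    ``eta``), suitable for mean-curve plots with standard-error bands.
    """
    if len(curves) < 2:
        raise ParameterError("need at least two curves to average")
    if nu_grid is None:
        nu_grid = np.linspace(0.0, 1.0, 201)
    taus = np.vstack([np.interp(nu_grid, c.nu, c.tau) for c in curves])
    etas = np.vstack([np.interp(nu_grid, c.nu, c.eta) for c in curves])
    k = len(curves)
    return pd.DataFrame(
        {
            "nu": nu_grid,
            "mean_tau": taus.mean(axis=0),
            "se_tau": taus.std(axis=0, ddof=1) / np.sqrt(k),
            "mean_eta": etas.mean(axis=0),
            "se_eta": etas.std(axis=0, ddof=1) / np.sqrt(k),
        }
    )
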