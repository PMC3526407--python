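"""Expression-dependent null-feature distribution.

The feature population is binned on average expression ``mu``. Within each
bin the conditional mean of log2 total variance at zero log fold change,
``LV_Th = E[LV | d = 0, mu]``, separates *null* (equally expressed) features
— those with ``LV < LV_Th(mu)`` — from candidates. The scale ``sigma0(mu)``
of the null log-fold-change distribution is estimated robustly per bin, and
the binned curves are smoothed and interpolated to give continuous
``LV_Th(mu)``, ``sigma0(mu)``, ``d0_center(mu)`` and the null average
variance ``v_bar_ee(mu) = 2**LV_Th(mu)``.

sigma0 is the MAD (about ``d0_center``) of *all* log fold changes in the
bin, scaled by 1/0.6745. Under the factorization assumption for null
features the d distribution of the low-variance subset equals that of all
null features, and the median resists the small fraction of truly regulated
features; restricting to the low-LV subset would bias sigma0 low because
total variance carries a between-class d**2 term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core_stats import FeatureSummaries
from .exceptions import EstimationError, ParameterError

__all__ = [
    "BinSpec",
    "NullModel",
    "NullCurves",
    "estimate_null_model",
    "evaluate_null_model",
    "classify_null_features",
    "null_model_table",
]

MAD_TO_SIGMA = 1.0 / 0.6745  # normal-consistent MAD scale factor

#: bins at least this large use the quadratic-regression estimate of
#: E[LV | d=0]; smaller bins fall back to averaging LV over small-|d| features
_REGRESSION_MIN = 200

#: fallback: mean LV over features with |d| <= this percentile of |d|
_FALLBACK_ABS_D_PCTL = 40.0


@dataclass(frozen=True)
class BinSpec:
    """Binning strategy for estimating the expression-dependent curves.

    ``n_bins=None`` resolves to ``clamp(n_usable // 200, 10, 50)``. Equal-count
    bins keep estimator variance uniform across the expression range.
    """

    strategy: str = "equal-count"
    n_bins: int | None = None
    min_per_bin: int = 100

    def __post_init__(self) -> None:
        if self.strategy not in ("equal-count", "equal-width"):
            raise ParameterError(f"unknown binning strategy {self.strategy!r}")
        if self.n_bins is not None and self.n_bins < 3:
            raise ParameterError(f"n_bins must be >= 3, got {self.n_bins}")
        if self.min_per_bin < 20:
            raise ParameterError(f"min_per_bin must be >= 20, got {self.min_per_bin}")

    def resolve_n_bins(self, n_usable: int) -> int:
        if self.n_bins is not None:
            return self.n_bins
        return int(np.clip(n_usable // 200, 10, 50))


class NullCurves(NamedTuple):
    """Null-model curves evaluated at query expression values."""

    lv_th: np.ndarray
    sigma0: np.ndarray
    d0_center: np.ndarray
    v_bar_ee: np.ndarray


@dataclass
class NullModel:
    """Binned + smoothed expression-dependent null-distribution curves."""

    bin_centers: np.ndarray
    lv_th: np.ndarray
    sigma0: np.ndarray
    d0_center: np.ndarray
    bin_counts: np.ndarray
    smoothing_window: int = 3

    def __post_init__(self) -> None:
        for name in ("bin_centers", "lv_th", "sigma0", "d0_center", "bin_counts"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            len(self.bin_centers) == len(self.lv_th) == len(self.sigma0)
            == len(self.d0_center) == len(self.bin_counts)
        ):
            raise EstimationError("null-model curve arrays must share a length")
        if len(self.bin_centers) < 3:
            raise EstimationError("need at least 3 bins for a null model")
        if not np.all(np.isfinite(self.lv_th)):
            raise EstimationError("non-finite LV_Th curve")
        if not (np.all(np.isfinite(self.sigma0)) and np.all(self.sigma0 > 0)):
            raise EstimationError("sigma0 must be finite and positive at every bin")

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def evaluate(self, mu) -> NullCurves:
        """Piecewise-linear interpolation, clamped outside the grid."""
        mu = np.asarray(mu, dtype=float)
        lv_th = np.interp(mu, self.bin_centers, self.lv_th)
        sigma0 = np.interp(mu, self.bin_centers, self.sigma0)
        d0 = np.interp(mu, self.bin_centers, self.d0_center)
        return NullCurves(lv_th=lv_th, sigma0=sigma0, d0_center=d0, v_bar_ee=2.0**lv_th)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "lv_th": self.lv_th,
                "sigma0": self.sigma0,
                "d0_center": self.d0_center,
                "n_features": self.bin_counts.astype(int),
            }
        )


def _lv_at_null_d(d: np.ndarray, lv: np.ndarray, d_ref: float) -> float:
    """Estimate E[LV | d = d_ref] within one bin (d_ref = null logFC center)."""
    if len(d) >= _REGRESSION_MIN and np.ptp(d) > 0:
        coef = np.polyfit(d, lv, 2)
        return float(np.polyval(coef, d_ref))
    cut = np.percentile(np.abs(d - d_ref), _FALLBACK_ABS_D_PCTL)
    sel = np.abs(d - d_ref) <= cut
    return float(np.mean(lv[sel]))


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(values) < window:
        return values
    padded = np.pad(values, window // 2, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def estimate_null_model(
    summaries: FeatureSummaries,
    bins: BinSpec | None = None,
    center_d0: bool = False,
) -> NullModel:
    """Fit the expression-dependent null model from the feature population.

    Features with zero total variance are excluded from estimation. Per bin:
    ``lv_th`` estimates ``E[LV | d=0, mu]``; the bin's null set is
    ``{LV < lv_th}`` (must hold at least 10 features); ``d0_center`` is 0 or,
    with ``center_d0=True``, the median d of the null set; ``sigma0`` is the
    scaled MAD of the bin's d values about ``d0_center``. The three curves
    are smoothed with a 3-bin moving average before interpolation.
    """
    bins = bins or BinSpec()
    usable = summaries.v_total > 0
    mu = summaries.mu[usable]
    d = summaries.d[usable]
    lv = summaries.lv[usable]
    n_usable = int(usable.sum())
    if n_usable < 3 * bins.min_per_bin:
        raise EstimationError(
            f"need at least {3 * bins.min_per_bin} features with positive total "
            f"variance to estimate a null model, got {n_usable}"
        )

    n_bins = bins.resolve_n_bins(n_usable)
    if bins.strategy == "equal-count":
        n_bins = min(n_bins, n_usable // bins.min_per_bin)
        if n_bins < 3:
            raise EstimationError(
                f"fewer than 3 usable bins (n={n_usable}, min_per_bin={bins.min_per_bin})"
            )
        order = np.argsort(mu, kind="stable")
        groups = [idx for idx in np.array_split(order, n_bins)]
    else:  # equal-width
        edges = np.linspace(mu.min(), mu.max(), n_bins + 1)
        which = np.clip(np.digitize(mu, edges[1:-1]), 0, n_bins - 1)
        groups = [np.flatnonzero(which == b) for b in range(n_bins)]
        groups = [g for g in groups if len(g) >= bins.min_per_bin]
        if len(groups) < 3:
            raise EstimationError(
                f"fewer than 3 usable equal-width bins with >= {bins.min_per_bin} features"
            )

    centers, lv_th, sigma0, d0_center, counts = [], [], [], [], []
    for b, idx in enumerate(groups):
        d_b, lv_b = d[idx], lv[idx]
        # with centering, the null logFC sits at the bin's median d (robust
        # to the small DE fraction), not at 0
        d_ref = float(np.median(d_b)) if center_d0 else 0.0
        lv0 = _lv_at_null_d(d_b, lv_b, d_ref)
        null_mask = lv_b < lv0
        n_null = int(null_mask.sum())
        if n_null < 10:
            raise EstimationError(
                f"null set in bin {b} has only {n_null} features (< 10); "
                "cannot estimate the null distribution there"
            )
        d0 = float(np.median(d_b[null_mask])) if center_d0 else 0.0
        s0 = float(np.median(np.abs(d_b - d0))) * MAD_TO_SIGMA
        if not s0 > 0:
            raise EstimationError(f"degenerate sigma0 (zero MAD) in bin {b}")
        centers.append(float(np.mean(mu[idx])))
        lv_th.append(lv0)
        sigma0.append(s0)
        d0_center.append(d0)
        counts.append(len(idx))

    centers = np.asarray(centers)
    order = np.argsort(centers, kind="stable")
    window = 3
    return NullModel(
        bin_centers=centers[order],
        lv_th=_moving_average(np.asarray(lv_th)[order], window),
        sigma0=_moving_average(np.asarray(sigma0)[order], window),
        d0_center=_moving_average(np.asarray(d0_center)[order], window),
        bin_counts=np.asarray(counts, dtype=float)[order],
        smoothing_window=window,
    )


def evaluate_null_model(model: NullModel, mu) -> NullCurves:
    """Evaluate the smoothed curves at ``mu`` (clamped outside the grid)."""
    return model.evaluate(mu)


def classify_null_features(summaries: FeatureSummaries, model: NullModel) -> np.ndarray:
    """Boolean mask: True where a feature is null (``LV < LV_Th(mu)``).

    The inequality is strict — a feature sitting exactly on the threshold is
    non-null. Features with zero total variance are null by convention.
    """
    curves = model.evaluate(summaries.mu)
    is_null = summaries.lv < curves.lv_th
    is_null[summaries.v_total == 0] = True
    return is_null


def null_model_table(summaries: FeatureSummaries, model: NullModel) -> pd.DataFrame:
    """Diagnostic (mu, LV, d) cloud with fitted curve values per feature."""
    curves = model.evaluate(summaries.mu)
    return pd.DataFrame(
        {
            "feature_id": summaries.feature_ids,
            "mu": summaries.mu,
            "d": summaries.d,
            "lv": summaries.lv,
            "lv_th": curves.lv_th,
            "sigma0": curves.sigma0,
            "d0_center": curves.d0_center,
            "is_null": classify_null_features(summaries, model),
        }
    )
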