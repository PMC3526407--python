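"""Per-feature summary statistics and the distributional fold-change score.

The central quantities for a two-class log2 expression matrix are, per
feature: the class means ``mu1``/``mu2``, their average ``mu``, the log2 fold
change ``d = mu1 - mu2`` (fold change ``FC = 2**d``), the unbiased
within-class variances, and the *total* variance ``v_total`` — the unbiased
variance of all ``n1 + n2`` values about the pooled grand mean, so that
between-class signal inflates it. ``LV = log2(v_total)``.

The DFC score is a signal-to-noise statistic intermediate between a normal
Z and a t statistic::

    Z_d = (d - d0_center) / sqrt(v_s(d) + v0)

where ``v_s(d)`` is the (optionally stabilized) sampling variance of ``d``
and ``v0`` the variance of the null features' log-fold-change distribution
at the feature's expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataValidationError, DegenerateVarianceError, SizeError

__all__ = [
    "ExpressionDataset",
    "FeatureSummary",
    "FeatureSummaries",
    "summarize_features",
    "stabilized_variance",
    "variance_of_d",
    "dfc_score",
]


@dataclass
class ExpressionDataset:
    """A log2-scale expression matrix with a two-class sample assignment.

    Parameters
    ----------
    values
        ``(n_features, n_samples)`` float array of log2 intensities.
    feature_ids
        Unique feature identifiers, one per row.
    class_labels
        Per-sample class label, each in ``{1, 2}``; both classes must have
        at least two samples.
    sample_ids
        Optional sample identifiers, one per column.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    class_labels: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.class_labels = np.asarray(self.class_labels, dtype=int)
        if self.values.ndim != 2:
            raise DataValidationError(
                f"expression matrix must be 2-D, got shape {self.values.shape}"
            )
        n_features, n_samples = self.values.shape
        if self.feature_ids.shape != (n_features,):
            raise DataValidationError(
                f"{len(self.feature_ids)} feature IDs for {n_features} rows"
            )
        if self.class_labels.shape != (n_samples,):
            raise DataValidationError(
                f"{len(self.class_labels)} class labels for {n_samples} columns"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                "missing/non-finite value at feature "
                f"{self.feature_ids[bad[0]]!r}, sample column {bad[1]}"
            )
        labels = set(self.class_labels.tolist())
        if not labels <= {1, 2}:
            raise DataValidationError(
                f"class labels must be 1 or 2, got {sorted(labels)}"
            )
        for k in (1, 2):
            if int(np.sum(self.class_labels == k)) < 2:
                raise SizeError(f"class {k} has fewer than 2 samples")
        if len(set(self.feature_ids.tolist())) != n_features:
            seen: set = set()
            dup = next(f for f in self.feature_ids.tolist() if f in seen or seen.add(f))
            raise DataValidationError(f"duplicate feature ID {dup!r}")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.shape != (n_samples,):
                raise DataValidationError(
                    f"{len(self.sample_ids)} sample IDs for {n_samples} columns"
                )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.class_labels == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.class_labels == 2))

    def class_values(self, k: int) -> np.ndarray:
        """Submatrix of the samples belonging to class ``k``."""
        return self.values[:, self.class_labels == k]

    def swap_classes(self) -> "ExpressionDataset":
        """Same data with class labels 1 and 2 exchanged."""
        return ExpressionDataset(
            values=self.values.copy(),
            feature_ids=self.feature_ids.copy(),
            class_labels=np.where(self.class_labels == 1, 2, 1),
            sample_ids=None if self.sample_ids is None else self.sample_ids.copy(),
        )


@dataclass(frozen=True)
class FeatureSummary:
    """Summary statistics for a single feature (a view into a table row)."""

    feature_id: object
    mu1: float
    mu2: float
    mu: float
    d: float
    var1: float
    var2: float
    v_total: float
    lv: float
    v_internal: float
    n1: int
    n2: int

    @property
    def fc(self) -> float:
        """Fold change ``2**d`` (valid when class variances are similar)."""
        return float(2.0 ** self.d)


@dataclass
class FeatureSummaries:
    """Vectorized per-feature summaries; indexable as a sequence.

    ``summaries[i]`` returns a :class:`FeatureSummary`; the attribute arrays
    (``mu``, ``d``, ``v_total``, ``lv`` ...) are what downstream estimation
    consumes. ``lv`` is ``-inf`` where ``v_total == 0`` (LV is only defined
    for positive total variance; such features are null by convention).
    """

    feature_ids: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    mu: np.ndarray
    d: np.ndarray
    var1: np.ndarray
    var2: np.ndarray
    v_total: np.ndarray
    lv: np.ndarray
    v_internal: np.ndarray
    n1: int
    n2: int

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __getitem__(self, i: int) -> FeatureSummary:
        return FeatureSummary(
            feature_id=self.feature_ids[i],
            mu1=float(self.mu1[i]),
            mu2=float(self.mu2[i]),
            mu=float(self.mu[i]),
            d=float(self.d[i]),
            var1=float(self.var1[i]),
            var2=float(self.var2[i]),
            v_total=float(self.v_total[i]),
            lv=float(self.lv[i]),
            v_internal=float(self.v_internal[i]),
            n1=self.n1,
            n2=self.n2,
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def fc(self) -> np.ndarray:
        return 2.0 ** self.d


def summarize_features(dataset: ExpressionDataset) -> FeatureSummaries:
    """Compute per-feature summary statistics for a two-class dataset.

    Returns one summary per feature, in input order. ``d = mu1 - mu2``,
    ``mu = (mu1 + mu2) / 2``; ``v_total`` is the unbiased variance of the
    pooled ``n1 + n2`` values about their grand mean, and ``v_internal`` the
    pooled within-class variance (diagnostic).
    """
    x1 = dataset.class_values(1)
    x2 = dataset.class_values(2)
    n1, n2 = dataset.n1, dataset.n2

    mu1 = x1.mean(axis=1)
    mu2 = x2.mean(axis=1)
    d = mu1 - mu2
    mu = (mu1 + mu2) / 2.0
    var1 = x1.var(axis=1, ddof=1)
    var2 = x2.var(axis=1, ddof=1)
    v_total = dataset.values.var(axis=1, ddof=1)
    v_internal = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore"):
        lv = np.where(v_total > 0, np.log2(np.where(v_total > 0, v_total, 1.0)), -np.inf)

    return FeatureSummaries(
        feature_ids=dataset.feature_ids.copy(),
        mu1=mu1,
        mu2=mu2,
        mu=mu,
        d=d,
        var1=var1,
        var2=var2,
        v_total=v_total,
        lv=lv,
        v_internal=v_internal,
        n1=n1,
        n2=n2,
    )


def stabilized_variance(sample_var, n: int, v_bar_ee):
    """Shrink a small-sample variance toward the local null-feature level.

    Returns ``((n - 1) / n) * sample_var + v_bar_ee / n``. This coincides
    with the unbiased variance when ``sample_var == v_bar_ee`` and with the
    maximum-likelihood variance when ``v_bar_ee == 0``. Accepts scalars or
    arrays for ``sample_var`` and ``v_bar_ee``.
    """
    if n < 2:
        raise SizeError(f"need n >= 2 samples, got {n}")
    sample_var = np.asarray(sample_var, dtype=float)
    v_bar_ee = np.asarray(v_bar_ee, dtype=float)
    if np.any(sample_var < 0) or np.any(v_bar_ee < 0):
        raise DegenerateVarianceError("variances must be non-negative")
    out = ((n - 1) / n) * sample_var + v_bar_ee / n
    return float(out) if out.ndim == 0 else out


def variance_of_d(vs1, vs2, n1: int, n2: int):
    """Sampling variance of ``d``, its standard deviation and Welch DF.

    ``vsd = vs1/n1 + vs2/n2``; ``s = sqrt(vsd)``; the degrees of freedom use
    the Welch–Satterthwaite approximation on the supplied (possibly
    stabilized) per-class variances. Scalars in → scalars out; with array
    input, features where both variances vanish get ``s = 0`` and
    ``df = nan`` instead of raising.
    """
    if n1 < 2 or n2 < 2:
        raise SizeError(f"need at least 2 samples per class, got {n1}, {n2}")
    vs1 = np.asarray(vs1, dtype=float)
    vs2 = np.asarray(vs2, dtype=float)
    if np.any(vs1 < 0) or np.any(vs2 < 0):
        raise DegenerateVarianceError("variances must be non-negative")
    scalar = vs1.ndim == 0 and vs2.ndim == 0
    if scalar and vs1 == 0 and vs2 == 0:
        raise DegenerateVarianceError("both class variances are zero")

    a1 = vs1 / n1
    a2 = vs2 / n2
    vsd = a1 + a2
    s = np.sqrt(vsd)
    denom = a1**2 / (n1 - 1) + a2**2 / (n2 - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = np.where(denom > 0, vsd**2 / np.where(denom > 0, denom, 1.0), np.nan)
    if scalar:
        return float(vsd), float(s), float(df)
    return vsd, s, df


def dfc_score(d, d0_center, vsd, v0):
    """DFC score ``Z_d = (d - d0_center) / sqrt(vsd + v0)``.

    ``v0`` is the local variance of the null log-fold-change distribution;
    with ``v0 = 0`` (and unstabilized ``vsd``) the score reduces to the
    Welch t statistic. Scalars in → scalar out; with array input, entries
    with a zero denominator yield ``nan`` (callers decide the convention).
    """
    d = np.asarray(d, dtype=float)
    d0_center = np.asarray(d0_center, dtype=float)
    vsd = np.asarray(vsd, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    total = vsd + v0
    scalar = total.ndim == 0 and d.ndim == 0
    if scalar and total == 0:
        raise DegenerateVarianceError("vsd + v0 must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(total > 0, (d - d0_center) / np.sqrt(np.where(total > 0, total, 1.0)), np.nan)
    return float(z) if z.ndim == 0 else z
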