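"""Seeded generator of two-class log2 expression datasets.

Features get a baseline expression ``mu`` drawn uniformly over a log2 range;
within-class values are independent normals with an expression-dependent
variance ``v(mu)`` given by a profile:

* ``flat`` — constant variance;
* ``mas5`` — monotone decreasing, ``v(mu) = a * 2**(-b*mu) + c``;
* ``rma`` — low plateau at high expression rising toward low expression,
  ``v(mu) = floor + rise / (1 + 2**(rate * (mu - mu0)))``.

A small fraction ``pi`` of features is truly differentially expressed with
symmetric-sign effect sizes ``|d| = effect_min + Gamma(shape, scale)`` so
small effects dominate. Archival-tissue-style degradation is emulated by a
fold-change compression factor in (0, 1] and an optional downward intensity
shift. Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core_stats import ExpressionDataset
from .exceptions import ParameterError

__all__ = [
    "FlatProfile",
    "Mas5Profile",
    "RmaProfile",
    "variance_profile_value",
    "profile_from_dict",
    "profile_to_dict",
    "PRESET_PROFILES",
    "SimulationConfig",
    "generate_dataset",
]


@dataclass(frozen=True)
class FlatProfile:
    """Constant within-class variance."""

    v: float = 0.25

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ParameterError(f"flat profile variance must be positive, got {self.v}")


@dataclass(frozen=True)
class Mas5Profile:
    """Monotone-decreasing variance trend ``a * 2**(-b*mu) + c``.

    With ``c = 0`` the variance halves every ``1/b`` log2 units.
    """

    a: float = 8.0
    b: float = 0.5
    c: float = 0.02

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c < 0:
            raise ParameterError(
                f"mas5 profile needs a > 0, b > 0, c >= 0, got a={self.a}, b={self.b}, c={self.c}"
            )


@dataclass(frozen=True)
class RmaProfile:
    """Flat-then-rising trend: plateau ``floor`` at high expression, rising
    by ``rise`` toward low expression around ``mu0`` (logistic in mu)."""

    floor: float = 0.05
    rise: float = 1.5
    mu0: float = 6.0
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.floor <= 0 or self.rise <= 0 or self.rate <= 0:
            raise ParameterError(
                "rma profile needs floor > 0, rise > 0, rate > 0, got "
                f"floor={self.floor}, rise={self.rise}, rate={self.rate}"
            )


VarianceProfile = FlatProfile | Mas5Profile | RmaProfile

PRESET_PROFILES: dict[str, VarianceProfile] = {
    "flat": FlatProfile(),
    "mas5": Mas5Profile(),
    "rma": RmaProfile(),
}


def variance_profile_value(profile: VarianceProfile, mu):
    """Evaluate a variance profile at expression level(s) ``mu`` (always > 0)."""
    mu = np.asarray(mu, dtype=float)
    if isinstance(profile, FlatProfile):
        out = np.full_like(mu, profile.v)
    elif isinstance(profile, Mas5Profile):
        out = profile.a * 2.0 ** (-profile.b * mu) + profile.c
    elif isinstance(profile, RmaProfile):
        out = profile.floor + profile.rise / (1.0 + 2.0 ** (profile.rate * (mu - profile.mu0)))
    else:
        raise ParameterError(f"unknown variance profile {profile!r}")
    return float(out) if out.ndim == 0 else out


def profile_to_dict(profile: VarianceProfile) -> dict:
    kind = {FlatProfile: "flat", Mas5Profile: "mas5", RmaProfile: "rma"}[type(profile)]
    return {"kind": kind, **asdict(profile)}


def profile_from_dict(spec: dict | str) -> VarianceProfile:
    if isinstance(spec, str):
        try:
            return PRESET_PROFILES[spec]
        except KeyError:
            raise ParameterError(f"unknown variance profile preset {spec!r}") from None
    spec = dict(spec)
    kind = spec.pop("kind", None)
    cls = {"flat": FlatProfile, "mas5": Mas5Profile, "rma": RmaProfile}.get(kind)
    if cls is None:
        raise ParameterError(f"unknown variance profile kind {kind!r}")
    return cls(**spec)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a synthetic two-class experiment.

    ``pi`` is the prior fraction of truly DE features (kept << 1, at most
    0.2). ``ffpe_compression`` multiplies every true effect size and
    ``mu_shift`` is added to every baseline expression (negative values
    emulate the downward intensity shift of degraded samples).
    """

    n_features: int = 5000
    n1: int = 10
    n2: int = 10
    pi: float = 0.02
    mu_low: float = 4.0
    mu_high: float = 14.0
    profile: VarianceProfile = field(default_factory=FlatProfile)
    effect_min: float = 0.5
    effect_shape: float = 2.0
    effect_scale: float = 0.5
    ffpe_compression: float = 1.0
    mu_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_features < 1:
            problems.append(f"n_features must be >= 1, got {self.n_features}")
        if self.n1 < 2:
            problems.append(f"n1 must be >= 2, got {self.n1}")
        if self.n2 < 2:
            problems.append(f"n2 must be >= 2, got {self.n2}")
        if not 0.0 <= self.pi <= 0.2:
            problems.append(f"pi must be in [0, 0.2], got {self.pi}")
        if not self.mu_low < self.mu_high:
            problems.append(f"mu_low must be < mu_high, got [{self.mu_low}, {self.mu_high}]")
        if self.effect_min < 0 or self.effect_shape <= 0 or self.effect_scale <= 0:
            problems.append(
                "effect distribution needs effect_min >= 0, effect_shape > 0, "
                f"effect_scale > 0, got {self.effect_min}, {self.effect_shape}, "
                f"{self.effect_scale}"
            )
        if not 0.0 < self.ffpe_compression <= 1.0:
            problems.append(
                f"ffpe_compression must be in (0, 1], got {self.ffpe_compression}"
            )
        if problems:
            raise ParameterError("invalid simulation config: " + "; ".join(problems))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profile"] = profile_to_dict(self.profile)
        return d

    @classmethod
    def from_dict(cls, spec: dict) -> "SimulationConfig":
        spec = dict(spec)
        if "profile" in spec:
            spec["profile"] = profile_from_dict(spec["profile"])
        return cls(**spec)


def generate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate a seeded two-class dataset and its truth sidecar.

    Exactly ``round(pi * n_features)`` features are DE: class means are
    ``mu +/- d_true/2`` with within-class variance ``v(mu)``. The truth
    frame has columns ``feature_id``, ``is_de``, ``d_true``.
    """
    rng = np.random.default_rng(config.seed)
    np_, n1, n2 = config.n_features, config.n1, config.n2

    mu = rng.uniform(config.mu_low, config.mu_high, np_) + config.mu_shift
    d_true = np.zeros(np_)
    n_de = round(config.pi * np_)
    if n_de:
        de_idx = rng.choice(np_, size=n_de, replace=False)
        magnitudes = config.effect_min + rng.gamma(config.effect_shape, config.effect_scale, n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        d_true[de_idx] = magnitudes * signs * config.ffpe_compression

    sd = np.sqrt(variance_profile_value(config.profile, mu))
    x1 = rng.normal((mu + d_true / 2.0)[:, None], sd[:, None], (np_, n1))
    x2 = rng.normal((mu - d_true / 2.0)[:, None], sd[:, None], (np_, n2))

    width = max(5, len(str(np_)))
    feature_ids = np.array([f"F{i:0{width}d}" for i in range(np_)], dtype=object)
    sample_ids = np.array(
        [f"A{j + 1}" for j in range(n1)] + [f"B{j + 1}" for j in range(n2)], dtype=object
    )
    dataset = ExpressionDataset(
        values=np.hstack([x1, x2]),
        feature_ids=feature_ids,
        class_labels=np.array([1] * n1 + [2] * n2),
        sample_ids=sample_ids,
    )
    truth = pd.DataFrame(
        {"feature_id": feature_ids, "is_de": d_true != 0.0, "d_true": d_true}
    )
    return dataset, truth
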