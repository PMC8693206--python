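"""Synthetic ward-level infection surveillance registry.

Real national surveillance registries link ward-level infection counts to
hospital attributes, but those data are not public. This module generates a
registry with the statistical structure the downstream analysis assumes:

* one record per hospital x ward, with categorical hospital attributes
  (expertise, affiliation, teaching status, accreditation grade), a ward
  type, and continuous utilization / case-mix measures;
* a positive exposure count (hospitalizations) per record;
* infection counts per type (RTI, UTI, SSI, BSI) drawn from a hurdle
  negative binomial: a logistic "hurdle" decides whether any infection is
  observed, and a zero-truncated NB2 with exposure-proportional mean
  generates the positive counts. This produces both overdispersion and an
  excess of zeros relative to Poisson.

The generating parameters are returned alongside the records so that
parameter-recovery and null-calibration tests can compare estimates against
a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import (
    CATEGORY_LEVELS,
    EXPOSURE_COLUMN,
    INFECTION_TYPES,
    base_predictors,
    build_design,
)

class ConfigError(ValueError):
    """Raised when a synthetic-registry configuration is invalid."""


#: Marginal category frequencies, loosely matching the composition of a
#: national hospital registry (mostly general, government, grade-1 hospitals).
DEFAULT_CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "ward_type": {
        "internal": 0.20, "icu": 0.18, "ccu": 0.10, "picu_nicu": 0.08,
        "burn": 0.03, "infectious": 0.06, "surgery": 0.20, "obgyn": 0.10,
        "other": 0.05,
    },
    "hospital_expertise": {
        "general": 0.85, "accident_burn": 0.01, "heart": 0.02,
        "pediatrics": 0.02, "obgyn": 0.03, "other": 0.07,
    },
    "affiliation": {"government": 0.72, "semigov_other": 0.10, "for_profit": 0.18},
    "hospital_type": {"nonteaching": 0.30, "teaching": 0.70},
    "accreditation": {"grade1": 0.82, "excellent": 0.03, "grade23": 0.15},
}

#: Count-part coefficients (log rate per hospitalization). The intercept sets
#: a baseline per-type infection risk of about 1.5% per hospitalization, so
#: the pooled four-type HAI rate lands near 8% — mid-range for a
#: well-performing hospital. Ward effects make intensive-care and burn wards
#: the riskiest settings.
DEFAULT_BETA: dict[str, float] = {
    "intercept": -3.8,
    "ward_type[icu]": 0.45,
    "ward_type[burn]": 0.65,
    "ward_type[surgery]": 0.15,
    "mean_age": 0.004,
    "nurse_bed_ratio": -0.15,
}

#: Hurdle coefficients (log odds of observing any infection of a type).
DEFAULT_GAMMA: dict[str, float] = {
    "intercept": 0.9,
    "ward_type[icu]": 0.6,
    "ward_type[burn]": 0.4,
}


@dataclass
class SyntheticConfig:
    """Generating parameters for a synthetic registry.

    Defaults emulate the scale of a national annual registry: 863 hospitals
    with four wards each (~3450 records), yearly ward exposures of a few
    hundred to a few thousand hospitalizations, NB2 dispersion alpha = 0.8,
    and a hurdle that leaves roughly 30% of type-specific counts at zero.
    """

    n_hospitals: int = 863
    wards_per_hospital: int = 4
    infection_types: tuple[str, ...] = INFECTION_TYPES
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    alpha: float = 0.8
    gamma: dict[str, float] | None = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    exposure_range: tuple[int, int] = (200, 3000)
    category_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CATEGORY_PROBS.items()}
    )
    missing_surgery_ratio_frac: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_hospitals < 1:
            raise ConfigError("n_hospitals must be a positive integer")
        if self.wards_per_hospital < 1:
            raise ConfigError("wards_per_hospital must be a positive integer")
        unknown = set(self.infection_types) - set(INFECTION_TYPES)
        if unknown:
            raise ConfigError(f"infection_types contains unknown types {sorted(unknown)}")
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        lo, hi = self.exposure_range
        if lo < 1 or hi < lo:
            raise ConfigError("exposure_range must satisfy 1 <= min <= max")
        if not 0 <= self.missing_surgery_ratio_frac < 1:
            raise ConfigError("missing_surgery_ratio_frac must be in [0, 1)")
        if "intercept" not in self.beta:
            raise ConfigError("beta must include an 'intercept' term")
        if self.gamma is not None and "intercept" not in self.gamma:
            raise ConfigError("gamma must include an 'intercept' term when present")
        for var, probs in self.category_probs.items():
            if var not in CATEGORY_LEVELS:
                raise ConfigError(f"category_probs names unknown variable {var!r}")
            if set(probs) - set(CATEGORY_LEVELS[var]):
                raise ConfigError(f"category_probs for {var!r} has undeclared levels")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"category_probs for {var!r} do not sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.exposure_range, list):
            cfg.exposure_range = tuple(cfg.exposure_range)
        if isinstance(cfg.infection_types, list):
            cfg.infection_types = tuple(cfg.infection_types)
        return cfg


@dataclass
class SyntheticTruth:
    """The generating parameters and per-record true moments.

    ``mu`` holds the per-record positive-part NB mean (already scaled by
    exposure) per infection type; ``pi0`` the per-record probability that the
    hurdle produces a zero.
    """

    beta: dict[str, float]
    gamma: dict[str, float] | None
    alpha: float
    seed: int
    mu: pd.DataFrame = field(repr=False)
    pi0: pd.DataFrame = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        d = {
            "beta": self.beta,
            "gamma": self.gamma,
            "alpha": self.alpha,
            "seed": self.seed,
            "mu": {c: [float(v) for v in self.mu[c]] for c in self.mu.columns},
            "pi0": {c: [float(v) for v in self.pi0[c]] for c in self.pi0.columns},
        }
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def sample_truncated_nb(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the zero-truncated NB2 by inverse-CDF over the upper tail.

    A uniform is drawn on (P(Y=0), 1) and passed through the untruncated NB
    quantile function, which is exact and vectorizes.
    """
    mu = np.asarray(mu, dtype=float)
    size = 1.0 / alpha
    p = size / (size + mu)
    p0 = stats.nbinom.pmf(0, size, p)
    u = p0 + (1.0 - p0) * rng.uniform(size=mu.shape)
    # guard against u == p0 at float precision mapping back to 0
    draws = stats.nbinom.ppf(np.clip(u, np.nextafter(p0, 1.0), 1.0 - 1e-16), size, p)
    return np.maximum(draws, 1.0).astype(np.int64)


def sample_hurdle_nb_count(
    mu: float | np.ndarray,
    alpha: float,
    p_zero: float | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hurdle-NB draw: 0 with probability p_zero, else zero-truncated NB2(mu, alpha)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    p_zero = np.broadcast_to(np.asarray(p_zero, dtype=float), mu.shape)
    if np.any(mu <= 0):
        raise ConfigError("mu must be > 0")
    if alpha <= 0:
        raise ConfigError("alpha must be > 0")
    if np.any((p_zero < 0) | (p_zero > 1)):
        raise ConfigError("p_zero must lie in [0, 1]")
    is_zero = rng.uniform(size=mu.shape) < p_zero
    out = np.zeros(mu.shape, dtype=np.int64)
    if np.any(~is_zero):
        out[~is_zero] = sample_truncated_nb(mu[~is_zero], alpha, rng)
    return out


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_covariates(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hospital- and ward-level covariates from loosely realistic marginals."""
    nh, w = cfg.n_hospitals, cfg.wards_per_hospital
    n = nh * w

    def cat(var, size, r):
        probs = cfg.category_probs.get(var, DEFAULT_CATEGORY_PROBS[var])
        levels = [lv for lv in CATEGORY_LEVELS[var] if lv in probs]
        p = np.array([probs[lv] for lv in levels])
        return r.choice(levels, size=size, p=p / p.sum())

    hosp = pd.DataFrame(
        {
            "hospital_id": [f"H{i:04d}" for i in range(nh)],
            "hospital_expertise": cat("hospital_expertise", nh, rng),
            "affiliation": cat("affiliation", nh, rng),
            "hospital_type": cat("hospital_type", nh, rng),
            "accreditation": cat("accreditation", nh, rng),
        }
    )
    df = hosp.loc[np.repeat(np.arange(nh), w)].reset_index(drop=True)
    df["ward_id"] = np.tile([f"W{j}" for j in range(w)], nh)
    df["ward_type"] = cat("ward_type", n, rng)

    beds = np.maximum(4, rng.lognormal(np.log(28.0), 0.5, n)).round()
    df["n_active_beds"] = beds.astype(np.int64)
    df["avg_los"] = rng.lognormal(np.log(4.0), 0.45, n).round(2)
    df["bto_rate"] = rng.lognormal(np.log(40.0), 0.35, n).round(2)
    df["nurse_bed_ratio"] = rng.lognormal(np.log(0.9), 0.30, n).round(3)
    df["device_days"] = rng.poisson(8.0 * beds)
    df["catheter_days"] = rng.poisson(5.0 * beds)
    df["ventilator_days"] = rng.poisson(2.5 * beds)
    df["mean_age"] = _truncated_normal(rng, 40.02, 23.56, 0.0, 100.0, n).round(2)
    df["los_until_infection"] = rng.lognormal(np.log(7.0), 0.6, n).round(2)
    df["duration_hospitalization"] = rng.lognormal(np.log(15.0), 0.5, n).round(2)
    df["male_female_ratio"] = rng.lognormal(0.0, 0.3, n).round(3)
    df["n_deaths_ward"] = rng.poisson(5.0, n)
    df["n_device_related_inf"] = rng.poisson(2.0, n)
    df["n_ventilator_related_inf"] = rng.poisson(1.2, n)
    df["n_catheter_related_inf"] = rng.poisson(1.5, n)
    df["bor"] = rng.uniform(40.0, 110.0, n).round(1)
    df["surgery_to_surgery_bed_ratio"] = rng.lognormal(np.log(1.2), 0.4, n).round(3)
    df["death_to_bedridden_ratio"] = rng.lognormal(np.log(0.02), 0.5, n).round(5)
    df["vent_cath_day_ratio"] = rng.lognormal(np.log(0.5), 0.4, n).round(3)
    lo, hi = cfg.exposure_range
    df[EXPOSURE_COLUMN] = rng.integers(lo, hi + 1, n)

    if cfg.missing_surgery_ratio_frac > 0:
        miss = rng.uniform(size=n) < cfg.missing_surgery_ratio_frac
        df.loc[miss, "surgery_to_surgery_bed_ratio"] = np.nan
    return df


def _linear_predictor(records: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """x' b for a named coefficient map, via the shared design-matrix builder."""
    names = base_predictors(list(coefs))
    probe = records.copy()
    # build_design needs a response/exposure; supply dummies if absent
    if "observed_RTI" not in probe.columns:
        probe["observed_RTI"] = 0
    dm = build_design(probe.fillna({"surgery_to_surgery_bed_ratio": 0.0}), names, "RTI")
    vec = np.array([coefs.get(t, 0.0) for t in dm.term_names])
    unknown = set(coefs) - set(dm.term_names)
    if unknown:
        raise ConfigError(f"coefficient map names unknown design terms {sorted(unknown)}")
    return dm.predictors @ vec


def generate_registry(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a ward-level registry under known hurdle-NB parameters.

    Returns the records (one row per hospital x ward, with one observed
    count column per infection type) and the :class:`SyntheticTruth` holding
    the generating coefficients and per-record true moments. Identical
    configurations (including seed) yield identical registries.

    When ``config.gamma`` is None the hurdle is disabled and counts are
    plain NB2 draws with mean mu * exposure — useful when an exactly
    exposure-proportional mean is required.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    df = _draw_covariates(config, rng)

    eta = _linear_predictor(df, config.beta)
    exposure = df[EXPOSURE_COLUMN].to_numpy(dtype=float)
    mu = np.exp(eta) * exposure  # positive-part NB mean per record

    if config.gamma is not None:
        p_pos = special.expit(_linear_predictor(df, config.gamma))
    else:
        # no hurdle: zero probability is the NB's own zero mass
        size = 1.0 / config.alpha
        p_pos = 1.0 - stats.nbinom.pmf(0, size, size / (size + mu))
    pi0 = 1.0 - p_pos

    mu_table, pi0_table = {}, {}
    for itype in config.infection_types:
        counts = sample_hurdle_nb_count(mu, config.alpha, pi0, rng)
        df[f"observed_{itype}"] = np.minimum(counts, df[EXPOSURE_COLUMN].to_numpy())
        mu_table[itype] = mu.copy()
        pi0_table[itype] = pi0.copy()

    truth = SyntheticTruth(
        beta=dict(config.beta),
        gamma=None if config.gamma is None else dict(config.gamma),
        alpha=config.alpha,
        seed=config.seed,
        mu=pd.DataFrame(mu_table),
        pi0=pd.DataFrame(pi0_table),
    )
    return df, truth


def write_registry(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as UTF-8 CSV, missing values as empty fields."""
    records.to_csv(path, index=False, na_rep="")


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read a registry CSV written by :func:`write_registry`."""
    df = pd.read_csv(path)
    for itype in INFECTION_TYPES:
        col = f"observed_{itype}"
        if col in df.columns:
            df[col] = df[col].astype(np.int64)
    return df


__all__ = [
    "ConfigError",
    "DEFAULT_BETA",
    "DEFAULT_CATEGORY_PROBS",
    "DEFAULT_GAMMA",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_registry",
    "read_registry",
    "sample_hurdle_nb_count",
    "sample_truncated_nb",
    "write_registry",
]
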