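"""Parametric prior configuration for vital rates and hyperpriors.

The informed population model takes all ancillary information (survival,
effective birth rates, emergence-curve parameters, the pre-study birth
cohort) as named parametric prior distributions supplied in
configuration -- a YAML mapping of distribution name plus parameters --
rather than as additional likelihoods.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = ["Prior", "VitalRatePriors", "load_priors", "default_priors"]

# integer codes shared with the compiled likelihood kernels
_CODES = {"beta": 0, "gamma": 1, "normal": 2, "uniform": 3, "truncnormal": 4}


@dataclasses.dataclass(frozen=True)
class Prior:
    """A univariate prior: distribution name plus two parameters.

    Supported distributions: ``beta(a, b)``, ``gamma(shape, rate)``,
    ``normal(mean, sd)``, ``uniform(lo, hi)``, ``truncnormal(mean, sd)``
    (a normal truncated to the positive half-line).
    """

    dist: str
    params: tuple[float, float]

    def __post_init__(self):
        if self.dist not in _CODES:
            raise ValueError(f"unknown prior distribution {self.dist!r}; "
                             f"choose from {sorted(_CODES)}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        a, b = self.params
        if self.dist in ("beta", "gamma") and (a <= 0 or b <= 0):
            raise ValueError(f"{self.dist} parameters must be positive")
        if self.dist in ("normal", "truncnormal") and b <= 0:
            raise ValueError("sd must be positive")
        if self.dist == "uniform" and b <= a:
            raise ValueError("uniform upper bound must exceed lower bound")

    @property
    def code(self) -> int:
        return _CODES[self.dist]

    def _frozen(self):
        a, b = self.params
        if self.dist == "beta":
            return stats.beta(a, b)
        if self.dist == "gamma":
            return stats.gamma(a, scale=1.0 / b)
        if self.dist == "normal":
            return stats.norm(a, b)
        if self.dist == "uniform":
            return stats.uniform(a, b - a)
        return stats.truncnorm(-a / b, np.inf, loc=a, scale=b)

    def logpdf(self, x: float) -> float:
        return float(self._frozen().logpdf(x))

    def rvs(self, rng: np.random.Generator, size=None):
        return self._frozen().rvs(size=size, random_state=rng)

    def mean(self) -> float:
        return float(self._frozen().mean())

    def support(self) -> tuple[float, float]:
        lo, hi = self._frozen().support()
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        return {"dist": self.dist, "params": list(self.params)}


def _half_normal_sd_from_precision(mean: float, precision: float) -> Prior:
    return Prior("truncnormal", (mean, math.sqrt(1.0 / precision)))


@dataclasses.dataclass
class VitalRatePriors:
    """Prior configuration for the 2-age-class informed population model.

    Attributes
    ----------
    b
        Effective birth rate priors, one per birth cohort: entry ``c``
        is the per-adult production of young that survive to transition
        to adults at the birth pulse of study year ``c`` (cohort 0 was
        born before the study).  ``n_years + 1`` entries are needed for
        an ``n_years`` study (the final cohort feeds juvenile abundance
        after the last pulse).
    s_ad_year
        Annual adult survival probability (scalarized over the 1 to 3+
        year age classes), shared across years.
    s_juv
        Annual juvenile (first-year) survival probability.
    mu_emerge, sd_emerge
        Emergence-curve location (days since birth at which relative
        juvenile availability reaches 0.5) and scale; one prior per
        study year.  Defaults: Uniform(150, 210) and a positive-half
        normal with mean 60 and precision 0.005.
    initial_adult
        Prior for expected adult abundance in the first modeled period;
        default Gamma(0.5, 1e-6), an approximation to Jeffreys' prior
        for a Poisson rate.
    initial_birth_cohort_bounds
        Uniform bounds for the pre-study adult abundance at the birth
        pulse preceding the study (sets the scale of cohort 0).
    """

    b: tuple[Prior, ...]
    s_ad_year: Prior
    s_juv: Prior
    mu_emerge: tuple[Prior, ...]
    sd_emerge: tuple[Prior, ...]
    initial_adult: Prior = Prior("gamma", (0.5, 1e-6))
    initial_birth_cohort_bounds: tuple[float, float] = (0.0, 1500.0)

    def validate(self, n_years: int) -> None:
        if len(self.b) != n_years + 1:
            raise ValueError(
                f"need {n_years + 1} birth-rate priors for {n_years} years, "
                f"got {len(self.b)}")
        if len(self.mu_emerge) != n_years or len(self.sd_emerge) != n_years:
            raise ValueError("mu_emerge and sd_emerge need one prior per year")
        for name, pr in (("s_ad_year", self.s_ad_year), ("s_juv", self.s_juv)):
            lo, hi = pr.support()
            if lo < 0 or hi > 1:
                raise ValueError(f"{name} prior support must lie within [0, 1]")
        lo, hi = self.initial_birth_cohort_bounds
        if not (0 <= lo < hi):
            raise ValueError("initial_birth_cohort_bounds must satisfy 0 <= lo < hi")

    def to_dict(self) -> dict:
        return {
            "b": [p.to_dict() for p in self.b],
            "s_ad_year": self.s_ad_year.to_dict(),
            "s_juv": self.s_juv.to_dict(),
            "mu_emerge": [p.to_dict() for p in self.mu_emerge],
            "sd_emerge": [p.to_dict() for p in self.sd_emerge],
            "initial_adult": self.initial_adult.to_dict(),
            "initial_birth_cohort_bounds": list(self.initial_birth_cohort_bounds),
        }


def _parse_prior(obj) -> Prior:
    if isinstance(obj, Prior):
        return obj
    if not isinstance(obj, dict) or "dist" not in obj or "params" not in obj:
        raise ValueError(f"prior entries need 'dist' and 'params': {obj!r}")
    return Prior(obj["dist"], tuple(obj["params"]))


def _parse_prior_list(obj, n: int, what: str) -> tuple[Prior, ...]:
    if isinstance(obj, (dict, Prior)):  # single prior replicated
        return tuple([_parse_prior(obj)] * n)
    out = tuple(_parse_prior(o) for o in obj)
    if len(out) != n:
        raise ValueError(f"{what}: expected {n} priors, got {len(out)}")
    return out


def load_priors(source, n_years: int) -> VitalRatePriors:
    """Load a :class:`VitalRatePriors` from a YAML file path or mapping.

    Missing components are rejected with the component named; single
    priors may be given where a per-year (or per-cohort) list is
    expected, in which case they are replicated.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        with open(source) as fh:  # type: ignore[arg-type]
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    for key in ("b", "s_ad_year", "s_juv"):
        if key not in cfg:
            raise ValueError(f"prior configuration missing component {key!r}")
    kwargs = dict(
        b=_parse_prior_list(cfg["b"], n_years + 1, "b"),
        s_ad_year=_parse_prior(cfg["s_ad_year"]),
        s_juv=_parse_prior(cfg["s_juv"]),
        mu_emerge=_parse_prior_list(
            cfg.get("mu_emerge", {"dist": "uniform", "params": [150, 210]}),
            n_years, "mu_emerge"),
        sd_emerge=_parse_prior_list(
            cfg.get("sd_emerge",
                    _half_normal_sd_from_precision(60.0, 0.005).to_dict()),
            n_years, "sd_emerge"),
    )
    if "initial_adult" in cfg:
        kwargs["initial_adult"] = _parse_prior(cfg["initial_adult"])
    if "initial_birth_cohort_bounds" in cfg:
        kwargs["initial_birth_cohort_bounds"] = tuple(
            float(v) for v in cfg["initial_birth_cohort_bounds"])
    priors = VitalRatePriors(**kwargs)
    priors.validate(n_years)
    return priors


def default_priors(
    n_years: int,
    b_mean: float = 0.7,
    b_sd: float = 0.15,
    s_ad_mean: float = 0.7,
    s_ad_conc: float = 40.0,
    s_juv_mean: float = 0.25,
    s_juv_conc: float = 40.0,
    cohort_bounds: tuple[float, float] = (0.0, 1500.0),
) -> VitalRatePriors:
    """Moderately informative priors for simulation and examples.

    Beta priors for survival are parameterized by mean and concentration
    (a + b); the effective birth rate gets a positive-half normal.
    """
    sad = Prior("beta", (s_ad_mean * s_ad_conc, (1 - s_ad_mean) * s_ad_conc))
    sjuv = Prior("beta", (s_juv_mean * s_juv_conc, (1 - s_juv_mean) * s_juv_conc))
    b = Prior("truncnormal", (b_mean, b_sd))
    return VitalRatePriors(
        b=tuple([b] * (n_years + 1)),
        s_ad_year=sad,
        s_juv=sjuv,
        mu_emerge=tuple([Prior("uniform", (150.0, 210.0))] * n_years),
        sd_emerge=tuple([_half_normal_sd_from_precision(60.0, 0.005)] * n_years),
        initial_birth_cohort_bounds=cohort_bounds,
    )
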