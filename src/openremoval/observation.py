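"""Zero-inflated removal observation model shared by both dynamics models.

Within a primary period, each day's removals are approximated as Poisson
with mean ``lambda * phi * pi_j * z``, where ``lambda`` is the expected
superpopulation, ``phi`` the availability bias (the probability a
superpopulation member is present and catchable in the period), ``pi_j``
the geometric removal-cell probability for day ``j`` given the daily
capture probability ``p``, and ``z`` the Bernoulli daily temporal
suitability (its marginal probability ``zprob`` yields the zero-inflated
form used for fitting).

Daily capture probability comes from trap effort: with capture efficiency
``theta`` (per trap per day) and ``traps`` independent traps,
``p = 1 - (1 - theta)**traps``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "daily_capture_prob",
    "removal_cell_probs",
    "expected_daily_removals",
    "zip_loglik",
    "period_effective_prob",
    "annual_effective_prob",
]


def daily_capture_prob(theta, traps):
    """Daily capture probability of the whole trap array.

    ``1 - (1 - theta)**traps``, computed as ``-expm1(traps*log1p(-theta))``
    to avoid underflow at large effort.  ``theta`` must lie in [0, 1];
    zero effort gives probability 0.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    traps = np.asarray(traps, dtype=float)
    if np.any(traps < 0):
        raise ValueError("traps must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(theta >= 1.0, np.where(traps > 0, 1.0, 0.0),
                       -np.expm1(traps * np.log1p(-np.minimum(theta, 1 - 1e-300))))
    out = np.where(traps == 0, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def removal_cell_probs(p: float, n_days: int) -> np.ndarray:
    """Geometric removal-cell probabilities ``pi_j = p*(1-p)**(j-1)``.

    Element ``j`` is the probability an animal available all period is
    first (and hence permanently) removed on day ``j``; the vector sums
    to ``1 - (1-p)**n_days``, the within-period removal probability of
    an available animal.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    j = np.arange(n_days, dtype=float)
    return p * (1.0 - p) ** j


def expected_daily_removals(lam, phi, pi_j, z_or_zprob):
    """Poisson mean for one day's removals: ``lam*phi*pi_j*z``.

    With the binary suitability indicator ``z`` this is the conditional
    mean; with the marginal suitability probability ``zprob`` it is the
    marginal mean used for expectations and discrepancy statistics.
    """
    return lam * phi * pi_j * z_or_zprob


def zip_loglik(y, mu, zprob):
    """Pointwise zero-inflated Poisson log-likelihood.

    ``log[(1-zprob)*1{y=0} + zprob*Poisson(y; mu)]`` -- the suitability
    indicator marginalized out, as used for WAIC and for samplers
    without discrete latent states.  ``mu = 0`` with ``y > 0`` returns
    ``-inf`` (an impossible observation under the parameters) rather
    than raising.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    zprob = np.asarray(zprob, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")

    y_f = y.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpois = np.where(
            (mu == 0) & (y_f > 0),
            -np.inf,
            y_f * np.log(np.where(mu > 0, mu, 1.0)) - mu
            - np.vectorize(math.lgamma)(y_f + 1.0),
        )
        out = np.where(
            y_f == 0,
            np.log((1.0 - zprob) + zprob * np.exp(-mu)),
            np.log(np.where(zprob > 0, zprob, 1.0)) + np.where(zprob > 0, logpois, -np.inf),
        )
    if out.ndim == 0:
        return float(out)
    return out


def period_effective_prob(p, zprob, phi, n_days):
    """Effective removal probability of a superpopulation member in a period.

    ``pset = 1 - (1 - p*zprob*phi)**n_days``: the chance an animal whose
    home range overlaps the trapping area is removed during the period,
    integrating daily capture, temporal suitability, and availability.
    """
    p = np.asarray(p, dtype=float)
    daily = p * np.asarray(zprob, dtype=float) * np.asarray(phi, dtype=float)
    with np.errstate(divide="ignore"):  # daily == 1 -> pset == 1 exactly
        out = -np.expm1(np.asarray(n_days, dtype=float)
                        * np.log1p(-np.minimum(daily, 1.0)))
    if out.ndim == 0:
        return float(out)
    return out


def annual_effective_prob(psets) -> float:
    """Annual removal probability ``pyear = 1 - prod(1 - pset_t)``.

    The removal probability over a year for an animal present in the
    superpopulation throughout; an empty vector gives 0.
    """
    psets = np.asarray(psets, dtype=float)
    if psets.size == 0:
        return 0.0
    return float(-np.expm1(np.sum(np.log1p(-np.minimum(psets, 1.0)))))
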