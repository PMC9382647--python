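"""Goodness-of-fit and model comparison.

Fit is assessed by a posterior predictive check with the Freeman-Tukey
discrepancy: for each retained draw the discrepancy of the observed
daily removals against their expected values is compared with that of
a replicate data set simulated from the same draw.  The Bayesian
p-value (fraction of draws whose replicate discrepancy exceeds the
observed one) is near 0.5 and the variance-inflation ratio c-hat
(mean observed over mean replicated discrepancy) near 1.0 under a
well-fitting model.

Model comparison uses WAIC with one (year, period, day) observation as
the pointwise unit, and a parsimony rule: the designated simpler model
is preferred when its WAIC is within 0.5 units of the minimum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp

__all__ = ["FitDiagnostics", "WAICResult", "freeman_tukey",
           "posterior_predictive_check", "waic", "compare_models"]


@dataclasses.dataclass
class FitDiagnostics:
    bayes_p: float
    c_hat: float
    T_obs: np.ndarray
    T_rep: np.ndarray

    def to_dict(self) -> dict:
        return {"bayes_p": self.bayes_p, "c_hat": self.c_hat,
                "n_draws": int(len(self.T_obs))}


@dataclasses.dataclass
class WAICResult:
    lppd: float
    p_waic: float

    @property
    def waic(self) -> float:
        return -2.0 * (self.lppd - self.p_waic)

    def to_dict(self) -> dict:
        return {"lppd": self.lppd, "p_waic": self.p_waic, "waic": self.waic}


def freeman_tukey(observed, expected) -> float:
    """Freeman-Tukey discrepancy ``sum_i (sqrt(obs_i) - sqrt(exp_i))**2``."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have equal length")
    if (observed < 0).any() or (expected < 0).any():
        raise ValueError("counts and expectations must be non-negative")
    return float(np.sum((np.sqrt(observed) - np.sqrt(expected)) ** 2))


def posterior_predictive_check(model, result, rng=None,
                               max_draws: int = 1000) -> FitDiagnostics:
    """Freeman-Tukey posterior predictive check of a fitted model.

    For each (thinned) draw: the observed discrepancy uses the
    marginal expected daily removals ``zprob * mu``; the replicate is
    a full generative re-draw (suitability re-sampled from ``zprob``,
    counts from Poisson).  Ties between replicate and observed
    discrepancies count half toward the Bayesian p-value.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    draws = result.stacked()
    S = draws.shape[0]
    idx = np.linspace(0, S - 1, min(S, max_draws)).astype(int)
    y = model.layout.y_obs
    T_obs = np.empty(len(idx))
    T_rep = np.empty(len(idx))
    for k, i in enumerate(idx):
        mu, zp = model.daily_means(draws[i])
        expected = zp * mu
        T_obs[k] = freeman_tukey(y, expected)
        z = rng.random(mu.shape) < zp
        y_rep = rng.poisson(mu * z)
        T_rep[k] = freeman_tukey(y_rep, expected)
    gt = np.mean(T_rep > T_obs)
    ties = np.mean(T_rep == T_obs)
    bayes_p = float(gt + 0.5 * ties)
    c_hat = float(np.mean(T_obs) / np.mean(T_rep))
    return FitDiagnostics(bayes_p=bayes_p, c_hat=c_hat, T_obs=T_obs, T_rep=T_rep)


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC from an ``(n_draws, n_points)`` pointwise log-likelihood array.

    ``lppd = sum_i log mean_s exp(ll[s, i])`` (stable log-sum-exp) and
    ``p_waic = sum_i var_s ll[s, i]``; ``waic = -2 (lppd - p_waic)``.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (n_draws, n_points)")
    S = ll.shape[0]
    all_ninf = np.all(np.isneginf(ll), axis=0)
    if all_ninf.any():
        raise ValueError(
            f"data point {int(np.argmax(all_ninf))} has zero likelihood "
            "in every draw")
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=0))) if S > 1 else 0.0
    return WAICResult(lppd=lppd, p_waic=p_waic)


def compare_models(waics: dict[str, WAICResult], simpler: str | None = None,
                   tolerance: float = 0.5) -> str:
    """Select the lowest-WAIC model, preferring the simpler one on ties.

    The designated ``simpler`` model wins whenever its WAIC is within
    ``tolerance`` (0.5 units) of the minimum; comparison is meaningful
    within a model class only.
    """
    if len(waics) < 2:
        raise ValueError("need at least two models to compare")
    scores = {name: w.waic for name, w in waics.items()}
    best = min(scores, key=scores.get)
    if simpler is not None and simpler in scores:
        if scores[simpler] - scores[best] < tolerance:
            return simpler
    return best
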