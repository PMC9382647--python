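"""Posterior sampling, convergence diagnostics, and summaries.

Any model object exposing ``n_params``, ``logpost(theta)``,
``initial_point(rng)`` and ``initial_scales()`` can be fitted; models
that additionally carry a compiled ``kernel``/``kernel_args`` pair (the
removal models here) are sampled entirely in compiled code.  Sampling
uses coordinatewise random-walk Metropolis with per-coordinate scale
adaptation during warm-up -- the same general-purpose strategy as the
Gibbs/slice samplers these hierarchical models are usually fitted with.

Convergence is judged by rank-normalized split-chain R-hat (< 1.1).
Point estimates are posterior medians; interval summaries use the 95%
highest-posterior-density interval for abundance-type quantities and
central quantile intervals otherwise.
"""

from __future__ import annotations

import dataclasses
import math

import arviz as az
import numpy as np
import pandas as pd

from . import _kernels

__all__ = ["MCMCConfig", "PAPER_MCMC", "DEFAULT_TEST_MCMC", "PosteriorResult",
           "fit", "hpd_interval", "rhat", "summarize"]

RHAT_THRESHOLD = 1.1


@dataclasses.dataclass(frozen=True)
class MCMCConfig:
    """Chain-length settings.

    ``n_adapt`` and ``n_burn`` sweeps are discarded warm-up (proposal
    scales adapt during both); ``n_iter`` post-warm-up sweeps are
    retained at rate ``1/thin`` in each of ``n_chains`` chains.
    """

    n_adapt: int = 1000
    n_burn: int = 2000
    n_iter: int = 2000
    thin: int = 1
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self):
        for f in ("n_adapt", "n_burn", "n_iter", "thin", "n_chains"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")

    @property
    def retained_draws(self) -> int:
        """Total retained draws across chains."""
        return self.n_chains * (self.n_iter // self.thin)


#: The full production profile: 10k adaptation, 100k burn-in, 200k
#: retained at thin 10 in each of three chains -- 60,000 draws.
PAPER_MCMC = MCMCConfig(n_adapt=10_000, n_burn=100_000, n_iter=200_000,
                        thin=10, n_chains=3)

#: Scaled-down profile for tests and desk-scale studies.
DEFAULT_TEST_MCMC = MCMCConfig(n_adapt=1000, n_burn=2000, n_iter=2000,
                               thin=1, n_chains=3)


@dataclasses.dataclass
class PosteriorResult:
    """Retained draws plus convergence diagnostics.

    ``draws`` has shape ``(n_chains, n_kept, n_params)``; ``rhat`` is
    per-parameter rank-normalized split-chain R-hat and ``converged``
    is True when every R-hat is below 1.1.
    """

    draws: np.ndarray
    logpost: np.ndarray
    param_names: list[str]
    rhat: np.ndarray
    converged: bool
    accept_rate: np.ndarray
    config: MCMCConfig

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def stacked(self) -> np.ndarray:
        """All chains concatenated: ``(n_draws, n_params)``."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def get(self, name: str) -> np.ndarray:
        return self.stacked()[:, self.param_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Long format: parameter, chain, iteration, value."""
        nc, nk, d = self.draws.shape
        rows = {
            "parameter": np.repeat(self.param_names, nc * nk),
            "chain": np.tile(np.repeat(np.arange(nc), nk), d),
            "iteration": np.tile(np.arange(nk), nc * d),
            "value": np.concatenate(
                [self.draws[:, :, i].ravel() for i in range(d)]),
        }
        return pd.DataFrame(rows)


def rhat(chains: np.ndarray) -> float:
    """Rank-normalized split-chain potential scale reduction factor."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be (n_chains, n_draws)")
    if np.allclose(chains, chains.flat[0]):
        return 1.0  # constant across all chains: nothing to diagnose
    return float(az.rhat(chains))


def _python_mwg(logpost, theta0, scale0, mult_mask,
                shift_lam, shift_phi, shift_start,
                shift_w, other_idx, other_w, other_start,
                rs_lam, rs_phi, rs_mu, rs_cumr, rs_start, rs_anchor, rs_sd,
                n_adapt, n_burn, n_iter, thin, seed):
    """Reference python implementation of the adaptive MwG sweep
    (mirrors the compiled sampler, including the product-preserving
    ridge shift moves)."""
    rng = np.random.default_rng(seed)
    d = len(theta0)
    nblk = len(shift_start) - 1
    theta = np.array(theta0, dtype=float)
    log_scale = np.log(np.asarray(scale0, dtype=float))
    blk_log_scale = np.full(nblk, math.log(10.0))
    nrs = len(rs_start) - 1
    rs_log_scale = np.full(nrs, math.log(0.3))
    rs_batch_acc = np.zeros(nrs)
    lp = logpost(theta)
    warm = n_adapt + n_burn
    total = warm + n_iter
    n_keep = n_iter // thin
    draws = np.empty((n_keep, d))
    lps = np.empty(n_keep)
    batch_acc = np.zeros(d)
    blk_batch_acc = np.zeros(nblk)
    acc_tot = np.zeros(d)
    kept = 0
    batch = 0
    for it in range(total):
        for i in range(d):
            old = theta[i]
            if mult_mask[i]:
                theta[i] = old * math.exp(
                    math.exp(log_scale[i]) * rng.standard_normal())
                corr = math.log(theta[i] / old)
            else:
                theta[i] = old + math.exp(log_scale[i]) * rng.standard_normal()
                corr = 0.0
            lp_new = logpost(theta)
            if np.isfinite(lp_new) and \
                    math.log(rng.random()) < lp_new - lp + corr:
                lp = lp_new
                batch_acc[i] += 1
                acc_tot[i] += 1
            else:
                theta[i] = old
        for k in range(nblk):
            delta = math.exp(blk_log_scale[k]) * rng.standard_normal()
            sl = slice(shift_start[k], shift_start[k + 1])
            li, pi, w = shift_lam[sl], shift_phi[sl], shift_w[sl]
            ol = slice(other_start[k], other_start[k + 1])
            oi, ow = other_idx[ol], other_w[ol]
            lam_old = theta[li]
            lam_new = lam_old + w * delta
            if np.any(lam_new <= 0):
                continue
            paired = pi >= 0
            old_phi = theta[pi[paired]]
            old_other = theta[oi]
            ratio = lam_old[paired] / lam_new[paired]
            theta[li] = lam_new
            theta[pi[paired]] = old_phi * ratio
            theta[oi] = old_other + ow * delta
            log_jac = float(np.sum(np.log(ratio)))
            lp_new = logpost(theta)
            if np.isfinite(lp_new) and \
                    math.log(rng.random()) < lp_new - lp + log_jac:
                lp = lp_new
                blk_batch_acc[k] += 1
            else:
                theta[li] = lam_old
                theta[pi[paired]] = old_phi
                theta[oi] = old_other
        for k in range(nrs):
            eps = math.exp(rs_log_scale[k]) * rng.standard_normal()
            a = math.exp(eps)
            sl = slice(rs_start[k], rs_start[k + 1])
            li, pi, mi, cr = rs_lam[sl], rs_phi[sl], rs_mu[sl], rs_cumr[sl]
            anchor = theta[rs_anchor[k]]
            targets = anchor - cr + np.cumsum(theta[mi])
            lam_old = theta[li]
            lam_new = a * lam_old + (1.0 - a) * targets
            if np.any(lam_new <= 0):
                continue
            paired = pi >= 0
            old_phi = theta[pi[paired]]
            sdi = rs_sd[k]
            sd_old = theta[sdi]
            ratio = lam_old[paired] / lam_new[paired]
            theta[li] = lam_new
            theta[pi[paired]] = old_phi * ratio
            theta[sdi] = sd_old * a
            log_jac = (len(li) + 1) * eps + float(np.sum(np.log(ratio)))
            lp_new = logpost(theta)
            if np.isfinite(lp_new) and \
                    math.log(rng.random()) < lp_new - lp + log_jac:
                lp = lp_new
                rs_batch_acc[k] += 1
            else:
                theta[li] = lam_old
                theta[pi[paired]] = old_phi
                theta[sdi] = sd_old
        if it < warm and (it + 1) % 50 == 0:
            batch += 1
            step = min(0.1, 1.0 / math.sqrt(batch))
            log_scale += np.where(batch_acc / 50.0 > 0.44, step, -step)
            batch_acc[:] = 0
            if nblk:
                blk_log_scale += np.where(blk_batch_acc / 50.0 > 0.44,
                                          step, -step)
                blk_batch_acc[:] = 0
            if nrs:
                rs_log_scale += np.where(rs_batch_acc / 50.0 > 0.44,
                                         step, -step)
                rs_batch_acc[:] = 0
        if it >= warm and (it - warm) % thin == thin - 1:
            draws[kept] = theta
            lps[kept] = lp
            kept += 1
    return draws, lps, acc_tot / total


def _pack_blocks(blocks):
    """Flatten ridge blocks.

    Each block is ``(lam_idx, phi_idx)`` (a level move, unit weights)
    or ``(lam_idx, phi_idx, weights, other_idx, other_w)`` (a weighted
    tilt move carrying plain additive coordinates along).
    """
    flat_lam, flat_phi, flat_w = [], [], []
    flat_oi, flat_ow = [], []
    start, ostart = [0], [0]
    for blk in blocks:
        if len(blk) == 2:
            lam_idx, phi_idx = blk
            w = np.ones(len(lam_idx))
            oi, ow = (), ()
        else:
            lam_idx, phi_idx, w, oi, ow = blk
        if len(lam_idx) != len(phi_idx) or len(lam_idx) != len(w):
            raise ValueError("ridge block index arrays must have equal length")
        flat_lam.extend(int(i) for i in lam_idx)
        flat_phi.extend(int(i) for i in phi_idx)
        flat_w.extend(float(x) for x in w)
        flat_oi.extend(int(i) for i in oi)
        flat_ow.extend(float(x) for x in ow)
        start.append(len(flat_lam))
        ostart.append(len(flat_oi))
    return (np.array(flat_lam, dtype=np.int64),
            np.array(flat_phi, dtype=np.int64),
            np.array(start, dtype=np.int64),
            np.array(flat_w, dtype=float),
            np.array(flat_oi, dtype=np.int64),
            np.array(flat_ow, dtype=float),
            np.array(ostart, dtype=np.int64))


def _pack_conjugate(blocks):
    """Flatten conjugate-mean blocks: each a dict with keys param,
    prior_mu, prior_sd, sd_idx, obs_i, obs_j, const."""
    params, pmu, psd, sdi = [], [], [], []
    oi, oj, cc, start = [], [], [], [0]
    for blk in blocks:
        params.append(int(blk["param"]))
        pmu.append(float(blk["prior_mu"]))
        psd.append(float(blk["prior_sd"]))
        sdi.append(int(blk["sd_idx"]))
        oi.extend(int(i) for i in blk["obs_i"])
        oj.extend(int(i) for i in blk["obs_j"])
        cc.extend(float(x) for x in blk["const"])
        start.append(len(oi))
    return (np.array(params, dtype=np.int64), np.array(pmu, dtype=float),
            np.array(psd, dtype=float), np.array(sdi, dtype=np.int64),
            np.array(oi, dtype=np.int64), np.array(oj, dtype=np.int64),
            np.array(cc, dtype=float), np.array(start, dtype=np.int64))


def _pack_rescale(blocks):
    """Flatten rescale (funnel) blocks: each is a dict with keys
    lam, phi, mu, cumr, anchor, sd."""
    flat_lam, flat_phi, flat_mu, flat_cumr = [], [], [], []
    start, anchors, sds = [0], [], []
    for blk in blocks:
        n = len(blk["lam"])
        if not (len(blk["phi"]) == len(blk["mu"]) == len(blk["cumr"]) == n):
            raise ValueError("rescale block arrays must have equal length")
        flat_lam.extend(int(i) for i in blk["lam"])
        flat_phi.extend(int(i) for i in blk["phi"])
        flat_mu.extend(int(i) for i in blk["mu"])
        flat_cumr.extend(float(x) for x in blk["cumr"])
        start.append(len(flat_lam))
        anchors.append(int(blk["anchor"]))
        sds.append(int(blk["sd"]))
    return (np.array(flat_lam, dtype=np.int64),
            np.array(flat_phi, dtype=np.int64),
            np.array(flat_mu, dtype=np.int64),
            np.array(flat_cumr, dtype=float),
            np.array(start, dtype=np.int64),
            np.array(anchors, dtype=np.int64),
            np.array(sds, dtype=np.int64))


def fit(model, config: MCMCConfig = DEFAULT_TEST_MCMC,
        max_init_attempts: int = 50) -> PosteriorResult:
    """Sample the joint posterior of a model specification by MCMC.

    Chains are seeded deterministically from ``config.seed`` and are
    exactly reproducible.  Initial points with non-finite posterior
    density are redrawn up to ``max_init_attempts`` times before the
    fit is rejected.
    """
    d = model.n_params
    n_keep = config.n_iter // config.thin
    draws = np.empty((config.n_chains, n_keep, d))
    lps = np.empty((config.n_chains, n_keep))
    acc = np.empty((config.n_chains, d))
    use_kernel = getattr(model, "kernel", None) is not None
    if hasattr(model, "mult_mask"):
        mult_mask = np.asarray(model.mult_mask(), dtype=np.bool_)
    else:
        mult_mask = np.zeros(d, dtype=np.bool_)
    blocks = model.ridge_blocks() if hasattr(model, "ridge_blocks") else []
    (shift_lam, shift_phi, shift_start, shift_w,
     other_idx, other_w, other_start) = _pack_blocks(blocks)
    rblocks = (model.rescale_blocks()
               if hasattr(model, "rescale_blocks") else [])
    (rs_lam, rs_phi, rs_mu, rs_cumr,
     rs_start, rs_anchor, rs_sd) = _pack_rescale(rblocks)
    cblocks = (model.conjugate_mean_blocks()
               if hasattr(model, "conjugate_mean_blocks") else [])
    (cg_param, cg_prior_mu, cg_prior_sd, cg_sd_idx,
     cg_obs_i, cg_obs_j, cg_const, cg_start) = _pack_conjugate(cblocks)

    for c in range(config.n_chains):
        chain_seed = (config.seed * 7919 + 104729 * c + 1) % (2**31 - 1)
        rng = np.random.default_rng(chain_seed)
        theta0 = None
        for _ in range(max_init_attempts):
            cand = np.asarray(model.initial_point(rng), dtype=float)
            if np.isfinite(model.logpost(cand)):
                theta0 = cand
                break
        if theta0 is None:
            raise RuntimeError(
                f"no finite starting point found in {max_init_attempts} "
                f"attempts for chain {c}; last log-posterior was "
                f"{model.logpost(cand)!r}")
        scales = np.asarray(model.initial_scales(), dtype=float)
        if use_kernel:
            ch_draws, ch_lps, ch_acc = _kernels.run_mwg(
                model.kernel, model.kernel_args, theta0, scales, mult_mask,
                shift_lam, shift_phi, shift_start, shift_w,
                other_idx, other_w, other_start,
                rs_lam, rs_phi, rs_mu, rs_cumr, rs_start, rs_anchor, rs_sd,
                cg_param, cg_prior_mu, cg_prior_sd, cg_sd_idx,
                cg_obs_i, cg_obs_j, cg_const, cg_start,
                config.n_adapt, config.n_burn, config.n_iter, config.thin,
                chain_seed)
        else:
            ch_draws, ch_lps, ch_acc = _python_mwg(
                model.logpost, theta0, scales, mult_mask,
                shift_lam, shift_phi, shift_start, shift_w,
                other_idx, other_w, other_start,
                rs_lam, rs_phi, rs_mu, rs_cumr, rs_start, rs_anchor, rs_sd,
                config.n_adapt, config.n_burn, config.n_iter, config.thin,
                chain_seed)
        draws[c], lps[c], acc[c] = ch_draws, ch_lps, ch_acc

    rhats = np.array([rhat(draws[:, :, i]) for i in range(d)])
    converged = bool(np.all(np.nan_to_num(rhats, nan=np.inf) < RHAT_THRESHOLD))
    names = list(getattr(model, "param_names", [f"p{i}" for i in range(d)]))
    return PosteriorResult(draws=draws, logpost=lps, param_names=names,
                           rhat=rhats, converged=converged,
                           accept_rate=acc.mean(axis=0), config=config)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` draws."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    k = int(math.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[np.arange(n - k + 1)]
    lo = int(np.argmin(widths))
    return float(x[lo]), float(x[lo + k - 1])


def summarize(result: PosteriorResult,
              abundance_names: set[str] = frozenset(),
              extra_draws: dict[str, np.ndarray] | None = None,
              tail_probs: dict[str, float] | None = None,
              mass: float = 0.95) -> pd.DataFrame:
    """Posterior medians and 95% intervals for all quantities.

    Parameters whose base name (the part before any ``[`` index) is in
    ``abundance_names`` get HPD intervals; others get central quantile
    intervals.  ``extra_draws`` adds derived quantities (name ->
    ``(n_draws,)`` or ``(n_draws, k)`` array).  ``tail_probs`` maps a
    quantity name to a threshold and adds ``Pr(X > threshold)``.
    """
    items: list[tuple[str, np.ndarray]] = list(
        zip(result.param_names, result.stacked().T))
    for name, arr in (extra_draws or {}).items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            items.append((name, arr))
        else:
            for k in range(arr.shape[1]):
                items.append((f"{name}[{k}]", arr[:, k]))
    rows = []
    alpha = (1.0 - mass) / 2.0
    for name, x in items:
        base = name.split("[")[0]
        if base in abundance_names:
            lo, hi = hpd_interval(x, mass)
            kind = "hpd"
        else:
            lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
            kind = "quantile"
        row = {"parameter": name, "median": float(np.median(x)),
               "lower": float(lo), "upper": float(hi), "interval": kind}
        if tail_probs and base in tail_probs:
            thr = tail_probs[base]
            row[f"pr_gt_{thr:g}"] = float(np.mean(x > thr))
        rows.append(row)
    return pd.DataFrame(rows)
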