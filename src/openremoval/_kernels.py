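"""Compiled log-posterior kernels and the Metropolis-within-Gibbs loop.

The joint posteriors of both removal models are plain products of the
zero-inflated Poisson likelihood over sampled days with the priors on
the latent vector, so sampling needs nothing beyond a fast scalar
log-posterior.  Each model packs its data into a flat tuple of arrays
and scalars (``kernel_args``) consumed by its kernel; the sampler below
takes any such kernel and performs coordinatewise random-walk
Metropolis updates with Robbins-Monro scale adaptation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

FLOOR = 1e-6  # positivity floor for expected abundances
NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# prior building blocks (codes match openremoval.priors._CODES)


@njit(cache=True)
def _prior_logpdf(code, a, b, x):
    """Unnormalized log-density for the coded prior families."""
    if code == 0:  # beta(a, b)
        if x <= 0.0 or x >= 1.0:
            return NEG_INF
        return (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x)
    if code == 1:  # gamma(shape a, rate b)
        if x <= 0.0:
            return NEG_INF
        return (a - 1.0) * math.log(x) - b * x
    if code == 2:  # normal(mean a, sd b)
        z = (x - a) / b
        return -0.5 * z * z
    if code == 3:  # uniform(a, b)
        if x < a or x > b:
            return NEG_INF
        return 0.0
    # truncnormal(mean a, sd b) on [0, inf)
    if x < 0.0:
        return NEG_INF
    z = (x - a) / b
    return -0.5 * z * z


@njit(cache=True)
def _half_t_1_logpdf(x, scale):
    """Half-t with 1 df (half-Cauchy), unnormalized."""
    if x <= 0.0:
        return NEG_INF
    r = x / scale
    return -math.log1p(r * r)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _cholesky(a, out):
    """In-place lower Cholesky of ``a`` into ``out``; returns False if
    the matrix is not (numerically) positive definite."""
    n = a.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = a[i, j]
            for k in range(j):
                s -= out[i, k] * out[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                out[i, i] = math.sqrt(s)
            else:
                out[i, j] = s / out[j, j]
        for j in range(i + 1, n):
            out[i, j] = 0.0
    return True


# ---------------------------------------------------------------------------
# random walk trend model


@njit(cache=True)
def rw_logpost(theta_vec, args):
    """Joint log posterior of the random-walk trend removal model.

    The expected-abundance path is the sampled quantity (one positive
    value per sampled period); the random-walk steps it implies carry
    their Gaussian priors (a reparameterization with unit Jacobian
    that mixes far better under coordinatewise updates than sampling
    the steps themselves).

    Parameter vector layout (Y years, P sampled periods, K trend
    groups): theta (Y) | zprob (Y) | phi (P) | lam (P) | mu_trend (K) |
    sd_trend (Y).
    """
    (sp_year, effort, ndays, rtot, delta_idx, ybound_idx, trend_idx,
     y_obs, lgam_obs, obs_sp, obs_day,
     n_years, n_trend, sd_year, mu_trend_sd, sd_trend_scale) = args

    P = sp_year.shape[0]
    Y = n_years
    K = n_trend

    i = 0
    theta = theta_vec[i:i + Y]; i += Y
    zprob = theta_vec[i:i + Y]; i += Y
    phi = theta_vec[i:i + P]; i += P
    lam = theta_vec[i:i + P]; i += P
    mu_trend = theta_vec[i:i + K]; i += K
    sd_trend = theta_vec[i:i + Y]; i += Y

    lp = 0.0
    # vague Beta(1,1) priors: support checks only
    for y in range(Y):
        if theta[y] <= 0.0 or theta[y] >= 1.0:
            return NEG_INF
        if zprob[y] <= 0.0 or zprob[y] >= 1.0:
            return NEG_INF
    for s in range(P):
        if phi[s] <= 0.0 or phi[s] >= 1.0:
            return NEG_INF
        if lam[s] <= 0.0:
            return NEG_INF
    # Gamma(0.5, 1e-6) initial-abundance prior
    lp += _prior_logpdf(1, 0.5, 1e-6, lam[0])
    if not np.isfinite(lp):
        return NEG_INF
    for y in range(Y):
        h = _half_t_1_logpdf(sd_trend[y], sd_trend_scale)
        if not np.isfinite(h):
            return NEG_INF
        lp += h
    for k in range(K):
        z = mu_trend[k] / mu_trend_sd
        lp += -0.5 * z * z
    # Gaussian priors on the implied steps: within-year steps subtract
    # the previous period's removals; the between-year step also does,
    # so no removals drop out of the accounting
    for s in range(1, P):
        if ybound_idx[s] >= 0:
            dy = lam[s] - (lam[s - 1] - rtot[s - 1])
            z = dy / sd_year
            lp += -0.5 * z * z
        else:
            d = lam[s] - lam[s - 1] + rtot[s - 1]
            sd = sd_trend[sp_year[s]]
            z = (d - mu_trend[trend_idx[s]]) / sd
            lp += -math.log(sd) - 0.5 * z * z

    # zero-inflated Poisson likelihood over sampled days; the geometric
    # removal-cell factor is carried iteratively through each period
    o = 0
    for s in range(P):
        th = theta[sp_year[s]]
        p = -math.expm1(effort[s] * math.log1p(-th))
        zp = zprob[sp_year[s]]
        base = lam[s] * phi[s]
        run = 1.0
        for _ in range(ndays[s]):
            mu = base * p * run
            run *= 1.0 - p
            yv = y_obs[o]
            if yv == 0.0:
                lp += math.log((1.0 - zp) + zp * math.exp(-mu))
            else:
                if mu <= 0.0:
                    return NEG_INF
                lp += math.log(zp) + yv * math.log(mu) - mu - lgam_obs[o]
            o += 1
    return lp


# ---------------------------------------------------------------------------
# 2-age-class informed population model


@njit(cache=True)
def infopm_logpost(theta_vec, args):
    """Joint log posterior of the 2-age-class informed population model.

    The expected-adult path over the full period chain is the sampled
    quantity; the net-migration increment each transition implies
    carries its Normal(mu_IE, sd_IE) prior (unit-Jacobian
    reparameterization, as in the random-walk kernel).

    Parameter vector layout (Y years, P sampled periods, L chain
    positions, K net-migration groups): theta (Y) | zprob (Y) |
    phi (P) | lam_ad (L) | lam_ad0_bp (1) | b (Y+1) |
    s_ad_year (1) | s_juv (1) | mu_emerge (Y) | sd_emerge (Y) |
    mu_IE (K) | sd_IE (Y).
    """
    (chain_year, chain_period, chain_sp, cohort_idx, omega,
     sp_year, effort, ndays, rtot,
     obs_start, obs_len, y_obs, lgam_obs, obs_day,
     ie_group, ie_sdyear,
     pr_code, pr_a, pr_b,
     n_years, n_iegroup, max_period, bp_period, days_per_period,
     cohort_lo, cohort_hi, mu_ie_sd, sd_ie_scale) = args

    L = chain_year.shape[0]
    P = sp_year.shape[0]
    Y = n_years
    K = n_iegroup

    i = 0
    theta = theta_vec[i:i + Y]; i += Y
    zprob = theta_vec[i:i + Y]; i += Y
    phi = theta_vec[i:i + P]; i += P
    lam_ad_path = theta_vec[i:i + L]; i += L
    lam_ad0_bp = theta_vec[i]; i += 1
    b = theta_vec[i:i + Y + 1]; i += Y + 1
    s_ad_year = theta_vec[i]; i += 1
    s_juv = theta_vec[i]; i += 1
    mu_em = theta_vec[i:i + Y]; i += Y
    sd_em = theta_vec[i:i + Y]; i += Y
    mu_ie = theta_vec[i:i + K]; i += K
    sd_ie = theta_vec[i:i + Y]; i += Y

    lp = 0.0
    for y in range(Y):
        if theta[y] <= 0.0 or theta[y] >= 1.0:
            return NEG_INF
        if zprob[y] <= 0.0 or zprob[y] >= 1.0:
            return NEG_INF
    for s in range(P):
        if phi[s] <= 0.0 or phi[s] >= 1.0:
            return NEG_INF
    for c in range(L):
        if lam_ad_path[c] <= 0.0:
            return NEG_INF
    if s_ad_year <= 0.0 or s_ad_year > 1.0 or s_juv <= 0.0 or s_juv > 1.0:
        return NEG_INF
    if lam_ad0_bp < cohort_lo or lam_ad0_bp > cohort_hi:
        return NEG_INF
    for y in range(Y):
        if sd_em[y] <= 0.0:
            return NEG_INF

    lp += _prior_logpdf(1, 0.5, 1e-6, lam_ad_path[0])
    # configured informative priors: b (Y+1), s_ad_year, s_juv,
    # mu_emerge (Y), sd_emerge (Y) -- packed in that order
    npr = pr_code.shape[0]
    xs = np.empty(npr)
    for c in range(Y + 1):
        xs[c] = b[c]
    xs[Y + 1] = s_ad_year
    xs[Y + 2] = s_juv
    for y in range(Y):
        xs[Y + 3 + y] = mu_em[y]
        xs[Y + 3 + Y + y] = sd_em[y]
    for c in range(npr):
        v = _prior_logpdf(pr_code[c], pr_a[c], pr_b[c], xs[c])
        if not np.isfinite(v):
            return NEG_INF
        lp += v
    for k in range(K):
        z = mu_ie[k] / mu_ie_sd
        lp += -0.5 * z * z
    for y in range(Y):
        h = _half_t_1_logpdf(sd_ie[y], sd_ie_scale)
        if not np.isfinite(h):
            return NEG_INF
        lp += h

    # dynamics recursion over every period of the chain
    sad_p = s_ad_year ** (1.0 / max_period)
    bcache = np.empty(Y + 1)
    have_b = np.zeros(Y + 1, dtype=np.int64)
    c0 = cohort_idx[0]
    bcache[c0] = b[c0] * lam_ad0_bp  # cohort alive at chain start
    have_b[c0] = 1

    rjuv_cum = 0.0
    for c in range(L):
        lam_ad = lam_ad_path[c]
        y = chain_year[c]
        t = chain_period[c]
        if t == bp_period:
            # birth-pulse anniversary: record adult abundance, seed the
            # next cohort, and start a fresh juvenile removal tally
            if y + 1 <= Y:
                bcache[y + 1] = b[y + 1] * lam_ad
                have_b[y + 1] = 1
            rjuv_cum = 0.0
        co = cohort_idx[c]
        if have_b[co] == 0:
            return NEG_INF  # chain starts after the pulse with no recorded cohort
        om = omega[c]
        lamj = bcache[co] * s_juv ** ((om - max_period) / max_period) - rjuv_cum
        if lamj < 0.0:
            lamj = 0.0
        phij = _norm_cdf((days_per_period * om - mu_em[y]) / sd_em[y])

        r_ad = 0.0
        r_juv = 0.0
        s = chain_sp[c]
        if s >= 0:
            lam_catch = lam_ad + phij * lamj
            # removal allocation by the catchable age distribution
            if rtot[s] > 0.0:
                pc_ad = lam_ad / lam_catch
                r_ad = pc_ad * rtot[s]
                r_juv = rtot[s] - r_ad
            rjuv_cum += r_juv
            # combined-likelihood observation model
            th = theta[y]
            p = -math.expm1(effort[s] * math.log1p(-th))
            zp = zprob[y]
            o0 = obs_start[s]
            base = lam_catch * phi[s]
            run = 1.0
            for o in range(o0, o0 + obs_len[s]):
                mu = base * p * run
                run *= 1.0 - p
                yv = y_obs[o]
                if yv == 0.0:
                    lp += math.log((1.0 - zp) + zp * math.exp(-mu))
                else:
                    if mu <= 0.0:
                        return NEG_INF
                    lp += math.log(zp) + yv * math.log(mu) - mu - lgam_obs[o]
        if c < L - 1:
            bta = 0.0
            if chain_period[c + 1] == bp_period:
                y2 = chain_year[c + 1]
                if have_b[y2] == 0:
                    return NEG_INF
                bta = bcache[y2] - rjuv_cum
                if bta < 0.0:
                    bta = 0.0
            # implied net migration carries the Normal(mu_IE, sd_IE) prior
            ie_c = lam_ad_path[c + 1] - (lam_ad * sad_p - r_ad + bta)
            sd = sd_ie[ie_sdyear[c]]
            z = (ie_c - mu_ie[ie_group[c]]) / sd
            lp += -math.log(sd) - 0.5 * z * z
    return lp


# ---------------------------------------------------------------------------
# adaptive Metropolis-within-Gibbs


@njit(cache=True)
def run_mwg(kernel, args, theta0, scale0, mult_mask,
            shift_lam, shift_phi, shift_start,
            shift_w, other_idx, other_w, other_start,
            rs_lam, rs_phi, rs_mu, rs_cumr, rs_start, rs_anchor, rs_sd,
            cg_param, cg_prior_mu, cg_prior_sd, cg_sd_idx,
            cg_obs_i, cg_obs_j, cg_const, cg_start,
            n_adapt, n_burn, n_iter, thin, seed):
    """Coordinatewise random-walk Metropolis with scale adaptation.

    Proposal scales adapt in batches of 50 sweeps toward a 0.44
    acceptance rate during the ``n_adapt + n_burn`` warm-up sweeps and
    are frozen afterwards.  Returns the thinned post-warm-up draws,
    their log posteriors, and per-coordinate acceptance rates.

    ``shift_lam``/``shift_phi`` (with ``shift_start`` offsets) describe
    ridge moves for abundance/availability coordinates identified only
    through their product: each block proposes a common additive shift
    ``lam += delta`` with the paired availability compensated as
    ``phi' = phi * lam / (lam + delta)`` so every product -- and hence
    the likelihood and the random-walk step priors -- is preserved
    exactly.  A pair entry of -1 in ``shift_phi`` marks an abundance
    coordinate with no availability partner (an unsampled period).
    ``shift_w`` weights the shift per abundance coordinate (1 for level
    moves; a centered linear ramp for tilt moves that shear a year's
    path), and ``other_idx``/``other_w`` list plain additive
    coordinates moved with the block (the trend mean accompanying a
    tilt).  The move is accepted with the posterior ratio times the
    Jacobian ``prod lam / (lam + w*delta)`` over the compensated pairs.

    The ``rs_*`` arrays describe funnel moves that jointly rescale one
    block's random-walk step residuals and its step standard deviation
    by ``a = exp(eps)``: because residual sums telescope, the new path
    is affine in the old (``lam' = a*lam + (1-a)*(anchor - cumR +
    sum(mu))``), availability is compensated to preserve the
    likelihood, and the Jacobian is ``a^(n_moved+1)`` times the
    compensation ratios.  This lets chains traverse the narrow-sd
    funnel of the hierarchical step prior.

    The ``cg_*`` arrays describe Gaussian-mean coordinates whose full
    conditional is conjugate (a step mean with Normal prior observing
    residuals ``theta[i] - theta[j] + const`` at a common scale
    coordinate); these are updated by exact Gibbs draws each sweep.
    """
    np.random.seed(seed)
    d = theta0.shape[0]
    nblk = shift_start.shape[0] - 1
    theta = theta0.copy()
    log_scale = np.log(scale0)
    blk_log_scale = np.full(nblk, math.log(10.0))
    lp = kernel(theta, args)

    nrs = rs_start.shape[0] - 1
    rs_log_scale = np.full(nrs, math.log(0.3))
    rs_batch_acc = np.zeros(nrs)
    scratch_lam = np.empty(d)
    scratch_phi = np.empty(d)

    # adaptive-covariance (Haario-style) global proposals: the running
    # posterior covariance is learned during warm-up and frozen after,
    # letting the sampler traverse correlated directions the
    # coordinatewise and structured moves miss
    am_mean = np.zeros(d)
    am_m2 = np.zeros((d, d))
    am_n = 0
    am_chol = np.zeros((d, d))
    am_ready = False
    am_log_scale = math.log(1.0)
    am_batch_acc = 0.0
    am_per_sweep = 25

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
            # heavy-tailed scale-like coordinates move multiplicatively
            # (log-scale random walk, Jacobian log(new/old))
            if mult_mask[i]:
                theta[i] = old * math.exp(
                    math.exp(log_scale[i]) * np.random.normal())
                corr = math.log(theta[i] / old)
            else:
                theta[i] = old + math.exp(log_scale[i]) * np.random.normal()
                corr = 0.0
            lp_new = kernel(theta, args)
            if np.isfinite(lp_new) and \
                    math.log(np.random.random()) < lp_new - lp + corr:
                lp = lp_new
                batch_acc[i] += 1.0
                acc_tot[i] += 1.0
            else:
                theta[i] = old
        for k in range(nblk):
            delta = math.exp(blk_log_scale[k]) * np.random.normal()
            b0, b1 = shift_start[k], shift_start[k + 1]
            o0, o1 = other_start[k], other_start[k + 1]
            ok = True
            log_jac = 0.0
            for q in range(b0, b1):
                li = shift_lam[q]
                if theta[li] + shift_w[q] * delta <= 0.0:
                    ok = False
                    break
            if not ok:
                continue
            for q in range(b0, b1):
                li = shift_lam[q]
                pi = shift_phi[q]
                lam_old = theta[li]
                theta[li] = lam_old + shift_w[q] * delta
                if pi >= 0:
                    theta[pi] *= lam_old / theta[li]
                    log_jac += math.log(lam_old / theta[li])
            for q in range(o0, o1):
                theta[other_idx[q]] += other_w[q] * delta
            lp_new = kernel(theta, args)
            if np.isfinite(lp_new) and \
                    math.log(np.random.random()) < lp_new - lp + log_jac:
                lp = lp_new
                blk_batch_acc[k] += 1.0
            else:
                for q in range(b0, b1):
                    li = shift_lam[q]
                    pi = shift_phi[q]
                    lam_new = theta[li]
                    theta[li] = lam_new - shift_w[q] * delta
                    if pi >= 0:
                        theta[pi] *= lam_new / theta[li]
                for q in range(o0, o1):
                    theta[other_idx[q]] -= other_w[q] * delta
        for k in range(nrs):
            eps = math.exp(rs_log_scale[k]) * np.random.normal()
            a = math.exp(eps)
            b0, b1 = rs_start[k], rs_start[k + 1]
            anchor = theta[rs_anchor[k]]
            musum = 0.0
            log_jac = 0.0
            ok = True
            nmoved = 0
            for q in range(b0, b1):
                musum += theta[rs_mu[q]]
                target = anchor - rs_cumr[q] + musum
                li = rs_lam[q]
                lam_old = theta[li]
                lam_new = a * lam_old + (1.0 - a) * target
                if lam_new <= 0.0:
                    ok = False
                    break
                scratch_lam[li] = lam_old
                theta[li] = lam_new
                log_jac += eps
                pi = rs_phi[q]
                if pi >= 0:
                    scratch_phi[pi] = theta[pi]
                    theta[pi] *= lam_old / lam_new
                    log_jac += math.log(lam_old / lam_new)
                nmoved = q + 1
            if ok:
                sdi = rs_sd[k]
                sd_old = theta[sdi]
                theta[sdi] = sd_old * a
                log_jac += eps
                lp_new = kernel(theta, args)
                if np.isfinite(lp_new) and \
                        math.log(np.random.random()) < lp_new - lp + log_jac:
                    lp = lp_new
                    rs_batch_acc[k] += 1.0
                else:
                    theta[sdi] = sd_old
                    for q in range(b0, b1):
                        theta[rs_lam[q]] = scratch_lam[rs_lam[q]]
                        if rs_phi[q] >= 0:
                            theta[rs_phi[q]] = scratch_phi[rs_phi[q]]
            else:
                for q in range(b0, nmoved):
                    theta[rs_lam[q]] = scratch_lam[rs_lam[q]]
                    if rs_phi[q] >= 0:
                        theta[rs_phi[q]] = scratch_phi[rs_phi[q]]
        ncg = cg_param.shape[0]
        for k in range(ncg):
            sd = theta[cg_sd_idx[k]]
            b0, b1 = cg_start[k], cg_start[k + 1]
            n_obs_k = b1 - b0
            ssum = 0.0
            for q in range(b0, b1):
                ssum += theta[cg_obs_i[q]] - theta[cg_obs_j[q]] + cg_const[q]
            prec = n_obs_k / (sd * sd) + 1.0 / (cg_prior_sd[k] * cg_prior_sd[k])
            mean = (ssum / (sd * sd)
                    + cg_prior_mu[k] / (cg_prior_sd[k] * cg_prior_sd[k])) / prec
            theta[cg_param[k]] = mean + np.random.normal() / math.sqrt(prec)
        if ncg > 0:
            lp = kernel(theta, args)
        if am_ready:
            for _ in range(am_per_sweep):
                stepv = np.random.normal(0.0, 1.0, d)
                prop = theta + math.exp(am_log_scale) * (am_chol @ stepv)
                lp_new = kernel(prop, args)
                if np.isfinite(lp_new) and \
                        math.log(np.random.random()) < lp_new - lp:
                    theta[:] = prop
                    lp = lp_new
                    am_batch_acc += 1.0
        if it < warm:
            # accumulate running mean / covariance (Welford)
            am_n += 1
            w_new = 1.0 / am_n
            delta_v = theta - am_mean
            am_mean += w_new * delta_v
            am_m2 += np.outer(delta_v, theta - am_mean)
            if it >= 300 and (it + 1) % 100 == 0 and am_n > 2 * d:
                cov = am_m2 / (am_n - 1)
                c = 2.38 * 2.38 / d
                for i in range(d):
                    cov[i, i] += 1e-10 + 1e-6 * cov[i, i]
                if _cholesky(c * cov, am_chol):
                    am_ready = True
        if it < warm and (it + 1) % 50 == 0:
            if am_ready:
                rate = am_batch_acc / (50.0 * am_per_sweep)
                if rate > 0.234:
                    am_log_scale += min(0.1, 1.0 / math.sqrt(batch + 1))
                else:
                    am_log_scale -= min(0.1, 1.0 / math.sqrt(batch + 1))
                am_batch_acc = 0.0
            batch += 1
            step = min(0.1, 1.0 / math.sqrt(batch))
            for i in range(d):
                if batch_acc[i] / 50.0 > 0.44:
                    log_scale[i] += step
                else:
                    log_scale[i] -= step
                batch_acc[i] = 0.0
            for k in range(nblk):
                if blk_batch_acc[k] / 50.0 > 0.44:
                    blk_log_scale[k] += step
                else:
                    blk_log_scale[k] -= step
                blk_batch_acc[k] = 0.0
            for k in range(nrs):
                if rs_batch_acc[k] / 50.0 > 0.44:
                    rs_log_scale[k] += step
                else:
                    rs_log_scale[k] -= step
                rs_batch_acc[k] = 0.0
        if it >= warm and (it - warm) % thin == thin - 1:
            draws[kept] = theta
            lps[kept] = lp
            kept += 1
    return draws, lps, acc_tot / total
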