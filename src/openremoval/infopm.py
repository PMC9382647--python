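"""2-age-class informed population model (InfoPM).

An explicit "adult" class (all animals one year and older, scalarized
from the underlying age-structured matrix model) evolves between
primary periods by per-period survival, net migration, removal of its
allocated share of the observed catch, and a single annual birth-pulse
recruitment.  An implicit juvenile cohort is predicted each period from
the effective birth cohort, annual juvenile survival raised to a
periods-since-birth exponent, and the cumulative juvenile removals.
Juveniles become catchable gradually through a cumulative-normal
emergence curve for their availability relative to adults; the combined
likelihood for the unstructured removal counts uses the catchable total
``lam_ad + phi_juv * lam_juv``.

All ancillary information (vital rates, emergence parameters, the
pre-study cohort scale) enters as informative priors, keeping a single
likelihood -- an informed rather than integrated population model.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from . import _kernels, observation
from ._kernels import FLOOR
from .design import SEASONS, RemovalSeries, StudyDesign
from ._packing import build_layout
from .priors import VitalRatePriors

__all__ = [
    "scalarize_survival", "juvenile_availability", "juvenile_abundance",
    "catchable_fraction", "allocate_removals", "adult_transition",
    "birth_transition", "combined_expected_removals", "corrected_rates",
    "build_infopm_model", "InfoPMModel", "project_no_removal",
]


# ---------------------------------------------------------------------------
# elementary operations


def scalarize_survival(s_annual: float, max_period: int) -> float:
    """Per-period survival from annual survival: ``s_annual**(1/max_period)``."""
    if not 0.0 < s_annual <= 1.0:
        raise ValueError("annual survival must lie in (0, 1]")
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    return float(s_annual ** (1.0 / max_period))


def juvenile_availability(days_since_birth, mu_emerge, sd_emerge):
    """Relative juvenile availability: cumulative-normal emergence curve.

    ``Phi((days_since_birth - mu_emerge) / sd_emerge)`` -- the fraction
    of the juvenile cohort catchable at adult rates, 0.5 exactly at the
    location parameter.
    """
    sd = np.asarray(sd_emerge, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd_emerge must be positive")
    out = stats.norm.cdf((np.asarray(days_since_birth, dtype=float)
                          - np.asarray(mu_emerge, dtype=float)) / sd)
    return float(out) if np.ndim(out) == 0 else out


def juvenile_abundance(B: float, s_juv: float, omega: float,
                       r_juv_cum: float, max_period: int) -> float:
    """Expected juveniles ``omega`` periods after the birth pulse.

    ``B * s_juv**((omega - max_period)/max_period) - r_juv_cum``,
    floored at zero.  The exponent runs from -1 at the pulse (the full
    cohort before first-year mortality, ``B / s_juv``) to 0 after a
    whole year cycle (the ``B`` survivors that transition to adults).
    """
    if s_juv <= 0:
        raise ValueError("s_juv must be positive")
    if not 0 <= omega <= max_period:
        raise ValueError("omega must lie in [0, max_period]")
    if B < 0 or r_juv_cum < 0:
        raise ValueError("B and r_juv_cum must be non-negative")
    return max(B * s_juv ** ((omega - max_period) / max_period) - r_juv_cum, 0.0)


def catchable_fraction(lam_ad: float, lam_juv: float, phi_juv: float) -> float:
    """Catchable proportion ``(lam_ad + phi_juv*lam_juv)/(lam_ad + lam_juv)``.

    With both abundances zero there is nothing to correct; the fraction
    is defined as 1.
    """
    total = lam_ad + lam_juv
    if total <= 0:
        return 1.0
    return (lam_ad + phi_juv * lam_juv) / total


def allocate_removals(lam_ad: float, lam_juv: float, phi_juv: float,
                      total_removals: float) -> tuple[float, float]:
    """Split total removals by the catchable age distribution.

    The adult share is ``pc_ad = lam_ad / (lam_ad + phi_juv*lam_juv)``;
    the two shares sum to the total exactly.
    """
    if total_removals < 0:
        raise ValueError("total_removals must be non-negative")
    if total_removals == 0:
        return 0.0, 0.0
    catchable = lam_ad + phi_juv * lam_juv
    if catchable <= 0:
        raise ValueError("removals observed but expected catchable abundance is zero")
    r_ad = (lam_ad / catchable) * total_removals
    return r_ad, total_removals - r_ad


def adult_transition(lam_ad: float, s_ad: float, ie: float,
                     r_ad: float, bta: float) -> float:
    """Adult dynamics step: ``max(lam_ad*s_ad + ie - r_ad + bta, floor)``."""
    if lam_ad < 0:
        raise ValueError("lam_ad must be non-negative")
    return max(lam_ad * s_ad + ie - r_ad + bta, FLOOR)


def birth_transition(b_prev: float, lam_ad_at_bp_prev: float,
                     r_juv_total: float, at_pulse: bool) -> float:
    """Juvenile-to-adult recruitment at the birth-pulse anniversary.

    Zero away from the pulse; at the pulse the effective cohort
    ``B = b_prev * lam_ad_at_bp_prev`` minus the juveniles already
    removed, floored at zero.
    """
    if min(b_prev, lam_ad_at_bp_prev, r_juv_total) < 0:
        raise ValueError("arguments must be non-negative")
    if not at_pulse:
        return 0.0
    return max(b_prev * lam_ad_at_bp_prev - r_juv_total, 0.0)


def combined_expected_removals(lam_ad, lam_juv, phi_juv, phi, pi_j, z):
    """Poisson mean for one day's removals over both age classes."""
    return (lam_ad + phi_juv * lam_juv) * phi * pi_j * z


def corrected_rates(p_catch, p, zprob, phi, n_days):
    """Effective removal probabilities corrected for the uncatchable fraction.

    ``pset*_t = 1 - (1 - p_catch_t * p_t * zprob * phi_t)**n_days_t``
    and ``pyear* = 1 - prod(1 - pset*_t)``.
    """
    p_catch = np.asarray(p_catch, dtype=float)
    daily = p_catch * np.asarray(p, dtype=float) * zprob * np.asarray(phi, dtype=float)
    with np.errstate(divide="ignore"):
        pset_star = -np.expm1(np.asarray(n_days, dtype=float)
                              * np.log1p(-np.minimum(daily, 1.0)))
        out_year = float(-np.expm1(np.sum(np.log1p(-pset_star))))
    return pset_star, out_year


# ---------------------------------------------------------------------------
# joint model


class InfoPMModel:
    """Joint InfoPM specification over the full period chain.

    The dynamics recursion runs over *every* primary period from the
    first sampled period to the last (including unsampled winter
    periods, where removals are zero), so that survival, net migration
    and the birth pulse act on their natural per-period time step.
    """

    kind = "infopm"

    def __init__(self, series: RemovalSeries, design: StudyDesign | None,
                 priors: VitalRatePriors, variant: str = "yearly",
                 mu_ie_sd: float = 100.0, sd_ie_scale: float = 5.0):
        self.design = series.design if design is None else design
        self.series = series
        self.variant = variant
        if variant not in ("yearly", "seasonal"):
            raise ValueError(f"variant must be 'yearly' or 'seasonal', got {variant!r}")
        self.priors = priors
        priors.validate(self.design.n_years)
        self.mu_ie_sd = float(mu_ie_sd)
        self.sd_ie_scale = float(sd_ie_scale)
        lay = self.layout = build_layout(series, self.design)
        des = self.design
        Y, T, bp = des.n_years, des.max_period, des.birth_pulse_period

        # chain of consecutive (year, period) positions
        first = (int(lay.sp_year[0]), int(lay.sp_period[0]))
        last = (int(lay.sp_year[-1]), int(lay.sp_period[-1]))
        chain: list[tuple[int, int]] = []
        y, t = first
        while True:
            chain.append((y, t))
            if (y, t) == last:
                break
            t += 1
            if t > T:
                t, y = 1, y + 1
        self.chain = chain
        L = len(chain)
        self.chain_year = np.array([c[0] for c in chain], dtype=np.int64)
        self.chain_period = np.array([c[1] for c in chain], dtype=np.int64)
        sp_of = {(int(lay.sp_year[s]), int(lay.sp_period[s])): s
                 for s in range(lay.n_periods)}
        self.chain_sp = np.array([sp_of.get(c, -1) for c in chain], dtype=np.int64)
        self.cohort_idx = np.where(self.chain_period >= bp,
                                   self.chain_year + 1, self.chain_year)
        self.omega = np.where(self.chain_period >= bp,
                              self.chain_period - bp,
                              self.chain_period - bp + T).astype(float)

        # net-migration groups over transitions (destination period)
        groups: dict[tuple, int] = {}
        names: list[str] = []
        ie_group = np.empty(L - 1, dtype=np.int64)
        ie_sdyear = np.empty(L - 1, dtype=np.int64)
        for c in range(L - 1):
            y2, t2 = chain[c + 1]
            ie_sdyear[c] = y2
            if variant == "yearly":
                key = (y2,)
                label = f"mu_IE[{des.years[y2]}]"
            else:
                season = int(des.seasons[t2 - 1])
                key = (y2, season)
                label = f"mu_IE[{des.years[y2]},{SEASONS[season]}]"
            if key not in groups:
                groups[key] = len(names)
                names.append(label)
            ie_group[c] = groups[key]
        self.ie_group, self.ie_sdyear = ie_group, ie_sdyear
        self._ie_names = names
        self.n_iegroup = len(names)

        # packed informative priors: b (Y+1), s_ad, s_juv, mu_em (Y), sd_em (Y)
        plist = list(priors.b) + [priors.s_ad_year, priors.s_juv] \
            + list(priors.mu_emerge) + list(priors.sd_emerge)
        self._prior_list = plist
        self.pr_code = np.array([p.code for p in plist], dtype=np.int64)
        self.pr_a = np.array([p.params[0] for p in plist])
        self.pr_b = np.array([p.params[1] for p in plist])

        years = des.years
        P = lay.n_periods
        names_all = [f"theta[{yr}]" for yr in years]
        names_all += [f"zprob[{yr}]" for yr in years]
        names_all += [f"phi[{years[lay.sp_year[s]]},{lay.sp_period[s]}]"
                      for s in range(P)]
        names_all += [f"lam_ad[{years[y]},{t}]" for y, t in chain]
        names_all += ["lam_ad_prepulse"]
        names_all += [f"b[{c}]" for c in range(Y + 1)]
        names_all += ["s_ad_year", "s_juv"]
        names_all += [f"mu_emerge[{yr}]" for yr in years]
        names_all += [f"sd_emerge[{yr}]" for yr in years]
        names_all += names
        names_all += [f"sd_IE[{yr}]" for yr in years]
        self.param_names = names_all
        self.n_params = len(names_all)

        lo, hi = priors.initial_birth_cohort_bounds
        self.kernel = _kernels.infopm_logpost
        self.kernel_args = (
            self.chain_year, self.chain_period, self.chain_sp,
            self.cohort_idx, self.omega,
            lay.sp_year, lay.effort, lay.ndays, lay.rtot,
            lay.obs_start, lay.obs_len, lay.y_obs, lay.lgam_obs, lay.obs_day,
            ie_group, ie_sdyear,
            self.pr_code, self.pr_a, self.pr_b,
            Y, self.n_iegroup, T, bp, float(des.period_length),
            float(lo), float(hi), self.mu_ie_sd, self.sd_ie_scale,
        )

    # -- parameter vector helpers -------------------------------------------

    def _slices(self):
        Y, P, L = self.design.n_years, self.layout.n_periods, len(self.chain)
        i = 0
        out = {}
        for name, n in (("theta", Y), ("zprob", Y), ("phi", P),
                        ("lam_ad", L), ("lam_ad_prepulse", 1), ("b", Y + 1),
                        ("s_ad_year", 1), ("s_juv", 1),
                        ("mu_emerge", Y), ("sd_emerge", Y),
                        ("mu_IE", self.n_iegroup), ("sd_IE", Y)):
            out[name] = slice(i, i + n)
            i += n
        assert i == self.n_params
        return out

    def unpack(self, vec):
        return {k: np.asarray(vec[sl]) for k, sl in self._slices().items()}

    def pack(self, **parts):
        vec = np.empty(self.n_params)
        for k, sl in self._slices().items():
            vec[sl] = parts[k]
        return vec

    def logpost(self, vec) -> float:
        return float(self.kernel(np.asarray(vec, dtype=float), self.kernel_args))

    # -- trajectories (python mirror of the kernel recursion) ---------------

    def trajectories(self, vec, with_removals: bool = True) -> dict:
        """Latent state per chain position for one parameter vector.

        With ``with_removals=True`` the adult path is read off the
        parameter vector and the net-migration increment each
        transition implies is returned alongside the juvenile state
        and removal allocation.  With ``with_removals=False`` the
        recursion is re-run with all removal terms dropped while
        holding survival, birth rates, emergence and exactly those
        implied net-migration increments fixed -- the no-removal
        counterfactual.
        """
        p = self.unpack(vec)
        des = self.design
        T, bp = des.max_period, des.birth_pulse_period
        Y = des.n_years
        L = len(self.chain)
        lay = self.layout
        sad_p = scalarize_survival(float(p["s_ad_year"][0]), T)
        s_juv = float(p["s_juv"][0])
        if not with_removals:
            return self._no_removal_trajectories(vec)

        bcache = np.full(Y + 1, np.nan)
        c0 = int(self.cohort_idx[0])
        bcache[c0] = p["b"][c0] * p["lam_ad_prepulse"][0]

        path = np.asarray(p["lam_ad"], dtype=float)
        lam_ad = np.empty(L)
        lam_juv = np.empty(L)
        phi_juv = np.empty(L)
        r_ad = np.zeros(L)
        r_juv = np.zeros(L)
        bta = np.zeros(L)
        ie = np.zeros(L - 1)

        cur = float(path[0])
        rjuv_cum = 0.0
        for c in range(L):
            lam_ad[c] = cur
            y, t = self.chain[c]
            if t == bp:
                if y + 1 <= Y:
                    bcache[y + 1] = p["b"][y + 1] * cur
                rjuv_cum = 0.0
            co = int(self.cohort_idx[c])
            om = self.omega[c]
            lam_juv[c] = max(bcache[co] * s_juv ** ((om - T) / T) - rjuv_cum, 0.0)
            phi_juv[c] = juvenile_availability(
                des.period_length * om, p["mu_emerge"][y], p["sd_emerge"][y])
            s = self.chain_sp[c]
            if s >= 0 and with_removals and lay.rtot[s] > 0:
                r_ad[c], r_juv[c] = allocate_removals(
                    cur, lam_juv[c], phi_juv[c], lay.rtot[s])
                rjuv_cum += r_juv[c]
            if c < L - 1:
                step_bta = 0.0
                if self.chain[c + 1][1] == bp:
                    y2 = self.chain[c + 1][0]
                    step_bta = max(bcache[y2] - rjuv_cum, 0.0)
                bta[c + 1] = step_bta
                nxt = float(path[c + 1])
                ie[c] = nxt - (cur * sad_p - r_ad[c] + step_bta)
                cur = nxt
        lam_catch = lam_ad + phi_juv * lam_juv
        return {
            "year": self.chain_year, "period": self.chain_period,
            "lam_ad": lam_ad, "lam_juv": lam_juv, "phi_juv": phi_juv,
            "lam_catch": lam_catch, "lam_star": lam_ad + lam_juv,
            "r_ad": r_ad, "r_juv": r_juv, "bta": bta, "ie": ie,
        }

    def _no_removal_trajectories(self, vec) -> dict:
        """Counterfactual recursion as an exact nonnegative increment on
        the estimated trajectory.

        The difference ``d`` between the no-removal and estimated adult
        paths obeys ``d' = d*sad + r_ad + (bta_cf - bta)`` with
        ``d[0] = 0``, which keeps the two scenarios bit-identical when
        no removals were observed and makes the counterfactual dominate
        the estimate draw-by-draw otherwise.
        """
        est = self.trajectories(vec, with_removals=True)
        p = self.unpack(vec)
        des = self.design
        T, bp = des.max_period, des.birth_pulse_period
        Y = des.n_years
        L = len(self.chain)
        sad_p = scalarize_survival(float(p["s_ad_year"][0]), T)
        s_juv = float(p["s_juv"][0])

        bcache = np.full(Y + 1, np.nan)
        c0 = int(self.cohort_idx[0])
        bcache[c0] = p["b"][c0] * p["lam_ad_prepulse"][0]

        lam_ad = np.empty(L)
        lam_juv = np.empty(L)
        bta = np.zeros(L)
        d = 0.0
        for c in range(L):
            y, t = self.chain[c]
            lam_ad[c] = est["lam_ad"][c] + d
            if t == bp:
                if y + 1 <= Y:
                    bcache[y + 1] = p["b"][y + 1] * lam_ad[c]
            co = int(self.cohort_idx[c])
            om = self.omega[c]
            lam_juv[c] = max(bcache[co] * s_juv ** ((om - T) / T), 0.0)
            if c < L - 1:
                step_bta = 0.0
                if self.chain[c + 1][1] == bp:
                    step_bta = max(bcache[self.chain[c + 1][0]], 0.0)
                bta[c + 1] = step_bta
                d = d * sad_p + est["r_ad"][c] + (step_bta - est["bta"][c + 1])
        phi_juv = est["phi_juv"]
        return {
            "year": self.chain_year, "period": self.chain_period,
            "lam_ad": lam_ad, "lam_juv": lam_juv, "phi_juv": phi_juv,
            "lam_catch": lam_ad + phi_juv * lam_juv,
            "lam_star": lam_ad + lam_juv,
            "r_ad": np.zeros(L), "r_juv": np.zeros(L), "bta": bta,
            "ie": est["ie"],
        }

    def daily_means(self, vec):
        """Per-observation conditional mean (z = 1) and zprob."""
        p = self.unpack(vec)
        lay = self.layout
        traj = self.trajectories(vec)
        lam_catch_sp = np.empty(lay.n_periods)
        lam_catch_sp[self.chain_sp[self.chain_sp >= 0]] = \
            traj["lam_catch"][self.chain_sp >= 0]
        p_day = observation.daily_capture_prob(p["theta"][lay.sp_year], lay.effort)
        pij = p_day[lay.obs_sp] * (1.0 - p_day[lay.obs_sp]) ** lay.obs_day
        mu = lam_catch_sp[lay.obs_sp] * p["phi"][lay.obs_sp] * pij
        zp = p["zprob"][lay.sp_year[lay.obs_sp]]
        return mu, zp

    def pointwise_loglik(self, vec):
        mu, zp = self.daily_means(vec)
        return observation.zip_loglik(self.layout.y_obs, mu, zp)

    def logpost_py(self, vec) -> float:
        """Pure-python log posterior (cross-check for the compiled kernel)."""
        p = self.unpack(vec)
        for key in ("theta", "zprob", "phi"):
            if np.any(p[key] <= 0) or np.any(p[key] >= 1):
                return -np.inf
        if np.any(p["lam_ad"] <= 0) or np.any(p["sd_emerge"] <= 0):
            return -np.inf
        if not (0 < p["s_ad_year"][0] <= 1 and 0 < p["s_juv"][0] <= 1):
            return -np.inf
        lo, hi = self.priors.initial_birth_cohort_bounds
        if not lo <= p["lam_ad_prepulse"][0] <= hi:
            return -np.inf
        lp = -0.5 * math.log(p["lam_ad"][0]) - 1e-6 * p["lam_ad"][0]
        xs = np.concatenate([p["b"], p["s_ad_year"], p["s_juv"],
                             p["mu_emerge"], p["sd_emerge"]])
        for pr, x in zip(self._prior_list, xs):
            v = float(_kernels._prior_logpdf(pr.code, *pr.params, float(x)))
            if not np.isfinite(v):
                return -np.inf
            lp += v
        lp -= 0.5 * np.sum((p["mu_IE"] / self.mu_ie_sd) ** 2)
        if np.any(p["sd_IE"] <= 0):
            return -np.inf
        lp -= np.sum(np.log1p((p["sd_IE"] / self.sd_ie_scale) ** 2))
        ie = self.trajectories(vec)["ie"]
        sd = p["sd_IE"][self.ie_sdyear]
        mu = p["mu_IE"][self.ie_group]
        lp += np.sum(-np.log(sd) - 0.5 * ((ie - mu) / sd) ** 2)
        return float(lp + self.pointwise_loglik(vec).sum())

    # -- initialization -----------------------------------------------------

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        lay = self.layout
        Y = self.design.n_years
        nonzero = np.zeros(Y)
        ndays_y = np.zeros(Y)
        r_year = np.zeros(Y)
        for s in range(lay.n_periods):
            y = lay.sp_year[s]
            o0, n = lay.obs_start[s], lay.obs_len[s]
            nonzero[y] += np.count_nonzero(lay.y_obs[o0:o0 + n])
            ndays_y[y] += n
            r_year[y] += lay.rtot[s]
        zprob0 = np.clip(nonzero / np.maximum(ndays_y, 1), 0.15, 0.9)
        zprob0 = np.clip(zprob0 * np.exp(rng.normal(0, 0.1, Y)), 0.05, 0.95)
        p0 = 0.05 * np.exp(rng.normal(0, 0.3))
        mean_eff = max(lay.effort.mean(), 1.0)
        theta0 = np.full(Y, 1.0 - (1.0 - p0) ** (1.0 / mean_eff))
        phi0 = np.clip(0.5 + rng.uniform(-0.15, 0.15, lay.n_periods), 0.05, 0.95)
        lo, hi = self.priors.initial_birth_cohort_bounds
        prepulse = lo + (hi - lo) * rng.uniform(0.3, 0.7)
        b0 = np.array([max(pr.mean(), 0.05) for pr in self.priors.b])
        s_ad0 = float(np.clip(self.priors.s_ad_year.mean(), 0.05, 0.98))
        s_juv0 = float(np.clip(self.priors.s_juv.mean(), 0.02, 0.98))
        mu_em0 = np.array([pr.mean() for pr in self.priors.mu_emerge])
        sd_em0 = np.array([max(pr.mean(), 5.0) for pr in self.priors.sd_emerge])
        # adult path initialized near a crude depletion-style estimate,
        # flat through unsampled periods
        L = len(self.chain)
        crude = np.maximum(lay.rtot / 0.5, 50.0)
        path0 = np.empty(L)
        for c in range(L):
            s = self.chain_sp[c]
            if s >= 0:
                path0[c] = crude[s]
            else:
                path0[c] = path0[c - 1] if c > 0 else crude[0]
        path0 = np.convolve(np.pad(path0, 1, mode="edge"),
                            np.ones(3) / 3.0, mode="valid")
        path0 *= np.exp(rng.normal(0, 0.15, L))
        return self.pack(
            theta=theta0, zprob=zprob0, phi=phi0, lam_ad=path0,
            lam_ad_prepulse=prepulse, b=b0, s_ad_year=s_ad0, s_juv=s_juv0,
            mu_emerge=mu_em0, sd_emerge=sd_em0,
            mu_IE=np.full(self.n_iegroup, 10.0),
            sd_IE=np.full(Y, 20.0))

    def ridge_blocks(self):
        """Product-preserving ridge moves: additive shifts of the adult
        path with availability compensated at sampled periods (winter
        positions shift with their year but have no availability
        partner), per period, per year, and globally."""
        sl = self._slices()
        lam0 = sl["lam_ad"].start
        phi0 = sl["phi"].start
        blocks = []
        L = len(self.chain)
        phi_of = np.where(self.chain_sp >= 0, phi0 + self.chain_sp, -1)
        mu0 = sl["mu_IE"].start
        for y in range(self.design.n_years):
            cy = np.nonzero(self.chain_year == y)[0]
            blocks.append((lam0 + cy, phi_of[cy]))
            w = np.arange(len(cy), dtype=float) - (len(cy) - 1) / 2.0
            groups = sorted({int(self.ie_group[c]) for c in cy if c < L - 1})
            blocks.append((lam0 + cy, phi_of[cy], w,
                           [mu0 + g for g in groups],
                           [1.0] * len(groups)))
        blocks.append((np.arange(lam0, lam0 + L), phi_of))
        blocks.extend(self._split_blocks(sl, lam0))
        return blocks

    def _split_blocks(self, sl, lam0):
        """Linear directions along the adult/juvenile split ridge.

        The combined likelihood constrains only the catchable total
        ``lam_ad + phi_juv*lam_juv``, so raising a cohort's scale (its
        birth rate, or the pre-study cohort) trades against the adult
        path.  Each direction moves one cohort-scale coordinate and
        compensates the adult path by the first-order juvenile change
        (coefficients frozen at prior means and a crude abundance
        level), proposed as a plain symmetric linear move.
        """
        des = self.design
        T = des.max_period
        lay = self.layout
        a_hat = max(float(np.median(lay.rtot)) / 0.5, 100.0)
        s_hat = float(np.clip(self.priors.s_juv.mean(), 0.02, 0.98))
        mu_hat = float(np.mean([p.mean() for p in self.priors.mu_emerge]))
        sd_hat = float(np.mean([max(p.mean(), 5.0)
                                for p in self.priors.sd_emerge]))
        phij_hat = juvenile_availability(
            des.period_length * self.omega, mu_hat, sd_hat)
        juv_scale = s_hat ** ((self.omega - T) / T)  # cohort units -> juveniles
        b0 = sl["b"].start
        pre = sl["lam_ad_prepulse"].start
        Y = des.n_years
        blocks = []
        for co in range(Y + 2):
            if co <= Y:
                pos = np.nonzero(self.cohort_idx == co)[0]
                if not len(pos):
                    continue
                if co == 0:
                    drive, dscale = pre, float(self.priors.b[0].mean())
                else:
                    drive, dscale = b0 + co, a_hat
                oi = [drive] + (lam0 + pos).tolist()
                ow = [1.0] + (-dscale * phij_hat[pos] * juv_scale[pos]).tolist()
            else:
                # global: all cohort scales against the whole adult path
                oi = list(range(b0, b0 + Y + 1))
                ow = [1.0] * (Y + 1)
                oi += (lam0 + np.arange(len(self.chain))).tolist()
                ow += (-a_hat * phij_hat * juv_scale).tolist()
            blocks.append(((), (), (), oi, ow))
        return blocks

    def mult_mask(self) -> np.ndarray:
        """Coordinates updated on the log scale."""
        mask = np.zeros(self.n_params, dtype=bool)
        sl = self._slices()
        mask[sl["sd_IE"]] = True
        mask[sl["theta"]] = True
        return mask

    def initial_scales(self) -> np.ndarray:
        sl = self._slices()
        scales = np.empty(self.n_params)
        scales[sl["theta"]] = 0.2      # log-scale step
        scales[sl["zprob"]] = 0.05
        scales[sl["phi"]] = 0.08
        scales[sl["lam_ad"]] = 25.0
        scales[sl["lam_ad_prepulse"]] = 50.0
        scales[sl["b"]] = 0.05
        scales[sl["s_ad_year"]] = 0.03
        scales[sl["s_juv"]] = 0.03
        scales[sl["mu_emerge"]] = 8.0
        scales[sl["sd_emerge"]] = 4.0
        scales[sl["mu_IE"]] = 10.0
        scales[sl["sd_IE"]] = 0.5      # log-scale step
        return scales

    # -- derived quantities -------------------------------------------------

    @property
    def abundance_names(self) -> set[str]:
        return {"lam", "lam_star", "lam_ad", "lam_juv", "M", "M_star", "Nhat"}

    def derived_draws(self, draws, rng: np.random.Generator) -> dict:
        """Derived quantities per posterior draw at the sampled periods."""
        lay = self.layout
        S = draws.shape[0]
        P = lay.n_periods
        Y = self.design.n_years
        at_sp = self.chain_sp >= 0
        sp_order = self.chain_sp[at_sp]
        out = {k: np.empty((S, P)) for k in
               ("lam", "lam_star", "lam_ad", "lam_juv", "phi_juv",
                "pset", "pset_star", "Nhat")}
        pyear = np.empty((S, Y))
        pyear_star = np.empty((S, Y))
        for i in range(S):
            vec = draws[i]
            p = self.unpack(vec)
            traj = self.trajectories(vec)
            for key, src in (("lam", "lam_catch"), ("lam_star", "lam_star"),
                             ("lam_ad", "lam_ad"), ("lam_juv", "lam_juv"),
                             ("phi_juv", "phi_juv")):
                out[key][i, sp_order] = traj[src][at_sp]
            p_day = observation.daily_capture_prob(
                p["theta"][lay.sp_year], lay.effort)
            zp = p["zprob"][lay.sp_year]
            out["pset"][i] = observation.period_effective_prob(
                p_day, zp, p["phi"], lay.ndays)
            p_catch = out["lam"][i] / np.maximum(out["lam_star"][i], FLOOR)
            out["pset_star"][i] = -np.expm1(
                lay.ndays * np.log1p(-p_catch * p_day * zp * p["phi"]))
            out["Nhat"][i] = p["phi"] * out["lam"][i]
            for y in range(Y):
                sel = lay.sp_year == y
                pyear[i, y] = observation.annual_effective_prob(out["pset"][i][sel])
                pyear_star[i, y] = observation.annual_effective_prob(
                    out["pset_star"][i][sel])
        out["M"] = rng.poisson(out["lam"]).astype(float)
        out["M_star"] = rng.poisson(out["lam_star"]).astype(float)
        out["pyear"] = pyear
        out["pyear_star"] = pyear_star
        return out

    def structure(self) -> dict:
        return {
            "kind": self.kind,
            "variant": self.variant,
            "n_params": self.n_params,
            "param_names": self.param_names,
            "n_obs": int(self.layout.n_obs),
            "n_sampled_periods": int(self.layout.n_periods),
            "chain_length": len(self.chain),
            "priors": self.priors.to_dict(),
        }


def build_infopm_model(series: RemovalSeries, design: StudyDesign | None,
                       priors: VitalRatePriors, variant: str = "yearly",
                       **kwargs) -> InfoPMModel:
    """Assemble the 2-age-class informed population model."""
    return InfoPMModel(series, design, priors, variant, **kwargs)


def project_no_removal(model: InfoPMModel, draws: np.ndarray,
                       rng: np.random.Generator | None = None) -> dict:
    """No-removal counterfactual trajectories for each posterior draw.

    Re-runs the dynamics recursion with all removal terms dropped while
    holding survival, birth rates, emergence and net migration at each
    draw's values.  Superpopulation draws (``M``, ``M_star``) for the
    estimated and counterfactual scenarios share common uniform variates
    (Poisson quantile coupling), so the counterfactual dominates the
    estimate draw-by-draw whenever its expectation does.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    S = draws.shape[0]
    L = len(model.chain)
    est = {k: np.empty((S, L)) for k in ("lam", "lam_star", "lam_ad", "lam_juv")}
    cf = {k: np.empty((S, L)) for k in ("lam", "lam_star", "lam_ad", "lam_juv")}
    for i in range(S):
        t_est = model.trajectories(draws[i], with_removals=True)
        t_cf = model.trajectories(draws[i], with_removals=False)
        for store, traj in ((est, t_est), (cf, t_cf)):
            store["lam"][i] = traj["lam_catch"]
            store["lam_star"][i] = traj["lam_star"]
            store["lam_ad"][i] = traj["lam_ad"]
            store["lam_juv"][i] = traj["lam_juv"]
    u_m = rng.uniform(size=(S, L))
    u_ms = rng.uniform(size=(S, L))
    for store in (est, cf):
        store["M"] = stats.poisson.ppf(u_m, store["lam"])
        store["M_star"] = stats.poisson.ppf(u_ms, store["lam_star"])
    return {
        "year": np.array([model.design.years[y] for y in model.chain_year]),
        "period": model.chain_period.copy(),
        "estimated": est,
        "no_removal": cf,
    }
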