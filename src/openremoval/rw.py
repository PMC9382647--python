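"""Random-walk linear-trend dynamics for the open removal model.

The expected superpopulation follows a Gaussian random walk with drift
between consecutive sampled primary periods within a year,

    lam[t+1] = max(lam[t] + Delta[t+1] - R[t], floor),
    Delta ~ Normal(mu_trend, sd_trend),

where R[t] are the observed removals of the preceding period.  Years
are linked by a single between-year step with a weakly informative
Normal(0, 31.62) prior (precision 0.001), reflecting limited population
change over the winter dormancy gap; removals of the final sampled
period are subtracted before the annual step so that no removals drop
out of the accounting.  The drift mean varies by year (``yearly``
variant) or by year and season (``seasonal``), the step standard
deviation by year in both.
"""

from __future__ import annotations

import numpy as np

from . import _kernels, observation
from ._kernels import FLOOR
from ._packing import build_layout, trend_groups
from .design import RemovalSeries, StudyDesign

__all__ = ["FLOOR", "rw_transition", "year_link", "build_rw_model", "RWModel",
           "SD_YEAR_DEFAULT"]

#: Between-year step standard deviation implied by precision 0.001.
SD_YEAR_DEFAULT = float(np.sqrt(1.0 / 0.001))  # 31.62...


def rw_transition(lam_prev: float, delta: float, removals: float) -> float:
    """One random-walk step: ``max(lam_prev + delta - removals, floor)``.

    The floor (1e-6) keeps the Poisson rate in its domain when a large
    step or removal total would drive the expectation negative.
    """
    if lam_prev < 0:
        raise ValueError("lam_prev must be non-negative")
    if removals < 0:
        raise ValueError("removals must be non-negative")
    return max(lam_prev + delta - removals, FLOOR)


def year_link(lam_last: float, delta_year: float) -> float:
    """Between-year step: ``max(lam_last + delta_year, floor)``."""
    if lam_last < 0:
        raise ValueError("lam_last must be non-negative")
    return max(lam_last + delta_year, FLOOR)


class RWModel:
    """Joint model specification: random-walk dynamics + observation model.

    Exposes the latent vector layout, a compiled joint log posterior
    (``logpost``), the pointwise zero-inflated log-likelihood used for
    WAIC, per-observation daily means for posterior predictive checks,
    and derived quantities (M, pset, pyear, N-hat) from posterior draws.
    """

    kind = "rw"

    def __init__(self, series: RemovalSeries, design: StudyDesign | None = None,
                 variant: str = "yearly",
                 sd_year: float = SD_YEAR_DEFAULT,
                 mu_trend_sd: float = 100.0,
                 sd_trend_scale: float = 5.0):
        self.design = series.design if design is None else design
        self.series = series
        self.variant = variant
        self.sd_year = float(sd_year)
        self.mu_trend_sd = float(mu_trend_sd)
        self.sd_trend_scale = float(sd_trend_scale)
        lay = self.layout = build_layout(series, self.design)

        self.trend_idx, self._trend_names = trend_groups(
            lay, self.design, variant, "mu_trend")
        self.n_trend = len(self._trend_names)

        # within-year transition (delta) index and between-year index
        P = lay.n_periods
        self.delta_idx = np.full(P, -1, dtype=np.int64)
        self.ybound_idx = np.full(P, -1, dtype=np.int64)
        d = 0
        for s in range(P):
            if s == 0:
                continue
            if lay.first_of_year[s]:
                self.ybound_idx[s] = lay.sp_year[s] - 1
            else:
                self.delta_idx[s] = d
                d += 1
        self.n_delta = d

        years = self.design.years
        Y = self.design.n_years
        names = [f"theta[{yr}]" for yr in years]
        names += [f"zprob[{yr}]" for yr in years]
        names += [f"phi[{years[lay.sp_year[s]]},{lay.sp_period[s]}]"
                  for s in range(P)]
        names += [f"lam[{years[lay.sp_year[s]]},{lay.sp_period[s]}]"
                  for s in range(P)]
        names += self._trend_names
        names += [f"sd_trend[{yr}]" for yr in years]
        self.param_names = names
        self.n_params = len(names)

        self.kernel = _kernels.rw_logpost
        self.kernel_args = (
            lay.sp_year, lay.effort, lay.ndays, lay.rtot,
            self.delta_idx, self.ybound_idx, self.trend_idx,
            lay.y_obs, lay.lgam_obs, lay.obs_sp, lay.obs_day,
            Y, self.n_trend, self.sd_year, self.mu_trend_sd,
            self.sd_trend_scale,
        )

    # -- parameter vector helpers -------------------------------------------

    def _slices(self):
        Y, P = self.design.n_years, self.layout.n_periods
        i = 0
        out = {}
        for name, n in (("theta", Y), ("zprob", Y), ("phi", P), ("lam", P),
                        ("mu_trend", self.n_trend), ("sd_trend", Y)):
            out[name] = slice(i, i + n)
            i += n
        assert i == self.n_params
        return out

    def unpack(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        return {k: np.asarray(vec[sl]) for k, sl in self._slices().items()}

    def pack(self, **parts) -> np.ndarray:
        vec = np.empty(self.n_params)
        for k, sl in self._slices().items():
            vec[sl] = parts[k]
        return vec

    # -- densities ----------------------------------------------------------

    def logpost(self, vec: np.ndarray) -> float:
        return float(self.kernel(np.asarray(vec, dtype=float), self.kernel_args))

    def lam_path(self, vec: np.ndarray) -> np.ndarray:
        """Expected superpopulation per sampled period."""
        return np.asarray(self.unpack(vec)["lam"], dtype=float)

    def implied_steps(self, vec: np.ndarray):
        """Random-walk steps implied by the abundance path.

        Returns ``(delta, delta_year)``: the within-year steps
        ``lam[t+1] - lam[t] + R[t]`` (one per within-year transition)
        and the between-year steps ``lam[y+1,first] -
        (lam[y,last] - R[y,last])``.
        """
        lam = self.lam_path(vec)
        lay = self.layout
        delta = np.array([lam[s] - lam[s - 1] + lay.rtot[s - 1]
                          for s in range(lay.n_periods)
                          if self.delta_idx[s] >= 0])
        dyear = np.array([lam[s] - (lam[s - 1] - lay.rtot[s - 1])
                          for s in range(lay.n_periods)
                          if self.ybound_idx[s] >= 0])
        return delta, dyear

    def daily_means(self, vec: np.ndarray):
        """Per-observation conditional mean (z = 1) and zprob.

        The conditional mean is ``lam * phi * pi_j``; together with the
        per-day suitability probability it determines both the
        marginal ZIP likelihood and generative replicates.
        """
        p = self.unpack(vec)
        lay = self.layout
        lam = self.lam_path(vec)
        p_day = observation.daily_capture_prob(p["theta"][lay.sp_year], lay.effort)
        pij = p_day[lay.obs_sp] * (1.0 - p_day[lay.obs_sp]) ** lay.obs_day
        mu = lam[lay.obs_sp] * p["phi"][lay.obs_sp] * pij
        zp = p["zprob"][lay.sp_year[lay.obs_sp]]
        return mu, zp

    def pointwise_loglik(self, vec: np.ndarray) -> np.ndarray:
        """Marginalized zero-inflated Poisson log-likelihood per sampled day."""
        mu, zp = self.daily_means(vec)
        return observation.zip_loglik(self.layout.y_obs, mu, zp)

    def logpost_py(self, vec: np.ndarray) -> float:
        """Pure-python log posterior (cross-check for the compiled kernel)."""
        p = self.unpack(vec)
        for key in ("theta", "zprob", "phi"):
            if np.any(p[key] <= 0) or np.any(p[key] >= 1):
                return -np.inf
        lam = p["lam"]
        if np.any(lam <= 0) or np.any(p["sd_trend"] <= 0):
            return -np.inf
        lp = -0.5 * np.log(lam[0]) - 1e-6 * lam[0]
        lp -= np.sum(np.log1p((p["sd_trend"] / self.sd_trend_scale) ** 2))
        lp -= 0.5 * np.sum((p["mu_trend"] / self.mu_trend_sd) ** 2)
        lay = self.layout
        for s in range(1, lay.n_periods):
            if self.ybound_idx[s] >= 0:
                dy = lam[s] - (lam[s - 1] - lay.rtot[s - 1])
                lp += -0.5 * (dy / self.sd_year) ** 2
            else:
                d = lam[s] - lam[s - 1] + lay.rtot[s - 1]
                sd = p["sd_trend"][lay.sp_year[s]]
                mu_t = p["mu_trend"][self.trend_idx[s]]
                lp += -np.log(sd) - 0.5 * ((d - mu_t) / sd) ** 2
        ll = self.pointwise_loglik(vec)
        return float(lp + ll.sum())

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
        # path initialized from the crude depletion-style estimate
        # lam_t ~ R_t / pset_guess, smoothed and jittered
        pset_guess = 0.45
        lam0 = np.maximum(lay.rtot / pset_guess, 50.0)
        lam0 = np.convolve(np.pad(lam0, 1, mode="edge"),
                           np.ones(3) / 3.0, mode="valid")
        lam0 *= np.exp(rng.normal(0, 0.15, lam0.shape))
        mu0 = np.full(self.n_trend, float(lay.rtot.mean()))
        sd0 = np.full(Y, max(float(lay.rtot.std()), 10.0))
        return self.pack(theta=theta0, zprob=zprob0, phi=phi0, lam=lam0,
                         mu_trend=mu0, sd_trend=sd0)

    def ridge_blocks(self):
        """Product-preserving ridge moves for the abundance level.

        The likelihood constrains only ``lam * phi`` within each
        period, and the step priors constrain only differences of
        ``lam``, so the posterior's slow direction is a common
        additive shift of the abundance path with availability
        compensated; blocks are per period, per year, and global.
        """
        sl = self._slices()
        P = self.layout.n_periods
        lam0 = sl["lam"].start
        phi0 = sl["phi"].start
        blocks = []
        mu0 = sl["mu_trend"].start
        for y in range(self.design.n_years):
            sel = np.nonzero(self.layout.sp_year == y)[0]
            blocks.append((lam0 + sel, phi0 + sel))
            # tilt: shear the year's path linearly and move the year's
            # trend mean(s) with it, so slope and drift mix jointly
            w = np.arange(len(sel), dtype=float) - (len(sel) - 1) / 2.0
            groups = sorted({int(self.trend_idx[s]) for s in sel
                             if self.trend_idx[s] >= 0})
            blocks.append((lam0 + sel, phi0 + sel, w,
                           [mu0 + g for g in groups],
                           [1.0] * len(groups)))
        blocks.append((np.arange(lam0, lam0 + P), np.arange(phi0, phi0 + P)))
        return blocks

    def rescale_blocks(self):
        """Funnel moves: jointly rescale each year's step residuals and
        its step standard deviation (availability compensated)."""
        sl = self._slices()
        lam0 = sl["lam"].start
        phi0 = sl["phi"].start
        mu0 = sl["mu_trend"].start
        sd0 = sl["sd_trend"].start
        lay = self.layout
        blocks = []
        for y in range(self.design.n_years):
            sel = np.nonzero(lay.sp_year == y)[0]
            if len(sel) < 2:
                continue
            body = sel[1:]
            # within-year steps only: the between-year link has its own
            # fixed-scale prior
            blocks.append({
                "lam": (lam0 + body).tolist(),
                "phi": (phi0 + body).tolist(),
                "mu": [mu0 + int(self.trend_idx[s]) for s in body],
                "cumr": np.cumsum(lay.rtot[sel[:-1]]).tolist(),
                "anchor": lam0 + int(sel[0]),
                "sd": sd0 + y,
            })
        return blocks

    def conjugate_mean_blocks(self):
        """Exact Gibbs updates for the trend means: each drift mean has
        a Normal prior and Gaussian step observations, so its full
        conditional is conjugate."""
        sl = self._slices()
        lam0 = sl["lam"].start
        mu0 = sl["mu_trend"].start
        sd0 = sl["sd_trend"].start
        lay = self.layout
        blocks = []
        for g in range(self.n_trend):
            dests = np.nonzero(self.trend_idx == g)[0]
            if not len(dests):
                continue
            blocks.append({
                "param": mu0 + g,
                "prior_mu": 0.0,
                "prior_sd": self.mu_trend_sd,
                "sd_idx": sd0 + int(lay.sp_year[dests[0]]),
                "obs_i": (lam0 + dests).tolist(),
                "obs_j": (lam0 + dests - 1).tolist(),
                "const": lay.rtot[dests - 1].tolist(),
            })
        return blocks

    def mult_mask(self) -> np.ndarray:
        """Coordinates updated on the log scale (heavy-tailed scales
        and the tiny capture efficiency)."""
        mask = np.zeros(self.n_params, dtype=bool)
        sl = self._slices()
        mask[sl["sd_trend"]] = True
        mask[sl["theta"]] = True
        return mask

    def initial_scales(self) -> np.ndarray:
        sl = self._slices()
        scales = np.empty(self.n_params)
        scales[sl["theta"]] = 0.2      # log-scale step
        scales[sl["zprob"]] = 0.05
        scales[sl["phi"]] = 0.08
        scales[sl["lam"]] = 30.0
        scales[sl["mu_trend"]] = 20.0
        scales[sl["sd_trend"]] = 0.5   # log-scale step
        return scales

    # -- derived quantities -------------------------------------------------

    @property
    def abundance_names(self) -> set[str]:
        return {"lam", "M", "Nhat"}

    def derived_draws(self, draws: np.ndarray,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Derived quantities per posterior draw.

        ``M`` is a posterior-predictive Poisson draw given ``lam``;
        ``Nhat = phi * lam`` is the expected available abundance;
        ``pset``/``pyear`` are the effective removal probabilities.
        """
        lay = self.layout
        S = draws.shape[0]
        Y = self.design.n_years
        lam = np.empty((S, lay.n_periods))
        pset = np.empty((S, lay.n_periods))
        nhat = np.empty((S, lay.n_periods))
        pyear = np.empty((S, Y))
        for s_i in range(S):
            vec = draws[s_i]
            p = self.unpack(vec)
            lam[s_i] = self.lam_path(vec)
            p_day = observation.daily_capture_prob(
                p["theta"][lay.sp_year], lay.effort)
            pset[s_i] = observation.period_effective_prob(
                p_day, p["zprob"][lay.sp_year], p["phi"], lay.ndays)
            nhat[s_i] = p["phi"] * lam[s_i]
            for y in range(Y):
                pyear[s_i, y] = observation.annual_effective_prob(
                    pset[s_i][lay.sp_year == y])
        M = rng.poisson(lam)
        return {"lam": lam, "M": M.astype(float), "Nhat": nhat,
                "pset": pset, "pyear": pyear}

    def structure(self) -> dict:
        """JSON-serializable model structure."""
        return {
            "kind": self.kind,
            "variant": self.variant,
            "n_params": self.n_params,
            "param_names": self.param_names,
            "n_obs": int(self.layout.n_obs),
            "n_sampled_periods": int(self.layout.n_periods),
            "sd_year": self.sd_year,
        }


def build_rw_model(series: RemovalSeries, design: StudyDesign | None = None,
                   variant: str = "yearly", **kwargs) -> RWModel:
    """Assemble the random-walk trend model for a removal series."""
    return RWModel(series, design, variant, **kwargs)
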