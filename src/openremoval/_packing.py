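"""Shared flattening of a removal series into kernel-ready index arrays."""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .design import SEASONS, RemovalSeries, StudyDesign


@dataclasses.dataclass
class SampledLayout:
    """Flat view of the sampled (year, period) cells and their days.

    Sampled periods are ordered by year then period; observations are
    the active days of each sampled period, concatenated in the same
    order (``obs_start``/``obs_len`` index into the flat day arrays).
    """

    sp_year: np.ndarray      # (P,) year index of each sampled period
    sp_period: np.ndarray    # (P,) 1-based period number
    effort: np.ndarray       # (P,) mean daily traps
    ndays: np.ndarray        # (P,) active days
    rtot: np.ndarray         # (P,) period total removals (float for kernels)
    obs_start: np.ndarray    # (P,)
    obs_len: np.ndarray      # (P,)
    y_obs: np.ndarray        # (n_obs,) daily removals, float
    lgam_obs: np.ndarray     # (n_obs,) lgamma(y+1)
    obs_sp: np.ndarray       # (n_obs,) sampled-period index
    obs_day: np.ndarray      # (n_obs,) day-within-period, 0-based, float
    first_of_year: np.ndarray  # (P,) bool

    @property
    def n_periods(self) -> int:
        return len(self.sp_year)

    @property
    def n_obs(self) -> int:
        return len(self.y_obs)


def build_layout(series: RemovalSeries, design: StudyDesign) -> SampledLayout:
    if series.design.max_period != design.max_period or \
            series.design.years != design.years:
        raise ValueError("removal series does not conform to the study design")
    mask = design.sampled_mask
    if not mask.any():
        raise ValueError("no sampled periods in the series")

    sp_year, sp_period, effort, ndays, rtot = [], [], [], [], []
    y_obs, obs_sp, obs_day, obs_start, obs_len, firsts = [], [], [], [], [], []
    for y in range(design.n_years):
        first = True
        for t in range(1, design.max_period + 1):
            if not mask[y, t - 1]:
                continue
            s = len(sp_year)
            nd = int(design.n_days[y, t - 1])
            sp_year.append(y)
            sp_period.append(t)
            effort.append(float(series.effort[y, t - 1]))
            ndays.append(nd)
            rtot.append(float(series.period_totals[y, t - 1]))
            firsts.append(first)
            first = False
            obs_start.append(len(y_obs))
            obs_len.append(nd)
            for j in range(nd):
                y_obs.append(float(series.removals[y, t - 1, j]))
                obs_sp.append(s)
                obs_day.append(float(j))

    y_arr = np.array(y_obs)
    return SampledLayout(
        sp_year=np.array(sp_year, dtype=np.int64),
        sp_period=np.array(sp_period, dtype=np.int64),
        effort=np.array(effort),
        ndays=np.array(ndays, dtype=np.int64),
        rtot=np.array(rtot),
        obs_start=np.array(obs_start, dtype=np.int64),
        obs_len=np.array(obs_len, dtype=np.int64),
        y_obs=y_arr,
        lgam_obs=np.array([math.lgamma(v + 1.0) for v in y_obs]),
        obs_sp=np.array(obs_sp, dtype=np.int64),
        obs_day=np.array(obs_day),
        first_of_year=np.array(firsts, dtype=bool),
    )


def trend_groups(layout: SampledLayout, design: StudyDesign, variant: str,
                 prefix: str):
    """Group index for each within-year transition mean.

    ``yearly`` gives one group per year; ``seasonal`` one per
    (year, season) combination actually entered by some transition.
    The season of a transition is that of its destination period.
    Returns (group index per sampled period, -1 where not a
    destination; ordered group names).
    """
    if variant not in ("yearly", "seasonal"):
        raise ValueError(f"variant must be 'yearly' or 'seasonal', got {variant!r}")
    years = design.years
    groups: dict[tuple, int] = {}
    names: list[str] = []
    idx = np.full(layout.n_periods, -1, dtype=np.int64)
    for s in range(layout.n_periods):
        if layout.first_of_year[s]:
            continue
        y = int(layout.sp_year[s])
        if variant == "yearly":
            key = (y,)
            label = f"{prefix}[{years[y]}]"
        else:
            season = int(design.seasons[layout.sp_period[s] - 1])
            key = (y, season)
            label = f"{prefix}[{years[y]},{SEASONS[season]}]"
        if key not in groups:
            groups[key] = len(names)
            names.append(label)
        idx[s] = groups[key]
    return idx, names
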