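"""Post-processing of simulation output into measured quantities.

Time averages of densities, payoffs and basal acquisition; per-capita birth
and death rates; lifespan statistics and histograms with an exponential tail
fit; a coefficient-of-variation oscillation flag; and a simulation-based
phase classifier that mirrors the mean-field one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunResult, run
from .meanfield import Phase
from .params import Params

__all__ = [
    "SummaryStats",
    "LifespanHistogram",
    "summarize",
    "lifespan_distribution",
    "classify_phase_sim",
]

# A strategy is "present" for classification when its time-averaged share of
# the population exceeds this cutoff; mutation alone maintains a small
# minority even where the type cannot persist.
DEFAULT_M_MIN = 0.05

# Coefficient of variation of N_C above which a window is flagged as
# oscillating; stable coexistence runs sit well below this.
DEFAULT_OSC_CV = 0.15


@dataclass(frozen=True)
class SummaryStats:
    """Time-averaged observables over a window of a run."""

    window: tuple[int, int]
    rho: float
    rho_C: float
    rho_D: float
    m: float
    payoff_C: float
    payoff_D: float
    basal_C: float
    basal_D: float
    birth_rate_C: float       # births per cooperator per step
    birth_rate_D: float
    death_rate_C: float
    death_rate_D: float
    mean_lifespan_C: float
    mean_lifespan_D: float
    oscillation_metric: float  # CV of N_C over the window
    oscillation_flag: bool
    absent_C: bool             # no cooperators anywhere in the window
    absent_D: bool


@dataclass(frozen=True)
class LifespanHistogram:
    strategy: str
    bin_edges: np.ndarray      # integer ages, contiguous unit bins
    counts: np.ndarray
    tail_decay_rate: Optional[float]   # fitted exponential rate, None if unfit

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


def _rate(numerator: pd.Series, denominator: pd.Series) -> tuple[float, bool]:
    """Per-capita per-step rate over steps where the type is present."""
    present = denominator > 0
    if not present.any():
        return 0.0, True
    return float(numerator[present].sum() / denominator[present].sum()), False


def summarize(
    time_series: pd.DataFrame,
    lifespans: pd.DataFrame,
    burn_in: int,
    osc_cv_threshold: float = DEFAULT_OSC_CV,
) -> SummaryStats:
    """Arithmetic time averages over steps ``t > burn_in``.

    Payoff and basal means are averaged over steps where the strategy was
    present (they are NaN otherwise); per-capita rates use per-step
    population denominators; lifespan means include deaths with
    ``death_time > burn_in``.  Absent types get rate 0 with a flag.
    """
    win = time_series[time_series["t"] > burn_in]
    if win.empty:
        raise ValueError("empty averaging window: burn_in >= run length")
    birth_c, absent_c = _rate(win["births_C"], win["N_C"])
    birth_d, absent_d = _rate(win["births_D"], win["N_D"])
    death_c, _ = _rate(win["deaths_C"], win["N_C"])
    death_d, _ = _rate(win["deaths_D"], win["N_D"])
    deaths = lifespans[lifespans["death_time"] > burn_in]
    tau_c = deaths.loc[deaths["strategy"] == "C", "lifespan"]
    tau_d = deaths.loc[deaths["strategy"] == "D", "lifespan"]
    mean_nc = float(win["N_C"].mean())
    cv = float(win["N_C"].std(ddof=0) / mean_nc) if mean_nc > 0 else 0.0
    return SummaryStats(
        window=(int(win["t"].iloc[0]), int(win["t"].iloc[-1])),
        rho=float(win["rho"].mean()),
        rho_C=float(win["rho_C"].mean()),
        rho_D=float(win["rho_D"].mean()),
        m=float(win["m"].mean()),
        payoff_C=float(np.nanmean(win["payoff_C"])) if not absent_c else 0.0,
        payoff_D=float(np.nanmean(win["payoff_D"])) if not absent_d else 0.0,
        basal_C=float(np.nanmean(win["basal_C"])) if not absent_c else 0.0,
        basal_D=float(np.nanmean(win["basal_D"])) if not absent_d else 0.0,
        birth_rate_C=birth_c,
        birth_rate_D=birth_d,
        death_rate_C=death_c,
        death_rate_D=death_d,
        mean_lifespan_C=float(tau_c.mean()) if len(tau_c) else float("nan"),
        mean_lifespan_D=float(tau_d.mean()) if len(tau_d) else float("nan"),
        oscillation_metric=cv,
        oscillation_flag=bool(cv > osc_cv_threshold),
        absent_C=absent_c,
        absent_D=absent_d,
    )


def lifespan_distribution(
    lifespans: pd.DataFrame,
    strategy: str,
    burn_in: int = 0,
    min_events_for_fit: int = 30,
    min_bin_count: int = 5,
) -> LifespanHistogram:
    """Unit-age histogram of lifespans with an exponential tail fit.

    The tail decay rate is the (positive) slope of a least-squares line on
    log counts over the upper half of the occupied bins with at least
    ``min_bin_count`` events.  With fewer than ``min_events_for_fit`` deaths
    the histogram is returned without a fit.
    """
    tau = lifespans.loc[
        (lifespans["strategy"] == strategy)
        & (lifespans["death_time"] > burn_in),
        "lifespan",
    ].to_numpy()
    if tau.size == 0:
        return LifespanHistogram(strategy, np.arange(2), np.zeros(1, int), None)
    hi = int(tau.max())
    edges = np.arange(1, hi + 2)
    counts, _ = np.histogram(tau, bins=edges)
    rate: Optional[float] = None
    if tau.size >= min_events_for_fit:
        ages = edges[:-1]
        occupied = counts >= min_bin_count
        if occupied.sum() >= 4:
            occ_ages = ages[occupied]
            cut = occ_ages[len(occ_ages) // 2]   # upper half of occupied bins
            sel = occupied & (ages >= cut)
            if sel.sum() >= 3:
                # Count-weighted least squares: log-count variance scales
                # like 1/count for Poisson bins.
                slope = np.polyfit(
                    ages[sel], np.log(counts[sel]), 1,
                    w=np.sqrt(counts[sel]),
                )[0]
                rate = float(-slope)
    return LifespanHistogram(strategy, edges, counts, rate)


def classify_phase_sim(
    params: Params,
    replicate_seeds: Sequence[int],
    m_min: float = DEFAULT_M_MIN,
    osc_cv_threshold: float = DEFAULT_OSC_CV,
) -> tuple[Phase, bool]:
    """Classify the dynamical phase by running the engine.

    Each seed is simulated and summarised after ``params.burn_in``.
    Cooperation counts as present when the time-averaged cooperator fraction
    exceeds ``m_min`` in a majority of replicates; defection likewise with
    ``1 - m``.  The oscillation flag is set when a majority of replicates
    exceed the CV threshold.
    """
    if not replicate_seeds:
        raise ValueError("at least one replicate seed is required")
    coop_votes = defect_votes = osc_votes = 0
    for seed in replicate_seeds:
        result = run(params.replace(seed=int(seed)))
        stats = summarize(
            result.time_series, result.lifespans, params.burn_in,
            osc_cv_threshold=osc_cv_threshold,
        )
        coop_votes += stats.m > m_min
        defect_votes += (1.0 - stats.m) > m_min
        osc_votes += stats.oscillation_flag
    n = len(replicate_seeds)
    coop = coop_votes * 2 > n
    defect = defect_votes * 2 > n
    osc = osc_votes * 2 > n
    if not coop:
        return Phase.NO_COOPERATION, osc
    if not defect:
        return Phase.FULL_COOPERATION, osc
    return (
        Phase.COEXISTENCE_FLUCTUATING if osc else Phase.COEXISTENCE,
        osc,
    )
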