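"""Dynamical mean-field description and the fluctuation onset.

The two-variable gradient-ascent equation

    d(rho_C)/dt = pi_C(rho_C, rho_D) + lam/rho - eta
    d(rho_D)/dt = pi_D(rho_C, rho_D) + lam/rho - eta

(with the Poisson mean payoffs of :mod:`ecoflow.theory`) says each
subpopulation grows when its per-capita resource gain exceeds the metabolic
rate.  With mutation the right-hand sides are mixed with weight ``nu``.  Its
boundary fixed points are the defectors-only / cooperators-only equilibria
and its interior fixed point is the Lambert-W coexistence solution.  As the
enhancement factor grows, the interior fixed point undergoes an oscillatory
(Hopf-type) loss of stability; beyond that critical ``r_c`` the dynamics
settles on a relaxation-like limit cycle, the mean-field image of the
non-equilibrium fluctuations seen in simulation.

Because the growth law is additive rather than proportional, trajectories
can reach zero density in finite time; integration therefore uses a
fixed-step RK4 with a positivity floor (an adaptive integrator stalls on the
clamp kink), cross-checked against an adaptive solver in the smooth regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .theory import (
    Branch,
    cooperation_threshold,
    equilibrium_densities,
    expected_payoffs_poisson,
)

__all__ = [
    "MeanFieldState",
    "FixedPoint",
    "FixedPointKind",
    "Phase",
    "rhs",
    "integrate",
    "find_fixed_points",
    "fluctuation_onset",
    "phase_boundaries",
]

_FLOOR = 1e-9


@dataclass(frozen=True)
class MeanFieldState:
    rho_C: float
    rho_D: float

    @property
    def rho(self) -> float:
        return self.rho_C + self.rho_D


class FixedPointKind(str, Enum):
    BOUNDARY_D = "boundary_D"   # defectors only (branch I)
    BOUNDARY_C = "boundary_C"   # cooperators only (branch III)
    INTERIOR = "interior"       # coexistence (branch II)


@dataclass(frozen=True)
class FixedPoint:
    state: MeanFieldState
    eigenvalues: tuple[complex, complex]
    stable: bool
    kind: FixedPointKind

    @property
    def max_real_eigenvalue(self) -> float:
        return max(ev.real for ev in self.eigenvalues)


class Phase(str, Enum):
    NO_COOPERATION = "no-cooperation"
    COEXISTENCE = "coexistence"
    COEXISTENCE_FLUCTUATING = "coexistence-fluctuating"
    FULL_COOPERATION = "full-cooperation"


def rhs(
    rho_C: float,
    rho_D: float,
    lam: float,
    eta: float,
    r: float,
    c: float,
    nu: float = 0.0,
) -> tuple[float, float]:
    """Growth rates (d rho_C/dt, d rho_D/dt) at the given densities."""
    rho = rho_C + rho_D
    if rho <= 0:
        raise ValueError("total density must be positive (lam/rho undefined)")
    pi_c, pi_d = expected_payoffs_poisson(rho_C, rho_D, r, c)
    f_c = pi_c + lam / rho - eta
    f_d = pi_d + lam / rho - eta
    return (1 - nu) * f_c + nu * f_d, (1 - nu) * f_d + nu * f_c


def _rhs_vec(y: np.ndarray, lam, eta, r, c, nu, floor=_FLOOR) -> np.ndarray:
    rc, rd = max(y[0], floor), max(y[1], floor)
    return np.array(rhs(rc, rd, lam, eta, r, c, nu))


def integrate(
    initial: MeanFieldState | tuple[float, float],
    lam: float,
    eta: float,
    r: float,
    c: float,
    nu: float = 0.0,
    t_end: float = 1000.0,
    dt: float = 0.02,
    dt_out: float = 1.0,
    floor: float = _FLOOR,
) -> pd.DataFrame:
    """Integrate the mean-field flow with a positivity floor.

    Fixed-step classical RK4; after each stage and step the state is clamped
    to ``floor``.  Returns a DataFrame with columns ``t, rho_C, rho_D``
    sampled every ``dt_out``.
    """
    if isinstance(initial, MeanFieldState):
        y = np.array([initial.rho_C, initial.rho_D], dtype=float)
    else:
        y = np.array(initial, dtype=float)
    if y.sum() <= 0:
        raise ValueError("initial total density must be positive")
    n_steps = int(round(t_end / dt))
    every = max(1, int(round(dt_out / dt)))
    args = (lam, eta, r, c, nu)
    out_t, out_y = [0.0], [y.copy()]
    for i in range(n_steps):
        k1 = _rhs_vec(y, *args, floor)
        k2 = _rhs_vec(np.maximum(y + 0.5 * dt * k1, floor), *args, floor)
        k3 = _rhs_vec(np.maximum(y + 0.5 * dt * k2, floor), *args, floor)
        k4 = _rhs_vec(np.maximum(y + dt * k3, floor), *args, floor)
        y = np.maximum(y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), floor)
        if (i + 1) % every == 0:
            out_t.append((i + 1) * dt)
            out_y.append(y.copy())
    arr = np.asarray(out_y)
    return pd.DataFrame({"t": out_t, "rho_C": arr[:, 0], "rho_D": arr[:, 1]})


def _jacobian(
    y: np.ndarray, lam, eta, r, c, nu, step: float = 1e-6
) -> np.ndarray:
    """Central-difference 2x2 Jacobian of the flow."""
    jac = np.zeros((2, 2))
    for j in range(2):
        yp = y.copy()
        ym = y.copy()
        yp[j] += step
        ym[j] -= step
        fp = np.array(rhs(yp[0], yp[1], lam, eta, r, c, nu))
        fm = np.array(rhs(ym[0], ym[1], lam, eta, r, c, nu))
        jac[:, j] = (fp - fm) / (2 * step)
    return jac


def _make_fixed_point(
    y: np.ndarray, kind: FixedPointKind, lam, eta, r, c, nu, jac_step: float
) -> FixedPoint:
    ev = np.linalg.eigvals(_jacobian(y, lam, eta, r, c, nu, jac_step))
    return FixedPoint(
        state=MeanFieldState(float(y[0]), float(y[1])),
        eigenvalues=(complex(ev[0]), complex(ev[1])),
        stable=bool(ev.real.max() < 0),
        kind=kind,
    )


def _boundary_fixed_point(
    kind: FixedPointKind, lam, eta, r, c
) -> FixedPoint:
    """Boundary equilibrium of the mutation-free flow with its stability.

    On a boundary the absent type's equation is dropped; since the growth
    law is additive, transverse stability is governed by the sign of the
    absent type's growth rate itself (the invasion rate), which is reported
    as the second "eigenvalue".  The first eigenvalue is the tangential
    derivative of the resident's growth rate.
    """
    if kind is FixedPointKind.BOUNDARY_D:
        rho_d = lam / eta
        tangential = -lam / rho_d**2              # d/d rho_D of (lam/rho_D - eta)
        pi_c, _ = expected_payoffs_poisson(0.0, rho_d, r, c)
        transverse = pi_c                          # invasion rate of cooperators
        state = MeanFieldState(0.0, rho_d)
    else:
        rho_c = lam / (eta - (r - 1.0) * c)
        tangential = -lam / rho_c**2
        _, pi_d = expected_payoffs_poisson(rho_c, 0.0, r, c)
        transverse = pi_d + lam / rho_c - eta      # invasion rate of defectors
        state = MeanFieldState(rho_c, 0.0)
    return FixedPoint(
        state=state,
        eigenvalues=(complex(tangential), complex(transverse)),
        stable=bool(max(tangential, transverse) < 0),
        kind=kind,
    )


def find_fixed_points(
    lam: float,
    eta: float,
    r: float,
    c: float,
    nu: float = 0.0,
    jac_step: float = 1e-6,
) -> list[FixedPoint]:
    """Locate boundary and interior fixed points with their stability.

    Root-finding is seeded from the closed-form equilibrium branches; the
    interior point's eigenvalues come from a central-difference Jacobian.
    For ``nu = 0`` the boundary equilibria are exact (see
    :func:`_boundary_fixed_point`); for ``nu > 0`` every seed is polished by
    a 2-D root solve, since mutation moves the fixed points off the axes by
    O(nu).
    """
    seeds: list[tuple[np.ndarray, FixedPointKind]] = []
    sol = equilibrium_densities(lam, eta, r, c)
    if sol.branch is Branch.COEXISTENCE:
        seeds.append(
            (np.array([sol.rho_C, sol.rho_D]), FixedPointKind.INTERIOR)
        )
    if lam > 0:
        seeds.append((np.array([0.0, lam / eta]), FixedPointKind.BOUNDARY_D))
    denom = eta - (r - 1.0) * c
    if lam > 0 and denom > 0:
        seeds.append((np.array([lam / denom, 0.0]), FixedPointKind.BOUNDARY_C))

    out: list[FixedPoint] = []
    for y0, kind in seeds:
        if nu == 0.0 and kind is not FixedPointKind.INTERIOR:
            out.append(_boundary_fixed_point(kind, lam, eta, r, c))
            continue
        res = root(
            lambda y: _rhs_vec(y, lam, eta, r, c, nu),
            np.maximum(y0, 1e-4 if nu > 0 else _FLOOR),
            method="hybr",
            tol=1e-12,
        )
        if not res.success:
            if kind is FixedPointKind.INTERIOR:
                raise RuntimeError(
                    f"fixed-point search failed from seed {y0} ({kind}): "
                    f"{res.message}"
                )
            # With mutation the boundary states stop being roots of the
            # unconstrained flow (any nu-mix of the two growth rates vanishes
            # only where both do); they survive only as corner equilibria of
            # the clamped dynamics, so a failed polish is expected there.
            import warnings

            warnings.warn(
                f"no off-axis root near {kind.value} seed {y0} for nu={nu}; "
                "boundary state is a corner equilibrium of the clamped flow",
                stacklevel=2,
            )
            continue
        out.append(
            _make_fixed_point(res.x, kind, lam, eta, r, c, nu, jac_step)
        )
    return out


def interior_fixed_point(
    lam: float, eta: float, r: float, c: float, nu: float = 0.0
) -> FixedPoint:
    """The coexistence fixed point, or raise if it does not exist."""
    for fp in find_fixed_points(lam, eta, r, c, nu):
        if fp.kind is FixedPointKind.INTERIOR:
            return fp
    raise ValueError(
        f"no interior fixed point at lam={lam}, eta={eta}, r={r}, c={c}"
    )


def fluctuation_onset(
    lam: float,
    eta: float,
    c: float,
    nu: float = 0.0,
    r_lo: float | None = None,
    r_hi: float = 20.0,
    tol: float = 1e-4,
    n_scan: int = 40,
) -> float:
    """Critical enhancement factor where the interior fixed point destabilises.

    Scans ``[r_lo, r_hi]`` for a sign change of the largest real eigenvalue
    part of the interior fixed point, then bisects to ``tol`` in r.  Defaults
    ``r_lo`` to slightly above the cooperation onset r*.
    """
    if r_lo is None:
        r_lo = cooperation_threshold(lam, eta) + 0.05 if lam > 0 else 1.05

    def max_re(r: float) -> float:
        return interior_fixed_point(lam, eta, r, c, nu).max_real_eigenvalue

    grid = np.linspace(r_lo, r_hi, n_scan)
    vals = [max_re(r) for r in grid]
    for i in range(len(grid) - 1):
        if vals[i] < 0 <= vals[i + 1]:
            return float(brentq(max_re, grid[i], grid[i + 1], xtol=tol))
    raise ValueError(
        f"no stability crossing of the interior fixed point in "
        f"[{r_lo}, {r_hi}] (max Re eigenvalue range "
        f"[{min(vals):.3g}, {max(vals):.3g}])"
    )


def phase_boundaries(
    r_grid: Sequence[float],
    ratio_grid: Sequence[float],
    eta: float = 0.4,
    c: float = 0.1,
    nu: float = 0.0,
    r_hi: float = 25.0,
) -> pd.DataFrame:
    """Classify a (r, lam/eta) grid from the mean-field theory.

    For each basal-inflow ratio the cooperation onset r* (closed form) and
    the fluctuation onset r_c (interior-fixed-point instability) split the r
    axis into no-cooperation / coexistence / fluctuating; parameter points
    whose equilibrium is the cooperators-only branch are labelled
    full-cooperation.  Returns a tidy DataFrame with columns
    ``r, ratio, lam, eta, phase``.
    """
    rows = []
    for ratio in ratio_grid:
        lam = ratio * eta
        r_star = cooperation_threshold(lam, eta)
        try:
            r_c = fluctuation_onset(lam, eta, c, nu, r_hi=r_hi)
        except ValueError:
            r_c = np.inf
        for r in r_grid:
            if r <= r_star:
                phase = Phase.NO_COOPERATION
            else:
                sol = equilibrium_densities(lam, eta, r, c)
                if sol.branch is Branch.FULL_COOPERATION:
                    phase = Phase.FULL_COOPERATION
                elif r > r_c:
                    phase = Phase.COEXISTENCE_FLUCTUATING
                else:
                    phase = Phase.COEXISTENCE
            rows.append(
                {"r": r, "ratio": ratio, "lam": lam, "eta": eta,
                 "phase": phase.value}
            )
    return pd.DataFrame(rows)
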