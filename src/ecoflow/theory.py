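"""Closed-form equilibrium theory for the perfectly mixed model (q = 1).

Two principles pin down the stationary state.  Resource conservation:
production (basal inflow ``lam`` per site plus the cooperative surplus
``(r-1) c rho_C``) balances consumption ``eta rho``.  Payoff equality: in a
mixed population the basal share is the same for both strategies, so
coexistence requires equal mean game payoffs.

With site occupancies Poisson-distributed (the q = 1 limit), the mean
payoffs have closed forms.  Writing ``g(rho) = (exp(-rho) + rho - 1)/rho^2``
(so ``g(0) = 1/2``):

    pi_C = c (r - 1) - c r rho_D g(rho)
    pi_D = c r rho_C g(rho)

These are algebraically identical to the double-Poisson sums over group
compositions.  Equal payoffs force ``exp(-rho) = 1 - rho/r``, whose positive
root is ``rho = r + W0(-r e^{-r})`` with ``W0`` the principal Lambert-W
branch; combining with resource conservation yields the three density
branches (defectors only / coexistence / cooperators only).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import lambertw

__all__ = [
    "Branch",
    "EquilibriumSolution",
    "ThresholdReport",
    "poisson_group_weight",
    "expected_payoffs_poisson",
    "equilibrium_densities",
    "cooperation_threshold",
    "zero_lambda_threshold",
    "coop_defector_ratio",
    "onset_payoff_identity",
]

# Branch-selection tolerance at exact boundaries.
_BOUNDARY_TOL = 1e-12


class Branch(str, Enum):
    """The three equilibrium regimes."""

    NO_COOPERATION = "I"       # defectors only, rho_D = lam/eta
    COEXISTENCE = "II"         # Lambert-W coexistence densities
    FULL_COOPERATION = "III"   # cooperators only, rho_C = lam/(eta-(r-1)c)


@dataclass(frozen=True)
class EquilibriumSolution:
    branch: Branch
    rho_C: float
    rho_D: float

    @property
    def rho(self) -> float:
        return self.rho_C + self.rho_D

    @property
    def m(self) -> float:
        return self.rho_C / self.rho if self.rho > 0 else 0.0


@dataclass(frozen=True)
class ThresholdReport:
    """Cooperation onset thresholds for a parameter set."""

    r_star: float                # onset for lam > 0, depends only on lam/eta
    zero_lambda_threshold: float  # 1 + eta/c, the lam -> 0 limit
    gamma: float | None = None   # cooperator:defector ratio, when requested


def _g(rho: np.ndarray | float) -> np.ndarray | float:
    """(exp(-rho) + rho - 1) / rho**2, stable down to rho = 0 (limit 1/2)."""
    rho = np.asarray(rho, dtype=float)
    out = np.empty_like(rho)
    small = rho < 1e-6
    rs = rho[small]
    # 4th-order series around 0 avoids the 0/0 at tiny densities.
    out[small] = 0.5 - rs / 6.0 + rs**2 / 24.0 - rs**3 / 120.0
    rb = rho[~small]
    out[~small] = (np.expm1(-rb) + rb) / rb**2
    return out if out.ndim else float(out)


def poisson_group_weight(n_c: int, n_d: int, rho_c: float, rho_d: float) -> float:
    """Probability that a focal individual finds ``n_c`` cooperators and
    ``n_d`` defectors (besides itself) on its site, in the mixed limit."""
    from scipy.stats import poisson

    return float(poisson.pmf(n_c, rho_c) * poisson.pmf(n_d, rho_d))


def expected_payoffs_poisson(
    rho_C: float, rho_D: float, r: float, c: float
) -> tuple[float, float]:
    """Mean game payoffs of a focal cooperator / defector at given densities.

    The focal individual sees Poisson(rho_C) cooperators and Poisson(rho_D)
    defectors besides itself.  Valid for the perfectly mixed topology.

    Returns ``(pi_C, pi_D)``.  In the empty limit ``pi_C -> c (r - 1)``
    (a lone cooperator keeps its own amplified investment) and ``pi_D -> 0``.
    """
    if rho_C < 0 or rho_D < 0:
        raise ValueError("densities must be non-negative")
    rho = rho_C + rho_D
    g = _g(rho)
    pi_c = c * (r - 1.0) - c * r * rho_D * g
    pi_d = c * r * rho_C * g
    return float(pi_c), float(pi_d)


def equilibrium_densities(
    lam: float, eta: float, r: float, c: float
) -> EquilibriumSolution:
    """Stationary densities from resource conservation + payoff equality.

    Branch selection: the coexistence candidate densities are

        rho_C = (-lam + r eta + eta W0(-r e^{-r})) / (c (r - 1))
        rho_D = r + W0(-r e^{-r}) - rho_C

    If the candidate rho_C is negative the population is defectors-only with
    ``rho_D = lam/eta``; if the candidate rho_D is negative it is
    cooperators-only with ``rho_C = lam/(eta - (r-1) c)`` (which requires
    ``eta > (r-1) c`` for a finite density when lam > 0).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if eta <= 0 or c <= 0:
        raise ValueError("eta and c must be positive")
    if r <= 1:
        raise ValueError("enhancement factor r must exceed 1")
    # -r e^{-r} lies in (-1/e, 0) for r > 1; clamp against rounding.
    arg = max(-r * np.exp(-r), -1.0 / np.e + 1e-15)
    w = float(lambertw(arg, 0).real)
    rho_c2 = (-lam + r * eta + eta * w) / (c * (r - 1.0))
    rho_d2 = r + w - rho_c2
    # Exact boundaries (candidate density = 0 within tolerance) are assigned
    # to the boundary branch, where the two solutions coincide.
    if rho_c2 < _BOUNDARY_TOL:
        return EquilibriumSolution(Branch.NO_COOPERATION, 0.0, lam / eta)
    if rho_d2 < _BOUNDARY_TOL:
        denom = eta - (r - 1.0) * c
        if denom <= 0:
            if lam > 0:
                raise ValueError(
                    "no finite full-cooperation equilibrium: eta <= (r-1)c "
                    "while lam > 0 (unbounded growth)"
                )
            return EquilibriumSolution(Branch.FULL_COOPERATION, 0.0, 0.0)
        return EquilibriumSolution(Branch.FULL_COOPERATION, lam / denom, 0.0)
    return EquilibriumSolution(Branch.COEXISTENCE, max(rho_c2, 0.0), max(rho_d2, 0.0))


def cooperation_threshold(lam: float, eta: float) -> float:
    """Critical enhancement factor r* = (lam/eta) / (1 - exp(-lam/eta)).

    Above r* cooperation invades an all-defector equilibrium; the threshold
    depends only on the ratio lam/eta (basal inflow over metabolic rate).
    """
    if lam <= 0:
        raise ValueError(
            "cooperation_threshold requires lam > 0; "
            "use zero_lambda_threshold for the lam -> 0 limit"
        )
    if eta <= 0:
        raise ValueError("eta must be positive")
    x = lam / eta
    return float(x / -np.expm1(-x))


def zero_lambda_threshold(eta: float, c: float) -> float:
    """Onset of cooperation without basal inflow: r must exceed 1 + eta/c.

    Equivalently the cooperative surplus c (r - 1) must exceed the metabolic
    rate eta, or the population cannot sustain itself at lam = 0.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    if eta <= 0:
        raise ValueError("eta must be positive")
    return 1.0 + eta / c


def coop_defector_ratio(
    lam: float, rho_D: float, r: float, c: float, eta: float
) -> float:
    """Cooperator-to-defector density ratio from resource conservation.

    gamma = -(lam/rho_D) / ((r-1) c - eta) + eta / ((r-1) c - eta);
    at lam = 0 this reduces to eta / ((r-1) c - eta), positive exactly when
    r exceeds 1 + eta/c.
    """
    if rho_D <= 0:
        raise ValueError("rho_D must be positive")
    denom = (r - 1.0) * c - eta
    if denom == 0:
        raise ValueError("(r-1) c == eta: ratio is singular")
    return float(-(lam / rho_D) / denom + eta / denom)


def onset_payoff_identity(rho_D: float, r: float, c: float) -> float:
    """Expected net payoff of a lone mutant cooperator among defectors.

    E[r c / (1 + n_D) - c] with n_D ~ Poisson(rho_D), in closed form
    ``c (r (1 - e^{-rho_D}) / rho_D - 1)``.  Its zero in rho_D = lam/eta
    reproduces the cooperation threshold r*.
    """
    if rho_D < 0:
        raise ValueError("rho_D must be non-negative")
    if rho_D == 0:
        return float(c * (r - 1.0))
    return float(c * (r * -np.expm1(-rho_D) / rho_D - 1.0))


def threshold_report(
    lam: float, eta: float, c: float, rho_D: float | None = None, r: float | None = None
) -> ThresholdReport:
    """Bundle the onset thresholds (and optionally gamma) for one parameter set."""
    gamma = None
    if rho_D is not None and r is not None:
        gamma = coop_defector_ratio(lam, rho_D, r, c, eta)
    return ThresholdReport(
        r_star=cooperation_threshold(lam, eta) if lam > 0 else 1.0 + eta / c,
        zero_lambda_threshold=zero_lambda_threshold(eta, c),
        gamma=gamma,
    )
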