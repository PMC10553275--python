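"""Per-site public goods game.

Every individual on a site plays one round of a public goods game with all
co-occupants.  Cooperators each invest a cost ``c``; the pooled investment is
multiplied by the enhancement factor ``r`` and shared equally by everyone on
the site, cooperators and defectors alike.  A focal individual in a group of
size ``k`` containing ``k_C`` cooperators therefore receives

    payoff = r * c * k_C / k - (c if cooperator else 0)

A lone cooperator self-benefits ``c * (r - 1)``; a lone defector gets 0.  The
net energy produced at a site is exactly ``(r - 1) * c * k_C``.

The engine talks to the game only through the small :class:`Game` interface,
so other interaction structures can be plugged in without touching the
simulation loop.
"""

from __future__ import annotations

from typing import Protocol, Sequence

import numpy as np


class Game(Protocol):
    """Interface the engine requires of an interaction model."""

    def payoffs_for_population(
        self, is_coop: np.ndarray, site: np.ndarray, n_sites: int
    ) -> np.ndarray:
        """Per-agent payoffs given each agent's strategy and site index."""
        ...


def site_payoffs(strategies: Sequence[str], r: float, c: float) -> np.ndarray:
    """Payoffs of a single co-located group, in input order.

    Parameters
    ----------
    strategies
        Non-empty sequence of ``"C"`` / ``"D"`` labels.
    r, c
        Enhancement factor (> 1) and cooperation cost (> 0).

    Returns
    -------
    numpy.ndarray
        One payoff per individual, same order as ``strategies``.
    """
    if len(strategies) == 0:
        raise ValueError("site_payoffs requires a non-empty group")
    is_coop = np.asarray([s == "C" for s in strategies], dtype=bool)
    if not all(s in ("C", "D") for s in strategies):
        raise ValueError("strategies must be 'C' or 'D'")
    k = is_coop.size
    k_c = int(is_coop.sum())
    share = r * c * k_c / k
    return share - c * is_coop.astype(float)


class PublicGoodsGame:
    """Vectorised public goods game over a whole population.

    ``payoffs_for_population`` computes, in one pass, the payoff of every
    agent from the game played on its site.
    """

    def __init__(self, r: float, c: float):
        if r <= 1:
            raise ValueError("enhancement factor r must exceed 1")
        if c <= 0:
            raise ValueError("cost c must be positive")
        self.r = float(r)
        self.c = float(c)

    def payoffs_for_population(
        self, is_coop: np.ndarray, site: np.ndarray, n_sites: int
    ) -> np.ndarray:
        occ = np.bincount(site, minlength=n_sites)
        n_c = np.bincount(site[is_coop], minlength=n_sites)
        share = np.zeros(n_sites)
        occupied = occ > 0
        share[occupied] = self.r * self.c * n_c[occupied] / occ[occupied]
        return share[site] - self.c * is_coop.astype(float)

    def payoffs_for_group(self, strategies: Sequence[str]) -> np.ndarray:
        return site_payoffs(strategies, self.r, self.c)
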