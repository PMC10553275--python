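"""Stochastic agent-based engine for the resource-flow model.

Individuals live on an ``L x L`` grid of sites.  Each site carries a stock of
basal resource that regenerates by ``lam`` per step.  Every step applies five
stages in a fixed order:

1. **gather + play** - each site's standing stock is split equally among its
   occupants, and everyone receives a public goods payoff from the game
   played with its co-occupants; both gains are added to internal energy.
2. **reproduce** - every individual with energy strictly above ``d`` divides:
   parent and offspring each keep half, the offspring starts on the parent's
   site and inherits the strategy, flipped with probability ``nu``.
3. **move** - each individual (newborns included) relocates with probability
   ``q``: to a uniformly chosen Moore neighbour (periodic boundaries) on the
   lattice, or to a uniformly chosen site in the mixed topology.
4. **metabolize + cull** - everyone pays ``eta``; individuals whose energy
   drops strictly below zero die.  If the population goes extinct, a single
   immigrant with a random strategy arrives on a random site.
5. **regenerate** - every site's stock increases by ``lam``.

The population state is held in flat numpy arrays (one slot per living
agent, kept in id order), so every stage is a vectorised pass.  All
randomness flows through one seeded generator per world, drawn in a fixed
stage-and-array order, which makes runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .game import Game, PublicGoodsGame
from .params import Params

# Moore neighbourhood displacement table (8 neighbours, self excluded).
_MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

TIME_SERIES_COLUMNS = [
    "t", "N_C", "N_D", "rho", "rho_C", "rho_D", "m",
    "payoff_C", "payoff_D", "basal_C", "basal_D",
    "births_C", "births_D", "deaths_C", "deaths_D",
    "mean_energy", "immigration",
]

LIFESPAN_COLUMNS = ["strategy", "birth_time", "death_time", "lifespan"]


@dataclass
class World:
    """Complete mutable simulation state.

    Agent attributes are parallel arrays in id (birth) order; transient
    per-step quantities (``last_basal``, ``last_payoff``) refer to the most
    recent gather stage.
    """

    t: int
    L: int
    stock: np.ndarray              # (L*L,) basal resource per site
    agent_id: np.ndarray           # (N,) unique int ids
    is_coop: np.ndarray            # (N,) bool
    energy: np.ndarray             # (N,) float
    site: np.ndarray               # (N,) int site index in [0, L*L)
    birth_time: np.ndarray         # (N,) int step of birth
    rng: np.random.Generator
    next_agent_id: int
    last_basal: np.ndarray = field(default_factory=lambda: np.empty(0))
    last_payoff: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_agents(self) -> int:
        return self.site.size

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    def total_energy(self) -> float:
        return float(self.energy.sum())

    def site_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (cooperator, defector) counts as L x L grids."""
        n_c = np.bincount(self.site[self.is_coop], minlength=self.n_sites)
        n_d = np.bincount(self.site[~self.is_coop], minlength=self.n_sites)
        return n_c.reshape(self.L, self.L), n_d.reshape(self.L, self.L)


@dataclass(frozen=True)
class StepRecord:
    """Per-step aggregates (the row contract of the time-series output).

    Per-strategy payoff and basal means average over agents alive at the
    gather stage and are NaN when the strategy is absent then.
    ``ledger_residual`` is the energy-bookkeeping mismatch of the step (see
    :func:`step`); it is diagnostic and not part of the CSV contract.
    """

    t: int
    N_C: int
    N_D: int
    rho: float
    rho_C: float
    rho_D: float
    m: float
    payoff_C: float
    payoff_D: float
    basal_C: float
    basal_D: float
    births_C: int
    births_D: int
    deaths_C: int
    deaths_D: int
    mean_energy: float
    immigration: bool
    ledger_residual: float = 0.0


@dataclass(frozen=True)
class LifespanEvents:
    """Column batch of death events emitted by one or more steps.

    ``residual_energy`` holds each dead agent's (strictly negative) energy
    after its final metabolic payment; it is deleted from the system on
    removal and is what closes the per-step energy ledger.
    """

    strategy: np.ndarray     # bool, True = cooperator
    birth_time: np.ndarray
    death_time: np.ndarray
    residual_energy: np.ndarray

    @property
    def lifespan(self) -> np.ndarray:
        # A newborn dying in its birth step (possible only when d < 2*eta)
        # counts as having lived one step.
        return np.maximum(1, self.death_time - self.birth_time)

    def __len__(self) -> int:
        return self.strategy.size


@dataclass
class RunResult:
    """Output of :func:`run`: per-step records, deaths and optional snapshots."""

    params: Params
    time_series: pd.DataFrame
    lifespans: pd.DataFrame
    snapshots: list[tuple[int, np.ndarray, np.ndarray]]

    @property
    def records(self) -> pd.DataFrame:  # convenience alias
        return self.time_series


def init_world(params: Params) -> World:
    """Create the initial world: founders on random sites, empty stocks.

    Founders are all defectors unless ``init_coop_fraction`` asks for a mixed
    start; each founder's site is an independent uniform draw, and the
    generator is seeded from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n0 = params.init_population
    site = rng.integers(0, params.n_sites, n0)
    is_coop = rng.random(n0) < params.init_coop_fraction
    return World(
        t=0,
        L=params.L,
        stock=np.zeros(params.n_sites),
        agent_id=np.arange(n0, dtype=np.int64),
        is_coop=is_coop,
        energy=np.full(n0, params.e0),
        site=site,
        birth_time=np.zeros(n0, dtype=np.int64),
        rng=rng,
        next_agent_id=n0,
    )


def stage_gather_and_play(
    world: World, params: Params, game: Optional[Game] = None
) -> World:
    """Split each site's standing stock among occupants and play the game.

    The entire stock of every occupied site is consumed (unoccupied sites
    keep accumulating); each agent's share and game payoff are recorded in
    ``last_basal`` / ``last_payoff`` and added to its energy.
    """
    if game is None:
        game = PublicGoodsGame(params.r, params.c)
    n_sites = world.n_sites
    if world.n_agents == 0:
        world.last_basal = np.empty(0)
        world.last_payoff = np.empty(0)
        return world
    occ = np.bincount(world.site, minlength=n_sites)
    kappa = world.stock[world.site] / occ[world.site]
    payoff = game.payoffs_for_population(world.is_coop, world.site, n_sites)
    world.energy += kappa + payoff
    world.stock[occ > 0] = 0.0
    world.last_basal = kappa
    world.last_payoff = payoff
    return world


def stage_reproduce(
    world: World, params: Params
) -> tuple[World, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Divide every agent whose energy strictly exceeds ``d``.

    Parent and child each keep half the energy; the child is placed on the
    parent's site with the parent's strategy, flipped with probability
    ``nu``.  At most one division per agent per step.  Returns
    ``(world, (parent_ids, child_ids, child_is_coop))``.
    """
    dividing = world.energy > params.d
    n_births = int(dividing.sum())
    if n_births == 0:
        empty = np.empty(0, dtype=np.int64)
        return world, (empty, empty, np.empty(0, dtype=bool))
    world.energy[dividing] *= 0.5
    flip = world.rng.random(n_births) < params.nu
    child_coop = world.is_coop[dividing] ^ flip
    child_ids = np.arange(
        world.next_agent_id, world.next_agent_id + n_births, dtype=np.int64
    )
    parent_ids = world.agent_id[dividing]
    world.agent_id = np.concatenate([world.agent_id, child_ids])
    world.is_coop = np.concatenate([world.is_coop, child_coop])
    world.energy = np.concatenate([world.energy, world.energy[dividing]])
    world.site = np.concatenate([world.site, world.site[dividing]])
    world.birth_time = np.concatenate(
        [world.birth_time, np.full(n_births, world.t + 1, dtype=np.int64)]
    )
    world.next_agent_id += n_births
    return world, (parent_ids, child_ids, child_coop)


def stage_move(world: World, params: Params) -> World:
    """Relocate each agent with probability ``q`` (newborns included)."""
    n = world.n_agents
    if n == 0 or params.q == 0.0:
        return world
    moving = world.rng.random(n) < params.q
    n_mov = int(moving.sum())
    if n_mov == 0:
        return world
    if params.topology == "mixed":
        world.site[moving] = world.rng.integers(0, world.n_sites, n_mov)
    else:
        L = world.L
        offs = _MOORE[world.rng.integers(0, 8, n_mov)]
        row = world.site[moving] // L
        col = world.site[moving] % L
        world.site[moving] = ((row + offs[:, 0]) % L) * L + (col + offs[:, 1]) % L
    return world


def stage_metabolize_and_cull(
    world: World, params: Params
) -> tuple[World, LifespanEvents, bool]:
    """Charge the metabolic cost, remove the starved, rescue extinction.

    Every agent pays ``eta``; agents whose energy is then strictly negative
    die and emit a lifespan event.  If nobody survives, a single immigrant
    with a uniformly random strategy, site and energy ``e0`` is added.
    Returns ``(world, deaths, immigration_flag)``.
    """
    world.energy -= params.eta
    dead = world.energy < 0.0
    deaths = LifespanEvents(
        strategy=world.is_coop[dead].copy(),
        birth_time=world.birth_time[dead].copy(),
        death_time=np.full(int(dead.sum()), world.t + 1, dtype=np.int64),
        residual_energy=world.energy[dead].copy(),
    )
    if dead.any():
        keep = ~dead
        world.agent_id = world.agent_id[keep]
        world.is_coop = world.is_coop[keep]
        world.energy = world.energy[keep]
        world.site = world.site[keep]
        world.birth_time = world.birth_time[keep]
    immigration = world.n_agents == 0
    if immigration:
        world.agent_id = np.array([world.next_agent_id], dtype=np.int64)
        world.next_agent_id += 1
        world.is_coop = world.rng.random(1) < 0.5
        world.energy = np.array([params.e0])
        world.site = world.rng.integers(0, world.n_sites, 1)
        world.birth_time = np.array([world.t + 1], dtype=np.int64)
    return world, deaths, immigration


def stage_regenerate(world: World, params: Params) -> World:
    """Add ``lam`` to every site's basal stock."""
    world.stock += params.lam
    return world


def step(
    world: World, params: Params, game: Optional[Game] = None
) -> tuple[World, StepRecord, LifespanEvents]:
    """Advance one time step (all five stages, fixed order).

    The returned :class:`StepRecord` aggregates payoff/basal means over
    agents alive at the gather stage, birth and death counts of the step,
    and post-step population state.  ``ledger_residual`` checks the step's
    energy bookkeeping: the change of (total agent energy + total stock)
    must equal basal inflow + game surplus - metabolic dissipation
    - energy removed with the dead + immigrant energy.
    """
    before = world.total_energy() + float(world.stock.sum())

    world = stage_gather_and_play(world, params, game)
    coop_gather = world.is_coop
    n_c_gather = int(coop_gather.sum())
    pay, bas = world.last_payoff, world.last_basal
    payoff_c = float(pay[coop_gather].mean()) if n_c_gather else float("nan")
    basal_c = float(bas[coop_gather].mean()) if n_c_gather else float("nan")
    n_d_gather = coop_gather.size - n_c_gather
    payoff_d = float(pay[~coop_gather].mean()) if n_d_gather else float("nan")
    basal_d = float(bas[~coop_gather].mean()) if n_d_gather else float("nan")
    game_surplus = (params.r - 1.0) * params.c * n_c_gather

    world, (_, _, child_coop) = stage_reproduce(world, params)
    births_c = int(child_coop.sum())
    births_d = child_coop.size - births_c

    world = stage_move(world, params)

    n_at_cull = world.n_agents
    world, deaths, immigration = stage_metabolize_and_cull(world, params)
    deaths_c = int(deaths.strategy.sum())
    deaths_d = len(deaths) - deaths_c

    world = stage_regenerate(world, params)
    world.t += 1

    after = world.total_energy() + float(world.stock.sum())
    expected = (
        game_surplus
        - params.eta * n_at_cull
        - float(deaths.residual_energy.sum())  # dead residuals are deleted
        + (params.e0 if immigration else 0.0)
        + params.lam * world.n_sites
    )
    ledger_residual = (after - before) - expected

    n = world.n_agents
    n_c = int(world.is_coop.sum())
    n_d = n - n_c
    rho = n / world.n_sites
    rho_c = n_c / world.n_sites
    rho_d = n_d / world.n_sites
    record = StepRecord(
        t=world.t,
        N_C=n_c,
        N_D=n_d,
        rho=rho,
        rho_C=rho_c,
        rho_D=rho_d,
        m=(n_c / n) if n else 0.0,
        payoff_C=payoff_c,
        payoff_D=payoff_d,
        basal_C=basal_c,
        basal_D=basal_d,
        births_C=births_c,
        births_D=births_d,
        deaths_C=deaths_c,
        deaths_D=deaths_d,
        mean_energy=float(world.energy.mean()) if n else float("nan"),
        immigration=immigration,
        ledger_residual=float(ledger_residual),
    )
    return world, record, deaths


def run(
    params: Params,
    snapshot_every: Optional[int] = None,
    game: Optional[Game] = None,
    progress: Optional["callable"] = None,
) -> RunResult:
    """Simulate ``params.steps`` steps from a fresh world.

    Returns the complete per-step time series, all death events, and
    (optionally) per-site strategy-count snapshots every ``snapshot_every``
    steps.  Fully reproducible given ``params.seed``.
    """
    world = init_world(params)
    rows: list[StepRecord] = []
    death_batches: list[LifespanEvents] = []
    snapshots: list[tuple[int, np.ndarray, np.ndarray]] = []
    for _ in range(params.steps):
        world, record, deaths = step(world, params, game)
        rows.append(record)
        if len(deaths):
            death_batches.append(deaths)
        if snapshot_every and world.t % snapshot_every == 0:
            n_c_grid, n_d_grid = world.site_counts()
            snapshots.append((world.t, n_c_grid, n_d_grid))
        if progress is not None and world.t % 1000 == 0:
            progress(world.t, params.steps)
    time_series = pd.DataFrame(rows)
    time_series["immigration"] = time_series["immigration"].astype(int)
    if death_batches:
        lifespans = pd.DataFrame(
            {
                "strategy": np.where(
                    np.concatenate([b.strategy for b in death_batches]), "C", "D"
                ),
                "birth_time": np.concatenate([b.birth_time for b in death_batches]),
                "death_time": np.concatenate([b.death_time for b in death_batches]),
            }
        )
        lifespans["lifespan"] = np.maximum(
            1, lifespans["death_time"] - lifespans["birth_time"]
        )
    else:
        lifespans = pd.DataFrame(
            {c: pd.Series(dtype="int64" if c != "strategy" else "object")
             for c in LIFESPAN_COLUMNS}
        )
    return RunResult(
        params=params,
        time_series=time_series,
        lifespans=lifespans,
        snapshots=snapshots,
    )
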