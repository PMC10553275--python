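"""Model parameters.

All model constants live in a single validated, immutable record.  Energy is
the only dimensional quantity: the basal inflow ``lam`` (per site per step),
the metabolic rate ``eta`` (per individual per step), the division threshold
``d``, and the cooperation cost ``c`` are all expressed in the same energy
units; one simulation step is the time unit.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Any

TOPOLOGIES = ("mixed", "lattice_moore")


@dataclass(frozen=True)
class Params:
    """Full parameter set of the resource-flow model.

    Parameters
    ----------
    r
        Enhancement factor of the public goods game (dimensionless, > 1):
        pooled investments are multiplied by ``r`` before being shared.
    lam
        Basal-resource regeneration rate per lattice site per step.
    eta
        Metabolic rate: energy dissipated by every individual each step.
    d
        Reproduction threshold: an individual whose internal energy exceeds
        ``d`` divides, splitting its energy equally with the offspring.
    c
        Cost paid by a cooperator each step to invest in the public good.
    nu
        Mutation probability per birth (offspring strategy is flipped).
    q
        Movement probability per individual per step.
    L
        Lattice side; the world has ``L * L`` sites.
    topology
        ``"mixed"`` (every site adjacent to every site) or
        ``"lattice_moore"`` (8-neighbour lattice, periodic boundaries).
    steps
        Number of time steps to simulate.
    burn_in
        Steps discarded before taking time averages.
    seed
        Seed for the single per-world pseudo-random generator.
    init_population
        Number of founder individuals.
    init_energy
        Founder (and rescue-immigrant) internal energy; defaults to ``d / 2``.
    init_coop_fraction
        Fraction of founders initialised as cooperators.  The default 0
        starts from an all-defector population, so cooperation must arise
        through mutation.
    """

    r: float = 3.0
    lam: float = 0.6
    eta: float = 0.4
    d: float = 2.0
    c: float = 0.1
    nu: float = 1e-4
    q: float = 1.0
    L: int = 100
    topology: str = "mixed"
    steps: int = 10000
    burn_in: int = 4000
    seed: int = 0
    init_population: int = 100
    init_energy: float | None = None
    init_coop_fraction: float = 0.0

    def __post_init__(self) -> None:
        def fail(field: str, msg: str) -> None:
            raise ValueError(f"invalid Params.{field}: {msg}")

        if not self.L >= 1:
            fail("L", f"lattice side must be a positive integer, got {self.L}")
        if self.topology not in TOPOLOGIES:
            fail("topology", f"must be one of {TOPOLOGIES}, got {self.topology!r}")
        for name in ("r", "lam", "eta", "d", "c", "nu", "q"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v == v and abs(v) != float("inf")):
                fail(name, f"must be a finite number, got {v!r}")
        if self.lam < 0:
            fail("lam", "regeneration rate must be non-negative")
        if self.eta <= 0:
            fail("eta", "metabolic rate must be positive")
        if self.d <= 0:
            fail("d", "reproduction threshold must be positive")
        if self.r <= 1:
            fail("r", f"enhancement factor must exceed 1, got {self.r}")
        if self.c <= 0:
            fail("c", "cooperation cost must be positive")
        if not 0.0 <= self.nu <= 1.0:
            fail("nu", f"mutation probability must lie in [0, 1], got {self.nu}")
        if not 0.0 <= self.q <= 1.0:
            fail("q", f"movement probability must lie in [0, 1], got {self.q}")
        if self.steps < 1:
            fail("steps", "must be a positive integer")
        if not 0 <= self.burn_in < self.steps:
            fail("burn_in", f"must satisfy 0 <= burn_in < steps, got {self.burn_in}")
        if self.seed < 0:
            fail("seed", "must be a non-negative integer")
        if self.init_population < 1:
            fail("init_population", "must be a positive integer")
        if self.init_energy is not None and self.init_energy <= 0:
            fail("init_energy", "must be positive")
        if not 0.0 <= self.init_coop_fraction <= 1.0:
            fail("init_coop_fraction", "must lie in [0, 1]")
        e0 = self.e0
        if e0 >= self.d:
            warnings.warn(
                "init_energy >= d: founders divide immediately at t=0",
                stacklevel=2,
            )

    @property
    def e0(self) -> float:
        """Founder energy (``init_energy`` or the default ``d / 2``)."""
        return self.d / 2.0 if self.init_energy is None else self.init_energy

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    def replace(self, **kwargs: Any) -> "Params":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["init_energy"] = self.e0
        return out
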