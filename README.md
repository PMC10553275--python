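# ecoflow

Eco-evolutionary dynamics driven by resource flow: an agent-based simulator
of individuals who gather regenerating environmental resources, play a
public goods game, pay metabolic costs, divide when their energy budget
allows, and mutate — together with the closed-form equilibrium theory of the
well-mixed limit and the dynamical mean-field equation that predicts when
the equilibrium gives way to sustained fluctuations.

## Who this is for

Researchers in evolutionary game theory and theoretical ecology who want an
explicit-energy alternative to fitness-based selection: here nobody is
"selected" — individuals simply accumulate energy `ε`, dissipate `η` per
step, die when `ε < 0` and divide when `ε > d`, and evolutionary outcomes
(such as whether cooperation survives) emerge from the bookkeeping of
resource production, consumption and flow.

## The model

Each step, on an `L × L` grid (Moore lattice or fully mixed):

1. each site's basal stock (replenished at rate `λ` per site) is split
   equally among its occupants, and every occupant plays a public goods
   game with its co-occupants: cooperators invest `c`, the pot is amplified
   by `r > 1` and shared by all group members;
2. individuals with `ε > d` divide, halving their energy with an offspring
   that inherits their strategy (flipped with probability `ν`);
3. each individual relocates with probability `q`;
4. everyone pays `η`; the starved (`ε < 0`) die; an extinct population is
   rescued by a single random immigrant;
5. stocks regenerate.

Two conservation principles pin down the well-mixed stationary state:
**resource conservation**, `(r−1)c ρ_C + λ = η ρ`, and **payoff equality**
between coexisting strategies. With Poisson site occupancies the mean
payoffs are closed-form, and the stationary densities fall on three
branches:

- defectors only: `ρ_D = λ/η`, when `r < r* = (λ/η) / (1 − e^{−λ/η})`;
- Lambert-W coexistence: `ρ_C + ρ_D = r + W₀(−r e^{−r})`, with
  `ρ_C = (−λ + rη + η W₀(−r e^{−r})) / (c(r−1))`;
- cooperators only: `ρ_C = λ / (η − (r−1)c)`.

The mean-field flow `dρ_s/dt = π̄_s + λ/ρ − η` has these states as fixed
points; the enhancement factor at which its interior fixed point loses
stability marks the onset of non-equilibrium oscillations (well-mixed) and
traveling waves (lattice).

## Worked example

```bash
python examples/01_simulate_basic.py
```

```
time-averaged densities (t > 2000):
  rho_C = 1.823   (equilibrium branch II: 1.951)
  rho_D = 0.321   (equilibrium branch II: 0.281)
  cooperator fraction m = 0.850
  mean payoffs: cooperators 0.1280, defectors 0.1251
  mean basal shares: cooperators 0.2798, defectors 0.2800
  payoff-equality gap = +0.0027 (should be ~0, scale eta = 0.4)
```

Starting from 100 defectors, mutation seeds cooperators and — because
`r = 2.5` exceeds `r* ≈ 1.93` at this basal inflow — they sweep to an 85%
majority. The time-averaged densities land close to the Lambert-W
coexistence point (the minority density runs systematically a few
hundredths high; see `docs/methods.md` for why the agent model is not
exactly its Poisson mean field), and the two strategies' total per-capita
gains are equal to within less than 1% of the metabolic rate: payoff
equality, the economic half of the equilibrium theory, emerges on its own.

The other example scripts cover the equilibrium branch structure
(`02_equilibrium_theory.py`), the fluctuation onset from the mean field
(`03_meanfield_onset.py`), life-history differences between cooperators and
defectors (`04_life_history.py`), and viscosity-driven assortment on the
lattice (`05_viscous_lattice.py`).

A thin CLI wraps the same functions:

```bash
ecoflow theory --r 3 --lambda 0.6 --eta 0.4 --cost 0.1
ecoflow simulate --r 2.5 --size 50 --steps 5000 --burn-in 2000 --seed 1 --out run1
ecoflow meanfield onset --lambda 0.6 --eta 0.4 --cost 0.1 --nu 0
ecoflow phase-scan --r-values 1.5,2.0,2.5 --size 50 --steps 4000 --burn-in 2000
```

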