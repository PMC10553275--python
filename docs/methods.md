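# Methods

## Model definition

The simulator tracks individuals with a single continuous state, internal
energy `ε`, on an `L × L` grid of sites. Each site carries a basal-resource
stock that grows by `λ` per step and is consumed entirely — split equally —
by whatever individuals stand on it. Individuals additionally play one
round of a public goods game per step with their co-occupants: each
cooperator invests `c`, the pooled investment is multiplied by `r > 1` and
divided equally among everyone present. A group of size `k` with `k_C`
cooperators therefore pays each member `r c k_C / k`, minus `c` for
cooperators; the site's net energy production is exactly `(r−1) c k_C`. A
lone cooperator keeps `c(r−1)` of its own amplified investment (group size
one is an ordinary group).

The per-step stage order is fixed: gather + play, reproduce, move,
metabolize + cull, regenerate. Reproduction is binary fission: any
individual with `ε > d` (strict) divides once, parent and offspring each
keeping `ε/2`; the offspring starts on the parent's site and inherits its
strategy, flipped with probability `ν`. Movement relocates each individual
(newborns included) with probability `q` — to a uniformly chosen Moore
neighbour on the periodic lattice, or to a uniformly chosen site (current
site included) in the mixed topology. Metabolism subtracts `η` from
everyone; individuals whose energy is then strictly negative are removed.
An extinct population is rescued by one immigrant with a uniformly random
strategy and site.

Conventions the model statement leaves open, fixed here once:

- founders (and immigrants) start with `e₀ = d/2`, all defectors, on
  independent uniform sites;
- offspring are full individuals immediately: they move and pay `η` in
  their birth step;
- boundaries are periodic (avoids edge artifacts and matches the
  translation-invariant mean field);
- ties are resolved strictly (`ε > d` divides, `ε < 0` dies); both events
  have measure zero for generic parameters;
- a newborn that dies in its birth step (possible only when `d < 2η`) is
  recorded with lifespan 1 — the birth step counts as one step lived;
- all randomness flows through one PCG64 generator per world, consumed in
  a fixed stage-and-array order (individuals in id order), so a run is a
  pure function of its parameters and seed.

## Energy ledger

Every step closes an exact energy budget: the change in (total internal
energy + total stock) equals `λL²` (inflow) plus `(r−1)c·N_C` (cooperative
surplus) minus `η·N` (dissipation) minus the residual energies deleted with
the dead, plus `e₀` per rescue immigrant. The engine records the residual
of this identity per step (`ledger_residual`); it is float64 rounding only
(≲1e-12 of system energy) and is asserted in the tests at 1e-9 relative.

## Equilibrium theory (well-mixed limit)

With `q = 1` the site occupancy seen by a focal individual is Poisson with
the global densities as means. Writing `g(ρ) = (e^{−ρ} + ρ − 1)/ρ²`, the
double-Poisson sums for the mean payoffs collapse to

    π̄_C = c(r−1) − c r ρ_D g(ρ),      π̄_D = c r ρ_C g(ρ),

which are the forms implemented (`g` switches to its 4th-order Maclaurin
series below `ρ = 1e-6`; `g(0) = 1/2`). These satisfy the site-level
production identity `ρ_C π̄_C + ρ_D π̄_D = (r−1)c ρ_C` exactly. Payoff
equality `π̄_C = π̄_D` forces `e^{−ρ} = 1 − ρ/r`, i.e.
`ρ = r + W₀(−r e^{−r})` (the W₀ argument lies in `(−1/e, 0)` for `r > 1`
and is clamped to `≥ −1/e` against rounding); combined with resource
conservation `(r−1)c ρ_C + λ = ηρ` this yields the three density branches.
Branch selection follows the sign of the coexistence candidates, with exact
zeros (tolerance 1e-12) assigned to the boundary branch. One algebraic
consequence used as a test oracle: branch III (`ρ_D^{II} < 0`) implies
`η − (r−1)c > λ/ρ > 0`, so the cooperators-only density is always finite
when `λ > 0`.

The cooperation onset for `λ > 0` is `r* = (λ/η)/(1 − e^{−λ/η})` — the
zero, at the resident density `ρ_D = λ/η`, of the lone-mutant payoff
`c(r(1−e^{−ρ_D})/ρ_D − 1)`; it depends only on the inflow-to-metabolism
ratio. In the strict `λ → 0` limit the persistence condition becomes
`r > 1 + η/c` (the cooperative surplus must beat metabolism). Note that at
any finite `λ > 0` and `r < 1 + η/c` above `r*`, the theory still admits a
small cooperators-only population `ρ_C = λ/(η − (r−1)c)`; the `1 + η/c`
threshold concerns the limit, not small-`λ` parameter points.

## Mean-field dynamics and fluctuation onset

The dynamical mean field grows each subpopulation by its net per-capita
resource gain: `dρ_s/dt = π̄_s + λ/ρ − η` (mixed with weight `ν` between
the two strategies when mutation is included). Its interior fixed point is
the coexistence branch — exactly, for every `ν`, because the mutation
mixing is an invertible linear map of the two growth rates, so the roots do
not move. The all-defector and all-cooperator states are equilibria of the
flow restricted to their boundary; since the growth law is additive (not
proportional), transverse stability there is the sign of the absent type's
growth rate itself, which reproduces `r*` as the invasion condition.
Likewise the cooperator-free axis is only invariant at the resident
equilibrium: below carrying capacity the additive law grows a vanishing
cooperator seed transiently before it decays again.

Numerics: the additive flow reaches zero density in finite time above the
fluctuation onset, and the non-negativity clamp creates a kink on which
adaptive step control stalls. Integration therefore uses a fixed-step
classical RK4 (default `dt = 0.02`) with the state floored at `1e-9` after
every stage; in the smooth regime it is cross-checked against scipy's
LSODA to 1e-7. Fixed points are located by hybrid-Powell root-finding
seeded from the closed-form branches; the Jacobian is central-difference
(step 1e-6); the fluctuation onset `r_c` is found by scanning the largest
real eigenvalue part of the interior fixed point over `r` and bisecting the
sign change to 1e-4. At the standard parameter point
(`λ=0.6, η=0.4, c=0.1, ν=0`) this gives `r_c ≈ 9.2`, with damped spirals
below and a bounded relaxation limit cycle (cooperator booms and crashes)
above.

## Observables

Time averages are arithmetic over steps after the burn-in; per-strategy
payoff and basal means average over the individuals alive at the gather
stage of each step and are undefined (NaN) for steps where the strategy is
absent. Per-capita birth/death rates divide event counts by the per-step
population of the strategy. Lifespan histograms use unit-age bins;
the exponential tail rate is a count-weighted least-squares slope of log
counts over the upper half of the occupied bins with at least 5 events
(weighting by √count matches the Poisson variance of log counts), fitted
only when at least 30 deaths are available. Oscillations are flagged when
the coefficient of variation of the cooperator count over the averaging
window exceeds 0.15 — stable-coexistence runs sit near 0.01–0.03, the
boom–crash regime orders of magnitude higher — and cooperation counts as
present when the time-averaged cooperator fraction exceeds 0.05 (mutation
alone sustains a far smaller minority). Both thresholds are configurable.

## What the simulations show, and their limits

The test suite and the acceptance script run the model at desk scale:
`L = 50` (2 500 sites, stationary populations of roughly 3 500–10 000
individuals), 3 000–5 000 steps with 1 000–2 000 steps of burn-in, and 2–3
seeds per condition, against the paper-scale choice of `L = 100` and 10⁴–
1.5·10⁴ steps. At this scale the defector-only density matches `λ/η` to
~3%, coexistence matches the Lambert-W point to ~6% in the majority
density, conservation residuals sit under 2%, and the payoff-equality gap
under 1% of `η`.

One deviation is systematic and worth knowing about: the minority
(defector) density in coexistence runs ~10–14% above the Poisson
mean-field value (an absolute offset of a few hundredths). It is not a
transient and not finite-size noise (it persists at `L = 100` with a 1%
coefficient of variation). The agent model is not exactly its mean field:
division is a threshold event, so selection depends on the correlation
between an individual's energy, its payoff history and its division
timing, not on mean payoff alone — changing `d` at fixed mean payoffs
shifts the stationary composition markedly. The theory treats `d` as
irrelevant; the agents do not.

In the resource-poor regime (`λ ≈ 0`) with `(r−1)c > η`, cooperator booms
are exponential and are arrested only when the mutation-seeded defector
load reaches a fraction `((r−1)c − η)/(rc)` of the population; at `L = 50`
each boom peaks near 3·10⁶ individuals before crashing to a handful of
survivors. These boom–crash cycles are the finite-population face of the
mean-field limit cycle; simulating them is memory-bound, which is why the
resource-poor runs use 3 000 steps.

The generator produces the study conditions themselves (there is no
external data): all-defector initial conditions exercise establishment by
mutation; the mixed-start option (`init_coop_fraction`) is used for viscous
lattices, where establishment from a single mutant cluster is slow and the
question of interest is the stationary pattern, not the establishment
time. What passing tests show is internal consistency of simulation,
closed-form theory and mean field at these scales; they do not show
anything about real ecosystems — the model has one resource, one game,
binary strategies, synchronous stages and no age structure or
spatial heterogeneity beyond the lattice itself.

## Known limitations

- The equilibrium closed forms hold only for the mixed topology (`q = 1`);
  viscous and lattice predictions come from simulation only.
- The payoff-before-consequences convention (gains and costs settle within
  the step, before reproduction and death) matches interactions fast
  relative to a generation; a variant where individuals can starve at the
  investment stage would introduce `d`- and `c`-dependent corrections and
  is not implemented.
- `phase-scan` over many grid points is sequential; budget roughly a few
  seconds per replicate at `L = 50`.
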