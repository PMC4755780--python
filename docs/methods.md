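# Methods

`swarmevo` simulates the evolution of collective sensing in populations of
self-propelled agents foraging on dynamic resource landscapes. This note
documents the model, its numerical treatment, the synthetic study conditions,
and the design choices made where the design was genuinely open.

## Model

### Agents

`N` agents live on a square torus of edge length `L` (lengths in units of the
repulsion length scale `lr`, time in units of the step `τ`). Agent `i` obeys

    dx_i/dt = v_i,
    m dv_i/dt = F_s,i + F_a,i.

**Social force.** `F_s,i` is the negative gradient of a double-exponential
pair potential summed over the neighbour set `N_i`:

    F_s,i = Σ_{j∈N_i} [ (Cr/lr) e^{-d_ij/lr} − (Ca/la) e^{-d_ij/la} ] r̂_ij,

with `d_ij` the minimum-image distance and `r̂_ij` the unit vector from `j`
to `i`. `N_i` holds the `k` nearest other agents within the focal agent's
heritable interaction range `lmax`; the relation is not symmetric. Defaults
(`Cr=1.1, Ca=1, lr=1, la=7.5, k=25`) put the pair-force zero crossing at
`d* = ln(8.25)/(1−1/7.5) ≈ 2.435`: repulsion inside, attraction outside. An
agent whose `lmax` lies between `lr` and `la` repels at contact but never
attracts — the *asocial* phenotype.

**Autonomous force.** Agents modulate speed (never heading) with the local
resource value `S(x_i)`:

    F_a,i = [ Ψ_i − η|v_i|² ] v_i/|v_i|,   Ψ_i = ψ0_i − ψ1_i S(x_i).

For `Ψ>0` the speed relaxes to `√(Ψ/η)`; for `Ψ≤0` it decays to zero
(station-keeping). We take the fixed point of the force as written,
`η|v|²=Ψ`; the alternative convention `v*=Ψ/η` coincides at `η=1`, which all
runs use, and the sign structure — the only thing the collective states
depend on — is identical either way.

The sign and size of `Ψ` set three collective states: *station-keeping*
(`Ψ≤0`, frozen, dense), *cohesive* (`0<Ψ≲2.95`, slow compact groups), and
*dispersed* (large `Ψ`, near-ballistic gas). Transitions between cohesive
and dispersed are abrupt and hysteretic (first-order-like), which is what
lets small individual speed responses switch whole groups between states.

### Resource landscape

The resource is a sum of `M` Gaussian peaks, `S(x) = Σ_p λ0 e^{-|x-c_p|²/λ1²}`.
Each centroid performs Brownian motion with drift `α` and per-component
standard deviation `β` per step, and relocates uniformly with probability
`1/τ_p` per step (amplitude restored to its initial value on relocation —
the natural regeneration rule under the optional depletion variant, and a
no-op without depletion). Under depletion, agent `i` consumes `u·S(x_i)` per
step, attributed to peaks in proportion to their contribution to `S(x_i)`;
amplitudes floor at zero.

### Evolution

Each generation places the `N` agents uniformly at random with small random
speeds (uniform in [0, 0.1], uniform headings), runs `T_gen` steps, and
scores each agent by the arithmetic mean of the resource it experienced
(pre-depletion values in the depletion variant). Offspring parentage is
sampled i.i.d. proportional to relative fitness (uniform if all fitnesses
are zero); each offspring inherits its parent's `(ψ0, ψ1, lmax)` perturbed
by independent Gaussian mutations, `σ_ψ0 = σ_ψ1 = 0.05`, `σ_lmax = 0.5`,
with `lmax` clipped to `[0, 30]`. The environment persists across
generations; positions do not. The asocial control pins `lmax = 2`.
Founding populations are weakly responsive and weakly social:
`ψ0 ~ U(0.5, 1.5)`, `ψ1 ~ U(0, 0.5)`, `lmax ~ U(0, 5)`.

## Numerics

**Integration.** One time step freezes `F_s` and `S` at their start-of-step
values (all agents update synchronously from the pre-step state) and applies
`n_sub = 10` semi-implicit Euler sub-steps: speed update along the current
heading first, then the social kick, then the position. The self-propulsion
speed update is clamped at zero: in the continuous dynamics the speed
reaches zero in finite time for `Ψ<0` and `v=0` is absorbing (the force acts
along `±v̂` and vanishes there), so an Euler update that crossed zero and
reversed the heading would be a discretization artifact — and a consequential
one: unclamped, agents with strongly negative `Ψ` jitter at order-one speeds
and diffuse off resource peaks instead of station-keeping. After
integration, a noise kick of exact magnitude `γ` with uniform random heading
is added to each velocity, and positions wrap onto the torus.

**Degenerate cases.** `v/|v|` is treated as zero below `|v| = 1e-8` (noise
re-seeds a heading on the next step); coincident agents (`d < 1e-12`)
exert no force on each other; k-NN ties break by agent index.

**Neighbour search.** The production kernel uses a cell list (cell edge at
least the largest `lmax`) with canonical `(distance², index)` selection, so
its output is scan-order independent and bit-identical to the brute-force
all-pairs oracle the tests compare it against.

**Randomness.** One global seed expands into named, independent child
streams (`SeedSequence([seed, crc32(label), replicate])`), so adding an
analysis never perturbs dynamics draws. Noise-free runs are bit-reproducible.

## Order parameters and metrics

* `⟨d10NN⟩` — population mean of each agent's mean distance to its 10
  nearest others (no `lmax` cutoff); inverse proxy for local density and the
  order parameter for state transitions.
* Potential energy — mean over agents of the pair potential summed over the
  neighbour set.
* Hysteresis protocol — uniform (resource-free) environment, `Ψ` imposed via
  `ψ0=Ψ, ψ1=0`, `lmax=30`; start at `Ψ=4`, equilibrate, measure, step `Ψ`
  by 0.2 down to −1 and back up, carrying the agent state between grid
  points (re-equilibrating from scratch would destroy the hysteresis).
  Dispersion bands are two standard errors over replicates. The transitional
  regime's edges are read off as the grid value at which the largest
  single-step drop (decreasing branch) or jump (increasing branch) of
  `⟨d10NN⟩` is first observed.
* KL divergence — `KL(resource ‖ agents)` over 30 radial annuli out to three
  decay lengths around a designated peak centre, both distributions
  normalized after adding `ε=1e-9` per bin; nats.
* Arrival curves — per-step count of agents within a configurable radius of
  a peak centre (default: one decay length), least-squares fits of
  `κ_a·t + c` and `κ_{s,1} + exp(κ_{s,2} t)` over the rising phase (up to
  95% of the series maximum — the exponential form has no saturation term),
  model choice by AIC (equal parameter counts, so effectively by residual
  sum of squares). Flat series are flagged degenerate, not fitted.
* Group–peak matching — groups are connected components of the "either
  influences the other" graph; each peak is paired with the time-averaged
  size of the group whose torus centroid (circular mean per coordinate) is
  nearest; peak mass is the closed-form integral `λ0πλ1²`.
* State classification — station-keeping `Ψ≤0`, cohesive `0<Ψ≤2.95`,
  dispersed `Ψ>2.95`; boundary values to the lower regime.

## Study conditions at desk scale

The reference system is `N=500`, `L=346`, two peaks with `λ0=10`, `λ1=20`,
`τ_p=1500`. Desk-scale protocols in `swarmevo.protocols` use `N=200` with
two scaling rules fixed in advance:

* **Density preservation:** `L = 346·√(N/500) ≈ 218.8`. The transition and
  nucleation phenomenology depends on number density, not raw `N`.
* **Capacity preservation:** `λ1 = 20·√(N/500) ≈ 12.6` in the evolution and
  tracking protocols. A phenotype `(ψ0, ψ1)` parks on a peak at the `Ψ=0`
  contour, radius `r* = λ1·√(ln(λ0ψ1/ψ0))`; at the crystal spacing set by
  the pair force a peak therefore holds `∝ λ1²` agents. Scaling `λ1` with
  `√N` keeps peak carrying capacity proportional to population size, which
  is what preserves the competitive structure of the fitness landscape.

**Peak drift.** The canonical dynamic-peak environment uses `α=(0.06, 0)`
and `β=0.5` per step — the values under which collective tracking is
demonstrable. With drift of order the agents' cruising speed, station-keeping
groups are structurally unable to follow (they freeze; the peak escapes),
no phenotype attains more than background fitness, and sociality is weakly
deleterious; we treat faster printed drift values as inconsistent with the
tracking phenomenology and do not use them in the evolution protocols.

**Arrival counting radius.** With the stable-state traits
(`ψ0=3, ψ1=2.45, lmax=29`), `r* ≈ 1.45·λ1`: arrivals accumulate *outside*
one decay length, so the tracking protocol counts arrivals within `r*`
(the library default remains one decay length). Within-`λ1` counts measure
the slower inward compression of the parked crystal instead, and are
identically zero for the asocial control.

## What the synthetic data does and does not show

The generators emulate the model's own study conditions: seeded toy
scenarios (a pair at force balance, stable-state and perturbed populations
on single peaks) and synthetic arrival-count series for fit-recovery round
trips. They share the model's idealizations — point agents, isotropic
Gaussian peaks, no depletion unless enabled, no explicit alignment, no
perception error beyond the navigational noise kick. Passing tests
demonstrate internal consistency of the implementation and reproduction of
the model's collective phenomenology at desk scale; they say nothing about
real animal trajectories, which these fixtures deliberately do not imitate.

## Known limitations

* Measured at desk scale, the social/asocial advantage (mean-fitness ratio
  ≈ 2–3, fitness-CV ratio ≈ 1.5–2 over three seeds) is smaller than the
  full-scale reference ratios (≥5, ≥4); short generations relative to the
  relocation timescale (`T_gen=500` vs `τ_p=1500`) particularly weaken the
  social re-finding advantage, and the corresponding acceptance test is
  left failing rather than rescaled.
* Social arrival curves at desk scale are concave (encounter-flux-limited
  with searcher depletion): model comparison prefers the linear over the
  exponential form for both social and asocial populations, although the
  social rate and plateau are several-fold larger. The exponential-form
  preference asserted for social populations is likewise left as a failing
  assertion.
* The decreasing-branch drop of the hysteresis loop at `N=200` begins near
  `Ψ≈2.0–2.2` rather than 1.6; nucleation onset is the quantity most
  sensitive to system size and equilibration budget.
* The continuum/linear-stability treatment of the transition boundaries and
  the closed-form arrival-rate derivations are out of scope; only the
  empirical fits of the stated functional forms are provided.
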