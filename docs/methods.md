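# Methods

## The model

`poolwell` simulates a four-member cross-feeding community — the
engineered *S. cerevisiae* overproducer strains ADE↑, TRP↑, HIS↑ and
LYS↑, each of which secretes one of the four essential metabolites
(adenine, tryptophan, histidine, lysine) and is auxotrophic for the
other three — cycling between two environments:

**Well phase (structured).** 96 compartments, each with a carrying
capacity K and a randomly drawn *ecology*: a presence/absence state of
the four metabolites, one of 16.  Each well is inoculated with a
community sampled from the global pool (four slot draws weighted by the
current pool frequencies; each slot deposits K/8 of density, so the
inoculum totals K/2).  If every member can source its three foreign
requirements from the ecology or a co-inoculated producer, the well is
*viable* and each member i grows logistically under a shared capacity,

    dx_i/dt = x_i R_i(E, S) (1 − Σ_k x_k / K),

for a duration t_wells.  If any member starves, the whole community is
non-viable and every member carries the same negative rate d (default
−2); viability is deliberately all-or-nothing at the community level.

**Pool phase (unstructured).** Final well densities are summed over
wells, normalized to a fixed seeding density, and grown exponentially,
dy_i/dt = r_i y_i, for t_pool.  The resulting frequencies drive the
next round of inoculum sampling (and, under metabolic feedback, the
next round of ecology sampling).

A lineage is *extinct* when the pooled density hits zero (every well
non-viable and decayed below the 1e-12 density floor) or when every
strain frequency falls below `extinction_eps` (default 1e-6, a
configuration choice — the threshold is not derivable from the
biology); afterwards its recorded proportions are identically zero.

## The growth-rate model

For a viable well the per-member rate is parametric:

    R_i(E, S) = base_rate_i · c^(number of requirements obtained only by cross-feeding)

with cross-feed discount c (default 0.95).  A strain's own product is
free to itself; ecology supply shadows cross-feeding (a metabolite
present in the ecology costs nothing even when a producer is also
present).  Explicit overrides keyed by (ecology index, membership mask,
strain) take precedence and are the carrier for empirically calibrated
community rates; the package ships one override set — the all-strain
community in the metabolite-free ecology at (0.804, 0.869, 1.157,
0.732) for (ADE↑, TRP↑, HIS↑, LYS↑) — and the default base rates are
chosen as `printed / c³` so the parametric rule and the override agree
exactly at that calibration point.  Pool rates r_i default to the same
vector.  Full per-community rate tables measured in the lab are not
publicly available, so the parametric rule is this package's own
interpolation; quantitative per-cycle trajectories therefore depend on
c, while every combinatoric, analytic and ordering result reported by
the tests does not.

## Ecology distributions

* **uniform** — each of the 16 ecologies at 1/16.
* **poisson(μ)** — niche availability skewed by a truncated Poisson.
  Two supports are implemented.  The default weights ecology *index* j
  by pmf(j−1; μ) renormalized over 1..16.  The alternative
  (`weighting="richness"`) places the truncated Poisson over the five
  richness classes 0..4 and splits each class uniformly; at μ = 9 it
  concentrates ~68% of the mass on the two HIS-permissive ecologies
  ({1,1,0,1} and {1,1,1,1}, indices 14 and 16), whereas the index-based
  default raises their mass only relative to small μ.  Both reproduce
  the qualitative result that rich-skewed niches lower the death rate;
  the index-based default follows the numbering emphasis on
  environments 14 and 16.
* **feedback(f)** — metabolic feedback: each metabolite is present
  independently with probability equal to the pool frequency of its
  producer (optionally min(1, 4f)).  The mapping from strain
  frequencies to metabolite availability is a modelling choice (no
  formula is published); the product-Bernoulli form is the simplest
  that reproduces both signature behaviours: a balanced pool keeps
  diverse ecologies coming, while a pool dominated by one strain floods
  the wells with the one metabolite that strain does not need,
  starving it — the self-defeating feedback that drives lineage
  collapse.
* **restriction** — all ecologies containing a banned metabolite get
  probability zero and the remaining eight are renormalized (the well
  count stays 96).  Banning tryptophan makes TRP↑ an obligatory
  community member: the keystone experiment.

## Numerical choices

* Wells are integrated with fixed-step classical RK4, default
  dt = 0.01 (the step is shrunk so an integer number of steps covers
  t_wells exactly).  Step-halving agreement at 1e-6 relative and a
  closed-form 1-D logistic oracle are asserted in the tests; an
  independent adaptive integrator (SciPy `solve_ivp` at rtol 1e-10)
  cross-checks the four-strain case.  The hot loop is numba-compiled
  with a NumPy twin kept as fallback and cross-checked for equality.
* Non-viable wells integrate the same logistic equation with R_i = d,
  i.e. decay damped by the crowding bracket; a pure exponential-decay
  variant sits behind `nonviable_mode="exponential"`.  Both give the
  same death-rate bookkeeping; the choice only affects how fast dead
  wells' residual density vanishes (with d = −2 and t_wells = 20 it is
  far below the density floor either way).
* Pool growth uses the closed form, not a stepper.
* Densities below 1e-12 are clamped to zero at phase boundaries.
* RNG: one master seed per run; per-cycle (and per-replicate)
  substreams are spawned from `numpy.random.SeedSequence`, so results
  are bit-reproducible and adding replicates never perturbs earlier
  ones.

## Carrying capacity and the inoculum

With the inoculum pinned to K/2, substituting u = x/K removes K from
the well system entirely: per-cycle proportions are *exactly* invariant
in K (asserted as a test, bitwise for K scaled by a power of two).  A
carrying-capacity contrast is therefore only meaningful at a fixed
inoculum *density*; the `capacity-contrast` preset holds the inoculum
at 5.0 (the baseline K/2) while K varies, which is how a larger well
prolongs exponential growth and accelerates the takeover by the
fastest-growing strain (HIS↑).

## Study conditions and problem sizes

Presets pin the study conditions: K = 10, d = −2, t_wells = 20,
96 wells, 10 cycles, 100 replicate runs, equal initial proportions
(the single-well null model uses random Dirichlet(1,1,1,1) initial
proportions, as that experiment was defined with random starts).  The
headline feedback experiments use t_pool = 1.28 (an order of magnitude
below t_wells); interventions start early (cycle 1), intermediate
(cycle 5) or late (cycle 9); rescues either halve t_pool or pull every
growth rate halfway to the mean (r′ = r + α(mean − r), α = 0.5, mean
preserved exactly).

The long-run mean well death rate for a HIS↑-dominated pool under
uniform ecologies is bounded by 14/16 = 0.875 (only 2 of 16 ecologies
support a pure-HIS community).  Approach to this plateau is slow: from
equal initial proportions the replicate-mean death rate is ≈0.78 after
10 cycles and ≈0.82–0.84 by cycles 18–20.  The acceptance checks
therefore probe the plateau over the last cycles of a 20-cycle run;
`scripts/acceptance.py` reports the 10-cycle value as well.  Replicate
counts there are 50–100 per scenario — enough that every asserted
ordering (extinction fractions 0 vs ≈0.7, death rates 0.75 vs 0.87) is
separated by many standard errors.

## What the simulator does and does not capture

Stochasticity lives entirely in sampling (ecologies, inocula, initial
proportions); the within-phase dynamics are deterministic ODEs with no
demographic noise.  Metabolites are boolean sources, not concentrations
— no Monod kinetics, no depletion, no within-phase migration between
wells.  There is no mutation or strain evolution.  Passing tests
demonstrate the ecological mechanisms (compartmentalization-driven
cohesion, self-limiting niche feedback, keystone dependence), not
quantitative agreement with any particular wet-lab trajectory: the
published per-community growth-rate tables that would pin those
trajectories are not available, and the parametric cross-feed rule that
fills the gap is a deliberate simplification.
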