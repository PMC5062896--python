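# Methods

## Model

The simulator couples a deterministic population model of blood-cell
formation to a stochastic description of mutation and early clonal
survival.

**Deterministic layer.**  The healthy white-cell lineage and every leukemic
clone consist of a mitotic compartment (stem and progenitor cells, counts
c₁ and l₁ⁱ) and a post-mitotic compartment (mature cells or blasts, c₂ and
l₂ⁱ).  Cell counts are continuous; the large population sizes (up to 10⁹ on
the model's scale) justify the mean-field treatment of established
populations.  All dividing populations respond to one cytokine-like
feedback signal s = 1/(1 + k·(c₂ + Σ l₂ⁱ)), a decreasing function of total
post-mitotic mass that models receptor-mediated cytokine clearance; it
multiplies each population's maximal self-renewal fraction â, so the
realized probability that a division's progeny stay mitotic is â·s(t).
The healthy steady state follows in closed form from 2·â_c·s̄ = 1:
c̄₂ = (2â_c − 1)/k and c̄₁ = d_c·c̄₂/p_c.  Leukemic clones obey the same
equations with their own (âᵢ, pᵢ) and a factor (1 − ν) on the mitotic
self-renewal influx that removes, in expectation, progeny carrying a new
mutation; healthy cells are assumed not to found leukemic clones, so their
equations carry no such factor.

**Stochastic layer.**  Mutated mitotic cells arise at rate
α(t) = Σᵢ 2·âᵢ·s·pᵢ·l₁ⁱ·ν, the intensity of an inhomogeneous Poisson
process.  Event times are generated by the integrated-hazard method: the
accumulated hazard Λ(t) = ∫α dt is carried as an extra ODE state and an
event fires when Λ crosses an Exp(1) threshold.  This is exact for rates
that depend on the evolving state, at the cost only of one auxiliary
equation, and it composes cleanly with adaptive integration; thinning-based
schemes would need an a-priori rate bound that the growing system does not
offer.  At an event the parent clone is drawn with probability αᵢ/α, and
the offspring's traits are sampled from independent truncated normals
centered on the parent's (â, p) with standard deviation σ (self-renewal
truncated to [0, 1]; proliferation to [1/365, 1] per day, one division per
year to one per day).  σ may be a schedule indexed by the clone's depth —
the cooperativity hypothesis that accumulated mutations potentiate larger
phenotypic jumps.

A new clone starts as one mitotic cell.  Whether its lineage survives
demographic stochasticity is decided by a Bernoulli draw with success
1 − p_e, where p_e is the extinction probability of the embedded
Galton–Watson process with offspring generating function
f(x) = a²x² + 2a(1−a)x + (1−a)²: the smaller root of f(x) = x, equal to
((1−a)/a)² for a > ½ and to 1 otherwise.  The variant with a per-division
death probability d, f(x) = (1−d)·f₀(x) + d, is implemented (solved as the
smaller quadratic root in a cancellation-safe form) but defaults to d = 0.
The filter is evaluated at the clone's maximal self-renewal fraction â
(`ExtinctionModel(trait="max")`).  The alternative reading — the realized
fraction â·s(t) at the moment of birth — is available as
`trait="realized"`; it is far more stringent (near the leukemic
quasi-equilibrium every new clone is close to critical), yields almost
exclusively monoclonal disease, and is not used by default because the
cohort structure it produces (one significant clone per patient, depth
barely responding to the mutation rate) contradicts the multi-clonal
hierarchies this model is meant to generate.

**Founder.**  Disease histories start from the healthy steady state plus
one founder clone (one mitotic cell) at t = 0, its traits drawn from
truncated normals centered on the healthy parameters.  By default the
founder is introduced deterministically; `founder_policy="filter"`
additionally subjects it to the extinction filter (patients whose founder
is rejected get status `founder_never_established`), and `"resample"`
redraws until a founder survives.  Under the default filter (trait "max")
the founder passes ~98% of the time, so the policies differ little; under
the realized-trait filter they differ strongly.

**Stopping, snapshots, significance.**  A patient dies when mature healthy
cells first fall below 5% of steady state; otherwise the simulation ends at
100 years.  Full system states are recorded at first crossing of 5%, 50%
and 95% mature-cell depletion and at termination.  A clone is significant
at a snapshot if it holds at least 1% of total cell mass (healthy plus
leukemic, both compartments) — a sequencing-sensitivity motivated
threshold — and significant for the patient if it is significant at any
recorded snapshot (terminal-only counting is available and is used for
end-of-simulation subgrouping).  Hierarchy depth is the maximal depth over
clones, the founder having depth 1.

## Numerical scheme

Between structural changes the system is integrated with SciPy solvers at
rtol 10⁻⁸ and atol 10⁻⁴ cells (10⁻¹² for the hazard state).  Two regimes
are distinguished:

- **Quiet phases** (mutation intensity below 0.02/day and at most 40 live
  clones): LSODA segments with dense output.  Mutation times are recovered
  by inverting the monotone hazard trajectory with bracketed root-finding;
  events whose clone fails the survival filter do not alter the
  deterministic state, so the solver is only restarted when a clone is
  actually inserted.
- **Event-dense phases**: a step-driven explicit Runge–Kutta (Dormand–
  Prince) loop.  A single-step method pays nothing to grow the state
  vector, whereas restarting a multistep stiff solver at every insertion
  dominates the cost when events arrive daily.  The stiffness of the
  system is mild — the fastest time scale is mature-cell clearance,
  1/d_c ≈ 0.4 days — so the stability-limited step of about a day is an
  acceptable trade for restart-free insertions.  Hazard, death and
  snapshot crossings are localized inside accepted steps on the step's
  dense interpolant.

Threshold crossings (death, snapshots) are found by scanning the solver's
own step points for sign changes and refining with Brent's method, which
reports the *first* downward crossing also for non-monotone trajectories.
A tolerance-halving test in the suite checks that death times are stable
to four significant digits.

**Truncation of negligible clones.**  With the â-based filter nearly every
mutant survives (p_e(0.87) ≈ 0.022), so thousands of clones per patient
are established while only a handful can ever grow: the feedback signal
falls monotonically over a disease course, hence a clone that is
subcritical at birth (2·â·s ≤ 1) decays forever.  Such clones are recorded
in the hierarchy (they count toward clone totals and depth) but not added
to the ODE system, and established clones are retired from integration
once they are declining and hold less than `retire_fraction` (default
10⁻⁵) of total cell mass.  Both truncations remove contributions of order
one cell against ~10⁹ — below solver tolerance for the dynamics, and a
relative error of order 10⁻³ in the expected number of future mutation
events.  `retire_fraction=0` disables them (exact mode, used in the
equivalence tests at small event counts); the ε-pruning of fully
decayed clones (both compartments below `prune_epsilon` ≤ 1 cell) is
applied in either mode and never removes a clone with at least one mitotic
cell.  Cohort statistics are insensitive to ten-fold variation of
`prune_epsilon` (tested).

**Reproducibility.**  One master seed spawns independent per-patient
`SeedSequence` streams; all draws (founder, thresholds, parent choice,
traits, survival) consume a single per-patient generator in a fixed order,
so identical configuration and seed give bit-identical results, and
cohorts are reproducible independently of execution order.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| â_c | 0.87 | – | healthy maximal self-renewal (transplant-calibrated) |
| p_c | 0.45 | 1/day | healthy proliferation rate |
| d_c | 2.3 | 1/day | mature-cell clearance |
| k | 1.85·10⁻⁹ | 1/cells | feedback strength; sets c̄₂ = 4·10⁸ |
| d_l | 0.5 | 1/day | leukemic post-mitotic death rate (all clones) |
| ν | 5·10⁻⁹ | – | mutation fraction per division (studied 10⁻¹¹–5·10⁻⁸) |
| σ | 0.005 | trait units | trait-jump sd; cooperativity schedule (0.0014, ×5, ×20, ×100) |
| stop fraction | 0.05 | – | death when c₂ < 5% of c̄₂ |
| horizon | 36 500 | days | 100 years |
| significance | 0.01 | – | mass fraction for a significant clone |

The mutable trait space is (â, p) only; d_l is shared and fixed, and a
single k serves all clones.  Time is in days; counts are abstract absolute
counts on the scale set by k.  Only the transplantation scenario assigns
clinical units, reading counts as cells per kg body weight: graft
4·10⁶ CD34⁺ cells/kg with a 3:1 myeloid:erythroid ratio gives
c₁(0) = 3·10⁶, and recovery is 5·10⁸ neutrophils per liter of blood
(5 L, 70 kg) ≈ 3.6·10⁷ per kg.  These conventions yield recovery in
16 days, inside the clinical 2–3 week window; the whole-body alternative
would place the recovery threshold above the steady state itself and was
rejected.

## Cohort experiments and their conventions

The standard experiments simulate desk-scale cohorts at
ν ∈ {5·10⁻¹⁰, 5·10⁻⁹, 5·10⁻⁸} with σ = 0.005 (300, 300 and 100 patients:
runtime per patient grows roughly linearly with ν, so the cheap low-rate
cohorts are sized up for precision of the means) and at σ ∈ {0.01, 0.05}
with ν = 5·10⁻⁹ (200 patients each), sharing per-patient seed streams
across grid points (common random numbers).  The σ sweep varies the
mutation-jump kernel only; the founder draw keeps its baseline spread
(0.005), so the cohort's founder composition is held fixed and the
comparison isolates the mutation kernel.  Per-patient
hierarchy statistics (significant-clone counts, depth, order-of-emergence
comparisons) are averaged over patients with at least one significant
clone: a virtual patient whose founder never grows out — about half of
them at σ = 0.005, where the founder draw straddles the healthy value —
has no clonal hierarchy to measure.  Pooled-fraction statistics (the share
of patients with fewer than ten significant clones) use all patients.  For
the mutation-rate response of hierarchy depth, depth is taken over *all*
established clones, matching the depth definition above; the
significant-only variant is systematically flatter (≈0.3 instead of ≈0.5
additional levels per ten-fold ν) because late, still-small clones carry
the deepest labels.

## What the synthetic cohorts do and do not show

The generator *is* the model: virtual patients are draws from the model's
own distribution, so cohort tests demonstrate internal consistency (the
selection ratchet on self-renewal, competition capping significant-clone
numbers, cooperativity deepening hierarchies), not clinical validity.
Real leukemias add measurement noise, ambiguous tree reconstruction from
variant-allele frequencies, treatment effects, spatial niche structure and
multi-lineage hematopoiesis, none of which are modeled.  Comparison to
observed patient hierarchies is supported only at the topology level
(canonical forms of significance-contracted trees); no patient data ship
with the package.

## Known limitations

- The extinction filter's trait choice is a modeling decision (see above);
  both variants are exposed, and conclusions that depend on near-critical
  clones differ between them.
- Subcritical-clone exclusion and retirement make the hierarchy's
  *insignificant* fringe approximate: clones that would, in the exact
  model, linger for years at single-cell size and very rarely spawn
  offspring are dropped early.  Significant-clone statistics are
  unaffected at the stated tolerances.
- Explicit stepping in event-dense phases is stability-limited to ~1-day
  steps; runtime grows roughly linearly with ν·(disease duration) and with
  the number of concurrently growing clones (the ν = 5·10⁻⁸ cohort of 100
  patients takes a few minutes on one CPU).
- The ε-pruning rule uses the instantaneous signal to classify a clone as
  declining; a clone exactly at criticality is kept, which is conservative.
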