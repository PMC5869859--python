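# Methods

## Model and assumptions

The package simulates a patch of tissue as a regular 2D or 3D lattice of
cell agents in four states (resting R, pre-senescent PS, senescent S, empty
E) with Moore neighbourhoods. One time unit is one day. The model captures
three competing processes: commitment of damaged cells to senescence
(induction), spread of senescence to neighbours via the SASP (bystander
effect), and removal of senescent cells by the immune system followed by
repopulation. It deliberately omits apoptosis, cell migration, lattice
growth, diffusing SASP fields, and any time variation of the immune
parameters.

Updates are **asynchronous**: within a time unit every cell is visited once
and the rule for its state *at visit time* is applied in place, so a
conversion made early in a sweep is visible to cells visited later in the
same sweep. The default visit order is a fresh uniform random permutation
per time unit, which avoids the directional artifacts of a fixed raster
sweep; a raster order is selectable for strictly ordered replays. A
consequence of in-place updates is that a cell converted R→PS by a
neighbour early in a sweep already accrues its first PS timer increment if
its own visit falls later in the same sweep; the enumeration oracle in the
test suite enumerates exactly this process, so the engine is checked
against the semantics as specified, not a synchronous approximation.

On a senescent cell's visit, bystander conversion is evaluated before the
clearance check, and the quorum count uses the lattice state at evaluation
time. Only resting cells are susceptible to bystander conversion or
induction; PS cells are already committed and S cells cannot be
re-inducted.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `p_bys` | bystander conversion per resting neighbour | /neighbour/day | 0.2 |
| `p_clr` | immune clearance, given the quorum | /day | 0.4 |
| `p_new` | repopulation of an empty site | /day | 0.5 |
| `t_i` | PS residence before S | days | 10 |
| `p_ind` | induction commitment (Bernoulli mode) | per event | 0.1 |
| `p_trigger` | stochastic-entry damage events | /resting cell/day | 0.02 |
| `dims` | lattice geometry | sites | 10×10 (2D), 10×10×10 (3D) |
| `n_steps` | simulated horizon | days | 250 |

The defaults are the reference parameterisation of the tissue simulations;
`n_steps` = 250 is long enough for the senescent fraction to plateau at
these rates. `p_ind` = 0.1 reflects the ~10% of an irradiated population
that commits to senescence.

**Boundaries.** Fixed (non-periodic) by default: the model describes a
tissue patch and edge cells simply have truncated neighbourhoods. Periodic
boundaries are available as a sensitivity option.

**Clearance quorum at edges.** The quorum is half the neighbourhood size.
The default `per_cell_half` policy takes ceil(half of the *actual*
neighbour count), which gives the canonical 4 (2D) and 13 (3D) for interior
sites and rescales proportionally at edges; a `fixed` policy (always 4 or
13) is selectable but makes corner cells in 3D unclearable (a corner has
only 7 neighbours), so it is not the default.

**Physiological plausibility.** `p_bys > p_clr` would let a single early
senescent cell drive runaway accumulation; the configuration layer warns in
that regime but does not forbid it.

## Induction layer

The engine asks the induction layer one question: does this resting cell
commit to senescence now? `bernoulli` mode answers with a coin flip.
`marker_surrogate` mode simulates one stochastic marker trajectory — four
senescence markers (p21, SA-β-Gal, ROS, DNA damage) rising along saturating
curves `base · (1 − e^(−0.25·day))` toward per-cell random plateaus — and
classifies the cell pre-senescent iff **all four** markers strictly exceed
thresholds equal to the day-21 population means of a dedicated reference
population (default 1000 cells, calibrated once per run so induction is
homogeneous across the lattice). The all-of-four reading of the threshold
rule is a design choice; strict inequality is the stated tie-break, so a
marker exactly at threshold never counts as exceeding it.

Plateau heterogeneity is log-normal with a **shared per-cell factor**
(σ = 2.5) and a small marker-specific factor (σ = 0.15), plus mild
day-to-day observation noise (σ = 0.05). The shared factor models the
cell-to-cell spread in damage response and correlates the four markers
within a cell — without it, four independent markers would each need to
beat their mean and the all-of-four fraction would be pinned near
0.5⁴ ≈ 6%. σ = 2.5 was fixed once so that the self-calibrated classified
fraction is ≈10% (measured 0.099 ± 0.016 over 6 seeds × 2000 cells),
matching the Bernoulli default. The surrogate is a stochastic stand-in with
the right population statistics, not an intracellular network model: its
trajectories are smooth saturating curves and carry no mechanistic meaning.

## Calibration

`scan_pbys` evaluates a grid of candidate `p_bys` values (default 0…1 in
steps of 0.05) in in-vitro mode — `p_clr = p_new = 0` on a 2D monolayer,
matching cultured cells without an immune system — and scores each with the
chi-squared objective against the observed senescent fractions. The
objective compares the observation to the **ensemble-mean** simulated
fraction (default 50 replicates): the simulator is stochastic but the
objective should be as deterministic as the budget allows. When the
observation carries per-day SDs the residuals are weighted by them;
otherwise an unweighted sum of squares is used and logged. The landscape
reports the per-candidate objective, the spread of single-replicate
objectives (an identifiability diagnostic), the argmin, and a flatness
ratio (max − min)/min across the grid.

Identifiability behaves as expected of this model: data covering the rise
of the senescent fraction pin `p_bys` to within one grid step, while data
sampled only near the saturated plateau cannot distinguish moderate from
large `p_bys` — the landscape is flat across the upper range, because
`p_bys` controls the kinetics of progression while the plateau itself is
set by `p_clr` and `p_new`.

## Synthetic data

`generate_invitro_series` stands in for an in-vitro senescence time course:
it runs the simulator itself in in-vitro mode at a known true `p_bys`
(default 0.2) under day-1 irradiation with Bernoulli induction 0.1, takes
the ensemble-mean senescent fraction at the recorded days (default 1, 5,
10, 15, 20, 25, 30 — a plausible month of sampling, chosen once and
documented as arbitrary), and adds Gaussian observation noise (default SD
0.01 on the fraction scale, truncated to [0, 1]; the emitted SD column
equals the noise SD). `generate_marker_population` emits marker
trajectories from the induction surrogate. Because the in-vitro generator
is the same simulator being calibrated, parameter-recovery tests are
exactly that — recovery under a correctly specified model. Passing them
shows the scan machinery is sound; it says nothing about model
misspecification against real cultures, real error structures, or real
marker panels, none of which the generators attempt to emulate.

## Numerical and reproducibility choices

- States are int8 arrays; neighbour flat-index lists and quorum thresholds
  are precomputed per lattice.
- All randomness flows through `numpy.random.Generator`. A run is fully
  determined by (parameters, seed); ensemble replicate `r` uses the
  counter-based seed `(base_seed · 1000003 + 7919·r + 1) mod 2³¹`, and the
  scan derives per-candidate seeds the same way, so landscapes are
  reproducible bit-for-bit.
- Draws are skipped when a probability is exactly 0, and the PS timer
  advances before the `t_i` comparison, so a cell entering PS at time `k`
  is senescent at exactly `k + t_i` when clearance is off.
- Degenerate inputs fail loudly: non-2D/3D or non-positive dims,
  out-of-range probabilities, empty calibration populations, observation
  days beyond the simulated horizon, non-positive SDs, and unknown config
  keys all raise named errors.

## Test problem sizes

Statistical tests run at sizes chosen to make their standard errors small
relative to the asserted tolerances: 1000 replicates for the day-1
induction level (3 binomial SEs ≈ 0.3 pp), 10⁵ cell-steps for the trigger
rate, 10⁴ sweeps against the enumeration oracle (chi-square goodness of
fit, p > 0.001), 50 replicates per candidate for the recovery scan, and
16–24 replicates of 150-day runs with the final 50 days time-averaged for
the steady-state comparisons.

## Known limitations

- The steady-state equivalence between a 10×10 monolayer and a 10×10×10
  lattice holds only approximately in this implementation: the long-run
  senescent fraction is ~2 percentage points higher in 3D (0.491 vs 0.469
  at the reference parameters), because the richer 26-site neighbourhood
  shortens a resting cell's wait before bystander re-conversion. The gap
  persists with periodic boundaries, so it is a genuine dimensionality
  effect of the update rules, and the equivalence test in the acceptance
  suite records it as a failure rather than widening its tolerance. The
  corresponding equivalences that do hold statistically: irradiation vs
  stochastic-entry induction, and the p_bys-independence of the plateau.
- Asynchronous in-place updating is itself a modelling choice; a
  synchronous variant would have slightly different single-step
  distributions and is out of scope.
- The cellular automaton scales poorly to large tissues (pure-Python sweep
  over sites); it is intended for desk-scale lattices of 10²–10⁴ sites.
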