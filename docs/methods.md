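# Methods

## Scope and units

The package analyses drug adsorption on carbon nanotubes at three levels:
macroscopic batch uptake, phenomenological model fitting (equilibrium and
kinetic), and geometric analysis of point-reduced molecular
configurations. Units are fixed throughout: concentrations in mg mL⁻¹,
capacities in mg g⁻¹, time in minutes, temperature in K, lengths in nm.
The gas constant is carried as 8.314×10⁻³ kJ mol⁻¹ K⁻¹ so the Temkin
constant *b* comes out in kJ mol⁻¹.

## Batch uptake and calibration

Capacities follow the mass balance q = V(C₀ − C)/m. Input validation
enforces 0 ≤ C ≤ C₀ (a measured concentration above the initial one is
inconsistent with adsorption and rejected). The spectrophotometric
standard curve is an ordinary least-squares line of absorbance on
concentration; inverting it can produce a slightly negative concentration
when a blank reads below the calibration intercept, which is clipped to
zero with a logged warning rather than raised — that is measurement noise,
not a logic error. The documented mixture fixture (4.5 mL total volume,
3×10⁻⁴ g adsorbent from 300 µL of a 1 mg mL⁻¹ suspension) is encoded in
examples and the acceptance script, not hard-wired into the library.

## Linearized fits and their statistics

Every classical fit here is a straight line in some transformed space, so
all of them share one OLS core (statsmodels) that returns slope,
intercept, their full covariance, and R². Two conventions matter:

- **R² is computed in the space where the regression ran.** Linearized
  mode reports R² of the transformed variables (the convention of the
  linear plots this field publishes); nonlinear mode reports R² in the
  original (Cₑ, qₑ) or (t, qₜ) space. The two are not comparable across
  modes, and the fit records its mode for that reason.
- **Parameter SDs are delta-method propagations** of the slope/intercept
  covariance (e.g. q_max = 1/slope gives sd(q_max) = sd(slope)/slope²).
  They are OLS standard errors, not replicate SDs, and are labelled as
  such.

The base-10 Lagergren plot uses the exact ln 10 where the classical
equation prints the rounded 2.303; this keeps noise-free round trips exact
to machine precision without changing the estimator.

Non-physical linearized results (negative Langmuir slope, negative Temkin
slope, decreasing Elovich trend) set a `valid=False` flag on the returned
fit instead of raising, so model comparison can still rank everything; the
ranking places invalid fits last, then sorts by R², breaking ties by the
count of non-finite parameters and finally by a fixed model order.

Nonlinear modes minimise squared error in the original space with
scipy's bounded trust-region least squares, started from the linearized
estimate (or a heuristic start when that estimate is unphysical on noisy
data) with positivity bounds on physically positive parameters. For the
Temkin model the "nonlinear" fit coincides with the linearized one — the
direct form is linear in ln Cₑ — which the tests treat as expected
behaviour, not a defect.

## Two-stage diffusion regression

The Weber–Morris fit regresses qₜ on √t piecewise. Breakpoints are chosen
by exhaustive search over every admissible segmentation (each segment
keeps at least 3 points), minimising total SSE; ties break toward the
earlier breakpoint, and the reported breakpoint time is the last sample
time of the earlier segment. A nesting property holds by construction: the
two-segment SSE never exceeds the one-segment SSE.

One fixture subtlety: the published two-line parameter set for this system
(slopes 1058.6 and 77.12 mg g⁻¹ min⁻½, intercepts 82.59 and 317.0 mg g⁻¹)
intersects near t ≈ 0.057 min, below the first shaking time of the
measurement protocol. A continuous synthetic curve built from those four
values therefore has all twelve protocol times on the second line; tests
and the acceptance script add five sub-minute samples so both stages are
populated and the round trip can be exact.

## Model selection for kinetics

Ranking is by R², but a model reporting a fitted equilibrium capacity is
additionally checked against the experimental plateau: relative deviation
beyond a configurable threshold (default 20%) marks the model "rejected
despite fit quality". This reproduces the standard argument for discarding
the pseudo-first-order law when its plateau (≈2290 mg g⁻¹) disagrees with
the observed ≈3900 mg g⁻¹ even though its straight line looks acceptable.
The pseudo-first-order fit requires the experimental plateau as an input
because its linearization transforms (qₑ − qₜ) before any qₑ is estimated;
points at or above the plateau are excluded with a logged count.

## Nanotube geometry

Zigzag (n, 0) walls are generated by wrapping the graphene sheet with arc
length preserved, so the diameter is exactly √3·a_cc·n/π (a_cc = 0.142
nm). The choice privileges the diameter — the quantity the study fixes —
at the cost of chords slightly shorter than a_cc (< 2% for n ≥ 40). Atoms
are organised in 2n-atom zigzag rings spanning two axial levels a_cc/2
apart; ring centroids are uniformly 1.5·a_cc apart and the atom rows
repeat with period 3·a_cc in alternating gaps a_cc/2, a_cc. The per-atom
ring index is carried on the wall so interior counting never re-derives
it. Tubes are truncated to whole rings, never partial ones, with enough
rings to cover the requested length. Chirality below n = 8 is rejected
(self-intersecting wrap). Multi-wall tubes realize each requested diameter
by the nearest integer chirality and share axis and origin, innermost
first.

## Configuration metrics

The aggregation analysis operates on molecule centres of mass only — the
analysis this emulates works at that resolution, and an all-atom drug
representation would add nothing testable. Choices that were genuinely
open:

- **Clustering criterion**: single linkage on COM–COM distance with a
  1.0 nm default cutoff, implemented with a union-find structure, molecule
  pairs linked under the minimum-image convention. The nanotube joins as a
  single super-node linked to molecules within 0.5 nm of any wall atom;
  the tube itself is never wrapped across the box.
- **Interior counting**: spheres sit on the ring centroids of the
  innermost wall (the interior is defined by the inner channel), with
  default radius 0.9× the inner wall radius ("smaller than the tube") and
  membership deduplicated across the union of spheres.
- **Inside ⊆ on-tube**: a molecule near the axis of a ~6 nm channel is
  farther than any contact cutoff from the wall, so distance linkage alone
  would leave interior molecules outside the tube aggregate while the
  phenomenology counts them as bound ("…of which a part aggregated
  inside"). The trajectory analyzer therefore merges any aggregate
  containing an interior-counted molecule into the tube aggregate before
  computing fractions, making the interior set a subset of the adsorbed
  set by construction. The low-level `cluster_molecules` stays purely
  distance-based.
- **Ring detection tolerance**: raw coordinate input is grouped into rings
  by axial gaps within 0.05 nm; an atom isolated beyond the tolerance, or
  a group spreading past it, is a diagnostic error naming the axial gap
  (deformed walls should fail loudly, not silently miscount).

Aggregate labels are canonical — numbered by first occurrence in molecule
order — so planted ground truth and analyzer output can be compared for
exact equality rather than up-to-relabelling.

## Synthetic data: what it emulates and what it does not

Measurement generators draw from the direct model forms with
multiplicative lognormal noise (capacities are positive; default relative
SD 0.01, a typical spectrophotometric repeatability). They emulate the
study conditions: equilibrium grids inside the measured concentration
window, the twelve shaking times (1–90 min) for kinetics. The Temkin
curve is only positive where k_T·Cₑ > 1, so Temkin grids sit in that
window. The Elovich generator offers both the full integrated form and the
large-t simplified form; the classical plot fits the simplified form, and
exact round trips are asserted only on data from it (the αβt ≫ 1
approximation gap is a property of the published linearization, not of
this code).

Planted configurations place molecules inside the channel (within half the
interior-sphere radius of the axis), on the outer wall (chains anchored
within half the contact cutoff of a wall atom), and in free blobs
separated from everything by at least twice the cluster cutoff, so the
planted partition is the unique single-linkage answer and the returned
ground truth is exact by construction. The toy aggregation dynamics —
rigid Brownian clusters merging irreversibly on contact — reproduces the
qualitative fast decay of the aggregate count; it is a toy, with no
energetics, hydrodynamics, or solvent, and nothing quantitative about real
trajectories should be read from it. Likewise, passing planted-recovery
tests shows the metrics are computed correctly, not that real simulation
frames are this clean: real aggregates deform, graze cutoffs, and wrap
boundaries in ways the planting deliberately avoids.

The default drug-count fixture keeps a 4:1 drug:carbon mass ratio using
the free-base molar mass 543.52 g mol⁻¹ (the hydrochloride value 579.98 is
also provided; the salt dissociates in suspension, so the free base is the
physically loaded species — the constant is exposed for users who prefer
the salt convention).

## Problem sizes

Tests and the acceptance script use 20-point equilibrium grids, the
12-point kinetic protocol (plus 5 sub-minute samples for the two-stage
fit), 200-molecule clustering instances, 100-molecule interior-count
instances against the full 15 580-atom n = 82 wall, 37-molecule planted
configurations, 100-seed noisy-recovery ensembles, and 60-molecule toy
dynamics for 30 steps. These sizes make every oracle comparison exhaustive
while the full suite runs in well under a minute.

## Known limitations

- Only zigzag chirality is generated; armchair/chiral tubes, caps, defects
  and surface functional groups are out of scope.
- The kinetic fits are the classical linearizations; no nonlinear mode is
  offered for them because the published plots and parameters follow the
  linear forms.
- k_T and K_L unit conventions vary across the literature; values are
  reported in the convention of the linearization used and carried as
  plain numbers, never silently converted.
- The pipeline's plotting is intentionally absent; the bundle holds tidy
  JSON/CSV for downstream tools.
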