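# Methods

This note documents the model, its numerical choices, the calibration and
sensitivity procedures, the synthetic-data generator, and the design
decisions made where the design was genuinely open.

## The carbon-balance model

### State and timestep

The simulator integrates a single plant from seeding (DAS 1) to DAS 90 with
an explicit-Euler step of 1 h. State comprises total leaf area *s* (m²),
leaf mass *M_L*, inflorescence/stem mass *M_i*, root mass *M_r* (g dry
mass), the transient starch pool Σ (µmol C), the remaining seed reserve (g),
and a cumulative carbon ledger. Drivers and state are evaluated at the start
of each hour; there is no implicit or adaptive stepping. Daylight occupies
hours [0, P) of each day (the model has no within-day asymmetry, so the
placement of the light block is inconsequential).

### Carbon supply

*Day.* Whole-plant assimilation per hour is `A(das) · s_eff · 3600`, where
`A` is area-based net photosynthesis and `s_eff = r·s + 0.1·(1−r)·s` corrects
for leaf overlap: the projected fraction *r* of the canopy photosynthesizes
at the measured rate, the shaded remainder at 10% of it. A fraction σ
(default 0.6) of fixed C goes to starch; the rest, minus inflorescence and
root maintenance respiration and root exudation, is the daytime NAR. Leaf
maintenance (and leaf growth respiration as a CO₂ flux) is **not** charged by
day because gas-exchange measurements of `A` are already net of it.

*Night.* The starch pool accumulated by dusk is drawn at the constant rate
Σ/night_h and is empty exactly at dawn (the final night hour draws the exact
remainder, so no floating-point residue accumulates). Nighttime NAR is the
draw minus maintenance respiration of **all** organs — leaf maintenance uses
total leaf area, since all tissue respires — minus exudation.

*Heterotrophic phase (DAS 1–4).* Growth is funded by mobilizing 25% of the
*initial* seed reserve per day (hourly micro-steps), so the reserve is
exactly depleted at the end of DAS 4; mobilizing 25% of the *remaining*
reserve would never deplete it, contradicting the stated 4-day depletion.
The reserve is the seed weight (initial cotyledon mass is 90% of it).
Mobilized C pays cotyledon maintenance first; the remainder grows cotyledon
mass and area with the germination-phase coefficients, inflorescence and
root allocation forced to zero (root growth starts only once photosynthesis
begins). Exudation is charged only once roots exist; its default magnitude
(10⁻³ µmol h⁻¹) is negligible either way.

### Growth allocation

Positive NAR is converted to growth carbon `G = NAR / C` with
C = 37 500 µmol C g⁻¹ dry mass (45% carbon at 12 g mol⁻¹). Per-phase
partition coefficients ι, ρ, ˢλ, ᵗλ ≥ 0 (summing to 1) split G among
inflorescence, roots, leaf area growth and leaf thickening. Each sink pays a
growth-respiration tax: new biomass is `G·coef·(1 − ŕ^g_organ)`, the rest is
respired. Growth respiration is charged identically day and night; although
a daytime gas-exchange `A` may partially include leaf growth respiration,
treating (1 − ŕ^g_L) as a tissue-construction cost on both sides of the diel
cycle keeps the allocation symmetric — a documented divergence candidate.
New leaf area is `Δs = SLA · ΔˢM_L` with SLA = s/M_L taken at the start of
the hour (no lag). The night-time allocation writing the leaf-area share as
(1 − ᵗλ − ι − ρ) is algebraically identical to using ˢλ and is implemented
as such.

Negative NAR (maintenance demand exceeding supply) clamps growth to zero and
records the shortfall in a deficit ledger; biomass is never decremented —
the model has no senescence or mass loss.

### The carbon ledger

Every hour the ledger accumulates fixed C, mobilized seed C, maintenance
respiration, growth respiration, exudation, biomass C (mass gains × C) and
unmet deficit. Conservation —

    fixed + mobilized + deficit
      = biomass C + maintenance + growth respiration + exudation + starch pool

— holds to machine precision by construction and is asserted to 10⁻⁹
relative in the tests across 50 randomized configurations.

### Discretization error

A brute-force per-second integration of one day differs from the hourly step
only through within-hour state feedback; the relative deviation of the daily
increments is about half the hourly relative growth rate (measured: 0.47% at
the fixture's fastest-growth day, 0.04% late in life). The test asserts
<0.1% agreement on a slow-growth day; during peak growth the 1 h step
under-integrates by a few tenths of a percent per day, which is immaterial
next to the parameter sensitivities of interest.

## Default parameters

| parameter | symbol | default | units |
|---|---|---|---|
| starch set-aside | σ | 0.6 | fraction of daytime fixed C |
| carbon content | C | 37 500 | µmol C g⁻¹ dry mass |
| leaf maintenance | R^m_L | 0.35 | µmol m⁻² s⁻¹ |
| inflorescence maintenance | ŕ^m_i | 7.0·10⁻³ | µmol g⁻¹ s⁻¹ |
| root maintenance | ŕ^m_r | 1.6·10⁻² | µmol g⁻¹ s⁻¹ |
| leaf growth respiration | ŕ^g_L | 0.104 | g C g⁻¹ |
| inflorescence growth respiration | ŕ^g_i | 0.17 | g C g⁻¹ |
| root growth respiration | ŕ^g_r | 0.13 | g C g⁻¹ |
| root exudation | E | 1.0·10⁻³ | µmol plant⁻¹ h⁻¹ |
| shaded-leaf photosynthesis | — | 0.1 | fraction of exposed rate |
| seed mobilization | — | 0.25 | day⁻¹ (of initial reserve) |
| initial leaf area | — | 5.0·10⁻⁶ | m² |
| initial leaf mass | — | 1.8·10⁻⁵ | g (90% of seed weight) |
| photoperiod | P | 8 | h |
| phases (wild type) | — | 1–4 / 5–45 / 46–66 / 67–90 | DAS |

The maintenance and growth respiration coefficients are literature values
for herbaceous tissue; σ = 0.6 is the empirically observed set-aside rather
than the theoretical optimum σ* = (24−P)/24 (= 2/3 at P = 8), which the
package computes via `optimal_sigma`, including its maintenance-asymmetry
correction `σ* = (1 − (R^m_D − R^m_N)/A)/(1 + P/(24−P))`.

The germination-phase coefficients (not part of the published set) default
to cotyledon-only growth: ι = ρ = 0, ˢλ = 0.8, ᵗλ = 0.2; they are
calibratable like the others.

## Calibration

Four observables — leaf area, leaf mass, root mass, stem (inflorescence)
mass — each contribute one objective: a sum over harvest points of
`1/(1 + exp(α·|dif|/SD + β))` with α = −10, β = 5. A point at the measured
mean contributes 1/(1+e⁵) ≈ 0.0067, a point one SD away 1/(1+e⁻⁵) ≈ 0.9933,
so an objective ≤ 1 ("qualified") means every point lies essentially within
its standard deviation. Points are unweighted by replicate count.

The 16 coefficients are encoded as a [0,1]¹⁶ genome; each phase is projected
onto the bounded simplex by a repair step (fixed coordinates pinned, the
rest clipped, renormalized, lower bounds re-enforced). The default
constraint box forbids inflorescence allocation before the late vegetative
phase and guarantees roots at least 1% of NAR after germination; both are
stand-ins for the study's unpublished constraint table and can be overridden
per phase (`bounds_overrides`). Note that the published wild-type solution
itself carries a 0.01 early-vegetative inflorescence coefficient, which the
default box excludes — recover such solutions by relaxing that bound.

The optimizer is an elitist non-dominated sorting GA (NSGA-II: fast
non-dominated sort, crowding distance, binary tournament, SBX η = 15 at
rate 0.9, polynomial mutation η = 20 at rate 1/16), population 64 for 200
generations by default. Because the sigmoid objective saturates beyond
~1.5 SD, a pure GA at desk scale stalls on a plateau (the original
calibration spent 200 000 iterations on a compute cluster); the run is
therefore memetic: every 50 generations, and again at the end, elite members
are polished by bounded trust-region least squares on the *signed* residuals
(model − mean)/SD — which remain informative everywhere — and re-injected in
place of the most dominated members. Qualified settings are censused across
the entire run (not just the final front), deduplicated at 6 decimals.
Everything is reproducible for a fixed seed.

Qualified settings are grouped by Ward agglomerative clustering on the
16-dimensional coefficient vectors (cluster count by silhouette over 2–8
unless fixed) and ranked by the sum of the leaf-area and leaf-mass
objectives, from which the top two settings are reported — fit to leaf area
and leaf mass being the emphasis of the original selection.

**Verified behaviour.** On noiseless synthetic data (SD floored at 5% of the
mean) generated from the packaged mutant-profile coefficient set, the
default run returns on the order of a thousand qualified settings whose
early-vegetative ˢλ and ᵗλ all lie within ±0.05 of truth; the later-phase
coefficients are less identifiable (the trajectory constrains them more
weakly), mirroring the bimodal posterior spread of the original study. With
10% noise the Pareto front exhibits the leaf-area/leaf-mass trade-off: its
leaf-area-best and leaf-mass-best members are distinct, each beating the
other on its own objective.

## Sensitivity analysis

One input is perturbed at a time, the model re-run, and percent change in
leaf area and plant mass reported at 26/44/66/86 DAS; an input is "sensitive"
if any output changes by more than 1%. Partition coefficients move by ±1
percentage point (0.01) with a named compensating coefficient absorbing the
opposite change (thickening ↔ area growth; roots ↔ thickening with area
growth held constant; inflorescence ↔ thickening); scalar inputs
(photosynthesis, initial leaf area) move ±1% relative; the starch fraction
moves ±1 point; vegetative-phase length moves ±1 day by shifting the
late-vegetative/reproductive boundary. Only the percentage-point reading of
coefficient perturbations yields the published order of magnitude (tens of
percent at 86 DAS).

With the packaged drivers the battery reproduces the published structure:
every response sign matches; ±responses are antisymmetric; the
thickening↔area shift dominates photosynthesis, which dominates the starch
fraction; early-life shifts amplify with age; late-vegetative inflorescence
shifts are sub-threshold; and checkpoints before a perturbation's phase are
exactly zero. Exact cell magnitudes depend on the unpublished measured
driver curves and are not reproduced — e.g. the ±1 day vegetative-length row
prints as 0 (integer-rounded) in the study but measures ≈ ±2% on final leaf
area with the synthetic drivers.

## Synthetic data

The generator stands in for the study's unpublished measurements and is
shape-faithful, not value-faithful:

* **Photosynthesis**: a declining cubic, ≈6.8 → 3.1 µmol m⁻² s⁻¹ over the
  life cycle for the wild-type profile; the large-rosette mutant profile is
  scaled to 80% (within the reported 15–23% deficit band).
* **Leaf overlap**: a power law in DAS, projected/total ratio ≈0.95 → 0.62
  (clamped to 1 for young rosettes, which genuinely do not overlap); the
  mutant profile has 8–10% less overlap. DAS-parameterization keeps the
  driver decoupled from simulated state; an area-based variant is available
  (`on_area=True`).
* **Harvests**: 4 days (26/44/66/86 DAS), n = 10 replicates, multiplicative
  lognormal noise with 10% CV by default — organ masses are positive and
  real measurement spread grows with the mean (a normal option is retained).
  Reported SD is the sample SD floored at 5% of the mean, so a noiseless
  study still carries finite measurement uncertainty (without the floor,
  CV = 0 gives SD = 0 and the weighted difference is undefined). Harvest
  days on which an organ has not emerged (no inflorescence before flowering)
  produce no data point, as in a real destructive harvest.

A green calibration test on these fixtures establishes that the pipeline
recovers parameters *when the model class is correct and the noise model is
known* — it says nothing about model misspecification, measurement bias,
within-plant sampling error, or day-to-day environmental variation, none of
which the generator emulates.

## Known limitations

* No water relations, turgor, nutrient or temperature response; no
  light-response curve (photosynthesis is an empirical time course).
* No senescence or mass loss; states are monotone non-decreasing.
* No night-time growth penalty (day and night growth are equally efficient
  given carbon).
* The 1 h explicit Euler step under-integrates by a few tenths of a percent
  per day during peak growth (see Discretization error).
* Absolute trajectories depend on driver curves the original study did not
  publish; the packaged fixtures reproduce shapes and sensitivity structure,
  not the study's absolute numbers.
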