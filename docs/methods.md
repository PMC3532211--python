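# Methods

## Model structure

The package implements a biomass-based, stage-structured approximation of
a physiologically structured consumer population: each species is reduced
to three biomass densities (small juveniles J, large juveniles LJ, adults
A) whose couplings are built so that equilibria of the reduced system
coincide with those of the underlying size-structured model.  Two such
populations — parameterized for North Sea sole and plaice — feed on three
semi-chemostat resources: one exclusive resource each, plus a shared
resource.

State vector (fixed order, g L⁻¹):
`(R_p, R_s, R_sh, J_p, LJ_p, A_p, J_s, LJ_s, A_s)`.

Resource dynamics: `dR/dt = r (K − R) − consumption`.  Semi-chemostat
(supply-limited) rather than logistic growth is assumed because the
benthic invertebrate resource base is renewed largely by external
recruitment rather than local self-replication.  The overlap fraction ω
splits the sole-side maximum `K_m` into `(1 − ω) K_m` (sole exclusive)
and `ω K_m` (shared); `K_p` is untouched.  The split conserves `K_m`
exactly for every ω, so ω moves competition intensity without changing
the total resource supply on the sole side.

Feeding: each stage ingests at
`IR = I_max (R_own + R_sh)/(R_h + R_own + R_sh)` — a Holling type-II
response in the *summed* availability of the two resources, consumed in
proportion to their densities.  This "no-preference" closure is the
simplest two-resource generalization consistent with a single
half-saturation constant and introduces no extra parameters; the degree
of sharing is controlled purely by the carrying-capacity split above.

Net biomass production: `ν = δ·IR − T` (conversion efficiency times
intake, minus mass-specific maintenance).  Negative ν is starvation: the
stage loses biomass at rate ν and neither matures nor reproduces.

Stage flows, per species (ν⁺ = max(ν, 0); μ_i = background plus fishing
mortality of stage i):

    dJ/dt  = ν_A⁺ A + ν_J J  − γ_J J  − μ_J J
    dLJ/dt = γ_J J + ν_LJ LJ − γ_LJ LJ − μ_LJ LJ
    dA/dt  = γ_LJ LJ + (ν_A − ν_A⁺) A − μ_A A

Adults never grow: positive adult production is reproduction (inflow to
J), negative adult production is starvation loss.  Maturation out of a
stage is

    γ(ν⁺, μ, z) = (ν⁺ − μ) / (1 − z^(1 − μ/ν⁺)),   γ = 0 for ν ≤ 0,

with z the stage's entry-to-exit mass ratio.  The expression has a
removable singularity at ν = μ with limit −ν/ln z; it is evaluated with
`expm1`, which keeps full floating-point precision arbitrarily close to
the singularity, and the z-power underflow regime (ν → 0⁺ with μ > 0) is
clamped to γ = 0.

Fishery: a single effort E acts on both species through stage- and
species-specific catchabilities, F = f·E, on large juveniles and adults
only (small juveniles pass through the gear).  Adults are landed;
large juveniles are below the minimum landing size and discarded.  Per
species: landings = f_A E A, discards = f_LJ E LJ, discard ratio =
discards/landings (0 when both flows vanish, flagged NaN when only
landings do), revenue = price × landings / 1000.  Because the state is
volumetric, revenue carries the unit EUR L⁻¹ d⁻¹; only curve shapes and
ratios are meaningful, not absolute euro amounts, and the effort unit is
likewise an arbitrary harvesting intensity (catchabilities were derived
so that E = 1 reproduces assessment-scale adult fishing mortalities).

## Parameters

The shipped default configuration (`data/default_params.yaml`) carries
all per-species biology and the resource base.  The entries that matter
most for the dynamics:

| symbol | meaning | unit | plaice | sole |
|---|---|---|---|---|
| I_max (J/LJ/A) | max mass-specific intake | g g⁻¹ d⁻¹ | 0.069/0.020/0.013 | 0.050/0.016/0.011 |
| T | maintenance rate | g g⁻¹ d⁻¹ | 0.0037 | 0.0032 |
| δ | food conversion factor | – | 0.36 | 0.36 |
| μ | background mortality | d⁻¹ | 0.001 | 0.001 |
| z (J→LJ, LJ→A) | stage mass ratios | – | 0.003, 0.048 | 0.0003, 0.118 |
| f (LJ, A) | catchabilities | per unit E | 5e-5, 0.001272 | 2e-6, 0.001455 |
| P | price | EUR kg⁻¹ | 1.38 | 10.06 |
| r, R_h | resource regrowth, half-saturation | d⁻¹, g L⁻¹ | 0.1, 0.01 | (shared) |
| K_m, K_p | resource maxima | g L⁻¹ | — K_p = 1 | K_m = 0.3 |

μ = 0.001 d⁻¹ corresponds to ≈ 70% annual survival; K_m = 0.3 g L⁻¹
converts a 10.1 g m⁻² areal benthos density into the 10-cm near-bottom
habitat layer with the fauna concentrated in one third of the surface.
Stage-average weights, average lengths and the z ratios are not free:
`derivation.validate_params` recomputes them from the length–weight
allometry (W = a L^b; logarithmic-mean stage weight
(W_max − W_min)/(ln W_max − ln W_min), the biomass-weighted mean of a
1/W-distributed cohort) and compares against the stored values.  Sole
rows agree within 2% plus printed-rounding slack; the stored plaice
weights are internally inconsistent with the stored plaice a, b
coefficients (a ≈ 0.0094 would be needed), so plaice rows are checked at
a relaxed 7% and the discrepancy is surfaced in the validation report
rather than silently accepted.  The dynamics never consume the weight
entries, so this is diagnostic only.

## Equilibrium computation

`solve_equilibrium` finds the attractor reached from a given initial
state:

1. **Integrate** (LSODA, rtol 1e-8, atol 1e-12) in chunks of growing
   length (2 000 → 64 000 d) until the relative state change over a chunk
   falls below 1e-7.  The system has an intrinsically slow mode — the
   juvenile stage of both species is a near-transparent conduit (tiny z
   makes γ_J ≈ ν_J − μ_J), so J relaxes on a ~1e5-day timescale — which
   makes "integrate until nothing moves" alone impractical.
2. **Polish** with a damped Newton iteration (Powell hybrid) on
   `rhs = 0`.  A species whose polished biomass is negative or whose
   total falls below the extinction tolerance 1e-9 g L⁻¹ is clamped to
   zero and the reduced system re-solved; this keeps the solver off
   shadow branches where a species "persists" at numerically meaningless
   densities.  Converged records satisfy max-norm residual < 1e-9.
3. **Warm starts**: inside sweeps each grid point starts from the
   neighbouring equilibrium and the Newton polish is attempted first; the
   result is accepted only if a finite-difference Jacobian has all
   eigenvalues with real part < 1e-8 d⁻¹.  This both confirms local
   stability and rejects extinct states that the absent species could
   re-invade.  On failure the solver falls back to integration.
   Non-convergence within the integration budget returns a flagged
   record, never a silent result.

Continuation follows the branch from the unfished (or zero-overlap) end
upward.  The model exhibits bistability near extinction thresholds (an
emergent Allee effect typical of stage-structured harvesting models):
cold starts from small seed densities can collapse at lower efforts than
the continuation branch persists to.  All reported thresholds are
therefore branch-following: extinction efforts are located by a doubling
search plus bisection on the persistence boundary (relative tolerance
1e-4), warm-started from the last persisting state.  Sentinels: +inf for
an unfishable species, NaN for a species already absent at E = 0.

Revenue curves are analyzed on the sweep grid (strict-neighbour local
maxima, tolerant of exact-tie plateaus), each maximum refined by bounded
golden-section search on re-solved equilibria, and classified as
flat/unimodal/bimodal/multimodal.  Whether the global maximum lies beyond
the plaice extinction effort is decided against the bisected threshold,
not the grid bracket.  In the default parameterization this comparison is
knife-edge: the combined-revenue maximum sits ~1% below the plaice
extinction effort at ω = 0.5 and 0.8, with the sole-only revenue plateau
beyond the threshold within ~2% of the peak value.

## Scenarios and problem sizes

The packaged scenarios emit curves plus a pass/fail property report:

- **competition**: ω ∈ [0, 1], E = 0; 101 points (tests use 21–101).
  Checks plaice biomass non-decreasing, sole non-increasing, sole
  excluded before complete overlap (default: ω ≈ 0.886).
- **effort**: E from 0 to an adaptive maximum (doubling search until both
  species are extinct, ×1.1 margin); 201 points.  At ω = 0: adult
  biomass monotone declining, J and LJ hump-shaped, discard ratio rising,
  plaice extinct before sole.  At ω > 0: sole biomass rises by
  competitive release while plaice declines toward extinction, then falls.
- **revenue**: effort sweeps at ω ∈ {0, 0.5, 0.8}, 201 points each, with
  maxima refinement as above.
- **equal-sizes**: both species rebuilt on a shared stage-boundary
  triple; z, stage weights and average lengths re-derived from each
  species' own allometry, intake/maintenance/catchability retained.  The
  default shared boundaries are sole's (0.85/12/24 cm): under that choice
  the headline structure survives with both extinction thresholds moved
  to higher effort (plaice ≈ 70 → 129, sole ≈ 742 → 752) and revenue
  bimodality intact.  Sharing plaice's boundaries instead collapses
  sole's LJ→A mass ratio (0.118 → 0.047) and lowers sole's threshold;
  both choices are exposed and exercised in tests.

## Synthetic pseudo-observations

`generate_pseudo_observations` emulates equilibrium survey/market data:
per-stage biomasses and discard fractions on an effort grid, each
multiplied by independent lognormal noise with unit median and a given
coefficient of variation (positivity-preserving, seed-reproducible).
It emulates *observation* error only — no process noise, no temporal
autocorrelation, no size-selective sampling bias, and the "observations"
come from exact model equilibria.  Passing calibration-recovery tests
therefore demonstrates that the tuning pipeline inverts the model
correctly under multiplicative noise, not that the model fits real
survey data.

`tune_catchability` solves, per species, the 1-D root-finding problem
"which f_LJ makes the equilibrium discard fraction hit the target"
(Brent, bracket expansion, achieved-fraction tolerance 1e-6 relative;
each probe re-solves the equilibrium).  Tuning defaults to ω = 0, where
the species decouple and two scalar solves suffice, at reference effort
E = 1 (the effort at which adult catchabilities reproduce
assessment-scale fishing mortalities); both are explicit arguments.  The
realized discard fraction is monotone in f_LJ over the relevant range,
which the tests verify.  Note that with the shipped default
catchabilities the realized equilibrium discard fractions at ω = 0,
E = 1 are 0.072 (plaice) and 0.0036 (sole); reaching fractions of
0.3/0.1 at unit effort requires f_LJ ≈ 1.9e-4 / 5.3e-5.  The structural
reason is that the near-transparent juvenile stage pins each resource
close to the adult break-even density, capping the equilibrium LJ/A
biomass ratio (≈ 1.8 plaice, ≈ 2.6 sole at E = 1); a closed-form version
of this argument serves as an independent oracle in the test suite.

## Numerical choices and degenerate inputs

- Extinction tolerance 1e-9 g L⁻¹ with clamp-and-repolish; residual
  tolerance 1e-9 (max-norm); settle tolerance 1e-7 per chunk.
- ω = 1 leaves the sole-exclusive resource as a state variable with
  K = 0 (it relaxes to zero; no re-dimensioning).
- Degenerate stage boundaries (L_entry = L_exit) give z = 1 and a
  lower-bound stage weight via the logarithmic-mean limit.
- Starving adults remain catchable: catchability is independent of
  condition.
- The RHS rejects NaN or negative states at the public interface and
  clips transient sub-zero excursions (≥ −1e-10 from the integrator)
  internally.
- Curve CSVs carry a `# key: value` provenance header (config hash,
  seed) and 12-significant-digit floats; every CLI run serializes its
  resolved configuration next to its outputs.

## Known limitations

- No seasonality, spatial structure, stochastic demography or
  individual-level size distribution; equilibrium analysis only (no
  cycle or chaos detection — the stability check would flag a Hopf
  crossing as non-convergence rather than follow it).
- Costs of fishing are out of scope; revenue, not profit, is the
  economic observable, and only its shape over the arbitrary effort unit
  is interpretable.
- The two-resource functional response assumes equal preference and a
  common half-saturation constant; species-specific preference for the
  shared resource would add a parameter the default set cannot pin down.
- Bistability near extinction thresholds means threshold estimates are
  branch-conventions (from low effort upward); management conclusions
  near those efforts inherit that convention.
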