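# Methods

## Model structure and assumptions

The culture model is a three-state ODE system (biomass X, medium nitrogen
N, nitrogen quota Q) for a well-mixed, carbon-replete, temperature- and
pH-controlled photobioreactor. Its assumptions, inherited from the
physical set-ups it represents:

- **Well-mixed reactor.** Nutrient and cell concentrations are spatially
  homogeneous; mixing is orders of magnitude faster than growth.
- **Light limits growth; nitrogen limits it through the quota.** The
  light response is Monod-type with a Hill exponent n on the
  culture-averaged intensity I_av. Nitrogen acts through the Droop quota:
  uptake and growth are decoupled, growth stops at Q_min and uptake stops
  at Q_max. The Droop factor is normalized so that μ_max is the actual
  maximum specific growth rate (μ = μ_max at saturating light and full
  quota); this reading is pinned by the half-saturation identity
  μ(K_I, Q_max) = μ_max/2 and by μ_max lying in the observed 1.5–2.7 d⁻¹
  range for this organism.
- **No photoinhibition, no nitrate inhibition, no surge uptake above
  Q_max.** The Droop structure guarantees Q(t) ∈ [Q_min, Q_max] whenever
  the inoculum quota is inside that interval.
- **No growth on internal carbon in the dark.** μ = 0 the instant the
  lights go off. Biomass decay (K_d) and nitrogen uptake continue in the
  dark by default: decay is a property of the biomass, and the Droop
  assumption explicitly decouples uptake from growth. Both are
  configurable flags (`SimulationOptions.dark_decay`, `dark_uptake`).
- **One-dimensional (panel) / in-plane (column) Beer–Lambert
  attenuation.** Absorption and scattering are lumped into a single
  coefficient Ka that tracks pigmentation through the quota
  (Ka = 2.74 Q + 0.21 L mg⁻¹ m⁻¹). No vertical variation, wall
  reflection or bubble optics.
- **Composition from the quota.** Total fatty acids follow the reciprocal
  law C_TFA = 3.68 Q^(−1.32) + 42.2 mg g⁻¹ DCW (decreasing in Q); the
  specific EPA content is the constant 55 mg g⁻¹ DCW, so the EPA fraction
  of TFA is 55/C_TFA(Q). The observed spread of the EPA content
  (s.d. ≈ 7.7 mg g⁻¹) is *not* modelled; composition is deterministic.

## Parameters

The eight kinetic constants (defaults are the calibrated values for
*P. tricornutum* in a 5 L flat-panel reactor):

| name   | meaning                      | default | unit |
|--------|------------------------------|---------|------|
| μ_max  | maximum specific growth rate | 2.4     | d⁻¹ |
| K_d    | biomass decay rate           | 0.010   | d⁻¹ |
| Q_min  | subsistence quota            | 0.034   | mg N mg⁻¹ DCW |
| Q_max  | storage capacity             | 0.12    | mg N mg⁻¹ DCW |
| U_max  | maximum uptake rate          | 0.59    | mg N mg⁻¹ DCW d⁻¹ |
| K_N    | uptake half-saturation       | 0.010   | mg N L⁻¹ |
| K_I    | light half-saturation        | 50      | µmol m⁻² s⁻¹ |
| n      | light Hill exponent          | 1.9     | — |

The empirical-correlation coefficients (Ka slope/intercept, TFA
coefficient/exponent/offset, EPA content) live in the same
`KineticParameters` object so a recalibrated model is a single value.
K_d may be exactly zero (the conservation limit); all other constants
must be strictly positive and Q_min < Q_max.

Media are specified by their f/2 strength: 1× f/2 supplies 880 µM NaNO₃ =
12.32 mg N L⁻¹. The inoculum is assumed nutrient-replete (Q₀ = Q_max) and
its biomass is derived from optical density by inverting the 10 mm-cuvette
relation, X₀ = OD₅₅₀ / (0.01 · Ka(Q_max)); both are overridable.

## Radiative field

Flat panel: I_av = I₀ (1 − e^(−a))/a with optical depth a = Ka·X·L; a
Taylor branch handles a → 0. Bubble column (three light banks at 120°
around a cylinder of radius R): I_av is the cross-section average of the
sum of three Beer–Lambert contributions, each attenuated over the chord
from the point to its bank. The double integral is evaluated on a
tensor-product rule — Gauss–Legendre in radius (64 nodes), uniform
periodic rule in angle (128 nodes, spectrally accurate for the periodic
integrand) — with an automatic resolution-doubling convergence check
(relative tolerance 5×10⁻³, chosen because the rule's worst-case error at
extreme optical depth Ka·X·R ≈ 400 is ≈ 2×10⁻³ while genuine
under-resolution produces errors orders of magnitude larger). The clear
culture limit is exactly 3·I₀ per construction.

Because the integral depends on biomass and pigmentation only through the
product Ka·X, the ODE right-hand side uses a cached monotone (PCHIP)
interpolant of I_av over that product (160 log-spaced points to
Ka·X = 2000 m⁻¹; measured error < 0.03%, asserted < 0.5% in the tests)
instead of re-integrating at every derivative evaluation.

## Integration

LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ by default. Light/dark transitions,
harvests and scheduled dilutions are hard discontinuities: the integrator
is restarted at each switch with exact state handoff. Nitrogen depletion
is recorded by event detection on the crossing N = 0.1 mg N L⁻¹ (the
external concentration only decays asymptotically under Monod uptake, so
"exhausted" needs an operational threshold; 0.1 mg L⁻¹ sits near the
practical detection limit of the UV nitrate assay). Inside the right-hand
side the state is clipped to its physical domain (X, N ≥ 0;
Q ∈ [Q_min, Q_max]) to absorb solver rounding; the kinetic functions
themselves reject violations beyond 10⁻⁹.

Correctness oracle: the nitrogen balance d(N + QX)/dt = −K_d·Q·X, exactly
conservative at K_d = 0. The reference run holds N + QX to < 10⁻⁶
relative; the residual (decay sink integrated by trapezoid) is reported in
`SimulationResult.metadata`.

The experimental practice of withdrawing ~3% of the broth on sampling days
and replacing it with nutrient-free salt solution is *not* simulated by
default (the core model deliberately omits it); `scheduled_dilutions`
provides the hook for fidelity studies.

## Repeated batch

A harvest replaces a volume fraction f instantaneously:
X ← (1−f)X, N ← (1−f)N + f·N_fresh, Q unchanged (intracellular). The
overall productivity of a run is defined as (cumulative harvested biomass
per litre + final standing biomass − initial biomass)/elapsed days; the
plain-batch comparison uses the batch definition DCW(t)/t. The packaged
optimization scenario follows the validated repeated-batch protocol:
5× f/2 starting medium, 6× f/2 refresh, 8-day batch then four cycles,
grid over intervals 1–7 days × fractions 10–90%.

## Calibration

The objective is a weighted root-mean-square misfit over variables k, days
j and replicates i: sqrt((1/(pqm)) Σ w_j (ŷ − y)²), with late-phase
emphasizing weights — biomass weighted by its day-mean, quota by the
reciprocal day-mean, nitrogen unweighted (day means are taken over
available replicates when one is missing). The weights make the biomass
term dominate by ~10³; this is deliberate (the late-batch biomass is the
commercially relevant prediction) but it flattens the quota's information
content, which is why the uptake constants are weakly identified.

Minimization is derivative-free Nelder–Mead on log-transformed parameters
(positivity by construction) with the quota pair reparameterized as
(Q_min, Q_max − Q_min) so Q_min < Q_max always. The plain simplex stalls
on a deceptive ridge of this objective (a local minimum trading K_I and
μ_max against Q_max); the implementation therefore uses the adaptive
simplex variant with alternating restarts — fresh starts jittered around
the initial guess (exploration) and restarts jittered around the best
point so far (exploitation), `FitSettings.restarts` legs in total —
stopping early once the objective has collapsed by five orders of
magnitude. Defaults are 50 outer iterations
and one restart; the fit is flagged converged when the objective improves
by < 1% over 15 iterations. A mask (`FitSettings.free`) freezes any
subset — by default K_d, K_N and U_max are frozen, since the sensitivity
analysis shows them nearly non-identifiable from batch growth data. The
initial biomass and medium nitrogen are experiment metadata, not fitted;
the inoculum quota is the candidate Q_max.

Trajectories are matched to observation days by exact-time integrator
restarts (`predict_states`), not by interpolating a daily output grid.

The empirical correlations are refit separately: ordinary least squares
for the Ka–Q line, damped (Levenberg–Marquardt) least squares in
log-parameters for the three-parameter TFA power law (more than three
pairs required).

## Sensitivity analysis

One-at-a-time ±20% on the eight constants, reporting the relative change
of the final biomass and final quota under two scenarios: nitrogen-limited
(the 4× f/2 reference batch) and nitrogen-sufficient, realized as
N₀ = 2000 mg N L⁻¹ so that N ≫ K_N holds for the entire run (a 15× f/2
medium actually runs dry by day 14 at these growth rates, which would mix
the regimes). Reproduced behavior: μ_max, K_I and n are influential in
both regimes; K_N and U_max are negligible (< 0.2%); Q_max dominates the
replete-culture quota and Q_min the starved-culture quota. One quantitative
caveat: Q_min retains a ~0.6–0.8% influence on the final biomass even when
nitrogen is replete, because the quota dips to ≈ 0.09–0.11 during the
light phase (uptake at U_max cannot keep pace with μ ≈ 2 d⁻¹ growth), so
the Droop factor never fully loses its Q_min dependence.

## Synthetic observations

The generator simulates the true trajectory and applies independent
multiplicative log-normal noise with unit mean (σ = sqrt(ln(1+rel²)), so
the relative s.d. is exact) — all observables are positive and replicate
scatter in this system is reported at 15–20%, so the defaults (5% biomass
and nitrogen, 10% quota) are realistic but well-posed for recovery tests.
Nitrogen readings are capped at N₀. Two quota modes mirror the
measurement chain: direct noise on Q, or derivation from the noisy N and X
via Q = (N₀−N)/X — the latter can push early-day quotas above Q_max,
which is flagged (warning) but never clipped, as the real indirect
measurement shows the same artefact. The generator does not emulate
instrument-specific error structure (spectrophotometer nonlinearity, GC
drift) or the sampling-withdrawal dilution, so passing recovery tests
demonstrates identifiability under the model's own noise assumptions, not
robustness to structural misspecification.

## Problem sizes

The test suite and the acceptance script run the 5 L reference batch at
16 days (output 24 points/day), the harvest grid at its full 7×9 cells
(4 points/day output), the Monte-Carlo cross-check of the column integral
at 10⁶ samples × 20 draws, and parameter recovery at 5 perturbed starts
on a 10-day, 3-replicate noiseless set — sizes chosen to exercise every
code path at full fidelity on a desktop.

## Known limitations

- No temperature, pH, salinity or CO₂ effects (held constant in the
  set-ups the model represents).
- No uncertainty quantification: the calibration returns point estimates;
  no confidence intervals are represented.
- Composition is quota-deterministic; per-fatty-acid speciation and EPA
  variability are out of scope.
- The radiative model has no scattering phase function, wall reflection
  or bubble optics; all optics are lumped into Ka(Q).
- Continuous/chemostat operation and economic objectives are not
  modelled.
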