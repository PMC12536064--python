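# Methods

This note documents the models implemented in `lichendry`, the choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## Conventions and units

Water potential Ψ and osmotic potential π are in MPa and non-positive;
turgor pressure P_T = Ψ − π is non-negative before turgor loss. Weights are
mg; water loss WL is counted in mg from the initial fresh weight; relative
water content RWC = (FW − DW)/DW × 100 is on a dry-mass basis and exceeds
100% in hydrated thalli. Acoustic hit times are seconds, drying checkpoints
minutes; amplitudes dB, absolute energies aJ.

## Pressure–volume elaboration

1. **Exclusion band.** Points with Ψ above −0.30 MPa are dropped before any
   fitting: dewpoint hygrometers are unreliable near zero and the earliest
   weight loss is apoplastic surface water. The band is read as the open
   interval above the threshold, so a reading of exactly −0.30 MPa is
   retained. The first retained fresh weight defines IFW.
2. **Exponential model.** |Ψ| = a·e^{b·WL} is fitted by nonlinear least
   squares (log-linear start values; bounds a > 0, b ≥ 0). The fit is
   flagged — not rejected — when its adjusted R² falls below the 0.96
   quality gate, which real isotherms of this kind routinely exceed. The
   choice to model |Ψ| (rather than Ψ or 1/Ψ) reads "exponential growth" as
   growth of the potential's magnitude with water loss.
3. **Osmotic line.** 1/Ψ is regressed on WL over the five points of highest
   water loss (ties broken toward the latest measurement). Past turgor
   loss Ψ = π, and van't Hoff solute concentration makes 1/π linear in WL,
   so this tail line is the 1/π–WL relationship, extrapolated over the
   full WL range.
4. **Turgor-loss sweep.** On a uniform grid of 10⁴ steps over
   [0, 1.05 × max WL], P_T = Ψ(WL) − π(WL) is evaluated from the two fitted
   relations; the first step where P_T ≤ 0 is refined by linear
   interpolation between the bracketing steps. Grid points past the pole of
   the 1/π line (where predicted π turns non-negative) are outside the
   line's validity and are not scanned. Halving the grid step moves Ψ_tlp
   by < 10⁻⁴ MPa (tested), so resolution error is far below measurement
   noise. P_T ≤ 0 already at WL = 0 raises an inconsistent-fits error; no
   sign change up to the sweep limit raises a no-turgor-loss error.

Fresh-weight non-monotonicity beyond 1% of IFW raises a warning but keeps
the points: transient balance drift should be visible, not silently
repaired.

### Osmometer calibration

The utility returns Ψ = −φ·ν·m·R·T with R = 0.0083145 L MPa mol⁻¹ K⁻¹.
For the 0.5 mol/kg KCl standard (ν = 2) the manufacturer-tabulated
osmotic coefficient φ = 0.900 at T = 293.15 K reproduces the printed
−2.19 MPa calibration value. Instrument labels sometimes quote this value
at 22 °C; at 295.15 K the same formula gives −2.21 MPa, so the temperature
label is stored as metadata and the 20 °C reference is used for the
standard.

## Fv/Fm response

Fv/Fm = (Fm − F0)/Fm, rejecting Fm ≤ 0 and Fm < F0 as invalid readings.
The sigmoidal response is the Weibull-type decline
fvfm = fmax·exp(−(|Ψ|/b)^c), the standard form in vulnerability-curve
fitting: fmax is the plateau, b the MPa scale at which the response has
fallen to fmax/e, c the shape. Its pointwise confidence band is a seeded
pairs bootstrap (default 1000 resamples, 95% percentile interval). A
constant response is returned as a flat fit with a flag rather than an
error.

The onset of the significant decline is estimated by two-segment
regression on the raw pooled (Ψ, Fv/Fm) points per species, not on the
sigmoid fit — sample identity is kept for robustness checks but the
breakpoint is a species-level quantity, matching how such curves are
plotted and read.

## Segmented regression

The continuous two-segment model y = β₀ + β₁x + β₂(x − ψ)₊ is estimated by
the gap-variable linearization: starting at ψ = median(x), each iteration
adds the regressor −1{x > ψ} and updates ψ by the ratio of its coefficient
to β₂, until the update falls below 10⁻⁶ × range(x) (max 50 iterations).
Candidate breaks are confined to the central 90% of x to avoid boundary
degeneracy; ties in RSS resolve toward the smallest x.

The iteration alone can stall in a local RSS minimum, so every fit is
checked against an exhaustive oracle — a 201-point lattice over the central
90% of x, least squares at each candidate — and restarted from the
oracle's break when the oracle attains a lower RSS (flags `grid_restart` /
`fallback_grid` record this). The oracle also serves as an independent
verification path in the test suite: the iterative estimate must match it
within one lattice step on every seeded instance.

The breakpoint standard error is the delta method on the (gap, slope
change) coefficients; the CI is ψ̂ ± z·se. On single-slope data the slope
change is indistinguishable from zero, the CI legitimately spans most of
the x range, and a no-break warning is raised.

**Limitation.** The Wald/delta interval is asymptotically valid but
slightly anti-conservative at small n for this estimator (the sampling
distribution of ψ̂ is skewed when the kink is weak). In coverage
simulations at the study-scale pooled sample size (~150 points per
species) the 95% interval covers in ~90–94 of 100 runs; at n ≤ 90 observed
coverage can drop to ~85%. Bootstrap or profile intervals would be the
remedy where small samples are unavoidable.

## Random-intercept mixed model and segmented mixed model

The model y = β₀ + β₁x + u_g + ε, u_g ~ N(0, σ_b²), ε ~ N(0, σ_w²) is
fitted by REML. Because each group's covariance is compound-symmetric, the
generalized least-squares pieces have closed forms given the variance
ratio λ = σ_b²/σ_w², and the REML criterion is minimized over log λ by
bounded scalar search (λ = 0 boundary checked explicitly; a boundary
solution is returned with a `singular` flag). Group effects are returned
as BLUPs. The implementation is cross-checked against an independent REML
implementation in the test suite.

For the segmented mixed model (rcUAE–RWC with sample as random effect) the
breakpoint is profiled: each candidate on a 41-point lattice over the
central 90% of x gets a full profile-REML fit with two-segment fixed
effects (same fixed-effect dimension at every candidate, so restricted
likelihoods are comparable), the maximizer is refined once on a local fine
lattice, and the 95% CI inverts the profile likelihood-ratio at the
χ²₁ threshold with linear interpolation between candidates. A nearly flat
profile raises a wide-CI warning; the reported standard error is the CI
half-width divided by 1.96.

The mixed model's response is rcUAE (the normalized cumulative count);
raw cumulative counts can be analyzed by passing them directly to
`fit_segmented_mixed`.

## Acoustic bookkeeping

The debounce filter keeps a hit only if it arrives at least 1 s after the
last **kept** hit ("< 1 s" read strictly, so a gap of exactly 1.0 s
survives). Measuring against the last kept hit rather than the previous
raw hit removes a whole reverberation burst in one pass and makes the
filter idempotent. Trajectories count kept hits up to each twin-sample
checkpoint; RWC always comes from the twin's fresh and dry weights — the
coupling gel spread on the monitored sample is bookkeeping metadata only
(validated as gel = FW_with − FW_without) and gel drying is not modelled.
Hardware acquisition settings (40 dB preamp, 30 dB threshold, peak/hit
definition and lockout times) travel as trace metadata.

A trace with no hits yields an all-zero trajectory flagged silent; the
RWC_UAE estimate requires at least one non-silent trajectory and at least
two trajectories overall. The 8–12% RWC band of the rubbery-to-glassy
cytoplasm transition can be annotated on trajectories for reporting; no
numeric analysis depends on it. No additional high-RWC noise filter is
applied beyond the debounce rule.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed).

**PV isotherms.** The emitted curve is one exponential decline
Ψ(WL) = −a·e^{b·WL} whose five highest-WL points simultaneously define,
through their reciprocals, the osmotic secant line the elaboration
recovers; turgor is the implied difference Ψ − π, positive up to its zero
crossing. The two knobs are an osmotic parameter π₀ (< 0) and an elastic
parameter ε (> 0): the crossing is placed at the symplastic water-loss
fraction |π₀|/(|π₀| + ε) — stiffer thalli lose turgor after less water
loss — and the amplitude a is calibrated (a single multiplication, since
rescaling a moves the exponential and its secant together) so that the
water potential at the crossing equals the harmonic combination

    Ψ_tlp = −|π₀|·ε / (|π₀| + ε)

exactly. This construction makes the generator's truth the exact fixed
point of the elaboration on noiseless data (recovered to ~10⁻⁷ %), so
parameter-recovery tests measure the pipeline's noise response, not an
arbitrary model mismatch. The price is that the generator does not impose
a literal linear-turgor PV curve; its turgor term is whatever the
exponential/secant geometry implies. Defaults (π₀ = −8, ε = 24 MPa,
IFW = 107 mg, DW = 40 mg, 10% apoplastic fraction) put Ψ_tlp at −6.0 MPa,
full-turgor RWC at ~167% and RWC_tlp near 100%, the magnitudes reported
for foliose lichens. An apoplastic plateau (Ψ in (−0.30, 0]) precedes the
exponential branch when the apoplastic fraction is positive. Noise is
i.i.d. Gaussian on Ψ and FW; real hygrometer error is likely
heteroscedastic near zero, which the generator does not model — passing
recovery tests therefore speak to the method's behavior under well-behaved
noise, not to instrument pathology.

**Fv/Fm curves.** Plateau-then-linear decline with Gaussian noise,
truncated at zero: plateau 0.68, break −8.7 MPa, slope 0.023 per MPa
(reaching zero near −38 MPa), σ = 0.03, with 150 pooled points per species
(~6 samples × 25 sequential readings). The sigmoid smoothness of real
curves around the knee is deliberately absent so that the two-segment
model is exactly true and breakpoint bias can be attributed to the
estimator.

**Acoustic experiments.** The twin dries exponentially,
FW(t) = DW + (FW₀ − DW)·2^(−t/h) with half-life h = 60 min from 380% RWC
down to 1%; checkpoints every 30 min. Background hits are homogeneous
Poisson (0.02 hits/min, giving rcUAE of a few percent at high RWC); burst
hits switch on below 6% RWC with intensity proportional to the drying
rate — i.e. emissions per unit water lost, 10 hits/min at onset — so the
expected rcUAE is exactly linear in RWC below the onset and the
trajectory's breakpoint is the onset itself (up to the 30-min checkpoint
discretization, which biases the recovered onset by a few tenths of an
RWC point). Amplitudes are uniform on 30–60 dB, lifted by up to 8 dB deep
into the burst; energies follow a monotone cubic of amplitude
(5, 0.1, 0.002, 0.0008 aJ/dBᵏ) with lognormal scatter (σ = 0.4). No
cavitation physics, bubble nucleation or glassy-state mechanics is
simulated — the generators target the statistical structure the analysis
assumes, nothing more.

## Numerical choices

* Turgor sweep: 10⁴ grid steps, linear interpolation at the sign change.
* Exponential and sigmoid fits: `scipy.optimize.curve_fit` with
  data-driven start values and physical bounds; non-convergence raises a
  fit-failure error with the optimizer's diagnostic.
* Cubic regression: predictor centered and scaled before building the
  Vandermonde basis; coefficients mapped back by polynomial composition;
  rank checked explicitly and reported naming the basis.
* REML: λ searched on log scale in [e⁻¹⁴, e¹⁴] plus the λ = 0 boundary;
  σ_w² floored at 10⁻³⁰⁰ inside logarithms to survive noiseless inputs.
* Defaults: exclusion −0.30 MPa, 5 tail points, QC gate 0.96, debounce
  1 s, CI level 95%, seed 20240724. All configurable via `RunConfig` /
  YAML / CLI flags.

## Known limitations

* Delta-method breakpoint CIs are slightly anti-conservative at small n
  (see above).
* The turgor-loss estimate inherits the exponential model's global nature:
  a misfit far from the crossing still moves the crossing slightly. On
  real isotherms whose Ψ(WL) deviates from an exponential the method's
  output depends on that functional choice; the generator's noiseless
  exactness does not certify it.
* The mixed model has random intercepts only (no random slopes), Gaussian
  errors, and a single common breakpoint across groups.
* Between-checkpoint RWC is linearly interpolated when per-hit stamps are
  needed; fast nonlinear drying within a 30-min window is not resolved.
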