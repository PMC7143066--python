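# Methods

This note records the models, conventions and numerical choices behind
`pdmix`, and what the tests do and do not establish.

## Experimental design

The study design is a two-factor Central Composite Rotatable design:
2^k factorial ("cube") points, 2k axial points at coded distance
α = (2^k)^(1/4) — 2^(1/2) ≈ 1.41 for k = 2 — and a replicated centre point.
α is kept at full precision internally and rounded to 2 decimals only for
display.

**Axial-extreme convention.** The stated factor ranges (FRR 1.0–12.0,
TFR 3.0–18.0 mL/h) are interpreted as the *axial* positions ±α, so the cube
levels are centre ± half_range/α. This is what reproduces the packaged run
table exactly (FRR cube levels 2.6/10.4, TFR cube levels 5.2/15.8); the
"circumscribed" label on such a design is then a nomenclature quirk we
reproduce without resolving.

**Pump rounding.** Natural settings are rounded to 1 decimal (syringe-pump
resolution) *before* they are stored, and every downstream fit uses these
realizable values — the settings the pumps actually delivered, and the ones
printed with the data.

Run order is a uniform random permutation from a seeded generator; the seed
is part of the design metadata so a layout is reproducible.

## Response-surface models

Surfaces are ordinary least squares on the natural (pump-rounded) factor
values, terms drawn from {1, FRR, TFR, FRR², TFR², FRR·TFR}. Coefficient
covariance is σ̂²(XᵀX)⁻¹; term p-values are coefficient t tests, which for
OLS coincide with partial F tests of a single term.

**Model reduction.** Backward elimination drops, one at a time, the
eligible term with the largest p above the *removal* threshold and refits.
Two deliberate choices:

* The removal threshold defaults to 0.10 — the customary alpha-to-remove of
  stepwise backward elimination — while 0.05 remains the level used to
  *report* term significance. On the packaged data the TFR main effect in
  the reduced PDI model sits at p ≈ 0.06: a 0.05 removal rule would expel
  it, whereas the 0.10 rule retains it and lands on the same four-term
  endpoints for size and PDI that the original analysis reported. Zeta
  potential reduces to the bare intercept either way and is flagged not
  significant.
* Hierarchy is enforced for retention: a main effect is never removed while
  its square *or* an interaction containing it is still present. Without
  shielding by interactions, TFR (p ≈ 0.96 in the five-term PDI model)
  would be expelled before FRR·TFR, which inverts the elimination order a
  practitioner's software would follow.

Reduction is idempotent: reducing an already-reduced model changes nothing.

**Goodness of fit.** R² = 1 − SSE/SST; adjusted R² uses the df-corrected
ratio; PRESS = Σ(eᵢ/(1−hᵢᵢ))² from leave-one-out residuals, and predicted
R² = 1 − PRESS/SST (stored raw, floored at zero in printed reports). The
model F statistic is (SSR/(p−1))/(SSE/(n−p)).

**Prediction intervals.** `predict` returns the SE of the *mean* response
(SE-fit = √(xᵀΣx)) with its 95% t interval, and separately the wider 95%
prediction interval for a new observation. The confidence-of-mean interval
is the primary quantity: at the size optimum it reproduces the study's
reported ≈[25, 57] nm band, which the prediction interval does not.

**Optimization.** The fitted quadratic is minimized/maximized over a
rectangular region by multi-start L-BFGS-B (corners plus a 4×4 interior
lattice). For the reduced size surface this lands on the closed-form
stationary point in FRR, −β₁/(2β₁₁) ≈ 8.56, with TFR pushed to its boundary;
tests cross-check the optimizer against a dense grid scan.

## Condition comparison

Tukey-Kramer all-pairs comparison pools the within-condition variance
(df = N − g) and refers |mᵢ−mⱼ|/√(MSE·(1/nᵢ+1/nⱼ)/2) to the studentized
range distribution; unequal replicate counts are handled by the Kramer
correction, which collapses to classic HSD for balanced groups. Letters are
assigned by the insert-and-absorb algorithm scanning conditions in
descending mean order, so the display does not depend on input order.
Condition means are printed at 2 decimals.

The paired t test (shelf-life stability) is two-sided on the differences;
identical samples give (t = 0, p = 1) and zero-variance nonzero differences
report the exact-limit p = 0 with a warning. Because the six-month
measurements exist only graphically in the source study, the paired test is
exercised on synthetic data only.

## Desk-scale mixing simulator

The original device model was a 3-D finite-element simulation; `pdmix`
solves the planar mid-depth footprint in 2-D at desk scale. All simulator
guarantees are therefore *property-based* (analytic oracles, conservation,
monotonicity, qualitative orderings), never field-by-field comparisons with
the 3-D solution.

**Geometry.** The channel is represented unrolled: width 300 µm, with 90
semicircular obstacles of radius 260 µm protruding from alternating walls
(narrowest gap 40 µm), pitch = one diameter, entrance/exit runs of 350 µm —
47.5 mm of path in total. Desk-scale runs truncate to the first 8 obstacles
(≈4.9 mm) on a 30-cells-across grid (10 µm cells, 4 cells across the
narrowest gap — the solver's minimum), which keeps a four-point FRR sweep
under ~10 s; obstacle count, pitch and resolution are user parameters.

**Flow.** MAC staggered-grid finite volumes. Default momentum balance is
creeping (Stokes) flow — the device operates at Re ≈ 10–20, and the tests'
linearity checks use this limit — with an optional Picard-linearized
first-order-upwind convection term (under-relaxed, residual-tracked, raising
a non-convergence signal with history if it stalls). Boundary conditions:
prescribed velocities on the two equal-width inlet arms (speeds
Q_arm/(arm area), organic stream on the bottom arm), no-slip walls and
obstacles, zero-gradient outlet with pressure datum 0. Momentum rows are
scaled by h²/µ and pressure by h/µ so the direct sparse factorization of
the saddle system conserves mass to ~1e−12 relative; the plane-Poiseuille
profile is reproduced within 0.2% at the default resolution.

**Transport.** Conservative finite-volume advection-diffusion of the
ethanol mass fraction: first-order upwind convection (monotone, so c stays
within the inlet bounds), central diffusion, Dirichlet inlet (c = 1 organic
arm, c = 0 aqueous), advective outlet, no-flux walls. The direct solve
balances species fluxes to machine precision. A Crank-Nicolson
time-integrator over the same diffusion operator backs the analytic
two-stream series validation. At coarse resolution the upwind scheme's
numerical diffusion exceeds the physical D (~1e−9 m²/s) wherever the flow
crosses the grid obliquely, so desk-scale mixing lengths are *qualitative*:
orderings and monotonicity are meaningful, absolute distances are not.

**Properties.** ρ(c), µ(c), D(c) are order-5 polynomial fits of a packaged
water–ethanol table at 25 °C (compiled approximate literature values —
density/viscosity from standard mixture tables, mutual diffusivity with its
characteristic minimum near w ≈ 0.4; the production hotplate ran at 70 °C,
but the packaged table governs and users may substitute their own).
Coupling is sequential, as in the original model: the flow uses properties
at the reference composition 1/(1+FRR) (the flow-averaged outlet fraction);
transport optionally Picard-iterates a composition-dependent D(c).

**Mixing efficiency.** Cross-sections are sampled at 50 uniform points (the
3-D model's 50×50 section grid degenerates to a line in 2-D; the parameter
is kept for interface compatibility). ME = (1 − σ²/σ₀²)·100% with the
Danckwerts segregated reference σ₀² = c̄(1−c̄) at the station's own mean.
Using the nominal organic fraction p = 1/(1+FRR) instead would make ME
negative near the inlet for FRR > 1, because the two arms merge at equal
*widths* (section variance 0.25) while p(1−p) < 0.25; the local-mean
normalization equals p(1−p) downstream of the merge and keeps
ME ∈ [0, 100] by construction. Ten stations span the channel by default.
`distance_to_threshold` interpolates linearly between bracketing stations
and returns a censored flag (not an error) when the threshold is never
reached. Transverse nonuniformity is summarized as the coefficient of
variation of the section samples.

## Synthetic data generator

Responses are drawn from the study's reduced surfaces — size from
236.3 − 26.95·FRR − 4.437·TFR + 1.573·FRR², PDI from
0.0663 + 0.03181·FRR + 0.00319·TFR − 0.001905·FRR² — plus i.i.d. Gaussian
replicate noise; zeta potential is factor-independent Gaussian. Defaults:
size SD 6 nm (mid-range of the 0.43–11.48 nm per-condition spread observed
in the study), PDI SD 0.02 and zeta −31.5 ± 4 mV (from the replicate spread
of the packaged table). PDI draws are clipped to (0, 1) with clip events
logged. The generator is homoscedastic and has no run-order drift, batch
effects, bubbles or DLS measurement structure — so passing recovery tests
demonstrates correctness of the estimation machinery under the stated noise
model, not robustness to real-world artefacts.

Problem sizes used by the test suite: 200 seeded replicates for the
coefficient-coverage study, 100 for the replicate-SD envelope, null-zeta
and term-elimination frequency checks, 500 for the paired-t type-I rate.

## Known limitations

* The simulator is 2-D: Dean vortices and any secondary flow in the depth
  direction are absent, so the original device's "90% mixing within tens to
  hundreds of milliseconds" sizing claim cannot be certified here.
* Obstacle spacing beyond radius/pitch/count is parameterized, not measured
  from the fabricated device.
* Quadratic surfaces cannot represent the size plateau at high FRR; the
  fitted optimum should be read as "≈41 nm near FRR 8.6", not as an exact
  asymptote.
* The stepwise endpoints depend on borderline p-values (TFR in the PDI
  model at p ≈ 0.06); with other data sets the 0.05-vs-0.10 distinction can
  change the retained terms.
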