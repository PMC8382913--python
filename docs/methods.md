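# Methods

## Models

### Exponential-growth two-strain model

Susceptibles S grow at per-capita rate g(A) − d under dose A and mutate to
resistants R at rate μ; R grows at ℓ g(λA) − d, i.e. each resistant feels
only a fraction λ ∈ (0,1) of the dose at a multiplicative growth cost
ℓ ∈ (0,1). From a clonal start (S=1, R=0) the solution is

    S(t) = e^(θ₁t),   R(t) = μ/(θ₁−θ₂) · (e^(θ₁t) − e^(θ₂t)),

θ₁ = g(A)−d−μ, θ₂ = ℓg(λA)−d. The susceptible frequency
ρ = S/(S+R) depends on d only through θ₁−θ₂, hence not at all — the dose
of fastest resistance enrichment is independent of the ancestral MIC. The
selection coefficient s(A) = θ₂−θ₁ has an interior maximum (the hotspot)
whenever ℓλ < 1; for g(A)=e^(−pA) it is A_hot = ln(1/(ℓλ))/(p(1−λ)).
Numerically, θ₁≈θ₂ (|θ₁−θ₂| < 1e−10·max(1,|θ₁|)) switches the solution to
the limit R = μt·e^(θ¹t), since the printed form is 0/0 there.

Two dose-response families are provided: exponential decline e^(−pA)
(closed-form hotspot) and the Hill form 1/((A/k)ⁿ+1) (hotspot by log-grid
scan plus bounded refinement to 1e−8; maxima at the origin or the bracket
edge are flagged rather than silently returned).

### Logistic competition model

dS/dt = S(1−A−(S+R)) − μS, dR/dt = R(1−(S+R)) + μS at unit carrying
capacity; integrated with adaptive RK (rtol 1e−8, atol 1e−9), negative
round-off clipped. Its total-density dose responses are monotone for short
treatments and non-monotone for longer ones, and the dose of fastest
density change climbs as the treatment lengthens — the qualitative
geometry the phenotypic statistics look for in data. The reference regime
used in tests and drivers is μ=1e−4, S0=0.01, R0=0, doses 0–1.5 (model
units), snapshots at 0/2/6/12/20 time units; it was chosen for the
qualitative geometry only, as no quantitative parameterisation of this
regime is available.

Two caveats discovered in implementation: the MPC exceeds the ancestral
MIC only for moderate cost/scaling (for exponential g the condition is
d < ℓ^(1/(1−λ)); the canonical ℓ=0.9, λ=0.5 regime satisfies it for any
d < 0.81), and the "zero dose adapts fastest when μ=0" statement holds for
time-difference windows anchored at t=0 — later windows peak at interior
doses purely through logistic saturation.

## Phenotypic statistics

**Growth fits and blanks.** Each well-season OD trace is fitted with
B₀+rt, B₀+ae^(rt) and B₀+K/(1+ae^(−rt)). The nonlinear fits use variable
projection — (B₀, a) and (B₀, K) are linear given the rate parameters and
are profiled out exactly — with logit-linearised starting values and a
small multi-start; this removes the ridge-shaped local minima a naive
4-parameter logistic fit falls into. Model choice is by Gaussian AICc,
k = model parameters + 1 (residual variance); when several models fit to
within numerical exactness (residual SD < 1e−6 of the data scale) the
fewest-parameter model wins, because AICc differences at machine-noise RSS
are meaningless. The winner's B₀ blank-corrects the trace; negative
corrected values are retained so downstream statistics see unbiased noise.

**Hill fit, MIC, EAD.** The 24-h dose response is fitted on replicate
means with B(A) = b_floor + (b_max−b_floor)/(1+(A/k)ⁿ); the floor defaults
to 0 (a detection-limit floor can be freed). The MIC is the IC99, solved
analytically from the Hill inverse, flagged "not attained" (NaN) when the
floor exceeds the 1% level. Its 95% CI comes from a nonparametric
bootstrap over replicate rows (default 1000 resamples, seeded); a
fit-covariance variant is available behind a flag. The EAD of density B*
is the Hill inverse of B*, zero when B* reaches the untreated density and
NaN below the floor. Round-tripping dose → density → EAD is exact to
well below 1e−9 on the informative range of the curve (roughly 0.2–5 k);
far outside it the curve saturates and the inverse is ill-conditioned.

**Rates of adaptation.** α = (Δr/2)/t_a with r(0), r(T) taken as 3-point
endpoint means (noise damping; window configurable) and t_a the first
linearly interpolated crossing of r(0)+Δr/2 in the direction of the net
change; Δr below tolerance gives α = 0 with t_a undefined. Under an affine
rescaling r → ar+b (a>0) t_a is invariant and α scales by a, with
sign(α) = sign(Δr). For serial-transfer data the phenotype series handed
to α is the *end-of-season density* (one value per 24-h season): the raw
saw-tooth trace would make α measure within-season growth, not
between-season adaptation. r_e is the maximal forward-difference
per-capita rate over 24 h evaluated on the fitted model (Δt = 20 min);
r_auc = B(24h)/∫B dt by trapezoid. Dose-increment changes use per-replicate
two-sided one-sample t-tests without multiplicity correction (raw P<0.05
convention; a BH flag exists downstream of the table).

**Inverted-U classification.** Replicate-mean ROA across dose is scanned
for interior local maxima with a prominence floor of the median replicate
SE (so noise does not mint peaks): one maximum is `inverted_u` (its dose is
the hotspot), none distinguishes `monotone_down`/`monotone_up`/`flat`, two
or more is `complex`. Per-dose significance against the lowest dose uses
two-sample t-tests.

**Periodogram.** Traces are resampled to a uniform grid, detrended by the
best-AICc growth fit (mean-only and raw variants available) and the rFFT
power spectrum returned with the leading interior peak wavelengths. On a
23.7-h window the 10-h instrument component leaks across the 12-h and 8-h
bins; analyses that need it therefore look among the top four peaks, and
recover the 0.75-h component best on replicate-mean traces (the
oscillation is coherent across wells, read noise is not).

## Genomic selection proxies

**Relative copies.** Feature depth (overlap-weighted) over a genome-wide
statistic (mean default; median and mode available), divided by the same
ratio in the ancestral sample. The whole-genome mean includes the
amplification itself: a 10%-of-genome feature at 3× true copies reports
2.5× under mean normalization and 3.0× under median — the configurability
exists precisely because of this bias.

**Amplification proxy.** F(t) = p₁(1+t)/(1+p₂(1+t)) is fitted with
p₁,p₂ ≥ 0 (excluding the pole) by bounded least squares with moment-based
multi-starts; t=0 at the first sequenced sample (24 h), so day-1/3/5
samples map to t = 0, 2, 4. The selection proxy is the maximal analytic
derivative p₁/(1+p₂(1+t))² over the observed span — for p₂>0 that is the
earliest time point. A flat track drives p₁≈p₂→large with proxy → 0; the
bound 1e7 keeps that limit finite. The quadratic dose regression reports
E_max = −b/2a clamped to the dose range when concave, else the boundary
argmax; the "3 SD" screen keeps genes whose predicted maximal proxy
exceeds 3× the quadratic's residual SD (the reference population for the
SD is not fixed by convention; residual SD is the implemented reading,
behind a flag).

**SNP selection and parallelism.** f(t) = 1/(1+pe^(−st)) by bounded least
squares (p>0, s free; log-odds-slope start); trajectories whose frequency
never reaches 5% are filtered before fitting. The parallelism coefficient
uses λ* = mean(f) (the closed-form projection onto the uniform ray — the
positivity constraint cannot bind for frequencies), P(g) = ‖f−λ*·1‖₂,
p(g) = P(g)/P*, flag at p(g) > 0.7. As defined, a *large* coefficient
marks across-dose variability (distance from uniformity) even though it is
used to flag "parallelism"; the definition is preserved as printed rather
than inverted.

## Synthetic data generator

Emulates the treatment assay with known truth. Within a season, densities
of copy-number classes c = 1,2,3 follow the competition model with the
felt dose attenuated by `copy_protection` = (1, 0.7, 0.49) — each extra
operon copy shields 30% of the dose — and a mutational chain at
`mu_per_h` = 2e−4 between adjacent classes; growth rate 0.7/h, dose scale
`mic_ug_ml` = 32 (model dose A = dose/32), inoculum 0.01, 1:100 transfer
between seasons. These values were fixed once so that the noise-free truth
reproduces the qualitative study geometry — no adaptation drug-free,
fastest adaptation just below the growth-zero dose, collapse above it —
with the hotspot at 30 µg/ml; they are design constants, not fitted
quantities. OD adds a well blank (0.07 ± 0.005), 5% multiplicative read
noise and two coherent instrument oscillations (10 h, 0.75 h, amplitude
0.005 OD). GFP reports Σ N_c · per_copy · c · repression^(c−1) with
repression √(2/3) ≈ 0.8165, so a tripled operon expresses ~2× per cell
(the calibration point for amplified-operon repression). Replicates share
the deterministic dynamics and differ only in blank and read noise.
Coverage tracks draw per-window negative-binomial depths with mean
depth × true copies; SNP tables draw Binomial(depth, f(t)) frequencies.
All outputs are byte-identical given the seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: biological replicate-to-replicate variability
(only measurement noise differs between replicates), lag phases and
diauxie, stochastic mutant appearance (the mutational chain is
deterministic), within-season copy-number loss, and a sigmoid 24-h
dose-response. The last matters quantitatively: the competition model's
growth term is linear in dose, so the emulated 24-h dose-response declines
quasi-linearly with a cliff near the growth-zero dose rather than
sigmoidally. A Hill function fitted to that shape underestimates the
exponent and the IC99 extrapolates high (≈55–65 µg/ml against a true
1%-density dose of ≈33 µg/ml on the default design). The estimator is the
standard one and behaves correctly on Hill-shaped data (parameter recovery
to <0.1% noiseless; bootstrap CI coverage ≈ nominal); the bias is a
property of the emulated dose-response shape and is reported, not
corrected.

## Problem sizes

Tests and the acceptance script run the full treatment design (11 doses ×
8 replicates × 7 seasons) for the inverted-U study (20 seeded runs), 500
loci at depth 1000 for SNP-recovery, 200 runs for hotspot recovery, and a
reduced design (2 replicates, 4 seasons) for the orchestration test; these
sizes give stable rates while keeping a desk-scale footprint.

## Known limitations

- The α statistic applied to raw (non-seasonal) saw-tooth traces is
  meaningless; callers must pass a per-season series
  (`season_endpoint_series` does this).
- IC99/MIC estimates inherit Hill-shape mismatch bias (above); compare
  the bootstrap CI, not the point estimate, across designs.
- `gene_dose_hotspot` assumes a single smooth dose optimum; genuinely
  bimodal ("M") profiles are classified but their E_max is the global
  quadratic argmax only.
- VCF ingestion reads AF or first-sample AD fields only; multi-allelic
  records use the first alternate allele.
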