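# Methods

`dwires` simulates a complete in-silico study of whether diffusion-weighted
MRI (DW-MRI) microstructure estimates are precise enough to distinguish two
ways a tumour can respond to treatment: apoptotic cell shrinkage (cells lose
volume, cell count constant) and cell loss (cells disappear, size constant).
Both raise the apparent diffusion coefficient (ADC), so telling them apart
requires estimating cell radius `R` and intracellular volume fraction `f_i`
directly — and the question is how much SNR that takes.

## Signal model

The normalized pulsed-gradient spin-echo (PGSE) signal of a voxel is

    S/S0 = exp(-TE/T2) [ f_i S_i(R, D_i; G, Δ, δ) + (1 - f_i) S_e(f_i, D_e; b) ]

* `S_i` — restricted diffusion inside impermeable spheres of radius `R`,
  evaluated with the Gaussian-phase-distribution (Murday–Cotts) series.  The
  eigenvalues `α_m = x_m / R` come from the roots of `j1'(x) = 0`
  (x₁ ≈ 2.0816), found by bracketed root finding between multiples of π.
* `S_e = exp(-b · D_e,tort)` — hindered extracellular diffusion.  The
  tortuosity rule is pluggable; the default is the classical hindrance
  around impermeable spheres, `D_e,tort = D_e / (1 + f_i/2)`, with
  `D_e (1 - f_i)` and `D_e sqrt(1 - f_i)` selectable.  The choice is
  explicit because published two-compartment models differ here.
* A single `T2` (default 125 ms, a representative tumour value) is shared by
  both compartments; there is no water exchange.

Internal units are µm, ms, mT/m with γ = 2.675×10⁻⁴ rad ms⁻¹ µm⁻¹ (mT/m)⁻¹;
b-values are reported in s/mm² (exact factor 1000 from ms/µm²).  This keeps
every factor in the GPD series within a comfortable floating-point range.

**Series truncation.** 20 eigen-roots by default.  Over the whole fitting
range (R ≤ 25 µm) at clinical gradient strengths the n→2n change in ln S_i
is below 10⁻⁵ — orders of magnitude below the noise floor (σ ≈ 10⁻²).
Truly unconverged regimes (e.g. the free-diffusion check at R = 200 µm,
which needs ~150 roots) are detected by a last-term-ratio diagnostic
(threshold 10⁻⁴) and refused rather than silently summed; the threshold
separates the fitting-range worst case (2.7×10⁻⁵) from the unconverged
cases (≥1.3×10⁻⁴) by half a decade on either side.

**Echo times.** Each measurement uses the minimum feasible echo time
TE = Δ + δ + T_c (T_c = 13 ms readout/pre-gradient time), capped at 100 ms.
The non-optimized comparison protocols were matched to the optimized ones
only on gradient strength and maximum b-value; their long-Δ measurements
have Δ + δ + T_c slightly above 100 ms and are pinned at the 100 ms
ceiling.  Timing comparisons throughout carry a 0.1 ms slack so protocol
tables printed to three significant figures validate.

## Noise and fitting

SNR is defined on the b = 0 signal at TE = 100 ms, so the Gaussian channel
noise is σ = exp(-100/T2)/SNR for unit proton density.  Magnitudes are
Rician: `sqrt((S + n₁)² + n₂²)`.  Each diffusion-weighted magnitude is
normalized by an independently noisy G = 0 magnitude at the same TE, as is
done experimentally.

The normalized measurement is modelled as Rician with location equal to the
normalized model prediction and scale σ_eff = σ / exp(-TE/T2).  Treating
the normalizing b0 as noise-free is an approximation: the b0 is the
highest-SNR measurement in the acquisition, and the induced relative bias
of the ratio is ≈ (σ/S0)², below 10⁻³ at the SNRs simulated.  Whether the
original analysis fitted ratios or joint raw magnitudes is not documented;
the ratio reading is implemented because it matches what the normalization
step produces.

Fitting maximizes the summed Rician log-likelihood (exponentially-scaled
Bessel `i0e`, so large arguments cannot overflow) with a multistart
Nelder–Mead simplex search: starts drawn uniformly within the bounds
R ∈ [0.1, 25] µm, f_i ∈ [0.01, 1], D_i, D_e ∈ [0.1, 3] µm²/ms; bounds
enforced by a logistic transform to unconstrained space; tolerances 10⁻⁶,
at most 10³ iterations per start; ties between restarts broken by the first
lowest objective.  With diffusivities fixed to ground truth (the
configuration used for all headline numbers) the search has 2 free
parameters, otherwise 4.

Because millions of fits are needed, all restarts of all noise repeats are
advanced in lock-step through a batched implementation of the same simplex
algorithm (`dwires._optim`), verified against `scipy.optimize.minimize`
per-problem.  The per-protocol part of the GPD series is precomputed so one
batched model evaluation is a single `exp` plus a matrix product.

**Exclusions.** A fit is "extreme" when any free parameter lies within 1%
of its constraint range of a bound (`p < lo + 0.01(hi-lo)` or the mirror).
Extreme fits are excluded from summaries; a condition where more than half
the fits are extreme is marked invalid.  Accuracy is the mean estimate
minus truth; precision is the sample standard deviation (n−1) of the
estimates, i.e. the parameter's standard error SE_p.

## Protocol design

The information a 4-measurement protocol carries is summarized by the
Fisher matrix under additive Gaussian noise with constant σ,
`M = σ⁻² Σ_k ∇θS ∇θSᵀ` over θ = (R, f_i, D_i, D_e), with gradients by
central differences (relative step 10⁻³, floor 10⁻⁴).  The Gaussian FIM is
standard in this design literature and makes |M| scale exactly as σ⁻⁸.
Robust D-optimum designs minimize `f = Σᵢ −log|Mᵢ|` over N = 100 tissues
drawn uniformly from R ∈ [5, 20] µm, f_i ∈ [0.1, 0.74],
D_i, D_e ∈ [0.5, 3] µm²/ms.

Feasibility: G ≤ G_max, b ∈ [150, 5000] s/mm², Δ − δ ≥ 12 ms,
Δ + δ ≤ TE − 13 ms, TE ≤ 100 ms, and predicted signal ≥ 2σ for the
prior-median tissue.  The SNR assumed for that floor is not pinned down by
the constraint statement itself; the default here is 20 (the lowest SNR
simulated), configurable.

The search is a real-coded genetic algorithm.  The genome is
4 × (G, t_sep, frac) where t_sep = Δ − δ and frac sets δ as a fraction of
the room left under the echo-time ceiling — a reparametrization under which
every decoded protocol satisfies all timing constraints by construction,
leaving only the b-range and SNR floor as graded penalties.  Operators:
tournament selection (size 2), blend crossover (rate 0.8), Gaussian
mutation annealed from 5% to 0.5% of each gene's range, single-individual
elitism, three independent repeats with the best kept, and a final
Nelder–Mead polish of each repeat's elite (the GA locates the basin, the
polish descends to its floor).  Desk-scale defaults are population 200 and
60 generations; at that scale the search typically lands within ~0.2 nats
per prior draw of the published optimized design's objective, versus
several nats for random feasible protocols.  The bundled published designs
ship as named fixtures (`D-opt_300/80/60`, `Non-opt_300/80/60`) and are
used for all simulation experiments, so the stochastic search never gates
reproducibility.

## Change scenarios

With v the fraction of cell volume lost (default 0.60, the largest volume
change reported for cisplatin-treated cells in vitro — a best case):

* shrinkage: R' = (1−v)^{1/3} R, f_i' = (1−v) f_i; density
  ρ = 3 f_i/(4πR³) conserved.
* cell loss: f_i' = (1−v) f_i, R unchanged; ρ scales by (1−v).
* asynchronous: a fraction p of cells keep their size, the rest shrink;
  cell counts are conserved within each subpopulation, giving
  f_same = p f_i, f_shrunk = (1−p)(1−v) f_i and a bimodal radius
  distribution.  The volume-fraction bookkeeping is isolated in this one
  operation; it is the natural reading of "a fraction of cells shrink" but
  other conventions (e.g. volume-weighted mixing) exist.

Sweep defaults: v ∈ {0.60, 0.40, 0.20}; p ∈ {0, 0.25, 0.50, 0.75}.

## Resolution limit

A change Δp = |p₂ − p₁| is detectable by a two-sample z-test at α = 0.05
when `sqrt(SE_p1² + SE_p2²) ≤ Δp / 1.96`.  The left side is simulated at
SNR ∈ {20, 50, 80, 110}, with baseline and changed states fitted
independently (their precisions genuinely differ, so no equal-precision
shortcut).  A curve m/SNR + c is least-squares fitted to the limits, the
SNR-20 point always excluded (its SE estimates are unstable when many fits
pin at the constraints), and the fit anchored by a pseudo-point
(SNR = 10⁶, limit 0) with unit weight expressing SE → 0 as SNR → ∞; the
anchor's position/weight are config-exposed since only its intent is
standard.  r² is computed on the real points only.  The required SNR is
the crossing m/(threshold − c); a cell-loss scenario has no R threshold
(nothing to detect) and reports NaN, and threshold ≤ c reports +inf
("undetectable under this extrapolation").

## Simulation scales and what they show

Two presets: `paper` (1500 noise repeats, 100 starts) and `desk` (300
repeats, 20 starts).  The headline change-detection analyses and the
acceptance script run at 1500 repeats × 20 starts: the sampling error of a
standard deviation is ≈ 1/sqrt(2n), and the r² of the 1/SNR fit only
stabilizes above 0.997 when that error is under ~2%, which needs n ≳ 1000;
20 starts suffice for the 2-parameter fixed-diffusivity fits (multistart
scatter is far below noise scatter).  Qualitative trend checks (precision
orderings across f_i, volume-decrease sweeps) use 120–150 repeats and 8
starts, enough to order conditions that differ by factors of ~2.

The generator emulates per-voxel magnitude signals under the same model
that is fitted.  It does not emulate model mismatch (cell size
distributions except the explicit bimodal case, nuclei, vasculature,
exchange, compartmental T2 differences), spatial structure, or scanner
artifacts — so passing tests demonstrate estimator behaviour under the
model's own assumptions (a best case), not performance on real tumour
data.  Fixing D_i and D_e at truth is likewise a best case; free-diffusivity
fitting is implemented and exposed but not used for the headline numbers.

## Numerical notes

* Rician log-density uses `log(i0e(z)) + z`; a naive `I0` overflows near
  z ~ 700 while typical arguments here reach 10⁴.
* Exponential arguments in the batched GPD evaluation are clamped at −60
  (terms below e⁻⁶⁰ are irrelevant) — this also keeps `exp` off the slow
  subnormal path that extreme trial radii would otherwise trigger.
* Sample SD uses the n−1 denominator throughout.
* All randomness flows from one root seed through `numpy.random.SeedSequence`
  spawning: one child stream per simulated condition, so any subset of an
  experiment reproduces independently of execution order or parallelism.

## Known limitations

* The GA is a stochastic search in a 12-dimensional multimodal landscape;
  desk-scale runs approach but do not exactly reproduce published designs
  (which used a population of 1600, three restarts and far more compute).
  Designs are therefore treated as fixtures for simulation, and the GA as a
  tool for exploring constraint sets.
* The resolution-limit z-test assumes Gaussian parameter estimates, which
  degrades at low SNR — the reason the SNR-20 point is excluded from the
  1/SNR fits.
* The normalized-ratio Rician approximation slightly misstates the
  likelihood at very low SNR (ratio distributions have heavier tails);
  at SNR ≥ 20 the effect on accuracy/precision summaries is below the
  Monte-Carlo noise at the scales used here.
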