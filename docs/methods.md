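# Methods

`rancistab` analyses accelerated-oxidation (Rancimat-type) experiments on
high-fat solid foods such as walnut kernels. This note documents the
models, the algorithmic choices where the instrument literature leaves the
procedure open, and what the synthetic-data generator does and does not
emulate.

## 1. Induction-time detection (`rancistab.induction`)

A Rancimat run bubbles heated air through the sample and traps volatile
organic acids in a water cell whose conductivity is logged over time. The
oxidative stability index (OSI, hours) is the time at which the fitted
baseline line intersects the tangent at the point of steepest conductivity
rise.

The tangent detector works on a trace `(t_i, c_i)` as follows.

1. **Smoothing and derivatives.** Quadratic Savitzky–Golay filtering
   (default window 11 samples) provides the smoothed curve and its first
   two least-squares derivatives. The LS derivative — rather than finite
   differences of the smoothed values — is used because it cannot
   overshoot the true slope at a kink. Uniform sampling is assumed; the
   median time step is used and a `nonuniform_sampling` quality flag is
   set when steps deviate by more than 0.1%.
2. **Rise onset.** The onset is the first sample from which the smoothed
   derivative stays above `max(5% of its maximum, median + 3·1.4826·MAD
   of the early-trace derivative)` for longer than the smoothing window
   (Savitzky–Golay derivative noise is correlated over one window, so a
   shorter run could be a single noise excursion).
3. **Baseline.** Ordinary least squares on the initial `baseline_fraction`
   (default 0.25) of the **pre-onset** samples, extended forward point by
   point while the residual standard error stays below twice its initial
   value, never past the onset. Restricting the window to pre-onset data
   matters for short induction times, where the sigmoid's exponential tail
   otherwise leaks into the baseline and biases the intersection by up to
   ~1%.
4. **Tangent.** Taken at the earliest point of maximal first derivative
   (conservative tie-break: shorter OSI). The slope is Richardson-corrected
   using a second Savitzky–Golay pass with a doubled window: attenuation of
   a smooth derivative peak scales with the squared window span, so
   `s = s_w + (s_w − s_2w)·span_w²/(span_2w² − span_w²)` removes the
   leading error term. On locally linear data the two estimates coincide
   and the correction vanishes exactly.
5. **Intersection.** OSI solves `b₀ + b₁t = c* + m(t − t*)`. A rise is
   only accepted when the maximal derivative exceeds
   `(1 + rise_factor)` × |baseline slope| (default `rise_factor` 5, i.e. a
   6× margin, absolute floor 1e−6 µS·cm⁻¹·h⁻¹); otherwise
   `NoInductionDetected` is raised, which distinguishes drift from
   induction on flat or drifting traces.

A second-derivative detector (OSI at the maximal curvature, the onset knee
of the rise) is exposed as a cross-check. On sigmoid traces the knee sits
before the steepest point but after the tangent intersection, so it reads
slightly later than the tangent method; on the reference logistic the two
agree within ~3%.

Accuracy on the stated synthetic world: noise-free logistic traces are
detected within 0.3% of the analytic intersection for induction times
2.3–15 h at sampling intervals up to 0.1 h; at 1% (of rise amplitude)
i.i.d. noise the median error at OSI = 10 h is ≈ 0.3%. Known limitation:
for very short induction times (≲ 3 h) combined with ≥ 1% noise, the
onset guard must sit above the derivative noise floor and some tail
contamination returns, giving a positive bias of a few percent.

## 2. Temperature kinetics (`rancistab.kinetics`)

Over 110–130 °C the induction time follows the log-linear law

    log10 OSI(T) = A·T + B,

fitted by OLS to the per-cell mean OSI (cell = temperature × airflow;
means rather than replicates match the conventional three-point reporting;
replicate-level fitting is available by passing replicate points
directly). Derived quantities:

- **Temperature coefficient** `t_coeff = 100·A` (slope in 10⁻² units).
- **Extrapolated shelf life** `osi_22 = 10^(22A + B)`: the stability a
  sample would show at a 22 °C shelf. This is an extrapolation over ~90 °C
  and inherits any mechanistic change between accelerated and ambient
  oxidation; it is a comparative index, not a guaranteed shelf life.
- **Q10** — the factor by which stability drops per 10 °C — is the
  arithmetic mean of successive ratios `OSI(T)/OSI(T+10)`. The slope form
  `10^(−10A)` coincides with it exactly on noise-free model data and is
  exposed separately (`q10_from_slope`) as a diagnostic; on real cell
  means the two differ in the second decimal.
- **CV** is the conventional percent coefficient of variation,
  `100 × sample SD / mean` (ddof = 1). Single-replicate cells report a
  missing CV, never zero.

## 3. Panel statistics (`rancistab.panel_stats`)

- **Pearson correlation** with the two-sided p-value from
  `t = r√((n−2)/(1−r²))` on n−2 degrees of freedom. Missing values are
  dropped pairwise and the effective n is reported per cell. Two-tier
  marks: `**` for p < 0.001, `*` for 0.001 ≤ p < 0.05. No multiple-testing
  correction is applied across the marker panel (matching field practice
  for these correlation tables).
- **Treatment comparison**: one-way ANOVA over the temperature × airflow
  cells followed by Tukey's HSD (Tukey–Kramer for unequal n, via
  statsmodels), summarised as a compact letter display built by the
  insert-and-absorb algorithm over cells sorted by descending mean, so
  `a` always tags the highest mean. If every cell has zero within-cell
  variance the HSD statistic is undefined and cells are grouped by exact
  mean equality.

## 4. Synthetic data (`rancistab.synthetic`)

The generator emulates the statistical structure the analysis assumes,
with ground truth retained; one integer seed drives everything through
`SeedSequence` spawning (identical seed + config ⇒ byte-identical data).

- **Traces**: logistic rise (default amplitude 100 µS/cm, steepness
  2 h⁻¹) over a drifting baseline (2 µS/cm + 0.02 µS·cm⁻¹·h⁻¹) plus
  Gaussian noise (default 0.1 µS/cm), sampled at 0.05 h. The logistic
  centre is placed at `osi + 2/k`, which makes the analytic
  baseline/tangent intersection equal the requested induction time
  exactly (the drift term cancels from the intersection algebra).
- **OSI grid**: `osi(T) = 10^(A·T+B)` × per-airflow multiplier (default 1;
  airflow effects on kernel OSI are typically insignificant) × unit-mean
  lognormal replicate noise with σ chosen so the theoretical CV equals
  `replicate_cv` (default 7%, inside the observed 4–11% range). Default
  design: 3 temperatures × 3 airflows × 8 replicates (one per instrument
  position), A = −0.037, B = 5.181.
- **Storage OSI**: kernel OSI of each lot decays by a factor 0.85 per
  month of ambient storage (chosen to reproduce the observed ~2.5× drop
  over six months), sampled at 0, 4 and 6 months, 8 lots per time.
- **Markers**: each marker is `base + slope·months + λ·z + σ·ε` with `z`
  the standardized kernel OSI. λ is solved in closed form so the
  *population* correlation with OSI equals the marker's target — including
  compensation of the covariance the storage trend itself shares with the
  decaying OSI (`λ = −u + ρ√((v+σ²−u²)/(1−ρ²))`, `u = cov(trend, z)`,
  `v = var(trend)`). Defaults: PV/hexanal/rancidity −0.8, K268 −0.7,
  K232 −0.6, fat −0.5, oil OSI +0.8, moisture 0 (uncorrelated). Values are
  clipped to physical ranges (moisture/fat 0–100%, rancidity 0–10,
  concentrations ≥ 0).

What the generator does **not** emulate: chemically mechanistic oxidation
kinetics, cultivar-specific fatty-acid effects, the non-monotone structure
of real replicate CVs across cells, instrument artefacts (spikes, ramp-in
transients), or correlated noise. Clipping truncates the Gaussian
residual; with the default marker levels this affects ≲ 2% of PV samples
and shifts correlations by well under the sampling noise, but a
configuration demanding strong correlations against a weakly structured
OSI series can clip heavily and attenuate the realized r. A green
closed-loop test therefore establishes that the *pipeline* is unbiased on
idealized sigmoid data — not that the instrument's own determination is.

## 5. Numerical conventions

- Hours and µS/cm fixed at the I/O boundary; logarithms base 10
  throughout (natural-log intercepts would be ~12, not ~5).
- Q10 requires an exact 10 °C chain; fits require ≥ 3 distinct
  temperatures; correlations ≥ 3 complete pairs and non-constant series.
- Reports round to field precision (OSI 1 dp, slopes 3 dp, r 3 dp); JSON
  keeps full precision. Decimal point always `.`, UTF-8 everywhere.
- The UV absorbance column is named `k268` (the 268 nm reading reported in
  the study data; some protocol texts name the neighbouring 270 nm band).
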