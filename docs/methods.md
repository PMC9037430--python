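# Methods

## The measurement and the quantity of interest

A real-time luminescence viability assay couples a NanoLuc luciferase to a
cell-permeable pro-substrate that only metabolically active cells convert to
the active form. Read repeatedly from the same wells, the signal (RLU,
relative luminescence units) is proportional to the number of live cells,
modulated by how much assay reagent remains. The analysis target is the
drug-induced change in the population's growth rate: for each (cell line,
drug, concentration) condition a single *rate* is extracted from the RLU
time course, divided by the *basal rate* of the matched undrugged control,
and the resulting normalized responses across a concentration series are
summarized by a four-parameter log-logistic (4PL) dose–response curve.
Because the normalized rate can be negative (the signal falls when cells
die), the method distinguishes cytotoxic from merely growth-slowing drugs —
something fixed-endpoint viability ratios cannot do.

## Rate extraction by trailing-slice R² maximization

Let `t_end` be the time of the control condition's peak luminescence; this
defines the usable end of the assay (beyond it, reagent depletion rather
than biology dominates every trace). For a window ending at `t_end`, every
contiguous *trailing* slice — the last L sampled points of the window, for
each L from `min_points` (default 5) up to the whole window — is fitted by
ordinary least squares, and the slope of the slice with the highest R² is
the condition's rate:

- **Controls** are windowed from their first timepoint to `t_end`.
- **Drugged wells** are windowed from their own luminescence peak to
  `t_end`, so that a post-peak decline (cell death) is what gets fitted.
  Peak ties resolve to the earliest time for the same reason.
- **Tie-breaking:** R² values within 1e-9 of the maximum are treated as
  numerically tied and the longest slice wins. Nested sub-slices of an
  exactly linear stretch differ only by rounding, and the longest of them is
  the statistically stable choice.
- **Degenerate flat slices:** a constant-y slice is an exact flat-line fit;
  its R² is defined as 1 (the Pearson correlation is undefined there, but
  the residuals vanish identically).
- **Short-window fallback:** when a drugged well's peak sits within
  `min_points` samples of `t_end` (weak or no drug effect — the trace is
  still rising at the end of the assay), the between-peaks window cannot
  support a fit. The well is then analyzed exactly like a control (full
  window from the first timepoint, R²-maximized) and flagged
  `short_window_fallback`. This choice is load-bearing: it guarantees that
  a drug with no effect reproduces the control computation and therefore
  normalizes to exactly 1. The obvious alternative — fitting only the last
  `min_points` samples — measures the flattening shoulder of the trace near
  its peak, systematically underestimates weak-effect rates, and breaks the
  monotonicity of the extracted dose–response; we verified this directly on
  noise-free simulations before settling on the full-window fallback.
- Replicates are averaged pointwise per condition before slicing (they must
  share a time grid); per-replicate extraction with post-hoc rate averaging
  is available by flag.
- A negative basal rate is flagged (`negative_control_rate`) but
  normalization proceeds; hiding the anomaly behind an error would silently
  drop whole cell lines from a screen.

Direct-count rates use the classic proliferation-rate estimator instead:
the OLS slope of log2(counts) versus time (doublings/h) over the full
series, and the same trailing-slice machinery applied to log2 counts inside
the pipeline's count channel.

**Linearity QC.** The assay is only quantitative while the undrugged signal
is approximately linear in time; `linearity_check` gates a series on
full-window R² strictly greater than 0.90. The strict inequality matters at
the boundary and is tested there.

## Dose–response model

Normalized rates y against molar concentration c are fitted to

    y(c) = Emax + (E0 − Emax) / (1 + (c / EC50)^h)

by bounded least squares on the log10-concentration axis. Choices:

- **E0 is free**, initialized at 1. The normalization should pin the
  zero-dose response at 1, but the lowest tested doses carry noise and the
  fourth parameter absorbs it; a fixed E0 = 1 would push that error into
  EC50 and Hill. A useful side effect: any distortion of the response scale
  that is *affine* in the underlying rate is absorbed entirely by E0 and
  Emax, leaving EC50 and Hill untouched.
- **Bounds:** Emax ∈ [−5, 1.5], h ∈ (0, 15], EC50 ∈ [1e−12, 1e3] M, E0 ∈
  [−5, 1.5], all configurable. Screens routinely contain curves with no
  information below the lowest dose; the box keeps those fits finite, and
  estimates landing on a bound are reported in `bounds_hit` rather than
  hidden. Published parameter tables for this assay family show exactly this
  signature (maximal responses pinned at −5.000, Hill values near 15,
  EC50s in the hundreds of molar), so the defaults mirror that envelope.
- **Multi-start:** steep-Hill sigmoids produce local minima; starts span
  h ∈ {0.5, 1, 3, 8} × EC50 seeds at the quartiles of the tested
  concentrations, best residual sum of squares wins. `residuals` is that
  sum of squared errors; `converged=False` marks the (rare) case where no
  start converges, with the best attempt still reported.
- ≥ 4 points over ≥ 3 distinct concentrations are required.

**Effect classes.** The maximal response classifies mechanism. The
four-class rule (tolerances default 0.1, configurable): |Emax − 1| ≤ tol →
no effect; |Emax| ≤ tol → cytostatic; Emax < −tol → cytotoxic; otherwise
anti-proliferative. For *cross-channel concordance* a coarser sign-based
grouping is the default: negative → cytotoxic, ≈1 → no effect, otherwise →
anti-proliferative/cytostatic. Near-zero maximal responses sit on the
boundary between cytostatic and the neighboring classes, and two channels
measuring the same wells can legitimately disagree by tolerance there; the
sign is the robust, mechanism-bearing feature, and it is the grouping under
which the bundled reference panel shows its published 11-of-12 agreement.

## Exact Wilcoxon signed-rank comparison

EC50s from the two channels are compared on the natural-log scale, paired
per (cell line, drug). Differences of zero are dropped (Wilcoxon's original
treatment), tied absolute differences receive midranks, and the reported
statistic is W = min(W⁺, W⁻), read against a lower-tail critical value.

The null distribution is computed exactly for n ≤ 25: ranks are doubled so
midranks become integers, and the distribution of the positive rank sum
over all 2^n sign assignments is built by convolution (adding one rank at a
time). This is algebraically identical to literal enumeration — the test
suite proves equivalence against an `itertools` enumeration oracle for all
n ≤ 12 — but costs O(n · Σr) instead of O(2^n). The two-sided p-value is
2 · min(P(W⁺ ≤ w⁺), P(W⁺ ≥ w⁺)) capped at 1, matching the exact-mode
convention of standard statistical software. Beyond n = 25 a normal
approximation with continuity correction and tie-corrected variance
(Var W⁺ = Σ rᵢ²/4) is used and labeled as such in the result.

`critical_value(n, alpha)` returns the largest c with 2 · P(W⁺ ≤ c) ≤ alpha
under the tie-free null, the classical two-tailed table value; alpha = 0
yields the sentinel −1 ("never reject"). Pairs whose EC50 sits on a fit
bound are retained by default — the published panel itself includes
bound-clipped entries — and flaggable for exclusion.

## The plate simulator

Each simulated well holds a population growing (or shrinking)
exponentially at a rate that is a 4PL function of dose:

    k(c) = k₀ · [Emax + (E0 − Emax) / (1 + (c/EC50)^h)],  k₀ = ln 2 / T_d

Luminescence is signal-per-cell × live cells × remaining reagent, with
reagent consumed by second-order kinetics (rate ∝ cells × reagent), which
integrates in closed form — N(t) = n₀e^{kt}, R(t) = exp(−γn₀(e^{kt}−1)/k),
L(t) = a·N(t)·R(t) — and yields the characteristic rise–peak–decline trace
with an analytic peak at t* = ln(k/(γn₀))/k whenever k > γn₀ > 0. The
closed form doubles as the test oracle for peak detection. Measurement
noise is multiplicative Gaussian truncated at zero (reader error scales
with signal); the count channel images a fraction of the well, modeled as
binomial thinning rescaled back to well units. Every draw comes from one
seeded generator: identical seeds give bit-identical plates.

**Default regime and why.** 300 cells seeded per well, reads every 4 h for
100 h (26 timepoints; a 12 h preset mirrors sparser protocols), triplicate
wells, an 8-point half-log dose series around 10 nM, cv = 0.05, imaged
fraction 0.2. Doubling time 36 h (typical of slower SCLC lines) and
γ = 1.18e-5 per cell per hour place the undrugged peak near 88 h, inside
the assay, with the pre-peak control trace passing the linearity gate
(R² ≈ 0.99). This calibration is deliberate: the trailing-slice/basal-ratio
analysis is quantitatively faithful only in the quasi-linear signal regime
that the assay's own protocol prescribes (seeding density is chosen in
practice precisely so the undrugged signal stays linear), so the simulator
defaults sit where the assay is validated, and the default programmed drug
(Emax = −0.5, EC50 = 1e-8 M, h = 3) matches the parameter ranges typical of
the published panel.

**What the simulator does and does not establish.** Under the defaults the
full pipeline recovers the programmed EC50 with median |log10 error| < 0.15
across 100 noisy plates and classifies the programmed effect sign
correctly in ≥ 95 of them (both under test). Outside that regime —
fast-growing lines, strong depletion, signal far from linear — the raw-RLU
slope ratio is a *biased* estimate of the growth-rate ratio: slopes taken
late in an exponential rise over- or under-weight conditions by e^{(k−k₀)t̄}
(t̄ the slice's mean time), compressing cytotoxic tails toward zero and
shifting apparent EC50s low. The bias is a property of the raw-slope method
itself, not of the simulator, and it is the reason for both the linearity
gate and the free-E0 4PL. Passing tests on simulated plates therefore
demonstrates correctness of the pipeline in the validated regime, not
unbiasedness of raw-slope normalization in general; real data additionally
contain temperature artifacts, edge effects, and heteroscedastic counting
error that the generator does not model.

## Numerical choices, edge cases

- CSV round-trips are exact: floats are serialized by shortest
  round-trip `repr` and parsed with round-trip precision.
- Times are hours and concentrations molar everywhere inside the data
  model; reader schemas carry unit multipliers.
- Vehicle controls are wells with concentration 0; drug labels in a
  configurable alias list (control/vehicle/DMSO/PBS) are coerced to 0.
- `min_points` = 5 by default ("more than four points"); configurable.
- A basal rate of exactly 0 makes normalization undefined and raises.
- Zero or negative counts cannot be log-transformed; the error names the
  offending timepoint.
- `wilcoxon_exact` refuses all-zero difference sets (the test is undefined).

## Known limitations

- Only trailing (end-anchored) slices are searched; interior changepoints
  are out of scope by design.
- No confidence intervals on 4PL parameters and no model selection beyond
  the single 4PL family.
- The depletion model is the simplest mechanism producing rise–peak–decline
  in closed form; it does not model drug-accelerated signal loss from dying
  cells, temperature transients, or evaporation.
- The exact-Wilcoxon path assumes exchangeable signed ranks; with heavy
  midrank ties the doubled-rank enumeration remains exact, but the critical
  value table is defined for the tie-free null only.
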