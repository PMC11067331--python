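# Methods

This note documents the statistical procedure the package implements, the
choices made where the method as practiced leaves room, and what the
synthetic validation does and does not establish.

## The indirect route, step by step

**Input.** Long-format measurement tables (CSV), one row per
subject × nerve × measure, with age/height/sex metadata and a cohort flag.
Rows with non-parseable, negative or non-finite values are dropped and
counted in a load report; no other data cleaning is performed by default —
the method is designed to be robust to outlying values, which land in the
curve's tails and are excluded by the plateau anyway. Known healthy
controls present in historical data should be removed via
`exclude_subjects` to avoid circularity when comparing against
control-derived limits.

**Stratification.** Age strata are inclusive integer-year intervals;
a row is assigned by `floor(age)`. The default strata are 9–18, 20–44 and
45–60 years, which leaves deliberate gaps (age 19, over-60); rows falling
in a gap are dropped with a logged count. Only groups with **n > 100**
(strict) are analyzed — below that the S-curve is too poorly resolved for
plateau identification. Height and sex are *not* adjusted for; that is the
main known limitation (see below).

**Curve.** Values are sorted ascending (stable sort; ties produce zero
differences, no jitter is added) and ranked 1..n. First-order differences
`d_i = x_(i+1) − x_(i)` visualize local density: small differences mark the
plateau. The rolling mean of the differences is right-aligned with width
`max(3, ceil(0.001·n))`; the 0.1 % fraction follows practice for large
laboratory samples, and the floor of 3 keeps smoothing defined at the
smallest admissible n (101, where 0.1 % would give width < 1). Leading
positions of the rolling mean use partial prefix windows rather than
missing values, so detectors and plots see full-length series. The cubic
overlay is an ordinary least-squares fit of value on raw rank; it is
computed on an internally scaled domain for conditioning and reported in
the raw-rank basis. Both the residual sign-change ranks and the cubic's
analytic inflection `−a2/(3·a3)` are exposed, since either reading of
"the cubic intersects at the inflection points" can be useful to a rater.

**Plateau, automated.** The detector operationalizes "fit the longest
tangent within a tolerated residual sum of squares, matched with the
interval of lowest first-order derivatives" as a constrained search: the
longest contiguous rank window whose least-squares line has
`RMSE ≤ rmse_tolerance × (x_(n) − x_(1))`, subject to the window's mean
smoothed first-difference not exceeding the curve-wide median (with a 1e-9
relative slack — on an exactly linear segment the window mean and the
median agree only to floating-point rounding). Ties on length break to
smaller RMSE, then to the leftmost window. Defaults:
`rmse_tolerance = 0.005` (0.5 % of the value range) and
`min_size = max(30, 0.1·n)`; both are reported in every output. The search
is an exhaustive all-windows scan (O(n²) with O(1) per-window residuals via
prefix sums, values centred on the grand mean to limit cancellation) up to
n = 5000, and a stride-then-refine scan above (stride `n // 2000`, exact
refinement around the first coarse hit). The exhaustive and strided paths
are held equal in tests where both can run.

Note the tolerance is *relative to the value range*: on curves with
extremely steep tails the absolute tolerance is correspondingly large and
the window may extend further into the near-flat base of a tail. On
realistic laboratory distributions (tails a few SD wide) the overreach is a
few ranks.

**Plateau, raters.** The blinded protocol is preserved in file form:
`rate` exports plots with hidden axis values (reducing confirmation bias
toward known limits) under salted-hash anonymized names, with the code
book in a sidecar; raters fill a marks CSV; `reconcile` merges two raters'
marks when their plateau *sizes* differ by strictly less than 10 % of the
mean size (the average of the two start and end coordinates, rounded
half-up — the original rounding convention is unstated), and otherwise
escalates to a third rater who picks one of the two marks. "Visually
dissimilar" cannot be automated and is not attempted; only the size rule is
implemented.

**Limits.** On the extract (indirect) or control sample (traditional):
if the adjusted Fisher–Pearson sample skewness exceeds +0.5 the values are
transformed with `y = ln(x + 0.1)` before computing `m ± k·s` (n−1
denominator), then back-transformed with `x = exp(y) − 0.1`. The +0.1
constant is added *inside* the logarithm — its purpose is to keep
zero-valued measurements transformable — and the skewness trigger
operationalizes "transform to normality as necessary", for which no
published rule exists; both are configurable. Limits are one-sided per the
measure's pathological direction. `k = 2` is the convention; `k = 2.5`
compensates for the variance deflation of the truncated extract (and in
validation overcorrects — see below). Percentile limits use linear
interpolation of the order statistics with plotting positions
`(i−1)/(n−1)` at the 1 % tails by default.

**Comparison.** A reading exactly equal to a limit is classified
*normal* (strict inequality; the boundary convention is otherwise
undefined). Abnormality ratios are undefined where the traditional %
abnormal is zero; such measures are excluded from summaries with a log
entry rather than imputed. Ratio summaries use the geometric mean
(log-average-exp). "Percentage agreement" is implemented as reading-level
classification concordance, averaged over measures with equal weight; the
phrase is used loosely in the field and this is the interpretation most
faithful to a mock deployment. In "table mode" the ratios are computed from
printed-precision percentage pairs, since the unrounded source data behind
published tables is not recoverable.

## The synthetic generator

`default_spec` emulates a conduction-velocity-like measure: healthy
N(50, 4) m/s (70 %), pathological N(35, 6) truncated at 0 (20 %, on the
measure's abnormal side), supernormal N(60, 3) (10 %). The shapes mirror
the qualitative structure of real peroneal conduction-velocity histograms —
an approximately Gaussian core with a heavier low tail — and the default
n = 5000 matches the scale of a single-laboratory age stratum accumulated
over years. Component membership is multinomial; truncation is by
rejection resampling, so component shapes above the bound are exact. All
draws flow from one explicit seed (package default 20240416); identical
specs give bit-identical samples.

What the generator does **not** emulate: covariate structure (age trends
within a stratum, height and sex effects), repeat visits by the same
patient, measurement rounding/quantization, and multi-modal pathology.
Passing recovery tests therefore show that the pipeline recovers known
mixture structure under clean conditions — not that any particular
laboratory's historical data satisfies those conditions.

`recovery_experiment` re-seeds the spec per repetition (`base_seed + i`),
runs generate → curve → plateau → extract → limits, and reports the bias
and RMSE of the plateau mean against the true healthy location, the
extract-vs-full-sample SDs, and achieved abnormal-classification rates.
Failed repetitions (no plateau within tolerance) are recorded, never
silently dropped.

## Validation results the tests compute

With the defaults above (20 repetitions, seeds 20240416+i, n = 5000):
the plateau mean recovers the healthy location with mean |bias| ≈ 0.07
units; the extract SD is below the full-sample SD in every repetition
(central truncation); and the 2.5-SD limit classifies strictly fewer
readings abnormal than the 2-SD limit in every repetition. On three-segment
constructions (exactly linear middle between steep exponential tails) the
detector recovers ≥ 95 % of the true segment with zero overreach at the
construction's scale. On a *pure* Gaussian sample the detected plateau
spans roughly three quarters of the ranks (simulated range 0.74–0.83 over
seeds) — the quantile curve is everywhere gently curved, so the "plateau"
is genuinely tolerance-bounded there, and its mean still sits within 0.2
units of the population mean.

## Numerical conventions

- Sample SD: n−1 denominator throughout.
- Quantiles: linear interpolation, plotting position `(i−1)/(n−1)`.
- Rounding of averaged rater coordinates: half-up.
- Per-window RMSE in the detector: computed from prefix sums of centred
  values with the closed form `Sxx = L(L²−1)/12` for consecutive integer
  ranks; negative round-off residuals are clamped to zero.
- Skewness: adjusted Fisher–Pearson (bias-corrected); defined as 0 for
  constant samples.
- Transform round-trip error is below 1e-9 over [0, 1e4].
- SVG plot output pins the renderer hash salt and omits date metadata, so
  identical inputs give byte-identical files.

## Known limitations

- No covariate adjustment (height, sex, BMI, temperature): limits must be
  stratified, which multiplies the data requirement. Regression-based
  extension is future work.
- The automated detector is a surrogate for rater judgment, not a model of
  it; reproducing specific human plateau placements is out of scope.
- The truncated extract's variance deflation means the 2-SD indirect limit
  leans strict and the 2.5-SD variant leans lenient; neither k is "correct"
  in general, and percentile limits at the 1 % tails are the principled
  alternative for non-Gaussian plateaus.
- Supernormal readings are excluded along with pathological ones, so the
  method cannot inform the supernormal side of the distribution.
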