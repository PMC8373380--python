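# Methods

## The model

`galmod` implements a phenomenological model of glucose inhibition of the
yeast GAL regulon. Glucose acts on the pathway through two separable
channels: it lowers the fraction of cells that commit to induction (an
indirect effect, via competition for galactose transport and hence Gal3p
signalling), and it lowers the expression level of the cells that do induce
(a direct effect, via Mig1p repression of *GAL4*). Each channel is a Hill
function that decreases with glucose concentration `g` (% w/v):

```
induced fraction:     f(g) = (αF90)^n / (g^n + (αF90)^n),   α = (0.9/0.1)^(1/n)
mean induced level:   log10 L(g) = 2.5 · (βE10)^n / (g^n + (βE10)^n) − 3,
                      β = (0.6/0.4)^(1/n)
```

The two thresholds are the model's strain-level parameters:

* **F90** — glucose at which the induced fraction has fallen to 90%. The
  conversion factor α places the Hill midpoint so that `f(F90) = 0.9`
  exactly.
* **E10** — glucose at which the induced subpopulation's mean level has
  fallen to 10% of its zero-glucose maximum (on the linear scale). With the
  level curve scaled over log10 ∈ [−3, −0.5], the 10%-of-maximal point is
  log10 L = −1.5, which sits at Hill fraction 0.6 of the *log-scale* range —
  hence β = (0.6/0.4)^(1/n). Both conversions were verified against a
  one-dimensional root finder in the test suite.

A population at condition `g` is the mixture of two normals in log10
relative expression: a fraction `f(g)` of induced cells around `L(g)` and
the rest around the constant uninduced baseline 10⁻³. Spreads come from an
empirical quadratic in the mean level,

```
sd(x) = −0.2 · (x + 1.75)² + 0.4
```

clamped at `sd_floor = 0.01` outside its positive range (roughly
x ∈ (−3.16, −0.34)); the only mean the default model produces outside that
range is never reached, and the uninduced baseline at −3 gives sd = 0.0875
without clamping. Default Hill coefficients are the mean values fitted to
natural isolates (level 1.15, fraction 1.69); the extremes (level 0.84–1.50,
fraction 0.75–2.95) are consumed as constants for the phase scan — this
package does not refit them to isolate data.

### Why the bimodal regime sits at high E10/F90

Bimodality requires some glucose concentration where the induced fraction is
intermediate (between the 0.15 minor-weight threshold and ~0.85, i.e.
`g ≳ F90`) while the induced level is still separated from the baseline by
more than twice the larger spread (`g ≲` a few-fold `E10`). Those two
windows overlap only when E10 exceeds F90 (up to order-one factors), so the
bimodal regime lies at high E10/F90 and the unimodal regime at low E10/F90.
This is consistent with the biology the model encodes: deleting the *MIG1*
repressor raises E10 and converts unimodal strains to bimodal ones, and
strong level repression (low E10) hides partially induced populations inside
the uninduced peak.

## Simulation

Populations default to 20,000 cells. The induced count is the half-up
rounding of `f·n` (a deterministic split rather than a binomial draw; the
recorded ground truth is the rounded fraction). The standard titration is
ninefold: glucose halved from 1% to 0.0039%, galactose constant at 0.25%
(metadata only — the model's curves depend on glucose alone). Profiles carry
two reference samples used by metric extraction: an uninduced reference (2%
glucose, induced fraction forced to 0) and a maximal-induction reference (2%
galactose, no glucose, fraction forced to 1). Per-condition seeds are
`master_seed + condition_index`; scans derive per-point seeds as
`(seed + 7919·index) mod 2³¹`.

## Modality classification

Each condition's distribution is binned into 64 equal-width density bins
over the sample range and fitted by least squares (`scipy.optimize.
curve_fit`, bounded so amplitudes and sds stay positive). A single Gaussian
is accepted when its degree-of-freedom-adjusted R² —
`1 − (1−R²)(N−1)/(N−p−1)` with `N = 64` bins and `p = 3k` parameters — is at
least 0.99. Otherwise a two-Gaussian curve is fitted and the condition is
bimodal iff the fitted means are more than 2× the larger fitted sd apart and
the smaller component's area weight exceeds 0.15. A profile is bimodal if at
least one condition is; across replicates a strain is bimodal only if every
replicate is. Fit failures surface as an explicit "unclassifiable" status
and are excluded from (never silently folded into) the profile rule.

Numerical choices: bin count, bin placement and the density target are not
dictated by the decision rule itself; 64 bins resolves both modes at 20,000
cells while keeping per-bin counts high. Two-component fits are initialized
deterministically from a fixed ladder — a 25th/75th-percentile split, then a
density-argmax split of the two half-ranges — keeping the best-SSE
convergent fit. The second start matters for strongly asymmetric mixtures
(minor weight ≲ 0.25), where both percentiles land inside the major mode and
the percentile start degenerates. There are no random restarts, so calls are
exactly reproducible.

**Estimator bias near the decision boundary.** The rule operates on fitted
parameters. For constructed mixtures with true separation near 2σ and minor
weight near 0.15 simultaneously, the least-squares optimum of the heavily
overlapping histogram can sit at a smaller separation than the construction
(e.g. true 2.1σ/0.16 fits at ≈1.7σ/0.19 — verified to be the global optimum,
not an initialization artifact). Calls in that corner reflect the fitted
geometry; away from the boundary fitted and true parameters agree and so do
the calls.

## Metric extraction

Cells are gated as induced when their log10 expression exceeds the 99th
percentile of the uninduced reference (a one-sided quantile gate; induction
only raises expression, and a literal min/max "range" gate is unstable at
20,000 cells). **F90** is read off the gated-fraction curve by linear
interpolation in log10(glucose) at fraction 0.9; **E10** by interpolating
the induced subpopulation's mean log level at 10% (one decade below) the
induced mean of the 2%-galactose reference. Because sampling noise can make
the empirical curves locally non-monotone, the crossing at the highest
glucose is used. When the fraction never drops below 0.9 on the grid the
F90 is reported as a lower bound at the highest glucose tested; when a
profile is classified unimodal its interpolated F90 is likewise flagged as a
lower bound, since level-suppressed induction hides cells from the gate and
shifts the apparent crossing to lower glucose. No crossing at all is
reported as "not reached", never as a number.

Hill coefficients can optionally be refitted to the empirical curves by
bounded least squares on the same two closed forms (`HillCurveModel`, a
model→`fit()`→results object with standard errors and a `summary()`).

## Phase diagram

The scan simulates every combination of 11 threshold values for E10 and F90
— the printed list, including the out-of-series value 0.156 (kept verbatim;
the twofold-consistent variant 0.0156 ships as `THRESHOLD_GRID_TWOFOLD`) —
with Hill coefficients at the fitted extremes plus the mean (3 values per
curve, 1089 points), one 20,000-cell replicate per point. Each point is
classified and re-measured. In log10(F90) vs log10(E10) space the regimes
are delineated by slope-1 bounding lines with the extreme intercepts that
capture all points of each class (exact min/max, not a regression); the band
between the lines, inclusive, is the ambiguous regime, and prediction for a
new (E10, F90) is a side-of-line test. The boundary orientation is inferred
from the scanned classes rather than hard-coded.

A scan-design caveat: points whose F90 lies below the titration floor
(0.0039%) combined with the steepest fraction curve (n = 2.95) never expose
an intermediate induced fraction to the measured glucose window — the
largest attainable minor weight on the grid is ≈0.14 < 0.15 — so they are
called unimodal even at extreme E10/F90. These grid-edge points widen the
ambiguous band of the full default scan; regime tests therefore assert the
clean separation for points whose fraction transition is inside the
titration window.

## Synthetic panels

`make_strain_panel` draws strain parameter sets with log-uniform thresholds
over [0.001, 1] % w/v and Hill coefficients uniform over the fitted ranges,
stratified so every panel of ≥2 strains spans both regimes (one strain with
E10/F90 < 0.1, one > 10). Pre-induction carbon "history" is emulated as a
multiplicative shift of F90 per history label (default fold 8.6 between
raffinose and mannose, with E10 left unshifted by default, fold 1.8
available) — an emulation of the observed effect size, not a biological
claim. `emit_fixture` writes every (strain, history, replicate) profile as
event-table CSVs plus a JSON manifest carrying the full ground truth, so the
whole pipeline runs without any external data.

## What the synthetic data do and do not show

The generator reproduces exactly the distributional assumptions of the
model: normal log-expression within subpopulations, the quadratic
mean–variance relation, a deterministic induced-cell count, and independence
across conditions. Real flow-cytometry data have features the generator
omits — scatter-correlated measurement noise, autofluorescence floors,
debris and doublets, day effects between replicates, and deviations from
normality in the induced peak. Passing tests therefore demonstrate that the
pipeline correctly recovers what the model puts in (thresholds, modality,
history shifts) at realistic sample sizes; they do not validate the gating
or fitting choices against instrument artifacts.

## Problem sizes and tolerances

Tests run at the study's population size (20,000 cells; one convergence
check at 200,000). Metric-recovery assertions use 2 twofold titration steps
per point and a 15% median relative error over the measurable combinations;
observed errors are far smaller (median < 1%) except where the F90 is a
lower bound by construction. Curve-fit convergence uses scipy defaults with
`maxfev = 20,000`; interpolations are linear in log10(glucose); ties at the
ambiguous band's boundary resolve to "ambiguous".

## Known limitations

* The modality call near the decision boundary inherits the histogram
  estimator's bias (above); a likelihood-based EM fit would shift, not
  remove, that boundary behavior.
* The measured F90 of unimodal strains is a lower bound; no correction is
  attempted.
* Galactose is metadata only; the model cannot represent galactose-dependent
  modality changes within a titration.
* The scan uses a single replicate per grid point, so the boundary intercepts
  carry sampling noise of order the titration's interpolation error.
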