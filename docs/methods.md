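# Methods

## Measurement model

A PEA assay reports one qPCR cycle threshold per (well, assay); each well
also carries an internal extension-control Ct. The package models the
normalization chain the way the assay is run:

- **Within-run**: `dCt = Ct − Ct_ext` removes per-well technical variation,
  because pipetting and amplification effects shift all assays of a well by
  the same number of cycles.
- **Between-run**: per plate and assay, the median of each non-blank
  calibrator triplicate is taken (robust to one aberrant well; an even
  replicate count yields the midpoint of the two central values), the three
  medians are averaged into `dCt_cal`, and `ddCt = dCt − dCt_cal`. Any
  plate-wide additive Ct shift cancels algebraically here.
- **Scale**: `NPX = cf − ddCt`. Only "relative to a correction factor" is
  fixed by the assay's definition; the sign is chosen so that larger NPX
  means more protein (more template → lower Ct), and `cf` defaults to 0,
  which leaves NPX relative with the blank background near zero.

A floating-point subtlety: the plate-shift cancellation is bit-exact only
when the shifted and unshifted Ct values are exactly representable on the
same binary grid. The simulator keeps Ct in [16, 32) (one binade of
doubles) by construction, so any dyadic shift (±0.5, ±1, 1.5, …) that stays
inside the binade cancels bit-identically; arbitrary real shifts cancel to
within one unit in the last place (~1e-12 in NPX). The tests assert
bit-identity for dyadic shifts and 1e-12 agreement otherwise.

## Standard curves

The concentration–response is a four-parameter logistic,
`NPX(x) = d + (a − d)/(1 + (x/c)^b)`, with plateaus `d < a`, inflection `c`
and slope `b`. The substitution `(a, d, b) → (d, a, −b)` is an exact
symmetry of this family, so fits are canonicalised to `a > d`; rising
curves (the physical case for PEA) then carry `b < 0`. Blank wells enter
the fit at `x = 0`, where the curve's limit is the baseline plateau, so
blanks anchor `d` for rising curves.

Fitting is plain least squares (Levenberg–Marquardt on `(a, d, log c, b)`),
initialised from the blank mean, the extreme NPX on the far side, the
geometric mid-concentration and a small multi-start slope grid
(±{0.5, 1, 2}); the best converged restart by RSS wins. Tolerances are set
tight (1e-14) because the zero-noise identity tests require the fit to be
exact to numerical precision.

- **LOD**: blank mean + 3 sample SD in NPX, inverted through the curve and
  multiplied by the predilution factor. At least two blank replicates are
  required; negative-control wells are preferred over the blank calibrator
  when both exist.
- **LLOQ/ULOQ**: per nominal standard concentration, replicates are
  back-calculated through the inverse curve; accuracy is the absolute
  relative bias of their mean and precision their CV. The quantifiable
  range is the longest contiguous run of standards with both ≤ 0.30
  (inclusive), reported on the neat-sample scale; no interpolation between
  standards is attempted, because the rule is defined on the measured grid.
  If no standard passes, the curve is flagged non-quantitative — the
  behaviour of an assay whose response is buried in noise.
- **Value reassignment**: the scale minimising the squared log2 difference
  between rescaled PEA and reference concentrations is the geometric mean
  of `reference/PEA` over in-range pairs (≥ 10 required); the 4PL is refit
  on the rescaled standards, which changes `c` by exactly that factor and
  preserves curve shape. Applied twice, the second scale is 1.
- **Censored imputation**: a lognormal is fit by maximum likelihood with
  below-LLOQ values as left-censored and above-ULOQ as right-censored
  (Nelder–Mead on `(μ, log σ)`); draws for below-LLOQ values are truncated
  above at the *minimum observed uncensored value* (not the LLOQ), and
  above-ULOQ draws truncated below at the ULOQ. All draws are
  inverse-CDF transforms of seeded uniforms, so imputation is reproducible.

## Analytical validation

Linearity of dilution mixes a high- and a low-concentration native sample
at equally spaced ratios; the theoretical value of a mixture is
`r·high + (1 − r)·low` with *measured* endpoint concentrations, and the
relative error is `(measured − theoretical)/theoretical` (mean reported
signed, maximum as absolute). QC accuracy is the replicate mean over the
pool's reference value (percent, accepted within 75–125% inclusive) and
precision the replicate CV; replicates may be pooled per plate (3) or per
plate pair (6). Method comparison works on log2 concentrations: Spearman ρ
(average ranks on ties), squared Pearson correlation, and Bland–Altman
mean/SD of `log2(PEA) − log2(reference)` with 1.96·SD limits.

## Survival layer

The case-cohort design keeps every case plus a random sample of non-cases
(about twice as many). Weights are Barlow-style: cases 1, sampled
non-cases the inverse non-case sampling fraction. The weighted Cox partial
likelihood uses Breslow tie handling (simulated data can avoid heavy ties,
and Breslow is the simplest estimator consistent with the weighted
likelihood) and is maximised by damped Newton steps (step halving on a
likelihood decrease, 50-iteration cap, gradient norm < 1e-9 at
convergence). The robust variance is the sandwich of the inverse
information with per-subject weighted score residuals; on equal weights it
reproduces the standard Lin–Wei estimator, verified against lifelines.
Simulation checks show the 95% robust CI covers a true log-HR of 0.5 at
~95% over repeated case-cohort draws.

Continuous covariates use Harrell's four-knot restricted cubic spline
(truncated-power basis normalised by the squared boundary span; knots at
the 5/35/65/95th percentiles by default), giving one linear and two
nonlinear columns that vanish at and below the first knot and leave the
function linear beyond the boundary knots. Which covariates keep splines
can be chosen by ranking each one's drop-in likelihood-ratio χ² in the
all-spline model and keeping the top K (default 5) — fewer degrees of
freedom, less overfitting. Hazard ratios are reported for the third versus
first quartile of a covariate's distribution, with delta-method CIs on the
robust covariance.

Harrell's C counts pairs where the earlier failure has the higher risk
score; a pair is comparable when one subject fails strictly before the
other's observed time, or at a tied time when the other is censored; score
ties count ½ and pairs are weighted by the product of the members'
sampling weights. The implementation is vectorised O(n²) and is tested for
exact agreement with a literal double-loop oracle.

FNI is `1 − χ²(model without the variable)/χ²(full model)`, clipped to
[0, 1] with a log note when sampling noise pushes it outside. Bootstrap
internal validation is Harrell–Efron optimism: per resample of subjects
(weights carried along), refit, and accumulate `C(resample) − C(original)`;
the corrected C subtracts the mean optimism. A resample without events or
with a failed fit is redrawn and logged. A fixed (non-refit) score has no
estimation step, hence zero optimism by definition. Pairwise C-index
differences between model configurations use a paired bootstrap over
subjects on the fitted risk scores (2000 resamples by default) rather than
a closed-form variance for correlated C indices; the bootstrap makes no
distributional assumptions and respects the weighting.

## Synthetic-data generator

The plate generator emits, per plate, triplicate High/Middle/Low/Blank
calibrators, triplicate QC1/QC2 pools, triplicate negative controls and a
configurable number of samples. Calibrator true concentrations default to
`16c`, `c`, `c/16` and 0 per assay — spanning the curve's dynamic region —
and are configurable. Sample concentrations are lognormal on the neat
scale and measured after ten-fold predilution; QC pools likewise. The
observed Ct is built as `ext_ctrl_ct + (anchor − NPX_true)` plus a
per-plate run offset (applied to every Ct including the extension control)
plus Gaussian Ct-level noise. Injecting noise at the Ct level — not the
NPX level — means the normalization chain has real work to do, as in the
actual measurement process. Defaults: extension-control Ct 17, Ct anchor
10, Ct noise SD 0.05 cycles, run-offset SD 0.5 cycles, 4PL truth
`(a, d, c, b) = (10, 0, 50·2^k, −1)` with staggered inflections across
assays.

The cohort generator draws covariates (normal, binary or lognormal),
exponential event times under a proportional-hazards model with
administrative censoring (defaults: baseline hazard 0.05/year, 3-year
horizon, cohort size 5000), then case-cohort samples it. Lognormal
covariates act on the hazard through their logarithm, matching how
biomarkers are modelled downstream.

What the generator does *not* emulate: assay cross-reactivity, competing
risks, covariate missingness, heavy tied event times, lot-to-lot curve
drift, and real plasma matrix effects. Passing tests therefore demonstrate
the correctness of the computational chain under its stated model, not the
wet-lab performance of any particular panel.

## Problem sizes and defaults in the verification runs

The test suite and `scripts/acceptance.py` use: 3-assay panels, 1–2 plates
with 8–12 samples each; standard curves with 12–30 two-fold dilutions, 4
replicates; 100–200 repeated-seed simulations for recovery/coverage rates;
cohorts of 1200 subjects (about 250 cases) for case-cohort checks; 30–100
bootstrap replicates for optimism and 10–200 for pairwise comparisons.
These sizes make every property measurable with comfortable Monte-Carlo
margins while keeping the full verification run fast.

## Known limitations

- The LLOQ/ULOQ search returns the longest passing run; with pathological
  noise two disjoint passing runs of equal length are resolved in favour
  of the first (lower) run.
- The non-case sampling fraction cannot be derived from a case-cohort
  table alone; deriving weights requires the source-cohort size, otherwise
  supplied weights are used as-is (or unit weights for a full cohort).
- The Cox fitter targets moderate dimensionality (tens of columns); no
  penalisation or stratification is implemented.
- Bootstrap optimism resamples subjects with their design weights carried
  along; whether to re-derive weights per resample is a design choice, and
  carrying them is the stabler of the two under moderate case counts.
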