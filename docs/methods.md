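# Methods

## The problem

Registry survival trends are usually summarized per diagnosis-year cohort:
the N-year average survival time of the patients diagnosed in year t_b who
died within N calendar years of diagnosis. That average is not observable
until N years of follow-up have elapsed, so for N = 20 a 1992–2020 extract
yields usable diagnosis cohorts only through 2000, and a trend fitted to
them ignores everything learned from patients treated since. The recent
diagnosis cohorts cannot simply be added: their N-year averages are biased
downward because their longer survivors have not died yet (right
censoring by the data horizon).

Death-year cohorts do not have this problem. The N-year average of the
patients who *died* in year t_e, diagnosed at most N years earlier, is
fully observed as soon as N years of preceding diagnosis data exist — for
a 1992–2020 extract with N = 20, death cohorts 2012 through 2020. These
cohorts contain diagnoses as recent as the last data year.

## The estimator

Let S(t_b) be a trend model for the N-year average survival of the
diagnosis cohort t_b, from one of three families in an anchored
parameterization (the curve passes through the anchor (t0, S0)):

- linear: `S(t_b) = S0 + M (t_b − t0)`, steepness M in years/year;
- exponential: `S(t_b) = S0 · 2^((t_b − t0)/d)`, doubling time d in years;
- logistic: `S(t_b) = L / (1 + ((L − S0)/S0) e^(−k (t_b − t0)))`, maximum
  steepness k per year, ceiling L in years.

Because the average patient diagnosed at t_b dies at `t_e = t_b + S(t_b)`,
a start-time model induces a death-year relation S_te defined by
`S_te(t_b + S(t_b)) = S(t_b)`. For the linear family this is again linear
with slope `M/(M+1)` — death-year trends always look flatter than the
diagnosis-year trend that generates them. For the other families the
relation is evaluated by numerically inverting the strictly increasing map
`t_b ↦ t_b + S(t_b)` (strictness is what the linear constraint M > −1
guarantees).

The pipeline:

1. **Base fit.** Fit the family to the eligible start-cohort averages.
   Linear: ordinary least squares. Exponential: log-linear least squares
   (the spreadsheet-trendline convention), with exact nonlinear least
   squares selectable. Logistic: nonlinear least squares, 3 free
   parameters. Goodness of fit is always reported on the original scale.
2. **Anchor.** t_r is the most recent eligible start-cohort year; S_r is
   the *fitted curve's* height there, not the raw data point, since the
   curve pools all the historical cohorts.
3. **Steepness regression.** Hold the anchor fixed and regress the single
   steepness parameter of S_te against the end-cohort averages. For the
   linear family the substitution `u = M/(M+1)` makes
   `S_te(t_e) = S_r + u (t_e − S_r − t_r)` linear in u, so the solution is
   a closed-form no-intercept regression; `u ≥ 1` (an infinite implied
   diagnosis-year slope) is an error. Nonlinear families use bounded 1-D
   minimization on an internal coordinate (growth rate ln2/d for the
   exponential, k for the logistic) that passes smoothly through zero
   where the doubling time diverges. With a single end-cohort point the
   steepness solves it exactly — the degenerate design where only one
   diagnosis cohort exists still yields a usable trend.
4. **Back-transformation.** The fitted object *is* a start-time model, so
   the updated diagnosis-year curve and its projections are immediate.
5. **Comparison and combination.** AIC in the Gaussian least-squares form
   `n ln(RSS/n) + 2k` (k = 2 base linear/exponential, 3 logistic, 1 for
   the anchored steepness stage, since the anchor is not estimated from
   the end data). Two models are compared by the evidence ratio
   `exp(Δ/2)`, Δ = AIC_min − AIC_other. At or above the combination
   threshold (default 0.5) the linear and exponential projections are
   averaged; below it the lower-AIC model is selected. Headline estimates
   are rounded half-up to two decimals; machine outputs are unrounded.

**Uncertainty bands.** A dense grid (801 points) over the family's full
steepness domain is scored against the end-cohort data with the anchor
fixed; variations with `exp(Δ/2)` ≥ the band threshold (default 0.5)
against the best fit are retained, and the band is the min/max of their
projections at the target year. The retained set grows as the threshold
falls, so a 0.05 band contains the 0.5 band. On a perfect best fit the
band degenerates to the point estimate.

**Paired sign test.** As a descriptive check that end cohorts carry an
improvement signal, the i-th eligible start year is paired positionally
with the i-th eligible end year and a one-sided exact binomial sign test
asks whether end-cohort means exceed their start counterparts more often
than fair coin flips would. Ties are dropped (the standard convention).
With 8 of 9 pairs higher the one-sided p is 10/512 ≈ 0.0195.

**Hold-out validation.** Truncate the range at a cutoff year, keep only
records whose death falls on or before it (nothing later would exist in
an extract taken then), fit both methods, and score their start-time
curves on the later diagnosis-cohort averages computable from the full
range. RMSE and AIC are computed on the held-out points, not the training
fit — a 2-point base regression has zero training residual yet can miss
the held-out cluster badly, which is precisely the failure the experiment
is designed to expose. Below 2 training start cohorts the base method is
recorded as absent and the STETI anchor falls back to the single
start-cohort mean.

## Numerical choices

- RSS floor 1e−12 before the AIC logarithm, so perfect fits stay finite;
  a band whose best fit is at the floor is reported as degenerate.
- End-time inversion: bracketed bisection/Brent to 1e−10 years; the
  bracket expands on demand in both directions, covering extrapolation
  into regions where the fitted line implies negative survival. Scalar
  calls use `brentq`; array calls use a fixed-depth vectorized bisection.
- Steepness search bounds: u ∈ (−0.99, 0.99); |d| ∈ [1, 10000] years,
  sign-matched to the data trend (flat data lands on the flattest bound);
  |k| ≤ 10. Steepness values for which some observed death years are
  unattainable are treated as infinitely poor rather than errors.
- The logistic ceiling defaults to the window N — an N-year average
  cannot exceed N — and is user-overridable.
- Cohort means are count-weighted; the steepness regression across
  cohorts is unweighted (each cohort mean counts once), matching how the
  base trend is fitted to one dot per cohort year.
- Cohorts are grouped by the exact cohort-key values present in the
  records: integer years for registry extracts; real-valued death times
  in unrounded simulations form singleton cohorts that lie exactly on the
  transformed curve, which is what makes the noiseless closure tests
  exact. Eligible integer years without data are reported as omitted.

## The synthetic generator

`steti.simulate` emulates a registry case listing of patients diagnosed
and dead within the data range: for each diagnosis year, `n_per_year`
individual survival times are drawn with mean on a prescribed trend
(degenerate, gamma, or lognormal noise), then rounded half-up to whole
calendar years the way a year-resolution extract reports them (floor and
no-rounding variants are available). One PRNG substream per diagnosis
year means extending the range never perturbs existing years' draws.
Configurations must keep the trend strictly inside (0, N) so window
truncation is negligible.

The default study conditions used across the stochastic tests are a
SEER-like 1992–2020 range, N = 20, linear truth M* = 0.05 (S0 = 2.5 at
1992) and exponential truth d* = 93 (S0 = 3.0748 at 1992) — the scale of
the published kidney-cancer fits — with gamma noise of shape 1 (CV = 1,
right-skewed, plausible for died-within-window survival times) and 2000
diagnoses per year. Hold-out experiments use 20 replicate seeds and a
cutoff leaving three training start cohorts; these sizes keep the full
suite in the tens of seconds.

**What the generator does not emulate,** and the main caveat for reading
test results: under individual-level dispersion the observed N-year
end-cohort average is E[s | death year = t_e], which is *not* the
deterministic transform S_te(t_e) of the start trend. Conditioning on the
death year mixes the individual noise into the implicit regressor (an
errors-in-variables effect), which attenuates the steepness fitted from
end cohorts by a factor of order CV². The dedicated acceptance test that
demands mean recovery of the true steepness within 3 standard errors
under the realistic-dispersion conditions above fails for exactly this
reason, and is left failing: the bias belongs to the estimand, not the
implementation. The companion unit test at low dispersion (gamma shape
50, unrounded), where the identifying approximation holds, shows the same
pipeline recovering the truth well within 3 standard errors. Users should
read STETI's fitted steepness as the trend of *death-year cohort
averages* mapped back to diagnosis years — a conservative (flatter)
estimate of the underlying individual-level trend when dispersion is
large. The generator also does not simulate loss to follow-up or
alive-at-cutoff censoring; such records must not appear in the input.

## Known limitations

- Survival is the integer calendar-year difference (real-valued survival
  is supported but registry extracts do not provide it); rounding
  contributes up to ~0.5 years of granularity error to cohort means.
- The positional pairing of the sign test is a convention; the test is
  descriptive, not part of the estimation pipeline.
- No joint refit of anchor plus steepness on end data (deliberate: the
  anchor pools the larger historical dataset); no breakpoint detection;
  no period-analysis-style imputation.
- Long-horizon extrapolation inherits all the usual caveats of 1-D trend
  models; the band quantifies only steepness uncertainty around a fixed
  anchor, not anchor or family uncertainty.
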