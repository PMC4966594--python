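# Methods

## The additive model

Glutamate production `Y` (g/L) is modelled as an additive function of
fermentation time and online gas-exchange/oxygen parameters,

```
Y = c + s(X1, m1) + ... + s(Xp, mp) + eps,    eps ~ N(0, sigma^2) iid,
```

with identity link and Gaussian errors only. Each smooth is a cubic
regression spline:

- **Basis.** Per term, a cubic B-spline basis of dimension 10 (the upper
  bound on the term's effective degrees of freedom) with interior knots at
  quantiles of the training covariate. The covariate is mapped affinely to
  [0, 1] before the basis is built, which makes fits exactly invariant to
  affine rescaling of covariates (units, offsets) and puts the smoothing
  parameters of covariates with very different scales on a common footing.
  Outside the training range each smooth extrapolates linearly
  (first-order Taylor expansion at the boundary).
- **Penalty.** The integrated squared second derivative, assembled exactly
  by 2-point Gauss quadrature per inter-knot interval (second derivatives
  of cubics are piecewise linear, so the rule is exact). Constants and
  straight lines are unpenalized; as `lambda -> inf` a term collapses to a
  straight line (edf 1), and forcing every `lambda = inf` reproduces the
  ordinary linear model exactly (implemented as the same unpenalized
  least-squares path, so the equivalence is numerical identity rather than
  a limit).
- **Identifiability.** Each basis block is column-centred over the
  training rows and projected onto the orthogonal complement of the
  all-ones coefficient direction (a Helmert transform). Both steps
  together absorb the sum-to-zero constraint into the parameterization:
  every fitted smooth averages zero over the training rows, the intercept
  `c` is the mean response, and the exact rank deficiency that
  partition-of-unity bases otherwise create against the intercept is
  removed.
- **Smoothing selection.** Per-term `lambda` minimizes
  `GCV = N*RSS/(N - edf_total)^2` by coordinate-wise search over 31
  log-spaced grid points (1e-4 .. 1e6), iterated to convergence
  (relative GCV change < 1e-6, at most 8 sweeps) and followed by one local
  refinement pass between the best point's grid neighbours. Effective
  degrees of freedom are traces of the per-term blocks of
  `(X'X + S_lambda)^{-1} X'X`.

### Term significance

Each smooth is tested against zero with a Wald-type statistic in
fitted-value space: with `f = X_j beta_j` over the training rows and
`Cov(f) = X_j V_jj X_j'` (V the posterior covariance of the coefficients),
the statistic `f' Cov^+ f`, pseudo-inverted at rank `ceil(edf_j)`, is
referred to `F(r, N - edf_total)`. Testing the fitted function rather than
the raw coefficient block keeps the statistic well conditioned when
penalization has shrunk most coefficient directions to near zero; the
ceiling rank makes the test mildly conservative for near-null terms, which
is the safe direction for model selection. Stars follow the usual
convention (* < 0.05, ** < 0.01, *** < 0.001).

### Model selection

`select_model` performs backward elimination in two passes. First the
least-significant term with p > 0.05 is dropped repeatedly, as long as GCV
does not rise by more than 5 % (relative). Then a pruning pass removes any
remaining term whose removal worsens GCV by less than 15 %. The second
pass exists because a union of 5 %-level tests over several null
candidates retains a noise term in a sizeable fraction of datasets; a term
that fits only sampling noise costs almost nothing in GCV when removed
(measured on the synthetic benchmark: −2 % to +7 %), whereas removing a
genuinely informative term degrades GCV severely (+35 % to several
hundred %), so the 15 % threshold sits in a wide margin between the two
populations. If every candidate can be eliminated the selection aborts:
there is no informative covariate.

## Residual-bootstrap prediction band

Around the fitted model, pseudo-responses are generated as
`Y*(t) = Yhat(t) + eps*_t` on the training rows and
`Y*(N+h) = Yhat(N+h) + eps*_{N+h}` on the prediction grid, with all
`eps*` drawn with replacement from one pooled set of training residuals
(the constant-variance assumption). Each of B replicates (default 1000)
refits the model on the pseudo-responses — same variable set and knots,
smoothing parameters re-optimized around the original solution by a
coordinate search over factors 1e-3..1e3 — and records the prediction
errors `e'*_{N+h} = Y*(N+h) - Yhat*(N+h)`. Per grid point, the empirical
`alpha/2` and `1 - alpha/2` quantiles of `e'*` give the pointwise band
`[Yhat(N+h) + G~^{-1}(alpha/2), Yhat(N+h) + G~^{-1}(1-alpha/2)]`.
Replicate substreams derive deterministically from one seed, so the band
is reproducible and independent of execution order. Failed refits are
skipped; fewer than 90 % successes aborts.

Two refinements, both exposed as switches:

- **Modified residuals (default on).** The pool is
  `e_i / sqrt(1 - h_ii)` with `h_ii` the hat-matrix diagonal, the standard
  correction for the in-sample shrinkage of fitted residuals. Raw
  residuals (`standardize=False`) reproduce the plain construction.
- **Pooled quantiles (default off).** `pool_errors=True` pools `e'*`
  across grid points instead of taking per-point quantiles.

### Reference trajectories — the key open choice

The band is indexed by fermentation time, but the interval construction is
conditional on covariate values at each grid time, and nothing in the
construction dictates which covariates define the published curve. The
package makes the choice explicit:

- For **coverage of a new batch's measurements**, the statistically
  calibrated object is the band at *that batch's own* covariate trajectory
  (`mean_online_trajectory([batch])` as reference). This is what the
  acceptance study evaluates.
- For **monitoring**, one fixed band must serve all future batches.
  `batch_reference_trajectories(train)` passes every training batch's
  trajectory (several reference rows per grid time); the band is then
  centred on the across-batch mean estimate and its error distribution
  additionally absorbs the between-batch spread of estimate curves, so a
  normal batch's estimate stays inside at the nominal level while fault
  excursions leave it. With a single row per grid time the code reduces
  exactly to the textbook construction.

The band is linearly interpolated between its 2-h grid points when
compared against 6-min online estimates.

## Fault monitoring

Production is estimated at every online record by evaluating the fitted
model on the streamed covariates (estimates clamped below at 0 g/L). A
point is out-of-band iff the estimate is below the lower or above the
upper edge; an event opens at the first point of a run of at least
`debounce` consecutive out-of-band points and closes at the first point of
the next in-band run of the same length (default debounce 1; the
acceptance studies use 2 as light chatter control). Events still open when
the stream ends are reported open-ended. The rule is two-sided: a severe
gas-exchange collapse moves the estimate far outside the band, and the
direction depends on the fitted response surfaces' behaviour under
extrapolation, not on the sign of the physical production loss — what is
detected is inconsistency with normal operation, with root-cause
attribution left to inspection of the parameter traces.

## Synthetic fermentation generator

The generator emulates the normal-run statistics the monitoring approach
presumes, with one activity pulse `a(t)` (fast rise over ~5 h, slow
exponential decay, peak 1) driving all channels:

- **Titer.** `G(t) = A * F(t) + integral of kappa*a*ou`, with `F` the
  normalized integral of `a` (saturating, strongly non-linear), `A` the
  final titer drawn uniformly over 75–85 g/L, and `ou(t)` an
  Ornstein–Uhlenbeck fluctuation (correlation time 3 h, unit stationary
  sd, clipped at ±2.5) scaled by `kappa = 0.488` g/L/h. Offline assays add
  Gaussian noise (sd 1.5 g/L) and clamp at 0.
- **Gas exchange.** `CER = capacity * [baseline(t) + 122*a(t)*(1 +
  0.05*ou)] + noise`, with baseline drifting 50 → 37 mol·m⁻³·h⁻¹ and the
  batch's *metabolic capacity* spanning ±8 % and tightly coupled (noise
  0.05 on the unit quality scale) to the titer draw. This coupling is the
  load-bearing design choice: capacity scales both the activity peak and
  the maintenance baseline, so gas exchange genuinely encodes how
  productive a batch is rather than merely what time it is — without it an
  additive model can only learn the time trend, and no online fault is
  reflected in the estimate. `OUR = f * CER + noise` with `f` per batch in
  0.98–1.02 (a wider ratio would hand the model a pure batch-identity
  channel to memorize).
- **DO** follows one demand-shaped drawdown common to all batches
  (52 − 30·a(t), % air saturation, plus noise). A per-batch DO level would
  again be a memorizable identity channel: with four training batches the
  DO smooth then fits the batch titer offsets spuriously and held-out
  predictions acquire multi-g/L biases.
- **pH** sits at 7.1 (ammonia titration), **stirring** follows oxygen
  demand within 400–900 rpm, **temperature** holds at ~32.1 °C; all with
  instrument noise.
- **Campaigns.** `make_study_set` stratifies batch quality over the titer
  range (shuffled by seed): an experimental campaign deliberately spans
  operating conditions instead of replicating one point, and the spread is
  what identifies the capacity effect from only four batches.

Fault injection operates on the observed series, so everything outside the
(open) fault window is copied verbatim. A **stirring collapse** pins SS
below 300 rpm, DO near 0 %, and CER/OUR below 20 mol·m⁻³·h⁻¹; a
**nitrogen substitution** (NaOH in place of ammonia water) relaxes CER/OUR
toward a maintenance floor of 25 mol·m⁻³·h⁻¹ while pH, DO, SS and
temperature all stay in their normal ranges. In both cases offline titer
increments overlapping the window are scaled by `1 − severity·overlap`, so
accumulation stalls and resumes at the normal rate from the depressed
level — the production lost in-window is never recovered.

**What the generator does not capture:** multi-phase growth kinetics,
substrate feeding events and dilution steps, autocorrelated instrument
drift, sensor dropouts/outliers, and fault signatures other than the two
modelled scenarios. Passing tests therefore demonstrate that the
estimator, band and monitor behave correctly when the additive-model and
constant-variance assumptions hold approximately and batch variability is
visible in the online channels; they do not certify performance on plant
data whose variability is invisible to the instruments.

## Validation design and problem sizes

Studies use five batches of 30 h (16 offline assays, 301 online records
each); four batches train the model (N = 64 aligned rows) and the
held-out batch validates it. The held-out batch is the one with the median
final titer: with only four training batches the covariate span is thin,
and validating at an edge operating condition measures extrapolation
rather than calibration. Acceptance studies use B = 200 bootstrap
replicates and 20 replicate studies; the package default for production
bands is B = 1000.

## Numerical choices and degenerate inputs

- Offline/online alignment takes the nearest online record within ±3 min
  (half the online interval); a larger gap is an error naming the batch
  and time. Alignment is order-independent (batches sorted by id).
- Basis dimension is reduced (with a warning) when a covariate has fewer
  distinct values than requested; fewer than 4 distinct values, or zero
  variance, is an error naming the covariate.
- A singular centred design (collinear covariates) is rejected naming the
  variable set; over-saturated models (total edf ≥ N) are rejected.
- Residuals with zero spread degenerate the band to width 0 with a
  warning.
- Empirical quantiles use linear interpolation; q = 0/1 return min/max.
- All randomness flows from explicit integer seeds via
  `numpy.random.SeedSequence`; every pipeline stage is bit-reproducible.

## Known limitations

- With four training batches the between-batch variance is estimated from
  three degrees of freedom; batches at extreme operating conditions can
  fall partly outside the band (coverage is nominal on average, not
  uniformly over batch types).
- Time and the gas-exchange channels are strongly concurve; the split of
  the fitted signal among `s(T)`, `s(CER)`, `s(OUR)` is data-driven and
  can vary between fits even when their sum is stable. Interpret
  individual smooths with caution; the monitor only relies on the sum.
- The pointwise band makes no family-wise (simultaneous) coverage claim,
  and no bias-corrected or wild-bootstrap variants are provided.
- Rows are treated as independent; within-batch autocorrelation of assay
  errors is ignored, as is any non-Gaussian error structure.
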