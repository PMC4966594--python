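# fermwatch

Online fault diagnosis for batch glutamate fermentation from small sample
sets.

Industrial glutamate is produced by *Corynebacterium glutamicum* in batch
fermenters. The product titer is assayed offline every ~2 h on drawn
samples, while process parameters — carbon dioxide evolution rate (CER),
dissolved oxygen (DO), oxygen uptake rate (OUR), pH, stirring speed (SS)
and temperature — are logged every 6 min by instruments. Classical
multivariate monitoring (MPCA/MPLS, kernel methods, neural networks) needs
far more training batches than a plant typically has. `fermwatch`
implements an alternative that works from a handful of normal runs:

1. **Soft sensor.** Fit an additive model of glutamate production on the
   online parameters,

   `Y = c + s(T, m1) + s(DO, m2) + s(OUR, m3) + s(CER, m4) + ε`,

   where each `s(·, m)` is a penalized cubic regression spline with
   effective degrees of freedom `m` chosen by minimizing the generalized
   cross-validation score `GCV = N·RSS/(N − edf)²`, and `ε` is Gaussian
   with constant variance. The ordinary linear model is the special case
   `m = 1`. Backward elimination (drop the least significant term while
   GCV tolerates it) selects the covariates.

2. **Uncertainty band.** Wrap the fitted model in a pointwise
   100(1−α)% prediction band by residual bootstrap: resample residuals
   with replacement, rebuild pseudo-responses, refit the model B times
   (default B = 1000), and take per-timepoint empirical quantiles of the
   bootstrap prediction errors
   `[Ŷ(N+h) + G̃⁻¹(α/2), Ŷ(N+h) + G̃⁻¹(1−α/2)]`.

3. **Fault monitor.** Estimate production from the live online stream at
   every 6-min record and flag a fault whenever the estimate leaves the
   95 % band; the report gives each fault's start, end (when the estimate
   returns into the band) and peak excursion. Faults in parameters that
   are *not* model covariates (e.g. a wrong titrant with normal pH) are
   still caught through their footprint on gas exchange.

A synthetic fermentation generator (`fermwatch.simulate`) reproduces the
statistical structure of normal runs — saturating titer curves ending at
75–85 g/L, CER rising from ~50 to ~170 mol·m⁻³·h⁻¹ before decaying, DO
between ~10 and 55 %, stirring at 400–900 rpm — and injects two reference
fault scenarios (stirring-speed collapse, nitrogen-source substitution),
so the whole pipeline is testable without plant data.

## Worked example

```sh
$ fermwatch simulate --n-normal 4 --fault stirring_drop:12.3:18.5:1.0 --seed 7 --out runs
$ mkdir train && cp runs/normal-* train/
$ fermwatch train --batches train --bootstrap 1000 --seed 0 --out model.json band.csv
fitted on N=64 rows: adj R^2 0.992, GCV 6.93
  s(T, 7.16) p=1.1e-45***
  s(DO, 2.00) p=0.56
  s(OUR, 1.00) p=0.96
  s(CER, 3.30) p=0.25
wrote model to model.json and band to band.csv

$ fermwatch monitor --model model.json --band band.csv \
      --online runs/fault-stirring_drop-01_online.csv --debounce 2
batch fault-stirring_drop-01:
  fault 1: start 12.40 h, end 18.50 h, duration 6.10 h, peak excursion 9.74 g/L
$ echo $?
2

$ fermwatch monitor --model model.json --band band.csv \
      --online train/normal-01_online.csv --debounce 2
batch normal-01:
  no faults detected
```

Reading the output: the additive model explains 99.2 % of the variance in
glutamate production across the 64 aligned training observations
(4 batches × 16 assays); fermentation time carries a strongly non-linear
effect (7.2 effective degrees of freedom). A stirring failure injected
over 12.3–18.5 h drives the online estimate outside the 95 % band from
12.4 h until 18.5 h — both the onset and the recovery are localized to
within one or two 6-min records — while a normal batch stays inside the
band for its whole run (exit code 0 vs 2).

The same pipeline is available as a library:

```python
from fermwatch import (make_study_set, split_batches, align_offline_online,
                       fit_gam, build_band, BandConfig,
                       batch_reference_trajectories, estimate_online,
                       detect_faults)

train, test = split_batches(make_study_set(5, [], base_seed=7))
table = align_offline_online(train)
fit = fit_gam(table, ["T", "DO", "OUR", "CER"])
band = build_band(fit, table, batch_reference_trajectories(train),
                  BandConfig(B=1000, alpha=0.05, seed=0))
report = detect_faults(estimate_online(fit, test.online), band, debounce=2)
```

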