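# gillscale

Respirometry processing, gill morphometry and allometric-scaling
inference for testing **gill-oxygen-limitation (GOL)** predictions in
growing fishes.

## The scientific problem

Aquatic ectotherms tend to reach smaller adult sizes when reared warm
(the temperature–size rule). One prominent proposed mechanism, the GOL
hypothesis, holds that growth is capped by the gills: gill surface area
(GSA) is a two-dimensional structure supplying a three-dimensional,
growing oxygen demand. Written as allometric power laws of body mass,
`y = a·M^b` (fitted as `log10 y = a + b·log10 M`), GOL predicts either

* **scenario 1** — geometric constraint caps both GSA and metabolic
  rate (MR) at a common slope `b < 1`, or
* **scenario 2** — MR outscales GSA, so the supply:demand ratio shrinks
  with size: `b_MR > b_GSA`.

The decisive statistic is the slope difference

```
b_S = b_GSA − b_MR
```

computed per temperature for both resting (RMR) and maximum (MMR)
metabolic rate. `b_S ≥ 0` means oxygen supply keeps pace with demand as
the fish grows — inconsistent with scenario 2.

`gillscale` implements the full quantitative chain needed to evaluate
this on a two-temperature rearing experiment with a fast-growing
salmonid cohort:

1. **Respirometry** (`gillscale.respirometry`) — 1 Hz dissolved-oxygen
   traces into oxygen-uptake estimates: flush/wait/measure cycle
   segmentation, per-segment OLS slopes with an `R² ≥ 0.9` filter, RMR
   as the mean of the lowest 25% of accepted estimates, MMR from the
   steepest 1-min rolling-regression window after an exhaustive chase,
   linear background-respiration subtraction, and critical oxygen
   tension (P_crit) by the LLO method (the PO2 where binned MO2 falls
   below the line joining RMR at normoxia to zero at anoxia).
2. **Gill morphometry** (`gillscale.gill_morphometry`) — bin-level
   filament and lamellar measurements into total filament length
   `L_fil`, lamellar frequency `n_lam`, mean bilateral lamellar area
   `A_lam`, and `GSA = L_fil · n_lam · A_lam`.
3. **Allometry** (`gillscale.allometry`) — per-temperature log10
   power-law fits with t-based CIs, `b_S`, exact component-slope
   decomposition of `b_GSA`, mass correction to a 24.0 g reference
   (`MR_mc = MR·(M_ref/M)^b`), Q10 and factorial aerobic scope.
4. **Growth** (`gillscale.organism_metrics`) — specific growth rate
   (`100·Δln M/Δt`), relative condition factor (`100·M/L^3.085`), fold
   changes.
5. **Synthetic data** (`gillscale.synthetic_data`) — cohorts, gill
   tables and oxygen traces generated from known true slopes, so every
   estimator can be validated against ground truth without any
   laboratory data.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/03_allometric_scaling.py` simulates 36 fish per
temperature with true slopes `b_GSA=0.97, b_RMR=0.87, b_MMR=0.94` and
prints:

```
15 degC  (n=36):
  b_GSA = 0.956  [95% CI 0.926, 0.986]
  b_RMR = 0.886  [95% CI 0.855, 0.918]
  b_MMR = 0.944  [95% CI 0.907, 0.980]
  b_S (GSA - RMR) = +0.070  -> inconsistent with GOL scenario 2
  b_S (GSA - MMR) = +0.013  -> inconsistent with GOL scenario 2
```

Each fitted slope covers its generating truth, and the positive `b_S`
values recover the configured supply-keeps-pace scenario: gill area
scales *above* both metabolic rates, so nothing in these data suggests
the gills are the bottleneck. `examples/05_full_pipeline.py` runs the
same logic end-to-end through rendered gill tables and oxygen traces,
and `examples/01_respirometry_trace.py` shows the trace-level
estimators on a single fish.

A thin CLI wraps the same functions
(`gillscale run --config run.yaml`, plus `simulate / respo / gills /
scale / growth / report` subcommands).

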