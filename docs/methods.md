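# Methods

This note documents the models, estimators, numerical choices and
limitations behind `gillscale`. It is written for a reader who wants to
know exactly what each number means and what the synthetic validation
does and does not demonstrate.

## Respirometry model

A trial records dissolved oxygen as % air saturation at a nominal 1 Hz
in a closed-loop respirometer of total volume `V_sys` (litres)
containing a fish of mass `M` (g). The effective water volume is
`V_eff = V_sys − M/1000`, treating fish density as 1 g mL⁻¹. Saturation
converts to concentration through the Benson–Krause freshwater O2
solubility at 1 atm and zero salinity (validity 0–40 °C); at 15 °C air
saturation is 10.08 mg L⁻¹ and at 20 °C 9.09 mg L⁻¹. An oxygen-uptake
rate follows from a depletion slope `s` (% sat s⁻¹) as

```
MO2 [mg O2 h⁻¹] = −(s/100) · C_sat(T) · V_eff · 3600
```

with uptake positive.

**Cycle segmentation.** Intermittent-flow trials tile the trace with
flush → wait → measure cycles from the first timestamp; the number of
cycles is `floor(duration / cycle length)` and a trailing partial cycle
is dropped. Only measure-phase samples are fitted; the wait phase
(mixing lag, visibly non-linear) is discarded. No additional
mixing-lag filtering is applied beyond dropping the wait phase.

**Slope fits and the R² filter.** Each segment gets an OLS slope and an
R² (squared Pearson correlation). Segments with `R² < 0.9` are retained
but flagged not-accepted and logged, so the filter is auditable. A
segment with zero O2 variance has slope 0 and undefined R², treated as
not accepted. The filter applies to resting segments only; the MMR
rolling window is not R²-filtered.

**RMR.** The mean of the `k = ceil(0.25·n)` smallest accepted
estimates. The ceiling rule is a deliberate choice where simple
"lowest 25%" language leaves rounding open: it guarantees at least one
value for any `n ≥ 1`.

**MMR.** OLS slope over every contiguous window spanning 60 s (stride
one sample) of the post-chase closed trace; the most negative slope
wins. The implementation is vectorised but is required by a property
test to agree with an exhaustive brute-force window search to 1e-12.

**Background respiration.** Microbial uptake measured in the empty
chamber before and after a trial is interpolated linearly in time and
subtracted at each estimate's window midpoint. Negative background
rates are clamped to 0 with a warning, as are corrected MO2 values
driven below 0; every clamp is logged. Whether the single MMR window
should also be background-corrected is ambiguous in common practice;
the default here is yes, controlled by `background_correct_mmr`.

**P_crit (LLO).** MO2 is computed per descending PO2 bin (default
width 2% sat) of the closed-chamber drawdown. The reference line runs
from RMR at normoxia to zero at anoxia, `L(P) = RMR·P/normoxia`.
P_crit is the linearly interpolated PO2 of the highest crossing where
binned MO2 drops below `L(P)` and stays below through the end of the
drawdown. Two numerical choices matter:

* *Bin width 2% sat* balances slope stability (≥3 samples per bin)
  against localisation; the planted-crossing test requires recovery
  within one bin width.
* *Guard band.* "Below the line" means `MO2 < L(P) − 0.001·RMR`. An
  exact oxyconformer (`MO2 = RMR·P/normoxia`) rides the line, and
  finite-bin curvature biases its binned MO2 about 1e-5 to 1e-3 of RMR
  below it; the guard keeps that degenerate case correctly classified
  as "undefined" while any real post-P_crit conformity drop (tens of
  percent of RMR) clears it by orders of magnitude. An undefined result
  is reported as NaN with the lowest observed PO2 attached.

P_crit is reported in % air saturation throughout.

## Gill morphometry

GSA is the exact product `L_fil · n_lam · A_lam`:

* `L_fil` — twice the sum over all right-side bins (all eight
  hemibranchs) of filament count × median filament length, the factor
  two accounting for the unmeasured left side.
* `n_lam` — on a single reference hemibranch (default hemibranch 4,
  the posterior hemibranch of the second arch): per-bin one-sided
  frequency is the simple mean of base and tip counts (a length-
  weighted within-filament mean is equally defensible; the simple mean
  was chosen and documented), weighted across bins by bin filament
  length, then doubled for the two sides of each filament.
* `A_lam` — per-bin mean of tip/middle/base bilateral areas, weighted
  by per-bin lamellae count.

Unit bookkeeping is the classic failure mode: frequencies are stored
one-sided and doubled at aggregation, areas are stored already
bilateral and never doubled again. The schema documents both.

Because the product is exact, `log10 GSA` is an exact sum of component
logs, and by OLS linearity the fitted component slopes (and intercepts)
must sum to the directly fitted GSA slope to numerical precision
(≤1e-10). The pipeline verifies this identity on every run; it is also
the basis for decomposing *how* a high GSA slope is achieved (in the
null preset, by keeping the lamellar-frequency slope near zero rather
than the isometric −1/3).

## Allometric inference

Power laws are fitted by OLS on log10–log10 axes from the closed-form
normal equations; the slope CI is t-based with `n − 2` df (the CI
method is a package choice; bootstrap alternatives gave no material
difference at these n). Temperature effects on scaling are tested by a
pooled OLS with a group indicator and indicator × log10-mass
interaction; the interaction coefficient equals the difference of the
separately fitted slopes exactly, which is tested as an identity.

`b_S = b_GSA − b_MR` is reported as a point difference per MR metric
and temperature, with the sign carrying the verdict (`b_S < 0` is the
scenario-2 signature). No standard error is attached to `b_S` by
default because the two slopes come from overlapping but non-identical
fish sets; a bootstrap over fish is available as a clearly-labelled
extra.

Mass correction uses `MR_mc = MR·(M_ref/M)^b` with `M_ref = 24.0 g`
(the study's geometric-mean mass) and the temperature-specific fitted
slope; a pooled-slope option exists but is off by default. Q10 is
`(R2/R1)^(10/(T2−T1))` on mass-corrected treatment means; FAS is the
ratio of mass-corrected MMR to RMR, warning when below 1.

## Synthetic-data generator

The generator emulates the structure of a two-temperature (15/20 °C)
rearing study with lethal sampling at 14, 90 and 180 days, 36 fish per
temperature by default.

**Growth.** Initial masses are Normal(2.62, 0.80) g (clipped at
0.2 g). Growth is exponential with a specific growth rate that
declines linearly with age, `s(t) = s0·(1 − c·t)`, and is reduced by a
fraction per °C above 15 °C. Defaults `s0 = 3.0 %/day`,
`c = 0.0033 /day` and penalty `0.044 /°C` were chosen once so the mean
trajectory reproduces the intended cohort endpoints — about 203 g at
15 °C and 78 g at 20 °C after 240 days (77-fold vs 30-fold gains) —
and are not revisited. Only the SGR semantics matter downstream; the
growth law itself is not under test.

**Latent traits.** Each record draws
`y = 10^(a + b·log10 M + ε)`, `ε ~ N(0, 0.05)` by default. The three
gill-component noise terms are drawn with variance `sd²/3` each and
*summed* to form the GSA noise term, so GSA remains the exact product
of its components per fish and slope decomposition is exact all the way
down. Default intercepts (GSA 251 mm² g⁻¹-equivalent at 1 g, RMR
0.15 mg O2 h⁻¹ at 1 g, MMR giving FAS ≈ 4, L_fil 500 mm, n_lam
40 mm⁻¹) are round figures in the physiological range for a small
salmonid. Scenario presets: *null* (b_GSA 0.97 ≥ b_MR), *scenario 1*
(all slopes 0.80), *scenario 2* (b_GSA 0.75 < b_RMR 0.90, b_MMR 0.95).

**Gill tables.** Eight hemibranchs, 5–7 bins each, ~12 filaments per
bin; raw per-bin values are drawn with realistic scatter then rescaled
so aggregation recovers the latent components exactly at zero noise.
Measurement noise multiplies each recorded cell by `10^N(0, sd)`.
Lamellar measurements exist only on the reference hemibranch,
mirroring the dissection protocol.

**Traces.** Resting traces encode `RMR·(1 + diel)` plus interpolated
background in each measure-phase slope, where diel is a half-rectified
sinusoid (amplitude 30% of RMR, period 24 h by default) that is exactly
zero half of each period — this is what makes the lowest-quartile
estimator a consistent target for the latent RMR. Neither the diel
amplitude nor the chase-recovery kinetics are estimates of real fish;
they are free parameters of the test surface. Chase traces hold MO2 at
MMR for a 90 s plateau (longer than the rolling window, so the planted
slope is recoverable exactly) then decay exponentially toward RMR
(τ = 300 s). Drawdown traces integrate `MO2(P) = RMR` above the latent
P_crit and `RMR·(P/P_crit)²` below it at the sample rate until a 5%
saturation floor. For the quadratic conformer the LLO crossing sits at
`P_crit²/normoxia` — an analytic oracle used in the tests.

**Determinism.** One global seed; each fish's stream derives from a
stable hash of (seed, fish id), so subsetting a cohort never changes
another fish's data. Identical configurations are byte-identical.

**What passing does and does not show.** The generator produces
power-law-exact latent traits with lognormal iid noise, linear
measure-phase depletion, and no tank effects, temperature drift within
trials, probe drift, or activity autocorrelation. Recovery of the
generating slopes therefore validates the estimators and their
plumbing, not the biological adequacy of power-law scaling or the
behaviour of the estimators under instrument pathologies.

## Problem sizes

The test suite and the acceptance script use: 36 fish per temperature
(the study's scale) for single-fit demonstrations; 100 seeded
replicates for CI-coverage (expected ≈95%, required ≥90%) and
scenario-verdict accuracy (required ≥90%); 100 random traces for the
rolling-vs-brute-force MMR identity; and 6–12 cycle traces for the
round-trip checks, with the diel period set equal to the trace span so
that half the cycles sit at exactly the latent RMR. Full end-to-end
runs (rendered gill tables and traces for every sampled fish) use 6–21
fish per temperature in tests and examples and 36 in the acceptance
script.

## Known limitations

* The temperature-interaction test assumes homoscedastic log-scale
  errors; the time-varying-dispersion mixed models sometimes used for
  growth analyses are out of scope.
* Background respiration is modelled linearly between two anchors; a
  chamber with non-monotone fouling would violate this.
* The LLO P_crit needs data well below the crossing ("stays below to
  the end"); a drawdown stopped early reports the result as undefined
  rather than extrapolating.
* Real AutoResp exports and other instrument formats are not parsed;
  input is the documented CSV schema.
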