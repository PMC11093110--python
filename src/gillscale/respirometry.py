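"""Intermittent-flow respirometry: oxygen traces to metabolic rates.

A trial records dissolved oxygen (% air saturation) at a nominal 1 Hz in
a closed-loop respirometer.  Resting trials cycle through flush (chamber
re-aerated), wait (mixing lag, discarded) and measure (closed chamber,
linear O2 depletion) phases; each measure phase yields one oxygen-uptake
estimate (MO2, mg O2 h⁻¹) from the OLS slope of saturation against time.

* RMR is the mean of the lowest 25% of accepted MO2 estimates
  (R² ≥ 0.9 filter), which discards spontaneous-activity peaks.
* MMR comes from a post-exhaustive-chase closed trace: the most negative
  OLS slope over a rolling 1-min window.
* Background (microbial) respiration measured before and after the trial
  is interpolated linearly in time and subtracted.
* P_crit is estimated by the LLO method from a closed-chamber drawdown:
  the PO2 at which binned MO2 falls below the line joining RMR at
  normoxia to zero at anoxia and stays below.

Saturation is converted to concentration with the Benson–Krause
freshwater O2 solubility (1 atm, zero salinity); effective chamber
volume is system volume minus fish volume at 1 g mL⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OxygenTrace",
    "CycleConfig",
    "Mo2Estimate",
    "MetabolicSummary",
    "PcritResult",
    "percent_sat_to_mg_per_l",
    "segment_cycles",
    "fit_segment_slope",
    "compute_mo2",
    "analyze_rmr_trace",
    "estimate_rmr",
    "estimate_mmr",
    "subtract_background",
    "estimate_pcrit_llo",
]


@dataclass
class OxygenTrace:
    """One respirometry trial's dissolved-oxygen time series."""

    fish_id: str
    temperature_c: float
    time_s: np.ndarray
    o2_percent_sat: np.ndarray
    system_volume_l: float
    fish_mass_g: float
    phase: np.ndarray | None = None  # optional per-sample labels

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_percent_sat = np.asarray(self.o2_percent_sat, dtype=float)
        if self.time_s.shape != self.o2_percent_sat.shape:
            raise ValueError("time and O2 arrays must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.o2_percent_sat)):
            raise ValueError("O2 values must be finite")
        if self.system_volume_l * 1000.0 <= self.fish_mass_g:
            raise ValueError(
                f"system volume {self.system_volume_l} L does not exceed "
                f"fish volume ({self.fish_mass_g} g at 1 g/mL)"
            )

    @property
    def effective_volume_l(self) -> float:
        """Water volume: system volume minus fish volume (density 1 g/mL)."""
        return self.system_volume_l - self.fish_mass_g / 1000.0

    @property
    def duration_s(self) -> float:
        if self.time_s.size == 0:
            return 0.0
        dt = float(np.median(np.diff(self.time_s))) if self.time_s.size > 1 else 1.0
        return float(self.time_s[-1] - self.time_s[0]) + dt


@dataclass(frozen=True)
class CycleConfig:
    """Flush/wait/measure phase durations of one intermittent-flow cycle."""

    flush_s: float
    wait_s: float
    measure_s: float

    def __post_init__(self) -> None:
        for name in ("flush_s", "wait_s", "measure_s"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def cycle_s(self) -> float:
        return self.flush_s + self.wait_s + self.measure_s


@dataclass
class Mo2Estimate:
    """One oxygen-uptake estimate from one closed-chamber segment."""

    window_start_s: float
    window_end_s: float
    slope_percent_sat_per_s: float
    r_squared: float  # NaN when undefined (zero O2 variance)
    mo2_mg_o2_per_h: float
    accepted: bool
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        if not self.window_end_s > self.window_start_s:
            raise ValueError("window end must exceed window start")

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.window_start_s + self.window_end_s)


@dataclass(frozen=True)
class PcritResult:
    """LLO critical oxygen tension; undefined when MO2 never drops below
    the normoxia-to-anoxia RMR line within the observed PO2 range."""

    pcrit_percent_sat: float  # NaN when undefined
    defined: bool
    lowest_po2_percent_sat: float
    n_bins: int


@dataclass
class MetabolicSummary:
    """Per-fish metabolic endpoints from one full respirometry trial."""

    fish_id: str
    rmr_mg_o2_per_h: float
    mmr_mg_o2_per_h: float | None = None
    fas: float | None = None
    pcrit_percent_sat: float | None = None
    n_slopes_total: int = 0
    n_slopes_accepted: int = 0

    def __post_init__(self) -> None:
        if (
            self.mmr_mg_o2_per_h is not None
            and self.mmr_mg_o2_per_h < self.rmr_mg_o2_per_h
        ):
            warnings.warn(
                f"{self.fish_id}: MMR {self.mmr_mg_o2_per_h:.3f} below RMR "
                f"{self.rmr_mg_o2_per_h:.3f}",
                stacklevel=2,
            )


# Benson–Krause coefficients for O2 solubility in freshwater at 1 atm
# (T in kelvin, result mg/L); valid 0–40 degC.
_BK = (-139.34411, 1.575701e5, -6.642308e7, 1.243800e10, -8.621949e11)


def o2_solubility_mg_per_l(temperature_c: float) -> float:
    """Air-equilibrated O2 concentration in freshwater at 1 atm (mg/L)."""
    if not 0.0 <= temperature_c <= 40.0:
        raise ValueError(
            f"temperature {temperature_c} degC outside solubility validity (0-40)"
        )
    t = temperature_c + 273.15
    ln_c = _BK[0] + _BK[1] / t + _BK[2] / t**2 + _BK[3] / t**3 + _BK[4] / t**4
    return math.exp(ln_c)


def percent_sat_to_mg_per_l(percent_sat: float, temperature_c: float) -> float:
    """Convert % air saturation to mg O2 per litre at temperature T."""
    if percent_sat < 0:
        raise ValueError(f"saturation must be >= 0, got {percent_sat}")
    return percent_sat / 100.0 * o2_solubility_mg_per_l(temperature_c)


def segment_cycles(
    trace: OxygenTrace, cycle: CycleConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Extract the measure-phase samples of each complete cycle.

    Cycles tile the trace from its first timestamp; the number of
    segments is floor(duration / cycle length) — a trailing partial
    cycle is dropped.  Each segment holds the samples with
    t in [cycle start + flush + wait, cycle end), i.e. the wait-phase
    mixing lag is excluded.  A trace shorter than one cycle yields an
    empty list with a warning.
    """
    duration = trace.duration_s
    n_cycles = int(duration // cycle.cycle_s)
    if n_cycles == 0:
        warnings.warn(
            f"trace {trace.fish_id}: duration {duration:.0f} s shorter than "
            f"one cycle ({cycle.cycle_s:.0f} s); no segments",
            stacklevel=2,
        )
        return []
    t0 = trace.time_s[0]
    segments = []
    for i in range(n_cycles):
        start = t0 + i * cycle.cycle_s + cycle.flush_s + cycle.wait_s
        end = t0 + (i + 1) * cycle.cycle_s
        mask = (trace.time_s >= start) & (trace.time_s < end)
        segments.append((trace.time_s[mask], trace.o2_percent_sat[mask]))
    return segments


def fit_segment_slope(
    time_s: np.ndarray, o2_percent_sat: np.ndarray
) -> tuple[float, float]:
    """OLS slope (% sat s⁻¹) and R² of one depletion segment.

    R² is the squared Pearson correlation.  A segment with zero O2
    variance returns slope 0 with R² = NaN (undefined, to be treated as
    not accepted); zero time variance is rejected.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(o2_percent_sat, dtype=float)
    if t.size < 3:
        raise ValueError(f"need >= 3 samples to fit a slope, got {t.size}")
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(np.dot(tc, tc))
    if stt == 0:
        raise ValueError("zero time variance in segment")
    syy = float(np.dot(yc, yc))
    if syy == 0:
        return 0.0, float("nan")
    sty = float(np.dot(tc, yc))
    slope = sty / stt
    r2 = sty * sty / (stt * syy)
    return slope, r2


def compute_mo2(
    slope_percent_sat_per_s: float,
    system_volume_l: float,
    fish_mass_g: float,
    temperature_c: float,
) -> float:
    """Oxygen uptake (mg O2 h⁻¹) from a depletion slope.

    The slope (% sat s⁻¹, negative for uptake) is converted to
    mg L⁻¹ s⁻¹ via the solubility at trial temperature, multiplied by the
    effective water volume (system minus fish, density 1 g mL⁻¹) and by
    3600 s/h; the sign convention makes uptake positive.
    """
    v_eff = system_volume_l - fish_mass_g / 1000.0
    if v_eff <= 0:
        raise ValueError(
            f"effective volume {v_eff:.4f} L not positive "
            f"(system {system_volume_l} L, fish {fish_mass_g} g)"
        )
    slope_mg_per_l_s = (
        slope_percent_sat_per_s / 100.0 * o2_solubility_mg_per_l(temperature_c)
    )
    return -slope_mg_per_l_s * v_eff * 3600.0


def analyze_rmr_trace(
    trace: OxygenTrace,
    cycle: CycleConfig,
    r2_threshold: float = 0.9,
) -> list[Mo2Estimate]:
    """Segment a resting trial and fit every measure phase.

    Each segment is fitted by OLS and converted to MO2; segments with
    R² below the threshold (or undefined) are retained but flagged
    not-accepted, so the filter is auditable.
    """
    estimates = []
    for t, y in segment_cycles(trace, cycle):
        if t.size < 3:
            continue
        slope, r2 = fit_segment_slope(t, y)
        mo2 = compute_mo2(
            slope, trace.system_volume_l, trace.fish_mass_g, trace.temperature_c
        )
        estimates.append(
            Mo2Estimate(
                window_start_s=float(t[0]),
                window_end_s=float(t[-1]),
                slope_percent_sat_per_s=slope,
                r_squared=r2,
                mo2_mg_o2_per_h=mo2,
                accepted=bool(np.isfinite(r2) and r2 >= r2_threshold),
            )
        )
    return estimates


def estimate_rmr(estimates: list[Mo2Estimate] | np.ndarray) -> float:
    """RMR: mean of the lowest 25% of accepted MO2 estimates.

    k = ceil(0.25 · n_accepted), guaranteeing at least one value.  With
    zero accepted estimates the per-segment R² values are reported in the
    error to aid diagnosis.
    """
    if isinstance(estimates, np.ndarray) or (
        len(estimates) and not isinstance(estimates[0], Mo2Estimate)
    ):
        values = np.sort(np.asarray(estimates, dtype=float))
    else:
        accepted = [e.mo2_mg_o2_per_h for e in estimates if e.accepted]
        if not accepted:
            r2s = [round(e.r_squared, 4) for e in estimates]
            raise ValueError(
                f"no accepted MO2 estimates (per-segment R2: {r2s})"
            )
        values = np.sort(np.asarray(accepted, dtype=float))
    if values.size == 0:
        raise ValueError("no MO2 estimates supplied")
    k = math.ceil(0.25 * values.size)
    return float(values[:k].mean())


def estimate_mmr(
    trace: OxygenTrace, window_s: float = 60.0
) -> tuple[float, Mo2Estimate]:
    """MMR: steepest 1-min rolling-regression slope of a post-chase trace.

    An OLS slope is fitted over every contiguous window of ``window_s``
    span (stride one sample); the most negative slope gives MMR.  Returns
    the MMR (mg O2 h⁻¹) and the winning window's estimate.
    """
    t = trace.time_s
    y = trace.o2_percent_sat
    if t.size < 3:
        raise ValueError("trace too short for any regression window")
    dt = float(np.median(np.diff(t)))
    w = int(round(window_s / dt))
    if w < 3:
        w = 3
    if t.size < w:
        raise ValueError(
            f"trace ({t.size} samples) shorter than rolling window ({w} samples)"
        )
    # rolling OLS via sliding windows; trace lengths here are small (<1e5)
    tw = np.lib.stride_tricks.sliding_window_view(t, w)
    yw = np.lib.stride_tricks.sliding_window_view(y, w)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    stt = np.sum((tw - tm) ** 2, axis=1)
    sty = np.sum((tw - tm) * (yw - ym), axis=1)
    slopes = sty / stt
    i = int(np.argmin(slopes))
    slope = float(slopes[i])
    mo2 = compute_mo2(
        slope, trace.system_volume_l, trace.fish_mass_g, trace.temperature_c
    )
    syy = float(np.sum((yw[i] - yw[i].mean()) ** 2))
    r2 = float(sty[i] ** 2 / (stt[i] * syy)) if syy > 0 else float("nan")
    est = Mo2Estimate(
        window_start_s=float(tw[i, 0]),
        window_end_s=float(tw[i, -1]),
        slope_percent_sat_per_s=slope,
        r_squared=r2,
        mo2_mg_o2_per_h=mo2,
        accepted=True,
    )
    return mo2, est


def subtract_background(
    estimates: list[Mo2Estimate],
    pre_rate_mg_o2_per_h: float,
    post_rate_mg_o2_per_h: float,
    t_pre_s: float,
    t_post_s: float,
) -> list[Mo2Estimate]:
    """Subtract linearly interpolated background respiration.

    Microbial background is measured in the empty chamber before and
    after the trial; it is interpolated linearly between those two
    anchors at each estimate's window midpoint and subtracted.  Negative
    background rates are clamped to 0 with a warning, as are corrected
    MO2 values driven below 0.
    """
    if t_post_s <= t_pre_s:
        raise ValueError("post-trial time must exceed pre-trial time")
    pre, post = pre_rate_mg_o2_per_h, post_rate_mg_o2_per_h
    if pre < 0 or post < 0:
        warnings.warn(
            f"negative background rate(s) (pre={pre}, post={post}); clamped to 0",
            stacklevel=2,
        )
        pre, post = max(pre, 0.0), max(post, 0.0)
    corrected = []
    n_clamped = 0
    for e in estimates:
        frac = (e.midpoint_s - t_pre_s) / (t_post_s - t_pre_s)
        bg = pre + frac * (post - pre)
        value = e.mo2_mg_o2_per_h - bg
        if value < 0:
            value = 0.0
            n_clamped += 1
        corrected.append(
            Mo2Estimate(
                window_start_s=e.window_start_s,
                window_end_s=e.window_end_s,
                slope_percent_sat_per_s=e.slope_percent_sat_per_s,
                r_squared=e.r_squared,
                mo2_mg_o2_per_h=value,
                accepted=e.accepted,
                background_subtracted=True,
            )
        )
    if n_clamped:
        warnings.warn(
            f"{n_clamped} MO2 estimate(s) below background; clamped to 0",
            stacklevel=2,
        )
    return corrected


def estimate_pcrit_llo(
    trace: OxygenTrace,
    rmr_mg_o2_per_h: float,
    normoxia_percent_sat: float = 100.0,
    bin_width_percent_sat: float = 2.0,
) -> PcritResult:
    """Critical oxygen tension by the LLO method.

    MO2 is computed per consecutive PO2 bin of a closed-chamber drawdown
    (OLS slope of the samples whose saturation falls in the bin).  The
    reference line runs from RMR at normoxia to zero at anoxia,
    L(P) = RMR · P / normoxia.  P_crit is the linearly interpolated PO2
    of the highest crossing where binned MO2 drops below L(P) and stays
    below through the end of the drawdown.  If MO2 never drops below the
    line the result is flagged undefined (P_crit is then below the lowest
    observed PO2).
    """
    if rmr_mg_o2_per_h <= 0:
        raise ValueError("RMR must be positive")
    y = trace.o2_percent_sat
    t = trace.time_s
    if y.size < 10:
        raise ValueError("drawdown trace too short")
    # bin edges descend from the trace's starting O2
    top = float(y.max())
    edges = np.arange(top, float(y.min()) - bin_width_percent_sat, -bin_width_percent_sat)
    centers, mo2s = [], []
    for hi, lo in zip(edges[:-1], edges[1:]):
        mask = (y <= hi) & (y > lo)
        if mask.sum() < 3:
            continue
        slope, _ = fit_segment_slope(t[mask], y[mask])
        mo2 = compute_mo2(
            slope, trace.system_volume_l, trace.fish_mass_g, trace.temperature_c
        )
        centers.append(float(y[mask].mean()))
        mo2s.append(mo2)
    if len(centers) < 2:
        raise ValueError("too few PO2 bins with enough samples")
    p = np.asarray(centers)  # descending
    m = np.asarray(mo2s)
    line = rmr_mg_o2_per_h * p / normoxia_percent_sat
    # guard band of 0.1% of RMR: finite-bin curvature bias on an exact
    # oxyconformer is an order of magnitude smaller, while any real
    # post-P_crit conformity drop is orders of magnitude larger
    below = m < line - 1e-3 * rmr_mg_o2_per_h
    if not below[-1]:
        # never (terminally) below the line: undefined
        return PcritResult(
            pcrit_percent_sat=float("nan"),
            defined=False,
            lowest_po2_percent_sat=float(y.min()),
            n_bins=p.size,
        )
    # highest crossing that stays below to the end
    j = int(np.nonzero(~below)[0][-1]) + 1 if not below.all() else 0
    if j == 0:
        # below the line from the first bin onward
        pcrit = float(p[0])
    else:
        d0 = m[j - 1] - line[j - 1]  # >= 0
        d1 = m[j] - line[j]  # < 0
        frac = d0 / (d0 - d1)
        pcrit = float(p[j - 1] + frac * (p[j] - p[j - 1]))
    return PcritResult(
        pcrit_percent_sat=pcrit,
        defined=True,
        lowest_po2_percent_sat=float(y.min()),
        n_bins=p.size,
    )
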