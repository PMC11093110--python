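"""Synthetic cohorts, oxygen traces and gill tables with known truth.

Every downstream stage of the pipeline (respirometry, gill morphometry,
allometric inference) can be exercised end-to-end without laboratory
data: this module simulates a two-temperature rearing experiment in
which each fish carries *latent* (ground-truth) traits drawn from
configurable power laws of its body mass,

    y = 10^a · M^b · 10^eps,   eps ~ Normal(0, sd_log10),

and then renders those latent traits into the raw observables the
pipeline actually ingests — bin-level gill measurements and 1 Hz
dissolved-oxygen traces.  At zero noise the rendered observables invert
exactly (to float precision), which is the basis of the round-trip
tests; at realistic noise, fitted slopes should recover the configured
truth within their confidence intervals.

Determinism: one global integer seed; every fish's random stream is
derived from (seed, fish identity), so subsetting a cohort never
changes another fish's data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gillscale.respirometry import OxygenTrace, o2_solubility_mg_per_l

__all__ = [
    "CohortConfig",
    "ScalingTruth",
    "TraceConfig",
    "generate_cohort",
    "generate_gill_bins",
    "generate_trace",
]


def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


@dataclass(frozen=True)
class CohortConfig:
    """Design of the simulated rearing experiment.

    Defaults emulate a cold-water salmonid cohort started at
    2.62 ± 0.80 g and grown for six months at an optimal (15°C) and an
    elevated (20°C) temperature, with lethal sampling of a subset at
    each timepoint.  Growth is exponential with a specific growth rate
    that declines linearly with age and is penalised at elevated
    temperature (the temperature–size-rule pattern).
    """

    n_per_temperature: int = 36
    temperatures: tuple[float, ...] = (15.0, 20.0)
    timepoints_days: tuple[int, ...] = (14, 90, 180)
    initial_mass_mean_g: float = 2.62
    initial_mass_sd_g: float = 0.80
    sgr_base_percent_per_day: float = 3.0
    sgr_age_decay_per_day: float = 0.0033
    sgr_temperature_penalty: float = 0.044  # fractional SGR loss per degC above ref
    reference_temperature_c: float = 15.0
    mass_noise_sd_log10: float = 0.02
    trait_noise_sd_log10: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_temperature < 2:
            raise ValueError("need at least 2 fish per temperature")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")
        for name in (
            "initial_mass_mean_g",
            "initial_mass_sd_g",
            "sgr_base_percent_per_day",
            "sgr_age_decay_per_day",
            "sgr_temperature_penalty",
            "mass_noise_sd_log10",
            "trait_noise_sd_log10",
        ):
            _check_finite(name, getattr(self, name))
        if self.initial_mass_sd_g < 0 or self.mass_noise_sd_log10 < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.trait_noise_sd_log10 < 0:
            raise ValueError("trait noise sd must be >= 0")


@dataclass(frozen=True)
class ScalingTruth:
    """True allometric parameters of the simulated traits.

    Slopes are dimensionless exponents of mass; intercepts are log10
    values at 1 g.  The gill-component slopes are constrained to sum to
    the GSA slope (GSA is an exact product of its components), and the
    per-fish component noise terms likewise sum to the GSA noise term,
    so slope decomposition is exact all the way down.

    Scenario presets encode the competing gill-oxygen-limitation
    predictions: under scenario 1 geometric constraints cap both GSA and
    metabolic-rate scaling at a common b < 1; under scenario 2 metabolic
    rate outscales GSA (b_MR > b_GSA, i.e. b_S < 0); under the null
    (supply-keeps-pace) scenario b_GSA >= b_MR.
    """

    b_gsa: float = 0.97
    b_rmr: float = 0.87
    b_mmr: float = 0.94
    a_gsa: float = 2.40  # log10 mm^2 at 1 g
    a_rmr: float = -0.82  # log10 mg O2/h at 1 g
    a_mmr: float = -0.22
    b_lfil: float = 0.454
    b_nlam: float = -0.036
    b_alam: float = 0.552
    a_lfil: float = 2.70  # log10 mm at 1 g
    a_nlam: float = 1.60  # log10 mm^-1 at 1 g
    pcrit_base_percent_sat: float = 25.0
    pcrit_per_degree: float = 0.8
    scenario: str = "null"

    def __post_init__(self) -> None:
        for name in ("b_gsa", "b_rmr", "b_mmr", "a_gsa", "a_rmr", "a_mmr"):
            _check_finite(name, getattr(self, name))
        if abs(self.b_lfil + self.b_nlam + self.b_alam - self.b_gsa) > 1e-12:
            raise ValueError(
                "component slopes must sum to b_gsa: "
                f"{self.b_lfil} + {self.b_nlam} + {self.b_alam} != {self.b_gsa}"
            )
        if self.scenario not in ("null", "gol_scenario1", "gol_scenario2"):
            raise ValueError(f"unknown scenario tag {self.scenario!r}")

    @property
    def a_alam(self) -> float:
        """Component intercepts also sum to the GSA intercept."""
        return self.a_gsa - self.a_lfil - self.a_nlam

    @classmethod
    def null_scenario(cls) -> "ScalingTruth":
        """Supply keeps pace with demand: b_GSA >= b_MR (b_S >= 0)."""
        return cls(scenario="null")

    @classmethod
    def gol_scenario1(cls) -> "ScalingTruth":
        """Common geometric cap: b_GSA < 1 with b_MR tracking b_GSA."""
        return cls(
            b_gsa=0.80,
            b_rmr=0.80,
            b_mmr=0.80,
            b_lfil=0.40,
            b_nlam=-0.10,
            b_alam=0.50,
            scenario="gol_scenario1",
        )

    @classmethod
    def gol_scenario2(cls) -> "ScalingTruth":
        """Demand outscales supply: b_MR > b_GSA (b_S < 0)."""
        return cls(
            b_gsa=0.75,
            b_rmr=0.90,
            b_mmr=0.95,
            b_lfil=0.35,
            b_nlam=-0.10,
            b_alam=0.50,
            scenario="gol_scenario2",
        )

    @classmethod
    def preset(cls, name: str) -> "ScalingTruth":
        presets = {
            "null": cls.null_scenario,
            "gol_scenario1": cls.gol_scenario1,
            "gol_scenario2": cls.gol_scenario2,
        }
        try:
            return presets[name]()
        except KeyError:
            raise ValueError(f"unknown scenario preset {name!r}") from None


@dataclass(frozen=True)
class TraceConfig:
    """Respirometry protocol parameters for trace simulation."""

    sample_rate_hz: float = 1.0
    flush_s: float = 240.0
    wait_s: float = 60.0
    measure_s: float = 300.0
    n_cycles: int = 12
    system_volume_l: float = 0.657
    background_rate_start: float = 0.0  # mg O2/h at trace start
    background_rate_end: float = 0.0  # mg O2/h at trace end
    o2_noise_sd_percent_sat: float = 0.0
    diel_amplitude_frac: float = 0.30  # peak activity excess over RMR
    diel_period_s: float = 86400.0
    mmr_plateau_s: float = 90.0  # post-chase window at full MMR
    mmr_decay_tau_s: float = 300.0  # recovery time constant toward RMR
    mmr_duration_s: float = 600.0
    drawdown_floor_percent_sat: float = 5.0  # simulated loss-of-equilibrium
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_rate_hz", "flush_s", "wait_s", "measure_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.system_volume_l <= 0:
            raise ValueError("system volume must be positive")
        if self.o2_noise_sd_percent_sat < 0:
            raise ValueError("noise sd must be >= 0")
        for name in ("background_rate_start", "background_rate_end"):
            _check_finite(name, getattr(self, name))

    @property
    def cycle_s(self) -> float:
        return self.flush_s + self.wait_s + self.measure_s


def _fish_rng(seed: int, fish_id: str) -> np.random.Generator:
    """Per-fish random stream: stable hash of (seed, fish id)."""
    return np.random.default_rng([seed, zlib.crc32(fish_id.encode("utf-8"))])


def _mass_at(
    t_days: float, m0: float, temperature_c: float, cfg: CohortConfig
) -> float:
    """Exponential growth; SGR declines linearly with age and with
    temperature above the reference (closed-form mass integral)."""
    penalty = 1.0 - cfg.sgr_temperature_penalty * (
        temperature_c - cfg.reference_temperature_c
    )
    s0 = cfg.sgr_base_percent_per_day * max(penalty, 0.0)
    decay = cfg.sgr_age_decay_per_day
    t_star = min(t_days, 1.0 / decay) if decay > 0 else t_days
    integral = s0 * (t_star - 0.5 * decay * t_star**2)
    return m0 * np.exp(integral / 100.0)


def generate_cohort(config: CohortConfig, truth: ScalingTruth) -> pd.DataFrame:
    """Simulate the cohort: one row per fish per timepoint.

    Columns: identity (``fish_id, temperature_c, timepoint_days``),
    observables (``mass_g, fork_length_mm``), the lethal-sampling flag
    ``is_sampled`` (each fish is assigned one sampling timepoint,
    balanced within temperature), and latent ground-truth traits
    (``latent_rmr/_mmr`` in mg O2 h⁻¹, ``latent_gsa/_lfil/_nlam/_alam``,
    ``latent_pcrit_percent_sat``).

    Latent gill-component noise terms are drawn so they sum to the GSA
    noise term, keeping GSA = L_fil · n_lam · A_lam exact per fish.
    """
    rows = []
    sd = config.trait_noise_sd_log10
    comp_sd = sd / np.sqrt(3.0)
    for ti, temp in enumerate(config.temperatures):
        for fi in range(config.n_per_temperature):
            fish_id = f"T{temp:g}_F{fi:03d}"
            rng = _fish_rng(config.seed, fish_id)
            m0 = float(
                np.clip(
                    rng.normal(config.initial_mass_mean_g, config.initial_mass_sd_g),
                    0.2,
                    None,
                )
            )
            k_cond = rng.normal(1.0, 0.05)
            sampled_tp = config.timepoints_days[fi % len(config.timepoints_days)]
            for t_days in config.timepoints_days:
                mass = _mass_at(t_days, m0, temp, config) * 10.0 ** rng.normal(
                    0.0, config.mass_noise_sd_log10
                )
                logm = np.log10(mass)
                e_lfil = rng.normal(0.0, comp_sd)
                e_nlam = rng.normal(0.0, comp_sd)
                e_alam = rng.normal(0.0, comp_sd)
                e_gsa = e_lfil + e_nlam + e_alam
                e_rmr = rng.normal(0.0, sd)
                e_mmr = rng.normal(0.0, sd)
                lfil = 10.0 ** (truth.a_lfil + truth.b_lfil * logm + e_lfil)
                nlam = 10.0 ** (truth.a_nlam + truth.b_nlam * logm + e_nlam)
                alam = 10.0 ** (truth.a_alam + truth.b_alam * logm + e_alam)
                length_cm = (100.0 * mass / max(k_cond, 0.5)) ** (1.0 / 3.085)
                rows.append(
                    {
                        "fish_id": fish_id,
                        "temperature_c": float(temp),
                        "timepoint_days": int(t_days),
                        "mass_g": mass,
                        "fork_length_mm": 10.0 * length_cm,
                        "is_sampled": t_days == sampled_tp,
                        "latent_rmr_mg_o2_per_h": 10.0
                        ** (truth.a_rmr + truth.b_rmr * logm + e_rmr),
                        "latent_mmr_mg_o2_per_h": 10.0
                        ** (truth.a_mmr + truth.b_mmr * logm + e_mmr),
                        "latent_gsa_mm2": 10.0
                        ** (truth.a_gsa + truth.b_gsa * logm + e_gsa),
                        "latent_lfil_mm": lfil,
                        "latent_nlam_per_mm": nlam,
                        "latent_alam_mm2": alam,
                        "latent_pcrit_percent_sat": truth.pcrit_base_percent_sat
                        + truth.pcrit_per_degree
                        * (temp - config.reference_temperature_c)
                        + rng.normal(0.0, 1.0),
                    }
                )
    return pd.DataFrame(rows)


def generate_gill_bins(
    fish: pd.Series | dict,
    truth: ScalingTruth | None = None,
    noise_sd_log10: float = 0.0,
    seed: int = 0,
    reference_hemibranch: int = 4,
) -> pd.DataFrame:
    """Render one fish's latent gill components as a bin-level table.

    Eight right-side hemibranchs, 5–7 bins each, ~12 filaments per bin.
    Raw per-bin values are drawn with realistic scatter and then rescaled
    so the aggregation pipeline recovers the latent ``L_fil``, ``n_lam``
    and ``A_lam`` exactly at zero measurement noise; with
    ``noise_sd_log10 > 0`` every recorded cell is perturbed by an
    independent lognormal measurement error.  Lamellar measurements are
    made only on the reference hemibranch (NaN elsewhere), matching the
    dissection protocol.
    """
    fish_id = str(fish["fish_id"])
    lfil = float(fish["latent_lfil_mm"])
    nlam = float(fish["latent_nlam_per_mm"])
    alam = float(fish["latent_alam_mm2"])
    if not (lfil > 0 and nlam > 0 and alam > 0):
        raise ValueError(f"{fish_id}: latent gill components must be positive")
    if noise_sd_log10 < 0:
        raise ValueError("noise sd must be >= 0")
    rng = _fish_rng(seed, "gill:" + fish_id)

    hemis, bin_ids, counts, raw_lens = [], [], [], []
    for h in range(1, 9):
        n_bins = int(rng.integers(5, 8))
        for b in range(1, n_bins + 1):
            hemis.append(h)
            bin_ids.append(b)
            counts.append(int(rng.integers(10, 15)))
            raw_lens.append(float(rng.uniform(0.5, 1.5)))
    hemis = np.array(hemis)
    counts = np.array(counts, dtype=float)
    raw_lens = np.array(raw_lens)
    # rescale lengths so 2 * sum(count * length) == latent L_fil exactly
    lens = raw_lens * (lfil / 2.0) / float(np.sum(counts * raw_lens))

    ref = hemis == reference_hemibranch
    bin_len_ref = counts[ref] * lens[ref]
    # one-sided frequencies: length-weighted mean must equal n_lam / 2
    raw_f = rng.uniform(0.8, 1.2, ref.sum())
    f = raw_f * (nlam / 2.0) / (
        float(np.sum(raw_f * bin_len_ref)) / float(np.sum(bin_len_ref))
    )
    split = rng.uniform(0.0, 0.15, ref.sum())
    freq_base = f * (1.0 + split)
    freq_tip = f * (1.0 - split)
    # bilateral areas: lamellae-count-weighted mean must equal A_lam
    w = f * bin_len_ref
    raw_a = rng.uniform(0.8, 1.2, ref.sum())
    a = raw_a * alam / (float(np.sum(raw_a * w)) / float(np.sum(w)))
    taper = rng.uniform(0.0, 0.2, ref.sum())
    area_tip = a * (1.0 - taper)
    area_mid = a.copy()
    area_base = a * (1.0 + taper)

    n = len(hemis)
    table = pd.DataFrame(
        {
            "fish_id": fish_id,
            "hemibranch_id": hemis,
            "bin_id": bin_ids,
            "filament_count": counts.astype(int),
            "median_filament_length_mm": lens,
            "lamellar_freq_base_per_mm": np.full(n, np.nan),
            "lamellar_freq_tip_per_mm": np.full(n, np.nan),
            "lamellar_area_tip_mm2": np.full(n, np.nan),
            "lamellar_area_mid_mm2": np.full(n, np.nan),
            "lamellar_area_base_mm2": np.full(n, np.nan),
        }
    )
    table.loc[ref, "lamellar_freq_base_per_mm"] = freq_base
    table.loc[ref, "lamellar_freq_tip_per_mm"] = freq_tip
    table.loc[ref, "lamellar_area_tip_mm2"] = area_tip
    table.loc[ref, "lamellar_area_mid_mm2"] = area_mid
    table.loc[ref, "lamellar_area_base_mm2"] = area_base

    if noise_sd_log10 > 0:
        for col in (
            "median_filament_length_mm",
            "lamellar_freq_base_per_mm",
            "lamellar_freq_tip_per_mm",
            "lamellar_area_tip_mm2",
            "lamellar_area_mid_mm2",
            "lamellar_area_base_mm2",
        ):
            table[col] = table[col] * 10.0 ** rng.normal(0.0, noise_sd_log10, n)
    return table


def _depletion_slope(
    mo2_mg_per_h: float, v_eff_l: float, temperature_c: float
) -> float:
    """%-saturation per second corresponding to a chamber-wide uptake rate."""
    sol = o2_solubility_mg_per_l(temperature_c)
    return -mo2_mg_per_h / (sol * v_eff_l * 3600.0) * 100.0


def generate_trace(
    fish: pd.Series | dict,
    config: TraceConfig,
    kind: str,
    temperature_c: float | None = None,
) -> OxygenTrace:
    """Simulate one respirometry trace for one fish.

    ``kind`` selects the protocol:

    ``"rmr"``
        Intermittent-flow sawtooth of flush/wait/measure cycles.  The
        measure-phase depletion slope of cycle *i* encodes
        RMR · (1 + diel(t_i)) plus the interpolated background rate,
        where diel is a non-negative half-rectified sinusoid (zero for
        half of each period), so the lowest-quartile estimator targets
        the latent RMR.  Wait phases are rendered with a quadratic
        mixing-lag curvature; flush phases sit at normoxia.
    ``"mmr_chase"``
        Closed chamber post-chase: uptake holds at latent MMR for a
        plateau (≥ the rolling window), then decays exponentially toward
        latent RMR.
    ``"pcrit_drawdown"``
        Closed-chamber drawdown with MO2(P) = RMR above the latent
        P_crit and RMR·(P/P_crit)² below it (oxyconforming), integrated
        at the sample rate until the loss-of-equilibrium floor.
    """
    fish_id = str(fish["fish_id"])
    temp = float(
        temperature_c if temperature_c is not None else fish["temperature_c"]
    )
    mass = float(fish["mass_g"])
    rmr = float(fish["latent_rmr_mg_o2_per_h"])
    v_eff = config.system_volume_l - mass / 1000.0
    if v_eff <= 0:
        raise ValueError(f"{fish_id}: fish does not fit in the chamber")
    rng = _fish_rng(config.seed, f"trace:{kind}:{fish_id}")
    dt = 1.0 / config.sample_rate_hz

    if kind == "rmr":
        n = int(round(config.n_cycles * config.cycle_s * config.sample_rate_hz))
        t = np.arange(n) * dt
        o2 = np.full(n, 100.0)
        duration = n * dt
        for i in range(config.n_cycles):
            c0 = i * config.cycle_s
            wait_start = c0 + config.flush_s
            meas_start = wait_start + config.wait_s
            cycle_end = c0 + config.cycle_s
            diel = config.diel_amplitude_frac * max(
                0.0, np.sin(2.0 * np.pi * meas_start / config.diel_period_s)
            )
            frac = meas_start / duration
            background = config.background_rate_start + frac * (
                config.background_rate_end - config.background_rate_start
            )
            mo2 = rmr * (1.0 + diel) + max(background, 0.0)
            slope = _depletion_slope(mo2, v_eff, temp)
            in_wait = (t >= wait_start) & (t < meas_start)
            in_meas = (t >= meas_start) & (t < cycle_end)
            # mixing lag: slope ramps in linearly over the wait phase
            tw = t[in_wait] - wait_start
            o2[in_wait] = 100.0 + 0.5 * slope * tw**2 / config.wait_s
            o2_meas_start = 100.0 + 0.5 * slope * config.wait_s
            o2[in_meas] = o2_meas_start + slope * (t[in_meas] - meas_start)
    elif kind == "mmr_chase":
        mmr = float(fish["latent_mmr_mg_o2_per_h"])
        n = int(round(config.mmr_duration_s * config.sample_rate_hz))
        t = np.arange(n) * dt
        elapsed = np.where(
            t <= config.mmr_plateau_s,
            0.0,
            t - config.mmr_plateau_s,
        )
        mo2_t = rmr + (mmr - rmr) * np.where(
            t <= config.mmr_plateau_s,
            1.0,
            np.exp(-elapsed / config.mmr_decay_tau_s),
        )
        slopes = _depletion_slope(1.0, v_eff, temp) * mo2_t
        o2 = 100.0 + np.concatenate([[0.0], np.cumsum(slopes[:-1] * dt)])
    elif kind == "pcrit_drawdown":
        pc = float(fish["latent_pcrit_percent_sat"])
        if not pc > 0:
            raise ValueError(f"{fish_id}: latent P_crit must be positive")
        unit = -_depletion_slope(1.0, v_eff, temp)  # % sat/s per (mg O2/h)
        floor = config.drawdown_floor_percent_sat
        max_n = int(24 * 3600 * config.sample_rate_hz)
        o2_list = [100.0]
        p = 100.0
        while p > floor and len(o2_list) < max_n:
            mo2 = rmr if p >= pc else rmr * (p / pc) ** 2
            p = p - unit * mo2 * dt
            o2_list.append(p)
        o2 = np.array(o2_list)
        t = np.arange(o2.size) * dt
    else:
        raise ValueError(
            f"unknown trace kind {kind!r}; expected rmr, mmr_chase or "
            "pcrit_drawdown"
        )

    if config.o2_noise_sd_percent_sat > 0:
        o2 = o2 + rng.normal(0.0, config.o2_noise_sd_percent_sat, o2.size)
    return OxygenTrace(
        fish_id=fish_id,
        temperature_c=temp,
        time_s=t,
        o2_percent_sat=o2,
        system_volume_l=config.system_volume_l,
        fish_mass_g=mass,
    )


def ground_truth_sidecar(config: CohortConfig, truth: ScalingTruth) -> dict:
    """JSON-serialisable record of the generating parameters."""
    return {
        "cohort": {
            "n_per_temperature": config.n_per_temperature,
            "temperatures": list(config.temperatures),
            "timepoints_days": list(config.timepoints_days),
            "seed": config.seed,
            "trait_noise_sd_log10": config.trait_noise_sd_log10,
        },
        "truth": {
            "scenario": truth.scenario,
            "b_gsa": truth.b_gsa,
            "b_rmr": truth.b_rmr,
            "b_mmr": truth.b_mmr,
            "b_lfil": truth.b_lfil,
            "b_nlam": truth.b_nlam,
            "b_alam": truth.b_alam,
            "a_gsa": truth.a_gsa,
            "a_rmr": truth.a_rmr,
            "a_mmr": truth.a_mmr,
        },
    }
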