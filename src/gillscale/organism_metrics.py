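"""Growth and condition metrics: SGR, relative condition factor, fold change."""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import pandas as pd

#: Length–mass exponent for the relative condition factor, estimated from
#: the study cohort's fork-length/mass regression.
DEFAULT_CONDITION_EXPONENT = 3.085


@dataclass(frozen=True)
class GrowthInterval:
    """Body masses of one fish at the ends of a time interval (days)."""

    fish_id: str
    t1_days: float
    t2_days: float
    m1_g: float
    m2_g: float

    def __post_init__(self) -> None:
        if not self.t2_days > self.t1_days:
            raise ValueError(
                f"{self.fish_id}: t2 ({self.t2_days}) must exceed t1 ({self.t1_days})"
            )
        if self.m1_g <= 0 or self.m2_g <= 0:
            raise ValueError(f"{self.fish_id}: masses must be positive")


def specific_growth_rate(interval: GrowthInterval) -> float:
    """Specific growth rate in % body mass per day.

    SGR = 100 · (ln M2 − ln M1) / (t2 − t1): the instantaneous relative
    growth rate under exponential growth, averaged over the interval.
    """
    return 100.0 * (log(interval.m2_g) - log(interval.m1_g)) / (
        interval.t2_days - interval.t1_days
    )


def condition_factor(
    mass_g: float,
    fork_length_cm: float,
    exponent: float = DEFAULT_CONDITION_EXPONENT,
) -> float:
    """Relative condition factor K = 100 · M / L^exponent (L in cm).

    With ``exponent=3`` this is Fulton's K; the default exponent comes
    from the cohort's own length–mass allometry so that K is
    size-independent for a typically proportioned fish.
    """
    if mass_g <= 0:
        raise ValueError(f"mass must be positive, got {mass_g}")
    if fork_length_cm <= 0:
        raise ValueError(f"fork length must be positive, got {fork_length_cm}")
    return 100.0 * mass_g / fork_length_cm**exponent


def fold_change(final_mean_g: float, initial_mean_g: float) -> float:
    """Ratio of final to initial mean body mass (dimensionless)."""
    if final_mean_g <= 0 or initial_mean_g <= 0:
        raise ValueError("means must be positive")
    return final_mean_g / initial_mean_g


def sgr_table(fish: pd.DataFrame) -> pd.DataFrame:
    """Per-fish SGR over consecutive timepoints of a longitudinal table.

    Expects columns ``fish_id, timepoint_days, mass_g`` (extra columns are
    carried through from the first row of each interval's fish).
    """
    required = {"fish_id", "timepoint_days", "mass_g"}
    missing = required - set(fish.columns)
    if missing:
        raise ValueError(f"fish table missing columns: {sorted(missing)}")
    rows = []
    for fish_id, sub in fish.groupby("fish_id", sort=True):
        sub = sub.sort_values("timepoint_days")
        for (_, a), (_, b) in zip(sub.iterrows(), sub.iloc[1:].iterrows()):
            iv = GrowthInterval(
                fish_id=str(fish_id),
                t1_days=float(a["timepoint_days"]),
                t2_days=float(b["timepoint_days"]),
                m1_g=float(a["mass_g"]),
                m2_g=float(b["mass_g"]),
            )
            row = {
                "fish_id": fish_id,
                "t1_days": iv.t1_days,
                "t2_days": iv.t2_days,
                "m1_g": iv.m1_g,
                "m2_g": iv.m2_g,
                "sgr_percent_per_day": specific_growth_rate(iv),
            }
            if "temperature_c" in sub.columns:
                row["temperature_c"] = a["temperature_c"]
            rows.append(row)
    return pd.DataFrame(rows)


def treatment_summary(fish: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd, s.e.m. and n of mass per temperature × timepoint."""
    required = {"temperature_c", "timepoint_days", "mass_g"}
    missing = required - set(fish.columns)
    if missing:
        raise ValueError(f"fish table missing columns: {sorted(missing)}")
    g = fish.groupby(["temperature_c", "timepoint_days"])["mass_g"]
    out = g.agg(mean_mass_g="mean", sd_mass_g="std", n="count").reset_index()
    out["sem_mass_g"] = out["sd_mass_g"] / out["n"] ** 0.5
    return out
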