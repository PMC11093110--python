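"""CSV readers/writers and YAML run configuration.

All tabular interchange is plain CSV (UTF-8, '.' decimal).  Readers
validate eagerly and report offending rows by number; writers emit
floats at six significant digits.

Schemas
-------
fish records
    ``fish_id, temperature_c, timepoint_days, mass_g[, fork_length_mm,
    is_sampled, latent_*]``
oxygen traces (long format)
    ``fish_id, time_s, o2_percent_sat[, phase, chamber_id]`` plus either
    per-row ``temperature_c, system_volume_l, fish_mass_g`` or a
    separate fish-metadata table passed to the reader.
gill bins
    ``fish_id, hemibranch_id, bin_id, filament_count,
    median_filament_length_mm, lamellar_freq_base_per_mm,
    lamellar_freq_tip_per_mm, lamellar_area_tip_mm2,
    lamellar_area_mid_mm2, lamellar_area_base_mm2`` (lamellar columns
    may be empty off the reference hemibranch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gillscale.respirometry import OxygenTrace

FLOAT_FORMAT = "%.6g"

FISH_REQUIRED = ["fish_id", "temperature_c", "timepoint_days", "mass_g"]
TRACE_REQUIRED = ["fish_id", "time_s", "o2_percent_sat"]
GILL_REQUIRED = [
    "fish_id",
    "hemibranch_id",
    "bin_id",
    "filament_count",
    "median_filament_length_mm",
]
GILL_LAMELLAR = [
    "lamellar_freq_base_per_mm",
    "lamellar_freq_tip_per_mm",
    "lamellar_area_tip_mm2",
    "lamellar_area_mid_mm2",
    "lamellar_area_base_mm2",
]


class ValidationError(ValueError):
    """A CSV or config failed validation; message names the offenders."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return df


def _require_numeric(
    df: pd.DataFrame, columns: list[str], name: str, allow_nan: bool = False
) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() if allow_nan else vals.isna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:10]  # 1-based incl. header
            raise ValidationError(
                f"{name}: non-numeric values in column {col!r} at file rows {rows}"
            )
        df[col] = vals


def read_fish(path: str | Path) -> pd.DataFrame:
    """Read and validate a fish-record table."""
    df = _read_csv(path, FISH_REQUIRED)
    name = Path(path).name
    _require_numeric(df, ["temperature_c", "timepoint_days", "mass_g"], name)
    bad = df.index[df["mass_g"] <= 0]
    if len(bad):
        raise ValidationError(
            f"{name}: non-positive mass at file rows {(bad + 2).tolist()}"
        )
    dup = df.duplicated(subset=["fish_id", "timepoint_days"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise ValidationError(
            f"{name}: duplicate fish_id x timepoint at file rows {rows}"
        )
    return df


def read_gills(path: str | Path) -> pd.DataFrame:
    """Read and validate a bin-level gill table."""
    df = _read_csv(path, GILL_REQUIRED)
    name = Path(path).name
    for col in GILL_LAMELLAR:
        if col not in df.columns:
            df[col] = np.nan
    _require_numeric(
        df,
        ["hemibranch_id", "bin_id", "filament_count", "median_filament_length_mm"],
        name,
    )
    _require_numeric(df, GILL_LAMELLAR, name, allow_nan=True)
    bad = df.index[df["filament_count"] < 1]
    if len(bad):
        raise ValidationError(
            f"{name}: filament_count < 1 at file rows {(bad + 2).tolist()}"
        )
    bad = df.index[df["median_filament_length_mm"] <= 0]
    if len(bad):
        raise ValidationError(
            f"{name}: non-positive filament length at file rows {(bad + 2).tolist()}"
        )
    return df


def read_traces(
    path: str | Path, fish_meta: pd.DataFrame | None = None
) -> list[OxygenTrace]:
    """Read a long-format trace table into per-fish :class:`OxygenTrace`.

    Chamber geometry and temperature come either from per-row columns
    (``temperature_c, system_volume_l, fish_mass_g``) or from a fish
    metadata table with those columns indexed by ``fish_id``.
    """
    df = _read_csv(path, TRACE_REQUIRED)
    name = Path(path).name
    _require_numeric(df, ["time_s", "o2_percent_sat"], name)
    return traces_from_frame(df, fish_meta, name=name)


def traces_from_frame(
    df: pd.DataFrame,
    fish_meta: pd.DataFrame | None = None,
    name: str = "traces",
) -> list[OxygenTrace]:
    """Group a validated long-format trace frame into per-fish traces."""
    meta_cols = ["temperature_c", "system_volume_l", "fish_mass_g"]
    inline = all(c in df.columns for c in meta_cols)
    if not inline and fish_meta is None:
        raise ValidationError(
            f"{name}: needs columns {meta_cols} or a fish metadata table"
        )
    traces = []
    for fish_id, sub in df.groupby("fish_id", sort=True):
        sub = sub.sort_values("time_s")
        if inline:
            temp = float(sub["temperature_c"].iloc[0])
            vol = float(sub["system_volume_l"].iloc[0])
            mass = float(sub["fish_mass_g"].iloc[0])
        else:
            row = fish_meta[fish_meta["fish_id"] == fish_id]
            if len(row) == 0:
                raise ValidationError(f"{name}: no metadata for fish {fish_id!r}")
            row = row.iloc[0]
            temp = float(row["temperature_c"])
            vol = float(row["system_volume_l"])
            mass = float(row["mass_g"] if "mass_g" in row else row["fish_mass_g"])
        traces.append(
            OxygenTrace(
                fish_id=str(fish_id),
                temperature_c=temp,
                time_s=sub["time_s"].to_numpy(),
                o2_percent_sat=sub["o2_percent_sat"].to_numpy(),
                system_volume_l=vol,
                fish_mass_g=mass,
                phase=sub["phase"].to_numpy() if "phase" in sub.columns else None,
            )
        )
    return traces


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV with floats at six significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# --------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class ChamberSpec:
    """Respirometer geometry and cycle timing for one sampling timepoint."""

    timepoint_days: int
    system_volume_l: float
    flush_s: float = 240.0
    wait_s: float = 60.0
    measure_s: float = 300.0

    def __post_init__(self) -> None:
        if self.system_volume_l <= 0:
            raise ValidationError("chamber volume must be positive")


#: Chamber volumes used at the three sampling timepoints (litres):
#: prefabricated 0.657 and 0.727 L chambers for the 2-week and 3-month
#: fish, a 4.012 L custom chamber for the 6-month fish.
DEFAULT_CHAMBERS = (
    ChamberSpec(timepoint_days=14, system_volume_l=0.657),
    ChamberSpec(timepoint_days=90, system_volume_l=0.727),
    ChamberSpec(timepoint_days=180, system_volume_l=4.012),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one end-to-end run.

    Either the three input paths are set (real-data mode) or
    ``simulate`` is set (a dict with optional ``cohort``, ``truth`` /
    ``scenario`` and ``trace`` blocks); exactly one mode.
    """

    fish_csv: str | None = None
    traces_csv: str | None = None
    gills_csv: str | None = None
    simulate: dict | None = None
    chambers: tuple[ChamberSpec, ...] = DEFAULT_CHAMBERS
    reference_hemibranch: int = 4
    reference_mass_g: float = 24.0
    r2_threshold: float = 0.9
    mmr_window_s: float = 60.0
    background_correct_mmr: bool = True
    pcrit_bin_width: float = 2.0
    include_pcrit: bool = True
    output_dir: str = "gillscale_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        real = self.fish_csv is not None
        if real == (self.simulate is not None):
            raise ValidationError(
                "config must set either input CSV paths or a simulate block"
            )
        if self.reference_mass_g <= 0:
            raise ValidationError("reference mass must be positive")

    def chamber_for(self, timepoint_days: int) -> ChamberSpec:
        for c in self.chambers:
            if c.timepoint_days == timepoint_days:
                return c
        # nearest chamber if the timepoint is not an exact match
        return min(
            self.chambers, key=lambda c: abs(c.timepoint_days - timepoint_days)
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    if "chambers" in raw:
        raw["chambers"] = tuple(ChamberSpec(**c) for c in raw["chambers"])
    return RunConfig(**raw)
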