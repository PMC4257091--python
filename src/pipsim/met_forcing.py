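"""Synthetic half-hourly meteorology and forcing-file I/O.

The simulator is driven by a gap-free half-hourly series of air temperature,
photosynthetically active radiation (PAR), vapour pressure deficit (VPD),
precipitation and ambient CO2.  A single base year is generated from a small
set of climate targets (mean annual temperature, annual precipitation,
latitude, seasonality) and recycled for multi-year runs, which removes
interannual variability from disturbance experiments.

The generator is an emulator of a semi-arid, winter-wet conifer-site climate,
not a reconstruction of any particular tower record:

* temperature = seasonal sinusoid (minimum 15 Jan) + diurnal sinusoid
  (maximum 15:00 solar time) + AR(1) noise, re-centred exactly on the target
  mean;
* PAR = clear-sky photon flux from solar geometry at the given latitude,
  scaled by a stochastic daily clearness index that drops on rain days;
* precipitation = Bernoulli event occurrence per half-hour with
  gamma-distributed depths, an annual-cycle event rate that concentrates the
  configured fraction of rain in the winter half-year, and an exact final
  rescale to the annual total;
* VPD = saturation vapour pressure (Tetens) times (1 - relative humidity),
  with humidity anticorrelated with temperature and boosted during rain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClimateTarget",
    "generate_met",
    "read_met_csv",
    "write_met_csv",
    "validate_met",
    "STEPS_PER_DAY",
    "DAYS_PER_YEAR",
    "STEPS_PER_YEAR",
]

STEPS_PER_DAY = 48
DAYS_PER_YEAR = 365
STEPS_PER_YEAR = STEPS_PER_DAY * DAYS_PER_YEAR  # 17520
STEP_SECONDS = 1800.0

#: canonical column order of the met CSV schema
MET_COLUMNS = ["timestamp", "TA", "PAR", "VPD", "P", "CO2"]

#: accepted aliases for each canonical column (case-insensitive match)
COLUMN_ALIASES = {
    "timestamp": ("timestamp", "time", "datetime"),
    "TA": ("ta", "t_air", "tair", "temp"),
    "PAR": ("par", "ppfd"),
    "VPD": ("vpd",),
    "P": ("p", "precip", "rain"),
    "CO2": ("co2", "ca"),
}

_INTERNAL = {"TA": "t_air", "PAR": "par", "VPD": "vpd", "P": "precip", "CO2": "co2"}

# plausibility ranges used by the reader, unit sanity only
_RANGES = {
    "t_air": (-60.0, 60.0),
    "par": (0.0, 3000.0),
    "vpd": (0.0, 20.0),
    "precip": (0.0, 200.0),
    "co2": (100.0, 2000.0),
}


@dataclass(frozen=True)
class ClimateTarget:
    """Climate statistics the synthetic base year is generated to match.

    Defaults describe a cool, summer-dry temperate conifer site: mean annual
    temperature 7.3 degC, 550 mm annual precipitation, 70 % of it falling in
    the winter half-year.
    """

    mean_annual_temp: float = 7.3      # degC
    annual_precip: float = 550.0       # mm
    latitude: float = 44.45            # degrees N
    seasonal_temp_amplitude: float = 9.0   # degC, half-range of annual cycle
    diurnal_temp_amplitude: float = 5.0    # degC, half-range of daily cycle
    precip_seasonality: float = 0.7    # winter-half-year fraction of precip
    co2: float = 380.0                 # ppm, held constant
    seed: int = 42

    def __post_init__(self) -> None:
        if self.annual_precip < 0:
            raise ValueError("annual_precip must be non-negative")
        if not 0.0 <= self.precip_seasonality <= 1.0:
            raise ValueError("precip_seasonality must lie in [0, 1]")


def _solar_cos_zenith(doy: np.ndarray, hour: np.ndarray, latitude: float) -> np.ndarray:
    """Cosine of the solar zenith angle (negative below the horizon)."""
    decl = np.deg2rad(-23.45) * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0)
    lat = np.deg2rad(latitude)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    return np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)


def saturation_vapour_pressure(t_air):
    """Tetens formula, kPa, over liquid water."""
    t = np.asarray(t_air, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def _base_year(target: ClimateTarget) -> pd.DataFrame:
    rng = np.random.default_rng(target.seed)

    doy = np.repeat(np.arange(DAYS_PER_YEAR, dtype=float), STEPS_PER_DAY)
    hour = np.tile(np.arange(STEPS_PER_DAY, dtype=float) / 2.0, DAYS_PER_YEAR)

    # --- temperature -----------------------------------------------------
    seasonal = -target.seasonal_temp_amplitude * np.cos(2.0 * np.pi * (doy - 14.0) / 365.0)
    diurnal = target.diurnal_temp_amplitude * np.cos(2.0 * np.pi * (hour - 15.0) / 24.0)
    rho = 0.95
    innov = rng.normal(0.0, 2.0 * np.sqrt(1.0 - rho * rho), STEPS_PER_YEAR)
    noise = np.empty(STEPS_PER_YEAR)
    acc = 0.0
    for i in range(STEPS_PER_YEAR):
        acc = rho * acc + innov[i]
        noise[i] = acc
    t_air = target.mean_annual_temp + seasonal + diurnal + noise
    t_air += target.mean_annual_temp - t_air.mean()  # exact re-centring

    # --- precipitation ---------------------------------------------------
    # winter-half-year weighting: fraction = 0.5 + a/pi for a cosine-modulated
    # event rate, so a = pi * (seasonality - 0.5)
    a = np.clip(np.pi * (target.precip_seasonality - 0.5), -1.0, 1.0)
    rate = 0.03 * (1.0 + a * np.cos(2.0 * np.pi * (doy - 14.0) / 365.0))
    wet = rng.random(STEPS_PER_YEAR) < rate
    depths = rng.gamma(shape=0.7, scale=1.5, size=STEPS_PER_YEAR)
    precip = np.where(wet, depths, 0.0)
    total = precip.sum()
    if target.annual_precip == 0.0 or total == 0.0:
        precip = np.zeros(STEPS_PER_YEAR)
    else:
        precip *= target.annual_precip / total  # exact rescale

    # --- radiation -------------------------------------------------------
    cosz = _solar_cos_zenith(doy, hour, target.latitude)
    wet_day = np.repeat(
        precip.reshape(DAYS_PER_YEAR, STEPS_PER_DAY).sum(axis=1) > 0.0, STEPS_PER_DAY
    )
    clearness_day = np.clip(
        0.85 - 0.45 * wet_day + 0.10 * np.repeat(rng.normal(size=DAYS_PER_YEAR), STEPS_PER_DAY),
        0.15,
        1.0,
    )
    par = 1800.0 * np.clip(cosz, 0.0, None) * clearness_day

    # --- humidity and VPD ------------------------------------------------
    rh = (
        0.60
        + 0.20 * np.cos(2.0 * np.pi * (doy - 14.0) / 365.0)   # humid winters
        - 0.15 * np.cos(2.0 * np.pi * (hour - 15.0) / 24.0)   # dry afternoons
        + 0.05 * rng.normal(size=STEPS_PER_YEAR)
    )
    rh = np.where(precip > 0.0, rh + 0.25, rh)
    rh = np.clip(rh, 0.2, 1.0)
    vpd = saturation_vapour_pressure(t_air) * (1.0 - rh)

    timestamps = pd.date_range("2005-01-01", periods=STEPS_PER_YEAR, freq="30min")
    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "t_air": t_air,
            "par": par,
            "vpd": vpd,
            "precip": precip,
            "co2": np.full(STEPS_PER_YEAR, target.co2),
        }
    )


def generate_met(target: ClimateTarget, n_years: int = 1) -> pd.DataFrame:
    """Generate ``n_years`` of half-hourly forcing by recycling one base year.

    The base year is produced once from ``target`` (deterministically for a
    given seed) and duplicated, so all years beyond the first are identical
    to year one except for the calendar offset of their timestamps.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    base = _base_year(target)
    if n_years == 1:
        return base
    years = []
    for k in range(n_years):
        yr = base.copy()
        yr["timestamp"] = base["timestamp"] + pd.Timedelta(days=DAYS_PER_YEAR * k)
        years.append(yr)
    return pd.concat(years, ignore_index=True)


def validate_met(met: pd.DataFrame) -> pd.DataFrame:
    """Check the physical and structural invariants of a forcing series."""
    missing = [c for c in ("timestamp", "t_air", "par", "vpd", "precip", "co2") if c not in met]
    if missing:
        raise ValueError(f"met series missing columns: {missing}")
    dt = pd.Series(met["timestamp"]).diff().dropna()
    if len(dt) and not (dt == pd.Timedelta(seconds=STEP_SECONDS)).all():
        bad = dt.index[dt != pd.Timedelta(seconds=STEP_SECONDS)].tolist()[:5]
        raise ValueError(f"timestamps not strictly increasing at 1800 s; first bad rows: {bad}")
    for col in ("par", "vpd", "precip"):
        if (met[col] < 0).any():
            row = int(np.argmax(met[col].to_numpy() < 0))
            raise ValueError(f"negative {col} at row {row}")
    for col, (lo, hi) in _RANGES.items():
        vals = met[col].to_numpy()
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            rows = np.nonzero(bad)[0][:5].tolist()
            raise ValueError(
                f"{col} outside physical range [{lo}, {hi}] at rows {rows}"
            )
    return met


def write_met_csv(met: pd.DataFrame, path) -> None:
    """Write forcing to the canonical CSV schema (lossless round trip)."""
    out = pd.DataFrame(
        {
            "timestamp": pd.Series(met["timestamp"]).dt.strftime("%Y-%m-%d %H:%M:%S"),
            "TA": met["t_air"].to_numpy(),
            "PAR": met["par"].to_numpy(),
            "VPD": met["vpd"].to_numpy(),
            "P": met["precip"].to_numpy(),
            "CO2": met["co2"].to_numpy(),
        }
    )
    # repr-precision floats so a written series reads back bit-identically
    out.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def _resolve_columns(columns) -> dict:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canon, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [c for c in COLUMN_ALIASES if c not in resolved]
    if missing:
        raise ValueError(f"met CSV missing required columns: {missing}")
    return resolved


def read_met_csv(path, max_gap_steps: int = 3) -> pd.DataFrame:
    """Read and validate a half-hourly forcing CSV.

    Short runs of missing values (up to ``max_gap_steps`` consecutive rows
    per variable) are linearly interpolated; longer gaps raise an error that
    names the offending interval.  Column names are matched against a small
    set of conventional aliases.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    resolved = _resolve_columns(raw.columns)
    met = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(raw[resolved["timestamp"]]),
            "t_air": pd.to_numeric(raw[resolved["TA"]], errors="coerce"),
            "par": pd.to_numeric(raw[resolved["PAR"]], errors="coerce"),
            "vpd": pd.to_numeric(raw[resolved["VPD"]], errors="coerce"),
            "precip": pd.to_numeric(raw[resolved["P"]], errors="coerce"),
            "co2": pd.to_numeric(raw[resolved["CO2"]], errors="coerce"),
        }
    )
    for col in ("t_air", "par", "vpd", "precip", "co2"):
        isna = met[col].isna().to_numpy()
        if isna.any():
            # longest run of consecutive NaNs
            run = 0
            start = None
            for i, flag in enumerate(isna):
                if flag:
                    run += 1
                    if start is None:
                        start = i
                    if run > max_gap_steps:
                        t0 = met["timestamp"].iloc[start]
                        raise ValueError(
                            f"gap longer than {max_gap_steps} steps in column "
                            f"{col!r} starting row {start} ({t0})"
                        )
                else:
                    run = 0
                    start = None
            met[col] = met[col].interpolate(method="linear", limit_direction="both")
    return validate_met(met)
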