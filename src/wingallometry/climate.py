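"""Annual-cycle climate windows and the species-year covariate matrix G.

Windows are derived from collection phenology: the peak spring/autumn
migration period of a species is the mean ordinal collection date plus or
minus one sample s.d. (rounded to whole days, both ends inclusive); the
pre-breeding period is the 30 days following the end of the spring window;
breeding and wintering are the fixed calendar months June and December.

Daily series (CPC-style min/max temperature and precipitation, already
averaged over a species' range polygon) are aggregated as window means;
monthly products (GISS-style temperature anomalies relative to a 1951-1980
baseline, GPCP-style precipitation) supply the June/December values directly.
Minimum rather than mean temperature is aggregated over the migratory range
because these species migrate at night.

All covariates, and by default the year term, are standardized to mean 0 /
s.d. 1 within each species over the modelled year range, yielding the design
matrix G (one row per species-year: a constant column, the scaled climate
terms in model order, and scaled year) that drives the second level of the
allometry hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BREEDING_MONTH = 6
WINTERING_MONTH = 12
PREBREEDING_DAYS = 30

#: term base -> (range label, source, detail); "daily" detail is (window, stat),
#: "monthly" detail is (month, column).
TERM_DEFS: dict[str, tuple[str, str, tuple]] = {
    "wintering_temp": ("wintering", "monthly", (WINTERING_MONTH, "anomaly")),
    "wintering_precip": ("wintering", "monthly", (WINTERING_MONTH, "precip")),
    "breeding_temp": ("breeding", "monthly", (BREEDING_MONTH, "anomaly")),
    "breeding_precip": ("breeding", "monthly", (BREEDING_MONTH, "precip")),
    "prebreeding_temp": ("breeding", "daily", ("prebreeding", "mean_tmean")),
    "prebreeding_precip": ("breeding", "daily", ("prebreeding", "mean_precip")),
    "spring_temp": ("migratory", "daily", ("spring", "mean_tmin")),
    "autumn_temp": ("migratory", "daily", ("autumn", "mean_tmin")),
}

#: Human-readable labels relative to an autumn HY collection (lag in years).
TERM_LABELS = {
    ("wintering_temp", 1): "prior wintering temperature",
    ("wintering_precip", 1): "prior wintering precipitation",
    ("wintering_precip", 2): "prior wintering precipitation",
    ("prebreeding_temp", 0): "pre-breeding temperature",
    ("prebreeding_precip", 0): "pre-breeding precipitation",
    ("breeding_temp", 0): "most recent breeding temperature",
    ("breeding_precip", 0): "most recent breeding precipitation",
}


def _round_half_away(x):
    """Round to the nearest integer with ties away from zero."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class CovariateTerm:
    """A covariate of the allometry model: a seasonal variable at a year lag.

    Lag L for year y reads the seasonal value of calendar year y - L.
    """

    base: str
    lag: int = 0

    def __post_init__(self):
        if self.base != "year" and self.base not in TERM_DEFS:
            raise ValueError(
                f"unknown covariate base {self.base!r}; known: {sorted(TERM_DEFS)}"
            )
        if self.lag < 0:
            raise ValueError("lag must be >= 0")

    @property
    def name(self) -> str:
        return self.base if self.lag == 0 else f"{self.base}_lag{self.lag}"


# Per-population covariate lists selected by the preliminary individual-level
# screening models (spring-migration temperature never qualified). Lags are
# relative to the collection year of the population.
_DEFAULT_TERMS: dict[str, list[CovariateTerm]] = {
    # HY birds collected in autumn of year y.
    "HY": [
        CovariateTerm("wintering_temp", 1),
        CovariateTerm("wintering_precip", 1),
        CovariateTerm("prebreeding_temp", 0),
        CovariateTerm("prebreeding_precip", 0),
        CovariateTerm("breeding_temp", 0),
        CovariateTerm("breeding_precip", 0),
    ],
    # AHY birds collected in spring of year y (hatched <= y-1).
    "AHY_spring": [
        CovariateTerm("wintering_precip", 2),
        CovariateTerm("prebreeding_precip", 1),
        CovariateTerm("breeding_temp", 1),
        CovariateTerm("breeding_precip", 1),
        CovariateTerm("autumn_temp", 1),
        CovariateTerm("wintering_precip", 1),
    ],
    # AHY birds collected in autumn of year y (hatched <= y-1).
    "AHY_autumn": [
        CovariateTerm("wintering_precip", 1),
        CovariateTerm("breeding_temp", 1),
        CovariateTerm("breeding_precip", 1),
        CovariateTerm("autumn_temp", 1),
        CovariateTerm("autumn_temp", 0),
    ],
}


@dataclass
class ModelSpec:
    """Which covariates enter the species-year regression of one population.

    ``terms`` are the climate covariates in table order; a year term is always
    appended as the last column (long-term trend proxy for non-climatic
    drivers), and a constant column always leads.
    """

    population: str
    terms: list[CovariateTerm] = field(default_factory=list)

    def __post_init__(self):
        if self.population not in ("HY", "AHY_spring", "AHY_autumn"):
            raise ValueError(f"unknown population {self.population!r}")

    @classmethod
    def default(cls, population: str) -> "ModelSpec":
        return cls(population, list(_DEFAULT_TERMS[population]))

    @property
    def column_names(self) -> list[str]:
        """G column order: constant, climate terms, year."""
        return ["const"] + [t.name for t in self.terms] + ["year"]

    @property
    def max_lag(self) -> int:
        return max((t.lag for t in self.terms), default=0)


@dataclass
class SeasonWindows:
    """Per-species annual-cycle windows in ordinal days (inclusive)."""

    species_id: str
    spring_window: tuple[int, int] | None = None
    autumn_window: tuple[int, int] | None = None
    prebreeding_window: tuple[int, int] | None = None
    breeding_month: int = BREEDING_MONTH
    wintering_month: int = WINTERING_MONTH

    def to_dict(self) -> dict:
        return {
            "species": self.species_id,
            "spring_window": self.spring_window,
            "autumn_window": self.autumn_window,
            "prebreeding_window": self.prebreeding_window,
            "breeding_month": self.breeding_month,
            "wintering_month": self.wintering_month,
        }


@dataclass
class CovariateTable:
    """The species-year design matrix G.

    ``table`` is indexed by (species, year) with columns ``column_spec``:
    a constant column of ones, then per-species standardized covariates.
    """

    table: pd.DataFrame
    column_spec: list[str]

    def row(self, species, year) -> np.ndarray:
        return self.table.loc[(species, year), self.column_spec].to_numpy(dtype=float)

    def matrix(self) -> np.ndarray:
        return self.table[self.column_spec].to_numpy(dtype=float)

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        # the scaled "year" covariate column shadows the index level name
        out.index = out.index.set_names(["species", "calendar_year"])
        out.reset_index().to_csv(path, index=False)


def migration_window(ordinal_dates) -> tuple[int, int]:
    """Peak migration window: mean ordinal date +/- one sample s.d.

    Bounds are rounded to the nearest whole day (ties away from zero) and
    clamped to [1, 366].
    """
    dates = np.asarray(ordinal_dates, dtype=float)
    if dates.size < 2:
        raise ValueError("insufficient phenology: need at least 2 collection dates")
    mean = dates.mean()
    sd = dates.std(ddof=1)
    start = int(np.clip(_round_half_away(mean - sd), 1, 366))
    end = int(np.clip(_round_half_away(mean + sd), 1, 366))
    return (start, end)


def prebreeding_window(spring_window: tuple[int, int]) -> tuple[int, int]:
    """The 30 days following the end of the peak spring migration window."""
    start, end = spring_window
    if not (1 <= start <= end <= 366):
        raise ValueError(f"invalid spring window {spring_window}")
    if end + PREBREEDING_DAYS > 366:
        raise ValueError(
            f"pre-breeding window for spring end {end} would cross the year "
            "boundary; no wrap rule is defined - supply windows explicitly"
        )
    return (end + 1, end + PREBREEDING_DAYS)


def mean_daily_temperature(tmax, tmin):
    """Mean daily temperature as the midpoint of the daily max and min."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    out = (tmax + tmin) / 2.0
    return float(out) if out.ndim == 0 else out


_WINDOW_STATS = ("mean_tmean", "mean_tmin", "mean_precip", "mean_anomaly")


def aggregate_window(series: pd.DataFrame, window: tuple[int, int],
                     year: int, stat: str) -> float:
    """Mean of a daily statistic over an inclusive ordinal-day window.

    ``series`` must carry a datetime ``date`` column plus the columns the
    statistic needs (``tmin``/``tmax``, optionally ``tmean``, ``precip``,
    ``anomaly``). Every calendar day of the window that exists in that year
    must be present exactly once; partial coverage is an error.
    """
    start, end = window
    if not (1 <= start <= end <= 366):
        raise ValueError(f"invalid window {window}")
    if stat not in _WINDOW_STATS:
        raise ValueError(f"unknown stat {stat!r}; expected one of {_WINDOW_STATS}")
    dates = pd.to_datetime(series["date"])
    doy = dates.dt.dayofyear
    in_win = (dates.dt.year == year) & (doy >= start) & (doy <= end)
    sub = series[in_win]
    days_in_year = 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365
    expected = set(range(start, min(end, days_in_year) + 1))
    have = set(doy[in_win].tolist())
    if not expected:
        raise ValueError(f"empty window {window} for year {year}")
    missing = sorted(expected - have)
    if missing:
        miss_dates = [
            (pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=d - 1)).date().isoformat()
            for d in missing[:10]
        ]
        raise ValueError(
            f"window {window} of year {year} is partially covered; "
            f"missing {len(missing)} day(s), e.g. {miss_dates}"
        )
    if stat == "mean_tmean":
        if "tmean" in sub.columns and sub["tmean"].notna().all():
            vals = sub["tmean"].to_numpy(dtype=float)
        else:
            vals = mean_daily_temperature(sub["tmax"].to_numpy(dtype=float),
                                          sub["tmin"].to_numpy(dtype=float))
    elif stat == "mean_tmin":
        vals = sub["tmin"].to_numpy(dtype=float)
    elif stat == "mean_precip":
        vals = sub["precip"].to_numpy(dtype=float)
    else:
        vals = sub["anomaly"].to_numpy(dtype=float)
    return float(np.mean(vals))


def season_windows(specimens: pd.DataFrame) -> dict[str, SeasonWindows]:
    """Derive per-species windows from pooled collection phenology.

    Ordinal dates are pooled across all years of a species (the phenology
    sample is the full collection record, not a per-year estimate). Species
    without spring records get no spring/pre-breeding window.
    """
    out: dict[str, SeasonWindows] = {}
    for species, grp in specimens.groupby("species", sort=True):
        sw = aw = pw = None
        spring = grp.loc[grp["season"] == "spring", "ordinal_date"].dropna()
        autumn = grp.loc[grp["season"] == "autumn", "ordinal_date"].dropna()
        if len(spring) >= 2:
            sw = migration_window(spring.to_numpy())
            pw = prebreeding_window(sw)
        if len(autumn) >= 2:
            aw = migration_window(autumn.to_numpy())
        out[str(species)] = SeasonWindows(str(species), sw, aw, pw)
    return out


def compute_seasonal_values(
    daily: pd.DataFrame | None,
    monthly: pd.DataFrame | None,
    windows: dict[str, SeasonWindows],
    years,
    terms: set[str] | None = None,
) -> pd.DataFrame:
    """Aggregate climate series into per-(species, year, term) values.

    ``daily`` follows the dialect ``species,range,date,tmin,tmax,precip
    [,tmean,anomaly]``; ``monthly`` follows ``species,range,year,month,
    anomaly,precip``. ``terms`` restricts which bases (keys of ``TERM_DEFS``)
    are computed; default all that the inputs support.
    """
    wanted = set(TERM_DEFS) if terms is None else set(terms)
    rows = []
    for species, win in windows.items():
        for base in sorted(wanted):
            range_label, source, detail = TERM_DEFS[base]
            if source == "monthly":
                if monthly is None:
                    continue
                month, column = detail
                sub = monthly[
                    (monthly["species"] == species)
                    & (monthly["range"] == range_label)
                    & (monthly["month"] == month)
                ]
                for y in years:
                    val = sub.loc[sub["year"] == y, column]
                    if len(val) == 0:
                        raise ValueError(
                            f"no monthly {column} for ({species}, {range_label}, "
                            f"{y}-{month:02d})"
                        )
                    rows.append((species, int(y), base, float(val.iloc[0])))
            else:
                if daily is None:
                    continue
                window_name, stat = detail
                window = getattr(win, f"{window_name}_window")
                if window is None:
                    continue
                sub = daily[
                    (daily["species"] == species) & (daily["range"] == range_label)
                ]
                for y in years:
                    rows.append(
                        (species, int(y), base,
                         aggregate_window(sub, window, int(y), stat))
                    )
    return pd.DataFrame(rows, columns=["species", "year", "term", "value"])


def build_covariate_table(
    seasonal_values: pd.DataFrame,
    spec: ModelSpec,
    years,
    *,
    scale_year: bool = True,
    species: list[str] | None = None,
) -> CovariateTable:
    """Assemble and standardize the species-year design matrix G.

    ``seasonal_values`` is long-form ``species, year, term, value`` with raw
    (unscaled) per-season values; lagged terms for year y read the value of
    year y - lag, so the table must cover ``min(years) - max_lag``. Each
    covariate column, and by default the year column, is standardized to
    mean 0 / sample s.d. 1 within each species over ``years``.
    """
    years = [int(y) for y in years]
    if not years:
        raise ValueError("empty year range")
    lut = seasonal_values.set_index(["species", "year", "term"])["value"]
    species_list = (sorted(seasonal_values["species"].unique())
                    if species is None else list(species))
    if not species_list:
        raise ValueError("no species to build a covariate table for")
    records = []
    for sp in species_list:
        for y in years:
            row = {"species": sp, "year": y, "const": 1.0}
            for t in spec.terms:
                src_year = y - t.lag
                try:
                    row[t.name] = float(lut.loc[(sp, src_year, t.base)])
                except KeyError:
                    raise ValueError(
                        f"cannot resolve covariate {t.name!r} for ({sp}, {y}): "
                        f"no {t.base!r} value for year {src_year}; trim the year "
                        "range or extend the climate series"
                    ) from None
            records.append(row)
    wide = pd.DataFrame.from_records(records)
    wide["year_raw"] = wide["year"]

    def _standardize(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"degenerate covariate column {col.name!r}: zero variance")
        return (col - col.mean()) / sd

    scaled_cols = [t.name for t in spec.terms]
    for c in scaled_cols:
        wide[c] = wide.groupby("species")[c].transform(_standardize)
    if scale_year:
        wide["year_col"] = wide.groupby("species")["year_raw"].transform(_standardize)
    else:
        wide["year_col"] = wide["year_raw"].astype(float)
    wide = wide.rename(columns={"year_col": "year_scaled"})
    table = wide.set_index(["species", "year"])
    table["year"] = table["year_scaled"]
    column_spec = spec.column_names
    return CovariateTable(table=table[column_spec].copy(), column_spec=column_spec)
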