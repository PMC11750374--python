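"""Specimen ingestion, outlier screening and per-species standardization.

The raw input is a specimen table of collision-salvaged migratory passerines:
one row per measured bird with species, collection year, ordinal collection
date, season (spring/autumn), age class (HY = hatch-year, AHY =
after-hatch-year), sex, tarsus length (mm, the body-size index) and relaxed
wing length (mm). Preparation follows the standard morphometric-time-series
recipe:

1. drop records missing any field the allometry model needs, counting them;
2. screen gross measurement/transcription errors per species with a median
   absolute deviation (MAD) filter on the raw tarsus and wing values
   (a record fails if *either* trait is more than ``k`` MADs from the
   species median, default ``k = 5``);
3. log-transform the surviving measurements and standardize them to mean 0 /
   s.d. 1 within each species, so the allometric intercept reads as mean
   wing length at mean body size and effects are comparable across species;
4. classify each record into one of the three model populations:
   ``HY`` (hatch-year, necessarily autumn), ``AHY_spring``, ``AHY_autumn``.

The MAD used is the raw median absolute deviation (no 1.4826 normal
consistency constant) unless ``mad_scaled=True``; filtering is single-pass
on the raw measurements, before the log transform.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("spring", "autumn")
AGE_CLASSES = ("HY", "AHY")
POPULATIONS = ("HY", "AHY_spring", "AHY_autumn")

#: Header of the specimen CSV dialect. Empty fields are treated as missing.
SPECIMEN_COLUMNS = [
    "species", "year", "ordinal_date", "season",
    "age_class", "sex", "tarsus_mm", "wing_mm",
]

#: Fields a record must have to enter the allometry model (complete-case rule).
REQUIRED_FIELDS = ("sex", "age_class", "tarsus_mm", "wing_mm")

#: Normal-consistency factor relating MAD to s.d. (used only if mad_scaled).
MAD_CONSISTENCY = 1.4826022185056018

DEFAULT_SEX_CODES = {"female": 0, "male": 1}


@dataclass(frozen=True)
class ScalingParams:
    """Per-species, per-trait log-scale standardization parameters.

    A raw measurement x (mm) maps to the model scale via
    ``(log(x) - log_mean) / log_sd``; the inverse recovers log(x) exactly.
    """

    species_id: str
    trait: str  # "tarsus" or "wing"
    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if not self.log_sd > 0:
            raise ValueError(f"log_sd must be positive, got {self.log_sd}")

    def transform(self, raw_mm):
        return (np.log(raw_mm) - self.log_mean) / self.log_sd

    def inverse_log(self, scaled):
        """Map a scaled value back to the log-measurement scale."""
        return np.asarray(scaled) * self.log_sd + self.log_mean

    def inverse_mm(self, scaled):
        return np.exp(self.inverse_log(scaled))


@dataclass
class PreparedMorphology:
    """Filtered, log-scaled morphology ready for the hierarchical model.

    ``records`` has one row per retained specimen with columns
    ``species, year, population, sex_code, z, w`` where ``z`` is scaled log
    tarsus (body size) and ``w`` scaled log wing length.
    """

    records: pd.DataFrame
    scaling: list[ScalingParams] = field(default_factory=list)
    n_dropped_outliers: int = 0
    n_dropped_missing: int = 0

    def scaling_for(self, species_id: str, trait: str) -> ScalingParams:
        for p in self.scaling:
            if p.species_id == species_id and p.trait == trait:
                return p
        raise KeyError(f"no scaling parameters for ({species_id!r}, {trait!r})")

    def write(self, outdir: str | Path, config: dict | None = None) -> dict:
        """Write prepared CSV, scaling CSV and a JSON provenance sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prepared_path = outdir / "prepared.csv"
        scaling_path = outdir / "scaling.csv"
        prov_path = outdir / "prepare_provenance.json"
        self.records.to_csv(prepared_path, index=False)
        pd.DataFrame(
            [
                {
                    "species": p.species_id,
                    "trait": p.trait,
                    "log_mean": p.log_mean,
                    "log_sd": p.log_sd,
                }
                for p in self.scaling
            ]
        ).to_csv(scaling_path, index=False)
        config = dict(config or {})
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()
        provenance = {
            "n_retained": int(len(self.records)),
            "n_dropped_outliers": int(self.n_dropped_outliers),
            "n_dropped_missing": int(self.n_dropped_missing),
            "config": config,
            "config_hash": cfg_hash,
        }
        prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True))
        return provenance


def mad_outlier_mask(values, k: float = 5.0, *, scaled: bool = False) -> np.ndarray:
    """Boolean keep-mask: True where a value lies within k MADs of the median.

    MAD is ``median(|x - median(x)|)``, unscaled by default. With ``MAD = 0``
    (at least half the values equal the median) only values exactly at the
    median survive, per the literal ``<=`` comparison.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if values.size == 0:
        raise ValueError("empty vector")
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    bad = ~np.isfinite(values)
    if bad.any():
        raise ValueError(f"non-finite entries at indices {np.flatnonzero(bad).tolist()}")
    med = np.median(values)
    absdev = np.abs(values - med)
    mad = float(np.median(absdev))
    if scaled:
        mad *= MAD_CONSISTENCY
    return absdev <= k * mad


def log_and_scale(values, groups, trait: str = "trait"):
    """Log-transform positive values and standardize within each group.

    Returns ``(scaled, params)`` where each group of ``scaled`` has mean 0 and
    sample s.d. 1 (denominator n-1), and ``params`` is a list of
    :class:`ScalingParams` (one per group, in first-appearance order) that
    invert the transform exactly.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    if np.any(~(values > 0)):
        bad = np.flatnonzero(~(values > 0)).tolist()
        raise ValueError(f"non-positive values at indices {bad}")
    logs = np.log(values)
    scaled = np.empty_like(logs)
    params: list[ScalingParams] = []
    seen: list = []
    for g in groups:
        if g not in seen:
            seen.append(g)
    for g in seen:
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        m = float(logs[mask].mean())
        sd = float(logs[mask].std(ddof=1))
        if sd == 0:
            raise ValueError(f"degenerate group {g!r}: zero variance of log {trait}")
        scaled[mask] = (logs[mask] - m) / sd
        params.append(ScalingParams(str(g), trait, m, sd))
    return scaled, params


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"specimen table is missing columns {missing_cols}")
    df = df.copy()
    for col in ("season", "age_class", "sex", "species"):
        if df[col].dtype == object:
            df[col] = df[col].replace("", np.nan)
    for col in ("tarsus_mm", "wing_mm", "ordinal_date", "year"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    season_vals = df["season"].dropna().unique()
    bad_season = [s for s in season_vals if s not in SEASONS]
    if bad_season:
        raise ValueError(f"invalid season values {bad_season}; expected {SEASONS}")
    age_vals = df["age_class"].dropna().unique()
    bad_age = [a for a in age_vals if a not in AGE_CLASSES]
    if bad_age:
        raise ValueError(f"invalid age_class values {bad_age}; expected {AGE_CLASSES}")

    ordd = df["ordinal_date"]
    bad_ord = ordd.notna() & ((ordd < 1) | (ordd > 366))
    if bad_ord.any():
        raise ValueError(
            f"ordinal_date out of [1, 366] at rows {df.index[bad_ord].tolist()}"
        )
    # Spring birds cannot be aged HY: anything collected in spring has, by
    # definition, completed at least one migration.
    hy_spring = (df["age_class"] == "HY") & (df["season"] == "spring")
    if hy_spring.any():
        raise ValueError(
            f"HY records with season=spring at rows {df.index[hy_spring].tolist()}; "
            "spring-collected birds must be AHY"
        )
    for col in ("tarsus_mm", "wing_mm"):
        nonpos = df[col].notna() & (df[col] <= 0)
        if nonpos.any():
            raise ValueError(
                f"non-positive {col} at rows {df.index[nonpos].tolist()}"
            )
    return df


def _model_population(age_class: str, season) -> str:
    if age_class == "HY":
        return "HY"
    return "AHY_spring" if season == "spring" else "AHY_autumn"


def prepare_dataset(
    records: pd.DataFrame,
    *,
    mad_k: float = 5.0,
    mad_scaled: bool = False,
    sex_codes: dict[str, int] | None = None,
    required_fields: tuple[str, ...] = REQUIRED_FIELDS,
) -> PreparedMorphology:
    """Filter, log-transform and standardize a specimen table.

    ``required_fields`` controls the complete-case definition: records with a
    missing value in any listed field are dropped and counted in
    ``n_dropped_missing`` (add ``"ordinal_date"`` or ``"season"`` for the
    stricter definition). The MAD filter runs per species on the raw tarsus
    and wing values independently; a record failing either is dropped. A
    species left with fewer than 2 records, or with zero log-variance in a
    trait, cannot be standardized and is excluded with a warning.
    """
    if len(records) == 0:
        raise ValueError("no specimen records supplied")
    sex_codes = dict(DEFAULT_SEX_CODES if sex_codes is None else sex_codes)
    df = _validate_records(pd.DataFrame(records))

    bad_sex = df["sex"].dropna().unique()
    bad_sex = [s for s in bad_sex if s not in sex_codes]
    if bad_sex:
        raise ValueError(f"unknown sex values {bad_sex}; expected {sorted(sex_codes)}")

    complete = df[list(required_fields)].notna().all(axis=1)
    n_missing = int((~complete).sum())
    df = df[complete].copy()

    n_outliers = 0
    kept_parts: list[pd.DataFrame] = []
    for species, grp in df.groupby("species", sort=True):
        keep = (
            mad_outlier_mask(grp["tarsus_mm"].to_numpy(), mad_k, scaled=mad_scaled)
            & mad_outlier_mask(grp["wing_mm"].to_numpy(), mad_k, scaled=mad_scaled)
        )
        n_outliers += int((~keep).sum())
        kept_parts.append(grp[keep])
    kept = pd.concat(kept_parts) if kept_parts else df.iloc[:0]

    scaling: list[ScalingParams] = []
    out_parts: list[pd.DataFrame] = []
    for species, grp in kept.groupby("species", sort=True):
        if len(grp) < 2:
            logger.warning(
                "species %r has %d surviving record(s); excluded from the model",
                species, len(grp),
            )
            continue
        try:
            z, p_t = log_and_scale(
                grp["tarsus_mm"].to_numpy(), np.repeat(species, len(grp)), "tarsus"
            )
            w, p_w = log_and_scale(
                grp["wing_mm"].to_numpy(), np.repeat(species, len(grp)), "wing"
            )
        except ValueError as exc:
            logger.warning("species %r excluded: %s", species, exc)
            continue
        scaling.extend(p_t)
        scaling.extend(p_w)
        out = pd.DataFrame(
            {
                "species": grp["species"].to_numpy(),
                "year": grp["year"].astype(int).to_numpy(),
                "population": [
                    _model_population(a, s)
                    for a, s in zip(grp["age_class"], grp["season"])
                ],
                "sex_code": [sex_codes[s] for s in grp["sex"]],
                "z": z,
                "w": w,
            }
        )
        out_parts.append(out)

    records_out = (
        pd.concat(out_parts, ignore_index=True)
        if out_parts
        else pd.DataFrame(columns=["species", "year", "population", "sex_code", "z", "w"])
    )
    return PreparedMorphology(
        records=records_out,
        scaling=scaling,
        n_dropped_outliers=n_outliers,
        n_dropped_missing=n_missing,
    )


def read_specimens(path: str | Path) -> pd.DataFrame:
    """Read the specimen CSV dialect (empty fields become missing)."""
    df = pd.read_csv(path, dtype={"species": str, "season": str,
                                  "age_class": str, "sex": str})
    return df
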