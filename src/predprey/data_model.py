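"""Survey records, body-weight assumptions, and density-to-biomass conversion.

The analysis starts from national survey estimates for Nepal's five lowland
protected areas (Parsa, Chitwan, Banke, Bardia, Shuklaphanta): tiger and
leopard densities are reported per 100 km^2, wild-prey density per km^2.
Biomass density in kg/km^2 is obtained by multiplying each density (expressed
per km^2) by a mean body mass: 180 kg for tigers, 42 kg for leopards, and for
the pooled prey community the arithmetic mean of the seven principal prey
species' masses (sambar 212, spotted deer 55, hog deer 40, wild boar 38,
barking deer 20, langur 8, rhesus monkey 8 kg), i.e. 54.43 kg by default.

Everything downstream (power-law fits, canonical-correlation margins) works
on the biomass records produced here.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Mean adult body masses (kg) used to convert densities to biomass densities.
TIGER_WEIGHT_KG = 180.0
LEOPARD_WEIGHT_KG = 42.0
PREY_WEIGHTS_KG: Mapping[str, float] = {
    "sambar": 212.0,
    "spotted_deer": 55.0,
    "hog_deer": 40.0,
    "wild_boar": 38.0,
    "barking_deer": 20.0,
    "langur": 8.0,
    "rhesus_monkey": 8.0,
}

#: Predator densities are surveyed per 100 km^2; prey per km^2.
PREDATOR_DENSITY_AREA_KM2 = 100.0

#: Column names of the standard density CSV.
DENSITY_COLUMNS = {
    "park": "park",
    "year": "year",
    "tiger": "tiger_density_per100km2",
    "leopard": "leopard_density_per100km2",
    "prey": "prey_density_perkm2",
    "tiger_se": "tiger_density_se_per100km2",
    "prey_se": "prey_density_se_perkm2",
    "prey_weight": "prey_mean_weight_kg",
}


@dataclass(frozen=True)
class SpeciesWeights:
    """Body-mass assumptions for the predator and prey communities.

    ``prey_mean_weight`` may be supplied explicitly (e.g. a park-specific
    assemblage mean); when ``None`` it defaults to the arithmetic mean of
    ``prey_weights``.
    """

    predator_weights: Mapping[str, float] = field(
        default_factory=lambda: {"tiger": TIGER_WEIGHT_KG, "leopard": LEOPARD_WEIGHT_KG}
    )
    prey_weights: Mapping[str, float] = field(default_factory=lambda: dict(PREY_WEIGHTS_KG))
    prey_mean_weight: float | None = None

    def __post_init__(self) -> None:
        for name, w in {**self.predator_weights, **self.prey_weights}.items():
            if not w > 0:
                raise ValueError(f"body weight for {name!r} must be strictly positive, got {w}")
        if self.prey_mean_weight is not None and not self.prey_mean_weight > 0:
            raise ValueError("prey_mean_weight must be strictly positive")

    @property
    def tiger(self) -> float:
        return float(self.predator_weights["tiger"])

    @property
    def leopard(self) -> float:
        return float(self.predator_weights["leopard"])

    @property
    def prey_mean(self) -> float:
        """Mean prey body mass (kg); arithmetic mean of the species list by default."""
        if self.prey_mean_weight is not None:
            return float(self.prey_mean_weight)
        return sum(self.prey_weights.values()) / len(self.prey_weights)


@dataclass(frozen=True)
class ParkYearDensities:
    """One park-year survey record in the units the surveys report.

    ``tiger_density`` and ``leopard_density`` are individuals per 100 km^2;
    ``prey_density`` is individuals per km^2. ``leopard_density`` is ``None``
    when no leopard estimate exists for that park-year (the record can still
    enter the tiger-only regression).
    """

    park: str
    year: int
    tiger_density: float
    prey_density: float
    leopard_density: float | None = None
    tiger_density_se: float | None = None
    prey_density_se: float | None = None
    prey_mean_weight: float | None = None

    def __post_init__(self) -> None:
        for name in ("tiger_density", "prey_density", "leopard_density",
                     "tiger_density_se", "prey_density_se"):
            v = getattr(self, name)
            if v is not None and (math.isnan(v) or v < 0):
                raise ValueError(
                    f"{name} must be non-negative for record ({self.park}, {self.year}); got {v}"
                )
        if self.prey_mean_weight is not None and not self.prey_mean_weight > 0:
            raise ValueError(
                f"prey_mean_weight must be positive for record ({self.park}, {self.year})"
            )

    @property
    def leopard_missing(self) -> bool:
        return self.leopard_density is None


@dataclass(frozen=True)
class ParkYearBiomass:
    """Derived biomass densities (kg/km^2) for one park-year.

    ``T`` and ``L`` are tiger and leopard biomass density, ``x`` the pooled
    wild-prey biomass density. ``predator_total`` is exactly ``T + L`` (or
    ``T`` with ``leopard_missing`` set when no leopard estimate exists).
    """

    park: str
    year: int
    T: float
    L: float
    x: float
    leopard_missing: bool = False
    units: str = "kg/km^2"

    @property
    def predator_total(self) -> float:
        return self.T + self.L


def densities_to_biomass(
    records: Sequence[ParkYearDensities],
    weights: SpeciesWeights | None = None,
) -> list[ParkYearBiomass]:
    """Convert survey densities to biomass densities (kg/km^2).

    Tiger biomass ``T = tiger_density / 100 * 180``; leopard biomass
    ``L = leopard_density / 100 * 42``; prey biomass
    ``x = prey_density * prey_mean_weight``. A record-level
    ``prey_mean_weight`` overrides the weight table's default. Records without
    a leopard density get ``L = 0`` and are flagged ``leopard_missing`` so the
    joint (CCA) stage can exclude them.
    """
    weights = weights or SpeciesWeights()
    _check_unique_park_years(records)
    out: list[ParkYearBiomass] = []
    for rec in records:
        prey_w = rec.prey_mean_weight if rec.prey_mean_weight is not None else weights.prey_mean
        missing = rec.leopard_density is None
        if missing:
            logger.warning("record (%s, %s): leopard density missing; usable for "
                           "tiger-only fit only", rec.park, rec.year)
        L = 0.0 if missing else rec.leopard_density / PREDATOR_DENSITY_AREA_KM2 * weights.leopard
        out.append(
            ParkYearBiomass(
                park=rec.park,
                year=rec.year,
                T=rec.tiger_density / PREDATOR_DENSITY_AREA_KM2 * weights.tiger,
                L=L,
                x=rec.prey_density * prey_w,
                leopard_missing=missing,
            )
        )
    return out


def biomass_to_densities(
    records: Sequence[ParkYearBiomass],
    weights: SpeciesWeights | None = None,
) -> list[ParkYearDensities]:
    """Inverse of :func:`densities_to_biomass` (divide by weights, re-apply
    the per-100-km^2 factor). Used by the synthetic generator and round-trip
    checks."""
    weights = weights or SpeciesWeights()
    out = []
    for rec in records:
        out.append(
            ParkYearDensities(
                park=rec.park,
                year=rec.year,
                tiger_density=rec.T / weights.tiger * PREDATOR_DENSITY_AREA_KM2,
                leopard_density=None if rec.leopard_missing
                else rec.L / weights.leopard * PREDATOR_DENSITY_AREA_KM2,
                prey_density=rec.x / weights.prey_mean,
            )
        )
    return out


def _check_unique_park_years(records: Sequence[ParkYearDensities | ParkYearBiomass]) -> None:
    seen: dict[tuple[str, int], int] = {}
    for i, rec in enumerate(records):
        key = (rec.park, rec.year)
        if key in seen:
            raise ValueError(
                f"duplicate (park, year) pair {key}: records {seen[key]} and {i}"
            )
        seen[key] = i


def read_density_table(path: str | Path) -> list[ParkYearDensities]:
    """Read the standard density CSV into typed, validated records.

    Required columns: ``park``, ``year``, ``tiger_density_per100km2``,
    ``prey_density_perkm2``. Optional: ``leopard_density_per100km2`` (absent
    column or blank cell flags the record leopard-missing), the ``*_se``
    columns and ``prey_mean_weight_kg``. Errors name the offending row
    (1-based data row, excluding the header).
    """
    df = pd.read_csv(path)
    required = [DENSITY_COLUMNS["park"], DENSITY_COLUMNS["year"],
                DENSITY_COLUMNS["tiger"], DENSITY_COLUMNS["prey"]]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")

    numeric_cols = [DENSITY_COLUMNS[k] for k in
                    ("tiger", "leopard", "prey", "tiger_se", "prey_se", "prey_weight")
                    if DENSITY_COLUMNS[k] in df.columns]
    records: list[ParkYearDensities] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        vals: dict[str, float | None] = {}
        for col in numeric_cols:
            raw = row_d[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                vals[col] = None
                continue
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(f"{path}: row {i}: non-numeric value {raw!r} in column {col!r}")
        try:
            records.append(
                ParkYearDensities(
                    park=str(row_d[DENSITY_COLUMNS["park"]]),
                    year=int(row_d[DENSITY_COLUMNS["year"]]),
                    tiger_density=_require(vals, DENSITY_COLUMNS["tiger"], path, i),
                    prey_density=_require(vals, DENSITY_COLUMNS["prey"], path, i),
                    leopard_density=vals.get(DENSITY_COLUMNS["leopard"]),
                    tiger_density_se=vals.get(DENSITY_COLUMNS["tiger_se"]),
                    prey_density_se=vals.get(DENSITY_COLUMNS["prey_se"]),
                    prey_mean_weight=vals.get(DENSITY_COLUMNS["prey_weight"]),
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: row {i}: {err}") from None
    _check_unique_park_years(records)
    return records


def _require(vals: Mapping[str, float | None], col: str, path, row: int) -> float:
    v = vals.get(col)
    if v is None:
        raise ValueError(f"{path}: row {row}: missing value in required column {col!r}")
    return v


def write_density_table(records: Sequence[ParkYearDensities], path: str | Path) -> None:
    """Write records to the standard density CSV."""
    rows = []
    for r in records:
        rows.append({
            DENSITY_COLUMNS["park"]: r.park,
            DENSITY_COLUMNS["year"]: r.year,
            DENSITY_COLUMNS["tiger"]: r.tiger_density,
            DENSITY_COLUMNS["leopard"]: r.leopard_density,
            DENSITY_COLUMNS["prey"]: r.prey_density,
            DENSITY_COLUMNS["tiger_se"]: r.tiger_density_se,
            DENSITY_COLUMNS["prey_se"]: r.prey_density_se,
            DENSITY_COLUMNS["prey_weight"]: r.prey_mean_weight,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def biomass_frame(records: Sequence[ParkYearBiomass]) -> pd.DataFrame:
    """Tabular view of biomass records (one row per park-year)."""
    return pd.DataFrame(
        {
            "park": [r.park for r in records],
            "year": [r.year for r in records],
            "tiger_biomass_kg_km2": [r.T for r in records],
            "leopard_biomass_kg_km2": [r.L for r in records],
            "predator_biomass_kg_km2": [r.predator_total for r in records],
            "prey_biomass_kg_km2": [r.x for r in records],
            "leopard_missing": [r.leopard_missing for r in records],
        }
    )


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def write_results(fits: Sequence, path: str | Path, *, seed: int | None = None,
                  config: Mapping | None = None, extra: Mapping | None = None) -> None:
    """Serialise fit summaries to a machine-readable JSON file.

    ``fits`` is any sequence of objects exposing ``summary_dict()`` (power-law
    fits, CCA fits, Wilks results, margins). The file records the seed and a
    hash of the configuration so results are traceable; identical seed and
    config give byte-identical output.
    """
    payload = {
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "fits": [f.summary_dict() for f in fits],
    }
    if extra:
        payload["extra"] = dict(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_results(path: str | Path) -> dict:
    """Read back a JSON summary written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
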