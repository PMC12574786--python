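"""Config-driven ingestion of heterogeneous ME/C tables into one wide schema.

Every jurisdiction publishes death records in its own dialect: different
column names, 1-5 cause-of-death text fields, location detail ranging from
exact coordinates to zip code only, and optional pending-investigation
status. A per-source configuration maps each dialect onto a fixed standard
column set so downstream extraction, geocoding, and summaries see one schema
regardless of origin.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "SourceConfig",
    "ConfigurationError",
    "STANDARD_COLUMNS",
    "GEO_RESOLUTIONS",
    "ingest",
    "merge_update",
    "merge_sources",
]


class ConfigurationError(ValueError):
    """Raised when a source configuration is inconsistent with its data."""


#: Standard (pre-flag) column set, identical for every source.
STANDARD_COLUMNS: list[str] = [
    "source_id",
    "case_id",
    "death_date",
    "age",
    "sex",
    "race",
    "ethnicity",
    "cod_text_1",
    "cod_text_2",
    "cod_text_3",
    "cod_text_4",
    "cod_text_5",
    "residence_zip",
    "injury_city",
    "injury_zip",
    "county",
    "address",
    "lat",
    "lng",
    "geo_resolution",
    "pending",
]

#: Geographic resolutions ordered fine -> coarse.
GEO_RESOLUTIONS: list[str] = ["point", "address", "zip", "city", "county", "none"]

# standard fields a field_map may target (cause-of-death fields are mapped
# through cod_fields, not field_map)
_MAPPABLE = {
    "case_id",
    "death_date",
    "age",
    "sex",
    "race",
    "ethnicity",
    "residence_zip",
    "injury_city",
    "injury_zip",
    "county",
    "address",
    "lat",
    "lng",
}

# small normalization map for demographic strings; values pass through
# otherwise (no recoding to fixed ontologies)
_DEMOGRAPHIC_VARIANTS = {
    "m": "male",
    "f": "female",
    "afr. american": "black",
    "african american": "black",
    "caucasian": "white",
}


class SourceConfig(BaseModel):
    """How to read one source's raw table into the standard schema.

    ``field_map`` maps raw column names to standard fields; ``cod_fields``
    lists the raw cause-of-death columns in order (1-5 of them);
    ``pending_field``/``pending_true_values`` declare how pending status is
    encoded when the source exposes it; ``date_formats`` is an ordered list
    of ``strptime`` patterns tried in turn (source convention decides
    day/month ambiguity).
    """

    source_id: str
    platform: Literal["socrata", "arcgis", "custom", "local"] = "local"
    url_or_path: str = ""
    field_map: dict[str, str]
    cod_fields: list[str] = Field(min_length=1, max_length=5)
    geocode: bool = False
    pending_field: Optional[str] = None
    pending_true_values: list[str] = Field(default_factory=lambda: ["true", "yes", "1", "pending"])
    date_formats: list[str] = Field(default_factory=lambda: ["%Y-%m-%d"])

    @field_validator("field_map")
    @classmethod
    def _known_targets(cls, v: dict[str, str]) -> dict[str, str]:
        unknown = set(v.values()) - _MAPPABLE
        if unknown:
            raise ValueError(f"field_map targets unknown standard fields: {sorted(unknown)}")
        if "case_id" not in v.values() or "death_date" not in v.values():
            raise ValueError("field_map must cover case_id and death_date")
        return v

    @model_validator(mode="after")
    def _geocode_needs_address(self) -> "SourceConfig":
        if self.geocode and "address" not in self.field_map.values():
            raise ValueError("geocode=true requires an address field in field_map")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "SourceConfig":
        return cls.model_validate(json.loads(Path(path).read_text(encoding="utf-8")))


def _parse_dates(raw: pd.Series, formats: list[str]) -> pd.Series:
    """Try each format in order; unparseable values become NaT with a warning."""
    out = pd.Series(pd.NaT, index=raw.index, dtype="datetime64[ns]")
    remaining = raw.notna() & (raw.astype(str).str.strip() != "")
    had_value = remaining.copy()
    for fmt in formats:
        if not remaining.any():
            break
        parsed = pd.to_datetime(raw[remaining], format=fmt, errors="coerce")
        out.loc[parsed.index] = out.loc[parsed.index].where(parsed.isna(), parsed)
        remaining = remaining & out.isna()
    failed = int((had_value & out.isna()).sum())
    if failed:
        logger.warning("%d death date(s) unparseable; kept with null date", failed)
    return out


def _finest_resolution(row: pd.Series) -> str:
    if pd.notna(row.get("lat")) and pd.notna(row.get("lng")):
        return "point"
    if pd.notna(row.get("address")) and str(row.get("address")).strip():
        return "address"
    for col, level in (
        ("injury_zip", "zip"),
        ("residence_zip", "zip"),
        ("injury_city", "city"),
        ("county", "county"),
    ):
        val = row.get(col)
        if pd.notna(val) and str(val).strip():
            return level
    return "none"


def _normalize_demographic(value: object) -> object:
    if pd.isna(value):
        return pd.NA
    text = str(value).strip().casefold()
    if not text:
        return pd.NA
    return _DEMOGRAPHIC_VARIANTS.get(text, text)


def ingest(
    config: SourceConfig,
    raw: pd.DataFrame | str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize one source's raw table.

    Returns ``(records, rejects)``: one standardized row per raw row, with
    rows failing hard validation (missing case id, out-of-range coordinates)
    routed to the reject frame with a reason column. Row count is conserved:
    ``len(records) + len(rejects) == len(raw)``.
    """
    if not isinstance(raw, pd.DataFrame):
        path = Path(raw)
        if path.suffix.lower() == ".json":
            raw = pd.read_json(path)
        else:
            raw = pd.read_csv(path, dtype=str)
    raw = raw.copy()

    missing = [c for c in config.field_map if c not in raw.columns]
    missing += [c for c in config.cod_fields if c not in raw.columns]
    if config.pending_field and config.pending_field not in raw.columns:
        missing.append(config.pending_field)
    if missing:
        raise ConfigurationError(
            f"source {config.source_id!r}: mapped column(s) missing from raw data: "
            f"{sorted(set(missing))}"
        )

    out = pd.DataFrame(index=raw.index, columns=STANDARD_COLUMNS, dtype="object")
    out["source_id"] = config.source_id
    for raw_col, std_col in config.field_map.items():
        out[std_col] = raw[raw_col]
    for i, raw_col in enumerate(config.cod_fields, start=1):
        out[f"cod_text_{i}"] = raw[raw_col]

    out["death_date"] = _parse_dates(out["death_date"], config.date_formats)
    for col in ("lat", "lng", "age"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in ("sex", "race", "ethnicity"):
        out[col] = out[col].map(_normalize_demographic)

    if config.pending_field:
        truthy = {v.casefold() for v in config.pending_true_values}
        out["pending"] = (
            raw[config.pending_field]
            .astype(str)
            .str.strip()
            .str.casefold()
            .isin(truthy)
            .map({True: "true", False: "false"})
        )
        out.loc[raw[config.pending_field].isna(), "pending"] = "unknown"
    else:
        out["pending"] = "unknown"

    # coordinates present only in part are dropped to keep the
    # point-iff-lat-and-lng invariant
    half = out["lat"].notna() ^ out["lng"].notna()
    out.loc[half, ["lat", "lng"]] = pd.NA

    out["geo_resolution"] = out.apply(_finest_resolution, axis=1)

    reasons = pd.Series("", index=out.index, dtype="object")
    no_case = out["case_id"].isna() | (out["case_id"].astype(str).str.strip() == "")
    reasons[no_case] += "missing case_id;"
    bad_lat = out["lat"].notna() & ~out["lat"].between(-90, 90)
    bad_lng = out["lng"].notna() & ~out["lng"].between(-180, 180)
    reasons[bad_lat | bad_lng] += "coordinates out of range;"

    bad = reasons != ""
    rejects = out[bad].copy()
    rejects["reject_reason"] = reasons[bad].str.rstrip(";")
    records = out[~bad].copy()

    dup = records.duplicated(subset=["source_id", "case_id"], keep=False)
    if dup.any():
        ids = sorted(records.loc[dup, "case_id"].astype(str).unique())
        raise ConfigurationError(
            f"source {config.source_id!r}: duplicate case id(s) in one batch: {ids}"
        )
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def merge_update(existing: pd.DataFrame, fresh: pd.DataFrame) -> pd.DataFrame:
    """Last-write-wins merge keyed on (source_id, case_id).

    A fresh row replaces its existing counterpart wholesale (open-data
    releases overwrite pending records once toxicology is finalized);
    existing records absent from the fresh batch are retained. Idempotent:
    applying the same batch twice equals applying it once.
    """
    key = ["source_id", "case_id"]
    for name, frame in (("existing", existing), ("fresh", fresh)):
        dup = frame.duplicated(subset=key, keep=False)
        if dup.any():
            ids = sorted(frame.loc[dup, "case_id"].astype(str).unique())
            raise ValueError(f"duplicate key(s) within {name} batch: {ids}")
    if existing.empty:
        return fresh.reset_index(drop=True)
    fresh_keys = set(map(tuple, fresh[key].astype(str).to_numpy()))
    keep = ~existing[key].astype(str).apply(tuple, axis=1).isin(fresh_keys)
    merged = pd.concat([existing[keep], fresh], ignore_index=True)
    return merged.reset_index(drop=True)


def merge_sources(per_source: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate standardized per-source tables into one merged table.

    Every input must carry the identical column set (schema stability is the
    point of harmonization); source_id distinguishes origin.
    """
    if not per_source:
        return pd.DataFrame(columns=STANDARD_COLUMNS)
    columns = list(per_source[0].columns)
    for frame in per_source[1:]:
        if list(frame.columns) != columns:
            raise ValueError(
                "per-source tables disagree on columns: "
                f"{sorted(set(columns) ^ set(frame.columns))}"
            )
    return pd.concat(per_source, ignore_index=True)
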