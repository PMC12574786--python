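"""Descriptive surveillance outputs from the flagged, harmonized table.

Two products: a per-source overdose summary (record counts, overdose-related
text matches, opioid/stimulant shares, total drug mentions) and the monthly
share of opioid overdoses that involve fentanyl — the series that tracks the
synthetic-opioid wave.

A record is "overdose-related by text match" when at least one lexicon drug
was flagged in its cause-of-death fields. Some jurisdictions also publish
pre-existing structured overdose fields; whether those count is a
config-level choice upstream, not part of these computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .extraction import DrugMatch, class_column, count_mentions, drug_column

logger = logging.getLogger(__name__)

__all__ = [
    "SourceSummary",
    "MonthlyShare",
    "summarize_source",
    "summarize_all_sources",
    "fentanyl_share_series",
    "flag_share",
    "pct_display",
]


def pct_display(value: Optional[float]) -> Optional[float]:
    """Half-up 1-decimal display for percentages."""
    if value is None:
        return None
    from .evaluation import round_display

    return round_display(value, places=1)


@dataclass(frozen=True)
class SourceSummary:
    """Per-source analogue of the overdose summary table."""

    source_id: str
    n_records: int
    n_overdose_matched: int
    n_opioid: int
    n_stimulant: int
    pct_opioid: Optional[float]
    pct_stimulant: Optional[float]
    n_drug_mentions: int


def _flag_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith("drug_")]


def _overdose_mask(records: pd.DataFrame) -> pd.Series:
    cols = _flag_columns(records)
    if not cols:
        raise ValueError("records carry no drug flag columns; run extraction first")
    return records[cols].sum(axis=1) > 0


def summarize_source(
    records: pd.DataFrame,
    per_record_matches: list[list[DrugMatch]] | None = None,
    source_id: str | None = None,
) -> SourceSummary:
    """Summarize one source's flagged records.

    Opioid/stimulant percentages are shares of the overdose-matched set and
    are None (undefined) when no record matched.
    """
    if source_id is None:
        ids = records["source_id"].unique() if "source_id" in records else []
        source_id = str(ids[0]) if len(ids) == 1 else "all"
    n_records = len(records)
    if n_records == 0:
        return SourceSummary(source_id, 0, 0, 0, 0, None, None, 0)
    overdose = _overdose_mask(records)
    n_matched = int(overdose.sum())
    n_opioid = int((records[class_column("opioid")] == 1).sum())
    n_stimulant = int((records[class_column("stimulant")] == 1).sum())
    pct_opioid = 100.0 * n_opioid / n_matched if n_matched else None
    pct_stimulant = 100.0 * n_stimulant / n_matched if n_matched else None
    mentions = count_mentions(per_record_matches) if per_record_matches is not None else 0
    return SourceSummary(
        source_id, n_records, n_matched, n_opioid, n_stimulant, pct_opioid, pct_stimulant, mentions
    )


def summarize_all_sources(
    records: pd.DataFrame,
    per_record_matches: list[list[DrugMatch]] | None = None,
) -> pd.DataFrame:
    """One summary row per source_id."""
    rows = []
    for sid, group in records.groupby("source_id", sort=True):
        matches = None
        if per_record_matches is not None:
            idx = records.index.get_indexer(group.index)
            matches = [per_record_matches[i] for i in idx]
        rows.append(summarize_source(group, matches, source_id=str(sid)).__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "source_id",
            "n_records",
            "n_overdose_matched",
            "n_opioid",
            "n_stimulant",
            "pct_opioid",
            "pct_stimulant",
            "n_drug_mentions",
        ],
    )


@dataclass(frozen=True)
class MonthlyShare:
    """Fentanyl share of opioid-flagged deaths in one calendar month."""

    month: str  # "YYYY-MM"
    n_opioid: int
    n_opioid_with_fentanyl: int
    share: Optional[float]


def fentanyl_share_series(records: pd.DataFrame) -> list[MonthlyShare]:
    """Monthly fentanyl share among opioid-flagged deaths.

    Months are calendar months of the death date; records without a date are
    excluded (count logged). Months present in the data but with zero
    opioid-flagged deaths get an undefined share, not 0.
    """
    if "death_date" not in records.columns:
        raise ValueError("records lack a death_date column")
    dated = records[records["death_date"].notna()].copy()
    dropped = len(records) - len(dated)
    if dropped:
        logger.info("%d record(s) lack death dates; excluded from series", dropped)
    if dated.empty:
        return []
    dated["month"] = pd.to_datetime(dated["death_date"]).dt.to_period("M")
    opioid = class_column("opioid")
    fent = drug_column("fentanyl")
    out = []
    for month, group in dated.groupby("month", sort=True):
        n_op = int((group[opioid] == 1).sum())
        n_f = int(((group[opioid] == 1) & (group[fent] == 1)).sum())
        share = n_f / n_op if n_op else None
        out.append(MonthlyShare(str(month), n_op, n_f, share))
    return out


def flag_share(
    numerator_flag: str,
    denominator_flag: str,
    records: pd.DataFrame,
) -> Optional[float]:
    """Percent of denominator-flagged records that also carry the numerator flag.

    Flags are named by canonical drug or class label; "overdose" denotes the
    any-drug-matched set. Undefined (None) when the denominator is empty.
    """

    def mask(label: str) -> pd.Series:
        if label == "overdose":
            return _overdose_mask(records)
        for col in (drug_column(label), class_column(label)):
            if col in records.columns:
                return records[col] == 1
        raise KeyError(f"unknown flag label {label!r}")

    den = mask(denominator_flag)
    n_den = int(den.sum())
    if n_den == 0:
        return None
    n_num = int((mask(numerator_flag) & den).sum())
    return 100.0 * n_num / n_den
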