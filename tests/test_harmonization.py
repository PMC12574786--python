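import pandas as pd
import pytest
from pydantic import ValidationError

from odpipeline.harmonization import (
    STANDARD_COLUMNS,
    ConfigurationError,
    SourceConfig,
    ingest,
    merge_sources,
    merge_update,
)
from odpipeline.synth import DIALECTS, SynthConfig, generate_source, source_config_for


def _config(**overrides) -> SourceConfig:
    base = dict(
        source_id="test",
        field_map={"case": "case_id", "dod": "death_date", "zipcode": "injury_zip"},
        cod_fields=["cause"],
        date_formats=["%Y-%m-%d"],
    )
    base.update(overrides)
    return SourceConfig(**base)


def _raw(**overrides) -> pd.DataFrame:
    base = {
        "case": ["A1", "A2"],
        "dod": ["2020-01-05", "2020-02-07"],
        "zipcode": ["60601", "60602"],
        "cause": ["fentanyl toxicity", "pneumonia"],
    }
    base.update(overrides)
    return pd.DataFrame(base)


def test_ingest_zip_only_source_resolution():
    records, rejects = ingest(_config(), _raw())
    assert rejects.empty
    assert list(records.columns) == STANDARD_COLUMNS
    assert (records["geo_resolution"] == "zip").all()
    assert records["ethnicity"].isna().all()  # unmapped fields stay null
    assert records["pending"].eq("unknown").all()


def test_ingest_point_resolution_and_ranges():
    cfg = _config(
        field_map={"case": "case_id", "dod": "death_date", "lat": "lat", "lng": "lng"}
    )
    raw = _raw(lat=["41.8", "99.9"], lng=["-87.6", "-87.6"])
    records, rejects = ingest(cfg, raw.drop(columns="zipcode"))
    assert len(records) == 1 and len(rejects) == 1
    assert records.iloc[0]["geo_resolution"] == "point"
    assert "coordinates out of range" in rejects.iloc[0]["reject_reason"]


def test_ingest_missing_column_is_config_error():
    with pytest.raises(ConfigurationError, match="zipcode"):
        ingest(_config(), _raw().drop(columns="zipcode"))


def test_unparseable_date_kept_with_null():
    records, rejects = ingest(_config(), _raw(dod=["2020-01-05", "not a date"]))
    assert len(records) == 2 and rejects.empty
    assert records["death_date"].isna().tolist() == [False, True]


def test_missing_case_id_rejected_row_count_conserved():
    records, rejects = ingest(_config(), _raw(case=["A1", None]))
    assert len(records) + len(rejects) == 2
    assert rejects.iloc[0]["reject_reason"] == "missing case_id"


def test_pending_three_valued():
    cfg = _config(pending_field="status", pending_true_values=["pending"])
    raw = _raw(status=["Pending", "Closed"])
    records, _ = ingest(cfg, raw)
    assert records["pending"].tolist() == ["true", "false"]


def test_config_validation():
    with pytest.raises(ValidationError, match="case_id"):
        _config(field_map={"dod": "death_date"})
    with pytest.raises(ValidationError, match="address"):
        _config(geocode=True)
    with pytest.raises(ValidationError):
        _config(cod_fields=[])


def test_duplicate_case_ids_in_batch_error():
    with pytest.raises(ConfigurationError, match="A1"):
        ingest(_config(), _raw(case=["A1", "A1"]))


def test_merge_update_last_write_wins():
    existing, _ = ingest(_config(), _raw())
    fresh_raw = _raw(case=["A2", "A3"], cause=["fentanyl and cocaine toxicity", "drowning"])
    fresh, _ = ingest(_config(), fresh_raw)
    merged = merge_update(existing, fresh)
    assert len(merged) == 3
    updated = merged[merged["case_id"] == "A2"].iloc[0]
    assert updated["cod_text_1"] == "fentanyl and cocaine toxicity"
    # idempotent: applying the same batch again changes nothing
    again = merge_update(merged, fresh)
    pd.testing.assert_frame_equal(
        merged.sort_values("case_id").reset_index(drop=True),
        again.sort_values("case_id").reset_index(drop=True),
    )


def test_merge_update_identity_and_disjoint():
    records, _ = ingest(_config(), _raw())
    same = merge_update(records, records)
    assert len(same) == len(records)
    other, _ = ingest(_config(), _raw(case=["B1", "B2"]))
    assert len(merge_update(records, other)) == 4


def test_merge_update_rejects_duplicate_keys():
    records, _ = ingest(_config(), _raw())
    dup = pd.concat([records, records], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate key"):
        merge_update(records, dup)


def test_all_dialects_harmonize_to_identical_schema():
    """Schema stability: every source dialect yields the same column set."""
    config = SynthConfig(seed=4, n_records=30)
    frames = []
    for dialect in sorted(DIALECTS):
        raw, _ = generate_source(config, dialect)
        records, rejects = ingest(source_config_for(dialect), raw)
        assert len(records) + len(rejects) == 30
        assert list(records.columns) == STANDARD_COLUMNS
        frames.append(records)
    merged = merge_sources(frames)
    assert len(merged) == 6 * 30
    assert set(merged["source_id"]) == set(DIALECTS)


def test_merge_sources_rejects_schema_mismatch():
    a = pd.DataFrame(columns=STANDARD_COLUMNS)
    b = pd.DataFrame(columns=STANDARD_COLUMNS[:-1])
    with pytest.raises(ValueError, match="disagree"):
        merge_sources([a, b])
    assert merge_sources([]).empty


def test_ethnicity_absent_for_dialects_lacking_it():
    config = SynthConfig(seed=4, n_records=25)
    for dialect in ("milwaukee", "santa_clara"):
        raw, _ = generate_source(config, dialect)
        records, _ = ingest(source_config_for(dialect), raw)
        assert records["ethnicity"].isna().all()
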