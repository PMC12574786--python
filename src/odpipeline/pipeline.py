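"""End-to-end orchestration: ingest -> extract -> geocode -> classify -> summarize.

Each stage reads and writes plain files so stages are independently
testable; a machine-readable run manifest (config hash, input digests,
per-stage record counts) is written alongside the outputs so re-runs on
identical inputs can be verified byte-for-byte (timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .extraction import flag_records, matches_to_frame
from .geospatial import (
    Gazetteer,
    GeoPoint,
    buffers_to_geojson,
    BufferZone,
    classify_against_buffers,
    geocode,
    load_pharmacies,
)
from .harmonization import SourceConfig, ingest, merge_sources
from .lexicon import DrugLexicon, default_lexicon, load_lexicon
from .similarity import SimilarityParams
from .summaries import fentanyl_share_series, summarize_all_sources

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunManifest", "run"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    input_digests: dict[str, str]
    version: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(
    config_path: str | Path,
    out_dir: str | Path,
    threshold: float | None = None,
    radius_miles: float = 1.0 / 3.0,
) -> RunManifest:
    """Execute the full pipeline from a multi-source JSON config.

    The config holds a ``sources`` list of per-source ingestion configs and
    optional ``lexicon``, ``gazetteer``, and ``pharmacies`` paths (relative
    paths resolve against the config file). A stage failure removes partial
    outputs and raises PipelineError.
    """
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw_config = json.loads(config_path.read_text(encoding="utf-8"))
    base = config_path.parent

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    manifest = RunManifest(
        config_hash=_digest(config_path),
        input_digests={},
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> Path:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)
        return path

    try:
        # --- ingest ---------------------------------------------------
        stage = "ingest"
        per_source, rejects = [], []
        for src in raw_config.get("sources", []):
            cfg = SourceConfig.model_validate(src)
            raw_path = resolve(cfg.url_or_path)
            manifest.input_digests[raw_path.name] = _digest(raw_path)
            records, rejected = ingest(cfg, raw_path)
            per_source.append(records)
            if not rejected.empty:
                rejects.append(rejected)
        merged = merge_sources(per_source)
        manifest.stage_counts["ingested"] = int(sum(len(f) for f in per_source))
        manifest.stage_counts["rejected"] = int(sum(len(f) for f in rejects))
        if rejects:
            emit("rejects.csv", pd.concat(rejects, ignore_index=True))

        # --- geocode ---------------------------------------------------
        stage = "geocode"
        gaz_path = raw_config.get("gazetteer")
        if gaz_path:
            gazetteer = Gazetteer.from_csv(resolve(gaz_path))
            needs = merged["lat"].isna() & merged["address"].notna()
            geocoded = 0
            for idx in merged.index[needs]:
                point = geocode(merged.at[idx, "address"], gazetteer)
                if point is not None:
                    merged.at[idx, "lat"] = point.lat
                    merged.at[idx, "lng"] = point.lng
                    merged.at[idx, "geo_resolution"] = "point"
                    geocoded += 1
            manifest.stage_counts["geocoded"] = geocoded

        # --- extract ---------------------------------------------------
        stage = "extract"
        lex_path = raw_config.get("lexicon")
        lexicon: DrugLexicon = (
            load_lexicon(resolve(lex_path)) if lex_path else default_lexicon()
        )
        params = SimilarityParams() if threshold is None else SimilarityParams(threshold=threshold)
        merged, per_record = flag_records(merged, lexicon, params)
        manifest.stage_counts["drug_mentions"] = sum(len(m) for m in per_record)
        emit("merged.csv", merged)
        emit("matches.csv", matches_to_frame(merged, per_record))

        # --- classify --------------------------------------------------
        stage = "classify"
        pharm_path = raw_config.get("pharmacies")
        if pharm_path:
            resources = load_pharmacies(resolve(pharm_path))
            pts = merged[merged["lat"].notna()]
            points = [GeoPoint(float(r["lat"]), float(r["lng"])) for _, r in pts.iterrows()]
            if points:
                classified = classify_against_buffers(points, resources, radius_miles)
                emit("buffer_classification.csv", classified)
                zones = [BufferZone(r, radius_miles) for r in resources]
                geojson_path = out / "buffers.geojson"
                geojson_path.write_text(
                    json.dumps(buffers_to_geojson(zones, classified), sort_keys=True)
                )
                written.append(geojson_path)
                manifest.stage_counts["points_inside_buffer"] = int(
                    classified["inside"].sum()
                )

        # --- summarize --------------------------------------------------
        stage = "summarize"
        emit("summary.csv", summarize_all_sources(merged, per_record))
        series = fentanyl_share_series(merged)
        emit(
            "fentanyl_share_monthly.csv",
            pd.DataFrame([s.__dict__ for s in series]),
        )
        manifest.stage_counts["merged_records"] = len(merged)
    except Exception as exc:  # partial outputs are removed on failure
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    manifest.write(out / "manifest.json")
    logger.info("pipeline complete: %s", manifest.stage_counts)
    return manifest
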