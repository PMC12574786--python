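"""Synthetic ME/C record bundles in six source dialects with ground truth.

Real open-data portals differ in column naming, number of cause-of-death
text fields (1-5), geographic resolution (coordinates, street address, zip),
availability of ethnicity and pending status, and date formatting. The
generator emits raw files exercising all of those axes, together with the
ground truth (true drug set, class flags, coordinates, pending state) each
record was built from, so every pipeline stage can be tested end to end
without downloading anything.

Cause-of-death strings are composed from short templates with lexicon drug
names; optional single-character typos (substitution or adjacent
transposition) are injected per matched phrase at ``typo_rate``. Typos never
touch the first 4 characters and are only applied to names of 8+ characters,
so the prefix-weighted similarity stays informative — a generator
convention, not a claim about real data.

One seeded pseudorandom generator threads through all draws; no global state.
"""

from __future__ import annotations

import json
import math
import random
import string
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

from .geospatial import MILES_PER_DEGREE, Gazetteer, GeoPoint
from .harmonization import SourceConfig
from .lexicon import DrugLexicon, default_lexicon

__all__ = [
    "SynthConfig",
    "DIALECTS",
    "generate_source",
    "generate_gazetteer_and_pharmacies",
    "source_config_for",
    "write_bundle",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generated bundle.

    ``class_frequencies`` weight which drug class each sampled substance is
    drawn from; ``typo_rate`` is the per-matched-phrase probability of a
    single character edit.
    """

    seed: int = 0
    n_records: int = 500
    overdose_fraction: float = 0.3
    typo_rate: float = 0.0
    pending_fraction: float = 0.1
    class_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            "opioid": 0.45,
            "stimulant": 0.25,
            "benzodiazepine": 0.10,
            "alcohol": 0.10,
            "anti-depressant": 0.05,
            "other": 0.05,
        }
    )

    def __post_init__(self) -> None:
        for name in ("overdose_fraction", "typo_rate", "pending_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")


@dataclass(frozen=True)
class Dialect:
    """Layout of one synthetic source, mirroring real portal facets."""

    source_id: str
    platform: str
    case_col: str
    date_col: str
    date_format: str
    cod_cols: tuple[str, ...]
    geo: str  # point | address | zip
    has_ethnicity: bool
    pending_col: str | None
    center: tuple[float, float]
    demo_cols: dict[str, str]  # standard field -> raw column


DIALECTS: dict[str, Dialect] = {
    "cook_county": Dialect(
        "cook_county",
        "socrata",
        "casenumber",
        "death_date",
        "%Y-%m-%d",
        (
            "primarycause",
            "primarycause_linea",
            "primarycause_lineb",
            "primarycause_linec",
            "secondarycause",
        ),
        "point",
        True,
        "pending",
        (41.85, -87.65),
        {"age": "age", "sex": "gender", "race": "race", "ethnicity": "latino"},
    ),
    "milwaukee": Dialect(
        "milwaukee",
        "arcgis",
        "CaseNum",
        "DeathDate",
        "%m/%d/%Y",
        ("CauseA", "CauseB", "CauseOther"),
        "address",
        False,
        None,
        (43.02, -87.95),
        {"age": "Age", "sex": "Sex", "race": "Race"},
    ),
    "san_diego": Dialect(
        "san_diego",
        "socrata",
        "case_number",
        "date_of_death",
        "%Y-%m-%d",
        ("cause_of_death", "other_significant_conditions", "contributing_factors"),
        "zip",
        True,
        "case_status",
        (32.72, -117.16),
        {"age": "age_years", "sex": "sex", "race": "race", "ethnicity": "ethnicity"},
    ),
    "connecticut": Dialect(
        "connecticut",
        "socrata",
        "CaseNumber",
        "Date",
        "%m/%d/%Y",
        ("COD",),
        "point",
        True,
        "Pending",
        (41.60, -72.70),
        {"age": "Age", "sex": "Sex", "race": "Race", "ethnicity": "Ethnicity"},
    ),
    "santa_clara": Dialect(
        "santa_clara",
        "custom",
        "case_id",
        "dod",
        "%Y-%m-%dT00:00:00",
        ("cause_of_death",),
        "point",
        False,
        "status",
        (37.33, -121.89),
        {"age": "age", "sex": "sex", "race": "race"},
    ),
    "sacramento": Dialect(
        "sacramento",
        "arcgis",
        "CASE_NO",
        "DEATH_DATE",
        "%m/%d/%Y",
        ("CAUSE_OF_DEATH",),
        "zip",
        False,
        "PENDING",
        (38.58, -121.49),
        {"age": "AGE", "sex": "SEX", "race": "RACE"},
    ),
}

_TEMPLATES = [
    "{drugs} toxicity",
    "combined {drugs} intoxication",
    "acute intoxication by the combined effects of {drugs}",
    "{drugs} overdose",
]

# natural/trauma causes free of lexicon collisions
_NON_OVERDOSE_CAUSES = [
    "hypertensive cardiovascular disease",
    "coronary artery atherosclerosis",
    "gunshot wound of head",
    "blunt force injuries",
    "complications of diabetes mellitus",
    "chronic obstructive pulmonary disease",
    "myocardial infarction",
    "pneumonia",
    "drowning",
    "hanging",
]

_SEXES = ["Male", "Female"]
_RACES = ["White", "Black", "Asian", "Other"]
_ETHNICITIES = ["Hispanic", "Non-Hispanic"]

_DATE_START = date(2012, 1, 1)
_DATE_END = date(2024, 9, 30)

#: minimum name length eligible for typo injection (edits never land in the
#: first 4 characters, so shorter names would leave too little signal)
_TYPO_MIN_LEN = 8


def _dialect_rng(config: SynthConfig, source_id: str) -> random.Random:
    order = sorted(DIALECTS)
    offset = order.index(source_id) + 1 if source_id in order else 97
    return random.Random(config.seed * 1009 + offset)


def _inject_typo(name: str, rng: random.Random) -> str:
    """One character substitution or adjacent transposition at position >= 4."""
    if len(name) < _TYPO_MIN_LEN:
        return name
    if rng.random() < 0.5:
        pos = rng.randrange(4, len(name))
        alternatives = [c for c in string.ascii_lowercase if c != name[pos]]
        return name[:pos] + rng.choice(alternatives) + name[pos + 1 :]
    pos = rng.randrange(4, len(name) - 1)
    if name[pos] == name[pos + 1]:  # swap of equal chars is a no-op; substitute
        alternatives = [c for c in string.ascii_lowercase if c != name[pos]]
        return name[:pos] + rng.choice(alternatives) + name[pos + 1 :]
    return name[:pos] + name[pos + 1] + name[pos] + name[pos + 2 :]


def _drugs_by_class(lexicon: DrugLexicon) -> dict[str, list[str]]:
    pools: dict[str, list[str]] = {}
    for entry in lexicon.entries:
        for cls in entry.classes:
            pools.setdefault(cls, []).append(entry.canonical_name)
    for pool in pools.values():
        pool.sort()
    return pools


def _sample_drugs(
    rng: random.Random, config: SynthConfig, pools: dict[str, list[str]]
) -> list[str]:
    n = rng.choices([1, 2, 3], weights=[0.45, 0.4, 0.15])[0]
    labels = [c for c in sorted(config.class_frequencies) if c in pools]
    weights = [config.class_frequencies[c] for c in labels]
    drugs: list[str] = []
    while len(drugs) < n:
        cls = rng.choices(labels, weights=weights)[0]
        drug = rng.choice(pools[cls])
        if drug not in drugs:
            drugs.append(drug)
    return drugs


def _compose_cod(
    drugs: list[str],
    n_fields: int,
    rng: random.Random,
    typo_rate: float,
) -> list[str]:
    """Fill the dialect's cause-of-death fields from a template."""
    rendered = [
        _inject_typo(d, rng) if rng.random() < typo_rate else d for d in drugs
    ]
    template = rng.choice(_TEMPLATES)
    if n_fields > 1 and len(rendered) > 1 and rng.random() < 0.4:
        first = template.format(drugs=" and ".join(rendered[:-1]))
        fields = [first, f"contributing: {rendered[-1]}"]
    else:
        joiner = " and " if len(rendered) <= 2 else ", "
        fields = [template.format(drugs=joiner.join(rendered))]
    fields += [""] * (n_fields - len(fields))
    return fields[:n_fields]


def _grid_address(i: int, j: int) -> str:
    streets = ["main st", "oak ave", "park blvd", "lake dr", "hill rd",
               "maple st", "grand ave", "center st", "river rd", "state st"]
    return f"{100 + i} {streets[j % len(streets)]}"


def generate_source(
    config: SynthConfig,
    dialect: str,
    lexicon: DrugLexicon | None = None,
    gazetteer: Gazetteer | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one source's raw table plus its ground truth.

    Deterministic given the config seed. The raw frame uses the dialect's
    own column names, date format, and geographic resolution; the truth
    frame records what each row was built from (true drugs, classes,
    overdose status, coordinates, pending state).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    spec = DIALECTS[dialect]
    if lexicon is None:
        lexicon = default_lexicon()
    rng = _dialect_rng(config, dialect)
    pools = _drugs_by_class(lexicon)
    span_days = (_DATE_END - _DATE_START).days

    raw_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(config.n_records):
        case_id = f"{spec.source_id.upper()[:4]}-{i + 1:05d}"
        when = _DATE_START + timedelta(days=rng.randrange(span_days + 1))
        is_overdose = rng.random() < config.overdose_fraction
        if is_overdose:
            drugs = _sample_drugs(rng, config, pools)
            cod_fields = _compose_cod(drugs, len(spec.cod_cols), rng, config.typo_rate)
        else:
            drugs = []
            cod_fields = [rng.choice(_NON_OVERDOSE_CAUSES)] + [""] * (len(spec.cod_cols) - 1)
        classes = sorted({c for d in drugs for c in lexicon.classes_of(d)})

        lat = spec.center[0] + rng.uniform(-0.15, 0.15)
        lng = spec.center[1] + rng.uniform(-0.15, 0.15)
        lat, lng = round(lat, 6), round(lng, 6)
        zipcode = f"{60000 + rng.randrange(100):05d}"
        address = _grid_address(rng.randrange(50), rng.randrange(10))

        pending = spec.pending_col is not None and rng.random() < config.pending_fraction

        row = {
            spec.case_col: case_id,
            spec.date_col: when.strftime(spec.date_format),
        }
        for k, (std, raw_col) in enumerate(sorted(spec.demo_cols.items())):
            if std == "age":
                row[raw_col] = rng.randrange(15, 90)
            elif std == "sex":
                row[raw_col] = rng.choice(_SEXES)
            elif std == "race":
                row[raw_col] = rng.choice(_RACES)
            elif std == "ethnicity":
                row[raw_col] = rng.choice(_ETHNICITIES)
        for col, text in zip(spec.cod_cols, cod_fields):
            row[col] = text
        if spec.geo == "point":
            row["latitude"], row["longitude"] = lat, lng
        elif spec.geo == "address":
            row["incident_address"] = address
        else:
            row["zip"] = zipcode
        if spec.pending_col:
            row[spec.pending_col] = "Pending" if pending else "Closed"
        raw_rows.append(row)

        truth_rows.append(
            {
                "source_id": spec.source_id,
                "case_id": case_id,
                "death_date": when.isoformat(),
                "is_overdose": int(is_overdose),
                "true_drugs": "|".join(drugs),
                "true_classes": "|".join(classes),
                "lat": lat if spec.geo == "point" else "",
                "lng": lng if spec.geo == "point" else "",
                "address": address if spec.geo == "address" else "",
                "zip": zipcode if spec.geo == "zip" else "",
                "pending": "true" if pending else ("false" if spec.pending_col else "unknown"),
            }
        )
        if gazetteer is not None and spec.geo == "address":
            gazetteer.add(address, GeoPoint(lat, lng))

    raw = pd.DataFrame(raw_rows)
    truth = pd.DataFrame(truth_rows)
    return raw, truth


def source_config_for(dialect: str, path: str = "") -> SourceConfig:
    """Ingestion config matching a generated dialect's layout."""
    spec = DIALECTS[dialect]
    field_map = {spec.case_col: "case_id", spec.date_col: "death_date"}
    for std, raw_col in spec.demo_cols.items():
        field_map[raw_col] = std
    if spec.geo == "point":
        field_map["latitude"] = "lat"
        field_map["longitude"] = "lng"
    elif spec.geo == "address":
        field_map["incident_address"] = "address"
    else:
        field_map["zip"] = "injury_zip"
    return SourceConfig(
        source_id=spec.source_id,
        platform=spec.platform,
        url_or_path=path,
        field_map=field_map,
        cod_fields=list(spec.cod_cols),
        geocode=spec.geo == "address",
        pending_field=spec.pending_col,
        pending_true_values=["pending"],
        date_formats=[spec.date_format],
    )


def generate_gazetteer_and_pharmacies(
    config: SynthConfig,
    n_pharmacies: int = 5,
    n_inside: int = 20,
    n_outside: int = 40,
    radius_miles: float = 1.0 / 3.0,
    center: tuple[float, float] = (43.02, -87.95),
) -> tuple[Gazetteer, pd.DataFrame, pd.DataFrame]:
    """Plant pharmacies and event points with a known inside/outside split.

    Pharmacies are spaced ~2 miles apart; ``n_inside`` event points are
    placed 0.05-0.25 miles from some pharmacy and ``n_outside`` points at
    least ~0.6 miles from every pharmacy, so exactly ``n_inside`` points lie
    within the buffer radius by construction. Returns the gazetteer mapping
    synthetic addresses to all planted points, the pharmacy table, and the
    event-point truth table.
    """
    rng = random.Random(config.seed * 1009 + 211)
    dlat_mile = 1.0 / MILES_PER_DEGREE  # degrees latitude per mile

    pharmacies = []
    for k in range(n_pharmacies):
        pharmacies.append(
            {
                "id": f"PH-{k + 1:03d}",
                "name": f"pharmacy {k + 1}",
                "lat": round(center[0] + 2.0 * k * dlat_mile, 6),
                "lng": center[1],
            }
        )
    pharm_frame = pd.DataFrame(pharmacies)

    gazetteer = Gazetteer()
    events = []
    for k in range(n_inside):
        base = pharmacies[k % n_pharmacies]
        dist = rng.uniform(0.05, min(0.25, radius_miles * 0.75))
        bearing = rng.uniform(0, 360)
        lat = base["lat"] + dist * dlat_mile * _cos_deg(bearing)
        lng = base["lng"] + dist * dlat_mile * _sin_deg(bearing) / _cos_deg(base["lat"])
        addr = f"{k + 1} inside ct"
        point = GeoPoint(round(lat, 6), round(lng, 6))
        gazetteer.add(addr, point)
        events.append({"address": addr, "lat": point.lat, "lng": point.lng, "planted_inside": 1})
    for k in range(n_outside):
        base = pharmacies[k % n_pharmacies]
        # offset strictly east-west, 0.6-0.9 miles: outside every buffer
        # (pharmacies are stacked north-south 2 miles apart)
        dist = rng.uniform(0.6, 0.9) * rng.choice([-1.0, 1.0])
        lng = base["lng"] + dist * dlat_mile / _cos_deg(base["lat"])
        addr = f"{k + 1} outside ln"
        point = GeoPoint(base["lat"], round(lng, 6))
        gazetteer.add(addr, point)
        events.append({"address": addr, "lat": point.lat, "lng": point.lng, "planted_inside": 0})
    return gazetteer, pharm_frame, pd.DataFrame(events)


def _cos_deg(deg: float) -> float:
    return math.cos(math.radians(deg))


def _sin_deg(deg: float) -> float:
    return math.sin(math.radians(deg))


def write_bundle(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full fixture bundle: six raw files, per-source ingestion
    configs, ground truth, gazetteer, pharmacies, and the default lexicon.

    Returns a name -> path map of everything written. Byte-identical for a
    fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lexicon = default_lexicon()
    gazetteer = Gazetteer()
    paths: dict[str, Path] = {}

    source_configs = []
    truths = []
    for dialect in sorted(DIALECTS):
        raw, truth = generate_source(config, dialect, lexicon, gazetteer)
        raw_path = out / f"raw_{dialect}.csv"
        raw.to_csv(raw_path, index=False)
        paths[f"raw_{dialect}"] = raw_path
        truths.append(truth)
        cfg = source_config_for(dialect, raw_path.name)  # relative to the bundle dir
        source_configs.append(json.loads(cfg.model_dump_json()))

    truth_path = out / "ground_truth.csv"
    pd.concat(truths, ignore_index=True).to_csv(truth_path, index=False)
    paths["ground_truth"] = truth_path

    config_path = out / "sources.json"
    config_path.write_text(
        json.dumps(
            {
                "sources": source_configs,
                "lexicon": "lexicon.csv",
                "gazetteer": "gazetteer.csv",
                "pharmacies": "pharmacies.csv",
            },
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    paths["sources"] = config_path

    gaz_bp, pharm_frame, planted = generate_gazetteer_and_pharmacies(config)
    # merge the buffer-plant addresses into the record gazetteer
    gaz_path = out / "gazetteer.csv"
    merged = Gazetteer()
    for g in (gazetteer, gaz_bp):
        for addr, point in g._table.items():  # noqa: SLF001 - same package
            merged.add(addr, point)
    merged.to_csv(gaz_path)
    paths["gazetteer"] = gaz_path

    pharm_path = out / "pharmacies.csv"
    pharm_frame.to_csv(pharm_path, index=False)
    paths["pharmacies"] = pharm_path

    planted_path = out / "planted_events.csv"
    planted.to_csv(planted_path, index=False)
    paths["planted_events"] = planted_path

    lex_path = out / "lexicon.csv"
    rows = [
        {
            "canonical": e.canonical_name,
            "synonyms": "|".join(sorted(e.synonyms)),
            "classes": "|".join(sorted(e.classes)),
        }
        for e in lexicon.entries
    ]
    pd.DataFrame(rows, columns=["canonical", "synonyms", "classes"]).to_csv(
        lex_path, index=False
    )
    paths["lexicon"] = lex_path
    return paths
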