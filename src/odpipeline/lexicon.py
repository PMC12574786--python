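"""Drug vocabulary: canonical substances, synonyms, and class memberships.

The lexicon drives extraction from cause-of-death text. Each entry collapses
spelling variants, abbreviations, and chemical names onto one canonical
substance (e.g. the IUPAC name
N-phenyl-N-[1-(2-phenylethyl)-4-piperidinyl]-propanamide onto fentanyl) and
records the drug classes the substance belongs to, which feed the per-class
indicator flags.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "CLASS_LABELS",
    "DrugEntry",
    "DrugLexicon",
    "LexiconError",
    "load_lexicon",
    "default_lexicon",
    "canonicalize",
    "classes_of",
]

CLASS_LABELS = frozenset(
    {"opioid", "stimulant", "benzodiazepine", "anti-depressant", "alcohol", "other"}
)


class LexiconError(ValueError):
    """Raised for invalid lexicon files (missing names, ambiguous synonyms)."""


@dataclass(frozen=True)
class DrugEntry:
    """One canonical substance with its synonyms and class memberships.

    The canonical name is implicitly a synonym of itself. An entry with no
    stated class is assigned the residual class ``other``.
    """

    canonical_name: str
    synonyms: frozenset[str] = frozenset()
    classes: frozenset[str] = frozenset({"other"})

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise LexiconError("canonical_name must be nonempty")
        if self.canonical_name != self.canonical_name.casefold():
            object.__setattr__(self, "canonical_name", self.canonical_name.casefold())
        object.__setattr__(
            self, "synonyms", frozenset(s.casefold() for s in self.synonyms if s)
        )
        classes = frozenset(c.casefold() for c in self.classes if c) or frozenset(
            {"other"}
        )
        unknown = classes - CLASS_LABELS
        if unknown:
            raise LexiconError(
                f"unknown class label(s) {sorted(unknown)} for {self.canonical_name!r}; "
                f"allowed: {sorted(CLASS_LABELS)}"
            )
        object.__setattr__(self, "classes", classes)

    @property
    def all_names(self) -> frozenset[str]:
        return self.synonyms | {self.canonical_name}


@dataclass
class DrugLexicon:
    """Validated matching vocabulary with a synonym -> canonical index."""

    entries: list[DrugEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, str] = {}
        self._by_canonical: dict[str, DrugEntry] = {}
        for entry in self.entries:
            if entry.canonical_name in self._by_canonical:
                raise LexiconError(f"duplicate canonical name {entry.canonical_name!r}")
            self._by_canonical[entry.canonical_name] = entry
            for name in entry.all_names:
                owner = self._index.get(name)
                if owner is not None and owner != entry.canonical_name:
                    raise LexiconError(
                        f"synonym {name!r} is claimed by both {owner!r} and "
                        f"{entry.canonical_name!r}"
                    )
                self._index[name] = entry.canonical_name

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, canonical_name: str) -> bool:
        return canonical_name.casefold() in self._by_canonical

    @property
    def max_phrase_tokens(self) -> int:
        """Token count of the longest synonym (0 for an empty lexicon)."""
        return max((len(name.split()) for name in self._index), default=0)

    @property
    def lookup_keys(self) -> frozenset[str]:
        return frozenset(self._index)

    def canonicalize(self, term: str) -> str | None:
        """Exact (casefolded) synonym lookup; None for unknown terms."""
        return self._index.get(term.casefold())

    def classes_of(self, canonical_name: str) -> frozenset[str]:
        key = canonical_name.casefold()
        if key not in self._by_canonical:
            raise KeyError(f"unknown canonical drug name {canonical_name!r}")
        return self._by_canonical[key].classes

    @property
    def canonical_names(self) -> list[str]:
        return sorted(self._by_canonical)

    @property
    def class_labels(self) -> list[str]:
        return sorted({c for e in self.entries for c in e.classes})


def _split_multi(value: str | None) -> list[str]:
    if value is None:
        return []
    return [part.strip() for part in str(value).split("|") if part.strip()]


def _entries_from_rows(rows: Iterable[dict], origin: str) -> list[DrugEntry]:
    entries = []
    for i, row in enumerate(rows, start=1):
        canonical = (row.get("canonical") or "").strip()
        if not canonical:
            raise LexiconError(f"{origin}: row {i} has no canonical name")
        syns = row.get("synonyms")
        if isinstance(syns, str) or syns is None:
            syns = _split_multi(syns)
        classes = row.get("classes")
        if isinstance(classes, str) or classes is None:
            classes = _split_multi(classes)
        entries.append(
            DrugEntry(canonical, frozenset(syns), frozenset(classes) or frozenset({"other"}))
        )
    return entries


def load_lexicon(path: str | Path, format: str | None = None) -> DrugLexicon:
    """Load a lexicon from a delimited table or a JSON record file.

    The delimited format has header ``canonical,synonyms,classes`` with
    pipe-separated multi-values; the JSON format is a list of objects with
    the same keys. All strings are casefolded on load; a synonym mapping to
    two different canonical names is a load-time error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        entries = _entries_from_rows(records, str(path))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            entries = _entries_from_rows(csv.DictReader(fh), str(path))
    else:
        raise ValueError(f"unknown lexicon format {format!r}")
    return DrugLexicon(entries)


def default_lexicon() -> DrugLexicon:
    """The lexicon shipped with the package (~40 common substances).

    Covers frequently implicated opioids, stimulants, benzodiazepines,
    anti-depressants, ethanol, and a few residual substances; it is a
    starting vocabulary meant to be adjusted or expanded per deployment,
    not an exhaustive dictionary.
    """
    with resources.files("odpipeline.data").joinpath("default_lexicon.csv").open(
        encoding="utf-8", newline=""
    ) as fh:
        return DrugLexicon(_entries_from_rows(csv.DictReader(fh), "default_lexicon"))


def canonicalize(term: str, lexicon: DrugLexicon) -> str | None:
    return lexicon.canonicalize(term)


def classes_of(canonical_name: str, lexicon: DrugLexicon) -> frozenset[str]:
    return lexicon.classes_of(canonical_name)
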