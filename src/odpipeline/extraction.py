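"""Find lexicon drugs in cause-of-death text and emit indicator flags.

Cause-of-death fields are short free-text phrases ("fentanyl and cocaine
toxicity", "combined drug intoxication"). Extraction scans every field of a
record independently, slides candidate n-grams (up to the longest synonym in
the vocabulary) over the tokens, and accepts either exact synonym hits
(score 1.0) or fuzzy Jaro-Winkler hits above a similarity threshold. Matches
are collapsed to per-record binary indicator flags: one per canonical drug
and one per drug class.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import DrugLexicon
from .similarity import SimilarityParams, jaro_winkler

__all__ = [
    "DrugMatch",
    "IndicatorFlags",
    "normalize_text",
    "match_drugs",
    "make_flags",
    "count_mentions",
    "flag_records",
    "matches_to_frame",
]

# characters stripped from token edges; hyphens and brackets are preserved
# because chemical names ("4-fbf", bracketed IUPAC names) depend on them
_EDGE_PUNCT = ".,;:!?\"'"


@dataclass(frozen=True)
class DrugMatch:
    """One lexicon hit: canonical drug, matched text, score, and location.

    ``span`` is a 0-based half-open token interval within ``field_index``.
    Exact synonym hits score exactly 1.0.
    """

    canonical_name: str
    matched_text: str
    score: float
    field_index: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError(f"span end must exceed start, got {self.span}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0,1], got {self.score}")


@dataclass(frozen=True)
class IndicatorFlags:
    """Binary per-drug and per-class presence flags for one record."""

    drug_flags: dict[str, int]
    class_flags: dict[str, int]


def normalize_text(raw: str | None) -> list[str]:
    """Casefold and whitespace-split, stripping punctuation at token edges.

    Intra-token hyphens, brackets, and commas survive so chemical names and
    abbreviations ("4-fibf") stay intact. None/empty input yields [].
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return []
    tokens = []
    for tok in str(raw).casefold().split():
        tok = tok.strip(_EDGE_PUNCT)
        if tok:
            tokens.append(tok)
    return tokens


def _candidate_matches(
    tokens: list[str],
    field_index: int,
    lexicon: DrugLexicon,
    params: SimilarityParams,
) -> list[DrugMatch]:
    """All scoring candidates for one field, before overlap resolution."""
    out: list[DrugMatch] = []
    max_n = min(lexicon.max_phrase_tokens, len(tokens)) if tokens else 0
    # fuzzy comparisons pair n-grams with synonyms of the same token count;
    # short names are exact-only (fuzzy matching on short strings is noisy)
    fuzzy_names: dict[int, list[str]] = {}
    for name in lexicon.lookup_keys:
        if len(name) >= params.min_fuzzy_len:
            fuzzy_names.setdefault(len(name.split()), []).append(name)
    for names in fuzzy_names.values():
        names.sort()
    for n in range(1, max_n + 1):
        for start in range(len(tokens) - n + 1):
            phrase = " ".join(tokens[start : start + n])
            canonical = lexicon.canonicalize(phrase)
            if canonical is not None:
                out.append(
                    DrugMatch(canonical, phrase, 1.0, field_index, (start, start + n))
                )
                continue
            if len(phrase) < params.min_fuzzy_len:
                continue
            best_score, best_canonical = 0.0, None
            for name in fuzzy_names.get(n, ()):
                score = jaro_winkler(phrase, name, params)
                if score > best_score:
                    best_score = score
                    best_canonical = lexicon.canonicalize(name)
            if best_canonical is not None and best_score >= params.threshold:
                out.append(
                    DrugMatch(
                        best_canonical,
                        phrase,
                        best_score,
                        field_index,
                        (start, start + n),
                    )
                )
    return out


def _resolve_overlaps(candidates: list[DrugMatch]) -> list[DrugMatch]:
    """Greedy overlap resolution within one field.

    Longest span first, then highest score, then lexicographic canonical
    name, then leftmost start — a deterministic total order.
    """
    chosen: list[DrugMatch] = []
    taken: set[int] = set()
    for m in sorted(
        candidates,
        key=lambda m: (
            -(m.span[1] - m.span[0]),
            -m.score,
            m.canonical_name,
            m.span[0],
        ),
    ):
        positions = set(range(*m.span))
        if positions & taken:
            continue
        taken |= positions
        chosen.append(m)
    return sorted(chosen, key=lambda m: m.span)


def match_drugs(
    fields: Sequence[str | None],
    lexicon: DrugLexicon,
    params: SimilarityParams | None = None,
) -> list[DrugMatch]:
    """Scan cause-of-death fields for lexicon drugs.

    Fields are scanned independently (never concatenated) so the originating
    field index is preserved; each matched span is reported once with its
    best-scoring canonical drug.
    """
    if params is None:
        params = SimilarityParams()
    matches: list[DrugMatch] = []
    for field_index, raw in enumerate(fields):
        tokens = normalize_text(raw)
        if not tokens:
            continue
        matches.extend(
            _resolve_overlaps(_candidate_matches(tokens, field_index, lexicon, params))
        )
    return matches


def make_flags(matches: Iterable[DrugMatch], lexicon: DrugLexicon) -> IndicatorFlags:
    """Collapse matches to binary flags; repeats never change a flag.

    A class flag is 1 iff some flagged drug belongs to that class.
    """
    drug_flags = {name: 0 for name in lexicon.canonical_names}
    class_flags = {label: 0 for label in lexicon.class_labels}
    for m in matches:
        if m.canonical_name not in drug_flags:
            raise KeyError(f"match references unknown drug {m.canonical_name!r}")
        drug_flags[m.canonical_name] = 1
        for label in lexicon.classes_of(m.canonical_name):
            class_flags[label] = 1
    return IndicatorFlags(drug_flags, class_flags)


def count_mentions(all_matches: Iterable[Iterable[DrugMatch]]) -> int:
    """Total drug mentions: every matched span counts once, across records."""
    return sum(len(list(ms)) for ms in all_matches)


def drug_column(canonical_name: str) -> str:
    return "drug_" + canonical_name.replace(" ", "_")


def class_column(label: str) -> str:
    return "class_" + label.replace(" ", "_")


def flag_records(
    records: pd.DataFrame,
    lexicon: DrugLexicon,
    params: SimilarityParams | None = None,
    cod_columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[list[DrugMatch]]]:
    """Append per-drug and per-class indicator columns to a harmonized table.

    Returns the widened table plus the per-record match lists (for mention
    counts and the long-format match table).
    """
    if params is None:
        params = SimilarityParams()
    if cod_columns is None:
        cod_columns = [c for c in records.columns if c.startswith("cod_text_")]
    per_record: list[list[DrugMatch]] = []
    rows: list[dict[str, int]] = []
    for _, row in records.iterrows():
        matches = match_drugs([row[c] for c in cod_columns], lexicon, params)
        per_record.append(matches)
        flags = make_flags(matches, lexicon)
        out = {drug_column(d): v for d, v in flags.drug_flags.items()}
        out.update({class_column(c): v for c, v in flags.class_flags.items()})
        rows.append(out)
    flag_frame = pd.DataFrame(rows, index=records.index, dtype="int64")
    if flag_frame.empty:
        cols = [drug_column(d) for d in lexicon.canonical_names]
        cols += [class_column(c) for c in lexicon.class_labels]
        flag_frame = pd.DataFrame(columns=cols, index=records.index, dtype="int64")
    return pd.concat([records, flag_frame], axis=1), per_record


def matches_to_frame(
    records: pd.DataFrame, per_record: list[list[DrugMatch]]
) -> pd.DataFrame:
    """Long-format match table: one row per matched span."""
    rows = []
    for (_, rec), matches in zip(records.iterrows(), per_record):
        for m in matches:
            rows.append(
                {
                    "source_id": rec.get("source_id"),
                    "case_id": rec.get("case_id"),
                    "canonical_name": m.canonical_name,
                    "matched_text": m.matched_text,
                    "score": m.score,
                    "field_index": m.field_index,
                    "span_start": m.span[0],
                    "span_end": m.span[1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "source_id",
            "case_id",
            "canonical_name",
            "matched_text",
            "score",
            "field_index",
            "span_start",
            "span_end",
        ],
    )
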