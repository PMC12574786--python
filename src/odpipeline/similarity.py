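"""Jaro and Jaro-Winkler string similarity.

These are the fuzzy-matching primitives used to recognise misspelled drug
names in cause-of-death text. Conventions (stated because variants exist in
the literature):

* Jaro: characters match if equal and within a window of
  ``floor(max(|s1|, |s2|) / 2) - 1`` positions; the transposition count ``t``
  is half the number of matched characters that are out of order; the
  similarity is ``(m/|s1| + m/|s2| + (m - t)/m) / 3``.
* Winkler boost: applied unconditionally (no boost-threshold variant) as
  ``jw = jaro + l * p * (1 - jaro)`` where ``l`` is the common-prefix length
  capped at ``max_l``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SimilarityParams", "jaro", "jaro_winkler"]


@dataclass(frozen=True)
class SimilarityParams:
    """Knobs for Jaro-Winkler matching.

    Parameters
    ----------
    p : float
        Winkler prefix scaling factor; the classical default is 0.1 and
        values above 0.25 can push the similarity past 1.
    max_l : int
        Maximum common-prefix length credited by the Winkler boost.
    threshold : float
        Minimum similarity accepted for a fuzzy hit, in (0, 1]. Drug names
        are long, so the default bar is high to limit false positives on
        chemical-name fragments.
    min_fuzzy_len : int
        Minimum candidate token length (in characters) eligible for fuzzy
        matching; shorter tokens (abbreviations like "4-fbf", "pcp") are
        matched exactly only.
    """

    p: float = 0.1
    max_l: int = 4
    threshold: float = 0.95
    min_fuzzy_len: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 0.25:
            raise ValueError(f"p must be in [0, 0.25], got {self.p}")
        if self.max_l < 0:
            raise ValueError(f"max_l must be >= 0, got {self.max_l}")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.min_fuzzy_len < 1:
            raise ValueError(f"min_fuzzy_len must be >= 1, got {self.min_fuzzy_len}")


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1]; 0 for no matching characters, 1 iff equal."""
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0

    window = max(len1, len2) // 2 - 1
    matched1 = [False] * len1
    matched2 = [False] * len2

    m = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not matched2[j] and s2[j] == c:
                matched1[i] = True
                matched2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0

    # transpositions: matched characters compared in order of appearance
    k = 0
    half_transpositions = 0
    for i in range(len1):
        if matched1[i]:
            while not matched2[k]:
                k += 1
            if s1[i] != s2[k]:
                half_transpositions += 1
            k += 1
    t = half_transpositions / 2.0

    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(s1: str, s2: str, params: SimilarityParams | None = None) -> float:
    """Jaro-Winkler similarity: Jaro plus a bonus for a shared prefix.

    Always >= the plain Jaro similarity and equals 1 iff the strings are
    identical.
    """
    if params is None:
        params = SimilarityParams()
    base = jaro(s1, s2)
    prefix = 0
    for c1, c2 in zip(s1, s2):
        if c1 != c2 or prefix >= params.max_l:
            break
        prefix += 1
    return base + prefix * params.p * (1.0 - base)
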