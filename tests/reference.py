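"""Independent naive reference implementations used as test oracles.

Deliberately written from the textbook definitions with different data
structures than the package (index lists instead of boolean flag arrays),
so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math


def ref_jaro(s1: str, s2: str) -> float:
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(len(s1), len(s2)) // 2 - 1
    # greedy left-to-right assignment of matching characters within window
    used: list[int] = []
    matched_pairs: list[tuple[int, int]] = []
    for i, c in enumerate(s1):
        for j in range(max(0, i - window), min(len(s2), i + window + 1)):
            if j not in used and s2[j] == c:
                used.append(j)
                matched_pairs.append((i, j))
                break
    m = len(matched_pairs)
    if m == 0:
        return 0.0
    seq1 = [s1[i] for i, _ in sorted(matched_pairs)]
    seq2 = [s2[j] for _, j in sorted(matched_pairs, key=lambda p: p[1])]
    t = sum(a != b for a, b in zip(seq1, seq2)) / 2
    return (m / len(s1) + m / len(s2) + (m - t) / m) / 3


def ref_jaro_winkler(s1: str, s2: str, p: float = 0.1, max_l: int = 4) -> float:
    base = ref_jaro(s1, s2)
    l = 0
    for a, b in zip(s1[:max_l], s2[:max_l]):
        if a != b:
            break
        l += 1
    return base + l * p * (1 - base)


def ref_haversine_miles(lat1, lng1, lat2, lng2, radius=3958.8) -> float:
    """Spherical law of cosines — a different formula than the haversine."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dlmb = math.radians(lng2 - lng1)
    cosang = math.sin(phi1) * math.sin(phi2) + math.cos(phi1) * math.cos(phi2) * math.cos(dlmb)
    return radius * math.acos(max(-1.0, min(1.0, cosang)))
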