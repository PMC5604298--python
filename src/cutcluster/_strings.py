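"""Jaro-Winkler string similarity.

The Jaro similarity of two strings counts matching characters (equal
characters no further apart than half the longer length, minus one) and
transpositions (matched characters appearing in a different order):

    jaro = (m/|s1| + m/|s2| + (m - t)/m) / 3

The Winkler variant boosts pairs sharing a common prefix (up to 4
characters, scale p = 0.1), which suits metadata keys and record linkage
where variants of one attribute name usually agree on the first tokens:

    jw = jaro + L * p * (1 - jaro)

Both scores live in [0, 1]; 1 means the strings are identical.
"""

from __future__ import annotations

__all__ = ["jaro_similarity", "jaro_winkler_similarity"]

_PREFIX_SCALE = 0.1
_MAX_PREFIX = 4


def jaro_similarity(s1: str, s2: str) -> float:
    """Plain Jaro similarity in [0, 1].

    Empty-string convention: two empty strings are identical (1.0); an
    empty string against a non-empty one shares nothing (0.0).
    """
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0

    window = max(len1, len2) // 2 - 1
    if window < 0:
        window = 0

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

    # transpositions: matched chars of s1 vs s2 in match order
    t = 0
    j = 0
    for i in range(len1):
        if matched1[i]:
            while not matched2[j]:
                j += 1
            if s1[i] != s2[j]:
                t += 1
            j += 1
    t //= 2

    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler_similarity(s1: str, s2: str) -> float:
    """Jaro-Winkler similarity with prefix scale 0.1 and max prefix 4."""
    jaro = jaro_similarity(s1, s2)
    if jaro == 1.0 or jaro == 0.0:
        return jaro
    prefix = 0
    for a, b in zip(s1, s2):
        if a != b or prefix >= _MAX_PREFIX:
            break
        prefix += 1
    return jaro + prefix * _PREFIX_SCALE * (1.0 - jaro)
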