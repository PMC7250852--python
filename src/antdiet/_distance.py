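"""Bounded Levenshtein (edit) distance for amplicon haplotypes.

MOTU clustering only ever needs to know whether two haplotypes are within
``d`` edits of each other (d is 4-6 bases in practice), so the DP is banded:
cells further than ``limit`` off the diagonal can never contribute to a
distance <= limit and are skipped.  The kernel is JIT-compiled with numba
when available; a pure-Python fallback keeps the package importable without
it (at a substantial speed cost).
"""

from __future__ import annotations

import numpy as np

__all__ = ["encode", "bounded_levenshtein", "levenshtein"]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _banded_kernel(a, b, limit):  # pragma: no cover - compiled
    n, m = len(a), len(b)
    if m < n:
        a, b = b, a
        n, m = m, n
    if m - n > limit:
        return limit + 1
    big = limit + 1
    prev = np.empty(m + 1, dtype=np.int32)
    cur = np.empty(m + 1, dtype=np.int32)
    for j in range(m + 1):
        prev[j] = j if j <= limit else big
    for i in range(1, n + 1):
        lo = i - limit
        if lo < 1:
            lo = 1
        hi = i + limit
        if hi > m:
            hi = m
        cur[lo - 1] = big
        for j in range(lo, hi + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            best = prev[j - 1] + cost
            if prev[j] + 1 < best:  # deletion
                best = prev[j] + 1
            if cur[j - 1] + 1 < best:  # insertion
                best = cur[j - 1] + 1
            cur[j] = best if best <= big else big
        if hi + 1 <= m:
            cur[hi + 1] = big
        prev, cur = cur, prev
    d = prev[m]
    return d if d <= limit else big


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _banded_jit = njit(cache=True, nogil=True)(_banded_kernel)
except Exception:  # pragma: no cover
    _banded_jit = _banded_kernel


def bounded_levenshtein(a: np.ndarray, b: np.ndarray, limit: int) -> int:
    """Edit distance between encoded sequences, capped at ``limit`` + 1.

    Returns the exact Levenshtein distance if it is <= limit, otherwise
    ``limit + 1``.
    """
    if limit < 0:
        raise ValueError("limit must be >= 0")
    return int(_banded_jit(a, b, limit))


def levenshtein(a: str, b: str) -> int:
    """Exact (unbounded) Levenshtein distance between two strings."""
    return bounded_levenshtein(encode(a), encode(b), max(len(a), len(b)))
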