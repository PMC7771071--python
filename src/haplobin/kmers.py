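"""Canonical k-mer counting, parent-specific k-mer sets, and haplotyping
precision.

k-mers are canonicalized to the lexicographic minimum of the k-mer and its
reverse complement and held as 2-bit-packed integers (k <= 31).  A haplotype
assembly's specific k-mers are intersected with the two parents' specific
k-mer sets; the fraction landing in the matching parent is the haplotyping
precision, reported per haplotype and as a weighted average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, ch in enumerate("ACGT"):
    _CODE[ord(ch)] = i
    _CODE[ord(ch.lower())] = i


def kmer_to_int(kmer: str) -> int:
    v = 0
    for ch in kmer:
        c = _CODE[ord(ch)]
        if c == 255:
            raise ValueError(f"non-ACGT base {ch!r} in k-mer")
        v = (v << 2) | int(c)
    return v


def int_to_kmer(v: int, k: int) -> str:
    return "".join("ACGT"[(v >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_int(v: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (v & 3))
        v >>= 2
    return out


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    k = len(kmer)
    v = kmer_to_int(kmer)
    return int_to_kmer(min(v, revcomp_int(v, k)), k)


def _canonical_ints(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of all k-mers of one sequence (vectorized);
    windows touching a non-ACGT symbol are dropped."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.array([], dtype=np.uint64)
    valid = codes != 255
    window_ok = np.ones(n, dtype=bool)
    bad = np.flatnonzero(~valid)
    for b in bad:
        window_ok[max(0, b - k + 1):b + 1] = False
    c = codes.astype(np.uint64)
    c[~valid] = 0
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        fwd |= c[i:i + n] << np.uint64(2 * (k - 1 - i))
        rev |= (np.uint64(3) - c[i:i + n]) << np.uint64(2 * i)
    canon = np.minimum(fwd, rev)
    return canon[window_ok]


def count_kmers(
    sequences: Iterable[str],
    k: int = 21,
    min_count: int = 1,
    max_count: float = float("inf"),
) -> dict[int, int]:
    """Canonical k-mer multiset over sequences, filtered to [min, max] counts
    inclusive.  Keys are 2-bit-packed integers (use int_to_kmer to decode)."""
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be odd and >= 3 (even k makes palindromes ambiguous)")
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing")
    parts = [_canonical_ints(s, k) for s in sequences]
    parts = [p for p in parts if len(p)]
    if not parts:
        return {}
    values, counts = np.unique(np.concatenate(parts), return_counts=True)
    keep = (counts >= min_count) & (counts <= max_count)
    return dict(zip(values[keep].tolist(), counts[keep].tolist()))


def build_specific_set(
    target_counts: dict[int, int],
    exclude_counts: dict[int, int],
    require_counts: dict[int, int],
    target_band: tuple[float, float] = (10, 60),
    exclude_floor: int = 2,
    require_band: tuple[float, float] = (10, 300),
) -> set[int]:
    """k-mers in the target band, absent from the exclude source (count below
    its floor counts as sequencing error, i.e. "not existing"), and present in
    the require source within its band.  Pure set algebra, order-independent.
    """
    lo, hi = target_band
    rlo, rhi = require_band
    out = set()
    for kv, c in target_counts.items():
        if not lo <= c <= hi:
            continue
        if exclude_counts.get(kv, 0) >= exclude_floor:
            continue
        rc = require_counts.get(kv, 0)
        if rlo <= rc <= rhi:
            out.add(kv)
    return out


@dataclass(frozen=True)
class KmerSetSummary:
    """Intersection counts between two haplotype-specific k-mer sets (r_1,
    r_2) and two parent-specific sets (p_1, p_2)."""

    k: int
    size_r1: int
    size_r2: int
    size_p1: int
    size_p2: int
    r1_p1: int
    r1_p2: int
    r2_p1: int
    r2_p2: int

    @classmethod
    def from_sets(cls, k: int, r1: set, r2: set, p1: set, p2: set) -> "KmerSetSummary":
        return cls(
            k, len(r1), len(r2), len(p1), len(p2),
            len(r1 & p1), len(r1 & p2), len(r2 & p1), len(r2 & p2),
        )


@dataclass(frozen=True)
class PrecisionResult:
    pairing: tuple[int, int]          # parent index matched to haplotypes (1, 2)
    precision_1: float | None         # % for haplotype 1 (None when undefined)
    precision_2: float | None
    average: float | None             # weighted by denominators


def precision(summary: KmerSetSummary) -> PrecisionResult:
    """Haplotyping precision from the four intersection counts.

    precision(haplotype r_X paired with parent p_P) =
    100 * |r_X ∩ p_P| / (|r_X ∩ p_P| + |r_X ∩ p_Q|).  The parent/haplotype
    pairing maximizing the weighted average is chosen and reported; a
    haplotype with zero denominator is excluded from the average.
    """
    def score(match1, mismatch1, match2, mismatch2):
        p1 = 100 * match1 / (match1 + mismatch1) if match1 + mismatch1 > 0 else None
        p2 = 100 * match2 / (match2 + mismatch2) if match2 + mismatch2 > 0 else None
        num = den = 0
        if p1 is not None:
            num += match1
            den += match1 + mismatch1
        if p2 is not None:
            num += match2
            den += match2 + mismatch2
        avg = 100 * num / den if den else None
        return p1, p2, avg

    direct = score(summary.r1_p1, summary.r1_p2, summary.r2_p2, summary.r2_p1)
    crossed = score(summary.r1_p2, summary.r1_p1, summary.r2_p1, summary.r2_p2)
    if (crossed[2] or -1) > (direct[2] or -1):
        return PrecisionResult((2, 1), crossed[0], crossed[1], crossed[2])
    return PrecisionResult((1, 2), direct[0], direct[1], direct[2])
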