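"""Bi-marker majority-voting phasing along contigs, per-gamete haplotype
strings, virtual end markers, and recombinant detection between marker pairs.

Phasing walks each contig's markers in positional order.  For every adjacent
pair it counts, over gametes covering both, S = gametes with the same raw
symbol (RR or AA) and D = gametes with different symbols.  If S >= D the two
markers keep the same orientation, else the orientation flips; S = D keeps
the previous orientation and flags the adjacency as a tie.  Orientation +1
means the alternative allele belongs to haplotype "a" of the contig; the
first marker is +1 by convention, so the global flip of a solution is the
same solution with relabelled haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossovers import DEFAULT_MIN_SUPPORT, end_symbols
from .gametes import A, GenotypeMatrix, N, R

SYMBOLS = np.array(["n", "a", "b"])


@dataclass
class ContigPhase:
    contig: str
    marker_ids: list[str]
    positions: np.ndarray
    orientations: np.ndarray       # +1 / -1 per marker, first is +1
    tie_flags: np.ndarray          # bool per adjacency (len = markers - 1)
    ref_alleles: list[str]
    alt_alleles: list[str]

    @property
    def hap_a_alleles(self) -> list[str]:
        """Allele carried by contig-local haplotype a at each marker."""
        return [
            (alt if o == 1 else ref)
            for o, ref, alt in zip(self.orientations, self.ref_alleles, self.alt_alleles)
        ]

    @property
    def hap_b_alleles(self) -> list[str]:
        return [
            (ref if o == 1 else alt)
            for o, ref, alt in zip(self.orientations, self.ref_alleles, self.alt_alleles)
        ]


@dataclass
class VirtualMarker:
    contig: str
    end: str                       # "head" | "tail"
    sequence: np.ndarray           # int8 over gametes: {0 n, 1 a, 2 b}

    def as_string(self) -> str:
        return "".join(SYMBOLS[self.sequence])


def phase_contig(
    raw_calls: np.ndarray,
    markers: pd.DataFrame,
    gamete_mask: np.ndarray | None = None,
) -> tuple[ContigPhase, np.ndarray]:
    """Phase one contig's markers and return (phase, phased calls).

    ``raw_calls`` is the gametes x markers slice of R/A/N codes for this
    contig, markers ordered by position.  ``gamete_mask`` optionally restricts
    the S/D counting to trusted (e.g. haploid) gametes; phased calls are
    still produced for every gamete.
    """
    if raw_calls.ndim != 2 or raw_calls.shape[1] != len(markers):
        raise ValueError("raw_calls must be gametes x markers for this contig")
    m = raw_calls.shape[1]
    if m == 0:
        raise ValueError("contig with no markers")
    voting = raw_calls if gamete_mask is None else raw_calls[np.asarray(gamete_mask)]
    left, right = voting[:, :-1], voting[:, 1:]
    both = (left != N) & (right != N)
    same = np.count_nonzero(both & (left == right), axis=0)
    diff = np.count_nonzero(both & (left != right), axis=0)
    rel = np.where(same >= diff, 1, -1).astype(np.int8)
    orientations = np.concatenate(([1], np.cumprod(rel))).astype(np.int8)
    tie_flags = same == diff

    contig = str(markers.contig.iloc[0])
    phase = ContigPhase(
        contig=contig,
        marker_ids=list(markers.marker_id),
        positions=markers.start.to_numpy(),
        orientations=orientations,
        tie_flags=tie_flags,
        ref_alleles=list(markers.ref),
        alt_alleles=list(markers.alt),
    )
    phased = phase_calls(raw_calls, orientations)
    return phase, phased


def phase_calls(raw_calls: np.ndarray, orientations: np.ndarray) -> np.ndarray:
    """Map raw R/A codes to a/b codes under per-marker orientations."""
    phased = np.zeros_like(raw_calls)
    plus = orientations == 1
    phased[:, plus] = np.where(
        raw_calls[:, plus] == A, 1, np.where(raw_calls[:, plus] == R, 2, 0)
    )
    phased[:, ~plus] = np.where(
        raw_calls[:, ~plus] == A, 2, np.where(raw_calls[:, ~plus] == R, 1, 0)
    )
    return phased.astype(np.int8)


def phase_all_contigs(
    matrix: GenotypeMatrix, gamete_mask: np.ndarray | None = None
) -> tuple[dict[str, ContigPhase], GenotypeMatrix]:
    """Phase every contig of a raw matrix; returns phases and the phased matrix."""
    phased = np.zeros_like(matrix.calls)
    phases: dict[str, ContigPhase] = {}
    for contig in matrix.contigs:
        sl = matrix.contig_slice(contig)
        phase, calls = phase_contig(
            matrix.calls[:, sl], matrix.markers.iloc[sl], gamete_mask
        )
        phases[contig] = phase
        phased[:, sl] = calls
    return phases, GenotypeMatrix(matrix.gamete_ids, matrix.markers, phased, phased=True)


def gamete_haplotype_string(
    phase: ContigPhase, phased_calls: np.ndarray, gamete_ids: list[str], gamete: str
) -> str:
    """One gamete's haplotype call string over this contig's markers."""
    try:
        g = gamete_ids.index(gamete)
    except ValueError as exc:
        raise KeyError(f"unknown gamete id {gamete!r}") from exc
    return "".join(SYMBOLS[phased_calls[g]])


def find_recombinants(calls1, calls2) -> set[int]:
    """1-based indices of gametes whose genotype switches between two markers.

    Accepts strings over "abn" or integer arrays; a gamete counts only when
    both calls are non-missing and differ.
    """
    a1 = _as_codes(calls1)
    a2 = _as_codes(calls2)
    if len(a1) != len(a2):
        raise ValueError(f"length mismatch: {len(a1)} vs {len(a2)}")
    hits = np.flatnonzero((a1 != 0) & (a2 != 0) & (a1 != a2))
    return {int(i) + 1 for i in hits}


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        lut = {"n": 0, "a": 1, "b": 2}
        try:
            return np.array([lut[ch] for ch in seq], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"invalid genotype symbol {exc.args[0]!r}") from exc
    return np.asarray(seq)


def impute_virtual_markers(
    phase: ContigPhase,
    phased_calls: np.ndarray,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> tuple[VirtualMarker, VirtualMarker]:
    """Impute each gamete's genotype at the head and tail of a contig.

    The head (tail) symbol is the consensus of the gamete's first (last)
    strong block under min-support segmentation, falling back to the raw
    first (last) non-missing symbol for gametes without a strong block;
    gametes with no calls at all get 'n' at both ends.  A gamete with head a
    and tail b (or b/a) has an odd number of crossovers inside the contig.
    """
    n_gametes = phased_calls.shape[0]
    head = np.zeros(n_gametes, dtype=np.int8)
    tail = np.zeros(n_gametes, dtype=np.int8)
    for g in range(n_gametes):
        head[g], tail[g] = end_symbols(phased_calls[g], min_support)
    return (
        VirtualMarker(phase.contig, "head", head),
        VirtualMarker(phase.contig, "tail", tail),
    )


def exhaustive_phase_orientations(raw_calls: np.ndarray) -> tuple[np.ndarray, int]:
    """Independent oracle for small contigs: the orientation vector (first
    fixed at +1) maximizing the total adjacent-pair agreement
    sum_i max-achievable agreement, found by brute force over 2^(m-1)
    assignments.  Returns (orientations, objective).  Objective for an
    assignment o is sum over adjacencies of (S if o_i == o_{i+1} else D).
    """
    m = raw_calls.shape[1]
    left, right = raw_calls[:, :-1], raw_calls[:, 1:]
    both = (left != N) & (right != N)
    same = np.count_nonzero(both & (left == right), axis=0)
    diff = np.count_nonzero(both & (left != right), axis=0)
    best, best_obj = None, -1
    for bits in range(2 ** (m - 1)):
        o = np.ones(m, dtype=np.int8)
        for j in range(m - 1):
            o[j + 1] = 1 if not (bits >> j) & 1 else -1
        agree = np.where(o[:-1] == o[1:], same, diff).sum()
        if agree > best_obj:
            best, best_obj = o, int(agree)
    return best, best_obj
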