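"""Two-point linkage, linkage grouping, marker ordering and centimorgan
assignment for a haploid gamete population, plus deletion-marker integration.

Genotype sequences are per-marker strings over {a, b, n} across the haploid
gametes.  For two markers, R = gametes where the symbols differ and NR =
where they match (over gametes informative for both).  Since marker phases
are arbitrary, R > NR indicates opposite phases and the pair is flipped
(recorded) so that r = R / (R + NR) <= 0.5.  The haploid two-point LOD is

    LOD = NR * log10(2 * (1 - r)) + R * log10(2 * r)

with LOD = (R + NR) * log10(2) when R = 0.  Markers join a linkage group when
connected by edges with LOD strictly above the threshold (default 3.0);
groups are ordered by greedy nearest-neighbour seriation refined by 2-opt,
and adjacent distances use the Haldane mapping function d = -50 ln(1 - 2r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LOD_THRESHOLD = 3.0
HALDANE_EPS = 1e-6
HALDANE_CAP_CM = 50.0


@dataclass(frozen=True)
class TwoPointLinkage:
    r_count: int        # recombinants after phase correction
    nr_count: int       # non-recombinants after phase correction
    flipped: bool       # True when raw R > NR and the pair was phase-flipped
    r: float            # recombination fraction (nan when uninformative)
    lod: float

    @property
    def informative(self) -> int:
        return self.r_count + self.nr_count


def two_point_lod(g1, g2) -> TwoPointLinkage:
    """Two-point linkage between two genotype sequences over {a, b, n}."""
    a1, a2 = _codes(g1), _codes(g2)
    if len(a1) != len(a2):
        raise ValueError(f"length mismatch: {len(a1)} vs {len(a2)}")
    both = (a1 != 0) & (a2 != 0)
    raw_r = int(np.count_nonzero(both & (a1 != a2)))
    raw_nr = int(np.count_nonzero(both & (a1 == a2)))
    flipped = raw_r > raw_nr
    r_count, nr_count = (raw_nr, raw_r) if flipped else (raw_r, raw_nr)
    n = r_count + nr_count
    if n == 0:
        return TwoPointLinkage(0, 0, False, float("nan"), 0.0)
    r = r_count / n
    lod = _lod_value(r_count, nr_count)
    return TwoPointLinkage(r_count, nr_count, flipped, r, lod)


def _lod_value(r_count: int, nr_count: int) -> float:
    n = r_count + nr_count
    if r_count == 0:
        return n * np.log10(2.0)
    r = r_count / n
    return float(nr_count * np.log10(2 * (1 - r)) + r_count * np.log10(2 * r))


def _codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        lut = {"n": 0, "a": 1, "b": 2}
        try:
            return np.array([lut[ch] for ch in seq], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"invalid genotype symbol {exc.args[0]!r}") from exc
    return np.asarray(seq)


def pairwise_linkage(sequences: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (r, LOD, flipped, informative) matrices, vectorized.

    Encodes a = +1, b = -1, n = 0; then sum of products over gametes equals
    NR - R and the informative count is the overlap of non-zero entries.
    """
    X = np.stack([np.where(s == 1, 1, np.where(s == 2, -1, 0)) for s in sequences]).astype(float)
    nz = (X != 0).astype(float)
    I = nz @ nz.T
    S = X @ X.T
    NR = (I + S) / 2
    Rm = (I - S) / 2
    flip = Rm > NR
    Rc = np.where(flip, NR, Rm)
    NRc = np.where(flip, Rm, NR)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(I > 0, Rc / np.where(I > 0, I, 1), np.nan)
        lod = np.where(
            Rc == 0,
            I * np.log10(2.0),
            NRc * np.log10(np.maximum(2 * (1 - r), 1e-300))
            + Rc * np.log10(np.maximum(2 * r, 1e-300)),
        )
    lod = np.where(I > 0, lod, 0.0)
    return r, lod, flip, I.astype(int)


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_markers(
    marker_keys: list,
    lod: np.ndarray,
    contig_of: dict | None = None,
    lod_threshold: float = LOD_THRESHOLD,
) -> list[list[int]]:
    """Connected components of the LOD-above-threshold graph (strict >).

    ``contig_of`` maps marker index -> contig id; when given, the two end
    markers of a contig are forced into one component (the one holding the
    marker's stronger edge), with a warning when they disagree.
    """
    n = len(marker_keys)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if lod[i, j] > lod_threshold:
                g.add_edge(i, j, lod=float(lod[i, j]))
    comp_of = {}
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    for ci, comp in enumerate(components):
        for i in comp:
            comp_of[i] = ci
    if contig_of:
        by_contig: dict = {}
        for i in range(n):
            by_contig.setdefault(contig_of[i], []).append(i)
        for contig, idxs in by_contig.items():
            comps = {comp_of[i] for i in idxs}
            if len(comps) > 1:
                log.warning("contig %s ends fall in different linkage groups; merging", contig)
                best = max(
                    idxs,
                    key=lambda i: max(
                        (lod[i, j] for j in range(n) if j != i and comp_of[j] == comp_of[i]),
                        default=0.0,
                    ),
                )
                target = comp_of[best]
                for i in idxs:
                    comp_of[i] = target
        merged: dict[int, list[int]] = {}
        for i in range(n):
            merged.setdefault(comp_of[i], []).append(i)
        components = [sorted(v) for v in merged.values()]
        components.sort(key=lambda c: c[0])
    return components


# ---------------------------------------------------------------------------
# Ordering and cM assignment
# ---------------------------------------------------------------------------

def haldane_cm(r: float) -> float:
    """Haldane map distance in cM; capped at 50 for r at/above 0.5 or undefined."""
    if not np.isfinite(r) or r >= 0.5 - HALDANE_EPS:
        return HALDANE_CAP_CM
    if r <= 0:
        return 0.0
    return float(-50.0 * np.log(1.0 - 2.0 * r))


def _adjacent_cost(order: list[int], r: np.ndarray) -> float:
    cost = 0.0
    for i, j in zip(order, order[1:]):
        rij = r[i, j]
        cost += 0.5 if not np.isfinite(rij) else min(float(rij), 0.5)
    return cost


def order_group(
    members: list[int],
    r: np.ndarray,
    lod: np.ndarray,
    ids: list | None = None,
) -> tuple[list[int], list[float]]:
    """Order one linkage group and assign cumulative centimorgan positions.

    Greedy nearest-neighbour seriation: seed with the pair of highest LOD,
    repeatedly attach the unplaced marker with the smallest recombination
    fraction to either chain end (ties broken by higher LOD, then by id),
    then 2-opt refinement minimizing the sum of adjacent r.  Pairs without
    informative gametes count as r = 0.5 and are joined at the 50-cM cap.
    """
    ids = ids or members
    if len(members) == 1:
        return list(members), [0.0]
    # seed pair
    best_pair, best_lod = None, -np.inf
    for ii, i in enumerate(members):
        for j in members[ii + 1:]:
            if lod[i, j] > best_lod:
                best_pair, best_lod = (i, j), lod[i, j]
    chain = list(best_pair)
    unplaced = [m for m in members if m not in chain]
    while unplaced:
        best = None  # (r, -lod, id, marker, side)
        for m in unplaced:
            for side, anchor in (("left", chain[0]), ("right", chain[-1])):
                rv = r[m, anchor]
                rv = 0.5 if not np.isfinite(rv) else min(float(rv), 0.5)
                key = (rv, -float(lod[m, anchor]), str(ids[members.index(m)]), m, side)
                if best is None or key < best:
                    best = key
        _, _, _, m, side = best
        unplaced.remove(m)
        if side == "left":
            chain.insert(0, m)
        else:
            chain.append(m)
    chain = _two_opt(chain, r)
    cms = [0.0]
    for i, j in zip(chain, chain[1:]):
        rij = r[i, j]
        step = haldane_cm(rij if np.isfinite(rij) else float("nan"))
        if not np.isfinite(rij):
            log.warning("uninformative adjacency in group; joined at %.0f cM cap", HALDANE_CAP_CM)
        cms.append(cms[-1] + step)
    return chain, cms


def _two_opt(order: list[int], r: np.ndarray) -> list[int]:
    """2-opt segment reversal; the adjacent-r objective never increases."""
    order = list(order)
    n = len(order)
    improved = True
    while improved:
        improved = False
        base = _adjacent_cost(order, r)
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                if _adjacent_cost(cand, r) < base - 1e-12:
                    order, base = cand, _adjacent_cost(cand, r)
                    improved = True
    return order


# ---------------------------------------------------------------------------
# The genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapEntry:
    contig: str
    end: str            # "head" | "tail" | deletion marker id
    cm: float
    phase: int          # 1 = genotype sequence flipped to the group convention


@dataclass
class LinkageGroup:
    entries: list[MapEntry]

    @property
    def length_cm(self) -> float:
        return self.entries[-1].cm - self.entries[0].cm if self.entries else 0.0


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    sequences: dict | None = field(default=None, compare=False, repr=False)

    def __eq__(self, other) -> bool:  # round-trip equality ignores sequences
        return isinstance(other, GeneticMap) and self.groups == other.groups

    @property
    def total_length_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    def contig_group(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for gi, group in enumerate(self.groups):
            for e in group.entries:
                out.setdefault(e.contig, gi)
        return out

    def contig_phase(self) -> dict[str, int]:
        """Per-contig phase value (head entry preferred, else first entry)."""
        out: dict[str, int] = {}
        for group in self.groups:
            for e in group.entries:
                if e.end == "head" or e.contig not in out:
                    out[e.contig] = e.phase
        return out


def build_genetic_map(
    virtual_markers: list,
    lod_threshold: float = LOD_THRESHOLD,
    max_missing: float = 0.10,
) -> GeneticMap:
    """Build the map from contig-end virtual markers.

    ``virtual_markers`` is a list of :class:`~haplobin.phasing.VirtualMarker`.
    Markers missing in more than ``max_missing`` of gametes are dropped before
    grouping.  Per-marker phase values are propagated along the maximum-LOD
    spanning tree of each group, rooted at the first marker in map order.
    """
    vms = [
        vm for vm in virtual_markers
        if np.count_nonzero(vm.sequence == 0) / len(vm.sequence) <= max_missing
    ]
    if not vms:
        return GeneticMap(groups=[])
    keys = [(vm.contig, vm.end) for vm in vms]
    seqs = [vm.sequence for vm in vms]
    r, lod, flip, _ = pairwise_linkage(seqs)
    contig_of = {i: vm.contig for i, vm in enumerate(vms)}
    components = group_markers(keys, lod, contig_of, lod_threshold)

    groups: list[LinkageGroup] = []
    for comp in components:
        chain, cms = order_group(comp, r, lod, ids=[keys[i] for i in comp])
        phases = _propagate_phases(chain, comp, lod, flip)
        entries = [
            MapEntry(contig=keys[i][0], end=keys[i][1], cm=float(c), phase=int(phases[i]))
            for i, c in zip(chain, cms)
        ]
        groups.append(LinkageGroup(entries=entries))
    groups.sort(key=lambda g: (-len(g.entries), g.entries[0].contig))
    sequences = {keys[i]: seqs[i] for i in range(len(vms))}
    return GeneticMap(groups=groups, sequences=sequences)


def _propagate_phases(
    chain: list[int], comp: list[int], lod: np.ndarray, flip: np.ndarray
) -> dict[int, int]:
    g = nx.Graph()
    g.add_nodes_from(comp)
    for ii, i in enumerate(comp):
        for j in comp[ii + 1:]:
            g.add_edge(i, j, weight=float(lod[i, j]))
    tree = nx.maximum_spanning_tree(g)
    phases = {chain[0]: 0}
    for parent, child in nx.bfs_edges(tree, chain[0]):
        phases[child] = phases[parent] ^ int(flip[parent, child])
    return phases


# ---------------------------------------------------------------------------
# Deletion markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeletionPlacement:
    region_id: str
    group: int
    cm: float
    phase: int              # presence allele 'a' maps to group hap a (0) or b (1)
    anchor: tuple
    divergence: float


def deletion_genotype_sequence(
    read_counts: np.ndarray,
    coverages: np.ndarray,
    region_length: int,
    short_read_length: int = 150,
    min_reads: int = 1,
    expected_reads_for_absence: float = 2.0,
) -> np.ndarray:
    """Per-gamete a/b/n sequence for one deletion region.

    'a' when reads are present; a zero count is recoded to 'b' (region absent)
    only when the gamete's depth made >= ``expected_reads_for_absence`` reads
    likely, otherwise absence of reads is uninformative and stays 'n'.
    """
    counts = np.asarray(read_counts)
    expected = np.asarray(coverages) * region_length / short_read_length
    seq = np.zeros(len(counts), dtype=np.int8)
    seq[counts >= min_reads] = 1
    seq[(counts < min_reads) & (expected >= expected_reads_for_absence)] = 2
    return seq


def integrate_deletion_marker(
    region_id: str,
    sequence: np.ndarray,
    gmap: GeneticMap,
    max_divergence: float = 0.1,
    min_overlap: int = 30,
) -> DeletionPlacement | None:
    """Place a deletion marker at the position of the placed marker with the
    minimum genotype-sequence divergence (over both phase assignments);
    unplaced when the minimum exceeds ``max_divergence`` or the informative
    overlap is too small."""
    if not gmap.groups:
        raise ValueError("empty genetic map")
    if gmap.sequences is None:
        raise ValueError("map carries no marker sequences; rebuild with build_genetic_map")
    placements = {}
    for gi, group in enumerate(gmap.groups):
        for e in group.entries:
            placements[(e.contig, e.end)] = (gi, e.cm, e.phase)
    seq = np.asarray(sequence)
    best = None  # (div, flip_rel, key)
    for key, mseq in gmap.sequences.items():
        if key not in placements:
            continue
        both = (seq != 0) & (mseq != 0)
        overlap = int(np.count_nonzero(both))
        if overlap < min_overlap:
            continue
        mism = int(np.count_nonzero(both & (seq != mseq)))
        for flip_rel, div in ((0, mism / overlap), (1, (overlap - mism) / overlap)):
            if best is None or div < best[0]:
                best = (div, flip_rel, key)
    if best is None or best[0] > max_divergence:
        return None
    div, flip_rel, key = best
    gi, cm, anchor_phase = placements[key]
    return DeletionPlacement(
        region_id=region_id, group=gi, cm=cm,
        phase=anchor_phase ^ flip_rel, anchor=key, divergence=div,
    )
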