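"""Haplotype-specific long-read binning.

Each read (via its best alignment) is assigned to one of 2 x (number of
linkage groups) bins by three cases, in order: (1) a read covering phased SNP
markers votes with its base at every marker and goes to the majority
haplotype; (2) a read covering no SNP marker but overlapping a placed
deletion region goes to the haplotype possessing the region; (3) a read
overlapping only conserved regions is assigned uniformly at random (seeded).
Reads on contigs absent from the genetic map, or matching no case, stay
unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_map import DeletionPlacement, GeneticMap
from .io import PafAlignment
from .phasing import ContigPhase

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    group: int | None       # linkage group index, None when unassigned
    haplotype: str          # "A" | "B" | "unassigned"
    evidence: str           # "snp_vote" | "deletion" | "random" | "none"
    votes_a: int = 0
    votes_b: int = 0


@dataclass
class BinningContext:
    """Per-contig lookup structures for read assignment.

    For each contig placed in the genetic map: sorted SNP positions with the
    base each group haplotype (A/B) carries there, placed deletion intervals
    with their possessing haplotype, and conserved intervals.
    """

    contig_group: dict[str, int]
    snp_positions: dict[str, np.ndarray] = field(default_factory=dict)
    allele_a: dict[str, np.ndarray] = field(default_factory=dict)   # uint8 base codes
    allele_b: dict[str, np.ndarray] = field(default_factory=dict)
    ref_allele: dict[str, np.ndarray] = field(default_factory=dict)
    deletions: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    conserved: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        phases: dict[str, ContigPhase],
        gmap: GeneticMap,
        deletion_placements: dict[str, DeletionPlacement] | None = None,
        deletion_regions: pd.DataFrame | None = None,
        conserved_regions: pd.DataFrame | None = None,
    ) -> "BinningContext":
        contig_group = gmap.contig_group()
        contig_phase = gmap.contig_phase()
        ctx = cls(contig_group=contig_group)
        for contig, phase in phases.items():
            if contig not in contig_group:
                continue
            p = contig_phase.get(contig, 0)
            local_a = phase.hap_a_alleles
            local_b = phase.hap_b_alleles
            if p == 1:
                local_a, local_b = local_b, local_a
            ctx.snp_positions[contig] = np.asarray(phase.positions)
            ctx.allele_a[contig] = np.frombuffer("".join(local_a).encode(), dtype=np.uint8)
            ctx.allele_b[contig] = np.frombuffer("".join(local_b).encode(), dtype=np.uint8)
            ctx.ref_allele[contig] = np.frombuffer("".join(phase.ref_alleles).encode(), dtype=np.uint8)
        if deletion_placements and deletion_regions is not None:
            reg = deletion_regions.drop_duplicates("region_id").set_index("region_id")
            for rid, pl in deletion_placements.items():
                if pl is None or rid not in reg.index:
                    continue
                row = reg.loc[rid]
                possessing = "A" if pl.phase == 0 else "B"
                ctx.deletions.setdefault(str(row.contig), []).append(
                    (int(row.start), int(row.end), possessing)
                )
        if conserved_regions is not None:
            for r in conserved_regions.itertuples():
                ctx.conserved.setdefault(str(r.contig), []).append((int(r.start), int(r.end)))
        return ctx


def assign_read(
    aln: PafAlignment,
    ctx: BinningContext,
    rng: np.random.Generator,
    min_purity: float = 0.0,
) -> ReadAssignment:
    """Assign one read by the three-case rule (see module docstring).

    The read base at each covered marker is its recorded substitution there,
    or the reference base when no substitution is recorded; a base matching
    neither haplotype's allele abstains.  A vote tie is broken at random
    (seeded) and still reported as snp_vote evidence with equal votes.  With
    ``min_purity`` > 0, reads whose winning-vote fraction falls below the
    threshold are demoted to the non-SNP cases.
    """
    group = ctx.contig_group.get(aln.contig)
    if group is None:
        return ReadAssignment(aln.read_id, None, "unassigned", "none")
    votes_a = votes_b = 0
    pos = ctx.snp_positions.get(aln.contig)
    if pos is not None and len(pos) and aln.has_cs:
        lo = int(np.searchsorted(pos, aln.target_start))
        hi = int(np.searchsorted(pos, aln.target_end))
        aa = ctx.allele_a[aln.contig]
        bb = ctx.allele_b[aln.contig]
        ref = ctx.ref_allele[aln.contig]
        for j in range(lo, hi):
            base = aln.substitutions.get(int(pos[j]))
            code = ord(base.upper()) if base is not None else int(ref[j])
            if code == aa[j]:
                votes_a += 1
            elif code == bb[j]:
                votes_b += 1
    total = votes_a + votes_b
    if total > 0 and (min_purity <= 0 or max(votes_a, votes_b) / total >= min_purity):
        if votes_a > votes_b:
            hap = "A"
        elif votes_b > votes_a:
            hap = "B"
        else:
            hap = "A" if rng.random() < 0.5 else "B"
        return ReadAssignment(aln.read_id, group, hap, "snp_vote", votes_a, votes_b)
    for start, end, possessing in ctx.deletions.get(aln.contig, []):
        if start < aln.target_end and end > aln.target_start:
            return ReadAssignment(aln.read_id, group, possessing, "deletion")
    for start, end in ctx.conserved.get(aln.contig, []):
        if start < aln.target_end and end > aln.target_start:
            hap = "A" if rng.random() < 0.5 else "B"
            return ReadAssignment(aln.read_id, group, hap, "random")
    return ReadAssignment(aln.read_id, None, "unassigned", "none")


@dataclass
class BinningSummary:
    n_reads: int
    n_assigned: int
    by_evidence: dict[str, int]

    @property
    def fraction_assigned(self) -> float:
        return self.n_assigned / self.n_reads if self.n_reads else 0.0


def bin_reads(
    alignments: list[PafAlignment],
    ctx: BinningContext,
    seed: int = 0,
    min_purity: float = 0.0,
) -> tuple[pd.DataFrame, BinningSummary]:
    """Assign every read exactly once across bins + unassigned.

    Duplicate read ids keep the first alignment (alignments are expected
    pre-sorted best-first) with a warning.
    """
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    rows = []
    by_evidence: dict[str, int] = {}
    for aln in alignments:
        if aln.read_id in seen:
            log.warning("duplicate read id %s; keeping first alignment", aln.read_id)
            continue
        seen.add(aln.read_id)
        asg = assign_read(aln, ctx, rng, min_purity)
        by_evidence[asg.evidence] = by_evidence.get(asg.evidence, 0) + 1
        rows.append(
            {"read_id": asg.read_id, "group": asg.group if asg.group is not None else -1,
             "haplotype": asg.haplotype, "evidence": asg.evidence,
             "votes_a": asg.votes_a, "votes_b": asg.votes_b}
        )
    table = pd.DataFrame(
        rows, columns=["read_id", "group", "haplotype", "evidence", "votes_a", "votes_b"]
    )
    n_assigned = int((table.haplotype != "unassigned").sum()) if len(table) else 0
    return table, BinningSummary(len(table), n_assigned, by_evidence)


def bin_membership(table: pd.DataFrame) -> dict[tuple[int, str], list[str]]:
    """Per-(linkage group, haplotype) read-id lists."""
    out: dict[tuple[int, str], list[str]] = {}
    assigned = table[table.haplotype.isin(["A", "B"])]
    for r in assigned.itertuples():
        out.setdefault((int(r.group), r.haplotype), []).append(r.read_id)
    return out
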