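"""End-to-end orchestration: markers -> genotypes -> phasing -> ploidy screen
-> virtual markers -> genetic map -> deletion integration -> crossover
detection -> read binning, plus truth-based evaluation helpers for synthetic
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crossovers as xo
from .binning import BinningContext, BinningSummary, bin_reads
from .gametes import GenotypeMatrix, build_genotype_matrix, screen_ploidy
from .genetic_map import (
    GeneticMap,
    build_genetic_map,
    deletion_genotype_sequence,
    integrate_deletion_marker,
)
from .markers import (
    RegionClassifierConfig,
    SnpFilterConfig,
    classify_regions,
    find_markerless_regions,
    select_snp_markers,
)
from .phasing import ContigPhase, impute_virtual_markers, phase_all_contigs
from .simulate import (
    SimulatedDataset,
    SimulationConfig,
    pooled_depth_for_intervals,
    simulate_all,
    simulate_region_observations,
)


@dataclass
class PipelineConfig:
    """Analysis thresholds (the simulator's knobs live in SimulationConfig)."""

    snp_filter: SnpFilterConfig = field(default_factory=SnpFilterConfig)
    region: RegionClassifierConfig = field(default_factory=RegionClassifierConfig)
    mode_depth: int = 208
    dominance_ratio: float = 3.0
    ploidy_threshold_per_100: float = 5.0
    ploidy_min_covered: int = 30
    lod_threshold: float = 3.0
    max_missing: float = 0.10
    min_support: int = 5
    max_divergence: float = 0.1
    min_deletion_overlap: int = 30


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    markers: pd.DataFrame
    regions: pd.DataFrame                  # classified markerless regions
    matrix: GenotypeMatrix                 # raw calls
    phases: dict[str, ContigPhase]
    phased: GenotypeMatrix
    ploidy: object
    haploid_ids: list[str]
    gmap: GeneticMap
    deletion_placements: dict
    assignments: pd.DataFrame
    summary: BinningSummary
    config: PipelineConfig


def run_pipeline(
    sim_config: SimulationConfig | None = None,
    dataset: SimulatedDataset | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full method on a synthetic dataset (simulated here unless
    provided)."""
    config = config or PipelineConfig()
    if dataset is None:
        if sim_config is None:
            raise ValueError("need a SimulationConfig or a SimulatedDataset")
        dataset = simulate_all(sim_config)
    truth = dataset.truth

    # 1. markers
    markers = select_snp_markers(dataset.candidates, config.snp_filter)
    contig_lengths = {
        str(r.contig): int(r.end - r.start) for r in truth.contigs.itertuples()
    }
    raw_regions = find_markerless_regions(markers, contig_lengths, config.region)
    depths = pooled_depth_for_intervals(truth, raw_regions, config.mode_depth)
    regions = classify_regions(raw_regions, depths, config.region)

    # 2. genotypes
    gamete_ids = list(truth.gametes.gamete)
    matrix = build_genotype_matrix(
        dataset.snp_obs, markers, gamete_ids, config.dominance_ratio
    )

    # 3. phase with everyone, screen ploidy, re-phase on haploids
    _, phased0 = phase_all_contigs(matrix)
    ploidy = screen_ploidy(
        phased0, config.ploidy_threshold_per_100, config.ploidy_min_covered
    )
    haploid_ids = ploidy.haploid_ids
    haploid_mask = np.array([g in set(haploid_ids) for g in gamete_ids])
    phases, phased = phase_all_contigs(matrix, gamete_mask=haploid_mask)

    # 4. virtual end markers over the haploid set
    vms = []
    for contig, phase in phases.items():
        sl = matrix.contig_slice(contig)
        head, tail = impute_virtual_markers(
            phase, phased.calls[haploid_mask][:, sl], config.min_support
        )
        vms.extend([head, tail])
    gmap = build_genetic_map(vms, config.lod_threshold, config.max_missing)

    # 5. deletion markers: genotype discovered deletion regions, integrate
    deletion_regions = regions[regions.kind == "deletion"].reset_index(drop=True)
    placements: dict = {}
    if len(deletion_regions) and gmap.groups:
        del_obs = simulate_region_observations(truth, deletion_regions, truth.config)
        del_obs = del_obs[del_obs.gamete.isin(set(haploid_ids))]
        genome_len = sum(contig_lengths.values())
        cov_by_gamete = {
            r.gamete: r.total_mapped * truth.config.short_read_length / genome_len
            for r in del_obs.drop_duplicates("gamete").itertuples()
        }
        order = {g: i for i, g in enumerate(haploid_ids)}
        for reg in deletion_regions.itertuples():
            rid = reg.region_id
            sub = del_obs[del_obs.marker_id == rid]
            counts = np.zeros(len(haploid_ids), dtype=int)
            counts[[order[g] for g in sub.gamete]] = sub.read_count.to_numpy()
            covs = np.array([cov_by_gamete.get(g, 0.0) for g in haploid_ids])
            seq = deletion_genotype_sequence(
                counts, covs, int(reg.end - reg.start), truth.config.short_read_length
            )
            placements[rid] = integrate_deletion_marker(
                rid, seq, gmap, config.max_divergence, config.min_deletion_overlap
            )

    # 6. bin the long reads
    conserved = regions[regions.kind == "conserved"][["contig", "start", "end"]]
    ctx = BinningContext.build(
        phases, gmap,
        deletion_placements={k: v for k, v in placements.items() if v is not None},
        deletion_regions=deletion_regions,
        conserved_regions=conserved,
    )
    assignments, summary = bin_reads(dataset.reads, ctx, seed=truth.config.seed)

    return PipelineResult(
        dataset=dataset, markers=markers, regions=regions, matrix=matrix,
        phases=phases, phased=phased, ploidy=ploidy, haploid_ids=haploid_ids,
        gmap=gmap, deletion_placements=placements, assignments=assignments,
        summary=summary, config=config,
    )


# ---------------------------------------------------------------------------
# Linkage-group coordinates and crossover detection
# ---------------------------------------------------------------------------

def group_traversal(gmap: GeneticMap, group_index: int) -> list[tuple[str, int]]:
    """Contigs of one group in map order with direction (+1 forward when the
    head end precedes the tail end, -1 reversed)."""
    entries = gmap.groups[group_index].entries
    seen: dict[str, list[str]] = {}
    order: list[str] = []
    for e in entries:
        if e.contig not in seen:
            order.append(e.contig)
            seen[e.contig] = []
        seen[e.contig].append(e.end)
    out = []
    for contig in order:
        ends = seen[contig]
        direction = -1 if (ends and ends[0] == "tail") else 1
        out.append((contig, direction))
    return out


def group_call_strings(
    result: PipelineResult, group_index: int, gamete_ids: list[str] | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-gamete phased call arrays along one linkage group in map order,
    with bp positions on a concatenated coordinate (contigs laid end to end
    in traversal order).  Contig phase values are applied so all calls share
    the group's a/b convention."""
    gmap = result.gmap
    matrix = result.phased
    contig_phase = gmap.contig_phase()
    contig_lengths = {
        str(r.contig): int(r.end - r.start)
        for r in result.dataset.truth.contigs.itertuples()
    }
    gamete_ids = gamete_ids or result.haploid_ids
    gidx = [result.matrix.gamete_ids.index(g) for g in gamete_ids]

    positions_parts: list[np.ndarray] = []
    calls_parts: list[np.ndarray] = []
    offset = 0
    for contig, direction in group_traversal(gmap, group_index):
        sl = matrix.contig_slice(contig)
        if len(sl) == 0:
            offset += contig_lengths.get(contig, 0)
            continue
        pos = matrix.markers.start.to_numpy()[sl]
        calls = matrix.calls[np.ix_(gidx, sl)]
        length = contig_lengths.get(contig, int(pos.max()) + 1)
        if direction == -1:
            pos = length - 1 - pos[::-1]
            calls = calls[:, ::-1]
        if contig_phase.get(contig, 0) == 1:
            calls = np.where(calls == 1, 2, np.where(calls == 2, 1, 0))
        positions_parts.append(pos + offset)
        calls_parts.append(calls)
        offset += length
    if not positions_parts:
        return np.array([], dtype=int), {g: np.array([], dtype=np.int8) for g in gamete_ids}
    positions = np.concatenate(positions_parts)
    calls = np.concatenate(calls_parts, axis=1)
    strings = {g: calls[i] for i, g in enumerate(gamete_ids)}
    return positions, strings


def detect_all_crossovers(result: PipelineResult, min_support: int | None = None) -> pd.DataFrame:
    """Crossover events for every gamete in every linkage group."""
    min_support = min_support or result.config.min_support
    parts = []
    for gi in range(len(result.gmap.groups)):
        positions, strings = group_call_strings(result, gi)
        if len(positions) == 0:
            continue
        parts.append(xo.detect_crossovers(strings, positions, group=str(gi), min_support=min_support))
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Truth-based evaluation (synthetic data only)
# ---------------------------------------------------------------------------

def group_truth_haplotype(result: PipelineResult) -> dict[int, int]:
    """For each linkage group, the simulator haplotype (0/1) that the group's
    haplotype "A" corresponds to, by majority vote over SNP markers.

    A marker's group-A allele is compared with the truth table: when group A
    carries the alternative allele, group A matches the haplotype that truly
    carries it.
    """
    truth = result.dataset.truth
    gmap = result.gmap
    contig_group = gmap.contig_group()
    contig_phase = gmap.contig_phase()
    truth_by_key = {
        (r.contig, r.ctg_pos): r.hap_with_alt for r in truth.snps.itertuples()
    }
    votes: dict[int, list[int]] = {}
    for contig, phase in result.phases.items():
        gi = contig_group.get(contig)
        if gi is None:
            continue
        p = contig_phase.get(contig, 0)
        for pos, o, ref, alt in zip(
            phase.positions, phase.orientations, phase.ref_alleles, phase.alt_alleles
        ):
            h = truth_by_key.get((contig, int(pos)))
            if h is None:
                continue
            alt_is_a = (o == 1) == (p == 0)
            votes.setdefault(gi, []).append(h if alt_is_a else 1 - h)
    return {gi: int(round(np.mean(v))) for gi, v in votes.items() if v}


def snp_vote_precision(result: PipelineResult) -> tuple[float, int]:
    """Fraction (in %) of SNP-voted reads assigned to their true haplotype,
    and the number of such reads."""
    truth_reads = result.dataset.truth.reads.set_index("read_id")
    mapping = group_truth_haplotype(result)
    voted = result.assignments[result.assignments.evidence == "snp_vote"]
    n_correct = 0
    n_total = 0
    for r in voted.itertuples():
        gi = int(r.group)
        if gi not in mapping:
            continue
        true_hap = int(truth_reads.loc[r.read_id, "hap"])
        assigned_hap = mapping[gi] if r.haplotype == "A" else 1 - mapping[gi]
        n_total += 1
        n_correct += int(assigned_hap == true_hap)
    return (100.0 * n_correct / n_total if n_total else float("nan")), n_total


def map_order_agreement(result: PipelineResult) -> tuple[int, float]:
    """(number of linkage groups, mean |Kendall tau| between map order and the
    true contig order within groups)."""
    from scipy.stats import kendalltau

    truth = result.dataset.truth
    true_rank = {
        str(r.contig): (str(r.chrom), int(r.order)) for r in truth.contigs.itertuples()
    }
    taus = []
    for gi in range(len(result.gmap.groups)):
        contigs = [c for c, _ in group_traversal(result.gmap, gi)]
        ranks = [true_rank[c][1] for c in contigs if c in true_rank]
        if len(ranks) >= 3:
            tau, _ = kendalltau(np.arange(len(ranks)), ranks)
            if np.isfinite(tau):
                taus.append(abs(tau))
        elif len(ranks) == 2:
            taus.append(1.0)
    return len(result.gmap.groups), float(np.mean(taus)) if taus else float("nan")
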