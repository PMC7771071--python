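"""Synthetic diploid genomes, recombinant gametes, sparse observations and
haplotype-tagged long reads, with full ground truth.

The generator emulates the statistical structure that gamete-based phasing
assumes: a heterozygous diploid whose two haplotypes differ at SNPs and at
haplotype-specific (deletion-like) regions, a fragmented "curated assembly"
carrying the reference allele at every SNP, hundreds of haploid gamete
genomes that are recombinant mosaics of the two haplotypes, shallow and
error-prone per-gamete allele observations (optionally pooled into doublets),
and long reads drawn from one haplotype each.

Deletion regions are modelled at the read-count level on the shared
coordinate frame: one haplotype simply produces no reads there.  This keeps a
single coordinate system for all truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PafAlignment, SnpCandidate

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults describe a desk-scale diploid: two 1-Mb chromosomes, one SNP per
    500 bp, 10% of the genome haplotype-specific, 200 gametes sequenced at a
    mean of 0.3x with 0.5% per-base genotyping error.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    snp_rate: float = 1 / 500
    deletion_fraction: float = 0.10
    conserved_fraction: float = 0.10
    deletion_mean_length: int = 15_000
    conserved_mean_length: int = 10_000
    contig_mean_length: int = 200_000
    contig_min_length: int = 30_000
    n_gametes: int = 200
    co_lambda: float = 1.0          # mean COs per chromosome per gamete
    obligate_co: bool = False
    co_min_distance: int = 0        # optional minimum bp between COs
    coverage: float = 0.3           # mean per-gamete depth (x)
    coverage_sigma: float = 0.5     # log-normal spread of per-gamete depth
    short_read_length: int = 150
    error_rate: float = 0.005       # per observed base, wrong-allele probability
    doublet_fraction: float = 0.0
    deletion_background_mean: float = 0.05  # false-positive reads in absent regions
    n_reads: int = 10_000
    read_length_mean: int = 15_000
    read_length_sd: int = 1_500
    read_min_length: int = 1_000
    read_error_rate: float = 0.0    # substitution noise at marker sites in long reads
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "deletion_fraction", "conserved_fraction",
                     "error_rate", "doublet_fraction", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.co_lambda < 0:
            raise ValueError("co_lambda must be >= 0")
        for name in ("n_chromosomes", "chromosome_length", "contig_mean_length",
                     "n_gametes", "short_read_length", "read_length_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.deletion_fraction + self.conserved_fraction >= 0.9:
            raise ValueError("deletion + conserved fractions leave too little SNP territory")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation; filled incrementally by the stages."""

    config: SimulationConfig
    chromosomes: dict[str, int]
    assembly: dict[str, np.ndarray]               # chrom -> uint8 base codes (0..3)
    snps: pd.DataFrame                            # chrom,pos,contig,ctg_pos,ref,alt,hap_with_alt
    regions: pd.DataFrame                         # region pieces clipped to contigs
    contigs: pd.DataFrame                         # contig,chrom,start,end,order,orientation
    # gamete stage
    gametes: pd.DataFrame | None = None           # gamete,is_doublet,components,coverage
    crossovers: pd.DataFrame | None = None        # underlying,chrom,pos
    mosaics: dict[tuple[int, str], tuple[int, np.ndarray]] = field(default_factory=dict)
    underlying_coverage: np.ndarray | None = None
    # read stage
    reads: pd.DataFrame | None = None             # read_id,hap,chrom,start,end,contig

    # -- sequence helpers ---------------------------------------------------

    def assembly_sequence(self, chrom: str) -> str:
        return _BASES[self.assembly[chrom]].tobytes().decode()

    def haplotype_sequence(self, chrom: str, hap: int, apply_deletions: bool = True) -> str:
        """Haplotype sequence: assembly with this haplotype's alternative
        alleles substituted and (optionally) its absent regions excised."""
        codes = self.assembly[chrom].copy()
        sub = self.snps[(self.snps.chrom == chrom) & (self.snps.hap_with_alt == hap)]
        if len(sub):
            alt_codes = np.frombuffer("".join(sub.alt).encode(), dtype=np.uint8)
            codes[sub.pos.to_numpy()] = _base_codes(alt_codes)
        if apply_deletions:
            absent = self.regions[
                (self.regions.chrom == chrom)
                & (self.regions.kind == "deletion")
                & (self.regions.present_in != hap)
            ]
            keep = np.ones(len(codes), dtype=bool)
            for r in absent.itertuples():
                keep[r.start:r.end] = False
            codes = codes[keep]
        return _BASES[codes].tobytes().decode()

    def gamete_hap_at(self, underlying: int, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Inherited haplotype (0/1) of one underlying gamete at positions."""
        start_hap, breaks = self.mosaics[(underlying, chrom)]
        return (start_hap + np.searchsorted(breaks, positions, side="right")) % 2

    def contig_of(self, chrom: str, pos: int) -> tuple[str, int]:
        sub = self.contigs[self.contigs.chrom == chrom]
        idx = int(np.searchsorted(sub.start.to_numpy(), pos, side="right")) - 1
        row = sub.iloc[idx]
        return row.contig, pos - int(row.start)


def _base_codes(ascii_codes: np.ndarray) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
    return lut[ascii_codes]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


# ---------------------------------------------------------------------------
# Stage 1: the diploid genome
# ---------------------------------------------------------------------------

def simulate_diploid(config: SimulationConfig) -> SyntheticTruth:
    """Draw the diploid genome: assembly, SNPs, regions, contig fragmentation."""
    rng = _rng(config, 1)
    L = config.chromosome_length
    chromosomes = {f"chr{i + 1}": L for i in range(config.n_chromosomes)}
    assembly: dict[str, np.ndarray] = {}
    snp_rows: list[dict] = []
    region_rows: list[dict] = []
    contig_rows: list[dict] = []

    for chrom in chromosomes:
        assembly[chrom] = rng.integers(0, 4, size=L, dtype=np.uint8)

        # Haplotype-specific and conserved regions, placed without overlap.
        segs: list[tuple[int, str]] = []
        for kind, frac, mean in (
            ("deletion", config.deletion_fraction, config.deletion_mean_length),
            ("conserved", config.conserved_fraction, config.conserved_mean_length),
        ):
            n = int(round(frac * L / mean)) if frac > 0 else 0
            for _ in range(n):
                length = int(rng.uniform(mean / 3, mean * 5 / 3))
                segs.append((length, kind))
        order = rng.permutation(len(segs))
        segs = [segs[i] for i in order]
        free = L - sum(length for length, _ in segs)
        if free < 0:
            raise ValueError("region fractions exceed chromosome length")
        gaps = rng.dirichlet(np.ones(len(segs) + 1)) * free if segs else np.array([free])
        pos = 0
        for (length, kind), gap in zip(segs, gaps[:-1]):
            pos += int(gap)
            present_in = int(rng.integers(0, 2)) if kind == "deletion" else -1
            region_rows.append(
                {"chrom": chrom, "start": pos, "end": pos + length,
                 "kind": kind, "present_in": present_in}
            )
            pos += length

        # SNPs in the remaining territory.
        hits = np.flatnonzero(rng.random(L) < config.snp_rate)
        blocked = np.zeros(L, dtype=bool)
        for r in region_rows:
            if r["chrom"] == chrom:
                blocked[r["start"]:r["end"]] = True
        hits = hits[~blocked[hits]]
        if len(hits) == 0:
            import warnings

            warnings.warn(f"no SNP markers simulated on {chrom}; rates too low")
        ref_codes = assembly[chrom][hits]
        alt_codes = (ref_codes + rng.integers(1, 4, size=len(hits))) % 4
        haps = rng.integers(0, 2, size=len(hits))
        for p, rc, ac, h in zip(hits, ref_codes, alt_codes, haps):
            snp_rows.append(
                {"chrom": chrom, "pos": int(p), "ref": "ACGT"[rc], "alt": "ACGT"[ac],
                 "hap_with_alt": int(h)}
            )

        # Fragment into contigs (exponential spacing, minimum length enforced).
        cuts: list[int] = []
        pos = 0
        while True:
            pos += max(config.contig_min_length, int(rng.exponential(config.contig_mean_length)))
            if pos >= L - config.contig_min_length:
                break
            cuts.append(pos)
        bounds = [0] + cuts + [L]
        for i in range(len(bounds) - 1):
            contig_rows.append(
                {"contig": f"{chrom}_c{i + 1:02d}", "chrom": chrom,
                 "start": bounds[i], "end": bounds[i + 1], "order": i, "orientation": "+"}
            )

    contigs = pd.DataFrame(contig_rows)
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt", "hap_with_alt"])
    snps = _attach_contigs(snps, contigs)
    regions = _clip_regions(pd.DataFrame(region_rows), contigs)
    return SyntheticTruth(
        config=config, chromosomes=chromosomes, assembly=assembly,
        snps=snps, regions=regions, contigs=contigs,
    )


def _attach_contigs(snps: pd.DataFrame, contigs: pd.DataFrame) -> pd.DataFrame:
    snps = snps.copy()
    snps["contig"] = ""
    snps["ctg_pos"] = 0
    for chrom, sub in contigs.groupby("chrom"):
        mask = snps.chrom == chrom
        starts = sub.start.to_numpy()
        idx = np.searchsorted(starts, snps.loc[mask, "pos"].to_numpy(), side="right") - 1
        snps.loc[mask, "contig"] = sub.contig.to_numpy()[idx]
        snps.loc[mask, "ctg_pos"] = snps.loc[mask, "pos"].to_numpy() - starts[idx]
    return snps.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _clip_regions(regions: pd.DataFrame, contigs: pd.DataFrame) -> pd.DataFrame:
    """Intersect chromosome-frame regions with contigs -> per-contig pieces."""
    rows = []
    for r in regions.itertuples():
        sub = contigs[contigs.chrom == r.chrom]
        for c in sub.itertuples():
            s, e = max(r.start, c.start), min(r.end, c.end)
            if e > s:
                rows.append(
                    {"chrom": r.chrom, "start": s, "end": e, "kind": r.kind,
                     "present_in": r.present_in, "contig": c.contig,
                     "ctg_start": s - c.start, "ctg_end": e - c.start,
                     "region_id": f"{c.contig}:{s - c.start}-{e - c.start}"}
                )
    cols = ["chrom", "start", "end", "kind", "present_in",
            "contig", "ctg_start", "ctg_end", "region_id"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Stage 2: recombinant gametes
# ---------------------------------------------------------------------------

def simulate_gametes(truth: SyntheticTruth, config: SimulationConfig | None = None) -> SyntheticTruth:
    """Draw per-gamete crossover mosaics (Poisson CO counts, uniform positions)
    and the doublet structure.  Doublets pool two independent underlying
    gametes under one visible id."""
    config = config or truth.config
    rng = _rng(config, 2)
    n_doublets = int(round(config.doublet_fraction * config.n_gametes))
    n_underlying = config.n_gametes + n_doublets

    co_rows = []
    for u in range(n_underlying):
        for chrom, L in truth.chromosomes.items():
            k = rng.poisson(config.co_lambda)
            if config.obligate_co and k == 0:
                k = 1 + rng.poisson(config.co_lambda)
            for _ in range(64):
                breaks = np.sort(rng.integers(1, L, size=k))
                if k < 2 or config.co_min_distance <= 0 or np.all(
                    np.diff(breaks) >= config.co_min_distance
                ):
                    break
            start_hap = int(rng.integers(0, 2))
            truth.mosaics[(u, chrom)] = (start_hap, breaks)
            for b in breaks:
                co_rows.append({"underlying": u, "chrom": chrom, "pos": int(b)})

    coverages = config.coverage * rng.lognormal(
        -config.coverage_sigma**2 / 2, config.coverage_sigma, size=n_underlying
    )
    truth.underlying_coverage = coverages
    gam_rows = []
    n_single = config.n_gametes - n_doublets
    for v in range(config.n_gametes):
        if v < n_single:
            comps = [v]
        else:
            comps = [v, config.n_gametes + (v - n_single)]
        gam_rows.append(
            {"gamete": f"g{v:04d}", "is_doublet": len(comps) > 1,
             "components": ",".join(map(str, comps)),
             "coverage": float(sum(coverages[c] for c in comps))}
        )
    truth.gametes = pd.DataFrame(gam_rows)
    truth.crossovers = pd.DataFrame(co_rows, columns=["underlying", "chrom", "pos"])
    return truth


# ---------------------------------------------------------------------------
# Stage 3: sparse observations
# ---------------------------------------------------------------------------

def simulate_observations(
    truth: SyntheticTruth, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gamete allele counts at every true SNP and read counts at every
    deletion-region piece.

    Returns ``(snp_obs, deletion_obs)``: snp_obs has columns (gamete,
    marker_id, contig, ctg_pos, ref_count, alt_count); deletion_obs has
    (gamete, marker_id, read_count, rpkm, total_mapped).
    """
    config = config or truth.config
    if truth.gametes is None:
        raise ValueError("simulate_gametes must run before simulate_observations")
    rng = _rng(config, 3)
    gametes = truth.gametes
    comp_lists = [list(map(int, c.split(","))) for c in gametes.components]
    underlying_cov = _underlying_coverages(truth, config)

    snp_parts = []
    for chrom in truth.chromosomes:
        sub = truth.snps[truth.snps.chrom == chrom]
        P = sub.pos.to_numpy()
        H = sub.hap_with_alt.to_numpy()
        M = len(P)
        if M == 0:
            continue
        total_ref = np.zeros((len(gametes), M), dtype=np.int32)
        total_alt = np.zeros((len(gametes), M), dtype=np.int32)
        for v, comps in enumerate(comp_lists):
            for u in comps:
                depth = rng.poisson(underlying_cov[u], size=M)
                covered = depth > 0
                if not covered.any():
                    continue
                is_alt = truth.gamete_hap_at(u, chrom, P[covered]) == H[covered]
                p_alt = np.where(is_alt, 1 - config.error_rate, config.error_rate)
                alt_n = rng.binomial(depth[covered], p_alt)
                total_alt[v, covered] += alt_n
                total_ref[v, covered] += depth[covered] - alt_n
        vv, mm = np.nonzero(total_ref + total_alt)
        part = pd.DataFrame(
            {
                "gamete": gametes.gamete.to_numpy()[vv],
                "contig": sub.contig.to_numpy()[mm],
                "ctg_pos": sub.ctg_pos.to_numpy()[mm],
                "ref_count": total_ref[vv, mm],
                "alt_count": total_alt[vv, mm],
            }
        )
        snp_parts.append(part)
    snp_obs = (
        pd.concat(snp_parts, ignore_index=True)
        if snp_parts
        else pd.DataFrame(columns=["gamete", "contig", "ctg_pos", "ref_count", "alt_count"])
    )
    snp_obs["marker_id"] = snp_obs.contig.astype(str) + ":" + snp_obs.ctg_pos.astype(str)

    # Deletion-region read counts.
    genome_len = sum(truth.chromosomes.values())
    del_rows = []
    pieces = truth.regions[truth.regions.kind == "deletion"]
    for v, comps in enumerate(comp_lists):
        total_mapped = sum(
            underlying_cov[u] * genome_len / config.short_read_length for u in comps
        )
        for r in pieces.itertuples():
            count = 0
            mid = np.array([(r.start + r.end) // 2])
            for u in comps:
                carries = truth.gamete_hap_at(u, r.chrom, mid)[0] == r.present_in
                lam = (
                    underlying_cov[u] * (r.end - r.start) / config.short_read_length
                    if carries
                    else config.deletion_background_mean
                )
                count += rng.poisson(lam)
            length_kb = (r.end - r.start) / 1e3
            rpkm = count / (length_kb * (total_mapped / 1e6)) if total_mapped > 0 else float("nan")
            del_rows.append(
                {"gamete": gametes.gamete.iloc[v], "marker_id": r.region_id,
                 "read_count": int(count), "rpkm": rpkm, "total_mapped": int(total_mapped)}
            )
    deletion_obs = pd.DataFrame(
        del_rows, columns=["gamete", "marker_id", "read_count", "rpkm", "total_mapped"]
    )
    return snp_obs, deletion_obs


def _underlying_coverages(truth: SyntheticTruth, config: SimulationConfig) -> np.ndarray:
    if truth.underlying_coverage is None:
        raise ValueError("simulate_gametes must run first")
    return truth.underlying_coverage


# ---------------------------------------------------------------------------
# Stage 4: long reads
# ---------------------------------------------------------------------------

def simulate_long_reads(
    truth: SyntheticTruth, config: SimulationConfig | None = None
) -> list[PafAlignment]:
    """Draw long reads from the two haplotypes and express each as a PAF-style
    alignment to the assembly with cs-style substitutions at the SNPs where
    the read's haplotype carries the alternative allele."""
    config = config or truth.config
    rng = _rng(config, 4)
    chroms = list(truth.chromosomes)
    lengths = np.array([truth.chromosomes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    absent: dict[tuple[str, int], np.ndarray] = {}
    for chrom in chroms:
        for hap in (0, 1):
            sub = truth.regions[
                (truth.regions.chrom == chrom)
                & (truth.regions.kind == "deletion")
                & (truth.regions.present_in != hap)
            ]
            absent[(chrom, hap)] = sub[["start", "end"]].to_numpy()

    contig_index = {
        chrom: sub.sort_values("start").reset_index(drop=True)
        for chrom, sub in truth.contigs.groupby("chrom")
    }
    snp_index = {
        chrom: (
            sub.pos.to_numpy(), sub.hap_with_alt.to_numpy(),
            sub.alt.to_numpy(), sub.ref.to_numpy(),
        )
        for chrom, sub in truth.snps.groupby("chrom")
    }

    records: list[PafAlignment] = []
    truth_rows = []
    for i in range(config.n_reads):
        hap = int(rng.integers(0, 2))
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        L = truth.chromosomes[chrom]
        for _ in range(100):
            rlen = max(config.read_min_length,
                       int(rng.normal(config.read_length_mean, config.read_length_sd)))
            rlen = min(rlen, L)
            start = int(rng.integers(0, L - rlen + 1))
            end = start + rlen
            iv = absent[(chrom, hap)]
            if len(iv) == 0 or not np.any((iv[:, 0] < end) & (iv[:, 1] > start)):
                break
        ctgs = contig_index[chrom]
        ci = int(np.searchsorted(ctgs.start.to_numpy(), start, side="right")) - 1
        ctg = ctgs.iloc[ci]
        tstart = start - int(ctg.start)
        tend = min(end, int(ctg.end)) - int(ctg.start)

        subs: dict[int, str] = {}
        if chrom in snp_index:
            P, H, ALT, REF = snp_index[chrom]
            lo = np.searchsorted(P, start)
            hi = np.searchsorted(P, min(end, int(ctg.end)))
            for j in range(lo, hi):
                base = ALT[j] if H[j] == hap else REF[j]
                if config.read_error_rate > 0 and rng.random() < config.read_error_rate:
                    base = "ACGT"[(("ACGT".index(base)) + int(rng.integers(1, 4))) % 4]
                if base != REF[j]:
                    subs[int(P[j]) - int(ctg.start)] = base
        read_id = f"read{i:06d}"
        records.append(
            PafAlignment(
                read_id=read_id, read_length=rlen, strand="+",
                contig=str(ctg.contig), contig_length=int(ctg.end - ctg.start),
                target_start=tstart, target_end=tend,
                score=tend - tstart, substitutions=subs,
            )
        )
        truth_rows.append(
            {"read_id": read_id, "hap": hap, "chrom": chrom,
             "start": start, "end": end, "contig": str(ctg.contig)}
        )
    truth.reads = pd.DataFrame(truth_rows)
    return records


# ---------------------------------------------------------------------------
# Pooled (bulk) summaries used for marker selection
# ---------------------------------------------------------------------------

def pooled_snp_candidates(
    truth: SyntheticTruth,
    mode_depth: int = 208,
    noise_per_mb: int = 200,
    config: SimulationConfig | None = None,
) -> list[SnpCandidate]:
    """Candidate SNPs as a bulk variant caller would emit them: every true SNP
    at ~50% alternative allele frequency plus error-like noise candidates at
    low frequency (which the frequency filter must remove)."""
    config = config or truth.config
    rng = _rng(config, 5)
    out: list[SnpCandidate] = []
    for r in truth.snps.itertuples():
        total = int(rng.poisson(mode_depth))
        alt = int(rng.binomial(total, 0.5)) if total else 0
        out.append(SnpCandidate(r.contig, int(r.ctg_pos), r.ref, r.alt, alt, total))
    snp_keys = set(zip(truth.snps.contig, truth.snps.ctg_pos))
    for c in truth.contigs.itertuples():
        clen = int(c.end - c.start)
        n_noise = int(round(noise_per_mb * clen / 1e6))
        for _ in range(n_noise):
            p = int(rng.integers(0, clen))
            if (c.contig, p) in snp_keys:
                continue
            total = int(rng.poisson(mode_depth))
            alt = int(rng.binomial(total, 0.05)) if total else 0
            ref = "ACGT"[truth.assembly[c.chrom][c.start + p]]
            alt_base = "ACGT"[("ACGT".index(ref) + 1) % 4]
            out.append(SnpCandidate(c.contig, p, ref, alt_base, alt, total))
    out.sort(key=lambda r: (r.contig, r.pos))
    return out


def pooled_region_depths(
    truth: SyntheticTruth, mode_depth: int = 208, config: SimulationConfig | None = None
) -> dict[str, float]:
    """Mean pooled sequencing depth over each markerless region piece: around
    mode_depth for conserved regions, around half of it for deletion regions
    (only one haplotype contributes reads)."""
    config = config or truth.config
    rng = _rng(config, 6)
    out: dict[str, float] = {}
    for r in truth.regions.itertuples():
        mean = mode_depth / 2 if r.kind == "deletion" else mode_depth
        length = r.end - r.start
        out[r.region_id] = rng.poisson(mean * length) / length
    return out


def simulate_region_observations(
    truth: SyntheticTruth,
    intervals: pd.DataFrame,
    config: SimulationConfig | None = None,
    stage: int = 8,
) -> pd.DataFrame:
    """Per-gamete read counts over arbitrary contig intervals (columns
    contig, start, end), as a coverage tool would report them.  An interval's
    expected count in a gamete is coverage * covered_length / read_length,
    where covered_length excludes haplotype-specific sub-regions the gamete's
    inherited haplotype lacks; a small Poisson background models mismapped
    reads.  Returns (gamete, marker_id, read_count, rpkm, total_mapped)."""
    config = config or truth.config
    if truth.gametes is None:
        raise ValueError("simulate_gametes must run first")
    rng = _rng(config, stage)
    cov = _underlying_coverages(truth, config)
    comp_lists = [list(map(int, c.split(","))) for c in truth.gametes.components]
    ctg = truth.contigs.set_index("contig")
    genome_len = sum(truth.chromosomes.values())
    rows = []
    for iv in intervals.itertuples():
        row = ctg.loc[iv.contig]
        chrom = str(row.chrom)
        g_start, g_end = int(row.start) + int(iv.start), int(row.start) + int(iv.end)
        length = g_end - g_start
        dels = truth.regions[
            (truth.regions.contig == iv.contig)
            & (truth.regions.kind == "deletion")
            & (truth.regions.start < g_end)
            & (truth.regions.end > g_start)
        ]
        marker_id = f"{iv.contig}:{iv.start}-{iv.end}"
        for v, comps in enumerate(comp_lists):
            total_mapped = sum(cov[u] * genome_len / config.short_read_length for u in comps)
            count = 0
            for u in comps:
                present_bp = length
                for r in dels.itertuples():
                    o = min(g_end, r.end) - max(g_start, r.start)
                    mid = np.array([(max(g_start, r.start) + min(g_end, r.end)) // 2])
                    if truth.gamete_hap_at(u, chrom, mid)[0] != r.present_in:
                        present_bp -= o
                lam = cov[u] * present_bp / config.short_read_length
                count += rng.poisson(lam + config.deletion_background_mean)
            rpkm = (
                count / ((length / 1e3) * (total_mapped / 1e6))
                if total_mapped > 0 else float("nan")
            )
            rows.append(
                {"gamete": truth.gametes.gamete.iloc[v], "marker_id": marker_id,
                 "read_count": int(count), "rpkm": rpkm,
                 "total_mapped": int(total_mapped)}
            )
    return pd.DataFrame(
        rows, columns=["gamete", "marker_id", "read_count", "rpkm", "total_mapped"]
    )


def pooled_depth_for_intervals(
    truth: SyntheticTruth,
    intervals: pd.DataFrame,
    mode_depth: int = 208,
    config: SimulationConfig | None = None,
) -> dict[str, float]:
    """Pooled depth over arbitrary contig intervals (columns contig,start,end),
    keyed by "contig:start-end".  Bases inside a haplotype-specific region get
    half the mode depth; shared bases the full mode depth; Poisson noise on
    the interval total."""
    config = config or truth.config
    rng = _rng(config, 7)
    ctg = truth.contigs.set_index("contig")
    out: dict[str, float] = {}
    for iv in intervals.itertuples():
        row = ctg.loc[iv.contig]
        g_start, g_end = int(row.start) + int(iv.start), int(row.start) + int(iv.end)
        dels = truth.regions[
            (truth.regions.contig == iv.contig) & (truth.regions.kind == "deletion")
        ]
        del_bp = 0
        for r in dels.itertuples():
            del_bp += max(0, min(g_end, r.end) - max(g_start, r.start))
        length = g_end - g_start
        expected = mode_depth * (length - del_bp) + (mode_depth / 2) * del_bp
        out[f"{iv.contig}:{iv.start}-{iv.end}"] = rng.poisson(expected) / length
    return out


# ---------------------------------------------------------------------------
# Convenience: run all stages
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    truth: SyntheticTruth
    snp_obs: pd.DataFrame
    deletion_obs: pd.DataFrame
    reads: list[PafAlignment]
    candidates: list[SnpCandidate]
    region_depths: dict[str, float]


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    truth = simulate_diploid(config)
    simulate_gametes(truth, config)
    snp_obs, deletion_obs = simulate_observations(truth, config)
    reads = simulate_long_reads(truth, config)
    candidates = pooled_snp_candidates(truth, config=config)
    depths = pooled_region_depths(truth, config=config)
    return SimulatedDataset(truth, snp_obs, deletion_obs, reads, candidates, depths)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write a simulated dataset to disk in the package's external formats."""
    from . import io as hio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = ds.truth
    haps = {}
    for chrom in truth.chromosomes:
        for hap in (0, 1):
            haps[f"{chrom}_hap{hap}"] = truth.haplotype_sequence(chrom, hap)
    hio.write_fasta(haps, outdir / "haplotypes.fasta")
    hio.write_vcf_candidates(ds.candidates, outdir / "candidates.vcf")
    hio.write_tsv(ds.snp_obs, outdir / "snp_observations.tsv")
    hio.write_tsv(ds.deletion_obs, outdir / "deletion_observations.tsv")
    hio.write_paf_alignments(ds.reads, outdir / "long_reads.paf")
    hio.write_tsv(truth.snps, outdir / "truth_snps.tsv")
    hio.write_tsv(truth.regions, outdir / "truth_regions.tsv")
    hio.write_tsv(truth.contigs, outdir / "truth_contigs.tsv")
    hio.write_tsv(truth.gametes, outdir / "truth_gametes.tsv")
    hio.write_tsv(truth.crossovers, outdir / "truth_crossovers.tsv")
    if truth.reads is not None:
        hio.write_tsv(truth.reads, outdir / "truth_reads.tsv")
    depths = pd.DataFrame(
        [{"region_id": k, "depth": v} for k, v in ds.region_depths.items()]
    )
    hio.write_tsv(depths, outdir / "region_depths.tsv")
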