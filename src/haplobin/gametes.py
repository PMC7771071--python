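"""Per-gamete genotype calls at SNP and deletion markers, and doublet
screening by inter-genotype transition rate.

Raw SNP calls live in {N=0 missing, R=1 reference allele, A=2 alternative
allele}; after phasing the same integer codes mean {n=0, a=1, b=2}.  A gamete
whose phased calls switch genotype more than 5 times per 100 covered markers
is labelled a doublet (two nuclei sharing one barcode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N, R, A = 0, 1, 2          # raw call codes
SYM_RAW = np.array(["N", "R", "A"])
SYM_PHASED = np.array(["n", "a", "b"])


@dataclass
class GenotypeMatrix:
    """gametes x markers call matrix plus the marker metadata that orders it.

    ``markers`` is sorted by (contig, start); ``calls[g, m]`` uses the integer
    codes above.  ``phased`` records whether codes mean R/A or a/b.
    """

    gamete_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    phased: bool = False

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.gamete_ids), len(self.markers)):
            raise ValueError("calls shape does not match id lists")

    def contig_slice(self, contig: str) -> np.ndarray:
        return np.flatnonzero((self.markers.contig == contig).to_numpy())

    @property
    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.markers.contig))

    def to_frame(self) -> pd.DataFrame:
        sym = SYM_PHASED if self.phased else SYM_RAW
        df = pd.DataFrame(
            sym[self.calls], index=self.gamete_ids, columns=self.markers.marker_id
        )
        df.index.name = "gamete"
        return df


def call_snp_genotype(ref_count: int, alt_count: int, dominance_ratio: float = 3.0) -> str:
    """Call one site in one gamete: N if uncovered, the pure allele if only one
    is seen, else the majority allele when it dominates by >= dominance_ratio."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    if ref_count == 0 and alt_count == 0:
        return "N"
    if alt_count == 0:
        return "R"
    if ref_count == 0:
        return "A"
    hi, lo = max(ref_count, alt_count), min(ref_count, alt_count)
    if hi / lo >= dominance_ratio:
        return "R" if ref_count > alt_count else "A"
    return "N"


def call_snp_genotypes(
    ref_counts: np.ndarray, alt_counts: np.ndarray, dominance_ratio: float = 3.0
) -> np.ndarray:
    """Vectorized :func:`call_snp_genotype` returning integer codes."""
    ref = np.asarray(ref_counts)
    alt = np.asarray(alt_counts)
    out = np.zeros(ref.shape, dtype=np.int8)
    out[(alt == 0) & (ref > 0)] = R
    out[(ref == 0) & (alt > 0)] = A
    both = (ref > 0) & (alt > 0)
    hi = np.maximum(ref, alt)
    lo = np.minimum(ref, alt)
    dominant = both & (hi >= dominance_ratio * lo)
    out[dominant & (ref > alt)] = R
    out[dominant & (alt > ref)] = A
    return out


def call_deletion_genotype(
    read_count: int,
    region_length: int,
    total_mapped_reads: int,
    min_reads: int = 1,
) -> tuple[str, float]:
    """Presence/absence call at a deletion marker with its RPKM.

    'a' = reads present (the haplotype carrying the region), 'n' = absent or
    uninformative.  RPKM = count / ((length/1e3) * (total/1e6)); NaN when no
    reads mapped at all (the call still goes by the raw count).
    """
    if region_length <= 0:
        raise ValueError("region length must be positive")
    if total_mapped_reads > 0:
        rpkm = read_count / ((region_length / 1e3) * (total_mapped_reads / 1e6))
    else:
        rpkm = float("nan")
    return ("a" if read_count >= min_reads else "n"), rpkm


def build_genotype_matrix(
    snp_obs: pd.DataFrame,
    markers: pd.DataFrame,
    gamete_ids: list[str] | None = None,
    dominance_ratio: float = 3.0,
) -> GenotypeMatrix:
    """Assemble the raw gametes x markers matrix from an ObservationTable.

    Observations at positions not in ``markers`` are ignored; markers never
    observed in a gamete stay N.
    """
    markers = markers[markers.kind == "snp"].sort_values(["contig", "start"]).reset_index(drop=True)
    if gamete_ids is None:
        gamete_ids = sorted(snp_obs.gamete.unique())
    gidx = {g: i for i, g in enumerate(gamete_ids)}
    midx = {m: j for j, m in enumerate(markers.marker_id)}
    calls = np.zeros((len(gamete_ids), len(markers)), dtype=np.int8)
    obs = snp_obs[snp_obs.marker_id.isin(midx.keys()) & snp_obs.gamete.isin(gidx.keys())]
    rows = obs.gamete.map(gidx).to_numpy()
    cols = obs.marker_id.map(midx).to_numpy()
    codes = call_snp_genotypes(
        obs.ref_count.to_numpy(), obs.alt_count.to_numpy(), dominance_ratio
    )
    calls[rows, cols] = codes
    return GenotypeMatrix(list(gamete_ids), markers, calls, phased=False)


@dataclass
class PloidyScreenResult:
    table: pd.DataFrame  # gamete, covered, transitions, ratio, label, low_coverage

    @property
    def haploid_ids(self) -> list[str]:
        return list(self.table[self.table.label == "haploid"].gamete)

    @property
    def doublet_ids(self) -> list[str]:
        return list(self.table[self.table.label == "doublet"].gamete)


def screen_ploidy(
    matrix: GenotypeMatrix,
    threshold_per_100: float = 5.0,
    min_covered: int = 30,
) -> PloidyScreenResult:
    """Label each gamete haploid or doublet from its phased calls.

    Transitions are counted between consecutive non-missing calls within each
    contig and summed over contigs.  A gamete is a doublet iff
    transitions / covered > threshold_per_100 / 100 (strict, per "more than").
    Gametes with fewer than ``min_covered`` covered markers are labelled
    haploid with the low-coverage flag set.
    """
    if not matrix.phased:
        raise ValueError("screen_ploidy expects phased calls (a/b/n)")
    slices = [matrix.contig_slice(c) for c in matrix.contigs]
    rows = []
    for g, gid in enumerate(matrix.gamete_ids):
        covered = 0
        transitions = 0
        for sl in slices:
            x = matrix.calls[g, sl]
            y = x[x != N]
            covered += len(y)
            if len(y) > 1:
                transitions += int(np.count_nonzero(np.diff(y)))
        ratio = transitions / covered if covered else 0.0
        low = covered < min_covered
        label = (
            "doublet"
            if (not low and ratio > threshold_per_100 / 100.0)
            else "haploid"
        )
        rows.append(
            {"gamete": gid, "covered": covered, "transitions": transitions,
             "ratio": ratio, "label": label, "low_coverage": low}
        )
    return PloidyScreenResult(pd.DataFrame(rows))
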