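"""SNP marker selection and markerless-region classification.

SNP candidates from a bulk variant call are kept when they look like true
heterozygous alleles of a diploid: alternative allele frequency near 0.5
(default band 0.38-0.62) and alternative/total depths inside bands around
half/all of the genome-wide mode depth (defaults 60-140 and 120-280 for a
208x dataset).  Long marker-free stretches are then classified by pooled
depth into haplotype-specific "deletion" regions (about half depth, default
ceiling 146) versus "conserved" regions shared by both haplotypes.

All bounds are inclusive.  Thresholds are dataset-relative: a helper rescales
the default depth bounds proportionally to an observed mode depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import MARKER_COLUMNS, SnpCandidate

DEFAULT_MODE_DEPTH = 208


@dataclass(frozen=True)
class SnpFilterConfig:
    freq_lo: float = 0.38
    freq_hi: float = 0.62
    alt_lo: int = 60
    alt_hi: int = 140
    depth_lo: int = 120
    depth_hi: int = 280

    def __post_init__(self) -> None:
        if not 0 <= self.freq_lo < self.freq_hi <= 1:
            raise ValueError("require 0 <= freq_lo < freq_hi <= 1")
        if not 0 <= self.alt_lo <= self.alt_hi:
            raise ValueError("require 0 <= alt_lo <= alt_hi")
        if not 0 < self.depth_lo <= self.depth_hi:
            raise ValueError("require 0 < depth_lo <= depth_hi")

    def rescaled(self, mode_depth: float) -> "SnpFilterConfig":
        """Depth bounds scaled proportionally to an observed mode depth
        (frequency bounds are depth-free and stay put)."""
        f = mode_depth / DEFAULT_MODE_DEPTH
        return replace(
            self,
            alt_lo=int(round(self.alt_lo * f)), alt_hi=int(round(self.alt_hi * f)),
            depth_lo=int(round(self.depth_lo * f)), depth_hi=int(round(self.depth_hi * f)),
        )


@dataclass(frozen=True)
class RegionClassifierConfig:
    min_length: int = 2000
    deletion_depth_ceiling: float = 146.0

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.deletion_depth_ceiling <= 0:
            raise ValueError("min_length and deletion_depth_ceiling must be positive")

    def rescaled(self, mode_depth: float) -> "RegionClassifierConfig":
        f = mode_depth / DEFAULT_MODE_DEPTH
        return replace(self, deletion_depth_ceiling=self.deletion_depth_ceiling * f)


def select_snp_markers(
    candidates: list[SnpCandidate] | pd.DataFrame,
    cfg: SnpFilterConfig | None = None,
) -> pd.DataFrame:
    """Filter candidate SNPs to the allele-frequency and depth bands.

    A candidate with zero total depth is rejected (reason "zero depth").
    Returns a MarkerTable DataFrame (kind 'snp'), sorted by (contig, start).
    """
    cfg = cfg or SnpFilterConfig()
    if isinstance(candidates, pd.DataFrame):
        df = candidates.copy()
    else:
        df = pd.DataFrame(
            [
                {"contig": c.contig, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                 "alt_depth": c.alt_depth, "total_depth": c.total_depth}
                for c in candidates
            ],
            columns=["contig", "pos", "ref", "alt", "alt_depth", "total_depth"],
        )
    if len(df) == 0:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    total = df.total_depth.to_numpy(dtype=float)
    alt = df.alt_depth.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(total > 0, alt / np.where(total > 0, total, 1), np.nan)
    keep = (
        (total > 0)
        & (freq >= cfg.freq_lo) & (freq <= cfg.freq_hi)
        & (alt >= cfg.alt_lo) & (alt <= cfg.alt_hi)
        & (total >= cfg.depth_lo) & (total <= cfg.depth_hi)
    )
    out = df[keep].copy()
    out["kind"] = "snp"
    out["start"] = out.pos.astype(int)
    out["end"] = out.start + 1
    out = out.sort_values(["contig", "start"]).reset_index(drop=True)
    out["marker_id"] = out.contig.astype(str) + ":" + out.start.astype(str)
    return out[MARKER_COLUMNS]


def rejection_reasons(candidate: SnpCandidate, cfg: SnpFilterConfig | None = None) -> list[str]:
    """Why one candidate fails the filter (empty list = retained)."""
    cfg = cfg or SnpFilterConfig()
    reasons = []
    if candidate.total_depth <= 0:
        return ["zero depth"]
    freq = candidate.alt_depth / candidate.total_depth
    if not cfg.freq_lo <= freq <= cfg.freq_hi:
        reasons.append("frequency")
    if not cfg.alt_lo <= candidate.alt_depth <= cfg.alt_hi:
        reasons.append("alt depth")
    if not cfg.depth_lo <= candidate.total_depth <= cfg.depth_hi:
        reasons.append("total depth")
    return reasons


def find_markerless_regions(
    markers: pd.DataFrame,
    contig_lengths: dict[str, int],
    cfg: RegionClassifierConfig | None = None,
) -> pd.DataFrame:
    """Maximal SNP-free intervals longer than cfg.min_length per contig.

    Intervals are 0-based half-open runs of bases not occupied by a SNP
    marker, including contig ends; a contig with no SNP at all yields one
    full-length interval.  A marker beyond the contig length is a consistency
    error.
    """
    cfg = cfg or RegionClassifierConfig()
    snp = markers[markers.kind == "snp"] if len(markers) else markers
    rows = []
    for contig, length in contig_lengths.items():
        pos = (
            np.sort(snp[snp.contig == contig].start.to_numpy())
            if len(snp)
            else np.array([], dtype=int)
        )
        if len(pos) and (pos[-1] >= length or pos[0] < 0):
            raise ValueError(f"marker beyond contig bounds on {contig}")
        edges_lo = np.concatenate(([0], pos + 1))
        edges_hi = np.concatenate((pos, [length]))
        for lo, hi in zip(edges_lo, edges_hi):
            if hi - lo > cfg.min_length:
                rows.append({"contig": contig, "start": int(lo), "end": int(hi)})
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def classify_region(
    interval: tuple[int, int] | None,
    mean_pooled_depth: float,
    cfg: RegionClassifierConfig | None = None,
) -> str:
    """'deletion' iff mean pooled depth <= ceiling (inclusive), else 'conserved'."""
    cfg = cfg or RegionClassifierConfig()
    if mean_pooled_depth < 0:
        raise ValueError(f"negative depth {mean_pooled_depth}")
    return "deletion" if mean_pooled_depth <= cfg.deletion_depth_ceiling else "conserved"


def classify_regions(
    regions: pd.DataFrame,
    depths: dict[str, float] | pd.Series,
    cfg: RegionClassifierConfig | None = None,
) -> pd.DataFrame:
    """Vector version of :func:`classify_region` over a region table.

    ``depths`` is keyed by "contig:start-end".  Adds 'region_id' and 'kind'.
    """
    cfg = cfg or RegionClassifierConfig()
    out = regions.copy()
    out["region_id"] = (
        out.contig.astype(str) + ":" + out.start.astype(str) + "-" + out.end.astype(str)
    )
    out["depth"] = [float(depths[rid]) for rid in out.region_id]
    if (out.depth < 0).any():
        raise ValueError("negative pooled depth")
    out["kind"] = np.where(out.depth <= cfg.deletion_depth_ceiling, "deletion", "conserved")
    return out


def depth_histogram_valley(depths: np.ndarray, bins: int = 100, smooth: int = 5) -> float:
    """Advisory helper: the depth at the valley of a smoothed depth histogram
    between its two highest peaks (the classical way to derive a
    deletion-depth ceiling from pooled data).  Never applied silently."""
    depths = np.asarray(depths, dtype=float)
    hist, edges = np.histogram(depths, bins=bins)
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(hist, kernel, mode="same")
    # two highest local maxima
    peaks = [i for i in range(1, bins - 1) if sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1]]
    if len(peaks) < 2:
        raise ValueError("fewer than two peaks in depth histogram")
    top = sorted(sorted(peaks, key=lambda i: -sm[i])[:2])
    lo, hi = top
    valley = lo + int(np.argmin(sm[lo:hi + 1]))
    centers = (edges[:-1] + edges[1:]) / 2
    return float(centers[valley])
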