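"""Crossover calling by min-support segmentation, and the recombination
landscape.

A gamete's phased call string along a contig or linkage group is compressed
to its non-missing symbols and split into maximal runs.  Runs of at least
``min_support`` markers are *strong blocks*; shorter runs are treated as
genotyping noise and absorbed into the flanking context.  A crossover is
emitted between every pair of consecutive strong blocks with opposite
symbols, localized to the interval between the last marker of the left block
and the first marker of the right block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_SUPPORT = 5


@dataclass(frozen=True)
class Block:
    symbol: int          # 1 = a, 2 = b
    first_index: int     # indices into the original (uncompressed) marker list
    last_index: int
    support: int         # number of non-missing markers in the run
    strong: bool


@dataclass(frozen=True)
class CrossoverEvent:
    gamete: str
    group: str
    left_index: int       # marker index of last left-block marker
    right_index: int      # marker index of first right-block marker
    left_pos: int         # bp position of the left flank marker
    right_pos: int        # bp position of the right flank marker
    left_support: int
    right_support: int

    @property
    def midpoint(self) -> float:
        return (self.left_pos + self.right_pos) / 2

    @property
    def resolution(self) -> int:
        return self.right_pos - self.left_pos


def _runs(symbols: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Maximal runs of identical non-missing symbols; each run carries the
    original marker indices of its members."""
    idx = np.flatnonzero(symbols != 0)
    if len(idx) == 0:
        return []
    vals = symbols[idx]
    cut = np.flatnonzero(np.diff(vals) != 0) + 1
    groups = np.split(idx, cut)
    return [(int(symbols[g[0]]), g) for g in groups]


def segment_blocks(symbols: np.ndarray, min_support: int = DEFAULT_MIN_SUPPORT) -> list[Block]:
    """All maximal runs, with the strong flag set where support >= min_support."""
    return [
        Block(sym, int(g[0]), int(g[-1]), len(g), len(g) >= min_support)
        for sym, g in _runs(np.asarray(symbols))
    ]


def end_symbols(symbols: np.ndarray, min_support: int = DEFAULT_MIN_SUPPORT) -> tuple[int, int]:
    """Consensus symbols of the first and last block of a call string.

    The consensus is the first/last *strong* block's symbol; when no run
    reaches min_support the raw first/last non-missing symbol is used; an
    all-missing string gives (0, 0).
    """
    blocks = segment_blocks(symbols, min_support)
    if not blocks:
        return 0, 0
    strong = [b for b in blocks if b.strong]
    head = strong[0].symbol if strong else blocks[0].symbol
    tail = strong[-1].symbol if strong else blocks[-1].symbol
    return head, tail


def segment_and_call(
    symbols: np.ndarray | str,
    positions: np.ndarray | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
    gamete: str = "",
    group: str = "",
) -> tuple[list[Block], list[CrossoverEvent]]:
    """Segment one call string and emit crossovers between consecutive strong
    blocks of opposite symbols.

    ``symbols`` may be an integer array ({0 n, 1 a, 2 b}) or a string over
    "abn".  ``positions`` gives the bp position of each marker (defaults to
    the marker index itself).
    """
    if isinstance(symbols, str):
        lut = {"n": 0, "a": 1, "b": 2}
        symbols = np.array([lut[ch] for ch in symbols], dtype=np.int8)
    symbols = np.asarray(symbols)
    if positions is None:
        positions = np.arange(len(symbols))
    positions = np.asarray(positions)
    blocks = segment_blocks(symbols, min_support)
    strong = [b for b in blocks if b.strong]
    events: list[CrossoverEvent] = []
    for left, right in zip(strong, strong[1:]):
        if left.symbol != right.symbol:
            events.append(
                CrossoverEvent(
                    gamete=gamete, group=group,
                    left_index=left.last_index, right_index=right.first_index,
                    left_pos=int(positions[left.last_index]),
                    right_pos=int(positions[right.first_index]),
                    left_support=left.support, right_support=right.support,
                )
            )
    return blocks, events


def detect_crossovers(
    call_strings: dict[str, np.ndarray],
    positions: np.ndarray,
    group: str = "",
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> pd.DataFrame:
    """Run :func:`segment_and_call` for every gamete of one linkage group.

    ``call_strings`` maps gamete id -> integer call array in map order with
    ``positions`` the bp coordinate of each marker.  Returns one row per CO.
    """
    rows = []
    for gid, symbols in call_strings.items():
        _, events = segment_and_call(symbols, positions, min_support, gamete=gid, group=group)
        for e in events:
            rows.append(
                {"gamete": e.gamete, "group": group,
                 "left_pos": e.left_pos, "right_pos": e.right_pos,
                 "midpoint": e.midpoint, "resolution": e.resolution,
                 "left_support": e.left_support, "right_support": e.right_support}
            )
    return pd.DataFrame(
        rows,
        columns=["gamete", "group", "left_pos", "right_pos", "midpoint",
                 "resolution", "left_support", "right_support"],
    )


def filter_events_by_coverage(
    events: pd.DataFrame, gamete_depth: dict[str, float] | pd.Series, min_depth: float = 0.1
) -> pd.DataFrame:
    """Keep events of gametes sequenced strictly above ``min_depth`` (the
    landscape uses only well-covered gametes)."""
    depth = pd.Series(gamete_depth)
    keep = events.gamete.map(depth) > min_depth
    return events[keep.fillna(False)].reset_index(drop=True)


def landscape(
    events: pd.DataFrame,
    n_gametes: int,
    chrom_length: int,
    window: int = 500_000,
    step: int = 50_000,
    snp_positions: np.ndarray | None = None,
    gene_intervals: pd.DataFrame | None = None,
    group: str = "",
) -> pd.DataFrame:
    """Sliding-window recombination landscape for one linkage group.

    Per window of size w: C = number of distinct gametes with a CO midpoint
    inside; recombination frequency (cM/Mb) = 100 * C / n / (w / 1e6).  SNP
    and gene densities are counts of features (midpoints) per Mb in the same
    windows.
    """
    if n_gametes <= 0:
        raise ValueError("n_gametes must be positive")
    sub = events[events.group == group] if ("group" in events and group) else events
    mids = sub.midpoint.to_numpy(dtype=float) if len(sub) else np.array([])
    gams = sub.gamete.to_numpy() if len(sub) else np.array([])
    gene_mids = None
    if gene_intervals is not None and len(gene_intervals):
        gene_mids = (
            gene_intervals.start.to_numpy() + gene_intervals.end.to_numpy()
        ) / 2.0
    rows = []
    start = 0
    while start + window <= chrom_length or start == 0:
        end = start + window
        inside = (mids >= start) & (mids < end)
        c = len(set(gams[inside]))
        freq = 100.0 * c / n_gametes / (window / 1e6)
        row = {"group": group, "start": start, "end": end, "C": c,
               "n": n_gametes, "cM_per_Mb": freq}
        if snp_positions is not None:
            n_snp = int(np.count_nonzero((snp_positions >= start) & (snp_positions < end)))
            row["snp_per_Mb"] = n_snp / (window / 1e6)
        if gene_mids is not None:
            n_gene = int(np.count_nonzero((gene_mids >= start) & (gene_mids < end)))
            row["gene_per_Mb"] = n_gene / (window / 1e6)
        rows.append(row)
        start += step
        if start + window > chrom_length:
            break
    return pd.DataFrame(rows)


def nonallelic_diagnostics(
    matrix_calls: np.ndarray,
    snp_obs: pd.DataFrame,
    gamete_ids: list[str],
) -> pd.DataFrame:
    """Per-gamete non-allelic-CO diagnostics: the fraction of covered markers
    where both alleles were observed (pseudo-heterozygosity), a signature of
    duplicated segments.  Advisory report only; no automated calling."""
    both = snp_obs[(snp_obs.ref_count > 0) & (snp_obs.alt_count > 0)]
    n_both = both.groupby("gamete").size()
    n_cov = snp_obs.groupby("gamete").size()
    rows = []
    for gid in gamete_ids:
        cov = int(n_cov.get(gid, 0))
        nb = int(n_both.get(gid, 0))
        rows.append(
            {"gamete": gid, "covered": cov, "both_alleles": nb,
             "pseudo_het_fraction": nb / cov if cov else 0.0}
        )
    return pd.DataFrame(rows)
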