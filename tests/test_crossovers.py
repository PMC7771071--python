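"""Min-support segmentation CO caller, recombination landscape, and
parameter recovery on synthetic truth."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from haplobin.crossovers import (
    end_symbols,
    filter_events_by_coverage,
    landscape,
    segment_and_call,
    segment_blocks,
)
from haplobin.pipeline import detect_all_crossovers, group_traversal


def oracle_events(symbols: str, min_support: int) -> int:
    """Independent segmentation oracle built on itertools.groupby: count sign
    changes between consecutive runs of >= min_support identical non-n
    symbols."""
    compressed = [ch for ch in symbols if ch != "n"]
    runs = [(k, len(list(g))) for k, g in itertools.groupby(compressed)]
    strong = [k for k, n in runs if n >= min_support]
    return sum(1 for x, y in zip(strong, strong[1:]) if x != y)


class TestSegmentation:
    @pytest.mark.parametrize("s,ms,n_events", [
        ("aaaaabbbbb", 3, 1),
        ("aaaaaaaaaa", 3, 0),
        ("aaaabaaaa", 3, 0),    # isolated flip absorbed as error
        ("aaabbbaaa", 3, 2),    # double recombinant
        ("", 5, 0),
        ("nnnn", 5, 0),
        ("aabb", 3, 0),         # no block reaches support
    ])
    def test_examples(self, s, ms, n_events):
        _, events = segment_and_call(s, min_support=ms)
        assert len(events) == n_events
        assert len(events) == oracle_events(s, ms)

    def test_event_interval_flanks(self):
        _, events = segment_and_call("aaaaabbbbb", min_support=3,
                                     positions=np.arange(0, 10_000, 1000))
        e = events[0]
        assert (e.left_pos, e.right_pos) == (4000, 5000)
        assert e.midpoint == 4500 and e.resolution == 1000
        assert e.left_support == 5 and e.right_support == 5

    def test_missing_symbols_ignored(self):
        _, ev1 = segment_and_call("aaannnbbb", min_support=3)
        _, ev2 = segment_and_call("aaabbb", min_support=3)
        assert len(ev1) == len(ev2) == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        s=st.text(alphabet="abn", min_size=0, max_size=40),
        ms=st.integers(1, 6),
    )
    def test_matches_groupby_oracle(self, s, ms):
        _, events = segment_and_call(s, min_support=ms)
        assert len(events) == oracle_events(s, ms)

    def test_blocks_cover_all_informative_markers(self):
        blocks = segment_blocks(np.array([1, 1, 0, 2, 2, 2, 1], dtype=np.int8), 2)
        supports = sum(b.support for b in blocks)
        assert supports == 6

    def test_end_symbols_fallback_without_strong_block(self):
        assert end_symbols(np.array([1, 1, 1, 2, 2], dtype=np.int8), 5) == (1, 2)


class TestLandscapeFormula:
    def test_single_recombinant_window(self):
        events = pd.DataFrame({"gamete": ["g1"], "group": [""], "midpoint": [250_000]})
        win = landscape(events, n_gametes=369, chrom_length=500_000)
        assert win.cM_per_Mb.iloc[0] == pytest.approx(100 * 1 / 369 / 0.5)
        assert win.cM_per_Mb.iloc[0] == pytest.approx(0.542, abs=1e-3)

    def test_no_events_zero_frequency(self):
        events = pd.DataFrame({"gamete": [], "group": [], "midpoint": []})
        win = landscape(events, n_gametes=100, chrom_length=600_000)
        assert (win.cM_per_Mb == 0).all()

    def test_gene_density(self):
        events = pd.DataFrame({"gamete": [], "group": [], "midpoint": []})
        genes = pd.DataFrame({"start": np.arange(10) * 1000,
                              "end": np.arange(10) * 1000 + 500})
        win = landscape(events, 10, 500_000, gene_intervals=genes)
        assert win.gene_per_Mb.iloc[0] == pytest.approx(20.0)

    def test_distinct_gametes_counted_once(self):
        events = pd.DataFrame({"gamete": ["g1", "g1", "g2"], "group": [""] * 3,
                               "midpoint": [100.0, 200.0, 300.0]})
        win = landscape(events, 10, 500_000)
        assert win.C.iloc[0] == 2

    def test_zero_gametes_rejected(self):
        with pytest.raises(ValueError):
            landscape(pd.DataFrame({"gamete": [], "group": [], "midpoint": []}),
                      0, 500_000)

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(8)
        events = pd.DataFrame({
            "gamete": rng.choice([f"g{i}" for i in range(30)], 100),
            "group": "",
            "midpoint": rng.uniform(0, 2_000_000, 100),
        })
        w, s = 500_000, 50_000
        win = landscape(events, 30, 2_000_000, window=w, step=s)
        for row in win.itertuples():
            inside = events[(events.midpoint >= row.start) & (events.midpoint < row.end)]
            c = inside.gamete.nunique()
            assert row.C == c
            assert row.cM_per_Mb == pytest.approx(100 * c / 30 / (w / 1e6))


class TestCoverageFilter:
    def _events(self):
        return pd.DataFrame({"gamete": ["g1", "g2", "g3"], "group": [""] * 3,
                             "midpoint": [1.0, 2.0, 3.0]})

    def test_shallow_gamete_dropped(self):
        depth = {"g1": 0.05, "g2": 0.5, "g3": 0.5}
        out = filter_events_by_coverage(self._events(), depth)
        assert set(out.gamete) == {"g2", "g3"}

    def test_boundary_is_strict(self):
        depth = {"g1": 0.1, "g2": 0.100001, "g3": 0.5}
        out = filter_events_by_coverage(self._events(), depth)
        assert set(out.gamete) == {"g2", "g3"}

    def test_all_above_is_identity(self):
        depth = {"g1": 1.0, "g2": 1.0, "g3": 1.0}
        out = filter_events_by_coverage(self._events(), depth)
        pd.testing.assert_frame_equal(out, self._events())


def map_true_breakpoints_to_group_coords(result, gi):
    """Project true CO positions (chromosome frame) onto the concatenated
    map coordinate of linkage group gi."""
    truth = result.dataset.truth
    contigs = truth.contigs.set_index("contig")
    offsets, directions = {}, {}
    offset = 0
    for contig, direction in group_traversal(result.gmap, gi):
        length = int(contigs.loc[contig].end - contigs.loc[contig].start)
        offsets[contig], directions[contig] = offset, direction
        offset += length
    gidx = {g: i for i, g in enumerate(truth.gametes.gamete)}
    rows = []
    for r in truth.crossovers.itertuples():
        sub = contigs[(contigs.chrom == r.chrom) & (contigs.start <= r.pos)
                      & (contigs.end > r.pos)]
        if not len(sub):
            continue
        contig = sub.index[0]
        if contig not in offsets:
            continue
        local = r.pos - int(sub.start.iloc[0])
        length = int(sub.end.iloc[0] - sub.start.iloc[0])
        coord = offsets[contig] + (local if directions[contig] == 1 else length - local)
        rows.append({"underlying": r.underlying, "coord": coord})
    return pd.DataFrame(rows), gidx


class TestRecoveryOnSyntheticTruth:
    def test_mean_co_count_within_10_percent_of_lambda(self, pipeline_default):
        res = pipeline_default
        events = detect_all_crossovers(res)
        cfg = res.dataset.truth.config
        # haploid gametes only, both groups
        mean = len(events) / len(res.haploid_ids)
        expected = cfg.co_lambda * cfg.n_chromosomes
        assert abs(mean - expected) / expected <= 0.10

    def test_co_intervals_contain_true_breakpoint(self, pipeline_default):
        """>= 95% of called CO intervals contain a true crossover of the same
        gamete (coordinates projected onto the map frame)."""
        res = pipeline_default
        truth = res.dataset.truth
        events = detect_all_crossovers(res)
        comp = {r.gamete: int(r.components.split(",")[0])
                for r in truth.gametes.itertuples()}
        hits = total = 0
        for gi in range(len(res.gmap.groups)):
            bp, _ = map_true_breakpoints_to_group_coords(res, gi)
            sub = events[events.group == str(gi)]
            for e in sub.itertuples():
                mine = bp[bp.underlying == comp[e.gamete]]
                total += 1
                pad = 2000  # marker-interval slack at the flanks
                hits += int(
                    ((mine.coord >= e.left_pos - pad)
                     & (mine.coord <= e.right_pos + pad)).any()
                )
        assert total > 0 and hits / total >= 0.95

    def test_uniform_simulation_gives_flat_landscape(self, pipelines_multi):
        """CO midpoints from uniform-CO simulations are uniform across
        non-overlapping windows (chi-square, alpha = 0.01, pooled seeds)."""
        counts = None
        for res in pipelines_multi:
            events = detect_all_crossovers(res)
            length = res.dataset.truth.config.chromosome_length
            win = landscape(events, len(res.haploid_ids), length,
                            window=100_000, step=100_000, group="0")
            c = win.C.to_numpy()
            counts = c if counts is None else counts + c
        _, p = chisquare(counts)
        assert p > 0.01

    def test_parity_of_end_symbols_matches_co_count(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s = "".join(rng.choice(list("ab"), 1)[0] * int(rng.integers(5, 15))
                        for _ in range(int(rng.integers(1, 5))))
            blocks, events = segment_and_call(s, min_support=5)
            head, tail = end_symbols(np.array(
                [{"a": 1, "b": 2}[ch] for ch in s], dtype=np.int8), 5)
            assert (head != tail) == (len(events) % 2 == 1)
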