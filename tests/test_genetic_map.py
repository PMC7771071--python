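"""Two-point LOD, linkage grouping, seriation ordering, Haldane distances,
deletion-marker integration, and map recovery on synthetic truth."""

import itertools

import numpy as np
import pytest

from haplobin.genetic_map import (
    GeneticMap,
    build_genetic_map,
    deletion_genotype_sequence,
    group_markers,
    haldane_cm,
    integrate_deletion_marker,
    order_group,
    pairwise_linkage,
    two_point_lod,
)
from haplobin.phasing import VirtualMarker
from haplobin.pipeline import map_order_agreement


class TestTwoPointLod:
    def test_no_recombinants(self):
        # 20 informative gametes, R = 0: LOD = 20 log10 2
        l = two_point_lod("a" * 20, "a" * 20)
        assert l.lod == pytest.approx(20 * np.log10(2), abs=1e-9)
        assert l.lod == pytest.approx(6.021, abs=1e-3)

    def test_half_recombinant_no_linkage(self):
        l = two_point_lod("ab" * 10, "aa" * 10)
        assert l.r == pytest.approx(0.5) and l.lod == pytest.approx(0.0, abs=1e-12)

    def test_phase_flip_applied(self):
        # raw R=18, NR=2 -> flipped to r = 0.1
        l = two_point_lod("b" * 18 + "a" * 2, "a" * 20)
        assert l.flipped and l.r == pytest.approx(0.1)
        expected = 18 * np.log10(1.8) + 2 * np.log10(0.2)
        assert l.lod == pytest.approx(expected, abs=1e-9)
        assert l.lod == pytest.approx(3.197, abs=1e-3)

    def test_uninformative_pair(self):
        l = two_point_lod("nn", "ab")
        assert np.isnan(l.r) and l.lod == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            two_point_lod("ab", "abc")

    def test_symmetry_and_flip_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s1 = rng.choice(list("abn"), 40)
            s2 = rng.choice(list("abn"), 40)
            l12 = two_point_lod("".join(s1), "".join(s2))
            l21 = two_point_lod("".join(s2), "".join(s1))
            assert l12.lod == pytest.approx(l21.lod) and (
                np.isnan(l12.r) or l12.r == pytest.approx(l21.r)
            )
            flip = "".join(s1).translate(str.maketrans("ab", "ba"))
            lf = two_point_lod(flip, "".join(s2))
            assert lf.lod == pytest.approx(l12.lod)

    def test_lod_strictly_decreasing_in_r(self):
        n = 100
        lods = [
            two_point_lod("a" * (n - k) + "b" * k, "a" * n).lod
            for k in range(0, n // 2 + 1, 5)
        ]
        assert all(x > y for x, y in zip(lods, lods[1:]))

    def test_pairwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(5)
        seqs = [rng.integers(0, 3, 50).astype(np.int8) for _ in range(6)]
        r, lod, flip, _ = pairwise_linkage(seqs)
        for i in range(6):
            for j in range(6):
                l = two_point_lod(seqs[i], seqs[j])
                assert lod[i, j] == pytest.approx(l.lod, abs=1e-9)
                if not np.isnan(l.r):
                    assert r[i, j] == pytest.approx(l.r)


class TestGrouping:
    def test_strong_triangle_one_group(self):
        lod = np.full((3, 3), 5.0)
        assert group_markers(list("xyz"), lod) == [[0, 1, 2]]

    def test_weak_edge_two_groups(self):
        lod = np.array([[0, 1.0], [1.0, 0]])
        assert group_markers(list("xy"), lod) == [[0], [1]]

    def test_threshold_is_strict(self):
        lod = np.array([[0, 3.0], [3.0, 0]])
        assert group_markers(list("xy"), lod) == [[0], [1]]

    def test_transitive_chain(self):
        lod = np.array([[0, 5, 1.0], [5, 0, 5], [1.0, 5, 0]])
        assert group_markers(list("xyz"), lod) == [[0, 1, 2]]

    def test_contig_ends_forced_together(self):
        # head of c2 links to c1, tail of c2 is an orphan: forced to join
        lod = np.array([
            [0, 5, 0.0],
            [5, 0, 0.0],
            [0, 0, 0.0],
        ])
        comps = group_markers(["c1h", "c2h", "c2t"], lod,
                              contig_of={0: "c1", 1: "c2", 2: "c2"})
        assert comps == [[0, 1, 2]]


class TestOrdering:
    def test_three_marker_chain(self):
        r = np.array([[0, .05, .10], [.05, 0, .05], [.10, .05, 0]])
        lod = 10 - 20 * r
        order, cms = order_group([0, 1, 2], r, lod)
        assert order in ([0, 1, 2], [2, 1, 0])
        assert cms[-1] == pytest.approx(2 * haldane_cm(0.05))

    def test_single_member(self):
        order, cms = order_group([0], np.zeros((1, 1)), np.zeros((1, 1)))
        assert order == [0] and cms == [0.0]

    def test_haldane_value(self):
        assert haldane_cm(0.1) == pytest.approx(-50 * np.log(0.8), abs=1e-9)
        assert haldane_cm(0.1) == pytest.approx(11.157, abs=1e-3)

    def test_haldane_cap(self):
        assert haldane_cm(0.5) == 50.0
        assert haldane_cm(float("nan")) == 50.0
        assert haldane_cm(0.0) == 0.0

    def test_matches_exhaustive_optimum_small_groups(self):
        """Seriation + 2-opt attains the exhaustive minimum of the adjacent-r
        objective for groups of up to 8 markers."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            true_pos = np.sort(rng.uniform(0, 1, n))
            r = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    d = abs(true_pos[i] - true_pos[j])
                    r[i, j] = 0.5 * (1 - np.exp(-2 * d))  # Haldane forward
            lod = 10 - 10 * r
            order, _ = order_group(list(range(n)), r, lod)
            best = min(
                sum(r[a, b] for a, b in zip(p, p[1:]))
                for p in itertools.permutations(range(n))
            )
            got = sum(r[a, b] for a, b in zip(order, order[1:]))
            assert got == pytest.approx(best, abs=1e-12)


def chain_markers(n_gametes=80, n_markers=6, r_step=0.08, seed=0, flip_mask=None):
    """Synthetic ordered chain of virtual markers with known adjacent r."""
    rng = np.random.default_rng(seed)
    seqs = [rng.integers(1, 3, n_gametes).astype(np.int8)]
    for _ in range(n_markers - 1):
        prev = seqs[-1]
        rec = rng.random(n_gametes) < r_step
        nxt = np.where(rec, 3 - prev, prev).astype(np.int8)
        seqs.append(nxt)
    vms = []
    for i, s in enumerate(seqs):
        if flip_mask and i in flip_mask:
            s = (3 - s).astype(np.int8)
        contig, end = f"c{i // 2 + 1}", ("head" if i % 2 == 0 else "tail")
        vms.append(VirtualMarker(contig, end, s))
    return vms


class TestBuildMap:
    def test_single_group_ordered_chain(self):
        gmap = build_genetic_map(chain_markers())
        assert len(gmap.groups) == 1
        contigs = [e.contig for e in gmap.groups[0].entries]
        # both ends of each contig adjacent, chain order recovered or reversed
        order = list(dict.fromkeys(contigs))
        assert order in (["c1", "c2", "c3"], ["c3", "c2", "c1"])

    def test_flipped_marker_gets_phase_one(self):
        gmap = build_genetic_map(chain_markers(flip_mask={2, 3}))
        phases = {e.contig: e.phase for e in gmap.groups[0].entries}
        assert phases["c2"] != phases["c1"]
        assert phases["c3"] == phases["c1"]

    def test_high_missing_markers_dropped(self):
        vms = chain_markers()
        vms[0].sequence[:30] = 0  # > 10% missing
        gmap = build_genetic_map(vms)
        keys = [(e.contig, e.end) for g in gmap.groups for e in g.entries]
        assert ("c1", "head") not in keys

    def test_cm_non_decreasing(self):
        gmap = build_genetic_map(chain_markers())
        for g in gmap.groups:
            cms = [e.cm for e in g.entries]
            assert all(x <= y for x, y in zip(cms, cms[1:]))


class TestDeletionIntegration:
    def _map(self):
        return build_genetic_map(chain_markers(seed=2))

    def test_identical_sequence_divergence_zero(self):
        gmap = self._map()
        key = (gmap.groups[0].entries[0].contig, gmap.groups[0].entries[0].end)
        seq = gmap.sequences[key].copy()
        pl = integrate_deletion_marker("d1", seq, gmap)
        assert pl is not None and pl.divergence == 0.0
        assert pl.phase == gmap.groups[0].entries[0].phase

    def test_complement_places_with_flipped_phase(self):
        gmap = self._map()
        entry = gmap.groups[0].entries[0]
        seq = gmap.sequences[(entry.contig, entry.end)].copy()
        flipped = np.where(seq == 1, 2, np.where(seq == 2, 1, 0)).astype(np.int8)
        pl = integrate_deletion_marker("d1", flipped, gmap)
        assert pl is not None and pl.divergence == 0.0
        assert pl.phase == entry.phase ^ 1

    def test_high_divergence_unplaced(self):
        gmap = self._map()
        rng = np.random.default_rng(0)
        noise = rng.integers(1, 3, 80).astype(np.int8)
        pl = integrate_deletion_marker("d1", noise, gmap, max_divergence=0.05)
        assert pl is None

    def test_small_overlap_unplaced(self):
        gmap = self._map()
        key = (gmap.groups[0].entries[0].contig, gmap.groups[0].entries[0].end)
        seq = gmap.sequences[key].copy()
        seq[10:] = 0  # only 10 informative gametes < default 30
        assert integrate_deletion_marker("d1", seq, gmap) is None

    def test_empty_map_raises(self):
        with pytest.raises(ValueError):
            integrate_deletion_marker("d1", np.ones(10, dtype=np.int8),
                                      GeneticMap(groups=[]))

    def test_absence_recoding_needs_expected_reads(self):
        counts = np.array([3, 0, 0])
        covs = np.array([0.5, 0.5, 0.01])  # third gamete too shallow to infer
        seq = deletion_genotype_sequence(counts, covs, region_length=5000)
        assert list(seq) == [1, 2, 0]


class TestMapRecovery:
    def test_group_count_and_order_on_synthetic_truth(self, pipeline_default):
        """Linkage-group count equals the simulated chromosome count and the
        within-group contig order matches the truth (|Kendall tau| >= 0.9)."""
        n_groups, tau = map_order_agreement(pipeline_default)
        assert n_groups == pipeline_default.dataset.truth.config.n_chromosomes
        assert tau >= 0.9

    def test_contig_ends_placed_in_same_group(self, pipeline_default):
        for gi, group in enumerate(pipeline_default.gmap.groups):
            by_contig = {}
            for e in group.entries:
                by_contig.setdefault(e.contig, set()).add(e.end)
        all_groups = pipeline_default.gmap.contig_group()
        seen = {}
        for gi, group in enumerate(pipeline_default.gmap.groups):
            for e in group.entries:
                seen.setdefault(e.contig, set()).add(gi)
        assert all(len(v) == 1 for v in seen.values())
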