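"""Bi-marker voting phasing: chaining rule, exhaustive-search oracle,
relabel symmetry, virtual markers, recombinant detection."""

import numpy as np
import pandas as pd
import pytest

from haplobin.gametes import GenotypeMatrix
from haplobin.phasing import (
    exhaustive_phase_orientations,
    find_recombinants,
    gamete_haplotype_string,
    impute_virtual_markers,
    phase_all_contigs,
    phase_contig,
)

LUT = {"N": 0, "R": 1, "A": 2}


def raw(strings):
    return np.array([[LUT[ch] for ch in s] for s in strings], dtype=np.int8)


def marker_frame(m, contig="c1"):
    return pd.DataFrame({
        "marker_id": [f"{contig}:{i}" for i in range(m)],
        "contig": contig, "kind": "snp", "start": range(m),
        "end": range(1, m + 1), "ref": "A", "alt": "G",
        "alt_depth": 0, "total_depth": 0,
    })


class TestPhaseContig:
    def test_perfect_cosegregation_all_plus(self):
        calls = raw(["AAA", "AAA", "RRR", "RRR"])
        phase, phased = phase_contig(calls, marker_frame(3))
        assert list(phase.orientations) == [1, 1, 1]
        strings = {"".join("nab"[c] for c in row) for row in phased}
        assert strings == {"aaa", "bbb"}

    def test_anticorrelated_middle_marker_flips(self):
        # marker 2 anti-correlated with markers 1 and 3
        calls = raw(["ARA", "ARA", "RAR", "RAR"])
        phase, _ = phase_contig(calls, marker_frame(3))
        assert list(phase.orientations) == [1, -1, 1]
        exh, _ = exhaustive_phase_orientations(calls)
        assert list(phase.orientations) == list(exh)

    def test_tie_keeps_orientation_and_flags(self):
        calls = raw(["AA", "AR"])  # S = 1, D = 1
        phase, _ = phase_contig(calls, marker_frame(2))
        assert list(phase.orientations) == [1, 1]
        assert phase.tie_flags.tolist() == [True]

    def test_single_marker_contig(self):
        phase, _ = phase_contig(raw(["A", "R"]), marker_frame(1))
        assert list(phase.orientations) == [1]
        assert len(phase.tie_flags) == 0

    def test_missing_calls_excluded_from_votes(self):
        calls = raw(["AN", "NA", "RR", "AA"])  # only rows 3,4 informative
        phase, _ = phase_contig(calls, marker_frame(2))
        assert list(phase.orientations) == [1, 1]

    def test_hap_a_alleles_follow_orientation(self):
        calls = raw(["ARA", "ARA", "RAR", "RAR"])
        phase, _ = phase_contig(calls, marker_frame(3))
        assert phase.hap_a_alleles == ["G", "A", "G"]
        assert phase.hap_b_alleles == ["A", "G", "A"]

    def test_greedy_matches_exhaustive_on_random_instances(self):
        """The adjacency objectives are independent, so greedy chaining must
        attain the exhaustive optimum; checked on random noisy instances with
        up to 12 markers."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            g, m = int(rng.integers(4, 12)), int(rng.integers(2, 13))
            truth = rng.integers(0, 2, size=(g, 1)) ^ (rng.random((g, m)) < 0.1)
            calls = np.where(truth, 2, 1).astype(np.int8)
            calls[rng.random((g, m)) < 0.3] = 0
            phase, _ = phase_contig(calls, marker_frame(m))
            _, best_obj = exhaustive_phase_orientations(calls)
            left, right = calls[:, :-1], calls[:, 1:]
            both = (left != 0) & (right != 0)
            same = np.count_nonzero(both & (left == right), axis=0)
            diff = np.count_nonzero(both & (left != right), axis=0)
            o = phase.orientations
            obj = int(np.where(o[:-1] == o[1:], same, diff).sum())
            assert obj == best_obj

    def test_global_flip_symmetry(self):
        """Flipping every orientation yields the relabelled (a<->b) calls."""
        calls = raw(["AAR", "RRA", "ARR", "AAA"])
        phase, phased = phase_contig(calls, marker_frame(3))
        from haplobin.phasing import phase_calls

        flipped = phase_calls(calls, -phase.orientations)
        swap = np.where(phased == 1, 2, np.where(phased == 2, 1, 0))
        assert (flipped == swap).all()


class TestGameteString:
    def _setup(self):
        calls = raw(["AAA", "RRR", "NAN"])
        markers = marker_frame(3)
        phase, phased = phase_contig(calls, markers)
        return phase, phased

    def test_all_alt_gamete(self):
        phase, phased = self._setup()
        assert gamete_haplotype_string(phase, phased, ["g0", "g1", "g2"], "g0") == "aaa"

    def test_uncovered_markers_are_n(self):
        phase, phased = self._setup()
        assert gamete_haplotype_string(phase, phased, ["g0", "g1", "g2"], "g2") == "nan"

    def test_unknown_gamete_raises(self):
        phase, phased = self._setup()
        with pytest.raises(KeyError):
            gamete_haplotype_string(phase, phased, ["g0"], "missing")


class TestFindRecombinants:
    def test_printed_fifteen_gamete_example(self):
        # two adjacent contig-end markers over 15 gametes: only the 7th
        # gamete's genotype switches
        assert find_recombinants("aaaaaababbbbbbb", "aaaaaaaabbbbbbb") == {7}

    def test_identical_sequences(self):
        assert find_recombinants("abab", "abab") == set()

    def test_missing_is_uninformative(self):
        assert find_recombinants("ab", "nn") == set()

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            find_recombinants("ab", "abc")

    def test_multiple_recombinants(self):
        assert find_recombinants("aabb", "abab") == {2, 3}


class TestVirtualMarkers:
    def _impute(self, strings, min_support=5):
        lut = {"n": 0, "a": 1, "b": 2}
        calls = np.array([[lut[ch] for ch in s] for s in strings], dtype=np.int8)
        m = calls.shape[1]
        phase, _ = phase_contig(np.ones_like(calls), marker_frame(m))
        head, tail = impute_virtual_markers(phase, calls, min_support)
        return head.as_string(), tail.as_string()

    def test_uniform_gamete_identical_ends(self):
        head, tail = self._impute(["aaaaa"])
        assert (head, tail) == ("a", "a")

    def test_crossover_gamete_opposite_ends(self):
        head, tail = self._impute(["aaabb"])
        assert (head, tail) == ("a", "b")

    def test_uncovered_gamete_missing_ends(self):
        head, tail = self._impute(["nnnnn"])
        assert (head, tail) == ("n", "n")

    def test_isolated_error_does_not_leak_into_ends(self):
        # a single stray b in a long a-run must not become the head consensus
        head, tail = self._impute(["baaaaaaaaa"], min_support=3)
        assert (head, tail) == ("a", "a")

    def test_parity_head_tail_vs_co_count(self):
        # odd number of crossovers <=> opposite end symbols
        head, tail = self._impute(["aaaaabbbbbaaaaa"], min_support=3)
        assert (head, tail) == ("a", "a")
        head, tail = self._impute(["aaaaabbbbb"], min_support=3)
        assert (head, tail) == ("a", "b")


class TestTruthRecovery:
    def test_phased_strings_match_inheritance_up_to_flip(self):
        """With zero error and no doublets, each gamete's phased calls equal
        its true inherited haplotype at observed markers, up to one global
        flip per contig."""
        from haplobin.gametes import build_genotype_matrix
        from haplobin.markers import select_snp_markers
        from haplobin.simulate import SimulationConfig, simulate_all

        cfg = SimulationConfig(n_chromosomes=1, chromosome_length=300_000,
                               n_gametes=60, coverage=0.6, error_rate=0.0,
                               n_reads=10, seed=21)
        ds = simulate_all(cfg)
        truth = ds.truth
        markers = select_snp_markers(ds.candidates)
        matrix = build_genotype_matrix(ds.snp_obs, markers, list(truth.gametes.gamete))
        phases, phased = phase_all_contigs(matrix)
        snp_truth = truth.snps.set_index(["contig", "ctg_pos"])
        for contig in matrix.contigs:
            sl = matrix.contig_slice(contig)
            sub = matrix.markers.iloc[sl]
            # per gamete true symbol: a iff inherited hap carries phase's hap-a allele
            keys = list(zip(sub.contig, sub.start))
            hap_alt = snp_truth.loc[keys, "hap_with_alt"].to_numpy()
            pos = snp_truth.loc[keys, "pos"].to_numpy()
            chrom = snp_truth.loc[keys, "chrom"].iloc[0]
            agree = disagree = 0
            for g in range(len(matrix.gamete_ids)):
                calls = phased.calls[g, sl]
                cov = calls != 0
                if not cov.any():
                    continue
                inherited = truth.gamete_hap_at(g, chrom, pos[cov])
                ori = phases[contig].orientations[cov]
                # call 'a' means: alt allele if ori +1 else ref allele
                call_is_alt = (calls[cov] == 1) == (ori == 1)
                true_is_alt = inherited == hap_alt[cov]
                agree += int((call_is_alt == true_is_alt).sum())
                disagree += int((call_is_alt != true_is_alt).sum())
            assert agree == 0 or disagree == 0  # perfect up to global flip
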