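"""Dereplication, homopolymer correction, identity and greedy clustering."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gliascan.cluster import (
    Dereplicate,
    SequenceCluster,
    abundance_gate,
    consensus,
    correct_homopolymers,
    dereplicate,
    filter_clusters,
    greedy_cluster,
    is_homopolymer_variant,
    pairwise_identity,
)

from conftest import derep, make_fragments, random_dna


def _seq(rng: np.random.Generator, length: int = 262) -> str:
    return random_dna(rng, length)


class TestDereplicate:
    def test_exact_grouping_sorted_by_abundance(self):
        frags = make_fragments("ACGT", 50) + make_fragments("ACGA", 30)
        out = dereplicate(frags)
        assert [(r.unique_nt, r.total) for r in out] == [("ACGT", 50), ("ACGA", 30)]

    def test_equal_counts_break_ties_lexicographically(self):
        frags = make_fragments("TTTT", 10) + make_fragments("AAAA", 10)
        out = dereplicate(frags)
        brute = sorted([("TTTT", 10), ("AAAA", 10)], key=lambda x: (-x[1], x[0]))
        assert [(r.unique_nt, r.total) for r in out] == brute

    def test_counts_conserved_and_per_sample(self):
        frags = make_fragments("ACGT", 5, "S1") + make_fragments("ACGT", 7, "S2")
        out = dereplicate(frags)
        assert out[0].per_sample_counts == {"S1": 5, "S2": 7}
        assert sum(r.total for r in out) == 12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dereplicate([])


class TestHomopolymerCorrection:
    TEMPLATE = "GGTCAACAAGGT" * 20  # abundant sequence with QQ-codon AA runs

    def test_single_run_indel_merged_into_dominant(self):
        extra = self.TEMPLATE[:5] + "A" + self.TEMPLATE[5:]  # CAACAA -> CAAACAA
        out = correct_homopolymers([derep(self.TEMPLATE, S1=900), derep(extra, S1=20)])
        assert len(out) == 1
        assert out[0].unique_nt == self.TEMPLATE
        assert out[0].total == 920

    def test_substitution_never_merged(self):
        sub = self.TEMPLATE[:5] + "T" + self.TEMPLATE[6:]
        out = correct_homopolymers([derep(self.TEMPLATE, S1=900), derep(sub, S1=20)])
        assert len(out) == 2

    def test_no_merge_without_dominant(self):
        extra = self.TEMPLATE[:5] + "A" + self.TEMPLATE[5:]
        out = correct_homopolymers([derep(self.TEMPLATE, S1=20), derep(extra, S1=20)])
        assert len(out) == 2

    def test_indel_outside_homopolymer_run_not_merged(self):
        seq = "GACTGACTGACT" * 20  # no runs at all
        missing = seq[:5] + seq[6:]
        assert not is_homopolymer_variant(seq, missing)
        out = correct_homopolymers([derep(seq, S1=900), derep(missing, S1=20)])
        assert len(out) == 2

    def test_two_run_indels_merged_three_not(self):
        t = self.TEMPLATE
        two = t[:5] + "A" + t[5:8] + "A" + t[8:]  # extends both AA runs
        assert is_homopolymer_variant(t, two, max_hp_indels=2)
        three = "G" + two  # extends the leading GG run as well
        assert not is_homopolymer_variant(t, three, max_hp_indels=2)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = _seq(rng)
        assert pairwise_identity(s, s) == 1.0

    def test_one_and_two_mismatches_bracket_the_threshold(self):
        rng = np.random.default_rng(1)
        s = _seq(rng)
        one = "T" + s[1:] if s[0] != "T" else "A" + s[1:]
        two = one[:-1] + ("T" if s[-1] != "T" else "A")
        assert pairwise_identity(s, one) == pytest.approx(261 / 262)
        assert pairwise_identity(s, one) >= 0.995
        assert pairwise_identity(s, two) == pytest.approx(260 / 262)
        assert pairwise_identity(s, two) < 0.995

    def test_symmetry_and_gap_counts_as_difference(self):
        rng = np.random.default_rng(2)
        s = _seq(rng)
        gapped = s[:100] + s[101:]
        assert pairwise_identity(s, gapped) == pairwise_identity(gapped, s)
        assert pairwise_identity(s, gapped) == pytest.approx(261 / 262)


class TestGreedyCluster:
    def test_one_mismatch_joins_two_separates(self):
        rng = np.random.default_rng(3)
        s = _seq(rng)
        one = ("T" if s[0] != "T" else "A") + s[1:]
        two = one[:-1] + ("T" if one[-1] != "T" else "A")
        both = greedy_cluster([derep(s, S1=100), derep(one, S1=30)])
        assert len(both) == 1
        split = greedy_cluster([derep(s, S1=100), derep(two, S1=30)])
        assert len(split) == 2

    def test_membership_is_against_representative_only(self):
        """B joins A; C is close to B but not to A, so C founds its own
        cluster even though it would have joined B."""
        rng = np.random.default_rng(4)
        a = _seq(rng, 500)

        def mutate(s, positions):
            out = list(s)
            for p in positions:
                out[p] = "T" if out[p] != "T" else "A"
            return "".join(out)

        b = mutate(a, [10, 20])          # identity 498/500 = 0.996 to A
        c = mutate(b, [30, 40])          # 0.996 to B but 0.992 to A
        assert pairwise_identity(a, b) >= 0.995
        assert pairwise_identity(b, c) >= 0.995
        assert pairwise_identity(a, c) < 0.995
        clusters = greedy_cluster(
            [derep(a, S1=100), derep(b, S1=50), derep(c, S1=40)]
        )
        assert [len(cl.members) for cl in clusters] == [2, 1]
        assert clusters[1].representative_nt == c

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([derep("ACGT", S1=5)], identity_threshold=1.5)

    def test_raising_threshold_never_reduces_cluster_count(self):
        rng = np.random.default_rng(5)
        base = _seq(rng, 80)
        records = [derep(base, S1=50)]
        for i in range(12):
            records.append(derep(_mutate_k(base, rng, rng.integers(0, 6)), **{"S1": int(rng.integers(1, 40))}))
        counts = []
        for thr in (0.90, 0.95, 0.99, 1.0):
            counts.append(len(greedy_cluster(records, identity_threshold=thr)))
        assert counts == sorted(counts)


def _mutate_k(s: str, rng: np.random.Generator, k: int) -> str:
    out = list(s)
    for p in rng.choice(len(s), size=int(k), replace=False):
        out[p] = "ACGT"[(("ACGT".index(out[p])) + 1 + rng.integers(0, 3)) % 4]
    return "".join(out)


class TestConsensus:
    def test_single_member_is_its_own_consensus(self):
        cl = SequenceCluster("C1", [derep("ACGTACGT", S1=5)])
        assert consensus(cl) == "ACGTACGT"

    def test_weighted_majority_overrides_minority_substitution(self):
        rng = np.random.default_rng(6)
        x = _seq(rng, 90)
        variant = x[:40] + ("T" if x[40] != "T" else "A") + x[41:]
        cl = SequenceCluster("C1", [derep(x, S1=90), derep(variant, S1=10)])
        assert consensus(cl) == x

    def test_tie_resolves_toward_representative(self):
        rng = np.random.default_rng(7)
        x = _seq(rng, 90)
        variant = x[:40] + ("T" if x[40] != "T" else "A") + x[41:]
        cl = SequenceCluster("C1", [derep(x, S1=50), derep(variant, S1=50)])
        assert consensus(cl) == x

    def test_minority_insertion_kept_out_of_consensus(self):
        rng = np.random.default_rng(8)
        x = _seq(rng, 90)
        longer = x[:40] + "A" + x[40:]
        cl = SequenceCluster("C1", [derep(x, S1=80), derep(longer, S1=20)])
        assert consensus(cl) == x


class TestGateAndFilter:
    def test_boundary_cluster_sizes(self):
        rng = np.random.default_rng(9)
        drop = SequenceCluster("C1", [derep(_seq(rng), S1=20)])
        keep = SequenceCluster("C2", [derep(_seq(rng), S1=21)])
        passed, dropped = filter_clusters([drop, keep])
        assert [c.cluster_id for c in passed] == ["C2"]
        assert [c.cluster_id for c in dropped] == ["C1"]

    def test_empty_input_passes_through(self):
        assert filter_clusters([]) == ([], [])

    def test_gate_uses_per_run_counts(self):
        rec = derep("ACGT", S1=12, S2=12)
        # pooled: 24 reads -> passes
        passed, _ = abundance_gate([rec])
        assert passed
        # split across two runs: 12 each -> dropped
        _, dropped = abundance_gate([rec], run_of_sample={"S1": "r1", "S2": "r2"})
        assert dropped

    def test_read_mass_conserved_through_gate_and_filter(self):
        rng = np.random.default_rng(10)
        records = [derep(_seq(rng, 60), S1=int(n)) for n in rng.integers(1, 80, size=30)]
        total = sum(r.total for r in records)
        passed, dropped = abundance_gate(records)
        clusters = greedy_cluster(passed)
        kept, small = filter_clusters(clusters)
        mass = (
            sum(c.total_reads for c in kept)
            + sum(c.total_reads for c in small)
            + sum(r.total for r in dropped)
        )
        assert mass == total


@given(st.integers(0, 2**31 - 1))
def test_identity_bounds_property(seed):
    rng = np.random.default_rng(seed)
    a = random_dna(rng, int(rng.integers(1, 40)))
    b = random_dna(rng, int(rng.integers(1, 40)))
    ident = pairwise_identity(a, b)
    assert 0.0 <= ident <= 1.0
    assert ident == pairwise_identity(b, a)
    assert pairwise_identity(a, a) == 1.0
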