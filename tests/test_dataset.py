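import numpy as np
import pytest

from pepprior import (
    DerivedPeptideRecord,
    InteractionRecord,
    PositionEnergyProfile,
    ProteinSequence,
    binarize,
    cluster_split,
    dedupe_interactions,
    filter_records,
    kmer_identity,
    merge_duplicates,
    windows_to_positions,
)
from pepprior.dataset import identity_graph_edges

from oracles import brute_position_energies


def rand_seq(rng, n, sid="s"):
    return ProteinSequence(sid, "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n)))


class TestDedupeInteractions:
    def test_near_duplicate_bsa_dropped(self):
        recs = [
            InteractionRecord("A", "B", 500.0),
            InteractionRecord("A", "B", 550.0),
        ]
        assert dedupe_interactions(recs) == [recs[0]]

    def test_distinct_bsa_both_kept(self):
        recs = [
            InteractionRecord("A", "B", 500.0),
            InteractionRecord("A", "B", 650.0),
        ]
        assert dedupe_interactions(recs) == recs

    def test_distinct_pairs_never_collide(self):
        recs = [
            InteractionRecord("A", "B", 500.0),
            InteractionRecord("A", "C", 500.0),
            InteractionRecord("B", "A", 510.0),  # unordered pair match
        ]
        assert dedupe_interactions(recs) == recs[:2]

    def test_negative_bsa_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            InteractionRecord("A", "B", -1.0)


class TestFilterRecords:
    LENGTHS = {"ok": 100, "short": 50, "long": 1023, "edge_lo": 51, "edge_hi": 1022}

    def test_reu_artifact_dropped(self):
        recs = [DerivedPeptideRecord("ok", 1, 10, -1500.0)]
        assert filter_records(recs, self.LENGTHS) == []

    def test_reu_above_floor_kept(self):
        recs = [DerivedPeptideRecord("ok", 1, 10, -999.0)]
        assert filter_records(recs, self.LENGTHS) == recs

    @pytest.mark.parametrize("sid, kept", [
        ("short", False), ("long", False), ("edge_lo", True), ("edge_hi", True),
    ])
    def test_length_bounds_are_strict(self, sid, kept):
        recs = [DerivedPeptideRecord(sid, 1, 10, -5.0)]
        assert (filter_records(recs, self.LENGTHS) == recs) is kept

    def test_out_of_bounds_window_names_record(self):
        recs = [DerivedPeptideRecord("short", 45, 10, -5.0)]
        with pytest.raises(ValueError, match="short"):
            filter_records(recs, self.LENGTHS)


class TestWindowsToPositions:
    def test_three_overlapping_windows(self):
        seq = ProteinSequence("s", "A" * 12)
        recs = [
            DerivedPeptideRecord("s", 1, 10, -3.0),
            DerivedPeptideRecord("s", 2, 10, -2.0),
            DerivedPeptideRecord("s", 3, 10, -1.0),
        ]
        prof = windows_to_positions(recs, seq)
        assert prof.energy[0] == -3.0 and prof.coverage[0] == 1
        assert prof.energy[2] == -2.0 and prof.coverage[2] == 3
        assert prof.energy[11] == -1.0 and prof.coverage[11] == 1

    def test_single_window_covers_exactly_window_length(self):
        seq = ProteinSequence("s", "A" * 20)
        prof = windows_to_positions([DerivedPeptideRecord("s", 5, 10, -4.0)], seq)
        covered = ~prof.missing
        assert covered.sum() == 10
        assert np.all(prof.energy[4:14] == -4.0)

    def test_zero_records_gives_all_missing(self):
        prof = windows_to_positions([], ProteinSequence("s", "ACDEF"))
        assert prof.missing.all() and (prof.coverage == 0).all()

    def test_wrong_sequence_rejected(self):
        with pytest.raises(ValueError, match="other"):
            windows_to_positions(
                [DerivedPeptideRecord("other", 1, 3, 0.0)], ProteinSequence("s", "ACDEF")
            )

    def test_matches_bruteforce_oracle_and_conserves_coverage(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(10, 40))
            seq = rand_seq(rng, n)
            recs = []
            for _ in range(int(rng.integers(0, 12))):
                w = int(rng.integers(1, min(10, n) + 1))
                start = int(rng.integers(1, n - w + 2))
                recs.append(DerivedPeptideRecord("s", start, w, float(rng.normal(-2, 3))))
            prof = windows_to_positions(recs, seq)
            energy, coverage = brute_position_energies(recs, n)
            np.testing.assert_allclose(prof.energy, energy, rtol=1e-12, equal_nan=True)
            np.testing.assert_array_equal(prof.coverage, coverage)
            assert prof.coverage.sum() == sum(r.window_length for r in recs)


class TestMergeDuplicates:
    def p(self, sid, residues, energy):
        energy = np.asarray(energy, dtype=float)
        coverage = (~np.isnan(energy)).astype(int)
        return PositionEnergyProfile(sid, residues, energy, coverage)

    def test_mean_of_two(self):
        merged = merge_duplicates([self.p("b", "A", [-2.0]), self.p("a", "A", [-4.0])])
        assert len(merged) == 1
        assert merged[0].energy[0] == -3.0
        assert merged[0].sequence_id == "a"  # lexicographically smallest id
        assert merged[0].merged_ids == ("a", "b")

    def test_singleton_identity(self):
        prof = self.p("x", "ACD", [-1.0, np.nan, 2.0])
        assert merge_duplicates([prof]) == [prof]

    def test_missing_position_takes_other_value(self):
        merged = merge_duplicates(
            [self.p("a", "AC", [-2.0, np.nan]), self.p("b", "AC", [-4.0, -6.0])]
        )
        assert merged[0].energy[0] == -3.0
        assert merged[0].energy[1] == -6.0

    def test_distinct_residue_strings_not_merged(self):
        out = merge_duplicates([self.p("a", "AC", [0, 0]), self.p("b", "AD", [0, 0])])
        assert len(out) == 2


class TestBinarize:
    def profile(self, energy):
        energy = np.asarray(energy, dtype=float)
        coverage = (~np.isnan(energy)).astype(int)
        return PositionEnergyProfile("s", "A" * len(energy), energy, coverage)

    @pytest.mark.parametrize("energy, label", [(-1.5, 1), (-1.0, 0), (-0.5, 0)])
    def test_strict_threshold(self, energy, label):
        assert binarize(self.profile([energy])).labels[0] == label

    def test_missing_positions_masked_and_zero(self):
        ls = binarize(self.profile([-2.0, np.nan]))
        assert ls.labels.tolist() == [1, 0]
        assert ls.mask.tolist() == [True, False]
        assert ls.weight == 1.0

    def test_monotone_in_energy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            e = rng.normal(-1, 1, 20)
            base = binarize(self.profile(e)).labels
            lowered = binarize(self.profile(e - rng.random(20))).labels
            assert np.all(lowered >= base)  # lowering energy never flips 1 -> 0


class TestClusterSplit:
    def test_identical_sequences_share_cluster_and_split(self):
        seqs = [ProteinSequence("a", "MKVLLACDEF" * 6), ProteinSequence("b", "MKVLLACDEF" * 6)]
        out = cluster_split(seqs, seed=0)
        assert out[0].cluster_id == out[1].cluster_id
        assert out[0].split == out[1].split

    def test_disjoint_alphabets_separate(self):
        seqs = [ProteinSequence("a", "A" * 60), ProteinSequence("b", "W" * 60)]
        out = cluster_split(seqs, seed=0)
        assert out[0].cluster_id != out[1].cluster_id
        assert kmer_identity("A" * 60, "W" * 60) == 0.0

    def test_transitive_chain_is_one_component(self):
        # A~B and B~C above threshold, A~C below: union-find must still
        # place all three in one connected component.
        seqs = [
            ProteinSequence("A", "AAAAA"),
            ProteinSequence("B", "CCCCC"),
            ProteinSequence("C", "DDDDD"),
        ]
        ident = {
            frozenset(("A", "B")): 0.9,
            frozenset(("B", "C")): 0.9,
            frozenset(("A", "C")): 0.1,
        }
        by_res = {s.residues: s.id for s in seqs}
        fn = lambda x, y: ident[frozenset((by_res[x], by_res[y]))]
        out = cluster_split(seqs, identity_fn=fn, seed=0)
        assert len({a.cluster_id for a in out}) == 1

    def test_forced_test_cluster_lands_in_test(self):
        rng = np.random.default_rng(5)
        seqs = []
        for i in range(8):
            seqs.append(rand_seq(rng, 30, f"s{i}"))
        out = cluster_split(seqs, forced_test_ids=["s3"], seed=1)
        by_id = {a.sequence_id: a for a in out}
        forced_cluster = by_id["s3"].cluster_id
        for a in out:
            if a.cluster_id == forced_cluster:
                assert a.split == "test"

    def test_no_identity_edge_crosses_splits(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            seqs = [rand_seq(rng, int(rng.integers(20, 60)), f"s{i}") for i in range(15)]
            out = cluster_split(seqs, seed=trial)
            split_of = {a.sequence_id: a.split for a in out}
            for i, j in identity_graph_edges(seqs, 0.25, kmer_identity):
                assert split_of[seqs[i].id] == split_of[seqs[j].id]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        seqs = [rand_seq(rng, 40, f"s{i}") for i in range(20)]
        assert cluster_split(seqs, seed=9) == cluster_split(seqs, seed=9)

    def test_bad_fractions_rejected(self):
        seqs = [ProteinSequence("a", "ACDEF")]
        with pytest.raises(ValueError, match="sum to 1"):
            cluster_split(seqs, fractions=(0.5, 0.2, 0.2))

    def test_precomputed_clusters_injectable(self):
        seqs = [ProteinSequence("a", "ACDEF"), ProteinSequence("b", "WWWWW")]
        out = cluster_split(seqs, precomputed_clusters={"a": 7, "b": 7}, seed=0)
        assert out[0].split == out[1].split
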