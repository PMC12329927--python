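"""Dereplication, pre-clustering, chimera removal, clustering, filtering."""

from __future__ import annotations

import numpy as np
import pytest

from mockeval.otu import (OTU, ClusterParams, cluster, dereplicate,
                          detect_chimeras, filter_rare, pairwise_distances,
                          partition_mcc, pick_representative, precluster,
                          run_otu_pipeline)
from mockeval.records import SequenceRecord
from mockeval.synthetic import DEFAULT_FLANKS, simulate_reads
from mockeval.preprocess import preprocess_pairs

from _oracles import oracle_distance, oracle_mcc
from conftest import mutate_at, random_seq


def rec(seq, id="r", weight=1):
    return SequenceRecord(id=id, sequence=seq, weight=weight)


class TestDereplicate:
    def test_counts_and_identity(self, rng):
        a = random_seq(rng, 50)
        b = random_seq(rng, 50)
        seqs = [rec(a, "r1"), rec(a, "r2"), rec(a, "r3"), rec(b, "r4")]
        out = dereplicate(seqs)
        assert {(o.id, o.weight) for o in out} == {("r1", 3), ("r4", 1)}
        assert sum(o.weight for o in out) == sum(s.weight for s in seqs)

    def test_all_distinct_is_identity(self, rng):
        seqs = [rec(random_seq(rng, 40), f"r{i}") for i in range(5)]
        out = dereplicate(seqs)
        assert len(out) == 5


class TestPrecluster:
    def test_child_absorbed_into_abundant_parent(self, rng):
        parent = random_seq(rng, 60)
        child = mutate_at(parent, [10], rng)
        out, log = precluster([rec(parent, "p", 100), rec(child, "c", 1)])
        assert len(out) == 1
        assert out[0].weight == 101
        assert log == [("c", "p")]

    def test_equal_weight_tie_lexicographic(self):
        a = "AAAACCCCGGGGTTTTAAAA"
        b = "AAAACCCCGGGGTTTTAAAT"   # 1 mismatch, lexicographically larger
        out, log = precluster([rec(a, "x", 5), rec(b, "y", 5)])
        assert len(out) == 1
        assert out[0].sequence == a

    def test_three_mismatches_both_retained(self, rng):
        parent = random_seq(rng, 60)
        child = mutate_at(parent, [5, 20, 40], rng)
        out, _ = precluster([rec(parent, "p", 100), rec(child, "c", 1)])
        assert len(out) == 2

    def test_absorbs_all_planted_error_children(self, rng):
        """Every child within two mismatches of an abundant parent merges."""
        parents = [rec(random_seq(rng, 80), f"p{i}", 50) for i in range(5)]
        children = []
        for i, p in enumerate(parents):
            for j in range(4):
                pos = rng.choice(80, size=int(rng.integers(1, 3)), replace=False)
                children.append(rec(mutate_at(p.sequence, pos, rng),
                                    f"c{i}_{j}", 1))
        out, log = precluster(parents + children)
        assert len(out) == 5
        assert len(log) == len(children)
        assert sum(o.weight for o in out) == 5 * 50 + len(children)


class TestChimeraDetection:
    def test_constructed_positive_flagged(self, rng):
        a = random_seq(rng, 200)
        b = random_seq(rng, 200)
        chim = a[:100] + b[100:]
        seqs = [rec(a, "pa", 50), rec(b, "pb", 50), rec(chim, "q", 5)]
        clean, flagged = detect_chimeras(seqs)
        assert flagged == ["q"]

    def test_true_sequence_not_flagged(self, rng):
        a = random_seq(rng, 200)
        b = random_seq(rng, 200)
        c = random_seq(rng, 200)   # unique differences from both parents
        seqs = [rec(a, "pa", 50), rec(b, "pb", 50), rec(c, "q", 5)]
        clean, flagged = detect_chimeras(seqs)
        assert flagged == []

    def test_sensitivity_and_false_flags_on_seeded_set(self, rng):
        """>= 0.9 sensitivity on planted chimeras, zero flags on clean ones."""
        parents = [rec(random_seq(rng, 250), f"p{i}", 100) for i in range(6)]
        chims, clean = [], []
        for i in range(100):
            pa, pb = rng.choice(6, size=2, replace=False)
            bp = int(rng.integers(60, 190))
            chims.append(rec(parents[pa].sequence[:bp]
                             + parents[pb].sequence[bp:], f"ch{i}", 2))
        for i in range(100):
            clean.append(rec(random_seq(rng, 250), f"cl{i}", 2))
        _, flagged = detect_chimeras(parents + chims + clean)
        flagged = set(flagged)
        sens = sum(1 for c in chims if c.id in flagged) / len(chims)
        false = sum(1 for c in clean if c.id in flagged)
        assert sens >= 0.9
        assert false == 0


class TestPairwiseDistances:
    def test_identical_zero_and_simple_case(self):
        seqs = [rec("ACGTACGTAC", "a"), rec("ACGTACGTAC", "b"),
                rec("ACGTTCGTAC", "c")]
        d = pairwise_distances(seqs)
        assert d[0] == 0.0                      # a-b
        assert d[1] == pytest.approx(0.1)       # a-c

    def test_matches_independent_dp_oracle(self, rng):
        seqs = []
        base = random_seq(rng, 50)
        for i in range(8):
            if i % 2 == 0:
                pos = rng.choice(50, size=int(rng.integers(0, 4)), replace=False)
                seqs.append(rec(mutate_at(base, pos, rng), f"s{i}"))
            else:
                seqs.append(rec(random_seq(rng, int(rng.integers(40, 55))),
                                f"s{i}"))
        related = {i for i in range(8) if i % 2 == 0}
        d = pairwise_distances(seqs)
        k = 0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                od = oracle_distance(seqs[i].sequence, seqs[j].sequence)
                if i in related and j in related:
                    # near-identical pairs: the optimal alignment is unique
                    assert d[k] == pytest.approx(od, abs=1e-12)
                else:
                    # unrelated pairs admit co-optimal alignments whose
                    # column counts differ slightly between implementations
                    assert d[k] == pytest.approx(od, abs=0.05)
                k += 1


class TestCluster:
    def test_below_cutoff_merges_above_splits(self):
        a = "A" * 20 + "C" * 20 + "G" * 20 + "T" * 20 + "A" * 20   # 100bp
        near = mutate_at(a, [3], np.random.default_rng(0))          # d = 0.01
        far = mutate_at(a, list(range(0, 30, 3)), np.random.default_rng(1))
        seqs = [rec(a, "a", 5), rec(near, "n", 3), rec(far, "f", 2)]
        parts = cluster(seqs, pairwise_distances(seqs))
        labels = {s.id: k for k, p in enumerate(parts) for i in p
                  for s in [seqs[i]]}
        assert labels["a"] == labels["n"]
        assert labels["a"] != labels["f"]

    def test_opticlust_beats_or_ties_greedy_baseline(self, rng):
        """MCC of the optimizer >= greedy complete-linkage on seeded sets."""
        for trial in range(3):
            base = [random_seq(rng, 120) for _ in range(4)]
            seqs = []
            for gi, b in enumerate(base):
                for j in range(8):
                    pos = rng.choice(120, size=int(rng.integers(0, 5)),
                                     replace=False)
                    seqs.append(rec(mutate_at(b, pos, rng), f"g{gi}_{j}",
                                    int(rng.integers(1, 20))))
            dists = pairwise_distances(seqs)
            n = len(seqs)
            sq = np.zeros((n, n))
            k = 0
            for i in range(n):
                for j in range(i + 1, n):
                    sq[i, j] = sq[j, i] = dists[k]
                    k += 1
            close = sq <= 0.03
            np.fill_diagonal(close, False)

            def mcc_of(parts):
                assign = [0] * n
                for ci, p in enumerate(parts):
                    for i in p:
                        assign[i] = ci
                return oracle_mcc(assign, close)

            opti = cluster(seqs, dists, ClusterParams(method="opticlust"))
            greedy = cluster(seqs, dists,
                             ClusterParams(method="greedy_baseline"))
            assert mcc_of(opti) >= mcc_of(greedy) - 1e-12

    def test_partition_mcc_agrees_with_oracle(self, rng):
        n = 10
        close = rng.random((n, n)) < 0.3
        close = np.triu(close, 1)
        close = close | close.T
        assign = list(rng.integers(0, 3, size=n))
        assert partition_mcc(assign, close) == pytest.approx(
            oracle_mcc(assign, close))


class TestRareFilterAndReps:
    def _otu(self, oid, weights):
        members = {f"{oid}m{i}": w for i, w in enumerate(weights)}
        seqs = [rec("ACGT" * 10, f"{oid}m{i}", w) for i, w in enumerate(weights)]
        return OTU(otu_id=oid, members=members,
                   representative=pick_representative(seqs))

    def test_exact_threshold_removed_inclusive(self):
        # 10000 reads total; an OTU at exactly 0.05% (5 reads) is removed
        otus = [self._otu("big", [9995]), self._otu("small", [5])]
        out = filter_rare(otus)
        assert [o.otu_id for o in out] == ["big"]

    def test_singleton_removed(self):
        otus = [self._otu("big", [9999]), self._otu("single", [1])]
        out = filter_rare(otus)
        assert [o.otu_id for o in out] == ["big"]

    def test_zero_override_keeps_non_singletons(self):
        otus = [self._otu("big", [9998]), self._otu("tiny", [2])]
        out = filter_rare(otus, threshold_override=0.0)
        assert [o.otu_id for o in out] == ["big", "tiny"]

    def test_representative_max_weight_and_tie(self):
        a = rec("CCCC", "a", 3)
        b = rec("AAAA", "b", 3)
        c = rec("GGGG", "c", 5)
        assert pick_representative([a, b, c]).id == "c"
        assert pick_representative([a, b]).sequence == "AAAA"
        with pytest.raises(ValueError):
            pick_representative([])


class TestEndToEndOTUs:
    def test_error_free_run_recovers_k_species(self, species_small,
                                               communities_small,
                                               clean_sim_params):
        """Error-free reads from well-separated species -> exactly k OTUs
        whose representatives equal the true markers."""
        comm = communities_small[0]
        fwd, rev, _ = simulate_reads(comm, species_small, "ITS1",
                                     clean_sim_params)
        pre = preprocess_pairs(fwd, rev, DEFAULT_FLANKS["ITS1"])
        otus, log = run_otu_pipeline(pre.markers, dmc_id=comm.dmc_id)
        assert len(otus) == len(comm.members)
        by_name = {s.species_name: s for s in species_small}
        true_markers = {by_name[m].marker_seqs["ITS1"] for m in comm.members}
        assert {o.representative.sequence for o in otus} == true_markers
        assert sum(o.total_count for o in otus) == log["input_reads"]

    def test_confusable_group_collapses_to_one_otu(self, rng):
        """Species within the 0.03 cutoff co-cluster into a single OTU."""
        from mockeval.synthetic import (generate_marker_sequences,
                                        generate_taxonomy)
        skel = generate_taxonomy(4, 3, seed=5)
        grp = {s.species_name for s in skel if s.genus == "Genus02"}
        species = generate_marker_sequences(skel, confusable_groups=[grp],
                                            seed=5)
        seqs = [rec(s.marker_seqs["ITS1"], s.species_name,
                    10 if s.species_name in grp else 10) for s in species]
        parts = cluster(seqs, pairwise_distances(seqs))
        labels = {}
        for k, p in enumerate(parts):
            for i in p:
                labels[seqs[i].id] = k
        grp_labels = {labels[n] for n in grp}
        assert len(grp_labels) == 1
        # and no outsider joins them
        outsiders = [s.species_name for s in species
                     if s.species_name not in grp]
        assert all(labels[o] not in grp_labels for o in outsiders)
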