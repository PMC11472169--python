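"""Motif similarity, permutation p-values, clustering and archetypes."""

import numpy as np
import pytest

from comotif.clustering import (
    build_archetype,
    cluster_motifs,
    motif_similarity,
    revcomp_pfm,
    similarity_pvalue,
    summarize_anchor_sequences,
)
from comotif.synthetic import pfm_from_consensus, sample_instance

from conftest import make_core


class TestRevcompPFM:
    def test_single_column_complement(self):
        assert revcomp_pfm(np.array([[3], [0], [0], [1]])).ravel().tolist() == [1, 0, 0, 3]

    def test_involution(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 10, size=(4, 7))
        assert np.allclose(revcomp_pfm(revcomp_pfm(m)), m)

    def test_palindrome_fixed_point(self):
        # AT dimer: A column then T column is its own reverse complement
        m = np.array([[10.0, 0.0], [0, 0], [0, 0], [0.0, 10.0]])
        assert np.allclose(revcomp_pfm(m), m)


class TestMotifSimilarity:
    def test_self_similarity(self):
        m = pfm_from_consensus("TGACGTCA")
        sim = motif_similarity(m, m)
        assert sim.score == pytest.approx(1.0)
        assert sim.offset == 0 and sim.orientation == "forward"
        assert sim.normalized_score == pytest.approx(1.0)

    def test_reverse_complement_detected(self):
        m = pfm_from_consensus("TGACTTCA")
        sim = motif_similarity(m, revcomp_pfm(m))
        assert sim.score == pytest.approx(1.0)
        assert sim.orientation == "reverse-complement"

    def test_offset_recovered_for_embedded_motif(self):
        inner = pfm_from_consensus("GACGT")
        outer = np.hstack([np.full((4, 3), 25.0), inner, np.full((4, 2), 25.0)])
        sim = motif_similarity(outer, inner)
        assert sim.offset == 3 and sim.orientation == "forward"
        assert sim.score == pytest.approx(1.0)
        assert sim.normalized_score == pytest.approx(5 / 10)

    def test_rc_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.uniform(0, 10, size=(4, int(rng.integers(4, 9))))
            b = rng.uniform(0, 10, size=(4, int(rng.integers(4, 9))))
            s1 = motif_similarity(a, b)
            s2 = motif_similarity(revcomp_pfm(a), revcomp_pfm(b))
            assert s1.score == pytest.approx(s2.score, abs=1e-9)

    def test_unrelated_motifs_score_below_one(self):
        rng = np.random.default_rng(2)
        scores = []
        for _ in range(20):
            a = pfm_from_consensus("".join(rng.choice(list("ACGT"), 8)))
            b = pfm_from_consensus("".join(rng.choice(list("ACGT"), 8)))
            scores.append(motif_similarity(a, b).score)
        assert np.median(scores) < 0.9


class TestSimilarityPvalue:
    def test_identical_informative_motifs_significant(self):
        m = pfm_from_consensus("TGACGTCA")
        p = similarity_pvalue(m, m, n_perm=499, seed=0)
        assert p < 0.05

    def test_width_one_candidate_uninformative(self):
        m = pfm_from_consensus("A")
        p = similarity_pvalue(m, pfm_from_consensus("TGACGTCA"), n_perm=199, seed=0)
        assert p == pytest.approx(1.0)  # column permutation cannot beat itself

    def test_pvalue_bounds_and_determinism(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 10, size=(4, 6))
        b = rng.uniform(0, 10, size=(4, 8))
        p1 = similarity_pvalue(a, b, n_perm=199, seed=5)
        p2 = similarity_pvalue(a, b, n_perm=199, seed=5)
        assert p1 == p2
        assert 1 / 200 <= p1 <= 1.0

    def test_min_permutations_enforced(self):
        m = pfm_from_consensus("ACGT")
        with pytest.raises(ValueError):
            similarity_pvalue(m, m, n_perm=50)


class TestClusterMotifs:
    def test_duplicates_merge(self):
        m = pfm_from_consensus("TGACGTCA")
        cores = [make_core(m, flank_offset=4), make_core(m, flank_offset=9)]
        clusters = cluster_motifs(cores)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_reverse_complement_merges_with_orientation(self):
        m = pfm_from_consensus("TGACTTCA")
        cores = [make_core(m), make_core(revcomp_pfm(m), flank_offset=5)]
        (cluster,) = cluster_motifs(cores)
        orientations = sorted(am.orientation for am in cluster.members)
        assert orientations == ["forward", "reverse-complement"]

    def test_dissimilar_motifs_stay_apart(self):
        a = pfm_from_consensus("AAAAAAAA")
        b = pfm_from_consensus("ACGTACGT")
        clusters = cluster_motifs([make_core(a), make_core(b)])
        assert len(clusters) == 2

    def test_empty_input(self):
        assert cluster_motifs([]) == []

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        motifs = [
            pfm_from_consensus("TGACGTCA"),
            pfm_from_consensus("TGACGTCA"),
            pfm_from_consensus("GGGGCCCC"),
            pfm_from_consensus("ATATATAT"),
        ]
        cores = [make_core(m, flank_offset=i) for i, m in enumerate(motifs)]
        for core, label in zip(cores, "abcd"):
            core.parent.pfm.dataset = label

        def partition(cluster_list):
            return sorted(
                tuple(sorted(am.core.parent.pfm.dataset for am in c.members))
                for c in cluster_list
            )

        base = partition(cluster_motifs(cores))
        for _ in range(3):
            order = rng.permutation(len(cores))
            shuffled = [cores[i] for i in order]
            assert partition(cluster_motifs(shuffled)) == base

    def test_seed_is_widest_member(self):
        wide = pfm_from_consensus("TGACGTCAGG")
        narrow = pfm_from_consensus("TGACGTCA")
        (cluster,) = cluster_motifs([make_core(narrow), make_core(wide)])
        assert cluster.seed.core_width == 10


class TestBuildArchetype:
    def test_singleton_identity(self):
        m = pfm_from_consensus("TGACGTCA")
        (cluster,) = cluster_motifs([make_core(m)])
        arch = build_archetype(cluster)
        assert np.allclose(arch.counts, m)

    def test_mean_of_identical_members(self):
        m = pfm_from_consensus("TGACGTCA")
        cores = [make_core(m, flank_offset=i) for i in range(4)]
        (cluster,) = cluster_motifs(cores)
        arch = build_archetype(cluster)
        assert np.allclose(arch.counts, m)

    def test_low_ic_edges_trimmed(self):
        m = pfm_from_consensus("TGACGTCA")
        padded = np.hstack([np.full((4, 2), 25.0), m, np.full((4, 2), 25.0)])
        (cluster,) = cluster_motifs([make_core(padded)])
        arch = build_archetype(cluster)
        assert arch.counts.shape[1] == 8
        assert np.allclose(arch.counts, m)
        assert arch.trimmed_range == (2, 10)

    def test_empty_cluster_rejected(self):
        from comotif.clustering import Cluster

        with pytest.raises(ValueError):
            build_archetype(Cluster(seed=None, members=[]))


class TestSummarizeAnchors:
    def test_identical_anchors_full_ic(self):
        counts = summarize_anchor_sequences(["ACGTACGTAC"] * 8)
        from comotif.motif_stats import ic_vector

        assert counts.sum(axis=0).tolist() == [8] * 10
        assert np.allclose(ic_vector(counts), 2.0)

    def test_sampled_anchors_recover_source_frequencies(self):
        rng = np.random.default_rng(5)
        source = pfm_from_consensus("TGACGTCA", dominance=0.7)
        seqs = [sample_instance(source, rng=rng) for _ in range(4000)]
        counts = summarize_anchor_sequences(seqs)
        freq = counts / counts.sum(axis=0)
        src = source / source.sum(axis=0)
        assert np.abs(freq - src).max() < 0.05

    def test_empty_and_ragged_inputs(self):
        with pytest.raises(ValueError):
            summarize_anchor_sequences([])
        with pytest.raises(ValueError):
            summarize_anchor_sequences(["ACGT", "ACG"])
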