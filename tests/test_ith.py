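"""Similarity-matrix entropy, mutation burden, and fractal dimensions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ithsim import ith, synthetic
from ithsim.ith import (
    EmptyPopulationError,
    box_counting_fd,
    cluster_subclones,
    clustered_fd,
    entropy,
    entropy_from_profiles,
    genome_matrix,
    mean_mutation_count,
    similarity_matrix,
)

RNG = np.random.default_rng(2024)


def random_genomes(m, rng=RNG):
    return rng.integers(0, 2, size=(m, 50))


class TestSimilarityMatrix:
    def test_identical_genomes_fully_similar(self):
        M = np.tile(random_genomes(1), (5, 1))
        S = similarity_matrix(M)
        assert np.allclose(S, 1.0)

    def test_five_of_fifty_differences(self):
        g = random_genomes(1)[0]
        h = g.copy()
        flip = RNG.choice(50, 5, replace=False)
        h[flip] = 1 - h[flip]
        S = similarity_matrix(np.array([g, h]))
        assert S[0, 1] == pytest.approx(0.9)

    def test_complementary_genomes_zero_similarity(self):
        g = random_genomes(1)[0]
        S = similarity_matrix(np.array([g, 1 - g]))
        assert S[0, 1] == pytest.approx(0.0)

    def test_symmetric_unit_diagonal_bounded(self):
        S = similarity_matrix(random_genomes(12))
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)
        assert S.min() >= 0.0 and S.max() <= 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyPopulationError):
            similarity_matrix(np.zeros((0, 50)))


class TestEntropy:
    def test_monoclonal_entropy_exactly_zero(self):
        for m in (1, 4, 100):
            M = np.tile(random_genomes(1), (m, 1))
            assert entropy(similarity_matrix(M)) == 0.0
            assert entropy_from_profiles(M) == 0.0

    def test_two_dissimilar_clones_of_two_gives_log2(self):
        g = random_genomes(1)[0]
        M = np.array([g, g, 1 - g, 1 - g])
        S = similarity_matrix(M)
        s = np.linalg.svd(S, compute_uv=False)
        assert np.allclose(np.sort(s)[::-1], [2, 2, 0, 0], atol=1e-12)
        assert entropy(S) == pytest.approx(np.log(2), abs=1e-12)

    @pytest.mark.parametrize("b", [2, 3, 4, 5, 6])
    def test_block_clone_closed_form_log_b(self, b):
        S = np.kron(np.eye(b), np.ones((7, 7)))
        assert entropy(S) == pytest.approx(np.log(b), abs=1e-9)

    def test_permutation_invariance(self):
        S = similarity_matrix(random_genomes(15))
        perm = RNG.permutation(15)
        assert entropy(S[np.ix_(perm, perm)]) == pytest.approx(entropy(S), abs=1e-10)

    def test_compressed_path_matches_direct_svd(self):
        M = np.vstack([random_genomes(8), np.tile(random_genomes(1), (20, 1))])
        direct = entropy(similarity_matrix(M))
        assert entropy_from_profiles(M) == pytest.approx(direct, abs=1e-9)

    def test_adding_dissimilar_clone_increases_entropy(self):
        g = random_genomes(1)[0]
        mono = np.tile(g, (6, 1))
        mixed = np.vstack([mono, np.tile(1 - g, (2, 1))])
        assert entropy_from_profiles(mixed) > entropy_from_profiles(mono)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 9999))
    def test_zero_entropy_iff_identical_rows(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.integers(0, 2, size=(6, 50))
        eps = entropy_from_profiles(M)
        identical = bool((M == M[0]).all())
        assert (eps == 0.0) == identical


class TestBeta:
    def test_all_wild_zero(self):
        assert mean_mutation_count(np.zeros((5, 50))) == 0.0

    def test_arithmetic_mean(self):
        M = np.zeros((2, 50))
        M[0, :1] = 1
        M[1, :3] = 1
        assert mean_mutation_count(M) == pytest.approx(2.0)

    def test_bounded_by_genome_size(self):
        assert mean_mutation_count(np.ones((4, 50))) == 50.0


class TestClusterSubclones:
    def test_single_profile_single_cluster(self):
        P = np.tile([1, 0, 0, 0, 0, 0, 0], (10, 1))
        labels = cluster_subclones(P, k=1)
        assert len(set(labels)) == 1

    def test_two_separated_profiles_partition_exactly(self):
        P = np.vstack([np.tile([1, 0, 0, 0, 0, 0, 0], (6, 1)),
                       np.tile([0, 1, 1, 0, 0, 0, 0], (4, 1))])
        labels = cluster_subclones(P, k=2)
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_reproducible_with_equal_rng(self):
        P = RNG.integers(0, 2, size=(40, 7))
        l1 = cluster_subclones(P, k=3, rng=np.random.default_rng(5))
        l2 = cluster_subclones(P, k=3, rng=np.random.default_rng(5))
        assert np.array_equal(l1, l2)

    def test_rare_combination_absorbed_by_default_k(self):
        P = np.vstack([np.tile([1, 0, 0, 0, 0, 0, 0], (200, 1)),
                       [[1, 0, 0, 1, 0, 0, 0]]])  # one straggler cell
        labels = cluster_subclones(P)
        assert len(set(labels)) == 1

    def test_k_larger_than_population_rejected(self):
        with pytest.raises(ValueError):
            cluster_subclones(np.zeros((3, 7)), k=5)


class TestBoxCountingFd:
    def test_filled_square_dimension_two(self):
        mask = np.zeros((140, 140), dtype=bool)
        mask[6:134, 6:134] = True
        assert box_counting_fd(mask) == pytest.approx(2.0, abs=0.05)

    def test_straight_line_dimension_one(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[100, 10:190] = True
        assert box_counting_fd(mask) == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_carpet_dimension(self):
        carpet = synthetic.sierpinski_carpet(5)
        assert carpet.shape == (243, 243)
        assert box_counting_fd(carpet) == pytest.approx(np.log(8) / np.log(3), abs=0.05)

    def test_translation_and_rotation_invariance(self):
        carpet = synthetic.sierpinski_carpet(4)
        base = box_counting_fd(carpet)
        big = np.zeros((200, 260), dtype=bool)
        big[37:118, 59:140] = carpet
        assert box_counting_fd(big) == pytest.approx(base, abs=0.02)
        assert box_counting_fd(np.rot90(carpet)) == pytest.approx(base, abs=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyPopulationError):
            box_counting_fd(np.zeros((10, 10), dtype=bool))


class TestClusteredFd:
    @staticmethod
    def _disk_snapshot(radius=40):
        mask = synthetic.disk_mask(radius)
        rows, cols = np.nonzero(mask)
        genome = "1" + "0" * 49  # BRAF-only clone
        return pd.DataFrame({
            "cell_id": np.arange(len(rows)), "type": "MTC",
            "row": rows, "col": cols, "birth_step": 0, "a0": 1.5,
            "genome": genome,
        })

    def test_monoclonal_disk_close_to_plane_filling(self):
        snap = self._disk_snapshot()
        fd = clustered_fd(snap, rng=np.random.default_rng(0))
        assert fd == pytest.approx(1.9, abs=0.15)

    def test_two_line_clusters_average_near_one(self):
        rows = np.concatenate([np.full(80, 10), np.full(80, 200)])
        cols = np.concatenate([np.arange(20, 100), np.arange(20, 100)])
        genomes = ["1" + "0" * 49] * 80 + ["01" + "0" * 48] * 80
        snap = pd.DataFrame({
            "cell_id": np.arange(160), "type": "MTC", "row": rows,
            "col": cols, "birth_step": 0, "a0": 1.5, "genome": genomes,
        })
        fd = clustered_fd(snap, k=2, rng=np.random.default_rng(0), grid_size=260)
        assert fd == pytest.approx(1.0, abs=0.1)

    def test_no_mtc_rejected(self):
        snap = self._disk_snapshot().assign(type="NC")
        with pytest.raises(EmptyPopulationError):
            clustered_fd(snap)


class TestGenomeMatrix:
    def test_round_trip_through_strings(self):
        M = random_genomes(7)
        snap = pd.DataFrame({
            "type": "MTC",
            "genome": ["".join(map(str, row)) for row in M],
        })
        assert np.array_equal(genome_matrix(snap), M)

    def test_ctls_excluded(self):
        snap = pd.DataFrame({
            "type": ["MTC", "CTL"],
            "genome": ["1" * 50, ""],
        })
        assert genome_matrix(snap).shape == (1, 50)
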