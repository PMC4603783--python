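"""Contact fingerprints, affinity, spectral embedding and k-medoids."""

import numpy as np
import pytest

from ensa.clustering import (ContactParams, affinity_matrix, cluster,
                             contact_fingerprint, fingerprint_matrix,
                             medoid_frames, residue_pairs, select_k,
                             spectral_embed)
from ensa.core import AtomRecord, Frame, Topology
from ensa.geometry import mainchain_com
from ensa.synthetic import (STRAND_TEMPLATE, build_backbone, build_hairpin,
                            generate_archetype_fingerprints)


def _point_residue_topology(n_res):
    """Residues whose four main-chain atoms coincide, so the main-chain
    COM of residue i is exactly its atoms' common position."""
    atoms = [[AtomRecord(nm, el, m, r) for nm, el, m, r in
              (("N", "N", 14.007, 1.55), ("CA", "C", 12.011, 1.70),
               ("C", "C", 12.011, 1.70), ("O", "O", 15.999, 1.52))]
             for _ in range(n_res)]
    return Topology(["ALA"] * n_res, atoms)


def _frame_with_coms(positions):
    coords = np.repeat(np.asarray(positions, dtype=float), 4, axis=0)
    return Frame(coords)


class TestFingerprint:
    def test_extended_chain_has_no_long_range_contacts(self):
        topo, frame = build_backbone([STRAND_TEMPLATE] * 12, "A" * 12)
        fp = contact_fingerprint(frame, topo)
        assert fp.bits.sum() == 0

    def test_contact_at_exactly_cutoff_is_zero(self):
        topo = _point_residue_topology(4)
        frame = _frame_with_coms([[0, 0, 0], [100, 0, 0], [200, 0, 0],
                                  [4.5, 0, 0]])
        fp = contact_fingerprint(frame, topo)
        pair_idx = fp.pairs.index((1, 4))
        assert fp.bits[pair_idx] == 0
        frame2 = _frame_with_coms([[0, 0, 0], [100, 0, 0], [200, 0, 0],
                                   [4.499, 0, 0]])
        assert contact_fingerprint(frame2, topo).bits[pair_idx] == 1

    def test_bits_match_brute_force_com_distances(self, hairpin):
        topo, frame = hairpin
        fp = contact_fingerprint(frame, topo)
        assert fp.bits.sum() > 0  # the hairpin does make contacts
        for (i, j), bit in zip(fp.pairs, fp.bits):
            d = np.linalg.norm(mainchain_com(frame, topo, i)
                               - mainchain_com(frame, topo, j))
            assert bit == (1 if d < 4.5 else 0)

    def test_pair_order_is_lexicographic(self):
        pairs = residue_pairs(6, 3)
        assert pairs == sorted(pairs)
        assert all(j - i >= 3 for i, j in pairs)

    def test_too_few_residues_give_empty_fingerprint(self):
        topo = _point_residue_topology(3)
        frame = _frame_with_coms([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        assert contact_fingerprint(frame, topo).bits.size == 0


class TestAffinity:
    def test_identical_fingerprints_have_unit_affinity(self):
        F = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 1, 0]],
                     dtype=np.uint8)
        A = affinity_matrix(F)
        assert A[0, 1] == pytest.approx(1.0)

    def test_complementary_vectors_with_unit_sigma(self):
        F = np.array([[0, 0, 0, 0], [1, 1, 1, 1]], dtype=np.uint8)
        A = affinity_matrix(F, sigma=1.0)
        assert A[0, 1] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_matches_xor_count_oracle(self):
        F = np.array([[1, 0, 0, 1, 1], [0, 0, 1, 1, 0], [1, 1, 1, 0, 1]],
                     dtype=np.uint8)
        sigma = 0.7
        A = affinity_matrix(F, sigma=sigma)
        for m in range(3):
            for n in range(3):
                h = np.sum(F[m] ^ F[n]) / F.shape[1]
                assert A[m, n] == pytest.approx(
                    np.exp(-h / (2 * sigma ** 2)), abs=1e-12)

    def test_degenerate_input_warns_and_returns_ones(self):
        F = np.zeros((4, 6), dtype=np.uint8)
        with pytest.warns(UserWarning, match="identical"):
            A = affinity_matrix(F)
        assert np.all(A == 1.0)

    def test_positive_semidefinite(self, rng):
        F = (rng.random((30, 40)) < 0.3).astype(np.uint8)
        A = affinity_matrix(F)
        w = np.linalg.eigvalsh(A)
        assert w.min() >= -1e-8 * w.max()


class TestSpectralEmbed:
    def test_identity_affinity_has_unit_singular_values(self):
        emb, s = spectral_embed(np.eye(5), n_vectors=3)
        assert np.allclose(s[:3], 1.0)

    def test_rank_one_affinity(self):
        x = np.array([1.0, 2.0, 3.0])
        A = np.outer(x, x)
        emb, s = spectral_embed(A, n_vectors=7)
        assert s[0] == pytest.approx(x @ x, abs=1e-10)
        assert emb.shape[1] == 1  # capped at rank

    def test_matches_dense_eigendecomposition(self, rng):
        F = (rng.random((5, 20)) < 0.4).astype(np.uint8)
        A = affinity_matrix(F, sigma=0.5)
        emb, s = spectral_embed(A, n_vectors=3)
        w, V = np.linalg.eigh(A)           # independent route
        order = np.argsort(w)[::-1]
        w = w[order]
        assert np.allclose(s[:3], w[:3], atol=1e-10)
        # embedding distances agree regardless of sign convention
        d_emb = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        Ve = V[:, order[:3]] * w[:3]
        d_ref = np.linalg.norm(Ve[:, None] - Ve[None, :], axis=2)
        assert np.allclose(d_emb, d_ref, atol=1e-8)


def _blob_embedding(rng, n_per=30, k=3, sep=20.0, sd=0.5):
    centers = rng.normal(scale=sep, size=(k, 4))
    while np.min([np.linalg.norm(a - b) for i, a in enumerate(centers)
                  for b in centers[i + 1:]] or [np.inf]) < 5 * sep / 2:
        centers = rng.normal(scale=sep, size=(k, 4))
    pts = np.concatenate([c + rng.normal(scale=sd, size=(n_per, 4))
                          for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return pts, labels


class TestKMedoids:
    def test_recovers_well_separated_blobs(self, rng):
        from sklearn.metrics import adjusted_rand_score
        pts, truth = _blob_embedding(rng)
        res = cluster(pts, 3, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_k_equals_n_gives_zero_cost(self, rng):
        pts = rng.normal(size=(8, 3))
        res = cluster(pts, 8, seed=0)
        assert res.within_cluster_sum == pytest.approx(0.0, abs=1e-12)
        assert sorted(res.medoid_indices) == list(range(8))

    def test_same_seed_reproduces_labels(self, rng):
        pts = rng.normal(size=(40, 5))
        a = cluster(pts, 4, seed=7)
        b = cluster(pts, 4, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.medoid_indices, b.medoid_indices)

    def test_partition_stable_under_frame_reordering(self, rng):
        pts, _ = _blob_embedding(rng)
        perm = rng.permutation(len(pts))
        a = cluster(pts, 3, seed=0)
        b = cluster(pts[perm], 3, seed=0)
        # same partition as sets of frame indices, up to cluster renaming
        part_a = {frozenset(np.nonzero(a.labels == c)[0]) for c in range(3)}
        part_b = {frozenset(perm[np.nonzero(b.labels == c)[0]])
                  for c in range(3)}
        assert part_a == part_b

    def test_medoids_are_exhaustive_minimizers(self, rng):
        pts, _ = _blob_embedding(rng, n_per=40)
        res = cluster(pts, 3, seed=1)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        for c, m in enumerate(res.medoid_indices):
            members = np.nonzero(res.labels == c)[0]
            sums = D[np.ix_(members, members)].sum(axis=1)
            assert D[m, members].sum() == pytest.approx(sums.min(),
                                                        abs=1e-9)

    def test_invalid_k_raises(self, rng):
        pts = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            cluster(pts, 6, seed=0)


class TestSelectK:
    def test_elbow_finds_planted_cluster_number(self, rng):
        pts, _ = _blob_embedding(rng)
        res = select_k(pts, range(2, 8), seed=0, n_restarts=5)
        assert res.suggested_k == 3

    def test_curve_is_non_increasing(self, rng):
        pts = rng.normal(size=(50, 4))
        res = select_k(pts, range(2, 10), seed=0, n_restarts=5)
        assert np.all(np.diff(res.sums) <= 1e-9)


def test_medoid_frames_returns_actual_frames(two_state_small):
    ensemble, _, _ = two_state_small
    F = fingerprint_matrix(ensemble)
    A = affinity_matrix(F)
    emb, s = spectral_embed(A, 7)
    res = cluster(emb, 2, seed=0, singular_values=s)
    frames, sizes = medoid_frames(ensemble, res)
    assert len(frames) == 2
    assert sizes.sum() == ensemble.n_frames
    for fr, m in zip(frames, res.medoid_indices):
        assert fr is ensemble.frames[int(m)]
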