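"""The synthetic-data generators and their planted ground truths."""

import numpy as np
import pytest

from ensa.core import read_multimodel_pdb, write_multimodel_pdb
from ensa.geometry import phi_series, psi_series
from ensa.sasa import hydrophobic_sasa
from ensa.synthetic import (GeneratorSpec, HELIX_TEMPLATE, STRAND_TEMPLATE,
                            build_backbone, compact_fold_angles,
                            generate_archetype_fingerprints,
                            generate_markov_trajectories,
                            generate_two_state_ensemble)


class TestBackboneBuilder:
    @pytest.mark.parametrize("template", [HELIX_TEMPLATE, STRAND_TEMPLATE,
                                          (-75.0, 150.0)])
    def test_requested_dihedrals_recovered(self, template):
        topo, frame = build_backbone([template] * 10, "A" * 10)
        phi = phi_series(frame, topo)
        psi = psi_series(frame, topo)
        assert np.allclose(phi[1:], template[0], atol=1e-5)
        assert np.allclose(psi[:-1], template[1], atol=1e-5)

    def test_extended_chain_grows_linearly(self):
        topo, frame = build_backbone([STRAND_TEMPLATE] * 20, "A" * 20)
        ca = np.array([frame.coords[topo.atom_index(r, "CA")]
                       for r in range(1, 21)])
        rise = np.linalg.norm(ca[-1] - ca[0]) / 19
        assert rise == pytest.approx(3.4, rel=0.10)

    def test_helical_rise_along_axis(self):
        topo, frame = build_backbone([HELIX_TEMPLATE] * 20, "A" * 20)
        ca = np.array([frame.coords[topo.atom_index(r, "CA")]
                       for r in range(1, 21)])
        centered = ca - ca.mean(axis=0)
        # helix axis = dominant principal direction of the Calpha trace
        _, _, vt = np.linalg.svd(centered)
        proj = centered @ vt[0]
        rise = (proj.max() - proj.min()) / 19
        assert rise == pytest.approx(1.5, rel=0.10)


class TestTwoStateGenerator:
    def test_exact_label_allocation(self, two_state_small):
        _, labels, spec = two_state_small
        assert (labels == 0).sum() == round(spec.mixing * len(labels))

    def test_same_seed_is_bit_identical(self):
        spec = GeneratorSpec(n_residues=16, seed=4)
        a, la = generate_two_state_ensemble(spec, n_frames=6,
                                            min_separation=0.0)
        b, lb = generate_two_state_ensemble(spec, n_frames=6,
                                            min_separation=0.0)
        assert np.array_equal(la, lb)
        assert np.array_equal(a.coords_stack(), b.coords_stack())

    def test_populations_are_separated_in_sasa(self, two_state_small):
        ensemble, labels, _ = two_state_small
        topo = ensemble.topology
        vals = np.array([hydrophobic_sasa(f, topo) for f in ensemble.frames])
        assert vals[labels == 0].max() < vals[labels == 1].min()

    def test_unattainable_separation_raises_with_advice(self):
        spec = GeneratorSpec(n_residues=16, seed=4)
        with pytest.raises(ValueError, match="noise"):
            generate_two_state_ensemble(spec, n_frames=6,
                                        min_separation=1e5, max_retries=1)

    def test_output_exercises_the_real_pdb_reader(self, two_state_small,
                                                  tmp_path):
        ensemble, _, _ = two_state_small
        from ensa.core import Ensemble
        sub = Ensemble(topology=ensemble.topology,
                       frames=ensemble.frames[:3])
        path = tmp_path / "gen.pdb"
        write_multimodel_pdb(sub, path)
        back = read_multimodel_pdb(path)
        assert np.abs(back.coords_stack()
                      - sub.coords_stack()).max() <= 1e-3 + 1e-9


class TestArchetypeFingerprints:
    def test_zero_flip_copies_archetypes_exactly(self):
        F, labels = generate_archetype_fingerprints(3, 50, 0.0, 10, seed=0)
        for c in range(3):
            block = F[labels == c]
            assert np.all(block == block[0])

    def test_single_class_has_uniform_labels(self):
        _, labels = generate_archetype_fingerprints(1, 30, 0.1, 20, seed=0)
        assert np.all(labels == 0)

    def test_within_class_hamming_matches_binomial_expectation(self):
        p = 0.05
        n_bits = 400
        F, labels = generate_archetype_fingerprints(2, n_bits, p, 40,
                                                    seed=3)
        # two independent flips disagree with prob 2p(1-p)
        expect = 2 * p * (1 - p)
        dists = []
        for c in range(2):
            block = F[labels == c].astype(bool)
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    dists.append(np.mean(block[i] ^ block[j]))
        obs = np.mean(dists)
        # pairs share members, so the mean's variance is governed by the
        # per-member flip counts: Var ≈ 4 p(1-p) / (n_bits · m)
        m = 40
        sd = np.sqrt(4 * p * (1 - p) / (n_bits * m))
        assert abs(obs - expect) < 3 * sd

    def test_archetypes_respect_minimum_separation(self):
        F, labels = generate_archetype_fingerprints(3, 60, 0.0, 1, seed=7)
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.mean(F[i] != F[j]) >= 0.3


class TestMarkovTrajectories:
    def test_absorbing_extended_state_orders_frames(self):
        spec = GeneratorSpec(n_residues=12, seed=6,
                             transition=((0.7, 0.3), (0.0, 1.0)))
        _, truth = generate_markov_trajectories(spec, n_traj=5, n_frames=30,
                                                build_frames=False)
        for _, g in truth.groupby("trajectory"):
            s = g.sort_values("time")["state"].to_numpy()
            assert np.all(np.diff(s) >= 0)   # CS frames all precede ES

    def test_occupancy_matches_stationary_distribution(self):
        p, q = 0.2, 0.1   # CS->ES and ES->CS switch probabilities
        spec = GeneratorSpec(n_residues=12, seed=8,
                             transition=((1 - p, p), (q, 1 - q)))
        _, truth = generate_markov_trajectories(spec, n_traj=20,
                                                n_frames=400,
                                                build_frames=False)
        stationary_es = p / (p + q)
        obs = truth["state"].mean()
        n = len(truth)
        sd = np.sqrt(stationary_es * (1 - stationary_es) / n)
        # frames are correlated; allow generous slack over the iid sd
        assert abs(obs - stationary_es) < 15 * sd

    def test_truth_and_frames_align(self):
        spec = GeneratorSpec(n_residues=12, seed=9)
        ens, truth = generate_markov_trajectories(spec, n_traj=2,
                                                  n_frames=5)
        assert ens.n_frames == len(truth) == 10
        assert list(ens.times) == list(truth["time"])
        assert list(ens.trajectory_ids) == list(truth["trajectory"])


def test_compact_fold_template_has_long_range_contacts():
    from ensa.clustering import contact_fingerprint
    from ensa.core import ABETA42_SEQUENCE
    angles = compact_fold_angles(42)
    topo, frame = build_backbone(angles, ABETA42_SEQUENCE)
    fp = contact_fingerprint(frame, topo)
    assert fp.bits.sum() >= 3
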