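"""Alignment, Kabsch fitting and full superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import homolig as h
from homolig.superpose import RigidTransform, secondary_structure_states


def random_cloud(n, seed):
    return np.random.default_rng(seed).uniform(-10, 10, (n, 3))


def euler_grid_min_rmsd(P, Q, step_deg=10.0):
    """Brute-force oracle: best RMSD over a rotation grid (centroids aligned)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    best = np.inf
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    betas = np.deg2rad(np.arange(0.0, 180.0 + step_deg, step_deg))
    for a in angles:
        ca_, sa = np.cos(a), np.sin(a)
        Rz1 = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
        for b in betas:
            cb, sb = np.cos(b), np.sin(b)
            Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for g in angles:
                cg, sg = np.cos(g), np.sin(g)
                Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                R = Rz1 @ Ry @ Rz2
                r = np.sqrt(np.mean(np.sum((Qc @ R.T - Pc) ** 2, axis=1)))
                best = min(best, r)
    return best


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_inverse_and_compose(self):
        T = RigidTransform.from_axis_angle((1, 2, 3), 40.0, (1.0, -2.0, 0.5))
        I = T.compose(T.inverse())
        assert np.allclose(I.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(I.translation, 0.0, atol=1e-12)

    def test_apply_matches_manual(self):
        T = RigidTransform.from_axis_angle((0, 0, 1), 90.0, (1.0, 2.0, 3.0))
        out = T.apply(np.array([[1.0, 0.0, 0.0]]))
        assert np.allclose(out, [[1.0, 3.0, 3.0]], atol=1e-12)


class TestAlignment:
    def test_identical_sequences_fully_paired(self):
        t = h.pairwise_align("MKTAYIAKQR", "MKTAYIAKQR")
        assert t.identity_fraction == 1.0
        assert t.pairs == [(i, i) for i in range(10)]

    def test_single_mismatch_example(self):
        t = h.pairwise_align("ACDEFG", "ACDEYG")
        assert t.pairs == [(i, i) for i in range(6)]
        assert t.identity_fraction == pytest.approx(5 / 6)

    def test_score_matches_independent_aligner(self):
        """Cross-check the affine-gap DP against Biopython's PairwiseAligner."""
        from Bio import Align
        from Bio.Align import substitution_matrices
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        aligner.mode = "global"
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(12):
            a = "".join(rng.choice(aas, rng.integers(8, 90)))
            b = "".join(rng.choice(aas, rng.integers(8, 90)))
            assert h.pairwise_align(a, b).score == pytest.approx(aligner.score(a, b))

    @given(seed=st.integers(0, 50))
    @settings(max_examples=15)
    def test_pairs_never_cross(self, seed):
        rng = np.random.default_rng(seed)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, 30))
        b = "".join(rng.choice(aas, 35))
        pairs = h.pairwise_align(a, b).pairs
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            assert i2 > i1 and j2 > j1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            h.pairwise_align("", "ACD")

    def test_helix_assigned_h_states(self):
        spec = h.FixtureSpec(n_helices=1, residues_per_helix=15, seed=0)
        _, ca = h.make_helical_bundle(spec).ca_array("A")
        states = secondary_structure_states(ca)
        assert set(states[:-3]) == {"H"}


class TestKabsch:
    def test_identical_point_sets(self):
        P = random_cloud(10, 0)
        T, rmsd = h.kabsch(P, P)
        assert rmsd < 1e-12
        assert np.allclose(T.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(T.translation, 0.0, atol=1e-10)

    def test_recovers_planted_transform_exactly(self):
        P = random_cloud(10, 1)
        truth = RigidTransform.from_axis_angle((0, 0, 1), 90.0, (1.0, 2.0, 3.0))
        Q = truth.inverse().apply(P)  # target = moved query
        T, rmsd = h.kabsch(P, Q)
        assert rmsd < 1e-10
        assert np.linalg.norm(T.rotation - truth.rotation) < 1e-9

    def test_noisy_fit_within_noise_scale_and_beats_grid(self):
        rng = np.random.default_rng(5)
        P = random_cloud(4, 2)
        truth = RigidTransform.from_axis_angle((1, 0, 1), 35.0, (2.0, 0.0, -1.0))
        Q = truth.inverse().apply(P) + rng.normal(0, 0.5, P.shape)
        T, rmsd = h.kabsch(P, Q)
        assert 0.1 <= rmsd <= 1.5
        assert rmsd <= euler_grid_min_rmsd(P, Q) + 1e-9

    @given(seed=st.integers(0, 20))
    @settings(max_examples=8)
    def test_optimality_against_rotation_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        P = rng.uniform(-8, 8, (n, 3))
        Q = rng.uniform(-8, 8, (n, 3))
        try:
            _, rmsd = h.kabsch(P, Q)
        except ValueError:
            return  # degenerate draw
        assert rmsd <= euler_grid_min_rmsd(P, Q) + 1e-9

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            h.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            h.kabsch(line, line + 1.0)


class TestSuperpose:
    def test_structure_vs_itself(self):
        spec = h.FixtureSpec(seed=2)
        b = h.make_helical_bundle(spec)
        res = h.superpose(b, b)
        assert res.rmsd < 1e-10
        assert res.n_pairs_retained == res.n_pairs_initial
        assert res.mode == "sequence_dependent"

    def test_planted_transform_recovered(self, bundle_and_homolog):
        spec, bundle, hom, truth, _ = bundle_and_homolog
        res = h.superpose(bundle, hom, mode="auto")
        assert res.mode == "sequence_dependent"
        assert res.rmsd <= 3 * spec.noise_sigma
        err = res.transform.compose(truth.inverse()).rotation_angle_deg()
        assert err < 2.0

    def test_noise_free_recovery_is_exact(self):
        spec = h.FixtureSpec(noise_sigma=0.0, identity=1.0, transform_angle_deg=70.0,
                             transform_axis=(2, 1, 0), translation=(3.0, 3.0, -4.0), seed=9)
        b = h.make_helical_bundle(spec)
        hom, truth, _ = h.make_homolog(b, spec)
        res = h.superpose(b, hom)
        assert np.linalg.norm(res.transform.rotation - truth.rotation) < 1e-6
        assert res.rmsd < 1e-8

    def test_low_identity_selects_sequence_independent(self):
        spec = h.FixtureSpec(noise_sigma=0.2, identity=0.15, transform_angle_deg=30.0,
                             translation=(3.0, 1.0, 0.0), seed=7,
                             n_helices=8, residues_per_helix=25)
        b = h.make_helical_bundle(spec)
        hom, truth, _ = h.make_homolog(b, spec)
        res = h.superpose(b, hom, mode="auto")
        assert res.identity_fraction <= 0.30
        assert res.mode == "sequence_independent"
        assert res.transform.compose(truth.inverse()).rotation_angle_deg() < 2.0

    def test_transform_always_proper(self, bundle_and_homolog):
        _, bundle, hom, _, _ = bundle_and_homolog
        res = h.superpose(bundle, hom)
        R = res.transform.rotation
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_rmsd_symmetric(self, bundle_and_homolog):
        _, bundle, hom, _, _ = bundle_and_homolog
        fwd = h.superpose(bundle, hom, max_cycles=1)
        rev = h.superpose(hom, bundle, max_cycles=1)
        assert fwd.rmsd == pytest.approx(rev.rmsd, abs=1e-6)

    def test_outlier_rejection_reduces_rmsd(self, bundle_and_homolog):
        _, bundle, hom, _, _ = bundle_and_homolog
        loose = h.superpose(bundle, hom, max_cycles=1)
        tight = h.superpose(bundle, hom, max_cycles=5, reject_cutoff=1.0)
        assert tight.rmsd <= loose.rmsd + 1e-12
        assert tight.n_pairs_retained <= loose.n_pairs_retained

    def test_too_small_structures_rejected(self, three_residue_pdb):
        st_ = h.read_structure(three_residue_pdb)
        with pytest.raises(ValueError, match="20"):
            h.superpose(st_, st_)
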