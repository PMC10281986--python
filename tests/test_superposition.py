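"""Kabsch/Umeyama superposition against brute-force and analytic oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nucdeform.errors import (
    CorrespondenceError,
    InsufficientPointsError,
    PruningCollapseError,
)
from nucdeform.superpose import (
    apply_transform,
    build_correspondence,
    kabsch,
    superpose_models,
    umeyama,
)
from tests.conftest import random_rotation


def oracle_min_rmsd(P, Q, n_grid=1500, seed=0):
    """Brute-force minimum RMSD: best of a rotation sample, locally refined.

    Independent of the closed-form path: translation is optimal for any
    rotation (centroid match), so the search runs over rotations only.
    """
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = P0 @ R.T - Q0
        return np.sqrt(np.mean(np.einsum("ij,ij->i", d, d)))

    samples = Rotation.random(n_grid, random_state=seed).as_rotvec()
    best = min(samples, key=rmsd_of)
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    return res.fun


class TestKabsch:
    def test_identity(self, rng):
        P = rng.normal(size=(10, 3))
        T, r = kabsch(P, P)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(T.translation, 0, atol=1e-10)

    def test_pure_translation(self, rng):
        P = rng.normal(size=(8, 3))
        Q = P + np.array([5.0, 0.0, 0.0])
        T, r = kabsch(P, Q)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(T.translation, [5, 0, 0], atol=1e-9)

    def test_symmetry_of_rmsd(self, rng):
        P = rng.normal(size=(12, 3))
        Q = rng.normal(size=(12, 3))
        _, r1 = kabsch(P, Q)
        _, r2 = kabsch(Q, P)
        assert abs(r1 - r2) < 1e-9

    def test_proper_rotation_even_for_reflected_input(self, rng):
        P = rng.normal(size=(10, 3))
        Q = P * np.array([1, 1, -1])  # mirrored cloud
        T, _ = kabsch(P, Q)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_warns_but_returns(self):
        P = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        Q = P.copy()
        with pytest.warns(UserWarning):
            _, r = kabsch(P, Q)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        """Closed-form optimum equals a rotation-search + refinement oracle."""
        for k in range(12):
            n = int(rng.integers(4, 11))
            P = rng.normal(size=(n, 3)) * 3
            R0 = random_rotation(rng)
            Q = P @ R0.T + rng.normal(size=3) + rng.normal(scale=0.1, size=(n, 3))
            _, r_kabsch = kabsch(P, Q)
            r_oracle = oracle_min_rmsd(P, Q, seed=k)
            assert abs(r_kabsch - r_oracle) < 1e-3

    def test_weighted_fit_ignores_zero_weight_outlier(self, rng):
        P = rng.normal(size=(9, 3))
        Q = P.copy()
        Q[0] += 50.0
        w = np.ones(9)
        w[0] = 0.0
        _, r = kabsch(P, Q, weights=w)
        assert r == pytest.approx(0.0, abs=1e-9)


class TestUmeyama:
    def test_pure_scale(self, rng):
        P = rng.normal(size=(20, 3))
        # the magnitude of a voxel-size miscalibration seen in practice
        T, r = umeyama(P, 1.06 * P)
        assert T.scale == pytest.approx(1.06, abs=1e-12)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_unit_scale_reproduces_kabsch(self):
        rng = np.random.default_rng(99)
        P = rng.normal(size=(15, 3))
        R0 = random_rotation(rng)
        Q = P @ R0.T + np.array([1.0, -2.0, 0.5]) + rng.normal(scale=0.05, size=(15, 3))
        Tk, rk = kabsch(P, Q)
        Tu, _ = umeyama(P, Q)
        # same rotation; scale near 1 for a rigid+noise pair
        assert np.allclose(Tk.rotation, Tu.rotation, atol=1e-9)
        assert Tu.scale == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("scale", [0.995, 1.0, 1.06])
    def test_scale_recovery_under_noise(self, scale, rng):
        errs = []
        for _ in range(100):
            P = rng.normal(size=(40, 3)) * 15
            R0 = random_rotation(rng)
            Q = scale * (P @ R0.T) + rng.normal(size=3) + rng.normal(scale=0.05, size=P.shape)
            T, _ = umeyama(P, Q)
            errs.append(abs(T.scale - scale))
        assert max(errs) < 0.002


class TestCorrespondence:
    def test_self_pairing_auth_number(self, ideal):
        cmap = build_correspondence(ideal, ideal, "H3", mode="auth_number")
        assert len(cmap) == len(ideal.chain_for_role("H3").residues)

    def test_sequence_align_recovers_renumbering(self, ideal):
        shifted = ideal.copy()
        chain = shifted.chain_for_role("H3")
        for r in chain.residues:
            object.__setattr__(r.ref, "auth_seq", r.ref.auth_seq + 100)
        n_plain = len(build_correspondence(ideal, ideal, "H3", mode="auth_number"))
        n_aln = len(build_correspondence(ideal, shifted, "H3", mode="sequence_align"))
        assert n_aln == n_plain

    def test_truncation_reduces_pairs(self, ideal):
        trunc = ideal.copy()
        chain = trunc.chain_for_role("H3")
        chain.residues = chain.residues[:-10]
        n_full = len(build_correspondence(ideal, ideal, "H3"))
        n_trunc = len(build_correspondence(trunc, ideal, "H3"))
        assert n_full - n_trunc == 10

    def test_absent_role_errors(self, ideal):
        noH3 = ideal.copy()
        noH3.roles = {c: r for c, r in noH3.roles.items() if r != "H3"}
        with pytest.raises(Exception):
            build_correspondence(ideal, noH3, "H3")

    def test_frame_position_mode_on_dna(self, ideal):
        cmap = build_correspondence(ideal, ideal, "strand_bottom",
                                    mode="frame_position", atom_filter=None)
        assert len(cmap) == len(ideal.chain_for_role("strand_bottom").residues)


class TestSuperposeModels:
    def test_recovers_rigid_transform(self, ideal, rng):
        from nucdeform.superpose import RigidTransform

        R0 = random_rotation(rng)
        T0 = RigidTransform(R0, np.array([10.0, -5.0, 3.0]))
        moved = apply_transform(ideal, T0)
        res = superpose_models(ideal, moved)
        assert res.diagnostics["anchor_rmsd"] < 1e-8
        assert res.diagnostics["pairs_dropped"] == 0
        back = apply_transform(moved, res.transform)
        x0 = np.array([a.xyz for _, a in ideal.structure.iter_atoms()])
        x1 = np.array([a.xyz for _, a in back.structure.iter_atoms()])
        assert np.max(np.abs(x0 - x1)) < 1e-7

    def test_pruning_drops_displaced_anchor_atoms(self, ideal):
        moved = ideal.copy()
        chain = moved.chain_for_role("H3")
        for r in chain.residues[:5]:
            r.atoms[0].xyz = r.atoms[0].xyz + np.array([10.0, 0, 0])
        res = superpose_models(ideal, moved, prune="iterative", prune_cutoff=2.0)
        assert res.diagnostics["pairs_dropped"] == 5

    def test_prune_noop_on_identical_pair(self, ideal):
        a = superpose_models(ideal, ideal, prune="none")
        b = superpose_models(ideal, ideal, prune="iterative")
        assert np.allclose(a.transform.rotation, b.transform.rotation, atol=1e-6)
        assert np.allclose(a.transform.translation, b.transform.translation, atol=1e-6)

    def test_pruning_collapse(self, ideal):
        moved = apply_transform(ideal, __import__("nucdeform").RigidTransform(
            np.eye(3), np.array([50.0, 0.0, 0.0])))
        # every anchor pair starts 50 A off; cutoff far below residuals after fit
        chain = moved.chain_for_role("H3")
        import numpy as np_

        rng = np_.random.default_rng(1)
        for r in chain.residues:
            r.atoms[0].xyz = r.atoms[0].xyz + rng.normal(scale=30.0, size=3)
        with pytest.raises(PruningCollapseError):
            superpose_models(ideal, moved, prune="iterative", prune_cutoff=0.01)

    def test_single_copy_anchor_flag(self, ideal):
        res = superpose_models(ideal, ideal, pool_copies=False)
        assert res.diagnostics["anchor_roles"] == ["H3"]
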