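import math

import numpy as np
import pytest

from bifacet.errors import (
    AxisMismatchError,
    CapacityError,
    ConditioningError,
    ValidationError,
)
from bifacet.structmodel import (
    Atom,
    ChainModel,
    Residue,
    RigidTransform,
    StructureModel,
    apply_transform,
    read_structure,
    rotation_angle_about_axis,
    superpose,
    write_structure,
)


def _chain(cid, n, offset=0.0):
    residues = [
        Residue(i + 1, "A", [Atom("CA", "C", [3.8 * i + offset, offset, 1.0])])
        for i in range(n)
    ]
    return ChainModel(cid, "other", residues)


def _structure(n_chains=2, n_res=10):
    return StructureModel(
        chains=[_chain(chr(ord("A") + k), n_res, offset=5.0 * k) for k in range(n_chains)]
    )


class TestModelInvariants:
    def test_residue_requires_ca(self):
        with pytest.raises(ValidationError):
            Residue(1, "A", [Atom("CB", "C", [0, 0, 0])])

    def test_residue_rejects_noncanonical_letter(self):
        with pytest.raises(ValidationError):
            Residue(1, "Z", [Atom("CA", "C", [0, 0, 0])])

    def test_atom_rejects_nonfinite_position(self):
        with pytest.raises(ValidationError):
            Atom("CA", "C", [0, np.nan, 0])

    def test_chain_indices_strictly_increasing(self):
        r1 = Residue(2, "A", [Atom("CA", "C", [0, 0, 0])])
        r2 = Residue(1, "A", [Atom("CA", "C", [3.8, 0, 0])])
        with pytest.raises(ValidationError):
            ChainModel("A", "other", [r1, r2])

    def test_helix_ranges_must_be_ordered_disjoint_in_bounds(self):
        residues = [Residue(i + 1, "A", [Atom("CA", "C", [i, 0, 0])]) for i in range(10)]
        with pytest.raises(ValidationError):
            ChainModel("A", "other", residues, helix_ranges=[(1, 5), (4, 8)])
        with pytest.raises(ValidationError):
            ChainModel("A", "other", residues, helix_ranges=[(1, 12)])

    def test_duplicate_chain_ids_rejected(self):
        with pytest.raises(ValidationError):
            StructureModel(chains=[_chain("A", 3), _chain("A", 3)])


class TestFileRoundTrip:
    def test_pdb_round_trip_preserves_counts_and_coordinates(self, tmp_path, crown):
        path = tmp_path / "crown.pdb"
        write_structure(crown, path)
        back = read_structure(path)
        assert len(back.chains) == len(crown.chains)
        assert [len(c) for c in back.chains] == [len(c) for c in crown.chains]
        # PDB fixed-width coordinates carry 3 decimals
        assert np.abs(back.ca_coords() - crown.ca_coords()).max() < 1e-3
        assert [c.entity_role for c in back.chains] == [c.entity_role for c in crown.chains]
        assert back.chains[0].helix_ranges == crown.chains[0].helix_ranges

    def test_mmcif_round_trip(self, tmp_path, trimer):
        path = tmp_path / "trimer.cif"
        write_structure(trimer, path, format="mmcif")
        back = read_structure(path, format="mmcif")
        assert len(back.chains) == 3
        assert np.abs(back.ca_coords() - trimer.ca_coords()).max() < 1e-3

    def test_two_chain_fixture_reads_back(self, tmp_path):
        s = _structure(2, 10)
        path = tmp_path / "two.pdb"
        write_structure(s, path)
        back = read_structure(path)
        assert len(back.chains) == 2
        assert all(len(c) == 10 for c in back.chains)

    def test_residue_without_ca_raises_with_residue_named(self, tmp_path):
        path = tmp_path / "noca.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(ValidationError, match="A/2"):
            read_structure(path)

    def test_empty_structure_write_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_structure(StructureModel(chains=[]), tmp_path / "x.pdb")

    def test_multicharacter_chain_ids_relabeled_deterministically(self, tmp_path):
        s = StructureModel(chains=[_chain("AB", 4), _chain("CD", 4, offset=9.0)])
        path = tmp_path / "re.pdb"
        write_structure(s, path)
        back = read_structure(path)
        assert [c.chain_id for c in back.chains] == ["A", "B"]
        with pytest.raises(CapacityError):
            write_structure(s, tmp_path / "strict.pdb", allow_relabel=False)

    def test_chain_capacity_limit_in_pdb_dialect(self, tmp_path):
        chains = [_chain(f"c{i}", 1, offset=4.0 * i) for i in range(63)]
        s = StructureModel(chains=chains)
        with pytest.raises(CapacityError):
            write_structure(s, tmp_path / "big.pdb")


class TestRigidTransform:
    def test_rejects_non_orthonormal_rotation(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValidationError):  # reflection: det = -1
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_identity_leaves_structure_unchanged(self, trimer):
        out = apply_transform(trimer, RigidTransform.identity())
        assert np.array_equal(out.ca_coords(), trimer.ca_coords())

    def test_pure_translation_shifts_z(self, trimer):
        out = apply_transform(trimer, RigidTransform.translation_along_z(10.0))
        delta = out.ca_coords() - trimer.ca_coords()
        assert np.allclose(delta[:, 2], 10.0) and np.allclose(delta[:, :2], 0.0)

    def test_rotation_preserves_pairwise_distances(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(3, 3), scale=5.0)
        t = RigidTransform.from_rotvec_deg(rng.normal(size=3), 113.0, rng.normal(size=3))
        moved = t.apply(pts)

        def pairwise(p):
            return [
                float(np.linalg.norm(p[i] - p[j]))
                for i in range(len(p))
                for j in range(i + 1, len(p))
            ]

        assert np.allclose(pairwise(moved), pairwise(pts), atol=1e-8)

    def test_group_laws_compose_inverse_identity(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            t = RigidTransform.from_rotvec_deg(
                rng.normal(size=3), float(rng.uniform(0, 360)), rng.normal(size=3)
            )
            ident = t.compose(t.inverse())
            assert np.allclose(ident.rotation, np.eye(3), atol=1e-8)
            assert np.allclose(ident.translation, 0.0, atol=1e-8)

    def test_apply_transform_is_isometry_on_random_structures(self, trimer):
        rng = np.random.default_rng(5)
        t = RigidTransform.from_rotvec_deg(rng.normal(size=3), 77.0, rng.normal(size=3))
        before = trimer.ca_coords()
        after = apply_transform(trimer, t).ca_coords()
        d_before = np.linalg.norm(before[1:] - before[:-1], axis=1)
        d_after = np.linalg.norm(after[1:] - after[:-1], axis=1)
        assert np.abs(d_before - d_after).max() < 1e-8


class TestSuperpose:
    def test_identical_sets_give_zero_rmsd_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        t, rmsd = superpose(pts, pts)
        assert rmsd < 1e-10
        assert np.allclose(t.rotation, np.eye(3), atol=1e-8)

    def test_recovers_72_degree_rotation(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        rot = RigidTransform.rotation_about_z(72.0)
        t, rmsd = superpose(pts, rot.apply(pts))
        assert rmsd < 1e-8
        assert abs(rotation_angle_about_axis(t, (0, 0, 1)) - 72.0) < 1e-6

    def test_agrees_with_grid_search_oracle_on_noisy_points(self):
        # independent oracle: numerical minimization over rotation vectors
        # from many starts, never calling the closed-form path
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(42)
        target = rng.normal(size=(4, 3), scale=4.0)
        true = RigidTransform.from_rotvec_deg((1, -2, 0.5), 33.0, (2, 0, -1))
        mobile = true.inverse().apply(target) + rng.normal(size=(4, 3), scale=0.3)

        def cost(rotvec):
            rmat = Rotation.from_rotvec(rotvec).as_matrix()
            moved = (mobile - mobile.mean(0)) @ rmat.T + target.mean(0)
            return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))

        best = min(
            minimize(cost, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in rng.normal(size=(12, 3))
        )
        _, rmsd = superpose(mobile, target)
        assert abs(rmsd - best) < 1e-3

    def test_returned_transform_reproduces_rmsd(self):
        rng = np.random.default_rng(9)
        mobile = rng.normal(size=(5, 3))
        target = rng.normal(size=(5, 3))
        t, rmsd = superpose(mobile, target)
        moved = t.apply(mobile)
        assert abs(float(np.sqrt(np.mean(np.sum((moved - target) ** 2, 1)))) - rmsd) < 1e-8

    def test_superpose_is_idempotent(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(7, 3))
        target = rng.normal(size=(7, 3))
        t, rmsd1 = superpose(mobile, target)
        _, rmsd2 = superpose(t.apply(mobile), target)
        assert abs(rmsd1 - rmsd2) < 1e-10

    def test_degenerate_sets_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ConditioningError):
            superpose(line, line)
        with pytest.raises(ConditioningError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRotationAngle:
    def test_identity_is_zero(self):
        assert rotation_angle_about_axis(RigidTransform.identity(), (0, 0, 1)) == 0.0

    def test_inverse_of_constructor(self):
        t = RigidTransform.rotation_about_z(25.0)
        assert abs(rotation_angle_about_axis(t, (0, 0, 1)) - 25.0) < 1e-9

    def test_composition_adds_angles(self):
        t = RigidTransform.rotation_about_z(72.0)
        assert abs(rotation_angle_about_axis(t.compose(t), (0, 0, 1)) - 144.0) < 1e-9

    def test_opposite_sense_reported_in_0_360(self):
        t = RigidTransform.rotation_about_z(-25.0)
        assert abs(rotation_angle_about_axis(t, (0, 0, 1)) - 335.0) < 1e-9

    def test_axis_mismatch_raises(self):
        t = RigidTransform.from_rotvec_deg((1, 0, 0), 30.0)
        with pytest.raises(AxisMismatchError):
            rotation_angle_about_axis(t, (0, 0, 1))
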