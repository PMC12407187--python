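import numpy as np
import pytest

from bifacet.architecture_edit import (
    CONTIG_INSERT_RANGES,
    AdjacencyTarget,
    cut_terminal_loop,
    emit_contig_spec,
    emit_diffusion_job,
    geometric_helix_contact_map,
    make_adjacency_target,
    make_extension_target,
    read_diffusion_manifest,
    write_adjacency_matrix,
    write_diffusion_manifest,
)
from bifacet.errors import ValidationError
from bifacet.structmodel import superpose, rotation_angle_about_axis
from bifacet.symmetry import CyclicSpec, verify_symmetry
from bifacet.structmodel import StructureModel


class TestCutTerminalLoop:
    def test_fragment_is_last_two_helices(self, trimer):
        c = trimer.chains[2]
        body, fragment, cut = cut_terminal_loop(c)
        helices = c.helix_ranges
        assert min(fragment) <= helices[-2][0]
        assert max(fragment) == c.residues[-1].index
        assert helices[-2][0] in fragment and helices[-1][1] in fragment
        assert helices[-3][1] in body

    def test_body_and_fragment_partition_chain(self, trimer):
        c = trimer.chains[2]
        body, fragment, _ = cut_terminal_loop(c)
        assert sorted(body + fragment) == [r.index for r in c.residues]
        assert set(body) & set(fragment) == set()

    def test_two_helix_chain_rejected(self):
        from bifacet.synthetic_blocks import BlockRecipe, make_pseudo_heterotrimer

        small = make_pseudo_heterotrimer(BlockRecipe(n_helices_per_subunit=2, helix_length=8))
        with pytest.raises(ValidationError):
            cut_terminal_loop(small.chains[2])


def _moved_coords(structure, selection):
    out = []
    for cid, residues in selection:
        chain = structure.chain(cid)
        sel = set(residues)
        out.append(np.array([r.ca.position for r in chain.residues if r.index in sel]))
    return np.vstack(out)


class TestExtensionTarget:
    def test_100A_extension_displaces_centroid_by_100_along_z(self, assembly):
        target, moved = make_extension_target(assembly.structure, 100.0, 0.0)
        before = _moved_coords(assembly.structure, target.moved_selection)
        after = _moved_coords(moved, target.moved_selection)
        delta = after.mean(axis=0) - before.mean(axis=0)
        assert np.allclose(delta, [0.0, 0.0, 100.0], atol=1e-9)

    def test_interface_fragments_bit_identical(self, assembly):
        target, moved = make_extension_target(assembly.structure, 100.0, 0.0)
        moved_sel = {cid: set(res) for cid, res in target.moved_selection}
        for chain in assembly.structure.chains:
            sel = moved_sel.get(chain.chain_id, set())
            for res, res_after in zip(chain.residues, moved.chain(chain.chain_id).residues):
                if res.index not in sel:
                    assert np.array_equal(res.ca.position, res_after.ca.position)

    def test_rotated_extension_recovers_25_degrees(self, assembly):
        target, moved = make_extension_target(assembly.structure, 50.0, 25.0)
        before = _moved_coords(assembly.structure, target.moved_selection)
        after = _moved_coords(moved, target.moved_selection)
        transform, rmsd = superpose(before, after)
        assert rmsd < 1e-6
        assert abs(rotation_angle_about_axis(transform, (0, 0, 1)) - 25.0) < 1e-6

    def test_zero_extension_is_identity(self, assembly):
        _, moved = make_extension_target(assembly.structure, 0.0, 0.0)
        assert np.abs(moved.ca_coords() - assembly.structure.ca_coords()).max() < 1e-12

    def test_negative_distance_rejected(self, assembly):
        with pytest.raises(ValidationError):
            make_extension_target(assembly.structure, -5.0, 0.0)

    def test_transform_is_rigid_on_moved_selection(self, assembly):
        target, moved = make_extension_target(assembly.structure, 50.0, 25.0)
        before = _moved_coords(assembly.structure, target.moved_selection)
        after = _moved_coords(moved, target.moved_selection)
        idx = np.random.default_rng(0).choice(len(before), size=40, replace=False)
        d_b = np.linalg.norm(before[idx][:, None] - before[idx][None, :], axis=-1)
        d_a = np.linalg.norm(after[idx][:, None] - after[idx][None, :], axis=-1)
        assert np.abs(d_b - d_a).max() < 1e-8

    def test_moved_ring_keeps_fivefold_closure(self, assembly):
        _, moved = make_extension_target(assembly.structure, 75.0, 0.0)
        report = verify_symmetry(moved, CyclicSpec(order_n=5), tol=1e-6)
        assert report.cyclic_closure_rmsd < 1e-6


class TestContigSpec:
    @pytest.mark.parametrize(
        "d,rho,expected",
        [
            (25.0, 0.0, (50, 150)),
            (50.0, 0.0, (100, 250)),
            (75.0, 0.0, (150, 350)),
            (100.0, 0.0, (250, 400)),
            (50.0, 25.0, (150, 350)),
        ],
    )
    def test_insert_range_lookup(self, assembly, d, rho, expected):
        target, moved = make_extension_target(assembly.structure, d, rho)
        spec = emit_contig_spec(target, moved)
        assert spec.insert_length_range == expected

    def test_lookup_table_covers_exactly_five_targets(self):
        assert len(CONTIG_INSERT_RANGES) == 5

    def test_unknown_distance_without_override_rejected(self, assembly):
        target, _ = make_extension_target(assembly.structure, 60.0, 0.0)
        with pytest.raises(ValidationError):
            emit_contig_spec(target)
        spec = emit_contig_spec(target, insert_range=(120, 260))
        assert spec.insert_length_range == (120, 260)

    def test_reduced_input_is_four_body_plus_two_interface_helices(self, assembly):
        target, moved = make_extension_target(assembly.structure, 50.0, 0.0)
        spec = emit_contig_spec(target, moved)
        assert len(spec.reduced_input_selection) == 6
        body_segs = spec.reduced_input_selection[:4]
        iface_segs = spec.reduced_input_selection[4:]
        assert all(e <= target.cut_point for _, _, e in body_segs)
        assert all(s > target.cut_point for _, s, _ in iface_segs)

    def test_contig_string_contains_insert_range(self, assembly):
        target, moved = make_extension_target(assembly.structure, 100.0, 0.0)
        s = emit_contig_spec(target, moved).to_contig_string()
        assert "250-400" in s


class TestAdjacencyTarget:
    def test_inserted_helix_contacts_requested_helices(self, trimer):
        c = trimer.chains[0]
        h = len(c.helix_ranges)
        order = list(range(3, 0, -1)) + list(range(4, h + 1)) + [h + 1]
        target = make_adjacency_target(c, order, new_helix_length=14,
                                       contacts=[(h + 1, 1), (h + 1, 2)])
        new_row = target.adjacency[h]
        assert int(new_row.sum()) == 2
        assert new_row[0] == 1 and new_row[1] == 1

    def test_reordering_first_three_helices_deletes_three_loops(self, trimer):
        c = trimer.chains[0]
        h = len(c.helix_ranges)
        order = [3, 2, 1] + list(range(4, h + 1))
        target = make_adjacency_target(c, order, contacts=[(1, 2)])
        assert len(target.deleted_loops) == 3

    def test_identity_order_defaults_to_geometric_contact_map(self, trimer):
        c = trimer.chains[0]
        h = len(c.helix_ranges)
        target = make_adjacency_target(c, list(range(1, h + 1)))
        # brute-force oracle: minimum CA-CA distance between helix segments
        coords = c.ca_coords()
        segs = [coords[s - 1 : e] for s, e in c.helix_ranges]
        expected = np.zeros((h, h), dtype=int)
        for i in range(h):
            for j in range(i + 1, h):
                dmin = np.linalg.norm(
                    segs[i][:, None, :] - segs[j][None, :, :], axis=-1
                ).min()
                if dmin < 10.0:
                    expected[i, j] = expected[j, i] = 1
        assert np.array_equal(target.adjacency, expected)

    def test_self_contact_rejected(self, trimer):
        c = trimer.chains[0]
        h = len(c.helix_ranges)
        with pytest.raises(ValidationError):
            make_adjacency_target(c, list(range(1, h + 1)), contacts=[(2, 2)])

    def test_invalid_permutation_rejected(self, trimer):
        c = trimer.chains[0]
        with pytest.raises(ValidationError):
            make_adjacency_target(c, [1, 1, 2], contacts=[(1, 2)])

    def test_adjacency_matrix_file_round_trip(self, trimer, tmp_path):
        c = trimer.chains[0]
        h = len(c.helix_ranges)
        target = make_adjacency_target(c, list(range(1, h + 1)))
        path = tmp_path / "adj.txt"
        write_adjacency_matrix(target, path)
        lines = path.read_text().strip().splitlines()
        mat = np.array([[int(v) for v in ln.split()] for ln in lines[1:]])
        assert np.array_equal(mat, target.adjacency)


class TestDiffusionJobs:
    def test_extension_job_defaults_to_100_backbones(self, assembly):
        target, _ = make_extension_target(assembly.structure, 50.0, 0.0)
        job = emit_diffusion_job(target)
        assert job["n_backbones"] == 100 and job["kind"] == "extension"

    def test_five_targets_give_five_jobs(self, assembly):
        jobs = [
            emit_diffusion_job(make_extension_target(assembly.structure, d, rho)[0])
            for d, rho in CONTIG_INSERT_RANGES
        ]
        assert len(jobs) == 5

    def test_manifest_round_trips(self, assembly, tmp_path):
        target, _ = make_extension_target(assembly.structure, 25.0, 0.0)
        jobs = [emit_diffusion_job(target, input_pdb="x.pdb", spec_path="c.txt")]
        path = tmp_path / "jobs.tsv"
        write_diffusion_manifest(jobs, path)
        back = read_diffusion_manifest(path)
        assert back[0]["kind"] == "extension" and back[0]["n_backbones"] == 100
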