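"""Helix axes, superposition, clustering, SASA, clashes, assembly, mass."""

import io

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ubamap import structgeom as sg
from ubamap import synthdata as sd

from conftest import make_model


def fib_shell(n, radius):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    th = np.pi * (1 + 5**0.5) * k
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(th), np.sin(phi) * np.sin(th), np.cos(phi)]
    )


class TestPdbIO:
    def test_multi_model_round_trip(self):
        h1 = sd.gen_ideal_helix(8)
        h2 = sd.gen_ideal_helix(8, origin=(5, 5, 5))
        buf = io.StringIO()
        sg.write_structure([h1, h2], buf)
        buf.seek(0)
        models = sg.read_structure(buf, model="all")
        assert len(models) == 2
        assert np.allclose(models[0].xyz, h1.xyz, atol=1e-3)
        assert np.allclose(models[1].xyz, h2.xyz, atol=1e-3)

    def test_single_model_selection(self):
        buf = io.StringIO()
        sg.write_structure([sd.gen_ideal_helix(8), sd.gen_ideal_helix(8)], buf)
        buf.seek(0)
        m = sg.read_structure(buf, model=2)
        assert m.n_atoms == 8

    def test_element_inferred_from_atom_name(self):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00\n"
            "END\n"
        )
        m = sg.read_structure(io.StringIO(pdb), model=1)
        assert list(m.element) == ["N", "C"]
        assert m.mass[0] == pytest.approx(14.007, abs=0.01)

    def test_garbage_input_rejected(self):
        with pytest.raises(ValueError):
            sg.read_structure(io.StringIO("not a pdb file\n"), model=1)


class TestHelixAxis:
    def test_ideal_helix_axis_and_rms(self):
        h = sd.gen_ideal_helix(10, direction=(0, 0, 1))
        ax = sg.helix_axis(h, range(1, 11))
        assert np.degrees(np.arccos(abs(ax.direction @ np.array([0, 0, 1.0])))) < 1.0
        assert ax.fit_rms < 1e-9

    def test_same_direction_zero_angle(self):
        a = sg.helix_axis(sd.gen_ideal_helix(10), range(1, 11))
        b = sg.helix_axis(sd.gen_ideal_helix(10, origin=(8, 0, 0)), range(1, 11))
        assert sg.interhelical_angle(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_antiparallel_180(self):
        a = sg.helix_axis(sd.gen_ideal_helix(10, direction=(0, 0, 1)), range(1, 11))
        b = sg.helix_axis(sd.gen_ideal_helix(10, direction=(0, 0, -1)), range(1, 11))
        assert sg.interhelical_angle(a, b) == pytest.approx(180.0, abs=1e-6)

    def test_constructed_98_degrees(self):
        d2 = (np.sin(np.radians(98)), 0, np.cos(np.radians(98)))
        a = sg.helix_axis(sd.gen_ideal_helix(5, **sd.HELIX_310), range(1, 6))
        b = sg.helix_axis(sd.gen_ideal_helix(7, direction=d2, origin=(0, 10, 0)), range(1, 8))
        assert sg.interhelical_angle(a, b) == pytest.approx(98.0, abs=2.0)

    def test_bundle_angles_recovered(self):
        bundle = sd.gen_helix_bundle(pair_angles_deg=(98.0, 138.0, 102.0))
        axes = [sg.helix_axis(bundle, rng) for rng in sd.UBA_HELIX_RANGES.values()]
        angles = [sg.interhelical_angle(a, b) for a, b in zip(axes, axes[1:])]
        assert angles == pytest.approx([98.0, 138.0, 102.0], abs=2.0)

    def test_supplement_of_negated_axis(self):
        a = sg.helix_axis(sd.gen_ideal_helix(10), range(1, 11))
        b = sg.helix_axis(sd.gen_ideal_helix(9, direction=(0.3, 0.4, 0.866)), range(1, 10))
        neg_b = sg.HelixAxis(anchor=b.anchor, direction=-b.direction, residue_range=b.residue_range, fit_rms=b.fit_rms)
        assert sg.interhelical_angle(a, b) + sg.interhelical_angle(a, neg_b) == pytest.approx(180.0)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            sg.helix_axis(sd.gen_ideal_helix(8), range(1, 4))


class TestKabsch:
    def test_self_superposition(self):
        h = sd.gen_ideal_helix(10)
        R, t, rmsd = sg.kabsch_superpose(h, h)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3))

    def test_known_rotation_recovered(self, random_rotation):
        h = sd.gen_ideal_helix(12)
        Q = random_rotation(3)
        moved = h.transformed(Q, np.array([1.0, -2.0, 3.0]))
        _, _, rmsd = sg.kabsch_superpose(moved, h)
        assert rmsd < 1e-8

    def test_matches_scipy_align_vectors(self, random_rotation):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        Y = X @ random_rotation(9).T + np.array([5.0, 0.0, -1.0])
        a, b = make_model(X), make_model(Y)
        R, t, rmsd = sg.kabsch_superpose(a, b)
        rot, ssd = Rotation.align_vectors(Y - Y.mean(0), X - X.mean(0))
        assert np.allclose(R, rot.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sg.kabsch_superpose(sd.gen_ideal_helix(10), sd.gen_ideal_helix(8))

    def test_no_reflection(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        Y = -X  # improper transform; the fit must still return det(R) = +1
        R, _, _ = sg.kabsch_superpose(make_model(X), make_model(Y))
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestRmsdMatrixClustering:
    def test_duplicates_give_zero_matrix(self):
        h = sd.gen_ideal_helix(10)
        mat = sg.pairwise_rmsd_matrix([h, h, h])
        assert np.allclose(mat, 0.0, atol=1e-10)

    def test_translation_invariance_and_symmetry(self, random_rotation):
        h = sd.gen_ideal_helix(10)
        moved = h.transformed(random_rotation(2), np.array([10.0, 0.0, 0.0]))
        mat = sg.pairwise_rmsd_matrix([h, moved])
        assert mat[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(mat, mat.T, atol=1e-10)

    def test_two_blobs_clustered(self):
        # constructed distance matrix: models 0-2 mutually close, 3-4 close
        mat = np.full((5, 5), 20.0)
        np.fill_diagonal(mat, 0.0)
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4)]:
            mat[i, j] = mat[j, i] = 1.0
        clusters = sg.cluster_models(mat, cutoff=5.0)
        assert clusters[0] == [0, 1, 2]
        assert clusters[1] == [3, 4]

    def test_all_far_all_singletons(self):
        mat = np.full((4, 4), 30.0)
        np.fill_diagonal(mat, 0.0)
        assert sg.cluster_models(mat, cutoff=5.0) == [[0], [1], [2], [3]]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 10, size=(8, 8))
        mat = (d + d.T) / 2
        np.fill_diagonal(mat, 0.0)
        clusters = sg.cluster_models(mat, cutoff=4.0)
        flat = sorted(i for c in clusters for i in c)
        assert flat == list(range(8))


class TestMassGeometry:
    def test_com_two_unit_masses(self):
        m = make_model([[0, 0, 0], [2, 0, 0]])
        m.mass[:] = 1.0
        assert np.allclose(sg.center_of_mass(m), [1, 0, 0])

    def test_rg_two_unit_masses(self):
        m = make_model([[0, 0, 0], [2, 0, 0]])
        m.mass[:] = 1.0
        assert sg.radius_of_gyration(m) == pytest.approx(1.0)

    def test_single_atom(self):
        m = make_model([[3, 4, 5]])
        assert np.allclose(sg.center_of_mass(m), [3, 4, 5])
        assert sg.radius_of_gyration(m) == pytest.approx(0.0, abs=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sg.center_of_mass(make_model([[0, 0, 0]]), dict(chain="Z"))

    def test_rigid_invariance(self, random_rotation):
        rng = np.random.default_rng(2)
        m = make_model(rng.normal(size=(30, 3)) * 5)
        moved = m.transformed(random_rotation(7), np.array([1.0, 2.0, 3.0]))
        assert sg.radius_of_gyration(moved) == pytest.approx(sg.radius_of_gyration(m))
        sel_a = dict(residues=range(1, 16))
        sel_b = dict(residues=range(16, 31))
        assert sg.com_distance(moved, sel_a, sel_b) == pytest.approx(sg.com_distance(m, sel_a, sel_b))


class TestSasa:
    def test_isolated_sphere_analytic(self):
        m = make_model([[0, 0, 0]])
        _, total = sg.sasa(m)
        assert total == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)

    def test_far_atoms_additive(self):
        m = make_model([[0, 0, 0], [50, 0, 0]])
        per, total = sg.sasa(m)
        assert per[0] == pytest.approx(per[1])
        assert total == pytest.approx(2 * 4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)

    def test_enclosed_atom_zero(self):
        xyz = np.vstack([[0, 0, 0], fib_shell(40, 1.2)])
        _, _ = per, total = sg.sasa(make_model(xyz))
        assert per[0] == 0.0

    def test_point_count_convergence(self):
        xyz = fib_shell(6, 2.5)
        m = make_model(xyz)
        _, a = sg.sasa(m, points=960)
        _, b = sg.sasa(m, points=3840)
        assert abs(a - b) / b < 0.005

    def test_unknown_element_rejected(self):
        m = make_model([[0, 0, 0]], element="Xx")
        with pytest.raises(ValueError, match="radius"):
            sg.sasa(m)


class TestBuriedSurface:
    def test_far_chains_zero(self):
        a = make_model([[0, 0, 0]], chain="A")
        b = make_model([[60, 0, 0]], chain="B")
        assert sg.buried_surface(a, b) == pytest.approx(0.0, abs=0.5)

    def test_symmetric(self):
        a = make_model(fib_shell(5, 2.0), chain="A")
        b = make_model(fib_shell(5, 2.0) + np.array([4.0, 0, 0]), chain="B")
        assert sg.buried_surface(a, b) == pytest.approx(sg.buried_surface(b, a), rel=1e-9)

    def test_two_touching_spheres_analytic(self):
        d = 2.0
        a = make_model([[0, 0, 0]], chain="A")
        b = make_model([[d, 0, 0]], chain="B")
        ra = 1.70 + 1.4
        cap_h = ra - d / 2  # equal radii
        exact_buried = 2 * (2 * np.pi * ra * cap_h)
        assert sg.buried_surface(a, b, points=3840) == pytest.approx(exact_buried, rel=0.02)

    def test_shared_chain_rejected(self):
        a = make_model([[0, 0, 0]], chain="A")
        with pytest.raises(ValueError):
            sg.buried_surface(a, a)


class TestClashes:
    def test_distant_chains_no_contacts(self):
        rep = sg.clash_report(make_model([[0, 0, 0]]), make_model([[50, 0, 0]]))
        assert rep.n_contacts == 0 and not rep.severe

    def test_superimposed_chains_all_clash(self):
        xyz = fib_shell(20, 5.0)
        rep = sg.clash_report(make_model(xyz), make_model(xyz))
        assert rep.n_clashes >= 20
        assert rep.severe

    def test_exact_pair_count(self):
        a = make_model([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        b = make_model([[2, 0, 0], [12, 0, 0], [22, 0, 0]], chain="B")
        rep = sg.clash_report(a, b)
        assert rep.n_clashes == 3


class TestAssembly:
    def _dimer_and_complex(self):
        p1 = sd.gen_ideal_helix(10, chain="A", start_resnum=1)
        p2 = sd.gen_ideal_helix(10, chain="B", start_resnum=1, origin=(12, 0, 0), direction=(0, 0, -1))
        dimer = sg.merge_models([p1, p2])
        rec = sd.gen_ideal_helix(10, chain="A", start_resnum=1)
        lig = sd.gen_ideal_helix(6, chain="B", start_resnum=100, origin=(4, 4, 0))
        cpx = sg.merge_models([rec, lig])
        return dimer, cpx

    def test_chain_bookkeeping(self):
        dimer, cpx = self._dimer_and_complex()
        asm = sg.build_assembly(dimer, cpx, receptor_chain="A", ligand_chains=["B"])
        assert len(asm.chains()) == 4  # dimer A,B + two transplanted ligands
        assert asm.n_atoms == dimer.n_atoms + 2 * 6

    def test_self_superposition_identity(self):
        _, cpx = self._dimer_and_complex()
        asm = sg.build_assembly(
            cpx.select(chain="A"), cpx, receptor_chain="A", ligand_chains=["B"], protomer_chains=["A"]
        )
        lig_new = asm.select(chain=[c for c in asm.chains() if c not in ("A",)][0])
        assert np.allclose(lig_new.xyz, cpx.select(chain="B").xyz, atol=1e-8)

    def test_transplanted_geometry(self):
        # ligand sits at +y of the receptor helix in the complex frame;
        # after assembly each copy must preserve its distance to its protomer
        dimer, cpx = self._dimer_and_complex()
        asm = sg.build_assembly(dimer, cpx, receptor_chain="A", ligand_chains=["B"])
        d_ref = np.linalg.norm(
            sg.center_of_mass(cpx.select(chain="B")) - sg.center_of_mass(cpx.select(chain="A"))
        )
        new_chains = [c for c in asm.chains() if c not in ("A", "B")]
        for prot, lig in zip(("A", "B"), new_chains):
            d = np.linalg.norm(
                sg.center_of_mass(asm.select(chain=lig)) - sg.center_of_mass(asm.select(chain=prot))
            )
            assert d == pytest.approx(d_ref, abs=1e-6)


class TestMolecularMass:
    def test_glycine(self):
        assert sg.molecular_mass("G") == pytest.approx(0.0751, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sg.molecular_mass("")

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            sg.molecular_mass("ACDB1")

    def test_concatenation_additive_minus_water(self):
        water = 18.015 / 1000
        total = sg.molecular_mass("ACDEF") + sg.molecular_mass("GHIKL") - water
        assert sg.molecular_mass("ACDEFGHIKL") == pytest.approx(total, abs=1e-4)
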