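"""PDB parsing, SASA, interface classification, linker reach and auditing."""

import math
import textwrap

import numpy as np
import pytest

from assocfit.structure import (
    PDBParseError,
    audit_constraints,
    classify_interface_residues,
    contact_residues,
    interface_area,
    linker_feasible,
    load_default_constraints,
    parse_constraints,
    read_pdb,
    sasa,
    write_pdb,
    StructureModel,
)
from assocfit.synthetic import gen_toy_dimer, toy_cap_area, toy_sphere_separation

MINIMAL_PDB = textwrap.dedent(
    """\
    ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
    ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
    ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00  0.00           C
    END
    """
)

ALTLOC_PDB = textwrap.dedent(
    """\
    ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
    ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
    ATOM      3  CA AALA A   2       5.000   0.000   0.000  0.50  0.00           C
    ATOM      4  CA BALA A   2       6.000   0.000   0.000  0.50  0.00           C
    ATOM      5  O   HOH A   3       9.000   0.000   0.000  1.00  0.00           O
    END
    """
)


class TestReadPDB:
    def test_minimal_fixture(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_pdb(p)
        assert model.atoms.array_length() == 3
        assert model.atoms.coord[0] == pytest.approx([11.104, 6.134, -6.504])
        assert list(model.atoms.atom_name) == ["N", "CA", "C"]

    def test_altloc_highest_occupancy_ties_take_a(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = read_pdb(p)
        # residue 1: B wins on occupancy; residue 2: tie -> A; water dropped
        assert model.atoms.array_length() == 2
        assert model.atoms.coord[0][0] == pytest.approx(1.0)
        assert model.atoms.coord[1][0] == pytest.approx(5.0)

    def test_no_atoms_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER  NOTHING\nEND\n")
        with pytest.raises(PDBParseError):
            read_pdb(p)

    def test_malformed_coordinates_named_with_line(self, tmp_path):
        bad = MINIMAL_PDB.replace("11.104", "xx.xxx")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(PDBParseError, match="line 1"):
            read_pdb(p)

    def test_write_read_round_trip(self, tmp_path):
        model = gen_toy_dimer("c2", separation=12.0, seed=1)
        p = tmp_path / "toy.pdb"
        write_pdb(model, p)
        back = read_pdb(p)
        assert back.atoms.array_length() == model.atoms.array_length()
        assert np.allclose(back.atoms.coord, model.atoms.coord, atol=1e-3)


class TestSASA:
    def test_single_atom_matches_analytic_sphere(self, sphere_radii):
        model = gen_toy_dimer("spheres", separation=100.0)
        res = sasa(model.chain("A"), radii_set=sphere_radii)
        analytic = 4.0 * math.pi * (8.0 + 1.4) ** 2
        assert res.total == pytest.approx(analytic, rel=0.01)

    def test_fully_overlapping_atoms_add_nothing(self, sphere_radii):
        # (near-)coincident identical spheres expose a single sphere's area;
        # the separation stays above the float32 coordinate resolution
        model = gen_toy_dimer("spheres", separation=1e-3)
        one = sasa(model.chain("A"), radii_set=sphere_radii).total
        both = sasa(model, radii_set=sphere_radii).total
        assert both == pytest.approx(one, rel=1e-2)

    def test_distant_atoms_are_additive(self, sphere_radii):
        model = gen_toy_dimer("spheres", separation=100.0)
        one = sasa(model.chain("A"), radii_set=sphere_radii).total
        both = sasa(model, radii_set=sphere_radii).total
        assert both == pytest.approx(2.0 * one, rel=1e-9)

    def test_rotation_invariance(self):
        # 5000 sphere points keep the orientational discretisation error of
        # the sampled sphere well below the 0.1 % invariance requirement
        model = gen_toy_dimer("c2", separation=10.0, seed=3)
        base = sasa(model, n_points=5000).total
        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rotated = StructureModel(model.atoms.copy())
        rotated.atoms.coord[:] = model.atoms.coord @ q.T + np.array([5.0, -3.0, 2.0])
        assert sasa(rotated, n_points=5000).total == pytest.approx(base, rel=1e-3)

    def test_unknown_element_policy(self, tmp_path):
        model = gen_toy_dimer("spheres", separation=100.0)
        with pytest.warns(RuntimeWarning, match="no vdW radius"):
            sasa(model, radii_set={"N": 1.5})
        with pytest.raises(ValueError):
            sasa(model, radii_set={"N": 1.5}, on_unknown="error")


class TestInterfaceArea:
    def test_separated_chains_bury_nothing(self, sphere_radii):
        model = gen_toy_dimer("spheres", separation=100.0)
        rep = interface_area(model, "A", "B", radii_set=sphere_radii)
        assert rep.buried_per_monomer == 0.0

    def test_overlapping_spheres_match_cap_area(self, sphere_radii):
        sep = toy_sphere_separation(500.0, 8.0)
        model = gen_toy_dimer("spheres", separation=sep)
        rep = interface_area(model, "A", "B", radii_set=sphere_radii)
        assert rep.buried_per_monomer == pytest.approx(500.0, rel=0.02)
        assert toy_cap_area(8.0, sep) == pytest.approx(500.0, rel=1e-12)

    def test_buried_area_non_increasing_with_separation(self, sphere_radii):
        seps = [2.0, 5.0, 9.0, 14.0, 20.0]
        buried = [
            interface_area(
                gen_toy_dimer("spheres", separation=s), "A", "B",
                radii_set=sphere_radii,
            ).buried_per_monomer
            for s in seps
        ]
        assert all(b1 >= b2 - 1e-9 for b1, b2 in zip(buried, buried[1:]))

    def test_missing_chain_rejected(self, sphere_radii):
        model = gen_toy_dimer("spheres", separation=10.0)
        with pytest.raises(ValueError):
            interface_area(model, "A", "Z", radii_set=sphere_radii)


def _burial_fixture():
    """Chain A: three GLY CA pseudo-atoms; chain B: a cage burying A:1.

    A:1 sits inside a dense fibonacci shell of B atoms (core);
    A:2 is far away (none); A:3 touches one B atom only (rim).
    """
    from assocfit.synthetic import _make_atoms

    records = [
        ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
        ("A", 2, "GLY", "CA", "C", (50.0, 0.0, 0.0)),
        ("A", 3, "GLY", "CA", "C", (25.0, 0.0, 0.0)),
    ]
    n_shell = 80
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for i in range(n_shell):
        z = 1.0 - 2.0 * i / (n_shell - 1)
        r = math.sqrt(max(1.0 - z * z, 0.0))
        th = golden * i
        records.append(
            ("B", i + 1, "GLY", "CA", "C",
             (4.6 * r * math.cos(th), 4.6 * r * math.sin(th), 4.6 * z))
        )
    records.append(("B", n_shell + 1, "GLY", "CA", "C", (25.0, 4.5, 0.0)))
    return StructureModel(_make_atoms(records))


class TestResidueClassification:
    def test_core_rim_and_none_classes(self):
        model = _burial_fixture()
        classes = classify_interface_residues(model, "A", "B")
        assert classes[("A", 1)] == "core"
        assert classes[("A", 2)] == "none"
        assert classes[("A", 3)] == "rim"

    def test_all_none_when_nothing_buried(self, sphere_radii):
        model = gen_toy_dimer("spheres", separation=100.0)
        classes = classify_interface_residues(model, "A", "B",
                                              radii_set=sphere_radii)
        assert set(classes.values()) == {"none"}


class TestContacts:
    def test_isolated_chain_has_no_contacts(self, sphere_radii):
        model = gen_toy_dimer("spheres", separation=100.0)
        assert contact_residues(model, "A", 1) == set()

    def test_cutoff_is_inclusive(self):
        from assocfit.synthetic import _make_atoms

        model = StructureModel(_make_atoms([
            ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("B", 1, "GLY", "CA", "C", (4.5, 0.0, 0.0)),
            ("B", 2, "GLY", "CA", "C", (4.5001, 10.0, 0.0)),
        ]))
        hits = contact_residues(model, "A", 1, cutoff=4.5)
        assert hits == {("B", 1)}

    def test_absent_residue_rejected(self):
        model = gen_toy_dimer("spheres", separation=10.0)
        with pytest.raises(ValueError):
            contact_residues(model, "A", 99)


class TestLinker:
    def test_zero_length_coincident_anchors(self):
        check = linker_feasible((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0)
        assert check.feasible and check.margin == 0.0

    def test_short_linker_cannot_span_40_angstrom(self):
        check = linker_feasible((0, 0, 0), (40.0, 0, 0), 5)
        assert not check.feasible
        assert check.margin == pytest.approx(19.0 - 40.0)

    def test_boundary_is_feasible(self):
        check = linker_feasible((0, 0, 0), (19.0, 0, 0), 5)
        assert check.feasible and check.margin == pytest.approx(0.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            linker_feasible((0, 0, 0), (1, 0, 0), -1)


class TestConstraintAudit:
    def test_empty_set_passes(self):
        model = gen_toy_dimer("c2", separation=12.0, seed=2)
        report = audit_constraints(model, [])
        assert report.overall_pass and len(report.results) == 0

    def test_single_violated_contact_fails_with_distance_margin(self):
        model = gen_toy_dimer("spheres", separation=10.0)
        cs = parse_constraints("contact A:1 B:1 4.0\ncontact A:1 B:1 15.0")
        report = audit_constraints(model, cs)
        st = {r.constraint.label: r for r in report.results}
        assert st["contact A:1 B:1 4.0"].status == "fail"
        assert st["contact A:1 B:1 4.0"].margin == pytest.approx(4.0 - 10.0)
        assert st["contact A:1 B:1 15.0"].status == "pass"

    def test_exact_c2_dimer_passes_symmetry(self):
        model = gen_toy_dimer("c2", separation=12.0, seed=4)
        report = audit_constraints(model, parse_constraints("symmetric A:B 0.01"))
        assert report.results[0].status == "pass"
        rmsd = 0.01 - report.results[0].margin
        assert rmsd < 0.01

    def test_absent_residue_is_unevaluable_not_failed(self):
        model = gen_toy_dimer("spheres", separation=10.0)
        report = audit_constraints(model, parse_constraints("contact A:1 Z:9 5.0"))
        assert report.results[0].status == "unevaluable"
        assert report.overall_pass

    def test_order_independence(self):
        model = _burial_fixture()
        text = "contact A:1 B:1 10.0\nburied A:1 0.07\naccessible A:2 0.5\nsymmetric A:B 5.0"
        fwd = audit_constraints(model, parse_constraints(text))
        rev = audit_constraints(model, parse_constraints(text)[::-1])
        fwd_map = {r.constraint.label: (r.status, r.margin) for r in fwd.results}
        rev_map = {r.constraint.label: (r.status, r.margin) for r in rev.results}
        assert fwd_map == rev_map

    def test_default_constraint_file_parses(self):
        constraints = load_default_constraints()
        kinds = {c.kind for c in constraints}
        assert {"interface_contains", "buried", "contact",
                "disjoint_interfaces", "symmetric"} <= kinds
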