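"""Structure parsing and per-residue geometry."""

import math

import numpy as np
import pytest

from protembed.structio import (
    CollinearPointsError,
    PdbParseError,
    PqrFormatError,
    Structure,
    center_of_mass,
    dihedral,
    dihedral_block,
    read_pdb,
    read_pqr,
    write_pdb,
)


def _pdb_line(serial, name, res, chain, res_id, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:^4s} {res:3s} {chain}{res_id:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


GLY_CA = _pdb_line(1, "CA", "GLY", "A", 1, 1.0, 2.0, 3.0, "C")


def test_read_pdb_minimal_single_atom(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(GLY_CA + "\n")
    s = read_pdb(path)
    assert len(s.atoms) == 1
    assert len(s.residues) == 1
    np.testing.assert_allclose(s.atoms[0].position, [1.0, 2.0, 3.0])


def test_read_pdb_two_chains_preserves_grouping(tmp_path):
    lines = []
    serial = 1
    for chain in "AB":
        for rid in range(1, 4):
            x = 10.0 * rid + (0 if chain == "A" else 100.0)
            lines.append(_pdb_line(serial, "CA", "ALA", chain, rid, x, 0, 0, "C"))
            serial += 1
    path = tmp_path / "two.pdb"
    path.write_text("\n".join(lines) + "\n")
    s = read_pdb(path)
    assert len(s.residues) == 6
    assert [r.chain_id for r in s.residues] == list("AAABBB")


def test_read_pdb_hetatm_only_raises_no_atoms(tmp_path):
    line = GLY_CA.replace("ATOM  ", "HETATM")
    path = tmp_path / "het.pdb"
    path.write_text(line + "\n")
    with pytest.raises(PdbParseError, match="no atoms"):
        read_pdb(path)


def test_read_pdb_malformed_coordinate_names_line(tmp_path):
    bad = GLY_CA[:30] + "  xx.xxx" + GLY_CA[38:]
    path = tmp_path / "bad.pdb"
    path.write_text(GLY_CA + "\n" + bad + "\n")
    with pytest.raises(PdbParseError, match="line 2"):
        read_pdb(path)


def test_pdb_write_read_round_trip(mini_protein):
    structure, _ = mini_protein
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "rt.pdb"
        write_pdb(structure, path)
        back = read_pdb(path)
    assert len(back.atoms) == len(structure.atoms)
    # PDB fixed-width contract: coordinates to 3 decimals
    np.testing.assert_allclose(
        back.positions(), structure.positions(), atol=5.1e-4
    )


PQR_ALA = """\
ATOM 1 N ALA A 1 0.000 0.000 0.000 -0.3000 1.55
ATOM 2 H1 ALA A 1 0.500 0.800 0.000 0.1000 1.20
ATOM 3 CA ALA A 1 1.458 0.000 0.000 0.1000 1.70
ATOM 4 HA ALA A 1 1.800 -0.900 0.400 0.0500 1.20
ATOM 5 CB ALA A 1 2.000 1.300 0.600 -0.2000 1.70
ATOM 6 HB1 ALA A 1 1.700 2.200 0.100 0.0500 1.20
ATOM 7 HB2 ALA A 1 3.090 1.280 0.650 0.0500 1.20
ATOM 8 HB3 ALA A 1 1.600 1.350 1.620 0.0500 1.20
ATOM 9 C ALA A 1 2.000 -1.000 -1.000 0.2500 1.70
ATOM 10 O ALA A 1 3.000 -1.500 -1.200 -0.1500 1.52
"""


def test_read_pqr_neutral_alanine(tmp_path):
    path = tmp_path / "ala.pqr"
    path.write_text(PQR_ALA)
    s = read_pqr(path)
    assert len(s.atoms) == 10
    assert all(a.partial_charge is not None for a in s.atoms)
    assert abs(sum(a.partial_charge for a in s.atoms)) < 1e-6
    # hydrogens retained
    assert sum(1 for a in s.atoms if a.element == "H") == 5


def test_read_pqr_missing_charge_field_is_format_error(tmp_path):
    broken = PQR_ALA.replace("ATOM 3 CA ALA A 1 1.458 0.000 0.000 0.1000 1.70",
                             "ATOM 3 CA ALA A 1 1.458 0.000 0.000 1.70")
    path = tmp_path / "broken.pqr"
    path.write_text(broken)
    with pytest.raises(PqrFormatError):
        read_pqr(path)


def test_read_pqr_charged_fragment_net_charge(tmp_path):
    lines = [
        f"ATOM {i+1} C{i+1} LYS A 1 {float(i):.3f} 0.000 0.000 {q:.4f} 1.70"
        for i, q in enumerate([0.3, 0.3, 0.2, 0.1, 0.1])
    ]
    path = tmp_path / "lys.pqr"
    path.write_text("\n".join(lines) + "\n")
    s = read_pqr(path)
    assert abs(sum(a.partial_charge for a in s.atoms) - 1.0) < 1e-6


@pytest.mark.parametrize(
    "points,expected",
    [
        (((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)), 180.0),
        (((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)), 0.0),
    ],
)
def test_dihedral_planar_cases(points, expected):
    assert math.isclose(abs(dihedral(*points)), expected, abs_tol=1e-9)


def test_dihedral_orthogonal_plane_is_ninety_degrees():
    ang = dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1))
    assert math.isclose(abs(ang), 90.0, abs_tol=1e-9)


def test_dihedral_collinear_raises():
    with pytest.raises(CollinearPointsError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0))


def test_dihedral_rigid_motion_invariant_and_mirror_flips(rng):
    from conftest import random_rotation

    pts = rng.normal(size=(4, 3)) * 3
    ref = dihedral(*pts)
    R = random_rotation(rng)
    t = rng.normal(size=3) * 10
    moved = [R @ p + t for p in pts]
    assert math.isclose(dihedral(*moved), ref, abs_tol=1e-9)
    mirrored = [p * np.array([1.0, 1.0, -1.0]) for p in pts]
    assert math.isclose(dihedral(*mirrored), -ref, abs_tol=1e-9)


def test_dihedral_block_is_always_fifteen_values(mini_protein):
    structure, _ = mini_protein
    for res in structure.residues:
        assert dihedral_block(structure, res).values.shape == (15,)


def test_dihedral_block_masks(mini_protein):
    structure, _ = mini_protein
    first = dihedral_block(structure, structure.residues[0])
    assert first.mask[0] == 0  # N-terminal phi does not exist
    last = dihedral_block(structure, structure.residues[-1])
    assert last.mask[1] == 0  # C-terminal psi does not exist
    for res in structure.residues:
        block = dihedral_block(structure, res)
        if res.name == "GLY":
            assert block.mask[2:].sum() == 0
        # masked angles have zeroed sin/cos; live ones lie on the unit circle
        for k in range(5):
            if block.mask[k] == 0:
                assert block.sin[k] == 0 and block.cos[k] == 0
            else:
                assert abs(block.sin[k] ** 2 + block.cos[k] ** 2 - 1) < 1e-6


def test_midchain_leucine_has_exactly_two_chi_angles():
    from protembed.synthetic import generate_mini_protein

    s, _ = generate_mini_protein(5, 0.0, np.random.default_rng(0), sequence="AALAA")
    leu = s.residues[2]
    assert leu.name == "LEU"
    # stub side chains stop at the gamma atom: chi1 defined, chi2 degraded
    block = dihedral_block(s, leu)
    assert list(block.mask) == [1, 1, 1, 0, 0]
    # complete the side chain: Leu defines exactly chi1 and chi2, never chi3
    from protembed.structio import Atom

    cg = leu.atom("CG")
    leu.atoms.append(
        Atom("C", "CD1", leu.index, "LEU", "A", cg.position + np.array([1.2, 0.5, 0.3]))
    )
    block = dihedral_block(s, leu)
    assert list(block.mask) == [1, 1, 1, 1, 0]


def _carbon(x, y, z, element="C", name="C", idx=0):
    from protembed.structio import Atom

    return Atom(element, name, idx, "GLY", "A", np.array([x, y, z], dtype=float))


def test_center_of_mass_cases():
    s = Structure([_carbon(0, 0, 0), _carbon(2, 0, 0)])
    np.testing.assert_allclose(center_of_mass(s), [1, 0, 0])
    single = Structure([_carbon(4, 5, 6)])
    np.testing.assert_allclose(center_of_mass(single), [4, 5, 6])
    co = Structure([_carbon(0, 0, 0), _carbon(1, 0, 0, element="O", name="O")])
    x = 15.999 / (12.011 + 15.999)
    np.testing.assert_allclose(center_of_mass(co), [x, 0, 0], atol=1e-6)
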