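"""Reading protein structures and computing per-residue geometry.

PDB files are parsed through biotite; PQR files (whitespace-delimited, with
partial charge and radius columns, as produced by PDB2PQR) are parsed
directly.  Both are exposed as a light :class:`Structure` container — an
ordered atom list grouped into residues — on which the featurization stage
computes backbone/side-chain dihedral angles, the center of mass and
Cα geometry.

Coordinates are in Å throughout.  Residues are indexed densely (0-based, in
parse order) for graph construction; author chain/residue numbering is kept
as metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DihedralBlock",
    "PdbParseError",
    "PqrFormatError",
    "CollinearPointsError",
    "read_pdb",
    "read_pqr",
    "write_pdb",
    "write_pqr",
    "dihedral",
    "dihedral_block",
    "center_of_mass",
    "STANDARD_AA",
    "AA_INDEX",
    "CHI_ATOMS",
    "ATOMIC_MASSES",
]


class PdbParseError(ValueError):
    """A PDB record could not be parsed (message names the line number)."""


class PqrFormatError(ValueError):
    """A PQR record is missing or has a malformed charge/radius field."""


class CollinearPointsError(ValueError):
    """Three consecutive points of a torsion quadruple are collinear."""


# Standard masses (u) for the elements that occur in proteins.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA_INDEX: dict[str, int] = {name: i for i, name in enumerate(STANDARD_AA)}

ONE_LETTER: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Non-standard residues mapped to the nearest standard parent type.
NONSTANDARD_MAP: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS", "HID": "HIS", "HIE": "HIS",
    "HIP": "HIS", "CYX": "CYS", "CYM": "CYS", "ASH": "ASP", "GLH": "GLU",
    "LYN": "LYS", "ARN": "ARG", "TYM": "TYR", "SEP": "SER", "TPO": "THR",
    "PTR": "TYR",
}

WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "DOD"}

# IUPAC side-chain torsion quadruples (first three chi angles only; branched
# terminal groups use the lower-numbered branch atom).
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ALA": (),
    "GLY": (),
    "ARG": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "NE")),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "CYS": (("N", "CA", "CB", "SG"),),
    "GLN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")),
    "GLU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "LYS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "CE")),
    "MET": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "PRO": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "VAL": (("N", "CA", "CB", "CG1"),),
}


@dataclass
class Atom:
    element: str
    name: str
    residue_index: int
    residue_type: str
    chain_id: str
    position: np.ndarray
    partial_charge: float | None = None

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.0)


@dataclass
class Residue:
    index: int              # dense 0-based order after parsing
    chain_id: str
    number: int             # author residue number (metadata)
    icode: str
    name: str               # 3-letter standard type after mapping
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_ca(self) -> bool:
        return self.atom("CA") is not None


class Structure:
    """An ordered list of atoms grouped into residues."""

    def __init__(self, atoms: list[Atom]):
        if not atoms:
            raise ValueError("no atoms: structure is empty after filtering")
        self.atoms = atoms
        self.residues: list[Residue] = []
        current_key = None
        for atom in atoms:
            key = (atom.chain_id, atom.residue_index)
            if key != current_key:
                self.residues.append(
                    Residue(
                        index=len(self.residues),
                        chain_id=atom.chain_id,
                        number=atom.residue_index,
                        icode="",
                        name=atom.residue_type,
                        atoms=[],
                    )
                )
                current_key = key
            self.residues[-1].atoms.append(atom)
        # re-densify atom residue indices to match residue order
        for res in self.residues:
            for a in res.atoms:
                a.residue_index = res.index

    def __len__(self) -> int:
        return len(self.residues)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=np.float64)

    def charges(self) -> np.ndarray:
        vals = [a.partial_charge for a in self.atoms]
        if any(v is None for v in vals):
            raise ValueError("charges required: structure has atoms without partial charges")
        return np.array(vals, dtype=np.float64)

    def sequence(self) -> str:
        return "".join(ONE_LETTER.get(r.name, "X") for r in self.residues)

    def ca_positions(self) -> np.ndarray:
        """Cα coordinates for residues that have one (NaN rows otherwise)."""
        out = np.full((len(self.residues), 3), np.nan)
        for r in self.residues:
            ca = r.atom("CA")
            if ca is not None:
                out[r.index] = ca.position
        return out


@dataclass
class DihedralBlock:
    """sin/cos/mask encoding of (φ, ψ, χ1, χ2, χ3) for one residue.

    Always 15 values: for each of the five angles, (sin, cos, mask) with
    mask 0 (and sin = cos = 0) when the angle does not exist.
    """

    sin: np.ndarray   # (5,)
    cos: np.ndarray   # (5,)
    mask: np.ndarray  # (5,)

    @property
    def values(self) -> np.ndarray:
        out = np.empty(15)
        out[0::3] = self.sin
        out[1::3] = self.cos
        out[2::3] = self.mask
        return out


# ---------------------------------------------------------------------------
# Parsing


def _map_residue_name(name: str) -> str | None:
    name = name.strip().upper()
    if name in AA_INDEX:
        return name
    if name in NONSTANDARD_MAP:
        return NONSTANDARD_MAP[name]
    return None


def _validate_pdb_lines(lines: list[str]) -> None:
    for i, line in enumerate(lines, start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line.rstrip("\n")) < 54:
                raise PdbParseError(f"malformed ATOM record at line {i}: too short")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PdbParseError(
                    f"malformed ATOM record at line {i}: bad coordinate field"
                ) from exc


def read_pdb(path: str | Path, keep_hydrogens: bool = False) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    HETATM records and waters are excluded; alternate locations are resolved
    to the highest-occupancy conformer; hydrogens are dropped by default (the
    residue-level pipeline uses heavy atoms only).
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    lines = path.read_text().splitlines()
    _validate_pdb_lines(lines)
    pdb_file = PDBFile.read(str(path))
    try:
        arr = pdb_file.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite's own failure modes
        raise PdbParseError(f"could not parse {path.name}: {exc}") from exc

    atoms: list[Atom] = []
    res_key_to_dense: dict[tuple, int] = {}
    for i in range(arr.array_length()):
        if arr.hetero[i]:
            continue
        res_name = str(arr.res_name[i])
        if res_name in WATER_NAMES:
            continue
        mapped = _map_residue_name(res_name)
        if mapped is None:
            logger.warning("dropping unmappable residue %s", res_name)
            continue
        element = str(arr.element[i]).upper()
        if not keep_hydrogens and element == "H":
            continue
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.ins_code[i]))
        if key not in res_key_to_dense:
            res_key_to_dense[key] = len(res_key_to_dense)
        atoms.append(
            Atom(
                element=element,
                name=str(arr.atom_name[i]),
                residue_index=res_key_to_dense[key],
                residue_type=mapped,
                chain_id=key[0],
                position=np.array(arr.coord[i], dtype=np.float64),
            )
        )
    if not atoms:
        raise PdbParseError(f"no atoms: {path.name} contains no usable ATOM records")
    return Structure(atoms)


def read_pqr(path: str | Path) -> Structure:
    """Parse a PQR file (PDB2PQR whitespace dialect, charge + radius columns).

    Every atom carries a partial charge; hydrogens are retained.
    """
    path = Path(path)
    atoms: list[Atom] = []
    res_key_to_dense: dict[tuple, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        # ATOM serial name resName [chain] resNum x y z charge radius
        if len(fields) == 11:
            _, _, name, res_name, chain, res_num, x, y, z, q, _r = fields
        elif len(fields) == 10:
            _, _, name, res_name, res_num, x, y, z, q, _r = fields
            chain = "A"
        else:
            raise PqrFormatError(
                f"line {lineno}: expected 10 or 11 whitespace-delimited fields "
                f"(missing charge or radius column?), got {len(fields)}"
            )
        mapped = _map_residue_name(res_name)
        if mapped is None:
            logger.warning("dropping unmappable residue %s", res_name)
            continue
        try:
            res_number = int(res_num)
            pos = np.array([float(x), float(y), float(z)])
            charge = float(q)
            float(_r)
        except ValueError as exc:
            raise PqrFormatError(f"line {lineno}: malformed numeric field") from exc
        element = _element_from_name(name)
        key = (chain, res_number)
        if key not in res_key_to_dense:
            res_key_to_dense[key] = len(res_key_to_dense)
        atoms.append(
            Atom(
                element=element,
                name=name,
                residue_index=res_key_to_dense[key],
                residue_type=mapped,
                chain_id=chain,
                position=pos,
                partial_charge=charge,
            )
        )
    if not atoms:
        raise PqrFormatError(f"no atoms: {path.name} contains no usable records")
    return Structure(atoms)


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB/PQR atom name (protein atoms only)."""
    stripped = name.strip()
    if not stripped:
        return "C"
    lead = stripped.lstrip("0123456789")
    first = lead[:1].upper()
    if first == "H" or (stripped[0].isdigit() and first == "H"):
        return "H"
    if lead[:2].upper() == "SE":
        return "SE"
    return first


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-width PDB ATOM records (via biotite)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(structure.atoms)
    arr = struc.AtomArray(n)
    for i, atom in enumerate(structure.atoms):
        res = structure.residues[atom.residue_index]
        arr.chain_id[i] = atom.chain_id
        arr.res_id[i] = res.index + 1
        arr.res_name[i] = atom.residue_type
        arr.atom_name[i] = atom.name
        arr.element[i] = atom.element
        arr.coord[i] = atom.position
    arr.hetero[:] = False
    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def write_pqr(structure: Structure, path: str | Path) -> None:
    """Write a Structure (with charges) in the PQR whitespace dialect."""
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        if atom.partial_charge is None:
            raise ValueError("charges required: cannot write PQR without partial charges")
        res = structure.residues[atom.residue_index]
        lines.append(
            f"ATOM {i:6d} {atom.name:<4s} {atom.residue_type:<4s} {atom.chain_id:s} "
            f"{res.number:4d} {atom.position[0]:10.4f} {atom.position[1]:10.4f} "
            f"{atom.position[2]:10.4f} {atom.partial_charge:8.4f} "
            f"{_vdw_radius(atom.element):7.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _vdw_radius(element: str) -> float:
    from .reference_props import VDW_RADII

    return VDW_RADII.get(element.upper(), 1.7)


# ---------------------------------------------------------------------------
# Geometry


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, in (-180, 180]) about the p2–p3 axis."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(1.0, np.linalg.norm(b1) * norm_b2):
        raise CollinearPointsError("p1, p2, p3 are collinear; torsion undefined")
    if np.linalg.norm(n2) < 1e-10 * max(1.0, norm_b2 * np.linalg.norm(b3)):
        raise CollinearPointsError("p2, p3, p4 are collinear; torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


def _chain_neighbor(structure: Structure, residue: Residue, offset: int) -> Residue | None:
    j = residue.index + offset
    if 0 <= j < len(structure.residues):
        nb = structure.residues[j]
        if nb.chain_id == residue.chain_id:
            return nb
    return None


def dihedral_block(structure: Structure, residue: Residue | int) -> DihedralBlock:
    """Compute the 15-value (φ, ψ, χ1–χ3) sin/cos/mask block for a residue.

    Missing atoms, chain termini and degenerate geometry all degrade to
    mask = 0 for the affected angle; this function never raises.
    """
    if isinstance(residue, int):
        residue = structure.residues[residue]
    sin = np.zeros(5)
    cos = np.zeros(5)
    mask = np.zeros(5)

    def fill(slot: int, quad) -> None:
        if quad is None or any(a is None for a in quad):
            return
        try:
            ang = dihedral(*(a.position for a in quad))
        except CollinearPointsError:
            return
        rad = math.radians(ang)
        sin[slot] = math.sin(rad)
        cos[slot] = math.cos(rad)
        mask[slot] = 1.0

    prev_res = _chain_neighbor(structure, residue, -1)
    next_res = _chain_neighbor(structure, residue, +1)
    if prev_res is not None:
        fill(0, (prev_res.atom("C"), residue.atom("N"), residue.atom("CA"), residue.atom("C")))
    if next_res is not None:
        fill(1, (residue.atom("N"), residue.atom("CA"), residue.atom("C"), next_res.atom("N")))
    for k, names in enumerate(CHI_ATOMS.get(residue.name, ())[:3]):
        fill(2 + k, tuple(residue.atom(n) for n in names))
    return DihedralBlock(sin=sin, cos=cos, mask=mask)


def center_of_mass(structure: Structure) -> np.ndarray:
    """Mass-weighted mean position over all parsed atoms (Å)."""
    pos = structure.positions()
    masses = np.array([a.mass for a in structure.atoms])
    return (masses[:, None] * pos).sum(axis=0) / masses.sum()
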