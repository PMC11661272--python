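"""Seeded generators for desk-scale structures with known ground truth.

Every stage of the pipeline is testable without downloads: the generators
emulate plausible polypeptide geometry (ideal backbone bond lengths and
angles, Cα–Cα spacing ≈ 3.8 Å, helical segments at φ ≈ −57°, ψ ≈ −47°,
coil segments with jittered torsions, Cβ and one-atom side-chain stubs)
and charged atomic environments whose per-residue partial charges sum to
integer formal charges.

Targets come either from the exact oracles in
:mod:`protembed.reference_props` (radius of gyration, Shrake–Rupley SASA)
or from documented deterministic *surrogate* formulas (hydrodynamic radius,
diffusion constants, volume, solvation free energy).  The surrogates are
declared surrogates: they have the right units, magnitudes and
correlations for exercising the multi-task training machinery, and are
never presented as physical reference values.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference_props import (
    DEFAULT_NULL_TABLE,
    IONIZABLE_TYPES,
    NullModelTable,
    radius_of_gyration,
    sasa_shrake_rupley,
)
from .structio import AA_INDEX, Atom, STANDARD_AA, Structure

__all__ = [
    "SynthSpec",
    "generate_mini_protein",
    "generate_structures",
    "generate_atomic_environment",
    "generate_property_table",
    "generate_pka_dataset",
    "generate_homolog_family",
    "PROPERTY_COLUMNS",
]

PROPERTY_COLUMNS = ("dG_sol", "Rg", "Rh", "Dt", "Dr", "V", "SASA")

# ideal backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB, B_CB_G = 1.458, 1.525, 1.329, 1.231, 1.530, 1.520
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_CA_C_O, A_N_CA_CB, A_CA_CB_G = 120.8, 110.5, 114.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0

# one-atom side-chain stub beyond Cβ, named by the IUPAC gamma atom
GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

FORMAL_CHARGE: dict[str, int] = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the mini-protein generator."""

    n_structures: int = 200
    length_range: tuple[int, int] = (12, 28)
    helix_fraction_range: tuple[float, float] = (0.0, 1.0)
    noise_scale: float = 0.0   # Å, optional coordinate jitter
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < 4:
            raise ValueError("chains must have at least 4 residues")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement of D bonded to c, given chain a-b-c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _element_of(name: str) -> str:
    return "S" if name.startswith("S") else ("O" if name.startswith("O") else name[0])


def generate_mini_protein(
    length: int,
    helix_fraction: float,
    rng: np.random.Generator,
    noise_scale: float = 0.0,
    sequence: str | None = None,
) -> tuple[Structure, str]:
    """Build one chain with ideal geometry and a contiguous helical block.

    Helical residues draw (φ, ψ) near (−57°, −47°) with ±2° jitter; coil
    residues draw broader jittered torsions from the extended region.
    Every residue carries N, CA, C, O plus Cβ and a one-atom side-chain
    stub where the residue type has one, so all dihedrals are recomputable
    from the coordinates.
    """
    if sequence is None:
        sequence3 = [STANDARD_AA[i] for i in rng.integers(0, 20, size=length)]
    else:
        from .structio import ONE_LETTER

        inv = {v: k for k, v in ONE_LETTER.items()}
        sequence3 = [inv[c] for c in sequence]
        length = len(sequence3)

    n_helix = int(round(helix_fraction * length))
    start = int(rng.integers(0, length - n_helix + 1)) if n_helix < length else 0
    is_helix = np.zeros(length, dtype=bool)
    is_helix[start : start + n_helix] = True

    phis = np.empty(length)
    psis = np.empty(length)
    for i in range(length):
        if is_helix[i]:
            phis[i] = HELIX_PHI + rng.normal(0.0, 2.0)
            psis[i] = HELIX_PSI + rng.normal(0.0, 2.0)
        else:
            phis[i] = -110.0 + rng.normal(0.0, 25.0)
            psis[i] = 125.0 + rng.normal(0.0, 25.0)

    atoms: list[Atom] = []

    def add(name: str, res_idx: int, pos: np.ndarray) -> np.ndarray:
        atoms.append(
            Atom(
                element=_element_of(name),
                name=name,
                residue_index=res_idx,
                residue_type=sequence3[res_idx],
                chain_id="A",
                position=np.asarray(pos, dtype=float),
            )
        )
        return atoms[-1].position

    # first residue seeds the frame
    n_pos = add("N", 0, np.zeros(3))
    ca_pos = add("CA", 0, np.array([B_N_CA, 0.0, 0.0]))
    ang = math.radians(A_N_CA_C)
    c_pos = add(
        "C", 0, ca_pos + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    )
    _finish_residue(add, 0, sequence3[0], n_pos, ca_pos, c_pos, psis[0], rng)
    prev = (n_pos, ca_pos, c_pos)

    for i in range(1, length):
        pn, pca, pc = prev
        n_pos = _place_atom(pn, pca, pc, B_C_N, A_CA_C_N, psis[i - 1])
        ca_pos = _place_atom(pca, pc, n_pos, B_N_CA, A_C_N_CA, 180.0)  # trans omega
        c_pos = _place_atom(pc, n_pos, ca_pos, B_CA_C, A_N_CA_C, phis[i])
        add("N", i, n_pos)
        add("CA", i, ca_pos)
        add("C", i, c_pos)
        _finish_residue(add, i, sequence3[i], n_pos, ca_pos, c_pos, psis[i], rng)
        prev = (n_pos, ca_pos, c_pos)

    if noise_scale > 0:
        for atom in atoms:
            atom.position = atom.position + rng.normal(0.0, noise_scale, size=3)
    # stable order: group atoms by residue
    atoms.sort(key=lambda a: a.residue_index)
    return Structure(atoms), "".join(sequence3)


def _finish_residue(add, i, res_type, n_pos, ca_pos, c_pos, psi, rng) -> None:
    """Carbonyl O, Cβ and the one-atom side-chain stub for residue i."""
    add("O", i, _place_atom(n_pos, ca_pos, c_pos, B_C_O, A_CA_C_O, psi + 180.0))
    if res_type == "GLY":
        return
    cb = _place_atom(c_pos, n_pos, ca_pos, B_CA_CB, A_N_CA_CB, 122.6)
    add("CB", i, cb)
    gamma = GAMMA_ATOM.get(res_type)
    if gamma is not None:
        chi1 = float(rng.choice([-60.0, 60.0, 180.0]) + rng.normal(0.0, 8.0))
        add(gamma, i, _place_atom(n_pos, ca_pos, cb, B_CB_G, A_CA_CB_G, chi1))


def generate_structures(spec: SynthSpec) -> tuple[list[Structure], list[str]]:
    """Generate ``spec.n_structures`` chains; pure function of the spec."""
    rng = np.random.default_rng(spec.seed)
    structures, sequences = [], []
    lo, hi = spec.length_range
    flo, fhi = spec.helix_fraction_range
    for _ in range(spec.n_structures):
        length = int(rng.integers(lo, hi + 1))
        frac = float(rng.uniform(flo, fhi))
        s, seq = generate_mini_protein(length, frac, rng, spec.noise_scale)
        structures.append(s)
        sequences.append(seq)
    return structures, sequences


# ---------------------------------------------------------------------------
# Atomic environments with charges


def generate_atomic_environment(
    rng: np.random.Generator,
    n_surround: int = 40,
    net_charge: int | None = None,
    target_type: str | None = None,
    max_radius: float = 12.0,
    min_separation: float = 2.0,
) -> tuple[Structure, int]:
    """One ionizable residue plus a charged atomic neighborhood.

    Surrounding atoms are grouped into pseudo-residues of ~5 atoms whose
    partial charges sum to an integer formal charge (0 or ±1); clash-free
    placement enforces a minimum interatomic separation by rejection
    sampling.  Returns (structure, dense index of the target residue).
    """
    if target_type is None:
        target_type = str(rng.choice(IONIZABLE_TYPES))
    atoms: list[Atom] = []

    # target residue fragment with ideal local geometry
    n_pos = np.array([-1.458, 0.0, 0.0])
    ca_pos = np.zeros(3)
    ang = math.radians(A_N_CA_C)
    c_pos = ca_pos + B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0]) * -1.0
    frag = [("N", n_pos), ("CA", ca_pos), ("C", c_pos)]
    frag.append(("O", _place_atom(n_pos, ca_pos, c_pos, B_C_O, A_CA_C_O, 120.0)))
    cb = _place_atom(c_pos, n_pos, ca_pos, B_CA_CB, A_N_CA_CB, 122.6)
    frag.append(("CB", cb))
    gamma = GAMMA_ATOM.get(target_type)
    if gamma is not None:
        frag.append((gamma, _place_atom(n_pos, ca_pos, cb, B_CB_G, A_CA_CB_G, -60.0)))
    target_formal = FORMAL_CHARGE.get(target_type, 0)
    raw = rng.normal(0.0, 0.3, size=len(frag))
    charges = raw - raw.mean() + target_formal / len(frag)
    for (name, pos), q in zip(frag, charges):
        atoms.append(
            Atom(
                element=_element_of(name),
                name=name,
                residue_index=0,
                residue_type=target_type,
                chain_id="A",
                position=pos,
                partial_charge=float(q),
            )
        )

    # surrounding pseudo-residues
    taken = [a.position for a in atoms]
    res_idx = 0
    placed = 0
    group_size = 5
    while placed < n_surround:
        res_idx += 1
        size = min(group_size, n_surround - placed)
        res_type = str(rng.choice(STANDARD_AA))
        formal = int(rng.choice([-1, 0, 0, 0, 1]))
        center = _random_point(rng, 4.0, max_radius - 1.5)
        raw = rng.normal(0.0, 0.25, size=size)
        qs = raw - raw.mean() + formal / size
        for k in range(size):
            for _ in range(200):  # rejection sampling for clash-free placement
                pos = center + rng.normal(0.0, 1.2, size=3)
                if np.linalg.norm(pos) > max_radius:
                    continue
                if all(np.linalg.norm(pos - t) >= min_separation for t in taken):
                    break
            else:
                pos = _random_point(rng, 4.0, max_radius)
            taken.append(pos)
            element = str(rng.choice(["C", "H", "N", "O", "S"], p=[0.38, 0.35, 0.12, 0.12, 0.03]))
            atoms.append(
                Atom(
                    element=element,
                    name=f"{element}{k + 1}",
                    residue_index=res_idx,
                    residue_type=res_type,
                    chain_id="A",
                    position=pos,
                    partial_charge=float(qs[k]),
                )
            )
            placed += 1

    structure = Structure(atoms)
    if net_charge is not None:
        total = sum(a.partial_charge for a in structure.atoms)
        shift = (net_charge - total) / len(structure.atoms)
        for a in structure.atoms:
            a.partial_charge += shift
    return structure, 0


def _random_point(rng: np.random.Generator, r_min: float, r_max: float) -> np.ndarray:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return direction * rng.uniform(r_min, r_max)


# ---------------------------------------------------------------------------
# Property tables


def generate_property_table(
    structures: list[Structure],
    mask_available_fraction: float = 0.2,
    seed: int = 0,
    sasa_points: int = 240,
) -> pd.DataFrame:
    """Six-target table (+ SASA) with a missing-data mask for dG_sol.

    Rg and SASA come from the exact oracles.  The remaining targets are
    deterministic surrogates with physically plausible magnitudes:

    * Rh  = 2.0 + 0.9 Rg                       [Å]
    * Dt  = 218 / Rh                           [nm²/μs]  (Stokes–Einstein shape)
    * Dr  = 2.0e4 / Rh³                        [μs⁻¹]
    * V   = 0.0121 n_atoms                     [nm³]
    * dG_sol = −(60 n_charged + 2.5 n_res + 8 Rg)  [kJ/mol]

    dG_sol is available for ``mask_available_fraction`` of rows (matching
    the sparse-reference study condition); the mask column marks rows with
    a reference value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in structures:
        rg = radius_of_gyration(s)
        sasa, _ = sasa_shrake_rupley(s, n_points=sasa_points)
        rh = 2.0 + 0.9 * rg
        n_charged = sum(1 for r in s.residues if r.name in FORMAL_CHARGE)
        rows.append(
            {
                "dG_sol": -(60.0 * n_charged + 2.5 * len(s.residues) + 8.0 * rg),
                "Rg": rg,
                "Rh": rh,
                "Dt": 218.0 / rh,
                "Dr": 2.0e4 / rh**3,
                "V": 0.0121 * len(s.atoms),
                "SASA": sasa,
            }
        )
    df = pd.DataFrame(rows)
    df["dG_mask"] = (rng.random(len(df)) < mask_available_fraction).astype(float)
    return df


# ---------------------------------------------------------------------------
# Planted-signal pKa data


def generate_pka_dataset(
    n_records: int = 500,
    seed: int = 0,
    alpha: float = 0.75,
    beta: float = 1.5,
    noise: float = 0.25,
    n_surround_range: tuple[int, int] = (25, 55),
    null_table: NullModelTable | None = None,
) -> tuple[pd.DataFrame, list[Structure]]:
    """Ionizable-residue records with a learnable planted signal.

    pKa = model-compound value + alpha * (net charge within 10 Å of the
    target Cα) + beta * (burial proxy − 0.5) + Gaussian noise, where the
    burial proxy is the atom count within 6 Å of the Cα divided by 40.
    alpha, beta and the noise scale are recorded in the table attrs.
    """
    rng = np.random.default_rng(seed)
    table = null_table or NullModelTable()
    rows = []
    structures: list[Structure] = []
    for i in range(n_records):
        n_surround = int(rng.integers(*n_surround_range))
        structure, target_idx = generate_atomic_environment(rng, n_surround=n_surround)
        target = structure.residues[target_idx]
        ca = target.atom("CA").position
        pos = structure.positions()
        q = structure.charges()
        d = np.linalg.norm(pos - ca, axis=1)
        local_charge = float(q[d <= 10.0].sum())
        burial = float((d <= 6.0).sum()) / 40.0
        pka = (
            table[target.name]
            + alpha * local_charge
            + beta * (burial - 0.5)
            + rng.normal(0.0, noise)
        )
        rows.append(
            {
                "structure_id": f"SYN{i:04d}",
                "chain": "A",
                "residue_number": target.number,
                "residue_type": target.name,
                "pka_exp": pka,
                "local_charge": local_charge,
                "burial": burial,
            }
        )
        structures.append(structure)
    df = pd.DataFrame(rows)
    df.attrs.update({"alpha": alpha, "beta": beta, "noise": noise, "null_table": dict(DEFAULT_NULL_TABLE if null_table is None else null_table.values)})
    return df, structures


# ---------------------------------------------------------------------------
# Homolog families for curation tests


def generate_homolog_family(
    n_families: int = 4,
    family_size: int = 4,
    length: int = 60,
    mutation_rate: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Families of homologous sequences with ionizable-site pKa records.

    Within a family, sequences derive from a common ancestor by point
    mutations (expected identity 1 − mutation_rate, above the 0.5
    clustering threshold); across families sequences are independent.
    Each sequence contributes a record at every ionizable position, so
    similarity-aware splitting has genuine leakage to catch.
    """
    rng = np.random.default_rng(seed)
    from .structio import ONE_LETTER

    one = [ONE_LETTER[a] for a in STANDARD_AA]
    ionizable_one = {ONE_LETTER[t]: t for t in IONIZABLE_TYPES}
    sequences: dict[str, str] = {}
    rows = []
    for f in range(n_families):
        ancestor = rng.choice(one, size=length)
        # plant ionizable sites
        for pos in rng.choice(length, size=max(3, length // 12), replace=False):
            ancestor[pos] = str(rng.choice(list(ionizable_one)))
        for m in range(family_size):
            seq = ancestor.copy()
            n_mut = rng.binomial(length, mutation_rate) if m else 0
            for pos in rng.choice(length, size=n_mut, replace=False):
                seq[pos] = str(rng.choice(one))
            sid = f"FAM{f}_{m}"
            sequences[sid] = "".join(seq)
            for pos, c in enumerate(seq):
                if c in ionizable_one:
                    rtype = ionizable_one[c]
                    rows.append(
                        {
                            "structure_id": sid,
                            "chain": "A",
                            "residue_number": pos + 1,
                            "residue_type": rtype,
                            "pka_exp": DEFAULT_NULL_TABLE[rtype] + rng.normal(0.0, 0.8),
                        }
                    )
    return sequences, pd.DataFrame(rows)
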