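"""E(3)-invariant graph construction for the two network resolutions.

Two graph representations are built from a parsed :class:`~protembed.structio.Structure`:

* **Residue graph** — one node per residue carrying the amino-acid index,
  the 15-value dihedral block and the distance of the residue's Cα to the
  protein center of mass; directed edges between all residue pairs whose Cα
  atoms lie within 15 Å, featurized by Gaussian smearing of the Cα–Cα
  distance onto 300 linearly spaced radial basis functions.

* **Atom graph** — the local environment of one ionizable residue: every
  C/H/N/O/S atom within 10 Å of the residue's Cα (inclusive), carrying the
  parent residue's amino-acid index, an atom-type index and the atomic
  partial charge; directed edges between atoms within 5 Å, smeared onto 300
  basis functions spanning 0–5 Å.

All features are functions of interatomic distances and internal torsions
only, so they are invariant under rigid rotations and translations, and
permutation-equivariant in the node ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structio import AA_INDEX, Structure, Residue, center_of_mass, dihedral_block

logger = logging.getLogger(__name__)

__all__ = [
    "RbfSpec",
    "RESIDUE_RBF",
    "ATOMIC_RBF",
    "ResidueGraph",
    "AtomGraph",
    "pairwise_distance",
    "gaussian_smear",
    "build_residue_graph",
    "build_atom_graph",
    "save_graph",
    "load_graph",
    "ATOM_TYPES",
    "ATOM_TYPE_INDEX",
]

ATOM_TYPES: tuple[str, ...] = ("C", "H", "N", "O", "S")
ATOM_TYPE_INDEX: dict[str, int] = {el: i for i, el in enumerate(ATOM_TYPES)}

RESIDUE_CUTOFF = 15.0  # Å, Cα–Cα edge cutoff of the residue graph
ATOM_SELECTION_RADIUS = 10.0  # Å, selection sphere around the target Cα
ATOM_EDGE_CUTOFF = 5.0  # Å, interatomic edge cutoff of the atom graph


@dataclass(frozen=True)
class RbfSpec:
    """Linearly spaced Gaussian basis for distance smearing.

    ``K`` centers from 0 to ``r_max`` Å; the width equals the spacing
    between consecutive centers, sigma = r_max / (K - 1).
    """

    K: int = 300
    r_max: float = 15.0

    @property
    def mu(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.K)

    @property
    def sigma(self) -> float:
        return self.r_max / (self.K - 1)


RESIDUE_RBF = RbfSpec(K=300, r_max=15.0)
ATOMIC_RBF = RbfSpec(K=300, r_max=5.0)


def pairwise_distance(p_i, p_j) -> float:
    """Euclidean distance between two points (Å)."""
    return float(np.linalg.norm(np.asarray(p_i, dtype=np.float64) - np.asarray(p_j, dtype=np.float64)))


def gaussian_smear(d, spec: RbfSpec) -> np.ndarray:
    """Expand distance(s) onto the Gaussian basis: exp(-(d - mu_k)^2 / 2 sigma^2).

    Accepts a scalar (returns shape (K,)) or an array of E distances
    (returns (E, K)).
    """
    d = np.asarray(d, dtype=np.float64)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    diff = d[:, None] - spec.mu[None, :]
    out = np.exp(-(diff**2) / (2.0 * spec.sigma**2))
    return out[0] if scalar else out


@dataclass
class ResidueGraph:
    aa_index: np.ndarray        # (n,) int
    dihedrals: np.ndarray       # (n, 15)
    d_com: np.ndarray           # (n,)
    ca_positions: np.ndarray    # (n, 3), kept for radius-subset pooling
    edge_src: np.ndarray        # (E,) int
    edge_dst: np.ndarray        # (E,) int
    edge_attr: np.ndarray       # (E, K)
    rbf: RbfSpec = field(default_factory=lambda: RESIDUE_RBF)
    residue_labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.aa_index)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)


@dataclass
class AtomGraph:
    aa_index: np.ndarray        # (n,) parent-residue amino-acid index
    atom_type: np.ndarray       # (n,) index into ATOM_TYPES
    charge: np.ndarray          # (n,) elementary charges
    positions: np.ndarray       # (n, 3)
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_attr: np.ndarray       # (E, K)
    target_ca: int              # node index of the target residue's Cα
    in_target: np.ndarray       # (n,) bool, atom belongs to the target residue
    rbf: RbfSpec = field(default_factory=lambda: ATOMIC_RBF)
    target_label: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.aa_index)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)


def _radius_edges(positions: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All ordered pairs (i, j), i != j, with ||p_i - p_j|| <= cutoff."""
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    mask = (dist <= cutoff) & ~np.eye(len(positions), dtype=bool)
    src, dst = np.nonzero(mask)
    return src.astype(np.intp), dst.astype(np.intp), dist[src, dst]


def build_residue_graph(structure: Structure, rbf: RbfSpec = RESIDUE_RBF) -> ResidueGraph:
    """Build the residue-level graph with Cα-distance edges within 15 Å.

    Residues without a Cα are excluded (with a logged warning); the distance
    to the center of mass is computed over all parsed atoms.
    """
    com = center_of_mass(structure)
    kept: list[Residue] = []
    for res in structure.residues:
        if res.has_ca and res.name in AA_INDEX:
            kept.append(res)
        else:
            logger.warning("excluding residue %s %s: no C-alpha", res.chain_id, res.index)
    if not kept:
        raise ValueError("no residues with C-alpha atoms")
    ca = np.array([r.atom("CA").position for r in kept])
    aa = np.array([AA_INDEX[r.name] for r in kept], dtype=np.intp)
    dih = np.array([dihedral_block(structure, r).values for r in kept])
    d_com = np.linalg.norm(ca - com[None, :], axis=1)
    src, dst, dist = _radius_edges(ca, rbf.r_max)
    return ResidueGraph(
        aa_index=aa,
        dihedrals=dih,
        d_com=d_com,
        ca_positions=ca,
        edge_src=src,
        edge_dst=dst,
        edge_attr=gaussian_smear(dist, rbf).astype(np.float64),
        rbf=rbf,
        residue_labels=[f"{r.chain_id}:{r.number}:{r.name}" for r in kept],
    )


def build_atom_graph(
    structure: Structure,
    target_residue: Residue | int,
    rbf: RbfSpec = ATOMIC_RBF,
    selection_radius: float = ATOM_SELECTION_RADIUS,
    edge_cutoff: float = ATOM_EDGE_CUTOFF,
) -> AtomGraph:
    """Build the atomic environment graph around one ionizable residue.

    Requires PQR-derived partial charges on every atom.  The node set is all
    C/H/N/O/S atoms within ``selection_radius`` of the target residue's Cα
    (inclusive, including the Cα itself); edges connect atoms within
    ``edge_cutoff`` Å.
    """
    if isinstance(target_residue, int):
        try:
            target_residue = structure.residues[target_residue]
        except IndexError as exc:
            raise KeyError(f"target residue index out of range: {exc}") from exc
    ca = target_residue.atom("CA")
    if ca is None:
        raise ValueError("target residue has no C-alpha atom")
    if any(a.partial_charge is None for a in structure.atoms):
        raise ValueError("charges required: atom graph needs PQR-derived partial charges")

    sel = [
        a
        for a in structure.atoms
        if a.element in ATOM_TYPE_INDEX
        and np.linalg.norm(a.position - ca.position) <= selection_radius
    ]
    positions = np.array([a.position for a in sel])
    aa = np.array(
        [AA_INDEX.get(a.residue_type, AA_INDEX["ALA"]) for a in sel], dtype=np.intp
    )
    types = np.array([ATOM_TYPE_INDEX[a.element] for a in sel], dtype=np.intp)
    charge = np.array([a.partial_charge for a in sel], dtype=np.float64)
    in_target = np.array([a.residue_index == target_residue.index for a in sel], dtype=bool)
    target_ca = next(i for i, a in enumerate(sel) if a is ca)
    src, dst, dist = _radius_edges(positions, edge_cutoff)
    return AtomGraph(
        aa_index=aa,
        atom_type=types,
        charge=charge,
        positions=positions,
        edge_src=src,
        edge_dst=dst,
        edge_attr=gaussian_smear(dist, rbf).astype(np.float64),
        target_ca=target_ca,
        in_target=in_target,
        rbf=rbf,
        target_label=f"{target_residue.chain_id}:{target_residue.number}:{target_residue.name}",
    )


# ---------------------------------------------------------------------------
# On-disk container (node table + edge table + spec header)


def save_graph(graph: ResidueGraph | AtomGraph, path: str | Path) -> None:
    """Serialize a graph to an ``.npz`` container with a JSON spec header."""
    header = {
        "kind": type(graph).__name__,
        "rbf": {"K": graph.rbf.K, "r_max": graph.rbf.r_max},
    }
    arrays = {k: v for k, v in graph.__dict__.items() if isinstance(v, np.ndarray)}
    if isinstance(graph, AtomGraph):
        header["target_ca"] = int(graph.target_ca)
        header["target_label"] = graph.target_label
    else:
        header["residue_labels"] = graph.residue_labels
    np.savez(path, __header__=np.array(json.dumps(header)), **arrays)


def load_graph(path: str | Path) -> ResidueGraph | AtomGraph:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        arrays = {k: data[k] for k in data.files if k != "__header__"}
    rbf = RbfSpec(K=header["rbf"]["K"], r_max=header["rbf"]["r_max"])
    if header["kind"] == "AtomGraph":
        return AtomGraph(rbf=rbf, target_ca=header["target_ca"],
                         target_label=header.get("target_label", ""), **arrays)
    return ResidueGraph(rbf=rbf, residue_labels=header.get("residue_labels", []), **arrays)
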