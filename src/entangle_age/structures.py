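"""Protein structure I/O, contact maps and shape descriptors.

Structures are held as a flat atom table plus a per-residue Cα trace.
Residues are renumbered 1..N on load so that downstream linking-number
integrals always see a gap-free chain; 1-based, inclusive residue spans
are used everywhere in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ProteinStructure",
    "ContactMap",
    "load_structure",
    "write_pdb",
    "mean_plddt_pass",
    "heavy_atom_contacts",
    "asphericity",
]

_HYDROGEN = {"H", "D"}


@dataclass
class ProteinStructure:
    """A single-chain protein model.

    Attributes
    ----------
    id : str
        Identifier (file stem or user supplied).
    res_names : (N,) array of str
        Three-letter residue names.
    ca_coords : (N, 3) float array
        Cα coordinates in Å, one row per residue, residue ``r`` (1-based)
        in row ``r - 1``.
    atom_coords : (M, 3) float array
        All heavy-atom (and, if present, hydrogen) coordinates in Å.
    atom_elements : (M,) array of str
        Element symbols for ``atom_coords``.
    atom_res_index : (M,) int array
        1-based residue index of each atom.
    plddt : (N,) float array or None
        Per-residue confidence score 0–100, read from the B-factor column
        of AlphaFold-style files when requested.
    """

    id: str
    res_names: np.ndarray
    ca_coords: np.ndarray
    atom_coords: np.ndarray
    atom_elements: np.ndarray
    atom_res_index: np.ndarray
    plddt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be (N, 3)")
        if not np.isfinite(self.ca_coords).all():
            raise ValueError("non-finite Cα coordinates")
        if len(self.res_names) != len(self.ca_coords):
            raise ValueError("res_names and ca_coords length mismatch")

    @property
    def n_residues(self) -> int:
        return len(self.ca_coords)

    @classmethod
    def from_ca(
        cls,
        ca_coords: np.ndarray,
        id: str = "synthetic",
        plddt: np.ndarray | None = None,
    ) -> "ProteinStructure":
        """Build a Cα-only structure (each residue one carbon pseudo-atom)."""
        ca = np.asarray(ca_coords, dtype=float)
        n = len(ca)
        return cls(
            id=id,
            res_names=np.array(["GLY"] * n),
            ca_coords=ca,
            atom_coords=ca.copy(),
            atom_elements=np.array(["C"] * n),
            atom_res_index=np.arange(1, n + 1),
            plddt=None if plddt is None else np.asarray(plddt, dtype=float),
        )

    def heavy_atom_mask(self) -> np.ndarray:
        return ~np.isin(self.atom_elements, list(_HYDROGEN))


@dataclass
class ContactMap:
    """Residue–residue contacts (i < j, 1-based) with the minimal
    inter-residue heavy-atom distance for each pair."""

    contacts: list
    cutoff: float
    min_seq_sep: int
    min_dists: dict = field(default_factory=dict)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in set(map(tuple, self.contacts))

    def __len__(self) -> int:
        return len(self.contacts)

    def pairs_array(self) -> np.ndarray:
        return np.asarray(self.contacts, dtype=int).reshape(-1, 2)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pairs = self.pairs_array()
        df = pd.DataFrame(
            {
                "i": pairs[:, 0] if len(pairs) else [],
                "j": pairs[:, 1] if len(pairs) else [],
                "min_dist": [self.min_dists.get((i, j), np.nan) for i, j in self.contacts],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def _from_atom_array(atoms, id: str, b_factor_is_plddt: bool) -> ProteinStructure:
    import biotite.structure as struc

    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError("no amino-acid atoms found")
    # altloc: biotite's reader already keeps one altloc when asked; guard anyway
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        atoms = atoms[atoms.chain_id == chains[0]]
        warnings.warn(f"multiple chains; keeping chain {chains[0]!r}")

    res_ids = atoms.res_id
    order = np.unique(res_ids)
    ca_list, names, plddt, keep_atoms = [], [], [], []
    for rid in order:
        sel = res_ids == rid
        res_atoms = atoms[sel]
        ca = res_atoms[res_atoms.atom_name == "CA"]
        if ca.array_length() == 0:
            warnings.warn(f"residue {rid} has no CA atom; dropped")
            continue
        ca_list.append(ca.coord[0])
        names.append(res_atoms.res_name[0])
        if b_factor_is_plddt:
            plddt.append(float(ca.b_factor[0]))
        keep_atoms.append(res_atoms)

    n = len(ca_list)
    if n == 0:
        raise ValueError("no residues with CA atoms")
    coords, elements, res_index = [], [], []
    for new_id, res_atoms in enumerate(keep_atoms, start=1):
        coords.append(res_atoms.coord)
        elements.append(res_atoms.element)
        res_index.append(np.full(res_atoms.array_length(), new_id))
    return ProteinStructure(
        id=id,
        res_names=np.array(names),
        ca_coords=np.array(ca_list, dtype=float),
        atom_coords=np.concatenate(coords),
        atom_elements=np.concatenate(elements),
        atom_res_index=np.concatenate(res_index),
        plddt=np.array(plddt, dtype=float) if b_factor_is_plddt else None,
    )


def load_structure(path, format: str | None = None, b_factor_is_plddt: bool = False,
                   model: int = 1) -> ProteinStructure:
    """Read a PDB or mmCIF file into a :class:`ProteinStructure`.

    Residues are renumbered 1..N preserving file order; residues missing a
    Cα atom are dropped with a warning; HETATM records and all chains but
    the first are ignored.  With ``b_factor_is_plddt`` the B-factor column
    is interpreted as the AlphaFold per-residue confidence (pLDDT).
    """
    path = str(path)
    if format is None:
        format = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        f = PDBFile.read(path)
        atoms = f.get_structure(model=model, extra_fields=["b_factor"], altloc="first")
    elif format == "mmcif":
        from biotite.structure.io.pdbx import CIFFile, get_structure

        f = CIFFile.read(path)
        atoms = get_structure(f, model=model, extra_fields=["b_factor"], altloc="first")
    else:
        raise ValueError(f"unknown format {format!r}")
    import os

    stem = os.path.splitext(os.path.basename(path))[0]
    return _from_atom_array(atoms, id=stem, b_factor_is_plddt=b_factor_is_plddt)


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write the structure (all atoms) as a PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = len(structure.atom_coords)
    atoms = struc.AtomArray(n_atoms)
    atoms.coord = np.asarray(structure.atom_coords, dtype=np.float32)
    atoms.chain_id = np.full(n_atoms, "A")
    atoms.res_id = structure.atom_res_index
    atoms.res_name = structure.res_names[structure.atom_res_index - 1]
    atoms.hetero = np.zeros(n_atoms, dtype=bool)
    atoms.element = structure.atom_elements
    # name CA atoms so a round-trip recovers the trace; other atoms get
    # element-derived names
    names = np.array([e for e in structure.atom_elements], dtype="U4")
    ca_rows = _ca_atom_rows(structure)
    names[ca_rows] = "CA"
    atoms.atom_name = names
    atoms.set_annotation(
        "b_factor",
        (structure.plddt[structure.atom_res_index - 1]
         if structure.plddt is not None else np.zeros(n_atoms)),
    )
    f = PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def _ca_atom_rows(structure: ProteinStructure) -> np.ndarray:
    """Row index into atom_coords of the Cα atom of each residue."""
    tree = cKDTree(structure.atom_coords)
    _, idx = tree.query(structure.ca_coords)
    return np.asarray(idx, dtype=int)


def mean_plddt_pass(structure: ProteinStructure, threshold: float = 70.0) -> bool:
    """True iff the mean per-residue pLDDT is at or above ``threshold``."""
    if structure.plddt is None:
        raise ValueError("structure has no pLDDT scores")
    return bool(np.mean(structure.plddt) >= threshold)


def heavy_atom_contacts(
    structure: ProteinStructure, cutoff: float = 4.5, min_seq_sep: int = 3
) -> ContactMap:
    """Residue pairs with any heavy atoms within ``cutoff`` Å, more than
    ``min_seq_sep`` residues apart in sequence.

    Hydrogens are excluded.  This is both the loop-closure criterion for
    entanglement detection and the native-contact definition for the Gō
    model and the fraction-of-native-contacts order parameter.
    """
    mask = structure.heavy_atom_mask()
    coords = structure.atom_coords[mask]
    res_idx = structure.atom_res_index[mask]
    if len(coords) == 0:
        raise ValueError("empty structure")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    best: dict[tuple, float] = {}
    if len(pairs):
        ri = res_idx[pairs[:, 0]]
        rj = res_idx[pairs[:, 1]]
        lo = np.minimum(ri, rj)
        hi = np.maximum(ri, rj)
        keep = hi - lo > min_seq_sep
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        for i, j, dist in zip(lo[keep], hi[keep], d[keep]):
            key = (int(i), int(j))
            if dist < best.get(key, np.inf):
                best[key] = float(dist)
    contacts = sorted(best)
    return ContactMap(contacts=contacts, cutoff=cutoff, min_seq_sep=min_seq_sep,
                      min_dists=best)


def asphericity(structure_or_coords) -> float:
    """Relative shape anisotropy Δ ∈ [0, 1] from the gyration tensor.

    Δ = 1 − 3(λ1λ2 + λ2λ3 + λ3λ1)/(λ1 + λ2 + λ3)² with λ the gyration
    tensor eigenvalues; 0 for a sphere, 1 for a rod.  Degenerate point
    clouds return the limiting value instead of raising.
    """
    if isinstance(structure_or_coords, ProteinStructure):
        coords = structure_or_coords.ca_coords
    else:
        coords = np.asarray(structure_or_coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 positions")
    centred = coords - coords.mean(axis=0)
    gyr = centred.T @ centred / len(coords)
    lam = np.linalg.eigvalsh(gyr)
    trace = lam.sum()
    if trace <= 0:
        return 0.0  # all points coincide
    delta = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / trace**2
    return float(np.clip(delta, 0.0, 1.0))
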