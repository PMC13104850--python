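"""Detection of native non-covalent lasso entanglements (NCLEs).

A lasso entanglement is a backbone loop, closed by a non-covalent
residue–residue contact (i, j), through which one of the chain termini is
threaded.  Threading is quantified by the discretized Gaussian linking
number between the loop segment and each terminal tail: the partial
double sum

    g = (1/4π) Σ_m Σ_n (R_m − R_n)/|R_m − R_n|³ · (dR_m × dR_n)

over bond midpoints R and bond vectors dR of the Cα trace.  |g| near an
integer L means the tail winds L times through the loop; the sign encodes
chirality.  The N-tail sum runs over bonds 6..i−5 and the C-tail over
j+6..N−5 (1-based), so the five residues at each chain end and flanking
the loop are excluded; an empty range contributes exactly zero.

A loop is called entangled when |gN| or |gC| reaches the detection
threshold (0.6 by default).  Crossing residues — where the tail pierces
the loop plane — are located as the half-integer crossings of the
cumulative (partial) linking profile along the tail.  Slipknots, whose
crossings cancel, are excluded.  Degenerate NCLEs sharing the same
crossing pattern are clustered and represented by the shortest loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import ContactMap, ProteinStructure

__all__ = [
    "GaussLinkage",
    "Crossing",
    "NCLE",
    "EntangledRegionMask",
    "discretize_curve",
    "gauss_linking",
    "partial_linking_profile",
    "find_crossings",
    "is_slipknot",
    "detect_ncles",
    "cluster_ncles",
    "entangled_region_mask",
    "is_entangled_protein",
]

# 1-based summation limits: N-tail bonds 6..i-5, C-tail bonds j+6..N-5,
# loop bonds i..j-1 (bond l connects residues l and l+1).
_TAIL_EXCLUSION = 5


@dataclass(frozen=True)
class GaussLinkage:
    loop: tuple
    gN: float
    gC: float

    @property
    def g_max_abs(self) -> float:
        return max(abs(self.gN), abs(self.gC))


@dataclass(frozen=True)
class Crossing:
    residue: int
    sign: int
    terminus: str  # "N" or "C"


@dataclass
class NCLE:
    loop: tuple
    gN: float
    gC: float
    crossings: list
    representative: bool = False
    cluster_id: int = -1

    @property
    def loop_length(self) -> int:
        return self.loop[1] - self.loop[0]


@dataclass
class EntangledRegionMask:
    protein_id: str
    mask: np.ndarray  # bool, index 0 <-> residue 1
    source_loops: list = field(default_factory=list)

    def residues(self) -> np.ndarray:
        return np.flatnonzero(self.mask) + 1

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "protein": self.protein_id,
                "residue": np.arange(1, len(self.mask) + 1),
                "in_region": self.mask.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)


def discretize_curve(ca_coords: np.ndarray):
    """Bond midpoints R_l and bond vectors dR_l of a Cα trace."""
    r = np.asarray(ca_coords, dtype=float)
    mid = 0.5 * (r[:-1] + r[1:])
    dr = r[1:] - r[:-1]
    return mid, dr


def _partial_sum(mid, dr, tail_bonds, loop_bonds) -> np.ndarray:
    """Per-tail-bond contribution to g, summed over loop bonds.

    Returns an array aligned with ``tail_bonds``; its sum is g.
    """
    if len(tail_bonds) == 0 or len(loop_bonds) == 0:
        return np.zeros(len(tail_bonds))
    Rm = mid[tail_bonds][:, None, :]
    Rn = mid[loop_bonds][None, :, :]
    diff = Rm - Rn
    dist3 = np.linalg.norm(diff, axis=-1) ** 3
    cross = np.cross(dr[tail_bonds][:, None, :], dr[loop_bonds][None, :, :])
    integrand = np.einsum("mnk,mnk->mn", diff, cross) / dist3
    return integrand.sum(axis=1) / (4.0 * np.pi)


def _bond_ranges(i: int, j: int, n_res: int):
    """0-based bond index arrays (N-tail, loop, C-tail) for loop (i, j)."""
    # 1-based bond l (connecting residues l, l+1) maps to 0-based l-1.
    # N-tail: l in [6, i-5]; loop: l in [i, j-1]; C-tail: l in [j+6, N-5].
    n_tail = np.arange(_TAIL_EXCLUSION, max(i - _TAIL_EXCLUSION, _TAIL_EXCLUSION))
    loop = np.arange(i - 1, j - 1)
    c_tail = np.arange(j + _TAIL_EXCLUSION, max(n_res - _TAIL_EXCLUSION, j + _TAIL_EXCLUSION))
    return n_tail, loop, c_tail


def gauss_linking(ca_coords: np.ndarray, loop: tuple) -> GaussLinkage:
    """Gaussian linking numbers gN and gC of the loop (i, j) with the two
    terminal tails.  Empty tail ranges give exactly 0."""
    i, j = int(loop[0]), int(loop[1])
    ca = np.asarray(ca_coords, dtype=float)
    if i >= j:
        raise ValueError("loop requires i < j")
    if not (1 <= i and j <= len(ca)):
        raise ValueError("loop indices out of range")
    if not np.isfinite(ca).all():
        raise ValueError("non-finite coordinates")
    mid, dr = discretize_curve(ca)
    n_tail, loop_bonds, c_tail = _bond_ranges(i, j, len(ca))
    gN = float(_partial_sum(mid, dr, n_tail, loop_bonds).sum())
    gC = float(_partial_sum(mid, dr, c_tail, loop_bonds).sum())
    return GaussLinkage(loop=(i, j), gN=gN, gC=gC)


def partial_linking_profile(ca_coords: np.ndarray, loop: tuple, terminus: str):
    """Cumulative linking number along one tail.

    Returns ``(residues, cumulative_g)`` where ``cumulative_g[k]`` is the
    linking contribution of all tail bonds up to (and including) the bond
    starting at ``residues[k]``; the last value equals gN or gC exactly.
    For the N-tail the accumulation runs from the chain start toward the
    loop; for the C-tail from the loop toward the chain end.
    """
    i, j = int(loop[0]), int(loop[1])
    ca = np.asarray(ca_coords, dtype=float)
    mid, dr = discretize_curve(ca)
    n_tail, loop_bonds, c_tail = _bond_ranges(i, j, len(ca))
    bonds = n_tail if terminus == "N" else c_tail
    if len(bonds) == 0:
        raise ValueError(f"empty {terminus}-tail for loop {loop}")
    contrib = _partial_sum(mid, dr, bonds, loop_bonds)
    return bonds + 1, np.cumsum(contrib)  # 1-based residue of each bond


def find_crossings(profile, terminus: str = "N") -> list:
    """Crossing residues from a cumulative linking profile.

    A crossing is reported wherever the cumulative g passes through a
    half-integer level k + 0.5 (k ∈ ℤ, both signs), with the sign of the
    step that crossed it.  One pierce of the loop plane changes g by ±1,
    so each threading event produces exactly one half-integer crossing.
    """
    residues, cum = profile
    crossings: list[Crossing] = []
    prev = 0.0
    for res, cur in zip(residues, cum):
        lo, hi = (prev, cur) if cur >= prev else (cur, prev)
        # half-integer levels strictly inside (lo, hi]
        k_lo = int(np.floor(lo - 0.5))
        k_hi = int(np.floor(hi - 0.5))
        n_crossed = k_hi - k_lo
        sign = 1 if cur >= prev else -1
        for _ in range(n_crossed):
            crossings.append(Crossing(residue=int(res), sign=sign, terminus=terminus))
        prev = cur
    return crossings


def is_slipknot(crossings: list) -> bool:
    """True when a tail threads the loop and then retracts: at least two
    crossings of opposite sign on the same tail."""
    for term in ("N", "C"):
        signs = [c.sign for c in crossings if c.terminus == term]
        if len(signs) >= 2 and (1 in signs) and (-1 in signs):
            return True
    return False


def detect_ncles(
    structure: ProteinStructure,
    contact_map: ContactMap,
    threshold: float = 0.6,
) -> list:
    """All non-slipknot NCLEs of a structure.

    Every contact (i, j) is a candidate loop closure; the loop is
    entangled when |gN| or |gC| reaches ``threshold``.  Each detected
    NCLE carries the crossing residues of every tail that is entangled.
    """
    ca = structure.ca_coords
    out: list[NCLE] = []
    for (i, j) in contact_map.contacts:
        lk = gauss_linking(ca, (i, j))
        if lk.g_max_abs < threshold:
            continue
        crossings: list[Crossing] = []
        for term, g in (("N", lk.gN), ("C", lk.gC)):
            if abs(g) < threshold:
                continue
            prof = partial_linking_profile(ca, (i, j), term)
            crossings.extend(find_crossings(prof, term))
        if is_slipknot(crossings):
            continue
        out.append(NCLE(loop=(i, j), gN=lk.gN, gC=lk.gC, crossings=crossings))
    return out


def _same_cluster(a: NCLE, b: NCLE, tol: int = 5) -> bool:
    ca = sorted(a.crossings, key=lambda c: (c.terminus, c.residue))
    cb = sorted(b.crossings, key=lambda c: (c.terminus, c.residue))
    if len(ca) != len(cb):
        return False
    for x, y in zip(ca, cb):
        if x.terminus != y.terminus or x.sign != y.sign:
            return False
        if abs(x.residue - y.residue) > tol:
            return False
    return True


def cluster_ncles(ncles: list, tol: int = 5) -> list:
    """Group degenerate NCLEs and mark one representative per cluster.

    Two NCLEs are degenerate when they have the same crossing pattern
    (same termini and signs, residues within ±``tol`` positions).  The
    representative is the member with the shortest loop; ties go to the
    smallest loop start.  Returns the same NCLE objects with cluster_id
    and representative set, ordered by cluster then loop.
    """
    n = len(ncles)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            if _same_cluster(ncles[a], ncles[b], tol):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    roots: dict[int, list[int]] = {}
    for idx in range(n):
        roots.setdefault(find(idx), []).append(idx)
    out: list[NCLE] = []
    for cid, members in enumerate(sorted(roots.values(), key=lambda m: min(m))):
        rep = min(members, key=lambda k: (ncles[k].loop_length, ncles[k].loop[0]))
        for k in sorted(members):
            ncles[k].cluster_id = cid
            ncles[k].representative = k == rep
            out.append(ncles[k])
    return out


def entangled_region_mask(
    structure: ProteinStructure,
    ncles: list,
    buffer: int = 3,
    contact_cutoff: float = 4.5,
) -> EntangledRegionMask:
    """Residue mask of the natively entangled region.

    The region is the union of (1) all residues within ±``buffer``
    sequence positions of any loop-closing contact residue or crossing
    residue of a representative NCLE, and (2) all residues with any heavy
    atom within ``contact_cutoff`` Å of those key residues.  Windows are
    clipped at the chain ends.
    """
    n = structure.n_residues
    mask = np.zeros(n, dtype=bool)
    key_residues: set[int] = set()
    loops = []
    use = [x for x in ncles if x.representative] or list(ncles)
    for ncle in use:
        key_residues.update(ncle.loop)
        key_residues.update(c.residue for c in ncle.crossings)
        loops.append(ncle.loop)
    for res in key_residues:
        lo = max(1, res - buffer)
        hi = min(n, res + buffer)
        mask[lo - 1 : hi] = True
    if key_residues:
        heavy = structure.heavy_atom_mask()
        coords = structure.atom_coords[heavy]
        res_idx = structure.atom_res_index[heavy]
        key_atoms = np.isin(res_idx, list(key_residues))
        if key_atoms.any():
            from scipy.spatial import cKDTree

            tree = cKDTree(coords[key_atoms])
            d, _ = tree.query(coords)
            near = res_idx[d <= contact_cutoff]
            mask[np.unique(near) - 1] = True
    return EntangledRegionMask(protein_id=structure.id, mask=mask, source_loops=loops)


def is_entangled_protein(structure: ProteinStructure, contact_map: ContactMap,
                         threshold: float = 0.6) -> bool:
    """Binary protein-level entanglement indicator: at least one NCLE."""
    return len(detect_ncles(structure, contact_map, threshold)) > 0
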