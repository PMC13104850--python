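"""Trajectory order parameters Q and G, state clustering, misfolding.

Q is the fraction of native contacts formed in a frame: a native pair
(i, j) counts as formed when its Cα distance is at most 1.2× its native
distance (the boundary counts as formed).  G is the fraction of native
contacts whose loop, closed by that contact, has a different integer
linking number with either terminal tail than in the native reference —
the topological signature of entanglement misfolding.  Both are in
[0, 1], with Q(native) = 1 and G(native) = 0.

Conformations pooled over trajectories are clustered on standardized
(Q, G): k-means++ microstates, a lag-τ transition matrix between them,
and PCCA+ spectral lumping into metastable macrostates.  The native
macrostate is the one with the highest mean Q and lowest mean G; the
misfolding probability over an analysis window is

    P_mis = N_mis / (N_native + N_mis) × 100%

where N_mis counts frames in non-native macrostates that are still
near-native (Q ≥ q_floor) and N_native counts frames in the native
macrostate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .entanglement import gauss_linking

__all__ = [
    "FrameMetrics",
    "StateAssignment",
    "MisfoldingEstimate",
    "native_contact_distances",
    "reference_linking",
    "compute_q",
    "compute_g",
    "metrics_for_trajectory",
    "cluster_states",
    "pcca_plus",
    "misfolding_probability",
]


@dataclass
class StateAssignment:
    micro: np.ndarray  # per-frame microstate id
    macro: np.ndarray  # per-frame macrostate id
    native_macrostate: int
    centroids: np.ndarray  # microstate centroids in (Q, G)
    macro_of_micro: np.ndarray
    q: np.ndarray
    g: np.ndarray

    @property
    def n_macrostates(self) -> int:
        return int(self.macro_of_micro.max()) + 1

    def macro_populations(self) -> np.ndarray:
        return np.bincount(self.macro, minlength=self.n_macrostates) / len(self.macro)


@dataclass
class MisfoldingEstimate:
    n_mis: int
    n_native: int

    @property
    def p_mis(self) -> float:
        denom = self.n_mis + self.n_native
        return 100.0 * self.n_mis / denom if denom else 0.0


# kept for API symmetry with the per-frame metrics TSV
@dataclass
class FrameMetrics:
    frame: int
    Q: float
    G: float


def native_contact_distances(ca_coords: np.ndarray, contacts) -> np.ndarray:
    """Native Cα–Cα distances r_ij^0 for each contact pair."""
    pairs = np.asarray(list(contacts), dtype=int)
    return np.linalg.norm(
        ca_coords[pairs[:, 0] - 1] - ca_coords[pairs[:, 1] - 1], axis=1
    )


def compute_q(frame_coords: np.ndarray, contacts, native_dists: np.ndarray,
              factor: float = 1.2) -> float:
    """Fraction of native contacts formed: r_ij(t) ≤ factor × r_ij^0."""
    pairs = np.asarray(list(contacts), dtype=int)
    if len(pairs) == 0:
        raise ValueError("empty native contact list")
    d = np.linalg.norm(
        frame_coords[pairs[:, 0] - 1] - frame_coords[pairs[:, 1] - 1], axis=1
    )
    return float(np.mean(d <= factor * np.asarray(native_dists)))


def reference_linking(ca_coords: np.ndarray, contacts) -> np.ndarray:
    """Rounded native (gN, gC) for every native-contact loop; shape (n, 2)."""
    out = np.empty((len(contacts), 2), dtype=int)
    for k, (i, j) in enumerate(contacts):
        lk = gauss_linking(ca_coords, (i, j))
        out[k] = (round(lk.gN), round(lk.gC))
    return out


def compute_g(frame_coords: np.ndarray, contacts, ref_linking: np.ndarray) -> float:
    """Fraction of native contacts with changed integer linking.

    Every native contact is evaluated, formed or not in the frame; a
    contact counts as changed when round(gN) or round(gC) of its loop
    differs from the native reference.
    """
    contacts = list(contacts)
    if len(contacts) != len(ref_linking):
        raise ValueError("reference linking does not match contact list")
    changed = 0
    for k, (i, j) in enumerate(contacts):
        lk = gauss_linking(frame_coords, (i, j))
        if round(lk.gN) != ref_linking[k, 0] or round(lk.gC) != ref_linking[k, 1]:
            changed += 1
    return changed / len(contacts)


def metrics_for_trajectory(frames: np.ndarray, contacts, native_dists,
                           ref_linking, factor: float = 1.2):
    """Per-frame (Q, G) for a stack of Cα frames; returns an (n, 2) array."""
    out = np.empty((len(frames), 2))
    for t, coords in enumerate(frames):
        out[t, 0] = compute_q(coords, contacts, native_dists, factor)
        out[t, 1] = compute_g(coords, contacts, ref_linking)
    return out


def _transition_matrix(micro: np.ndarray, n_states: int, lag: int,
                       traj_bounds=None, reg: float = 1e-8) -> np.ndarray:
    """Row-stochastic lag-τ transition matrix from microstate sequences.

    ``traj_bounds`` lists (start, stop) index ranges of individual
    trajectories so that counts never cross a trajectory boundary;
    symmetrized counts plus a small regularizer keep the chain ergodic.
    """
    counts = np.full((n_states, n_states), reg)
    bounds = traj_bounds or [(0, len(micro))]
    for lo, hi in bounds:
        seg = micro[lo:hi]
        if len(seg) > lag:
            np.add.at(counts, (seg[:-lag], seg[lag:]), 1.0)
    counts = 0.5 * (counts + counts.T)  # detailed-balance estimate
    return counts / counts.sum(axis=1, keepdims=True)


def pcca_plus(T: np.ndarray, n_macro: int) -> np.ndarray:
    """PCCA+ spectral lumping of a row-stochastic matrix.

    Uses the inner-simplex algorithm: the leading ``n_macro`` right
    eigenvectors span a simplex whose vertices are the metastable sets;
    memberships follow from the linear map onto barycentric coordinates.
    Returns the hard macrostate label of each microstate.
    """
    evals, evecs = np.linalg.eig(T)
    order = np.argsort(-evals.real)
    X = evecs[:, order[:n_macro]].real
    # normalize sign/scale: first column is the stationary (constant) one
    X[:, 0] = 1.0
    # inner-simplex vertex search (Deuflhard & Weber)
    verts = [int(np.argmax(np.linalg.norm(X - X.mean(axis=0), axis=1)))]
    Y = X - X[verts[0]]
    for _ in range(1, n_macro):
        dist = np.linalg.norm(Y, axis=1)
        v = int(np.argmax(dist))
        verts.append(v)
        norm = Y[v] / (np.linalg.norm(Y[v]) ** 2)
        Y = Y - np.outer(Y @ norm, Y[v])
    A = np.linalg.pinv(X[verts])
    chi = X @ A
    return np.argmax(chi, axis=1)


def _auto_n_macro(T: np.ndarray, k_max: int = 8) -> int:
    """Macrostate count from the largest gap in the sorted eigenvalues."""
    evals = np.sort(np.linalg.eigvals(T).real)[::-1]
    k_max = min(k_max, len(evals) - 1)
    if k_max < 2:
        return 1
    gaps = evals[1:k_max] - evals[2 : k_max + 1]
    lead_gap = evals[0] - evals[1]
    best = int(np.argmax(gaps)) + 2
    # a dominant first gap means a single metastable set
    return 1 if lead_gap > gaps.max() * 2.0 and evals[1] < 0.5 else best


def cluster_states(
    qg: np.ndarray,
    k_micro: int = 100,
    lag: int = 10,
    n_macro: int | str = "auto",
    seed: int = 0,
    traj_bounds=None,
) -> StateAssignment:
    """Microstate/macrostate assignment of pooled (Q, G) frames.

    K-means++ on standardized (Q, G) gives ``k_micro`` microstates (the
    count is reduced with a warning when there are fewer frames); a
    lag-τ transition matrix between microstates is lumped into
    macrostates with PCCA+.  ``n_macro="auto"`` picks the count at the
    largest spectral gap.  The native macrostate maximizes mean Q − mean
    G over its frames.
    """
    from sklearn.cluster import KMeans

    qg = np.asarray(qg, dtype=float)
    if qg.ndim != 2 or qg.shape[1] != 2:
        raise ValueError("qg must be (n_frames, 2)")
    n = len(qg)
    if n < k_micro:
        warnings.warn(f"only {n} frames; reducing k_micro from {k_micro}")
        k_micro = max(1, n // 2)
    sd = qg.std(axis=0)
    sd[sd == 0] = 1.0
    z = (qg - qg.mean(axis=0)) / sd
    km = KMeans(n_clusters=k_micro, init="k-means++", n_init=10, random_state=seed)
    micro = km.fit_predict(z)
    T = _transition_matrix(micro, k_micro, lag, traj_bounds)
    if n_macro == "auto":
        n_macro = _auto_n_macro(T)
    n_macro = int(n_macro)
    if n_macro <= 1:
        macro_of_micro = np.zeros(k_micro, dtype=int)
    else:
        macro_of_micro = pcca_plus(T, n_macro)
    macro = macro_of_micro[micro]
    # native macrostate: highest mean Q, lowest mean G
    scores = []
    for m in range(int(macro_of_micro.max()) + 1):
        sel = macro == m
        scores.append(qg[sel, 0].mean() - qg[sel, 1].mean() if sel.any() else -np.inf)
    native = int(np.argmax(scores))
    centroids = km.cluster_centers_ * sd + qg.mean(axis=0)
    return StateAssignment(
        micro=micro,
        macro=macro,
        native_macrostate=native,
        centroids=centroids,
        macro_of_micro=macro_of_micro,
        q=qg[:, 0],
        g=qg[:, 1],
    )


def misfolding_probability(
    assignment: StateAssignment,
    window: slice | None = None,
    q_floor: float = 0.6,
) -> MisfoldingEstimate:
    """P_mis over an analysis window (default: all frames).

    Frames of the native macrostate count toward N_native; frames of
    non-native macrostates with Q ≥ ``q_floor`` (near-native misfolded)
    count toward N_mis.
    """
    sl = window if window is not None else slice(None)
    macro = assignment.macro[sl]
    q = assignment.q[sl]
    if len(macro) == 0:
        raise ValueError("empty analysis window")
    native = macro == assignment.native_macrostate
    mis = (~native) & (q >= q_floor)
    return MisfoldingEstimate(n_mis=int(mis.sum()), n_native=int(native.sum()))
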