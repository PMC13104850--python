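"""Synthetic-data generators with known ground truth.

Every stage of the pipeline has a generator here that emulates the
statistical or geometric structure of its real input — threaded and
unthreaded backbone curves with a planted linking number, mini-protein
Cα traces with or without a planted lasso entanglement, LiP-MS-style
peptide tables with planted protein- and residue-level odds ratios,
two-population (Q, G) trajectory series with planted state occupancies,
and paired per-site SASA ensembles with planted mean shifts.

Generators are deterministic in their seed and return the data together
with a plain ``dict`` of ground truth; the ground truth is written to a
sidecar JSON by the CLI, never into the data files themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structures import ProteinStructure

__all__ = [
    "gen_loop_curve",
    "gen_mini_protein",
    "gen_peptide_table",
    "gen_qg_series",
    "gen_sasa_ensembles",
]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _min_nonadjacent_dist(ca: np.ndarray, skip: int = 2) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(ca)
    d, idx = tree.query(ca, k=min(len(ca), skip + 2))
    best = np.inf
    for row in range(len(ca)):
        for col in range(1, d.shape[1]):
            if abs(idx[row, col] - row) > skip:
                best = min(best, d[row, col])
    return best


def gen_loop_curve(
    n_loop: int = 20,
    threaded: bool = True,
    turns: int = 1,
    chirality: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_tail: int = 26,
    radius: float = 5.0,
    rotate: bool = True,
    max_retries: int = 20,
):
    """Closed loop plus C-terminal tail with a planted linking number.

    The loop is a circle of ``n_loop`` points winding ``turns`` times in
    the xy-plane (sense set by ``chirality``); the tail either descends
    through the loop center (``threaded``, linking = chirality × turns)
    or outside the loop (linking 0).  Gaussian positional noise and a
    random rigid rotation are applied.  Returns
    ``(ProteinStructure, truth_dict)`` with the planted linking number,
    the loop span and the tail residue at which the plane is pierced.
    """
    if n_loop < 12:
        raise ValueError("n_loop must be >= 12")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        # loop winding sense chosen so chirality=+1 yields positive g for
        # the descending threaded tail
        theta = np.linspace(0.0, 2 * np.pi * turns, n_loop) * (-np.sign(chirality))
        # slight radial/vertical drift keeps multi-turn windings apart
        drift = np.linspace(0.0, 0.6 * max(turns - 1, 0), n_loop)
        loop_pts = np.stack(
            [
                (radius + drift) * np.cos(theta),
                (radius + drift) * np.sin(theta),
                0.05 * drift,
            ],
            axis=1,
        )
        # Tail-exclusion windows drop the 6 bonds after the loop and the
        # final 4 bonds, so the geometry puts the uninformative approach
        # into those windows: a vertical rise at the rim (excluded), an
        # arc over to high above the center, then a deep axial descent
        # (threaded) or a descent far outside the loop (unthreaded).
        end = loop_pts[-1]
        rim_rise = np.stack(
            [end + np.array([0.0, 0.0, dz]) for dz in (2.5, 5.0, 7.5, 10.0, 12.5, 15.0)]
        )
        if threaded:
            over = np.stack(
                [
                    [end[0] * 0.6, end[1] * 0.6, 17.5],
                    [0.0, 0.0, 19.0],
                ]
            )
            depth = 2.0 * (n_tail - 1)
            z = np.linspace(19.0 - 2.0, 19.0 - depth, n_tail - 1)
            tail = np.stack([np.zeros(len(z)), np.zeros(len(z)), z], axis=1)
        else:
            x_out = radius + 12.0
            over = np.stack(
                [
                    [end[0] + (x_out - end[0]) * 0.5, end[1] * 0.5, 17.0],
                    [x_out, 0.0, 16.0],
                ]
            )
            z = np.linspace(14.0, 16.0 - 2.0 * (n_tail - 1), n_tail - 1)
            tail = np.stack([np.full(len(z), x_out), np.zeros(len(z)), z], axis=1)
        ca = np.concatenate([loop_pts, rim_rise, over, tail], axis=0)
        if noise_sd > 0:
            ca = ca + rng.normal(scale=noise_sd, size=ca.shape)
        if rotate:
            ca = ca @ _random_rotation(rng).T
        if noise_sd == 0 or _min_nonadjacent_dist(ca) > 4 * noise_sd:
            break
    n = len(ca)
    loop_span = (1, n_loop)
    # tail residue nearest the loop plane (z = 0 before rotation)
    pierce = (
        int(n_loop + len(rim_rise) + len(over) + np.argmin(np.abs(z))) + 1
        if threaded
        else None
    )
    truth = {
        "linking_number": int(np.sign(chirality) * turns) if threaded else 0,
        "loop": loop_span,
        "crossing_residue": pierce,
        "n_residues": n,
    }
    return ProteinStructure.from_ca(ca, id=f"loop_curve_s{seed}"), truth


def _ideal_helix(n: int, rise: float = 1.5, radius: float = 2.3,
                 twist_deg: float = 100.0) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(twist_deg)
    z = np.arange(n) * rise
    return np.stack([radius * np.cos(t), radius * np.sin(t), z], axis=1)


def _resample_arc(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at (approximately) constant arc spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_out = max(int(round(s[-1] / spacing)) + 1, 2)
    si = np.linspace(0.0, s[-1], n_out)
    out = np.stack([np.interp(si, s, points[:, k]) for k in range(3)], axis=1)
    return out


def gen_mini_protein(motif: str = "helix_hairpin", seed: int = 0, jitter: float = 0.05):
    """40–60 residue Cα trace, optionally with one planted NCLE.

    ``helix_hairpin``: two packed antiparallel α-helices joined by a
    turn; topologically trivial.  ``entangled_hairpin``: an N-terminal
    segment threads a 16-residue loop whose ends are closed by a Cα
    contact; the planted loop-closing contact and crossing residue are
    returned in the truth dict and the construction is verified to have
    |g| ≥ 0.6.  Bond lengths are ~3.8 Å throughout.
    """
    rng = np.random.default_rng(seed)
    if motif == "helix_bundle":
        # three packed antiparallel helices; the best-behaved fold/unfold
        # fixture for the Gō model (well-anchored helix ends)
        nh = 17
        offsets = [np.array([0.0, 0.0, 0.0]), np.array([8.8, 0.0, 0.0]),
                   np.array([4.4, 7.6, 0.0])]
        # turn control-point offsets chosen so that every backbone angle
        # stays below ~157 deg (clear of the collinear singularity) with
        # ~3.8 A bonds and no steric clash
        bulges = [np.array([0.195, 7.962, 0.75]),
                  np.array([-3.847, -2.294, -6.629])]
        pieces = []
        prev_end = None
        for k in range(3):
            h = _ideal_helix(nh)
            if k % 2 == 1:
                h = h @ np.diag([1.0, -1.0, -1.0])
                h += np.array([0.0, 0.0, (nh - 1) * 1.5])
            h = h + offsets[k]
            if prev_end is not None:
                a, b = prev_end, h[0]
                ctrl = 0.5 * (a + b) + bulges[k - 1]
                t = np.linspace(0.0, 1.0, 32)[:, None]
                bez = (1 - t) ** 2 * a + 2 * (1 - t) * t * ctrl + t**2 * b
                pieces.append(_resample_arc(bez, 3.8)[1:-1])
            pieces.append(h)
            prev_end = h[-1]
        ca = np.concatenate(pieces, axis=0)
        truth = {"motif": motif, "entangled": False, "loop_contact": None,
                 "crossing_residue": None}
    elif motif == "helix_hairpin":
        h1 = _ideal_helix(18)
        h2 = _ideal_helix(18)
        # antiparallel second helix, packed ~9 Å away
        h2 = h2 @ np.diag([1.0, -1.0, -1.0])
        h2 += np.array([9.0, 0.0, h1[-1, 2] + 0.0])
        # curved turn (quadratic Bezier) connecting helix ends; keeps all
        # backbone angles well away from collinear
        a, b = h1[-1], h2[0]
        ctrl = 0.5 * (a + b) + np.array([0.0, 7.0, 5.0])
        t = np.linspace(0.0, 1.0, 24)[:, None]
        bez = (1 - t) ** 2 * a + 2 * (1 - t) * t * ctrl + t**2 * b
        turn = _resample_arc(bez, 3.8)[1:-1]
        ca = np.concatenate([h1, turn, h2], axis=0)
        truth = {"motif": motif, "entangled": False, "loop_contact": None,
                 "crossing_residue": None}
    elif motif == "entangled_hairpin":
        n_loop = 12
        radius = 3.8 * n_loop / (2 * np.pi)  # ~7.3 Å, 3.8 Å spacing
        # 5-residue leader lies flat far below the loop; its bonds fall
        # inside the N-terminal exclusion window of the linking sums, so
        # the measured thread starts already 22 Å beneath the loop plane
        leader = np.stack(
            [[3.8 * (4 - k), 0.0, -22.0] for k in range(5)], axis=0
        )
        # thread ascends through the loop center
        n_thread = 12
        z = np.linspace(-22.0 + 3.8, 20.0, n_thread)
        thread = np.stack([np.zeros(n_thread), np.zeros(n_thread), z], axis=1)
        # connector arcs from the thread top outward and down to the rim
        raw = np.stack(
            [
                thread[-1],
                [radius * 0.7, -3.5, 15.0],
                [radius + 3.0, -3.0, 8.0],
                [radius + 1.0, 0.0, 2.5],
                [radius, 0.0, 0.0],
            ],
            axis=0,
        )
        conn = _resample_arc(raw, 3.8)[1:-1]
        theta = np.linspace(0.0, 2 * np.pi * (n_loop - 1) / n_loop, n_loop)
        loop_pts = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                             np.zeros(n_loop)], axis=1)
        # C-terminal extension leaves the loop radially in-plane; it never
        # threads, so the loop's C-tail linking stays near zero
        last = loop_pts[-1]
        out_dir = last[:2] / np.linalg.norm(last[:2])
        ext = np.stack(
            [np.r_[last[:2] + out_dir * 3.8 * k, 1.5] for k in range(1, 11)], axis=0
        )
        ca = np.concatenate([leader, thread, conn, loop_pts, ext], axis=0)
        i = len(leader) + n_thread + len(conn) + 1  # first loop residue
        j = i + n_loop - 1                          # last; 3.8 Å from first
        crossing = len(leader) + int(np.argmin(np.abs(z))) + 1
        truth = {"motif": motif, "entangled": True, "loop_contact": (i, j),
                 "crossing_residue": crossing}
    else:
        raise ValueError(f"unknown motif {motif!r}")
    if jitter > 0:
        ca = ca + rng.normal(scale=jitter, size=ca.shape)
    ca = ca @ _random_rotation(rng).T
    ca = ca - ca.mean(axis=0)
    truth["n_residues"] = len(ca)
    return ProteinStructure.from_ca(ca, id=f"{motif}_s{seed}"), truth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gen_peptide_table(
    n_proteins: int = 2256,
    prevalence_exposed: float = 0.218,
    prevalence_unexposed: float = 0.123,
    frac_entangled: float = 0.747,
    length_distribution: tuple = (5.9, 0.45),
    residue_enrichment: float = 1.62,
    seed: int = 0,
    beta: tuple | None = None,
    confounded: bool = False,
    mean_peptides: float = 6.0,
    fc_threshold: float = 5.0,
    alpha: float = 0.05,
):
    """LiP-MS-style peptide and annotation tables with planted odds ratios.

    Per protein: a length (lognormal, ``length_distribution`` = (μ, σ)
    of log length, clipped to [60, 1200]), a binary entanglement flag, a
    contiguous entangled region (~20% of the chain, entangled proteins
    only) and a set of tryptic/half-tryptic peptides.  A protein planted
    as "changed" receives 1–3 significant peptides (|fold change| >
    ``fc_threshold``, adjusted p < ``alpha``); significant sites land
    inside the entangled region with the odds implied by
    ``residue_enrichment``.

    Two outcome models: prevalence mode (default) draws the changed flag
    with ``prevalence_exposed`` / ``prevalence_unexposed``; logistic mode
    (``beta`` = (β0, β1, β2)) uses p = σ(β0 + β1·E + β2·L*) with L* the
    standardized log-scale-free length, and ``confounded=True``
    additionally makes length drive the entanglement flag, so that the
    crude odds ratio is biased while the adjusted one is not.

    Returns ``(peptides_df, annotations_df, truth_dict)``.
    """
    for name, val in (("prevalence_exposed", prevalence_exposed),
                      ("prevalence_unexposed", prevalence_unexposed),
                      ("frac_entangled", frac_entangled)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    rng = np.random.default_rng(seed)
    mu, sg = length_distribution
    lengths = np.clip(np.round(np.exp(rng.normal(mu, sg, n_proteins))), 60, 1200).astype(int)
    l_std = (lengths - lengths.mean()) / lengths.std()

    if confounded:
        entangled = rng.random(n_proteins) < _sigmoid(
            np.log(frac_entangled / (1 - frac_entangled)) + 1.5 * l_std
        )
    else:
        entangled = rng.random(n_proteins) < frac_entangled

    if beta is not None:
        b0, b1, b2 = beta
        p_changed = _sigmoid(b0 + b1 * entangled + b2 * l_std)
    else:
        p_changed = np.where(entangled, prevalence_exposed, prevalence_unexposed)
    changed = rng.random(n_proteins) < p_changed

    # entangled region: contiguous ~20% stretch
    region_frac = 0.2
    reg_len = np.maximum((region_frac * lengths).astype(int), 9)
    reg_start = np.array(
        [rng.integers(4, max(L - rl - 3, 5)) for L, rl in zip(lengths, reg_len)]
    )
    reg_start = np.where(entangled, reg_start, 0)
    reg_end = np.where(entangled, reg_start + reg_len - 1, 0)

    rows = []
    for k in range(n_proteins):
        pid = f"P{k:05d}"
        L = lengths[k]
        n_pep = rng.poisson(mean_peptides) + 1
        for _ in range(n_pep):
            plen = int(rng.integers(7, 25))
            start = int(rng.integers(1, max(L - plen, 2)))
            rows.append(
                (pid, start, start + plen - 1, "tryptic", "none",
                 float(rng.normal(1.0, 0.8)), float(rng.uniform(alpha, 1.0)))
            )
        if changed[k]:
            rho = reg_len[k] / L if entangled[k] else 0.0
            p_in = residue_enrichment * rho / (1 - rho + residue_enrichment * rho)
            for _ in range(int(rng.integers(1, 4))):
                if entangled[k] and rng.random() < p_in:
                    site = int(rng.integers(reg_start[k], reg_end[k] + 1))
                else:
                    # outside the region (or anywhere for non-entangled)
                    while True:
                        site = int(rng.integers(1, L + 1))
                        if not (entangled[k] and reg_start[k] <= site <= reg_end[k]):
                            break
                plen = int(rng.integers(7, 25))
                fc = float(rng.choice([-1, 1]) * (fc_threshold + rng.exponential(4.0)))
                adj_p = float(rng.uniform(0.0, alpha * 0.9))
                if rng.random() < 0.5:
                    # half-tryptic: PK cut at the site
                    if rng.random() < 0.5 and site + plen - 1 <= L:
                        rows.append((pid, site, site + plen - 1, "half_tryptic",
                                     "start", fc, adj_p))
                    else:
                        s = max(1, site - plen + 1)
                        rows.append((pid, s, site, "half_tryptic", "end", fc, adj_p))
                else:
                    # tryptic with the site central
                    half = plen // 2
                    s = max(1, min(site - half, L - plen + 1))
                    rows.append((pid, s, s + plen - 1, "tryptic", "none", fc, adj_p))

    peptides = pd.DataFrame(
        rows, columns=["protein", "start", "end", "kind", "pk_terminus",
                       "fold_change", "adj_p"],
    )
    annotations = pd.DataFrame(
        {
            "protein": [f"P{k:05d}" for k in range(n_proteins)],
            "length": lengths,
            "entangled": entangled.astype(int),
            "region_start": reg_start,
            "region_end": reg_end,
        }
    )
    a = int(np.sum(entangled & changed))
    b = int(np.sum(entangled & ~changed))
    c = int(np.sum(~entangled & changed))
    d = int(np.sum(~entangled & ~changed))
    truth = {
        "planted_protein_or": (
            (prevalence_exposed / (1 - prevalence_exposed))
            / (prevalence_unexposed / (1 - prevalence_unexposed))
            if beta is None
            else float(np.exp(beta[1]))
        ),
        "beta": None if beta is None else list(beta),
        "confounded": confounded,
        "planted_residue_or": residue_enrichment,
        "changed": {f"P{k:05d}": bool(changed[k]) for k in range(n_proteins)},
        "counts": {"a": a, "b": b, "c": c, "d": d},
    }
    return peptides, annotations, truth


def gen_qg_series(
    state_means,
    populations,
    n_frames: int = 5000,
    noise_sd: float = 0.03,
    seed: int = 0,
    dwell: float = 20.0,
):
    """Markov-switching Gaussian mixture over (Q, G) with planted occupancies.

    States dwell ``dwell`` frames on average and are left by resampling
    from the stationary distribution, so the planted ``populations`` are
    exactly stationary.  Emissions are isotropic Gaussians clipped to
    [0, 1]².  Returns ``(metrics_df, truth_dict)`` with per-frame true
    state labels.
    """
    means = np.asarray(state_means, dtype=float)
    pops = np.asarray(populations, dtype=float)
    if not np.isclose(pops.sum(), 1.0):
        raise ValueError("populations must sum to 1")
    if len(means) > 1:
        dmin = np.min(
            [np.linalg.norm(means[a] - means[b])
             for a in range(len(means)) for b in range(a + 1, len(means))]
        )
        if dmin < noise_sd:
            import warnings

            warnings.warn("state means closer than noise; recovery not guaranteed")
    rng = np.random.default_rng(seed)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(len(pops), p=pops)
    switch = rng.random(n_frames) < 1.0 / dwell
    draws = rng.choice(len(pops), size=n_frames, p=pops)
    for t in range(1, n_frames):
        states[t] = draws[t] if switch[t] else states[t - 1]
    qg = means[states] + rng.normal(scale=noise_sd, size=(n_frames, 2))
    qg = np.clip(qg, 0.0, 1.0)
    df = pd.DataFrame({"frame": np.arange(n_frames), "Q": qg[:, 0], "G": qg[:, 1]})
    occ = np.bincount(states, minlength=len(pops)) / n_frames
    truth = {
        "labels": states,
        "populations": pops.tolist(),
        "realized_populations": occ.tolist(),
        "state_means": means.tolist(),
    }
    return df, truth


def gen_sasa_ensembles(
    n_native: int = 200,
    n_mis: int = 200,
    n_sites: int = 5,
    shift_sites=(0,),
    shift_magnitude: float = 0.0,
    seed: int = 0,
    base_mean: float = 60.0,
    sd: float = 8.0,
):
    """Paired per-site window-SASA ensembles with planted mean shifts.

    Returns ``(native, misfolded, truth)`` where the arrays are
    (n_conformations, n_sites) in Å² and the misfolded ensemble's mean is
    shifted by ``shift_magnitude`` Å² at ``shift_sites`` only.
    """
    shift_sites = tuple(shift_sites)
    if any(s < 0 or s >= n_sites for s in shift_sites):
        raise ValueError("shift_sites out of range")
    rng = np.random.default_rng(seed)
    native = rng.normal(base_mean, sd, size=(n_native, n_sites))
    mis = rng.normal(base_mean, sd, size=(n_mis, n_sites))
    shift = np.zeros(n_sites)
    if shift_magnitude != 0.0:
        shift[list(shift_sites)] = shift_magnitude
    mis = mis + shift
    truth = {"shift_sites": list(shift_sites), "shift_magnitude": shift_magnitude,
             "sd": sd}
    return np.maximum(native, 0.0), np.maximum(mis, 0.0), truth
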