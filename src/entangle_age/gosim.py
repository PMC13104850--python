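"""Cα Gō-model construction and temperature-quench refolding.

Each residue is one bead at its Cα position.  The native structure
defines the force field: harmonic bonds and angles at their native
values, 1- and 3-fold cosine dihedrals centred on the native torsions,
a 12-10 Lennard-Jones well of uniform depth ε on every native-contact
pair (minimum at the native separation), and a purely repulsive r⁻¹²
wall between all other bead pairs.  Because only native interactions
attract, the global minimum is the native fold; misfolded states arise
from topological traps, not energetic frustration.

The refolding protocol mirrors a temperature-quench experiment: a leg
at 600 K unfolds the chain, then the thermostat is dropped to 300 K and
the chain refolds (or misfolds).  Dynamics are Langevin (BAOAB
splitting) with a 15 fs time step and 0.05 ps⁻¹ friction; frames are
saved every 5000 steps.  Production scale in the source analysis is 50
trajectories × 1.5 μs per protein; the desk-scale defaults here are 10
trajectories × 50 ns, suitable for ≤60-residue fixtures.

Internal units: kcal/mol, Å, amu, AKMA time (1 tu = 48.888 fs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .structures import ContactMap, ProteinStructure

__all__ = [
    "GoModel",
    "QuenchProtocol",
    "Trajectory",
    "build_go_model",
    "minimize",
    "run_leg",
    "run_quench",
    "mirror_flag",
]

KB = 0.0019872041  # kcal/mol/K
TU_FS = 48.88821  # one AKMA time unit in fs

# force-field constants (kcal/mol based); ε calibrated so the bundled
# 40-residue helix-hairpin fixture is stable at 300 K and unfolds at 600 K
K_BOND = 50.0        # kcal/mol/Å²
K_ANGLE = 20.0       # kcal/mol/rad²
K_DIHED_1 = 0.5      # kcal/mol
K_DIHED_3 = 0.25     # kcal/mol
EPS_NATIVE = 1.2     # kcal/mol, native 12-10 well depth
EPS_REP = 1.0        # kcal/mol, non-native wall
SIGMA_REP = 4.0      # Å
BEAD_MASS = 110.0    # amu, average residue


@dataclass
class GoModel:
    n_beads: int
    x0: np.ndarray              # native Cα coordinates, Å
    bond_r0: np.ndarray         # (n-1,)
    angle_t0: np.ndarray        # (n-2,) radians
    dihed_p0: np.ndarray        # (n-3,) radians
    native_pairs: np.ndarray    # (m, 2) 0-based bead indices
    native_sigma: np.ndarray    # (m,) native separations, Å
    rep_pairs: np.ndarray       # (k, 2) non-native pairs, |i-j| >= 3
    eps_native: float = EPS_NATIVE
    masses: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.masses is None:
            self.masses = np.full(self.n_beads, BEAD_MASS)


@dataclass
class QuenchProtocol:
    t_unfold_ns: float = 15.0
    T_unfold: float = 600.0
    T_quench: float = 300.0
    t_traj_ns: float = 50.0
    dt_fs: float = 15.0
    friction_ps: float = 0.05
    n_traj: int = 10
    save_stride: int = 5000

    def __post_init__(self):
        for name in ("t_unfold_ns", "T_unfold", "T_quench", "t_traj_ns",
                     "dt_fs", "friction_ps", "save_stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    frames: np.ndarray          # (n_frames, n_beads, 3) Å
    temperatures: np.ndarray    # thermostat setpoint per frame
    leg: np.ndarray             # 0 = unfold leg, 1 = quench leg
    dt_fs: float
    save_stride: int

    @property
    def frame_interval_ns(self) -> float:
        return self.dt_fs * self.save_stride * 1e-6


def _angles(x: np.ndarray) -> np.ndarray:
    b1 = x[1:-1] - x[:-2]
    b2 = x[2:] - x[1:-1]
    cos = -np.einsum("ij,ij->i", b1, b2) / (
        np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)
    )
    return np.arccos(np.clip(cos, -1.0, 1.0))


def _dihedrals(x: np.ndarray) -> np.ndarray:
    b1 = x[1:-2] - x[:-3]
    b2 = x[2:-1] - x[1:-2]
    b3 = x[3:] - x[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    xx = np.einsum("ij,ij->i", n1, n2)
    yy = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(yy, xx)


def build_go_model(structure: ProteinStructure, contact_map: ContactMap,
                   eps_native: float = EPS_NATIVE) -> GoModel:
    """Construct the Cα Gō model from a structure and its contact map.

    Native pairs are exactly the contact-map pairs; all equilibrium
    values (bond lengths, angles, torsions, pair separations) are taken
    from the native coordinates, so the native configuration is at (or
    very near) a local minimum by construction.
    """
    x0 = np.asarray(structure.ca_coords, dtype=float)
    n = len(x0)
    if n < 5:
        raise ValueError("chain too short for a Gō model (need >= 5 residues)")
    pairs = contact_map.pairs_array() - 1  # to 0-based
    sigma = np.linalg.norm(x0[pairs[:, 0]] - x0[pairs[:, 1]], axis=1)
    native_set = {(int(i), int(j)) for i, j in pairs}
    rep = [
        (i, j)
        for i in range(n)
        for j in range(i + 3, n)
        if (i, j) not in native_set
    ]
    return GoModel(
        n_beads=n,
        x0=x0.copy(),
        bond_r0=np.linalg.norm(np.diff(x0, axis=0), axis=1),
        angle_t0=_angles(x0),
        dihed_p0=_dihedrals(x0),
        native_pairs=pairs.astype(np.int64),
        native_sigma=sigma,
        rep_pairs=np.asarray(rep, dtype=np.int64).reshape(-1, 2),
        eps_native=float(eps_native),
    )


@njit(cache=True)
def _forces_into(x, f, bond_r0, angle_t0, dihed_p0, npairs, nsigma, rpairs,
                 eps_nat, eps_rep, sigma_rep, k_bond, k_angle, kd1, kd3):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    energy = 0.0
    # bonds
    for k in range(n - 1):
        dx0 = x[k + 1, 0] - x[k, 0]
        dx1 = x[k + 1, 1] - x[k, 1]
        dx2 = x[k + 1, 2] - x[k, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - bond_r0[k]
        energy += k_bond * dr * dr
        c = 2.0 * k_bond * dr / r
        f[k, 0] += c * dx0
        f[k, 1] += c * dx1
        f[k, 2] += c * dx2
        f[k + 1, 0] -= c * dx0
        f[k + 1, 1] -= c * dx1
        f[k + 1, 2] -= c * dx2
    # angles
    for k in range(n - 2):
        a0 = x[k, 0] - x[k + 1, 0]
        a1 = x[k, 1] - x[k + 1, 1]
        a2 = x[k, 2] - x[k + 1, 2]
        b0 = x[k + 2, 0] - x[k + 1, 0]
        b1_ = x[k + 2, 1] - x[k + 1, 1]
        b2_ = x[k + 2, 2] - x[k + 1, 2]
        na = np.sqrt(a0 * a0 + a1 * a1 + a2 * a2)
        nb = np.sqrt(b0 * b0 + b1_ * b1_ + b2_ * b2_)
        cos_t = (a0 * b0 + a1 * b1_ + a2 * b2_) / (na * nb)
        if cos_t > 1.0:
            cos_t = 1.0
        if cos_t < -1.0:
            cos_t = -1.0
        theta = np.arccos(cos_t)
        dtheta = theta - angle_t0[k]
        energy += k_angle * dtheta * dtheta
        sin_t = np.sqrt(1.0 - cos_t * cos_t)
        if sin_t < 1e-4:
            sin_t = 1e-4
        coef = -2.0 * k_angle * dtheta / sin_t
        d10 = (cos_t * a0 / na - b0 / nb) / na
        d11 = (cos_t * a1 / na - b1_ / nb) / na
        d12 = (cos_t * a2 / na - b2_ / nb) / na
        d20 = (cos_t * b0 / nb - a0 / na) / nb
        d21 = (cos_t * b1_ / nb - a1 / na) / nb
        d22 = (cos_t * b2_ / nb - a2 / na) / nb
        f[k, 0] += coef * d10
        f[k, 1] += coef * d11
        f[k, 2] += coef * d12
        f[k + 2, 0] += coef * d20
        f[k + 2, 1] += coef * d21
        f[k + 2, 2] += coef * d22
        f[k + 1, 0] -= coef * (d10 + d20)
        f[k + 1, 1] -= coef * (d11 + d21)
        f[k + 1, 2] -= coef * (d12 + d22)
    # dihedrals: V = kd1(1-cos(p-p0)) + kd3(1-cos(3(p-p0)))
    for k in range(n - 3):
        b10 = x[k + 1, 0] - x[k, 0]
        b11 = x[k + 1, 1] - x[k, 1]
        b12 = x[k + 1, 2] - x[k, 2]
        b20 = x[k + 2, 0] - x[k + 1, 0]
        b21 = x[k + 2, 1] - x[k + 1, 1]
        b22 = x[k + 2, 2] - x[k + 1, 2]
        b30 = x[k + 3, 0] - x[k + 2, 0]
        b31 = x[k + 3, 1] - x[k + 2, 1]
        b32 = x[k + 3, 2] - x[k + 2, 2]
        c10 = b11 * b22 - b12 * b21
        c11 = b12 * b20 - b10 * b22
        c12 = b10 * b21 - b11 * b20
        c20 = b21 * b32 - b22 * b31
        c21 = b22 * b30 - b20 * b32
        c22 = b20 * b31 - b21 * b30
        nb2 = np.sqrt(b20 * b20 + b21 * b21 + b22 * b22)
        m10 = (c11 * b22 - c12 * b21) / nb2
        m11 = (c12 * b20 - c10 * b22) / nb2
        m12 = (c10 * b21 - c11 * b20) / nb2
        xx = c10 * c20 + c11 * c21 + c12 * c22
        yy = m10 * c20 + m11 * c21 + m12 * c22
        phi = np.arctan2(yy, xx)
        dphi = phi - dihed_p0[k]
        energy += kd1 * (1.0 - np.cos(dphi)) + kd3 * (1.0 - np.cos(3.0 * dphi))
        dv = kd1 * np.sin(dphi) + 3.0 * kd3 * np.sin(3.0 * dphi)
        nc1 = c10 * c10 + c11 * c11 + c12 * c12
        nc2 = c20 * c20 + c21 * c21 + c22 * c22
        # floor the plane normals at sin²θ ≈ 1e-3 to bound the torsion
        # force through transiently near-collinear backbone angles
        nb1sq = b10 * b10 + b11 * b11 + b12 * b12
        nb3sq = b30 * b30 + b31 * b31 + b32 * b32
        floor1 = 1e-3 * nb1sq * nb2 * nb2
        floor2 = 1e-3 * nb3sq * nb2 * nb2
        if nc1 < floor1:
            nc1 = floor1
        if nc2 < floor2:
            nc2 = floor2
        # analytic torsion gradient: dphi/dx1 ∝ +n1, dphi/dx4 ∝ -n2,
        # middle atoms from translation/rotation balance
        b1b2 = b10 * b20 + b11 * b21 + b12 * b22
        b3b2 = b30 * b20 + b31 * b21 + b32 * b22
        t = b1b2 / (nb2 * nb2)
        u = b3b2 / (nb2 * nb2)
        g1 = nb2 / nc1
        g4 = -nb2 / nc2
        d1x = g1 * c10
        d1y = g1 * c11
        d1z = g1 * c12
        d4x = g4 * c20
        d4y = g4 * c21
        d4z = g4 * c22
        f[k, 0] += -dv * d1x
        f[k, 1] += -dv * d1y
        f[k, 2] += -dv * d1z
        f[k + 1, 0] += -dv * (-(1.0 + t) * d1x + u * d4x)
        f[k + 1, 1] += -dv * (-(1.0 + t) * d1y + u * d4y)
        f[k + 1, 2] += -dv * (-(1.0 + t) * d1z + u * d4z)
        f[k + 2, 0] += -dv * (t * d1x - (1.0 + u) * d4x)
        f[k + 2, 1] += -dv * (t * d1y - (1.0 + u) * d4y)
        f[k + 2, 2] += -dv * (t * d1z - (1.0 + u) * d4z)
        f[k + 3, 0] += -dv * d4x
        f[k + 3, 1] += -dv * d4y
        f[k + 3, 2] += -dv * d4z
    # native 12-10 pairs
    for p in range(npairs.shape[0]):
        i = npairs[p, 0]
        j = npairs[p, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        r = np.sqrt(r2)
        s = nsigma[p] / r
        s10 = s ** 10
        s12 = s10 * s * s
        energy += eps_nat * (5.0 * s12 - 6.0 * s10)
        c = eps_nat * 60.0 * (s12 - s10) / r2
        f[i, 0] += c * dx0
        f[i, 1] += c * dx1
        f[i, 2] += c * dx2
        f[j, 0] -= c * dx0
        f[j, 1] -= c * dx1
        f[j, 2] -= c * dx2
    # non-native repulsion
    cut2 = (2.5 * sigma_rep) ** 2
    for p in range(rpairs.shape[0]):
        i = rpairs[p, 0]
        j = rpairs[p, 1]
        dx0 = x[i, 0] - x[j, 0]
        dx1 = x[i, 1] - x[j, 1]
        dx2 = x[i, 2] - x[j, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        if r2 > cut2:
            continue
        s12 = (sigma_rep * sigma_rep / r2) ** 6
        energy += eps_rep * s12
        c = 12.0 * eps_rep * s12 / r2
        f[i, 0] += c * dx0
        f[i, 1] += c * dx1
        f[i, 2] += c * dx2
        f[j, 0] -= c * dx0
        f[j, 1] -= c * dx1
        f[j, 2] -= c * dx2
    return energy


@njit(cache=True)
def _forces(x, bond_r0, angle_t0, dihed_p0, npairs, nsigma, rpairs,
            eps_nat, eps_rep, sigma_rep, k_bond, k_angle, kd1, kd3):
    f = np.zeros((x.shape[0], 3))
    e = _forces_into(x, f, bond_r0, angle_t0, dihed_p0, npairs, nsigma, rpairs,
                     eps_nat, eps_rep, sigma_rep, k_bond, k_angle, kd1, kd3)
    return f, e


@njit(cache=True)
def _run_leg(x, v, n_steps, dt, gamma, kT, masses, seed, save_stride,
             bond_r0, angle_t0, dihed_p0, npairs, nsigma, rpairs,
             eps_nat, eps_rep, sigma_rep, k_bond, k_angle, kd1, kd3):
    np.random.seed(seed)
    n = x.shape[0]
    n_frames = n_steps // save_stride
    frames = np.empty((n_frames, n, 3))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    f = np.zeros((n, 3))
    _forces_into(x, f, bond_r0, angle_t0, dihed_p0, npairs, nsigma, rpairs,
                 eps_nat, eps_rep, sigma_rep, k_bond, k_angle, kd1, kd3)
    half = 0.5 * dt
    frame = 0
    for step in range(n_steps):
        for i in range(n):
            im = half / masses[i]
            for d in range(3):
                v[i, d] += im * f[i, d]
                x[i, d] += half * v[i, d]
        if gamma > 0.0:
            for i in range(n):
                sd = np.sqrt(kT / masses[i])
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * sd * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                x[i, d] += half * v[i, d]
        _forces_into(x, f, bond_r0, angle_t0, dihed_p0, npairs, nsigma, rpairs,
                     eps_nat, eps_rep, sigma_rep, k_bond, k_angle, kd1, kd3)
        for i in range(n):
            im = half / masses[i]
            for d in range(3):
                v[i, d] += im * f[i, d]
        if (step + 1) % save_stride == 0:
            if not np.isfinite(x).all():
                return frames[:frame], x, v, False
            frames[frame] = x
            frame += 1
    return frames[:frame], x, v, True


def _model_args(model: GoModel):
    return (
        model.bond_r0, model.angle_t0, model.dihed_p0,
        model.native_pairs, model.native_sigma, model.rep_pairs,
        model.eps_native, EPS_REP, SIGMA_REP, K_BOND, K_ANGLE,
        K_DIHED_1, K_DIHED_3,
    )


def potential_energy(model: GoModel, x: np.ndarray) -> float:
    _, e = _forces(np.ascontiguousarray(x, dtype=float), *_model_args(model))
    return float(e)


def forces(model: GoModel, x: np.ndarray) -> np.ndarray:
    f, _ = _forces(np.ascontiguousarray(x, dtype=float), *_model_args(model))
    return f


def minimize(model: GoModel, x: np.ndarray | None = None, n_steps: int = 100,
             step0: float = 1e-3) -> np.ndarray:
    """Steepest-descent minimization with backtracking (desk tool)."""
    x = np.array(model.x0 if x is None else x, dtype=float)
    e = potential_energy(model, x)
    step = step0
    for _ in range(n_steps):
        f = forces(model, x)
        x_new = x + step * f
        e_new = potential_energy(model, x_new)
        if e_new < e:
            x, e = x_new, e_new
            step *= 1.2
        else:
            step *= 0.5
    return x


def run_leg(model: GoModel, x: np.ndarray, v: np.ndarray | None,
            t_ns: float, temperature: float, seed: int,
            dt_fs: float = 15.0, friction_ps: float = 0.05,
            save_stride: int = 5000):
    """One constant-temperature Langevin leg; returns (frames, x, v)."""
    dt = dt_fs / TU_FS
    gamma = friction_ps * TU_FS * 1e-3
    kT = KB * temperature
    n_steps = int(round(t_ns * 1e6 / dt_fs))
    rng = np.random.default_rng(seed)
    if v is None:
        v = rng.normal(size=(model.n_beads, 3)) * np.sqrt(
            kT / model.masses[:, None]
        )
    frames, x, v, ok = _run_leg(
        np.ascontiguousarray(x, dtype=float), np.ascontiguousarray(v, dtype=float),
        n_steps, dt, gamma, kT, model.masses, seed % (2**31 - 1), save_stride,
        *_model_args(model),
    )
    if not ok:
        raise FloatingPointError(
            "numerical blow-up (non-finite coordinates); reduce dt or check model"
        )
    return frames, x, v


def run_quench(model: GoModel, protocol: QuenchProtocol | None = None,
               seed: int = 0) -> Trajectory:
    """Thermal unfold at T_unfold then refolding leg at T_quench.

    Fully deterministic per (model, protocol, seed).  Frames from both
    legs are concatenated; the ``leg`` array marks 0 = unfold,
    1 = quench.  A zero-length leg contributes only its initial frame.
    """
    protocol = protocol or QuenchProtocol()
    x = model.x0.copy()
    uf, x, v = run_leg(
        model, x, None, protocol.t_unfold_ns, protocol.T_unfold, seed,
        protocol.dt_fs, protocol.friction_ps, protocol.save_stride,
    )
    qf, x, v = run_leg(
        model, x, v, protocol.t_traj_ns, protocol.T_quench, seed + 1_000_003,
        protocol.dt_fs, protocol.friction_ps, protocol.save_stride,
    )
    if len(uf) + len(qf) == 0:
        frames = model.x0[None].copy()
        return Trajectory(frames, np.array([protocol.T_unfold]),
                          np.array([0]), protocol.dt_fs, protocol.save_stride)
    frames = np.concatenate([uf, qf]) if len(uf) and len(qf) else (uf if len(uf) else qf)
    temps = np.concatenate(
        [np.full(len(uf), protocol.T_unfold), np.full(len(qf), protocol.T_quench)]
    )
    leg = np.concatenate([np.zeros(len(uf), dtype=int), np.ones(len(qf), dtype=int)])
    return Trajectory(frames, temps, leg, protocol.dt_fs, protocol.save_stride)


def _helical_segments(model: GoModel, min_len: int = 4):
    """Runs of consecutive native torsions in the helical band
    (25° < |φ| < 85°, either hand)."""
    phi = np.abs(model.dihed_p0)
    helical = (phi > np.deg2rad(25)) & (phi < np.deg2rad(85))
    segs, start = [], None
    for k, h in enumerate(helical):
        if h and start is None:
            start = k
        elif not h and start is not None:
            if k - start >= min_len:
                segs.append((start, k))
            start = None
    if start is not None and len(helical) - start >= min_len:
        segs.append((start, len(helical)))
    return segs


def mirror_flag(trajectory: Trajectory, model: GoModel,
                tail_fraction: float = 0.1) -> bool:
    """Heuristic mirror-image detection.

    Over the final ``tail_fraction`` of frames, the median sign of the
    Cα (i, i+1, i+2, i+3) torsions across natively helical segments is
    compared with the native sign; a globally inverted chirality marks
    a mirror-image trajectory (to be discarded and re-seeded).
    """
    import warnings

    segs = _helical_segments(model)
    if not segs:
        warnings.warn("no helical segments; mirror detection inconclusive")
        return False
    idx = np.concatenate([np.arange(a, b) for a, b in segs])
    native_sign = np.sign(np.median(model.dihed_p0[idx]))
    n_tail = max(1, int(len(trajectory.frames) * tail_fraction))
    signs = []
    for x in trajectory.frames[-n_tail:]:
        phi = _dihedrals(x)
        signs.append(np.median(np.sign(phi[idx])))
    return bool(np.median(signs) == -native_sign)
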