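import numpy as np
import pytest

from entangle_age.structures import heavy_atom_contacts
from entangle_age.synth import gen_mini_protein

# Synthetic Cα-only fixtures use an 8 Å Cα contact cutoff (Cα–Cα contact
# distances run 5–7 Å, so the 4.5 Å heavy-atom rule applies to all-atom
# inputs only).
CA_CUTOFF = 8.0


def dense_gauss_oracle(curve_a: np.ndarray, curve_b: np.ndarray,
                       subdivisions: int = 12) -> float:
    """Independent dense numerical Gauss double integral between two
    polylines: each segment is subdivided and the discretized double sum
    evaluated over the refined curves."""

    def refine(c):
        pts = []
        for a, b in zip(c[:-1], c[1:]):
            for t in np.linspace(0.0, 1.0, subdivisions, endpoint=False):
                pts.append(a + (b - a) * t)
        pts.append(c[-1])
        return np.array(pts)

    c1, c2 = refine(np.asarray(curve_a)), refine(np.asarray(curve_b))
    m1 = 0.5 * (c1[:-1] + c1[1:])
    d1 = np.diff(c1, axis=0)
    m2 = 0.5 * (c2[:-1] + c2[1:])
    d2 = np.diff(c2, axis=0)
    diff = m1[:, None, :] - m2[None, :, :]
    dist3 = np.linalg.norm(diff, axis=-1) ** 3
    cross = np.cross(d1[:, None, :], d2[None, :, :])
    return float(
        np.einsum("mnk,mnk->mn", diff, cross / dist3[..., None]).sum() / (4 * np.pi)
    )


@pytest.fixture(scope="session")
def hairpin():
    structure, truth = gen_mini_protein("helix_hairpin", seed=0)
    return structure, truth


@pytest.fixture(scope="session")
def entangled_hairpin():
    structure, truth = gen_mini_protein("entangled_hairpin", seed=0)
    return structure, truth


@pytest.fixture(scope="session")
def hairpin_contacts(hairpin):
    return heavy_atom_contacts(hairpin[0], cutoff=CA_CUTOFF, min_seq_sep=3)


@pytest.fixture(scope="session")
def go_model(hairpin, hairpin_contacts):
    from entangle_age.gosim import build_go_model

    return build_go_model(hairpin[0], hairpin_contacts)
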