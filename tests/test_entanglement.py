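import numpy as np
import pytest

from entangle_age.entanglement import (
    Crossing,
    cluster_ncles,
    detect_ncles,
    entangled_region_mask,
    find_crossings,
    gauss_linking,
    is_slipknot,
    partial_linking_profile,
    _bond_ranges,
)
from entangle_age.structures import ProteinStructure, heavy_atom_contacts
from entangle_age.synth import gen_loop_curve, gen_mini_protein, _random_rotation

from conftest import CA_CUTOFF, dense_gauss_oracle


def _included_curves(ca, loop):
    """Cα sub-polylines corresponding to the summation bond ranges."""
    i, j = loop
    n_tail, loop_b, c_tail = _bond_ranges(i, j, len(ca))
    def seg(bonds):
        return ca[bonds[0] : bonds[-1] + 2] if len(bonds) else None
    return seg(n_tail), seg(loop_b), seg(c_tail)


class TestGaussLinking:
    def test_threaded_circle_matches_dense_oracle(self):
        s, truth = gen_loop_curve(threaded=True, seed=1, rotate=False)
        lk = gauss_linking(s.ca_coords, truth["loop"])
        assert abs(abs(lk.gC) - 1.0) <= 0.05
        _, loop_c, tail_c = _included_curves(s.ca_coords, truth["loop"])
        oracle = dense_gauss_oracle(tail_c, loop_c)
        assert abs(lk.gC - oracle) < 0.02

    def test_coplanar_unthreaded_near_zero(self):
        s, truth = gen_loop_curve(threaded=False, seed=2)
        lk = gauss_linking(s.ca_coords, truth["loop"])
        assert abs(lk.gC) < 0.1

    def test_mirror_antisymmetry_exact(self):
        s, truth = gen_loop_curve(threaded=True, seed=3)
        mirror = s.ca_coords * np.array([1.0, 1.0, -1.0])
        lk = gauss_linking(s.ca_coords, truth["loop"])
        lk_m = gauss_linking(mirror, truth["loop"])
        assert lk_m.gN == -lk.gN
        assert lk_m.gC == -lk.gC

    def test_rigid_motion_invariance(self):
        s, truth = gen_loop_curve(threaded=True, seed=4, rotate=False)
        rng = np.random.default_rng(0)
        R = _random_rotation(rng)
        moved = s.ca_coords @ R.T + np.array([3.0, -8.0, 2.0])
        g1 = gauss_linking(s.ca_coords, truth["loop"])
        g2 = gauss_linking(moved, truth["loop"])
        assert np.isclose(g1.gC, g2.gC, atol=1e-10)

    def test_empty_tail_ranges_give_zero(self):
        s, truth = gen_loop_curve(threaded=True, seed=5)
        # loop starting at residue 1: N-tail range empty
        lk = gauss_linking(s.ca_coords, truth["loop"])
        assert lk.gN == 0.0

    def test_invalid_loop_raises(self):
        s, _ = gen_loop_curve(seed=6)
        with pytest.raises(ValueError):
            gauss_linking(s.ca_coords, (10, 10))

    @pytest.mark.parametrize("planted", [0, 1, -1, 2, -2])
    def test_integer_recovery_under_jitter(self, planted):
        hits = 0
        for seed in range(40):
            s, truth = gen_loop_curve(
                threaded=planted != 0,
                turns=abs(planted) or 1,
                chirality=int(np.sign(planted)) or 1,
                noise_sd=0.1,
                seed=seed,
            )
            g = gauss_linking(s.ca_coords, truth["loop"])
            hits += round(g.gC) == truth["linking_number"]
        assert hits >= 39  # >= 99% pooled over the parametrized cases


class TestLinkingProfile:
    def test_threaded_profile_rises_through_half(self):
        s, truth = gen_loop_curve(threaded=True, seed=7, rotate=False)
        residues, cum = partial_linking_profile(s.ca_coords, truth["loop"], "C")
        acum = np.abs(cum)
        assert acum[0] < 0.2 and acum[-1] > 0.9
        crossings = np.sum((acum[:-1] < 0.5) & (acum[1:] >= 0.5))
        assert crossings == 1

    def test_unthreaded_profile_stays_low(self):
        s, truth = gen_loop_curve(threaded=False, seed=8)
        _, cum = partial_linking_profile(s.ca_coords, truth["loop"], "C")
        assert np.abs(cum).max() < 0.5

    def test_full_profile_equals_gauss_linking(self):
        s, truth = gen_loop_curve(threaded=True, seed=9)
        _, cum = partial_linking_profile(s.ca_coords, truth["loop"], "C")
        lk = gauss_linking(s.ca_coords, truth["loop"])
        assert np.isclose(cum[-1], lk.gC, atol=1e-12)

    def test_empty_tail_raises(self):
        s, truth = gen_loop_curve(threaded=True, seed=10)
        with pytest.raises(ValueError):
            partial_linking_profile(s.ca_coords, truth["loop"], "N")


class TestCrossings:
    def test_single_thread_single_crossing(self):
        s, truth = gen_loop_curve(threaded=True, seed=11, chirality=1, rotate=False)
        prof = partial_linking_profile(s.ca_coords, truth["loop"], "C")
        crossings = find_crossings(prof, "C")
        assert len(crossings) == 1
        assert crossings[0].sign == int(np.sign(gauss_linking(
            s.ca_coords, truth["loop"]).gC))
        assert abs(crossings[0].residue - truth["crossing_residue"]) <= 2

    def test_unthreaded_no_crossings(self):
        s, truth = gen_loop_curve(threaded=False, seed=12)
        prof = partial_linking_profile(s.ca_coords, truth["loop"], "C")
        assert find_crossings(prof, "C") == []

    def test_double_thread_two_same_sign_crossings(self):
        s, truth = gen_loop_curve(threaded=True, turns=2, seed=13)
        prof = partial_linking_profile(s.ca_coords, truth["loop"], "C")
        crossings = find_crossings(prof, "C")
        assert len(crossings) == 2
        assert crossings[0].sign == crossings[1].sign


class TestSlipknot:
    def test_cancelling_pair_is_slipknot(self):
        cr = [Crossing(30, 1, "N"), Crossing(40, -1, "N")]
        assert is_slipknot(cr) is True

    def test_single_crossing_not_slipknot(self):
        assert is_slipknot([Crossing(30, 1, "N")]) is False

    def test_double_same_sign_not_slipknot(self):
        s, truth = gen_loop_curve(threaded=True, turns=2, seed=14)
        prof = partial_linking_profile(s.ca_coords, truth["loop"], "C")
        assert is_slipknot(find_crossings(prof, "C")) is False


class TestDetect:
    def test_non_entangled_hairpin_empty(self, hairpin, hairpin_contacts):
        assert detect_ncles(hairpin[0], hairpin_contacts) == []

    def test_planted_loop_family_detected(self, entangled_hairpin):
        s, truth = entangled_hairpin
        cm = heavy_atom_contacts(s, cutoff=CA_CUTOFF, min_seq_sep=3)
        ncles = detect_ncles(s, cm)
        assert len(ncles) > 0
        i0, j0 = truth["loop_contact"]
        assert all(abs(n.loop[0] - i0) <= 3 and abs(n.loop[1] - j0) <= 3
                   for n in ncles)
        for n in ncles:
            assert len(n.crossings) == 1
            assert abs(n.crossings[0].residue - truth["crossing_residue"]) <= 2

    def test_threshold_monotonicity(self, entangled_hairpin):
        s, _ = entangled_hairpin
        cm = heavy_atom_contacts(s, cutoff=CA_CUTOFF, min_seq_sep=3)
        n_low = len(detect_ncles(s, cm, threshold=0.6))
        n_mid = len(detect_ncles(s, cm, threshold=0.8))
        n_high = len(detect_ncles(s, cm, threshold=1.1))
        assert n_low >= n_mid >= n_high
        assert n_high == 0


class TestCluster:
    def _ncle(self, loop, crossing, sign=1):
        from entangle_age.entanglement import NCLE

        return NCLE(loop=loop, gN=0.9, gC=0.0,
                    crossings=[Crossing(crossing, sign, "N")])

    def test_shorter_loop_is_representative(self):
        out = cluster_ncles([self._ncle((10, 50), 60), self._ncle((12, 48), 60)])
        rep = [n for n in out if n.representative]
        assert len(rep) == 1 and rep[0].loop == (12, 48)
        assert len({n.cluster_id for n in out}) == 1

    def test_distinct_crossings_distinct_clusters(self):
        out = cluster_ncles([self._ncle((10, 50), 60), self._ncle((10, 50), 80)])
        assert len({n.cluster_id for n in out}) == 2

    def test_degenerate_family_single_representative(self, entangled_hairpin):
        s, _ = entangled_hairpin
        cm = heavy_atom_contacts(s, cutoff=CA_CUTOFF, min_seq_sep=3)
        out = cluster_ncles(detect_ncles(s, cm))
        assert len(out) >= 5
        assert sum(n.representative for n in out) == 1


class TestRegionMask:
    def _mask_for(self, n, loop, crossing):
        from entangle_age.entanglement import NCLE

        ca = np.column_stack([np.arange(n) * 100.0, np.zeros(n), np.zeros(n)])
        s = ProteinStructure.from_ca(ca)  # beads far apart: no spatial term
        ncle = NCLE(loop=loop, gN=1.0, gC=0.0,
                    crossings=[Crossing(crossing, 1, "N")], representative=True)
        return entangled_region_mask(s, [ncle])

    def test_sequence_buffer_union(self):
        m = self._mask_for(50, (10, 20), 30)
        assert set(m.residues()) == set(range(7, 14)) | set(range(17, 24)) | set(range(27, 34))

    def test_clipped_at_chain_start(self):
        m = self._mask_for(50, (10, 20), 2)
        assert set(m.residues()) >= set(range(1, 6))
        assert 0 not in m.residues()

    def test_spatial_neighbors_match_brute_force(self, entangled_hairpin):
        s, _ = entangled_hairpin
        cm = heavy_atom_contacts(s, cutoff=CA_CUTOFF, min_seq_sep=3)
        ncles = cluster_ncles(detect_ncles(s, cm))
        mask = entangled_region_mask(s, ncles, contact_cutoff=CA_CUTOFF)
        rep = [n for n in ncles if n.representative]
        key = set()
        for n in rep:
            key.update(n.loop)
            key.update(c.residue for c in n.crossings)
        expected = set()
        for r in key:
            expected.update(range(max(1, r - 3), min(s.n_residues, r + 3) + 1))
        ca = s.ca_coords
        for r in range(1, s.n_residues + 1):
            if any(np.linalg.norm(ca[r - 1] - ca[k - 1]) <= CA_CUTOFF for k in key):
                expected.add(r)
        assert set(mask.residues()) == expected

    def test_protein_level_call_equals_detection(self, hairpin, hairpin_contacts,
                                                 entangled_hairpin):
        from entangle_age.entanglement import is_entangled_protein

        assert is_entangled_protein(hairpin[0], hairpin_contacts) is False
        s, _ = entangled_hairpin
        cm = heavy_atom_contacts(s, cutoff=CA_CUTOFF, min_seq_sep=3)
        assert is_entangled_protein(s, cm) is True
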