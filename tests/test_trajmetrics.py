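import numpy as np
import pytest

from entangle_age.structures import heavy_atom_contacts
from entangle_age.synth import gen_mini_protein, gen_qg_series, _random_rotation
from entangle_age.trajmetrics import (
    cluster_states,
    compute_g,
    compute_q,
    misfolding_probability,
    native_contact_distances,
    reference_linking,
)

from conftest import CA_CUTOFF


@pytest.fixture(scope="module")
def native_setup():
    s, _ = gen_mini_protein("entangled_hairpin", seed=0)
    cm = heavy_atom_contacts(s, cutoff=CA_CUTOFF, min_seq_sep=3)
    nd = native_contact_distances(s.ca_coords, cm.contacts)
    ref = reference_linking(s.ca_coords, cm.contacts)
    return s, cm, nd, ref


class TestQ:
    def test_native_frame_is_one(self, native_setup):
        s, cm, nd, _ = native_setup
        assert compute_q(s.ca_coords, cm.contacts, nd) == 1.0

    def test_extended_chain_is_zero(self, native_setup):
        s, cm, nd, _ = native_setup
        n = s.n_residues
        ext = np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)])
        assert compute_q(ext, cm.contacts, nd) == 0.0

    def test_boundary_counts_as_formed(self):
        # 2 pairs exactly at 1.2 x r0, 2 pairs far: Q = 0.5
        native = np.array([[0, 0, 0], [20, 0, 0], [40, 0, 0], [60, 0, 0],
                           [5, 0, 0], [25, 0, 0], [80, 0, 0], [100, 0, 0.]])
        contacts = [(1, 5), (2, 6), (3, 7), (4, 8)]
        nd = native_contact_distances(native, contacts)
        frame = native.copy()
        frame[4] = [6.0, 0, 0]       # pair 1: 6.0 = 1.2 x 5
        frame[5] = [26.0, 0, 0]      # pair 2: boundary
        frame[6] = [120.0, 0, 0]     # pair 3: 2x
        frame[7] = [180.0, 0, 0]     # pair 4: far
        assert compute_q(frame, contacts, nd) == 0.5

    def test_rigid_motion_invariance_and_expansion_monotone(self, native_setup):
        s, cm, nd, _ = native_setup
        R = _random_rotation(np.random.default_rng(0))
        moved = s.ca_coords @ R.T + 11.0
        assert compute_q(moved, cm.contacts, nd) == 1.0
        com = s.ca_coords.mean(axis=0)
        prev = 1.0
        for scale in (1.1, 1.3, 1.6, 2.5):
            q = compute_q(com + (s.ca_coords - com) * scale, cm.contacts, nd)
            assert q <= prev
            prev = q

    def test_empty_contacts_raise(self, native_setup):
        s, _, _, _ = native_setup
        with pytest.raises(ValueError):
            compute_q(s.ca_coords, [], np.array([]))


class TestG:
    def test_native_frame_is_zero(self, native_setup):
        s, cm, _, ref = native_setup
        assert compute_g(s.ca_coords, cm.contacts, ref) == 0.0

    def test_mirror_flips_chirally_linked_contacts(self, native_setup):
        s, cm, _, ref = native_setup
        mirrored = s.ca_coords * np.array([1.0, 1.0, -1.0])
        g = compute_g(mirrored, cm.contacts, ref)
        n_linked = int(np.sum(np.abs(ref).max(axis=1) > 0))
        assert np.isclose(g, n_linked / len(cm.contacts))

    def test_thread_pulled_out_changes_linked_fraction(self, native_setup):
        s, cm, _, ref = native_setup
        # straighten the N-terminal thread away from the loop: linked
        # contacts lose their linking, the rest keep it
        coords = s.ca_coords.copy()
        frame = coords.copy()
        # move first 17 residues (leader+thread) onto a distant straight line
        n_move = 17
        direction = np.array([1.0, 0.0, 0.0])
        origin = coords[:, 0].min() * direction * 3 - np.array([0.0, 0.0, 60.0])
        for k in range(n_move):
            frame[k] = origin + direction * 3.8 * k
        g = compute_g(frame, cm.contacts, ref)
        n_linked = int(np.sum(np.abs(ref).max(axis=1) > 0))
        assert g >= n_linked / len(cm.contacts) * 0.99
        assert g <= 0.5

    def test_reference_mismatch_raises(self, native_setup):
        s, cm, _, ref = native_setup
        with pytest.raises(ValueError):
            compute_g(s.ca_coords, list(cm.contacts)[:3], ref)


class TestClustering:
    def test_two_planted_states_recovered(self):
        df, truth = gen_qg_series([(0.95, 0.02), (0.9, 0.3)], [0.7, 0.3],
                                  n_frames=5000, seed=0)
        asg = cluster_states(df[["Q", "G"]].to_numpy(), k_micro=100, lag=10,
                             n_macro=2, seed=0)
        lab = truth["labels"]
        native_pred = asg.macro == asg.native_macrostate
        acc = max(np.mean(native_pred == (lab == 0)),
                  np.mean(native_pred == (lab == 1)))
        assert acc >= 0.99
        pops = asg.macro_populations()
        realized = np.sort(truth["realized_populations"])[0]
        assert abs(np.sort(pops)[0] - realized) < 0.02

    def test_single_cluster_auto_gives_one_macrostate(self):
        df, _ = gen_qg_series([(0.9, 0.05)], [1.0], n_frames=2000, seed=1)
        asg = cluster_states(df[["Q", "G"]].to_numpy(), k_micro=50,
                             n_macro="auto", seed=0)
        assert asg.n_macrostates == 1

    def test_determinism_of_centroids(self):
        df, _ = gen_qg_series([(0.95, 0.02), (0.9, 0.3)], [0.5, 0.5],
                              n_frames=3000, seed=2)
        qg = df[["Q", "G"]].to_numpy()
        a = cluster_states(qg, k_micro=60, n_macro=2, seed=5)
        b = cluster_states(qg, k_micro=60, n_macro=2, seed=5)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.macro, b.macro)

    def test_few_frames_reduces_k_with_warning(self):
        df, _ = gen_qg_series([(0.9, 0.1)], [1.0], n_frames=40, seed=3)
        with pytest.warns(UserWarning):
            asg = cluster_states(df[["Q", "G"]].to_numpy(), k_micro=100, seed=0)
        assert asg.micro.max() < 40


class TestMisfoldingProbability:
    def _assignment(self, macro, q, native=0):
        from entangle_age.trajmetrics import StateAssignment

        macro = np.asarray(macro)
        return StateAssignment(
            micro=macro.copy(), macro=macro, native_macrostate=native,
            centroids=np.zeros((2, 2)), macro_of_micro=np.array([0, 1]),
            q=np.asarray(q, dtype=float), g=np.zeros(len(macro)),
        )

    def test_all_native_zero(self):
        a = self._assignment([0] * 100, [0.95] * 100)
        assert misfolding_probability(a).p_mis == 0.0

    def test_equal_split_fifty(self):
        a = self._assignment([0] * 50 + [1] * 50, [0.95] * 100)
        assert misfolding_probability(a).p_mis == 50.0

    def test_planted_30_70(self):
        a = self._assignment([1] * 30 + [0] * 70, [0.9] * 100)
        assert misfolding_probability(a).p_mis == 30.0

    def test_q_floor_excludes_unfolded(self):
        a = self._assignment([1] * 30 + [0] * 70, [0.3] * 30 + [0.95] * 70)
        assert misfolding_probability(a, q_floor=0.6).p_mis == 0.0

    def test_pooling_consistency_identity(self):
        rng = np.random.default_rng(0)
        macro = (rng.random(300) < 0.4).astype(int)
        q = np.full(300, 0.9)
        a = self._assignment(macro, q)
        pooled = misfolding_probability(a)
        n_mis = n_nat = 0
        for lo, hi in ((0, 100), (100, 200), (200, 300)):
            part = misfolding_probability(a, window=slice(lo, hi))
            n_mis += part.n_mis
            n_nat += part.n_native
        assert pooled.n_mis == n_mis and pooled.n_native == n_nat

    def test_empty_window_raises(self):
        a = self._assignment([0] * 10, [0.9] * 10)
        with pytest.raises(ValueError):
            misfolding_probability(a, window=slice(10, 10))
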