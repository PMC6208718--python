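"""Synthetic geometry, transfer matrix, beat and noise generation."""

import numpy as np
import pytest

import epiwave as ew
from epiwave.geometry import TorsoHeartGeometry


class TestSphereGeometry:
    def test_experimental_scale_setup(self):
        g = ew.make_sphere_geometry(99, 192, 30.0, 120.0, seed=0)
        assert g.n_heart == 99
        assert g.n_torso == 192
        radii = np.linalg.norm(g.heart_nodes, axis=1)
        assert np.abs(radii - 30.0).max() < 1e-9
        assert g.heart_inside_torso_hull()

    def test_minimal_instance(self):
        # 4 torso nodes form a tetrahedral hull whose inradius is roughly a
        # third of its circumradius, so the torso sphere must be several
        # times larger than the heart sphere for strict containment
        g = ew.make_sphere_geometry(4, 4, 1.0, 4.0, seed=1)
        assert g.n_heart == 4 and g.n_torso == 4
        assert g.heart_inside_torso_hull()

    def test_deterministic_given_seed(self):
        g1 = ew.make_sphere_geometry(20, 30, 10.0, 40.0, seed=3)
        g2 = ew.make_sphere_geometry(20, 30, 10.0, 40.0, seed=3)
        np.testing.assert_array_equal(g1.heart_nodes, g2.heart_nodes)
        np.testing.assert_array_equal(g1.torso_nodes, g2.torso_nodes)
        np.testing.assert_array_equal(g1.heart_faces, g2.heart_faces)

    @pytest.mark.parametrize("hr,tr", [(-1.0, 2.0), (2.0, 1.0), (0.0, 1.0)])
    def test_invalid_radii_rejected(self, hr, tr):
        with pytest.raises(ValueError):
            ew.make_sphere_geometry(10, 10, hr, tr, seed=0)

    def test_mesh_edge_graph_connected(self, geometry):
        from scipy.sparse.csgraph import connected_components
        n, _ = connected_components(geometry.edge_graph(), directed=False)
        assert n == 1


class TestMonopoleTransfer:
    def test_rows_sum_to_one(self, transfer):
        np.testing.assert_allclose(transfer.entries.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_equidistant_nodes_get_equal_entries(self):
        # torso node on the symmetry axis of three heart nodes
        heart = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        torso = np.array([[0, 0, 5.0], [0, 0, -5.0], [5.0, 0, 0], [-5.0, 0, 0],
                          [0, 5.0, 0], [0, -5.0, 0]])
        from scipy.spatial import ConvexHull
        geom = TorsoHeartGeometry(heart, torso, ConvexHull(heart).simplices)
        A = ew.monopole_transfer_matrix(geom)
        # node (0,0,-5) is equidistant from (1,0,0), (-1,0,0) and (0,1,0)
        assert A.entries[1, 0] == pytest.approx(A.entries[1, 1], rel=1e-12)
        assert A.entries[1, 0] == pytest.approx(A.entries[1, 2], rel=1e-12)

    def test_ill_conditioned_at_experimental_scale(self):
        g = ew.make_sphere_geometry(99, 192, 30.0, 120.0, seed=0)
        A = ew.monopole_transfer_matrix(g)
        assert A.condition_number > 1e3

    def test_nonpositive_conductivity_rejected(self, geometry):
        with pytest.raises(ValueError):
            ew.monopole_transfer_matrix(geometry, sigma=0.0)


class TestSimulateBeat:
    def test_pacing_node_activates_at_zero(self, geometry):
        beat = ew.simulate_beat(geometry, pacing_node=5, seed=0, cv=1.0,
                                apd_base=100.0, apd_dispersion=10.0,
                                duration=256.0)
        assert beat.activation_ms[5] == 0.0

    def test_doubling_cv_halves_activation(self, geometry):
        kw = dict(pacing_node=0, seed=0, apd_base=100.0, apd_dispersion=0.0,
                  duration=256.0)
        slow = ew.simulate_beat(geometry, cv=1.0, **kw)
        fast = ew.simulate_beat(geometry, cv=2.0, **kw)
        np.testing.assert_allclose(fast.activation_ms,
                                   slow.activation_ms / 2.0, atol=1e-12)

    def test_dispersion_free_recovery_offset(self, geometry):
        beat = ew.simulate_beat(geometry, pacing_node=0, seed=0, cv=1.0,
                                apd_base=100.0, apd_dispersion=0.0,
                                duration=256.0)
        np.testing.assert_allclose(
            beat.recovery_ms, beat.activation_ms + 100.0, atol=1e-12
        )

    def test_activation_respects_edge_lengths(self, geometry):
        """Geodesic AT differences across any mesh edge <= edge length / cv."""
        cv = 1.0
        beat = ew.simulate_beat(geometry, pacing_node=0, seed=0, cv=cv,
                                apd_base=100.0, apd_dispersion=0.0,
                                duration=256.0)
        g = geometry.edge_graph().tocoo()
        at = beat.activation_ms
        assert (np.abs(at[g.row] - at[g.col]) <= g.data / cv + 1e-9).all()

    def test_pacing_node_out_of_range(self, geometry):
        with pytest.raises(ValueError):
            ew.simulate_beat(geometry, pacing_node=geometry.n_heart, seed=0)

    def test_duration_too_short_rejected(self, geometry):
        with pytest.raises(ValueError, match="duration"):
            ew.simulate_beat(geometry, pacing_node=0, seed=0, apd_base=250.0,
                             duration=128.0)

    def test_deterministic(self, geometry):
        kw = dict(pacing_node=3, seed=11, cv=1.0, apd_base=100.0,
                  apd_dispersion=10.0, duration=256.0)
        b1 = ew.simulate_beat(geometry, **kw)
        b2 = ew.simulate_beat(geometry, **kw)
        np.testing.assert_array_equal(b1.phi_h_true.data, b2.phi_h_true.data)
        np.testing.assert_array_equal(b1.recovery_ms, b2.recovery_ms)


class TestForwardProject:
    def test_noiseless_is_exact(self, geometry, transfer):
        beat = ew.simulate_beat(geometry, pacing_node=0, seed=0, cv=1.0,
                                apd_base=100.0, duration=256.0)
        out = ew.forward_project(transfer, beat,
                                 ew.NoiseModel(snr_db=np.inf, seed=0))
        np.testing.assert_array_equal(out.data,
                                      transfer.entries @ beat.phi_h_true.data)

    def test_empirical_snr_matches_target(self, geometry, transfer):
        beat = ew.simulate_beat(geometry, pacing_node=0, seed=0)  # 512 ms
        clean = ew.forward_project(transfer, beat)
        noisy = ew.forward_project(transfer, beat,
                                   ew.NoiseModel(snr_db=20.0, seed=4))
        noise = noisy.data - clean.data
        snr = 10.0 * np.log10(np.mean(clean.data**2) / np.mean(noise**2))
        assert abs(snr - 20.0) < 0.5

    def test_zero_signal_uses_absolute_sigma(self, transfer):
        q = transfer.shape[1]
        silent = ew.PotentialRecording(np.zeros((q, 256)))
        out = ew.forward_project(transfer, silent,
                                 ew.NoiseModel(snr_db=20.0, seed=0,
                                               sigma_abs=0.01))
        sd = out.data.std()
        assert 0.008 < sd < 0.012

    def test_same_seed_same_noise(self, geometry, transfer):
        beat = ew.simulate_beat(geometry, pacing_node=0, seed=0, cv=1.0,
                                apd_base=100.0, duration=256.0)
        a = ew.forward_project(transfer, beat, ew.NoiseModel(20.0, seed=7))
        b = ew.forward_project(transfer, beat, ew.NoiseModel(20.0, seed=7))
        np.testing.assert_array_equal(a.data, b.data)

    def test_dimension_mismatch_rejected(self, transfer):
        with pytest.raises(ValueError):
            ew.forward_project(transfer,
                               ew.PotentialRecording(np.zeros((3, 16))))


class TestSimulatorEstimatorConsistency:
    def test_timings_recovered_from_truth_electrograms(self, geometry):
        """On noiseless ground truth, slope detection recovers AT/RT
        within one sample at every node (simulator and estimator agree)."""
        beat = ew.simulate_beat(geometry, pacing_node=0, seed=0, cv=1.0,
                                apd_base=100.0, apd_dispersion=10.0,
                                duration=256.0)
        split = 0.5 * (beat.activation_ms.max() + beat.recovery_ms.min())
        iso = ew.compute_isochrones(beat.phi_h_true, (0.0, split),
                                    (split, 255.0))
        assert np.abs(iso.activation_ms - beat.activation_ms).max() <= 1.0
        assert np.abs(iso.recovery_ms - beat.recovery_ms).max() <= 1.0
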