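"""Polarization extraction, Stokes mapping, compensation and DOPU."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psoct_rnfl.polarization import (apply_retarder,
                                     compensate_anterior_segment,
                                     compute_dopu, extract_polarization,
                                     polarization_from_stokes, to_stokes)
from psoct_rnfl.synthetic_data import ComplexBScanPair


def pure_state(delta_deg: float, dphi_deg: float) -> ComplexBScanPair:
    d = np.deg2rad(delta_deg)
    H = np.array([[np.cos(d)]], dtype=complex)
    V = np.array([[np.sin(d) * np.exp(1j * np.deg2rad(dphi_deg))]])
    return ComplexBScanPair(H, V)


def random_pure_states(n: int, seed: int = 0) -> ComplexBScanPair:
    rng = np.random.default_rng(seed)
    chi = 0.5 * np.arccos(rng.uniform(-1, 1, (1, n)))
    beta = rng.uniform(0, 2 * np.pi, (1, n))
    amp = rng.uniform(0.1, 2.0, (1, n))
    return ComplexBScanPair(amp * np.cos(chi),
                            amp * np.sin(chi) * np.exp(1j * beta))


class TestExtractPolarization:
    @pytest.mark.parametrize("delta,dphi,exp_delta,exp_theta", [
        (0.0, 0.0, 0.0, -90.0),     # co-polarized: theta 90 wraps to -90
        (45.0, 0.0, 45.0, -90.0),   # equal amplitudes
        (20.0, 60.0, 20.0, 60.0),   # theta = (180 - 60)/2
    ])
    def test_single_state_examples(self, delta, dphi, exp_delta, exp_theta):
        pol = extract_polarization(pure_state(delta, dphi))
        assert pol.retardation_deg[0, 0] == pytest.approx(exp_delta, abs=1e-9)
        if delta > 0:  # axis undefined without cross-polarized light
            assert pol.axis_deg[0, 0] == pytest.approx(exp_theta, abs=1e-9)

    def test_dark_pixels_get_floor_and_zero(self):
        pair = ComplexBScanPair(np.zeros((2, 2), complex),
                                np.zeros((2, 2), complex))
        pol = extract_polarization(pair)
        assert np.all(pol.retardation_deg == 0)
        assert np.all(pol.reflectivity_db == -100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ComplexBScanPair(np.zeros((2, 2), complex),
                             np.zeros((3, 2), complex))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ranges(self, seed):
        pair = random_pure_states(64, seed)
        pol = extract_polarization(pair)
        assert np.all((pol.retardation_deg >= 0)
                      & (pol.retardation_deg <= 90))
        assert np.all((pol.axis_deg >= -90) & (pol.axis_deg < 90))


class TestStokes:
    def test_horizontal_state(self):
        s = to_stokes(pure_state(0.0, 0.0))
        assert np.allclose([s.I, s.Q, s.U, s.V],
                           [[[1]], [[1]], [[0]], [[0]]])

    def test_circular_state(self):
        s = to_stokes(pure_state(45.0, 90.0))
        assert np.allclose([s.I, s.Q, s.U, s.V],
                           [[[1]], [[0]], [[0]], [[1]]], atol=1e-15)

    def test_purity_identity(self):
        pair = random_pure_states(1000, 3)
        s = to_stokes(pair)
        assert np.allclose(s.Q ** 2 + s.U ** 2 + s.V ** 2, s.I ** 2,
                           atol=1e-12)

    def test_roundtrip_matches_direct_extraction(self):
        pair = random_pure_states(1000, 4)
        direct = extract_polarization(pair)
        via_stokes = polarization_from_stokes(to_stokes(pair))
        assert np.max(np.abs(via_stokes.retardation_deg
                             - direct.retardation_deg)) < 1e-9

    @pytest.mark.parametrize("stokes_vec,exp_delta", [
        ((1, 1, 0, 0), 0.0), ((1, 0, 0, 1), 45.0), ((1, -1, 0, 0), 90.0)])
    def test_from_stokes_examples(self, stokes_vec, exp_delta):
        from psoct_rnfl.polarization import StokesBScan
        arrays = [np.array([[float(c)]]) for c in stokes_vec]
        pol = polarization_from_stokes(StokesBScan(*arrays))
        assert pol.retardation_deg[0, 0] == pytest.approx(exp_delta)

    def test_degenerate_pixels_flagged(self):
        from psoct_rnfl.polarization import StokesBScan
        z = np.zeros((1, 1))
        pol = polarization_from_stokes(StokesBScan(np.ones((1, 1)), z, z, z))
        assert pol.degenerate[0, 0]
        assert pol.retardation_deg[0, 0] == 0.0

    def test_mean_of_identical_states_is_exact(self):
        pair = random_pure_states(100, 5)
        s = to_stokes(pair)
        from psoct_rnfl.polarization import StokesBScan
        mean = StokesBScan(*(np.mean([getattr(s, c)] * 7, axis=0)
                             for c in "IQUV"))
        diff = (polarization_from_stokes(mean).retardation_deg
                - polarization_from_stokes(s).retardation_deg)
        assert np.abs(diff).max() < 1e-9


class TestRenderRoundTrip:
    def test_cumulative_retardation_recovered_everywhere(self,
                                                         flat_quiet_scene):
        phantom, geometry, pairs, gt = flat_quiet_scene
        pol = extract_polarization(pairs[0])
        pitch = geometry.axial_pitch_um
        dn = gt.biref_deg_per_um
        for x in (0, 100, 333):
            zs = np.arange(gt.ilm_idx[x], gt.rnfl_lower_idx[x])
            expected = dn[x] * np.minimum((zs - gt.ilm_idx[x] + 1) * pitch,
                                          gt.thickness_um[x])
            err = np.abs(pol.retardation_deg[zs, x] - expected)
            assert err.max() < 1e-6


class TestCompensation:
    def test_identity_without_corneal_retarder(self, flat_quiet_scene):
        _, _, pairs, gt = flat_quiet_scene
        stokes = [to_stokes(pairs[0])]
        comp, rot = compensate_anterior_segment(stokes, gt.ilm_idx)
        assert np.allclose(rot, np.eye(3), atol=1e-6)
        assert np.allclose(comp[0].Q, stokes[0].Q, atol=1e-6)

    def test_known_retarder_is_removed(self, flat_quiet_scene):
        _, _, pairs, gt = flat_quiet_scene
        corrupted = apply_retarder(pairs[0], 10.0, 30.0)
        comp, _ = compensate_anterior_segment([to_stokes(corrupted)],
                                              gt.ilm_idx)
        pol = polarization_from_stokes(comp[0])
        band = pol.retardation_deg[gt.ilm_idx[0]:gt.ilm_idx[0] + 3, :]
        assert band.mean() < 1.0

    def test_retina_invariant_under_different_corneas(self, flat_quiet_scene):
        _, _, pairs, gt = flat_quiet_scene
        rnfl = np.zeros(pairs[0].shape, dtype=bool)
        rnfl[gt.ilm_idx[0]:gt.rnfl_lower_idx[0], :] = True
        rets = []
        for (ret, ax) in ((10.0, 30.0), (25.0, -60.0)):
            comp, _ = compensate_anterior_segment(
                [to_stokes(apply_retarder(pairs[0], ret, ax))], gt.ilm_idx)
            rets.append(polarization_from_stokes(comp[0]).retardation_deg)
        assert np.abs(rets[0][rnfl] - rets[1][rnfl]).max() < 0.5

    def test_empty_surface_band_rejected(self, flat_quiet_scene):
        _, _, pairs, _ = flat_quiet_scene
        bad = np.full(pairs[0].shape[1], -1)
        with pytest.raises(ValueError):
            compensate_anterior_segment([to_stokes(pairs[0])], bad)


class TestDopu:
    def test_uniform_pure_state_gives_one(self):
        pair = pure_state(30.0, 45.0)
        pair = ComplexBScanPair(np.tile(pair.H, (16, 16)),
                                np.tile(pair.V, (16, 16)))
        d = compute_dopu(to_stokes(pair), (8, 4))
        assert np.allclose(d, 1.0, atol=1e-12)

    def test_random_states_depolarize(self):
        # resultant of 64 random unit vectors is O(1/8); well below 0.35
        rng = np.random.default_rng(0)
        n = 128
        chi = 0.5 * np.arccos(rng.uniform(-1, 1, (n, n)))
        beta = rng.uniform(0, 2 * np.pi, (n, n))
        pair = ComplexBScanPair(np.cos(chi) + 0j,
                                np.sin(chi) * np.exp(1j * beta))
        d = compute_dopu(to_stokes(pair), (8, 8))
        assert d.mean() < 0.35

    def test_single_pixel_window_is_one_on_pure_states(self):
        pair = random_pure_states(64, 6)
        d = compute_dopu(to_stokes(pair), (1, 1))
        assert np.allclose(d, 1.0, atol=1e-9)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            compute_dopu(to_stokes(random_pure_states(4)), (16, 16))

    def test_invariant_under_global_stokes_rotation(self):
        pair = random_pure_states(256, 7)
        pair2 = apply_retarder(pair, 37.0, 21.0)  # a global unitary
        d1 = compute_dopu(to_stokes(pair), (1, 8))
        d2 = compute_dopu(to_stokes(pair2), (1, 8))
        assert np.allclose(d1, d2, atol=1e-9)
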