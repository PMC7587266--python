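"""Frame ranking, registration and Stokes averaging."""

import dataclasses

import numpy as np
import pytest

from psoct_rnfl.averaging import (average_scan, estimate_shift,
                                  rank_by_correlation, select_frames)
from psoct_rnfl.polarization import (extract_polarization,
                                     polarization_from_stokes, to_stokes)
from psoct_rnfl.synthetic_data import (NoiseParams, make_phantom,
                                       render_circular_sequence)

from conftest import small_geometry


def _pol_frames(pairs):
    return [extract_polarization(p) for p in pairs]


class TestRanking:
    def test_identical_frames_all_score_one(self, flat_quiet_scene):
        _, _, pairs, _ = flat_quiet_scene
        _, scores = rank_by_correlation(_pol_frames(pairs), "first")
        assert np.allclose(scores, 1.0, atol=1e-12)

    def test_corrupted_frames_rank_last(self):
        # dropout + large shift against a clean majority
        geometry = small_geometry(n_bscans=20, n_ascans=128, n_depth=288)
        noise = NoiseParams(speckle=False, snr_db=25.0, jitter_sd_px=0.0,
                            corrupted_fraction=0.25)
        ph = make_phantom("flat", {"noise": noise}, seed=0, n_phi=128)
        pairs, gt = render_circular_sequence(ph, geometry, seed=3)
        _, scores = rank_by_correlation(_pol_frames(pairs), "first")
        worst = set(np.argsort(scores)[:int(gt.corrupted.sum())])
        assert worst == set(np.nonzero(gt.corrupted)[0])

    def test_scores_decrease_with_noise_level(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(0.5, 1.5, (64, 96))
        frames = []
        from psoct_rnfl.synthetic_data import ComplexBScanPair
        for k in range(20):
            noisy = base + 0.02 * (k + 1) * rng.standard_normal(base.shape)
            H = np.sqrt(np.clip(noisy, 1e-6, None)).astype(complex)
            frames.append(extract_polarization(
                ComplexBScanPair(H, np.zeros_like(H))))
        ref = extract_polarization(ComplexBScanPair(
            np.sqrt(base).astype(complex), np.zeros_like(base, complex)))
        _, scores = rank_by_correlation([ref] + frames, 0)
        assert np.all(np.diff(scores[1:]) < 0)

    def test_single_frame_rejected(self, flat_quiet_scene):
        _, _, pairs, _ = flat_quiet_scene
        with pytest.raises(ValueError):
            rank_by_correlation(_pol_frames(pairs[:1]))

    def test_medoid_avoids_shifted_outlier(self, flat_quiet_scene):
        _, _, pairs, _ = flat_quiet_scene
        pol = _pol_frames(pairs)
        shifted = dataclasses.replace(
            pol[0], reflectivity_db=np.roll(pol[0].reflectivity_db, 40, 0))
        ref_idx, _ = rank_by_correlation(pol[:3] + [shifted], "medoid")
        assert ref_idx < 3


class TestEstimateShift:
    def test_identity(self, flat_quiet_scene):
        _, _, pairs, _ = flat_quiet_scene
        pol = _pol_frames(pairs)
        assert estimate_shift(pol[0], pol[0]) == (0, 0)

    def test_constructed_roll_recovered(self, healthy_noisy_run):
        pol = extract_polarization(healthy_noisy_run["pairs"][0])
        rolled = dataclasses.replace(
            pol, reflectivity_db=np.roll(
                np.roll(pol.reflectivity_db, 3, axis=0), 17, axis=1))
        # frame = reference rolled by (+3, +17): align by rolling back
        assert estimate_shift(rolled, pol) == (-3, -17)

    def test_noisy_shift_recovery_rate(self):
        rng = np.random.default_rng(21)
        from psoct_rnfl.synthetic_data import ComplexBScanPair
        base = np.zeros((96, 128))
        base[30:60, :] = 1.0
        base += 0.05 * rng.standard_normal(base.shape)
        ref = extract_polarization(ComplexBScanPair(
            np.sqrt(np.clip(base, 1e-9, None)).astype(complex),
            np.zeros_like(base, complex)))
        hits = 0
        for _ in range(100):
            img = np.roll(np.roll(base, 2, axis=0), 5, axis=1)
            img = img + 0.1 * rng.standard_normal(img.shape)  # ~20 dB
            frame = extract_polarization(ComplexBScanPair(
                np.sqrt(np.clip(img, 1e-9, None)).astype(complex),
                np.zeros_like(img, complex)))
            if estimate_shift(frame, ref) == (-2, -5):
                hits += 1
        assert hits >= 95


class TestSelection:
    def test_selected_scores_dominate_rejected(self):
        scores = np.array([0.3, 0.9, 0.5, 0.8, 0.1, 0.7])
        sel = select_frames(scores, 3)
        rej = np.setdiff1d(np.arange(6), sel)
        assert scores[sel].min() >= scores[rej].max()

    def test_short_sequence_selects_all_with_warning(self):
        with pytest.warns(UserWarning, match="selecting all"):
            sel = select_frames(np.array([0.5, 0.6]), 50)
        assert len(sel) == 2


class TestAverageScan:
    def test_identical_frames_idempotent(self, flat_quiet_scene):
        _, geometry, pairs, _ = flat_quiet_scene
        stokes = [to_stokes(p) for p in pairs]
        n = len(stokes)
        avg = average_scan(stokes, np.arange(n), np.zeros((n, 2), int),
                           geometry)
        single = polarization_from_stokes(stokes[0])
        assert np.allclose(avg.mean_retardation_deg, single.retardation_deg,
                           atol=1e-9)

    def test_single_frame_selection_reproduces_frame(self, healthy_noisy_run):
        stokes = [to_stokes(healthy_noisy_run["pairs"][0])]
        avg = average_scan(stokes, np.array([0]), np.zeros((1, 2), int))
        direct = polarization_from_stokes(stokes[0])
        assert np.allclose(avg.mean_retardation_deg, direct.retardation_deg)

    def test_permutation_invariance(self, healthy_noisy_run):
        pairs = healthy_noisy_run["pairs"][:6]
        stokes = [to_stokes(p) for p in pairs]
        shifts = np.zeros((6, 2), int)
        a = average_scan(stokes, np.arange(6), shifts)
        perm = np.array([4, 2, 0, 5, 1, 3])
        b = average_scan(stokes, perm, shifts)
        assert np.allclose(a.mean_retardation_deg, b.mean_retardation_deg,
                           atol=1e-9)

    def test_empty_selection_rejected(self, flat_quiet_scene):
        _, _, pairs, _ = flat_quiet_scene
        with pytest.raises(ValueError):
            average_scan([to_stokes(pairs[0])], np.array([], int),
                         np.zeros((0, 2), int))

    def test_registration_undoes_pure_jitter(self):
        # noise-free but jittered structured scene: exact shift recovery,
        # and the average matches the unjittered frame away from the
        # axially zero-filled edges
        geometry = small_geometry(n_bscans=6, n_ascans=128, n_depth=288)
        noise = NoiseParams(speckle=False, snr_db=None, jitter_sd_px=3.0,
                            corrupted_fraction=0.0)
        ph = make_phantom("healthy", {"noise": noise}, seed=0, n_phi=128)
        pairs, gt = render_circular_sequence(ph, geometry, seed=5)
        pol = _pol_frames(pairs)
        ref_idx, scores = rank_by_correlation(pol, "medoid")
        shifts = np.array([estimate_shift(pol[i], pol[ref_idx])
                           for i in range(6)])
        assert np.array_equal(shifts, gt.shifts[ref_idx] - gt.shifts)
        stokes = [to_stokes(p) for p in pairs]
        avg = average_scan(stokes, np.arange(6), shifts, geometry,
                           reference_index=ref_idx)
        ref_ret = polarization_from_stokes(stokes[ref_idx]).retardation_deg
        max_shift = int(np.abs(gt.shifts[:, 0]).max()
                        + abs(gt.shifts[ref_idx, 0]))
        inner = slice(max_shift + 1, 288 - max_shift - 1)
        assert np.allclose(avg.mean_retardation_deg[inner, :],
                           ref_ret[inner, :], atol=1e-6)

    def test_speckle_variance_reduction(self):
        # retardation noise arises from detector noise at speckle-dimmed
        # pixels; Stokes averaging over 50 frames must cut it by >> 5x
        geometry = small_geometry(n_bscans=50, n_ascans=96, n_depth=256)
        noise = NoiseParams(speckle=True, snr_db=30.0, jitter_sd_px=0.0,
                            corrupted_fraction=0.0)
        ph = make_phantom("flat", {"noise": noise}, seed=0, n_phi=96)
        pairs, gt = render_circular_sequence(ph, geometry, seed=6)
        stokes = [to_stokes(p) for p in pairs]
        avg = average_scan(stokes, np.arange(50), np.zeros((50, 2), int),
                           geometry)
        rnfl = slice(gt.ilm_idx[0] + 5, gt.rnfl_lower_idx[0] - 5)
        single = polarization_from_stokes(stokes[0]).retardation_deg
        true_ret = 0.135 * np.minimum(
            (np.arange(256)[rnfl] - gt.ilm_idx[0] + 1) * 2.0, 125.0)
        err_single = (single[rnfl, :] - true_ret[:, None]).std()
        err_avg = (avg.mean_retardation_deg[rnfl, :]
                   - true_ret[:, None]).std()
        assert err_avg < err_single / 5.0
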