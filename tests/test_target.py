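import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srtrack.levelset import LevelSet, init_level_set
from srtrack.target import (
    RegionModels,
    bhattacharyya_energy,
    bin_map,
    build_models,
    pixel_weights,
    region_distributions,
)
from tests.conftest import disk_mask


class TestInitLevelSet:
    def test_disk_signed_distance(self):
        mask = disk_mask((64, 64), (32, 32), 10)
        ls = init_level_set(mask)
        assert ls.phi[32, 32] == pytest.approx(10, abs=0.5)
        # zero level on the circle
        for ang in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            y = int(round(32 + 10 * np.sin(ang)))
            x = int(round(32 + 10 * np.cos(ang)))
            assert abs(ls.phi[y, x]) < 1.2

    def test_complement_flips_sign(self):
        mask = disk_mask((64, 64), (32, 32), 10)
        phi = init_level_set(mask).phi
        phic = init_level_set(~mask).phi
        off_boundary = np.abs(phi) > 1.0
        np.testing.assert_allclose(phi[off_boundary], -phic[off_boundary], atol=1.0)

    def test_band_pixel_count_matches_annulus_area(self):
        mask = disk_mask((64, 64), (32, 32), 10)
        ls = init_level_set(mask, th=3.0)
        count = int(ls.band.sum())
        annulus = np.pi * (13**2 - 10**2)  # approx 217
        assert abs(count - annulus) / annulus < 0.15

    def test_gradient_magnitude_near_one_on_band(self):
        mask = disk_mask((64, 64), (32, 32), 12)
        ls = init_level_set(mask)
        gy, gx = np.gradient(ls.phi)
        mag = np.sqrt(gx**2 + gy**2)
        band = np.abs(ls.phi) < 8
        assert 0.8 <= np.median(mag[band]) <= 1.2

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValueError):
            init_level_set(np.zeros((8, 8), bool))
        with pytest.raises(ValueError):
            init_level_set(np.ones((8, 8), bool))


class TestBuildModels:
    def test_single_intensity_foreground_is_indicator(self):
        mask = disk_mask((32, 32), (16, 16), 6)
        frame = np.where(mask, 0.9, 0.1)
        ls = init_level_set(mask)
        m = build_models(frame, ls, r=8)
        assert m.fd[7] == pytest.approx(1.0)
        assert m.fd[:7].sum() == pytest.approx(0.0)

    def test_histograms_normalized(self, rng):
        mask = disk_mask((32, 32), (16, 16), 6)
        frame = rng.random((32, 32))
        m = build_models(frame, init_level_set(mask), r=16)
        assert m.fd.sum() == pytest.approx(1.0, abs=1e-12)
        assert m.bd.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_counted_two_bin_histogram(self):
        # 3x3 foreground: four pixels at 0.1, five at 0.6; r=2 -> (4/9, 5/9)
        frame = np.full((16, 16), 0.6)
        frame[6, 6] = frame[6, 7] = frame[7, 6] = frame[7, 7] = 0.1
        mask = np.zeros((16, 16), bool)
        mask[6:9, 6:9] = True
        m = build_models(frame, init_level_set(mask, th=4), r=2)
        np.testing.assert_allclose(m.fd, [4 / 9, 5 / 9], atol=1e-12)

    def test_too_few_bins_rejected(self, disk_phantom):
        frame, mask = disk_phantom
        with pytest.raises(ValueError):
            build_models(frame, init_level_set(mask), r=1)


class TestRegionDistributions:
    def test_crisp_heaviside_reduces_to_models(self, rng):
        mask = disk_mask((48, 48), (24, 24), 8)
        frame = rng.random((48, 48))
        ls = init_level_set(mask)
        m = build_models(frame, ls, r=8)
        d = region_distributions(frame, ls, r=8, eps=1e-9)
        np.testing.assert_allclose(d.fg, m.fd, atol=1e-6)
        np.testing.assert_allclose(d.bg, m.bd, atol=1e-6)

    def test_distributions_sum_to_one(self, noisy_disk_phantom):
        frame, mask = noisy_disk_phantom
        d = region_distributions(frame, init_level_set(mask))
        assert d.fg.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.bg.sum() == pytest.approx(1.0, abs=1e-12)

    def test_boundary_pixel_contributes_half_mass(self):
        # phi = 0 exactly at one pixel: H_eps(0) = 0.5
        phi = np.full((9, 9), -5.0)
        phi[4, 4] = 0.0
        frame = np.full((9, 9), 0.95)
        ls = LevelSet(phi=phi, th=10.0)
        d = region_distributions(frame, ls, r=4, eps=1.5)
        assert d.Ff == pytest.approx(0.5 + 80 * 0.5 * (1 + (2 / np.pi) * np.arctan(-5 / 1.5)),
                                     rel=1e-9)


class TestBhattacharyya:
    def _uniform(self, r):
        v = np.full(r, 1.0 / r)
        return v

    def test_perfect_match_scores_one_plus_gamma(self):
        r = 8
        models = RegionModels(fd=self._uniform(r), bd=self._uniform(r), r=r,
                              bin_edges=np.linspace(0, 1, r + 1))
        from srtrack.target import RegionDistributions

        d = RegionDistributions(fg=self._uniform(r), bg=self._uniform(r), Ff=10, Fb=10)
        assert bhattacharyya_energy(d, models, gamma=1.0) == pytest.approx(2.0)

    def test_disjoint_supports_score_zero(self):
        from srtrack.target import RegionDistributions

        fd = np.array([1.0, 0.0])
        fg = np.array([0.0, 1.0])
        models = RegionModels(fd=fd, bd=fd.copy(), r=2, bin_edges=np.linspace(0, 1, 3))
        d = RegionDistributions(fg=fg, bg=fg.copy(), Ff=1, Fb=1)
        assert bhattacharyya_energy(d, models, gamma=1.0) == 0.0

    def test_hand_value_gamma_zero(self):
        from srtrack.target import RegionDistributions

        models = RegionModels(fd=np.array([0.25, 0.75]), bd=np.array([0.5, 0.5]),
                              r=2, bin_edges=np.linspace(0, 1, 3))
        d = RegionDistributions(fg=np.array([0.5, 0.5]), bg=np.array([0.5, 0.5]),
                                Ff=1, Fb=1)
        val = bhattacharyya_energy(d, models, gamma=0.0)
        assert val == pytest.approx(np.sqrt(0.125) + np.sqrt(0.375), rel=1e-12)
        assert val == pytest.approx(0.96593, abs=1e-5)

    def test_length_mismatch_rejected(self):
        from srtrack.target import RegionDistributions

        models = RegionModels(fd=self._uniform(4), bd=self._uniform(4), r=4,
                              bin_edges=np.linspace(0, 1, 5))
        d = RegionDistributions(fg=self._uniform(8), bg=self._uniform(8), Ff=1, Fb=1)
        with pytest.raises(ValueError):
            bhattacharyya_energy(d, models)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 2.0))
    def test_bounded_by_one_plus_gamma(self, seed, gamma):
        from srtrack.target import RegionDistributions

        r = 8
        rng = np.random.default_rng(seed)
        def rand_dist():
            v = rng.random(r) + 1e-12
            return v / v.sum()

        models = RegionModels(fd=rand_dist(), bd=rand_dist(), r=r,
                              bin_edges=np.linspace(0, 1, r + 1))
        d = RegionDistributions(fg=rand_dist(), bg=rand_dist(), Ff=1, Fb=1)
        val = bhattacharyya_energy(d, models, gamma=gamma)
        assert 0.0 <= val <= 1.0 + gamma + 1e-9

    def test_invariant_under_bin_permutation(self, rng):
        from srtrack.target import RegionDistributions

        r = 8
        def rand_dist():
            v = rng.random(r) + 1e-12
            return v / v.sum()

        fd, bd, fg, bg = rand_dist(), rand_dist(), rand_dist(), rand_dist()
        perm = rng.permutation(r)
        models = RegionModels(fd=fd, bd=bd, r=r, bin_edges=np.linspace(0, 1, r + 1))
        modelsP = RegionModels(fd=fd[perm], bd=bd[perm], r=r, bin_edges=np.linspace(0, 1, r + 1))
        d = RegionDistributions(fg=fg, bg=bg, Ff=1, Fb=1)
        dP = RegionDistributions(fg=fg[perm], bg=bg[perm], Ff=1, Fb=1)
        assert bhattacharyya_energy(d, models) == pytest.approx(
            bhattacharyya_energy(dP, modelsP), rel=1e-12
        )


class TestPixelWeights:
    def test_matching_distributions_give_unit_weights(self, rng):
        mask = disk_mask((48, 48), (24, 24), 8)
        frame = rng.random((48, 48))
        ls = init_level_set(mask)
        m = build_models(frame, ls, r=8)
        d = region_distributions(frame, ls, r=8, eps=1e-9)
        hf, _ = pixel_weights(frame, ls, m, d)
        fg_pixels = ls.foreground
        np.testing.assert_allclose(hf[fg_pixels], 1.0, atol=1e-3)

    def test_zero_model_bin_gives_zero_weight(self):
        from srtrack.target import RegionDistributions

        frame = np.array([[0.1, 0.9]])
        models = RegionModels(fd=np.array([0.0, 1.0]), bd=np.array([1.0, 0.0]),
                              r=2, bin_edges=np.linspace(0, 1, 3))
        d = RegionDistributions(fg=np.array([0.5, 0.5]), bg=np.array([0.5, 0.5]),
                                Ff=1, Fb=1)
        ls = LevelSet(phi=np.zeros((1, 2)))
        hf, hb = pixel_weights(frame, ls, models, d)
        assert hf[0, 0] == 0.0  # fd == 0 in that bin
        assert hb[0, 1] == 0.0

    def test_hand_values(self):
        from srtrack.target import RegionDistributions

        frame = np.array([[0.1, 0.9]])  # bin 0, bin 1
        models = RegionModels(fd=np.array([0.8, 0.2]), bd=np.array([0.5, 0.5]),
                              r=2, bin_edges=np.linspace(0, 1, 3))
        d = RegionDistributions(fg=np.array([0.5, 0.5]), bg=np.array([0.5, 0.5]),
                                Ff=1, Fb=1)
        hf, _ = pixel_weights(frame, LevelSet(phi=np.zeros((1, 2))), models, d)
        assert hf[0, 0] == pytest.approx(np.sqrt(1.6), rel=1e-12)
        assert hf[0, 1] == pytest.approx(np.sqrt(0.4), rel=1e-12)
        assert hf[0, 0] == pytest.approx(1.2649, abs=1e-4)
        assert hf[0, 1] == pytest.approx(0.6325, abs=1e-4)


def test_translation_sweep_peaks_at_true_shift(rng):
    """Brute-force energy sweep over candidate translations peaks at the
    true rigid shift of the target (+-1 px)."""
    from srtrack.registration import AffinePose, registration_energy, warp_level_set

    yy, xx = np.mgrid[0:64, 0:64]
    m0 = (np.abs(xx - 28) <= 7) & (np.abs(yy - 30) <= 7)
    f0 = np.where(m0, 0.75, 0.3) + 0.02 * rng.normal(size=(64, 64))
    m1 = (np.abs(xx - 31) <= 7) & (np.abs(yy - 28) <= 7)  # shift (+3, -2)
    f1 = np.where(m1, 0.75, 0.3) + 0.02 * rng.normal(size=(64, 64))
    ls = init_level_set(m0)
    models = build_models(f0, ls)
    d0 = region_distributions(f1, ls)
    hf, hb = pixel_weights(f1, ls, models, d0)
    best = None
    for tx in range(-5, 6):
        for ty in range(-5, 6):
            w = warp_level_set(ls, AffinePose.translation(tx, ty))
            e = registration_energy(w.phi, ls.th, hf, hb, 0.5, 1.5)
            if best is None or e > best[0]:
                best = (e, tx, ty)
    assert abs(best[1] - 3) <= 1 and abs(best[2] + 2) <= 1


def test_bin_map_edges():
    assert bin_map(np.array([[0.0, 0.999, 1.0]]), 8).tolist() == [[0, 7, 7]]
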