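import numpy as np
import pytest

from destripe import HeightImage, make_gaussian_logf_fixture
from destripe.spectrum import LogF, forward_spectrum, log_amplitude, reflect_index
from destripe import detect
from destripe.detect import (
    InertiaSummary,
    PixelLabelGrid,
    central_candidates,
    fit_central_gaussian,
    gaussian_deviation,
    global_sampling,
    grow_central_region,
    heterogeneity_map,
    inertia_summary,
    laplacian_map,
    screen_and_cluster,
    threshold_from_histogram,
)

from oracles import eig2_brute, heterogeneity_brute, laplacian_brute


def make_het(H):
    """Heterogeneity container with a hand-designed H map."""
    H = np.asarray(H, dtype=float)
    return detect.HeterogeneityMap(H, np.zeros_like(H), 0.0, 1.0, 0.0, 1.0)


class TestLaplacian:
    def test_annihilates_constants(self):
        logf = LogF(np.full((9, 9), 2.5))
        np.testing.assert_array_equal(laplacian_map(logf), np.zeros((9, 9)))

    def test_impulse_response_is_kernel(self):
        vals = np.zeros((9, 9))
        vals[4, 4] = 1.0
        lap = laplacian_map(LogF(vals))
        assert lap[4, 4] == 8.0
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if (di, dj) != (0, 0):
                    assert lap[4 + di, 4 + dj] == -1.0
        lap[3:6, 3:6] = 0.0
        assert not lap.any()

    def test_matches_brute_force_with_wraparound(self, rng):
        vals = rng.normal(size=(8, 8))
        np.testing.assert_allclose(
            laplacian_map(LogF(vals)), laplacian_brute(vals), atol=1e-12
        )


class TestHeterogeneity:
    def test_flat_map_is_all_zero(self):
        het = heterogeneity_map(LogF(np.full((8, 8), 1.3)))
        np.testing.assert_array_equal(het.H, np.zeros((8, 8)))

    def test_spike_attains_one(self):
        vals = np.zeros((9, 9))
        vals[4, 4] = 5.0  # both the Laplacian and intensity maxima
        het = heterogeneity_map(LogF(vals))
        assert het.H[4, 4] == pytest.approx(1.0)
        assert het.H.max() == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        vals = rng.normal(size=(8, 8))
        het = heterogeneity_map(LogF(vals))
        np.testing.assert_allclose(het.H, heterogeneity_brute(vals), atol=1e-12)
        assert het.H.min() >= 0.0 and het.H.max() <= 1.0


class TestThresholdFromHistogram:
    @staticmethod
    def values_with_bins(populations, n_bins=20):
        vals = []
        width = 1.0 / n_bins
        for b, pop in enumerate(populations):
            vals.extend([b * width + width / 2] * pop)
        return np.array(vals)

    def test_hand_enumerated_example(self):
        pops = [0] * 20
        pops[2], pops[3], pops[4], pops[5], pops[6] = 5, 10, 8, 4, 2
        thr, bins, tbin = threshold_from_histogram(self.values_with_bins(pops), 20)
        assert bins == pops
        assert tbin == 5  # first bin at <= half the run maximum
        assert thr == pytest.approx(0.275)

    def test_single_bin_degenerate(self):
        thr, bins, tbin = threshold_from_histogram(np.full(50, 0.42), 20)
        assert tbin is None
        assert thr == pytest.approx(0.45)  # upper edge of the lone bin
        assert (np.full(50, 0.42) > thr).sum() == 0

    def test_tie_broken_by_population(self):
        pops = [0] * 20
        pops[1], pops[2] = 3, 3
        pops[5], pops[6] = 10, 2
        thr, _, tbin = threshold_from_histogram(self.values_with_bins(pops), 20)
        assert tbin == 6
        assert thr == pytest.approx(0.325)

    def test_exact_tie_prefers_lower_values(self):
        pops = [0] * 20
        pops[1], pops[2] = 4, 2
        pops[5], pops[6] = 4, 2
        thr, _, tbin = threshold_from_histogram(self.values_with_bins(pops), 20)
        assert tbin == 2
        assert thr == pytest.approx(0.125)

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            threshold_from_histogram(np.array([]), 20)
        with pytest.raises(ValueError):
            threshold_from_histogram(np.array([0.5, 1.2]), 20)


class TestGlobalSampling:
    def test_flat_logf_selects_nothing(self):
        pn1, thr = global_sampling(LogF(np.full((16, 16), 3.0)))
        assert not pn1.any()

    def test_planted_spikes_are_selected(self):
        # smooth radial decay whose roughness grows only where intensity is
        # low, so background pixels can never clear both thresholds at once
        rng = np.random.default_rng(7)
        ii, jj = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        r = np.hypot(ii - 16, jj - 16)
        vals = 5.0 - 0.1 * r + 0.5 * (r / 22.0) ** 2 * rng.standard_normal((32, 32))
        planted = [(6, 16), (26, 16), (16, 6), (16, 26), (9, 9),
                   (9, 23), (23, 9), (23, 23), (6, 10), (26, 22)]
        for p in planted:
            vals[p] = 9.0
        pn1, thr = global_sampling(LogF(vals))
        for p in planted:
            assert pn1[p], f"planted spike {p} missed"
        # smooth background stays out
        background = pn1.copy()
        for p in planted:
            background[p] = False
        assert background.sum() == 0

    def test_membership_definition_reasserted(self, rng):
        vals = rng.normal(size=(16, 16)) + np.linspace(0, 3, 256).reshape(16, 16)
        logf = LogF(vals)
        pn1, thr = global_sampling(logf)
        het = heterogeneity_map(logf)
        for p in np.argwhere(pn1):
            p = tuple(p)
            assert het.H[p] > thr.h_ref and vals[p] > thr.i_ref

    def test_raising_h_ref_never_recruits_new_pixels(self, rng):
        vals = rng.normal(size=(24, 24)) * 2.0
        logf = LogF(vals)
        base, _ = global_sampling(logf)
        for scale in (1.2, 1.5, 2.0):
            smaller, _ = global_sampling(logf, h_ref_scale=scale)
            assert not (smaller & ~base).any()

    def test_symmetric_spectrum_gives_symmetric_candidates(self, rng):
        img = HeightImage(rng.normal(size=(32, 32)) + 1.0)
        logf = log_amplitude(forward_spectrum(img))
        pn1, _ = global_sampling(logf)
        mirrored = np.zeros_like(pn1)
        for p in np.argwhere(pn1):
            mirrored[reflect_index(tuple(p), logf.dc, logf.shape)] = True
        disagree = (pn1 ^ mirrored).sum()
        assert disagree <= max(1, 0.05 * pn1.sum())


class TestInertia:
    def test_single_pixel_degenerate(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[5, 9] = True
        s = inertia_summary(mask, LogF(np.full((16, 16), 2.0)))
        assert s.centroid == (5.0, 9.0)
        assert s.sigma_x == pytest.approx(0.0)
        assert s.sigma_y == pytest.approx(0.0)
        assert s.initial_radius == 1.0  # floored

    def test_cross_second_moment_by_hand(self):
        mask = np.zeros((16, 16), dtype=bool)
        for p in [(8, 8), (6, 8), (10, 8), (8, 6), (8, 10)]:
            mask[p] = True
        s = inertia_summary(mask, LogF(np.full((16, 16), 3.0)))
        assert s.centroid == (8.0, 8.0)
        # arms of length 2: weighted positional variance 8/5 per axis
        assert s.sigma_x == pytest.approx(1.6)
        assert s.sigma_y == pytest.approx(1.6)
        assert s.initial_radius == pytest.approx(np.sqrt(3.2))

    def test_matches_brute_force_eigensolver(self, rng):
        for _ in range(10):
            mask = rng.random((12, 12)) < 0.3
            if mask.sum() < 2:
                continue
            vals = rng.normal(size=(12, 12))
            s = inertia_summary(mask, LogF(vals))
            idx = np.argwhere(mask).astype(float)
            w = vals[mask]
            w = w - min(0.0, w.min())
            if w.sum() <= 0:
                w = np.ones_like(w)
            cen = (w @ idx) / w.sum()
            d = idx - cen
            a = float((w * d[:, 0] ** 2).sum() / w.sum())
            b = float((w * d[:, 0] * d[:, 1]).sum() / w.sum())
            c = float((w * d[:, 1] ** 2).sum() / w.sum())
            hi, lo = eig2_brute(a, b, c)
            assert s.sigma_x == pytest.approx(hi, abs=1e-10)
            assert s.sigma_y == pytest.approx(lo, abs=1e-10)
            # eigenvector property: T v = lambda v
            T = np.array([[a, b], [b, c]])
            np.testing.assert_allclose(T @ s.eigvec_x, hi * s.eigvec_x, atol=1e-8)
            assert np.dot(s.eigvec_x, s.eigvec_y) == pytest.approx(0.0, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            inertia_summary(np.zeros((8, 8), dtype=bool), LogF(np.zeros((8, 8))))


class TestGrowCentralRegion:
    def test_dense_core_stops_at_dilution(self):
        shape = (33, 33)
        ii, jj = np.meshgrid(np.arange(33), np.arange(33), indexing="ij")
        dist = np.hypot(ii - 16, jj - 16)
        pn1 = dist <= 6.0  # a filled disk, density 1 inside, 0 outside
        inertia = inertia_summary(pn1, LogF(np.full(shape, 2.0)))
        c0, pn2, r_final = grow_central_region(pn1, inertia, shape)
        # re-derive the stop radius independently
        step = inertia.initial_radius / 10.0
        r = step
        while True:
            disk = dist <= r
            if (pn1 & disk).sum() / disk.sum() <= 0.85:
                break
            r += step
        assert r_final == pytest.approx(r)
        np.testing.assert_array_equal(c0, pn1 & (dist <= r_final))
        assert r_final > 6.0  # kept growing while fully dense

    def test_sparse_set_stops_immediately(self):
        shape = (32, 32)
        pn1 = np.zeros(shape, dtype=bool)
        pn1[4, 4] = pn1[28, 28] = True
        inertia = inertia_summary(pn1, LogF(np.full(shape, 1.0)))
        c0, pn2, r_final = grow_central_region(pn1, inertia, shape)
        assert r_final == pytest.approx(inertia.initial_radius / 10.0)
        np.testing.assert_array_equal(c0 | pn2, pn1)

    def test_partitions_pn1(self, rng):
        for _ in range(5):
            pn1 = rng.random((20, 20)) < 0.2
            if not pn1.any():
                continue
            logf = LogF(rng.normal(size=(20, 20)))
            inertia = inertia_summary(pn1, logf)
            c0, pn2, _ = grow_central_region(pn1, inertia, (20, 20))
            np.testing.assert_array_equal(c0 | pn2, pn1)
            assert not (c0 & pn2).any()


def exact_inertia(center, sigmas, eigvec_x):
    ex = np.asarray(eigvec_x, dtype=float)
    ey = np.array([-ex[1], ex[0]])
    return InertiaSummary(
        centroid=center,
        sigma_x=sigmas[0],
        sigma_y=sigmas[1],
        eigvec_x=ex,
        eigvec_y=ey,
        initial_radius=max(1.0, float(np.sqrt(sigmas[0] + sigmas[1]))),
    )


class TestGaussianFit:
    def test_recovers_planted_parameters_exactly(self):
        logf = make_gaussian_logf_fixture((7, 7), 10.0, 1.0, 1.0, (4.0, 4.0))
        inertia = exact_inertia((3.0, 3.0), (4.0, 4.0), (1.0, 0.0))
        model = fit_central_gaussian(np.ones((7, 7), dtype=bool), logf, inertia)
        assert model.i0_value == pytest.approx(10.0, abs=1e-6)
        assert model.c1 == pytest.approx(1.0, abs=1e-6)
        assert model.c2 == pytest.approx(1.0, abs=1e-6)
        assert model.residual <= 1e-12

    def test_rotation_identity_theta_zero(self):
        inertia = exact_inertia((3.0, 3.0), (6.0, 2.0), (1.0, 0.0))
        sx, sy, theta = detect._rotated_sigmas(inertia)
        assert theta == pytest.approx(0.0)
        assert (sx, sy) == (pytest.approx(6.0), pytest.approx(2.0))

    def test_rotation_swaps_at_ninety_degrees(self):
        inertia = exact_inertia((3.0, 3.0), (6.0, 2.0), (0.0, 1.0))
        sx, sy, theta = detect._rotated_sigmas(inertia)
        assert abs(theta) == pytest.approx(np.pi / 2)
        assert sx == pytest.approx(2.0)  # sigma_x' = sigma_y
        assert sy == pytest.approx(6.0)  # sigma_y' = sigma_x*sigma_y/sigma_x'

    def test_too_few_pixels_rejected(self):
        logf = make_gaussian_logf_fixture((7, 7), 10.0, 1.0, 1.0, (4.0, 4.0))
        c0 = np.zeros((7, 7), dtype=bool)
        c0[3, 3] = c0[3, 4] = c0[4, 3] = True
        inertia = exact_inertia((3.0, 3.0), (4.0, 4.0), (1.0, 0.0))
        with pytest.raises(ValueError, match="need >= 4"):
            fit_central_gaussian(c0, logf, inertia)

    def test_noisy_recovery_within_five_percent(self):
        for seed in range(3):
            logf = make_gaussian_logf_fixture(
                (9, 9), 10.0, 1.0, 1.0, (4.0, 4.0), noise_sd=0.1, seed=seed
            )
            inertia = exact_inertia((4.0, 4.0), (4.0, 4.0), (1.0, 0.0))
            model = fit_central_gaussian(np.ones((9, 9), dtype=bool), logf, inertia)
            assert model.i0_value == pytest.approx(10.0, rel=0.05)
            assert model.c1 == pytest.approx(1.0, rel=0.05)
            assert model.c2 == pytest.approx(1.0, rel=0.05)


class TestCentralCandidates:
    def _setup(self):
        logf = make_gaussian_logf_fixture((7, 7), 10.0, 1.0, 1.0, (4.0, 4.0))
        inertia = exact_inertia((3.0, 3.0), (4.0, 4.0), (1.0, 0.0))
        c0 = np.ones((7, 7), dtype=bool)
        model = fit_central_gaussian(c0, logf, inertia)
        return logf, c0, model

    def test_exact_model_data_yields_empty_set(self):
        logf, c0, model = self._setup()
        assert not central_candidates(c0, model, logf).any()

    def test_inflated_pixel_is_caught(self):
        logf, c0, model = self._setup()
        logf.values[1, 5] *= 2.0
        cn1 = central_candidates(c0, model, logf)
        assert cn1[1, 5]
        f = gaussian_deviation(model, logf, np.argwhere(cn1))
        assert (f > 0).all()

    def test_subset_of_c0(self, rng):
        logf, c0, model = self._setup()
        logf.values += rng.normal(0, 0.5, size=(7, 7))
        c0[0, :] = False
        cn1 = central_candidates(c0, model, logf)
        assert not (cn1 & ~c0).any()


class TestScreenAndCluster:
    def test_empty_candidates(self):
        out = screen_and_cluster(
            np.zeros((20, 20), dtype=bool), LogF(np.zeros((20, 20))), 20
        )
        assert not out.any()

    def _bulk_and(self, shape, special, H_special=0.85):
        """Candidates: a low-H bulk plus hand-placed high-H pixels."""
        H = np.zeros(shape)
        cand = np.zeros(shape, dtype=bool)
        # scattered bulk, one pixel per row stride, H = 0.15
        k = 0
        for i in range(0, shape[0], 2):
            j = (7 * k) % shape[1]
            if not any((i, j) == p for p in special):
                H[i, j] = 0.15
                cand[i, j] = True
            k += 1
        for p in special:
            H[p] = H_special
            cand[p] = True
        return cand, make_het(H)

    def test_vertical_run_of_five_retained(self):
        special = [(r, 10) for r in range(5, 10)]
        cand, het = self._bulk_and((20, 20), special)
        out = screen_and_cluster(cand, LogF(np.zeros((20, 20))), 20, het=het)
        for p in special:
            assert out[p]
        assert out.sum() == 5

    def test_scattered_isolated_pixels_dropped(self):
        special = [(3, 3), (9, 15), (15, 7)]
        cand, het = self._bulk_and((20, 20), special)
        out = screen_and_cluster(cand, LogF(np.zeros((20, 20))), 20, het=het)
        assert not out.any()

    def test_line_span_criterion_catches_gappy_stripe(self):
        special = [(4, j) for j in (1, 5, 9, 13, 17)]  # span 17 > 2/3 * 20
        cand, het = self._bulk_and((20, 20), special)
        out = screen_and_cluster(cand, LogF(np.zeros((20, 20))), 20, het=het)
        for p in special:
            assert out[p]
        assert out.sum() == 5


class TestPixelLabelGrid:
    def test_set_algebra_enforced(self):
        g = PixelLabelGrid((8, 8))
        g.pn1[1, 1] = True
        g.c0[1, 1] = True
        g.cn1[1, 1] = True
        g.cn2[1, 1] = True
        g.validate()
        g.cn2[2, 2] = True  # Cn2 must stay inside Cn1
        with pytest.raises(ValueError, match="Cn2"):
            g.validate()

    def test_pn2_is_derived_partition(self):
        g = PixelLabelGrid((8, 8))
        g.pn1[0, 0] = g.pn1[0, 1] = True
        g.c0[0, 0] = True
        assert g.pn2[0, 1] and not g.pn2[0, 0]
        assert g.counts()["Pn2"] == 1

    def test_label_codes_use_deepest_set(self):
        g = PixelLabelGrid((8, 8))
        g.pn1[1, 1] = g.c0[1, 1] = g.cn1[1, 1] = g.cn2[1, 1] = True
        g.pn1[2, 2] = True
        codes = g.label_codes()
        assert codes[1, 1] == detect.LABEL_CODES["Cn2"]
        assert codes[2, 2] == detect.LABEL_CODES["Pn2"]
        assert codes[0, 0] == detect.LABEL_CODES["clean"]
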