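"""Enhancement chain: gamma, band selection, erosion, LoG, PCA, subtraction, CNR."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from corneahsi import (
    BallSE,
    EnhanceConfig,
    HyperCube,
    ReferenceFrames,
    cnr,
    enhance_image,
    erode,
    flat_field_correct,
    gamma_adjust,
    log_filter,
    log_kernel,
    make_scene,
    pc_subtract,
    pca_fit,
    select_band_group,
)


class TestGammaAdjust:
    def test_gamma_one_is_identity(self, rng):
        img = rng.uniform(10, 90, (16, 16))
        np.testing.assert_allclose(gamma_adjust(img, 1.0, (0, 100)), img, atol=1e-12)

    def test_known_power_law_values(self):
        # image spanning [0, 1] with clip (0, 100): normalised value r maps to r**gamma
        img = np.array([[0.0, 0.25, 0.5, 1.0]])
        out = gamma_adjust(img, 0.5, (0, 100))
        assert out[0, 1] == pytest.approx(0.5)
        out = gamma_adjust(img, 2.0, (0, 100))
        assert out[0, 2] == pytest.approx(0.25)

    def test_gamma_above_one_darkens(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        out = gamma_adjust(img, 2.0, (0, 100))
        assert (out <= img + 1e-12).all()

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gamma_adjust(np.full((8, 8), 3.0), 0.7)


def _ball_offsets(se: BallSE):
    r = se.radius
    offs = []
    for u in range(-r, r + 1):
        for v in range(-r, r + 1):
            if u * u + v * v <= r * r:
                offs.append((u, v, se.height * np.sqrt(1 - (u * u + v * v) / r**2)))
    return offs


class TestErosion:
    def test_constant_image_flat_se(self):
        out = erode(np.full((10, 10), 4.0), np.ones((3, 3), dtype=bool))
        np.testing.assert_allclose(out, 4.0)

    def test_constant_image_ball_drops_by_height(self):
        out = erode(np.full((12, 12), 9.0), BallSE(3, 5.0))
        # min over support of (c - b(u)) = c - max b = c - h
        np.testing.assert_allclose(out, 4.0)

    def test_matches_brute_force_oracle_interior(self, rng):
        img = rng.uniform(0, 10, (12, 12))
        se = BallSE(2, 3.0)
        out = erode(img, se)
        offs = _ball_offsets(se)
        for i in range(2, 10):
            for j in range(2, 10):
                expected = min(img[i + u, j + v] - b for u, v, b in offs)
                assert out[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_grey_erosion(self, rng):
        img = rng.uniform(0, 100, (20, 20))
        se = BallSE(4, 7.0)
        ours = erode(img, se, border="reflect")
        ref = ndi.grey_erosion(img, footprint=se.footprint, structure=se.heights, mode="reflect")
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_anti_extensive_for_nonnegative_height(self, rng):
        img = rng.uniform(0, 10, (15, 15))
        assert (erode(img, BallSE(2, 1.5)) <= img + 1e-12).all()

    def test_order_preserving(self, rng):
        img1 = rng.uniform(0, 10, (15, 15))
        img2 = img1 + rng.uniform(0, 5, (15, 15))
        se = BallSE(2, 2.0)
        assert (erode(img1, se) <= erode(img2, se) + 1e-12).all()

    def test_omit_border_policy_interior_unchanged(self, rng):
        img = rng.uniform(0, 10, (15, 15))
        se = BallSE(2, 2.0)
        a = erode(img, se, border="reflect")
        b = erode(img, se, border="omit")
        np.testing.assert_allclose(a[2:-2, 2:-2], b[2:-2, 2:-2], atol=1e-12)

    def test_se_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            erode(np.zeros((5, 5)), BallSE(4, 1.0))


class TestLoG:
    def test_kernel_matches_sampled_expression(self):
        size, sigma = 7, 1.2
        half = size // 2
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        r2 = xx**2 + yy**2
        raw = (r2 - 2 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
        k = log_kernel(size, sigma)
        np.testing.assert_allclose(k, raw - raw.mean(), atol=1e-14)
        # centre of the sampled expression before the zero-sum shift is -2/sigma^2
        assert raw[half, half] == pytest.approx(-2 / sigma**2)
        assert abs(k.sum()) < 1e-12

    def test_constant_image_zero_response(self):
        out = log_filter(np.full((20, 20), 37.0), 9, 0.5)
        assert np.abs(out).max() <= 1e-9

    def test_impulse_reproduces_kernel(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        out = log_filter(img, 7, 0.8)
        k = log_kernel(7, 0.8)
        np.testing.assert_allclose(out[7:14, 7:14], k[::-1, ::-1], atol=1e-12)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            log_kernel(8, 1.0)


class TestPCA:
    def test_rank_one_data_has_single_component(self, rng):
        b1 = rng.uniform(0, 1, (8, 8))
        pcs = pca_fit([b1, 2 * b1])
        assert pcs.n_retained == 1  # second eigenvalue is zero and dropped

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        bands = [rng.uniform(0, 1, (10, 10)) for _ in range(4)]
        pcs = pca_fit(bands)
        X = np.stack([b.ravel() for b in bands], axis=1)
        total_var = ((X - X.mean(0)) ** 2).sum(1).mean()
        assert pcs.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_toy_covariance_hand_eigendecomposition(self):
        # 3 pixels, 2 bands: {(1,0),(0,1),(-1,-1)} -> Cov [[2/3,1/3],[1/3,2/3]]
        b1 = np.array([[1.0], [0.0], [-1.0]])
        b2 = np.array([[0.0], [1.0], [-1.0]])
        pcs = pca_fit([b1, b2])
        np.testing.assert_allclose(pcs.eigenvalues, [1.0, 1.0 / 3.0], atol=1e-12)

    def test_eigenvectors_orthonormal_with_positive_dominant_entry(self, rng):
        bands = [rng.uniform(0, 1, (9, 9)) for _ in range(5)]
        pcs = pca_fit(bands)
        E = pcs.eigenvectors
        np.testing.assert_allclose(E.T @ E, np.eye(E.shape[1]), atol=1e-8)
        for i in range(E.shape[1]):
            assert E[np.argmax(np.abs(E[:, i])), i] > 0

    def test_matches_dense_covariance_oracle(self, rng):
        bands = [rng.uniform(0, 5, (16, 16)) for _ in range(5)]
        pcs = pca_fit(bands)
        X = np.stack([b.ravel() for b in bands], axis=1)
        cov = np.cov(X.T, bias=True)
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(pcs.eigenvalues, oracle[: pcs.n_retained], atol=1e-8)

    def test_too_few_bands_rejected(self, rng):
        with pytest.raises(ValueError, match="two"):
            pca_fit([rng.uniform(0, 1, (4, 4))])

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_fit([np.full((4, 4), 2.0), np.full((4, 4), 5.0)])


class TestPCSubtract:
    def _pcs(self, rng):
        bands = [rng.uniform(0, 1, (12, 12)) for _ in range(4)]
        return pca_fit(bands)

    def test_swapped_pair_inverts_gray_levels(self, rng):
        pcs = self._pcs(rng)
        a = pc_subtract(pcs, (2, 1)).astype(int)
        b = pc_subtract(pcs, (1, 2)).astype(int)
        assert np.abs((255 - a) - b).max() <= 1  # rounding of the mirrored scale

    def test_constant_difference_maps_to_zeros(self):
        b1 = np.array([[1.0, 2.0], [3.0, 4.0]])
        pcs = pca_fit([b1, b1 * 2, b1 * 3])
        # duplicate a score image so the difference is exactly zero
        pcs.score_images.append(pcs.score_images[0].copy())
        out = pc_subtract(pcs, (len(pcs.score_images), 1))
        assert out.dtype == np.uint8 and not out.any()

    def test_rank_two_cube_difference_in_pattern_span(self, rng):
        # two orthogonal zero-mean spatial patterns with distinct variances
        n = 16
        p1 = np.outer(np.sin(np.linspace(0, np.pi, n)), np.cos(np.linspace(0, 3, n)))
        p1 -= p1.mean()
        p2 = rng.standard_normal((n, n))
        p2 -= p2.mean()
        p2 -= p1 * (p1.ravel() @ p2.ravel()) / (p1.ravel() @ p1.ravel())
        bands = [2.0 * p1, 1.0 * p2, -2.0 * p1, -1.0 * p2]
        pcs = pca_fit(bands)
        diff = pcs.score_images[1] - pcs.score_images[0]
        basis = np.stack([p1.ravel(), p2.ravel()], axis=1)
        resid = diff.ravel() - basis @ np.linalg.lstsq(basis, diff.ravel(), rcond=None)[0]
        assert np.abs(resid).max() < 1e-8

    def test_out_of_range_pair_rejected(self, rng):
        with pytest.raises(ValueError, match="retained"):
            pc_subtract(self._pcs(rng), (1, 9))


class TestCNR:
    def test_equal_means_give_zero(self, rng):
        img = np.zeros((10, 10))
        img[:, 5:] = rng.standard_normal((10, 5))
        img[:, 5:] -= img[:, 5:].mean()
        roi = np.zeros((10, 10), bool)
        roi[:, :5] = True
        assert cnr(img, roi, ~roi) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        img = np.zeros((4, 4))
        img[:2] = 100.0
        img[2:] = [[40.0, 60.0, 40.0, 60.0]] * 2  # mean 50, population std 10
        roi = np.zeros((4, 4), bool)
        roi[:2] = True
        assert cnr(img, roi, ~roi) == pytest.approx(5.0)

    def test_scale_invariance(self, rng):
        img = rng.uniform(0, 1, (12, 12))
        roi = np.zeros((12, 12), bool)
        roi[3:6, 3:6] = True
        assert cnr(3.7 * img, roi, ~roi) == pytest.approx(cnr(img, roi, ~roi))

    def test_overlapping_masks_rejected(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        roi = np.zeros((8, 8), bool)
        roi[:4] = True
        with pytest.raises(ValueError, match="disjoint"):
            cnr(img, roi, roi)


def _structured_cube(rng, n_bands=15, structured_group=2):
    """Five 3-band groups; one carries a shared pattern, the rest pure noise."""
    pattern = np.zeros((32, 32))
    pattern[8:24, 8:24] = 5.0
    data = rng.standard_normal((32, 32, n_bands))
    lo, hi = structured_group * 3, structured_group * 3 + 3
    data[:, :, lo:hi] += pattern[:, :, None]
    return HyperCube(data + 10.0, np.linspace(400, 1000, n_bands), "reflectance")


def _mi_oracle(a, b, bins=64):
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / h.sum()
    px, py = p.sum(1), p.sum(0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return mi


class TestBandGroupSelection:
    def test_structured_group_wins(self, rng):
        cube = _structured_cube(rng, structured_group=3)
        groups = [(0, 3), (3, 6), (6, 9), (9, 12), (12, 15)]
        chosen, scores = select_band_group(cube, groups)
        assert chosen == (9, 12)
        assert np.argmax(scores) == 3

    def test_scores_match_histogram_counting_oracle(self, rng):
        cube = _structured_cube(rng)
        groups = [(0, 3), (3, 6)]
        _, scores = select_band_group(cube, groups)
        for g, (a, b) in enumerate(groups):
            block = cube.data[:, :, a:b]
            mean_img = block.mean(axis=2)
            expected = np.mean([_mi_oracle(block[:, :, i], mean_img) for i in range(b - a)])
            assert scores[g] == pytest.approx(expected, rel=1e-10)

    def test_identical_bands_tie_break_to_first_group(self, rng):
        band = rng.uniform(0, 1, (16, 16))
        data = np.repeat(band[:, :, None], 10, axis=2)
        cube = HyperCube(data, np.linspace(400, 1000, 10), "reflectance")
        chosen, scores = select_band_group(cube, [(0, 5), (5, 10)])
        assert chosen == (0, 5)
        assert scores[0] == pytest.approx(scores[1])

    def test_empty_group_rejected(self, rng):
        cube = _structured_cube(rng)
        with pytest.raises(ValueError, match="empty"):
            select_band_group(cube, [(3, 3)])


@pytest.fixture(scope="module")
def scenes():
    import corneahsi

    model = corneahsi.SpectrumModel(wavelengths=np.linspace(400, 1000, 16))
    out = {}
    for label in ("healthy", "injured"):
        scene = make_scene(model, size=(72, 72), label=label, seed=11)
        refl = flat_field_correct(scene.cube, ReferenceFrames(scene.dark, scene.white))
        out[label] = (scene, refl)
    return out


class TestEnhanceConfig:
    def test_json_round_trip(self):
        cfg = EnhanceConfig(gamma=1.2, band_groups=((0, 5), (5, 10)), se_radius=7)
        back = EnhanceConfig.from_json(cfg.to_json())
        assert back == cfg

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            EnhanceConfig(gamma=0.0)
        with pytest.raises(ValueError):
            EnhanceConfig(log_size=8)


class TestEnhanceChain:
    CFG = EnhanceConfig(se_radius=15, se_height=15.0)

    def test_deterministic(self, scenes):
        _, refl = scenes["injured"]
        a = enhance_image(refl, self.CFG)
        b = enhance_image(refl, self.CFG)
        assert np.array_equal(a.final, b.final)

    def test_final_is_8bit(self, scenes):
        _, refl = scenes["injured"]
        res = enhance_image(refl, self.CFG)
        assert res.final.dtype == np.uint8

    def test_healthy_and_injured_cnr_differ(self, scenes):
        rr, cc = np.mgrid[:72, :72]
        roi = np.hypot(rr - 35.5, cc - 35.5) <= 15
        values = {}
        for label in ("healthy", "injured"):
            _, refl = scenes[label]
            res = enhance_image(refl, self.CFG)
            values[label] = cnr(res.final, roi, ~roi)
        assert values["healthy"] != values["injured"]

    def test_gradient_concentrates_at_widened_boundary(self, scenes):
        """The enhanced image localises the injury: top-decile gradient
        magnitudes sit within the morphological margin (SE radius + 3 px)
        of the true boundary."""
        from scipy.ndimage import binary_dilation, binary_erosion

        scene, refl = scenes["injured"]
        res = enhance_image(refl, self.CFG)
        gy, gx = np.gradient(res.final.astype(float))
        gmag = np.hypot(gy, gx)
        top = gmag >= np.quantile(gmag, 0.9)
        boundary = scene.injury_mask ^ binary_erosion(scene.injury_mask)
        r = self.CFG.se_radius + 3
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        near = binary_dilation(boundary, yy**2 + xx**2 <= r**2)
        assert (top & near).sum() / top.sum() >= 0.7
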