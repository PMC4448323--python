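"""Polar transform, histogram features, GLCM/Haralick statistics, and the
feature-set assembly contracts.

The Haralick oracle below evaluates every statistic by direct summation
loops over the GLCM definition formulas, independently of the vectorized
implementation.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcnaphase.features import (FEATURE_SET_IDS, GLCM, PolarImage,
                                assemble_features, basic_histogram_features,
                                curvature_histogram, glcm, haralick_features,
                                haralick_polar_vector, intensity_histogram,
                                segments_from_labels, to_polar, zone_means)
from pcnaphase.io_config import IntensityImage, PipelineConfig
from pcnaphase.synthetic_data import (PhaseLabel, SceneSpec, generate_nucleus,
                                      generate_nucleus_bank)


def disc_segment(radius=15, value=100.0, shape=(40, 40), fn=None):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cx = shape[1] / 2 - 0.5
    cy = shape[0] / 2 - 0.5
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    img = np.zeros(shape)
    img[mask] = value if fn is None else fn(xx[mask] - cx, yy[mask] - cy)
    image = IntensityImage(np.clip(img, 0, None))
    seg = segments_from_labels(image, mask.astype(int))[0]
    return image, seg


# ---------------------------------------------------------------------------
# Haralick direct-summation oracle
# ---------------------------------------------------------------------------

def haralick_oracle(p: np.ndarray) -> np.ndarray:
    """Loop-based evaluation of the 13 statistics from their definitions."""
    n = p.shape[0]
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    def h(vals):
        return -sum(v * np.log(v) for v in vals if v > 0)

    asm = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    contrast = sum(k ** 2 * p_diff[k] for k in range(n))
    if sd_x * sd_y > 0:
        corr = sum((i - mu_x) * (j - mu_y) * p[i][j]
                   for i in range(n) for j in range(n)) / (sd_x * sd_y)
    else:
        corr = 1.0
    var = sum((i - mu_x) ** 2 * p[i][j] for i in range(n) for j in range(n))
    idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    s_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    s_var = sum((k - s_avg) ** 2 * p_sum[k] for k in range(2 * n - 1))
    s_ent = h(p_sum)
    ent = h([p[i][j] for i in range(n) for j in range(n)])
    d_mean = sum(k * p_diff[k] for k in range(n))
    d_var = sum((k - d_mean) ** 2 * p_diff[k] for k in range(n))
    d_ent = h(p_diff)
    hx, hy = h(px), h(py)
    hxy1 = -sum(p[i][j] * np.log(px[i] * py[j])
                for i in range(n) for j in range(n)
                if p[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = h([px[i] * py[j] for i in range(n) for j in range(n)])
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - ent))))
    return np.array([asm, contrast, corr, var, idm, s_avg, s_var, s_ent,
                     ent, d_var, d_ent, imc1, imc2])


class TestHaralick:
    def test_oracle_agreement_random_glcms(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            raw = rng.random((8, 8))
            p = (raw + raw.T)
            p /= p.sum()
            np.testing.assert_allclose(haralick_features(p),
                                       haralick_oracle(p), atol=1e-10)

    def test_constant_image_limits(self):
        p = np.zeros((8, 8))
        p[0, 0] = 1.0
        f = haralick_features(p)
        assert f[0] == 1.0           # ASM
        assert f[1] == 0.0           # contrast
        assert f[8] == 0.0           # entropy
        assert f[2] == 1.0           # correlation convention at zero variance

    def test_hand_checked_two_level_cases(self):
        diag = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = haralick_features(diag)
        assert f[0] == pytest.approx(0.5)     # ASM
        assert f[1] == pytest.approx(0.0)     # contrast
        off = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = haralick_features(off)
        assert f[1] == pytest.approx(1.0)     # contrast between levels 0,1

    def test_invalid_glcm_rejected(self):
        with pytest.raises(ValueError):
            haralick_features(np.ones((4, 4)))  # does not sum to 1


class TestGLCM:
    def _polar(self, grid):
        grid = np.asarray(grid, dtype=float)
        return PolarImage(values=grid, valid=np.ones_like(grid, dtype=bool),
                          center=(0.0, 0.0), r_max=1.0)

    def test_horizontal_pairs(self):
        g = glcm(self._polar([[0, 0], [1, 1]]), levels=2, d=1,
                 direction="horizontal")
        np.testing.assert_allclose(g.matrix, [[0.5, 0], [0, 0.5]])

    def test_vertical_pairs_all_cross(self):
        g = glcm(self._polar([[0, 0], [1, 1]]), levels=2, d=1,
                 direction="vertical")
        assert g.matrix[0, 1] + g.matrix[1, 0] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_sums_to_one_with_partial_validity(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((12, 10))
        valid = rng.random((12, 10)) < 0.8
        polar = PolarImage(values=values, valid=valid, center=(0, 0),
                           r_max=1.0)
        for direction in ("horizontal", "vertical"):
            try:
                g = glcm(polar, levels=4, d=1, direction=direction)
            except ValueError:
                continue  # no valid pairs: contract error, acceptable here
            assert g.matrix.sum() == pytest.approx(1.0)
            assert (g.matrix >= 0).all()

    def test_no_valid_pairs_rejected(self):
        polar = PolarImage(values=np.zeros((4, 4)),
                           valid=np.zeros((4, 4), dtype=bool),
                           center=(0, 0), r_max=1.0)
        with pytest.raises(ValueError):
            glcm(polar, levels=2, d=1, direction="horizontal")


class TestPolar:
    def test_uniform_disc_constant(self):
        image, seg = disc_segment(value=77.0)
        polar = to_polar(image, seg)
        assert np.allclose(polar.values[polar.valid], 77.0)

    def test_rotation_is_cyclic_shift(self):
        rng = np.random.default_rng(4)
        smooth = rng.random((41, 41))
        import scipy.ndimage as ndi

        smooth = ndi.gaussian_filter(smooth, 3.0) * 100 + 50
        yy, xx = np.mgrid[:41, :41]
        mask = (xx - 20) ** 2 + (yy - 20) ** 2 <= 15 ** 2
        img1 = IntensityImage(np.where(mask, smooth, 0.0))
        seg1 = segments_from_labels(img1, mask.astype(int))[0]
        p1 = to_polar(img1, seg1)
        img2 = IntensityImage(np.rot90(img1.pixels).copy())
        seg2 = segments_from_labels(img2, np.rot90(mask).astype(int).copy())[0]
        p2 = to_polar(img2, seg2)
        shift = p1.values.shape[0] // 4
        rolled = np.roll(p2.values, shift, axis=0)
        valid = p1.valid & np.roll(p2.valid, shift, axis=0)
        assert np.allclose(p1.values[valid], rolled[valid], rtol=0.02,
                           atol=1.0)

    def test_radial_gradient_column_means(self):
        image, seg = disc_segment(fn=lambda dx, dy: np.hypot(dx, dy) + 1.0)
        polar = to_polar(image, seg, n_radius=16)
        means = np.array([polar.values[:, j][polar.valid[:, j]].mean()
                          if polar.valid[:, j].any() else np.nan
                          for j in range(16)])
        radii = (np.arange(16) + 0.5) / 16 * polar.r_max
        # exclude the cone apex (non-band-limited) and boundary columns
        inner = slice(2, 13)
        np.testing.assert_allclose(means[inner], radii[inner] + 1.0, rtol=0.02)


class TestZoneMeans:
    def test_uniform_disc_equal_zones(self):
        image, seg = disc_segment(value=10.0)
        zm = zone_means(to_polar(image, seg), n_zones=4)
        np.testing.assert_allclose(zm, 10.0)

    def test_late_s_center_heavy(self):
        rng = np.random.default_rng(6)
        spec = SceneSpec()
        img_count = 0
        for _ in range(5):
            mask, tex, cen = generate_nucleus(PhaseLabel.LATE_S, spec, rng)
            image = IntensityImage(np.clip(tex, 0, None))
            seg = segments_from_labels(image, mask.astype(int))[0]
            zm = zone_means(to_polar(image, seg), n_zones=8)
            assert zm[0] > zm[-1]
            img_count += 1
        assert img_count == 5

    def test_mid_s_periphery_heavy(self):
        rng = np.random.default_rng(6)
        spec = SceneSpec()
        for _ in range(5):
            mask, tex, cen = generate_nucleus(PhaseLabel.MID_S, spec, rng)
            image = IntensityImage(np.clip(tex, 0, None))
            seg = segments_from_labels(image, mask.astype(int))[0]
            zm = zone_means(to_polar(image, seg), n_zones=8)
            assert max(zm[5:]) > zm[0]


class TestHistograms:
    def test_basic_statistics_conventions(self):
        image, seg = disc_segment(value=2.0)
        f = basic_histogram_features(seg)
        np.testing.assert_allclose(f, [2, 2, 2, 0, 0, 0])

    def test_symmetric_sample_zero_skew(self):
        seg = dataclasses.replace(
            disc_segment()[1], intensities=np.array([1.0, 2.0, 3.0]))
        f = basic_histogram_features(seg)
        assert f[4] == pytest.approx(0.0)

    def test_hand_checked_moments(self):
        seg = dataclasses.replace(
            disc_segment()[1], intensities=np.array([0.0, 0.0, 0.0, 1.0]))
        f = basic_histogram_features(seg)
        assert f[2] == pytest.approx(0.25)     # mean
        assert f[3] == pytest.approx(0.1875)   # population variance

    def test_intensity_histogram_normalization(self):
        rng = np.random.default_rng(3)
        seg = dataclasses.replace(disc_segment()[1],
                                  intensities=rng.random(500) * 100)
        h = intensity_histogram(seg)
        assert h.sum() == pytest.approx(1.0)
        assert len(h) == 64

    def test_two_valued_segment_two_bins(self):
        seg = dataclasses.replace(
            disc_segment()[1],
            intensities=np.array([0.0] * 10 + [100.0] * 5))
        h = intensity_histogram(seg)
        assert (h > 0).sum() == 2

    def test_ramp_near_flat(self):
        seg = dataclasses.replace(disc_segment()[1],
                                  intensities=np.linspace(0, 1, 6400))
        h = intensity_histogram(seg)
        assert np.allclose(h, 1 / 64, atol=1.1 / 6400)

    def test_constant_segment_first_bin(self):
        seg = dataclasses.replace(disc_segment()[1],
                                  intensities=np.full(50, 3.0))
        h = intensity_histogram(seg)
        assert h[0] == 1.0 and h[1:].sum() == 0.0


class TestCurvatureHistogram:
    def test_constant_image_single_bin(self):
        image, seg = disc_segment(value=50.0, radius=12)
        # restrict to interior so no boundary step enters the Hessian
        inner = dataclasses.replace(
            seg, mask=np.pad(seg.mask[3:-3, 3:-3], 3)[:seg.mask.shape[0],
                                                      :seg.mask.shape[1]])
        img = IntensityImage(np.full_like(image.pixels, 50.0))
        h = curvature_histogram(img, seg, sigma=1.5)
        assert h.max() == 1.0 and (h > 0).sum() == 1

    def test_gaussian_focus_negative_curvature(self):
        s = 2.0
        image, seg = disc_segment(
            radius=12, fn=lambda dx, dy: 100 * np.exp(-(dx ** 2 + dy ** 2)
                                                      / (2 * s * s)))
        k = __import__("pcnaphase.features", fromlist=["principal_curvatures"]
                       ).principal_curvatures(image, seg, sigma=1.0)
        # at the peak both principal curvatures are strongly negative
        assert k.min() < -100 / (s * s) * 0.2
        h = curvature_histogram(image, seg, sigma=1.0)
        assert h[:32].sum() > 0.1  # substantial negative-curvature mass

    def test_sums_to_one(self):
        rng = np.random.default_rng(12)
        image, seg = disc_segment(fn=lambda dx, dy: rng.random(dx.shape) * 50)
        h = curvature_histogram(image, seg, sigma=1.5)
        assert h.sum() == pytest.approx(1.0)

    def test_small_segment_rejected(self):
        image, seg = disc_segment(radius=2, shape=(8, 8))
        with pytest.raises(ValueError, match="support"):
            curvature_histogram(image, seg, sigma=3.0)


class TestAssembly:
    @pytest.mark.parametrize("set_id,length", [
        ("basic_hist", 6 + 8), ("haralick_polar", 104),
        ("hist_intensity", 64), ("hist_curvature", 64),
        ("proposed", 6 + 8 + 104), ("ersoy", 128),
    ])
    def test_lengths_and_names(self, set_id, length, config):
        bank = generate_nucleus_bank(1, SceneSpec(), seed=1)
        img, mask, _ = bank[0]
        seg = segments_from_labels(img, mask.astype(int))[0]
        v, names = assemble_features(img, seg, set_id, config)
        assert len(v) == length == len(names)
        assert len(set(names)) == length
        assert np.isfinite(v).all()

    def test_unknown_set_rejected(self, config):
        bank = generate_nucleus_bank(1, SceneSpec(), seed=1)
        img, mask, _ = bank[0]
        seg = segments_from_labels(img, mask.astype(int))[0]
        with pytest.raises(ValueError, match="unknown feature set"):
            assemble_features(img, seg, "wavelets", config)

    def test_deterministic(self, config):
        bank = generate_nucleus_bank(1, SceneSpec(), seed=1)
        img, mask, _ = bank[0]
        seg = segments_from_labels(img, mask.astype(int))[0]
        v1, _ = assemble_features(img, seg, "proposed", config)
        v2, _ = assemble_features(img, seg, "proposed", config)
        assert np.array_equal(v1, v2)

    def test_uniform_disc_stripes_agree(self, config):
        image, seg = disc_segment(value=30.0, radius=16, shape=(44, 44))
        v, names = haralick_polar_vector(image, seg, config)
        inner = {n.replace("inner", "X"): v[i] for i, n in enumerate(names)
                 if "inner" in n}
        outer = {n.replace("outer", "X"): v[i] for i, n in enumerate(names)
                 if "outer" in n}
        for key in inner:
            assert inner[key] == pytest.approx(outer[key], abs=1e-6)


class TestInvariance:
    """Translation and 90-degree rotation leave histogram-family features
    exactly unchanged; polar-Haralick is unchanged up to float ordering."""

    @pytest.mark.parametrize("set_id", ["basic_hist", "hist_intensity",
                                        "hist_curvature", "haralick_polar"])
    def test_translation_exact(self, set_id, config):
        bank = generate_nucleus_bank(1, SceneSpec(), seed=2)
        img, mask, _ = bank[0]
        seg = segments_from_labels(img, mask.astype(int))[0]
        v1, _ = assemble_features(img, seg, set_id, config)
        big = np.zeros((img.pixels.shape[0] + 9, img.pixels.shape[1] + 13))
        big[9:, 13:] = img.pixels
        bmask = np.zeros_like(big, dtype=int)
        bmask[9:, 13:] = mask.astype(int)
        seg2 = segments_from_labels(IntensityImage(big), bmask)[0]
        v2, _ = assemble_features(IntensityImage(big), seg2, set_id, config)
        np.testing.assert_allclose(v1, v2, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("set_id", ["basic_hist", "hist_intensity",
                                        "hist_curvature", "haralick_polar"])
    def test_rot90_exact(self, set_id, config):
        bank = generate_nucleus_bank(1, SceneSpec(), seed=2)
        img, mask, _ = bank[0]
        seg = segments_from_labels(img, mask.astype(int))[0]
        v1, _ = assemble_features(img, seg, set_id, config)
        rimg = IntensityImage(np.rot90(img.pixels).copy())
        rmask = np.rot90(mask).astype(int).copy()
        seg2 = segments_from_labels(rimg, rmask)[0]
        v2, _ = assemble_features(rimg, seg2, set_id, config)
        np.testing.assert_allclose(v1, v2, rtol=1e-9, atol=1e-9)
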