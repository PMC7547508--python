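from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from crownedge import (
    GfParams,
    GuidanceImage,
    HyperspectralCube,
    JbfParams,
    ProbabilityStack,
    filter_stack,
    guided_filter,
    joint_bilateral_filter,
    pca_false_color,
    resample_guidance,
)

from .oracles import gf_bruteforce, jbf_bruteforce, spatial_kernel_blur


def _random_instance(rng, size=16, channels=1):
    p = rng.uniform(0, 1, (size, size))
    g = rng.uniform(0, 1, (size, size) if channels == 1 else (size, size, channels))
    return p, g


class TestJointBilateralFilter:
    @pytest.mark.parametrize("spatial_squared", [False, True])
    @pytest.mark.parametrize("channels", [1, 3])
    def test_matches_bruteforce_oracle(self, rng, spatial_squared, channels):
        """Vectorized JBF equals the literal pixel-pair double loop."""
        params_grid = [(1.0, 0.1), (2.0, 0.4), (1.0, 0.01)]
        n_instances = 0
        for sigma_d, sigma_r in params_grid:
            for _ in range(4):
                p, g = _random_instance(rng, channels=channels)
                ours = joint_bilateral_filter(
                    p, g, JbfParams(sigma_d, sigma_r, spatial_squared=spatial_squared)
                )
                oracle = jbf_bruteforce(p, g, sigma_d, sigma_r,
                                        spatial_squared=spatial_squared)
                assert np.max(np.abs(ours - oracle)) < 1e-10
                n_instances += 1
        assert n_instances >= 12

    def test_constant_map_unchanged(self, rng):
        """Normalized weights make the output a convex combination, so a
        constant map is a fixed point for any parameters."""
        g = rng.uniform(0, 1, (12, 12, 3))
        p = np.full((12, 12), 0.37)
        for params in [JbfParams(1, 0.1), JbfParams(3, 0.4), JbfParams(0.5, 0.01)]:
            np.testing.assert_allclose(
                joint_bilateral_filter(p, g, params), 0.37, atol=1e-12
            )

    def test_sigma_r_infinity_is_spatial_blur(self, rng):
        """With an enormous range width the guidance becomes irrelevant and
        the JBF collapses to the pure (truncated) spatial kernel blur."""
        p, g = _random_instance(rng)
        for spatial_squared in (False, True):
            ours = joint_bilateral_filter(
                p, g, JbfParams(1.5, 1e6, spatial_squared=spatial_squared)
            )
            blur = spatial_kernel_blur(p, 1.5, spatial_squared=spatial_squared)
            assert np.max(np.abs(ours - blur)) < 1e-8

    def test_output_within_input_range(self, rng):
        p, g = _random_instance(rng, channels=3)
        out = joint_bilateral_filter(p, g, JbfParams(2, 0.2))
        assert out.min() >= p.min() - 1e-12
        assert out.max() <= p.max() + 1e-12

    def test_affine_equivariance(self, rng):
        """Adding a constant to the input shifts the output by that constant
        (weights depend only on the guidance)."""
        p, g = _random_instance(rng)
        params = JbfParams(1, 0.1)
        base = joint_bilateral_filter(p, g, params)
        shifted = joint_bilateral_filter(p + 5.0, g, params)
        np.testing.assert_allclose(shifted, base + 5.0, atol=1e-9)

    def test_invalid_params_rejected(self, rng):
        p, g = _random_instance(rng)
        with pytest.raises(ValueError):
            JbfParams(-1, 0.1)
        with pytest.raises(ValueError):
            JbfParams(1, 0)
        with pytest.raises(ValueError, match="shape"):
            joint_bilateral_filter(p, g[:8, :8], JbfParams(1, 0.1))


class TestGuidedFilter:
    def test_matches_bruteforce_oracle(self, rng):
        """Box-filter implementation equals the literal per-window
        least-squares solve + window averaging."""
        n_instances = 0
        for r, eps in [(1, 0.01), (2, 0.04), (1, 0.0001), (4, 0.16)]:
            for _ in range(3):
                p, g = _random_instance(rng)
                ours = guided_filter(p, g, GfParams(r, eps))
                oracle = gf_bruteforce(p, g, r, eps)
                assert np.max(np.abs(ours - oracle)) < 1e-10
                n_instances += 1
        assert n_instances >= 12

    def test_self_guidance_identity(self, rng):
        """P = I with epsilon = 0 gives a_k = 1, b_k = 0 in every window,
        hence the exact identity."""
        p = rng.uniform(0, 1, (20, 20))
        out = guided_filter(p, p, GfParams(2, 0.0))
        np.testing.assert_array_equal(out, p)

    def test_epsilon_infinity_is_double_box_mean(self, rng):
        """A huge regularizer forces a_k -> 0 and b_k -> window mean; the
        output then averages those window means over the windows containing
        each pixel — the twice-iterated (2r+1) box mean."""
        p, g = _random_instance(rng)
        for r in (1, 2):
            out = guided_filter(p, g, GfParams(r, 1e9))
            box2 = uniform_filter(
                uniform_filter(p, 2 * r + 1, mode="reflect"), 2 * r + 1, mode="reflect"
            )
            assert np.max(np.abs(out - box2)) < 1e-6

    def test_affine_equivariance(self, rng):
        p, g = _random_instance(rng)
        params = GfParams(1, 0.01)
        base = guided_filter(p, g, params)
        shifted = guided_filter(p + 3.0, g, params)
        np.testing.assert_allclose(shifted, base + 3.0, atol=1e-9)

    def test_three_channel_guidance_uses_luminance(self, rng):
        p = rng.uniform(0, 1, (10, 10))
        g3 = GuidanceImage(rng.uniform(0, 1, (10, 10, 3)))
        np.testing.assert_array_equal(
            guided_filter(p, g3, GfParams(1, 0.01)),
            guided_filter(p, g3.luminance(), GfParams(1, 0.01)),
        )

    def test_invalid_params_rejected(self, rng):
        with pytest.raises(ValueError):
            GfParams(0, 0.01)
        p, g = _random_instance(rng)
        with pytest.raises(ValueError, match="shape"):
            guided_filter(p, g[:4, :4], GfParams(1, 0.01))


class TestPcaFalseColor:
    def test_three_pattern_cube_spans_subspace(self, rng):
        """Bands built from 3 independent spatial patterns (+ tiny noise):
        the PCA channels must reconstruct the band space with R^2 > 0.99,
        checked against an explicit eigendecomposition oracle."""
        h = w = 24
        patterns = rng.uniform(0, 1, (3, h, w))
        mix = rng.uniform(0.2, 1.0, (8, 3))
        bands = np.einsum("bk,khw->hwb", mix, patterns)
        bands += 1e-4 * rng.standard_normal(bands.shape)
        bands = (bands - bands.min()) / (bands.max() - bands.min())
        cube = HyperspectralCube(bands)
        guide = pca_false_color(cube)
        assert guide.values.shape == (h, w, 3)
        assert guide.provenance == "pca_false_color"

        # oracle: project band space onto top-3 eigenvectors of the band
        # covariance and measure reconstruction R^2
        x = bands.reshape(-1, 8)
        xc = x - x.mean(0)
        evals, evecs = np.linalg.eigh(np.cov(xc.T))
        top = evecs[:, np.argsort(evals)[::-1][:3]]
        recon = xc @ top @ top.T
        r2_oracle = 1 - ((xc - recon) ** 2).sum() / (xc**2).sum()
        assert r2_oracle > 0.99

        # the produced channels span the same subspace: regressing each
        # centered band on the 3 channels reproduces it
        c = guide.values.reshape(-1, 3)
        cc = c - c.mean(0)
        coef, *_ = np.linalg.lstsq(cc, xc, rcond=None)
        resid = xc - cc @ coef
        r2 = 1 - (resid**2).sum() / (xc**2).sum()
        assert r2 > 0.99

    def test_deterministic_sign_rule(self, small_scene):
        _, cube, _ = small_scene
        a = pca_false_color(cube)
        b = pca_false_color(cube)
        np.testing.assert_array_equal(a.values, b.values)

    def test_constant_cube_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca_false_color(HyperspectralCube(np.full((5, 5, 4), 0.5)))

    def test_too_few_bands_rejected(self):
        with pytest.raises(ValueError, match="3 bands"):
            pca_false_color(HyperspectralCube(np.random.rand(5, 5, 2)))


class TestResampleGuidance:
    def test_downsample_to_cube_shape(self, rng):
        g = GuidanceImage(rng.uniform(0, 1, (40, 40, 3)))
        out = resample_guidance(g, (20, 20))
        assert out.spatial_shape == (20, 20)
        assert out.provenance == "rgb_resampled"

    def test_identity_shape_unchanged(self, rng):
        g = GuidanceImage(rng.uniform(0, 1, (10, 10, 3)))
        np.testing.assert_array_equal(resample_guidance(g, (10, 10)).values, g.values)

    def test_constant_stays_constant(self):
        g = GuidanceImage(np.full((30, 20, 3), 0.6))
        np.testing.assert_allclose(resample_guidance(g, (11, 7)).values, 0.6,
                                   atol=1e-12)

    def test_nonpositive_target_rejected(self, rng):
        g = GuidanceImage(rng.uniform(0, 1, (10, 10, 3)))
        with pytest.raises(ValueError):
            resample_guidance(g, (0, 10))


class TestFilterStack:
    def _stack(self, rng, k=4, size=12):
        v = rng.uniform(0.1, 1.0, (size, size, k))
        v /= v.sum(axis=2, keepdims=True)
        return ProbabilityStack(v, [f"c{i}" for i in range(k)])

    @pytest.mark.parametrize("method,params", [
        ("jbf", JbfParams(1, 0.1)),
        ("gf", GfParams(1, 0.01)),
    ])
    def test_per_map_independence(self, rng, method, params):
        """Filtering the stack equals filtering each class map separately."""
        stack = self._stack(rng)
        g = GuidanceImage(rng.uniform(0, 1, (12, 12, 3)))
        out = filter_stack(stack, g, method, params)
        for k in range(4):
            single = (joint_bilateral_filter(stack.values[:, :, k], g, params)
                      if method == "jbf"
                      else guided_filter(stack.values[:, :, k], g, params))
            np.testing.assert_allclose(out.values[:, :, k],
                                       np.clip(single, 0, 1), atol=1e-12)
        assert out.normalized is False

    def test_constant_stack_unchanged(self, rng):
        v = np.full((10, 10, 4), 0.25)
        stack = ProbabilityStack(v, list("abcd"))
        g = GuidanceImage(rng.uniform(0, 1, (10, 10, 3)))
        for method, params in [("jbf", JbfParams(1, 0.1)), ("gf", GfParams(1, 0.01))]:
            out = filter_stack(stack, g, method, params)
            np.testing.assert_allclose(out.values, 0.25, atol=1e-9)

    def test_displaced_edge_moves_toward_guidance(self):
        """Complementary step-edge maps + a guidance whose true edge sits
        1 px away: the filtered argmax edge must move to the guidance edge.
        Verified against the brute-force oracle as well."""
        size = 16
        p0 = np.zeros((size, size))
        p0[:, : size // 2 + 1] = 1.0  # probability edge after column 8
        stack = ProbabilityStack(
            np.stack([p0, 1 - p0], axis=-1), ["a", "b"]
        )
        g = np.zeros((size, size))
        g[:, : size // 2] = 1.0  # guidance edge after column 7 (displaced by 1)
        params = JbfParams(2, 0.05)
        out = filter_stack(stack, GuidanceImage(g), "jbf", params)
        fused = np.argmax(out.values, axis=2)
        # oracle agreement on the underlying map
        oracle = jbf_bruteforce(p0, g, 2, 0.05)
        np.testing.assert_allclose(out.values[:, :, 0], np.clip(oracle, 0, 1),
                                   atol=1e-10)
        # the fused class-a region now ends where the guidance edge is
        assert np.all(fused[:, : size // 2] == 0)
        assert np.all(fused[:, size // 2 :] == 1)

    def test_shape_mismatch_propagates(self, rng):
        stack = self._stack(rng)
        g = GuidanceImage(rng.uniform(0, 1, (8, 8, 3)))
        with pytest.raises(ValueError):
            filter_stack(stack, g, "jbf", JbfParams(1, 0.1))
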