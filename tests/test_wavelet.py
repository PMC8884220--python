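"""Wavelet decomposition/fusion: perfect reconstruction, selection, degeneracy."""

import numpy as np
import pytest

from edofuse.metrics import gradient_energy, luminance
from edofuse.stack import ZStack
from edofuse.wavelet import (WaveletFusionConfig, consistency_filter, decompose,
                             fuse_stack_wavelet, reconstruct,
                             select_coefficients)


class TestTransform:
    def test_perfect_reconstruction(self, rng):
        cfg = WaveletFusionConfig()
        for _ in range(10):
            img = rng.random((64, 64))
            residual = np.abs(reconstruct(decompose(img, cfg), cfg,
                                          shape=img.shape) - img).max()
            assert residual < 1e-8

    def test_constant_image_has_zero_details(self):
        cfg = WaveletFusionConfig(levels=3)
        pyr = decompose(np.full((32, 32), 0.7), cfg)
        for level in pyr[1:]:
            for band in level:
                np.testing.assert_allclose(band, 0.0, atol=1e-10)

    def test_single_level_structure(self, rng):
        pyr = decompose(rng.random((32, 32)), WaveletFusionConfig(levels=1))
        assert len(pyr) == 2
        assert len(pyr[1]) == 3

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ValueError):
            decompose(rng.random((8, 8)), WaveletFusionConfig(levels=4))


class TestSelection:
    def test_identical_pyramids_fuse_to_themselves(self, rng):
        cfg = WaveletFusionConfig(levels=2, consistency_radius=0)
        pyr = decompose(rng.random((32, 32)), cfg)
        fused, _ = select_coefficients([pyr, pyr, pyr], cfg)
        np.testing.assert_allclose(fused[0], pyr[0], atol=1e-12)
        for lev in range(1, len(pyr)):
            for b in range(3):
                np.testing.assert_allclose(fused[lev][b], pyr[lev][b],
                                           atol=1e-12)

    def test_zero_pyramid_loses_to_arbitrary(self, rng):
        cfg = WaveletFusionConfig(levels=2, selection="max_abs",
                                  consistency_radius=0)
        pyr = decompose(rng.random((32, 32)), cfg)
        zero = [np.zeros_like(pyr[0])] + [
            tuple(np.zeros_like(b) for b in lev) for lev in pyr[1:]]
        fused, _ = select_coefficients([zero, pyr], cfg)
        for lev in range(1, len(pyr)):
            for b in range(3):
                np.testing.assert_allclose(fused[lev][b], pyr[lev][b],
                                           atol=1e-12)

    def test_two_plane_argmax_matches_brute_force(self, rng):
        # elementwise |coefficient| argmax oracle, no consistency filtering
        cfg = WaveletFusionConfig(levels=3, selection="max_abs",
                                  consistency_radius=0)
        p0 = decompose(rng.random((64, 64)), cfg)
        p1 = decompose(rng.random((64, 64)), cfg)
        fused, maps = select_coefficients([p0, p1], cfg)
        for lev in range(1, 4):
            for b in range(3):
                expected = np.where(np.abs(p0[lev][b]) >= np.abs(p1[lev][b]),
                                    p0[lev][b], p1[lev][b])
                np.testing.assert_allclose(fused[lev][b], expected, atol=1e-12)
        np.testing.assert_allclose(fused[0], (p0[0] + p1[0]) / 2, atol=1e-12)

    def test_incongruent_pyramids_rejected(self, rng):
        cfg = WaveletFusionConfig(levels=2)
        p0 = decompose(rng.random((32, 32)), cfg)
        p1 = decompose(rng.random((64, 64)), cfg)
        with pytest.raises(ValueError):
            select_coefficients([p0, p1], cfg)


class TestConsistencyFilter:
    def test_uniform_map_unchanged(self):
        m = np.full((9, 9), 3, dtype=int)
        np.testing.assert_array_equal(consistency_filter(m, 2), m)

    def test_single_dissent_removed(self):
        m = np.zeros((9, 9), dtype=int)
        m[4, 4] = 1
        out = consistency_filter(m, 1)
        assert out[4, 4] == 0
        np.testing.assert_array_equal(out, np.zeros_like(m))

    def test_radius_zero_is_identity(self, rng):
        m = rng.integers(0, 5, (16, 16))
        np.testing.assert_array_equal(consistency_filter(m, 0), m)

    def test_tie_keeps_original(self):
        # two-label checkerboard: every 3x3 window has a 5/4 or 4/5 split,
        # so the center pixel's own label always wins or ties
        m = np.indices((8, 8)).sum(axis=0) % 2
        out = consistency_filter(m, 1)
        # interior windows: center label occurs 5 times of 9 -> unchanged
        np.testing.assert_array_equal(out[1:-1, 1:-1], m[1:-1, 1:-1])


class TestStackFusion:
    def test_identical_planes_fuse_to_plane(self, rng):
        plane = rng.random((64, 64, 3))
        stack = ZStack(planes=np.stack([plane] * 4), axial_step=0.5)
        fused = fuse_stack_wavelet(stack)
        assert fused.method == "wavelet"
        assert fused.source_planes == 4
        np.testing.assert_allclose(fused.image, plane, atol=1e-6)

    def test_single_plane_identity(self, rng):
        plane = rng.random((64, 64, 3))
        stack = ZStack(planes=plane[None], axial_step=0.5)
        np.testing.assert_allclose(fuse_stack_wavelet(stack).image, plane,
                                   atol=1e-6)

    def test_fusion_raises_gradient_energy(self, two_plane_halves):
        stack, _ = two_plane_halves
        fused = fuse_stack_wavelet(stack)
        e_fused = gradient_energy(luminance(fused.image))
        e_planes = [gradient_energy(luminance(p)) for p in stack.as_float01()]
        assert e_fused >= max(e_planes) * 0.999

    def test_fusion_recovers_sharp_plane_energy(self, rng):
        # one all-in-focus plane among blurred copies: fused luminance
        # gradient energy within 5% of the sharp plane's
        from scipy import ndimage

        sharp = rng.random((64, 64, 3))
        planes = [sharp] + [ndimage.gaussian_filter(sharp, (s, s, 0))
                            for s in (1.5, 3.0)]
        stack = ZStack(planes=np.stack(planes), axial_step=0.5)
        fused = fuse_stack_wavelet(stack)
        e_sharp = gradient_energy(luminance(sharp))
        e_fused = gradient_energy(luminance(fused.image))
        assert abs(e_fused - e_sharp) / e_sharp < 0.05

    def test_permutation_invariance_without_ties(self, two_plane_halves):
        stack, _ = two_plane_halves
        rev = ZStack(planes=stack.planes[::-1].copy(), axial_step=0.5)
        a = fuse_stack_wavelet(stack).image
        b = fuse_stack_wavelet(rev).image
        # identical up to argmax tie-breaking on equal coefficients
        assert np.mean(np.abs(a - b)) < 1e-3

    def test_nonsquare_and_odd_sizes_handled(self, rng):
        stack = ZStack(planes=rng.random((3, 50, 70, 3)), axial_step=0.5)
        fused = fuse_stack_wavelet(stack)
        assert fused.image.shape == (50, 70, 3)
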