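"""Stack data model, TIFF round-trips, white balance, decimation, geometry."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from edofuse.optics import AcquisitionGeometry, depth_of_field, required_planes
from edofuse.stack import (StackFormatError, ZStack, decimate_stack,
                           denormalize_from_network, normalize_for_network,
                           read_stack, white_balance, write_stack)


class TestIO:
    def test_roundtrip_uint8_bit_exact(self, rng, tmp_path):
        planes = rng.integers(0, 256, (14, 32, 32, 3), dtype=np.uint8)
        stack = ZStack(planes=planes, axial_step=0.5)
        path = tmp_path / "s.tif"
        write_stack(stack, path)
        back = read_stack(path, axial_step=0.5)
        assert back.n_planes == 14
        assert back.axial_step == 0.5
        assert back.value_range == (0.0, 255.0)
        np.testing.assert_array_equal(back.planes, planes)

    def test_single_page_stack(self, rng, tmp_path):
        planes = rng.integers(0, 256, (1, 16, 16, 3), dtype=np.uint8)
        path = tmp_path / "one.tif"
        write_stack(ZStack(planes=planes, axial_step=1.0), path)
        back = read_stack(path, axial_step=1.0)
        assert back.n_planes == 1
        np.testing.assert_array_equal(back.planes, planes)

    def test_mixed_page_sizes_rejected(self, rng, tmp_path):
        path = tmp_path / "mixed.tif"
        with tifffile.TiffWriter(path) as tw:
            tw.write(rng.integers(0, 256, (16, 16, 3), dtype=np.uint8))
            tw.write(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8))
        with pytest.raises(StackFormatError):
            read_stack(path, axial_step=0.5)

    def test_empty_plane_list_refused(self):
        with pytest.raises(StackFormatError):
            ZStack(planes=np.zeros((0, 8, 8, 3)), axial_step=0.5)

    def test_invalid_axial_step(self, rng):
        with pytest.raises(ValueError):
            ZStack(planes=rng.random((2, 8, 8, 3)), axial_step=0.0)


class TestWhiteBalance:
    def test_uniform_reference_is_identity(self, rng):
        plane = rng.random((16, 16, 3))
        ref = np.full((16, 16, 3), 0.7)
        np.testing.assert_allclose(white_balance(plane, ref), plane, atol=1e-12)

    def test_plane_equal_reference_gives_channel_means(self, rng):
        ref = rng.random((16, 16, 3)) * 0.8 + 0.1
        out = white_balance(ref, ref)
        expected = np.broadcast_to(ref.mean(axis=(0, 1)), ref.shape)
        np.testing.assert_allclose(out, np.clip(expected, 0, 1), atol=1e-12)

    def test_division_is_linear_in_reference_gain(self, rng):
        # a spatially varying gain on one reference channel divides that
        # channel of the output by the mean-normalised gain profile
        plane = rng.random((16, 16, 3)) * 0.4
        ref = np.full((16, 16, 3), 0.5)
        ref[:8, :, 1] *= 3.0
        out = white_balance(plane, ref)
        gain = ref[..., 1] / ref[..., 1].mean()
        np.testing.assert_allclose(out[..., 1], plane[..., 1] / gain, atol=1e-12)
        # untouched channels are unaffected
        np.testing.assert_allclose(out[..., 0], plane[..., 0], atol=1e-12)

    def test_uniform_channel_scaling_normalises_away(self, rng):
        # mean-normalisation makes the balance invariant to per-channel
        # exposure: scaling a whole reference channel changes nothing
        plane = rng.random((16, 16, 3)) * 0.4
        ref = rng.random((16, 16, 3)) * 0.5 + 0.3
        ref2 = ref.copy()
        ref2[..., 2] *= 2.0
        np.testing.assert_allclose(white_balance(plane, ref2),
                                   white_balance(plane, ref), atol=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            white_balance(rng.random((8, 8, 3)), rng.random((4, 4, 3)))

    def test_zero_reference_warns(self, rng):
        ref = rng.random((8, 8, 3))
        ref[0, 0, 0] = 0.0
        with pytest.warns(UserWarning):
            out = white_balance(rng.random((8, 8, 3)), ref)
        assert np.all(np.isfinite(out))


class TestDecimation:
    @pytest.mark.parametrize("d, k, expected_planes, expected_step", [
        (14, 2, 7, 1.0),
        (14, 4, 3, 2.0),
        (7, 2, 3, 1.0),
        (7, 1, 7, 0.5),
    ])
    def test_plane_counts_and_steps(self, rng, d, k, expected_planes,
                                    expected_step):
        stack = ZStack(planes=rng.random((d, 8, 8, 3)), axial_step=0.5)
        out = decimate_stack(stack, k)
        assert out.n_planes == expected_planes
        assert out.axial_step == pytest.approx(expected_step)

    def test_identity_decimation_preserves_planes(self, random_stack):
        out = decimate_stack(random_stack, 1)
        np.testing.assert_array_equal(out.planes, random_stack.planes)
        assert out.axial_step == random_stack.axial_step

    def test_keeps_every_kth_from_the_kth(self, rng):
        stack = ZStack(planes=rng.random((14, 8, 8, 3)), axial_step=0.5)
        out = decimate_stack(stack, 2)
        np.testing.assert_array_equal(out.planes, stack.planes[1::2])

    def test_factor_exceeding_depth_rejected(self, random_stack):
        with pytest.raises(ValueError):
            decimate_stack(random_stack, random_stack.n_planes + 1)


class TestNormalization:
    @pytest.mark.parametrize("value, expected", [(0.0, -1.0), (1.0, 1.0),
                                                 (0.5, 0.0)])
    def test_range_endpoints(self, value, expected):
        stack = ZStack(planes=np.full((1, 8, 8, 3), value), axial_step=0.5,
                       value_range=(0.0, 1.0))
        out = normalize_for_network(stack)
        np.testing.assert_allclose(out.planes, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(lo=st.sampled_from([0.0]), hi=st.sampled_from([1.0, 255.0]),
           seed=st.integers(0, 1000))
    def test_roundtrip_recovers_input(self, lo, hi, seed):
        data = np.random.default_rng(seed).random((2, 8, 8, 3)) * (hi - lo) + lo
        stack = ZStack(planes=data, axial_step=0.5, value_range=(lo, hi))
        out = normalize_for_network(stack)
        back = denormalize_from_network(out.planes, out.meta["normalize"])
        np.testing.assert_allclose(back, data, atol=1e-6)


class TestGeometry:
    def test_depth_of_field_formula(self):
        geom = AcquisitionGeometry(wavelength=0.53, na=1.4, sample_thickness=3.5)
        assert depth_of_field(geom) == pytest.approx(0.53 / 1.4**2)
        assert depth_of_field(geom) == pytest.approx(0.2704, abs=1e-4)

    def test_depth_of_field_unit_case_and_scaling(self):
        g1 = AcquisitionGeometry(1.0, 1.0, 1.0)
        assert depth_of_field(g1) == pytest.approx(1.0)
        g2 = AcquisitionGeometry(1.0, 1.4, 1.0)
        g3 = AcquisitionGeometry(1.0, 0.7, 1.0)
        assert depth_of_field(g3) == pytest.approx(4 * depth_of_field(g2))

    def test_required_planes_malaria_smear(self):
        # 3.5 µm slab, 100x/1.4NA, green light -> 7 planes
        geom = AcquisitionGeometry(wavelength=0.53, na=1.4, sample_thickness=3.5)
        assert required_planes(geom) == 7

    def test_required_planes_one_dof_slab(self):
        lam, na = 0.5, 1.0
        geom = AcquisitionGeometry(lam, na, 2 * lam / na**2)
        assert required_planes(geom) == 1

    def test_required_planes_linear_in_thickness(self):
        g1 = AcquisitionGeometry(0.53, 1.4, 3.52)  # slightly off the ceiling
        g2 = AcquisitionGeometry(0.53, 1.4, 7.04)
        raw1 = 3.52 * 1.4**2 / (2 * 0.53)
        assert required_planes(g2) == int(np.ceil(2 * raw1))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(0.53, 1.6, 3.5)
        with pytest.raises(ValueError):
            AcquisitionGeometry(-0.5, 1.4, 3.5)
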