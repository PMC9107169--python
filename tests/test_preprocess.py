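"""Projection, windowing, resizing, model-input construction.

The projection operators are checked against an explicit brute-force
per-ray triple loop; windowing against its closed form.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctqc.phantom import PhantomSpec, generate_phantom
from ctqc.preprocess import (
    ConversionMethod,
    Plane,
    WindowParams,
    apply_window,
    convert_series,
    project,
    representative_images,
    resize,
    to_model_input,
)
from ctqc.volume_io import CTVolume, read_png

METHODS = list(ConversionMethod)
PLANES = list(Plane)


def brute_force_project(voxels, method, plane):
    """Independent oracle: explicit per-ray loops over the collapsed axis."""
    axis = {"axial": 0, "coronal": 1, "sagittal": 2}[plane.value]
    kept = [a for a in range(3) if a != axis]
    out = np.empty((voxels.shape[kept[0]], voxels.shape[kept[1]]))
    for a in range(out.shape[0]):
        for b in range(out.shape[1]):
            idx = [0, 0, 0]
            idx[kept[0]], idx[kept[1]] = a, b
            ray = []
            for k in range(voxels.shape[axis]):
                idx[axis] = k
                ray.append(voxels[tuple(idx)])
            if method is ConversionMethod.MIP:
                out[a, b] = max(ray)
            elif method is ConversionMethod.AIP:
                out[a, b] = sum(ray) / len(ray)
            else:
                out[a, b] = ray[voxels.shape[axis] // 2]
    return out


class TestProject:
    def test_worked_example_2x2x2(self):
        """voxels[z][y][x] = 1 + x + 2y + 4z."""
        v = np.array([[[1, 2], [3, 4]], [[5, 6], [7, 8]]], dtype=float)
        vol = CTVolume(v)
        np.testing.assert_array_equal(
            project(vol, ConversionMethod.MIP, Plane.AXIAL).pixels, [[5, 6], [7, 8]]
        )
        np.testing.assert_array_equal(
            project(vol, ConversionMethod.AIP, Plane.AXIAL).pixels, [[3, 4], [5, 6]]
        )
        np.testing.assert_array_equal(
            project(vol, ConversionMethod.MID, Plane.AXIAL).pixels, [[5, 6], [7, 8]]
        )

    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("plane", PLANES)
    def test_matches_brute_force_oracle(self, method, plane, rng):
        for _ in range(25):
            shape = tuple(rng.integers(1, 9, size=3))
            vol = CTVolume(rng.uniform(-1000, 1000, size=shape))
            expected = brute_force_project(vol.voxels, method, plane)
            np.testing.assert_allclose(project(vol, method, plane).pixels, expected,
                                       rtol=0, atol=1e-9)

    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("plane", PLANES)
    def test_constant_volume(self, method, plane):
        vol = CTVolume(np.full((4, 5, 6), 37.0))
        assert np.all(project(vol, method, plane).pixels == 37.0)

    @pytest.mark.parametrize("method", METHODS)
    def test_single_slice_axial_identity(self, method, rng):
        vol = CTVolume(rng.uniform(-100, 100, size=(1, 6, 7)))
        np.testing.assert_array_equal(project(vol, method, Plane.AXIAL).pixels,
                                      vol.voxels[0])

    def test_mip_dominates_aip_pointwise(self, rng):
        vol = CTVolume(rng.uniform(-1000, 1000, size=(7, 8, 9)))
        for plane in PLANES:
            mip = project(vol, ConversionMethod.MIP, plane).pixels
            aip = project(vol, ConversionMethod.AIP, plane).pixels
            assert np.all(mip >= aip - 1e-12)

    def test_output_dims_are_remaining_axes(self, rng):
        vol = CTVolume(rng.uniform(0, 1, size=(3, 5, 7)))
        assert project(vol, ConversionMethod.MIP, Plane.AXIAL).pixels.shape == (5, 7)
        assert project(vol, ConversionMethod.MIP, Plane.CORONAL).pixels.shape == (3, 7)
        assert project(vol, ConversionMethod.MIP, Plane.SAGITTAL).pixels.shape == (3, 5)


class TestWindow:
    @pytest.mark.parametrize("hu,expected", [
        (-450.0, 0.0), (50.0, 0.5), (550.0, 1.0), (-1000.0, 0.0), (300.0, 0.75),
    ])
    def test_default_window_closed_form(self, hu, expected):
        vol = CTVolume(np.full((1, 2, 2), hu))
        proj = project(vol, ConversionMethod.MID, Plane.AXIAL)
        assert apply_window(proj).pixels[0, 0] == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(-2000, 4000, allow_nan=False), min_size=2, max_size=32))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_hu(self, values):
        arr = np.sort(np.asarray(values))
        proj = project(CTVolume(arr.reshape(1, 1, -1)), ConversionMethod.MID, Plane.AXIAL)
        out = apply_window(proj).pixels[0]
        assert np.all(np.diff(out) >= 0)

    def test_level_shift_invariance(self, rng):
        """Shifting HU and window level together leaves the output unchanged."""
        hu = rng.uniform(-500, 600, size=(1, 4, 4))
        shift = 123.0
        a = apply_window(project(CTVolume(hu), ConversionMethod.MID, Plane.AXIAL),
                         WindowParams(50, 1000)).pixels
        b = apply_window(project(CTVolume(hu + shift), ConversionMethod.MID, Plane.AXIAL),
                         WindowParams(50 + shift, 1000)).pixels
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_invalid_width(self):
        with pytest.raises(ValueError, match="width"):
            WindowParams(50, 0)

    def test_requires_raw_state(self, chest_volume):
        windowed = apply_window(project(chest_volume, ConversionMethod.MIP, Plane.AXIAL))
        with pytest.raises(ValueError, match="raw_hu"):
            apply_window(windowed)


class TestResize:
    def test_constant_stays_constant(self):
        out = resize(np.full((37, 21), 0.3), 512)
        assert out.shape == (512, 512)
        np.testing.assert_allclose(out, 0.3, atol=1e-12)

    def test_identity_at_target_size(self, rng):
        img = rng.uniform(0, 1, size=(512, 512))
        np.testing.assert_array_equal(resize(img, 512), img)

    def test_checkerboard_upsample_preserves_mean(self):
        cb = np.indices((4, 4)).sum(axis=0) % 2
        out = resize(cb.astype(float), 8)
        assert out.mean() == pytest.approx(cb.mean(), abs=1e-6)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            resize(np.zeros((4, 4)), 0)


class TestModelInput:
    def test_three_identical_channels(self, rng):
        t = to_model_input(rng.uniform(0, 1, size=(64, 64)))
        assert t.shape == (299, 299, 3)
        np.testing.assert_array_equal(t[:, :, 0], t[:, :, 1])
        np.testing.assert_array_equal(t[:, :, 0], t[:, :, 2])

    def test_constant_one(self):
        np.testing.assert_array_equal(to_model_input(np.ones((32, 32))), 1.0)

    def test_idempotent_at_native_size(self, rng):
        t = to_model_input(rng.uniform(0, 1, size=(64, 64)))
        t2 = to_model_input(t[:, :, 0])
        np.testing.assert_array_equal(t, t2)


class TestConvertSeries:
    def test_chest_mip_coronal_shows_dark_lungs(self, chest_volume, tmp_path):
        path, _ = convert_series(chest_volume, ConversionMethod.MID, Plane.CORONAL,
                                 out_dir=tmp_path)
        png = read_png(path)
        # mid-coronal slice passes through both lungs: distinctly dark pixels
        assert png.shape == (512, 512)
        assert (png < 0.1).mean() > 0.05
        assert png.max() > 0.9  # rib bone saturates the window

    def test_constant_50_hu_volume_is_mid_gray(self, tmp_path):
        vol = CTVolume(np.full((4, 8, 8), 50.0), series_id="const")
        path, _ = convert_series(vol, ConversionMethod.AIP, Plane.AXIAL, out_dir=tmp_path)
        png = read_png(path)
        assert np.all(np.isin(np.round(png * 255), [127, 128]))

    def test_nine_distinct_named_outputs(self, chest_volume, tmp_path):
        paths = set()
        for m in METHODS:
            for p in PLANES:
                path, tensor = convert_series(chest_volume, m, p, out_dir=tmp_path)
                assert path.name == f"{chest_volume.series_id}_{m.value}_{p.value}.png"
                assert tensor.shape == (299, 299, 3)
                paths.add(path)
        assert len(paths) == 9
        assert len(representative_images(chest_volume)) == 9

    def test_deterministic_png_bytes(self, chest_volume, tmp_path):
        a, _ = convert_series(chest_volume, ConversionMethod.MIP, Plane.AXIAL,
                              out_dir=tmp_path / "a")
        b, _ = convert_series(chest_volume, ConversionMethod.MIP, Plane.AXIAL,
                              out_dir=tmp_path / "b")
        assert a.read_bytes() == b.read_bytes()
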