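import numpy as np
import pytest

from leafspec.hsicube import (
    HyperCube,
    Mask,
    ReferencePair,
    calibrate_reflectance,
    mean_spectrum,
    read_envi,
    segment_canopy,
    write_envi,
)
from leafspec.synthdata import GeneratorConfig, simulate_canopy_cube


def make_raw(data, wl=None):
    wl = wl if wl is not None else np.linspace(400, 900, data.shape[2])
    return HyperCube(data=data, wavelengths=wl, kind="raw")


class TestCalibration:
    def test_raw_equals_white_gives_one(self, rng):
        white = rng.uniform(1000, 4000, size=8)
        dark = rng.uniform(0, 100, size=8)
        raw = make_raw(np.broadcast_to(white, (5, 6, 8)).copy())
        out = calibrate_reflectance(raw, ReferencePair(white, dark))
        assert np.allclose(out.data, 1.0, atol=1e-12)
        assert out.kind == "reflectance"

    def test_raw_equals_dark_gives_zero(self, rng):
        white = rng.uniform(1000, 4000, size=8)
        dark = rng.uniform(0, 100, size=8)
        raw = make_raw(np.broadcast_to(dark, (5, 6, 8)).copy())
        out = calibrate_reflectance(raw, ReferencePair(white, dark))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_midpoint_gives_half(self, rng):
        white = rng.uniform(1000, 4000, size=4)
        dark = rng.uniform(0, 100, size=4)
        raw = make_raw(np.broadcast_to((white + dark) / 2, (3, 3, 4)).copy())
        out = calibrate_reflectance(raw, ReferencePair(white, dark))
        assert np.allclose(out.data, 0.5, atol=1e-12)

    def test_matches_elementwise_formula_on_random_cube(self, rng):
        raw = make_raw(rng.uniform(0, 4000, size=(4, 5, 6)))
        white = rng.uniform(2000, 4000, size=6)
        dark = rng.uniform(0, 50, size=6)
        out = calibrate_reflectance(raw, ReferencePair(white, dark))
        assert np.allclose(out.data, (raw.data - dark) / (white - dark))

    def test_cube_references_reduced_by_mean(self, rng):
        raw = make_raw(rng.uniform(0, 100, size=(4, 4, 3)))
        white_cube = rng.uniform(3000, 3500, size=(4, 4, 3))
        dark_cube = rng.uniform(0, 10, size=(4, 4, 3))
        out = calibrate_reflectance(raw, ReferencePair(white_cube, dark_cube))
        w, d = white_cube.mean(axis=(0, 1)), dark_cube.mean(axis=(0, 1))
        assert np.allclose(out.data, (raw.data - d) / (w - d))

    def test_white_leq_dark_is_hard_error(self, rng):
        raw = make_raw(rng.uniform(0, 100, size=(2, 2, 3)))
        white = np.array([100.0, 5.0, 100.0])
        dark = np.array([1.0, 10.0, 1.0])
        with pytest.raises(ValueError, match="band 1"):
            calibrate_reflectance(raw, ReferencePair(white, dark))

    def test_rejects_already_calibrated(self, rng):
        cube = HyperCube(rng.uniform(0, 1, (2, 2, 3)), np.array([1.0, 2, 3]))
        with pytest.raises(ValueError):
            calibrate_reflectance(cube, ReferencePair(np.ones(3), np.zeros(3)))


class TestSegmentation:
    def test_recovers_synthetic_disk(self):
        scene = simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=4), 48, 48, 0.05)
        mask = segment_canopy(scene.cube)
        inter = (mask.foreground & scene.mask).sum()
        union = (mask.foreground | scene.mask).sum()
        assert inter / union >= 0.99
        assert mask.provenance["method"] == "otsu"

    def test_nir_plateau_band_also_works(self):
        scene = simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=4), 48, 48, 0.05)
        mask = segment_canopy(scene.cube, band_nm=976.0)
        inter = (mask.foreground & scene.mask).sum()
        union = (mask.foreground | scene.mask).sum()
        assert inter / union >= 0.95

    def test_uniform_image_flagged(self):
        cube = HyperCube(np.full((8, 8, 3), 0.5), np.array([700.0, 750, 800]))
        with pytest.warns(UserWarning):
            mask = segment_canopy(cube, band_nm=750)
        assert mask.foreground.sum() in (0, 64)

    def test_otsu_invariant_to_monotone_rescale(self):
        scene = simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=5), 32, 32, 0.0)
        m1 = segment_canopy(scene.cube)
        scaled = HyperCube(
            scene.cube.data * 1.7 + 0.05, scene.cube.wavelengths, "reflectance"
        )
        m2 = segment_canopy(scaled)
        assert np.array_equal(m1.foreground, m2.foreground)

    def test_band_outside_range_rejected(self):
        cube = HyperCube(np.zeros((4, 4, 2)), np.array([500.0, 600.0]))
        with pytest.raises(ValueError):
            segment_canopy(cube, band_nm=900.0)


class TestMeanSpectrum:
    def test_single_pixel_roi(self, rng):
        cube = HyperCube(rng.uniform(0, 1, (5, 5, 7)), np.arange(7.0) + 1)
        spec = mean_spectrum(cube, (np.array([2]), np.array([3])))
        assert np.array_equal(spec, cube.data[2, 3])

    def test_symmetric_pair_averages_to_constant(self):
        wl = np.arange(6.0) + 1
        s = np.linspace(0, 1, 6)
        c = 0.4
        data = np.stack([[s, -s + 2 * c]])
        cube = HyperCube(data, wl)
        spec = mean_spectrum(cube, np.ones((1, 2), dtype=bool))
        assert np.allclose(spec, c)

    def test_gradient_zero_canopy_mean_equals_shared_spectrum(self):
        scene = simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=6), 32, 32, 0.0)
        spec = mean_spectrum(scene.cube, Mask(scene.mask))
        one = scene.cube.data[scene.mask][0]
        assert np.allclose(spec, one, atol=1e-12)

    def test_union_linearity(self, rng):
        cube = HyperCube(rng.uniform(0, 1, (6, 6, 4)), np.arange(4.0) + 1)
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[:3] = True
        b[4:] = True
        na, nb = a.sum(), b.sum()
        lhs = mean_spectrum(cube, a | b)
        rhs = (na * mean_spectrum(cube, a) + nb * mean_spectrum(cube, b)) / (na + nb)
        assert np.allclose(lhs, rhs)

    def test_empty_selection_rejected(self, rng):
        cube = HyperCube(rng.uniform(0, 1, (3, 3, 2)), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            mean_spectrum(cube, np.zeros((3, 3), dtype=bool))


class TestEnviIO:
    def test_round_trip_bitwise(self, tmp_path, rng):
        cube = HyperCube(
            rng.uniform(0, 1, (4, 4, 5)).astype(np.float32),
            np.linspace(400, 800, 5),
        )
        write_envi(cube, tmp_path / "c")
        back = read_envi(tmp_path / "c")
        assert np.array_equal(back.data, cube.data)
        assert np.allclose(back.wavelengths, cube.wavelengths, atol=1e-6)

    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_interleaves_equivalent(self, tmp_path, rng, interleave):
        cube = HyperCube(
            rng.uniform(0, 1, (3, 5, 4)).astype(np.float32), np.arange(4.0) + 1
        )
        write_envi(cube, tmp_path / interleave, interleave=interleave)
        back = read_envi(tmp_path / interleave)
        assert np.array_equal(back.data, cube.data)

    def test_uint16_dialect(self, tmp_path, rng):
        cube = HyperCube(
            rng.integers(0, 65535, size=(3, 3, 2)).astype(np.uint16),
            np.array([1.0, 2.0]),
        )
        write_envi(cube, tmp_path / "u16", interleave="bil")
        back = read_envi(tmp_path / "u16")
        assert back.data.dtype == np.uint16
        assert np.array_equal(back.data, cube.data)

    def test_band_count_mismatch_rejected(self, tmp_path, rng):
        cube = HyperCube(
            rng.uniform(0, 1, (2, 2, 5)).astype(np.float32), np.linspace(1, 5, 5)
        )
        write_envi(cube, tmp_path / "bad")
        hdr = (tmp_path / "bad.hdr").read_text()
        hdr = hdr.replace("bands = 5", "bands = 4")
        (tmp_path / "bad.hdr").write_text(hdr)
        with pytest.raises(ValueError, match="wavelength"):
            read_envi(tmp_path / "bad")

    def test_missing_wavelengths_rejected(self, tmp_path, rng):
        cube = HyperCube(
            rng.uniform(0, 1, (2, 2, 3)).astype(np.float32), np.arange(3.0) + 1
        )
        write_envi(cube, tmp_path / "nw")
        hdr = "\n".join(
            l for l in (tmp_path / "nw.hdr").read_text().splitlines()
            if not l.startswith("wavelength =")
        )
        (tmp_path / "nw.hdr").write_text(hdr)
        with pytest.raises(ValueError, match="wavelength"):
            read_envi(tmp_path / "nw")
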