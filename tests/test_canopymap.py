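import json

import numpy as np
import pytest

from leafspec.canopymap import invert_canopy, render_map, summarize_by_type
from leafspec.chemomodels import fit_plsr
from leafspec.prep import PrepSpec
from leafspec.synthdata import GeneratorConfig, simulate_canopy_cube, simulate_leaf_spectra


class LinearOracle:
    """Exact linear inverse of the noise-free generator at the truth bands."""

    def __init__(self, batch, pigment_col):
        A = np.column_stack(
            [batch.spectra[:, batch.truth_bands], np.ones(batch.n_samples)]
        )
        self.bands = batch.truth_bands
        self.coef, *_ = np.linalg.lstsq(A, batch.targets[:, pigment_col], rcond=None)

    def predict(self, X):
        A = np.column_stack([X[:, self.bands], np.ones(X.shape[0])])
        return A @ self.coef


@pytest.fixture(scope="module")
def scene():
    return simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=31), 40, 40, 0.1)


@pytest.fixture(scope="module")
def leaf_batch():
    return simulate_leaf_spectra(GeneratorConfig(n_samples=200, noise_sd=0.0, seed=32))


class TestInvertCanopy:
    def test_gradient_zero_exact_recovery(self, leaf_batch):
        flat = simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=33), 32, 32, 0.0)
        predictors = {"chla": LinearOracle(leaf_batch, 0)}
        pmap = invert_canopy(flat.cube, flat.mask, predictors)
        truth = flat.truth["chla"][flat.mask]
        assert np.allclose(pmap.planes["chla"][flat.mask], truth, atol=1e-8)

    def test_radial_gradient_high_correlation(self, scene, leaf_batch):
        predictors = {"chla": fit_plsr(leaf_batch.spectra, leaf_batch.target("chla"))}
        pmap = invert_canopy(scene.cube, scene.mask, predictors)
        pred = pmap.planes["chla"][scene.mask]
        truth = scene.truth["chla"][scene.mask]
        r = np.corrcoef(pred, truth)[0, 1]
        assert r >= 0.99

    def test_background_carries_sentinel(self, scene, leaf_batch):
        predictors = {"chla": LinearOracle(leaf_batch, 0)}
        pmap = invert_canopy(scene.cube, scene.mask, predictors)
        assert np.all(np.isnan(pmap.planes["chla"][~scene.mask]))

    def test_empty_mask_gives_all_sentinel(self, scene, leaf_batch):
        predictors = {"chla": LinearOracle(leaf_batch, 0)}
        pmap = invert_canopy(
            scene.cube, np.zeros(scene.mask.shape, dtype=bool), predictors
        )
        assert np.all(np.isnan(pmap.planes["chla"]))

    def test_pixelwise_no_spatial_mixing(self, scene, leaf_batch):
        """Each foreground pixel equals predictor(that pixel's spectrum)."""
        predictors = {"chla": LinearOracle(leaf_batch, 0)}
        pmap = invert_canopy(scene.cube, scene.mask, predictors)
        rows, cols = np.where(scene.mask)
        pick = slice(0, 20)
        expected = predictors["chla"].predict(
            scene.cube.data[rows[pick], cols[pick], :]
        )
        assert np.allclose(
            pmap.planes["chla"][rows[pick], cols[pick]], expected, atol=1e-12
        )

    def test_tpc_plane_synthesized_as_sum(self, scene, leaf_batch):
        predictors = {
            "chla": LinearOracle(leaf_batch, 0),
            "chlb": LinearOracle(leaf_batch, 1),
            "car": LinearOracle(leaf_batch, 2),
        }
        pmap = invert_canopy(scene.cube, scene.mask, predictors)
        fg = scene.mask
        assert np.allclose(
            pmap.planes["tpc"][fg],
            pmap.planes["chla"][fg] + pmap.planes["chlb"][fg] + pmap.planes["car"][fg],
        )

    def test_rotation_invariant_statistics(self, scene, leaf_batch):
        from leafspec.hsicube import HyperCube

        predictors = {"chla": LinearOracle(leaf_batch, 0)}
        pmap1 = invert_canopy(scene.cube, scene.mask, predictors)
        rot = HyperCube(
            np.rot90(scene.cube.data, axes=(0, 1)).copy(),
            scene.cube.wavelengths,
        )
        pmap2 = invert_canopy(rot, np.rot90(scene.mask).copy(), predictors)
        v1 = np.sort(pmap1.planes["chla"][scene.mask])
        v2 = np.sort(pmap2.planes["chla"][np.rot90(scene.mask)])
        assert np.allclose(v1, v2, atol=1e-12)

    def test_prep_travels_with_the_model(self, scene, leaf_batch):
        """A model trained on SNV spectra must see SNV pixel spectra."""
        from leafspec.prep import snv

        Xs = snv(leaf_batch.spectra)
        predictors = {"chla": fit_plsr(Xs, leaf_batch.target("chla"))}
        pmap = invert_canopy(
            scene.cube, scene.mask, predictors, prep=PrepSpec("snv")
        )
        truth = scene.truth["chla"][scene.mask]
        r = np.corrcoef(pmap.planes["chla"][scene.mask], truth)[0, 1]
        assert r >= 0.99


class TestSummaries:
    def test_gradient_zero_has_zero_cv(self, leaf_batch):
        flat = simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=34), 32, 32, 0.0)
        pmap = invert_canopy(flat.cube, flat.mask, {"chla": LinearOracle(leaf_batch, 0)})
        stats = summarize_by_type([pmap], ["romaine"])
        row = stats[(stats.type == "romaine") & (stats.pigment == "chla")].iloc[0]
        assert row.sd == pytest.approx(0.0, abs=1e-9)
        assert row.cv == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_ranges_order_type_means(self, leaf_batch):
        lo = simulate_canopy_cube(
            GeneratorConfig(noise_sd=0.0, seed=35,
                            pigment_ranges={"chla": (0.3, 0.4),
                                            "chlb": (0.29, 0.45),
                                            "car": (0.14, 0.23)}),
            24, 24, 0.0,
        )
        hi = simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=36), 24, 24, 0.0)
        oracle = LinearOracle(leaf_batch, 0)
        maps = [
            invert_canopy(lo.cube, lo.mask, {"chla": oracle}),
            invert_canopy(hi.cube, hi.mask, {"chla": oracle}),
        ]
        stats = summarize_by_type(maps, ["low", "high"])
        mlow = stats[stats.type == "low"]["mean"].iloc[0]
        mhigh = stats[stats.type == "high"]["mean"].iloc[0]
        assert mlow < mhigh

    def test_duplicating_a_map_leaves_statistics_unchanged(self, scene, leaf_batch):
        pmap = invert_canopy(scene.cube, scene.mask, {"chla": LinearOracle(leaf_batch, 0)})
        s1 = summarize_by_type([pmap], ["a"])
        s2 = summarize_by_type([pmap, pmap], ["a", "a"])
        for col in ("mean", "sd", "cv", "median"):
            assert s1[col].iloc[0] == pytest.approx(s2[col].iloc[0], abs=1e-12)

    def test_unlabeled_map_rejected(self, scene, leaf_batch):
        pmap = invert_canopy(scene.cube, scene.mask, {"chla": LinearOracle(leaf_batch, 0)})
        with pytest.raises(ValueError):
            summarize_by_type([pmap], [""])


class TestRenderMap:
    def test_constant_foreground_single_color(self, tmp_path, leaf_batch):
        flat = simulate_canopy_cube(GeneratorConfig(noise_sd=0.0, seed=37), 24, 24, 0.0)
        pmap = invert_canopy(flat.cube, flat.mask, {"chla": LinearOracle(leaf_batch, 0)})
        sidecar = render_map(pmap, "chla", tmp_path / "m")
        from PIL import Image

        img = np.array(Image.open(tmp_path / "m.png"))
        fg_colors = img[flat.mask]
        assert len(np.unique(fg_colors, axis=0)) == 1
        assert np.all(img[~flat.mask] == 0)
        assert sidecar["vmin"] == pytest.approx(sidecar["vmax"])

    def test_sidecar_min_max_match_plane(self, tmp_path, scene, leaf_batch):
        pmap = invert_canopy(scene.cube, scene.mask, {"chla": LinearOracle(leaf_batch, 0)})
        sidecar = render_map(pmap, "chla", tmp_path / "r")
        vals = pmap.planes["chla"][scene.mask]
        assert sidecar["vmin"] == pytest.approx(vals.min())
        assert sidecar["vmax"] == pytest.approx(vals.max())
        saved = json.loads((tmp_path / "r.json").read_text())
        assert saved["colormap"] == "viridis"

    def test_monotone_color_progression_along_radius(self, tmp_path, scene, leaf_batch):
        pmap = invert_canopy(scene.cube, scene.mask, {"chla": LinearOracle(leaf_batch, 0)})
        render_map(pmap, "chla", tmp_path / "g", colormap="gray")
        from PIL import Image

        img = np.array(Image.open(tmp_path / "g.png"))[:, :, 0].astype(float)
        vals = pmap.planes["chla"][scene.mask]
        shades = img[scene.mask]
        order = np.argsort(vals)
        # grayscale shade must be non-decreasing with predicted value
        assert np.all(np.diff(shades[order]) >= -1)

    def test_all_sentinel_plane_rejected(self, scene, leaf_batch):
        pmap = invert_canopy(
            scene.cube, np.zeros(scene.mask.shape, dtype=bool),
            {"chla": LinearOracle(leaf_batch, 0)},
        )
        with pytest.raises(ValueError):
            render_map(pmap, "chla", "/tmp/never")
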