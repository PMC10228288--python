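"""Tests for the phantom generator: physics, determinism, presets and
dataset assembly."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedGroupKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from dermoct.ac import ac_map, fit_decay
from dermoct.config import PipelineConfig
from dermoct.pipeline import analyze_image, gabor_bank_from_config
from dermoct.synthetic import (
    Layer,
    PhantomSpec,
    benign_spec,
    make_dataset,
    melanoma_spec,
    render,
)

from conftest import single_layer_spec


class TestRenderPhysics:
    def test_noiseless_single_layer_follows_beer_lambert_exactly(self):
        spec = PhantomSpec(
            width=40, depth=220, surface_row=30,
            layers=(Layer(190, 2.0, 0.8),), speckle_sigma=0.0,
        )
        phantom = render(spec)
        col = phantom.bscan.pixels[:, 20]
        x = np.arange(220) * 0.01  # mm
        below = slice(32, 220)  # below the 2-row entrance band
        expected = 0.8 * np.exp(-2.0 * 2.0 * (x[below] - x[30]))
        assert np.allclose(col[below], expected, rtol=1e-12)
        assert np.all(col[:30] == 0.0)

    def test_entrance_line_is_three_times_subsurface(self):
        spec = PhantomSpec(
            width=40, depth=220, surface_row=30,
            layers=(Layer(190, 2.0, 0.8),), speckle_sigma=0.0,
        )
        col = render(spec).bscan.pixels[:, 20]
        assert col[30] == pytest.approx(3.0 * col[32])
        assert col[31] == col[30]

    def test_same_seed_renders_identical_arrays(self):
        a = render(benign_spec(seed=21))
        b = render(benign_spec(seed=21))
        assert np.array_equal(a.bscan.pixels, b.bscan.pixels)
        assert np.array_equal(a.mu_map, b.mu_map)
        assert np.array_equal(a.surface_rows, b.surface_rows)

    def test_different_seeds_render_different_speckle(self):
        a = render(benign_spec(seed=21))
        b = render(benign_spec(seed=22))
        assert not np.array_equal(a.bscan.pixels, b.bscan.pixels)

    @pytest.mark.parametrize("mu", [0.5, 2.0, 8.0])
    def test_noiseless_profile_recovers_configured_mu(self, mu):
        phantom = render(single_layer_spec(mu=mu))
        profile = phantom.bscan.pixels[10:200, 20]
        fit = fit_decay(profile, axial_pitch=10.0)
        assert abs(fit.mu - mu) / mu < 0.001

    def test_speckle_is_unit_mean(self):
        spec = single_layer_spec(mu=0.0, speckle_sigma=0.3, seed=5, width=200)
        phantom = render(spec)
        tissue = phantom.bscan.pixels[50:200]
        assert tissue.mean() == pytest.approx(1.0, rel=0.01)

    def test_artifact_bands_suppress_signal_and_set_mask(self):
        spec = benign_spec(seed=3, artifacts=((30, 5),))
        phantom = render(spec)
        assert phantom.artifact_mask[:, 30:35].all()
        assert not phantom.artifact_mask[:, :30].any()
        inside = phantom.bscan.pixels[60:200, 30:35].mean()
        outside = phantom.bscan.pixels[60:200, 40:45].mean()
        assert inside < 0.1 * outside

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(layers=(Layer(500, 2.0, 1.0),))  # too thick
        with pytest.raises(ValueError):
            PhantomSpec(effacement=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(speckle_sigma=-0.1)
        with pytest.raises(ValueError):
            PhantomSpec(class_label="dysplastic")


class TestPresetContrast:
    def test_benign_attenuation_exceeds_melanoma_in_most_renders(self):
        # Monte-Carlo check over 40 seed pairs: median AC over the ROI
        # depth range should rank benign above melanoma nearly always.
        wins = 0
        n = 40
        for seed in range(n):
            medians = {}
            for preset in (benign_spec, melanoma_spec):
                phantom = render(preset(seed=seed))
                amap = ac_map(phantom.bscan)
                top = int(phantom.surface_rows.max()) + 8
                medians[phantom.label] = float(
                    np.median(amap.values[top:top + 150, 10:110])
                )
            wins += medians["benign"] > medians["melanoma"]
        assert wins >= int(0.95 * n)

    def test_identical_physics_removes_class_separability(self):
        # With melanoma rendered from the benign physics (same layers, no
        # effacement, ridges on), grouped CV accuracy collapses to chance:
        # the rendering pipeline leaks no label information.
        ref = benign_spec()
        phantoms, _ = make_dataset(
            16, 16, seed=3,
            layers=ref.layers, effacement=0.0, rete_amplitude=6.0,
        )
        cfg = PipelineConfig()
        bank = gabor_bank_from_config(cfg)
        X, y, groups = [], [], []
        for ph in phantoms:
            a = analyze_image(ph.bscan, cfg, label=ph.label, bank=bank)
            X.append(a.features)
            y += [ph.label] * len(a.rois)
            groups += [ph.bscan.source_id] * len(a.rois)
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
        acc = cross_val_score(
            clf, np.vstack(X), np.array(y), groups=np.array(groups), cv=StratifiedGroupKFold(5)
        ).mean()
        assert 0.3 <= acc <= 0.7


class TestMakeDataset:
    def test_train_test_design_sizes(self):
        _, manifest = make_dataset(37 + 6, 37 + 6, seed=0)
        labels = [m["label"] for m in manifest]
        assert len(manifest) == 86
        assert labels.count("benign") == 43 and labels.count("melanoma") == 43

    def test_manifest_reproducible_for_fixed_seed(self):
        _, a = make_dataset(3, 3, seed=9)
        _, b = make_dataset(3, 3, seed=9)
        assert a == b

    def test_minimal_dataset_one_of_each(self):
        phantoms, manifest = make_dataset(1, 1, seed=0)
        assert [m["label"] for m in manifest] == ["benign", "melanoma"]
        assert phantoms[0].label == "benign" and phantoms[1].label == "melanoma"

    def test_jitter_makes_images_distinct(self):
        phantoms, _ = make_dataset(2, 1, seed=4)
        assert not np.array_equal(phantoms[0].bscan.pixels, phantoms[1].bscan.pixels)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(0, 5)

    def test_writes_images_ground_truth_and_manifest(self, tmp_path):
        make_dataset(1, 1, seed=0, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        for stem in ("benign_000", "melanoma_001"):
            assert (tmp_path / f"{stem}.tif").exists()
            assert (tmp_path / f"{stem}_mu.tif").exists()
            assert (tmp_path / f"{stem}_mask.png").exists()
            assert (tmp_path / f"{stem}_surface.csv").exists()
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert list(manifest.columns) == ["image_id", "label", "seed"]
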