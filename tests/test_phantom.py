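"""Phantom generator: geometry, artifact model, dose pairs, dataset output."""

import numpy as np
import pytest

from cbct2ct import (ArtifactParams, PhantomConfig, degrade_to_cbct, dsc,
                     generate_anatomy, generate_dataset, generate_pair,
                     make_dose_pair, mae, perturb_mask)
from cbct2ct.phantom import ContourMask, PhantomConfigError
from dataclasses import replace


class TestAnatomy:
    def test_background_exactly_zero(self, small_phantom):
        _, ct, masks = small_phantom
        assert np.all(ct.values[~masks["body"].mask] == 0.0)

    def test_deterministic_given_seed(self):
        cfg = PhantomConfig(image_size=64, seed=5)
        a, _ = generate_anatomy(cfg)
        b, _ = generate_anatomy(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_organs_disjoint_and_inside_body(self, small_phantom):
        _, _, masks = small_phantom
        body = masks["body"].mask
        organs = [masks[k].mask for k in ("bladder", "rectum", "bone")]
        for m in organs:
            assert not np.any(m & ~body)
        assert not np.any(organs[0] & organs[1])
        assert not np.any(organs[0] & organs[2])
        assert not np.any(organs[1] & organs[2])

    def test_tissue_classes_hit_their_hu(self, small_phantom):
        cfg, ct, masks = small_phantom
        hu = cfg.hu_table
        # texture is small, so means should sit near the class values
        assert abs(ct.values[masks["bone"].mask].mean() - hu["bone"]) < 20
        assert abs(ct.values[masks["bladder"].mask].mean()
                   - hu["bladder"]) < 20

    @pytest.mark.parametrize("bad", [
        dict(image_size=33),
        dict(image_size=16),
        dict(bladder_radii=(0.0, 0.1)),
        dict(bladder_center=(0.05, 0.05)),        # outside the body
        dict(hu_table={**PhantomConfig().hu_table, "bone": 9000.0}),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(PhantomConfigError):
            generate_anatomy(PhantomConfig(**bad))


class TestDegradation:
    def test_zero_params_is_identity(self, small_phantom):
        _, ct, masks = small_phantom
        params = ArtifactParams(cupping_amplitude=0, streak_count=0,
                                streak_amplitude=0,
                                beam_hardening_amplitude=0, noise_sigma=0,
                                global_shift=0)
        out = degrade_to_cbct(ct, masks, params)
        np.testing.assert_array_equal(out.values, ct.values)

    def test_pure_global_shift(self, small_phantom):
        _, ct, masks = small_phantom
        params = ArtifactParams(cupping_amplitude=0, streak_count=0,
                                streak_amplitude=0,
                                beam_hardening_amplitude=0, noise_sigma=0,
                                global_shift=50.0)
        out = degrade_to_cbct(ct, masks, params)
        body = masks["body"].mask
        diff = out.values[body] - ct.values[body]
        assert np.allclose(diff, 50.0, atol=1e-4)
        assert np.all(out.values[~body] == 0.0)

    def test_deterministic_and_seed_sensitive(self, small_phantom,
                                              default_artifacts):
        _, ct, masks = small_phantom
        a = degrade_to_cbct(ct, masks, default_artifacts)
        b = degrade_to_cbct(ct, masks, default_artifacts)
        np.testing.assert_array_equal(a.values, b.values)
        c = degrade_to_cbct(ct, masks,
                            replace(default_artifacts,
                                    seed=default_artifacts.seed + 1))
        assert np.any(a.values != c.values)

    def test_mae_positive_with_any_artifact(self, small_phantom,
                                            default_artifacts):
        _, ct, masks = small_phantom
        body = masks["body"].mask
        cbct = degrade_to_cbct(ct, masks, default_artifacts)
        assert mae(cbct.values, ct.values, body) > 0

    def test_mae_monotone_in_global_shift(self, small_phantom):
        _, ct, masks = small_phantom
        body = masks["body"].mask
        maes = []
        for shift in (10.0, 25.0, 80.0):
            p = ArtifactParams(cupping_amplitude=0, streak_count=0,
                               streak_amplitude=0,
                               beam_hardening_amplitude=0, noise_sigma=0,
                               global_shift=shift)
            cbct = degrade_to_cbct(ct, masks, p)
            maes.append(mae(cbct.values, ct.values, body))
        assert maes[0] < maes[1] < maes[2]

    def test_mismatched_grids_rejected(self, small_phantom):
        _, ct, _ = small_phantom
        _, other_masks = generate_anatomy(PhantomConfig(image_size=128))
        with pytest.raises(ValueError):
            degrade_to_cbct(ct, other_masks, ArtifactParams())


class TestPerturbMask:
    def test_magnitude_zero_is_identity(self, small_phantom):
        _, _, masks = small_phantom
        out = perturb_mask(masks["bladder"], 0.0, seed=3)
        np.testing.assert_array_equal(out.mask, masks["bladder"].mask)

    def test_dilated_square_dice(self):
        """3x3-dilating a 10x10 square: DSC = 2*100/(100+144)."""
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        from scipy.ndimage import binary_dilation
        d = binary_dilation(m, structure=np.ones((3, 3), bool))
        assert dsc(ContourMask(m), ContourMask(d)) == pytest.approx(
            2 * 100 / (100 + 144))

    def test_stays_within_clip_region(self, small_phantom):
        _, _, masks = small_phantom
        out = perturb_mask(masks["bladder"], 2.0, seed=9,
                           within=masks["body"])
        assert not np.any(out.mask & ~masks["body"].mask)
        assert out.mask.any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            perturb_mask(ContourMask(np.zeros((8, 8), bool)), 1.0)


class TestDosePair:
    def test_zero_perturbation_identical(self):
        ref, ev = make_dose_pair((8, 8, 8), (2, 2, 2), 50.0, 0.0)
        np.testing.assert_array_equal(ref.values, ev.values)

    def test_peak_equals_prescription(self):
        ref, _ = make_dose_pair((9, 9, 9), (2, 2, 2), 45.0, 0.02)
        assert ref.values.max() == pytest.approx(45.0)

    def test_difference_scales_with_local_dose(self):
        p = 50.0
        ref, ev = make_dose_pair((9, 9, 9), (2, 2, 2), p, 0.01)
        diff = ev.values - ref.values
        # relative-to-prescription difference is 1% at the peak and
        # proportionally less elsewhere
        np.testing.assert_allclose(diff, 0.01 * ref.values, rtol=1e-12)
        assert diff.max() == pytest.approx(0.01 * p)

    def test_bad_prescription_rejected(self):
        with pytest.raises(ValueError):
            make_dose_pair((4, 4, 4), (1, 1, 1), 0.0, 0.01)


class TestDataset:
    def test_manifest_counts_and_determinism(self, tmp_path):
        cfg = PhantomConfig(image_size=64, seed=21)
        params = ArtifactParams(seed=22)
        m1 = generate_dataset(10, cfg, params, tmp_path / "a",
                              split=(0.8, 0.1, 0.1))
        assert len(m1) == 10
        assert (m1["split"] == "train").sum() == 8
        assert (m1["split"] == "val").sum() == 1
        assert (m1["split"] == "test").sum() == 1
        generate_dataset(10, cfg, params, tmp_path / "b",
                         split=(0.8, 0.1, 0.1))
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
               (tmp_path / "b" / "manifest.csv").read_bytes()

    def test_written_pairs_respect_invariants(self, tmp_path):
        from cbct2ct.io import read_volume
        cfg = PhantomConfig(image_size=64, seed=33)
        m = generate_dataset(3, cfg, ArtifactParams(seed=1),
                             tmp_path, split=(1.0, 0.0, 0.0))
        for _, row in m.iterrows():
            ct, sp_ct = read_volume(tmp_path / row["ct"], squeeze=True)
            cbct, sp_cb = read_volume(tmp_path / row["cbct"], squeeze=True)
            body = read_volume(tmp_path / row["mask_body"],
                               squeeze=True)[0] > 0
            assert ct.shape == cbct.shape and sp_ct == sp_cb
            assert np.all(ct[~body] == 0) and np.all(cbct[~body] == 0)
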