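"""Generator guarantees: exact variance, determinism, dose scaling, ground truth."""

import numpy as np
import pytest

from ctiq.roi_metrics import extract_roi_stats
from ctiq.stats import cohen_kappa
from ctiq.synthetic import (NoiseModel, TissueLayout, TissueRegion,
                            abdomen_layout, chest_layout, make_dose_series,
                            make_dose_table, make_patient_slice, make_phantom,
                            make_scores, phantom_interior_mask)

SPACING = (2.5, 0.5, 0.5)


class TestPhantom:
    def test_zero_sigma_is_constant(self):
        vol = make_phantom((2, 64, 64), SPACING, 12.5, NoiseModel(sigma=0.0))
        assert (vol.voxels == 12.5).all()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            NoiseModel(sigma=-1.0)

    def test_interior_variance_is_exact(self):
        # image-domain rescale makes the interior sample SD equal sigma exactly
        vol = make_phantom((4, 128, 128), SPACING, 0.0,
                           NoiseModel(sigma=10.0, shape="fbp_like", params={"f0": 0.15}, seed=3))
        interior = phantom_interior_mask(vol.shape[1:])
        sd = vol.voxels[:, interior].std(ddof=1)
        assert sd == pytest.approx(10.0, rel=1e-6)
        assert vol.voxels[:, interior].mean() == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_identical_volumes(self):
        model = NoiseModel(sigma=5.0, shape="smooth", params={"fc": 0.3}, seed=11)
        a = make_phantom((2, 64, 64), SPACING, 0.0, model)
        b = make_phantom((2, 64, 64), SPACING, 0.0, model)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_background_disc(self):
        vol = make_phantom((1, 64, 64), SPACING, 100.0, NoiseModel(sigma=0.0),
                           background_hu=-1000.0)
        interior = phantom_interior_mask((64, 64))
        assert (vol.voxels[0][interior] == 100.0).all()
        assert (vol.voxels[0][~interior] == -1000.0).all()

    def test_too_small_for_nps_rejected(self):
        with pytest.raises(ValueError, match="64x64"):
            make_phantom((1, 32, 32), SPACING, 0.0, NoiseModel(sigma=1.0))


class TestDoseSeries:
    def test_sd_scales_as_inverse_sqrt_dose(self):
        series = make_dose_series((2, 64, 64), SPACING, 0.0,
                                  NoiseModel(sigma=10.0, seed=1), doses_mgy=(1, 3, 5))
        interior = phantom_interior_mask((64, 64))
        sds = {d: v.voxels[:, interior].std(ddof=1) for d, v in series}
        assert sds[5] / sds[1] == pytest.approx(1 / np.sqrt(5), rel=1e-9)
        assert sds[3] / sds[1] == pytest.approx(1 / np.sqrt(3), rel=1e-9)

    def test_single_dose_matches_make_phantom(self):
        model = NoiseModel(sigma=6.0, shape="fbp_like", params={"f0": 0.15}, seed=5)
        [(dose, vol)] = make_dose_series((2, 64, 64), SPACING, 0.0, model, doses_mgy=(1,))
        direct = make_phantom((2, 64, 64), SPACING, 0.0, model)
        np.testing.assert_array_equal(vol.voxels, direct.voxels)

    @pytest.mark.parametrize("doses", [(0, 1), (-2,), (1, 1)])
    def test_invalid_doses_rejected(self, doses):
        with pytest.raises(ValueError):
            make_dose_series((1, 64, 64), SPACING, 0.0, NoiseModel(sigma=1.0), doses)


class TestPatientSlice:
    def test_ground_truth_recovered_at_chest_settings(self):
        # non-contrast chest targets: lung -795.9 HU, muscle 56.1 HU, noise 21.8 HU
        layout = chest_layout((160, 160), 0.35)
        ps = make_patient_slice(layout, NoiseModel(sigma=21.8, seed=2),
                                size_yx=(160, 160), spacing=(2.5, 0.35, 0.35),
                                roi_diameter_mm=10.0)
        stats = {r.label: extract_roi_stats(ps.volume, r) for r in ps.rois}
        assert stats["lung"].n_voxels >= 400
        assert stats["lung"].mean_hu == pytest.approx(-795.9, abs=3.0)
        assert stats["muscle"].mean_hu == pytest.approx(56.1, abs=3.0)
        assert stats["muscle"].sd_hu == pytest.approx(21.8, rel=0.05)

    def test_zero_sigma_gives_zero_roi_sd(self):
        ps = make_patient_slice(chest_layout((128, 128), 0.5), NoiseModel(sigma=0.0),
                                size_yx=(128, 128))
        for roi in ps.rois:
            assert extract_roi_stats(ps.volume, roi).sd_hu == 0.0

    def test_cnr_recovered_from_abdomen_truth(self):
        # liver 131, aorta 186, muscle 71, sigma 19.9 -> CNR_liver = 60/19.9 = 3.02
        layout = abdomen_layout((160, 160), 0.35, liver_hu=131.0, aorta_hu=186.0,
                                muscle_hu=71.0)
        ps = make_patient_slice(layout, NoiseModel(sigma=19.9, seed=4),
                                size_yx=(160, 160), spacing=(2.5, 0.35, 0.35),
                                roi_diameter_mm=10.0)
        stats = {r.label: extract_roi_stats(ps.volume, r) for r in ps.rois}
        cnr = abs(stats["liver"].mean_hu - stats["muscle"].mean_hu) / stats["muscle"].sd_hu
        assert cnr == pytest.approx(abs(131.0 - 71.0) / 19.9, rel=0.10)

    def test_overlapping_regions_rejected(self):
        layout = TissueLayout([TissueRegion("liver", (50, 50), 20.0, 131.0),
                               TissueRegion("aorta", (50, 55), 20.0, 186.0)])
        with pytest.raises(ValueError, match="overlap"):
            make_patient_slice(layout, NoiseModel(sigma=1.0), size_yx=(128, 128))

    def test_duplicate_tissue_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            TissueLayout([TissueRegion("liver", (30, 30), 10.0, 131.0),
                          TissueRegion("liver", (90, 90), 10.0, 120.0)])


class TestScores:
    def test_full_agreement_gives_kappa_one(self):
        df = make_scores(51, (0, 11, 40, 0), agreement_level=1.0, seed=0)
        res = cohen_kappa(df["reviewer_1"], df["reviewer_2"])
        assert res.kappa == 1.0
        assert not res.degenerate

    def test_constant_reviewer_margin_degenerates_to_zero(self):
        # one score category only, both reviewers -> expected agreement 1
        df = make_scores(51, (0, 0, 51, 0), agreement_level=1.0, seed=0)
        res = cohen_kappa(df["reviewer_1"], df["reviewer_2"])
        assert res.kappa == 0.0
        assert res.degenerate

    def test_independent_reviewers_give_near_zero_kappa(self):
        df = make_scores(4000, (400, 1400, 1800, 400), agreement_level=0.0, seed=1)
        res = cohen_kappa(df["reviewer_1"], df["reviewer_2"])
        assert abs(res.kappa) < 0.05

    def test_profile_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            make_scores(51, (0, 10, 10, 0), agreement_level=1.0, seed=0)


class TestDoseTable:
    def test_kvp_follows_weight_bands(self):
        df = make_dose_table(200, "chest", seed=0)
        assert ((df.weight_kg > 40) == (df.kvp == 100)).all()
        assert ((df.weight_kg < 15) == (df.kvp == 70)).all()

    def test_deterministic_and_positive(self):
        a = make_dose_table(20, "abdomen", seed=3)
        b = make_dose_table(20, "abdomen", seed=3)
        assert a.equals(b)
        assert (a[["ctdivol_mgy", "dlp_mgycm", "ap_dim_cm", "lat_dim_cm"]] > 0).all().all()

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="region"):
            make_dose_table(5, "head", seed=0)
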