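"""ROI statistics and the CNR/SNR conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctiq.io_formats import ImageVolume, ROISpec
from ctiq.roi_metrics import (build_metric_table, compute_cnr, compute_snr,
                              disc_mask, extract_roi_stats, summarize_metrics)
from ctiq.synthetic import NoiseModel, abdomen_layout, make_patient_slice

SPACING = (2.5, 0.5, 0.5)

finite = st.floats(-2000, 3000, allow_nan=False)
positive = st.floats(0.5, 100, allow_nan=False)


class TestExtractRoiStats:
    def test_constant_region(self):
        vol = ImageVolume(np.full((1, 32, 32), 56.0), SPACING)
        m = extract_roi_stats(vol, ROISpec("muscle", (0, 16, 16), 9.0))
        assert (m.mean_hu, m.sd_hu) == (56.0, 0.0)

    def test_hand_listed_values(self):
        # a 5-voxel plus-shaped disc holding {1..5}: mean 3, SD sqrt(2.5)
        vox = np.zeros((1, 32, 32))
        vox[0, 16, 16] = 1
        vox[0, 15, 16] = 2
        vox[0, 17, 16] = 3
        vox[0, 16, 15] = 4
        vox[0, 16, 17] = 5
        vol = ImageVolume(vox, (2.5, 1.0, 1.0))
        # diameter 2.5 mm at 1 mm pixels: strict radius 1.25 keeps the 4-neighbours only
        m = extract_roi_stats(vol, ROISpec("custom", (0, 16, 16), 2.5))
        assert m.n_voxels == 5
        assert m.mean_hu == pytest.approx(3.0)
        assert m.sd_hu == pytest.approx(1.5811, abs=1e-4)

    def test_out_of_bounds_rejected(self):
        vol = ImageVolume(np.zeros((1, 32, 32)), SPACING)
        with pytest.raises(ValueError, match="fully inside"):
            extract_roi_stats(vol, ROISpec("muscle", (0, 1, 1), 9.0))

    def test_tiny_roi_rejected(self):
        vol = ImageVolume(np.zeros((1, 32, 32)), (2.5, 1.0, 1.0))
        with pytest.raises(ValueError, match="voxels"):
            extract_roi_stats(vol, ROISpec("muscle", (0, 16, 16), 0.5))

    def test_disc_membership_monotone_in_diameter(self):
        counts = [disc_mask((64, 64), (32, 32), d, (0.5, 0.5)).sum()
                  for d in np.linspace(2, 30, 20)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestFormulas:
    @given(finite, finite, positive)
    def test_cnr_matches_one_line_oracle(self, hu_obj, hu_mus, sd):
        assert compute_cnr(hu_obj, hu_mus, sd) == abs(hu_obj - hu_mus) / sd

    @given(finite, positive)
    def test_snr_matches_one_line_oracle(self, hu_obj, sd):
        assert compute_snr(hu_obj, sd) == hu_obj / sd

    @given(finite, finite, positive, st.floats(-500, 500, allow_nan=False))
    def test_cnr_translation_invariant(self, hu_obj, hu_mus, sd, c):
        assert compute_cnr(hu_obj + c, hu_mus + c, sd) == pytest.approx(
            compute_cnr(hu_obj, hu_mus, sd), rel=1e-9, abs=1e-9)

    @given(finite, positive, st.floats(0.1, 10, allow_nan=False))
    def test_snr_scale_invariant(self, hu_obj, sd, c):
        assert compute_snr(c * hu_obj, c * sd) == pytest.approx(
            compute_snr(hu_obj, sd), rel=1e-9, abs=1e-9)

    def test_abdomen_mean_arithmetic(self):
        # formula check on the published abdomen group means (not the printed
        # group CNR, which averages per-patient ratios)
        assert compute_cnr(131.4, 71.2, 19.9) == pytest.approx(3.0251, abs=1e-4)
        assert compute_snr(131.4, 19.9) == pytest.approx(6.603, abs=1e-3)

    def test_lung_snr_sign_preserved(self):
        assert compute_snr(-795.9, 21.8) < 0

    @pytest.mark.parametrize("fn,args", [(compute_cnr, (10.0, 5.0, 0.0)),
                                         (compute_snr, (10.0, -1.0))])
    def test_nonpositive_noise_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


def _cohort(n, sigmas, seed0=0, recons=("ASIR-V 50",)):
    volumes, rois = {}, {}
    for i in range(n):
        subj = f"S{i}"
        for j, recon in enumerate(recons):
            ps = make_patient_slice(
                abdomen_layout((160, 160), 0.35),
                NoiseModel(sigma=sigmas[i], seed=seed0 + 97 * i + j),
                size_yx=(160, 160), spacing=(2.5, 0.35, 0.35), roi_diameter_mm=10.0)
            volumes[(subj, recon)] = ps.volume
            rois[subj] = ps.rois
    return volumes, rois


class TestMetricTable:
    def test_single_subject_single_recon(self):
        volumes, rois = _cohort(1, [15.0])
        table = build_metric_table(volumes, rois)
        assert len(table) == 1
        row = table.iloc[0]
        assert {"cnr_liver", "snr_liver", "cnr_aorta", "snr_aorta", "noise"} <= set(table.columns)
        assert row["noise"] > 0

    def test_inconsistent_reconstruction_sets_rejected(self):
        volumes, rois = _cohort(2, [15.0, 15.0])
        volumes.pop(("S1", "ASIR-V 50"))
        ps = make_patient_slice(abdomen_layout((160, 160), 0.35), NoiseModel(sigma=15.0),
                                size_yx=(160, 160), spacing=(2.5, 0.35, 0.35))
        volumes[("S1", "other")] = ps.volume
        with pytest.raises(ValueError, match="inconsistent reconstruction sets"):
            build_metric_table(volumes, rois)

    def test_group_summary_is_mean_of_ratios(self):
        # hand counterexample: per-subject CNRs 2 and 3 -> mean-of-ratios 2.5,
        # whereas the ratio of group means is 20/7.5 = 2.667
        table = pd.DataFrame({
            "subject_id": ["a", "b"], "reconstruction_id": ["R", "R"],
            "noise": [5.0, 10.0], "cnr_liver": [10.0 / 5.0, 30.0 / 10.0],
        })
        summ = summarize_metrics(table).set_index("metric")
        assert summ.loc["cnr_liver", "mean"] == pytest.approx(2.5)
        ratio_of_means = (10.0 + 30.0) / 2.0 / ((5.0 + 10.0) / 2.0)
        assert summ.loc["cnr_liver", "mean"] != pytest.approx(ratio_of_means)

    def test_group_mean_noise_recovers_published_chest_level(self):
        # cohorts at the non-contrast-chest noise level (21.8 +/- 3.7 HU, n=16):
        # the seed-averaged group-mean measured noise lands within 5%
        means = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            sigmas = np.clip(rng.normal(21.8, 3.7, 16), 2.0, None)
            volumes, rois = _cohort(16, sigmas, seed0=1000 * seed)
            table = build_metric_table(volumes, rois)
            means.append(table["noise"].mean())
        assert np.mean(means) == pytest.approx(21.8, rel=0.05)

    def test_noise_denominator_is_configurable(self):
        volumes, rois = _cohort(1, [15.0])
        default = build_metric_table(volumes, rois)
        alt = build_metric_table(volumes, rois, noise_label="liver")
        assert "cnr_muscle" in alt.columns and "cnr_liver" in default.columns
        assert default.loc[0, "noise"] != alt.loc[0, "noise"]
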