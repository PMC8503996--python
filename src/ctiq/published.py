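"""Published reference values of the pediatric chest/abdomen CT
reconstruction-comparison study this package models.

These are the printed group summaries (quantitative metric means, phantom
NPS summaries, reader-score distributions) and the derived percent-change
claims of its results text.  They serve two purposes: recomputing the
percent-change claims from the printed group means
(:func:`ctiq.pipeline.reproduce_published_changes`), and parameterizing the
synthetic-data presets.  Per-patient raw data were never released, so
nothing here is a per-patient reproduction target.

Reconstructions: ASIR-V 50 (the clinical baseline, 50% hybrid iterative
blending), ASIR-V 100, and deep-learning reconstruction at medium (DLR-M)
and high (DLR-H) strength.  Protocols: non-contrast chest (n=16),
contrast-enhanced chest (n=12), contrast-enhanced abdomen (n=23).
"""

RECONSTRUCTIONS = ("ASIR-V 50", "ASIR-V 100", "DLR-M", "DLR-H")
BASELINE = "ASIR-V 50"

#: protocol -> parameter -> reconstruction -> (group mean, group SD)
TABLE1 = {
    "nc_chest": {
        "n": 16,
        "attenuation_lung": {"ASIR-V 50": (-795.9, 91.1), "ASIR-V 100": (-796.2, 94.2),
                             "DLR-M": (-797.6, 94.3), "DLR-H": (-796.7, 93.9)},
        "attenuation_muscle": {"ASIR-V 50": (56.1, 11.1), "ASIR-V 100": (54.6, 12.1),
                               "DLR-M": (56.3, 10.7), "DLR-H": (54.9, 9.8)},
        "noise": {"ASIR-V 50": (21.8, 3.7), "ASIR-V 100": (15.6, 10.9),
                  "DLR-M": (20.2, 3.8), "DLR-H": (14.6, 2.5)},
        "cnr_lung": {"ASIR-V 50": (11.4, 3.7), "ASIR-V 100": (22.9, 6.9),
                     "DLR-M": (25.8, 13.3), "DLR-H": (28.4, 11.4)},
        "snr_lung": {"ASIR-V 50": (10.7, 3.5), "ASIR-V 100": (21.4, 6.4),
                     "DLR-M": (24.1, 12.5), "DLR-H": (26.6, 10.8)},
    },
    "ce_chest": {
        "n": 12,
        "attenuation_lung": {"ASIR-V 50": (-718.9, 139.4), "ASIR-V 100": (-718.7, 144.0),
                             "DLR-M": (-720.5, 145.4), "DLR-H": (-719.1, 142.8)},
        "attenuation_muscle": {"ASIR-V 50": (65.0, 8.5), "ASIR-V 100": (64.6, 5.8),
                               "DLR-M": (64.3, 5.2), "DLR-H": (62.6, 6.8)},
        "noise": {"ASIR-V 50": (24.5, 6.1), "ASIR-V 100": (12.6, 3.8),
                  "DLR-M": (21.3, 4.9), "DLR-H": (14.8, 4.7)},
        "cnr_lung": {"ASIR-V 50": (10.4, 4.0), "ASIR-V 100": (17.8, 8.1),
                     "DLR-M": (20.0, 6.9), "DLR-H": (21.4, 8.6)},
        "snr_lung": {"ASIR-V 50": (9.6, 3.7), "ASIR-V 100": (16.4, 7.6),
                     "DLR-M": (18.4, 6.6), "DLR-H": (19.8, 8.1)},
    },
    "ce_abdomen": {
        "n": 23,
        "attenuation_liver": {"ASIR-V 50": (131.4, 28.4), "ASIR-V 100": (131.7, 28.7),
                              "DLR-M": (125.9, 39.1), "DLR-H": (132.6, 28.6)},
        "attenuation_aorta": {"ASIR-V 50": (185.7, 45.2), "ASIR-V 100": (184.9, 45.9),
                              "DLR-M": (185.3, 45.1), "DLR-H": (187.6, 45.4)},
        "attenuation_muscle": {"ASIR-V 50": (71.2, 8.4), "ASIR-V 100": (71.3, 6.6),
                               "DLR-M": (72.7, 6.0), "DLR-H": (71.1, 6.2)},
        "noise": {"ASIR-V 50": (19.9, 3.7), "ASIR-V 100": (11.1, 3.6),
                  "DLR-M": (16.3, 3.1), "DLR-H": (12.2, 2.4)},
        "cnr_liver": {"ASIR-V 50": (3.2, 1.7), "ASIR-V 100": (5.3, 3.0),
                      "DLR-M": (3.2, 2.4), "DLR-H": (4.9, 2.5)},
        "cnr_aorta": {"ASIR-V 50": (5.3, 2.2), "ASIR-V 100": (9.5, 4.3),
                      "DLR-M": (5.8, 1.9), "DLR-H": (8.0, 2.9)},
        "snr_liver": {"ASIR-V 50": (6.8, 2.1), "ASIR-V 100": (11.5, 3.9),
                      "DLR-M": (7.6, 2.7), "DLR-H": (10.7, 2.9)},
        "snr_aorta": {"ASIR-V 50": (8.5, 2.4), "ASIR-V 100": (15.6, 5.1),
                      "DLR-M": (9.7, 2.0), "DLR-H": (13.0, 3.2)},
    },
}

#: phantom NPS peak (HU^2.mm^2), dose (mGy) -> reconstruction -> value
TABLE2_NPS_PEAK = {
    1: {"ASIR-V 50": 69.30, "ASIR-V 100": 45.71, "DLR-M": 46.76, "DLR-H": 34.47},
    3: {"ASIR-V 50": 22.03, "ASIR-V 100": 14.61, "DLR-M": 15.10, "DLR-H": 10.03},
    5: {"ASIR-V 50": 14.86, "ASIR-V 100": 9.86, "DLR-M": 10.40, "DLR-H": 7.20},
}

#: phantom NPS average spatial frequency (mm^-1)
TABLE2_NPS_FAVG = {
    1: {"ASIR-V 50": 0.27, "ASIR-V 100": 0.19, "DLR-M": 0.30, "DLR-H": 0.28},
    3: {"ASIR-V 50": 0.29, "ASIR-V 100": 0.19, "DLR-M": 0.32, "DLR-H": 0.31},
    5: {"ASIR-V 50": 0.28, "ASIR-V 100": 0.19, "DLR-M": 0.32, "DLR-H": 0.31},
}

#: reader-score distributions (counts of scores 1/2/3/4 over all 51 patients)
#: parameter -> reconstruction -> {"reviewer_1": counts, "reviewer_2": counts, "kappa": value}
TABLE3 = {
    "overall_quality": {
        "ASIR-V 50": {"reviewer_1": (0, 47, 4, 0), "reviewer_2": (0, 47, 4, 0), "kappa": 0.728},
        "ASIR-V 100": {"reviewer_1": (0, 4, 47, 0), "reviewer_2": (0, 0, 51, 0), "kappa": 0.0},
        "DLR-M": {"reviewer_1": (0, 0, 49, 1), "reviewer_2": (0, 0, 49, 1), "kappa": -0.02},
        "DLR-H": {"reviewer_1": (0, 0, 38, 13), "reviewer_2": (0, 0, 35, 16), "kappa": 0.568},
    },
    "noise": {
        "ASIR-V 50": {"reviewer_1": (0, 47, 4, 0), "reviewer_2": (0, 49, 2, 0), "kappa": 0.297},
        "ASIR-V 100": {"reviewer_1": (0, 8, 43, 0), "reviewer_2": (0, 0, 51, 0), "kappa": 0.0},
        "DLR-M": {"reviewer_1": (0, 1, 48, 1), "reviewer_2": (0, 0, 51, 0), "kappa": 0.0},
        "DLR-H": {"reviewer_1": (0, 1, 34, 16), "reviewer_2": (0, 0, 33, 18), "kappa": 0.62},
    },
    "artifact": {
        "ASIR-V 50": {"reviewer_1": (0, 11, 40, 0), "reviewer_2": (0, 12, 39, 0), "kappa": 0.944},
        "ASIR-V 100": {"reviewer_1": (0, 11, 40, 0), "reviewer_2": (0, 12, 39, 0), "kappa": 0.944},
        "DLR-M": {"reviewer_1": (0, 11, 40, 0), "reviewer_2": (0, 12, 39, 0), "kappa": 0.94},
        "DLR-H": {"reviewer_1": (0, 11, 40, 0), "reviewer_2": (0, 12, 39, 0), "kappa": 0.944},
    },
}

#: percent-change claims of the results text, all DLR-H vs ASIR-V 50 except
#: the last (DLR-H vs ASIR-V 100).  (protocol, metric, direction, printed %)
RESULTS_PERCENT_CLAIMS = [
    ("nc_chest", "noise", "reduction", 33.0),
    ("ce_chest", "noise", "reduction", 39.6),
    ("ce_abdomen", "noise", "reduction", 38.7),
    ("nc_chest", "cnr_lung", "increase", 149.1),
    ("ce_chest", "cnr_lung", "increase", 105.8),
    ("ce_abdomen", "cnr_liver", "increase", 53.1),
    ("nc_chest", "snr_lung", "increase", 148.6),
    ("ce_chest", "snr_lung", "increase", 106.3),
    ("ce_abdomen", "snr_liver", "increase", 57.4),
]

#: DLR-H vs ASIR-V 100 CNR gain, non-contrast chest ("by 24%")
RESULTS_CNR_VS_ASIRV100 = ("nc_chest", "cnr_lung", "increase", 24.0)

#: reported mean NPS-peak decrease rate from 1 to 5 mGy, percent remaining
NPS_PEAK_DECREASE_RATE_PCT = 21.0

#: reported interobserver agreement for artifacts
ARTIFACT_KAPPA = 0.944
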