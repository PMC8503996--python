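"""Reconstruction and protocol presets for the synthetic study conditions.

Each reconstruction label gets a spectral-shape preset and a phantom noise
magnitude at the 1 mGy reference dose.  Shapes and magnitudes are chosen
analytically (via :func:`ctiq.synthetic.expected_nps`) so the synthetic
phantom reproduces the published orderings: NPS peaks decreasing in the
order ASIR-V 50 > DLR-M > ASIR-V 100 > DLR-H with the DLR presets keeping a
higher average spatial frequency at lower magnitude ("reduce the noise,
keep the texture"), and the 100% iterative preset the coarsest texture.
Patient-protocol noise levels come from the published group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import published
from .synthetic import NoiseModel


@dataclass
class ReconPreset:
    recon_id: str
    shape: str
    shape_params: dict
    phantom_sigma_1mgy: float   # HU at the 1 mGy reference dose
    #: protocol -> (cohort mean noise SD, between-subject SD), HU
    patient_noise: dict = field(default_factory=dict)

    def noise_model(self, sigma: float, seed: int) -> NoiseModel:
        return NoiseModel(sigma=sigma, shape=self.shape, params=dict(self.shape_params), seed=seed)


def _patient_noise(recon: str) -> dict:
    return {proto: published.TABLE1[proto]["noise"][recon] for proto in published.TABLE1}


RECON_PRESETS = {
    "ASIR-V 50": ReconPreset("ASIR-V 50", "fbp_like", {"f0": 0.145}, 7.05,
                             _patient_noise("ASIR-V 50")),
    "ASIR-V 100": ReconPreset("ASIR-V 100", "smooth", {"fc": 0.34}, 4.05,
                              _patient_noise("ASIR-V 100")),
    "DLR-M": ReconPreset("DLR-M", "fbp_like", {"f0": 0.165}, 6.60,
                         _patient_noise("DLR-M")),
    "DLR-H": ReconPreset("DLR-H", "fbp_like", {"f0": 0.16}, 5.50,
                         _patient_noise("DLR-H")),
}

BASELINE = published.BASELINE
DOSE_LEVELS_MGY = (1.0, 3.0, 5.0)

#: protocol -> tissue mean HU at baseline (attenuation is reconstruction-invariant)
PROTOCOL_TISSUES = {
    proto: {
        key.removeprefix("attenuation_"): vals[BASELINE][0]
        for key, vals in published.TABLE1[proto].items()
        if isinstance(vals, dict) and key.startswith("attenuation_")
    }
    for proto in published.TABLE1
}

PROTOCOL_N = {proto: published.TABLE1[proto]["n"] for proto in published.TABLE1}
PROTOCOL_REGION = {"nc_chest": "chest", "ce_chest": "chest", "ce_abdomen": "abdomen"}

#: subject-level correlation of noise across reconstructions (paired design:
#: a big patient is noisy under every reconstruction)
NOISE_SUBJECT_CORRELATION = 0.7

#: reader-score agreement levels used when simulating the two reviewers
SCORE_AGREEMENT = {"overall_quality": 0.85, "noise": 0.85, "artifact": 0.95}
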