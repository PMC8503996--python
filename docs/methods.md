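# Methods

`ctiq` models the image-quality side of a pediatric chest/abdomen CT
reconstruction comparison: four reconstructions of the same raw data
(ASIR-V 50 as clinical baseline, ASIR-V 100, and deep-learning
reconstruction at medium and high strength) assessed with a phantom noise
power spectrum, ROI metrics on patient images, dose conversion, and paired
statistics.  Because neither the patient images nor the phantom scans of
the modeled study were deposited, the package carries a synthetic-data
module that emulates both at the study's published settings; everything
downstream is exercised against that generator's known ground truth.

## Noise model and synthetic data

Noise is stationary, zero-mean, correlated Gaussian noise, generated by
spectral shaping: a white Gaussian field is transformed with the 2D FFT,
multiplied by the square root of a target radial power-spectrum shape
S(f), inverse-transformed, and finally rescaled in the image domain so the
interior sample SD equals the requested sigma exactly (n−1 denominator).
Slices are generated independently, so the 3D spectrum is separable with a
white through-plane axis.  Real CT noise is neither perfectly stationary
nor Gaussian, and its slice correlation depends on the reconstruction;
this is the standard uniform-phantom idealization, and passing tests
demonstrate estimator correctness under that idealization, not robustness
to non-stationarity, streaks, or object-dependent texture.

Three shape families cover the textures that matter here (f in mm^-1):

| shape      | S(f)                    | parameter | role |
|------------|-------------------------|-----------|------|
| `white`    | 1                       | —         | calibration/flatness checks |
| `fbp_like` | (f/f0)·exp(1 − f/f0)    | peak f0   | band-pass, ramp-filtered look |
| `smooth`   | exp(−(f/fc)^2)          | cutoff fc | low-pass, blotchy over-smoothed look |

Reconstruction presets (`ctiq.presets`) pair a shape with a phantom noise
magnitude at the 1 mGy reference dose.  The parameters were chosen
analytically — `expected_nps` converts (sigma, shape) into the NPS curve
the estimator should see — so that the four presets reproduce the
published phantom orderings: peaks decreasing ASIR-V 50 (≈69) > DLR-M
(≈47) > ASIR-V 100 (≈46) > DLR-H (≈34) HU²·mm², with the DLR presets
keeping average spatial frequency near 0.31 mm⁻¹ against 0.20 mm⁻¹ for the
fully iterative preset ("lower noise, preserved texture").  The published
study gives no functional form for its NPS curves, so the shapes reproduce
the summary orderings, not the curves themselves.

Dose dependence uses the quantum-noise limit, variance ∝ 1/dose, which
matches the published ~21% peak ratio between 1 and 5 mGy.  Patient-like
slices place non-overlapping circular tissue regions (lung/muscle for
chest, liver/aorta/muscle for abdomen) at the published mean HU, add one
shared-texture noise field, and return ground truth plus ready-made ROIs.
Cohort simulation draws each subject's noise level from the published
group mean ± SD with a between-reconstruction subject correlation of 0.7
(a large patient is noisy under every reconstruction), emulating the
paired design.  Reader scores are generated from the published reviewer-1
marginal distributions; reviewer 2 copies reviewer 1 with probability
`agreement_level` and otherwise draws independently from the margins.

All generation is deterministic given the seed (numpy PCG64); sub-seeds
are derived by SHA-256 of a tag string, so results are stable across
platforms and insertion order.

## NPS estimation

Single-scan ensemble estimator: overlapping square ROIs (default 64²,
50% overlap) are tiled over the uniform region; each ROI is detrended by
subtracting its least-squares 2nd-order polynomial surface (order
configurable).  Pair-subtraction detrending is not used because the
modeled study has one volume per condition.  The spectrum is

    NPS(f) = (Δx·Δy / Nx·Ny) · ⟨|DFT(roi)|²⟩,

with the 3D mode using the analogous three-axis normalization
(HU²·mm³) and additionally integrating over f_z (× Δf_z) to report an
in-plane HU²·mm² curve comparable with the 2D convention.  Radial binning
uses bin width 1/(N·Δx), averages (not sums) grid cells, drops empty
bins, and is restricted to f ≤ Nyquist; the DC bin and both
zero-frequency axis lines are excluded from the 1D curve because
detrending suppresses them unreliably.  Isotropic in-plane spacing is
required for radial binning.  No taper window is applied by default
(polynomial detrending suffices on uniform phantoms).

Summaries: peak = max of the radial curve (noise magnitude); f_avg =
Σ f·NPS / Σ NPS over f > 0 (noise texture).  An all-zero spectrum is
flagged (`f_avg_defined=False`); a single-ROI ensemble is flagged
high-variance.  Guaranteed identities, enforced by tests: the Cartesian
integral equals the ensemble-mean residual variance (Parseval, to float
precision); NPS(c·x) = c²·NPS(x); adding a constant changes nothing.

Known biases, accepted and documented: overlapping ROIs correlate
ensemble members (standard practice; slows convergence, does not bias);
detrending removes a small amount of genuine low-frequency noise power,
so for low-pass shapes whose peak sits in the lowest radial bin the
estimated peak is attenuated by the detrend convention — the parameter
recovery guarantees are therefore stated for band-pass shapes, and the
low-pass preset is compared on orderings only.

## ROI metrics

Disc membership: voxel centers strictly inside the radius, Euclidean
distance in mm; SD uses n−1; ROIs under 5 voxels are rejected.  Noise is
the SD of the paraspinal-muscle ROI; CNR = |HU_obj − HU_muscle|/SD_noise;
SNR = HU_obj/SD_noise with sign preserved (lung SNR is negative — the
published tables print magnitudes).  The noise denominator is exposed as
a parameter because it is a convention, not physics.  Group summaries
average per-subject values (mean of ratios), never the ratio of group
means; the two differ materially whenever noise varies across subjects,
and only the per-subject convention is consistent with the published
group CNR values and with paired testing.

## Dose conversion

SSDE = CTDIvol × f(size), with f interpolated linearly in the AP+LAT
dimension sum from a shipped table for the 32-cm body reference phantom
(assumed for both regions, configurable).  The shipped table is generated
from the standard exponential fit f = 3.704369·exp(−0.03671937·d_eff)
with d_eff = (AP+LAT)/2; sums outside 16–90 cm are clamped with a warning
(or raise, configurable).  ED = DLP × W_T with W_T from a shipped CSV
keyed by (region, kVp band, age band); 70 kVp studies adopt the 80 kVp
coefficient because nothing lower is tabulated.  Both tables are editable
configuration: the modeled study printed neither, so per-patient SSDE/ED
values are pipeline capability, not reproduction targets.

## Statistics

* RM-ANOVA: one-way within-subject F (via pingouin), listwise deletion,
  no sphericity correction by default (the correction flag exists
  upstream); pairwise paired t-tests against the baseline only — the
  three printed comparisons — Bonferroni-adjusted as p_adj = min(1, 3p).
  All-identical conditions short-circuit to F = 0, p = 1 with a
  degenerate flag.
* Wilcoxon signed-rank: zeros dropped, midranks; exact enumeration of all
  2^n sign assignments for ≤ 12 non-zero pairs (two-sided tail of
  |W − μ|), normal approximation with continuity correction and
  tie-corrected variance Σr²/4 above.  Implemented directly because this
  exact convention is part of the contract; the no-ties path is
  cross-checked against scipy's exact method in tests.
* Cohen's kappa: unweighted, full 4×4 table; when both raters are
  constant, expected agreement is 1 and kappa is defined as 0 with a
  degenerate flag (this matches the zero entries in the published
  agreement table for constant-margin rows).  Bands: ≤0.20 poor, ≤0.40
  fair, ≤0.60 moderate, ≤0.80 good, else excellent; negative values fall
  in "poor".
* percent change: 100·(baseline−new)/baseline (reduction) or
  100·(new−baseline)/baseline (increase), rounded only at display.

## Problem sizes and numerical choices

Default phantom runs use 8 slices of 256² at (2.5, 0.5, 0.5) mm — 392
overlapping ROIs per volume — and cohort runs one 160² slice per subject
per reconstruction; these sizes give estimator standard errors of a few
percent, well inside the stated stochastic tolerances, and keep a full
pipeline run under a minute.  The in-plane pixel spacing of the modeled
study is not published; 0.5 mm is a representative value and every
computation carries spacing explicitly, so nothing depends on the choice.
Tissue-region discs are 20 mm with 9–10 mm ROIs so every disc holds
hundreds of voxels.  Patch detrending uses a shared projector matrix
(pseudo-inverse computed once), and constant ROIs report SD exactly 0.

## Limitations

The proprietary reconstructions themselves are never modeled — presets
are labeled conditions, not algorithm emulations; there is no
projection-domain physics, no artifact synthesis (the modeled study found
artifacts unchanged across methods), no MTF/detectability analysis, and
no non-stationary NPS maps.  The published per-patient tables, per-patient
dose values and reader cross-tables are not recoverable from printed
summaries; the synthetic cohorts reproduce group-level behavior only.
The published lung CNR/SNR magnitudes cannot be reconciled exactly with
the stated muscle-SD denominator; the package implements the stated
definition and leaves the denominator configurable.
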