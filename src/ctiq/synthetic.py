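"""Synthetic CT data: phantoms with shaped noise, patient-like slices, dose
and reader-score tables.

The noise model is stationary correlated Gaussian noise: white Gaussian
noise is shaped in the 2D frequency domain by multiplying its spectrum with
the square root of a target radial power-spectrum shape, inverse
transformed, and finally rescaled in the image domain so the interior
sample variance equals the requested sigma^2 exactly.  Slices are
independent (no through-plane correlation by default), which makes the 3D
spectrum separable and through-plane white.

This is the standard uniform-phantom idealization: real CT noise is neither
perfectly stationary nor Gaussian, and dose-dependence is emulated with the
quantum-noise-limit law variance ~ 1/dose.

Spectral shapes (radial, frequency f in mm^-1):

``white``      S(f) = 1
``fbp_like``   S(f) = (f/f0)·exp(1 − f/f0)  — band-pass, peaking at ``f0``;
               the ramp-filtered look of analytic reconstruction
``smooth``     S(f) = exp(−(f/fc)^2)         — low-pass with cutoff ``fc``;
               the blotchy look of aggressive iterative smoothing

All generation is deterministic given the model seed (numpy Generator,
PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ImageVolume, ROISpec

SHAPE_NAMES = ("white", "fbp_like", "smooth")


def shape_function(shape: str, params: dict) -> Callable[[np.ndarray], np.ndarray]:
    """Return the radial spectral-shape function S(f) for a named shape."""
    if shape == "white":
        return lambda f: np.ones_like(np.asarray(f, dtype=float))
    if shape == "fbp_like":
        f0 = float(params["f0"])
        if f0 <= 0:
            raise ValueError("fbp_like shape needs f0 > 0")
        return lambda f: (np.asarray(f, float) / f0) * np.exp(1.0 - np.asarray(f, float) / f0)
    if shape == "smooth":
        fc = float(params["fc"])
        if fc <= 0:
            raise ValueError("smooth shape needs fc > 0")
        return lambda f: np.exp(-((np.asarray(f, float) / fc) ** 2))
    raise ValueError(f"unknown spectral shape {shape!r}; known: {SHAPE_NAMES}")


@dataclass
class NoiseModel:
    """Target noise magnitude and texture.

    sigma   target noise SD in HU (interior sample SD is rescaled to this
            value exactly)
    shape   named radial spectral shape, see module docstring
    params  shape parameters (``f0`` for fbp_like, ``fc`` for smooth), mm^-1
    seed    integer seed for the underlying white-noise field
    """

    sigma: float
    shape: str = "white"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        self.shape_fn = shape_function(self.shape, self.params)

    def with_(self, **kwargs) -> "NoiseModel":
        d = dict(sigma=self.sigma, shape=self.shape, params=dict(self.params), seed=self.seed)
        d.update(kwargs)
        return NoiseModel(**d)


def _shaped_noise_field(n_slices: int, ny: int, nx: int,
                        spacing: tuple[float, float, float],
                        model: NoiseModel) -> np.ndarray:
    """Unit-scale correlated noise field, one independent 2D field per slice."""
    _, dy, dx = spacing
    fy = np.fft.fftfreq(ny, d=dy)
    fx = np.fft.fftfreq(nx, d=dx)
    r = np.hypot(fy[:, None], fx[None, :])
    amp = np.sqrt(np.maximum(model.shape_fn(r), 0.0))
    rng = np.random.default_rng(model.seed)
    white = rng.standard_normal((n_slices, ny, nx))
    return np.fft.ifft2(np.fft.fft2(white, axes=(1, 2)) * amp[None], axes=(1, 2)).real


def phantom_interior_mask(shape_yx: tuple[int, int], radius_fraction: float = 0.45) -> np.ndarray:
    """Boolean in-plane mask of the phantom interior disc (index space)."""
    ny, nx = shape_yx
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = radius_fraction * min(ny, nx)
    yy, xx = np.mgrid[0:ny, 0:nx]
    return (yy - cy) ** 2 + (xx - cx) ** 2 < radius**2


def uniform_square_region(shape_yx: tuple[int, int], radius_fraction: float = 0.45) -> tuple[int, int, int, int]:
    """Largest axis-aligned square inscribed in the interior disc, as (y0, y1, x0, x1)."""
    ny, nx = shape_yx
    half = int(np.floor(radius_fraction * min(ny, nx) / np.sqrt(2.0)))
    cy, cx = ny // 2, nx // 2
    return cy - half, cy + half, cx - half, cx + half


def make_phantom(size: tuple[int, int, int],
                 spacing: tuple[float, float, float],
                 mean_hu: float,
                 noise_model: NoiseModel,
                 background_hu: float | None = None) -> ImageVolume:
    """Uniform cylindrical phantom volume with shaped stationary noise.

    ``size`` is (slices, rows, columns) with >= 64x64 in-plane for NPS work.
    The interior disc (45% radius fraction) has mean ``mean_hu`` and sample
    noise SD exactly ``noise_model.sigma`` (n−1 denominator).  With
    ``background_hu=None`` the whole field is phantom material (the
    uniformity-module idealization); otherwise voxels outside the disc get
    ``background_hu`` plus the same noise texture.
    """
    nz, ny, nx = size
    if ny < 64 or nx < 64:
        raise ValueError(f"phantom must be >= 64x64 in-plane for NPS work, got {ny}x{nx}")
    interior = phantom_interior_mask((ny, nx))
    if noise_model.sigma == 0:
        noise = np.zeros(size)
    else:
        field_ = _shaped_noise_field(nz, ny, nx, spacing, noise_model)
        vals = field_[:, interior]
        m, s = vals.mean(), vals.std(ddof=1)
        noise = (field_ - m) * (noise_model.sigma / s)
    voxels = mean_hu + noise
    if background_hu is not None:
        voxels[:, ~interior] = background_hu + noise[:, ~interior]
    return ImageVolume(voxels, spacing, origin_label=f"synthetic phantom {noise_model.shape} sigma={noise_model.sigma}")


def make_dose_series(size: tuple[int, int, int],
                     spacing: tuple[float, float, float],
                     mean_hu: float,
                     noise_model: NoiseModel,
                     doses_mgy: Sequence[float],
                     ref_dose_mgy: float | None = None) -> list[tuple[float, ImageVolume]]:
    """Phantom volumes across dose levels under variance ∝ 1/dose.

    ``noise_model.sigma`` is the SD at ``ref_dose_mgy`` (default: the first
    dose listed); a volume at dose D gets sigma·sqrt(ref/D), same spectral
    shape.  The volume at the reference dose (index 0) reuses the model seed
    unchanged, so a single-dose series reproduces ``make_phantom`` exactly.
    """
    doses = [float(d) for d in doses_mgy]
    if any(d <= 0 for d in doses):
        raise ValueError(f"doses must be > 0 mGy, got {doses}")
    if len(set(doses)) != len(doses):
        raise ValueError(f"duplicate dose levels: {doses}")
    ref = float(ref_dose_mgy) if ref_dose_mgy is not None else doses[0]
    out = []
    for i, d in enumerate(doses):
        model = noise_model.with_(sigma=noise_model.sigma * np.sqrt(ref / d),
                                  seed=noise_model.seed + i)
        out.append((d, make_phantom(size, spacing, mean_hu, model)))
    return out


# ---------------------------------------------------------------------------
# analytic expectations for the generated noise (ground truth for tests)


def expected_nps(noise_model: NoiseModel, patch_size: int,
                 pixel_mm: float) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Analytic radial NPS curve the estimator should recover.

    The generator scales the shaped field to variance sigma^2, so the true
    Cartesian NPS is C·S(f) with C = sigma^2 / ΣS(grid)·df^2.  Returns
    ``(freq, curve, peak, f_avg)`` on radial bin centers k/(N·Δx),
    k = 1..N/2 (DC excluded, as in the estimator).
    """
    n, dx = patch_size, pixel_mm
    f1 = np.fft.fftfreq(n, d=dx)
    r = np.hypot(f1[:, None], f1[None, :])
    df = 1.0 / (n * dx)
    s_grid = noise_model.shape_fn(r)
    norm = noise_model.sigma**2 / (s_grid.sum() * df * df)
    freq = df * np.arange(1, n // 2 + 1)
    curve = norm * noise_model.shape_fn(freq)
    peak = float(curve.max())
    f_avg = float((freq * curve).sum() / curve.sum()) if curve.sum() > 0 else float("nan")
    return freq, curve, peak, f_avg


# ---------------------------------------------------------------------------
# patient-like slices


@dataclass
class TissueRegion:
    label: str
    center_yx: tuple[int, int]   # voxel indices
    diameter_mm: float
    mean_hu: float


@dataclass
class TissueLayout:
    """Non-overlapping circular tissue regions on one axial slice."""

    regions: list[TissueRegion]
    background_hu: float = -50.0

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"tissue labels must be unique per slice, got {labels}")

    def validate_geometry(self, spacing_yx: tuple[float, float]) -> None:
        dy, dx = spacing_yx
        if abs(dy - dx) > 1e-9:
            raise ValueError("tissue layouts assume isotropic in-plane spacing")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                dist_mm = np.hypot((a.center_yx[0] - b.center_yx[0]) * dy,
                                   (a.center_yx[1] - b.center_yx[1]) * dx)
                if dist_mm < (a.diameter_mm + b.diameter_mm) / 2.0:
                    raise ValueError(f"tissue regions {a.label!r} and {b.label!r} overlap")


@dataclass
class PatientSlice:
    """A generated patient-like slice plus its ground truth for oracle tests."""

    volume: ImageVolume
    truth_mean_hu: dict[str, float]
    truth_sigma: float
    rois: list[ROISpec]


def chest_layout(size_yx: tuple[int, int], pixel_mm: float,
                 lung_hu: float = -795.9, muscle_hu: float = 56.1,
                 region_diameter_mm: float = 20.0) -> TissueLayout:
    """Lung + paraspinal-muscle targets, as measured at the carina level."""
    ny, nx = size_yx
    return TissueLayout(
        regions=[
            TissueRegion("lung", (ny // 3, nx // 3), region_diameter_mm, lung_hu),
            TissueRegion("muscle", (2 * ny // 3, 2 * nx // 3), region_diameter_mm, muscle_hu),
        ],
        background_hu=-30.0,
    )


def abdomen_layout(size_yx: tuple[int, int], pixel_mm: float,
                   liver_hu: float = 131.4, aorta_hu: float = 185.7,
                   muscle_hu: float = 71.2, region_diameter_mm: float = 20.0) -> TissueLayout:
    """Liver + aorta + paraspinal-muscle targets, portal-vein level."""
    ny, nx = size_yx
    return TissueLayout(
        regions=[
            TissueRegion("liver", (ny // 4, nx // 4), region_diameter_mm, liver_hu),
            TissueRegion("aorta", (ny // 4, 3 * nx // 4), region_diameter_mm, aorta_hu),
            TissueRegion("muscle", (3 * ny // 4, nx // 2), region_diameter_mm, muscle_hu),
        ],
        background_hu=20.0,
    )


def make_patient_slice(layout: TissueLayout, noise_model: NoiseModel,
                       size_yx: tuple[int, int] = (160, 160),
                       spacing: tuple[float, float, float] = (2.5, 0.5, 0.5),
                       roi_diameter_mm: float = 9.0) -> PatientSlice:
    """One axial slice with per-tissue mean HU plus shared-texture noise.

    The noise field is rescaled so the slice-wide sample SD equals sigma
    exactly; every tissue region therefore carries the same noise texture
    (the paired-reconstruction situation the comparisons assume).  ROIs of
    ``roi_diameter_mm`` centered on each region are returned for metric
    extraction.
    """
    ny, nx = size_yx
    dz, dy, dx = spacing
    layout.validate_geometry((dy, dx))
    base = np.full((ny, nx), float(layout.background_hu))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for reg in layout.regions:
        cy, cx = reg.center_yx
        rad_vox = reg.diameter_mm / 2.0 / dx
        base[(yy - cy) ** 2 + (xx - cx) ** 2 < rad_vox**2] = reg.mean_hu
    if noise_model.sigma == 0:
        noise = np.zeros((1, ny, nx))
    else:
        field_ = _shaped_noise_field(1, ny, nx, spacing, noise_model)
        noise = (field_ - field_.mean()) * (noise_model.sigma / field_.std(ddof=1))
    vol = ImageVolume(base[None] + noise, spacing, origin_label="synthetic patient slice")
    rois = [ROISpec(r.label, (0, r.center_yx[0], r.center_yx[1]), roi_diameter_mm) for r in layout.regions]
    truth = {r.label: r.mean_hu for r in layout.regions}
    return PatientSlice(vol, truth, noise_model.sigma, rois)


# ---------------------------------------------------------------------------
# reader scores


def make_scores(n_subjects: int, marginal_profile: Sequence[int],
                agreement_level: float, seed: int) -> pd.DataFrame:
    """Two-reviewer 4-point ordinal scores with tunable agreement.

    ``marginal_profile`` gives reviewer 1's counts for scores 1..4 and must
    sum to ``n_subjects``.  Reviewer 2 copies reviewer 1's score with
    probability ``agreement_level`` and otherwise draws independently from
    the profile distribution; at ``agreement_level=1`` the reviewers are
    identical.  Returns a frame with columns subject_id, reviewer_1,
    reviewer_2.
    """
    profile = np.asarray(marginal_profile, dtype=int)
    if profile.shape != (4,) or (profile < 0).any():
        raise ValueError("marginal_profile must be four non-negative counts for scores 1..4")
    if profile.sum() != n_subjects:
        raise ValueError(f"marginal_profile sums to {profile.sum()}, expected n_subjects={n_subjects}")
    if not 0.0 <= agreement_level <= 1.0:
        raise ValueError("agreement_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    r1 = np.repeat(np.arange(1, 5), profile)
    rng.shuffle(r1)
    p = profile / profile.sum()
    independent = rng.choice(np.arange(1, 5), size=n_subjects, p=p)
    copy = rng.random(n_subjects) < agreement_level
    r2 = np.where(copy, r1, independent)
    return pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n_subjects)],
        "reviewer_1": r1.astype(int),
        "reviewer_2": r2.astype(int),
    })


# ---------------------------------------------------------------------------
# dose metadata tables


def make_dose_table(n_subjects: int, region: str, seed: int,
                    ctdivol_mean_sd: tuple[float, float] = (1.4, 0.5),
                    dlp_mean_sd: tuple[float, float] = (60.0, 30.0)) -> pd.DataFrame:
    """Scanner dose-descriptor table for a synthetic pediatric cohort.

    Weights follow the cohort description (mean 44 ± 19 kg, truncated to
    5–90 kg); kVp follows the weight bands 100 kVp > 40 kg, 80 kVp for
    15–40 kg, 70 kVp < 15 kg.  AP+LAT size grows linearly with weight.
    """
    if region not in ("chest", "abdomen"):
        raise ValueError(f"region must be chest or abdomen, got {region!r}")
    rng = np.random.default_rng(seed)
    weight = np.clip(rng.normal(44.3, 18.9, n_subjects), 5.0, 90.0)
    kvp = np.where(weight > 40, 100, np.where(weight >= 15, 80, 70))
    ctdivol = np.clip(rng.normal(*ctdivol_mean_sd, n_subjects), 0.3, None)
    dlp = np.clip(rng.normal(*dlp_mean_sd, n_subjects), 10.0, None)
    dim_sum = 18.0 + 0.55 * weight + rng.normal(0, 2.0, n_subjects)
    return pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n_subjects)],
        "region": region,
        "weight_kg": np.round(weight, 1),
        "kvp": kvp.astype(int),
        "ctdivol_mgy": np.round(ctdivol, 3),
        "dlp_mgycm": np.round(dlp, 2),
        "ap_dim_cm": np.round(0.45 * dim_sum, 2),
        "lat_dim_cm": np.round(0.55 * dim_sum, 2),
    })
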