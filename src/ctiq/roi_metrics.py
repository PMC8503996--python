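"""Per-ROI attenuation/noise and per-subject CNR / SNR.

Definitions:

    noise = SD of the paraspinal-muscle ROI (HU)
    CNR   = |HU_object - HU_muscle| / SD_noise
    SNR   = HU_object / SD_noise          (sign preserved; lung is negative)

Group summaries are the mean +/- SD of per-subject values (mean of ratios),
never the ratio of group means — the two differ whenever noise varies
across subjects, and only the per-subject convention is consistent with
paired statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ImageVolume, ROISpec

MIN_ROI_VOXELS = 5


@dataclass
class ROIMeasurement:
    label: str
    mean_hu: float
    sd_hu: float
    n_voxels: int


def disc_mask(shape_yx: tuple[int, int], center_yx: tuple[float, float],
              diameter_mm: float, spacing_yx: tuple[float, float]) -> np.ndarray:
    """Voxels whose centers lie strictly within the disc radius (Euclidean, mm)."""
    ny, nx = shape_yx
    dy, dx = spacing_yx
    cy, cx = center_yx
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist2 = ((yy - cy) * dy) ** 2 + ((xx - cx) * dx) ** 2
    return dist2 < (diameter_mm / 2.0) ** 2


def extract_roi_stats(volume: ImageVolume, roi: ROISpec) -> ROIMeasurement:
    """Mean and SD (n-1 denominator) over the ROI disc."""
    roi.check_bounds(volume)
    z, y, x = roi.center
    mask = disc_mask(volume.shape[1:], (y, x), roi.diameter_mm, volume.spacing[1:])
    vals = volume.voxels[z][mask]
    if vals.size < MIN_ROI_VOXELS:
        raise ValueError(
            f"ROI {roi.label!r} covers only {vals.size} voxels (< {MIN_ROI_VOXELS}); "
            "enlarge the diameter or refine the grid"
        )
    # a truly constant region has SD exactly 0 (guard against summation jitter)
    sd = 0.0 if vals.max() == vals.min() else float(vals.std(ddof=1))
    return ROIMeasurement(roi.label, float(vals.mean()), sd, int(vals.size))


def compute_cnr(hu_object: float, hu_muscle: float, sd_noise: float) -> float:
    """CNR = |HU_object - HU_muscle| / SD_noise."""
    if sd_noise <= 0:
        raise ValueError(f"CNR undefined for sd_noise <= 0 (got {sd_noise})")
    return abs(hu_object - hu_muscle) / sd_noise


def compute_snr(hu_object: float, sd_noise: float) -> float:
    """SNR = HU_object / SD_noise, sign preserved."""
    if sd_noise <= 0:
        raise ValueError(f"SNR undefined for sd_noise <= 0 (got {sd_noise})")
    return hu_object / sd_noise


def build_metric_table(volumes: Mapping[tuple[str, str], ImageVolume],
                       rois: Mapping[str, Sequence[ROISpec]] | Sequence[ROISpec],
                       noise_label: str = "muscle") -> pd.DataFrame:
    """One metric row per subject x reconstruction.

    ``volumes`` maps ``(subject_id, reconstruction_id)`` to a volume;
    ``rois`` is either a shared ROI list or a per-subject mapping.  Every
    subject must carry the same reconstruction set.  ``noise_label`` names
    the ROI whose SD defines the noise denominator (the stated definition
    uses paraspinal muscle; the parameter exists because that choice is a
    convention).  Rows whose noise ROI is missing are flagged
    (``complete=False``) so paired statistics can drop them listwise.
    """
    recon_sets: dict[str, set[str]] = {}
    for subj, recon in volumes:
        recon_sets.setdefault(subj, set()).add(recon)
    ref = None
    for subj, rs in recon_sets.items():
        if ref is None:
            ref = rs
        elif rs != ref:
            raise ValueError(f"inconsistent reconstruction sets: subject {subj} has {sorted(rs)}, expected {sorted(ref)}")

    rows = []
    for (subj, recon), vol in sorted(volumes.items()):
        roi_list = rois[subj] if isinstance(rois, Mapping) else rois
        meas = {}
        for i, roi in enumerate(roi_list):
            key = roi.label if roi.label not in meas else f"{roi.label}_{i}"
            meas[key] = extract_roi_stats(vol, roi)
        row: dict = {"subject_id": subj, "reconstruction_id": recon}
        for label, m in meas.items():
            row[f"attenuation_{label}"] = m.mean_hu
        noise_meas = meas.get(noise_label)
        row["noise"] = noise_meas.sd_hu if noise_meas else np.nan
        row["complete"] = noise_meas is not None
        for label, m in meas.items():
            if label == noise_label:
                continue
            if noise_meas and noise_meas.sd_hu > 0:
                row[f"cnr_{label}"] = compute_cnr(m.mean_hu, noise_meas.mean_hu, noise_meas.sd_hu)
                row[f"snr_{label}"] = compute_snr(m.mean_hu, noise_meas.sd_hu)
            else:
                row[f"cnr_{label}"] = np.nan
                row[f"snr_{label}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_metrics(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD per reconstruction for every numeric metric column.

    Averages per-subject values (mean of ratios for CNR/SNR).  Returns one
    row per (reconstruction, metric) with mean, sd and n.
    """
    value_cols = [c for c in metric_table.columns
                  if c not in ("subject_id", "reconstruction_id", "complete")]
    rows = []
    for recon, grp in metric_table.groupby("reconstruction_id", sort=True):
        for col in value_cols:
            vals = grp[col].dropna()
            rows.append({"reconstruction_id": recon, "metric": col,
                         "mean": float(vals.mean()) if len(vals) else np.nan,
                         "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                         "n": int(len(vals))})
    return pd.DataFrame(rows)
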