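"""Noise power spectrum (NPS) estimation on uniform volumes.

The estimator follows the standard ensemble-DFT recipe for single-scan
phantom data: overlapping ROIs are tiled over a uniform region, each ROI is
detrended by subtracting a least-squares 2nd-order polynomial surface, and

    NPS(f) = (prod_i dx_i / prod_i N_i) * <|DFT(patch)|^2>_ensemble.

The Cartesian spectrum is radially averaged (bin width = grid frequency
step, empty bins dropped) into a 1D curve summarized by its peak (noise
magnitude, HU^2.mm^2) and its NPS-weighted average spatial frequency
(noise texture, mm^-1).  The DC bin and the zero-frequency axis lines are
excluded from the radial summaries because detrending suppresses them
unreliably; the 1D curve is restricted to f <= Nyquist.

3D mode transforms (z, y, x) blocks and additionally collapses the native
HU^2.mm^3 spectrum over f_z (integration, x df_z) into an in-plane
HU^2.mm^2 curve comparable with the 2D convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ImageVolume


# ---------------------------------------------------------------------------
# patch extraction and detrending


def _poly2d_design(ny: int, nx: int, order: int) -> np.ndarray:
    y = np.linspace(-1.0, 1.0, ny)
    x = np.linspace(-1.0, 1.0, nx)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [np.ones_like(yy)]
    for total in range(1, order + 1):
        for py in range(total + 1):
            cols.append(yy**py * xx ** (total - py))
    return np.stack([c.ravel() for c in cols], axis=1)


def detrend_patch(patch: np.ndarray, order: int = 2) -> np.ndarray:
    """Subtract the least-squares 2D polynomial surface of given order."""
    ny, nx = patch.shape
    a = _poly2d_design(ny, nx, order)
    coef, *_ = np.linalg.lstsq(a, patch.ravel(), rcond=None)
    return patch - (a @ coef).reshape(ny, nx)


def extract_noise_rois(volume: ImageVolume, roi_size: int = 64,
                       overlap_fraction: float = 0.5,
                       uniform_region: tuple[int, int, int, int] | None = None,
                       mode: str = "2d",
                       detrend_order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Tile detrended noise patches over a uniform region.

    ``uniform_region`` is ``(y0, y1, x0, x1)`` (half-open, in voxels;
    default = the full in-plane extent).  Patches of ``roi_size``^2 are
    placed with stride ``roi_size*(1-overlap_fraction)``.  In 2d mode every
    slice contributes independent 2D patches; in 3d mode patches are
    (n_slices, roi, roi) blocks, detrended slice-by-slice in-plane.

    Returns ``(patches, residual_variances)`` where variances are the
    per-patch mean squared residuals.
    """
    nz, ny, nx = volume.shape
    y0, y1, x0, x1 = uniform_region if uniform_region is not None else (0, ny, 0, nx)
    h, w = y1 - y0, x1 - x0
    if h < roi_size or w < roi_size:
        raise ValueError(
            f"uniform region {h}x{w} too small for {roi_size}x{roi_size} ROIs; "
            f"minimum region size is {roi_size}x{roi_size}"
        )
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    stride = max(1, int(round(roi_size * (1.0 - overlap_fraction))))
    ys = range(y0, y1 - roi_size + 1, stride)
    xs = range(x0, x1 - roi_size + 1, stride)

    a = _poly2d_design(roi_size, roi_size, detrend_order)
    proj = a @ np.linalg.pinv(a)  # fitted-surface projector, shared by all patches

    def _detrend2d(p: np.ndarray) -> np.ndarray:
        return p - (proj @ p.ravel()).reshape(roi_size, roi_size)

    patches = []
    if mode == "2d":
        for z in range(nz):
            sl = volume.voxels[z]
            for yy in ys:
                for xx in xs:
                    patches.append(_detrend2d(sl[yy:yy + roi_size, xx:xx + roi_size]))
    elif mode == "3d":
        for yy in ys:
            for xx in xs:
                block = volume.voxels[:, yy:yy + roi_size, xx:xx + roi_size]
                patches.append(np.stack([_detrend2d(b) for b in block]))
    else:
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    patches = np.stack(patches)
    variances = (patches**2).mean(axis=tuple(range(1, patches.ndim)))
    return patches, variances


# ---------------------------------------------------------------------------
# the estimator


@dataclass
class NPSEstimate:
    """Radially binned 1D NPS plus the full Cartesian grid.

    ``nps_1d`` is in HU^2.mm^2 (2D mode and the collapsed in-plane 3D
    curve); ``nps_grid`` keeps the native units (HU^2.mm^3 in 3D).
    """

    freq: np.ndarray                  # radial bin centers, mm^-1
    nps_1d: np.ndarray                # HU^2.mm^2
    nps_grid: np.ndarray              # native Cartesian spectrum
    freq_axes: tuple[np.ndarray, ...]  # fftfreq per grid axis
    spacing: tuple[float, ...]        # per-axis sample spacing, mm
    mode: str
    n_rois: int
    mean_residual_variance: float
    peak: float = field(init=False)
    f_avg: float = field(init=False)
    f_avg_defined: bool = field(init=False)
    low_ensemble: bool = False        # single-patch estimates are high-variance

    def __post_init__(self) -> None:
        if (self.nps_1d < -1e-12).any():
            raise ValueError("NPS values must be non-negative")
        self.peak, self.f_avg = nps_summary((self.freq, self.nps_1d))
        self.f_avg_defined = np.isfinite(self.f_avg)

    def grid_integral(self) -> float:
        """Integral of the Cartesian NPS over frequency — the noise variance (Parseval)."""
        dfs = [abs(ax[1] - ax[0]) for ax in self.freq_axes]
        return float(self.nps_grid.sum() * np.prod(dfs))

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.spacing[-1])


def _radial_curve(grid2d: np.ndarray, fy: np.ndarray, fx: np.ndarray,
                  df: float, nyquist: float) -> tuple[np.ndarray, np.ndarray]:
    r = np.hypot(fy[:, None], fx[None, :])
    keep = (fy[:, None] != 0) & (fx[None, :] != 0) & (r <= nyquist + df / 2)
    k = np.rint(r[keep] / df).astype(int)
    vals = grid2d[keep]
    sums = np.bincount(k, weights=vals)
    counts = np.bincount(k)
    nonempty = counts > 0
    freq = df * np.nonzero(nonempty)[0].astype(float)
    curve = sums[nonempty] / counts[nonempty]
    return freq, curve


def estimate_nps(patches: np.ndarray | Sequence[np.ndarray],
                 spacing: Sequence[float], mode: str = "2d") -> NPSEstimate:
    """Ensemble NPS of detrended patches.

    ``patches`` is (n, ny, nx) for 2d or (n, nz, ny, nx) for 3d; ``spacing``
    gives the per-axis sample spacing in mm matching the trailing patch axes
    (a full (dz, dy, dx) tuple is accepted in 2d mode, the in-plane pair is
    used).  Radial binning requires isotropic in-plane spacing.
    """
    if not isinstance(patches, np.ndarray):
        shapes = {p.shape for p in patches}
        if len(shapes) != 1:
            raise ValueError(f"patches of unequal size: {sorted(shapes)}")
        patches = np.stack(list(patches))
    want = 3 if mode == "2d" else 4
    if mode not in ("2d", "3d"):
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    if patches.ndim != want:
        raise ValueError(f"{mode} mode expects {want}D patch array, got ndim={patches.ndim}")
    n = patches.shape[0]
    if n < 1:
        raise ValueError("need at least one patch")
    low_ensemble = n == 1
    if low_ensemble:
        warnings.warn("single-patch NPS estimate: expect high variance", stacklevel=2)

    spacing = tuple(float(s) for s in spacing)
    if mode == "2d" and len(spacing) == 3:
        spacing = spacing[1:]
    if len(spacing) != patches.ndim - 1:
        raise ValueError(f"spacing {spacing} does not match patch dimensionality")
    dy, dx = spacing[-2], spacing[-1]
    if abs(dy - dx) > 1e-9:
        raise ValueError("radial binning requires isotropic in-plane spacing")

    axes = tuple(range(1, patches.ndim))
    sizes = patches.shape[1:]
    spec = np.abs(np.fft.fftn(patches, axes=axes)) ** 2
    grid = spec.mean(axis=0) * np.prod(spacing) / np.prod(sizes)
    freq_axes = tuple(np.fft.fftfreq(nn, d=ss) for nn, ss in zip(sizes, spacing))
    mean_resid_var = float((patches**2).mean())

    nx = sizes[-1]
    df = 1.0 / (nx * dx)
    nyq = 1.0 / (2.0 * dx)
    if mode == "2d":
        freq, curve = _radial_curve(grid, freq_axes[0], freq_axes[1], df, nyq)
    else:
        dfz = abs(freq_axes[0][1] - freq_axes[0][0]) if sizes[0] > 1 else 1.0 / spacing[0]
        inplane = grid.sum(axis=0) * dfz  # integrate over f_z -> HU^2.mm^2
        freq, curve = _radial_curve(inplane, freq_axes[1], freq_axes[2], df, nyq)

    return NPSEstimate(freq=freq, nps_1d=np.maximum(curve, 0.0), nps_grid=grid,
                       freq_axes=freq_axes, spacing=spacing, mode=mode, n_rois=n,
                       mean_residual_variance=mean_resid_var, low_ensemble=low_ensemble)


def estimate_volume_nps(volume: ImageVolume, roi_size: int = 64,
                        overlap_fraction: float = 0.5,
                        uniform_region: tuple[int, int, int, int] | None = None,
                        mode: str = "2d") -> NPSEstimate:
    """Convenience wrapper: extract detrended ROIs from a volume and estimate."""
    patches, _ = extract_noise_rois(volume, roi_size, overlap_fraction, uniform_region, mode)
    spacing = volume.spacing if mode == "3d" else volume.spacing[1:]
    return estimate_nps(patches, spacing, mode)


def nps_summary(estimate) -> tuple[float, float]:
    """(peak, f_avg) of a radial NPS curve.

    peak = max bin value; f_avg = sum(f*NPS)/sum(NPS) over f > 0.  An
    all-zero spectrum has no defined texture: f_avg is NaN.
    Accepts an :class:`NPSEstimate` or a ``(freq, values)`` pair.
    """
    if isinstance(estimate, NPSEstimate):
        freq, vals = estimate.freq, estimate.nps_1d
    else:
        freq, vals = (np.asarray(a, dtype=float) for a in estimate)
    pos = freq > 0
    vals_pos = vals[pos]
    peak = float(vals_pos.max()) if vals_pos.size else 0.0
    total = vals_pos.sum()
    f_avg = float((freq[pos] * vals_pos).sum() / total) if total > 0 else float("nan")
    return peak, f_avg


# ---------------------------------------------------------------------------
# dose comparison


@dataclass
class DoseComparison:
    """Pairwise NPS-summary comparison across dose levels."""

    pairs: pd.DataFrame            # dose_a, dose_b, peak_ratio, f_avg_delta
    f_avg_invariant: bool          # texture unchanged across dose within tolerance
    f_avg_max_rel_spread: float


def _peak_favg(value) -> tuple[float, float]:
    if isinstance(value, NPSEstimate):
        return value.peak, value.f_avg
    if np.isscalar(value):
        return float(value), float("nan")
    peak, favg = value
    return float(peak), float(favg)


def compare_nps_by_dose(series, f_avg_tolerance: float = 0.05) -> DoseComparison:
    """Peak ratios and f_avg deltas across a dose series.

    ``series`` maps dose (mGy) to an :class:`NPSEstimate`, a ``(peak,
    f_avg)`` pair, or a bare peak value; a sequence of ``(dose, value)``
    pairs is also accepted.  Duplicate dose keys are an error.  The
    ``f_avg_invariant`` flag reports whether the noise texture is
    dose-invariant within ``f_avg_tolerance`` (relative spread of f_avg).
    """
    if isinstance(series, dict):
        items = list(series.items())
    else:
        items = [(float(d), v) for d, v in series]
        doses = [d for d, _ in items]
        if len(set(doses)) != len(doses):
            raise ValueError(f"duplicate dose keys: {doses}")
    if len(items) < 2:
        raise ValueError("need >= 2 dose levels to compare")
    items.sort(key=lambda kv: kv[0])
    summ = {d: _peak_favg(v) for d, v in items}

    rows = []
    doses = [d for d, _ in items]
    for i, da in enumerate(doses):
        for db in doses[i + 1:]:
            pa, fa = summ[da]
            pb, fb = summ[db]
            rows.append({"dose_a_mgy": da, "dose_b_mgy": db,
                         "peak_ratio": pb / pa if pa else float("nan"),
                         "f_avg_delta": fb - fa})
    favgs = np.array([f for _, f in summ.values()])
    if np.isfinite(favgs).all() and favgs.mean() != 0:
        spread = float((favgs.max() - favgs.min()) / abs(favgs.mean()))
    else:
        spread = float("nan")
    invariant = bool(np.isfinite(spread) and spread <= f_avg_tolerance)
    return DoseComparison(pd.DataFrame(rows), invariant, spread)
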