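"""Readers and writers for every external artifact the pipeline touches.

Conventions used package-wide (stated once, here):

* Voxel indexing is 0-based with dimension order ``(slice, row, column)``,
  i.e. ``(z, y, x)``.
* Spacing is ``(dz, dy, dx)`` in millimetres; all public distances and
  spatial frequencies are in mm / mm^-1, never in voxel units.
* Image values are Hounsfield units (HU).  DICOM rescale slope/intercept
  are applied on read; window/level display metadata are ignored.

Supported volume formats: a DICOM series directory, NIfTI (``.nii`` /
``.nii.gz``), and a plain array container (a ``.npy`` file next to a JSON
sidecar carrying spacing) used by the test-suite so the core never depends
on DICOM fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ALLOWED_ROI_LABELS = ("lung", "liver", "aorta", "muscle", "phantom_uniform", "custom")


@dataclass
class ImageVolume:
    """A 3D voxel grid in HU with per-axis spacing in mm."""

    voxels: np.ndarray           # (slice, row, column)
    spacing: tuple[float, float, float]  # (dz, dy, dx) in mm
    origin_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (slice, row, column), got ndim={self.voxels.ndim}")
        nz, ny, nx = self.voxels.shape
        if nz < 1 or ny < 8 or nx < 8:
            raise ValueError(f"volume must have >=1 slice and >=8x8 in-plane size, got {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three strictly positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROISpec:
    """A circular ROI in the axial plane.

    ``center`` is ``(z, y, x)`` in 0-based voxel indices; ``diameter_mm`` is
    the disc diameter in the axial plane (typical clinical placement uses
    8-10 mm discs).
    """

    label: str
    center: tuple[int, int, int]
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.label not in ALLOWED_ROI_LABELS:
            raise ValueError(
                f"unknown tissue label {self.label!r}; allowed labels: {', '.join(ALLOWED_ROI_LABELS)}"
            )
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be > 0, got {self.diameter_mm}")
        self.center = tuple(int(c) for c in self.center)

    def check_bounds(self, volume: ImageVolume) -> None:
        """Raise if the disc does not lie fully inside its slice."""
        nz, ny, nx = volume.shape
        dz, dy, dx = volume.spacing
        z, y, x = self.center
        if not (0 <= z < nz):
            raise ValueError(f"ROI {self.label!r}: slice index {z} outside [0, {nz})")
        ry = self.diameter_mm / 2.0 / dy
        rx = self.diameter_mm / 2.0 / dx
        if y - ry < -0.5 or y + ry > ny - 0.5 or x - rx < -0.5 or x + rx > nx - 0.5:
            raise ValueError(
                f"ROI {self.label!r} (center=({z},{y},{x}), diameter={self.diameter_mm} mm) "
                f"does not lie fully inside the {ny}x{nx} slice"
            )


# ---------------------------------------------------------------------------
# volumes


def _read_plain(path: Path) -> ImageVolume:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"plain array container {path} has no JSON sidecar {sidecar.name} with spacing")
    meta = json.loads(sidecar.read_text())
    if "spacing" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required 'spacing' (never assumed to be 1 mm)")
    return ImageVolume(np.load(path), tuple(meta["spacing"]), meta.get("origin_label", str(path)))


def _read_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    if any(z <= 0 for z in zooms):
        raise ValueError(f"NIfTI {path} has non-positive voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj)  # (x, y, z)
    voxels = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return ImageVolume(voxels, spacing, str(path))


def _read_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    datasets = [pydicom.dcmread(str(p)) for p in files]
    datasets = [ds for ds in datasets if hasattr(ds, "PixelData")]
    if not datasets:
        raise ValueError(f"no DICOM images found in {path}")

    orientations = {tuple(round(float(v), 5) for v in getattr(ds, "ImageOrientationPatient", ()))
                    for ds in datasets}
    if len(orientations) > 1:
        raise ValueError(f"mixed-orientation DICOM series in {path}: {sorted(orientations)}")

    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError(f"DICOM series {path} lacks PixelSpacing; spacing is never assumed")
    dy, dx = (float(v) for v in first.PixelSpacing)

    # sort along the scan axis: project position onto the slice normal
    if all(hasattr(ds, "ImagePositionPatient") for ds in datasets) and orientations and len(next(iter(orientations))) == 6:
        iop = np.array(next(iter(orientations)), dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        keyed = sorted(datasets, key=lambda ds: float(np.dot(normal, np.array(ds.ImagePositionPatient, float))))
        positions = [float(np.dot(normal, np.array(ds.ImagePositionPatient, float))) for ds in keyed]
    elif all(hasattr(ds, "InstanceNumber") for ds in datasets):
        keyed = sorted(datasets, key=lambda ds: int(ds.InstanceNumber))
        positions = None
    else:
        raise ValueError(f"DICOM series {path}: cannot order slices (no positions or instance numbers)")

    if positions is not None and len(positions) > 1:
        dz = float(np.median(np.diff(positions)))
        if dz <= 0:
            raise ValueError(f"DICOM series {path}: non-increasing slice positions")
    else:
        if not hasattr(first, "SliceThickness"):
            raise ValueError(f"DICOM series {path}: single slice without SliceThickness; spacing unknown")
        dz = float(first.SliceThickness)

    slices = []
    for ds in keyed:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(float) * slope + intercept)
    return ImageVolume(np.stack(slices), (dz, dy, dx), str(path))


def read_volume(path: str | Path, format_hint: str | None = None) -> ImageVolume:
    """Read an :class:`ImageVolume` from DICOM, NIfTI or the plain container.

    The format is inferred from the path unless ``format_hint`` is one of
    ``{"dicom", "nifti", "plain"}``.  Missing spacing metadata is a hard
    error — 1 mm is never silently assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif path.suffix == ".npy":
            fmt = "plain"
        else:
            raise ValueError(f"cannot infer volume format of {path}; pass format_hint")
    if fmt == "dicom":
        return _read_dicom_series(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "plain":
        return _read_plain(path)
    raise ValueError(f"unknown format_hint {fmt!r}")


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (``.nii``/``.nii.gz``) or plain container (``.npy`` + JSON)."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        dz, dy, dx = volume.spacing
        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(np.transpose(volume.voxels, (2, 1, 0)), affine)
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, str(path))
    elif path.suffix == ".npy":
        np.save(path, volume.voxels)
        path.with_suffix(".json").write_text(
            json.dumps({"spacing": list(volume.spacing), "origin_label": volume.origin_label})
        )
    else:
        raise ValueError(f"unsupported volume output format: {path.name}")
    return path


# ---------------------------------------------------------------------------
# ROI files


def read_rois(path: str | Path, volume: ImageVolume | None = None) -> list[ROISpec]:
    """Read ROI definitions from JSON (list of objects) or CSV.

    Required fields: ``label``, center (``center: [z, y, x]`` in JSON, columns
    ``z, y, x`` in CSV) and ``diameter_mm``.  If ``volume`` is given, every
    disc is bounds-checked against it and offenders are rejected by label.
    Duplicate labels are accepted (disambiguate by list index downstream).
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
        rois = [ROISpec(r["label"], tuple(r["center"]), float(r["diameter_mm"])) for r in raw]
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
        missing = {"label", "z", "y", "x", "diameter_mm"} - set(df.columns)
        if missing:
            raise ValueError(f"ROI CSV {path} lacks columns: {sorted(missing)}")
        rois = [ROISpec(r.label, (r.z, r.y, r.x), float(r.diameter_mm)) for r in df.itertuples()]
    else:
        raise ValueError(f"ROI file must be .json or .csv, got {path.name}")
    if volume is not None:
        for roi in rois:
            roi.check_bounds(volume)
    return rois


def write_rois(rois: Sequence[ROISpec], path: str | Path) -> Path:
    path = Path(path)
    payload = [{"label": r.label, "center": list(r.center), "diameter_mm": r.diameter_mm} for r in rois]
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# tabular reports


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    results = list(results)
    if results and hasattr(results[0], "__dataclass_fields__"):
        from dataclasses import asdict

        return pd.DataFrame([asdict(r) for r in results])
    return pd.DataFrame(results)


def write_report(results, path: str | Path, kind: str = "csv") -> Path:
    """Write a tabular result (DataFrame / list of dicts or dataclasses).

    Column order is the input order (deterministic); floats keep full
    precision so the file re-reads into an equal table.
    """
    path = Path(path)
    df = _as_frame(results)
    if kind == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif kind == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1, default=float))
    else:
        raise ValueError(f"kind must be 'csv' or 'json', got {kind!r}")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"report must be .csv or .json, got {path.name}")
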