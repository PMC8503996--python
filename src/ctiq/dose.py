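"""Dose descriptors: size-specific dose estimate (SSDE) and effective dose (ED).

    SSDE = CTDIvol x f(size)       f from a size-conversion table for the
                                   32-cm body phantom, keyed by the sum of
                                   the AP and lateral patient dimensions
    ED   = DLP x W_T               W_T in mSv/(mGy.cm), keyed by body
                                   region, kVp band and age band

Both lookup tables ship as editable CSV configuration (``ctiq/data``); the
shipped numbers are representative, not measured truth.  W_T coefficients
below 80 kVp are not tabulated, so 70 kVp studies adopt the 80 kVp
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


@dataclass
class DoseRecord:
    subject_id: str
    region: str              # chest | abdomen
    kvp: int
    ctdivol_mgy: float
    dlp_mgycm: float
    ap_dim_cm: float
    lat_dim_cm: float
    conversion_factor: float
    ssde_mgy: float
    w_t: float               # mSv per mGy.cm
    ed_msv: float


def _load_data_csv(name: str) -> pd.DataFrame:
    with resources.files("ctiq.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


_SIZE_TABLE: pd.DataFrame | None = None
_WT_TABLE: pd.DataFrame | None = None


def load_size_conversion_table() -> pd.DataFrame:
    """Size-conversion factors vs AP+LAT sum (cm), 32-cm body phantom."""
    global _SIZE_TABLE
    if _SIZE_TABLE is None:
        _SIZE_TABLE = _load_data_csv("aapm204_body32.csv")
    return _SIZE_TABLE


def load_wt_table() -> pd.DataFrame:
    global _WT_TABLE
    if _WT_TABLE is None:
        _WT_TABLE = _load_data_csv("effective_dose_coefficients.csv")
    return _WT_TABLE


def conversion_factor_from_dims(ap_dim_cm: float, lat_dim_cm: float,
                                table: pd.DataFrame | None = None,
                                out_of_range: str = "clamp") -> float:
    """Size-conversion factor from patient AP and lateral dimensions.

    Linear interpolation between tabulated AP+LAT sums; sums outside the
    table range are clamped to the end values with a warning
    (``out_of_range="error"`` raises instead).  The factor is monotone
    non-increasing in patient size.
    """
    if ap_dim_cm <= 0 or lat_dim_cm <= 0:
        raise ValueError("patient dimensions must be > 0 cm")
    table = table if table is not None else load_size_conversion_table()
    sums = table["sum_ap_lat_cm"].to_numpy(dtype=float)
    factors = table["conversion_factor"].to_numpy(dtype=float)
    s = ap_dim_cm + lat_dim_cm
    if s < sums[0] or s > sums[-1]:
        if out_of_range == "error":
            raise ValueError(f"AP+LAT sum {s:.1f} cm outside table range [{sums[0]}, {sums[-1]}]")
        warnings.warn(f"AP+LAT sum {s:.1f} cm outside table range; clamping", stacklevel=2)
        s = min(max(s, sums[0]), sums[-1])
    return float(np.interp(s, sums, factors))


def compute_ssde(ctdivol_mgy: float, factor: float) -> float:
    """SSDE = CTDIvol x conversion factor (mGy)."""
    if ctdivol_mgy < 0 or factor < 0:
        raise ValueError("CTDIvol and conversion factor must be >= 0")
    return ctdivol_mgy * factor


def resolve_w_t(region: str, kvp: int, age_band: str = "pediatric",
                table: pd.DataFrame | None = None) -> float:
    """Look up the DLP->ED coefficient for (region, kVp band, age band).

    70 kVp maps to the 80 kVp coefficient (no tabulated values below 80).
    """
    table = table if table is not None else load_wt_table()
    kvp_eff = 80 if kvp < 80 else int(kvp)
    hit = table[(table.region == region) & (table.kvp == kvp_eff) & (table.age_band == age_band)]
    if hit.empty:
        raise KeyError(
            f"no W_T coefficient for (region={region!r}, kvp={kvp_eff}, age_band={age_band!r})"
        )
    return float(hit["w_t_msv_per_mgycm"].iloc[0])


def compute_ed(dlp_mgycm: float, w_t: float) -> float:
    """ED = DLP x W_T (mSv)."""
    if dlp_mgycm < 0 or w_t < 0:
        raise ValueError("DLP and W_T must be >= 0")
    return dlp_mgycm * w_t


def build_dose_records(dose_table: pd.DataFrame, age_band: str = "pediatric") -> pd.DataFrame:
    """SSDE and ED for every row of a dose-descriptor table.

    Expects columns subject_id, region, kvp, ctdivol_mgy, dlp_mgycm,
    ap_dim_cm, lat_dim_cm (as produced by
    :func:`ctiq.synthetic.make_dose_table` or read from CSV).
    """
    rows = []
    for r in dose_table.itertuples():
        factor = conversion_factor_from_dims(r.ap_dim_cm, r.lat_dim_cm)
        w_t = resolve_w_t(r.region, int(r.kvp), age_band)
        rows.append(DoseRecord(
            subject_id=str(r.subject_id), region=r.region, kvp=int(r.kvp),
            ctdivol_mgy=float(r.ctdivol_mgy), dlp_mgycm=float(r.dlp_mgycm),
            ap_dim_cm=float(r.ap_dim_cm), lat_dim_cm=float(r.lat_dim_cm),
            conversion_factor=factor,
            ssde_mgy=compute_ssde(float(r.ctdivol_mgy), factor),
            w_t=w_t, ed_msv=compute_ed(float(r.dlp_mgycm), w_t)))
    from dataclasses import asdict
    return pd.DataFrame([asdict(r) for r in rows])
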