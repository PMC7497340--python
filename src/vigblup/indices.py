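"""Vegetation indices from plot-level mean band reflectances.

Six indices are supported, all computed from reflectance *fractions* (0–1):

====== =====================================================================
NDVI   (NIR − R) / (NIR + R)
GNDVI  NDVI with the green band substituted for red
NDRE   NDVI with the red-edge band substituted for red
SAVI   (NIR − R)(1 + L) / (NIR + R + L), soil-adjustment factor L (0.5)
EVI    2.5 (NIR − R) / (NIR + 6R − 7.5B + 1)
Ratio  NIR / R
====== =====================================================================

Batch computation flags undefined rows (zero denominators) instead of
raising; the single-record path raises so interactive misuse fails loudly.
An optional log10 transform is provided; downstream models default to the
untransformed values.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError, UndefinedValueError

INDEX_NAMES = ("NDVI", "GNDVI", "NDRE", "SAVI", "EVI", "Ratio")

#: bands each index reads, keyed by the column names of the band table
_REQUIRED_BANDS: Mapping[str, tuple[str, ...]] = {
    "NDVI": ("r_nir", "r_red"),
    "GNDVI": ("r_nir", "r_green"),
    "NDRE": ("r_nir", "r_rededge"),
    "SAVI": ("r_nir", "r_red"),
    "EVI": ("r_nir", "r_red", "r_blue"),
    "Ratio": ("r_nir", "r_red"),
}

BAND_COLUMNS = ("r_blue", "r_green", "r_red", "r_rededge", "r_nir")
KEY_COLUMNS = ("plot_id", "time_label")


def _normalized_difference(nir: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    denom = nir + other
    ok = denom != 0
    out = np.full_like(denom, np.nan, dtype=float)
    np.divide(nir - other, denom, out=out, where=ok)
    return out, ok


def _vi_arrays(bands: pd.DataFrame, index_name: str, soil_l: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized index values plus a validity mask (False = zero denominator)."""
    nir = bands["r_nir"].to_numpy(float)
    if index_name == "NDVI":
        return _normalized_difference(nir, bands["r_red"].to_numpy(float))
    if index_name == "GNDVI":
        return _normalized_difference(nir, bands["r_green"].to_numpy(float))
    if index_name == "NDRE":
        return _normalized_difference(nir, bands["r_rededge"].to_numpy(float))
    if index_name == "SAVI":
        red = bands["r_red"].to_numpy(float)
        denom = nir + red + soil_l
        ok = denom != 0
        out = np.full_like(denom, np.nan)
        np.divide((nir - red) * (1.0 + soil_l), denom, out=out, where=ok)
        return out, ok
    if index_name == "EVI":
        red = bands["r_red"].to_numpy(float)
        blue = bands["r_blue"].to_numpy(float)
        denom = nir + 6.0 * red - 7.5 * blue + 1.0
        ok = denom != 0
        out = np.full_like(denom, np.nan)
        np.divide(2.5 * (nir - red), denom, out=out, where=ok)
        return out, ok
    if index_name == "Ratio":
        red = bands["r_red"].to_numpy(float)
        ok = red != 0
        out = np.full_like(red, np.nan)
        np.divide(nir, red, out=out, where=ok)
        return out, ok
    raise ParameterError(f"unknown vegetation index {index_name!r}")


def compute_vi(bands: Mapping[str, float], index_name: str, soil_l: float = 0.5) -> float:
    """Compute one vegetation index for a single plot record.

    Parameters
    ----------
    bands
        Mapping with the reflectance fractions the index needs
        (``r_nir``, ``r_red``, ``r_green``, ``r_rededge``, ``r_blue``).
    index_name
        One of :data:`INDEX_NAMES`.
    soil_l
        Soil-background correction factor for SAVI (default 0.5).

    Raises
    ------
    SchemaError
        If a required band is missing.
    UndefinedValueError
        If the index denominator is zero.
    """
    if index_name not in INDEX_NAMES:
        raise ParameterError(f"unknown vegetation index {index_name!r}")
    missing = [b for b in _REQUIRED_BANDS[index_name] if b not in bands]
    if missing:
        raise SchemaError(f"{index_name} requires band(s) {missing}")
    row = pd.DataFrame({c: [float(bands.get(c, np.nan))] for c in BAND_COLUMNS})
    values, ok = _vi_arrays(row, index_name, soil_l)
    if not ok[0]:
        plot = bands.get("plot_id", "<unknown plot>")
        raise UndefinedValueError(f"{index_name} undefined for plot {plot}: zero denominator")
    return float(values[0])


def compute_all_indices(
    bands: pd.DataFrame,
    indices: Iterable[str] = INDEX_NAMES,
    soil_l: float = 0.5,
) -> pd.DataFrame:
    """Compute every requested index for every plot × time row.

    Input must be tidy with columns ``plot_id, time_label, gdd`` plus the five
    band columns; one row per plot × flight. Output is long with one row per
    plot × time × index. Rows whose denominator is zero are kept with value
    NaN and ``flag='undefined_denominator'`` rather than dropped.

    Raises
    ------
    SchemaError
        On missing columns or duplicated ``(plot_id, time_label)`` rows.
    """
    required = list(KEY_COLUMNS) + ["gdd"]
    missing = [c for c in required if c not in bands.columns]
    if missing:
        raise SchemaError(f"band table missing column(s) {missing}")
    if bands.duplicated(subset=list(KEY_COLUMNS)).any():
        dupes = bands.loc[bands.duplicated(subset=list(KEY_COLUMNS)), list(KEY_COLUMNS)]
        raise SchemaError(f"duplicate (plot_id, time_label) rows: {dupes.values.tolist()[:5]}")
    out_frames = []
    for name in indices:
        needed = [c for c in _REQUIRED_BANDS[name] if c not in bands.columns]
        if needed:
            raise SchemaError(f"{name} requires band column(s) {needed}")
        values, ok = _vi_arrays(bands, name, soil_l)
        frame = bands.loc[:, required].copy()
        frame["index"] = name
        frame["value"] = values
        frame["flag"] = np.where(ok, "ok", "undefined_denominator")
        out_frames.append(frame)
    if not out_frames or not len(bands):
        return pd.DataFrame(columns=required + ["index", "value", "flag"])
    out = pd.concat(out_frames, ignore_index=True)
    return out


def log10_transform(vi: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with index values replaced by log10(value).

    The transform is recorded in ``result.attrs['transform']``. Skew-reducing
    transforms made no difference to the mixed-model results on these
    bounded, saturating indices, so the pipeline default is untransformed;
    this is provided for parity checks.

    Raises
    ------
    UndefinedValueError
        If any value is ≤ 0 (log10 undefined).
    """
    if "value" not in vi.columns:
        raise SchemaError("expected a 'value' column")
    values = vi["value"].to_numpy(float)
    bad = np.isfinite(values) & (values <= 0)
    if bad.any():
        i = int(np.argmax(bad))
        raise UndefinedValueError(f"log10 undefined for nonpositive value {values[i]} at row {i}")
    out = vi.copy()
    out["value"] = np.log10(values)
    out.attrs["transform"] = "log10"
    return out
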