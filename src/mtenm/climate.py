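"""Analysis-ready climate grids: averaging, regridding, bias correction.

Gridded environmental inputs (sea ice concentration, sea surface
temperature and salinity, bathymetry) come from different sources at
different resolutions and with systematic model biases.  This module
turns them into aligned per-bin grids:

* :func:`timebin_average` — summer (June-October) means over 35-year bins;
* :func:`regrid_distance_weighted` — inverse-distance interpolation of a
  scattered/native grid onto the analysis grid;
* :func:`interp_bathymetry_time` — linear time interpolation of
  bathymetry snapshots to bin midpoints (future bins reuse the
  contemporary snapshot);
* :func:`delta_correct` — additive (SST) and multiplicative (SSS) delta
  corrections that match a model's per-cell overlap climatology to the
  reference;
* :func:`distance_to_coast` — exact Euclidean distance to the nearest
  land cell, a covariate of the SIC bias model;
* :class:`BetaGAMCorrector` (re-exported from :mod:`mtenm.bias_gam`) —
  the beta-regression GAM used for bounded SIC correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import xarray as xr
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .binning import TimeBinning
from .bias_gam import BetaGAMCorrector, fit_sic_bias_gam, predict_sic

__all__ = [
    "timebin_average",
    "regrid_distance_weighted",
    "interp_bathymetry_time",
    "delta_correct",
    "distance_to_coast",
    "BetaGAMCorrector",
    "fit_sic_bias_gam",
    "predict_sic",
]

SUMMER_MONTHS = (6, 7, 8, 9, 10)


def timebin_average(
    monthly: xr.DataArray,
    binning: TimeBinning,
    months: tuple = SUMMER_MONTHS,
) -> xr.DataArray:
    """Summer mean per time bin.

    ``monthly`` must have ``year`` and ``month`` dimensions (plus any
    spatial dims).  For each bin the mean is taken over the requested
    months of all years inside the bin, ignoring missing values; a cell is
    missing in the output only if it has no valid month at all.  A bin
    containing no year of data raises ``ValueError``.
    """
    monthly = monthly.sel(month=list(months))
    years = monthly["year"].values
    bins = binning.year_to_bin(years)
    out = []
    for b in range(binning.n_bins):
        sel = bins == b
        if not sel.any():
            raise ValueError(f"bin {b} contains no years of monthly data")
        chunk = monthly.isel(year=np.nonzero(sel)[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            out.append(chunk.mean(dim=("year", "month"), skipna=True))
    res = xr.concat(out, dim="bin")
    res = res.assign_coords(bin=np.arange(binning.n_bins))
    return res


def regrid_distance_weighted(
    values: np.ndarray,
    src_xy: np.ndarray,
    tgt_xy: np.ndarray,
    k: int = 4,
    power: float = 1.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of scattered values.

    ``values`` are source values at ``src_xy`` (n, 2) coordinates (km);
    non-finite source values are ignored.  Each target point gets
    ``sum(w_i v_i) / sum(w_i)`` over its ``k`` nearest valid sources with
    ``w_i = d_i ** -power``; a target coincident with a source (d = 0)
    returns that source's value exactly.
    """
    values = np.asarray(values, dtype=float).ravel()
    src_xy = np.asarray(src_xy, dtype=float)
    tgt_xy = np.asarray(tgt_xy, dtype=float)
    valid = np.isfinite(values)
    if not valid.any():
        raise ValueError("no valid source cells")
    vv = values[valid]
    tree = cKDTree(src_xy[valid])
    kk = min(k, vv.size)
    dist, idx = tree.query(tgt_xy, k=kk)
    dist = np.atleast_2d(dist.reshape(len(tgt_xy), kk))
    idx = np.atleast_2d(idx.reshape(len(tgt_xy), kk))
    out = np.empty(len(tgt_xy))
    exact = dist[:, 0] == 0.0
    out[exact] = vv[idx[exact, 0]]
    rest = ~exact
    if rest.any():
        w = dist[rest] ** (-power)
        out[rest] = (w * vv[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return out


def interp_bathymetry_time(
    snapshots: xr.DataArray,
    binning: TimeBinning,
) -> xr.DataArray:
    """Per-cell linear interpolation of bathymetry snapshots to bin midpoints.

    ``snapshots`` has a ``year`` dimension at the native node years
    (e.g. 500-year spacing).  Bin midpoints after the last node reuse the
    last (contemporary) snapshot unchanged; a midpoint before the first
    node raises ``ValueError``.
    """
    node_years = snapshots["year"].values.astype(float)
    if node_years.size < 2:
        raise ValueError("need at least two bathymetry snapshots")
    mids = binning.midpoints()
    if (mids < node_years.min()).any():
        raise ValueError("bin midpoint precedes the first bathymetry snapshot")
    clamped = np.minimum(mids, node_years.max())
    interp = snapshots.interp(year=clamped, method="linear")
    interp = interp.rename(year="bin").assign_coords(bin=np.arange(binning.n_bins))
    return interp


def delta_correct(
    model: xr.DataArray,
    reference: xr.DataArray,
    overlap_bins,
    mode: str = "additive",
):
    """Delta-method bias correction against a reference climatology.

    Per cell, with overlap means ``m`` (model) and ``r`` (reference):

    * additive:        ``corrected = model - (m - r)``  (used for SST)
    * multiplicative:  ``corrected = model * (r / m)``  (used for SSS)

    Cells where a multiplicative correction would divide by a zero model
    mean fall back to the additive form and are reported in the
    diagnostics.  Over the overlap window the corrected per-cell mean
    equals the reference per-cell mean by construction.

    Returns ``(corrected, diagnostics)`` where diagnostics holds the
    per-cell deltas and the fallback mask.
    """
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown mode {mode!r}")
    overlap_bins = np.asarray(overlap_bins, dtype=int)
    m = model.isel(bin=overlap_bins).mean(dim="bin")
    r = reference.isel(bin=overlap_bins).mean(dim="bin")
    diagnostics = {"mode": mode}
    if mode == "additive":
        corrected = model - (m - r)
        diagnostics["delta"] = (m - r)
    else:
        zero = (m == 0) & m.notnull()
        ratio = xr.where(zero, 1.0, r / m)
        corrected = model * ratio
        if bool(zero.any()):
            corrected = xr.where(zero, model - (m - r), corrected)
            warnings.warn(
                f"multiplicative delta: {int(zero.sum())} cells with zero "
                "overlap mean fell back to additive correction"
            )
        diagnostics["ratio"] = ratio
        diagnostics["additive_fallback"] = zero
    return corrected, diagnostics


def distance_to_coast(mask: np.ndarray, cell_km: float = 90.0) -> np.ndarray:
    """Exact Euclidean distance (km) from each ocean cell to nearest land.

    ``mask`` is 1/True on ocean.  Land cells are NaN in the output.  An
    all-ocean mask yields +inf everywhere, with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        warnings.warn("mask has no land cells; distance to coast is infinite")
        out = np.full(mask.shape, np.inf)
        return out
    # distance from every cell to the nearest land (zero) cell
    dist = distance_transform_edt(mask) * cell_km
    out = np.where(mask, dist, np.nan)
    return out
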