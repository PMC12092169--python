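"""Habitat-suitability products: thresholding, isobands, stocks, change maps.

Once a tuned niche model has been projected onto every time bin, the
analytic products are:

* an *occupiable* layer per bin — suitability at or above the 10th
  percentile of training-presence suitability;
* sea-ice isoband summaries — cells stratified into SIC classes
  (0-15, 15-30, 30-45, > 45 %) with per-band extent, mean suitability,
  and proportion occupiable;
* stock time series — mean +/- sd suitability over each management
  stock's cells per bin;
* change maps vs a long-term baseline — persistence / contraction /
  expansion / never-suitable, where the baseline is occupiability in at
  least half of the baseline bins;
* percent declines of extent or suitability against the baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "threshold_occupiable",
    "classify_isoband",
    "isoband_summary",
    "stock_series",
    "change_map",
    "percent_change",
    "ISOBANDS",
    "CHANGE_CATEGORIES",
]

#: half-open SIC bands [0,15), [15,30), [30,45); the top band closes at 100
ISOBANDS = ("0-15", "15-30", "30-45", ">45")
_BAND_EDGES = np.array([15.0, 30.0, 45.0])

CHANGE_CATEGORIES = ("never-suitable", "persistence", "contraction", "expansion")


def threshold_occupiable(
    suit: xr.DataArray, training_suitabilities
) -> xr.Dataset:
    """Binary occupiable layer from the 10th-percentile training threshold.

    The threshold is the lower-interpolation 10th percentile of the
    training-presence suitabilities under the selected model; a cell is
    occupiable when its suitability is >= the threshold (cells exactly at
    the threshold count as occupiable).
    """
    ts = np.asarray(training_suitabilities, dtype=float)
    if ts.size < 10:
        raise ValueError("need at least 10 training suitabilities")
    if np.all(ts == 0):
        raise ValueError("training suitabilities are all zero")
    thr = float(np.percentile(ts, 10.0, method="lower"))
    occ = (suit >= thr).where(suit.notnull())
    ds = xr.Dataset({"suitability": suit, "occupiable": occ})
    ds.attrs["threshold"] = thr
    return ds


def classify_isoband(sic):
    """Isoband label(s) for SIC values in [0, 100]."""
    arr = np.asarray(sic, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise ValueError("SIC outside [0, 100]")
    idx = np.digitize(arr, _BAND_EDGES)  # [0,15)->0, [15,30)->1, ...
    labels = np.array(ISOBANDS, dtype=object)[idx]
    labels = np.where(np.isfinite(arr), labels, None)
    if np.isscalar(sic) or np.ndim(sic) == 0:
        return labels.item()
    return labels


def isoband_summary(occ_map: xr.Dataset, sic: xr.DataArray, cell_km: float = 90.0) -> pd.DataFrame:
    """Per-isoband extent, mean suitability, and occupiable proportion.

    Empty bands are absent from the table (missing, not zero).  Extent is
    cell count times cell area, in 1e6 km^2.
    """
    suit = occ_map["suitability"].values
    occ = occ_map["occupiable"].values
    sicv = sic.values
    ocean = np.isfinite(suit) & np.isfinite(sicv)
    bands = classify_isoband(np.where(ocean, sicv, np.nan))
    rows = []
    for band in ISOBANDS:
        sel = ocean & (bands == band)
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append(
            {
                "band": band,
                "n_cells": n,
                "extent_1e6km2": n * cell_km**2 / 1e6,
                "mean_suitability": float(suit[sel].mean()),
                "prop_occupiable": float(np.nanmean(occ[sel].astype(float))),
            }
        )
    return pd.DataFrame(rows, columns=["band", "n_cells", "extent_1e6km2", "mean_suitability", "prop_occupiable"])


def stock_series(maps: list, stock_masks: dict) -> pd.DataFrame:
    """Mean +/- sd suitability per stock per bin.

    ``maps`` is a sequence of per-bin suitability DataArrays (ocean NaN on
    land); ``stock_masks`` maps stock label -> boolean cell mask.  Masks
    should be disjoint; overlaps are flagged with a warning.  The sd is
    the sample standard deviation over the stock's ocean cells (0 for a
    single cell).
    """
    labels = sorted(stock_masks)
    total = np.zeros_like(next(iter(stock_masks.values())), dtype=int)
    for m in stock_masks.values():
        total += np.asarray(m, dtype=bool).astype(int)
    if (total > 1).any():
        warnings.warn("stock masks overlap; overlapping cells counted in each")
    rows = []
    for b, mp in enumerate(maps):
        vals = mp.values if hasattr(mp, "values") else np.asarray(mp)
        for lab in labels:
            sel = np.asarray(stock_masks[lab], dtype=bool) & np.isfinite(vals)
            if not sel.any():
                raise ValueError(f"stock {lab!r} has no ocean cells")
            v = vals[sel]
            sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
            rows.append(
                {"stock": lab, "bin": b, "mean_suitability": float(v.mean()), "sd_suitability": sd}
            )
    return pd.DataFrame(rows)


def change_map(
    holocene_occ: list,
    future_occ: xr.DataArray,
    baseline_frac: float = 0.5,
) -> xr.DataArray:
    """Categorical habitat-change map against a long-term baseline.

    A cell is baseline-occupiable when occupiable in at least
    ``baseline_frac`` of the baseline (Holocene) bins.  Categories:
    persistence (baseline and future), contraction (baseline only),
    expansion (future only), never-suitable (neither).
    """
    if len(holocene_occ) == 0:
        raise ValueError("need at least one baseline map")
    stack = np.stack([np.asarray(m.values if hasattr(m, "values") else m, dtype=float) for m in holocene_occ])
    ocean = np.isfinite(stack).any(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN land cells
        freq = np.nanmean(np.where(np.isfinite(stack), stack, np.nan), axis=0)
    baseline = (freq >= baseline_frac) & ocean
    fut = np.asarray(future_occ.values if hasattr(future_occ, "values") else future_occ, dtype=float)
    future = (fut == 1) & np.isfinite(fut)
    cat = np.zeros(baseline.shape, dtype=float)  # never-suitable
    cat[baseline & future] = 1  # persistence
    cat[baseline & ~future] = 2  # contraction
    cat[~baseline & future] = 3  # expansion
    cat[~ocean & ~np.isfinite(fut)] = np.nan
    dims = future_occ.dims if hasattr(future_occ, "dims") else ("y", "x")
    coords = future_occ.coords if hasattr(future_occ, "coords") else None
    out = xr.DataArray(cat, dims=dims, coords=coords)
    out.attrs["categories"] = {i: c for i, c in enumerate(CHANGE_CATEGORIES)}
    return out


def percent_change(reference: float, target: float) -> float:
    """Percent decline vs a reference: 100 (ref - target) / ref.

    Positive values are declines; requires ``reference > 0``.
    """
    from .exceptions import ZeroReferenceError

    if reference <= 0:
        raise ZeroReferenceError("reference value must be > 0")
    return 100.0 * (reference - target) / reference
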