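"""Occurrence cleaning, thinning, weighting, annotation, and CV folds.

Records live in a pandas DataFrame with columns ``id, x, y, era, stock,
year, month, age_mass, weight`` (see :mod:`mtenm.synthetic` for the CSV
dialect).  The processing order used by the pipeline is:

1. :func:`filter_summer` — keep June-October sightings; fossils are kept
   unconditionally (they are assumed summer sea-ice entrapments).
2. :func:`snap_to_ocean` — move records stranded on land by the coarse
   land-sea mask to the nearest ocean cell if it is < 170 km away.
3. :func:`fossil_pseudo_replicates` — explode each fossil into one record
   per time bin carrying that bin's calibrated-age mass as its weight, so
   each fossil contributes total weight 1.
4. :func:`spatial_thin` — one record per 90 km cell per 35-year bin.
5. :func:`extract_environment` — annotate each record with the mean
   environment of its 3x3 ocean neighbourhood in its bin.
6. :func:`assign_folds` — ten cross-validation folds stratified by
   stock x era.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree

from .binning import TimeBinning
from .exceptions import AllMaskedError, EmptyAgeMassError, MissingMonthError

__all__ = [
    "filter_summer",
    "snap_to_ocean",
    "spatial_thin",
    "fossil_pseudo_replicates",
    "extract_environment",
    "extract_environment_table",
    "assign_folds",
    "assign_bins",
    "cleaning_report",
]

SUMMER_MONTHS = (6, 7, 8, 9, 10)


def filter_summer(records: pd.DataFrame) -> pd.DataFrame:
    """Keep summer (June-October) records; fossils always pass.

    Raises :class:`MissingMonthError` if a non-fossil record has no month.
    """
    fossil = records["era"] == "fossil"
    month = records["month"]
    if month.isna().any() and (~fossil & month.isna()).any():
        bad = records.loc[~fossil & month.isna(), "id"].tolist()
        raise MissingMonthError(f"non-fossil records without month: {bad[:5]}")
    keep = fossil | month.isin(SUMMER_MONTHS)
    return records.loc[keep].reset_index(drop=True)


def snap_to_ocean(
    records: pd.DataFrame,
    mask: np.ndarray,
    cell_km: float = 90.0,
    max_km: float = 170.0,
):
    """Snap land-stranded records to the nearest ocean cell center.

    Records already on ocean are untouched.  A record on land moves to the
    nearest ocean cell if the center-to-center distance is < ``max_km``,
    otherwise it is dropped.  Returns ``(kept, drop_log)``.
    """
    mask = np.asarray(mask, dtype=bool)
    oy, ox = np.nonzero(mask)
    if oy.size == 0:
        raise ValueError("mask has no ocean cells")
    tree = cKDTree(np.column_stack([ox, oy]) * cell_km)
    out = records.copy()
    on_land = ~mask[out["y"].to_numpy(int), out["x"].to_numpy(int)]
    dropped = []
    if on_land.any():
        pts = out.loc[on_land, ["x", "y"]].to_numpy(float) * cell_km
        dist, idx = tree.query(pts)
        movable = dist < max_km
        land_idx = np.nonzero(on_land)[0]
        out.iloc[land_idx[movable], out.columns.get_loc("x")] = ox[idx[movable]]
        out.iloc[land_idx[movable], out.columns.get_loc("y")] = oy[idx[movable]]
        for pos, j in enumerate(land_idx):
            if not movable[pos]:
                dropped.append(
                    {"id": out.iloc[j]["id"], "nearest_ocean_km": float(dist[pos])}
                )
        out = out.drop(out.index[land_idx[~movable]])
    drop_log = pd.DataFrame(dropped, columns=["id", "nearest_ocean_km"])
    return out.reset_index(drop=True), drop_log


def assign_bins(records: pd.DataFrame, binning: TimeBinning) -> pd.DataFrame:
    """Attach a ``bin`` column from ``year`` to records lacking one.

    Fossil pseudo-replicates already carry a bin; other records are placed
    in the half-open bin containing their calendar year.
    """
    out = records.copy()
    if "bin" not in out:
        out["bin"] = -1
    missing = out["bin"] < 0
    out.loc[missing, "bin"] = binning.year_to_bin(out.loc[missing, "year"].to_numpy(float))
    if (out["bin"] < 0).any():
        bad = out.loc[out["bin"] < 0, "id"].tolist()
        raise ValueError(f"records outside the bin lattice: {bad[:5]}")
    out["bin"] = out["bin"].astype(int)
    return out


def spatial_thin(records: pd.DataFrame, compete: bool = True) -> pd.DataFrame:
    """Thin to at most one record per (cell, time bin).

    The survivor is deterministic: earliest year, then lexicographically
    smallest id (records without a year sort last).  With
    ``compete=False`` fossil pseudo-replicates are thinned separately from
    non-fossil records within each bin.
    """
    out = records.copy()
    if "bin" not in out:
        raise ValueError("records must carry a 'bin' column (see assign_bins)")
    sort_year = out["year"].astype(float).fillna(np.inf)
    out = out.assign(_sy=sort_year).sort_values(
        ["_sy", "id"], kind="mergesort"
    )
    keys = ["x", "y", "bin"]
    if not compete:
        out["_grp"] = (out["era"] == "fossil").astype(int)
        keys = keys + ["_grp"]
    out = out.drop_duplicates(subset=keys, keep="first")
    return (
        out.drop(columns=[c for c in ("_sy", "_grp") if c in out])
        .sort_index()
        .reset_index(drop=True)
    )


def fossil_pseudo_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Explode fossils into per-bin weighted pseudo-replicates.

    Each fossil becomes one replicate per bin with positive calibrated-age
    mass; the replicate weight is that bin's mass, so the weights of one
    fossil sum to 1.  Non-fossil records pass through unchanged.
    """
    rows = []
    for _, rec in records.iterrows():
        if rec["era"] != "fossil":
            rows.append(rec)
            continue
        mass = rec["age_mass"]
        if not mass:
            raise EmptyAgeMassError(f"fossil {rec['id']} has empty age_mass")
        for b, w in sorted(mass.items()):
            rep = rec.copy()
            rep["id"] = f"{rec['id']}#b{b}"
            rep["weight"] = float(rec.get("weight", 1.0)) * float(w)
            rep["bin"] = int(b)
            rows.append(rep)
    out = pd.DataFrame(rows).reset_index(drop=True)
    if "bin" in out:
        out["bin"] = out["bin"].fillna(-1).astype(int)
    return out


def extract_environment(x: int, y: int, b: int, world: xr.Dataset):
    """Mean environment of the 3x3 ocean neighbourhood of cell (x, y) in bin b.

    Returns ``(env, n_cells)`` where ``env`` is a dict with keys
    ``sic, sst, sss, bathy`` and ``n_cells`` counts contributing ocean
    cells.  Raises :class:`AllMaskedError` if the whole neighbourhood is
    land.
    """
    ny, nx = world.sizes["y"], world.sizes["x"]
    y0, y1 = max(y - 1, 0), min(y + 2, ny)
    x0, x1 = max(x - 1, 0), min(x + 2, nx)
    sub_mask = world["mask"].values[y0:y1, x0:x1] == 1
    n = int(sub_mask.sum())
    if n == 0:
        raise AllMaskedError(f"all cells masked around ({x}, {y})")
    env = {}
    for v in ("sic", "sst", "sss", "bathy"):
        vals = world[v].values[b, y0:y1, x0:x1][sub_mask]
        env[v] = float(np.nanmean(vals))
    return env, n


def extract_environment_table(records: pd.DataFrame, world: xr.Dataset) -> pd.DataFrame:
    """Vectorized :func:`extract_environment` over a record table."""
    envs = []
    for _, rec in records.iterrows():
        env, n = extract_environment(int(rec["x"]), int(rec["y"]), int(rec["bin"]), world)
        env["n_env_cells"] = n
        envs.append(env)
    return pd.concat([records.reset_index(drop=True), pd.DataFrame(envs)], axis=1)


def assign_folds(records: pd.DataFrame, k: int = 10, seed: int = 0) -> pd.Series:
    """Stratified cross-validation folds (1..k), stratified by stock x era.

    Within every stratum records are shuffled with a seeded RNG and dealt
    round-robin, so per-stratum fold sizes differ by at most 1.  The
    assignment depends only on the record ids within each stratum, not on
    input order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    for _, grp in records.groupby(["stock", "era"], sort=True):
        ids = np.sort(grp["id"].to_numpy())
        rng.shuffle(ids)
        for pos, rid in enumerate(ids):
            assignment[rid] = pos % k + 1
    fold = pd.Series(assignment, name="fold", dtype=int)
    fold.index.name = "id"
    return fold


def cleaning_report(stage_counts: dict) -> dict:
    """JSON-ready report of record counts per cleaning stage."""
    return {"stages": [{"stage": s, "n_records": int(n)} for s, n in stage_counts.items()]}
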