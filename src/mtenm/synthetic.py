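"""Synthetic worlds, niches, and occurrence records.

Real multi-temporal niche models for Arctic megafauna are trained on
fossil, whaling-logbook, and contemporary sightings matched to paleoclimate
simulations.  None of that is downloadable at test time, so this module
generates the same statistical structure from scratch:

* a gridded "truth" climate world (SIC, SST, SSS, bathymetry + land mask)
  on an abstract equal-area grid of 90 km cells in 35-year time bins, with
  a latitudinal sea-ice gradient and configurable secular trends;
* a second, "biased model" world derived from the truth by a configurable
  additive SST offset, multiplicative SSS factor, and logit-scale SIC
  shift, plus iid noise — emulating the mismatch between two climate
  models over an overlap window;
* a known 4-D Gaussian niche from which presence records are sampled, with
  era labels, months (including deliberate off-season contamination so the
  summer filter is exercised), quadrant stock labels, and discretized
  Gaussian calibrated-age distributions for fossils.

Everything is deterministic given the config seed.  The grid is abstract
(cell indices scaled by ``cell_km``); because the real analysis grid is
equal-area no geodesy is needed and the y axis acts as a pseudo-latitude:
sea ice increases toward the grid top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit, logit

from .binning import TimeBinning

__all__ = [
    "WorldConfig",
    "TrueNiche",
    "generate_world",
    "sample_occurrences",
    "true_suitability_grid",
    "write_world",
    "read_world",
    "write_occurrences",
    "read_occurrences",
]

#: era boundary years: fossil < FOSSIL_END <= historical < HISTORICAL_END <= contemporary
FOSSIL_END = 1500.0
HISTORICAL_END = 1910.0
#: observations end here even when the world extends into scenario bins
OBSERVATION_END = 2020.0

ERAS = ("fossil", "historical", "contemporary")

#: stock labels assigned by grid quadrant (x-half, y-half)
QUADRANT_STOCKS = {
    (0, 0): "okhotsk",          # warm south-west
    (1, 0): "bering",           # south-east
    (0, 1): "canada_greenland",  # north-west
    (1, 1): "svalbard_barents",  # north-east
}


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of a synthetic climate world.

    Trends are per-bin drifts applied to the truth; biases and noise define
    the second ("uncorrected model") world.  SIC is kept within [0, 100].
    """

    grid_nx: int = 24
    grid_ny: int = 24
    cell_km: float = 90.0
    n_bins: int = 40
    bin_width_yr: float = 35.0
    final_year: float = 2020.0
    land_cols: int = 3            # contiguous land strip at the grid's west edge
    # truth climatology (south -> north gradients)
    sic_south: float = 0.0
    sic_north: float = 90.0
    sst_south: float = 12.0
    sst_north: float = -1.0
    sss_west: float = 30.0
    sss_east: float = 33.0
    depth_coast_m: float = 50.0
    depth_slope_m_per_cell: float = 60.0
    # per-bin trends in the truth
    sic_trend: float = 0.0        # %/bin (negative = decline)
    sst_trend: float = 0.0        # degC/bin
    sss_trend: float = 0.0        # psu/bin
    trend_start_bin: int = 0      # trends accrue from this bin onward
    # biases of the "uncorrected model"
    sst_bias: float = 2.0         # additive, degC
    sss_bias_factor: float = 1.1  # multiplicative
    sic_logit_shift: float = 0.5  # shift on logit(SIC/100)
    # iid noise of the "uncorrected model"
    sic_noise_sd: float = 2.0
    sst_noise_sd: float = 0.3
    sss_noise_sd: float = 0.2
    # natural (truth-side) variability shared by both models; this breaks
    # the collinearity between climate and the spatial coordinates that a
    # perfectly stationary world would have
    sic_variability_sd: float = 4.0
    sst_variability_sd: float = 0.4
    sss_variability_sd: float = 0.2
    # overlap window (calendar years) where both models are trusted
    overlap_years: tuple = (1850.0, 1950.0)
    seed: int = 0

    def __post_init__(self):
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be > 0")
        if min(self.sic_noise_sd, self.sst_noise_sd, self.sss_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.land_cols < self.grid_nx:
            raise ValueError("land_cols must leave at least one ocean column")

    @property
    def binning(self) -> TimeBinning:
        return TimeBinning(self.n_bins, self.bin_width_yr, self.final_year)


@dataclass(frozen=True)
class TrueNiche:
    """A known 4-D Gaussian niche used as ground truth.

    Suitability is the product of independent Gaussian kernels on the four
    niche axes (SIC %, SST degC, SSS psu, depth m), normalized to a maximum
    of 1 at the optimum.  The default SIC optimum sits inside the 15-30%
    band where bowhead habitat suitability peaks.
    """

    optimum: tuple = (22.5, 8.5, 31.5, 180.0)
    widths: tuple = (14.0, 4.0, 2.5, 700.0)

    def __post_init__(self):
        if len(self.optimum) != 4 or len(self.widths) != 4:
            raise ValueError("optimum and widths must have 4 components")
        if min(self.widths) <= 0:
            raise ValueError("widths must be strictly positive")

    def suitability(self, env) -> np.ndarray:
        """True suitability in [0, 1] for an (..., 4) array of environments."""
        env = np.asarray(env, dtype=float)
        z = (env - np.asarray(self.optimum)) / np.asarray(self.widths)
        return np.exp(-0.5 * np.sum(z * z, axis=-1))


def _truth_layers(cfg: WorldConfig):
    """Noise-free truth fields, shape (n_bins, ny, nx)."""
    ny, nx, nb = cfg.grid_ny, cfg.grid_nx, cfg.n_bins
    yfrac = (np.arange(ny) / (ny - 1))[:, None] * np.ones((1, nx))
    xfrac = (np.arange(nx) / (nx - 1))[None, :] * np.ones((ny, 1))
    t = np.maximum(np.arange(nb) - cfg.trend_start_bin, 0.0)[:, None, None]

    sic = cfg.sic_south + (cfg.sic_north - cfg.sic_south) * yfrac + cfg.sic_trend * t
    sst = cfg.sst_south + (cfg.sst_north - cfg.sst_south) * yfrac + cfg.sst_trend * t
    sss = cfg.sss_west + (cfg.sss_east - cfg.sss_west) * xfrac + cfg.sss_trend * t
    dist_from_coast_cells = np.maximum(np.arange(nx)[None, :] - (cfg.land_cols - 1), 1)
    bathy = cfg.depth_coast_m + cfg.depth_slope_m_per_cell * (dist_from_coast_cells - 1)
    bathy = np.broadcast_to(bathy * np.ones((ny, 1)), (nb, ny, nx)).copy()
    sic = np.clip(sic, 0.0, 100.0)
    sst = np.broadcast_to(sst, (nb, ny, nx)).copy() if sst.shape[0] != nb else sst
    sss = np.broadcast_to(sss, (nb, ny, nx)).copy() if sss.shape[0] != nb else sss
    return sic, sst, sss, bathy


def _as_dataset(cfg: WorldConfig, sic, sst, sss, bathy, mask) -> xr.Dataset:
    nb = cfg.n_bins
    ds = xr.Dataset(
        {
            "sic": (("bin", "y", "x"), sic),
            "sst": (("bin", "y", "x"), sst),
            "sss": (("bin", "y", "x"), sss),
            "bathy": (("bin", "y", "x"), bathy),
            "mask": (("y", "x"), mask.astype(np.int8)),
        },
        coords={
            "bin": np.arange(nb),
            "y": np.arange(cfg.grid_ny),
            "x": np.arange(cfg.grid_nx),
        },
        attrs={
            "cell_km": cfg.cell_km,
            "bin_width_yr": cfg.bin_width_yr,
            "final_year": cfg.final_year,
        },
    )
    # masked cells carry NaN, never 0
    land = mask == 0
    for v in ("sic", "sst", "sss", "bathy"):
        ds[v] = ds[v].where(~land)
    return ds


def generate_world(cfg: WorldConfig):
    """Generate aligned truth and biased-model worlds.

    Returns
    -------
    truth : xr.Dataset
        Noise-free reference world (dims ``bin, y, x``; variables ``sic``,
        ``sst``, ``sss``, ``bathy``, ``mask``; mask 1 = ocean).
    biased : xr.Dataset
        The truth transformed by the configured biases plus iid noise.
    overlap_bins : np.ndarray
        Indices of bins whose midpoint falls in ``cfg.overlap_years``.
    """
    rng = np.random.default_rng(cfg.seed)
    sic, sst, sss, bathy = _truth_layers(cfg)
    mask = np.ones((cfg.grid_ny, cfg.grid_nx), dtype=bool)
    mask[:, : cfg.land_cols] = False  # contiguous land strip

    shape = sic.shape
    # natural variability lives in the truth and is inherited by the
    # biased model (both models see the same climate trajectory)
    sic = np.clip(sic + rng.normal(0.0, cfg.sic_variability_sd, shape), 0.0, 100.0)
    sst = sst + rng.normal(0.0, cfg.sst_variability_sd, shape)
    sss = sss + rng.normal(0.0, cfg.sss_variability_sd, shape)
    eps = 1e-6
    sic_b = 100.0 * expit(logit(np.clip(sic / 100.0, eps, 1 - eps)) + cfg.sic_logit_shift)
    # 0% and 100% are fixed points of a logit-scale shift
    sic_b = np.where(sic <= 0.0, 0.0, np.where(sic >= 100.0, 100.0, sic_b))
    sic_b = np.clip(sic_b + rng.normal(0.0, cfg.sic_noise_sd, shape), 0.0, 100.0)
    sst_b = sst + cfg.sst_bias + rng.normal(0.0, cfg.sst_noise_sd, shape)
    sss_b = sss * cfg.sss_bias_factor + rng.normal(0.0, cfg.sss_noise_sd, shape)

    truth = _as_dataset(cfg, sic, sst, sss, bathy, mask)
    biased = _as_dataset(cfg, sic_b, sst_b, sss_b, bathy.copy(), mask)

    mids = cfg.binning.midpoints()
    lo, hi = cfg.overlap_years
    overlap_bins = np.nonzero((mids >= lo) & (mids < hi))[0]
    return truth, biased, overlap_bins


def true_suitability_grid(world: xr.Dataset, niche: TrueNiche) -> xr.DataArray:
    """True suitability of every cell in every bin (NaN on land)."""
    env = np.stack(
        [world[v].values for v in ("sic", "sst", "sss", "bathy")], axis=-1
    )
    suit = niche.suitability(env)
    suit = np.where(world["mask"].values[None, :, :] == 1, suit, np.nan)
    return xr.DataArray(suit, dims=("bin", "y", "x"), coords=world["sic"].coords)


def _era_of_year(year: float) -> str:
    if year < FOSSIL_END:
        return "fossil"
    if year < HISTORICAL_END:
        return "historical"
    return "contemporary"


def sample_occurrences(
    world: xr.Dataset,
    niche: TrueNiche,
    n_per_era: dict | None = None,
    fossil_age_sd_yr: float = 120.0,
    offseason_frac: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample presence records from the true niche.

    Cells are drawn (with replacement) with probability proportional to the
    true suitability of the cell's environment in the record's bin, within
    the bins belonging to each era.  Historical/contemporary records get a
    summer month (June-October) except for an ``offseason_frac`` fraction
    drawn from the other months; fossils get no month but a discretized
    Gaussian calibrated-age mass over bins (sd ``fossil_age_sd_yr``,
    truncated to the central 95% and renormalized to sum to 1).  Stocks are
    assigned by grid quadrant.
    """
    if n_per_era is None:
        n_per_era = {"fossil": 60, "historical": 120, "contemporary": 320}
    rng = np.random.default_rng(seed)
    binning = TimeBinning(world.sizes["bin"], world.attrs["bin_width_yr"], world.attrs["final_year"])
    edges = binning.edges()
    suit = true_suitability_grid(world, niche).values  # (nb, ny, nx)
    ny, nx = world.sizes["y"], world.sizes["x"]
    rows = []
    for era in ERAS:
        n = int(n_per_era.get(era, 0))
        if n == 0:
            continue
        if era == "fossil":
            lo, hi = binning.start_year, FOSSIL_END
        elif era == "historical":
            lo, hi = FOSSIL_END, HISTORICAL_END
        else:
            lo, hi = HISTORICAL_END, min(OBSERVATION_END, binning.final_year)
        lo = max(lo, binning.start_year)
        era_bins = [b for b in range(binning.n_bins) if edges[b + 1] > lo and edges[b] < hi]
        if not era_bins:
            raise ValueError(f"no time bins overlap the {era} era")
        w = np.nan_to_num(suit[era_bins], nan=0.0).ravel()
        if w.sum() <= 0:
            raise ValueError(f"no suitable cells available in the {era} era")
        n_positive = int((w > 0).sum())
        if n > n_positive:
            warnings.warn(
                f"{era}: requested {n} records exceeds the {n_positive} "
                "suitable (cell, bin) combinations; sampling with replacement"
            )
        picks = rng.choice(w.size, size=n, p=w / w.sum())
        bsel, ysel, xsel = np.unravel_index(picks, (len(era_bins), ny, nx))
        for i in range(n):
            b = era_bins[bsel[i]]
            yr_lo = max(edges[b], lo)
            yr_hi = min(edges[b + 1], hi)
            year = rng.uniform(yr_lo, yr_hi)
            stock = QUADRANT_STOCKS[(int(xsel[i] >= nx / 2), int(ysel[i] >= ny / 2))]
            rec = {
                "id": f"{era[:4]}-{len(rows):05d}",
                "x": int(xsel[i]),
                "y": int(ysel[i]),
                "era": era,
                "stock": stock,
                "year": float(year),
                "month": np.nan,
                "age_mass": None,
                "weight": 1.0,
            }
            if era == "fossil":
                rec["age_mass"] = binning.bin_mass(year, fossil_age_sd_yr)
            else:
                if rng.uniform() < offseason_frac:
                    rec["month"] = int(rng.choice([1, 2, 3, 4, 5, 11, 12]))
                else:
                    rec["month"] = int(rng.integers(6, 11))
            rows.append(rec)
    df = pd.DataFrame(rows)
    df["month"] = df["month"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# I/O: gridded worlds as NetCDF (scipy backend), occurrences as CSV
# ---------------------------------------------------------------------------

def write_world(world: xr.Dataset, path) -> None:
    world.to_netcdf(path, engine="scipy")


def read_world(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def _age_mass_to_str(mass) -> str:
    if mass is None or (isinstance(mass, float) and np.isnan(mass)):
        return ""
    return "|".join(f"{b}:{w:.12g}" for b, w in sorted(mass.items()))


def _age_mass_from_str(s):
    if not isinstance(s, str) or not s:
        return None
    out = {}
    for part in s.split("|"):
        b, w = part.split(":")
        out[int(b)] = float(w)
    return out


def write_occurrences(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["age_mass"] = out["age_mass"].map(_age_mass_to_str)
    out.to_csv(path, index=False, float_format="%.10g")


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True)
    df["age_mass"] = df["age_mass"].map(_age_mass_from_str) if "age_mass" in df else None
    df["month"] = df["month"].astype("Int64")
    return df
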