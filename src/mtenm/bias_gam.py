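"""Beta-regression GAM for bounded sea-ice-concentration bias correction.

Delta methods cannot correct sea ice concentration: SIC is bounded at 0%
and 100% and responds nonlinearly to its drivers.  Instead the reference
SIC is modelled as a smooth function of the source model's SIC plus
physical covariates, with a beta likelihood and logit link so predictions
are bounded by construction:

    SIC_ref/100 ~ Beta(mu * phi, (1 - mu) * phi)
    logit(mu) = f1(SIC_src) + f2(bathymetry) + f3(dist_coast)
                + f4(month, cyclic) + f5(x, y)

where f1-f3 are penalized cubic B-spline smooths, f4 is a cyclic Fourier
smooth of month, and f5 is a tensor-product surface of the two spatial
coordinates.  The model is fit on the overlap window where both the
reference and the source model exist, then applied to any other period by
feeding the source model's SIC through the fitted smooths.

Because the beta likelihood excludes the endpoints {0, 1}, the response is
shrunk from [0, 1] to (0, 1) with the standard boundary transform
``y' = (y (n - 1) + 0.5) / n`` before fitting and inverted afterwards.

Smoothing uses fixed second-difference ridge penalties (one multiplier per
smooth, ``penalty``); the fit maximizes the penalized beta likelihood with
analytic gradients (L-BFGS).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConvergenceError, DegenerateResponseError

__all__ = ["BetaGAMCorrector", "fit_sic_bias_gam", "predict_sic"]

_COVARIATES = ("sic", "bathy", "dist_coast", "month", "x", "y")


def _bspline_knots(lo: float, hi: float, n_basis: int, degree: int = 3) -> np.ndarray:
    if n_basis < degree + 1:
        raise ValueError(f"need at least {degree + 1} basis functions")
    if hi <= lo:
        hi = lo + 1.0  # constant covariate: degenerate but well-defined basis
    interior = np.linspace(lo, hi, n_basis - degree + 1)[1:-1]
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    x = np.clip(x, knots[0], knots[-1] - 1e-12 * max(1.0, abs(knots[-1])))
    return BSpline.design_matrix(x, knots, degree).toarray()


def _second_diff_penalty(n: int) -> np.ndarray:
    if n < 3:
        return np.eye(n)
    d = np.diff(np.eye(n), n=2, axis=0)
    return d.T @ d


def _fourier_month(month: np.ndarray, n_harmonics: int) -> np.ndarray:
    ang = 2.0 * np.pi * np.asarray(month, dtype=float) / 12.0
    cols = []
    for h in range(1, n_harmonics + 1):
        cols.append(np.sin(h * ang))
        cols.append(np.cos(h * ang))
    return np.column_stack(cols)


class BetaGAMCorrector(BaseEstimator, RegressorMixin):
    """Penalized beta-regression GAM mapping source-model SIC to reference SIC.

    Parameters
    ----------
    k_sic, k_bathy, k_dist : int
        Cubic B-spline basis sizes for the 1-D smooths of source SIC,
        bathymetry, and distance-to-coast.
    n_month_harmonics : int
        Fourier harmonics for the cyclic month smooth.
    k_space : int
        Marginal basis size of the spatial tensor-product smooth
        (``k_space ** 2`` coefficients).
    penalty : float
        Fixed smoothing-penalty multiplier applied to every smooth's
        second-difference (or ridge) penalty.
    mode : {"direct", "anomaly"}
        ``direct`` predicts reference SIC itself; ``anomaly`` models the
        percent-point change (reference - source) and adds the predicted
        change back onto the source SIC.
    max_iter : int
        L-BFGS iteration cap.

    Attributes (after fit)
    ----------------------
    coef_ : spline/Fourier coefficients (including intercept)
    phi_ : beta precision parameter
    n_obs_ : training sample size (drives the boundary transform)
    opt_result_ : the scipy optimizer result (iteration trace)
    """

    def __init__(
        self,
        k_sic: int = 8,
        k_bathy: int = 6,
        k_dist: int = 6,
        n_month_harmonics: int = 2,
        k_space: int = 4,
        penalty: float = 1.0,
        ridge: float = 1e-4,
        mode: str = "direct",
        max_iter: int = 300,
    ):
        self.k_sic = k_sic
        self.k_bathy = k_bathy
        self.k_dist = k_dist
        self.n_month_harmonics = n_month_harmonics
        self.k_space = k_space
        self.penalty = penalty
        self.ridge = ridge
        self.mode = mode
        self.max_iter = max_iter

    # -- design ------------------------------------------------------------

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(X), 1))]
        for name in ("sic", "bathy", "dist_coast"):
            blocks.append(_bspline_design(X[name].to_numpy(float), self.knots_[name]))
        blocks.append(_fourier_month(X["month"].to_numpy(float), self.n_month_harmonics))
        bx = _bspline_design(X["x"].to_numpy(float), self.knots_["x"])
        by = _bspline_design(X["y"].to_numpy(float), self.knots_["y"])
        # row-wise tensor product of the two marginal spatial bases
        tensor = (bx[:, :, None] * by[:, None, :]).reshape(len(X), -1)
        blocks.append(tensor)
        return np.hstack(blocks)

    def _penalty_matrix(self, p: int) -> np.ndarray:
        P = np.zeros((p, p))
        i = 1  # skip intercept
        for name, k in (("sic", self.k_sic), ("bathy", self.k_bathy), ("dist", self.k_dist)):
            P[i : i + k, i : i + k] = self.penalty * _second_diff_penalty(k)
            i += k
        nm = 2 * self.n_month_harmonics
        P[i : i + nm, i : i + nm] = self.penalty * np.eye(nm)
        i += nm
        ks = self.k_space
        Sx = _second_diff_penalty(ks)
        S2 = np.kron(Sx, np.eye(ks)) + np.kron(np.eye(ks), Sx)
        P[i : i + ks * ks, i : i + ks * ks] = self.penalty * S2
        P[1:, 1:] += self.ridge * np.eye(p - 1)  # identifiability
        return P

    # -- likelihood --------------------------------------------------------

    @staticmethod
    def _nll_grad(theta, D, yprime, P):
        beta, logphi = theta[:-1], theta[-1]
        phi = np.exp(logphi)
        eta = D @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        a, b = mu * phi, (1 - mu) * phi
        ly, l1y = np.log(yprime), np.log1p(-yprime)
        ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * ly + (b - 1) * l1y
        pen = 0.5 * beta @ P @ beta
        nll = -ll.sum() + pen
        dll_dmu = phi * (ly - l1y - digamma(a) + digamma(b))
        g_beta = -(D.T @ (dll_dmu * mu * (1 - mu))) + P @ beta
        dll_dphi = digamma(phi) - mu * digamma(a) - (1 - mu) * digamma(b) + mu * ly + (1 - mu) * l1y
        g_logphi = -dll_dphi.sum() * phi
        return nll, np.r_[g_beta, g_logphi]

    # -- API ---------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        """Fit on overlap-period observations.

        ``X`` needs columns ``sic, bathy, dist_coast, month, x, y``;
        ``y`` is the reference SIC in [0, 100].
        """
        X = pd.DataFrame(X)
        missing = set(_COVARIATES) - set(X.columns)
        if missing:
            raise ValueError(f"missing covariates: {sorted(missing)}")
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise DegenerateResponseError("response SIC values are all equal")
        if y.min() < 0 or y.max() > 100:
            raise ValueError("response SIC must lie in [0, 100]")

        if self.mode == "anomaly":
            resp = (y - X["sic"].to_numpy(float) + 100.0) / 200.0
        elif self.mode == "direct":
            resp = y / 100.0
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        n = resp.size
        self.n_obs_ = n
        yprime = (resp * (n - 1) + 0.5) / n

        self.knots_ = {}
        for name, k in (
            ("sic", self.k_sic),
            ("bathy", self.k_bathy),
            ("dist_coast", self.k_dist),
            ("x", self.k_space),
            ("y", self.k_space),
        ):
            col = X[name].to_numpy(float)
            self.knots_[name] = _bspline_knots(col.min(), col.max(), k)

        D = self._design(X)
        P = self._penalty_matrix(D.shape[1])

        z = logit(np.clip(yprime, 1e-6, 1 - 1e-6))
        beta0 = np.linalg.solve(D.T @ D + P + 1e-6 * np.eye(D.shape[1]), D.T @ z)
        theta0 = np.r_[beta0, np.log(20.0)]

        res = minimize(
            self._nll_grad,
            theta0,
            args=(D, yprime, P),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        self.opt_result_ = res
        gnorm = np.linalg.norm(res.jac) / max(n, 1)
        if not res.success and gnorm > 1.0:
            raise ConvergenceError(
                f"beta-GAM did not converge: {res.message} "
                f"(nit={res.nit}, |grad|/n={gnorm:.3g})",
                trace=res,
            )
        self.coef_ = res.x[:-1]
        self.phi_ = float(np.exp(res.x[-1]))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Corrected SIC in [0, 100] for any covariate input.

        Covariates outside the training range are clamped to it, so
        extrapolated predictions remain bounded.
        """
        X = pd.DataFrame(X)
        D = self._design(X)
        mu = expit(D @ self.coef_)
        n = self.n_obs_
        resp = (mu * n - 0.5) / (n - 1)
        if self.mode == "anomaly":
            delta = resp * 200.0 - 100.0
            out = X["sic"].to_numpy(float) + delta
        else:
            out = resp * 100.0
        return np.clip(out, 0.0, 100.0)


def _covariate_table(
    source_sic: xr.DataArray,
    bathy: xr.DataArray,
    dist_coast: np.ndarray,
    bins,
    month: int,
) -> pd.DataFrame:
    """Flatten gridded covariates over ocean cells of the given bins."""
    rows = []
    for b in np.asarray(bins, dtype=int):
        sic = source_sic.isel(bin=b).values
        bat = bathy.isel(bin=b).values if "bin" in bathy.dims else bathy.values
        ok = np.isfinite(sic) & np.isfinite(bat) & np.isfinite(dist_coast)
        yy, xx = np.nonzero(ok)
        rows.append(
            pd.DataFrame(
                {
                    "sic": sic[yy, xx],
                    "bathy": bat[yy, xx],
                    "dist_coast": np.asarray(dist_coast)[yy, xx],
                    "month": month,
                    "x": xx.astype(float),
                    "y": yy.astype(float),
                    "bin": b,
                    "iy": yy,
                    "ix": xx,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def fit_sic_bias_gam(
    target_sic: xr.DataArray,
    source_sic: xr.DataArray,
    bathy: xr.DataArray,
    dist_coast: np.ndarray,
    overlap_bins,
    month: int = 8,
    **kwargs,
) -> BetaGAMCorrector:
    """Fit the SIC bias model on the overlap window of two gridded series.

    ``target_sic`` is the reference (e.g. ensemble) SIC, ``source_sic``
    the model to be corrected; both have dims ``(bin, y, x)``.  Bin-level
    summer means carry no month axis, so a representative mid-summer month
    is used for the cyclic term (constant, absorbed by the intercept).
    """
    table = _covariate_table(source_sic, bathy, dist_coast, overlap_bins, month)
    y = target_sic.values[table["bin"].to_numpy(int), table["iy"], table["ix"]]
    ok = np.isfinite(y)
    model = BetaGAMCorrector(**kwargs)
    model.fit(table.loc[ok, list(_COVARIATES)], y[ok])
    return model


def predict_sic(
    model: BetaGAMCorrector,
    source_sic: xr.DataArray,
    bathy: xr.DataArray,
    dist_coast: np.ndarray,
    month: int = 8,
) -> xr.DataArray:
    """Corrected SIC grid for every bin of ``source_sic`` (NaN on land)."""
    bins = np.arange(source_sic.sizes["bin"])
    table = _covariate_table(source_sic, bathy, dist_coast, bins, month)
    pred = model.predict(table[list(_COVARIATES)])
    out = np.full(source_sic.shape, np.nan)
    out[table["bin"].to_numpy(int), table["iy"], table["ix"]] = pred
    return xr.DataArray(out, dims=source_sic.dims, coords=source_sic.coords)
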