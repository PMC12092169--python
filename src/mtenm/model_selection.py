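"""Validation metrics, ten-fold cross-validation, and the one-SE rule.

Presence-only niche models are validated with three complementary
metrics per held-out fold:

* ROC-AUC against pseudo-background points drawn uniformly from the
  bounding region of the fitted hypervolume and scored by the same model;
* the Continuous Boyce Index — the Spearman correlation between the
  predicted-to-expected presence ratio and suitability across moving
  windows, +1 for a well-calibrated model;
* Sensitivity — the fraction of held-out presences scoring at or above
  the 10th percentile of training-presence suitability.

For model selection the fold-mean metrics are z-scored across the tuning
grid, summed into a combined score, and the most parsimonious
configuration within one standard error of the best is selected
(larger bandwidth, then larger mass quantile, then smaller truncation
radius count as simpler).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .exceptions import DegenerateSuitabilityError, EmptyInputError
from .hypervolume import GaussianHypervolume

__all__ = [
    "roc_auc",
    "continuous_boyce",
    "sensitivity",
    "sample_background",
    "cross_validate",
    "grid_search",
    "select_one_se",
    "TuningResult",
    "results_frame",
]

METRICS = ("auc", "boyce", "sensitivity")


def roc_auc(presence, background) -> float:
    """Mann-Whitney AUC: P(presence > background) + 0.5 P(tie)."""
    presence = np.asarray(presence, dtype=float)
    background = np.asarray(background, dtype=float)
    if presence.size == 0 or background.size == 0:
        raise EmptyInputError("need at least one presence and one background value")
    ranks = rankdata(np.r_[presence, background])
    rp = ranks[: presence.size].sum()
    n_p, n_b = presence.size, background.size
    return float((rp - n_p * (n_p + 1) / 2.0) / (n_p * n_b))


def continuous_boyce(
    presence,
    available,
    n_windows: int = 101,
    window_frac: float = 0.1,
) -> float:
    """Continuous Boyce Index in [-1, 1].

    Overlapping windows of width ``window_frac`` of the available-
    suitability range are slid across that range; per window P is the
    fraction of presences inside and E the fraction of available cells.
    The index is the Spearman correlation of P/E with the window midpoint
    over windows with E > 0 (at least two are required).
    """
    presence = np.asarray(presence, dtype=float)
    available = np.asarray(available, dtype=float)
    if presence.size == 0 or available.size == 0:
        raise EmptyInputError("need presences and available suitabilities")
    lo, hi = float(available.min()), float(available.max())
    if hi <= lo:
        raise DegenerateSuitabilityError("available suitability is constant")
    width = window_frac * (hi - lo)
    starts = np.linspace(lo, hi - width, n_windows)
    mids, ratios = [], []
    for s in starts:
        e = np.mean((available >= s) & (available <= s + width))
        if e <= 0:
            continue
        p = np.mean((presence >= s) & (presence <= s + width))
        mids.append(s + width / 2.0)
        ratios.append(p / e)
    if len(mids) < 2:
        raise DegenerateSuitabilityError("fewer than two windows with expected mass")
    rho = spearmanr(ratios, mids).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def sensitivity(presence, threshold: float, weights=None) -> float:
    """(Weighted) fraction of presences with suitability >= threshold."""
    presence = np.asarray(presence, dtype=float)
    if presence.size == 0:
        raise EmptyInputError("no presence suitabilities")
    hit = presence >= threshold
    if weights is None:
        return float(hit.mean())
    weights = np.asarray(weights, dtype=float)
    return float((hit * weights).sum() / weights.sum())


def sample_background(hv: GaussianHypervolume, n: int, rng) -> np.ndarray:
    """Uniform pseudo-background environments from the hypervolume's
    bounding region (the axis-aligned box of its boundary sample)."""
    lo = hv.boundary_points_.min(axis=0)
    hi = hv.boundary_points_.max(axis=0)
    z = rng.uniform(lo, hi, size=(n, hv.points_.shape[1]))
    return z * hv.scale_ + hv.mean_


@dataclass
class TuningResult:
    """Cross-validated metric summary for one hyperparameter combination."""

    config: dict
    fold_metrics: dict = field(default_factory=dict)  # metric -> per-fold array
    means: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    combined: float = np.nan
    selected: bool = False


def cross_validate(
    X,
    weights,
    folds,
    config: dict,
    avail_X,
    seed: int = 0,
    background_mult: int = 10,
    sens_percentile: float = 10.0,
) -> TuningResult:
    """Ten-fold CV of one configuration.

    ``X`` are record environments (n, 4) with ``weights`` and fold labels
    ``folds`` (1..k); ``avail_X`` are the available-environment rows used
    for the Boyce index.  Per fold the hypervolume is fitted on the
    out-of-fold records and the three metrics evaluated on the held-out
    records with freshly drawn background.  Folds with no test presences
    are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    weights = np.ones(len(X)) if weights is None else np.asarray(weights, float)
    folds = np.asarray(folds)
    labels = np.unique(folds)
    proj_keys = ("edges_zero_distance_factor", "weight_exponent")
    fit_cfg = {k: v for k, v in config.items() if k not in proj_keys}
    per_fold = {m: [] for m in METRICS}
    for f in labels:
        test = folds == f
        train = ~test
        if not test.any() or not train.any():
            warnings.warn(f"fold {f} has no presences on one side; skipped")
            continue
        # derive the fold RNG from the fold's membership, not its label, so
        # relabeling folds cannot change any metric
        members = np.sort(np.nonzero(test)[0])
        rng = np.random.default_rng([seed, *(int(i) for i in members)])
        hv = GaussianHypervolume(
            **fit_cfg,
            **{k: config[k] for k in proj_keys if k in config},
            random_state=int(rng.integers(2**31 - 1)),
        )
        hv.fit(X[train], sample_weight=weights[train])
        s_test = hv.predict(X[test])
        bg = sample_background(hv, background_mult * int(test.sum()), rng)
        s_bg = hv.predict(bg)
        per_fold["auc"].append(roc_auc(s_test, s_bg))
        try:
            s_avail = hv.predict(np.asarray(avail_X, dtype=float))
            per_fold["boyce"].append(continuous_boyce(s_test, s_avail))
        except DegenerateSuitabilityError:
            warnings.warn(f"fold {f}: degenerate suitability, Boyce skipped")
            per_fold["boyce"].append(np.nan)
        s_train = hv.predict(X[train])
        thr = np.percentile(s_train, sens_percentile, method="lower")
        per_fold["sensitivity"].append(sensitivity(s_test, thr, weights=weights[test]))

    result = TuningResult(config=dict(config))
    for m in METRICS:
        vals = np.asarray(per_fold[m], dtype=float)
        ok = vals[np.isfinite(vals)]
        result.fold_metrics[m] = vals
        result.means[m] = float(ok.mean()) if ok.size else np.nan
        result.ses[m] = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else 0.0
    return result


def grid_search(
    X,
    weights,
    folds,
    avail_X,
    param_grid: dict,
    seed: int = 0,
    **cv_kwargs,
) -> list:
    """Cross-validate every combination of the hyperparameter grid."""
    keys = sorted(param_grid)
    results = []
    for combo in itertools.product(*(param_grid[k] for k in keys)):
        config = dict(zip(keys, combo))
        results.append(
            cross_validate(X, weights, folds, config, avail_X, seed=seed, **cv_kwargs)
        )
    return results


def select_one_se(results: list) -> TuningResult:
    """One-standard-error model selection over a tuning grid.

    Fold-mean metrics are z-scored across configurations and summed into a
    combined score.  All configurations scoring within one standard error
    of the best (the best's SE, propagated as the root-sum-square of its
    z-scaled metric SEs) are eligible; the most parsimonious eligible
    configuration wins, ordered by larger ``bandwidth_mult``, then larger
    ``quantile``, then smaller ``sd_count``, then grid order.
    """
    if not results:
        raise ValueError("no tuning results")
    z_sds = {}
    for m in METRICS:
        vals = np.asarray([r.means[m] for r in results], dtype=float)
        mu, sd = np.nanmean(vals), np.nanstd(vals)
        z_sds[m] = sd
        z = np.zeros(len(results)) if sd == 0 else (vals - mu) / sd
        for r, zi in zip(results, np.nan_to_num(z)):
            r.__dict__.setdefault("_z", {})[m] = float(zi)
    for r in results:
        r.combined = float(sum(r._z[m] for m in METRICS))
    best_idx = int(np.argmax([r.combined for r in results]))
    best = results[best_idx]
    se_best = float(
        np.sqrt(
            sum(
                (best.ses[m] / z_sds[m]) ** 2
                for m in METRICS
                if z_sds[m] > 0
            )
        )
    )
    eligible = [
        (i, r) for i, r in enumerate(results) if r.combined >= best.combined - se_best
    ]

    def parsimony(item):
        i, r = item
        c = r.config
        return (
            -c.get("bandwidth_mult", 0.0),
            -c.get("quantile", 0.0),
            c.get("sd_count", 0),
            i,
        )

    winner = min(eligible, key=parsimony)[1]
    for r in results:
        r.selected = r is winner
    return winner


def results_frame(results: list) -> pd.DataFrame:
    """Tuning results as a tidy table (one row per configuration)."""
    rows = []
    for r in results:
        row = dict(r.config)
        for m in METRICS:
            row[f"{m}_mean"] = r.means[m]
            row[f"{m}_se"] = r.ses[m]
        row["combined"] = r.combined
        row["selected"] = r.selected
        rows.append(row)
    return pd.DataFrame(rows)
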