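"""Time binning for multi-temporal niche models.

Occurrences and climate fields are aggregated into fixed-width calendar
bins (default 35 years, roughly one bowhead whale generation).  Bins are
half-open ``[start, end)`` and anchored so the final bin ends at a fixed
calendar year (2020 CE by default); future scenario bins simply extend the
same lattice past the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeBinning"]


@dataclass(frozen=True)
class TimeBinning:
    """A lattice of half-open calendar-year bins.

    Parameters
    ----------
    n_bins : int
        Number of bins, indexed ``0 .. n_bins - 1`` from oldest to newest.
    width_yr : float
        Bin width in calendar years.
    final_year : float
        Exclusive end of the last bin (bin ``n_bins - 1`` covers
        ``[final_year - width_yr, final_year)``).
    """

    n_bins: int
    width_yr: float = 35.0
    final_year: float = 2020.0

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.width_yr <= 0:
            raise ValueError("width_yr must be > 0")

    @property
    def start_year(self) -> float:
        return self.final_year - self.n_bins * self.width_yr

    def edges(self) -> np.ndarray:
        """Bin edges, length ``n_bins + 1``, oldest first."""
        return self.start_year + self.width_yr * np.arange(self.n_bins + 1)

    def midpoints(self) -> np.ndarray:
        return self.start_year + self.width_yr * (np.arange(self.n_bins) + 0.5)

    def year_to_bin(self, year):
        """Map calendar year(s) to bin index; -1 where outside the lattice.

        Bins are half-open: a year exactly on an edge belongs to the later
        bin, so ``final_year`` itself falls outside.
        """
        year = np.asarray(year, dtype=float)
        idx = np.floor((year - self.start_year) / self.width_yr).astype(int)
        idx = np.where((year < self.start_year) | (year >= self.final_year), -1, idx)
        return idx if idx.ndim else int(idx)

    def bin_mass(self, mu: float, sd: float, central: float = 0.95) -> dict[int, float]:
        """Discretize a Gaussian age distribution onto the bin lattice.

        The Gaussian ``N(mu, sd)`` over calendar years is truncated to its
        central ``central`` interval, integrated over each bin, and
        renormalized so the returned masses sum to exactly 1.  Degenerate
        ``sd == 0`` puts all mass in the bin containing ``mu``.
        """
        from scipy.stats import norm

        if sd <= 0:
            b = self.year_to_bin(mu)
            if b < 0:
                raise ValueError("age outside the bin lattice")
            return {int(b): 1.0}
        lo, hi = norm.interval(central, loc=mu, scale=sd)
        edges = self.edges()
        cdf = norm.cdf(np.clip(edges, lo, hi), loc=mu, scale=sd)
        mass = np.diff(cdf)
        total = mass.sum()
        if total <= 0:
            raise ValueError("age distribution has no mass inside the bin lattice")
        mass = mass / total
        return {int(b): float(m) for b, m in enumerate(mass) if m > 0}
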