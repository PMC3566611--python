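"""Binned degree distributions and power-law tail fits.

Interaction-network degree distributions are heavy-tailed but typically
deviate from a pure power law at low degree, so the tail exponent is
estimated only above a lower degree cutoff: degrees are binned with a
fixed bin width (default 5, first bin [1, 5]), and an ordinary least
squares line is fit through (log10 bin midpoint, log10 bin count) over
the non-empty bins whose lower edge is at or above the cutoff.  The slope
of that line is the reported exponent.  Cutoffs are chosen by inspection
of the distribution, not automatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DegreeDistribution",
    "PowerLawFit",
    "EmptyDistributionError",
    "InsufficientDataError",
    "bin_degrees",
    "fit_power_law",
]


class EmptyDistributionError(ValueError):
    """No degrees remain after the minimum-degree filter."""


class InsufficientDataError(ValueError):
    """Fewer than three usable bins for the tail fit."""


@dataclass(frozen=True)
class Bin:
    lower: int
    upper: int  # inclusive
    count: int

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2.0


@dataclass(frozen=True)
class DegreeDistribution:
    """Unnormalised histogram of node degrees with fixed bin width."""

    bin_size: int
    bins: tuple[Bin, ...]
    total_nodes: int

    def counts(self) -> np.ndarray:
        return np.array([b.count for b in self.bins], dtype=int)

    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.bins], dtype=float)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS line through the log–log binned tail.

    ``exponent`` is the slope (negative for decaying tails); ``goodness``
    is the coefficient of determination R² of the log–log regression.
    """

    exponent: float
    cutoff: int
    n_bins_used: int
    goodness: float
    intercept: float


def bin_degrees(
    degrees: Sequence[int],
    bin_size: int = 5,
    min_degree: int = 1,
) -> DegreeDistribution:
    """Histogram ``degrees`` into contiguous bins [1, s], [s+1, 2s], …

    Degrees below ``min_degree`` are discarded before binning; trailing
    empty bins are trimmed.  Raises :class:`EmptyDistributionError` when
    nothing survives the filter.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    degs = np.asarray(list(degrees), dtype=int)
    if degs.size and degs.min() < 1:
        raise ValueError("degrees must be positive integers")
    degs = degs[degs >= min_degree]
    if degs.size == 0:
        raise EmptyDistributionError(
            f"no degrees at or above min_degree={min_degree}")
    n_bins = int((degs.max() - 1) // bin_size) + 1
    idx = (degs - 1) // bin_size
    counts = np.bincount(idx, minlength=n_bins)
    bins = tuple(
        Bin(lower=i * bin_size + 1, upper=(i + 1) * bin_size, count=int(c))
        for i, c in enumerate(counts)
    )
    return DegreeDistribution(bin_size=bin_size, bins=bins,
                              total_nodes=int(degs.size))


def fit_power_law(dist: DegreeDistribution, cutoff: int = 1) -> PowerLawFit:
    """Fit the tail exponent over bins whose lower edge is >= ``cutoff``.

    Empty bins carry no point (log of zero); at least three non-empty
    bins must remain or :class:`InsufficientDataError` is raised.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    pts = [(b.midpoint, b.count) for b in dist.bins
           if b.lower >= cutoff and b.count > 0]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"only {len(pts)} non-empty bins at or above cutoff={cutoff}; "
            "need at least 3")
    x = np.log10([p[0] for p in pts])
    y = np.log10([p[1] for p in pts])
    res = stats.linregress(x, y)
    return PowerLawFit(
        exponent=float(res.slope),
        cutoff=int(cutoff),
        n_bins_used=len(pts),
        goodness=float(res.rvalue**2),
        intercept=float(res.intercept),
    )


def write_distribution(dist: DegreeDistribution, path) -> None:
    """TSV of (bin_lower, bin_upper, count)."""
    with open(path, "w") as fh:
        fh.write("bin_lower\tbin_upper\tcount\n")
        for b in dist.bins:
            fh.write(f"{b.lower}\t{b.upper}\t{b.count}\n")
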