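"""Boundary-uncertainty and interpretability diagnostics.

The confidence-interval width ratio (CIWR) compares the interval width at a
covariate endpoint with the mean width over the interior of the covariate
range; values around 1-2 indicate boundary uncertainty in line with the
reduction of data near the bounds, while very large or near-zero values
signal numerically unstable or overconfident fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PositionTrace, SpikeTrain
from .fit import GLMFit, IntensityCurve

__all__ = [
    "CIWRReport",
    "ciwr",
    "param_correlation",
    "occupancy_rate_map",
    "spike_autocorrelation",
    "isi_histogram",
]


@dataclass
class CIWRReport:
    """Confidence-interval width ratio at both covariate endpoints.

    Widths are measured on the exponentiated (intensity-modulation) scale of
    the curve; the interior is the covariate sub-range from 0.05 to 0.95
    times the full range.
    """

    w_start: float
    w_end: float
    mean_interior: float
    ciwr_start: float
    ciwr_end: float
    interior_range: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "w_start": self.w_start,
            "w_end": self.w_end,
            "mean_interior": self.mean_interior,
            "ciwr_start": self.ciwr_start,
            "ciwr_end": self.ciwr_end,
            "interior_range": list(self.interior_range),
        }


def ciwr(curve: IntensityCurve, log_scale: bool = False) -> CIWRReport:
    """Confidence-interval width ratio of a modulation curve.

    ``W_end`` is the interval width at the exact first/last grid point;
    ``mean_interior`` averages widths over grid points within
    ``[min + 0.05*range, min + 0.95*range]``.  Set ``log_scale=True`` to
    measure widths on the log-intensity scale instead.
    """
    grid = curve.grid
    if grid.size < 3:
        raise ValueError("curve grid too small for a CIWR computation")
    if log_scale:
        with np.errstate(divide="ignore"):
            widths = np.log(curve.upper) - np.log(curve.lower)
    else:
        widths = curve.width
    lo, hi = float(grid.min()), float(grid.max())
    rng = hi - lo
    interior = (grid >= lo + 0.05 * rng) & (grid <= lo + 0.95 * rng)
    if not interior.any():
        raise ValueError("no interior grid points in [min+0.05r, min+0.95r]")
    i_start = int(np.argmin(grid))
    i_end = int(np.argmax(grid))
    w_start = float(widths[i_start])
    w_end = float(widths[i_end])
    mean_interior = float(np.mean(widths[interior]))
    return CIWRReport(
        w_start=w_start,
        w_end=w_end,
        mean_interior=mean_interior,
        ciwr_start=w_start / mean_interior,
        ciwr_end=w_end / mean_interior,
        interior_range=(lo + 0.05 * rng, lo + 0.95 * rng),
    )


def param_correlation(fit: GLMFit, block: str | None = None) -> pd.DataFrame:
    """Coefficient correlation matrix from the inverse Fisher information.

    ``rho_ij = cov_ij / sqrt(cov_ii * cov_jj)``.  Separated or zero-variance
    columns are excluded (with their labels dropped from the result).
    Restrict to one design block by name via ``block``.
    """
    if block is not None:
        sl = fit.block_slice(block)
        cov = fit.cov[sl, sl]
        labels = list(fit.labels[sl])
        flagged = fit.separated[sl]
    else:
        cov = fit.cov
        labels = list(fit.labels)
        flagged = fit.separated
    var = np.diag(cov)
    keep = (~flagged) & np.isfinite(var) & (var > 0)
    if not keep.any():
        raise ValueError("no usable columns for a correlation matrix")
    sub = cov[np.ix_(keep, keep)]
    d = np.sqrt(np.diag(sub))
    rho = sub / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    kept_labels = [lab for lab, k in zip(labels, keep) if k]
    return pd.DataFrame(rho, index=kept_labels, columns=kept_labels)


def occupancy_rate_map(
    pos: PositionTrace, train: SpikeTrain, space_edges
) -> pd.DataFrame:
    """Occupancy-normalized firing rate per spatial bin (spikes/s).

    Bins with zero occupancy get NaN rates.  Raises if nothing is occupied.
    """
    if pos.n_bins != train.n_bins:
        raise ValueError("position trace and spike train must be aligned")
    edges = np.asarray(space_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("space_edges must be increasing with >= 2 entries")
    occ_bins, _ = np.histogram(pos.positions, bins=edges)
    occupancy = occ_bins * train.bin_width
    if not np.any(occupancy > 0):
        raise ValueError("no occupancy in any spatial bin")
    spikes, _ = np.histogram(
        pos.positions, bins=edges, weights=train.counts.astype(float)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, spikes / occupancy, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame(
        {"position": centers, "occupancy_s": occupancy, "spikes": spikes, "rate": rate}
    )


def spike_autocorrelation(train: SpikeTrain, max_lag: int) -> np.ndarray:
    """Autocorrelation of the mean-centered binned train at lags 1..max_lag."""
    c = train.counts.astype(float)
    if c.size <= max_lag:
        raise ValueError("max_lag must be shorter than the train")
    c = c - c.mean()
    denom = float(c @ c)
    if denom == 0:
        raise ValueError("train has no variance (no spikes?)")
    return np.array([float(c[lag:] @ c[:-lag]) / denom for lag in range(1, max_lag + 1)])


def plot_intensity_curve(curve: IntensityCurve, ax=None, **line_kwargs):
    """Plot a modulation curve with its confidence band (matplotlib optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.grid, curve.estimate, color="tab:blue", **line_kwargs)
    ax.plot(curve.grid, curve.lower, color="black", lw=0.8)
    ax.plot(curve.grid, curve.upper, color="black", lw=0.8)
    ax.set_ylabel("intensity modulation")
    return ax


def plot_correlation(corr: pd.DataFrame, ax=None):
    """Heatmap of a parameter correlation matrix (matplotlib optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.figure.colorbar(im, ax=ax)
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr.index)), corr.index, fontsize=7)
    return ax


def isi_histogram(
    spike_times, bin_width: float, max_isi: float | None = None
) -> pd.DataFrame:
    """Histogram of inter-spike intervals with bins of ``bin_width`` seconds."""
    times = np.sort(np.asarray(spike_times, dtype=float))
    if times.size < 2:
        raise ValueError("need at least 2 spikes for ISIs")
    isis = np.diff(times)
    top = max_isi if max_isi is not None else float(isis.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(isis, bins=edges)
    return pd.DataFrame(
        {"isi": 0.5 * (edges[:-1] + edges[1:]), "count": counts}
    )
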