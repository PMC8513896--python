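"""Binned spike trains, position traces, and design-matrix assembly.

The model's log conditional intensity is a sum of a spatial component (basis
functions of the animal's linearized position) and a spike-history component
(basis functions of lagged spike counts), each contributing one labeled
block of design columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import oaconvolve

from .splines import BasisMatrix, KnotGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "PositionTrace",
    "DesignBlock",
    "Design",
    "bin_spikes",
    "resample_positions",
    "history_block",
    "spatial_block",
    "assemble_design",
    "default_history_grid",
]

#: default history knot locations in ms lag, matching a 5-dimensional
#: modified spline over lags 1..200 ms with fine resolution at short lags
DEFAULT_HISTORY_KNOTS_MS = (1.0, 10.0, 40.0, 100.0, 200.0)


def default_history_grid(variant: str = "modified", tension: float = 0.5) -> KnotGrid:
    """Default history-lag knot grid ({1,10,40,100,200} ms)."""
    if variant == "cardinal":
        return KnotGrid.cardinal_with_ghosts(DEFAULT_HISTORY_KNOTS_MS, tension)
    return KnotGrid(DEFAULT_HISTORY_KNOTS_MS, tension=tension, variant=variant)


@dataclass
class SpikeTrain:
    """Event counts on a regular time grid of width ``bin_width`` seconds."""

    counts: np.ndarray
    bin_width: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def spike_times(self) -> np.ndarray:
        """Bin-center times of non-empty bins, repeated by count."""
        return np.repeat(self.bin_centers(), self.counts)


@dataclass
class PositionTrace:
    """Per-bin linearized position (cm), aligned to a SpikeTrain's bins."""

    positions: np.ndarray
    bin_width: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.positions.size


@dataclass
class DesignBlock:
    """Labeled sample x basis-weight matrix for one covariate stream.

    ``spec`` is the generating basis specification (any object with an
    ``evaluate(values) -> BasisMatrix`` method); it is retained so that
    intensity curves can be evaluated on arbitrary grids after fitting.
    """

    name: str
    matrix: np.ndarray
    labels: tuple
    spec: object = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("block matrix must be 2-D")
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"block {self.name!r} contains non-finite entries")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]


def bin_spikes(spike_times, t0: float, t1: float, bin_width: float) -> SpikeTrain:
    """Bin event times into counts over ``[t0, t1)``.

    Bin ``k`` counts events in ``[t0 + k*bin_width, t0 + (k+1)*bin_width)``;
    events outside ``[t0, t1)`` are dropped with a logged count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    times = np.sort(np.asarray(spike_times, dtype=float))
    n_bins = int(np.ceil((t1 - t0) / bin_width))
    inside = (times >= t0) & (times < t1)
    dropped = times.size - int(inside.sum())
    if dropped:
        logger.info("dropped %d spikes outside [%g, %g)", dropped, t0, t1)
    # small forward nudge keeps edge spikes in their bin under representable
    # time shifts (translation invariance up to float round-off)
    idx = np.floor((times[inside] - t0) / bin_width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return SpikeTrain(counts=counts, bin_width=bin_width, t0=t0)


def resample_positions(
    times, positions, train: SpikeTrain
) -> PositionTrace:
    """Resample a (time, position) trace to the train's bin centers.

    Uses nearest-time interpolation so sparse position samples are carried
    across bins without smoothing artefacts.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if times.size != positions.size or times.size == 0:
        raise ValueError("times and positions must be equal-length, non-empty")
    order = np.argsort(times)
    times, positions = times[order], positions[order]
    centers = train.bin_centers()
    idx = np.searchsorted(times, centers)
    idx = np.clip(idx, 1, times.size - 1)
    left_closer = (centers - times[idx - 1]) <= (times[idx] - centers)
    nearest = np.where(left_closer, idx - 1, idx)
    # edge bins before the first / after the last sample take that sample
    nearest[centers <= times[0]] = 0
    nearest[centers >= times[-1]] = times.size - 1
    return PositionTrace(
        positions=positions[nearest], bin_width=train.bin_width, t0=train.t0
    )


def history_block(
    train: SpikeTrain,
    lag_basis: BasisMatrix,
    spec: object = None,
    name: str = "history",
) -> DesignBlock:
    """Convolve the spike train with each lag-basis function.

    ``lag_basis`` must be evaluated on the integer lags ``1..L`` (in bins);
    column ``j`` of the block at bin ``t`` is
    ``sum_l lag_basis[l, j] * counts[t - l]``, with counts before the start
    of the session treated as zero (cold start).  Lag 0 is excluded: only
    past spikes influence the present bin.
    """
    L = lag_basis.matrix.shape[0]
    if L >= train.n_bins:
        raise ValueError(
            f"history length L={L} must be shorter than the session ({train.n_bins} bins)"
        )
    counts = train.counts.astype(float)
    cols = []
    for j in range(lag_basis.n_basis):
        kernel = np.concatenate([[0.0], lag_basis.matrix[:, j]])  # enforce lag >= 1
        cols.append(oaconvolve(counts, kernel)[: train.n_bins])
    matrix = np.column_stack(cols)
    # fftconvolve leaves ~1e-13 noise; snap exact zeros where no spike is in range
    matrix[np.abs(matrix) < 1e-12] = 0.0
    return DesignBlock(
        name=name, matrix=matrix, labels=tuple(lag_basis.column_labels), spec=spec
    )


def history_block_from_spec(
    train: SpikeTrain, spec, history_length_ms: float = 200.0, name: str = "history"
) -> DesignBlock:
    """Build a history block from a basis spec over ms lags.

    Lags run ``1..L`` bins where ``L = history_length_ms / (1000 * bin_width)``;
    the basis is evaluated at each lag's duration in ms.
    """
    L = int(round(history_length_ms / (1000.0 * train.bin_width)))
    lags_ms = np.arange(1, L + 1) * train.bin_width * 1000.0
    lag_basis = spec.evaluate(lags_ms)
    return history_block(train, lag_basis, spec=spec, name=name)


def spatial_block(
    pos: PositionTrace,
    spec,
    name: str = "spatial",
    out_of_range: str = "raise",
) -> DesignBlock:
    """Evaluate a spatial basis spec at every bin's position."""
    try:
        basis = spec.evaluate(pos.positions, out_of_range=out_of_range)
    except TypeError:
        basis = spec.evaluate(pos.positions)
    return DesignBlock(
        name=name, matrix=basis.matrix, labels=tuple(basis.column_labels), spec=spec
    )


@dataclass
class Design:
    """Assembled design matrix with block provenance."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    blocks: dict = field(default_factory=dict)  # name -> (slice, spec)

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def block_slice(self, name: str) -> slice:
        return self.blocks[name][0]

    def block_spec(self, name: str):
        return self.blocks[name][1]


def _spans_constant(matrix: np.ndarray) -> bool:
    """True when rows of the block sum to 1 (partition of unity)."""
    return bool(np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9))


def assemble_design(blocks: Sequence[DesignBlock], intercept: bool = False) -> Design:
    """Concatenate design blocks horizontally with provenance-keeping labels.

    Emits a collinearity warning when an intercept is requested alongside a
    partition-of-unity block (their columns already span the constant).
    """
    if not blocks:
        raise ValueError("need at least one design block")
    n_bins = blocks[0].n_bins
    for b in blocks:
        if b.n_bins != n_bins:
            raise ValueError(
                f"block {b.name!r} has {b.n_bins} rows, expected {n_bins}"
            )
    parts = []
    labels: list[str] = []
    block_map: dict = {}
    start = 0
    if intercept:
        parts.append(np.ones((n_bins, 1)))
        labels.append("intercept")
        block_map["intercept"] = (slice(0, 1), None)
        start = 1
        for b in blocks:
            if _spans_constant(b.matrix):
                warnings.warn(
                    f"intercept is exactly collinear with partition-of-unity "
                    f"block {b.name!r}",
                    UserWarning,
                    stacklevel=2,
                )
    for b in blocks:
        parts.append(b.matrix)
        labels.extend(f"{b.name}[{lab}]" for lab in b.labels)
        block_map[b.name] = (slice(start, start + b.n_cols), b.spec)
        start += b.n_cols
    return Design(
        matrix=np.hstack(parts), labels=tuple(labels), blocks=block_map
    )
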