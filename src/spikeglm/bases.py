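"""Raised-cosine and indicator comparison bases.

Both families share the :class:`~spikeglm.splines.BasisMatrix` contract with
the spline bases so the downstream design/fit code is basis-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .splines import BasisMatrix

__all__ = [
    "RaisedCosineSpec",
    "PartitionSpec",
    "raised_cosine_matrix",
    "indicator_matrix",
]

_PHI_SPACING = np.pi / 2


@dataclass(frozen=True)
class RaisedCosineSpec:
    """Log-time raised cosine basis: peaks at phases ``phis``, pi/2 apart.

    Column ``j`` at ``x`` is ``(1 + cos(a*log(x+c) - phi_j)) / 2`` where
    ``a*log(x+c)`` lies within ``phi_j +- pi``, and 0 elsewhere.  The log
    scaling gives fine resolution at small ``x`` and broad coverage at
    large ``x``.
    """

    a: float
    c: float
    phis: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phis", tuple(float(p) for p in self.phis))
        if len(self.phis) < 1:
            raise ValueError("need at least one peak phase")
        spacing = np.diff(self.phis)
        if len(spacing) and not np.allclose(spacing, _PHI_SPACING, atol=1e-9):
            raise ValueError("peak phases must be evenly spaced at pi/2")
        if not (np.isfinite(self.a) and np.isfinite(self.c)):
            raise ValueError("a and c must be finite")

    @classmethod
    def spanning(
        cls, lo: float, hi: float, n_basis: int = 5, c: float = 1.0
    ) -> "RaisedCosineSpec":
        """Spec whose bumps tile ``[lo, hi]``: first peak at ``lo``, support of
        the last bump falling to zero at ``hi``.

        The log scaling packs the peaks toward small covariate values, giving
        fine resolution at early lags and broad, overlapping coverage at late
        lags; the upper end of the range sits on the decaying tail of the last
        bump.  The pi/2 peak spacing fixes the log-scaling rate
        ``a = ((n_basis-1)*pi/2 + pi) / (log(hi+c) - log(lo+c))``.
        """
        if not lo + c > 0 or not hi > lo:
            raise ValueError("need hi > lo and lo + c > 0")
        if n_basis < 2:
            raise ValueError("need at least 2 basis functions to span a range")
        span = (n_basis - 1) * _PHI_SPACING + np.pi
        a = span / (np.log(hi + c) - np.log(lo + c))
        phi0 = a * np.log(lo + c)
        phis = tuple(phi0 + j * _PHI_SPACING for j in range(n_basis))
        return cls(a=float(a), c=float(c), phis=phis)

    def evaluate(self, values) -> BasisMatrix:
        return raised_cosine_matrix(values, self)

    @property
    def evaluable_range(self) -> tuple[float, float]:
        # positivity of x + c is the only hard constraint
        return (-self.c, np.inf)


def raised_cosine_matrix(values, spec: RaisedCosineSpec) -> BasisMatrix:
    """Evaluate the raised-cosine basis at ``values`` (requires ``x + c > 0``)."""
    x = np.atleast_1d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("evaluation values must be finite")
    if np.any(x + spec.c <= 0):
        bad = x[x + spec.c <= 0][0]
        raise ValueError(f"value {bad!r} violates x + c > 0 (c = {spec.c})")
    z = spec.a * np.log(x + spec.c)
    phis = np.asarray(spec.phis)
    arg = z[:, None] - phis[None, :]
    out = np.where(np.abs(arg) <= np.pi, 0.5 * (1.0 + np.cos(arg)), 0.0)
    return BasisMatrix(values=x, matrix=out, column_labels=spec.phis)


@dataclass(frozen=True)
class PartitionSpec:
    """Indicator basis over the half-open partition induced by ``edges``.

    Interval ``j`` is ``[edges[j], edges[j+1])``; the final interval is
    closed at the top so the partition covers ``[edges[0], edges[-1]]``.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))
        arr = np.asarray(self.edges)
        if arr.size < 2:
            raise ValueError("need at least 2 edges")
        if not np.all(np.isfinite(arr)) or np.any(np.diff(arr) <= 0):
            raise ValueError("edges must be finite and strictly increasing")

    @classmethod
    def uniform(cls, lo: float, hi: float, n_bins: int) -> "PartitionSpec":
        return cls(tuple(np.linspace(lo, hi, n_bins + 1)))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def evaluable_range(self) -> tuple[float, float]:
        return self.edges[0], self.edges[-1]

    def evaluate(self, values) -> BasisMatrix:
        return indicator_matrix(values, self)


def indicator_matrix(values, spec: PartitionSpec) -> BasisMatrix:
    """One-hot rows: the column of the partition interval containing the value."""
    x = np.atleast_1d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("evaluation values must be finite")
    edges = np.asarray(spec.edges)
    if np.any(x < edges[0]) or np.any(x > edges[-1]):
        bad = x[(x < edges[0]) | (x > edges[-1])][0]
        raise ValueError(
            f"value {bad!r} outside the partition range [{edges[0]}, {edges[-1]}]"
        )
    idx = np.searchsorted(edges, x, side="right") - 1
    idx = np.clip(idx, 0, spec.n_bins - 1)  # top edge joins the last interval
    out = np.zeros((x.size, spec.n_bins))
    out[np.arange(x.size), idx] = 1.0
    labels = tuple(
        0.5 * (edges[j] + edges[j + 1]) for j in range(spec.n_bins)
    )
    return BasisMatrix(values=x, matrix=out, column_labels=labels)
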