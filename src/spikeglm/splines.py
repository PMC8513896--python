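"""Cardinal spline bases with a flat-derivative boundary modification.

A cardinal (Catmull-Rom-type) spline interpolates a set of control points
(knots) with piecewise cubic Hermite segments whose knot derivatives are set
from the neighbouring control points through a tension parameter ``s``.  The
value of the spline at any covariate value is therefore a *linear* combination
of the control-point parameters, which is what lets the spline act as a basis
for a GLM: each evaluation point yields one row of basis weights.

Two variants are provided:

``cardinal``
    The classical construction.  The first and last knot are "ghost" control
    points placed beyond the covariate range; they only pin down the boundary
    derivative and the spline is evaluable on ``[x_2, x_{n-1}]`` only.

``modified``
    The boundary segments are rebuilt under the assumption that the spline's
    derivative is exactly zero at the first and last knot.  No ghost knots are
    needed, the basis has two fewer dimensions, and the spline is evaluable on
    the full knot span ``[x_1, x_n]``.

All weight functions accept scalars or arrays for ``u`` and broadcast.

Note on spacing ratios: for a segment ``[x_i, x_{i+1}]`` the ratios are
``l1 = (x_{i+1}-x_{i-1})/(x_{i+1}-x_i)`` and ``l2 = (x_{i+2}-x_i)/(x_{i+1}-x_i)``
(so ``l = 2`` on a uniform grid), and the knot derivative is
``s*l1*(p_{i+1}-p_{i-1})``.  At ``s = 0.5`` on a uniform grid this differs from
the textbook Catmull-Rom derivative ``(p_{i+1}-p_{i-1})/2`` by the factor
``l``; the convention here is kept as-is and ``s`` is user-configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KnotGrid",
    "SegmentWeights",
    "BasisMatrix",
    "hermite_components",
    "interior_weights",
    "boundary_weights_first",
    "boundary_weights_last",
    "single_segment_weights",
    "build_basis_matrix",
]

#: tolerance for accepting u marginally outside [0, 1] from float round-off
_U_SLACK = 1e-12


def _check_u(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("local coordinate u must be finite")
    if np.any(u < -_U_SLACK) or np.any(u > 1.0 + _U_SLACK):
        raise ValueError(f"local coordinate u must lie in [0, 1]; got {u!r}")
    return np.clip(u, 0.0, 1.0)


def hermite_components(u):
    """Cubic Hermite blending polynomials ``(h00, h10, h01, h11)`` at ``u``.

    ``h00 = 2u^3 - 3u^2 + 1``, ``h10 = u^3 - 2u^2 + u``,
    ``h01 = -2u^3 + 3u^2``, ``h11 = u^3 - u^2``.

    A segment with endpoint values ``p0, p1`` and endpoint derivatives
    ``m0, m1`` (in local coordinates) is ``h00*p0 + h10*m0 + h01*p1 + h11*m1``.
    """
    u = _check_u(u)
    u2 = u * u
    u3 = u2 * u
    h00 = 2.0 * u3 - 3.0 * u2 + 1.0
    h10 = u3 - 2.0 * u2 + u
    h01 = -2.0 * u3 + 3.0 * u2
    h11 = u3 - u2
    return h00, h10, h01, h11


def _check_finite(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite; got {value!r}")


def interior_weights(u, s, l1, l2):
    """Weights on ``(p_{i-1}, p_i, p_{i+1}, p_{i+2})`` for an interior segment.

    The segment satisfies ``S(0) = p_i``, ``S(1) = p_{i+1}``,
    ``S'(0) = s*l1*(p_{i+1} - p_{i-1})`` and ``S'(1) = s*l2*(p_{i+2} - p_i)``.
    Returns an array of shape ``u.shape + (4,)``; the weights sum to 1.
    """
    _check_finite(s=s, l1=l1, l2=l2)
    h00, h10, h01, h11 = hermite_components(u)
    w = np.stack(
        [
            -s * l1 * h10,
            h00 - s * l2 * h11,
            h01 + s * l1 * h10,
            s * l2 * h11,
        ],
        axis=-1,
    )
    return w


def boundary_weights_first(u, s, lb):
    """Weights on ``(p_1, p_2, p_3)`` for the flat-start boundary segment.

    The segment satisfies ``S(0) = p_1``, ``S(1) = p_2``, ``S'(0) = 0`` and
    ``S'(1) = s*lb*(p_3 - p_1)``.
    """
    _check_finite(s=s, lb=lb)
    u = _check_u(u)
    u2 = u * u
    u3 = u2 * u
    slb = s * lb
    w = np.stack(
        [
            (2.0 - slb) * u3 + (slb - 3.0) * u2 + 1.0,
            -2.0 * u3 + 3.0 * u2,
            slb * (u3 - u2),
        ],
        axis=-1,
    )
    return w


def boundary_weights_last(u, s, le):
    """Weights on ``(p_{n-2}, p_{n-1}, p_n)`` for the flat-end boundary segment.

    The segment satisfies ``S(0) = p_{n-1}``, ``S(1) = p_n``,
    ``S'(0) = s*le*(p_n - p_{n-2})`` and ``S'(1) = 0``.
    """
    _check_finite(s=s, le=le)
    u = _check_u(u)
    u2 = u * u
    u3 = u2 * u
    sle = s * le
    w = np.stack(
        [
            -sle * (u3 - 2.0 * u2 + u),
            2.0 * u3 - 3.0 * u2 + 1.0,
            (sle - 2.0) * u3 + (3.0 - 2.0 * sle) * u2 + sle * u,
        ],
        axis=-1,
    )
    return w


def single_segment_weights(u):
    """Weights on ``(p_1, p_2)`` for a two-knot spline with flat ends.

    The single segment satisfies ``S(0) = p_1``, ``S(1) = p_2`` and
    ``S'(0) = S'(1) = 0`` (a smoothstep between the two control values).
    """
    u = _check_u(u)
    u2 = u * u
    u3 = u2 * u
    return np.stack([2.0 * u3 - 3.0 * u2 + 1.0, -2.0 * u3 + 3.0 * u2], axis=-1)


@dataclass(frozen=True)
class SegmentWeights:
    """Basis weights at one local coordinate, tagged with control-point columns."""

    u: float
    weights: np.ndarray
    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.columns):
            raise ValueError("weights and columns must have equal length")


@dataclass(frozen=True)
class KnotGrid:
    """Ordered spline control-point locations with tension.

    Parameters
    ----------
    locations
        Strictly increasing knot locations in covariate units.  For the
        ``cardinal`` variant this includes the two ghost knots (use
        :meth:`cardinal_with_ghosts` to append them automatically).
    tension
        Positive tension parameter ``s`` scaling the knot derivatives.
    variant
        ``"modified"`` (flat boundary derivative, no ghosts, default) or
        ``"cardinal"`` (classical, first/last knots are ghosts).
    """

    locations: tuple[float, ...]
    tension: float = 0.5
    variant: str = "modified"

    def __post_init__(self) -> None:
        loc = tuple(float(x) for x in np.asarray(self.locations, dtype=float))
        object.__setattr__(self, "locations", loc)
        arr = np.asarray(loc)
        if not np.all(np.isfinite(arr)):
            raise ValueError("knot locations must be finite")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("knot locations must be strictly increasing")
        if self.variant not in ("modified", "cardinal"):
            raise ValueError(f"unknown variant {self.variant!r}")
        min_n = 2 if self.variant == "modified" else 4
        if len(loc) < min_n:
            raise ValueError(
                f"variant={self.variant!r} requires at least {min_n} knots; got {len(loc)}"
            )
        if not (np.isfinite(self.tension) and self.tension > 0):
            raise ValueError("tension must be a positive finite number")

    @classmethod
    def cardinal_with_ghosts(
        cls, locations: Sequence[float], tension: float = 0.5
    ) -> "KnotGrid":
        """Cardinal grid with ghost knots auto-placed beyond the extremes.

        The ghosts sit one adjacent-knot spacing beyond the first and last
        user knot, so an n-knot user grid yields an (n+2)-column basis.
        """
        loc = np.asarray(locations, dtype=float)
        if loc.size < 2:
            raise ValueError("need at least 2 knots to place ghosts")
        ghosted = np.concatenate(
            [[loc[0] - (loc[1] - loc[0])], loc, [loc[-1] + (loc[-1] - loc[-2])]]
        )
        return cls(tuple(ghosted), tension=tension, variant="cardinal")

    @property
    def n(self) -> int:
        return len(self.locations)

    @property
    def evaluable_range(self) -> tuple[float, float]:
        """Covariate interval on which the basis is defined."""
        loc = self.locations
        if self.variant == "modified":
            return loc[0], loc[-1]
        return loc[1], loc[-2]

    def segment_weights(self, index: int, u) -> SegmentWeights:
        """Weights for segment ``[x_index, x_index+1]`` (0-based) at ``u``."""
        w, cols = _segment_weights_raw(self, index, u)
        return SegmentWeights(u=float(u), weights=np.asarray(w), columns=cols)

    def evaluate(self, values, out_of_range: str = "raise") -> "BasisMatrix":
        """Basis matrix at ``values``; see :func:`build_basis_matrix`."""
        return build_basis_matrix(values, self, out_of_range=out_of_range)


def _segment_weights_raw(grid: KnotGrid, index: int, u):
    """Weights and 0-based column indices for one segment of ``grid``."""
    loc = np.asarray(grid.locations)
    n = grid.n
    s = grid.tension
    d = loc[index + 1] - loc[index]
    if grid.variant == "modified":
        if n == 2:
            return single_segment_weights(u), (0, 1)
        if index == 0:
            lb = (loc[2] - loc[0]) / d
            return boundary_weights_first(u, s, lb), (0, 1, 2)
        if index == n - 2:
            le = (loc[n - 1] - loc[n - 3]) / d
            return boundary_weights_last(u, s, le), (n - 3, n - 2, n - 1)
    else:
        if index < 1 or index > n - 3:
            raise ValueError(
                f"cardinal segment index must be in [1, {n - 3}]; got {index}"
            )
    l1 = (loc[index + 1] - loc[index - 1]) / d
    l2 = (loc[index + 2] - loc[index]) / d
    return interior_weights(u, s, l1, l2), (index - 1, index, index + 1, index + 2)


@dataclass
class BasisMatrix:
    """Evaluation points x basis-function weight matrix.

    For spline and indicator bases every row sums to 1 (partition of unity)
    and a row at an interior knot location is one-hot for that knot's column.
    """

    values: np.ndarray
    matrix: np.ndarray
    column_labels: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.values.size, len(self.column_labels)):
            raise ValueError("matrix shape inconsistent with values/labels")

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[1]


def build_basis_matrix(
    values, grid: KnotGrid, out_of_range: str = "raise"
) -> BasisMatrix:
    """Evaluate the spline basis at ``values``.

    Each row carries the segment weights in the columns of that segment's
    control points and zeros elsewhere.  Segment membership uses half-open
    intervals ``[x_i, x_{i+1})``, except that the maximum of the evaluable
    range belongs to the final segment.

    Parameters
    ----------
    values
        Covariate values; must lie within ``grid.evaluable_range`` unless
        ``out_of_range="clamp"``, which maps stragglers to the nearest
        endpoint and logs how many were clamped.
    """
    x = np.atleast_1d(np.asarray(values, dtype=float))
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("evaluation values must be finite")
    lo, hi = grid.evaluable_range
    outside = (x < lo) | (x > hi)
    if np.any(outside):
        if out_of_range == "clamp":
            logger.warning(
                "clamped %d of %d values to the evaluable range [%g, %g]",
                int(outside.sum()), x.size, lo, hi,
            )
            x = np.clip(x, lo, hi)
        else:
            bad = x[outside][0]
            raise ValueError(
                f"value {bad!r} outside the evaluable range [{lo}, {hi}] "
                f"of the {grid.variant} spline basis"
            )

    loc = np.asarray(grid.locations)
    n = grid.n
    first_seg = 0 if grid.variant == "modified" else 1
    last_seg = n - 2 if grid.variant == "modified" else n - 3
    seg = np.searchsorted(loc, x, side="right") - 1
    seg = np.clip(seg, first_seg, last_seg)

    out = np.zeros((x.size, n))
    for index in np.unique(seg):
        mask = seg == index
        d = loc[index + 1] - loc[index]
        u = (x[mask] - loc[index]) / d
        w, cols = _segment_weights_raw(grid, int(index), u)
        out[np.ix_(mask, cols)] = w
    return BasisMatrix(values=x, matrix=out, column_labels=grid.locations)
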