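"""Poisson point-process GLM fitting by IRLS.

Counts binned at width ``delta`` are modeled as Poisson with mean
``mu_t = exp(x_t' theta + offset)``; the default offset ``log(delta)`` puts
the exponentiated coefficients on a per-second intensity scale.  The Poisson
log link makes the log-likelihood concave, so the Newton/IRLS iteration with
step-halving converges to the global maximum.  Uncertainty comes from the
observed Fisher information ``X' W X`` with ``W = diag(mu)`` at the optimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .design import Design, SpikeTrain

logger = logging.getLogger(__name__)

__all__ = [
    "GLMFit",
    "IntensityCurve",
    "fit_irls",
    "param_ci",
    "intensity_curve",
    "detect_separation",
    "time_rescaling_ks",
    "KSResult",
]

#: |coefficient| beyond which a column is treated as numerically divergent
SEPARATION_BOUND = 15.0

_ETA_MAX = 500.0  # guard exp overflow during line search on wild steps


@dataclass
class GLMFit:
    """Maximum-likelihood fit of the Poisson point-process GLM."""

    coef: np.ndarray
    fisher: np.ndarray
    cov: np.ndarray
    loglik: float
    deviance: float
    aic: float
    n_iter: int
    converged: bool
    separated: np.ndarray
    labels: tuple[str, ...]
    blocks: dict = field(default_factory=dict)
    offset: float = 0.0
    bin_width: float | None = None
    fitted_mu: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.coef.size

    def block_slice(self, name: str) -> slice:
        return self.blocks[name][0]

    def block_spec(self, name: str):
        return self.blocks[name][1]


def _poisson_loglik(y, eta, log_yfact):
    mu = np.exp(np.minimum(eta, _ETA_MAX))
    return float(y @ eta - mu.sum() - log_yfact)


def _deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * (term.sum() - (y - mu).sum()))


def fit_irls(
    design,
    counts,
    offset: float | np.ndarray | None = None,
    max_iter: int = 100,
    tol_coef: float = 1e-8,
    tol_loglik: float = 1e-10,
    ridge: float = 1e-8,
    theta_init: np.ndarray | None = None,
) -> GLMFit:
    """Fit the Poisson GLM by iteratively re-weighted least squares.

    Parameters
    ----------
    design
        A :class:`~spikeglm.design.Design` or a plain 2-D array.
    counts
        A :class:`~spikeglm.design.SpikeTrain` or integer array of bin counts.
    offset
        Log-exposure per bin.  Defaults to ``log(bin_width)`` when ``counts``
        is a SpikeTrain (per-second coefficient scale), otherwise 0.

    Notes
    -----
    Starts at ``theta = 0`` and takes damped Newton steps (step-halving
    whenever the log-likelihood would decrease, so the deviance never
    increases across accepted iterations).  If the normal equations are
    singular a ridge jitter is added with a logged notice.  Non-convergence
    returns a fit with ``converged=False`` and a warning rather than raising:
    complete separation legitimately pushes coefficients toward -inf and is
    reported through the ``separated`` flags instead.
    """
    if isinstance(design, Design):
        X = design.matrix
        labels = design.labels
        blocks = design.blocks
    else:
        X = np.asarray(design, dtype=float)
        labels = tuple(f"x{j}" for j in range(X.shape[1]))
        blocks = {}
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix must be finite")

    bin_width = None
    if isinstance(counts, SpikeTrain):
        bin_width = counts.bin_width
        y = counts.counts.astype(float)
    else:
        y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    if offset is None:
        offset = np.log(bin_width) if bin_width is not None else 0.0
    off = np.broadcast_to(np.asarray(offset, dtype=float), y.shape)

    n, p = X.shape
    if y.size != n:
        raise ValueError("counts length must match design rows")
    log_yfact = float(gammaln(y + 1.0).sum())

    theta = np.zeros(p) if theta_init is None else np.asarray(theta_init, float).copy()
    if theta.shape != (p,):
        raise ValueError("theta_init has the wrong length")
    eta = X @ theta + off
    ll = _poisson_loglik(y, eta, log_yfact)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(np.minimum(eta, _ETA_MAX))
        grad = X.T @ (y - mu)
        H = X.T @ (X * mu[:, None])
        try:
            delta = np.linalg.solve(H, grad)
            if not np.all(np.isfinite(delta)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            jitter = ridge * max(float(np.trace(H)) / max(p, 1), 1.0)
            logger.info("singular IRLS step; adding ridge jitter %.3g", jitter)
            delta = np.linalg.solve(H + jitter * np.eye(p), grad)
        # damped Newton: halve the step until the log-likelihood improves
        step = 1.0
        for _ in range(60):
            theta_new = theta + step * delta
            eta_new = X @ theta_new + off
            ll_new = _poisson_loglik(y, eta_new, log_yfact)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:  # pragma: no cover - pathological
            theta_new, eta_new, ll_new = theta, eta, ll
        max_change = float(np.max(np.abs(theta_new - theta))) if p else 0.0
        rel_ll = abs(ll_new - ll) / max(abs(ll), 1.0)
        theta, eta, ll_prev, ll = theta_new, eta_new, ll, ll_new
        if max_change < tol_coef or rel_ll < tol_loglik:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last max coefficient change {max_change:.3g})",
            UserWarning,
            stacklevel=2,
        )

    mu = np.exp(np.minimum(eta, _ETA_MAX))
    fisher = X.T @ (X * mu[:, None])
    separated = detect_separation(X, y, theta)
    cov = _covariance(fisher, separated)
    deviance = _deviance(y, mu)
    aic = -2.0 * ll + 2.0 * p
    logger.info(
        "IRLS: %d bins, %d spikes, %d columns, %d iterations, converged=%s, "
        "%d separated columns",
        n, int(y.sum()), p, it, converged, int(separated.sum()),
    )
    return GLMFit(
        coef=theta,
        fisher=fisher,
        cov=cov,
        loglik=ll,
        deviance=deviance,
        aic=aic,
        n_iter=it,
        converged=converged,
        separated=separated,
        labels=labels,
        blocks=blocks,
        offset=float(np.mean(off)),
        bin_width=bin_width,
        fitted_mu=mu,
    )


def _covariance(fisher: np.ndarray, separated: np.ndarray) -> np.ndarray:
    """Invert the Fisher information on the non-flagged subspace.

    Flagged columns get infinite variance (zero covariance with the rest)
    rather than raising: separation produces flat likelihood directions whose
    uncertainty is genuinely unbounded.
    """
    p = fisher.shape[0]
    cov = np.zeros((p, p))
    keep = ~separated
    if keep.any():
        sub = fisher[np.ix_(keep, keep)]
        try:
            sub_inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            logger.info("singular Fisher information; using pseudo-inverse")
            sub_inv = np.linalg.pinv(sub)
        cov[np.ix_(keep, keep)] = sub_inv
    cov[np.diag_indices(p)] = np.where(separated, np.inf, np.diag(cov))
    return cov


def detect_separation(
    X: np.ndarray,
    y: np.ndarray,
    coef: np.ndarray,
    bound: float = SEPARATION_BOUND,
    support_tol: float = 1e-8,
) -> np.ndarray:
    """Flag design columns subject to perfect prediction / complete separation.

    A column is flagged when its support (rows where it is materially
    nonzero) contains zero spikes — the MLE for its coefficient diverges to
    -inf — or when the fitted coefficient magnitude exceeds ``bound`` on the
    log scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scale = np.maximum(np.max(np.abs(X), axis=0), 1e-300)
    support = np.abs(X) > support_tol * scale[None, :]
    spikes_on_support = support.T @ (y > 0)
    flags = spikes_on_support == 0
    flags |= np.abs(np.asarray(coef, dtype=float)) > bound
    return flags


def param_ci(fit: GLMFit, level: float = 0.95):
    """Wald confidence intervals per coefficient, log and exponentiated scales.

    Returns a pandas DataFrame with one row per design column.  Separated
    columns get infinite-width intervals rather than raising.
    """
    import pandas as pd

    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    var = np.diag(fit.cov).copy()
    se = np.sqrt(np.maximum(var, 0.0))
    lo = fit.coef - z * se
    hi = fit.coef + z * se
    lo = np.where(fit.separated, -np.inf, lo)
    hi = np.where(fit.separated, np.inf, hi)
    return pd.DataFrame(
        {
            "label": list(fit.labels),
            "coef": fit.coef,
            "se": se,
            "lo": lo,
            "hi": hi,
            "rate": np.exp(fit.coef),
            "rate_lo": np.exp(lo),
            "rate_hi": np.exp(hi),
            "separated": fit.separated,
        }
    )


@dataclass
class IntensityCurve:
    """Pointwise estimate and Wald bounds of one block's modulation curve."""

    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def intensity_curve(
    fit: GLMFit, block: str, grid, level: float = 0.95
) -> IntensityCurve:
    """Exponentiated modulation curve of one design block with Wald bounds.

    At each grid point with basis row ``x`` the estimate is
    ``exp(x' theta_block)`` and the bounds are
    ``exp(x' theta_block +- z*sqrt(x' Sigma_block x))`` using the block's full
    sub-covariance (off-diagonal terms included); other blocks contribute
    nothing.  Grid points whose basis row touches a separated column get
    ``(0, inf)`` bounds.
    """
    if block not in fit.blocks:
        raise KeyError(f"fit has no block named {block!r}")
    sl = fit.block_slice(block)
    spec = fit.block_spec(block)
    if spec is None:
        raise ValueError(f"block {block!r} has no stored basis spec")
    basis = spec.evaluate(np.asarray(grid, dtype=float))
    B = basis.matrix
    theta = fit.coef[sl]
    cov = fit.cov[sl, sl]
    flagged = fit.separated[sl]
    z = norm.ppf(0.5 + level / 2.0)

    eta = B @ theta
    keep = ~flagged
    var = np.einsum(
        "ij,jk,ik->i", B[:, keep], cov[np.ix_(keep, keep)], B[:, keep]
    )
    se = np.sqrt(np.maximum(var, 0.0))
    lower = np.exp(eta - z * se)
    upper = np.exp(eta + z * se)
    touches = np.abs(B[:, flagged]).sum(axis=1) > 1e-12 if flagged.any() else None
    if touches is not None and touches.any():
        lower = np.where(touches, 0.0, lower)
        upper = np.where(touches, np.inf, upper)
    return IntensityCurve(
        grid=basis.values, estimate=np.exp(eta), lower=lower, upper=upper, level=level
    )


@dataclass
class KSResult:
    """Kolmogorov-Smirnov summary of time-rescaled inter-spike intervals."""

    statistic: float
    band: float
    n_isi: int
    rescaled: np.ndarray

    @property
    def within_band(self) -> bool:
        return self.statistic <= self.band


def time_rescaling_ks(fit: GLMFit, counts=None) -> KSResult:
    """Time-rescaling goodness-of-fit via the KS distance to Uniform(0, 1).

    Each inter-spike interval is rescaled by the integrated fitted intensity
    ``z_k = sum mu_t`` over the bins since the previous spike; under a correct
    model ``1 - exp(-z_k)`` is Uniform(0, 1).  The 95% acceptance band is
    ``1.36 / sqrt(#ISIs)``.
    """
    if fit.fitted_mu is None:
        raise ValueError("fit has no stored per-bin intensities")
    if counts is None:
        raise ValueError("counts are required to locate spikes")
    y = counts.counts if isinstance(counts, SpikeTrain) else np.asarray(counts)
    spike_bins = np.flatnonzero(y > 0)
    if spike_bins.size < 2:
        raise ValueError("need at least 2 spikes for rescaled intervals")
    cum = np.concatenate([[0.0], np.cumsum(fit.fitted_mu)])
    # integrated intensity from just after the previous spike bin through this one
    z = cum[spike_bins[1:] + 1] - cum[spike_bins[:-1] + 1]
    u = np.sort(1.0 - np.exp(-z))
    n = u.size
    k = np.arange(1, n + 1)
    stat = float(np.max(np.maximum(k / n - u, u - (k - 1) / n)))
    return KSResult(statistic=stat, band=1.36 / np.sqrt(n), n_isi=n, rescaled=u)
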