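import numpy as np
import pytest

from spikeglm import SimConfig, simulate_session
from spikeglm.pipeline import fit_session


@pytest.fixture(scope="session")
def short_session():
    """One 120 s synthetic session with default ground truth."""
    return simulate_session(SimConfig(seed=101, duration=120.0))


@pytest.fixture(scope="session")
def short_fit(short_session):
    """Modified-spline spatial + history fit of the short session."""
    cfg = short_session.config
    fit, design = fit_session(
        short_session.counts,
        short_session.positions,
        cfg.spatial_grid(),
        cfg.history_grid(),
    )
    return fit, design


def random_knot_grid(rng, n_knots, variant="modified", uniform=False):
    """Random strictly-increasing knot grid with random tension.

    With ``uniform=True`` the spacing is constant (random magnitude): the
    construction's knot derivatives are segment-local, so C1 continuity only
    holds exactly on uniformly spaced grids.
    """
    from spikeglm import KnotGrid

    start = rng.uniform(-5, 5)
    if uniform:
        spacings = np.full(n_knots - 1, rng.uniform(0.3, 3.0))
    else:
        spacings = rng.uniform(0.3, 3.0, size=n_knots - 1)
    locations = start + np.concatenate([[0.0], np.cumsum(spacings)])
    tension = rng.uniform(0.1, 1.5)
    return KnotGrid(tuple(locations), tension=tension, variant=variant)
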