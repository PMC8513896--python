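"""Convenience wiring from raw session data to a fitted place + history model."""

from __future__ import annotations

import numpy as np

from .design import (
    Design,
    PositionTrace,
    SpikeTrain,
    assemble_design,
    history_block_from_spec,
    spatial_block,
)
from .fit import GLMFit, fit_irls

__all__ = ["build_session_design", "fit_session"]


def build_session_design(
    train: SpikeTrain,
    pos: PositionTrace,
    spatial_spec,
    history_spec,
    history_length_ms: float = 200.0,
    out_of_range: str = "raise",
) -> Design:
    """Assemble the spatial + spike-history design for one session."""
    blocks = [
        spatial_block(pos, spatial_spec, out_of_range=out_of_range),
        history_block_from_spec(train, history_spec, history_length_ms),
    ]
    return assemble_design(blocks)


def fit_session(
    train: SpikeTrain,
    pos: PositionTrace,
    spatial_spec,
    history_spec,
    history_length_ms: float = 200.0,
    out_of_range: str = "raise",
    **fit_kwargs,
) -> tuple[GLMFit, Design]:
    """Build the session design and fit the Poisson GLM; returns (fit, design)."""
    design = build_session_design(
        train, pos, spatial_spec, history_spec, history_length_ms, out_of_range
    )
    fit = fit_irls(design, train, **fit_kwargs)
    return fit, design
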