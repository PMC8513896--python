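"""Delimited-text and JSON readers/writers for sessions, models, and reports.

Spike times are a single-column CSV (seconds, header row); positions are a
two-column CSV (``time_s, position_cm``).  Fitted models round-trip through a
JSON document that stores coefficients, covariance, labels, basis specs, and
convergence metadata, so curves and diagnostics can be recomputed later.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .bases import PartitionSpec, RaisedCosineSpec
from .fit import GLMFit, IntensityCurve
from .splines import KnotGrid

__all__ = [
    "read_spike_times",
    "read_positions",
    "write_spike_times",
    "write_positions",
    "write_curve",
    "read_curve",
    "model_to_dict",
    "model_from_dict",
    "write_model_json",
    "read_model_json",
    "load_config",
]


def _parse_numeric_rows(path, n_cols: int):
    """Parse a delimited text file of floats, reporting bad rows by line number."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1:
                try:
                    [float(p) for p in parts]
                except ValueError:
                    continue  # header row
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})")
    return np.asarray(rows, dtype=float).reshape(-1, n_cols)


def read_spike_times(path) -> np.ndarray:
    """Read spike times (seconds) from a one-column CSV with header."""
    return _parse_numeric_rows(path, 1)[:, 0]


def read_positions(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a position trace CSV (``time_s, position_cm``)."""
    arr = _parse_numeric_rows(path, 2)
    return arr[:, 0], arr[:, 1]


def write_spike_times(path, spike_times) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("spike_time_s\n")
        for t in np.asarray(spike_times, dtype=float):
            fh.write(f"{t:.6f}\n")


def write_positions(path, times, positions) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,position_cm\n")
        for t, x in zip(np.asarray(times, float), np.asarray(positions, float)):
            fh.write(f"{t:.6f},{x:.6f}\n")


def write_curve(path, curve: IntensityCurve) -> None:
    """Write an intensity curve as CSV (grid, estimate, lower, upper)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("grid,estimate,lower,upper\n")
        for g, e, lo, hi in zip(curve.grid, curve.estimate, curve.lower, curve.upper):
            fh.write(f"{float(g)!r},{float(e)!r},{float(lo)!r},{float(hi)!r}\n")


def read_curve(path) -> IntensityCurve:
    arr = _parse_numeric_rows(path, 4)
    return IntensityCurve(
        grid=arr[:, 0], estimate=arr[:, 1], lower=arr[:, 2], upper=arr[:, 3],
        level=float("nan"),
    )


def _spec_to_dict(spec) -> dict | None:
    if spec is None:
        return None
    if isinstance(spec, KnotGrid):
        return {
            "type": "knot_grid",
            "locations": list(spec.locations),
            "tension": spec.tension,
            "variant": spec.variant,
        }
    if isinstance(spec, RaisedCosineSpec):
        return {"type": "raised_cosine", "a": spec.a, "c": spec.c, "phis": list(spec.phis)}
    if isinstance(spec, PartitionSpec):
        return {"type": "partition", "edges": list(spec.edges)}
    raise TypeError(f"cannot serialize basis spec of type {type(spec)!r}")


def _spec_from_dict(d: dict | None):
    if d is None:
        return None
    kind = d["type"]
    if kind == "knot_grid":
        return KnotGrid(tuple(d["locations"]), tension=d["tension"], variant=d["variant"])
    if kind == "raised_cosine":
        return RaisedCosineSpec(a=d["a"], c=d["c"], phis=tuple(d["phis"]))
    if kind == "partition":
        return PartitionSpec(tuple(d["edges"]))
    raise ValueError(f"unknown basis spec type {kind!r}")


def model_to_dict(fit: GLMFit, config: dict | None = None) -> dict:
    """Serializable model dump (excludes the per-bin fitted intensities)."""
    cov = np.where(np.isfinite(fit.cov), fit.cov, None)  # JSON has no inf
    return {
        "coefficients": fit.coef.tolist(),
        "labels": list(fit.labels),
        "covariance": [[None if v is None else float(v) for v in row] for row in cov.tolist()],
        "fisher": fit.fisher.tolist(),
        "separated": fit.separated.astype(bool).tolist(),
        "loglik": fit.loglik,
        "deviance": fit.deviance,
        "aic": fit.aic,
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "offset": fit.offset,
        "bin_width": fit.bin_width,
        "blocks": {
            name: {
                "start": sl.start,
                "stop": sl.stop,
                "spec": _spec_to_dict(spec),
            }
            for name, (sl, spec) in fit.blocks.items()
        },
        "config": config or {},
    }


def model_from_dict(d: dict) -> GLMFit:
    cov = np.asarray(
        [[np.inf if v is None else v for v in row] for row in d["covariance"]],
        dtype=float,
    )
    blocks = {
        name: (slice(b["start"], b["stop"]), _spec_from_dict(b["spec"]))
        for name, b in d["blocks"].items()
    }
    return GLMFit(
        coef=np.asarray(d["coefficients"], dtype=float),
        fisher=np.asarray(d["fisher"], dtype=float),
        cov=cov,
        loglik=d["loglik"],
        deviance=d["deviance"],
        aic=d["aic"],
        n_iter=d["n_iter"],
        converged=d["converged"],
        separated=np.asarray(d["separated"], dtype=bool),
        labels=tuple(d["labels"]),
        blocks=blocks,
        offset=d["offset"],
        bin_width=d["bin_width"],
    )


def write_model_json(path, fit: GLMFit, config: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(fit, config), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_json(path) -> GLMFit:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def load_config(path) -> dict:
    """Load a YAML or JSON run-configuration file."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return out
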