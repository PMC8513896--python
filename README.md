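# spikeglm

Point-process GLM regression for neural spike trains, built around cardinal
spline bases with a flat-derivative boundary modification.

When the signals that drive spiking are bounded — a position on a finite
track, or the lag since the last spike (bounded below by 0) — standard
cardinal splines need ghost control points beyond the bounds to pin down the
boundary derivative. Those extra parameters see very little data, which
inflates confidence intervals at the boundary and can destabilize fits.
`spikeglm` provides a modified basis whose boundary segments assume a zero
derivative at the first and last knot: two fewer parameters, the same interior
segments, and well-behaved uncertainty at the bounds.

The package contains:

- **`spikeglm.splines`** — cardinal and modified cardinal spline bases
  (`KnotGrid`, `build_basis_matrix`). Closed-form segment weights expose the
  spline value at any covariate value as a linear combination of the
  control-point parameters.
- **`spikeglm.bases`** — raised-cosine (log-scaled time axis) and indicator
  comparison bases under the same `BasisMatrix` contract.
- **`spikeglm.design`** — spike binning, position resampling, spike-history
  convolution and design assembly for models of the form
  `log λ(t) = spatial(position_t) + Σ_ℓ f(ℓ)·ΔN(t−ℓ)`.
- **`spikeglm.fit`** — Poisson maximum likelihood by damped IRLS with the
  observed Fisher information, Wald intervals, modulation curves with full
  covariance propagation, perfect-prediction (complete separation) detection,
  and time-rescaling KS goodness-of-fit.
- **`spikeglm.diagnostics`** — the confidence-interval width ratio (CIWR:
  endpoint interval width over mean interior width), parameter correlation
  matrices, occupancy-normalized rate maps, spike autocorrelation and ISI
  histograms.
- **`spikeglm.simulate`** — a synthetic place-cell session generator
  (Gaussian spatial tuning on a bounded track, refractory/bursting history
  kernel, thinning-valid Bernoulli sampling) plus a population experiment that
  compares CIWR distributions across basis families.

## CLI

```sh
# write a synthetic session (spikes.csv, positions.csv, ground_truth.json)
spikeglm simulate --out session/ --seed 1 --duration 600

# fit the spatial + spike-history model; writes model.json, curve tables,
# CIWR report, parameter correlations and a KS goodness-of-fit summary
spikeglm fit --spikes session/spikes.csv --positions session/positions.csv \
    --out fit/ --history-basis modified

# recompute the CIWR report from the stored history curve
spikeglm ciwr --model fit/model.json

# time-rescaling goodness-of-fit of a stored model against data
spikeglm gof --model fit/model.json --spikes session/spikes.csv \
    --positions session/positions.csv
```

Every flag can also be supplied through `--config config.yaml` (file values
override flags). Basis families for either block: `modified`, `cardinal`
(ghost knots auto-placed one spacing beyond the extremes), `cosine`,
`indicator`.

## Notes

- Spacing ratios follow the printed convention `l = (wider span)/(segment
  span)` with tension `s` (default 0.5). Under this convention the knot
  derivatives are segment-local, so the spline is exactly C1 only on
  uniformly spaced knot grids; on non-uniform grids (e.g. the default history
  knots {1, 10, 40, 100, 200} ms) adjacent segments share the knot value but
  not the exact derivative.
- Out-of-range covariate values raise by default; pass
  `out_of_range="clamp"` (CLI: `--clamp`) to map them to the nearest basis
  endpoint with a logged count.
- Separated (perfect-prediction) columns are reported with infinite-width
  intervals rather than aborting the fit.
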