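"""Bivariate product-Gaussian kernel density estimation on the MA plane.

The density field is the engine behind both normalizers: a probe sitting in
the dense cluster of null genes receives a high estimated density, a probe
belonging to a (sparser) differentially expressed group a low one.  KDL
raises the density to a power ("multiplicity", default 4) and uses it as a
loess prior weight; KDQ ranks probes by density to select an invariant set.

The estimator is the plain product kernel

    f̂(x, y) = 1/(n·h_A·h_M) · Σ_i φ((x − A_i)/h_A) · φ((y − M_i)/h_M)

with φ the standard univariate normal pdf and independent bandwidths per
margin (no cross term).  Bandwidths default to the two-dimensional
normal-reference (Scott) rule per margin, h = σ̂ · n^(−1/6) with σ̂ the
sample standard deviation.  Evaluation is exact by default; a linear-binned
grid fast path (:func:`kde2d_grid`) is provided for large inputs and agrees
with exact evaluation to ~1e-3 relative error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MAProjection

_TWO_PI = 2.0 * np.pi


def normal_reference_bandwidth(values) -> float:
    """Scott's rule for a 2-D product kernel, applied per margin.

    h = σ̂ · n^(−1/6), σ̂ the sample standard deviation (ddof=1).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("bandwidth selection needs at least 2 one-dimensional values")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError("constant input: normal-reference bandwidth would be 0")
    return float(sd * len(v) ** (-1.0 / 6.0))


def _check_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (a, m) pairs")
    if pts.shape[0] < 1:
        raise ValueError("need at least one sample point")
    return pts


def kde2d(points, bandwidths, eval_points=None, chunk_size: int = 1024) -> np.ndarray:
    """Exact product-Gaussian KDE evaluated at ``eval_points``.

    Parameters
    ----------
    points
        (n, 2) sample of (A, M) pairs.
    bandwidths
        Pair (h_A, h_M) of positive reals.
    eval_points
        (k, 2) evaluation points; defaults to the sample itself.
    chunk_size
        Evaluation points are processed in blocks of this size so that
        the pairwise kernel matrix never exceeds O(chunk_size · n) memory.
    """
    pts = _check_points(points)
    h_a, h_m = (float(bandwidths[0]), float(bandwidths[1]))
    if h_a <= 0 or h_m <= 0:
        raise ValueError(f"bandwidths must be positive, got ({h_a}, {h_m})")
    ev = pts if eval_points is None else _check_points(eval_points)

    n = pts.shape[0]
    a, m = pts[:, 0], pts[:, 1]
    out = np.empty(ev.shape[0], dtype=float)
    norm = 1.0 / (n * h_a * h_m * _TWO_PI)
    for start in range(0, ev.shape[0], chunk_size):
        block = ev[start : start + chunk_size]
        za = (block[:, 0][:, None] - a[None, :]) / h_a
        zm = (block[:, 1][:, None] - m[None, :]) / h_m
        out[start : start + chunk_size] = (
            np.exp(-0.5 * (za * za + zm * zm)).sum(axis=1) * norm
        )
    return out


def kde2d_grid(
    points,
    bandwidths,
    eval_points=None,
    grid_size: int = 1024,
) -> np.ndarray:
    """Fast approximate KDE: linear binning + separable Gaussian smoothing.

    Samples are spread onto a ``grid_size`` × ``grid_size`` mesh with
    bilinear weights, smoothed by a discrete Gaussian with the requested
    bandwidths (in pixel units), and read back at the evaluation points by
    bilinear interpolation.  Agrees with :func:`kde2d` to roughly 1e-3
    relative error for n up to several thousand; intended as an opt-in fast
    path, never the default.
    """
    pts = _check_points(points)
    h_a, h_m = (float(bandwidths[0]), float(bandwidths[1]))
    if h_a <= 0 or h_m <= 0:
        raise ValueError(f"bandwidths must be positive, got ({h_a}, {h_m})")
    ev = pts if eval_points is None else _check_points(eval_points)

    pad = 5.0
    lo = pts.min(axis=0) - pad * np.array([h_a, h_m])
    hi = pts.max(axis=0) + pad * np.array([h_a, h_m])
    span = np.maximum(hi - lo, 1e-12)
    step = span / (grid_size - 1)

    # bilinear ("linear") binning of the sample counts
    grid = np.zeros((grid_size, grid_size), dtype=float)
    gx = (pts[:, 0] - lo[0]) / step[0]
    gy = (pts[:, 1] - lo[1]) / step[1]
    ix = np.clip(gx.astype(int), 0, grid_size - 2)
    iy = np.clip(gy.astype(int), 0, grid_size - 2)
    fx = gx - ix
    fy = gy - iy
    np.add.at(grid, (ix, iy), (1 - fx) * (1 - fy))
    np.add.at(grid, (ix + 1, iy), fx * (1 - fy))
    np.add.at(grid, (ix, iy + 1), (1 - fx) * fy)
    np.add.at(grid, (ix + 1, iy + 1), fx * fy)

    sigma = (h_a / step[0], h_m / step[1])
    smooth = ndimage.gaussian_filter(grid, sigma=sigma, mode="constant", truncate=8.0)
    dens_grid = smooth / (pts.shape[0] * step[0] * step[1])

    ex = np.clip((ev[:, 0] - lo[0]) / step[0], 0, grid_size - 1)
    ey = np.clip((ev[:, 1] - lo[1]) / step[1], 0, grid_size - 1)
    return ndimage.map_coordinates(dens_grid, np.vstack([ex, ey]), order=1)


@dataclass
class DensityWeightField:
    """Per-probe density f̂(A_i, M_i) and the derived weight f̂^multiplicity."""

    density: np.ndarray
    weight: np.ndarray
    bandwidths: tuple[float, float]
    multiplicity: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if (self.density < 0).any():
            raise ValueError("densities must be non-negative")
        if self.multiplicity < 0:
            raise ValueError("multiplicity must be non-negative")


def density_weights(
    ma: MAProjection,
    multiplicity: float = 4.0,
    bandwidths: tuple[float, float] | None = None,
) -> DensityWeightField:
    """Density of each probe at its own (A, M), raised to ``multiplicity``.

    Multiplicity 0 gives all weights exactly 1 (the unweighted-loess limit);
    larger multiplicities concentrate the fit ever harder on the dense null
    cluster.  Weights are used as-is downstream — only their relative
    magnitude matters, so no renormalization is applied.
    """
    if len(ma.A) < 2:
        raise ValueError("density weighting needs at least 2 probes")
    if np.ptp(ma.A) == 0:
        raise ValueError("degenerate A margin: all reference intensities equal")
    if np.ptp(ma.M) == 0:
        raise ValueError("degenerate M margin: all M values equal")
    if bandwidths is None:
        bandwidths = (
            normal_reference_bandwidth(ma.A),
            normal_reference_bandwidth(ma.M),
        )
    pts = np.column_stack([ma.A, ma.M])
    dens = kde2d(pts, bandwidths)
    weight = np.ones_like(dens) if multiplicity == 0 else dens**multiplicity
    return DensityWeightField(
        density=dens,
        weight=weight,
        bandwidths=(float(bandwidths[0]), float(bandwidths[1])),
        multiplicity=float(multiplicity),
    )
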