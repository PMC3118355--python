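"""Prior-weighted local linear regression (loess) and KDL normalization.

The loess engine here is the classic configuration — degree-1 local fits,
tricube distance weights, nearest-neighbour span — extended with one extra
ingredient: per-point *prior* weights that multiply the tricube weights in
every neighbourhood.  With uniform priors it reduces exactly to ordinary
loess.  KDL (kernel-density-weighted loess) supplies the priors as the
estimated (A, M) density raised to a power, so that the curve tracks the
dense null-gene cluster instead of the overall (possibly asymmetric) trend.

No robustness (IRLS) iterations are performed: the density weights are the
sole reweighting mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .core import LOG2, ExpressionMatrix, MAProjection, common_reference
from .density import density_weights


@dataclass
class LoessFit:
    """Result of a weighted loess fit.

    ``x``/``y``/``prior_weights`` are stored sorted by x (with the sort
    permutation kept) so that predictions can refit local neighbourhoods;
    ``fitted`` is reported in the original input order.
    """

    x: np.ndarray              # sorted ascending
    y: np.ndarray              # matching x order
    prior_weights: np.ndarray  # matching x order
    span: float
    fitted: np.ndarray         # original input order
    degree: int = 1

    @property
    def fitted_sorted(self) -> np.ndarray:
        return self._fitted_sorted

    def __post_init__(self) -> None:
        order = np.argsort(self.x, kind="stable")
        # already sorted by construction in weighted_loess_fit; keep guard cheap
        if not np.all(order == np.arange(len(order))):
            raise ValueError("LoessFit.x must be sorted ascending")


def _tricube(u: np.ndarray) -> np.ndarray:
    t = np.clip(1.0 - u**3, 0.0, None)
    return t**3


def _neighborhood(xs: np.ndarray, x0: float, start: int, k: int) -> tuple[int, int, int]:
    """Advance the sliding window of the k nearest points to x0.

    xs is sorted, evaluation proceeds in increasing x0, so the optimal
    window start is monotone non-decreasing.  Returns (start, lo, hi) where
    [lo, hi) includes boundary ties in |x - x0|.
    """
    n = len(xs)
    while start + k < n and xs[start + k] - x0 < x0 - xs[start]:
        start += 1
    lo, hi = start, start + k
    d_max = max(x0 - xs[lo], xs[hi - 1] - x0)
    while hi < n and xs[hi] - x0 == d_max:
        hi += 1
    while lo > 0 and x0 - xs[lo - 1] == d_max:
        lo -= 1
    return start, lo, hi


def _fit_local(
    xs: np.ndarray,
    ys: np.ndarray,
    ws: np.ndarray,
    x0s: np.ndarray,
    k: int,
) -> np.ndarray:
    """Evaluate the weighted local-linear fit at sorted points x0s."""
    out = np.empty(len(x0s), dtype=float)
    start = 0
    for i, x0 in enumerate(x0s):
        start, lo, hi = _neighborhood(xs, x0, start, k)
        xw = xs[lo:hi]
        yw = ys[lo:hi]
        pw = ws[lo:hi]
        if not (pw > 0).any():
            raise ValueError(
                f"all prior weights are zero in the neighbourhood of x={x0!r}"
            )
        d = np.abs(xw - x0)
        d_max = d.max()
        if d_max == 0.0:
            # all neighbours share x0: weighted mean fallback
            out[i] = np.average(yw, weights=pw)
            continue
        w = _tricube(d / d_max) * pw
        sw = w.sum()
        if sw <= 0.0:
            # priors live only on the (zero-tricube) boundary; drop distance
            # weighting rather than fail
            w = pw
            sw = w.sum()
        xm = np.dot(w, xw) / sw
        ym = np.dot(w, yw) / sw
        dx = xw - xm
        sxx = np.dot(w, dx * dx)
        if sxx <= 0.0:
            out[i] = ym
        else:
            slope = np.dot(w, dx * (yw - ym)) / sxx
            out[i] = ym + slope * (x0 - xm)
    return out


def weighted_loess_fit(
    x, y, prior_weights, span: float = 0.2
) -> LoessFit:
    """Degree-1 loess with multiplicative prior weights.

    For each evaluation point the k = ceil(span·n) nearest training points
    (ties at the boundary included) are fitted by weighted least squares
    with weights tricube(d/d_max) · prior_weight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pw = np.asarray(prior_weights, dtype=float)
    n = len(x)
    if not (len(y) == n and len(pw) == n):
        raise ValueError("x, y and prior_weights must have equal length")
    if n < 10:
        raise ValueError(f"loess needs at least 10 points, got {n}")
    if (pw < 0).any():
        raise ValueError("prior weights must be non-negative")
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    k = ceil(span * n)
    if k < 4:
        raise ValueError(
            f"span·n = {span * n:.2f} gives a neighbourhood of {k} < 4 points; "
            "increase the span"
        )
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], pw[order]
    fitted_sorted = _fit_local(xs, ys, ws, xs, k)
    fitted = np.empty(n, dtype=float)
    fitted[order] = fitted_sorted
    fit = LoessFit(x=xs, y=ys, prior_weights=ws, span=span, fitted=fitted)
    fit._fitted_sorted = fitted_sorted
    return fit


def loess_predict(fit: LoessFit, x_new) -> np.ndarray:
    """Predict at new points by refitting local neighbourhoods.

    This is a genuine refit against the training points and weights, not an
    interpolation of the stored fitted values; x_new beyond the training
    range is scored by the boundary neighbourhood's regression line.
    """
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    k = ceil(fit.span * len(fit.x))
    order = np.argsort(x_new, kind="stable")
    pred_sorted = _fit_local(fit.x, fit.y, fit.prior_weights, x_new[order], k)
    pred = np.empty(len(x_new), dtype=float)
    pred[order] = pred_sorted
    return pred


def kdl_normalize(
    m: ExpressionMatrix,
    span: float = 0.2,
    multiplicity: float = 4.0,
    bandwidths: tuple[float, float] | None = None,
) -> ExpressionMatrix:
    """Kernel-density-weighted loess normalization.

    Each array is projected onto (A, M) against the common reference (the
    per-probe mean over all arrays, fixed once), the (A, M) density is
    estimated and raised to ``multiplicity`` to give prior weights, and the
    weighted loess curve c(A) is subtracted: x ← x − c(A).

    With ``multiplicity=0`` this is plain (unweighted) global loess
    normalization.
    """
    if m.scale != LOG2:
        raise ValueError("kdl_normalize expects a log2-scale matrix")
    if m.n_arrays < 2:
        raise ValueError("normalization requires at least 2 arrays")
    reference = common_reference(m)
    out = np.empty_like(m.values)
    for j, array_id in enumerate(m.array_ids):
        try:
            ma = MAProjection(
                A=reference, M=m.values[:, j] - reference, target_array_id=array_id
            )
            if np.ptp(ma.M) == 0.0:
                # constant offset (e.g. identical arrays): the local linear
                # fit of a constant is that constant for any weights
                curve = ma.M
            else:
                if multiplicity == 0:
                    weights = np.ones_like(ma.M)
                else:
                    weights = density_weights(
                        ma, multiplicity=multiplicity, bandwidths=bandwidths
                    ).weight
                curve = weighted_loess_fit(ma.A, ma.M, weights, span=span).fitted
            out[:, j] = m.values[:, j] - curve
        except ValueError as err:
            raise ValueError(f"array {array_id!r}: {err}") from err
    return m.with_values(out)
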