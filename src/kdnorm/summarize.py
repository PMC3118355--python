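"""Comparison baselines, probe-set summarization, and the probe-level wrapper.

Summarization collapses the probes of each probe set into a single
expression value per array, either by the plain median or by Tukey's median
polish (the standard robust choice).  The probe-level wrapper lets any
matrix → matrix normalizer operate on probe-level data: the per-probe-set
medians are normalized, and each probe is reconstructed by adding back its
offset relative to the original median, so within-probe-set structure is
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .core import ExpressionMatrix
from .loess import kdl_normalize


def global_loess_normalize(m: ExpressionMatrix, span: float = 0.2) -> ExpressionMatrix:
    """Plain (unweighted) loess normalization against the common reference.

    Definitionally identical to :func:`kdl_normalize` with multiplicity 0:
    every probe gets prior weight 1.
    """
    return kdl_normalize(m, span=span, multiplicity=0.0)


class ProbesetMap:
    """Total probe → probe-set mapping.

    Every probe of a matrix must be assigned to exactly one probe set.
    Probe-set order is first appearance in the probe order supplied.
    """

    def __init__(self, mapping: Mapping):
        self._map = dict(mapping)
        if not self._map:
            raise ValueError("probeset map is empty")

    def __getitem__(self, probe_id):
        return self._map[probe_id]

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, probe_id) -> bool:
        return probe_id in self._map

    def items(self):
        return self._map.items()

    def probeset_of(self, probe_ids: np.ndarray) -> np.ndarray:
        missing = [p for p in probe_ids if p not in self._map]
        if missing:
            raise ValueError(f"probe {missing[0]!r} is missing from the probeset map")
        return np.asarray([self._map[p] for p in probe_ids], dtype=object)


def median_summarize(m: ExpressionMatrix, pmap: ProbesetMap) -> ExpressionMatrix:
    """Per probe set and array, the median of member-probe values."""
    ps = pmap.probeset_of(m.probe_ids)
    df = pd.DataFrame(m.values)
    grouped = df.groupby(pd.Series(ps), sort=False).median()
    return ExpressionMatrix(
        values=grouped.to_numpy(),
        probe_ids=grouped.index.to_numpy(dtype=object),
        array_ids=m.array_ids.copy(),
        scale=m.scale,
    )


@dataclass
class MedianPolishResult:
    """Additive decomposition x_ij = overall + row_i + col_j + residual_ij."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int

    @property
    def summary(self) -> np.ndarray:
        """Per-array summarized expression: overall + column effect."""
        return self.overall + self.col_effects


def median_polish(
    matrix, tol: float = 1e-6, max_iter: int = 10
) -> MedianPolishResult:
    """Tukey's median polish: alternating row/column median sweeps.

    Rows are swept first, then columns; iteration stops when the change in
    the sum of absolute residuals is <= ``tol`` or after ``max_iter``
    full sweeps.  The reconstruction identity
    overall + row_i + col_j + residual_ij == x_ij holds exactly.
    """
    r = np.array(matrix, dtype=float)
    if r.ndim != 2 or r.size == 0:
        raise ValueError("median polish expects a non-empty 2-D matrix")
    overall = 0.0
    row = np.zeros(r.shape[0])
    col = np.zeros(r.shape[1])
    old_sum = np.abs(r).sum()
    n_iter = 0
    for _ in range(max_iter):
        n_iter += 1
        rdelta = np.median(r, axis=1)
        r -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta

        cdelta = np.median(r, axis=0)
        r -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta

        new_sum = np.abs(r).sum()
        if abs(old_sum - new_sum) <= tol:
            break
        old_sum = new_sum
    return MedianPolishResult(
        overall=float(overall),
        row_effects=row,
        col_effects=col,
        residuals=r,
        n_iter=n_iter,
    )


def median_polish_summarize(m: ExpressionMatrix, pmap: ProbesetMap) -> ExpressionMatrix:
    """Median-polish each probe set's probes × arrays block; keep overall + column effects."""
    ps = pmap.probeset_of(m.probe_ids)
    seen: dict = {}
    for p in ps:
        if p not in seen:
            seen[p] = len(seen)
    out = np.empty((len(seen), m.n_arrays), dtype=float)
    for probeset, row_idx in seen.items():
        block = m.values[ps == probeset, :]
        out[row_idx] = median_polish(block).summary
    return ExpressionMatrix(
        values=out,
        probe_ids=np.asarray(list(seen), dtype=object),
        array_ids=m.array_ids.copy(),
        scale=m.scale,
    )


def probe_level_wrap(
    m: ExpressionMatrix,
    pmap: ProbesetMap,
    normalizer: Callable[[ExpressionMatrix], ExpressionMatrix],
) -> ExpressionMatrix:
    """Apply a probe-set-level normalizer to probe-level data.

    The per-probe-set medians are normalized, and every probe is
    reconstructed as normalized_median + (probe − original_median), so the
    within-probe-set offsets are untouched.
    """
    medians = median_summarize(m, pmap)
    normalized = normalizer(medians)
    ps = pmap.probeset_of(m.probe_ids)
    ps_index = {p: i for i, p in enumerate(medians.probe_ids)}
    rows = np.asarray([ps_index[p] for p in ps], dtype=int)
    out = normalized.values[rows, :] + (m.values - medians.values[rows, :])
    return m.with_values(out)
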