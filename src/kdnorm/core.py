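"""Expression-matrix container, log transforms, and MA-plot projection.

The container is deliberately minimal: a dense probes × arrays float matrix
with unique row/column identifiers and an explicit scale flag (``raw`` linear
intensities or ``log2``).  All normalization in this package is fitted and
subtracted on the log2 scale, so the scale flag is checked at every entry
point rather than guessed from the data.

The MA projection used throughout is the *common-reference* variant: the
reference profile is the per-probe mean of the log2 intensities over **all**
arrays, computed once per matrix.  For a target array ``x``,

    A_i = reference_i            (not the pairwise (x + ref)/2 average)
    M_i = x_i - reference_i

Keeping A fixed at the reference makes the A coordinate of a probe identical
across every target array of the matrix, which is what lets a single density
field describe the null-gene cluster consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RAW = "raw"
LOG2 = "log2"
_SCALES = (RAW, LOG2)


def _as_id_array(ids, name: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if len(set(arr)) != len(arr):
        seen: set = set()
        for x in arr:
            if x in seen:
                raise ValueError(f"duplicate {name[:-1]} {x!r}")
            seen.add(x)
    return arr


@dataclass
class ExpressionMatrix:
    """Probes × arrays intensity matrix with identifiers and a scale flag.

    Parameters
    ----------
    values
        2-D float array, one row per probe (or probe set), one column per
        array.  No missing entries are allowed.  On the ``raw`` scale all
        values must be >= 0; on the ``log2`` scale they must be finite.
    probe_ids, array_ids
        Unique string identifiers matching the matrix dimensions.
    scale
        Either ``"raw"`` or ``"log2"``.
    """

    values: np.ndarray
    probe_ids: np.ndarray
    array_ids: np.ndarray
    scale: str = RAW

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probes × arrays matrix")
        self.probe_ids = _as_id_array(self.probe_ids, "probe_ids")
        self.array_ids = _as_id_array(self.array_ids, "array_ids")
        if self.values.shape != (len(self.probe_ids), len(self.array_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes × {len(self.array_ids)} arrays"
            )
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at probe {self.probe_ids[i]!r}, "
                f"array {self.array_ids[j]!r}"
            )
        if self.scale == RAW:
            if (self.values < 0).any():
                i = int(np.argwhere((self.values < 0).any(axis=1))[0][0])
                raise ValueError(
                    f"negative raw intensity at probe {self.probe_ids[i]!r}"
                )
        else:
            if not np.isfinite(self.values).all():
                i = int(np.argwhere(~np.isfinite(self.values).all(axis=1))[0][0])
                raise ValueError(
                    f"non-finite log2 intensity at probe {self.probe_ids[i]!r}"
                )

    # -- conveniences -----------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def array_index(self, array_id) -> int:
        hits = np.flatnonzero(self.array_ids == array_id)
        if len(hits) == 0:
            raise KeyError(f"unknown array id {array_id!r}")
        return int(hits[0])

    def column(self, array_id) -> np.ndarray:
        return self.values[:, self.array_index(array_id)]

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        """New matrix sharing this one's identifiers."""
        return ExpressionMatrix(
            values=values,
            probe_ids=self.probe_ids.copy(),
            array_ids=self.array_ids.copy(),
            scale=self.scale if scale is None else scale,
        )

    def copy(self) -> "ExpressionMatrix":
        return self.with_values(self.values.copy())

    def subset_probes(self, mask_or_indices) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_indices)
        return ExpressionMatrix(
            values=self.values[idx],
            probe_ids=self.probe_ids[idx],
            array_ids=self.array_ids.copy(),
            scale=self.scale,
        )


@dataclass
class MAProjection:
    """Per-probe (A, M) coordinates of one array against the common reference."""

    A: np.ndarray
    M: np.ndarray
    target_array_id: object

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.A.shape != self.M.shape or self.A.ndim != 1:
            raise ValueError("A and M must be 1-D arrays of equal length")


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(raw + offset); the offset guards zero intensities."""
    if m.scale != RAW:
        raise ValueError("log2_transform expects a raw-scale matrix")
    if (m.values < 0).any():
        i = int(np.argwhere((m.values < 0).any(axis=1))[0][0])
        raise ValueError(f"negative raw intensity at probe {m.probe_ids[i]!r}")
    if offset <= 0 and (m.values + offset <= 0).any():
        raise ValueError("offset too small: log2 argument would be non-positive")
    return m.with_values(np.log2(m.values + offset), scale=LOG2)


def unlog2(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform`: 2**x - offset, clipped at 0."""
    if m.scale != LOG2:
        raise ValueError("unlog2 expects a log2-scale matrix")
    raw = np.exp2(m.values) - offset
    return m.with_values(np.maximum(raw, 0.0), scale=RAW)


def common_reference(m: ExpressionMatrix) -> np.ndarray:
    """Per-probe arithmetic mean of log2 intensities over all arrays.

    This single profile is the reference side of every MA projection of the
    matrix; it is computed once per normalization run and never updated.
    """
    if m.scale != LOG2:
        raise ValueError("common_reference expects a log2-scale matrix")
    if m.n_arrays < 2:
        raise ValueError("common reference requires at least 2 arrays")
    return m.values.mean(axis=1)


def ma_project(
    m: ExpressionMatrix, array_id, reference: np.ndarray | None = None
) -> MAProjection:
    """Project one array onto (A, M) against the common reference.

    A is the reference itself (identical for every target array); M is the
    target-minus-reference log2 difference.  The projection is exactly
    invertible: x = A + M.
    """
    if m.scale != LOG2:
        raise ValueError("ma_project expects a log2-scale matrix")
    if reference is None:
        reference = common_reference(m)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (m.n_probes,):
        raise ValueError(
            f"reference length {reference.shape} does not match {m.n_probes} probes"
        )
    x = m.column(array_id)
    return MAProjection(A=reference.copy(), M=x - reference, target_array_id=array_id)
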