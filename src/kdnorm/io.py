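"""Delimited-text readers and writers for matrices and probe-set maps.

The matrix dialect is plain TSV: a header row whose first cell labels the
probe-id column and whose remaining cells are array ids, then one row per
probe with the probe id in column 1.  Floats are written with Python's
shortest round-trip representation, so write → read is lossless.
"""

from __future__ import annotations

import numpy as np

from .core import RAW, ExpressionMatrix
from .summarize import ProbesetMap


def read_matrix(path, scale: str = RAW) -> ExpressionMatrix:
    """Parse a TSV expression matrix; errors carry 1-based line numbers."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise ValueError(f"{path}: line 1: header needs at least one array column")
        array_ids = cols[1:]
        n_arrays = len(array_ids)
        probe_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_arrays + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_arrays + 1} columns, "
                    f"got {len(parts)}"
                )
            pid = parts[0]
            if pid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate probe id {pid!r}")
            seen.add(pid)
            probe_ids.append(pid)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: non-numeric cell ({err})") from err
    return ExpressionMatrix(
        values=np.asarray(rows, dtype=float),
        probe_ids=probe_ids,
        array_ids=array_ids,
        scale=scale,
    )


def write_matrix(m: ExpressionMatrix, path, id_label: str = "probe_id") -> None:
    """Write a matrix as TSV with full-precision (round-trip) floats."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(id_label + "\t" + "\t".join(str(a) for a in m.array_ids) + "\n")
        for pid, row in zip(m.probe_ids, m.values):
            fh.write(str(pid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_probeset_map(path) -> ProbesetMap:
    """Two-column TSV (probe_id, probeset_id), optional header line."""
    mapping: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts == ["probe_id", "probeset_id"]:
                continue
            if parts[0] in mapping:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate probe id {parts[0]!r}"
                )
            mapping[parts[0]] = parts[1]
    return ProbesetMap(mapping)


def write_probeset_map(pmap: ProbesetMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tprobeset_id\n")
        for probe, probeset in pmap.items():
            fh.write(f"{probe}\t{probeset}\n")
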