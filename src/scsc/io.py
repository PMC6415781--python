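"""Delimited-text and JSON input/output.

Formats
-------
* trajectories: long form, one row per (state, time) with columns
  ``state,time,<coord_1>..<coord_d>``; comma or tab delimited (the dialect
  is auto-detected unless given).  All states must share the time grid.
* adjacency / transition matrices: square delimited matrix, optional
  header row of state labels.
* eigen-solution export: one row per state (label plus the scalar value on
  each retained eigenvector) with a JSON sidecar of eigenvalues and merits.
* dendrogram: Newick (node labels are bit-code prefixes, branch lengths in
  z units) and a JSON report with member lists, counts and widths.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import DendrogramTree
from .dissimilarity import AdjacencyMatrix, TrajectoryEnsemble
from .errors import InputError
from .msm import TransitionMatrix
from .spectral import SpectralSolution

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_adjacency",
    "write_adjacency",
    "read_transition_matrix",
    "write_transition_matrix",
    "write_eigen_solution",
    "write_tree",
]


def _read_delimited(path, delimiter: str | None) -> pd.DataFrame:
    # cells are read as strings and converted with numpy's correctly
    # rounding parser so writes round-trip bit-exactly
    try:
        if delimiter is None:
            return pd.read_csv(path, sep=None, engine="python", dtype=str)
        return pd.read_csv(path, sep=delimiter, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # parser errors carry little position info
        raise InputError(f"could not parse {path}: {exc}") from exc


def _column_to_float(df: pd.DataFrame, col, path) -> np.ndarray:
    """Convert one string column to float64, naming the first bad line."""
    raw = df[col].to_numpy(dtype=object)
    missing = pd.isna(raw)
    if missing.any():
        line = int(np.flatnonzero(missing)[0]) + 2  # header + 1-based
        raise InputError(f"{path}: missing value in column {col!r} at line {line}")
    try:
        return raw.astype(np.float64)
    except ValueError:
        for i, cell in enumerate(raw):
            try:
                float(cell)
            except ValueError:
                raise InputError(
                    f"{path}: non-numeric value {cell!r} in column {col!r} "
                    f"at line {i + 2}"
                ) from None
        raise


def read_trajectories(
    path,
    delimiter: str | None = None,
    periodic_lengths=None,
) -> TrajectoryEnsemble:
    """Read a long-form trajectory file into an ensemble.

    Errors name the offending states (ragged time grids) or line numbers
    (non-numeric cells).  ``periodic_lengths`` is metadata not stored in
    the file and may be supplied here.
    """
    df = _read_delimited(path, delimiter)
    if df.shape[1] < 4:
        raise InputError(
            f"{path}: expected columns state,time,coord_1..coord_d (>= 4 columns), "
            f"got {df.shape[1]}"
        )
    state_col = df.columns[0]
    numeric_cols = list(df.columns[1:])
    for col in numeric_cols:
        df[col] = _column_to_float(df, col, path)

    states = list(dict.fromkeys(df[state_col].tolist()))  # first-appearance order
    if len(states) < 2:
        raise InputError(f"{path}: at least two states are required")
    groups = {s: g for s, g in df.groupby(state_col, sort=False)}
    times = groups[states[0]][df.columns[1]].to_numpy(dtype=float)
    ragged = []
    for s in states:
        ts = groups[s][df.columns[1]].to_numpy(dtype=float)
        if ts.shape != times.shape or not np.array_equal(ts, times):
            ragged.append(s)
    if ragged:
        raise InputError(
            f"{path}: states {ragged} do not share the common time grid"
        )
    d = len(numeric_cols) - 1
    positions = np.empty((len(states), times.size, d))
    for i, s in enumerate(states):
        positions[i] = groups[s][numeric_cols[1:]].to_numpy(dtype=float)
    return TrajectoryEnsemble(
        positions=positions,
        times=times,
        periodic_lengths=periodic_lengths,
        labels=tuple(str(s) for s in states),
    )


def write_trajectories(ensemble: TrajectoryEnsemble, path, delimiter: str = ",") -> None:
    """Write the long-form trajectory format (full float precision)."""
    n, T, d = ensemble.positions.shape
    labels = ensemble.labels or tuple(range(n))
    coord_names = ["x", "y", "z"][:d] if d <= 3 else [f"x{j + 1}" for j in range(d)]
    header = delimiter.join(["state", "time", *coord_names])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(n):
            for k in range(T):
                row = [str(labels[i]), repr(float(ensemble.times[k]))]
                row += [repr(float(v)) for v in ensemble.positions[i, k]]
                fh.write(delimiter.join(row) + "\n")


def _read_square_matrix(path, delimiter):
    with open(path) as fh:
        first = fh.readline()
    sep = delimiter
    if sep is None:
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    tokens = [t.strip() for t in first.rstrip("\n").split(sep)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t)
    labels = tuple(t for t in tokens if t) if has_header else None
    values = np.loadtxt(path, delimiter=sep, skiprows=1 if has_header else 0, ndmin=2)
    if not has_header and values.shape[0] == values.shape[1] + 1:
        # a label row made of numbers is indistinguishable by content alone
        labels = tuple(t for t in tokens if t)
        values = values[1:]
    if values.shape[0] != values.shape[1]:
        raise InputError(f"{path}: matrix is not square: {values.shape}")
    return values, labels


def read_adjacency(path, delimiter: str | None = None) -> AdjacencyMatrix:
    values, labels = _read_square_matrix(path, delimiter)
    return AdjacencyMatrix(values, labels=labels)


def write_adjacency(A: AdjacencyMatrix, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        if A.labels is not None:
            fh.write(delimiter.join(str(l) for l in A.labels) + "\n")
        for row in A.values:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def read_transition_matrix(path, delimiter: str | None = None) -> TransitionMatrix:
    values, _ = _read_square_matrix(path, delimiter)
    return TransitionMatrix(values, lag_note=f"read from {path}")


def write_transition_matrix(T: TransitionMatrix, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        for row in T.probs:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def write_eigen_solution(
    solution: SpectralSolution,
    csv_path,
    json_path=None,
    labels=None,
    n_keep: int | None = None,
    delimiter: str = ",",
) -> None:
    """Export per-state eigenvector values plus a JSON sidecar of spectra."""
    n = solution.n
    k = n if n_keep is None else min(int(n_keep), n)
    labels = labels or tuple(range(n))
    with open(csv_path, "w") as fh:
        header = ["state"] + [f"X{j + 1}" for j in range(k)]
        fh.write(delimiter.join(header) + "\n")
        for i in range(n):
            row = [str(labels[i])] + [
                repr(float(v)) for v in solution.eigenvectors[i, :k]
            ]
            fh.write(delimiter.join(row) + "\n")
    if json_path is not None:
        sidecar = {
            "n_states": n,
            "n_retained": k,
            "eigenvalues": solution.eigenvalues[:k].tolist(),
            "merit_values": solution.merit_values[:k].tolist(),
            "degrees": solution.degrees.tolist(),
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_tree(
    tree: DendrogramTree,
    newick_path=None,
    json_path=None,
    labels=None,
    meta: dict | None = None,
) -> None:
    """Write the dendrogram as Newick and/or a JSON report."""
    if newick_path is not None:
        Path(newick_path).write_text(tree.to_newick() + "\n")
    if json_path is not None:
        doc = tree.to_dict(labels=labels)
        if meta:
            doc["meta"] = meta
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
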