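"""Pairwise dissimilarity metrics and adjacency-matrix assembly.

The clustering machinery consumes a symmetric, nonnegative *dissimilarity*
matrix ``A`` with zero diagonal (note this is the opposite of the usual
similarity-graph convention: larger entries mean *more different*).  Two
metrics are provided:

* a normalized separation-variability metric for Lagrangian trajectories:
  the root-sum-square deviation of the instantaneous pair distance from its
  time mean, divided by that mean.  Pairs of tracers that travel together
  score near zero; pairs straddling a transport barrier separate
  exponentially and score high.
* the square root of the Jensen-Shannon divergence for probability
  distributions (e.g. rows of a Markov-state-model transition matrix),
  bounded by ``sqrt(ln 2)`` with natural logarithms.

Neither metric is required to satisfy the triangle inequality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DuplicateStateWarning, InputError

__all__ = [
    "TrajectoryEnsemble",
    "AdjacencyMatrix",
    "DiscreteDistribution",
    "trajectory_dissimilarity",
    "js_dissimilarity",
    "build_adjacency",
    "SQRT_LN2",
]

#: Upper bound of the sqrt-Jensen-Shannon metric (natural log).
SQRT_LN2 = float(np.sqrt(np.log(2.0)))


@dataclass
class TrajectoryEnsemble:
    """``n`` tracer trajectories sampled on a shared time grid.

    Parameters
    ----------
    positions
        Array of shape ``(n, T, d)``: state, time sample, spatial dimension.
        Positions in periodic dimensions may be stored unwrapped; distances
        are always taken with the minimum-image convention.
    times
        Strictly increasing sample times, length ``T`` (``T >= 2``).
    periodic_lengths
        Optional per-dimension domain extent for periodic dimensions;
        ``nan`` (or ``None`` for the whole array) marks aperiodic dimensions.
    labels
        Optional state identifiers, length ``n``.
    """

    positions: np.ndarray
    times: np.ndarray
    periodic_lengths: np.ndarray | None = None
    labels: tuple | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.ndim != 3:
            raise InputError(
                f"positions must have shape (n, T, d); got {self.positions.shape}"
            )
        n, T, d = self.positions.shape
        if n < 1:
            raise InputError("an ensemble needs at least one state")
        if T < 2:
            raise InputError("at least two time samples are required (T >= 2)")
        if self.times.shape != (T,):
            raise InputError(
                f"times has length {self.times.shape}, expected ({T},)"
            )
        if not np.all(np.isfinite(self.positions)):
            raise InputError("positions contain non-finite values")
        if not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")
        if self.periodic_lengths is not None:
            self.periodic_lengths = np.asarray(self.periodic_lengths, dtype=float)
            if self.periodic_lengths.shape != (d,):
                raise InputError(
                    f"periodic_lengths must have length d={d}"
                )
            finite = np.isfinite(self.periodic_lengths)
            if np.any(self.periodic_lengths[finite] <= 0):
                raise InputError("periodic_lengths must be positive where finite")
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != n:
                raise InputError("labels length must equal the state count")

    @property
    def n_states(self) -> int:
        return self.positions.shape[0]

    @property
    def n_times(self) -> int:
        return self.positions.shape[1]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[2]


@dataclass
class AdjacencyMatrix:
    """Symmetric nonnegative pairwise-dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    labels: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InputError(f"adjacency must be square; got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"adjacency entry ({bad[0]}, {bad[1]}) is not finite"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise InputError(
                f"adjacency entry ({bad[0]}, {bad[1]}) is negative"
            )
        if not np.allclose(self.values, self.values.T, rtol=1e-8, atol=1e-12):
            raise InputError("adjacency matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise InputError("adjacency diagonal must be zero")
        # enforce exact symmetry / zero diagonal so downstream algebra is clean
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise InputError("labels length must equal the state count")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DiscreteDistribution:
    """A finite probability distribution (nonnegative, sums to one)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1:
            raise InputError("a distribution must be a 1-D vector")
        if np.any(self.probs < 0):
            raise InputError("distribution entries must be nonnegative")
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-6:
            raise InputError(f"distribution sums to {total}, not 1")


def _instant_distances(
    pos: np.ndarray, periodic_lengths: np.ndarray | None
) -> np.ndarray:
    """Condensed pairwise Euclidean distances for one time sample.

    Applies the minimum-image convention in every periodic dimension.
    """
    if periodic_lengths is None or not np.any(np.isfinite(periodic_lengths)):
        return pdist(pos)
    sq = None
    for j in range(pos.shape[1]):
        dj = pdist(pos[:, j : j + 1])
        lj = periodic_lengths[j]
        if np.isfinite(lj):
            dj = np.mod(dj, lj)
            np.minimum(dj, lj - dj, out=dj)
        sq = dj * dj if sq is None else sq + dj * dj
    return np.sqrt(sq)


def _trajectory_adjacency_values(ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Full condensed vector of the trajectory metric, one pass per time sample.

    Only running sums of r and r^2 are kept, so memory stays O(n^2) rather
    than O(n^2 T):  sum_k (rbar - r_k)^2 = sum_k r_k^2 - T rbar^2.
    """
    n, T, _ = ensemble.positions.shape
    n_pairs = n * (n - 1) // 2
    s1 = np.zeros(n_pairs)
    s2 = np.zeros(n_pairs)
    for k in range(T):
        r = _instant_distances(ensemble.positions[:, k, :], ensemble.periodic_lengths)
        s1 += r
        s2 += r * r
    rbar = s1 / T
    ss = s2 - T * rbar * rbar
    np.clip(ss, 0.0, None, out=ss)  # guard tiny negative rounding
    out = np.zeros(n_pairs)
    live = rbar > 0
    out[live] = np.sqrt(ss[live]) / rbar[live]
    if not np.all(live):
        warnings.warn(
            f"{int(np.sum(~live))} state pair(s) are coincident at every time; "
            "their dissimilarity is set to 0 (duplicate states)",
            DuplicateStateWarning,
            stacklevel=3,
        )
    return out


def trajectory_dissimilarity(
    ensemble: TrajectoryEnsemble, i: int, j: int
) -> float:
    """Normalized separation variability between trajectories ``i`` and ``j``.

    Returns ``(1/rbar) * sqrt(sum_k (rbar - r(t_k))^2)`` where ``r(t_k)`` is
    the (minimum-image) Euclidean distance at sample ``k`` and ``rbar`` its
    arithmetic mean over the ``T`` samples.  Symmetric in ``(i, j)``; scale
    invariant (both numerator and ``rbar`` scale with the coordinates); grows
    like ``sqrt(T)`` for fixed relative noise because the sum over samples is
    not averaged.
    """
    n = ensemble.n_states
    for idx in (i, j):
        if not (-n <= idx < n):
            raise InputError(f"state index {idx} out of range for n={n}")
    if i == j:
        return 0.0
    diff = ensemble.positions[i] - ensemble.positions[j]  # (T, d)
    per = ensemble.periodic_lengths
    if per is not None:
        diff = np.abs(diff)
        for k in range(diff.shape[1]):
            lk = per[k]
            if np.isfinite(lk):
                dk = np.mod(diff[:, k], lk)
                diff[:, k] = np.minimum(dk, lk - dk)
    r = np.sqrt(np.sum(diff * diff, axis=1))
    rbar = float(r.mean())
    if rbar == 0.0:
        warnings.warn(
            f"states {i} and {j} are coincident at every time; "
            "dissimilarity set to 0 (duplicate states)",
            DuplicateStateWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.sqrt(np.sum((rbar - r) ** 2)) / rbar)


def js_dissimilarity(p, q) -> float:
    """Square root of the Jensen-Shannon divergence between two distributions.

    ``div_JS = 0.5 sum p log(p/m) + 0.5 sum q log(q/m)`` with
    ``m = (p + q)/2``, natural logarithm and the convention
    ``0 * log(0/x) = 0``.  The returned value lies in ``[0, sqrt(ln 2)]``;
    the maximum is attained exactly for disjoint supports.
    """
    if isinstance(p, DiscreteDistribution):
        p = p.probs
    if isinstance(q, DiscreteDistribution):
        q = q.probs
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise InputError(
            f"distributions must be 1-D and of equal length; got {p.shape}, {q.shape}"
        )
    if np.any(p < 0) or np.any(q < 0):
        raise InputError("distribution entries must be nonnegative")
    for name, v in (("p", p), ("q", q)):
        total = float(v.sum())
        if abs(total - 1.0) > 1e-6:
            raise InputError(f"{name} sums to {total}, not 1")
    m = 0.5 * (p + q)
    div = 0.0
    for v in (p, q):
        nz = v > 0
        div += 0.5 * float(np.sum(v[nz] * np.log(v[nz] / m[nz])))
    div = min(max(div, 0.0), float(np.log(2.0)))
    return float(np.sqrt(div))


def _distribution_rows(states) -> np.ndarray | None:
    """Coerce a sequence of distributions to an (n, m) row matrix, else None."""
    if isinstance(states, np.ndarray):
        return np.asarray(states, dtype=float) if states.ndim == 2 else None
    try:
        rows = np.vstack(
            [
                s.probs if isinstance(s, DiscreteDistribution) else np.asarray(s, dtype=float)
                for s in states
            ]
        )
    except Exception:
        return None
    return rows if rows.ndim == 2 else None


def build_adjacency(
    states,
    metric: str | Callable = "trajectory",
    labels: Sequence | None = None,
) -> AdjacencyMatrix:
    """Assemble the symmetric dissimilarity matrix from ``n`` states.

    Exactly ``n (n-1) / 2`` metric evaluations are performed (each unordered
    pair once); the result is independent of evaluation order.

    Parameters
    ----------
    states
        A :class:`TrajectoryEnsemble` (``metric="trajectory"``), a sequence
        or row matrix of probability distributions (``metric="js"``), or any
        sequence of objects together with a callable ``metric(a, b)``.
    metric
        ``"trajectory"``, ``"js"``, or a symmetric callable.
    """
    if isinstance(states, TrajectoryEnsemble):
        if callable(metric):
            raise InputError(
                "callable metrics are supported for generic sequences; "
                "use metric='trajectory' for ensembles"
            )
        if metric not in ("trajectory",):
            raise InputError(f"unsupported metric {metric!r} for trajectory input")
        if states.n_states < 2:
            raise InputError("at least two states are required")
        condensed = _trajectory_adjacency_values(states)
        values = squareform(condensed)
        lab = labels if labels is not None else states.labels
        return AdjacencyMatrix(values, labels=lab)

    if callable(metric):
        items = list(states)
        n = len(items)
        if n < 2:
            raise InputError("at least two states are required")
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                v = float(metric(items[i], items[j]))
                if not np.isfinite(v):
                    raise InputError(
                        f"metric returned a non-finite value for pair ({i}, {j})"
                    )
                values[i, j] = values[j, i] = v
        return AdjacencyMatrix(values, labels=labels)

    if metric == "js":
        rows = _distribution_rows(states)
        if rows is None:
            raise InputError("metric='js' expects a sequence of distributions")
        n = rows.shape[0]
        if n < 2:
            raise InputError("at least two states are required")
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = js_dissimilarity(rows[i], rows[j])
        return AdjacencyMatrix(values, labels=labels)

    raise InputError(f"unknown metric {metric!r}")
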