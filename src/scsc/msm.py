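"""Synthetic Markov-state-model surrogates and MVCA coarse-graining.

A Markov state model (MSM) summarizes dynamics as a row-stochastic
transition matrix over microstates; each row is the probability
distribution of the next microstate.  Coarse-graining groups microstates
into macrostates.  Minimum variance clustering analysis (MVCA) does this
with Ward-linkage agglomerative clustering on the square-root
Jensen-Shannon dissimilarity between transition-matrix rows; the coloring
dendrogram built from the same dissimilarities provides an independent,
hierarchy-revealing alternative and the two should agree on well-separated
metastable structure.

Because real protein-folding MSMs require external multi-millisecond MD
data, this module generates synthetic row-stochastic matrices with planted
metastable blocks (Dirichlet-distributed probability mass, a configurable
fraction of each row inside its own block) at a comparable scale
(~175 microstates), so the macrostate workflow is fully testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dissimilarity import AdjacencyMatrix, js_dissimilarity
from .errors import InputError

__all__ = [
    "TransitionMatrix",
    "PlantedBlockSpec",
    "planted_block_spec",
    "synthetic_transition_matrix",
    "transition_adjacency",
    "mvca_cluster",
    "reversibilize",
    "macrostate_report",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix; row ``i`` is the jump distribution from state ``i``."""

    probs: np.ndarray
    lag_note: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise InputError(f"transition matrix must be square; got {self.probs.shape}")
        if np.any(self.probs < 0):
            raise InputError("transition probabilities must be nonnegative")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise InputError(
                f"row {bad} sums to {sums[bad]!r}, not 1 (tolerance 1e-9)"
            )

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class PlantedBlockSpec:
    """Recipe for a transition matrix with planted metastable blocks.

    ``intra_mass`` is the fraction of each row's probability placed on the
    row's own block (> 0.5 so blocks are genuinely metastable);
    ``concentration`` is the Dirichlet parameter used both within and
    outside the block.
    """

    n_states: int
    block_labels: np.ndarray
    intra_mass: float = 0.95
    seed: int = 0
    concentration: float = 1.0

    def __post_init__(self) -> None:
        self.block_labels = np.asarray(self.block_labels, dtype=int)
        if self.block_labels.shape != (self.n_states,):
            raise InputError("block_labels must have length n_states")
        if not (0.5 < self.intra_mass <= 1.0):
            raise InputError("intra_mass must lie in (0.5, 1]")
        if self.concentration <= 0:
            raise InputError("concentration must be positive")
        blocks, counts = np.unique(self.block_labels, return_counts=True)
        if blocks.size < 1 or np.any(counts < 1):
            raise InputError("every block must be non-empty")

    @property
    def n_blocks(self) -> int:
        return int(np.unique(self.block_labels).size)


def planted_block_spec(
    n_states: int,
    n_blocks: int,
    intra_mass: float = 0.95,
    seed: int = 0,
    concentration: float = 1.0,
) -> PlantedBlockSpec:
    """Convenience constructor with blocks of (near-)equal size."""
    if not (1 <= n_blocks <= n_states):
        raise InputError("need 1 <= n_blocks <= n_states")
    labels = np.arange(n_states) * n_blocks // n_states
    return PlantedBlockSpec(
        n_states=n_states,
        block_labels=labels,
        intra_mass=intra_mass,
        seed=seed,
        concentration=concentration,
    )


def synthetic_transition_matrix(spec: PlantedBlockSpec) -> TransitionMatrix:
    """Sample a row-stochastic matrix with the planted block structure.

    Row ``i`` places exactly ``intra_mass`` probability on the members of
    its own block (Dirichlet-distributed) and the remainder uniformly
    Dirichlet over all other states.  Seeded and reproducible.  Detailed
    balance is *not* enforced (the clustering consumes only the row
    distributions); see :func:`reversibilize` for an optional symmetrized
    variant.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_states
    alpha = spec.concentration
    probs = np.zeros((n, n))
    for i in range(n):
        inside = spec.block_labels == spec.block_labels[i]
        n_in = int(inside.sum())
        n_out = n - n_in
        probs[i, inside] = spec.intra_mass * rng.dirichlet(np.full(n_in, alpha))
        if n_out and spec.intra_mass < 1.0:
            probs[i, ~inside] = (1.0 - spec.intra_mass) * rng.dirichlet(
                np.full(n_out, alpha)
            )
        elif n_out == 0:
            probs[i, inside] /= spec.intra_mass  # single block: whole row inside
    # exact renormalization against floating-point drift
    probs /= probs.sum(axis=1, keepdims=True)
    note = (
        f"synthetic planted-block matrix: {spec.n_blocks} blocks, "
        f"intra_mass={spec.intra_mass}, seed={spec.seed}"
    )
    return TransitionMatrix(probs=probs, lag_note=note)


def stationary_distribution(T: TransitionMatrix) -> np.ndarray:
    """Left Perron eigenvector of the transition matrix, normalized to 1."""
    w, V = np.linalg.eig(T.probs.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(V[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def reversibilize(T: TransitionMatrix) -> TransitionMatrix:
    """Symmetrize by stationary flow: row-normalize ``(diag(pi) T + T' diag(pi)) / 2``."""
    pi = stationary_distribution(T)
    F = pi[:, None] * T.probs
    Fs = 0.5 * (F + F.T)
    probs = Fs / Fs.sum(axis=1, keepdims=True)
    return TransitionMatrix(probs=probs, lag_note=T.lag_note + " (reversibilized)")


def transition_adjacency(T: TransitionMatrix) -> AdjacencyMatrix:
    """Square-root Jensen-Shannon dissimilarity between all row pairs."""
    n = T.n
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = js_dissimilarity(T.probs[i], T.probs[j])
    return AdjacencyMatrix(values)


def mvca_cluster(A: AdjacencyMatrix, n_macrostates: int) -> np.ndarray:
    """Ward-linkage agglomerative clustering cut to ``n_macrostates`` labels.

    Deterministic given ``A``; labels are integers in ``[0, n_macrostates)``.
    """
    if not (1 <= n_macrostates <= A.n):
        raise InputError(f"n_macrostates must lie in [1, {A.n}]")
    if n_macrostates == 1:
        return np.zeros(A.n, dtype=int)
    if n_macrostates == A.n:
        return np.arange(A.n, dtype=int)
    condensed = squareform(A.values, checks=False)
    Z = linkage(condensed, method="ward")
    return fcluster(Z, n_macrostates, criterion="maxclust").astype(int) - 1


def macrostate_report(tree, labels=None) -> list[dict]:
    """Per-branch macrostate summary: code, microstate count, width, branch z.

    One record per branch at the tree's full depth (the converged
    macrostates), mirroring a per-macrostate state-count table.
    """
    recs = []
    for nd in sorted(tree.leaves(), key=lambda nd: nd.prefix):
        code = nd.prefix[: nd.creation_level] if nd.creation_level else nd.prefix
        origin = tree.nodes.get(code, nd)  # split that created the macrostate
        members = (
            [labels[i] for i in nd.members.tolist()]
            if labels is not None
            else nd.members.tolist()
        )
        recs.append(
            {
                "code": code,
                "n_microstates": nd.count,
                "width": nd.width,
                "branch_z": origin.branch_length,
                "creation_level": nd.creation_level,
                "members": members,
            }
        )
    return recs
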