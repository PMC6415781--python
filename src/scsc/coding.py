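"""Binary coding of the eigenvector sequence and the occupancy dendrogram.

Each eigenvector, taken in order of decreasing eigenvalue, is bifurcated
*globally* (one threshold cut assigning all states at once) into two
groups, contributing one bit to every state's binary code; the leading bit
comes from the largest eigenvalue.  The threshold sits at the deepest
density valley separating two substantial value modes when one exists,
and otherwise only a significantly separated extreme-value splinter — if
any — is shed (see :func:`bifurcate_scalar_field`).
After ``k`` eigenvectors there are at most ``2^k`` numerically possible
codes, but typically far fewer are occupied: unoccupied codes are the
natural stopping criterion, and branches whose member set stops changing as
more eigenvectors are added are the converged clusters.

The codes are arranged in a prefix tree.  The branch pair created when a
node splits at level ``k`` is assigned a length equal to the coloring merit
of eigenvector ``X_k`` summed only over the node's members, so branch
lengths are in merit (z) units; a node whose members all receive the same
next bit passes through unsplit (a single child with the identical member
set).

Label convention (arbitrary, as is the 0/1 polarity of any bifurcation):
bit 0 goes to the larger of the two clusters, ties to the cluster with the
smaller mean scalar value.  All downstream logic is invariant to flipping
any level's bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from scipy.cluster.hierarchy import fcluster, linkage

from .dissimilarity import AdjacencyMatrix
from .errors import DegenerateSplitError, InputError
from .spectral import SpectralSolution, coloring_merit

__all__ = [
    "BinaryCodeTable",
    "DendrogramNode",
    "DendrogramTree",
    "bifurcate_scalar_field",
    "assign_codes",
    "build_dendrogram",
    "converged_clusters",
]


#: Bandwidth factor applied to Silverman's rule in the valley search.
#: Silverman's rule is derived for unimodal densities and oversmooths
#: multimodal ones, filling in exactly the valleys being sought; a mild
#: undersmoothing restores them without manufacturing valleys in
#: structureless samples.
KDE_BANDWIDTH_FACTOR = 1.0


def _density_valley(
    x: np.ndarray, min_mode_frac: float, grid_size: int = 512
) -> tuple[float, float] | None:
    """Deepest internal density valley separating two substantial modes.

    Returns ``(score, threshold)`` where ``score`` is the valley density
    divided by the smaller of the two flanking density maxima (0 = fully
    separated modes, 1 = no dip), or ``None`` when no internal local
    minimum leaves at least ``min_mode_frac`` of the states on both sides.
    """
    n = x.size
    kde = scipy.stats.gaussian_kde(x)
    kde.set_bandwidth(kde.factor * KDE_BANDWIDTH_FACTOR)
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    xs = np.sort(x)
    min_side = max(2.0, min_mode_frac * n)
    best: tuple[float, float] | None = None
    interior = np.flatnonzero(
        (dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])
    ) + 1
    for m in interior:
        left = np.searchsorted(xs, grid[m], side="right")
        if min(left, n - left) < min_side:
            continue
        score = dens[m] / min(dens[:m].max(), dens[m + 1 :].max())
        if best is None or score < best[0]:
            best = (float(score), float(grid[m]))
    return best


#: A tail group only splinters off when the spacing separating it exceeds
#: this multiple of the median consecutive spacing; otherwise the level is
#: inert (no split), which is what lets branches truly converge and codes
#: go unoccupied.
TAIL_GAP_FACTOR = 20.0


def _tail_splinter(x: np.ndarray, min_mode_frac: float) -> np.ndarray | None:
    """Split off the most separated extreme-value group (< min_mode_frac).

    Scans the largest spacing between consecutive sorted values among cuts
    that leave fewer than ``min_mode_frac`` of the states on the outer
    side, in either tail; returns 0/1 labels with 1 on the splinter, or
    ``None`` when no tail group is separated by more than
    ``TAIL_GAP_FACTOR`` times the median spacing (an inert level).
    """
    n = x.size
    order = np.argsort(x)
    xs = x[order]
    m_max = max(1, int(np.floor(min_mode_frac * n)))
    best_gap, best_cut = -1.0, None  # best_cut = (side, size)
    for m in range(1, m_max + 1):
        g_left = xs[m] - xs[m - 1]
        if g_left > best_gap:
            best_gap, best_cut = g_left, ("left", m)
        g_right = xs[n - m] - xs[n - m - 1]
        if g_right > best_gap:
            best_gap, best_cut = g_right, ("right", m)
    spacings = np.diff(xs)
    spacings = spacings[spacings > 0]
    typical = np.median(spacings) if spacings.size else 0.0
    if typical > 0 and best_gap < TAIL_GAP_FACTOR * typical:
        return None
    labels = np.zeros(n, dtype=np.uint8)
    side, m = best_cut
    idx = order[:m] if side == "left" else order[n - m :]
    labels[idx] = 1
    return labels


#: Below this size the KDE-based mode search is skipped and the plain
#: final-merge cut of the average-linkage dendrogram is used.
SMALL_N_EXACT_CUT = 25


def bifurcate_scalar_field(
    x,
    min_mode_frac: float = 0.05,
    valley_ratio: float = 0.8,
    groups=None,
    group_min_frac: float = 0.2,
) -> np.ndarray:
    """Split a scalar field into its two dominant groups; returns 0/1 labels.

    The eigenproblem pulls dissimilar states toward the two ends of each
    coordinate, so a coordinate that still carries structure shows two (or
    more) value modes separated by a density valley, while an exhausted
    coordinate is a featureless continuum.  The split is always a *global*
    cut (every state is assigned by the same boundary; a coherent group
    lying entirely on one side simply is not bifurcated further), located
    as follows:

    1. search the value density (Gaussian KDE) for an internal local
       minimum with at least ``min_mode_frac`` of the states on each side
       and a density no greater than ``valley_ratio`` times the lower of
       its two flanking maxima.  When ``groups`` (a partition of the
       states, e.g. the branches formed by the preceding levels) is given,
       the same search also runs on the values restricted to each group
       holding at least ``group_min_frac`` of the states — a mode
       structure confined to one major subset is diluted in the global
       density but obvious in the conditional one, while small converged
       branches are deliberately not allowed to nominate cuts.  The
       deepest qualifying valley, global or conditional, sets the cut.
    2. if no qualifying valley exists, split off the most separated
       extreme-value group smaller than ``min_mode_frac`` (the largest
       value spacing in either tail) — the small fully-converged splinter
       that structureless data is expected to shed at every level.  When
       even the tails are unremarkable (no spacing beyond
       ``TAIL_GAP_FACTOR`` times the median), the level is inert and all
       states receive the same bit: branches pass through unsplit, which
       is exactly how codes go unoccupied and clusters converge.

    For fewer than ``SMALL_N_EXACT_CUT`` states, where a density estimate
    is meaningless, the two-cluster cut at the final average-linkage merge
    is used directly.

    Label 0 marks the larger group (tie: the group with the smaller mean
    value).  The labeling is invariant, up to a global bit swap, under
    ``x -> -x`` and ``x -> x + c``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InputError("x must be a 1-D vector with at least two entries")
    if not np.all(np.isfinite(x)):
        raise InputError("x contains non-finite values")
    if np.ptp(x) == 0.0:
        raise DegenerateSplitError("all scalar values are equal; cannot bifurcate")
    if not (0 < min_mode_frac < 0.5):
        raise InputError("min_mode_frac must lie in (0, 0.5)")
    if not (0 < valley_ratio <= 1):
        raise InputError("valley_ratio must lie in (0, 1]")
    n = x.size
    if n < SMALL_N_EXACT_CUT:
        Z = linkage(x[:, None], method="average")
        flat = fcluster(Z, 2, criterion="maxclust")  # values in {1, 2}
        labels = (flat == 2).astype(np.uint8)
    else:
        candidates = []
        fields = [x]
        if groups is not None:
            groups = np.asarray(groups)
            if groups.shape != x.shape:
                raise InputError("groups must assign one group id per state")
            min_group = max(SMALL_N_EXACT_CUT, group_min_frac * n)
            for g in np.unique(groups):
                xg = x[groups == g]
                if xg.size >= min_group and np.ptp(xg) > 0:
                    fields.append(xg)
        for field_values in fields:
            valley = _density_valley(field_values, min_mode_frac)
            if valley is not None and valley[0] <= valley_ratio:
                candidates.append(valley)
        if candidates:
            _, threshold = min(candidates)
            labels = (x > threshold).astype(np.uint8)
        else:
            splinter = _tail_splinter(x, min_mode_frac)
            if splinter is None:  # inert level: nothing separates
                return np.zeros(n, dtype=np.uint8)
            labels = splinter
    size1 = int(labels.sum())
    size0 = n - size1
    swap = size1 > size0 or (
        size1 == size0 and x[labels == 1].mean() < x[labels == 0].mean()
    )
    if swap:
        labels = 1 - labels
    return labels


@dataclass
class BinaryCodeTable:
    """Per-state bit codes, one bit per eigenvector level.

    ``codes`` has shape ``(n, depth)`` with bit ``k`` (column ``k``) from
    the bifurcation of the eigenvector with the ``(k+1)``-th largest
    eigenvalue.  Levels that separated nothing carry a uniform 0 bit and
    are listed in ``inert_levels`` (1-based).
    """

    codes: np.ndarray
    depth: int
    inert_levels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[1] != self.depth:
            raise InputError(
                f"codes must have shape (n, depth={self.depth}); got {self.codes.shape}"
            )
        if self.codes.size and self.codes.max() > 1:
            raise InputError("codes must contain bits 0/1 only")
        self.inert_levels = tuple(int(k) for k in self.inert_levels)

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def strings(self) -> list[str]:
        return ["".join(str(b) for b in row) for row in self.codes]

    def occupied(self, depth: int | None = None) -> list[str]:
        """Distinct occupied code prefixes at the given depth."""
        depth = self.depth if depth is None else depth
        if not (1 <= depth <= self.depth):
            raise InputError(f"depth must be in [1, {self.depth}]")
        return sorted({s[:depth] for s in self.strings})


def assign_codes(
    solution: SpectralSolution,
    depth: int,
    min_mode_frac: float = 0.05,
    valley_ratio: float = 0.8,
) -> BinaryCodeTable:
    """Bifurcate the first ``depth`` eigenvectors into a binary code table.

    The constant zero-eigenvalue eigenvector (always the last) is never
    used, hence ``depth <= n - 1``.  A level that separates nothing —
    either degenerate (constant eigenvector) or with neither a qualifying
    density valley nor a significant tail splinter — contributes a
    uniform 0 bit and is flagged inert.
    """
    n = solution.n
    if not (1 <= depth <= n - 1):
        raise InputError(f"depth must satisfy 1 <= depth <= n-1 = {n - 1}")
    codes = np.zeros((n, depth), dtype=np.uint8)
    inert: list[int] = []
    for k in range(depth):
        groups = None
        if k > 0:
            _, groups = np.unique(codes[:, :k], axis=0, return_inverse=True)
        try:
            bits = bifurcate_scalar_field(
                solution.eigenvectors[:, k],
                min_mode_frac=min_mode_frac,
                valley_ratio=valley_ratio,
                groups=groups,
            )
        except DegenerateSplitError:
            inert.append(k + 1)
            continue
        codes[:, k] = bits
        if bits.min() == bits.max():  # nothing separated at this level
            inert.append(k + 1)
    return BinaryCodeTable(codes=codes, depth=depth, inert_levels=tuple(inert))


@dataclass
class DendrogramNode:
    """One occupied code prefix: its members, width and z-unit branch length.

    ``branch_length`` is the coloring merit of the splitting eigenvector
    over the *parent's* member set (both branches of a pair share it);
    the root has length 0.  ``creation_level`` is the level at which this
    member set first appeared (pass-through nodes inherit it).
    """

    prefix: str
    members: np.ndarray
    branch_length: float
    width: float
    creation_level: int
    children: list["DendrogramNode"] = field(default_factory=list)

    @property
    def level(self) -> int:
        return len(self.prefix)

    @property
    def count(self) -> int:
        return int(self.members.size)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class DendrogramTree:
    """Prefix tree over occupied binary codes with z-unit branch lengths."""

    root: DendrogramNode
    depth: int
    n: int
    nodes: dict[str, DendrogramNode]

    def node(self, prefix: str) -> DendrogramNode:
        try:
            return self.nodes[prefix]
        except KeyError:
            raise InputError(f"no occupied branch with code {prefix!r}") from None

    def levels(self, level: int) -> list[DendrogramNode]:
        """All occupied nodes whose prefix has the given length."""
        if not (0 <= level <= self.depth):
            raise InputError(f"level must be in [0, {self.depth}]")
        return [nd for nd in self.nodes.values() if nd.level == level]

    def leaves(self) -> list[DendrogramNode]:
        """Nodes at full depth (they partition the state set)."""
        return self.levels(self.depth)

    def to_dict(self, labels=None) -> dict:
        """JSON-ready summary: one record per occupied node."""
        recs = []
        for prefix in sorted(self.nodes, key=lambda p: (len(p), p)):
            nd = self.nodes[prefix]
            members = (
                [labels[i] for i in nd.members.tolist()]
                if labels is not None
                else nd.members.tolist()
            )
            recs.append(
                {
                    "code": prefix,
                    "level": nd.level,
                    "creation_level": nd.creation_level,
                    "count": nd.count,
                    "width": nd.width,
                    "branch_z": nd.branch_length,
                    "members": members,
                }
            )
        return {"n_states": self.n, "depth": self.depth, "nodes": recs}

    def to_newick(self) -> str:
        """Newick string; node labels are code prefixes, lengths are in z units."""

        def fmt(nd: DendrogramNode) -> str:
            label = nd.prefix if nd.prefix else "root"
            if nd.is_leaf:
                return f"{label}:{nd.branch_length:.10g}"
            inner = ",".join(fmt(c) for c in nd.children)
            return f"({inner}){label}:{nd.branch_length:.10g}"

        return fmt(self.root) + ";"


def build_dendrogram(
    codes: BinaryCodeTable,
    solution: SpectralSolution,
    A: AdjacencyMatrix,
    min_branch_z: float = 0.0,
) -> DendrogramTree:
    """Arrange occupied codes in a prefix tree with z-unit branch lengths.

    A split at level ``k`` assigns both children a branch length equal to
    the merit of eigenvector ``X_k`` over the parent's members.  If that
    merit falls below ``min_branch_z`` the split is suppressed and the node
    passes through unsplit (an optional significance cutoff; 0 disables it).
    """
    n = codes.n
    if solution.n != n or A.n != n:
        raise InputError("codes, solution and adjacency refer to different state counts")
    bits = codes.codes
    root = DendrogramNode(
        prefix="",
        members=np.arange(n),
        branch_length=0.0,
        width=1.0,
        creation_level=0,
    )
    nodes = {"": root}
    stack = [root]
    while stack:
        node = stack.pop()
        k = node.level  # 0-based index of the next splitting eigenvector
        if k >= codes.depth:
            continue
        z = coloring_merit(solution.eigenvectors[:, k], A, subset=node.members)
        node_bits = bits[node.members, k]
        halves = [node.members[node_bits == b] for b in (0, 1)]
        suppress = 0.0 < z < min_branch_z
        if suppress or not all(h.size for h in halves):
            # pass-through: single child, identical member set
            b = 0 if (suppress or halves[0].size) else 1
            child = DendrogramNode(
                prefix=node.prefix + str(b),
                members=node.members,
                branch_length=z,
                width=node.width,
                creation_level=node.creation_level,
            )
            node.children.append(child)
            nodes[child.prefix] = child
            stack.append(child)
            continue
        for b, mem in enumerate(halves):
            child = DendrogramNode(
                prefix=node.prefix + str(b),
                members=mem,
                branch_length=z,
                width=mem.size / n,
                creation_level=k + 1,
            )
            node.children.append(child)
            nodes[child.prefix] = child
            stack.append(child)
    return DendrogramTree(root=root, depth=codes.depth, n=n, nodes=nodes)


def converged_clusters(tree: DendrogramTree, depth: int | None = None) -> list[np.ndarray]:
    """Member sets of branches that undergo no splitting up to ``depth``.

    Every branch at ``depth`` is traced back to the level at which its
    member set was created; the returned sets are those stable member sets
    (disjoint, and jointly covering all states).  Branches created at
    ``depth`` itself are trivially included.
    """
    depth = tree.depth if depth is None else int(depth)
    if depth > tree.depth:
        raise InputError(
            f"requested depth {depth} exceeds the built tree depth {tree.depth}"
        )
    if depth < 0:
        raise InputError("depth must be nonnegative")
    return [nd.members.copy() for nd in tree.levels(depth)]
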