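"""Besag (ICAR) structure from a province adjacency graph, with scaling.

The intrinsic CAR ("Besag") model says that a province's effect,
conditional on all others, is centred at the mean of its neighbours with
variance inversely proportional to the neighbour count; the implied
precision structure is ``R = D - A`` (degree matrix minus adjacency).

``R`` is rank-deficient (one flat direction per connected component) and
its implicit marginal variances depend on the graph, so a variance
parameter placed in front of it is not comparable across graphs.  The
scaled-Besag convention fixes this: each connected component's block is
rescaled so that the geometric mean of the marginal variances — computed
under a within-component sum-to-zero constraint via the generalized
inverse — equals one.  Components with a single node (islands without
internal edges) carry no spatial structure and fall back to an
independent standard-normal effect.  These per-component adjustments are
what make the BYM2 mixing parameter interpretable on a disconnected
graph such as Italy's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import ValidationError

__all__ = [
    "AdjacencyGraph",
    "ScaledStructure",
    "read_graph",
    "write_graph",
    "connected_components",
    "besag_structure",
    "scale_structure",
    "scaled_besag",
    "besag_basis",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbour structure over nodes 1..n (no self-loops)."""

    n_nodes: int
    neighbors: dict[int, frozenset[int]]

    def __post_init__(self) -> None:
        for i in range(1, self.n_nodes + 1):
            if i not in self.neighbors:
                raise ValidationError(f"node {i} missing from neighbor map")
        for i, nbrs in self.neighbors.items():
            if not (1 <= i <= self.n_nodes):
                raise ValidationError(f"node id {i} out of range 1..{self.n_nodes}")
            if i in nbrs:
                raise ValidationError(f"self-loop at node {i}")
            for j in nbrs:
                if not (1 <= j <= self.n_nodes):
                    raise ValidationError(f"neighbor id {j} of node {i} out of range")
                if i not in self.neighbors[j]:
                    raise ValidationError(f"asymmetric adjacency: {i}->{j} but not {j}->{i}")

    @property
    def components(self) -> tuple[tuple[int, ...], ...]:
        return connected_components(self)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_nodes + 1))
        g.add_edges_from((i, j) for i, nbrs in self.neighbors.items() for j in nbrs if i < j)
        return g


@dataclass(frozen=True)
class ScaledStructure:
    """Scaled Besag precision structure with per-component metadata.

    ``structure`` is the symmetric PSD matrix Q* whose variance parameter
    is unit-scaled per component; singleton components have a 1 on the
    diagonal (independent standard-normal fallback).  ``component_scales``
    stores the multiplier applied to each component block (1.0 for
    singletons) and ``null_space_dim`` the number of non-singleton
    components, i.e. the number of sum-to-zero constraints needed.
    """

    structure: np.ndarray
    components: tuple[tuple[int, ...], ...]
    component_scales: tuple[float, ...]
    null_space_dim: int

    @property
    def n_nodes(self) -> int:
        return self.structure.shape[0]


# ---------------------------------------------------------------------------
# graph file dialect: first line "n"; then one line per node
# "node_id degree neighbor ...".


def read_graph(path) -> AdjacencyGraph:
    """Read a neighbor-list graph file; asymmetric listings are symmetrized with a warning."""
    with open(path) as fh:
        tokens_per_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_per_line:
        raise ValidationError(f"empty graph file {path}")
    n = int(tokens_per_line[0][0])
    listed: dict[int, set[int]] = {i: set() for i in range(1, n + 1)}
    for toks in tokens_per_line[1:]:
        node = int(toks[0])
        if not (1 <= node <= n):
            raise ValidationError(f"node id {node} out of range 1..{n}")
        degree, nbrs = int(toks[1]), [int(t) for t in toks[2:]]
        if len(nbrs) != degree:
            raise ValidationError(f"node {node}: declared degree {degree} but {len(nbrs)} neighbors listed")
        for j in nbrs:
            if j == node:
                raise ValidationError(f"self-loop at node {node}")
            if not (1 <= j <= n):
                raise ValidationError(f"neighbor id {j} of node {node} out of range 1..{n}")
        listed[node].update(nbrs)
    asym = [(i, j) for i, nbrs in listed.items() for j in nbrs if i not in listed[j]]
    if asym:
        warnings.warn(f"symmetrizing {len(asym)} one-sided adjacency listings (e.g. {asym[0]})")
        for i, j in asym:
            listed[j].add(i)
    return AdjacencyGraph(n, {i: frozenset(nbrs) for i, nbrs in listed.items()})


def write_graph(graph: AdjacencyGraph, path) -> None:
    """Write the same neighbor-list dialect ``read_graph`` reads."""
    with open(path, "w") as fh:
        fh.write(f"{graph.n_nodes}\n")
        for i in range(1, graph.n_nodes + 1):
            nbrs = sorted(graph.neighbors[i])
            fh.write(" ".join(str(x) for x in [i, len(nbrs), *nbrs]) + "\n")


def connected_components(graph: AdjacencyGraph) -> tuple[tuple[int, ...], ...]:
    """Connected components as sorted tuples, ordered by smallest member."""
    comps = [tuple(sorted(c)) for c in nx.connected_components(graph.to_networkx())]
    return tuple(sorted(comps, key=lambda c: c[0]))


# ---------------------------------------------------------------------------
# structure matrices


def besag_structure(graph: AdjacencyGraph) -> np.ndarray:
    """Intrinsic CAR structure R = D - A implied by the neighbour-average conditionals."""
    n = graph.n_nodes
    R = np.zeros((n, n))
    for i in range(1, n + 1):
        nbrs = graph.neighbors[i]
        R[i - 1, i - 1] = len(nbrs)
        for j in nbrs:
            R[i - 1, j - 1] = -1.0
    return R


def _constrained_marginal_variances(block: np.ndarray) -> np.ndarray:
    """Marginal variances of the intrinsic field under the component sum-to-zero constraint.

    For a connected Besag block the null space is the constant vector, so
    the Moore-Penrose pseudo-inverse *is* the covariance of the
    sum-to-zero constrained field.
    """
    return np.diag(np.linalg.pinv(block, hermitian=True)).copy()


def scale_structure(R: np.ndarray, components: tuple[tuple[int, ...], ...]) -> ScaledStructure:
    """Rescale each component block of ``R`` to unit geometric-mean marginal variance.

    Singleton components (no internal edges) get a diagonal 1, i.e. an
    independent standard-normal effect, so that the variance parameter in
    front of the scaled structure means the same thing for every node.
    """
    Q = np.array(R, dtype=float, copy=True)
    scales: list[float] = []
    null_dim = 0
    for comp in components:
        idx = np.array(comp) - 1
        if len(comp) == 1:
            assert R[idx[0], idx[0]] == 0.0, "singleton component with edges"
            Q[idx[0], idx[0]] = 1.0
            scales.append(1.0)
            continue
        block = R[np.ix_(idx, idx)]
        assert block.diagonal().min() > 0, "multi-node component with an isolated node"
        mvars = _constrained_marginal_variances(block)
        gm = float(np.exp(np.mean(np.log(mvars))))
        # multiplying the precision block by gm divides variances by gm
        Q[np.ix_(idx, idx)] = block * gm
        scales.append(gm)
        null_dim += 1
    return ScaledStructure(Q, tuple(tuple(c) for c in components), tuple(scales), null_dim)


def scaled_besag(graph: AdjacencyGraph) -> ScaledStructure:
    """Convenience: besag_structure + connected_components + scale_structure."""
    return scale_structure(besag_structure(graph), connected_components(graph))


def besag_basis(scaled: ScaledStructure) -> np.ndarray:
    """Orthogonal sampling basis B with u = B eta, eta ~ N(0, I).

    Columns span the proper subspace of the scaled structure (sum-to-zero
    within each non-singleton component) plus a unit vector per
    singleton, so ``B @ B.T`` equals the constrained covariance and draws
    ``B @ standard_normal`` realize the scaled Besag field exactly.
    """
    n = scaled.n_nodes
    cols: list[np.ndarray] = []
    for comp in scaled.components:
        idx = np.array(comp) - 1
        if len(comp) == 1:
            e = np.zeros(n)
            e[idx[0]] = 1.0
            cols.append(e)
            continue
        block = scaled.structure[np.ix_(idx, idx)]
        evals, evecs = np.linalg.eigh(block)
        keep = evals > 1e-10 * evals.max()
        for lam, vec in zip(evals[keep], evecs[:, keep].T):
            col = np.zeros(n)
            col[idx] = vec / np.sqrt(lam)
            cols.append(col)
    return np.column_stack(cols)
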