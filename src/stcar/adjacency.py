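"""Areal adjacency structures and the Leroux-type GMRF precision matrix.

The spatial skeleton of the model is an undirected graph over the K areal
units.  Spatial smoothing strength between adjacent areas k and j is carried
by a weight w_kj in (0, 1]; in the standard model all weights are 1 (binary
contiguity), while the adaptive variant treats them as unknowns.

The precision matrix interpolates between independence and the intrinsic
CAR (graph Laplacian) model:

    Q(W, rho) = rho * [diag(W 1) - W] + (1 - rho) * I,    rho in [0, 1].

Q is positive definite for rho < 1 (its eigenvalues are bounded below by
1 - rho) and singular at rho = 1, where it equals the weighted Laplacian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["AdjacencyStructure", "make_lattice", "build_precision"]


@dataclass
class AdjacencyStructure:
    """Symmetric weighted adjacency over K areal units.

    Parameters
    ----------
    area_ids : list
        Labels of the K areas, in the canonical order used throughout the
        package (rows of the precision matrix, rows of the random-effect
        field, ...).
    edges : ndarray of shape (n_edges, 2)
        Integer index pairs (i, j) with i < j, each unordered pair listed
        once.  No self edges.
    weights : ndarray of shape (n_edges,)
        Edge weights in (0, 1].  Defaults to all ones (binary contiguity).
    """

    area_ids: list
    edges: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.area_ids = list(self.area_ids)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.weights is None:
            self.weights = np.ones(len(self.edges))
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        K = self.K
        if K < 2:
            raise ValueError("an adjacency structure needs at least 2 areas")
        if len(self.weights) != len(self.edges):
            raise ValueError("weights and edges must have the same length")
        if len(self.edges):
            if self.edges.min() < 0 or self.edges.max() >= K:
                raise ValueError("edge indices out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-edges (w_kk != 0) are not allowed")
            # canonicalise: i < j, unique pairs
            lo = self.edges.min(axis=1)
            hi = self.edges.max(axis=1)
            pairs = np.stack([lo, hi], axis=1)
            keys = pairs[:, 0] * K + pairs[:, 1]
            if len(np.unique(keys)) != len(pairs):
                raise ValueError("duplicate edges in edge list")
            order = np.argsort(keys)  # canonical lexicographic edge order
            self.edges = pairs[order]
            self.weights = self.weights[order]
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("edge weights must lie in (0, 1]")
        if not self.is_connected():
            warnings.warn("adjacency graph is not connected", stacklevel=2)

    @property
    def K(self) -> int:
        return len(self.area_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def area_index(self) -> dict:
        return {a: i for i, a in enumerate(self.area_ids)}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.K))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph())

    def weight_matrix(self, weights: np.ndarray | None = None) -> sp.csr_matrix:
        """Symmetric K x K weight matrix W (zero diagonal)."""
        w = self.weights if weights is None else np.asarray(weights, float)
        i, j = self.edges.T
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        vals = np.concatenate([w, w])
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.K, self.K))

    def degrees(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Weighted degree vector W 1."""
        w = self.weights if weights is None else np.asarray(weights, float)
        d = np.zeros(self.K)
        np.add.at(d, self.edges[:, 0], w)
        np.add.at(d, self.edges[:, 1], w)
        return d

    def laplacian(self, weights: np.ndarray | None = None) -> sp.csr_matrix:
        """Weighted graph Laplacian diag(W 1) - W."""
        W = self.weight_matrix(weights)
        return sp.diags(self.degrees(weights)) - W

    def coloring(self) -> np.ndarray:
        """Greedy proper colouring of the area graph.

        Areas of the same colour share no edge, so their random effects are
        conditionally independent given the rest of the field (within one
        month); the sampler uses this to batch single-site updates.
        """
        cmap = nx.greedy_color(self.graph(), strategy="largest_first")
        return np.array([cmap[i] for i in range(self.K)], dtype=np.int64)

    def permute(self, perm: np.ndarray) -> "AdjacencyStructure":
        """Relabel areas: new index of old area i is perm[i]."""
        perm = np.asarray(perm, dtype=np.int64)
        new_ids = [None] * self.K
        for old, new in enumerate(perm):
            new_ids[new] = self.area_ids[old]
        return AdjacencyStructure(new_ids, perm[self.edges], self.weights.copy())


def make_lattice(rows: int, cols: int) -> AdjacencyStructure:
    """Rook-adjacency lattice of rows x cols areas.

    Area ids are strings ``"a{r}_{c}"``; the edge count is
    rows*(cols-1) + cols*(rows-1).
    """
    if rows < 2 or cols < 2:
        raise ValueError("lattice dimensions must both be >= 2")
    ids = [f"a{r}_{c}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c
            if c + 1 < cols:
                edges.append((k, k + 1))
            if r + 1 < rows:
                edges.append((k, k + cols))
    return AdjacencyStructure(ids, np.array(edges))


def build_precision(
    adjacency: AdjacencyStructure,
    rho: float,
    weights: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Leroux precision matrix Q(W, rho) = rho[diag(W1) - W] + (1 - rho)I.

    Symmetric; positive definite for rho < 1; equals the (singular) graph
    Laplacian at rho = 1.

    Parameters
    ----------
    adjacency : AdjacencyStructure
    rho : float in [0, 1]
        Spatial dependence parameter (0 = independence, 1 = intrinsic CAR).
    weights : optional override of the structure's edge weights.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    K = adjacency.K
    return (rho * adjacency.laplacian(weights) + (1.0 - rho) * sp.identity(K)).tocsr()
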