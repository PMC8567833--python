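"""Connectome input/output and probabilistic binarization.

The raw unit of analysis is a weighted, undirected connectome whose weights
are fractional-anisotropy (FA) values in [0, 1].  FA measures the directional
coherence of water diffusion along a white-matter tract and, being bounded in
[0, 1], is interpreted here as the probability that a structural link exists.
Binarization therefore draws, for every node pair, a uniform random number and
keeps the link when the FA weight exceeds it — one Bernoulli(w_ij) coin per
unordered pair, so the sampled graph is always symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "WeightedConnectome",
    "BinaryGraph",
    "read_weighted_matrix",
    "write_weighted_matrix",
    "binarize_fa",
    "largest_component",
]

_SYM_TOL = 1e-12


def _default_labels(n: int) -> list[str]:
    return [f"node{i}" for i in range(n)]


@dataclass(frozen=True)
class WeightedConnectome:
    """Labeled symmetric FA-weight matrix with entries in [0, 1], zero diagonal.

    Parameters
    ----------
    W : (N, N) ndarray
        Symmetric matrix of link probabilities w_ij in [0, 1].
    node_labels : sequence of str
        Region identifiers, in matrix order.
    """

    W: np.ndarray
    node_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {W.shape}")
        if np.isnan(W).any():
            raise ValueError("weight matrix contains NaN entries")
        asym = np.abs(W - W.T).max() if W.size else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"weight matrix asymmetry {asym:.3g} exceeds {_SYM_TOL}")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        if W.min() < 0.0 or W.max() > 1.0:
            raise ValueError("weights must lie in [0, 1]")
        labels = self.node_labels
        if labels is None:
            labels = _default_labels(W.shape[0])
        labels = tuple(str(x) for x in labels)
        if len(labels) != W.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for a {W.shape[0]}-node matrix"
            )
        W.setflags(write=False)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Simple undirected graph as a symmetric 0/1 adjacency with zero diagonal."""

    A: np.ndarray
    node_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        vals = np.unique(A)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        A = A.astype(np.int8)
        if np.diagonal(A).any():
            raise ValueError("self-loops are not allowed")
        labels = self.node_labels
        if labels is None:
            labels = _default_labels(A.shape[0])
        labels = tuple(str(x) for x in labels)
        if len(labels) != A.shape[0]:
            raise ValueError(f"{len(labels)} labels for a {A.shape[0]}-node graph")
        A.setflags(write=False)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.A.sum(axis=1).astype(np.int64)

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        n_comp, _ = connected_components(csr_matrix(self.A), directed=False)
        return n_comp == 1


def read_weighted_matrix(
    path: str | Path,
    fmt: str = "dense",
    one_based: bool = False,
    n_nodes: int | None = None,
) -> WeightedConnectome:
    """Read a weighted connectome from a plain-text file.

    Parameters
    ----------
    path : path
        Input file.
    fmt : {"dense", "edgelist"}
        ``dense``: N x N numeric text, whitespace- or comma-separated.
        ``edgelist``: rows of ``i j w``.
    one_based : bool
        Edge-list node indices start at 1 instead of 0.
    n_nodes : int, optional
        Force the node count for edge lists (otherwise max index + 1).
    """
    path = Path(path)
    if fmt == "dense":
        text = path.read_text()
        delimiter = "," if "," in text.splitlines()[0] else None
        W = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        return WeightedConnectome(W)
    if fmt == "edgelist":
        rows = np.loadtxt(path, ndmin=2)
        if rows.shape[1] != 3:
            raise ValueError("edge list must have three columns: i j w")
        i = rows[:, 0].astype(int)
        j = rows[:, 1].astype(int)
        if one_based:
            i, j = i - 1, j - 1
        if i.min(initial=0) < 0 or j.min(initial=0) < 0:
            raise ValueError("negative node index in edge list")
        n = n_nodes if n_nodes is not None else int(max(i.max(), j.max())) + 1
        W = np.zeros((n, n))
        W[i, j] = rows[:, 2]
        W[j, i] = rows[:, 2]
        return WeightedConnectome(W)
    raise ValueError(f"unknown format {fmt!r}")


def write_weighted_matrix(
    conn: WeightedConnectome, path: str | Path, fmt: str = "dense"
) -> None:
    """Write a connectome as dense text or an (i, j, w) edge list (0-based)."""
    path = Path(path)
    if fmt == "dense":
        np.savetxt(path, conn.W, fmt="%.17g")
    elif fmt == "edgelist":
        iu, ju = np.triu_indices(conn.n_nodes, k=1)
        mask = conn.W[iu, ju] > 0
        with path.open("w") as fh:
            for a, b, w in zip(iu[mask], ju[mask], conn.W[iu, ju][mask]):
                fh.write(f"{a} {b} {w:.17g}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def binarize_fa(
    conn: WeightedConnectome, seed: int | np.random.Generator
) -> BinaryGraph:
    """Sample a binary graph from FA link probabilities.

    For each unordered pair {i, j} one uniform variate r ~ U(0, 1) is drawn and
    the edge exists iff w_ij > r, i.e. each edge is an independent
    Bernoulli(w_ij) draw.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    n = conn.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    r = rng.random(iu.size)
    edges = conn.W[iu, ju] > r
    A = np.zeros((n, n), dtype=np.int8)
    A[iu[edges], ju[edges]] = 1
    A[ju[edges], iu[edges]] = 1
    return BinaryGraph(A, conn.node_labels)


def largest_component(g: BinaryGraph) -> BinaryGraph:
    """Induced subgraph on the largest connected component.

    Ties between equal-sized components are broken in favour of the component
    containing the smallest node index.  Original node labels are retained.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot take the largest component of an empty graph")
    n_comp, membership = connected_components(csr_matrix(g.A), directed=False)
    sizes = np.bincount(membership, minlength=n_comp)
    # connected_components labels components in order of first node encountered,
    # so argmax on sizes already prefers the smallest minimum node index on ties
    keep = membership == int(np.argmax(sizes))
    idx = np.flatnonzero(keep)
    A = g.A[np.ix_(idx, idx)]
    labels = tuple(g.node_labels[i] for i in idx)
    return BinaryGraph(A, labels)


def write_node_table(
    labels: Sequence[str], values: Sequence[float], path: str | Path
) -> None:
    """Export a (label, value) node table as two-column CSV."""
    pd.DataFrame({"label": list(labels), "value": list(values)}).to_csv(
        path, index=False
    )
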