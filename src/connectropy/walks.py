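"""Random-walk dynamics on binary connectomes.

Two diffusive processes probe information flow on a graph:

* **CRW** — the classical random walk.  The walker only knows its local
  neighbourhood and jumps uniformly over incident edges:
  ``T_ij = A_ij / k_i``.
* **MERW** — the maximal-entropy random walk.  The walker uses global
  knowledge of the topology so that all trajectories of equal length between
  two nodes are equiprobable.  With ``a_N`` the leading adjacency eigenvalue
  and ``q`` its (positive, Perron) eigenvector,
  ``T_ij = A_ij q_j / (a_N q_i)``.

Both walks share the Laplacian ``L = I - T`` that generates the
continuous-time master equation ``dp/dτ = -p L`` with solution
``p(τ) = p(0) e^{-τL}``.

The Laplacian spectra used downstream are computed from symmetric similar
matrices (``D^{-1/2} A D^{-1/2}`` for CRW, ``A / a_N`` for MERW), which keeps
them exactly real: CRW and MERW Laplacian eigenvalues both lie in [0, 2].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .io import BinaryGraph

__all__ = [
    "WalkKind",
    "WalkSystem",
    "crw_system",
    "merw_system",
    "walk_system",
    "laplacian_spectrum",
    "evolve",
    "steady_state_map",
]


class WalkKind(str, enum.Enum):
    """The two walk dynamics: local-knowledge CRW, global-knowledge MERW."""

    CRW = "crw"
    MERW = "merw"


@dataclass(frozen=True)
class WalkSystem:
    """Transition matrix, Laplacian and stationary state of one walk.

    Attributes
    ----------
    kind : WalkKind
    T : (N, N) ndarray
        Row-stochastic transition matrix.
    L : (N, N) ndarray
        ``I - T``.
    pi : (N,) ndarray
        Stationary distribution (left Perron vector of T).
    a_N : float or None
        Leading adjacency eigenvalue (MERW only).
    q : (N,) ndarray or None
        Positive unit-norm leading adjacency eigenvector (MERW only).
    lambdas : (N,) ndarray
        Real eigenvalues of L, ascending.
    """

    kind: WalkKind
    T: np.ndarray
    L: np.ndarray
    pi: np.ndarray
    lambdas: np.ndarray
    a_N: float | None = None
    q: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.T.shape[0]


def crw_system(g: BinaryGraph) -> WalkSystem:
    """Classical random walk: T_ij = A_ij / k_i, pi_i = k_i / 2M."""
    A = g.A.astype(float)
    k = A.sum(axis=1)
    isolated = np.flatnonzero(k == 0)
    if isolated.size:
        labels = [g.node_labels[i] for i in isolated[:5]]
        raise ValueError(
            f"isolated node(s) {labels} have no edges; the classical walk is "
            "undefined there — remove them (largest_component) first"
        )
    T = A / k[:, None]
    L = np.eye(g.n_nodes) - T
    pi = k / k.sum()
    # symmetric similar matrix D^{-1/2} A D^{-1/2} gives the exact real spectrum
    s = 1.0 / np.sqrt(k)
    sym = A * s[:, None] * s[None, :]
    lambdas = np.sort(1.0 - scipy.linalg.eigvalsh(sym))
    return WalkSystem(WalkKind.CRW, T, L, pi, lambdas)


def merw_system(g: BinaryGraph) -> WalkSystem:
    """Maximal-entropy random walk from the adjacency Perron eigenpair.

    Requires a connected graph so that the Perron vector is strictly positive;
    disconnected inputs are rejected rather than silently fixed.
    """
    if not g.is_connected():
        raise ValueError(
            "MERW requires a connected graph (the Perron eigenvector must be "
            "positive); apply largest_component first"
        )
    A = g.A.astype(float)
    evals, evecs = scipy.linalg.eigh(A)
    a_N = float(evals[-1])
    q = evecs[:, -1]
    if q.sum() < 0:
        q = -q
    if q.min() <= 0:  # pragma: no cover - Perron–Frobenius guarantees positivity
        raise ValueError("leading eigenvector is not strictly positive")
    q = q / np.linalg.norm(q)
    T = A * q[None, :] / (a_N * q[:, None])
    L = np.eye(g.n_nodes) - T
    pi = q**2 / np.sum(q**2)
    lambdas = np.sort(1.0 - evals / a_N)
    return WalkSystem(WalkKind.MERW, T, L, pi, lambdas, a_N=a_N, q=q)


def walk_system(g: BinaryGraph, kind: WalkKind | str) -> WalkSystem:
    """Dispatch to :func:`crw_system` or :func:`merw_system`."""
    kind = WalkKind(kind)
    return crw_system(g) if kind is WalkKind.CRW else merw_system(g)


def laplacian_spectrum(g: BinaryGraph, kind: WalkKind | str) -> np.ndarray:
    """Real ascending eigenvalues of the walk Laplacian L = I - T."""
    return walk_system(g, kind).lambdas


def evolve(p0: np.ndarray, sys: WalkSystem, tau: float) -> np.ndarray:
    """Propagate an occupation probability: p(τ) = p(0) e^{-τL}.

    The master equation in continuous time conserves total probability, so the
    result is renormalized only against round-off.
    """
    if tau < 0:
        raise ValueError("Markov time tau must be nonnegative")
    p0 = np.asarray(p0, dtype=float)
    if p0.min() < 0 or abs(p0.sum() - 1.0) > 1e-12:
        raise ValueError("p0 must be a probability vector")
    p = p0 @ scipy.linalg.expm(-tau * sys.L)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def steady_state_map(sys: WalkSystem, labels) -> pd.DataFrame:
    """Stationary occupation per node, the exported brain-map surrogate.

    Returns a (label, pi) table in input node order; for CRW ``pi`` is
    proportional to degree, for MERW to the squared Perron eigenvector.
    """
    labels = list(labels)
    if len(labels) != sys.n_nodes:
        raise ValueError("label count does not match system size")
    return pd.DataFrame({"label": labels, "pi": sys.pi})
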