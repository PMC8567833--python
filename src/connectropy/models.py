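"""Generative network models fitted per connectome, as fit/sample estimators.

Four null/generative ensembles of increasing structural complexity are fitted
to each binarized connectome and sampled to form synthetic ensembles:

* :class:`ErdosRenyiModel` — G(N, M): same node and edge count, structure
  otherwise random.
* :class:`ConfigurationModel` — exact degree sequence, randomized by
  degree-preserving double-edge swaps on simple graphs.
* :class:`DegreeCorrectedSBM` — modular (block) structure plus per-node degree
  propensities, fitted by greedy agglomerative minimization of a
  description-length criterion and sampled with the Karrer–Newman kernel.
* :class:`HyperbolicS1Model` — latent-geometry S¹ model with per-node
  popularity (kappa) and angular similarity (theta) coordinates, and a global
  clustering parameter beta.

All estimators follow the scikit-learn convention: parameters in
``__init__``, ``fit(g)`` storing fitted attributes with a trailing
underscore and returning ``self``, and ``sample(n_samples, seed)`` returning
a list of :class:`~connectropy.io.BinaryGraph`.  Every sampled graph is
simple (no self-loops or multi-edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .entropy import EntropyCurve, curve_from_spectrum, default_tau_grid
from .io import BinaryGraph, largest_component
from .walks import WalkKind, laplacian_spectrum

__all__ = [
    "ErdosRenyiModel",
    "ConfigurationModel",
    "DegreeCorrectedSBM",
    "HyperbolicS1Model",
    "MODEL_FAMILIES",
    "EnsembleResult",
    "ensemble_entropy",
]


def _as_graph(g: BinaryGraph | np.ndarray) -> BinaryGraph:
    return g if isinstance(g, BinaryGraph) else BinaryGraph(np.asarray(g))


class _GraphModel(BaseEstimator):
    """Shared helpers for fit/sample graph estimators."""

    family: str = ""

    def _check_fitted(self) -> None:
        if not hasattr(self, "n_nodes_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")

    def sample_one(self, rng: np.random.Generator) -> BinaryGraph:
        raise NotImplementedError

    def sample(
        self, n_samples: int = 1, seed: int | np.random.Generator | None = None
    ) -> list[BinaryGraph]:
        """Draw ``n_samples`` independent realizations; deterministic per seed."""
        self._check_fitted()
        rng = np.random.default_rng(seed)
        return [self.sample_one(rng) for _ in range(n_samples)]

    def spec_dict(self) -> dict:
        """Key-value summary of the fitted model for serialization."""
        self._check_fitted()
        return {"family": self.family, "n_nodes": int(self.n_nodes_)}


class ErdosRenyiModel(_GraphModel):
    """Uniform random graph G(N, M) matching node and edge counts."""

    family = "ERM"

    def fit(self, g: BinaryGraph | np.ndarray, y=None) -> "ErdosRenyiModel":
        g = _as_graph(g)
        n, m = g.n_nodes, g.n_edges
        if n < 2:
            raise ValueError("need at least 2 nodes")
        if m > n * (n - 1) // 2:
            raise ValueError("edge count exceeds the simple-graph maximum")
        self.n_nodes_ = n
        self.n_edges_ = m
        return self

    def sample_one(self, rng: np.random.Generator) -> BinaryGraph:
        n = self.n_nodes_
        iu, ju = np.triu_indices(n, k=1)
        pick = rng.choice(iu.size, size=self.n_edges_, replace=False)
        A = np.zeros((n, n), dtype=np.int8)
        A[iu[pick], ju[pick]] = 1
        A[ju[pick], iu[pick]] = 1
        return BinaryGraph(A)

    def spec_dict(self) -> dict:
        d = super().spec_dict()
        d["n_edges"] = int(self.n_edges_)
        return d


class ConfigurationModel(_GraphModel):
    """Degree-preserving randomization by double-edge swaps on simple graphs.

    Each sample starts from the fitted graph and applies ``swap_factor * M``
    attempted double-edge swaps; a swap is rejected whenever it would create a
    self-loop or a multi-edge, so the degree sequence is preserved exactly and
    the graph stays simple.
    """

    family = "CM"

    def __init__(self, swap_factor: int = 10):
        self.swap_factor = swap_factor

    def fit(self, g: BinaryGraph | np.ndarray, y=None) -> "ConfigurationModel":
        g = _as_graph(g)
        iu, ju = np.nonzero(np.triu(g.A, k=1))
        self.n_nodes_ = g.n_nodes
        self.edges_ = np.column_stack([iu, ju]).astype(np.int64)
        self.degrees_ = g.degrees
        return self

    def sample_one(self, rng: np.random.Generator) -> BinaryGraph:
        n = self.n_nodes_
        edges = self.edges_.copy()
        m = len(edges)
        present = {(int(u), int(v)) for u, v in edges}
        if m >= 2:
            n_attempts = self.swap_factor * m
            idx = rng.integers(0, m, size=(n_attempts, 2))
            flips = rng.random(n_attempts) < 0.5
            for (e1, e2), flip in zip(idx, flips):
                if e1 == e2:
                    continue
                u, v = edges[e1]
                x, y = edges[e2]
                if flip:
                    x, y = y, x
                # proposed rewiring: (u,v),(x,y) -> (u,x),(v,y)
                if u == x or v == y:
                    continue
                a = (min(u, x), max(u, x))
                b = (min(v, y), max(v, y))
                if a in present or b in present:
                    continue
                present.discard((int(min(u, v)), int(max(u, v))))
                present.discard(
                    (int(min(edges[e2][0], edges[e2][1])),
                     int(max(edges[e2][0], edges[e2][1])))
                )
                present.add((int(a[0]), int(a[1])))
                present.add((int(b[0]), int(b[1])))
                edges[e1] = a
                edges[e2] = b
        A = np.zeros((n, n), dtype=np.int8)
        if m:
            A[edges[:, 0], edges[:, 1]] = 1
            A[edges[:, 1], edges[:, 0]] = 1
        return BinaryGraph(A)

    def spec_dict(self) -> dict:
        d = super().spec_dict()
        d["degrees"] = self.degrees_.tolist()
        return d


def _f(m: np.ndarray, x: np.ndarray) -> np.ndarray:
    """m * ln(m / x) with the 0 * ln 0 = 0 convention."""
    out = np.zeros(np.broadcast(m, x).shape)
    mask = np.asarray(m) > 0
    mm = np.broadcast_to(m, out.shape)[mask]
    xx = np.broadcast_to(x, out.shape)[mask]
    out[mask] = mm * np.log(mm / xx)
    return out


class DegreeCorrectedSBM(_GraphModel):
    """Degree-corrected stochastic block model: fit by agglomeration, sample
    with the Karrer–Newman kernel.

    Fitting starts from one block per node and greedily merges the pair of
    blocks that most decreases a description-length criterion

        DL(b) = -sum_rs m_rs ln(m_rs / (kappa_r kappa_s))
                + B(B+1)/2 * ln(2M) + N ln B,

    where ``m_rs`` are inter-block edge counts (diagonal counted twice),
    ``kappa_r`` block total degrees, B the block count.  The first term is the
    (negative, unnormalized) degree-corrected block-model log-likelihood; the
    penalty prices the block-affinity matrix and the node partition.  Merging
    stops when no candidate merge decreases DL.  ``n_restarts`` randomized
    greedy runs are performed and the lowest-DL partition kept.

    Sampling places an edge between i and j with probability
    ``1 - exp(-omega_ij)`` where ``omega_ij = k_i k_j e_{b_i b_j} /
    (kappa_{b_i} kappa_{b_j})`` is the expected Poisson multiplicity;
    collapsing multiplicities and dropping self-loops keeps the graph simple.
    """

    family = "DCSBM"

    def __init__(
        self,
        max_B: int | None = None,
        n_restarts: int = 10,
        random_state: int | None = None,
    ):
        self.max_B = max_B
        self.n_restarts = n_restarts
        self.random_state = random_state

    # ---- description length machinery -------------------------------------

    @staticmethod
    def _dl(m: np.ndarray, kappa: np.ndarray, n_nodes: int, M: int) -> float:
        B = len(kappa)
        loglik = _f(m, np.outer(kappa, kappa)).sum()
        penalty = B * (B + 1) / 2 * np.log(max(2 * M, 2)) + n_nodes * np.log(B)
        return float(-loglik + penalty)

    @staticmethod
    def _merge_deltas(
        m: np.ndarray, kappa: np.ndarray, pairs: np.ndarray, n_nodes: int, M: int
    ) -> np.ndarray:
        """Change in DL for merging each candidate block pair (vectorized)."""
        B = len(kappa)
        r, s = pairs[:, 0], pairs[:, 1]
        kr, ks = kappa[r], kappa[s]
        ku = kr + ks
        mr, ms = m[r], m[s]  # (P, B)
        # old off-diagonal contribution of rows r and s (t runs over all blocks)
        old_r = _f(mr, kr[:, None] * kappa[None, :]).sum(axis=1)
        old_s = _f(ms, ks[:, None] * kappa[None, :]).sum(axis=1)
        mrr = m[r, r]
        mss = m[s, s]
        mrs = m[r, s]
        f_rr = _f(mrr, kr * kr)
        f_ss = _f(mss, ks * ks)
        f_rs = _f(mrs, kr * ks)
        f_sr = _f(mrs, ks * kr)
        old_off = 2 * (old_r - f_rr - f_rs + old_s - f_ss - f_sr)
        old = old_off + f_rr + f_ss + 2 * f_rs
        # merged row u = r + s
        mu_row = mr + ms
        new_full = _f(mu_row, ku[:, None] * kappa[None, :]).sum(axis=1)
        new_at_r = _f(mu_row[np.arange(len(r)), r], ku * kr)
        new_at_s = _f(mu_row[np.arange(len(s)), s], ku * ks)
        new_diag = _f(mrr + mss + 2 * mrs, ku * ku)
        new = 2 * (new_full - new_at_r - new_at_s) + new_diag
        d_loglik = new - old
        d_penalty = (
            -B * np.log(max(2 * M, 2))
            + n_nodes * (np.log(B - 1) - np.log(B))
        )
        return -d_loglik + d_penalty

    def _greedy_run(
        self, A: np.ndarray, rng: np.random.Generator, randomized: bool
    ) -> tuple[np.ndarray, float]:
        n = A.shape[0]
        k = A.sum(axis=1).astype(float)
        M = int(A.sum()) // 2
        max_B = self.max_B if self.max_B is not None else n
        labels = np.arange(n)
        m = A.astype(float).copy()
        np.fill_diagonal(m, 2 * np.diagonal(A))  # self-edges counted twice
        kappa = k.copy()
        while len(kappa) > 1:
            B = len(kappa)
            iu, ju = np.nonzero(np.triu(m, k=1))
            if iu.size == 0:  # disconnected block graph: allow any pair
                iu, ju = np.triu_indices(B, k=1)
            pairs = np.column_stack([iu, ju])
            deltas = self._merge_deltas(m, kappa, pairs, n, M)
            order = np.argsort(deltas)
            improving = deltas[order] < 0
            if improving.any():
                top = order[improving][: 3 if randomized else 1]
                choice = top[rng.integers(len(top))] if randomized else top[0]
            elif B > max_B:
                choice = order[0]  # forced merge down to max_B
            else:
                break
            r, s = pairs[choice]
            # fold block s into block r, then drop s
            m[r] += m[s]
            m[:, r] += m[:, s]
            kappa[r] += kappa[s]
            m = np.delete(np.delete(m, s, axis=0), s, axis=1)
            kappa = np.delete(kappa, s)
            labels[labels == s] = r
            labels[labels > s] -= 1
        return labels, self._dl(m, kappa, n, M)

    def fit(self, g: BinaryGraph | np.ndarray, y=None) -> "DegreeCorrectedSBM":
        g = _as_graph(g)
        if self.max_B is not None and self.max_B < 1:
            raise ValueError("max_B must be at least 1")
        A = g.A.astype(np.int64)
        rng = np.random.default_rng(self.random_state)
        best_labels, best_dl = self._greedy_run(A, rng, randomized=False)
        for _ in range(max(self.n_restarts - 1, 0)):
            labels, dl = self._greedy_run(A, rng, randomized=True)
            if dl < best_dl:
                best_labels, best_dl = labels, dl
        self.n_nodes_ = g.n_nodes
        self.block_assignment_ = best_labels
        self.n_blocks_ = int(best_labels.max()) + 1
        self.description_length_ = best_dl
        self.degrees_ = g.degrees.astype(float)
        B = self.n_blocks_
        onehot = np.zeros((g.n_nodes, B))
        onehot[np.arange(g.n_nodes), best_labels] = 1.0
        # e_rr counts each internal edge twice (both end-points), as required
        self.edge_counts_ = onehot.T @ A @ onehot
        self.block_degrees_ = onehot.T @ self.degrees_
        return self

    def expected_multiplicity(self) -> np.ndarray:
        """Karrer–Newman expected edge multiplicity omega_ij for all pairs."""
        self._check_fitted()
        b = self.block_assignment_
        kb = self.block_degrees_[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            omega = (
                np.outer(self.degrees_, self.degrees_)
                * self.edge_counts_[np.ix_(b, b)]
                / np.outer(kb, kb)
            )
        omega[~np.isfinite(omega)] = 0.0
        np.fill_diagonal(omega, 0.0)
        return omega

    def sample_one(self, rng: np.random.Generator) -> BinaryGraph:
        omega = self.expected_multiplicity()
        n = self.n_nodes_
        iu, ju = np.triu_indices(n, k=1)
        p = 1.0 - np.exp(-omega[iu, ju])
        edges = rng.random(iu.size) < p
        A = np.zeros((n, n), dtype=np.int8)
        A[iu[edges], ju[edges]] = 1
        A[ju[edges], iu[edges]] = 1
        return BinaryGraph(A)

    def spec_dict(self) -> dict:
        d = super().spec_dict()
        d.update(
            n_blocks=self.n_blocks_,
            description_length=float(self.description_length_),
            block_assignment=self.block_assignment_.tolist(),
        )
        return d


class HyperbolicS1Model(_GraphModel):
    """Latent-geometry S¹ network model with popularity and similarity.

    Nodes live on a circle of radius ``N / 2π`` (unit node density) at angular
    coordinates theta_i; each node carries a popularity (expected-degree)
    parameter kappa_i.  An edge between i and j exists independently with

        p_ij = 1 / (1 + (d_ij / (mu kappa_i kappa_j))^beta),

    where ``d_ij = (N / 2π) Δθ_ij`` is the arc distance, beta > 1 controls
    clustering (short-range preference) and mu sets the density.

    Fitting is a simplified two-stage embedding: kappa_i are set to the
    observed degrees; theta follows the circular angular order of the two
    leading non-trivial eigenvectors of the symmetrically normalized
    adjacency, refined by one sweep of single-node likelihood improvement;
    beta is found
    by bisection so that the sampled mean local clustering coefficient matches
    the input graph's within ``clustering_tol``; mu is calibrated at each
    candidate beta so the expected mean degree matches the input.
    """

    family = "HM"

    def __init__(
        self,
        clustering_tol: float = 0.02,
        beta_min: float = 1.05,
        beta_max: float = 10.0,
        n_calibration_samples: int = 5,
        random_state: int | None = None,
    ):
        self.clustering_tol = clustering_tol
        self.beta_min = beta_min
        self.beta_max = beta_max
        self.n_calibration_samples = n_calibration_samples
        self.random_state = random_state

    # ---- geometry helpers -------------------------------------------------

    @staticmethod
    def _chi(theta: np.ndarray, kappa: np.ndarray) -> np.ndarray:
        """d_ij / (kappa_i kappa_j) for all pairs (diagonal set to inf)."""
        n = len(theta)
        dtheta = np.abs(theta[:, None] - theta[None, :])
        dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)
        d = (n / (2 * np.pi)) * dtheta
        chi = d / np.outer(kappa, kappa)
        np.fill_diagonal(chi, np.inf)
        return chi

    @staticmethod
    def _edge_probs(chi: np.ndarray, mu: float, beta: float) -> np.ndarray:
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + (chi / mu) ** beta)
        np.fill_diagonal(p, 0.0)
        return p

    def _calibrate_mu(
        self, chi: np.ndarray, beta: float, target_degree: float
    ) -> float:
        """Bisect mu so the expected mean degree matches the target."""
        n = chi.shape[0]

        def mean_deg(mu: float) -> float:
            return self._edge_probs(chi, mu, beta).sum() / n

        lo, hi = 1e-8, 1.0
        while mean_deg(hi) < target_degree and hi < 1e8:
            hi *= 10.0
        for _ in range(60):
            mid = np.sqrt(lo * hi)
            if mean_deg(mid) < target_degree:
                lo = mid
            else:
                hi = mid
        return float(np.sqrt(lo * hi))

    def _expected_clustering(
        self,
        chi: np.ndarray,
        mu: float,
        beta: float,
        rng: np.random.Generator,
    ) -> float:
        p = self._edge_probs(chi, mu, beta)
        n = chi.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        vals = []
        for _ in range(self.n_calibration_samples):
            edges = rng.random(iu.size) < p[iu, ju]
            G = nx.Graph()
            G.add_nodes_from(range(n))
            G.add_edges_from(zip(iu[edges], ju[edges]))
            vals.append(nx.average_clustering(G))
        return float(np.mean(vals))

    def _loglik_rows(
        self, theta: np.ndarray, kappa: np.ndarray, A: np.ndarray,
        mu: float, beta: float, i: int,
    ) -> float:
        n = len(theta)
        dtheta = np.abs(theta - theta[i])
        dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)
        chi = (n / (2 * np.pi)) * dtheta / (kappa * kappa[i])
        chi[i] = np.inf
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + (chi / mu) ** beta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        a = A[i]
        ll = a * np.log(p) + (1 - a) * np.log1p(-p)
        ll[i] = 0.0
        return float(ll.sum())

    # ---- fit / sample -----------------------------------------------------

    def fit(self, g: BinaryGraph | np.ndarray, y=None) -> "HyperbolicS1Model":
        g = _as_graph(g)
        if not g.is_connected():
            raise ValueError("S1 fitting requires a connected graph")
        A = g.A.astype(float)
        n = g.n_nodes
        k = g.degrees.astype(float)
        rng = np.random.default_rng(self.random_state)

        kappa = np.maximum(k, 0.5)
        # circular spectral ordering: the two leading non-trivial eigenvectors
        # of the normalized adjacency parametrize the latent circle; nodes are
        # ranked by their atan2 angle and spread uniformly
        s = 1.0 / np.sqrt(np.maximum(k, 1.0))
        sym = A * s[:, None] * s[None, :]
        _, vecs = scipy.linalg.eigh(sym)
        ang = np.arctan2(vecs[:, -3], vecs[:, -2])  # -1 is the Perron mode
        order = rankdata(ang, method="ordinal") - 1
        theta = 2 * np.pi * order / n

        chi = self._chi(theta, kappa)
        target_c = nx.average_clustering(nx.from_numpy_array(g.A))
        mean_k = k.mean()

        lo, hi = self.beta_min, self.beta_max
        c_lo = self._expected_clustering(
            chi, self._calibrate_mu(chi, lo, mean_k), lo, rng
        )
        if c_lo > target_c:
            warnings.warn(
                "input clustering below the low-beta floor; falling back to "
                "beta = 1.5",
                RuntimeWarning,
            )
            beta = 1.5
        else:
            c_hi = self._expected_clustering(
                chi, self._calibrate_mu(chi, hi, mean_k), hi, rng
            )
            if c_hi < target_c:
                beta = hi
            else:
                beta = 0.5 * (lo + hi)
                for _ in range(12):
                    beta = 0.5 * (lo + hi)
                    c_mid = self._expected_clustering(
                        chi, self._calibrate_mu(chi, beta, mean_k), beta, rng
                    )
                    if abs(c_mid - target_c) < self.clustering_tol:
                        break
                    if c_mid < target_c:
                        lo = beta
                    else:
                        hi = beta
        mu = self._calibrate_mu(chi, beta, mean_k)

        # one sweep of local likelihood refinement: move each node toward the
        # circular mean of its neighbours when that improves its likelihood
        for i in rng.permutation(n):
            nbrs = np.flatnonzero(A[i])
            if nbrs.size == 0:
                continue
            cand = float(
                np.arctan2(
                    np.sin(theta[nbrs]).mean(), np.cos(theta[nbrs]).mean()
                )
                % (2 * np.pi)
            )
            cur = self._loglik_rows(theta, kappa, A, mu, beta, i)
            old = theta[i]
            theta[i] = cand
            new = self._loglik_rows(theta, kappa, A, mu, beta, i)
            if new < cur:
                theta[i] = old
        mu = self._calibrate_mu(self._chi(theta, kappa), beta, mean_k)

        self.n_nodes_ = n
        self.kappa_ = kappa
        self.theta_ = theta
        self.beta_ = float(beta)
        self.mu_ = float(mu)
        return self

    def edge_probabilities(self) -> np.ndarray:
        self._check_fitted()
        chi = self._chi(self.theta_, self.kappa_)
        return self._edge_probs(chi, self.mu_, self.beta_)

    def sample_one(self, rng: np.random.Generator) -> BinaryGraph:
        p = self.edge_probabilities()
        n = self.n_nodes_
        iu, ju = np.triu_indices(n, k=1)
        edges = rng.random(iu.size) < p[iu, ju]
        A = np.zeros((n, n), dtype=np.int8)
        A[iu[edges], ju[edges]] = 1
        A[ju[edges], iu[edges]] = 1
        return BinaryGraph(A)

    def spec_dict(self) -> dict:
        d = super().spec_dict()
        d.update(
            beta=self.beta_,
            mu=self.mu_,
            kappa=self.kappa_.tolist(),
            theta=self.theta_.tolist(),
        )
        return d

    @staticmethod
    def from_embedding(
        kappa: np.ndarray, theta: np.ndarray, beta: float, mu: float
    ) -> "HyperbolicS1Model":
        """Build a sampling-ready model from known S¹ coordinates."""
        model = HyperbolicS1Model()
        model.n_nodes_ = len(kappa)
        model.kappa_ = np.asarray(kappa, float)
        model.theta_ = np.asarray(theta, float)
        model.beta_ = float(beta)
        model.mu_ = float(mu)
        return model


MODEL_FAMILIES: dict[str, type[_GraphModel]] = {
    "ERM": ErdosRenyiModel,
    "CM": ConfigurationModel,
    "DCSBM": DegreeCorrectedSBM,
    "HM": HyperbolicS1Model,
}


@dataclass
class EnsembleResult:
    """Pooled entropy samples of a model ensemble on a shared tau grid."""

    family: str
    kind: WalkKind
    taus: np.ndarray
    samples: np.ndarray  # (n_curves, n_taus)
    n_nodes: np.ndarray | None = None  # node count of each pooled realization

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        if self.samples.shape[0] < 2:
            return np.zeros(self.samples.shape[1])
        return self.samples.std(axis=0, ddof=1)

    def curves(self) -> list[EntropyCurve]:
        ns = (
            self.n_nodes
            if self.n_nodes is not None
            else np.zeros(self.samples.shape[0], dtype=int)
        )
        return [
            EntropyCurve(self.taus, s, int(n), self.kind)
            for s, n in zip(self.samples, ns)
        ]


def ensemble_entropy(
    models: list[_GraphModel],
    realizations_per_subject: int,
    kind: WalkKind | str,
    taus: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> EnsembleResult:
    """Pool entropy curves over model realizations for a set of fitted models.

    For each subject-fitted model, draws ``realizations_per_subject``
    independent graphs, restricts each to its largest component, computes its
    entropy curve for the requested walk, and pools all curves.
    """
    if realizations_per_subject < 1:
        raise ValueError("need at least one realization per subject")
    if not models:
        raise ValueError("need at least one fitted model")
    if taus is None:
        taus = default_tau_grid()
    taus = np.asarray(taus, float)
    kind = WalkKind(kind)
    rng = np.random.default_rng(seed)
    family = models[0].family
    rows, sizes = [], []
    for model in models:
        if model.family != family:
            raise ValueError("all models in an ensemble must share a family")
        for g in model.sample(realizations_per_subject, rng):
            gc = largest_component(g)
            if gc.n_nodes < 2:
                continue  # degenerate draw: no spectrum worth pooling
            lambdas = laplacian_spectrum(gc, kind)
            rows.append(curve_from_spectrum(lambdas, taus, kind).S)
            sizes.append(gc.n_nodes)
    return EnsembleResult(family, kind, taus, np.vstack(rows), np.array(sizes))
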