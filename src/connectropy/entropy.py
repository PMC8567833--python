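"""Spectral (von Neumann) entropy of a network across Markov time.

The state of information flow at Markov time τ is summarized by the
Gibbs-like density matrix ``ρ = e^{-τL} / Z`` with partition function
``Z = Tr[e^{-τL}]`` and L the walk Laplacian.  Its von Neumann entropy

    S_τ(G) = -Tr[ρ log2 ρ]   (bits)

measures the diversity (mixedness) of information streams: S = log2 N at
τ = 0 when nothing has propagated, and S → 0 for large τ on graphs whose
diffusion collapses onto a single dominant mode.  Because ρ shares the
Laplacian's eigenvectors, S is computed directly from the eigenvalues as the
Shannon entropy of the Gibbs weights ``p_i = e^{-τλ_i} / Σ_j e^{-τλ_j}``.

Markov time is split into three bands by the node count N: microscale
(τ < √N), mesoscale (√N ≤ τ < N) and macroscale (τ ≥ N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BinaryGraph
from .walks import WalkKind, laplacian_spectrum

__all__ = [
    "spectral_entropy",
    "gibbs_weights",
    "EntropyCurve",
    "entropy_curve",
    "entropic_ratio",
    "ScaleBands",
    "scale_bands",
    "default_tau_grid",
]


def default_tau_grid(
    tau_min: float = 0.1, tau_max: float = 1e3, n_points: int = 60
) -> np.ndarray:
    """Geometric Markov-time grid covering micro- to macroscale for N ≤ 1000."""
    return np.geomspace(tau_min, tau_max, n_points)


def gibbs_weights(lambdas: np.ndarray, tau: float) -> np.ndarray:
    """Eigenvalue occupation probabilities e^{-τλ_i}/Z, overflow-safe.

    The spectrum is shifted by its minimum before exponentiation; the entropy
    is invariant under this shift because Z rescales by the same factor.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.iscomplexobj(lambdas) or not np.isfinite(lambdas).all():
        raise ValueError("eigenvalues must be real and finite")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    w = np.exp(-tau * (lambdas - lambdas.min()))
    return w / w.sum()


def spectral_entropy(lambdas: np.ndarray, tau: float) -> float:
    """Von Neumann entropy in bits at Markov time τ from Laplacian eigenvalues."""
    p = gibbs_weights(lambdas, tau)
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


@dataclass(frozen=True)
class EntropyCurve:
    """Spectral entropy along a Markov-time grid for one graph and walk kind."""

    taus: np.ndarray
    S: np.ndarray
    N: int
    kind: WalkKind

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        S = np.asarray(self.S, dtype=float)
        if taus.shape != S.shape:
            raise ValueError("taus and S must have matching shapes")
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "S", S)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.taus, "S": self.S, "walk_kind": self.kind.value}
        )


def entropy_curve(
    g: BinaryGraph, kind: WalkKind | str, taus: np.ndarray | None = None
) -> EntropyCurve:
    """Entropy S(τ) over a grid, from the walk Laplacian spectrum of ``g``."""
    if taus is None:
        taus = default_tau_grid()
    taus = np.asarray(taus, dtype=float)
    if taus.size and ((taus < 0).any() or (np.diff(taus) <= 0).any()):
        raise ValueError("taus must be strictly increasing and nonnegative")
    lambdas = laplacian_spectrum(g, kind)
    S = np.array([spectral_entropy(lambdas, t) for t in taus])
    return EntropyCurve(taus, S, g.n_nodes, WalkKind(kind))


def curve_from_spectrum(
    lambdas: np.ndarray, taus: np.ndarray, kind: WalkKind | str = WalkKind.CRW
) -> EntropyCurve:
    """Entropy curve directly from a precomputed Laplacian spectrum."""
    taus = np.asarray(taus, dtype=float)
    S = np.array([spectral_entropy(lambdas, t) for t in taus])
    return EntropyCurve(taus, S, len(lambdas), WalkKind(kind))


def _stack(curves: list[EntropyCurve]) -> tuple[np.ndarray, np.ndarray]:
    if not curves:
        raise ValueError("need at least one entropy curve")
    taus = curves[0].taus
    for c in curves[1:]:
        if not np.array_equal(c.taus, taus):
            raise ValueError("entropy curves are on mismatched tau grids")
    return taus, np.vstack([c.S for c in curves])


def entropic_ratio(
    model_curves: list[EntropyCurve], data_curves: list[EntropyCurve]
) -> pd.DataFrame:
    """Per-τ ratio r_τ = <S(model)> / <S(data)> with a 1-sd dispersion band.

    The standard deviation of the ratio is propagated to first order from the
    sample standard deviations of the two means:
    ``sd_r = r * sqrt((sd_m/<S_m>)^2 + (sd_d/<S_d>)^2)``.  Grid points where
    the data mean vanishes are flagged as undefined (NaN ratio).
    """
    taus_m, Sm = _stack(model_curves)
    taus_d, Sd = _stack(data_curves)
    if not np.array_equal(taus_m, taus_d):
        raise ValueError("model and data curves are on mismatched tau grids")
    mm, md = Sm.mean(axis=0), Sd.mean(axis=0)
    sm = Sm.std(axis=0, ddof=1) if Sm.shape[0] > 1 else np.zeros_like(mm)
    sd = Sd.std(axis=0, ddof=1) if Sd.shape[0] > 1 else np.zeros_like(md)
    ok = md > 0
    ratio = np.full_like(mm, np.nan)
    band = np.full_like(mm, np.nan)
    ratio[ok] = mm[ok] / md[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(
            np.where(mm > 0, (sm / np.where(mm > 0, mm, 1.0)) ** 2, 0.0)
            + np.where(md > 0, (sd / np.where(md > 0, md, 1.0)) ** 2, 0.0)
        )
    band[ok] = ratio[ok] * rel[ok]
    return pd.DataFrame(
        {"tau": taus_m, "ratio": ratio, "sd": band, "defined": ok}
    )


@dataclass(frozen=True)
class ScaleBands:
    """Markov-time bands: micro (τ < √N), meso (√N ≤ τ < N), macro (τ ≥ N)."""

    N: int

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least 2 nodes")

    @property
    def micro_meso(self) -> float:
        return float(np.sqrt(self.N))

    @property
    def meso_macro(self) -> float:
        return float(self.N)

    def classify(self, tau: float) -> str:
        if tau < self.micro_meso:
            return "micro"
        if tau < self.meso_macro:
            return "meso"
        return "macro"

    def labels(self, taus: np.ndarray) -> np.ndarray:
        return np.array([self.classify(t) for t in np.asarray(taus, float)])


def scale_bands(N: int) -> ScaleBands:
    """Scale bands delimited by √N and N for an N-node network."""
    return ScaleBands(N)
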