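"""Synthetic FA-like connectome cohorts with a tunable group effect.

The generator emulates the statistical structure the analysis assumes of
structural connectomes: weights in [0, 1] playing the role of
fractional-anisotropy link probabilities, modular (block) organization, and
a geometric distance-decay of connection strength.  It is a statistical
stand-in for empirical cohorts, not a digital twin of any dataset.

Each group shares a noiseless template built from

* ``n_blocks`` contiguous blocks on a ring of ``n_nodes`` nodes, with
  separate intra- and inter-block mean FA levels, and
* multiplicative attenuation ``(1 - delta)^attenuation`` of the mean with
  normalized ring distance ``delta``.

A *disease effect* of strength ``eta`` rewires a fraction ``eta`` of the
strong intra-block entries to uniformly random node pairs, eroding modular
redundancy.  Because the walk Laplacian always has mean eigenvalue 1, this
narrows the spectrum around it, which slows the initial entropy decay: a
diseased group shows *higher* spectral entropy at small Markov times.

Per-subject weights are jittered with Beta noise around the template mean,
which keeps every weight inside [0, 1] by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import WeightedConnectome, write_weighted_matrix

__all__ = ["CohortSpec", "template_graph", "generate_cohort", "write_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Attributes
    ----------
    n_nodes : int
        Network size; 90 emulates an AAL-like parcellation, 188 the larger
        cortical/subcortical one.
    n_subjects : int
        Subjects per group.
    groups : tuple of (label, eta)
        Group labels with their disease-effect strength eta in [0, 1];
        eta = 0 is the healthy template.
    n_blocks : int
        Number of contiguous modules on the ring.
    intra_mean, inter_mean : float
        Mean FA of within- and between-block entries before attenuation.
    attenuation : float
        Exponent of the (1 - delta)^attenuation ring-distance decay; 0
        disables geometry.
    subject_sigma : float
        Standard-deviation scale of the per-subject Beta jitter; 0 copies
        the template exactly.
    seed : int
        Master seed; the cohort is a deterministic function of the spec.
    """

    n_nodes: int = 90
    n_subjects: int = 25
    groups: tuple[tuple[str, float], ...] = (("H", 0.0),)
    n_blocks: int = 5
    intra_mean: float = 0.5
    inter_mean: float = 0.08
    attenuation: float = 1.0
    subject_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_blocks <= self.n_nodes:
            raise ValueError("n_blocks must lie in [1, n_nodes]")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject per group")
        for m in (self.intra_mean, self.inter_mean):
            if not 0.0 <= m <= 1.0:
                raise ValueError("FA means must lie in [0, 1]")
        for label, eta in self.groups:
            if not 0.0 <= eta <= 1.0:
                raise ValueError(f"group {label!r}: eta must lie in [0, 1]")
        if self.subject_sigma < 0 or self.attenuation < 0:
            raise ValueError("subject_sigma and attenuation must be >= 0")

    def block_assignment(self) -> np.ndarray:
        return (np.arange(self.n_nodes) * self.n_blocks) // self.n_nodes


def _base_template(spec: CohortSpec) -> np.ndarray:
    n = spec.n_nodes
    blocks = spec.block_assignment()
    same = blocks[:, None] == blocks[None, :]
    mean = np.where(same, spec.intra_mean, spec.inter_mean)
    i = np.arange(n)
    d = np.abs(i[:, None] - i[None, :])
    d = np.minimum(d, n - d)
    delta = d / (n / 2.0)
    W = mean * (1.0 - delta) ** spec.attenuation
    np.fill_diagonal(W, 0.0)
    return W


def _rewire_strong_entries(
    W: np.ndarray, eta: float, rng: np.random.Generator
) -> np.ndarray:
    """Swap a fraction eta of strong intra-pattern weights to random pairs."""
    if eta == 0.0:
        return W
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju].copy()
    pos = w[w > 0]
    if pos.size == 0:
        return W
    strong = np.flatnonzero(w > np.median(pos))
    n_move = int(round(eta * strong.size))
    if n_move == 0:
        return W
    src = rng.choice(strong, size=n_move, replace=False)
    dst = rng.choice(w.size, size=n_move, replace=False)
    w[src], w[dst] = w[dst].copy(), w[src].copy()
    out = np.zeros_like(W)
    out[iu, ju] = w
    out[ju, iu] = w
    return out


def template_graph(
    spec: CohortSpec, group: str | None = None
) -> WeightedConnectome:
    """Noiseless group template (jitter-free), exposed for testing.

    ``group`` selects which group's template (with its eta rewiring applied);
    default is the first group.
    """
    labels = [lab for lab, _ in spec.groups]
    if group is None:
        group = labels[0]
    if group not in labels:
        raise ValueError(f"unknown group {group!r}")
    gi = labels.index(group)
    eta = dict(spec.groups)[group]
    W = _base_template(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed).spawn(len(labels))[gi]
    )
    W = _rewire_strong_entries(W, eta, rng)
    return WeightedConnectome(W)


def _beta_jitter(
    W: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Beta-distributed noise with mean W and sd scale sigma, within [0, 1]."""
    if sigma == 0.0:
        return W.copy()
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    m = W[iu, ju]
    out = np.zeros_like(W)
    active = (m > 0) & (m < 1)
    mm = m[active]
    # Beta(m*nu, (1-m)*nu) has variance m(1-m)/(nu+1); cap nu from below so
    # the density stays unimodal even for extreme means
    nu = np.maximum(mm * (1 - mm) / sigma**2 - 1.0, 2.0)
    w = m.copy()
    w[active] = rng.beta(mm * nu, (1 - mm) * nu)
    out[iu, ju] = w
    out[ju, iu] = w
    return out


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[str, WeightedConnectome]]:
    """Generate (group label, connectome) pairs, deterministic per spec."""
    base = _base_template(spec)
    root = np.random.SeedSequence(spec.seed)
    group_seeds = root.spawn(len(spec.groups))
    cohort: list[tuple[str, WeightedConnectome]] = []
    for gseed, (label, eta) in zip(group_seeds, spec.groups):
        grng = np.random.default_rng(gseed)
        Wg = _rewire_strong_entries(base, eta, grng)
        for _ in range(spec.n_subjects):
            Ws = _beta_jitter(Wg, spec.subject_sigma, grng)
            cohort.append((label, WeightedConnectome(Ws)))
    return cohort


def write_cohort(
    cohort: list[tuple[str, WeightedConnectome]], outdir: str | Path
) -> Path:
    """Write per-subject dense matrices plus a manifest CSV; returns manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, (label, conn) in enumerate(cohort):
        fname = f"subject_{idx:03d}.txt"
        write_weighted_matrix(conn, outdir / fname)
        rows.append({"subject": f"subject_{idx:03d}", "group": label, "file": fname})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same cohort spec with every group effect switched off."""
    return replace(spec, groups=tuple((lab, 0.0) for lab, _ in spec.groups))
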