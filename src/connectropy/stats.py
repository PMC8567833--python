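"""Per-τ group statistics: Welch t tests, Holm adjustment, Bayes calibration.

Spectral-entropy samples of two groups (patients vs. controls, or model
ensemble vs. data) are compared independently at every Markov time with a
two-sided unequal-variance (Welch) t test.  Within each τ, the family of
simultaneous comparisons (e.g. the four generative models, or the two
patient groups against controls) is adjusted with the step-down
Bonferroni–Holm procedure.

To give the adjusted p values a Bayesian reading they are recalibrated to
the maximum posterior probability of the null, via the Sellke–Bayarri–Berger
lower bound on the Bayes factor,

    B(p) = -e p ln p          (p < 1/e)
    alpha(p) = (1 + B(p)^{-1})^{-1},

which, at equal prior odds, is the least favourable posterior probability of
H0 — equivalently the frequentist error probability of rejecting a true
null.  For p >= 1/e the bound carries no evidence and alpha is capped at
its maximum 1/2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .entropy import ScaleBands

__all__ = [
    "welch_t",
    "holm_adjust",
    "bayes_factor_bound",
    "bayes_calibration",
    "per_tau_tests",
]


def welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch (unequal-variance) t-test p value.

    Degenerate zero-variance inputs: equal constant samples give p = 1,
    different constants give p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if x.std() == 0.0 and y.std() == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(sps.ttest_ind(x, y, equal_var=False).pvalue)


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Step-down Bonferroni–Holm adjusted p values, in input order."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return pvals
    if (pvals < 0).any() or (pvals > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(pvals, method="holm")[1]


def bayes_factor_bound(p: float) -> float:
    """Lower bound on the Bayes factor in favour of H0: -e p ln p for p < 1/e."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p == 0.0:
        return 0.0
    if p >= 1.0 / np.e:
        return 1.0  # no-evidence cap: the bound exceeds 1 past 1/e
    return float(-np.e * p * np.log(p))


def bayes_calibration(p_adj: float) -> float:
    """Maximum posterior probability of H0 from an (adjusted) p value.

    alpha = B/(1+B) with B the Bayes-factor bound; strictly increasing on
    (0, 1/e) and capped at 1/2 for p >= 1/e.
    """
    B = bayes_factor_bound(p_adj)
    if B == 0.0:
        return 0.0
    return float(1.0 / (1.0 + 1.0 / B))


def per_tau_tests(
    samples: dict[str, np.ndarray],
    reference: np.ndarray,
    taus: np.ndarray,
    n_nodes: int,
    family_across_tau: bool = False,
) -> pd.DataFrame:
    """Welch/Holm/posterior table for several comparisons against a reference.

    Parameters
    ----------
    samples : dict of comparison label -> (n_obs, n_taus) entropy samples
        One sample matrix per comparison (e.g. each generative model, or each
        patient group).
    reference : (n_obs_ref, n_taus) ndarray
        The common reference group (empirical data, or healthy controls).
    taus : (n_taus,) ndarray
        Markov-time grid shared by all matrices.
    n_nodes : int
        Node count used to attach micro/meso/macro band labels.
    family_across_tau : bool
        If True, the Holm family spans all comparisons at all τ jointly;
        default is one family per τ across the simultaneous comparisons.

    Returns
    -------
    DataFrame with columns tau, comparison, p_raw, p_adj, alpha_post, band.
    """
    taus = np.asarray(taus, float)
    reference = np.atleast_2d(np.asarray(reference, float))
    if reference.shape[1] != taus.size:
        raise ValueError("reference sample grid does not match taus")
    labels = list(samples)
    n_t = taus.size
    p_raw = np.empty((len(labels), n_t))
    for a, lab in enumerate(labels):
        mat = np.atleast_2d(np.asarray(samples[lab], float))
        if mat.shape[1] != n_t:
            raise ValueError(f"sample {lab!r} grid does not match taus")
        for t in range(n_t):
            p_raw[a, t] = welch_t(mat[:, t], reference[:, t])
    if family_across_tau:
        p_adj = holm_adjust(p_raw.ravel()).reshape(p_raw.shape)
    else:
        p_adj = np.empty_like(p_raw)
        for t in range(n_t):
            p_adj[:, t] = holm_adjust(p_raw[:, t])
    bands = ScaleBands(n_nodes).labels(taus)
    rows = []
    for a, lab in enumerate(labels):
        for t in range(n_t):
            rows.append(
                {
                    "tau": taus[t],
                    "comparison": lab,
                    "p_raw": p_raw[a, t],
                    "p_adj": p_adj[a, t],
                    "alpha_post": bayes_calibration(p_adj[a, t]),
                    "band": bands[t],
                }
            )
    return pd.DataFrame(rows)
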