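# connectropy

Multiscale spectral-entropy analysis of structural brain networks.

`connectropy` characterizes how information can flow on a connectome — a
network whose nodes are brain regions and whose edges are white-matter
connections weighted by fractional anisotropy (FA) — by watching a diffusion
process unfold on it and measuring, at every temporal scale, how many bits
are needed to describe the state of the flow.  It is aimed at network
neuroscientists who want to (a) rank generative network models by how well
they reproduce the information dynamics of measured connectomes and (b)
contrast subject groups (e.g. healthy controls against dementia patients)
in a scale-resolved, statistically calibrated way.

## The method

FA weights `w_ij ∈ [0, 1]` are read as link-existence probabilities: each
unordered pair is kept with probability `w_ij` (one uniform draw per pair),
giving a simple binary graph `A`.  On that graph two diffusive dynamics are
built from a row-stochastic transition matrix `T` and its Laplacian
`L = I − T`:

* **CRW** (classical random walk): `T_ij = A_ij / k_i` — the walker only
  knows its local neighbourhood;
* **MERW** (maximal-entropy random walk):
  `T_ij = A_ij q_j / (a_N q_i)` with `(a_N, q)` the Perron eigenpair of `A`
  — all equal-length trajectories between two nodes become equiprobable,
  i.e. the walker exploits global knowledge of the topology.

The state of the flow at Markov time τ is the Gibbs-like density matrix
`ρ = e^{−τL} / Z`, `Z = Tr e^{−τL}`, whose von Neumann entropy

```
S_τ(G) = −Tr[ρ log₂ ρ]        (bits)
```

quantifies the diversity of the information streams: `S = log₂ N` at τ = 0
and `S → 0` when diffusion collapses onto one dominant mode.  Markov time is
split by the node count into microscale (τ < √N), mesoscale (√N ≤ τ < N)
and macroscale (τ ≥ N).

Around this core the package provides:

* four generative models fitted per subject and sampled as ensembles —
  Erdős–Rényi `G(N, M)`, configuration model (exact degrees, double-edge
  swaps), degree-corrected stochastic block model (greedy description-length
  agglomeration, Karrer–Newman sampling kernel), and a latent-geometry S¹
  model (popularity × similarity kernel, spectral angular embedding) — all
  scikit-learn-style `fit`/`sample` estimators;
* entropic ratios `r_τ = ⟨S_τ(model)⟩ / ⟨S_τ(data)⟩` with dispersion bands;
* per-τ Welch t tests with step-down Bonferroni–Holm adjustment, recalibrated
  to the maximum posterior probability of the null
  `α(p) = (1 + (−e·p·ln p)^{−1})^{−1}` (capped at 1/2 for p ≥ 1/e);
* a synthetic FA-cohort generator (modular + ring-geometric templates, Beta
  subject noise, tunable disease effect) so the whole pipeline is testable
  without any neuroimaging download;
* a CLI: `connectropy simulate | entropy | models | groups`.

## Worked example

Contrast a healthy-like group with a "disease" group whose connectomes have
30% of their strong within-module links rewired to random positions:

```python
import numpy as np
from connectropy import (
    CohortSpec, generate_cohort, binarize_fa, largest_component,
    entropy_curve, scale_bands,
)
from connectropy.stats import per_tau_tests

spec = CohortSpec(n_nodes=90, n_subjects=25,
                  groups=(("H", 0.0), ("AD", 0.3)), seed=11)
taus = np.geomspace(0.1, 1e3, 60)
rng = np.random.default_rng(5)
curves = {"H": [], "AD": []}
for label, conn in generate_cohort(spec):
    g = largest_component(binarize_fa(conn, rng))
    curves[label].append(entropy_curve(g, "crw", taus).S)

H, AD = (np.vstack(curves[k]) for k in ("H", "AD"))
table = per_tau_tests({"AD": AD}, H, taus, n_nodes=90)
```

Selecting the most significant microscale Markov time with an entropy
excess in the disease group prints:

```
micro/meso boundary sqrt(N) = 9.487, meso/macro boundary N = 90
strongest excess at micro tau = 3.63:
  S_H  = 5.101 bits   S_AD = 5.312 bits   gap = +0.211 bits
  Holm-adjusted p = 1.88e-24   alpha_post = 2.79e-22
```

Read: at τ ≈ 3.6 (microscale for N = 90) the disease group needs about
0.21 bits more to describe its information flow than controls — the random
rewiring erodes modular redundancy, so early diffusion stays more diverse —
and both the Holm-adjusted p value and its Bayesian recalibration (the
maximum posterior probability that the groups match) are vanishingly small.

The same analysis from the shell:

```bash
connectropy simulate --n-nodes 90 --n-subjects 25 \
    --group H:0.0 --group AD:0.3 --seed 11 --out cohort/
connectropy groups --manifest cohort/manifest.csv --walk crw \
    --seed 5 --out results/
```

which writes `group_entropy_curves.csv`, `group_entropic_ratios.csv`,
`group_tests.csv` (tau, comparison, p_raw, p_adj, alpha_post, band) and
`steady_state_maps.csv` (the per-region stationary occupation, the tabular
surrogate of a brain map).

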