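# Methods

This note documents the models, conventions and design choices behind
`connectropy`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. From FA weights to binary graphs

Inputs are symmetric matrices of fractional-anisotropy (FA) weights
`w_ij ∈ [0, 1]` with zero diagonal, read either as dense text or as
`i j w` edge lists (0-based by default, 1-based behind a flag).  FA is
bounded in [0, 1] and is interpreted as the probability that a structural
link exists, so binarization is a sampling step rather than a threshold:
for each unordered pair one uniform variate `r` is drawn and the edge is
kept iff `w_ij > r`.

Conventions:

* **One draw per pair, not per matrix entry.**  The sampled graph is then
  symmetric by construction; sampling entries independently would require an
  arbitrary symmetrization rule afterwards.
* **Strict inequality** `w > r`: the boundary event has probability zero, so
  the convention is immaterial but fixed.
* **One binarization per subject per pipeline seed** by default; the
  `binarization_draws` option averages a subject's entropy curve over B
  independent draws instead (per-subject curves, then group statistics).
* Graphs are reduced to their **largest connected component** before any
  walk is built.  MERW requires connectivity (a strictly positive Perron
  eigenvector); rather than silently patching disconnected graphs the walk
  constructors reject them and the pipeline applies the reduction
  explicitly, logging removed node counts.  Ties between equal-sized
  components go to the one containing the smallest node index.

## 2. Walk dynamics and spectra

Both walks are encoded by a row-stochastic transition matrix `T` with
Laplacian `L = I − T` generating `p(τ) = p(0) e^{−τL}`:

* CRW: `T_ij = A_ij / k_i`, stationary distribution `π_i = k_i / 2M`.
* MERW: `T_ij = A_ij q_j / (a_N q_i)` with `(a_N, q)` the leading adjacency
  eigenpair; `π_i = q_i²` (unit-norm `q`).  Every length-τ path from i to j
  then has probability `q_j / (a_N^τ q_i)` — trajectories of equal length
  are equiprobable, which the tests verify by exhaustive enumeration on
  small graphs.

Numerics: eigenvalues of the non-symmetric `L` are computed from the
symmetric similar matrices `D^{−1/2} A D^{−1/2}` (CRW) and `A / a_N`
(MERW), so the spectra are exactly real and lie in [0, 2].  Leading
eigenpairs come from dense symmetric solvers (`scipy.linalg.eigh`), adequate
for the N ≤ a-few-hundred networks this package targets; no sparse path is
provided.

## 3. Spectral entropy across Markov time

The density matrix `ρ = e^{−τL}/Z` shares eigenvectors with `L`, so its von
Neumann entropy is the Shannon entropy of the Gibbs weights
`p_i = e^{−τλ_i}/Σ_j e^{−τλ_j}`.  Entropy is reported in **bits**
throughout.  The spectrum is shifted by `λ_min` before exponentiation —
entropy is invariant under the shift and the computation cannot overflow at
large τ.  `0 · log 0` terms contribute zero.

Properties asserted on every computed curve: `S(0) = log₂ N`,
`0 ≤ S ≤ log₂ N`, and monotone non-increase in τ (a Gibbs state's entropy
decreases with inverse temperature).  For graphs up to N = 30 the
eigenvalue route is checked to 1e-8 against an independent dense oracle
(`expm`, normalize, eigendecompose, `−Tr ρ log₂ ρ`).

**Scale bands.**  Markov time is partitioned at `√N` and `N` into
micro/meso/macroscale, with the left-closed convention
micro < √N ≤ meso < N ≤ macro.  The default grid is 60 geometrically spaced
times in [0.1, 1000], which covers all three bands for N ≤ 1000.

**Entropic ratio.**  `r_τ = ⟨S_τ(model)⟩ / ⟨S_τ(data)⟩`, with a
one-standard-deviation band propagated to first order from the two sample
standard deviations.  All samples of an ensemble are pooled (across
subjects and realizations alike) before averaging; grid points where the
data mean vanishes are flagged undefined rather than clipped.

## 4. Generative models

All four models are scikit-learn-style estimators (`fit(graph)` →
fitted attributes, `sample(n, seed)` → list of simple graphs).  They are
fitted to each subject's binarized largest component separately, matching a
per-subject ensemble protocol (default 100 realizations per subject in the
pipeline).

* **ERM** — uniform `G(N, M)`: edge positions drawn without replacement.
* **CM** — exact degree sequence.  Samples are generated by `10·M`
  attempted double-edge swaps from the fitted graph, rejecting any swap that
  would create a self-loop or multi-edge.  Swaps guarantee simplicity
  without the rejection storms stub-matching suffers on skewed degree
  sequences; the chain's proposal kernel is symmetric, so its stationary law
  is uniform on the reachable simple realizations.
* **DC-SBM** — the partition is found by greedy agglomerative minimization
  of a description-length criterion
  `DL(b) = −Σ_rs m_rs ln(m_rs/(κ_r κ_s)) + B(B+1)/2 · ln(2M) + N ln B`
  (first term: the unnormalized degree-corrected block-model
  log-likelihood; penalty: the cost of the block-affinity matrix and the
  partition).  Merging starts from singleton blocks, considers pairs of
  blocks connected in the block graph, and stops when no merge lowers DL;
  accepted merges therefore never increase DL.  Ten restarts are run, the
  first fully greedy, the rest choosing randomly among the top-3 improving
  merges; the lowest-DL partition wins.  Sampling uses the Karrer–Newman
  kernel `ω_ij = k_i k_j e_{b_i b_j}/(κ_{b_i} κ_{b_j})` as a Poisson mean
  and keeps the graph simple by collapsing multiplicities
  (`P(edge) = 1 − e^{−ω}`) and dropping self-loops; block-level edge counts
  therefore match `e_rs` exactly only in the sparse regime, a deliberate
  trade of calibration for simplicity.  This greedy fitter is an
  approximation to full MCMC posterior inference; its quality gate is
  planted-partition recovery (adjusted Rand index 1.0 on a 60-node
  two-block instance with p_in = 0.5, p_out = 0.02), not equivalence to any
  particular sampler.
* **S¹ (hyperbolic) model** — nodes at angles θ on a circle of radius
  N/2π with popularity parameters κ; edges independent with
  `p_ij = 1/(1 + (d_ij/(μ κ_i κ_j))^β)`, `d_ij` the arc distance.  Fitting
  is a simplified two-stage embedder: κ = observed degrees (floored at
  0.5); θ from the circular (atan2) embedding of the two leading
  non-trivial eigenvectors of the normalized adjacency, rank-spread to
  uniform angles — one eigenvector alone linearizes the circle and loses
  the wrap-around, which in practice halves the angular recovery — followed
  by one sweep of per-node likelihood refinement toward the circular mean
  of each node's neighbours; β by bisection on [1.05, 10] until the sampled
  mean local clustering matches the input graph's within 0.02 (fallback
  β = 1.5 with a warning when the input clustering sits below the low-β
  floor, cap at 10 above); μ recalibrated at every candidate β by bisection
  so the expected mean degree matches the input.  The quality gate is
  self-consistency: graphs generated from known (κ, θ, β) and refitted
  recover the pairwise circular-distance ordering with rank correlation
  > 0.8 at N = 200, β = 2.5.

## 5. Statistics

Per-τ two-sample comparisons use the **Welch** (unequal-variance) t test —
group sizes and variances genuinely differ in the intended applications —
with degenerate zero-variance samples mapped to p = 1 (equal means) or
p = 0 (different means).  Within each τ the simultaneous comparisons (the
four models, or the patient groups) form one **Bonferroni–Holm** family;
a flag moves the family across the whole τ grid instead.  Holm output is
order-invariant and dominates both the raw p and plain Bonferroni from
below.

Adjusted p values are recalibrated to the **maximum posterior probability**
of the null via the Bayes-factor lower bound `B(p) = −e·p·ln p` (natural
log — the base is pinned by the anchor B(1/e) = 1), giving
`α = B/(1+B)` under equal prior odds.  For p ≥ 1/e the bound is vacuous
and α is capped at its supremum 1/2 ("no evidence against H0").  α is
strictly increasing on (0, 1/e) and continuous at the cap.

## 6. Synthetic cohorts

The generator emulates the statistical features the analysis relies on —
FA-like weights in [0, 1], modular organization, geometric distance decay,
between-subject variability, a group effect — without attempting to match
any empirical dataset's summary statistics.

Defaults (chosen once as the package's study conditions): N = 90 nodes
(an AAL-like parcellation; 188 mimics a finer one), 25 subjects per group,
5 contiguous blocks on a ring, intra/inter-block mean FA 0.5/0.08,
multiplicative attenuation `(1 − δ)^1` with normalized ring distance δ,
Beta-distributed subject jitter with sd scale σ = 0.08 (the Beta
parametrization keeps weights in [0, 1] by construction; entries at exactly
0 or 1 are left untouched).  These densities give mean degree ≈ 10 after
binarization and connected subject graphs in > 99% of draws, which the
tests assert over 100 seeds.

**Disease effect.**  A group with effect strength η has a fraction η of its
strong intra-block template entries (those above the median positive
weight) swapped with uniformly random pairs before subject noise is added.
Rationale: the walk Laplacian always satisfies Tr L = N, so its mean
eigenvalue is pinned at 1, and randomizing modular structure narrows the
spectrum around that mean; a narrower spectrum decays more slowly at small
τ, so the diseased group shows *higher* microscale entropy.  The effect is
a topological caricature chosen for this provable spectral signature, not a
claim of biological fidelity.  The micro-band entropy gap is empirically
non-decreasing in η (tested at η = 0, 0.15, 0.3 with paired seeds), and the
gap reverses sign near the micro/meso boundary where the curves cross.

What passing tests on these cohorts show: the pipeline detects a planted
modular/geometric group difference with calibrated error rates under
Beta-noise, Bernoulli-sampling variability.  What they do not show:
robustness to registration or tractography artefacts, non-modular disease
signatures, heavy-tailed weight distributions, or any property of a real
neuroimaging cohort.

## 7. Pipeline and reproducibility

A master seed feeds a `numpy` seed-sequence tree spawned per subject, per
model family and per stage, so any sub-computation can be replayed without
re-running the rest.  Identical configurations reproduce byte-identical
CSVs (asserted in tests), and each CSV's first line carries a 12-hex hash
of the full configuration.  Problem sizes in the shipped tests and the
acceptance script are scaled to desk size — e.g. 10-subject, N = 60
cohorts with 20 realizations per model for the model comparison, and a
25 + 25-subject N = 90 cohort for effect recovery — which keeps a full
cycle within minutes while still exercising every stage at realistic
parcellation sizes (90- and 188-node networks are well inside the dense
solver's comfort zone).

## 8. Known limitations

* The DC-SBM fitter is greedy; it can merge past the optimum on graphs with
  weak or hierarchical block structure, and `max_B` only bounds the start of
  the forced-merge phase.  No nested/hierarchical variant is provided.
* The S¹ embedder assumes a single circular similarity dimension and a
  connected input; κ is moment-matched, not likelihood-optimal, and β is
  capped at 10.
* MERW is undefined on disconnected graphs by design; analyses of highly
  fragmented binarizations (very low FA) reduce to their largest component
  and silently change N, which the band boundaries then reflect.
* The entropic-ratio dispersion band uses first-order (delta-method)
  propagation, which understates skew when the data mean is near zero.
* No weighted-graph dynamics: FA enters only through the Bernoulli
  binarization, never as edge capacity.
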