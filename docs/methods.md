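# Methods

## The model

`cosie` works with collections of m undirected graphs observed on the same
n vertices — brain connectomes of several subjects registered to one
atlas, multilayer social or biological interaction networks, replicate
measurements of one system. The common subspace independent-edge (COSIE)
model assumes the graphs share latent structure but differ in how strongly
that structure expresses itself in each graph:

    E[A^(i)] = P^(i) = V R^(i) V^T,    i = 1, ..., m,

where V (n × d) has orthonormal columns spanning a subspace common to all
graphs, and each R^(i) (d × d, symmetric) is a graph-specific *score
matrix*. Edges are independent Bernoulli draws on the upper triangle;
adjacency matrices are symmetric, hollow, binary.

The multilayer stochastic blockmodel (SBM) — one community partition Z,
per-graph block connectivities B^(i) — is an exact sub-model. The
embedding is constructive (`sbm_to_cosie`): with Ξ = diag of community
sizes, an orthonormal basis W of the column space of the concatenated
scaled blocks Ξ^{1/2}B^(i)Ξ^{1/2} gives V = ZΞ^{-1/2}W and
R^(i) = W^TΞ^{1/2}B^(i)Ξ^{1/2}W, reproducing ZB^(i)Z^T exactly. The joint
dimension d is the numerical rank of the concatenation (singular values
above max(K, mK)·eps·σ₁) and can exceed every individual rank(B^(i)):
two layers that each merge a pair of communities can still jointly
separate all three. Individual parameters are identifiable only up to one
shared orthogonal rotation (V → VW, R^(i) → W^TR^(i)W), so everything the
package reports about fits is rotation-invariant or explicitly aligned by
orthogonal Procrustes.

## The estimator

`mase_fit` implements multiple adjacency spectral embedding:

1. per-graph adjacency spectral embedding (ASE) — top-d_i eigenpairs of
   A^(i) by magnitude; unscaled (eigenvectors) by default, or scaled
   (eigenvectors times √|eigenvalues|);
2. concatenate the embeddings into an n × Σd_i matrix;
3. the d leading left singular vectors of the concatenation are V̂;
4. R̂^(i) = V̂^T A^(i) V̂ — the closed-form least-squares minimiser of
   ‖A^(i) − V̂RV̂^T‖_F over symmetric R.

The unscaled variant is the default because its subspace-consistency
theory is the better understood one; the scaled variant is exposed since
it can down-weight poorly estimated trailing dimensions and sometimes wins
empirically. The key error scale is ε = (1/m)·Σ δ(P^(i))/λ²_min(R^(i))
(`epsilon_stat`), with δ the maximum expected degree: the subspace error
decays like √(ε/m) plus an ε-order bias, so more graphs help until the
per-graph embedding bias dominates. Averaging the adjacency matrices and
embedding once has a similar rate when all graphs share one expectation
but breaks on heterogeneous collections — the trend study below measures
exactly this contrast.

Embedding dimensions, when not supplied, come from the profile-likelihood
elbow of the scree (`select_dim_elbow`): the split point of the ordered
values maximising a two-segment equal-variance Gaussian likelihood,
recursing past the elbow when several elbows are requested. For spectra
with one dominant value the first elbow sits inside the signal block
(a well-known trait of the method), which is why the number of elbows and
which one to use are parameters; defaults are two elbows, report the
first. A constant scree returns 1 with a warning.

## Downstream inference

**Community detection.** In the multilayer SBM, V has K distinct rows, so
clustering the rows of V̂ (`cluster_subspace`) recovers the partition.
K-means with 20 seeded restarts is the default (it minimises the
objective the misclustering theory is written for); a full-covariance GMM
is available. `misclustering_error` aligns labels by optimal assignment
on the confusion matrix — provably equal to minimising ‖Ẑ − ZQ‖_F over
permutations, which the tests verify against brute-force enumeration for
K = 3.

**Two-sample testing.** For a pair of graphs, equality of the probability
matrices reduces to equality of score matrices; the statistic is
T = ‖R̂^(1) − R̂^(2)‖²_F from a joint fit of the pair. Two nulls:

- *Parametric bootstrap*: each graph's probability matrix is estimated by
  its scaled single-graph embedding (X̂X̂^T clipped to [0,1]); pairs are
  resampled from one estimate (half the replicates from each), refit with
  MASE at the same d, and T recomputed. This mirrors the observed
  statistic's whole pipeline.
- *Asymptotic*: the half-vectorised score estimate vec(V^TAV) is linear
  in the independent edges, so its covariance Σ has the closed form
  Σ_(kl),(k'l') = Σ_{s<t} P_st(1−P_st)(V_sk V_tl + V_tk V_sl)(V_sk' V_tl' + V_tk' V_sl'),
  which is *exact* at the true (V, P) — the package's Monte Carlo test
  checks it as an identity, not an approximation. Under the null the
  score difference is approximately N(0, 2Σ), making T a generalized
  chi-square; it is simulated by Gaussian draws from the plug-in Σ̂ at
  (V̂, P̂), mixing the two graphs' plug-ins equally. Mapping ‖·‖²_F to vec
  coordinates weights off-diagonal entries twice. Plug-in covariances are
  floored at zero eigenvalues (PSD projection) before sampling. This
  route neglects the finite-m alignment bias of the fitted subspace and
  requires full-rank score matrices; with rank-deficient scores it can be
  anticonservative, and the bootstrap is the safer default.

P-values are upper-tail with add-one correction,
p = (1 + #{T_null ≥ T_obs})/(n_null + 1), so large score distances give
small p-values. Pairwise Frobenius distances between fitted scores
(`pairwise_score_distances`) are rotation-invariant and feed distance
methods (MDS, k-NN) directly; p-values for all-pairs comparisons are
reported raw.

## Synthetic data

All tests and the acceptance script run on simulated ensembles
(`cosie.simulate`); the named scenarios fix the benchmark conditions:

- `homo-3block`: n = 729 (overridable), three balanced communities, every
  layer the same B = [[.4,.1,.1],[.1,.4,.2],[.1,.2,.3]].
- `hetero-3block`: same partition, each layer's symmetric B^(i) drawn
  entrywise U(0,1) — the heterogeneous regime where mean-adjacency
  embedding fails.
- `four-class`: n = 256, m = 40 two-block graphs in four classes of 10,
  B^(i) = 0.25·11^T + α·C^(class) with C^(1) = diag(.1,.1),
  C^(2) = −diag(.1,.1), C^(3) = diag(.1,0), C^(4) = diag(0,.1); α scales
  both class separation and the smallest score eigenvalue.
- `mmsbm-pair-a` / `mmsbm-pair-b`: pairs of mixed-membership SBM graphs
  with three communities, membership rows i.i.d. symmetric Dirichlet(0.1)
  and base connectivity B = 0.3I + 0.1·11^T; scenario (a) shifts the
  (1,1) block entry of the second graph (same memberships), scenario (b)
  resamples the memberships of the first t vertices (same connectivity;
  t defaults to n/2).

Samplers use one root seed with per-graph child streams, so graph i is
reproducible regardless of ensemble size. The generator draws exactly
independent Bernoulli edges — it does not emulate degree heterogeneity
beyond the block/membership structure, edge weights, sparsity growth
regimes, or the alignment noise of real registration pipelines, so
passing tests certify the estimator under its own model assumptions, not
performance on arbitrary real networks.

## Numerical choices

- Eigen/singular decompositions: dense solvers below n = 2000, Lanczos
  above; eigenvalues ordered by magnitude, ties by signed value then
  index; each eigenvector's largest-magnitude entry is made positive so
  outputs are deterministic.
- Rank thresholds: relative 1e-10·σ₁ (rank decisions), probability-range
  tolerance 1e-12 in validation, orthonormality defect measured as
  max|σ_i(V) − 1|.
- Score matrices symmetrised as (R + R^T)/2 to absorb floating-point
  asymmetry.
- Degenerate inputs: all-zero spectra are flagged rather than fatal;
  empty communities and singular score matrices raise.

## Study sizes in the test and acceptance runs

The qualitative asymptotics are measured at desk scale: the
subspace-error trend and community recovery at n = 243 (m up to 64,
25 replicates in the tests, 10 in the acceptance script), score normality
and eigenvalue bias on the n = 300 two-block model with m ∈ {1, 5, 20}
(200/100 replicates), test calibration and power at n = 150 with
bootstrap sizes 200/100 and 100–200 replicates, and the covariance
identity at n = 8 with 10⁵ Monte Carlo graphs. Normality is assessed by
Kolmogorov–Smirnov on centred standardised entries — centring because the
theory includes a finite-m mean bias that shrinks as m grows, which the
eigenvalue-bias trend measures separately against the spectrum of the
hollow expected adjacency (the sampled graphs have zero diagonals, so
that is the quantity the estimator actually targets).

## Known limitations

- The finite-m bias of the fitted subspace is not estimable and is only
  characterised behaviourally (bias shrinking in m).
- The asymptotic null degrades when score matrices are rank deficient
  (e.g. pairs needing d larger than each graph's rank).
- Laplacian or regularized embeddings, degree-corrected/overlapping
  blockmodel variants, weighted or directed edge models are out of scope;
  the readers accept weighted files but the estimator theory here is for
  the binary case.
- Automatic dimension selection inherits the elbow method's sensitivity
  to dominant leading values; treat the selected d as a starting point.
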