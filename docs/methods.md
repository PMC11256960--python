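# Methods

## Model

`pathfactor` represents each sample of a matched multi-omics cohort
hierarchically: a low-dimensional latent loading vector per sample, projected
into pathway activities, reconstructed into the observed markers of each
modality through prior pathway knowledge.

For modality `x` with `m_x` markers (genes or proteins) and `n` shared
samples, the observations `Y_x (m_x x n)` follow

    Y_x[m, j] ~ Normal( c_x * (C_x U B)[m, j], sigma_x[m]^2 )

with

- `C_x in {0,1}^(m_x x p)` — the binary marker-by-pathway membership mask,
  built from a GMT gene-set collection (e.g. the 50 MSigDB Hallmark sets);
  both modalities must cover the same `p` pathways in the same order, the
  proteomics mask being obtained by translating gene sets through a
  gene-to-protein mapping table;
- `U >= 0 (p x k)` — pathway-to-latent relevance weights, constrained
  non-negative so a pathway's contribution to a latent is interpretable as
  an abundance;
- `B (k x n)` — per-sample latent loadings; the product `P = U B` is the
  pathway-activity matrix used for all downstream association analyses;
- `sigma_x (m_x)` — per-marker heteroscedastic observation noise, learned;
- `c_x > 0` — one scalar per modality absorbing residual calibration
  differences between, say, RNA-seq counts and DIA-MS intensities.

Entrywise zero-mean Gaussian priors complete the model:
`U[i,l] ~ N(0, 1/Lambda[i,l])` (automatic relevance determination, entrywise)
and `B[l,j] ~ N(0, 1/delta[l])` (per-latent).  All normalization constants
are kept in the objective, so the negative log joint is comparable across
hyperparameter settings.

## Inference

Parameters are obtained by MAP estimation with alternating block-Newton
(equivalently, alternating least squares): the objective is exactly
quadratic in `U` at fixed `B` and vice versa, so each damped Newton step
with step size `gamma in (0, 1]` is a (damped) exact ridge solve.  `B`'s
Hessian factorizes as `A_B (x) I_n` with a small `k x k` factor; `U`'s
Hessian is a dense `pk x pk` matrix `(sum_x c_x^2 C_sigma^T C) (x) (B B^T) +
diag(Lambda)` (a diagonal approximation is available for large `p*k`).

Hyperparameters are co-optimized by maximizing a Laplace approximation of
their marginal likelihood, evaluated with the same block Hessians already
needed for the Newton steps, giving closed-form fixed-point updates per
iteration:

    Lambda[i,l] <- (1 - Lambda[i,l] [H_U^-1]_(il,il)) / U[i,l]^2
    delta[l]    <- n (1 - delta[l] [A_B^-1]_(l,l)) / sum_j B[l,j]^2
    sigma_m^2   <- sum_j r_mj^2 / d,   r = Y - c C U B

Precisions are clamped to `[prec_min, prec_max] = [1e-6, 1e12]`; a latent
with `delta` at `prec_max` is reported as pruned.  The noise denominator `d`
uses the sparse-Bayesian-learning effective degrees of freedom
`n - k + tr(diag(delta) A_B^-1)` by default (`dof_mode="sbl"`); the
alternative `dof_mode="as_printed"` replaces `k` by `p`.  Both are clamped
to `>= 1` and the variance floored at `sigma_floor = 1e-8`, so `sigma^2`
stays positive even when `p > n`.

### Numerical choices that required care

- **Non-negativity of `U`.**  A plain "Newton step, then clamp negatives"
  is not monotone: the curvature coupling can turn the clamped direction
  into ascent, and a pure reject-if-worse safeguard deadlocks at the `U = 0`
  boundary.  `update_U` therefore uses two-metric projection: the Newton
  solve is restricted to the free coordinates (interior entries, plus zero
  entries whose gradient points inward), followed by an exact line search
  along the feasible segment (the objective restricted to `U` is quadratic,
  so the predicted change `g^T d + d^T H d / 2` is exact) and a
  projected-gradient fallback.  In the interior this reduces to the plain
  Newton step; descent is guaranteed for every `gamma in (0, 1]`.
- **Where the fixed-point updates are evaluated.**  The ARD updates are
  derived at the MAP.  Evaluated at a `gamma = 0.1`-damped iterate they
  misprice `1/U^2` by `1/gamma^2`-like factors and irreversibly prune most
  of the true support within the first iterations.  The fit loop therefore
  (i) skips hyperparameter updates for the first `hyper_warmup = 10`
  iterations (five damped steps per block), and (ii) evaluates them at the
  undamped Newton candidates of both blocks, computed from the same
  Hessians; at convergence the candidate and the iterate coincide, so the
  fixed points are unchanged.  A `U` entry that is zero in the candidate
  but has an inward-pointing gradient is transiently clamped, not dead, and
  keeps its previous precision instead of being pruned.  As a side effect
  genuinely unsupported latents collapse at the proper super-exponential
  ARD rate instead of the slow geometric rate of the damped iterate.
- **Scale-factor gauge.**  The likelihood is invariant under
  `(c_x -> s c_x, U -> U/s)`; combined with damped `U` steps the exact
  scale update ratchets `c` upward indefinitely.  After each scale update
  the geometric mean of the scales is folded back into `U`, fixing the
  gauge so the scales carry only the *relative* calibration between
  modalities (their intended role).
- **SVD initialization.**  `U` starts at zero and `B` at the
  singular-value-scaled right factor of the first modality's truncated SVD.
  Singular-vector signs are arbitrary, but non-negative `U` cannot
  represent a sign-flipped component, so each component is oriented to make
  its left singular vector predominantly positive.  Initial precisions are
  log-spaced over `10^-4 .. 10^4` across latents.
- **Iteration order.**  Odd iterations update `U`, even iterations `B`;
  each iteration forms each Hessian block at most once and reuses it for
  the parameter step, the hyperparameter updates and the Laplace evidence.
  The loop stops at `n_iter` or when the relative objective change falls
  below `rel_tol = 1e-6`.

Held-out samples get loadings from the exact ridge solution at frozen
parameters (identical to one full Newton step on `B` from zero), and are
scored by the entrywise Gaussian log-density of their reconstruction under
the frozen model.

## Synthetic benchmark

The generator emulates a matched RNA + proteomics tumor cohort with known
ground truth:

- 50 pathways, each assigned to exactly one of 8 process categories
  (balanced round-robin, then shuffled); the binary pathway-by-category
  membership is the ground-truth `U`.
- RNA pathway membership: 200 marker IDs per pathway drawn from a shared
  universe of 5000 genes (overlaps allowed), approximating Hallmark set
  sizes.  Proteomics membership: a per-pathway 25% subsample of the RNA
  markers, relabelled through a generated gene-to-protein mapping —
  approximating the ~4.6k proteins vs ~19.6k genes coverage ratio of
  DIA-MS against RNA-seq.
- Loadings: a mixture of three isotropic Gaussians (equal weights,
  within-cluster sd 1) whose cluster means are themselves isotropic
  Gaussian with sd 2, emulating clustered cohorts.
- Noise: per-marker standard deviations from a log-normal moment-matched to
  mean 0.95 / spread 0.25 (RNA) and mean 0.98 / spread 0.10 (proteomics) —
  means as observed in real matched cohorts, the spread ordering encoding
  that proteomics marker precisions vary less than RNA.  The noise family
  itself and the mixture variances are not pinned down by any published
  value; they are configuration defaults chosen once.

What the generator does *not* emulate: count-based (non-Gaussian) marginal
distributions, missing values, batch effects, or biologically correlated
residuals.  Passing recovery tests on this benchmark therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness to real-data violations of them.

## Evaluation protocol and study sizes

The packaged experiments (test suite and worked examples) use these
problem sizes, chosen to exercise the full default generator while keeping
a complete run on a single CPU comfortable:

- parameter recovery: default cohort (p=50, k_true=8, n=100, both
  modalities), fit with k=10, 300 iterations, 10 seeds; scored by the
  Pearson correlation of vectorized true vs fitted pathway activities.
- multimodal benefit: n_train=20, n_test=50, k=8, 10 seeds; held-out
  proteomics reconstruction log-likelihood of the bimodal vs
  unimodal-proteomics fit.
- noise recovery: mean absolute error of fitted vs true `sigma` at
  n_train in {10, 30, 100}, 10 seeds.
- latent pruning: k=12 on k_true=8 data, 800 iterations without the
  relative-tolerance stop, 10 seeds; a latent counts as pruned when its
  `delta` reaches `prec_max`.

## Known limitations

- The Laplace evidence is evaluated with the Hessian as given even when
  entries of `U` sit on the non-negativity boundary; no constrained-Laplace
  correction is attempted.
- The Gaussian likelihood is a modelling choice; count data are expected to
  be preprocessed (CPM, log1p, per-sample inverse-normal quantile mapping,
  per-marker z-score) rather than modelled natively.
- ARD pruning decides by evidence, not identifiability: a surplus latent
  that splits a true category between two latents is a legitimate local
  optimum and will not always be pruned.
- Markers outside every pathway are retained with all-zero mask rows; their
  residual is explained entirely by their noise term.
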