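# Methods

## The model

`arglmm` fits the linear mixed model

    y = X b + g + e,      g ~ N(0, tau2 * B),   e ~ N(0, sige2 * I)

where the genetic relatedness matrix `B` is derived from an ancestral
recombination graph (ARG) rather than from genotypes or a pedigree.
Writing the ARG as a succinct tree sequence (nodes with times in
generations; edges carrying genome segments `[left, right)` in bp), every
edge decomposes into *sub-edges*: maximal fragments over which the set of
sample nodes below the edge's child is constant (no recombination below
the fragment).  Under an infinite-sites view, mutations on a sub-edge `e`
are shared by exactly the samples below it, so the genetic value is
`g = Z u` with `Z[i, e]` the number of haplotypes individual `i` inherits
from `e` (diploids: 0, 1 or 2), and independent sub-edge effects
`u_e ~ N(0, tau2 * A_e)` with area `A_e = span * (t_parent - t_child)`
(bp·generations) — the sub-edge's opportunity for mutation.  This yields
the *branch GRM*

    B = Z Sigma_A Z',     Sigma_A = diag(A_e),

and gives `tau2` units of mutational-effect variance per generation per
base-pair.  Mean effects are absorbed by the intercept, which `fit`
therefore always includes.

The assumptions that matter: additivity of mutational effects (epistasis
and dominance enter only as a first-order approximation), independence of
sub-edge effects (violated mildly by recurrent mutation at a shared
site), and variance proportional to area (i.e. causal mutations uniform
along the genome and in time).  Gaussianity of effects is used for the
likelihood but not required for consistency of the point estimates: REML
solves moment-type score equations that depend only on the first two
moments, and the package's own tests confirm recovery when phenotypes are
generated from discrete mutation effects instead.

## Implicit GRM products

Neither `Z` nor `B` is ever formed.  A product `B w` is one sweep along
the genome over the tree sequence's edge-insertion/removal events,
maintaining per node: the weight sum below it (`w`-pass, up), a
cumulative per-sample contribution `pi` ("rain", down), the genome
position `x` at which its parent branch was last settled, and the
parent's `pi` value at the last synchronization (`off`).  An event on a
node's path to the root finalizes the pending branch fragment
`[x, pos)` — adding `area * weight-sum` to `pi` — and absorbs rain
top-down along that path only; nodes off the path catch up lazily at
their own next event via the `pi[parent] - off` difference.  Each event
costs O(depth), so a product is O(N + E log N) per column for N samples
and E edges.  The same sweep with Gaussian draws of variance
`tau2 * area` per settled fragment *simulates* `g = Z u` exactly, because
the settled fragments refine the sub-edge partition; this is the
generative simulator used throughout the tests.

Centering (`Bc = Pc B Pc`, `Pc = I - 11'/N`) is applied to the weight
vectors on the way in and out.  Submatrix products `B[rows, cols] w`
scatter onto the column set, run the full sweep, and gather rows;
centering, when requested, is always over all N individuals.  Individual
weights are replicated to both haplotypes before the sweep and summed
afterwards, realizing the {0,1,2} dosage without materializing it.

Dense `B` construction (guarded to N <= 2000) exists purely as an oracle:
a transparent tree-by-tree rank-1 accumulation, plus a faster path that
materializes columns through tskit's independent C implementation of the
branch-relatedness product.  The test suite asserts agreement between the
two and against the sweep kernel; the kernel never builds its own oracle.

## Variance components

The REML objective (−2 log restricted likelihood up to a constant) is

    l = log det V + log det(X' V^-1 X) + y' P y,
    V = tau2 B + sige2 I,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

minimized by average-information steps `theta <- theta - AI^-1 grad` with

    grad  = (tr(P) - y'PPy,  tr(PB) - y'PBPy)
    AI_ij = y' P Vdot_i P Vdot_j P y,     Vdot = (I, B).

`AI` equals the mean of the observed Hessian and the Fisher information
of `l`; the expensive trace terms of the two cancel, so the AI matrix is
computed exactly from four projected vectors and is symmetric PSD by
construction (a Gram matrix in the P inner product) — the only stochastic
ingredient of an iteration is the gradient.  Quadratic forms use
`P y = V^-1 (y - X bhat)` with `bhat = (X'V^-1X)^-1 X'V^-1 y`; all
`V^-1` products run through conjugate gradient (CG) on the implicit
operator.  The traces decompose as
`tr(P) = tr(V^-1) - tr((X'V^-1X)^-1 X'V^-2X)` (and analogously for
`tr(PB)`), leaving one large trace each, estimated by XTrace.

Defaults (all overridable through `RemlConfig`):

| parameter | default | role |
| --- | --- | --- |
| `cg_tol` | 1e-5 | relative-residual CG stop |
| `n_trace_vectors` | 50 | XTrace probes per gradient trace |
| `nystrom_rank` | 500 | rank of the CG preconditioner |
| `n_he_vectors` | 50 | XTrace probes for the HE initializer |
| `rel_change_threshold` | 0.05 | relative change that triggers stopping |
| `min_post_steps` | 15 | iterations run after the trigger |
| `max_iter` | 100 | hard cap |
| threads | 1 | products are single-threaded |

Iteration starts from the randomized Haseman–Elston solve, clamps each
component to `>= 1e-8 * var(y)` after every step (keeping V SPD for CG),
and, once both components change by less than 5% relative to the
previous iterate (relative to `max(|theta|, 1e-8 var(y))` to handle the
zero boundary), runs 15 further iterations and returns their mean — the
trailing average filters the stochastic-gradient jitter.  Reported
standard errors are `sqrt(diag(2 AI^-1))` at the returned estimate, the
asymptotic REML covariance under the `AI ~ half the expected information
of -2 log L` identity.  Trace probes are redrawn each iteration from a
per-iteration seed derived from the fit seed, keeping gradient noise
independent across iterations while the whole fit stays reproducible.

Sign conventions: the gradient above is the exact derivative of `l`, and
the PSD `AI` makes `theta - AI^-1 grad` a descent step on `l`; both
facts are asserted against dense finite differences in the tests.

### Haseman–Elston initialization

The randomized HE estimator residualizes `y` against `X` (OLS) and
solves the 2x2 moment system

    [tr(Bt^2)  tr(Bt)] [tau2 ]   [r' B r]
    [tr(Bt)    N - K ] [sige2] = [r' r  ]

where `Bt = Px B Px` is the GRM projected onto the residual space of
`X`.  The projection makes the left side the exact expectation of the
right side under the model; without it (i.e. with raw `tr(B)`,
`tr(B^2)`) the estimator is badly shrunk toward zero on deep-genealogy
GRMs, whose leading component is far from orthogonal to the intercept.
With no covariates the unprojected system is used as-is.  Traces are
XTrace estimates with 50 probes.  HE is also exposed directly
(`ARGLMM(method="he")`) as the comparison estimator.

### Randomized linear algebra

*Conjugate gradient* solves many right-hand sides in one pass — the
trace probes arrive 50 at a time — with per-column convergence tracking
and frozen converged columns.  It is written in-package because SciPy's
`cg` is single-RHS and the batched products dominate total cost.

*Nystrom preconditioner.*  A rank-`r` randomized Nystrom approximation
`B ~= U diag(L) U'` is sketched once per fit; the preconditioner for
`V = tau2 B + sige2 I` at any iterate is then
`U (tau2 L + sige2)^-1 U' + (1/sige2)(I - U U')` — exact re-use is
possible because the Nystrom approximation commutes with positive
rescaling, so one sketch serves every iteration.  The shift is the
current `sige2`, which bounds V's spectrum from below.  When
`rank >= dim` (small fixtures) the sketch degenerates to an exact
eigendecomposition.

*XTrace.*  The trace estimator averages, over sphere-normalized Gaussian
probes `w_i`, the leave-one-out quantity
`t_i = tr(Q_i' A Q_i) + w_i'(I - P_i) A (I - P_i) w_i`, where `Q_i`
orthonormalizes the sketch `A W` with column `i` removed and
`P_i = Q_i Q_i'`.  Because the deflation basis is independent of `w_i`,
each `t_i` is unbiased; because the dominant eigenspace is projected
out, the variance decays roughly as 1/k^2 in the number of probes
(versus 1/k for plain Hutchinson, which the tests implement as a
reference).  The implementation reduces everything to two batched
products (`A W`, `A Q`) plus O(n k^2) dense work, using
`span(Y) ∩ span(Y_-i)^perp = span(Q R^-T e_i)`; it does not require
symmetry, which `tr(V^-1 B)` needs.

### Dense oracle

`dense_spectral_reml` eigendecomposes `B`, rotates `y` and `X`, and
minimizes the exactly-evaluated restricted likelihood by bounded
L-BFGS-B from several starts.  It is deterministic and serves as the
reference the stochastic fit is tested against at N up to 500.

## Genetic prediction

Empirical BLUPs follow the Gaussian conditional mean

    ghat_n = tau2 B_no (tau2 B_oo + sige2 I)^-1 (y_o - X_o bhat),

with one CG solve shared by every prediction and one submatrix product
per target set; `tau2`, `sige2`, `b` are replaced by their estimates.
Conditional variances (`tau2 B_nn - tau2 B_no Sigma_zz^-1 tau2 B_on`)
cost one CG solve per target and are computed only on request, guarded
to 2000 targets.  `predict_linear_combination` generalizes the target to
any linear functional of sub-edge effects given its cross-covariance
operator — per-window BLUPs, ancestral values, and similar.

## Additive genetic variance

The sample quantity `VG = (1/N) sum (g_i - gbar)^2` has model expectation
`tau2 tr(Bc)/N` and, for Gaussian effects, variance
`2 tau2^2 tr(Bc^2) / N^2` (the standard Gaussian quadratic-form variance
`2 tr((A Sigma)^2)`; the factor 2 is confirmed against 2,000 generative
draws in the tests).  `estimate_vg` evaluates both with XTrace on the
centered operator.  `tau2` itself is a generative-process parameter;
`VG` is an emergent property of the sample, and the two should not be
conflated.

## The synthetic-data harness

ARGs come from msprime coalescent simulations of the benchmark
demography: a panmictic population of 100,000 diploids today declining
backward at 1% per generation (continuous rate 0.01 — the discrete
/continuous distinction is far below the resolution of any test),
recombination 1e-8 per bp per generation, genomes 20 kb–1 Mb depending on
the test.  Phenotypes follow the generative model: genetic values from
Gaussian sub-edge effects (or, in `mode="mutation"`, from
msprime-placed mutations with 1% marked causal and standard-normal
effects), divided by `sqrt(4 * sum_T span_T * t_root,T)` so genetic and
environmental variances are comparable, then `y = g + e` with
`e ~ N(0, sige2)`.  A fit on such data recovers the generating `tau2`
when the GRM carries the matching scale `1/(4 sum span*t_root)`
(`ARGLMM(normalize=True)`).

What the harness does *not* emulate: ARG inference error (all fits use
the true simulated ARG; the upstream tsinfer/tsdate step is out of
scope), genotyping artifacts, ascertainment, and non-equilibrium spatial
structure beyond the reduced `structured_fixture` — a low-migration
stepping-stone coalescent whose GRM spectrum decays more slowly than the
panmictic one (asserted via the top-eigenvalue share of the trace),
standing in for forward spatial simulations.  Passing tests therefore
demonstrate correctness of the algorithms and calibration under the
generative model, not robustness to real-data pathologies.

Comparison GRMs: the SNP GRM implements the standard
`(x - 2p)(x - 2p)'/(2p(1-p))` average over variants with MAF >= 0.005;
the Monte-Carlo GRM product drops Poisson(mu * A_e) mutations on the ARG
and forms the unnormalized genotype cross-product, whose expectation is
`mu * B` — tests confirm the mean and the accuracy-vs-mu monotonicity.

## Numerical choices and edge cases

- Positions are 0-based half-open bp; times in generations increasing
  into the past; multi-root trees contribute area only over existing
  edges, and `total_root_area` sums span × root time over all roots.
- CG starts from zero (no warm starts) for reproducibility; breakdown
  directions (`p'Ap <= 0` on semidefinite operators) freeze the step and
  surface as a convergence error if the residual stalls.
- The HE 2x2 system raises on singularity (e.g. `B` proportional to I).
- Constant phenotypes and rank-deficient covariates are rejected.
- Components are clamped at `1e-8 var(y)`; a fit at the `tau2 = 0`
  boundary typically clamps immediately and converges fast.
- All seeds are 32-bit; every public sampler takes an explicit seed and
  fixed seeds give bit-identical output (the sweep simulator draws
  inside the compiled kernel from a seeded generator).

## Problem sizes in the default test run

Unit tests run on hand-built 2–3-sample ARGs and simulated ARGs of
15–100 diploids.  The end-to-end checks use: 20 random ARGs (≤100
haplotypes) for matvec exactness; 2,000 generative draws for moment and
VG checks; N ∈ {200, 500}, 1 Mb with 10 stochastic seeds for the
dense-oracle equivalence; and N = 2,000 diploids, 1 Mb, 4 replicates per
`tau2 ∈ {0, 0.5, 1.0}` for parameter recovery, the REML-vs-HE accuracy
ordering, and the median-relative-error summary.  These sizes are the
package's choice of desk scale; the same pipeline runs unchanged at
larger N (cost grows near-linearly in edges, and the fit remains
matrix-free throughout).  `scripts/acceptance.py` re-runs the same
studies from scratch (3 replicates per cell) and writes the measured
numbers to JSON.

## Known limitations

- Only the two-component model (`tau2 B + sige2 I`) is implemented; the
  operator layer is written so further components could be added, but
  multiple GRMs, frequency weighting `(p(1-p))^alpha`, and GWAS-style
  backsolving are out of scope.
- REML standard errors use the asymptotic inverse-information identity
  and inherit trace-estimation noise; they are diagnostics, not
  guarantees.
- The HE estimator is reported unclamped when used as a comparison
  (its signed error is its true error); fitted components exposed to
  users are clamped non-negative.
- At N around 1,000 and 1 Mb genomes the REML point estimate of an
  intermediate `tau2` shows visible finite-size skew (measured ~-25%
  at `tau2 = 0.5`) that disappears by N = 2,000; this is a property of
  the estimator at low effective GRM rank, not of the solver — the
  stochastic fit agrees with the dense oracle to well within seed noise
  at every size tested.
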