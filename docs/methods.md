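# Methods

This note documents the models and procedures implemented in `dpath`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Observation model and weighted Poisson NMF

Let `X` be the genes × cells matrix of log-transformed TPM values
(`log(TPM+1)`, natural log, pseudocount 1; both configurable).  The
expected value of `X_nm` is modelled as a linear combination of `K`
non-negative metagene basis vectors,

    mu_nm = sum_k U_nk V_km,      U >= 0,  V >= 0,  sum_k V_km = 1,

so each cell's coefficient column lies on the probability simplex and can
be read as the mixture weights of `K` latent expression programmes.
Each observation is a two-component mixture: with probability `pi_nm` it
follows a Poisson distribution with mean `mu_nm` (the gene is expressed),
otherwise a low-magnitude Poisson with mean `lambda0 = 0.1` (a dropout
event).  Because log-TPM values are real, the Poisson density is used in
its continuous extension `exp(-mu) mu^x / Gamma(x+1)`.  The weights are
the posterior odds of expression,

    pi_nm = f(X_nm; mu_nm) / (f(X_nm; mu_nm) + f(X_nm; lambda0)),

and enter a weighted log-likelihood
`L = sum_nm pi_nm [X log mu - mu - log Gamma(X+1)]`.

**Optimization.**  `L` is maximized at fixed `pi` by
majorization-minimization sweeps.  The basis update is the standard
multiplicative rule `U <- U ∘ ((pi∘X/mu) Vᵀ) / (pi Vᵀ)`.  For `V` the
simplex constraint is handled exactly: the surrogate separates per column
into `max sum_k (A_k log v_k - B_k v_k)` with `A = V ∘ (Uᵀ(pi∘X/mu))`,
`B = Uᵀpi`, whose constrained optimum is `v_k = A_k/(B_k + lam)` with the
column's Lagrange multiplier `lam` found by bisection on the monotone
function `g(lam) = sum_k A_k/(B_k+lam)`.  (A naive "update then rescale
the column" projection is the `lam = 0` special case and does not
guarantee ascent; the exact step does, and the likelihood trace is
asserted non-decreasing between weight re-estimations in the tests.)
`pi` is re-estimated every 10 sweeps (`pi_every`).  `mu` is floored at
1e-10.  Convergence: relative likelihood change below `tol = 1e-5` over a
10-sweep window, at most 500 main sweeps.

**Burn-in and initialization.**  A weighted-KL NMF burn-in (at most 100
sweeps) precedes the main loop, with fixed weight `w0 = 0.1` on zero
entries and 1 elsewhere.  `V` starts from NNDSVD (zeros replaced by
`1e-6 · mean(X)` so multiplicative updates cannot lock them); `U` starts
from i.i.d. exponential draws with mean `mean(X)` — dispersed enough that
independent restarts explore distinct optima of the non-convex objective.

**Ensemble.**  The fit is repeated `r_mf` times (default 20; the
benchmarks below use 10) with seeds `seed+1 … seed+r_mf`.  The first run
keeps the deterministic NNDSVD start for `V`; later runs draw `V` from a
Dirichlet.  This matters: with a shared NNDSVD start every run lands in
the same basin and the ensemble is pointless.  Runs are aligned to the
first by Hungarian matching on the correlation of coefficient rows, since
NMF component order is arbitrary.  Two aggregates are kept: `V_bar`, the
column-renormalized mean of aligned coefficients (the landscape input),
and the maximum-likelihood run, used wherever a single representative
factorization is needed (recovery metrics, benchmark comparisons) — a
standard restart-selection rule, and empirically the likelihood
discriminates good from bad local optima on simulated data.

**Rank selection.**  The consensus matrix records the fraction of runs in
which two cells share a dominant metagene; its cophenetic correlation
(average linkage on `1 - consensus`) is scanned over a rank grid and the
largest `K` before the first drop exceeding `delta = 0.01` is selected.
A constant consensus is assigned cophenetic 1 by convention.  Limitation:
this instability heuristic assumes restarts disagree above the true rank.
The exact-MM optimizer here is consistent enough on clean simulated data
that the profile can stay above 0.97 for every candidate rank, in which
case the scan returns the largest rank with an explicit warning flag; on
noisy mixture data the profile is informative but seed-sensitive.

**Metagene entropy.**  `H_m = -sum_k V_km log V_km` (natural log,
unnormalized; a `normalized=True` option divides by `log K`).  High
entropy means several programmes are simultaneously active — a
progenitor-like state; zero entropy means full commitment to one
programme.

## Metacell landscape

A batch SOM maps cells (their coefficient columns, from `V_bar` or a
single fit) onto a 15 × 15 hexagonal grid of 225 prototype *metacells*.
Grid convention: odd-row offset layout, unit spacing; six neighbours at
planar distance 1.  The codebook initializes on the plane of the two
leading principal components and trains for 100 epochs with a Gaussian
neighbourhood whose radius decays linearly from `max(rows, cols)/2` to 1.
The batch rule makes refits with the same seed bit-identical.

The codebook is min–max scaled per metagene across metacells (`W`, making
programme intensities comparable); per-metacell columns of `W` are
renormalized to the simplex for the metacell entropy `H_p`.  A constant
metagene row scales to zero with a warning.

**Partitioning.**  PAM (k-medoids; BUILD + best-improvement SWAP on
Euclidean codebook distances, deterministic tie-breaks) clusters the
metacells.  Given no target count, the scan runs `C` from
`floor(225/15) = 15` down to 2 and returns the first partition whose
clusters all contain at least `min_size = 15` metacells and are connected
on the hex grid; if none qualifies, a single cluster is returned with a
warning.  Connectivity only makes sense for codebooks that vary smoothly
over the grid — which fitted SOMs are by construction; spatially random
codebooks admit no connected partition.

**Metacell expression.**  `Y_np` is the mean expression of gene `n` over
the cells assigned to metacell `p`.  Empty metacells are imputed from the
mean of their already-filled grid neighbours (iterating outward; isolated
empty regions fall back to the global occupied mean) and flagged.

## State graph, prioritization, gene scores

The heterogeneous graph has `K` metagene plus `P` metacell vertices and a
row-stochastic transition matrix:

- metacell → metacell: only between grid neighbours and only in the
  direction of *decreasing* entropy (committed mode) or *increasing*
  entropy (progenitor mode); a fraction `beta = 0.85` of the row mass,
  split proportionally to the Gaussian similarity
  `s_pq = exp(-d_pq²/sigma²)` with `d_pq` the Euclidean distance between
  codebook columns and `sigma` the median neighbour distance
  (configurable);
- metacell → metagene: the remaining `1 - beta`, proportional to `W_kp`;
  a metacell with no admissible neighbour sends all its mass here;
- metagene → metacell: proportional to `W_kp`.

Rows without outgoing mass get a self-loop.  With distinct entropies the
committed and progenitor metacell blocks are exact structural transposes.

Random walk with restart iterates `u <- (1-r) Gᵀ u + r e` (restart
probability `r = 0.85`, `e` uniform on the restart metagenes) to an L1
tolerance of 1e-12; the metacell sub-vector is renormalized to a
probability vector.  A committed query restarts at one metagene on the
committed-mode graph; a progenitor query restarts at several metagenes on
the progenitor-mode graph.  The fixed point equals the dense solve of
`(I - (1-r)Gᵀ) u = r e`, asserted in the tests on all graphs up to 50
vertices.

Genes are scored against a prioritization by
`E_n = sum_p (u_p - mean(u)) Y_np`: the centering makes constant genes
score zero, so `E_n` measures covariation of expression with the
steady state.

## Trajectories and pseudotime

Termini are the argmax metacells of the progenitor query and of each
committed query (ties break toward higher entropy for progenitor, lower
for committed, then index; a flat steady state is rejected).  The
trajectory is the shortest path on the hex grid with codebook-distance
edge weights (Dijkstra with a fewest-hops-then-lexicographic tie-break,
verified against exhaustive enumeration on small grids).  Cells assigned
to path metacells (optionally including grid neighbours) inherit the
normalized cumulative arc-length of their metacell as pseudotime in
[0, 1]; a rank-based variant is available.  Within a metacell, ordering
is refined by decreasing coefficient-space distance to the committed
terminus.  Agreement with ordinal stage labels uses Kendall's tau-b,
whose tie correction suits staged designs; an entropy-only ordering (most
plastic first) is computed alongside as the simple comparator.

## Synthetic data

`simulate_expression` draws membership `V` as i.i.d. Bernoulli 0/1
entries (active with probability 0.7; all-zero columns resampled),
rescales columns to the simplex, draws the basis `U` i.i.d. from
Gamma(shape 2, rate 0.05), and observes `X ~ Poisson(U V)` masked to zero
by an independent Bernoulli(0.5) dropout indicator.  Defaults: 200 genes,
50 cells, 4 metagenes.  The Gamma rate puts the mean expression at 40
(s.d. ≈ 28), the overdispersed tens-of-TPM magnitude typical of detected,
variable genes after filtering; at substantially lower magnitudes the
Poisson and dropout noise drown the block structure entirely (even
oracle clustering of the noiseless-free columns fails), so no method
could be evaluated against the ground truth.  Simulated `X` feeds the
factorization directly: it already lives on the model's observation
scale, playing the role log-TPM plays for real data.

The staged variant splits cells evenly over three ordinal stages with
commitment levels (0, 0.6, 1): stage-0 cells are uniform mixtures
(progenitors), stage-2 cells one-hot (committed), each non-progenitor
cell carrying a random target lineage.

**What the simulator does not emulate:** library-size variation, gene
length effects, amplification bias, mean-dependent dropout, correlated
gene modules beyond the metagene structure, or doublets.  Passing the
benchmarks therefore shows the estimator recovers the generative
structure it assumes under heavy dropout — not that it is robust to every
artefact of real single-cell data.

**Recovery metric.**  Because membership entries are 0/1, most simulated
cells have several *exactly tied* top coefficients, so "the dominant
metagene" of a cell is decided by an arbitrary tie-break that no
estimator can reproduce.  Recovery is therefore scored as the adjusted
Rand index between *active-set partitions*: cells are grouped by which
metagenes exceed `1/(2K)` (half the smallest active level of the mixture
model), in truth and in the fit.  This is invariant to metagene order and
well-defined under ties.

**Benchmark.**  For each of 10 simulation seeds, an ensemble wp-NMF fit
(K = 4, `r_mf` = 10) is compared with top-4 PCA scores of `log(X+1)` on:
leave-one-out error of a linear SVM (C = 1, one-vs-rest) predicting the
argmax-label classes, and the within/total sum-of-squares ratio of the
factors under those classes.  Both comparisons are relative — the same
labels and the same folds for both methods — so the SVM constant matters
little.  The acceptance script recomputes all of this from scratch at the
given seed, with problem sizes as above.

## Numerical notes

- Bisection for the simplex multiplier runs 80 halvings with the
  denominator clipped at the one-hot limit, so columns stay finite.
- Poisson log-densities are evaluated in log space via `xlogy` and
  `gammaln`; `X = 0` contributes `-mu` exactly.
- All randomness flows through `numpy.random.default_rng` seeds carried
  in the config objects; ensemble member `r` uses `seed + 1 + r`.
- PAM, the SOM, Dijkstra and the hex-grid machinery are deterministic
  given their inputs (ties break toward lower indices).
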