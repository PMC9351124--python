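# Methods

## Model

For subject *i* with paired cell-level matrices `G_i (m_i × p)` and
`X_i (m_i × q)` over the same cells and a univariate outcome `y_i`, the
predictor is the cross-modal Pearson correlation matrix
`Z_i[j,k] = corr(x_ij, g_ik)` over the `m_i` cells. Collapsing cells into
a correlation matrix standardizes both the per-subject dimensions (cell
counts differ across subjects) and the value range ([−1, 1]), at the cost
of discarding mean-expression information: the method detects features
whose *co-expression* relates to the outcome, not features whose
expression level does. Zero-variance columns (typically all-dropout
features) receive correlation 0 rather than NaN, which leaves them
unselectable by signal. At least 3 cells per subject are required.

The regression is a rank-1 tensor GLM with canonical link,

    g(μ_i) = β₀ + λᵀu_i + β_Xᵀ Z_i β_G ,

for gaussian/identity or binomial/logit families. The factorization is
scale non-identifiable — `(τ β_X, β_G/τ)` is an equally good model — so
on exit `β_G` is normalized to unit L2 norm with the magnitude absorbed
into `β_X`; selections are invariant to this convention.

## Estimation

**Block relaxation.** Holding `β_G` fixed, the model is a GLM of `y` on
the n-row design whose *i*-th row is `Z_i β_G`; symmetrically for `β_G`.
The two blocks are alternated until the relative deviance change falls
below `tol` (default 1e-6) or 100 iterations.

**Support caps instead of penalty weights.** Each block solves an
elastic-net GLM (L1 weight α, via scikit-learn's coordinate descent for
gaussian and saga for binomial) along a penalty path from `alpha_max`
down to `alpha_max × path_eps` (default 1e-3, 50 points). The returned
solution is the largest-support path point with at most `max_nonzero`
nonzero coefficients, ties resolved toward the weakest penalty. Two edge
rules matter in practice: a pure-L2 penalty never yields exact zeros, so
α is floored at 0.01 inside the path; and when the support jumps from
empty past the cap in a single path step (highly collinear designs at
small caps), the first over-cap solution is truncated to its cap largest
magnitudes instead of returning a spurious all-zero fit. Intercept and
covariates are unpenalized — exactly so for the gaussian family via
Frisch–Waugh residualization; for the binomial family the covariates ride
in the saga design (penalized) but never count against the cap.

**Initialization and local optima.** The alternation is a local search:
with many candidate features and few subjects it can settle in basins
with no overlap with the dominant outcome-linked block. Two deterministic
starts are run and the lower final deviance kept: (1) a *supervised
spectral start* — the top right singular vector of the q×p matrix of
entrywise correlations between `Z` and `y`, hard-thresholded at
`3/sqrt(n)` before the SVD so the sea of chance-level correlations does
not dominate the leading direction — and (2) the flat unit vector.
Seeded random restarts are used only if a block degenerates to all zeros.
A support pair that recurs without deviance improvement is treated as a
selection cycle and the best state seen is returned.

## Stability tuning

The four hyperparameters are tuned one dimension at a time by an
instability criterion: for each candidate cap (starting at 5, stepping by
5), selection is repeated on R subject subsamples of size c for each α in
the grid; instability is `mean_j 2 θ_j (1 − θ_j)` over the tuned
dimension's features, the α minimizing it is kept (ties toward smaller α,
whose heavier L2 component is the stabler choice under collinearity), and
the cap grows while that minimum stays below φ. The returned cap is the
largest one that stayed stable; if even the initial cap is unstable it is
returned unchanged with a warning flag. The X dimension is tuned first
with the G dimension held wide open (α_G = 0.5, max_G = ⌊p/2⌋), then G is
tuned at the tuned X values. Subsampling is without replacement over
subjects, never over cells; with c = n−1 the scheme becomes leave-one-out
with each of the n subsets used at least once.

Subsample fits inside the tuner run a single screen-initialized block
alternation rather than iterating to convergence. The support is fixed in
the first alternation; further iterations refine magnitudes (irrelevant
to selection frequencies) and add local-search noise to exactly the
quantity — selection consistency — the instability estimate measures.
This also makes the tuner several-fold faster; the final fit at tuned
hyperparameters always uses the full iteration budget.

## Synthetic studies

The generator emulates a CITE-seq-like supervised network study with
planted truth. Feature blocks: in the gene modality, `H` (outcome-linked
but unrelated to the marker modality), the network genes `G`, the decoy
`G′` (cross-modal but outcome-unrelated) and independent noise genes; in
the marker modality, `S`, network `X`, decoy `X′` and noise. Default
sizes are H=15, G=10, G′=15, 1400 noise genes (p=1440) and S=20, X=15,
X′=20, 1500 noise markers (q=1555); the `scaled_down_structure(k)` helper
divides the two noise blocks by k for desk-scale work.

**Latent layer.** One scalar per block per subject is drawn from a
zero-mean MVN whose nonzero off-diagonals are exactly the planted edges:
G–X and G′–X′ at `rho_link` (0.6), H–y and S–y at `rho_y` (0.2), G–y and
X–y at `rho_y_net` (0.85); positive definiteness is verified at
construction. Each cell additionally draws a six-block latent vector.
The cell-level G–X covariance for subject *i* is `coexpr · w_i` with
`w_i = min(t²/4, 1)` and `t` the standardized mean of the subject's G and
X latents — so network genes and markers genuinely co-fluctuate across a
subject's cells, with a strength that tracks the outcome. The decoy
edge G′–X′ gets the same treatment from its own (outcome-independent)
latents, so decoy co-expression varies just as much but carries no
outcome signal. H and S share no cell-level edge. Per-feature loadings on
the cell component are drawn once per study (log-normal, sd 0.4),
giving features persistent, hub-like identities that selection can rank.

**Gene means and outcome.** Gaussian latents cannot serve as count means;
each cell × feature latent `z` is mapped through `z²/sd(z)`, which is
Gamma(shape 1/2, scale 2·sd) distributed. The outcome mean passes through
the same transform: because `z²` has zero third-moment coupling to `z`,
an *untransformed* outcome latent would be exactly linearly uncorrelated
with every gene mean, leaving the generator unsupervised — the squared
outcome fixes all signs by construction (`outcome_transform="identity"`
exposes the literal alternative). Observed `y_i` adds N(0, σ_y²) noise,
σ_y = 0.2. Noise-feature means are drawn independently from
Gamma(0.6, 2).

**Counts.** A Splatter-style pipeline per subject: feature-level
expression outliers (probability 0.05, median × LogNormal(1, 0.5)
replacement), one mean-1 gamma subject dispersion multiplier scaling the
gamma-Poisson mixing variance, a log-normal per-cell library factor, a
global sequencing-depth multiplier `mean_scale`, Poisson sampling, and
logistic mean-dependent dropout (probability `1/(1+exp(k(log λ − x₀)))`).
The technical-noise axis maps level → (x₀, BCV², depth, subject-dispersion
shape, library sd): low (−2, 0.05, 3.0, 20, 0.2), moderate (−0.5, 0.25,
1.5, 8, 0.35), high (2.0, 1.0, 0.4, 0.7, 0.7). Notably, dropout alone
does not degrade network recovery — mean-dependent dropout concentrates
the surviving counts in the most informative cells — so the axis also
shallows the depth and inflates between-subject nuisance, which is what
actually erodes the correlation tensor's outcome link. Per-subject cell
counts are Poisson around the setting's mean, floored at 3.

**What the generator does and does not emulate.** It reproduces count
marginals with realistic sparsity (34% zeros at the low setting, 86%+ at
high), library/dispersion/outlier/dropout nuisance, and a planted
cross-modal network whose per-entry correlation with the outcome reaches
≈0.8 at 1000 cells under low noise. It does not emulate cell-type
mixtures, batch effects, trajectories, or raw-data preprocessing
(inputs to the selector are assumed preprocessed), and the latent
magnitudes are this package's own stand-ins: passing recovery tests here
demonstrates correct mechanics under a strong planted signal, not
performance guarantees on any particular real dataset.

## Benchmarks and evaluation

The AUC competitor binarizes the outcome at its median (ties → 0,
constant outcomes are an error), labels every cell with its subject's
class, and computes a tie-corrected Mann–Whitney AUC per feature over the
pooled cells (normal-approximation two-sided p-values; exact enumeration
is infeasible at cell scale). Selection is either Bonferroni-adjusted
p < 0.05 or AUC outside (0.3, 0.7), strict inequalities; a subject-level
aggregation unit is available as an option. Selections are scored against
simulated truth by sensitivity and specificity.

## Numerical choices and limitations

- Convergence: relative deviance change < 1e-6, ≤100 outer iterations;
  path: 50 alphas spanning 3 decades, coordinate-descent tol 1e-5.
  OLS-limit behavior (used by several tests) needs `path_eps≈1e-9,
  path_tol≈1e-12`.
- Deterministic given (data, hyperparameters, seed); subject order does
  not affect selections.
- Desk-scale problem sizes used by the shipped checks: tuning runs use
  n=40 subjects × ~500 cells with noise blocks reduced fivefold (three
  seeds, minutes on one CPU); recovery runs use n=60 × ~1000 cells
  (ten seeds per noise level).
- Rank is fixed at 1: a single network per run. Multiple cell clusters
  are handled by running the selector per cluster. No standard errors or
  hypothesis tests are provided for the selected coefficients.
- The block iteration is a local optimizer; the spectral start makes the
  outcome-linked basin reliably reachable in the regimes above, but
  convergence to the global penalized optimum is not guaranteed.
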