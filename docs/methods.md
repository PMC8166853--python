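# Methods

This note documents the models implemented in `commdesign`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reading was
defensible.

## Community assembly model

Species abundances $X_i$ (OD600 units) follow generalized Lotka–Volterra
dynamics, $\dot X_i = X_i (r_i + \sum_j a_{ij} X_j)$, over a 48-hour batch
culture started from a total inoculum of OD 0.0066 split equally across the
inoculated species. The diagonal coefficients $a_{ii}$ are constrained
negative (intra-species competition), which bounds growth; off-diagonal
$a_{ij}$ are growth interactions. Extinction is absorbing: species absent at
t = 0 are excluded from the integrated state, so their trajectories are
exactly zero rather than numerically small.

Two integrators coexist deliberately:

- `simulate_glv` uses LSODA (stiff-capable, rtol 1e-6, atol 1e-9) and is the
  reference path for single trajectories. Abundances below 1e-10 are clamped
  to zero to prevent sign flips.
- The batched fixed-step RK4 routines integrate many communities and/or many
  parameter sets in one vectorized pass (BLAS batched matmul per stage).
  With the rate scales of this system (|r| < 1 h⁻¹, |aX| of order 1 h⁻¹) a
  0.1 h step gives endpoint agreement with LSODA at the 1e-9 level
  (48-h endpoints sit near attracting equilibria, which absorbs local
  truncation error); the inference cost function uses 0.5 h steps, still
  far below measurement noise. The batched state is clipped to [0, 1e4] OD:
  the upper cap is unreachable for physical parameters and exists so that an
  optimizer probing runaway-positive interaction regions receives a large
  finite cost instead of an overflow.

## Parameter inference

The fitting objective is the joint weighted cost over endpoint ("single")
and monoculture time-series ("dynamic") data plus an L2 penalty on
prior-standardized parameter deviations, $\lambda \sum_j ((\theta_j -
\mu_j)/s_j)^2$. The initial prior is N(0, 1) per parameter; after a fit, the
bootstrap ensemble's per-parameter mean/sd (sd floored at 1e-3) becomes the
prior for the next update, so information chains across experiment rounds.

Numerics. Monoculture trajectories use the exact logistic closed form (the
single-species gLV solution), written in an overflow-safe parameterization
with the $r \to 0$ limit handled separately. The MAP problem is solved as a
bounded nonlinear least-squares problem (scipy's trust-region reflective
solver) on the weighted residual vector; the Jacobian is a forward-difference
approximation computed for all N+N² parameter directions in a single batched
integration, which makes one Jacobian no more expensive than ~P function
evaluations fused into one vectorized pass. A quasi-Newton minimizer on the
scalar cost was an order of magnitude slower to reach the same optimum and
was dropped. Bounds impose $a_{ii} \le -10^{-4}$. Multi-start (prior mean,
previous MAP when given, jittered prior mean; best final cost wins, ties to
the smaller parameter norm) guards against local minima; bootstrap members
warm-start from the MAP and use a single start.

The bootstrap ensemble perturbs every observed mean with zero-mean Gaussian
noise scaled by the replicate standard deviation (`noise_scale`, default 1 —
the proportionality constant is not pinned down by the underlying method
description, so it is exposed), truncating negative abundances at zero.
Member 0 is always the unperturbed MAP. If the perturbed dataset is
identical to the original (all replicate sd zero), the member is the MAP by
construction and the refit is skipped. A run fails only if more than 20% of
members fail to fit.

λ and w. The default weight on dynamic residuals is w = 10 (monoculture
series are both more informative per point and fewer in number). λ defaults
to 0.01, but every reported recovery experiment selects it by the package's
standard procedure: fit on 80% of endpoint communities over a coarse
log-spaced grid and keep the strongest λ whose held-out endpoint SSE is
within 5% of the best — regularize as hard as the data allow. On noiseless
data this selects the smallest grid value, on 5%-noise data typically
0.01–0.1.

## Interaction imputation

Pairs never cultured together leave $a_{ij}$ at its prior; those entries are
filled by KNN imputation (K = 2) on the interaction matrix sorted into
phylogenetic leaf order. Distance between species rows is nan-aware
Euclidean over commonly observed columns scaled by
$\sqrt{N_\text{cols}/N_\text{shared}}$; the imputed value is the unweighted
mean of the k nearest rows' observed values in the target column
(scikit-learn's `KNNImputer`, verified in tests against a hand-written
brute-force oracle). Neighbor search is row-wise only and $a_{ij}$, $a_{ji}$
are imputed independently; imputation is repeated independently for each
ensemble member. The distance metric is permutation-invariant, so the
phylogenetic ordering matters for reporting and for which species count as
"neighbors" only through their row content, not their position — asserted by
a permutation round-trip test. A species row sharing no observed entries
with any other row is an error naming the species, not a silent column-mean
fill.

## Production regression

Butyrate at 48 h is a linear model with interactions over the producer guild
(presence intercepts + abundance slopes per producer, pair-presence
intercepts + abundance-product slopes per producer×partner ordered pair,
self-pairs excluded; 2|BP| + 2|BP|(N−1) coefficients). Indicators key on
inoculation, not endpoint abundance. Third-order terms are assumed
negligible. The model derives from growth-coupled production — specific
productivity proportional to specific growth rate, with composition-dependent
modulation — whose time integrals are linearly approximated at the endpoint;
a test integrates the mechanistic two-species version numerically and
confirms the fitted producer slope is positive (the approximation is
directionally valid).

Fitting uses lasso with no global intercept (the presence indicators play
that role). Continuous features are scaled to unit variance for the fit
(penalty fairness across OD-scale and OD²-scale columns) and coefficients
back-transformed; 0/1 indicators are left unscaled. The penalty is chosen on
a 30-point log grid (1e-4…10) by 10-fold CV, lowest median test MSE, ties
toward the stronger penalty; folds are shuffled with a recorded seed.
Negative raw predictions are reported as 0 mM (raw value available).
`refit_on_support` provides the OLS debiasing step used when coefficient
values rather than support are of interest. A constant response returns the
all-zero model with a warning.

## Design-space exploration

Constrained enumeration (richness bounds, required / at-least-one-of /
excluded sets) streams subsets in deterministic lexicographic order over the
phylogenetic species order; the closed-form count uses inclusion–exclusion
over binomial sums and is exhaustively checked against enumeration on small
pools. Ensemble prediction simulates each community under every parameter
set and maps endpoints through the regression; summaries are the 50th and
20th/80th percentiles (linear interpolation) — the "60% confidence
interval" names the band, not an estimator, so the percentile convention is
ours. Full-pool sweeps (2²⁵−1 communities) use the best-fit parameter set
only and stream in chunks, storing float32 butyrate/biomass values per
richness level for exact percentile computation; ensemble propagation is
intended for panels up to ~1e5 communities.

Panel selection takes the n_low lowest and n_high highest predicted medians
within a richness range and draws a random panel of equal size with a
matched richness distribution (seeded). This extreme-plus-matched-random
reading is one admissible version of "spanning the predicted range"; the
designed panel's higher variance relative to the random panel is asserted on
synthetic landscapes.

## Measurement model and QC

Absolute abundance = relative sequencing abundance × OD600. The phenol-red
pH curve is the Henderson–Hasselbalch form pH = pKa + b·log₁₀((A −
A_min)/(A_max − A)) with A_min/A_max anchored to the pH 3 / pH 11 standards
(which therefore cannot enter the regression) and (pKa, b) from OLS of pH on
the log term for standards in the linear range pH 5.2–11. Samples are
excluded when >1% of reads map outside the expected membership
(contamination) or when total reads <1000 while OD600 >0.1 (too few reads
not explained by absent growth); low-read non-growing samples are retained.
Boundary values (exactly 1%, exactly 1000 reads) are retained — the
thresholds are strict inequalities as stated, and whether boundary-equal
samples passed in the original protocol is not documented.

## Synthetic data generator

The generator defines the study conditions the pipeline is tested under: a
25-species pool with 5 butyrate producers by default (8/2 in the compact
test conditions), growth rates uniform in 0.15–0.65 h⁻¹, carrying capacities
0.3–1.2 OD (setting $a_{ii} = -r_i/K_i$), and off-diagonal interactions
drawn in three classes — negative (49.8%), positive (1.7%), near-neutral —
relative to the ±0.05 h⁻¹·OD⁻¹ magnitude thresholds, matching the inferred
interaction structure of the emulated system. The production truth has
positive α for every producer and a configurable number of nonzero β pairs
(default 10; 4 in the compact conditions), with magnitudes that keep
community butyrate in the observed 0–50 mM range.

Measurement emulation: OD and butyrate receive mean-one multiplicative
lognormal noise (cv 5% — a replicate-scale noise law chosen for
non-negativity; the true heteroscedasticity structure across species is
unknown), read counts are multinomial at Poisson(20,000) depth, butyrate is
floored at 0, and a configurable fraction of samples receives ≥1.1%
contaminating reads from a non-member species to exercise QC. Monoculture
time series use an 8-point grid over 0–48 h. What this does **not** emulate:
pH dynamics and buffering, metabolite cross-feeding beyond the regression
structure, batch effects, primer/copy-number bias in sequencing, or
model-mismatch between gLV and real growth — so passing tests demonstrate
correct inference under the model's own assumptions, not robustness to
misspecification.

## Reference experiment sizes

The recovery benchmark uses 8 species: monocultures, all 28 pairs, and 50
random 4–8-member communities (3 replicates); the end-to-end round trains on
monocultures, all producer-containing pairs and 30 random 3–5-member
producer-containing communities, blinds one producer-free pair from training
so the imputation stage is genuinely load-bearing, fits a 30-member
ensemble, and validates on 30 held-out communities. These sizes keep each
experiment at minutes on a single core while leaving the inference problem
genuinely underdetermined in places (which is what the prior, ensemble, and
imputation machinery exist for).

## Known limitations

- The gLV family cannot represent non-monotonic pairwise effects or
  higher-order interactions; the production regression absorbs some of this
  but only at the endpoint.
- Bootstrap-refit ensembles approximate posterior uncertainty; they are not
  MCMC samples and can be overconfident along well-constrained directions.
- Finite-difference Jacobians limit parameter counts to a few hundred
  (N ≲ 25 is comfortable); larger pools would warrant forward sensitivities.
- λ selection uses a single 80/20 split for speed, not repeated CV.
- The full 2²⁵ sweep is supported by the streaming API but takes
  CPU-days at the default step size, as in any single-machine setting.
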