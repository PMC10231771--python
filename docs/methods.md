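# Methods

`graphmr` infers a directed network of causal effects among T traits from
GWAS summary statistics in two stages: (1) bidirectional Mendelian
randomization (MR) by constrained maximum likelihood, robust to invalid
instruments and to overlapping GWAS samples, estimates the *total* causal
effect for every ordered trait pair; (2) network deconvolution inverts the
total-effect matrix into the *direct*-effect matrix. Inference throughout is
by data perturbation: resampling the summary statistics from their estimated
sampling distribution and re-running the full estimation (including invalid-
instrument selection) on every perturbed copy.

## The bivariate likelihood and the constrained MLE

For SNP i with marginal effects b_Xi on the exposure and
b_Yi = theta b_Xi + r_i on the outcome, the GWAS estimates are modeled as

    (beta_x_i, beta_y_i) ~ N2( (b_Xi, theta b_Xi + r_i),
                               [[sx_i^2, rho sx_i sy_i],
                                [rho sx_i sy_i, sy_i^2]] ),

independently across SNPs (instruments are LD-clumped per pair). r_i
collects all pleiotropic paths to the outcome that bypass the exposure —
both uncorrelated (direct SNP effects) and correlated (confounder-loading)
pleiotropy; SNP i is an *invalid* instrument iff r_i != 0. rho is the
correlation between the two traits' estimates induced by shared GWAS
participants: for continuous traits rho = (N0 / sqrt(N1 N2)) r(x, y) with N0
overlapping individuals and phenotypic correlation r(x, y). At rho = 0 the
model is the classic two-independent-sample MR likelihood.

The constrained MLE minimizes the negative log-likelihood subject to exactly
K of the r_i being nonzero. Coordinate descent alternates:

* Step 1 — closed-form r update; the K SNPs whose freed r_i most increases
  the likelihood are selected (stable tie-break by SNP index), all others
  get r_i = 0. The per-SNP gain is always >= 0.
* Step 2 — closed-form b_X update, then the closed-form theta update
  (a weighted regression through the origin with a rho correction).

The objective is non-increasing across iterations (each step is an exact
conditional minimization); convergence is declared at |delta theta| < 1e-7
(max 200 iterations; non-convergence is flagged, not raised). At
convergence the selected invalid instruments are profiled out exactly
(b_X = beta_x, r = beta_y - theta beta_x), so they contribute neither to
theta nor to its curvature.

K is chosen by BIC(K) = -2 l + log(N) K with N = min(N1, N2); ties go to
the smallest K. Identification rests on the plurality condition: the valid
instruments form the largest group sharing a single ratio value, so K can
range over 0..m-2.

**Multi-start and subset refinement.** The profile likelihood in theta is
multimodal when pleiotropic instruments form competing ratio clusters.
`select_bic` therefore starts coordinate descent from the IVW estimate, a
null start (theta = 0), and uniform draws on IVW +/- 0.5; with few
instruments (m <= 12 by default) each converged fit is additionally refined
by a 1-swap local search over the invalid subset, which escapes the corner
solutions greedy per-iteration selection can settle on. With m = 6 this
matches exhaustive invalid-subset enumeration with full numeric optimization
to 1e-6 in the log-likelihood on every tested instance.

**Standard errors.** The default SE comes from the observed Fisher
information over (theta, {b_Xi : i valid}), inverted via the Schur
complement of the diagonal b_X block. For fits performed under working
independence (rho set to 0 when the truth may differ) a robust sandwich SE
A^-1 B A^-T is provided: A is the observed working information and B the
variance of the summed score, computed analytically from the linearity of
the per-SNP scores in the estimates under the true bivariate covariance.
The two coincide when rho = 0 (exactly so at residual-free fits, since the
observed information carries residual terms the expected meat does not).

## Data perturbation

Perturbed copies beta(b) ~ N2(beta_hat, Sigma_hat) are drawn per SNP
(equivalent to bootstrapping the underlying individual-level data); the
full BIC-selected fit is re-run on each of B copies, and the mean and
sample SD of the B estimates give the point estimate and SE, with a
two-sided normal p-value. This propagates model-selection uncertainty that
the plug-in Fisher SE ignores; on datasets where selection is unstable the
perturbation SE exceeds the Fisher SE. Non-converged perturbations are
dropped and counted (> 20% failures raises). Defaults: B = 2000 for data
analysis, B = 200 inside simulations; perturbation fits use two starts
(IVW and null).

## The graph stage

For T traits the m x T matrices of estimates (B_hat) and SEs (S) are
perturbed jointly: Z = B_hat / S, Z(b) = Z + E(b), B_hat(b) = Z(b) * S,
with matrix-normal noise E(b) ~ MN(0, R, P) — R the m x m SNP LD
correlation (block-diagonal over approximately independent LD blocks), P
the T x T trait correlation from overlapping samples (small entries
|rho| < 0.1 may be shrunk to exactly 0). vec(E) then has covariance
P kron R, which captures simultaneously LD between the instrument sets of
different pairs and the reuse of each trait across pairs. Sampling uses
E = L_R V L_P^T with V iid standard normal and L L^T factors from separate
eigen-decompositions after PSD repair (eigenvalue clipping) — algebraically
identical to factoring the mT x mT Kronecker matrix but tractable at
m in the thousands. Noise is generated for the full grid and applied only
to observed cells.

Each perturbed matrix is analyzed by bidirectional BIC-selected
constrained-ML MR on every unmasked ordered pair, using that pair's
registered (screened, LD-clumped) instruments and rho = P[i, j]; the
per-perturbation total graphs are summarized elementwise (mean, SD, normal
p-values). Instrument screening selects source-significant SNPs
(p < 5e-8) and removes candidates whose target association is stronger
than their source association (p_target < p_source); screening is done once
on the observed data and the instrument sets are held fixed across
perturbations. Edges forbidden a priori (e.g. nothing can causally affect
birth weight) are fixed at zero throughout. All perturbation noise is drawn
up front from one seeded stream, so results are independent of the order in
which pairs are processed.

Multiple testing uses a Bonferroni adjustment at alpha / m_eff, with the
effective number of independent tests m_eff estimated from the eigenvalues
lambda_i of the correlation matrix of the per-perturbation edge estimates:
m_eff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]
(eigenvalues within 1e-9 of an integer are snapped to it first — floor() is
discontinuous there and eigensolver noise would otherwise shift the count
by a full unit). Plain Bonferroni over all edges is available as an option.

## Network deconvolution

Under linear relations with direct-effect matrix D (zero diagonal) and
spectral radius(D) < 1, the total effects satisfy
T_tot = D + D^2 + ... = D (I - D)^-1, hence D = T_tot (I + T_tot)^-1.
The inversion is applied directly — no scaling, thresholding or
symmetrization of the total graph. Pairwise MR estimates only the
off-diagonal totals:

* **d0** sets the unknown diagonal to zero (exact for acyclic direct
  graphs).
* **d1** estimates the diagonal from the cycle identity
  T_ii = sum_{j != i} D_ij T_ji, initialized at
  T_ii = sum_{j != i} T_ij T_ji and alternated with the inversion until
  the diagonal moves < 1e-8 (max 1000 sweeps); on non-convergence the
  initial completion is used and flagged.

The returned direct graph has its diagonal forced to exactly zero, and
zero-masked edges are re-zeroed after inversion (the inverse does not
preserve exact zeros). Deconvolution is applied to every perturbed total
graph; the per-perturbation spectral radius, the d1 convergence flag, and
the fraction of perturbations with radius >= 1 are reported as diagnostics.

## Synthetic data

**Two-trait individual-level design.** A confounder U = G phi + eU loads
on exposure and outcome (unit loadings), X = gamma G + U + eX,
Y = theta X + G alpha + U + eY with standard-normal errors. Defaults are
the reference conditions: 20 instruments at MAF 0.3 with strength
gamma = 0.08, N1 = N2 = 25000, invalid instruments receiving
alpha ~ N(0.04, 0.05^2) (uncorrelated pleiotropy) and optionally
phi ~ Unif(0, 0.01) (correlated pleiotropy), plus 1000 null SNPs. The
exposure GWAS uses individuals [0, N1) and the outcome GWAS a window
shifted so that a fraction of participants overlap (e.g. individuals
12501..37500 for 50% overlap). Marginal estimates come from closed-form
per-SNP simple regressions (vectorized; genotypes held in reusable float32
buffers — 0/1/2 and all column sums are exact in float32, and the
regression accumulations are carried in float64). rho is estimated as the
sample correlation of the null-SNP Z-scores (no |Z| threshold — the nulls
are known); the real-data estimator defaults to |Z| < 2 in both traits and
requires >= 50 surviving SNPs. The generator does not emulate LD, allele
frequency spectra, binary traits, or winner's-curse instrument selection,
so passing tests speak to estimator calibration under the stated model,
not to those complications.

**Multi-trait summary design.** Each trait receives 30-50 instruments
with signed effects 0.02-0.05 (strongly significant at SEs ~ 1/sqrt(n),
n = 2e5); direct effects propagate along all paths, B = Gamma (I - D)^-1,
and estimates add matrix-normal noise B_hat = B + S * E with a trait
correlation P containing a few 0.3 entries (consortium-style overlap).
A configurable fraction of instruments can receive pleiotropic effects on
a second trait.

A subtlety worth recording: under this linear-SEM propagation, two-trait MR
with source-trait instruments identifies M_ij / M_ii (M = (I - D)^-1),
i.e. the total effect attenuated by 1 + T_ii. For acyclic graphs M_ii = 1
and the estimand is exactly T_ij; with cycles through i the pairwise
"total" is attenuated, d0 still preserves exact zeros of D (its output is
D_ij M_jj on the off-diagonal), while d1's diagonal completion assumes
unattenuated totals and is exact only as cycles weaken. At the simulated
cycle strengths (radius < 0.6, edges 0.15-0.3) the resulting bias stayed
well below the detection threshold in all replications (null-edge
rejections 0.2% with d1).

## Problem sizes and numerical choices

Replication studies run at desk scale: 200 replicates for the two-trait
calibration studies (B = 200 perturbations each), 20 replicates per graph
setting (6 traits, B = 200), 500 random graphs for deconvolution round
trips, 2e5 draws for the sampler check. Graph analyses cap the BIC grid at
K <= 15 per pair (configurable; the full grid is the default for single-pair
analyses) — with 30-50 strong instruments the selected K never approaches
the cap. Degenerate inputs raise typed exceptions (see
`graphmr.exceptions`); PSD repair clips negative eigenvalues at zero and is
a projection; BIC ties prefer the smallest K; selection ties prefer the
smallest SNP index.

## Known limitations

* Instruments within a pair are assumed independent (LD enters only across
  pairs through R); correlated-instrument likelihoods are out of scope.
* Strand-ambiguous SNPs are dropped rather than frequency-resolved.
* rho is a single scalar per trait pair, used for both directions.
* Winner's curse from selecting instruments in the same sample is not
  corrected.
* The d1 diagonal completion inherits the attenuation caveat above for
  strongly cyclic systems.
* LD-score-regression-based estimation of P is not implemented; supply a
  precomputed matrix (or use the null-Z estimator).
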