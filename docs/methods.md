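# Methods

## Model and estimation

The phenotype for subject *i* is the pair (t_i, delta_i): the observed
event-or-censoring time and the event indicator. The conditional hazard is
`lambda0(t) exp(X_i' beta + b_i)` with Gaussian frailty `b ~ N(0, tau V)`;
`V` is the genetic relationship matrix `Z Z' / M` over a panel of M
standardized markers (`z = (g - 2p)/sqrt(2p(1-p))` with the sample allele
frequency; this is the standard GCTA scaling — the covariance model the
mixed-model literature assumes). Zero-variance markers are dropped from M
with a logged warning. Missing genotypes are mean-imputed (2·AF) both for
the GRM and for testing, the standard mixed-model GWAS convention.

Profiling `lambda0` with Breslow's estimator (pooled ties) converts the
censored-data likelihood into a modified Poisson likelihood with mean
`mu_i = Lambda0(t_i) exp(eta_i)`; for unrelated samples the profiled fit is
exactly the Cox partial-likelihood MLE, and the test suite asserts this
equivalence numerically. The null fit alternates three steps until joint
convergence (relative tolerances 1e-6 inner, 1e-4 outer, at most 20/50
iterations, all configurable):

1. Breslow update of the baseline jumps `d_k / S0_k` at the current linear
   predictor.
2. PQL working-response update of (beta, b) at fixed tau. The working model
   carries an explicit intercept for numerical stability; after each outer
   iteration the fitted intercept is folded into the baseline jumps
   (multiply by exp(intercept)) so `Lambda0` stays identifiable. Solves
   against `Sigma = W^-1 + tau V` use Jacobi-preconditioned conjugate
   gradient (relative residual 1e-6) with GRM matvecs streamed from packed
   genotypes; subjects censored before the first event time have mu = 0 and
   get a weight floor of 1e-8, which removes them from the working fit
   without special-casing.
3. One AI-REML step for tau, clamped at zero (declared boundary after two
   negative steps). The trace tr(PV) is evaluated exactly through a dense
   Cholesky of Sigma for n <= 5000 — the same factorization then serves all
   Sigma-solves of the step — and by a seeded 30-probe Rademacher
   (Hutchinson) estimator above that, the standard choice for cohorts too
   large to factorize.

Initial values: tau = 0.1, beta = 0, b = 0. The tracked convergence
diagnostic is the penalized *profile* log-likelihood (using log dLambda0 at
the event times); it is monotone over outer iterations at fixed tau, which a
test asserts. Times are used exactly as given; a rounding utility is not
needed by any consumer and was not built.

## Exact score variance and the attenuation operator

The exact per-variant variance is `G' Q G` with
`Q = S^-1 - S^-1 X (X' S^-1 X)^-1 X' S^-1` and `S = (W - U)^-1 + tau V`.
`U = A D A'` (with `A[i,k] = exp(eta_i) 1{t_i >= t_k}`,
`D = diag(d_k / S0_k^2)`) is the attenuation from estimating the baseline;
`W - U` applied to a covariate reproduces the observed Cox
partial-likelihood information, which the suite verifies against a
numerical Hessian. Two numerical facts shape the implementation:

- `(W - U)` annihilates vectors constant on every risk set, so `(W - U)^-1`
  does not literally exist. `S^-1` is defined by the continuous extension
  `B^{1/2} (I + tau B^{1/2} V B^{1/2})^{-1} B^{1/2}` (B = W - U), which
  agrees with the naive formula whenever B is invertible and sends the
  kernel to zero — the profile-likelihood-correct behaviour.
- The fixed-effect correction in Q uses the covariates *without* the
  intercept column (S^-1 1 = 0 already).

The production route expands the extension by Woodbury,
`S^-1 = B - BZ ((M/tau) I + Z'BZ)^{-1} Z'B`, which never forms an n-by-n
matrix (memory O(nM + M^2)); a dense eigendecomposition route exists as an
oracle and the two agree to 1e-8 relative in tests.

## Variance ratio

Per-marker ratios `G'QG / G'WG` are computed for 30 randomly drawn
genotyped markers with MAC >= 20, growing by 10 until the coefficient of
variation of the *mean* ratio (sd/(mean sqrt(K))) drops below 0.001, with a
hard cap of 500 markers (an error beyond it). The population CV of the
per-marker ratios (sd/mean, ~0.01 on simulated pedigree data at n ~ 2500)
is also reported; it does not shrink with K, which is why the stopping rule
is read as precision-of-the-mean. At a few hundred samples the per-marker
spread is large enough that the 0.001 default cannot be met within the cap;
small-sample runs should relax `--vr-cv-threshold` (the demo uses 0.01).

## Saddlepoint p-values

`T_adj` within 2 SD of zero takes the normal p-value. Beyond that, each
tail is computed from the CGF
`K(xi) = sum_i mu_i (exp(g_i c xi) - g_i c xi - 1)`,
`c = (r G'WG)^{-1/2}`, via the Barndorff-Nielsen formula
`Phi(w + log(v/w)/w)` with `w = sign(xi) sqrt(2(xi s - K))` and
`v = xi sqrt(K'')` evaluated at the saddlepoint. The saddlepoint equation
`K'(xi) = s` is
solved by Newton from `xi0 = s` (valid because K''(0) = 1) with a
geometrically grown bracket and bisection safeguard; exponent arguments are
guarded at |700|, and any failure falls back to the normal p-value with a
`spa_converged = False` flag rather than raising. p-values are floored at
1e-300. Both `p_spa` and `p_norm` are always emitted, so the no-SPA
comparator needs no separate run.

The fast CGF splits carriers (raw dosage != 0, evaluated exactly) from
non-carriers, whose adjusted genotype is `-X_i h` with `h` the (p+1)-vector
of projection coefficients: for intercept-only models that value is a
single constant and the non-carrier term is closed-form; with covariates it
is evaluated from precomputed weighted moments (orders 2-8 Taylor), falling
back to the exact O(N) sum whenever `max|q c xi| > 0.1`. Agreement with the
full CGF is machine-precision for intercept-only and better than 1e-6
relative with covariates (tested).

The per-variant hazard ratio is the one-step estimator
`log HR = T / var(T)`, `se = var(T)^{-1/2}`; simulation shows it mildly
shrunk (recovery within 15% is asserted in tests), which is expected of
one-step score-based estimators.

## Simulator

Founder dosages are i.i.d. Binomial(2, MAF) per variant (independent
"pseudo" variants, no linkage); non-founders receive one allele per parent
with probability dosage/2 (gene dropping). The default pedigree has 10
members across three generations — a founder couple, three children, two
married-in founders, three grandchildren — giving full sibs (kinship 1/4),
first cousins (1/16) and grandparent pairs (1/8); it is configurable, and
all kinship-based assertions derive from whatever pedigree is configured.
Frailties are `sqrt(tau) L z` with L the Cholesky factor of the pedigree
relationship matrix (identity for singletons; 1e-8 jitter if needed).
Event times are `-log(U) / (lambda exp(eta))`, censoring times
Exp(lambda_c); `t = min`, `delta = 1{T_f <= T_c}` (events win ties).
`lambda` is calibrated by bracketing bisection of the closed-form expected
event fraction `mean_i lam e^eta / (lam e^eta + lambda_c)`; "censoring
rate" here always means the fraction with delta = 0. Null phenotypes use
`eta = 0.5 X1 + b` with `X1 ~ N(0,1)`; the power design uses
`X1 ~ Bernoulli(0.5)`, `X2 ~ N(0,1)`, both coefficients 0.5, plus
`gamma * sum_j G_j` for the causal markers. Default MAF spectra:
log-uniform on [5e-4, 0.5] for test variants (heavy at rare frequencies,
qualitatively like biobank imputation spectra) and log-uniform on
[0.01, 0.5] for the GRM panel.

What the simulator does not emulate: linkage disequilibrium (variants are
independent), genotyping/imputation error, population stratification, and
non-exponential baselines. Passing tests therefore demonstrate correctness
of the statistical machinery under the model's own assumptions, not
robustness to real-data artifacts.

## Problem sizes used by the test suite and reproduction script

Chosen so the whole suite and the script each run on one CPU in well under
their practical budgets; all are the package's own reduced-scale analogues
of the original study conditions:

- Calibrated-vs-exact comparison (reproduction script): 150 ten-member
  families + 1000 singletons (n = 2500), tau = 0.25, 50% censoring, GRM
  panel M = 2000, ~1000 common test variants (MAF > 5%).
- Cox-equivalence check: n = 2000 unrelated, tau fixed at 0, 1000 common
  variants against a partial-likelihood score-test oracle.
- Type-I error: n = 3000 (200 families + 1000 singletons), tau = 0.1,
  censoring 75% and 90%, 1.5e5 null variants with realized MAC in [20, 50],
  evaluated at alpha = 1e-3 and 1e-4 (the deepest tails that give stable
  counts at this variant budget).
- Saddlepoint tail accuracy: n = 500, 95% censoring, MAC-20 variant,
  3e5-draw permutation null.
- Power parity: n = 1200, 25 replicates, alpha = 5e-8, MAF 0.05 and 0.2
  with log hazard ratios log(2.1) and log(1.5) — chosen to put power in the
  informative mid-range at this n, within the hazard-ratio range of the
  original power curves.
- tau recovery: n = 2500 (150 families + 1000 singletons), GRM panel
  M = 12000 common markers, 5 replicates per tau in {0.1, 0.25}.

## Known limitations

- PQL variance components for binary-indicator working models are biased
  downward (the Breslow-Lin phenomenon); on simulated pedigree data at 50%
  censoring the tau = 0.25 condition recovers ~0.15-0.20 on average even
  with the exact pedigree covariance supplied. Using a marker GRM adds
  regression-dilution attenuation that decays with the marker-to-sample
  ratio (the original design used M = 15n). Downstream calibration is
  unaffected in our experiments — the variance ratio absorbs the scale —
  but tau_hat itself should not be interpreted as an unbiased heritability
  component.
- The exact-variance Woodbury route stores an M-by-M factor, so it assumes
  a GRM panel of at most a few tens of thousands of markers.
- No left truncation, time-varying covariates, competing risks, stratified
  baselines, or dosage (BGEN/VCF) input.
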