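"""Per-variant association testing (step 2).

The score statistic for a variant with dosage vector G is
T = G'(delta - mu), evaluated at the null-model fit, so no per-variant model
refit is needed.  Its exact variance G'QG involves solves against
S = (W - U)^-1 + tau*V; a genome-wide scan instead calibrates the cheap
denominator G'WG with a variance ratio r estimated once from a marker
subset.  The standardized statistic T_adj = T / sqrt(r * G'WG) is referred
to a saddlepoint approximation of its null distribution when it falls more
than a configurable number of standard deviations from zero, and to the
normal approximation otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .genotype_io import GenotypeBlock, VariantInfo, allele_stats, get_dosage
from .grm import GRMOperator
from .null_model import AttenuationMatrix, NullModelFit

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceRatio",
    "ScoreTestResult",
    "TestOptions",
    "SaddlepointFailure",
    "AssociationEngine",
    "ExactVarianceCalculator",
    "adjust_genotype",
    "score_statistic",
    "exact_variance",
    "estimate_variance_ratio",
    "cgf",
    "spa_pvalue",
    "hazard_ratio_estimate",
    "test_variant",
]

_P_FLOOR = 1e-300
_EXP_GUARD = 700.0


class SaddlepointFailure(RuntimeError):
    """CGF evaluation left the overflow-guarded domain."""


@dataclass
class VarianceRatio:
    """Calibration constant relating G'WG to the exact score variance."""

    r_hat: float
    cv: float  # sd(ratios)/mean(ratios) over the final marker set
    cv_of_mean: float  # cv / sqrt(n_markers); the stopping criterion
    n_markers_used: int
    ratios: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.r_hat <= 0:
            raise ValueError("variance ratio must be positive")


@dataclass
class TestOptions:
    __test__ = False  # not a pytest class despite the name

    mac_min: int = 20
    spa_cutoff_sd: float = 2.0
    use_spa: bool = True
    fast_spa: bool = True


@dataclass
class ScoreTestResult:
    variant: Optional[VariantInfo]
    n: int
    ac: int
    af: float
    mac: int
    T: float
    var_T: float
    T_adj: float
    p_spa: float
    p_norm: float
    spa_converged: bool
    used_spa: bool
    log_hr: float
    se_log_hr: float
    skip_reason: Optional[str] = None


# ---------------------------------------------------------------------
# covariate adjustment and score


class AssociationEngine:
    """Caches the per-fit quantities shared by every variant test."""

    def __init__(self, fit: NullModelFit, vr: Optional[VarianceRatio] = None):
        self.fit = fit
        self.vr = vr
        self.xt = fit.xtilde()
        self.W = fit.mu_hat
        self.resid = fit.delta - fit.mu_hat
        self.wxt = self.W[:, None] * self.xt
        xtwx = self.xt.T @ self.wxt
        try:
            self._xtwx_cho = cho_factor(xtwx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("collinear covariates: X'WX is singular") from exc

    def project_coefficients(self, G: np.ndarray) -> np.ndarray:
        """h = (X'WX)^-1 X'W G (weighted least-squares coefficients)."""
        return cho_solve(self._xtwx_cho, self.wxt.T @ G)

    def adjust(self, G: np.ndarray) -> np.ndarray:
        """Covariate-and-intercept adjusted genotype, W-orthogonal to X."""
        return G - self.xt @ self.project_coefficients(G)

    def score(self, Gtilde: np.ndarray) -> float:
        return float(Gtilde @ self.resid)

    def gwg(self, Gtilde: np.ndarray) -> float:
        return float(self.W @ Gtilde**2)


def adjust_genotype(G: np.ndarray, fit: NullModelFit) -> np.ndarray:
    """G - X(X'WX)^-1 X'W G with X the intercept-augmented covariates."""
    return AssociationEngine(fit).adjust(np.asarray(G, dtype=float))


def score_statistic(Gtilde: np.ndarray, fit: NullModelFit) -> float:
    """T = G'(delta - mu); identical for raw and adjusted genotypes."""
    return float(np.asarray(Gtilde, dtype=float) @ (fit.delta - fit.mu_hat))


# ---------------------------------------------------------------------
# exact score variance


class ExactVarianceCalculator:
    """Exact variance G'QG with S = (W-U)^-1 + tau*V.

    Because W - U annihilates vectors constant on every risk set, S is
    defined through the continuous extension
    S^-1 = B^(1/2) (I + tau B^(1/2) V B^(1/2))^-1 B^(1/2) with B = W - U.
    Two equivalent routes are provided:

    - ``woodbury``: S^-1 = B - BZ ((M/tau) I + Z'BZ)^-1 Z'B with Z the
      standardized GRM genotypes; never forms an n x n matrix (memory
      O(nM + M^2)), the default whenever a GRM is present.
    - ``dense``: eigendecomposition of dense B; O(n^2) memory oracle path.

    With tau = 0 (or no GRM) S^-1 reduces to B itself.
    """

    def __init__(self, fit: NullModelFit, grm: Optional[GRMOperator], mode: str = "auto"):
        self.fit = fit
        self.tau = fit.tau_hat
        self.W = fit.mu_hat
        self.att = fit.attenuation()
        # S^-1 annihilates constants (B 1 = 0), so the fixed-effect
        # correction uses the covariates without the intercept column.
        self.X = fit.X
        n = len(self.W)
        if mode == "auto":
            mode = "woodbury" if (grm is not None and self.tau > 0) else "b_only"
        if grm is None or self.tau == 0.0:
            mode = "b_only"
        self.mode = mode

        if mode == "woodbury":
            Z = grm.standardized_matrix()
            self.M = Z.shape[1]
            self.BZ = self._apply_B(Z)
            C = (Z.T @ self.BZ) + (self.M / self.tau) * np.eye(self.M)
            self._c_cho = cho_factor(C)
        elif mode == "dense":
            B = np.diag(self.W) - self.att.dense()
            evals, evecs = np.linalg.eigh(B)
            evals = np.clip(evals, 0.0, None)
            root = np.sqrt(evals)
            self._Bh = evecs * root  # so B^(1/2) = Bh @ evecs', B = Bh @ Bh'
            if grm is not None and self.tau > 0:
                V = grm.dense()
                # I + tau * B^(1/2) V B^(1/2) expressed in the eigenbasis of B
                Vh = (evecs.T @ V @ evecs) * np.outer(root, root)
                self._m_cho = cho_factor(np.eye(n) + self.tau * Vh)
            else:
                self._m_cho = None
        elif mode != "b_only":
            raise ValueError(f"unknown exact-variance mode {mode!r}")

        # fixed-effect correction pieces: S^-1 X and (X' S^-1 X)^-1
        if self.X.shape[1]:
            self._sinv_x = self._apply_sinv(self.X)
            self._r_cho = cho_factor(self.X.T @ self._sinv_x)
        else:
            self._sinv_x = None
            self._r_cho = None

    def _apply_B(self, v: np.ndarray) -> np.ndarray:
        return (self.W * v.T).T - self.att.apply(v)

    def _apply_sinv(self, v: np.ndarray) -> np.ndarray:
        if self.mode == "b_only":
            return self._apply_B(v)
        if self.mode == "woodbury":
            bv = self._apply_B(v)
            return bv - self.BZ @ cho_solve(self._c_cho, self.BZ.T @ v)
        # dense: S^-1 = Bh (I + tau Bh' V Bh)^-1 Bh' in B's eigenbasis
        hv = self._Bh.T @ v
        if self._m_cho is not None:
            hv = cho_solve(self._m_cho, hv)
        return self._Bh @ hv

    def variance(self, Gtilde: np.ndarray) -> float:
        """G'QG = G'S^-1 G - (X'S^-1 G)' (X'S^-1 X)^-1 (X'S^-1 G)."""
        g = np.asarray(Gtilde, dtype=float)
        sg = self._apply_sinv(g)
        out = float(g @ sg)
        if self._sinv_x is not None:
            xg = self._sinv_x.T @ g
            out -= float(xg @ cho_solve(self._r_cho, xg))
        return max(out, 0.0)


def exact_variance(
    Gtilde: np.ndarray,
    fit: NullModelFit,
    grm: Optional[GRMOperator] = None,
    mode: str = "auto",
) -> float:
    """One-shot exact variance; build :class:`ExactVarianceCalculator` to amortize."""
    return ExactVarianceCalculator(fit, grm, mode=mode).variance(Gtilde)


# ---------------------------------------------------------------------
# variance ratio


def estimate_variance_ratio(
    fit: NullModelFit,
    grm: Optional[GRMOperator],
    marker_source: GenotypeBlock,
    seed: int = 1,
    mac_min: int = 20,
    n_initial: int = 30,
    increment: int = 10,
    cv_threshold: float = 0.001,
    max_markers: int = 500,
    ratio_fn=None,
) -> VarianceRatio:
    """Estimate r = G'QG / G'WG from randomly drawn genotyped markers.

    Starts from ``n_initial`` markers with MAC >= ``mac_min``; while the
    coefficient of variation of the estimated mean ratio
    (sd / (mean * sqrt(K))) exceeds ``cv_threshold``, ``increment`` more
    markers are added, up to ``max_markers``.  ``ratio_fn`` overrides the
    per-marker ratio computation (testing hook).
    """
    eligible = [
        j
        for j in range(marker_source.n_variants)
        if allele_stats(marker_source, j).mac >= mac_min
    ]
    if len(eligible) < n_initial:
        raise ValueError(
            f"only {len(eligible)} markers with MAC >= {mac_min}; need {n_initial}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))

    if ratio_fn is None:
        engine = AssociationEngine(fit)
        calc = ExactVarianceCalculator(fit, grm)

        def ratio_fn(j: int) -> float:
            gt = engine.adjust(get_dosage(marker_source, j))
            return calc.variance(gt) / engine.gwg(gt)

    ratios: list[float] = []
    k = n_initial
    while True:
        while len(ratios) < k:
            ratios.append(ratio_fn(eligible[order[len(ratios)]]))
        arr = np.array(ratios)
        cv = float(arr.std(ddof=1) / arr.mean())
        cv_mean = cv / math.sqrt(len(arr))
        if cv_mean < cv_threshold:
            return VarianceRatio(float(arr.mean()), cv, cv_mean, len(arr), arr)
        if k >= max_markers or k >= len(eligible):
            raise RuntimeError(
                f"variance-ratio CV {cv_mean:.2e} still above {cv_threshold} "
                f"after {len(arr)} markers"
            )
        k = min(k + increment, max_markers, len(eligible))


# ---------------------------------------------------------------------
# saddlepoint approximation


def cgf(xi: float, mu_hat: np.ndarray, Gtilde: np.ndarray, c: float):
    """CGF of the standardized score under the modified Poisson model.

    K(xi) = sum_i mu_i (exp(g_i c xi) - g_i c xi - 1); returns
    (K, K', K'') at ``xi``.  K''(0) = 1 by construction of c.
    """
    gc = np.asarray(Gtilde, dtype=float) * c
    arg = gc * xi
    if np.max(np.abs(arg)) > _EXP_GUARD:
        raise SaddlepointFailure(f"CGF argument exceeds overflow guard at xi={xi}")
    e = np.exp(arg)
    mu = np.asarray(mu_hat, dtype=float)
    K = float(np.sum(mu * (e - arg - 1.0)))
    K1 = float(np.sum(mu * gc * (e - 1.0)))
    K2 = float(np.sum(mu * gc**2 * e))
    return K, K1, K2


class _FullCGF:
    """Direct O(N) CGF evaluations."""

    def __init__(self, mu: np.ndarray, Gtilde: np.ndarray, c: float):
        self.mu = mu
        self.g = Gtilde
        self.c = c

    def __call__(self, xi: float):
        return cgf(xi, self.mu, self.g, self.c)


class _FastCGF:
    """Carrier/non-carrier split of the CGF.

    Carriers (raw dosage != 0) are evaluated exactly.  Non-carriers have
    adjusted genotype -q_i with q = X h, which is tiny; their contribution
    uses a closed form when q is constant (intercept-only model) and an
    eighth-order moment expansion otherwise, falling back to the exact sum
    whenever the expansion leaves its validity region |q c xi| <= 0.1.
    """

    _ORDERS = range(2, 9)

    def __init__(self, G: np.ndarray, q: np.ndarray, mu: np.ndarray, c: float):
        self.c = c
        carriers = G != 0
        self.mu_c = mu[carriers]
        self.g_c = (G - q)[carriers]
        q_nc = q[~carriers]
        mu_nc = mu[~carriers]
        self.constant_q = len(np.unique(q_nc)) <= 1
        if self.constant_q:
            self.q0 = float(q_nc[0]) if len(q_nc) else 0.0
            self.mu_nc_sum = float(mu_nc.sum())
            self.mu_nc_q = self.mu_nc_sum * self.q0
            self.mu_nc_q2 = self.mu_nc_sum * self.q0**2
        else:
            self.q_nc = q_nc
            self.mu_nc = mu_nc
            self.qmax = float(np.max(np.abs(q_nc))) if len(q_nc) else 0.0
            self.moments = {k: float(np.sum(mu_nc * q_nc**k)) for k in self._ORDERS}
            self.m1 = float(np.sum(mu_nc * q_nc))

    def __call__(self, xi: float):
        arg_c = self.g_c * self.c * xi
        if len(arg_c) and np.max(np.abs(arg_c)) > _EXP_GUARD:
            raise SaddlepointFailure(f"CGF argument exceeds overflow guard at xi={xi}")
        e = np.exp(arg_c)
        K = float(np.sum(self.mu_c * (e - arg_c - 1.0)))
        K1 = float(np.sum(self.mu_c * self.g_c * self.c * (e - 1.0)))
        K2 = float(np.sum(self.mu_c * (self.g_c * self.c) ** 2 * e))
        Knc, K1nc, K2nc = self._noncarrier(xi)
        return K + Knc, K1 + K1nc, K2 + K2nc

    def _noncarrier(self, xi: float):
        u = -self.c * xi  # non-carrier adjusted genotype is -q
        if self.constant_q:
            a = u * self.q0
            if abs(a) > _EXP_GUARD:
                raise SaddlepointFailure("non-carrier CGF overflow")
            ea = math.exp(a)
            K = self.mu_nc_sum * (ea - a - 1.0)
            K1 = -self.c * self.mu_nc_q * (ea - 1.0)
            K2 = self.c**2 * self.mu_nc_q2 * ea
            return K, K1, K2
        if self.qmax * abs(u) > 0.1:
            arg = self.q_nc * u
            e = np.exp(arg)
            K = float(np.sum(self.mu_nc * (e - arg - 1.0)))
            K1 = float(np.sum(self.mu_nc * (-self.c) * self.q_nc * (e - 1.0)))
            K2 = float(np.sum(self.mu_nc * (self.c * self.q_nc) ** 2 * e))
            return K, K1, K2
        # moment expansion: sum mu (e^{qu} - qu - 1) = sum_k>=2 m_k u^k / k!
        K = K1 = K2 = 0.0
        for k in self._ORDERS:
            term = self.moments[k] / math.factorial(k)
            K += term * u**k
            K1 += term * k * u ** (k - 1) * (-self.c)
            K2 += term * k * (k - 1) * u ** (k - 2) * self.c**2
        # K2 needs the m_2-level constant term handled by k=2 above; fine.
        return K, K1, K2


def _solve_saddlepoint(cgf_fn, s: float, tol: float = 1e-8, max_iter: int = 50):
    """Solve K'(xi) = s by Newton with geometric bracketing + bisection."""
    xi = s  # K''(0) = 1 makes this a natural start
    lo, hi = (0.0, None) if s > 0 else (None, 0.0)
    for _ in range(max_iter):
        try:
            _, K1, K2 = cgf_fn(xi)
        except SaddlepointFailure:
            xi = 0.5 * xi
            continue
        f = K1 - s
        if abs(f) < tol * max(1.0, abs(s)):
            return xi
        if f < 0:
            lo = xi if lo is None else max(lo, xi)
        else:
            hi = xi if hi is None else min(hi, xi)
        step = f / max(K2, 1e-12)
        xi_new = xi - step
        if lo is not None and hi is not None and not (lo < xi_new < hi):
            xi_new = 0.5 * (lo + hi)
        elif hi is None and xi_new <= (lo if lo is not None else -np.inf):
            xi_new = 2.0 * xi if xi != 0 else 1.0
        elif lo is None and xi_new >= (hi if hi is not None else np.inf):
            xi_new = 2.0 * xi if xi != 0 else -1.0
        xi = xi_new
    raise SaddlepointFailure(f"saddlepoint root solve did not converge for s={s}")


def _spa_tail(cgf_fn, s: float) -> float:
    """Pr(T_adj > s) for s > 0 (or Pr(T_adj < s) for s < 0) by the
    Barndorff-Nielsen formula."""
    xi = _solve_saddlepoint(cgf_fn, s)
    K, _, K2 = cgf_fn(xi)
    w2 = 2.0 * (xi * s - K)
    if w2 <= 0 or K2 <= 0:
        raise SaddlepointFailure("degenerate saddlepoint (w^2 <= 0)")
    w = math.copysign(math.sqrt(w2), xi)
    v = xi * math.sqrt(K2)
    if abs(w) < 1e-5 or v == 0.0:
        # too close to the mean for the correction term; use normal tail
        return float(norm.sf(abs(s)) if s > 0 else norm.cdf(s))
    z = w + math.log(v / w) / w
    return float(norm.sf(z)) if s > 0 else float(norm.cdf(z))


def spa_pvalue(
    s: float,
    mu_hat: np.ndarray,
    Gtilde: np.ndarray,
    c: float,
    fast_cgf: Optional[_FastCGF] = None,
    cutoff_sd: float = 2.0,
) -> tuple[float, bool, bool]:
    """Two-sided p-value for the standardized score statistic.

    Returns (p, spa_converged, used_spa).  Inside ``cutoff_sd`` standard
    deviations of zero the normal approximation is returned directly; a
    failed saddlepoint solve also falls back to the normal p-value with
    ``spa_converged=False`` (never raises).
    """
    p_norm = 2.0 * float(norm.sf(abs(s)))
    if abs(s) < cutoff_sd:
        return max(p_norm, _P_FLOOR), True, False
    cgf_fn = fast_cgf if fast_cgf is not None else _FullCGF(mu_hat, Gtilde, c)
    try:
        upper = _spa_tail(cgf_fn, abs(s))
        lower = _spa_tail(cgf_fn, -abs(s))
        p = upper + lower
    except SaddlepointFailure:
        return max(p_norm, _P_FLOOR), False, False
    if not np.isfinite(p) or p <= 0:
        return max(p_norm, _P_FLOOR), False, False
    return max(min(p, 1.0), _P_FLOOR), True, True


def hazard_ratio_estimate(T: float, var_T: float) -> tuple[float, float]:
    """One-step log hazard-ratio estimate from the score and its variance."""
    if var_T <= 0:
        return float("nan"), float("nan")
    return T / var_T, 1.0 / math.sqrt(var_T)


# ---------------------------------------------------------------------
# per-variant pipeline


def test_variant(
    G: np.ndarray,
    fit: NullModelFit,
    vr: Optional[VarianceRatio],
    options: TestOptions | None = None,
    engine: Optional[AssociationEngine] = None,
    variant: Optional[VariantInfo] = None,
    mac: Optional[int] = None,
    ac: Optional[int] = None,
    af: Optional[float] = None,
) -> ScoreTestResult:
    """Run the full adjust -> score -> calibrate -> SPA pipeline on a dosage."""
    options = options or TestOptions()
    engine = engine or AssociationEngine(fit, vr)
    G = np.asarray(G, dtype=float)
    n = len(G)
    if mac is None:
        acalc = float(G.sum())
        n2 = 2 * n
        ac = int(round(acalc))
        af = acalc / n2
        mac = int(round(min(acalc, n2 - acalc)))
    if mac < options.mac_min:
        return ScoreTestResult(
            variant, n, ac, af, mac, math.nan, math.nan, math.nan, math.nan,
            math.nan, False, False, math.nan, math.nan,
            skip_reason=f"MAC<{options.mac_min}",
        )
    h = engine.project_coefficients(G)
    Gtilde = G - engine.xt @ h
    T = engine.score(Gtilde)
    gwg = engine.gwg(Gtilde)
    r_hat = vr.r_hat if vr is not None else 1.0
    var_T = r_hat * gwg
    if var_T <= 0:
        return ScoreTestResult(
            variant, n, ac, af, mac, T, 0.0, math.nan, math.nan, math.nan,
            False, False, math.nan, math.nan, skip_reason="zero variance",
        )
    c = 1.0 / math.sqrt(var_T)
    s = T * c
    p_norm = max(2.0 * float(norm.sf(abs(s))), _P_FLOOR)
    if options.use_spa:
        fast = _FastCGF(G, engine.xt @ h, fit.mu_hat, c) if options.fast_spa else None
        p_spa, converged, used = spa_pvalue(
            s, fit.mu_hat, Gtilde, c, fast_cgf=fast, cutoff_sd=options.spa_cutoff_sd
        )
    else:
        p_spa, converged, used = p_norm, True, False
    log_hr, se = hazard_ratio_estimate(T, var_T)
    return ScoreTestResult(
        variant, n, ac, af, mac, T, var_T, s, p_spa, p_norm, converged, used, log_hr, se
    )


def test_block(
    block: GenotypeBlock,
    fit: NullModelFit,
    vr: Optional[VarianceRatio],
    options: TestOptions | None = None,
    variant_indices: Optional[Sequence[int]] = None,
) -> list[ScoreTestResult]:
    """Test every variant of a packed block (streaming, one decode per variant)."""
    options = options or TestOptions()
    engine = AssociationEngine(fit, vr)
    indices = range(block.n_variants) if variant_indices is None else variant_indices
    results = []
    for j in indices:
        stats = allele_stats(block, j)
        g = get_dosage(block, j)
        results.append(
            test_variant(
                g, fit, vr, options, engine=engine, variant=block.variants[j],
                mac=stats.mac, ac=stats.ac, af=stats.af,
            )
        )
    return results


def test_dosage_matrix(
    Gmat: np.ndarray,
    fit: NullModelFit,
    vr: Optional[VarianceRatio],
    options: TestOptions | None = None,
    engine: Optional[AssociationEngine] = None,
) -> dict:
    """Vectorized pipeline over an (n_samples, n_variants) dosage matrix.

    Returns arrays keyed T, var_T, T_adj, p_norm, p_spa, mac, tested.
    Variants failing the MAC filter get NaN statistics and tested=False.
    The saddlepoint branch runs per variant, only where |T_adj| exceeds
    the cutoff.
    """
    options = options or TestOptions()
    engine = engine or AssociationEngine(fit, vr)
    G = np.asarray(Gmat, dtype=float)
    n, m = G.shape
    ac = G.sum(axis=0)
    mac = np.minimum(ac, 2 * n - ac)
    tested = mac >= options.mac_min

    H = cho_solve(engine._xtwx_cho, engine.wxt.T @ G)  # (p+1, m)
    Gt = G - engine.xt @ H
    T = Gt.T @ engine.resid
    gwg = engine.W @ Gt**2
    r_hat = vr.r_hat if vr is not None else 1.0
    var_T = r_hat * gwg
    ok = tested & (var_T > 0)
    s = np.full(m, np.nan)
    s[ok] = T[ok] / np.sqrt(var_T[ok])
    p_norm = np.where(ok, 2.0 * norm.sf(np.abs(s)), np.nan)
    p_spa = p_norm.copy()
    spa_conv = np.ones(m, dtype=bool)
    if options.use_spa:
        flagged = np.flatnonzero(ok & (np.abs(s) >= options.spa_cutoff_sd))
        for j in flagged:
            c = 1.0 / math.sqrt(var_T[j])
            fast = (
                _FastCGF(G[:, j], engine.xt @ H[:, j], fit.mu_hat, c)
                if options.fast_spa
                else None
            )
            p_spa[j], spa_conv[j], _ = spa_pvalue(
                s[j], fit.mu_hat, Gt[:, j], c, fast_cgf=fast, cutoff_sd=options.spa_cutoff_sd
            )
    return {
        "T": T,
        "var_T": var_T,
        "T_adj": s,
        "p_norm": np.maximum(p_norm, _P_FLOOR),
        "p_spa": np.maximum(p_spa, _P_FLOOR),
        "mac": mac,
        "tested": ok,
        "spa_converged": spa_conv,
        "Gtilde": Gt,
    }


def results_to_frame(results: list[ScoreTestResult]):
    """Summary-statistics table, one row per tested variant."""
    import pandas as pd

    rows = []
    for r in results:
        v = r.variant
        rows.append(
            {
                "CHR": v.chrom if v else ".",
                "POS": v.pos if v else 0,
                "ID": v.id if v else ".",
                "Allele1": v.allele1 if v else ".",
                "Allele2": v.allele2 if v else ".",
                "AC": r.ac,
                "AF": r.af,
                "MAC": r.mac,
                "N": r.n,
                "T": r.T,
                "var_T": r.var_T,
                "T_adj": r.T_adj,
                "p_norm": r.p_norm,
                "p_spa": r.p_spa,
                "spa_converged": r.spa_converged,
                "log_HR": r.log_hr,
                "SE_log_HR": r.se_log_hr,
                "skip_reason": r.skip_reason or "",
            }
        )
    return pd.DataFrame(rows)
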