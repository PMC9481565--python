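"""Null frailty-model fitting (step 1).

The frailty model puts a Gaussian random effect b ~ N(0, tau*V) on the log
hazard: lambda_i(t | b_i) = lambda0(t) * exp(X_i' beta + b_i), with V the
genetic relationship matrix.  Profiling the baseline hazard with Breslow's
estimator turns the censored-data likelihood into a modified Poisson
log-linear mixed model with mean mu_i = Lambda0(t_i) * exp(eta_i), which is
fitted by iterating three steps until joint convergence:

1. Breslow cumulative-hazard update given the current linear predictor.
2. Penalized quasi-likelihood (PQL) working-response update of (beta, b)
   at fixed tau, with all solves against Sigma = W^-1 + tau*V done by
   preconditioned conjugate gradient.
3. An average-information REML step for the variance component tau.

The attenuation operator U-hat (risk-set projection A D A') captures the
extra variability from estimating Lambda0 and enters the exact score
variance in step 2; (W - U) applied to a covariate reproduces the Cox
partial-likelihood observed information.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .grm import GRMOperator, PCGConfig, pcg_solve

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalPhenotype",
    "BaselineHazard",
    "AttenuationMatrix",
    "NullModelFit",
    "NullModelConfig",
    "read_phenotypes",
    "breslow_cumhaz",
    "pql_update",
    "aireml_tau_update",
    "fit_null",
    "attenuation_apply",
]

_ETA_CLIP = 500.0  # exp overflow guard on the linear predictor
_MU_FLOOR = 1e-8  # weight floor for subjects censored before the first event


# ---------------------------------------------------------------------
# phenotype container


@dataclass
class SurvivalPhenotype:
    """Observed times, event indicators and covariates, aligned by sample.

    ``X`` holds the covariates only; the intercept is absorbed by the
    baseline hazard and must not be included as a column.
    """

    sample_ids: list[str]
    t: np.ndarray
    delta: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.delta = np.asarray(self.delta, dtype=np.int64)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] != len(self.t) and self.X.size:
            self.X = self.X.reshape(len(self.t), -1)
        if self.X.size == 0:
            self.X = np.empty((len(self.t), 0))
        n = len(self.sample_ids)
        if not (len(self.t) == len(self.delta) == self.X.shape[0] == n):
            raise ValueError("phenotype fields have inconsistent lengths")
        if np.any(self.t <= 0):
            raise ValueError("observed times must be positive")
        if not np.isin(self.delta, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if np.isnan(self.X).any():
            raise ValueError("covariates contain missing values")
        if self.X.shape[1] and np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("covariate matrix is rank-deficient")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())

    def xtilde(self) -> np.ndarray:
        """Augmented covariate matrix [1 X] used in working models."""
        return np.column_stack([np.ones(self.n), self.X])

    def align(self, sample_ids: list[str]) -> "SurvivalPhenotype":
        """Reorder to ``sample_ids``; samples absent from self are an error."""
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [sid for sid in sample_ids if sid not in index]
        if missing:
            raise KeyError(f"{len(missing)} genotyped samples lack phenotypes, e.g. {missing[:3]}")
        order = np.array([index[sid] for sid in sample_ids])
        return SurvivalPhenotype(list(sample_ids), self.t[order], self.delta[order], self.X[order])


def read_phenotypes(path, id_col="id", time_col="time", status_col="status") -> SurvivalPhenotype:
    """Read a delimited phenotype table: id, time, status, then covariates."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (id_col, time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"phenotype file lacks required column {col!r}")
    covar_cols = [c for c in df.columns if c not in (id_col, time_col, status_col)]
    return SurvivalPhenotype(
        df[id_col].astype(str).tolist(),
        df[time_col].to_numpy(dtype=float),
        df[status_col].to_numpy(dtype=int),
        df[covar_cols].to_numpy(dtype=float) if covar_cols else np.empty((len(df), 0)),
    )


# ---------------------------------------------------------------------
# Breslow baseline hazard


@dataclass
class BaselineHazard:
    """Step-function cumulative baseline hazard with jumps at event times."""

    event_times: np.ndarray
    jumps: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=np.float64)
        self.jumps = np.asarray(self.jumps, dtype=np.float64)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.jumps <= 0):
            raise ValueError("baseline-hazard jumps must be positive")

    def cumulative(self, t: np.ndarray) -> np.ndarray:
        """Right-continuous Lambda0(t) = sum of jumps at event times <= t."""
        csum = np.concatenate([[0.0], np.cumsum(self.jumps)])
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        return csum[idx]


def breslow_cumhaz(t: np.ndarray, delta: np.ndarray, eta: np.ndarray) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard.

    Jump at each distinct event time t_(k): d_k / S0_k, with d_k the number
    of events at t_(k) (pooled Breslow tie convention) and
    S0_k = sum over the risk set {i : t_i >= t_(k)} of exp(eta_i).
    """
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta)
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("linear predictor contains non-finite values")
    if delta.sum() == 0:
        raise ValueError("no events observed; baseline hazard undefined")
    event_times, d_k = np.unique(t[delta == 1], return_counts=True)
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    w_sorted = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))[order]
    # suffix sums of exp(eta) over samples with t >= t_(k)
    suffix = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
    pos = np.searchsorted(t_sorted, event_times, side="left")
    s0 = suffix[pos]
    return BaselineHazard(event_times, d_k / s0)


# ---------------------------------------------------------------------
# attenuation operator


class AttenuationMatrix:
    """Risk-set operator U = A D A' from profiling the baseline hazard.

    A[i, k] = exp(eta_i) * 1{t_i >= t_(k)}, D = diag(d_k / S0_k^2).  The
    product U v is computed with sorted suffix/prefix sums in O(n log n);
    U is symmetric PSD and W - U is PSD (it is the Breslow-profile
    information operator).
    """

    def __init__(self, t: np.ndarray, delta: np.ndarray, eta: np.ndarray):
        t = np.asarray(t, dtype=float)
        delta = np.asarray(delta)
        eta = np.asarray(eta, dtype=float)
        self.n = len(t)
        self.w = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        self.event_times, self.d_k = np.unique(t[delta == 1], return_counts=True)
        self._order = np.argsort(t, kind="stable")
        t_sorted = t[self._order]
        # first sorted index belonging to risk set R_k
        self._risk_start = np.searchsorted(t_sorted, self.event_times, side="left")
        w_sorted = self.w[self._order]
        suffix = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
        self.s0 = suffix[self._risk_start]
        self.D = self.d_k / self.s0**2
        # number of event times <= t_i, per sample
        self._rank = np.searchsorted(self.event_times, t, side="right")

    def apply(self, v: np.ndarray) -> np.ndarray:
        """U @ v for a vector or column-stacked matrix."""
        v = np.asarray(v, dtype=np.float64)
        if v.shape[0] != self.n:
            raise ValueError(f"vector length {v.shape[0]} != n {self.n}")
        wv = (self.w * v.T).T
        suffix = np.concatenate(
            [np.cumsum(wv[self._order][::-1], axis=0)[::-1], np.zeros((1,) + wv.shape[1:])]
        )
        at_v = suffix[self._risk_start]  # (K, ...)
        u = (self.D * at_v.T).T
        prefix = np.concatenate([np.zeros((1,) + u.shape[1:]), np.cumsum(u, axis=0)])
        return (self.w * prefix[self._rank].T).T

    __call__ = apply

    def dense(self) -> np.ndarray:
        """Assemble dense U (small-n oracle path)."""
        t_mask = np.zeros((self.n, len(self.event_times)))
        for k, start in enumerate(self._risk_start):
            t_mask[self._order[start:], k] = 1.0
        A = self.w[:, None] * t_mask
        return A @ (self.D[:, None] * A.T)


def attenuation_apply(att: AttenuationMatrix, v: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`AttenuationMatrix.apply`."""
    return att.apply(v)


# ---------------------------------------------------------------------
# fit containers and configuration


@dataclass
class NullModelConfig:
    """Tunable knobs for the null-model fit."""

    inner_tol: float = 1e-6
    outer_tol: float = 1e-4
    max_inner: int = 20
    max_outer: int = 50
    tau_init: float = 0.1
    fix_tau: Optional[float] = None  # fit with tau frozen at this value
    trace_mode: str = "auto"  # auto | exact | hutchinson
    dense_trace_max_n: int = 5000
    n_trace_probes: int = 30
    seed: int = 1
    pcg: PCGConfig = field(default_factory=lambda: PCGConfig(rel_tolerance=1e-6, max_iter=1000))


@dataclass
class NullModelFit:
    """Converged null-model parameters consumed by the association step."""

    sample_ids: list[str]
    beta_hat: np.ndarray
    tau_hat: float
    b_hat: np.ndarray
    eta_hat: np.ndarray
    mu_hat: np.ndarray
    baseline: BaselineHazard
    t: np.ndarray
    delta: np.ndarray
    X: np.ndarray
    converged: bool
    n_iter: int
    tau_path: list[float] = field(default_factory=list)
    objective_path: list[float] = field(default_factory=list)
    tau_boundary: bool = False

    @property
    def W(self) -> np.ndarray:
        """Diagonal working weights (the fitted means)."""
        return self.mu_hat

    def xtilde(self) -> np.ndarray:
        return np.column_stack([np.ones(len(self.t)), self.X])

    def attenuation(self) -> AttenuationMatrix:
        return AttenuationMatrix(self.t, self.delta, self.eta_hat)

    # -- serialization -------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "sample_ids": self.sample_ids,
            "beta_hat": self.beta_hat.tolist(),
            "tau_hat": self.tau_hat,
            "b_hat": self.b_hat.tolist(),
            "eta_hat": self.eta_hat.tolist(),
            "mu_hat": self.mu_hat.tolist(),
            "baseline": {
                "event_times": self.baseline.event_times.tolist(),
                "jumps": self.baseline.jumps.tolist(),
            },
            "t": self.t.tolist(),
            "delta": self.delta.tolist(),
            "X": self.X.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "tau_path": self.tau_path,
            "tau_boundary": self.tau_boundary,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "NullModelFit":
        d = json.loads(Path(path).read_text())
        return cls(
            sample_ids=d["sample_ids"],
            beta_hat=np.array(d["beta_hat"]),
            tau_hat=d["tau_hat"],
            b_hat=np.array(d["b_hat"]),
            eta_hat=np.array(d["eta_hat"]),
            mu_hat=np.array(d["mu_hat"]),
            baseline=BaselineHazard(np.array(d["baseline"]["event_times"]), np.array(d["baseline"]["jumps"])),
            t=np.array(d["t"]),
            delta=np.array(d["delta"], dtype=np.int64),
            X=np.array(d["X"]).reshape(len(d["t"]), -1),
            converged=d["converged"],
            n_iter=d["n_iter"],
            tau_path=d["tau_path"],
            tau_boundary=d["tau_boundary"],
        )


# ---------------------------------------------------------------------
# Sigma = W^-1 + tau*V solves


class _SigmaSolver:
    """PCG solves against Sigma = W^-1 + tau*V with Jacobi preconditioning."""

    def __init__(self, W: np.ndarray, tau: float, grm: Optional[GRMOperator], cfg: PCGConfig):
        self.W = W
        self.tau = tau
        self.grm = grm
        self.cfg = cfg
        self.inv_w = 1.0 / W
        self.diagonal_only = grm is None or tau == 0.0
        if not self.diagonal_only:
            self.diag = self.inv_w + tau * grm.diag()

    def apply(self, v: np.ndarray) -> np.ndarray:
        if self.diagonal_only:
            return self.inv_w * v
        return self.inv_w * v + self.tau * self.grm.matvec(v)

    def solve(self, rhs: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        if self.diagonal_only:
            return self.W * rhs
        x, _ = pcg_solve(self.apply, rhs, self.cfg, diag=self.diag, x0=x0)
        return x

    def solve_mat(self, rhs: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        if self.diagonal_only:
            return self.W[:, None] * rhs
        out = np.empty_like(rhs)
        for j in range(rhs.shape[1]):
            out[:, j] = self.solve(rhs[:, j], None if x0 is None else x0[:, j])
        return out


# ---------------------------------------------------------------------
# PQL update


def pql_update(
    phen: SurvivalPhenotype,
    grm: Optional[GRMOperator],
    tau: float,
    baseline: BaselineHazard,
    beta0: np.ndarray,
    b0: np.ndarray,
    config: NullModelConfig | None = None,
):
    """Inner Newton/Fisher cycle for (beta, b) at fixed tau and baseline.

    The working model is Poisson with offset log Lambda0(t_i) and an
    explicit intercept column (folded back into the baseline by the outer
    loop).  Returns (beta_tilde, b, eta_lin, mu, ytilde, W) where
    ``beta_tilde`` includes the working intercept as its first entry and
    ``eta_lin`` = Xtilde @ beta_tilde + b.
    """
    config = config or NullModelConfig()
    xt = phen.xtilde()
    offset = np.log(np.maximum(baseline.cumulative(phen.t), 1e-300))
    beta_t = np.asarray(beta0, dtype=float).copy()
    if beta_t.shape[0] == xt.shape[1] - 1:  # intercept not supplied
        beta_t = np.concatenate([[0.0], beta_t])
    b = np.asarray(b0, dtype=float).copy()
    delta = phen.delta.astype(float)

    sx_warm = sy_warm = None
    for _ in range(config.max_inner):
        eta_lin = xt @ beta_t + b
        mu = np.exp(np.clip(offset + eta_lin, -_ETA_CLIP, _ETA_CLIP))
        W = np.maximum(mu, _MU_FLOOR)
        if not np.any(mu > _MU_FLOOR):
            raise RuntimeError("degenerate fit: all working weights underflowed")
        ytilde = eta_lin + (delta - mu) / W
        solver = _SigmaSolver(W, tau, grm, config.pcg)
        sx = solver.solve_mat(xt, sx_warm)
        sy = solver.solve(ytilde, sy_warm)
        sx_warm, sy_warm = sx, sy
        xtsx = xt.T @ sx
        try:
            beta_new = np.linalg.solve(xtsx, sx.T @ ytilde)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular working-model normal equations") from exc
        alpha = sy - sx @ beta_new  # Sigma^-1 (ytilde - X beta)
        b_new = tau * grm.matvec(alpha) if (grm is not None and tau > 0) else np.zeros_like(b)
        denom = np.maximum(np.max(np.abs(np.concatenate([beta_t, b]))), 1e-8)
        change = np.max(np.abs(np.concatenate([beta_new - beta_t, b_new - b]))) / denom
        beta_t, b = beta_new, b_new
        if change < config.inner_tol:
            break

    eta_lin = xt @ beta_t + b
    mu = np.exp(np.clip(offset + eta_lin, -_ETA_CLIP, _ETA_CLIP))
    W = np.maximum(mu, _MU_FLOOR)
    ytilde = eta_lin + (delta - mu) / W
    # exact frailty penalty: b'V^-1 b/(2 tau) = alpha'b/2 since b = tau*V*alpha
    penalty = 0.5 * float(alpha @ b) if (grm is not None and tau > 0) else 0.0
    return beta_t, b, eta_lin, mu, ytilde, W, penalty


# ---------------------------------------------------------------------
# AI-REML variance-component update


def _trace_PV_hutchinson(solver, grm, xt, sx, xtsx_cho, n_probes, rng):
    """Stochastic trace tr(PV) with Rademacher probes."""
    n = xt.shape[0]
    total = 0.0
    for _ in range(n_probes):
        z = rng.choice((-1.0, 1.0), size=n)
        sz = solver.solve(z)
        pz = sz - sx @ cho_solve(xtsx_cho, xt.T @ sz)
        total += float(pz @ grm.matvec(z))
    return total / n_probes


def aireml_tau_update(
    ytilde: np.ndarray,
    W: np.ndarray,
    xt: np.ndarray,
    grm: GRMOperator,
    tau: float,
    config: NullModelConfig,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """One average-information REML step for tau.

    Returns (tau_new, step_went_negative).  The score is
    0.5*(y' P V P y - tr(PV)) and the average information
    0.5 * y' P V P V P y, with P the Sigma^-1 projection off the fixed
    effects.  A non-positive AI falls back to a halved score step.

    In dense-trace mode (n at most ``config.dense_trace_max_n``) all
    Sigma^-1 products reuse one Cholesky factorization of Sigma; above it
    tr(PV) switches to a seeded Hutchinson estimator with Rademacher
    probes and products go through PCG.
    """
    tau_eff = max(tau, 1e-6)
    n = len(ytilde)
    use_exact = config.trace_mode == "exact" or (
        config.trace_mode == "auto" and n <= config.dense_trace_max_n
    )
    if use_exact:
        V = grm.dense()
        sigma = tau_eff * V
        sigma[np.diag_indices(n)] += 1.0 / W
        sig_cho = cho_factor(sigma, lower=True)
        solve = lambda rhs: cho_solve(sig_cho, rhs)
    else:
        solver = _SigmaSolver(W, tau_eff, grm, config.pcg)
        solve = lambda rhs: solver.solve(rhs) if rhs.ndim == 1 else solver.solve_mat(rhs)
    sx = solve(xt)
    sy = solve(ytilde)
    xtsx_cho = cho_factor(xt.T @ sx)
    py = sy - sx @ cho_solve(xtsx_cho, xt.T @ sy)
    vpy = grm.matvec(py)
    s_vpy = solve(vpy)
    pvpy = s_vpy - sx @ cho_solve(xtsx_cho, xt.T @ s_vpy)

    ypvpy = float(ytilde @ pvpy)
    ai = 0.5 * float(vpy @ pvpy)

    if use_exact:
        L = sig_cho[0]
        LV = solve_triangular(L, V, lower=True, check_finite=False)
        SV = solve_triangular(L.T, LV, lower=False, check_finite=False)
        tr_sv = float(np.trace(SV))
        corr = float(np.trace(cho_solve(xtsx_cho, sx.T @ (V @ sx))))
        tr_pv = tr_sv - corr
    else:
        tr_pv = _trace_PV_hutchinson(solver, grm, xt, sx, xtsx_cho, config.n_trace_probes, rng)

    score = 0.5 * (ypvpy - tr_pv)
    if ai > 0:
        step = score / ai
    else:
        logger.warning("AI-REML: non-positive average information, halving score step")
        step = 0.5 * score
    tau_new = tau + step
    went_negative = tau_new < 0
    if went_negative:
        tau_new = max(tau / 2.0, 0.0) if tau > 1e-4 else 0.0
    # damp huge steps to keep the outer loop stable
    tau_new = min(tau_new, 5.0 * tau + 0.5)
    return float(tau_new), went_negative


# ---------------------------------------------------------------------
# outer loop


def fit_null(
    phen: SurvivalPhenotype,
    grm: Optional[GRMOperator] = None,
    config: NullModelConfig | None = None,
) -> NullModelFit:
    """Fit the null frailty model by alternating Breslow / PQL / AI-REML.

    With ``grm`` omitted or ``config.fix_tau == 0`` the fit reduces to the
    Cox model profile likelihood (no random effects), and the estimated
    (beta, Lambda0) reproduce the partial-likelihood MLE.
    """
    config = config or NullModelConfig()
    if phen.n_events == 0:
        raise ValueError("phenotype has zero events; cannot fit a survival model")
    if grm is not None and grm.n != phen.n:
        raise ValueError("GRM operator and phenotype have different sample counts")
    rng = np.random.default_rng(config.seed)

    estimate_tau = config.fix_tau is None and grm is not None
    tau = float(config.fix_tau) if config.fix_tau is not None else (config.tau_init if grm is not None else 0.0)

    p = phen.X.shape[1]
    beta = np.zeros(p)
    b = np.zeros(phen.n)
    jumps_prev = None
    tau_path = [tau]
    objective_path: list[float] = []
    negative_steps = 0
    boundary = False
    converged = False
    n_iter = 0

    for outer in range(1, config.max_outer + 1):
        n_iter = outer
        eta = phen.X @ beta + b
        baseline = breslow_cumhaz(phen.t, phen.delta, eta)
        beta_t, b, eta_lin, mu, ytilde, W, penalty = pql_update(
            phen, grm, tau, baseline, beta, b, config
        )
        # fold the working intercept into the baseline jumps
        intercept = beta_t[0]
        baseline = BaselineHazard(baseline.event_times, baseline.jumps * np.exp(intercept))
        beta = beta_t[1:]
        eta = phen.X @ beta + b
        mu = np.maximum(baseline.cumulative(phen.t), 0.0) * np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

        objective_path.append(
            _pql_objective(phen.t, phen.delta, eta, baseline, mu, penalty)
        )

        tau_old = tau
        if estimate_tau and tau > 0:
            tau, went_neg = aireml_tau_update(ytilde, W, phen.xtilde(), grm, tau, config, rng)
            if went_neg:
                negative_steps += 1
                if negative_steps >= 2:
                    tau, boundary = 0.0, True
        tau_path.append(tau)

        tau_change = abs(tau - tau_old) / (tau_old + 1e-4)
        if jumps_prev is not None and len(jumps_prev) == len(baseline.jumps):
            param_change = max(
                np.max(np.abs(baseline.jumps - jumps_prev) / np.maximum(np.abs(jumps_prev), 1e-8)),
                (np.max(np.abs(beta - beta_prev) / np.maximum(np.abs(beta_prev), 1e-4)) if p else 0.0),
            )
        else:
            param_change = np.inf
        jumps_prev, beta_prev = baseline.jumps.copy(), beta.copy()
        if tau_change < config.outer_tol and param_change < config.outer_tol:
            converged = True
            break

    if not converged:
        raise RuntimeError(
            f"null model did not converge in {config.max_outer} outer iterations; "
            f"tau trajectory: {np.round(tau_path, 4).tolist()}"
        )

    # final profiling pass so the score identity sum(delta) = sum(mu) is exact
    eta = phen.X @ beta + b
    baseline = breslow_cumhaz(phen.t, phen.delta, eta)
    mu = baseline.cumulative(phen.t) * np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    return NullModelFit(
        sample_ids=list(phen.sample_ids),
        beta_hat=beta,
        tau_hat=tau,
        b_hat=b,
        eta_hat=eta,
        mu_hat=mu,
        baseline=baseline,
        t=phen.t,
        delta=phen.delta,
        X=phen.X,
        converged=converged,
        n_iter=n_iter,
        tau_path=[float(x) for x in tau_path],
        objective_path=objective_path,
        tau_boundary=boundary,
    )


def _pql_objective(t, delta, eta, baseline: BaselineHazard, mu, penalty: float) -> float:
    """Penalized profile log-likelihood: the censored-data log-likelihood
    sum_i [delta_i (log dLambda0(t_i) + eta_i) - Lambda0(t_i) e^eta_i]
    at the Breslow-profiled baseline, minus the frailty penalty."""
    ev = np.asarray(delta) == 1
    idx = np.searchsorted(baseline.event_times, np.asarray(t, dtype=float)[ev])
    log_jumps = np.log(baseline.jumps[idx])
    return float(log_jumps.sum() + np.asarray(eta)[ev].sum() - mu.sum()) - penalty
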