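"""Independent oracles built on the Cox partial likelihood (Breslow ties).

These are deliberately derived from the partial-likelihood risk-set sums,
not from the package's Poisson working-model machinery, so they serve as
cross-checks for the score test, the attenuation operator and the
baseline-hazard profiling.
"""

from __future__ import annotations

import numpy as np


def _risk_set_sums(t, delta, w, *stacks):
    """Per distinct event time: d_k, S0_k and suffix sums of w * stack."""
    t = np.asarray(t, dtype=float)
    order = np.argsort(t, kind="stable")
    ts = t[order]
    event_times, d_k = np.unique(t[np.asarray(delta) == 1], return_counts=True)
    pos = np.searchsorted(ts, event_times, side="left")
    ws = w[order]
    s0 = np.concatenate([np.cumsum(ws[::-1])[::-1], [0.0]])[pos]
    out = []
    for arr in stacks:
        a = (w * arr.T).T[order]
        suffix = np.concatenate([np.cumsum(a[::-1], axis=0)[::-1], np.zeros((1,) + a.shape[1:])])
        out.append(suffix[pos])
    return event_times, d_k, s0, out


def cox_log_partial_likelihood(params, covs, t, delta):
    """Breslow-ties log partial likelihood for covariate matrix ``covs``."""
    covs = np.atleast_2d(np.asarray(covs, dtype=float))
    if covs.shape[0] != len(t):
        covs = covs.T
    eta = covs @ np.asarray(params, dtype=float)
    w = np.exp(eta)
    event_times, d_k, s0, _ = _risk_set_sums(t, delta, w)
    ll = float(eta[np.asarray(delta) == 1].sum()) - float(np.sum(d_k * np.log(s0)))
    return ll


def cox_score_test(Gmat, X, t, delta, beta_hat):
    """Score test for adding each column of ``Gmat`` to a Cox model with
    covariates ``X`` fitted at ``beta_hat`` (Breslow ties).

    Returns (U, var) per variant, with the covariate block profiled out via
    the Schur complement of the observed partial-likelihood information.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        X = np.empty((len(t), 0))
    if X.shape[0] != len(t):
        X = X.T
    G = np.asarray(Gmat, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, p = X.shape
    w = np.exp(X @ np.asarray(beta_hat, dtype=float)) if p else np.ones(n)
    delta = np.asarray(delta)

    xx = np.einsum("ip,iq->ipq", X, X).reshape(n, p * p) if p else np.empty((n, 0))
    gx = np.einsum("im,ip->imp", G, X).reshape(n, -1) if p else np.empty((n, 0))
    event_times, d_k, s0, (Sg, Sgg, Sx, Sxx, Sgx) = _risk_set_sums(
        t, delta, w, G, G**2, X, xx, gx
    )
    m = G.shape[1]
    ev = delta == 1
    # sum of g over events at each event time
    t_ev = np.asarray(t, dtype=float)[ev]
    order_ev = np.argsort(t_ev, kind="stable")
    G_ev = G[ev][order_ev]
    bounds = np.searchsorted(np.sort(t_ev), event_times, side="left")
    cum = np.concatenate([np.zeros((1, m)), np.cumsum(G_ev, axis=0)])
    ends = np.searchsorted(np.sort(t_ev), event_times, side="right")
    sum_g_events = cum[ends] - cum[bounds]

    mean_g = Sg / s0[:, None]
    U = sum_g_events.sum(axis=0) - (d_k[:, None] * mean_g).sum(axis=0)
    I_gg = np.sum(d_k[:, None] * (Sgg / s0[:, None] - mean_g**2), axis=0)
    if p:
        mean_x = Sx / s0[:, None]
        I_xx = np.sum(
            d_k[:, None, None]
            * (Sxx.reshape(-1, p, p) / s0[:, None, None]
               - np.einsum("kp,kq->kpq", mean_x, mean_x)),
            axis=0,
        )
        I_gx = np.sum(
            d_k[:, None, None]
            * (Sgx.reshape(-1, m, p) / s0[:, None, None]
               - np.einsum("km,kp->kmp", mean_g, mean_x)),
            axis=0,
        )
        corr = np.einsum("mp,pq,mq->m", I_gx, np.linalg.inv(I_xx), I_gx)
        var = I_gg - corr
    else:
        var = I_gg
    return U, var


def numerical_hessian_1d(f, x0, h=1e-4):
    """Second derivative of a scalar function by central differences."""
    return (f(x0 + h) - 2.0 * f(x0) + f(x0 - h)) / h**2
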