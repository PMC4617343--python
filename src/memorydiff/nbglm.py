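"""Batched negative-binomial GLM fitting.

All transcripts share one design matrix, so iteratively reweighted least
squares can be vectorised across transcripts: each iteration solves one
small (p x p) weighted normal-equation system per transcript via a
batched ``numpy.linalg.solve``. Dispersions are held fixed during
fitting (NB2 parameterisation, variance = mu + phi mu^2); with known
phi the model is an ordinary GLM with log link.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_ETA_MIN, _ETA_MAX = -30.0, 30.0
_POISSON_PHI = 1e-10


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood; ``y``/``mu`` are (T, n), ``phi`` is
    (T,) or scalar. phi below 1e-10 falls back to the Poisson limit."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(mu, 1e-300, None)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))
    out = np.empty(y.shape[0])
    pois = phi < _POISSON_PHI
    if pois.any():
        out[pois] = (
            y[pois] * np.log(mu[pois]) - mu[pois] - gammaln(y[pois] + 1.0)
        ).sum(axis=1)
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb][:, None]
        m = mu[nb]
        yy = y[nb]
        out[nb] = (
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1.0)
            + r * np.log(r / (r + m))
            + yy * np.log(m / (r + m))
        ).sum(axis=1)
    return out


def _mu_from_beta(beta: np.ndarray, X: np.ndarray, offset: np.ndarray) -> np.ndarray:
    eta = beta @ X.T + offset
    return np.exp(np.clip(eta, _ETA_MIN, _ETA_MAX))


def fit_nbglm(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray | float,
    max_iter: int = 100,
    tol: float = 1e-8,
    beta0: np.ndarray | None = None,
):
    """Fit an NB GLM with log link and fixed dispersion to every row of Y.

    Parameters
    ----------
    Y : (T, n) nonnegative counts
    X : (n, p) full-rank design matrix; column 0 must be an intercept
    offset : (n,) log library-size offsets
    phi : per-row dispersion, (T,) or scalar
    beta0 : optional warm-start coefficients, (T, p)

    Returns
    -------
    beta : (T, p), ll : (T,), mu : (T, n), converged : (T,) bool
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    T, n = Y.shape
    p = X.shape[1]
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (T,)).copy()

    if beta0 is None:
        beta = np.zeros((T, p))
        base = np.log(np.clip((Y * np.exp(-offset)).mean(axis=1), 1e-8, None))
        beta[:, 0] = base
    else:
        beta = np.array(beta0, dtype=float)

    mu = _mu_from_beta(beta, X, offset)
    ll = nb_loglik(Y, mu, phi_arr)
    converged = np.zeros(T, dtype=bool)
    ridge = 1e-8 * np.eye(p)

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        Ya, mua, phia, betaa = Y[active], mu[active], phi_arr[active], beta[active]
        eta = np.log(mua)
        W = mua / (1.0 + phia[:, None] * mua)
        z = (eta - offset) + (Ya - mua) / mua
        XtWX = np.einsum("ni,tn,nj->tij", X, W, X) + ridge
        XtWz = np.einsum("tn,ni->ti", W * z, X)
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(XtWX, XtWz)]
            )

        # step-halving where the update lowers the likelihood
        delta = beta_new - betaa
        ll_old = ll[active]
        for _half in range(12):
            mu_new = _mu_from_beta(betaa + delta, X, offset)
            ll_new = nb_loglik(Ya, mu_new, phia)
            bad = ll_new < ll_old - 1e-12
            if not bad.any():
                break
            delta[bad] *= 0.5
        beta_act = betaa + delta
        mu_act = _mu_from_beta(beta_act, X, offset)
        ll_act = nb_loglik(Ya, mu_act, phia)

        done = np.abs(ll_act - ll_old) < tol * (np.abs(ll_old) + 1.0)
        beta[active] = beta_act
        mu[active] = mu_act
        ll[active] = ll_act
        idx = np.flatnonzero(active)
        converged[idx[done]] = True

    return beta, ll, mu, converged


def cox_reid_adjustment(
    mu: np.ndarray, X: np.ndarray, phi: np.ndarray | float
) -> np.ndarray:
    """0.5 * logdet(X' W X) per row — the Cox-Reid correction used by the
    adjusted profile likelihood for dispersion estimation."""
    T = mu.shape[0]
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (T,))
    W = mu / (1.0 + phi_arr[:, None] * mu)
    XtWX = np.einsum("ni,tn,nj->tij", X, W, X) + 1e-10 * np.eye(X.shape[1])
    sign, logdet = np.linalg.slogdet(XtWX)
    return 0.5 * logdet


def adjusted_profile_loglik(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    beta0: np.ndarray | None = None,
):
    """Summed Cox-Reid adjusted profile log-likelihood at a common
    dispersion ``phi``; returns (apl_sum, fitted beta for warm starts)."""
    beta, ll, mu, _ = fit_nbglm(Y, X, offset, phi, beta0=beta0)
    apl = ll - cox_reid_adjustment(mu, X, phi)
    return float(apl.sum()), beta
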