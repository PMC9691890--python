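"""Restricted maximum likelihood for linear mixed models with variance
components.

The model is ``y = X b + sum_k u_k + e`` with ``u_k ~ N(0, s2_k G_k)`` and
``e ~ N(0, s2_e I)``, where each ``G_k`` is a known n × n covariance structure
(``Z_k Z_k'`` for a grouping factor, or a genomic relationship / kernel
matrix).  Components are estimated by average-information REML with
step-halving and a positivity floor; negative solutions are truncated at zero
on exit and flagged.

This direct ``V``-based formulation keeps every per-iteration quantity as a
dense Cholesky solve, which is the right trade-off at the problem sizes this
package works with (n up to a few thousand observations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve


@dataclass
class REMLResult:
    """Outcome of an AI-REML fit.

    ``sigma2`` holds the K genetic-term components followed by the residual
    component.  ``Py`` is the projected response ``P y`` needed for BLUP
    back-solving (``u_hat_k = sigma2_k G_k P y`` on the observation scale, or
    ``sigma2_k Z_k' P y`` for factor effects).  ``se`` are asymptotic standard
    errors from the inverse average-information matrix.
    """

    sigma2: np.ndarray
    Py: np.ndarray
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    truncated: np.ndarray
    se: np.ndarray


def _project(Vc, X, XtVinvX_c, VinvX, M):
    """Apply P = Vinv - Vinv X (X' Vinv X)^-1 X' Vinv to the columns of M."""
    VinvM = cho_solve(Vc, M)
    return VinvM - VinvX @ cho_solve(XtVinvX_c, VinvX.T @ M)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    structures: list[np.ndarray],
    *,
    max_iter: int = 60,
    tol: float = 1e-12,
    start: np.ndarray | None = None,
) -> REMLResult:
    """Estimate variance components by average-information REML.

    Parameters
    ----------
    y
        Response vector, length n.
    X
        Fixed-effects design, n × p, full column rank.
    structures
        One n × n symmetric PSD matrix per random term (residual excluded; an
        identity residual term is always appended internally).
    start
        Optional initial values for all K+1 components; defaults to an equal
        split of the OLS residual variance.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have inconsistent numbers of rows")
    K = len(structures)
    for G in structures:
        if G.shape != (n, n):
            raise ValueError("every covariance structure must be n × n")

    # OLS residual variance anchors the scale of starts and floors
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    vary = float(resid @ resid) / max(n - p, 1)
    if vary <= 0:
        vary = max(float(np.var(y)), 1e-12)
    floor = 1e-8 * vary

    theta = (
        np.full(K + 1, vary / (K + 1))
        if start is None
        else np.asarray(start, dtype=float).copy()
    )
    theta = np.maximum(theta, floor)

    I_n = np.eye(n)

    def build_V(th):
        V = th[K] * I_n
        for k in range(K):
            V = V + th[k] * structures[k]
        return V

    def loglik_and_parts(th):
        V = build_V(th)
        Vc = cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(Vc[0])))
        VinvX = cho_solve(Vc, X)
        XtVinvX = X.T @ VinvX
        XtVinvX_c = cho_factor(XtVinvX, lower=True)
        logdetX = 2.0 * np.sum(np.log(np.diag(XtVinvX_c[0])))
        Vinvy = cho_solve(Vc, y)
        beta = cho_solve(XtVinvX_c, VinvX.T @ y)
        Py = Vinvy - VinvX @ beta
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return ll, Vc, VinvX, XtVinvX_c, Py, beta

    ll, Vc, VinvX, XtVinvX_c, Py, beta = loglik_and_parts(theta)
    converged = False
    it = 0
    AI = np.eye(K + 1)
    for it in range(1, max_iter + 1):
        # scores: dl/dtheta_k = -0.5 (tr(P G_k) - y'P G_k P y)
        Vinv = cho_solve(Vc, I_n)
        PX_part = cho_solve(XtVinvX_c, VinvX.T)  # (p × n)
        score = np.empty(K + 1)
        F = np.empty((n, K + 1))
        for k in range(K):
            Gk = structures[k]
            trPG = float(np.sum(Vinv * Gk)) - float(np.sum(VinvX.T * (PX_part @ Gk)))
            F[:, k] = Gk @ Py
            score[k] = -0.5 * (trPG - float(Py @ F[:, k]))
        trP = float(np.trace(Vinv)) - float(np.sum(VinvX.T * PX_part))
        F[:, K] = Py
        score[K] = -0.5 * (trP - float(Py @ Py))

        PF = _project(Vc, X, XtVinvX_c, VinvX, F)
        AI = 0.5 * (F.T @ PF)

        # active set: components held at the floor with negative score are
        # pinned there (boundary solutions); the Newton step runs on the rest
        pinned = (theta <= 1.001 * floor) & (score < 0)
        free = ~pinned
        delta = np.zeros(K + 1)
        if free.any():
            AIf = AI[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(
                    AIf + 1e-12 * np.eye(int(free.sum())), score[free]
                )
            except np.linalg.LinAlgError:
                delta[free] = score[free] / np.maximum(np.diag(AIf), 1e-12)
        if not np.isfinite(delta).all():
            delta = np.zeros(K + 1)
        if not delta.any():
            converged = True
            break
        # trust region: degenerate (noise-free) responses make the AI matrix
        # ill-conditioned and propose wild steps along a flat ridge
        cap = 5.0 * np.maximum(theta, 0.01 * vary)
        delta = np.clip(delta, -cap, cap)

        # step-halving guards against genuine divergence only; near the
        # optimum the likelihood is numerically flat and Newton steps are
        # accepted on the strength of the score instead
        step = 1.0
        accepted = False
        for _ in range(25):
            cand = np.maximum(theta + step * delta, floor)
            try:
                ll_new, Vc_n, VinvX_n, XtVinvX_c_n, Py_n, beta_n = loglik_and_parts(cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if ll_new >= ll - 1e-10 * (1.0 + abs(ll)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # cannot move without losing likelihood
            break
        moved = np.max(np.abs(cand - theta)) / max(vary, 1e-12)
        dll = ll_new - ll
        theta, ll = cand, ll_new
        Vc, VinvX, XtVinvX_c, Py, beta = Vc_n, VinvX_n, XtVinvX_c_n, Py_n, beta_n
        if (
            moved < 1e-10
            or (dll < tol * (1.0 + abs(ll)) and moved < 1e-9)
            or (step == 1.0 and dll < tol * (1.0 + abs(ll)))
        ):
            converged = True
            break

    truncated = theta <= 10.0 * floor
    sigma2 = np.where(truncated, 0.0, theta)
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(K + 1, np.nan)
    return REMLResult(
        sigma2=sigma2,
        Py=Py,
        beta=beta,
        loglik=ll,
        converged=converged,
        n_iter=it,
        truncated=truncated,
        se=se,
    )
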