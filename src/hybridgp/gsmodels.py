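"""The five genomic-prediction models.

* ``gblup`` — genetic values with a genomic relationship covariance
  K = Zc Zc' / c per effect term (Zc column-centred codes, c the sum of
  column variances); components by REML (default) or Gibbs.
* ``rkhs`` — reproducing kernel Hilbert space regression with Gaussian
  kernels K_h = exp(−h · D / mean(D)) over the bandwidths h (default
  {0.1, 0.5, 2.5}), all kernels fitted jointly with their own variances
  (kernel averaging); components by Gibbs (default) or REML.
* ``bayes_a`` / ``bayes_c`` / ``bayesian_lasso`` — hierarchical marker-effect
  models fitted by single-site Gibbs sampling (see ``_samplers``).

The additive-plus-dominance (AD) model passes two coded matrices; every
method then carries one independent variance (or prior scale) per term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _samplers
from .hybridcode import CodedMatrix
from .reml import reml_fit

METHODS = ("gblup", "rkhs", "bayes_a", "bayes_c", "bayesian_lasso")

#: weakly-informative hyperprior defaults shared by the samplers
DF_BETA = 5.0
DF_E = 5.0
R2_PRIOR = 0.5
PI_A, PI_B = 1.0, 9.0
EIG_TOL = 1e-8


@dataclass
class ModelSpec:
    """Configuration of one genomic-prediction fit."""

    method: str = "gblup"
    effect_terms: tuple[str, ...] = ("additive",)
    rkhs_bandwidths: tuple[float, ...] = (0.1, 0.5, 2.5)
    n_iter: int = 12000
    burn_in: int = 3000
    thin: int = 5
    seed: int = 0
    estimator: str | None = None  # "reml" | "gibbs"; None = method default

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not self.effect_terms:
            raise ValueError("effect_terms must be non-empty")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if any(h <= 0 for h in self.rkhs_bandwidths):
            raise ValueError("bandwidths must be positive")

    @property
    def resolved_estimator(self) -> str:
        if self.estimator is not None:
            return self.estimator
        return "reml" if self.method == "gblup" else "gibbs"


@dataclass
class FittedModel:
    """A fitted genomic-prediction model ready for prediction."""

    spec: ModelSpec
    intercept: float
    n_train: int
    term_values: list[np.ndarray]  # genetic values per term, training rows
    variance_components: dict[str, float]
    # marker methods
    marker_effects: list[np.ndarray] | None = None
    col_means: list[np.ndarray] | None = None
    # kernel methods
    kernel_info: list[dict] | None = None
    kernel_alphas: list[np.ndarray] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def fitted_values(self) -> np.ndarray:
        out = np.full(self.n_train, self.intercept)
        for g in self.term_values:
            out = out + g
        return out


def _as_array(term) -> np.ndarray:
    if isinstance(term, CodedMatrix):
        return term.values
    return np.asarray(term, dtype=float)


def _effective_sample_size(draws: np.ndarray) -> float:
    """Initial-positive-sequence ESS estimate for a single chain."""
    d = np.asarray(draws, dtype=float)
    n = d.size
    if n < 10 or np.var(d) == 0:
        return float(n)
    d = d - d.mean()
    acf = np.correlate(d, d, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(d))
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


# ---------------------------------------------------------------- kernels


def _grm(Z: np.ndarray, means: np.ndarray | None = None, c: float | None = None):
    """Genomic relationship matrix from a coded matrix.

    Columns are centred and the cross-product divided by the sum of column
    variances — a scaling that stays meaningful for fractional hybrid codes
    where allele-frequency-based scalings are undefined.
    """
    if means is None:
        means = Z.mean(axis=0)
    Zc = Z - means
    if c is None:
        c = float((Zc**2).sum(axis=1).mean())  # == sum of column variances
        c = max(c, 1e-12)
    return Zc @ Zc.T / c, means, c


def _grm_cross(Z_new: np.ndarray, Z_train: np.ndarray, means: np.ndarray, c: float):
    return (Z_new - means) @ (Z_train - means).T / c


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = (A**2).sum(axis=1)[:, None]
    bb = (B**2).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * A @ B.T, 0.0)


def _gaussian_kernels(Z: np.ndarray, bandwidths) -> tuple[list[np.ndarray], float]:
    D = _sq_dists(Z, Z)
    dbar = float(D.mean())
    if dbar <= 0:
        dbar = 1.0
    return [np.exp(-h * D / dbar) for h in bandwidths], dbar


def _build_kernels(spec: ModelSpec, terms: list[np.ndarray]):
    """Kernel list plus the bookkeeping needed to form cross-kernels later."""
    kernels, info = [], []
    for t_idx, Z in enumerate(terms):
        if spec.method == "gblup":
            K, means, c = _grm(Z)
            kernels.append(K)
            info.append({"kind": "grm", "term": t_idx, "means": means, "c": c, "Z": Z})
        else:  # rkhs
            Ks, dbar = _gaussian_kernels(Z, spec.rkhs_bandwidths)
            for h, K in zip(spec.rkhs_bandwidths, Ks):
                kernels.append(K)
                info.append({"kind": "gauss", "term": t_idx, "h": h, "dbar": dbar, "Z": Z})
    return kernels, info


def _cross_kernel(info: dict, Z_new: np.ndarray) -> np.ndarray:
    if info["kind"] == "grm":
        return _grm_cross(Z_new, info["Z"], info["means"], info["c"])
    D = _sq_dists(Z_new, info["Z"])
    return np.exp(-info["h"] * D / info["dbar"])


# ------------------------------------------------------------- kernel fits


def _single_kernel_reml(y: np.ndarray, K: np.ndarray) -> tuple[float, float, float]:
    """Exact REML for y = 1·mu + g + e, g ~ N(0, s2_g K), via the eigenbasis.

    Profiles the likelihood over the variance ratio gamma = s2_g / s2_e with
    a bounded scalar search; returns (mu, s2_g, s2_e).  Much faster than the
    generic AI-REML when only one kernel is present (the dominant case in
    cross-validation loops).
    """
    from scipy.optimize import minimize_scalar

    n = y.shape[0]
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def profile(log_gamma):
        g = np.exp(log_gamma)
        w = 1.0 / (1.0 + g * lam)
        xwx = float((xt * w * xt).sum())
        beta = float((xt * w * yt).sum()) / xwx
        r = yt - xt * beta
        rss = float((r * w * r).sum())
        s2e = rss / (n - 1)
        ll = -0.5 * (
            np.sum(np.log(1.0 / w))
            + np.log(xwx)
            + (n - 1) * (1.0 + np.log(s2e))
        )
        return ll, beta, s2e

    res = minimize_scalar(
        lambda lg: -profile(lg)[0], bounds=(-25.0, 25.0), method="bounded",
        options={"xatol": 1e-10},
    )
    gamma = float(np.exp(res.x))
    _, beta, s2e = profile(res.x)
    return beta, gamma * s2e, s2e


def _fit_kernel_reml(y, kernels, info, spec: ModelSpec) -> FittedModel:
    n = len(y)
    X = np.ones((n, 1))
    if len(kernels) == 1:
        mu, s2g, s2e = _single_kernel_reml(y, kernels[0])
        V = s2g * kernels[0] + s2e * np.eye(n)
        try:
            alpha = s2g * np.linalg.solve(V, y - mu)
        except np.linalg.LinAlgError:  # noise-free boundary
            V = V + 1e-10 * (np.trace(V) / n) * np.eye(n)
            alpha = s2g * np.linalg.solve(V, y - mu)
        return FittedModel(
            spec=spec,
            intercept=mu,
            n_train=n,
            term_values=[kernels[0] @ alpha],
            variance_components={"kernel_0": s2g, "residual": s2e},
            kernel_info=info,
            kernel_alphas=[alpha],
            diagnostics={"estimator": "reml", "converged": True},
        )
    res = reml_fit(y, X, kernels)
    alphas = [res.sigma2[k] * res.Py for k in range(len(kernels))]
    term_values = [kernels[k] @ alphas[k] for k in range(len(kernels))]
    vcs = {f"kernel_{k}": float(res.sigma2[k]) for k in range(len(kernels))}
    vcs["residual"] = float(res.sigma2[-1])
    return FittedModel(
        spec=spec,
        intercept=float(res.beta[0]),
        n_train=n,
        term_values=term_values,
        variance_components=vcs,
        kernel_info=info,
        kernel_alphas=alphas,
        diagnostics={"estimator": "reml", "converged": bool(res.converged)},
    )


def _fit_kernel_gibbs(y, kernels, info, spec: ModelSpec) -> FittedModel:
    """BGLR-style Gibbs sampler over eigendecomposed kernel random effects."""
    rng = np.random.default_rng(spec.seed)
    n = len(y)
    vary = float(np.var(y))
    n_k = len(kernels)
    eig = []
    for K in kernels:
        w, V = np.linalg.eigh(K)
        keep = w > EIG_TOL * w.max()
        eig.append((V[:, keep], w[keep]))

    S_k = R2_PRIOR * vary * (DF_BETA + 2.0) / n_k
    S_e = (1.0 - R2_PRIOR) * vary * (DF_E + 2.0)
    mu = float(y.mean())
    var_e = max(vary * (1.0 - R2_PRIOR), 1e-10)
    var_k = np.full(n_k, max(R2_PRIOR * vary / n_k, 1e-10))
    delta = [np.zeros(lam.size) for _, lam in eig]
    u = [np.zeros(n) for _ in range(n_k)]

    n_kept = (spec.n_iter - spec.burn_in) // spec.thin
    u_mean = [np.zeros(n) for _ in range(n_k)]
    w_mean = [np.zeros(n) for _ in range(n_k)]
    mu_mean = 0.0
    var_draws = np.zeros((n_kept, n_k + 1))
    kept = 0
    for it in range(spec.n_iter):
        # intercept
        resid = y - mu - sum(u)
        resid += mu
        mu = float(resid.mean() + rng.standard_normal() * np.sqrt(var_e / n))
        resid -= mu
        # kernel effects on the eigenbasis (orthonormal columns make the
        # full conditional of the coefficients diagonal)
        for k in range(n_k):
            Gam, lam = eig[k]
            resid += u[k]
            ytil = Gam.T @ resid
            post_var = 1.0 / (1.0 / var_e + 1.0 / (var_k[k] * lam))
            post_mean = post_var * ytil / var_e
            delta[k] = post_mean + rng.standard_normal(lam.size) * np.sqrt(post_var)
            u[k] = Gam @ delta[k]
            resid -= u[k]
            ss = float((delta[k] ** 2 / lam).sum())
            var_k[k] = (S_k * DF_BETA + ss) / rng.chisquare(DF_BETA + lam.size)
        var_e = (S_e * DF_E + float(resid @ resid)) / rng.chisquare(DF_E + n)
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            for k in range(n_k):
                Gam, lam = eig[k]
                u_mean[k] += u[k]
                w_mean[k] += Gam @ (delta[k] / lam)  # K^-1 u, for cross-kernel BLUP
            mu_mean += mu
            var_draws[kept, :n_k] = var_k
            var_draws[kept, n_k] = var_e
            kept += 1

    u_mean = [v / n_kept for v in u_mean]
    w_mean = [v / n_kept for v in w_mean]
    vcs = {f"kernel_{k}": float(var_draws[:, k].mean()) for k in range(n_k)}
    vcs["residual"] = float(var_draws[:, n_k].mean())
    return FittedModel(
        spec=spec,
        intercept=mu_mean / n_kept,
        n_train=n,
        term_values=u_mean,
        variance_components=vcs,
        kernel_info=info,
        kernel_alphas=w_mean,
        diagnostics={
            "estimator": "gibbs",
            "n_kept": n_kept,
            "ess_var_e": _effective_sample_size(var_draws[:, n_k]),
            "var_e_trace_mean": float(var_draws[:, n_k].mean()),
            "var_e_trace_sd": float(var_draws[:, n_k].std()),
        },
    )


# ------------------------------------------------------------- marker fits


def _fit_marker(y, terms, spec: ModelSpec) -> FittedModel:
    n = len(y)
    vary = float(np.var(y))
    col_means = [Z.mean(axis=0) for Z in terms]
    Xc = np.asfortranarray(np.column_stack([Z - m for Z, m in zip(terms, col_means)]))
    term_id = np.concatenate(
        [np.full(Z.shape[1], t, dtype=np.int64) for t, Z in enumerate(terms)]
    )
    n_terms = len(terms)
    msx = np.array(
        [max(float((Z - m).var(axis=0).sum()), 1e-12) for Z, m in zip(terms, col_means)]
    )
    S_e = (1.0 - R2_PRIOR) * vary * (DF_E + 2.0)
    yc = np.asarray(y, dtype=float)

    if spec.method == "bayes_a":
        S_beta = R2_PRIOR * vary * (DF_BETA + 2.0) / (n_terms * msx)
        beta, mu, var_e_draws = _samplers.bayes_a(
            Xc, yc, term_id, n_terms, S_beta, DF_BETA, S_e, DF_E,
            spec.n_iter, spec.burn_in, spec.thin, spec.seed % 2**31,
        )
        extra = {}
    elif spec.method == "bayes_c":
        pi0 = PI_A / (PI_A + PI_B)
        S_beta = R2_PRIOR * vary * (DF_BETA + 2.0) / (n_terms * msx * pi0)
        beta, mu, var_e_draws, pip = _samplers.bayes_c(
            Xc, yc, term_id, n_terms, S_beta, DF_BETA, S_e, DF_E,
            PI_A, PI_B, spec.n_iter, spec.burn_in, spec.thin, spec.seed % 2**31,
        )
        extra = {"inclusion_prob": pip}
    else:  # bayesian_lasso
        var_e0 = (1.0 - R2_PRIOR) * vary
        lam2_init = np.array(
            [2.0 * var_e0 * msx[t] / max(R2_PRIOR * vary, 1e-12) for t in range(n_terms)]
        )
        gamma_shape = 1.1
        gamma_rate = np.mean(gamma_shape / np.maximum(lam2_init, 1e-12))
        beta, mu, var_e_draws = _samplers.bayesian_lasso(
            Xc, yc, term_id, n_terms, lam2_init, gamma_shape, gamma_rate,
            S_e, DF_E, spec.n_iter, spec.burn_in, spec.thin, spec.seed % 2**31,
        )
        extra = {}

    effects = []
    term_values = []
    start = 0
    for Z, m_ in zip(terms, col_means):
        b = beta[start : start + Z.shape[1]]
        effects.append(b)
        term_values.append((Z - m_) @ b)
        start += Z.shape[1]
    fm = FittedModel(
        spec=spec,
        intercept=float(mu),
        n_train=n,
        term_values=term_values,
        variance_components={"residual": float(np.mean(var_e_draws))},
        marker_effects=effects,
        col_means=col_means,
        diagnostics={
            "estimator": "gibbs",
            "n_kept": len(var_e_draws),
            "ess_var_e": _effective_sample_size(var_e_draws),
            "var_e_trace_mean": float(np.mean(var_e_draws)),
            "var_e_trace_sd": float(np.std(var_e_draws)),
            **extra,
        },
    )
    return fm


# -------------------------------------------------------------------- API


def fit(y, X_terms, spec: ModelSpec) -> FittedModel:
    """Fit one genomic-prediction model.

    ``X_terms`` is one coded matrix (or array) per effect term; rows align
    with ``y``.  Coded matrices must be fully observed.
    """
    terms = [_as_array(t) for t in X_terms]
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    for Z in terms:
        if Z.shape[0] != n:
            raise ValueError("rows of y and coded matrices do not align")
        if np.isnan(Z).any():
            raise ValueError("coded matrices must not contain missing values")

    if float(np.var(y)) < 1e-14:
        # degenerate constant response: intercept only, zero genetic variance
        zero_vals = [np.zeros(n) for _ in terms]
        fm = FittedModel(
            spec=spec,
            intercept=float(y.mean()),
            n_train=n,
            term_values=zero_vals,
            variance_components={"residual": 0.0},
            diagnostics={"degenerate": True},
        )
        if spec.method in ("gblup", "rkhs"):
            kernels, info = _build_kernels(spec, terms)
            fm.kernel_info = info
            fm.kernel_alphas = [np.zeros(n) for _ in kernels]
            fm.term_values = [np.zeros(n) for _ in kernels]
        else:
            fm.marker_effects = [np.zeros(Z.shape[1]) for Z in terms]
            fm.col_means = [Z.mean(axis=0) for Z in terms]
        return fm

    if spec.method in ("gblup", "rkhs"):
        kernels, info = _build_kernels(spec, terms)
        if spec.resolved_estimator == "reml":
            return _fit_kernel_reml(y, kernels, info, spec)
        return _fit_kernel_gibbs(y, kernels, info, spec)
    return _fit_marker(y, terms, spec)


def predict(model: FittedModel, X_terms_new) -> np.ndarray:
    """Predict genetic merit of new rows coded identically to training."""
    terms = [_as_array(t) for t in X_terms_new]
    if model.marker_effects is not None:
        if len(terms) != len(model.marker_effects):
            raise ValueError("number of effect terms differs from training")
        out = np.full(terms[0].shape[0], model.intercept)
        for Z, b, m_ in zip(terms, model.marker_effects, model.col_means):
            if Z.shape[1] != b.shape[0]:
                raise ValueError("marker set differs from training")
            out = out + (Z - m_) @ b
        return out
    if model.kernel_info is None:
        raise ValueError("model carries neither marker effects nor kernels")
    out = np.full(terms[0].shape[0], model.intercept)
    for info, alpha in zip(model.kernel_info, model.kernel_alphas):
        Z_new = terms[info["term"]]
        if Z_new.shape[1] != info["Z"].shape[1]:
            raise ValueError("marker set differs from training")
        out = out + _cross_kernel(info, Z_new) @ alpha
    return out
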