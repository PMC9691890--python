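"""NC-II combining-ability analysis.

Fits the multi-environment mixed model for line × tester hybrids

    y = mu + E + R(E) + GCA_L + GCA_T + SCA
        + GCA_L×E + GCA_T×E + SCA×E + eps

with environment and replicate-within-environment fixed and all combining
ability terms random, estimates variance components by REML, predicts GCA and
SCA effects (BLUP), computes entry-mean BLUEs, and evaluates the GCA and
entry-mean heritabilities.

For balanced complete designs a method-of-moments estimator based on expected
mean squares (:func:`anova_mom_ncii`) is provided as well; on balanced data
in the interior of the parameter space it coincides with REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MatingDesign, PhenotypeTable
from .reml import reml_fit

TERM_NAMES = [
    "sigma2_gca_l",
    "sigma2_gca_t",
    "sigma2_sca",
    "sigma2_gca_l_x_e",
    "sigma2_gca_t_x_e",
    "sigma2_sca_x_e",
    "sigma2_eps",
]


@dataclass
class VarianceComponents:
    """Variance components of the NC-II mixed model plus design constants.

    ``t``, ``r`` and ``e`` are the numbers of testers, replicates and
    environments; they enter the GCA-heritability denominator.
    """

    sigma2_gca_l: float
    sigma2_gca_t: float
    sigma2_sca: float
    sigma2_gca_l_x_e: float
    sigma2_gca_t_x_e: float
    sigma2_sca_x_e: float
    sigma2_eps: float
    t: int = 1
    r: int = 1
    e: int = 1
    se: dict = field(default_factory=dict)
    truncated: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in TERM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.t, self.r, self.e) < 1:
            raise ValueError("design constants t, r, e must be >= 1")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in TERM_NAMES}


@dataclass
class GCATable:
    """BLUP combining-ability effects and entry-mean BLUEs for one trait."""

    gca_lines: pd.Series
    gca_testers: pd.Series
    sca: pd.Series
    blues: pd.Series


def _factor(values) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(np.asarray(values), sort=True)
    return codes, list(levels)


def _equality_structure(codes: np.ndarray) -> np.ndarray:
    """Z Z' for a grouping factor: 1 where two rows share a level."""
    return (codes[:, None] == codes[None, :]).astype(float)


def _fixed_design(env_codes, rep_codes, n_envs):
    """Intercept + env dummies + replicate-within-environment dummies."""
    n = len(env_codes)
    cols = [np.ones(n)]
    for k in range(1, n_envs):
        cols.append((env_codes == k).astype(float))
    # replicates nested in environment, first replicate as reference
    pair = env_codes * (rep_codes.max() + 1) + rep_codes
    for p in np.unique(pair):
        if p % (rep_codes.max() + 1) == 0:
            continue
        cols.append((pair == p).astype(float))
    X = np.column_stack(cols)
    # drop any collinear columns (single-replicate layouts)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10
    return X[:, keep]


def fit_ncii(
    pheno: PhenotypeTable, design: MatingDesign, trait: str
) -> tuple[VarianceComponents, GCATable]:
    """Fit the NC-II mixed model by REML and back-solve BLUP effects.

    Environment and replicate are fixed; GCA, SCA and their environment
    interactions are random.  With a single environment the interaction terms
    are dropped (they are not identifiable) with a warning.  Negative
    component estimates are truncated at zero and flagged in
    ``VarianceComponents.truncated``.
    """
    df = pheno.data
    if trait not in pheno.traits:
        raise KeyError(f"unknown trait {trait!r}")
    unmatched = set(df["hybrid"]) - set(design.hybrids)
    if unmatched:
        raise ValueError(f"phenotyped hybrids missing from design: {sorted(unmatched)[:5]}")
    if len(design.lines) < 2 or len(design.testers) < 2:
        raise ValueError("NC-II analysis needs at least 2 lines and 2 testers")

    parent = design.table.set_index("hybrid")
    lines = parent.loc[df["hybrid"], "line"].to_numpy()
    testers = parent.loc[df["hybrid"], "tester"].to_numpy()
    y = df[trait].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if not ok.all():
        df = df.loc[ok]
        lines, testers, y = lines[ok], testers[ok], y[ok]

    line_codes, line_levels = _factor(lines)
    tester_codes, tester_levels = _factor(testers)
    hyb_codes, hyb_levels = _factor(df["hybrid"])
    env_codes, env_levels = _factor(df["env"])
    rep_codes, _ = _factor(df["rep"])
    n_envs = len(env_levels)

    X = _fixed_design(env_codes, rep_codes, n_envs)

    term_codes = [line_codes, tester_codes, hyb_codes]
    active = TERM_NAMES[:3]
    if n_envs >= 2:
        le = line_codes * n_envs + env_codes
        te = tester_codes * n_envs + env_codes
        se_ = hyb_codes * n_envs + env_codes
        term_codes += [le, te, se_]
        active = TERM_NAMES[:6]
    else:
        warnings.warn(
            "single environment: GCA×E, SCA×E terms dropped (not identifiable)",
            stacklevel=2,
        )

    structures = [_equality_structure(c) for c in term_codes]
    res = reml_fit(y, X, structures)

    values = dict.fromkeys(TERM_NAMES, 0.0)
    ses = dict.fromkeys(TERM_NAMES, float("nan"))
    trunc = dict.fromkeys(TERM_NAMES, False)
    for i, name in enumerate(active):
        values[name] = float(res.sigma2[i])
        ses[name] = float(res.se[i])
        trunc[name] = bool(res.truncated[i])
    values["sigma2_eps"] = float(res.sigma2[-1])
    ses["sigma2_eps"] = float(res.se[-1])
    trunc["sigma2_eps"] = bool(res.truncated[-1])

    vc = VarianceComponents(
        **values,
        t=len(tester_levels),
        r=int(pd.Series(rep_codes).nunique()),
        e=n_envs,
        se=ses,
        truncated=trunc,
    )

    # BLUP effects: u_hat_k = sigma2_k Z_k' P y, aggregated per level
    def blup(codes, levels, sigma2):
        raw = np.bincount(codes, weights=res.Py, minlength=len(levels))
        return pd.Series(sigma2 * raw, index=levels)

    table = GCATable(
        gca_lines=blup(line_codes, line_levels, values["sigma2_gca_l"]),
        gca_testers=blup(tester_codes, tester_levels, values["sigma2_gca_t"]),
        sca=blup(hyb_codes, hyb_levels, values["sigma2_sca"]),
        blues=blues(pheno, trait),
    )
    return vc, table


def gca_heritability(vc: VarianceComponents) -> float:
    """Heritability of GCA effects on the line-mean basis.

    H2_GCA = (s2_GCA_L + s2_GCA_T) /
             (s2_GCA_L + s2_GCA_T + s2_SCA/t + s2_GCA_L×E/e + s2_GCA_T×E/e
              + s2_SCA×E/(t e) + s2_eps/(t e r))
    """
    t, r, e = vc.t, vc.r, vc.e
    num = vc.sigma2_gca_l + vc.sigma2_gca_t
    den = (
        num
        + vc.sigma2_sca / t
        + vc.sigma2_gca_l_x_e / e
        + vc.sigma2_gca_t_x_e / e
        + vc.sigma2_sca_x_e / (t * e)
        + vc.sigma2_eps / (t * e * r)
    )
    if den == 0:
        return float("nan")
    return num / den


def entry_heritability(pheno: PhenotypeTable, trait: str) -> float:
    """Entry-mean (hybrid-mean) heritability.

    Fits y = mu + E + R(E) + G + G×E + eps with the hybrid term G random and
    returns s2_G / (s2_G + s2_GE/e + s2_eps/(e r)).
    """
    df = pheno.data
    if trait not in pheno.traits:
        raise KeyError(f"unknown trait {trait!r}")
    y = df[trait].to_numpy(dtype=float)
    hyb_codes, _ = _factor(df["hybrid"])
    env_codes, env_levels = _factor(df["env"])
    rep_codes, rep_levels = _factor(df["rep"])
    e, r = len(env_levels), len(rep_levels)
    if e * r < 2:
        raise ValueError("entry-mean heritability needs replication (>=2 obs/hybrid)")

    X = _fixed_design(env_codes, rep_codes, e)
    structures = [_equality_structure(hyb_codes)]
    if e >= 2:
        structures.append(_equality_structure(hyb_codes * e + env_codes))
    res = reml_fit(y, X, structures)
    s2_g = res.sigma2[0]
    s2_ge = res.sigma2[1] if e >= 2 else 0.0
    s2_eps = res.sigma2[-1]
    den = s2_g + s2_ge / e + s2_eps / (e * r)
    if den == 0:
        return float("nan")
    return float(min(max(s2_g / den, 0.0), 1.0))


def _check_connected(df: pd.DataFrame) -> None:
    """Hybrids and environments must form one connected layout for BLUEs."""
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for h, env in zip(df["hybrid"], df["env"]):
        a, b = find(("h", h)), find(("e", env))
        if a != b:
            parent[a] = b
    roots = {find(("h", h)) for h in df["hybrid"].unique()}
    if len(roots) > 1:
        raise ValueError(
            f"hybrid/environment layout is disconnected ({len(roots)} components)"
        )


def blues(pheno: PhenotypeTable, trait: str) -> pd.Series:
    """Entry-mean BLUEs from the fixed model y = mu + env + rep(env) + hybrid.

    Environment and replicate effects use sum-to-zero contrasts, so on
    balanced data the BLUE equals the hybrid's raw mean; on unbalanced data it
    is the least-squares adjusted mean.
    """
    df = pheno.data
    if trait not in pheno.traits:
        raise KeyError(f"unknown trait {trait!r}")
    y = df[trait].to_numpy(dtype=float)
    _check_connected(df)
    hyb_codes, hyb_levels = _factor(df["hybrid"])
    env_codes, env_levels = _factor(df["env"])
    rep_codes, rep_levels = _factor(df["rep"])
    e, r = len(env_levels), len(rep_levels)
    n, h = len(y), len(hyb_levels)

    cols = []
    # sum-to-zero environment contrasts
    for k in range(e - 1):
        c = np.zeros(n)
        c[env_codes == k] = 1.0
        c[env_codes == e - 1] = -1.0
        cols.append(c)
    # sum-to-zero replicate-within-environment contrasts
    for k in range(e):
        for j in range(r - 1):
            c = np.zeros(n)
            c[(env_codes == k) & (rep_codes == j)] = 1.0
            c[(env_codes == k) & (rep_codes == r - 1)] = -1.0
            cols.append(c)
    H = np.zeros((n, h))
    H[np.arange(n), hyb_codes] = 1.0
    X = np.column_stack([H] + cols) if cols else H
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(coef[:h], index=list(hyb_levels))


def anova_mom_ncii(
    pheno: PhenotypeTable, design: MatingDesign, trait: str
) -> VarianceComponents:
    """Expected-mean-squares (method-of-moments) estimator for balanced
    complete NC-II layouts.

    Closed-form ANOVA estimator; serves as an independent cross-check of the
    iterative REML fit, with which it agrees on balanced data whenever the
    solution is interior.  Estimates are not truncated.
    """
    df = pheno.data.copy()
    parent = design.table.set_index("hybrid")
    df["line"] = parent.loc[df["hybrid"], "line"].to_numpy()
    df["tester"] = parent.loc[df["hybrid"], "tester"].to_numpy()
    l = df["line"].nunique()
    t = df["tester"].nunique()
    e = df["env"].nunique()
    r = df["rep"].nunique()
    if len(df) != l * t * e * r:
        raise ValueError("method-of-moments estimator requires a balanced complete layout")
    y = df[trait].to_numpy(dtype=float)

    def mean_over(*by):
        return df.groupby(list(by), sort=True)[trait].mean()

    g = float(y.mean())
    m_l = mean_over("line") - g
    m_t = mean_over("tester") - g
    m_e = mean_over("env") - g
    m_lt = mean_over("line", "tester")
    m_le = mean_over("line", "env")
    m_te = mean_over("tester", "env")
    m_lte = mean_over("line", "tester", "env")
    m_re = mean_over("env", "rep")

    ss_l = r * t * e * float((m_l**2).sum())
    ss_t = r * l * e * float((m_t**2).sum())
    lt_dev = m_lt - m_l.reindex(m_lt.index.get_level_values(0)).to_numpy() \
        - m_t.reindex(m_lt.index.get_level_values(1)).to_numpy() - g
    ss_lt = r * e * float((lt_dev**2).sum())
    le_dev = m_le - m_l.reindex(m_le.index.get_level_values(0)).to_numpy() \
        - m_e.reindex(m_le.index.get_level_values(1)).to_numpy() - g
    ss_le = r * t * float((le_dev**2).sum())
    te_dev = m_te - m_t.reindex(m_te.index.get_level_values(0)).to_numpy() \
        - m_e.reindex(m_te.index.get_level_values(1)).to_numpy() - g
    ss_te = r * l * float((te_dev**2).sum())

    lte = m_lte.reset_index()
    lte_dev = (
        m_lte.to_numpy()
        - m_lt.loc[list(zip(lte["line"], lte["tester"]))].to_numpy()
        - m_le.loc[list(zip(lte["line"], lte["env"]))].to_numpy()
        - m_te.loc[list(zip(lte["tester"], lte["env"]))].to_numpy()
        + m_l.loc[lte["line"]].to_numpy() + g
        + m_t.loc[lte["tester"]].to_numpy() + g
        + m_e.loc[lte["env"]].to_numpy() + g
        - g
    )
    ss_lte = r * float((lte_dev**2).sum())

    cell = m_lte.loc[list(zip(df["line"], df["tester"], df["env"]))].to_numpy()
    repm = m_re.loc[list(zip(df["env"], df["rep"]))].to_numpy()
    envm = (m_e + g).loc[df["env"]].to_numpy()
    ss_err = float(((y - cell - repm + envm) ** 2).sum())

    ms_l = ss_l / (l - 1)
    ms_t = ss_t / (t - 1)
    ms_lt = ss_lt / ((l - 1) * (t - 1))
    ms_lte = ms_le = ms_te = 0.0
    if e >= 2:
        ms_le = ss_le / ((l - 1) * (e - 1))
        ms_te = ss_te / ((t - 1) * (e - 1))
        ms_lte = ss_lte / ((l - 1) * (t - 1) * (e - 1))
    df_err = e * (r - 1) * (l * t - 1)
    ms_err = ss_err / df_err if df_err > 0 else 0.0

    s2_eps = ms_err
    if e >= 2:
        s2_lte = (ms_lte - ms_err) / r
        s2_le = (ms_le - ms_lte) / (r * t)
        s2_te = (ms_te - ms_lte) / (r * l)
        s2_lt = (ms_lt - ms_lte) / (r * e)
        s2_l = (ms_l - ms_le - ms_lt + ms_lte) / (r * t * e)
        s2_t = (ms_t - ms_te - ms_lt + ms_lte) / (r * l * e)
    else:
        s2_lte = s2_le = s2_te = 0.0
        s2_lt = (ms_lt - ms_err) / (r * e)
        s2_l = (ms_l - ms_lt) / (r * t * e)
        s2_t = (ms_t - ms_lt) / (r * l * e)

    return VarianceComponents(
        sigma2_gca_l=max(s2_l, 0.0),
        sigma2_gca_t=max(s2_t, 0.0),
        sigma2_sca=max(s2_lt, 0.0),
        sigma2_gca_l_x_e=max(s2_le, 0.0),
        sigma2_gca_t_x_e=max(s2_te, 0.0),
        sigma2_sca_x_e=max(s2_lte, 0.0),
        sigma2_eps=max(s2_eps, 0.0),
        t=t,
        r=r,
        e=e,
    )
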