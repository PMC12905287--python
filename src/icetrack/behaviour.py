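"""Behaviour--environment models: logit move persistence vs covariates.

The model is a linear mixed model for logit(gamma_t) with fixed
environmental effects, a random intercept per individual (variance V), and
first-order autoregressive (AR1, coefficient phi) within-individual
residuals of variance sigma^2:

    logit(gamma_tj) = beta0 + beta' x_tj + V_j + eps_tj,
    corr(eps_tj, eps_(t-1)j) = phi,

so the per-individual marginal covariance is V * J + sigma^2 * AR1(phi).
The AR1 index is observation order within an individual (regular-step
tracks make order and lag equivalent); optional block ids reset the
correlation across track gaps.  Likelihoods are evaluated in O(n) per
individual via the analytic AR1 whitening transform plus a Woodbury rank-1
update for the random intercept, with sigma^2 profiled out; the remaining
(variance-ratio, phi) problem is solved quasi-Newton on unconstrained
scales with restarts.  Candidate models are fitted by ML and ranked by
AICc; the winner is refitted by REML.  Fixed-effect p-values use the normal
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.optimize import minimize
from scipy.stats import norm

from icetrack.ssm import aicc as _aicc

__all__ = [
    "LMMFit",
    "CVReport",
    "fit_lmm_ar1",
    "select_candidates",
    "diagnostics",
    "partial_responses",
    "loocv",
]


@dataclass
class LMMFit:
    """A fitted AR1 + random-intercept linear mixed model."""

    coef: pd.DataFrame  # term, coef, se, p
    phi: float
    re_variance: float  # V (random-intercept variance)
    resid_variance: float  # sigma^2
    loglik: float
    aicc: float
    mode: str  # "ml" or "reml"
    converged: bool
    names: list
    formula: str | None = None
    meta: dict = field(default_factory=dict)
    _data: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> np.ndarray:
        return self.coef["coef"].to_numpy()

    @property
    def cov_params(self) -> np.ndarray:
        return self._data["cov_beta"]


def _group_blocks(groups, blocks):
    """Indices per individual and AR1 block boundaries within each."""
    groups = np.asarray(groups)
    if blocks is None:
        blocks = groups
    blocks = np.asarray(blocks)
    out = []
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        bl = blocks[idx]
        # contiguous runs of equal block id
        cuts = np.flatnonzero(bl[1:] != bl[:-1]) + 1
        bounds = np.concatenate([[0], cuts, [len(idx)]])
        out.append((g, idx, bounds))
    return out


def _whiten_ar1(a: np.ndarray, phi: float, bounds: np.ndarray) -> np.ndarray:
    """Apply W with W R(phi) W' = I per AR1 block (columns independently)."""
    z = a.astype(float).copy()
    c = np.sqrt(1.0 - phi * phi)
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if hi - lo > 1:
            z[lo + 1 : hi] = (a[lo + 1 : hi] - phi * a[lo : hi - 1]) / c
    return z


def _profiled_nll(theta, y, X, info, mode, out=None):
    """Negative log-likelihood with sigma^2 profiled out.

    theta = (log rho, z) with V = rho * sigma^2 and phi = tanh(z).
    """
    rho = np.exp(theta[0])
    phi = np.tanh(theta[1])
    N, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdet = 0.0
    cache = []
    for g, idx, bounds in info:
        Xg = _whiten_ar1(X[idx], phi, bounds)
        yg = _whiten_ar1(y[idx], phi, bounds)
        ug = _whiten_ar1(np.ones((len(idx), 1)), phi, bounds)[:, 0]
        s = ug @ ug
        alpha = rho / (1.0 + rho * s)
        # C^{-1} = I - alpha u u' (C = R + rho 11' whitened); logdet C:
        n_g = len(idx)
        nblocks = len(bounds) - 1
        logdet += (n_g - nblocks) * np.log(1.0 - phi * phi) + np.log(1.0 + rho * s)
        Xu = Xg.T @ ug
        yu = yg @ ug
        A += Xg.T @ Xg - alpha * np.outer(Xu, Xu)
        b += Xg.T @ yg - alpha * Xu * yu
        cache.append((Xg, yg, ug, alpha, Xu, yu))
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return 1e12
    Q = 0.0
    for Xg, yg, ug, alpha, Xu, yu in cache:
        r = yg - Xg @ beta
        ru = yu - Xu @ beta
        Q += r @ r - alpha * ru * ru
    if Q <= 0:
        return 1e12
    if mode == "ml":
        s2 = Q / N
        nll = 0.5 * (N * np.log(2.0 * np.pi) + N * np.log(s2) + logdet + N)
    else:  # REML
        s2 = Q / (N - p)
        sign, ld_A = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        nll = 0.5 * (
            (N - p) * np.log(2.0 * np.pi)
            + (N - p) * np.log(s2)
            + logdet
            + ld_A
            + (N - p)
        )
    if out is not None:
        out["beta"] = beta
        out["sigma2"] = s2
        out["V"] = rho * s2
        out["phi"] = phi
        out["cov_beta"] = s2 * np.linalg.inv(A)
    return nll if np.isfinite(nll) else 1e12


def fit_lmm_ar1(
    y,
    X,
    groups,
    blocks=None,
    mode: str = "ml",
    names: list | None = None,
    formula: str | None = None,
    n_restarts: int = 3,
) -> LMMFit:
    """Fit the AR1 + random-intercept LMM by (RE)ML.

    ``X`` may be a DataFrame (column names kept) or an array; an intercept
    column is expected to be part of ``X``.  Individuals with fewer than 3
    observations are excluded with a warning.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    if blocks is not None:
        blocks = np.asarray(blocks)

    sizes = pd.Series(groups).value_counts()
    tiny = sizes[sizes < 3].index
    if len(tiny):
        warnings.warn(f"excluding {len(tiny)} individual(s) with < 3 observations")
        keep = ~pd.Series(groups).isin(tiny).to_numpy()
        y, X, groups = y[keep], X[keep], groups[keep]
        blocks = blocks[keep] if blocks is not None else None

    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(
            f"design matrix is numerically rank-deficient (condition {cond:.2e}); "
            "check covariate coverage (e.g. spline columns outside the knot span)"
        )
    info = _group_blocks(groups, blocks)
    starts = [np.array([np.log(0.2), np.arctanh(0.3)])]
    rng = default_rng(0)
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(starts[0] + rng.normal(0, 1.0, 2))
    best = None
    for s in starts:
        res = minimize(
            _profiled_nll,
            s,
            args=(y, X, info, mode),
            method="L-BFGS-B",
            bounds=[(np.log(1e-10), np.log(1e6)), (np.arctanh(-0.999), np.arctanh(0.999))],
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    out = {}
    nll = _profiled_nll(best.x, y, X, info, mode, out=out)
    se = np.sqrt(np.diag(out["cov_beta"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * norm.sf(np.abs(out["beta"] / se))
    coef = pd.DataFrame({"term": names, "coef": out["beta"], "se": se, "p": p})
    k = X.shape[1] + 3  # fixed effects + phi + two variances
    ll = -float(nll)
    fit = LMMFit(
        coef=coef,
        phi=float(out["phi"]),
        re_variance=float(out["V"]),
        resid_variance=float(out["sigma2"]),
        loglik=ll,
        aicc=_aicc(ll, k, len(y)),
        mode=mode,
        converged=bool(best.success),
        names=names,
        formula=formula,
        _data={"y": y, "X": X, "groups": groups, "blocks": blocks, "cov_beta": out["cov_beta"]},
    )
    return fit


def select_candidates(
    data: pd.DataFrame,
    formulas: list[str],
    response: str,
    group_col: str,
    block_col: str | None = None,
) -> tuple[LMMFit, pd.DataFrame]:
    """Fit candidate fixed-effect formulas by ML, rank by AICc, refit the
    winner by REML.

    Formulas are patsy right-hand sides evaluated against ``data``.  Returns
    the REML-refitted best model and a ranking table that also reports, per
    covariate, the size of the top AICc-consecutive run of models containing
    it (``in_best``).
    """
    from patsy import dmatrix

    if len(formulas) < 2:
        raise ValueError("need at least 2 candidate formulas")
    fits = []
    for f in formulas:
        M = dmatrix(f, data, return_type="dataframe")
        try:
            fit = fit_lmm_ar1(
                data[response].to_numpy(float),
                M,
                data[group_col].to_numpy(),
                blocks=data[block_col].to_numpy() if block_col else None,
                mode="ml",
                formula=f,
            )
        except Exception as exc:  # noqa: BLE001 - candidate may fail to fit
            warnings.warn(f"candidate {f!r} failed: {exc}")
            fit = None
        fits.append(fit)
    ok = [(f, fit) for f, fit in zip(formulas, fits) if fit is not None and fit.converged]
    if not ok:
        raise RuntimeError("no candidate model converged")
    ranked = sorted(ok, key=lambda t: t[1].aicc)
    rank_rows = [
        {"formula": f, "aicc": fit.aicc, "loglik": fit.loglik, "k": len(fit.names)}
        for f, fit in ranked
    ]
    ranking = pd.DataFrame(rank_rows)
    # covariate-inclusion runs: longest top-r streak containing the term
    all_terms = sorted({t for _, fit in ranked for t in fit.names if t != "Intercept"})
    runs = {}
    for term in all_terms:
        r = 0
        for _, fit in ranked:
            if term in fit.names:
                r += 1
            else:
                break
        runs[term] = r
    ranking.attrs["in_best"] = runs
    best_formula = ranked[0][0]
    M = dmatrix(best_formula, data, return_type="dataframe")
    winner = fit_lmm_ar1(
        data[response].to_numpy(float),
        M,
        data[group_col].to_numpy(),
        blocks=data[block_col].to_numpy() if block_col else None,
        mode="reml",
        formula=best_formula,
    )
    return winner, ranking


# ---------------------------------------------------------------------------
# diagnostics


def _vif(X: np.ndarray, names: list, blocks: dict | None = None) -> pd.DataFrame:
    """Variance inflation factors; column groups get the generalized VIF."""
    keep = [j for j, n in enumerate(names) if n.lower() not in ("intercept", "_intercept")]
    Z = X[:, keep]
    znames = [names[j] for j in keep]
    sd = Z.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"constant column(s): {[znames[j] for j in np.flatnonzero(sd == 0)]}")
    Zs = (Z - Z.mean(axis=0)) / sd
    R = np.atleast_2d(np.corrcoef(Zs.T))
    # exact collinearity check with offender names
    for a in range(len(znames)):
        for b in range(a + 1, len(znames)):
            if abs(R[a, b]) > 1.0 - 1e-12:
                raise ValueError(f"exactly collinear columns: {znames[a]!r} and {znames[b]!r}")
    if np.linalg.matrix_rank(R) < R.shape[0]:
        raise ValueError("rank-deficient design")
    blocks = blocks or {}
    grouped = set(c for cols in blocks.values() for c in cols)
    rows = []
    Rinv = np.linalg.inv(R)
    for j, n in enumerate(znames):
        if n in grouped:
            continue
        rows.append({"term": n, "vif": float(Rinv[j, j]), "df": 1})
    for bname, cols in blocks.items():
        ii = [znames.index(c) for c in cols if c in znames]
        if not ii:
            continue
        jj = [j for j in range(len(znames)) if j not in ii]
        det = np.linalg.det
        gvif = det(R[np.ix_(ii, ii)]) * det(R[np.ix_(jj, jj)]) / det(R)
        rows.append({"term": bname, "vif": float(gvif), "df": len(ii)})
    return pd.DataFrame(rows)


def _whitened_residuals(fit: LMMFit) -> np.ndarray:
    """Residuals whitened by the full fitted covariance (unit variance,
    uncorrelated under the model)."""
    d = fit._data
    y, X, groups, blocks = d["y"], d["X"], d["groups"], d["blocks"]
    r = y - X @ fit.params
    out = np.empty_like(r)
    phi, V, s2 = fit.phi, fit.re_variance, fit.resid_variance
    for g, idx, bounds in _group_blocks(groups, blocks):
        n_g = len(idx)
        # dense per-group covariance: s2 * blockdiag(AR1) + V
        C = np.full((n_g, n_g), V)
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            tt = np.arange(hi - lo)
            C[lo:hi, lo:hi] += s2 * phi ** np.abs(tt[:, None] - tt[None, :])
        w, U = np.linalg.eigh(C)
        out[idx] = (U / np.sqrt(np.maximum(w, 1e-12))) .T @ r[idx]
    return out


def diagnostics(fit: LMMFit, spline_blocks: dict | None = None) -> dict:
    """VIF table, whitened-residual summary, and partial responses.

    ``spline_blocks`` maps a display name to its basis column names (e.g.
    ``{"depth": ["dpth_1", ..., "dpth_4"]}``) for generalized VIFs.
    """
    if not fit.converged:
        raise ValueError("diagnostics need a converged fit")
    d = fit._data
    vif = _vif(d["X"], fit.names, spline_blocks)
    z = _whitened_residuals(fit)
    lag1 = float(np.corrcoef(z[:-1], z[1:])[0, 1]) if len(z) > 2 else np.nan
    resid = {"mean": float(z.mean()), "var": float(z.var()), "lag1_acf": lag1}
    partial = partial_responses(fit)
    return {"vif": vif, "residuals": resid, "partial_responses": partial}


def partial_responses(fit: LMMFit, n_grid: int = 50) -> pd.DataFrame:
    """Per-covariate response curves, others held at their mean.

    Returns rows (term, value, response, lo, hi); the 95 % band is the
    normal-theory band from the fixed-effect covariance.
    """
    d = fit._data
    X = d["X"]
    mean_row = X.mean(axis=0)
    rows = []
    for j, n in enumerate(fit.names):
        if n.lower() in ("intercept", "_intercept"):
            continue
        grid = np.linspace(X[:, j].min(), X[:, j].max(), n_grid)
        Xg = np.tile(mean_row, (n_grid, 1))
        Xg[:, j] = grid
        mu = Xg @ fit.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit.cov_params, Xg))
        for v, m, s in zip(grid, mu, se):
            rows.append(
                {"term": n, "value": float(v), "response": float(m),
                 "lo": float(m - 1.96 * s), "hi": float(m + 1.96 * s)}
            )
    return pd.DataFrame(rows)


@dataclass
class CVReport:
    """Leave-one-individual-out cross-validation summary."""

    table: pd.DataFrame  # term, q05, q95, trend (% refits inside full CI)
    n_refits: int
    failed: list


def loocv(fit: LMMFit) -> CVReport:
    """Leave-one-individual-out refits of a fitted model.

    Each individual is dropped in turn and the model refitted in the same
    mode; reports the 5 % and 95 % quantiles of each coefficient across
    refits and the estimated trend: the percentage of refits whose
    coefficient falls inside the full model's 95 % confidence interval.
    """
    d = fit._data
    groups = d["groups"]
    ids = pd.unique(groups)
    if len(ids) < 3:
        raise ValueError("need at least 3 individuals for leave-one-out CV")
    coefs = []
    failed = []
    for g in ids:
        keep = groups != g
        try:
            sub = fit_lmm_ar1(
                d["y"][keep],
                d["X"][keep],
                groups[keep],
                blocks=d["blocks"][keep] if d["blocks"] is not None else None,
                mode=fit.mode,
                names=fit.names,
            )
        except Exception as exc:  # noqa: BLE001
            failed.append((g, str(exc)))
            continue
        if not sub.converged:
            failed.append((g, "non-convergence"))
            continue
        coefs.append(sub.params)
    C = np.asarray(coefs)
    full = fit.params
    se = fit.coef["se"].to_numpy()
    lo, hi = full - 1.96 * se, full + 1.96 * se
    q05 = np.quantile(C, 0.05, axis=0)
    q95 = np.quantile(C, 0.95, axis=0)
    trend = 100.0 * np.mean((C >= lo) & (C <= hi), axis=0)
    table = pd.DataFrame({"term": fit.names, "q05": q05, "q95": q95, "trend": trend})
    return CVReport(table=table, n_refits=len(coefs), failed=failed)
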