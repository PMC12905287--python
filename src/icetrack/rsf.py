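"""Monte-Carlo resource-selection functions on used vs simulated tracks.

Used (predicted) locations are contrasted with available locations taken
from simulated availability tracks.  Because both are autocorrelated,
variance from a single logistic fit is unrealistically small; instead each
of the 20 retained simulated tracks per segment is randomly assigned
(without replacement) to one of 20 model datasets, each dataset pairing all
observed rows with one simulated track per segment.  Every dataset is fitted
as a logistic regression with a per-segment random intercept, and the
coefficient estimate / standard error are the mean / SD of estimates across
the 20 Monte-Carlo fits, with two-sided normal-theory p-values.  Model
selection is backward stepwise on those p-values; the depth spline block is
dropped only as a unit.

The depth covariate enters through a natural cubic spline (interior knots at
220 m, 500 m and 2,500 m; boundary knots at the data range) to capture the
strongly bimodal shelf/basin depth use.  All continuous design columns are
centered and scaled on the pooled used + available rows so coefficient
magnitudes are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "MCRSFResult",
    "natural_spline_basis",
    "build_design",
    "fit_mc_rsf",
    "backward_stepwise",
    "DEPTH_KNOTS_M",
]

DEPTH_KNOTS_M = (220.0, 500.0, 2500.0)


def natural_spline_basis(values, knots=DEPTH_KNOTS_M, boundary=None) -> np.ndarray:
    """Natural cubic regression spline basis (no intercept column).

    Cubic B-splines on the interior ``knots`` with boundary knots at the
    data range (or ``boundary``), projected onto the subspace with zero
    second derivative at both boundaries, and linear extrapolation beyond
    them.  With 3 interior knots this yields 4 columns (dpth_1..dpth_4 when
    applied to depth).  The construction is the numerically stable one used
    by standard regression-spline implementations; any natural cubic spline
    basis on the same knots spans the same function space.
    """
    from scipy.interpolate import BSpline

    x = np.asarray(values, float)
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise ValueError("need at least 2 distinct values for a spline basis")
    knots = np.asarray(knots, float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    if boundary is None:
        # data range, widened if needed so the boundary brackets the knots
        boundary = (
            min(float(np.nanmin(x)), knots[0] - 1e-6 * (knots[-1] - knots[0])),
            max(float(np.nanmax(x)), knots[-1] + 1e-6 * (knots[-1] - knots[0])),
        )
    lo, hi = boundary
    t = np.concatenate([[lo] * 4, knots, [hi] * 4])
    m = len(knots) + 4  # number of cubic B-splines

    def bmat(pts, deriv=0):
        out = np.empty((len(pts), m))
        for i in range(m):
            c = np.zeros(m)
            c[i] = 1.0
            sp = BSpline(t, c, 3, extrapolate=False)
            if deriv:
                sp = sp.derivative(deriv)
            v = sp(np.clip(pts, lo, hi))
            out[:, i] = np.nan_to_num(v)
        return out

    # null space of the boundary second-derivative constraints
    const = bmat(np.array([lo, hi]), deriv=2)  # (2, m)
    q, _ = np.linalg.qr(const.T, mode="complete")
    N = q[:, 2:]  # (m, m-2) natural subspace, includes the constant

    inside = (x >= lo) & (x <= hi)
    B = np.empty((len(x), m))
    B[inside] = bmat(x[inside])
    if np.any(~inside):  # linear extension beyond the boundary knots
        for side, edge in ((x < lo, lo), (x > hi, hi)):
            if np.any(side):
                b0 = bmat(np.array([edge]))
                b1 = bmat(np.array([edge]), deriv=1)
                B[side] = b0 + (x[side] - edge)[:, None] * b1
    basis = B @ N
    return basis[:, 1:]  # drop the intercept direction


def _standardize(col: np.ndarray):
    mu, sd = float(np.mean(col)), float(np.std(col))
    if sd == 0:
        return col - mu, (mu, 1.0)
    return (col - mu) / sd, (mu, sd)


def build_design(
    used: pd.DataFrame,
    sims: dict,
    seascape,
    depth_knots=DEPTH_KNOTS_M,
) -> tuple[pd.DataFrame, dict]:
    """Assemble standardized used/available design rows from a seascape.

    Parameters
    ----------
    used : DataFrame
        Predicted (used) locations with columns x, y, segment.
    sims : dict
        segment id -> list of simulated availability tracks, each an (n, 2)
        array or a DataFrame with x, y; each track contributes available
        rows (use = 0) under the same segment id, tagged with its index.
    seascape : SeascapeStack
        Source of the covariates depth, sst, ice, dist_ice_edge.

    Returns
    -------
    (design, scaling)
        ``design`` has use, segment, sim and columns dpth_1..dpth_4, sst,
        in_ice, ice, ice_sq.  Standardization is pooled over all rows and
        recorded in ``scaling``; ice_sq is the square of the standardized
        ice column, itself standardized.  in_ice (1 inside the ice edge,
        i.e. negative signed edge distance) stays binary.
    """
    parts = [used.assign(use=1, sim=-1)[["x", "y", "segment", "use", "sim"]]]
    for seg, tracks in sims.items():
        for k, t in enumerate(tracks):
            xy = t[["x", "y"]].to_numpy(float) if isinstance(t, pd.DataFrame) else np.asarray(t, float)
            parts.append(
                pd.DataFrame(
                    {"x": xy[:, 0], "y": xy[:, 1], "segment": seg, "use": 0, "sim": k}
                )
            )
    rows = pd.concat(parts, ignore_index=True)

    x, y = rows["x"].to_numpy(float), rows["y"].to_numpy(float)
    raw = {}
    for name in ("depth", "sst", "ice", "dist_ice_edge"):
        v = seascape.sample(name, x, y)
        v = np.asarray(v, float)
        if np.isnan(v).any():  # points on (rerouted-adjacent) land cells
            mu = np.nanmean(v)
            v = np.where(np.isnan(v), mu, v)
        raw[name] = v

    scaling = {}
    spline = natural_spline_basis(raw["depth"], knots=depth_knots)
    design = {
        "use": rows["use"].to_numpy(),
        "segment": rows["segment"].to_numpy(),
        "sim": rows["sim"].to_numpy(),
        "x": x,
        "y": y,
    }
    for j in range(spline.shape[1]):
        col, sc = _standardize(spline[:, j])
        design[f"dpth_{j + 1}"] = col
        scaling[f"dpth_{j + 1}"] = sc
    col, sc = _standardize(raw["sst"])
    design["sst"] = col
    scaling["sst"] = sc
    design["in_ice"] = (raw["dist_ice_edge"] < 0).astype(float)
    ice_std, sc = _standardize(raw["ice"])
    design["ice"] = ice_std
    scaling["ice"] = sc
    ice_sq, sc = _standardize(ice_std**2)
    design["ice_sq"] = ice_sq
    scaling["ice_sq"] = sc
    scaling["depth_knots"] = tuple(depth_knots)
    scaling["depth_boundary"] = (float(np.min(raw["depth"])), float(np.max(raw["depth"])))
    return pd.DataFrame(design), scaling


# ---------------------------------------------------------------------------
# random-intercept logistic regression (Laplace approximation)


def _logistic_irls(X, y, max_iter=100, tol=1e-10):
    """Plain logistic regression by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / w
        A = X.T @ (X * w[:, None])
        beta_new = np.linalg.solve(A, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    ll = float(np.sum(y * (X @ beta) - np.logaddexp(0.0, X @ beta)))
    return beta, ll


def _laplace_nll(theta, X, y, codes, G, state):
    """Negative Laplace marginal log-likelihood for the random-intercept
    logistic model; inner Newton over group intercepts is vectorized."""
    beta = theta[:-1]
    s2 = np.exp(theta[-1])
    v = state.get("v")
    if v is None or len(v) != G:
        v = np.zeros(G)
    xb = X @ beta
    for _ in range(50):
        eta = xb + v[codes]
        p = expit(eta)
        grad = np.bincount(codes, weights=y - p, minlength=G) - v / s2
        hess = np.bincount(codes, weights=p * (1 - p), minlength=G) + 1.0 / s2
        step = grad / hess
        v = v + step
        if np.max(np.abs(step)) < 1e-10:
            break
    state["v"] = v
    eta = xb + v[codes]
    p = expit(eta)
    ll_cond = np.sum(y * eta - np.logaddexp(0.0, eta))
    hess = np.bincount(codes, weights=p * (1 - p), minlength=G) + 1.0 / s2
    ll = ll_cond - 0.5 * np.sum(v**2) / s2 - 0.5 * G * np.log(s2) - 0.5 * np.sum(np.log(hess))
    return -ll if np.isfinite(ll) else 1e12


def fit_ri_logistic(X, y, groups, random_effect: bool = True):
    """Random-intercept logistic regression via Laplace approximation.

    Falls back to a plain logistic fit when the estimated random-effect
    variance collapses (< 1e-8) or ``random_effect`` is False.  Returns
    (beta, sigma2_v, converged).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    codes, _ = pd.factorize(groups)
    G = int(codes.max()) + 1
    beta0, _ = _logistic_irls(X, y)
    if not random_effect or G < 2:
        return beta0, 0.0, True
    state = {}
    theta0 = np.concatenate([beta0, [np.log(0.5)]])
    res = minimize(
        _laplace_nll,
        theta0,
        args=(X, y, codes, G, state),
        method="L-BFGS-B",
        bounds=[(None, None)] * len(beta0) + [(np.log(1e-10), np.log(1e4))],
        options={"maxiter": 200},
    )
    beta = res.x[:-1]
    s2 = float(np.exp(res.x[-1]))
    if s2 < 1e-8:
        return beta0, 0.0, True
    return beta, s2, bool(res.success)


@dataclass
class MCRSFResult:
    """Aggregated Monte-Carlo RSF estimates."""

    table: pd.DataFrame  # covariate, coef, se, ci_lo, ci_hi, p
    per_fit: pd.DataFrame  # n_fits x covariates
    re_variance: np.ndarray
    covariates: list
    n_fits: int
    seed: int
    dropped: list = field(default_factory=list)  # stepwise history


def fit_mc_rsf(
    design: pd.DataFrame,
    covariates: list[str] | None = None,
    n_fits: int = 20,
    seed: int = 0,
    random_effect: bool = True,
) -> MCRSFResult:
    """Monte-Carlo aggregation of random-assignment logistic fits.

    Each of ``n_fits`` datasets pairs all used rows with one simulated track
    per segment, assigned by a per-segment permutation (each simulation used
    exactly once across datasets).  Coefficient = mean across fits, SE = SD
    across fits, CI = mean +/- 1.96 SE, p from a two-sided normal test.
    Fits with complete separation (exploding coefficients) are excluded with
    a warning.
    """
    if covariates is None:
        covariates = [c for c in design.columns if c not in ("use", "segment", "sim", "x", "y")]
    rng = default_rng(seed)
    used = design[design["use"] == 1]
    avail = design[design["use"] == 0]
    seg_ids = sorted(used["segment"].unique(), key=str)
    perms = {}
    for seg in seg_ids:
        sims = np.sort(avail.loc[avail["segment"] == seg, "sim"].unique())
        if len(sims) != n_fits:
            raise ValueError(
                f"segment {seg!r} has {len(sims)} simulated tracks, expected {n_fits}"
            )
        perms[seg] = rng.permutation(sims)

    cols = ["_intercept"] + list(covariates)
    coefs = []
    re_vars = []
    for f in range(n_fits):
        pieces = [used]
        for seg in seg_ids:
            pick = perms[seg][f]
            pieces.append(avail[(avail["segment"] == seg) & (avail["sim"] == pick)])
        dat = pd.concat(pieces, ignore_index=True)
        X = np.column_stack([np.ones(len(dat))] + [dat[c].to_numpy(float) for c in covariates])
        y = dat["use"].to_numpy(float)
        beta, s2, ok = fit_ri_logistic(X, y, dat["segment"].to_numpy(), random_effect)
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30.0:
            warnings.warn(f"Monte-Carlo fit {f} shows separation; excluded from aggregation")
            continue
        coefs.append(beta)
        re_vars.append(s2)
    if not coefs:
        raise RuntimeError("all Monte-Carlo fits failed")
    per_fit = pd.DataFrame(coefs, columns=cols)
    mean = per_fit.mean(axis=0)
    sd = per_fit.std(axis=0, ddof=1)
    if np.any(sd.to_numpy() == 0):
        warnings.warn("degenerate aggregation: zero SD across Monte-Carlo fits; p undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = mean / sd
        p = 2.0 * norm.sf(np.abs(z))
    p = np.where(sd.to_numpy() == 0, np.nan, p)
    table = pd.DataFrame(
        {
            "covariate": cols,
            "coef": mean.to_numpy(),
            "se": sd.to_numpy(),
            "ci_lo": mean.to_numpy() - 1.96 * sd.to_numpy(),
            "ci_hi": mean.to_numpy() + 1.96 * sd.to_numpy(),
            "p": p,
        }
    )
    return MCRSFResult(
        table=table,
        per_fit=per_fit,
        re_variance=np.asarray(re_vars),
        covariates=list(covariates),
        n_fits=n_fits,
        seed=seed,
    )


def _terms(covariates: list[str]) -> list[tuple[str, list[str]]]:
    """Group covariates into stepwise terms; the depth spline block is one
    term."""
    spline = [c for c in covariates if c.startswith("dpth_")]
    terms = []
    seen_spline = False
    for c in covariates:
        if c.startswith("dpth_"):
            if not seen_spline:
                terms.append(("depth", spline))
                seen_spline = True
        else:
            terms.append((c, [c]))
    return terms


def backward_stepwise(
    design: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    n_fits: int = 20,
    seed: int = 0,
    random_effect: bool = True,
) -> MCRSFResult:
    """Backward stepwise selection on Monte-Carlo p-values.

    At each pass the term with the largest p above ``alpha`` is dropped (the
    spline block only if all of its columns exceed ``alpha``; its ordering
    p is then the block minimum) and the full Monte-Carlo procedure is
    refitted with fresh random assignment under a derived seed.  Ties drop
    the later term in declaration order.
    """
    if covariates is None:
        covariates = [c for c in design.columns if c not in ("use", "segment", "sim", "x", "y")]
    current = list(covariates)
    dropped = []
    it = 0
    while True:
        result = fit_mc_rsf(design, current, n_fits=n_fits, seed=seed + it, random_effect=random_effect)
        pvals = result.table.set_index("covariate")["p"]
        worst_name, worst_p = None, alpha
        for name, cols in _terms(current):
            ps = pvals.loc[cols]
            if bool((ps > alpha).all()):
                term_p = float(ps.min()) if len(cols) > 1 else float(ps.iloc[0])
                if term_p >= worst_p:  # >= so later declaration wins ties
                    worst_name, worst_p = (name, cols), term_p
        if worst_name is None:
            result.dropped = dropped
            return result
        name, cols = worst_name
        dropped.append({"term": name, "p": worst_p, "iteration": it})
        current = [c for c in current if c not in cols]
        it += 1
        if not current:
            warnings.warn("all covariates dropped; returning intercept-only model")
            result = fit_mc_rsf(design, [], n_fits=n_fits, seed=seed + it, random_effect=random_effect)
            result.dropped = dropped
            return result
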