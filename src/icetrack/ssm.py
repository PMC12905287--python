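"""Continuous-time state-space models for error-prone, irregular fixes.

Two process models are supported, both linear-Gaussian and discretized
exactly for arbitrary time intervals:

* ``rw`` — Brownian position: per-axis diffusion variance ``sigma2``
  (m^2 / h), transition x_{t+dt} = x_t + N(0, sigma2 * dt).
* ``crw`` — continuous-time correlated random walk: position integrates an
  Ornstein--Uhlenbeck velocity, dv = -beta * v dt + sigma dW, with reversion
  rate ``beta`` (1/h) and velocity noise rate ``sigma2`` (m^2 / h^3) shared
  across axes.  The velocity autocorrelation over a step dt is exp(-beta dt).

Each fix carries its own observation covariance, built from the Argos error
ellipse (rotated to grid axes) when available, or from a per-class isotropic
fallback.  Maximum-likelihood parameters come from a quasi-Newton search on
log scales with restarts; states are smoothed by fixed-interval (RTS)
smoothing.  Standardized Kalman innovations serve as one-step-ahead
prediction residuals (OSAR) for diagnostics, and fits are compared by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.optimize import minimize

from icetrack.prep import TrackSegment
from icetrack.proj import unproject

__all__ = [
    "SSMFit",
    "SimulatedTrackSet",
    "fit_ssm",
    "predict_regular",
    "validate_and_select",
    "simulate_and_filter",
    "reroute",
    "aicc",
    "observation_covariances",
    "CLASS_FALLBACK_SD_M",
]

#: Isotropic 1-sigma fallback (m) per location class when no ellipse is given.
CLASS_FALLBACK_SD_M = {
    "3": 250.0,
    "2": 500.0,
    "1": 1500.0,
    "0": 4000.0,
    "A": 4000.0,
    "B": 6000.0,
    "G": 30.0,
}

POS_PRIOR_VAR = 1.0e8  # m^2 (10 km SD), vague prior on initial position
VEL_PRIOR_VAR = 2.5e7  # (m/h)^2, vague prior on initial velocity
_LOG2PI = np.log(2.0 * np.pi)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def observation_covariances(df: pd.DataFrame, fallback=CLASS_FALLBACK_SD_M) -> np.ndarray:
    """Per-fix 2x2 observation covariance (m^2).

    Kalman-filtered Argos fixes with a valid ellipse get the rotated
    elliptical covariance (orientation measured clockwise from north);
    everything else gets the isotropic class fallback.
    """
    n = len(df)
    R = np.empty((n, 2, 2))
    smaj = df.get("smaj_m", pd.Series(np.nan, index=df.index)).to_numpy(float)
    smin = df.get("smin_m", pd.Series(np.nan, index=df.index)).to_numpy(float)
    eor = df.get("eor_deg", pd.Series(0.0, index=df.index)).to_numpy(float)
    lc = df["lc"].astype(str).to_numpy()
    for i in range(n):
        a, b = smaj[i], smin[i]
        if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0 and a >= b:
            e = np.radians(eor[i])
            u = np.array([np.sin(e), np.cos(e)])  # major axis, from north CW
            v = np.array([-np.cos(e), np.sin(e)])
            R[i] = a * a * np.outer(u, u) + b * b * np.outer(v, v)
        else:
            sd = fallback.get(lc[i], fallback["B"])
            R[i] = np.diag([sd * sd, sd * sd])
        if np.linalg.det(R[i]) <= 0:
            raise ValueError(f"singular observation covariance at fix {i}")
    return R


# ---------------------------------------------------------------------------
# process models


def _rw_FQ(dt: np.ndarray, params):
    sx2, sy2 = params["sigma2_x"], params["sigma2_y"]
    n = len(dt)
    F = np.broadcast_to(np.eye(2), (n, 2, 2))
    Q = np.zeros((n, 2, 2))
    Q[:, 0, 0] = sx2 * dt
    Q[:, 1, 1] = sy2 * dt
    return F, Q


def _crw_FQ(dt: np.ndarray, params):
    beta, s2 = params["beta"], params["sigma2"]
    n = len(dt)
    eb = np.exp(-beta * dt)
    e2b = np.exp(-2.0 * beta * dt)
    f01 = (1.0 - eb) / beta
    qxx = s2 / beta**2 * (dt - 2.0 * (1.0 - eb) / beta + (1.0 - e2b) / (2.0 * beta))
    qxv = s2 / (2.0 * beta**2) * (1.0 - 2.0 * eb + e2b)
    qvv = s2 / (2.0 * beta) * (1.0 - e2b)
    F = np.zeros((n, 4, 4))
    Q = np.zeros((n, 4, 4))
    for ax, (ip, iv) in enumerate(((0, 1), (2, 3))):
        F[:, ip, ip] = 1.0
        F[:, ip, iv] = f01
        F[:, iv, iv] = eb
        Q[:, ip, ip] = qxx
        Q[:, ip, iv] = Q[:, iv, ip] = qxv
        Q[:, iv, iv] = qvv
    return F, Q


_MODELS = {
    "rw": {"dim": 2, "FQ": _rw_FQ, "H": np.eye(2), "k": 2},
    "crw": {
        "dim": 4,
        "FQ": _crw_FQ,
        "H": np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]]),
        "k": 2,
    },
}


def _init_state(model: str, y0: np.ndarray):
    if model == "rw":
        m0 = y0.copy()
        P0 = np.diag([POS_PRIOR_VAR, POS_PRIOR_VAR])
    else:
        m0 = np.array([y0[0], 0.0, y0[1], 0.0])
        P0 = np.diag([POS_PRIOR_VAR, VEL_PRIOR_VAR, POS_PRIOR_VAR, VEL_PRIOR_VAR])
    return m0, P0


def _kalman(model, params, times, ys, Rs, obs_mask=None, store=False):
    """Kalman filter over an (optionally partially observed) timeline.

    ``obs_mask[i]`` False means no measurement at ``times[i]`` (prediction
    point).  Returns loglik and, with ``store``, the arrays needed for RTS
    smoothing and OSAR.
    """
    spec = _MODELS[model]
    dim, H = spec["dim"], spec["H"]
    n = len(times)
    if obs_mask is None:
        obs_mask = np.ones(n, dtype=bool)
    dts = np.diff(times)
    F, Q = spec["FQ"](dts, params)

    first_obs = int(np.flatnonzero(obs_mask)[0])
    m, P = _init_state(model, ys[first_obs])
    ll = 0.0
    if store:
        mf = np.empty((n, dim))
        Pf = np.empty((n, dim, dim))
        mp = np.empty((n, dim))
        Pp = np.empty((n, dim, dim))
        osar = np.full((n, 2), np.nan)

    for i in range(n):
        if i > 0:
            Fi = F[i - 1]
            m = Fi @ m
            P = Fi @ P @ Fi.T + Q[i - 1]
        if store:
            mp[i], Pp[i] = m, P
        if obs_mask[i]:
            S = H @ P @ H.T + Rs[i]
            det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
            if det <= 0 or not np.isfinite(det):
                return (-np.inf, None) if store else -np.inf
            Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
            nu = ys[i] - H @ m
            ll += -0.5 * (2.0 * _LOG2PI + np.log(det) + nu @ Sinv @ nu)
            K = P @ H.T @ Sinv
            m = m + K @ nu
            P = P - K @ S @ K.T
            P = 0.5 * (P + P.T)
            if store:
                L = np.linalg.cholesky(S)
                osar[i] = np.linalg.solve(L, nu)
        if store:
            mf[i], Pf[i] = m, P
    if store:
        return ll, {"mf": mf, "Pf": Pf, "mp": mp, "Pp": Pp, "F": F, "osar": osar}
    return ll


def _rts_smooth(store):
    mf, Pf, mp, Pp, F = store["mf"], store["Pf"], store["mp"], store["Pp"], store["F"]
    n, dim = mf.shape
    ms = mf.copy()
    Ps = Pf.copy()
    for i in range(n - 2, -1, -1):
        Fi = F[i]
        # gain via solve on the predicted covariance at i+1
        C = Pf[i] @ Fi.T
        G = np.linalg.solve(Pp[i + 1].T, C.T).T
        ms[i] = mf[i] + G @ (ms[i + 1] - mp[i + 1])
        Ps[i] = Pf[i] + G @ (Ps[i + 1] - Pp[i + 1]) @ G.T
        Ps[i] = 0.5 * (Ps[i] + Ps[i].T)
    return ms, Ps


@dataclass
class SSMFit:
    """A fitted state-space model for one track segment."""

    model: str
    params: dict
    loglik: float
    aicc: float
    converged: bool
    segment_id: str
    animal_id: str
    t0: pd.Timestamp
    times_h: np.ndarray
    ys: np.ndarray
    Rs: np.ndarray
    smoothed_mean: np.ndarray = field(repr=False, default=None)
    smoothed_cov: np.ndarray = field(repr=False, default=None)
    osar: np.ndarray = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.times_h)

    def positions(self, means: np.ndarray) -> np.ndarray:
        """Project state means onto (x, y)."""
        H = _MODELS[self.model]["H"]
        return means @ H.T


def _nll_factory(model, times, ys, Rs):
    def unpack(theta):
        if model == "rw":
            return {"sigma2_x": np.exp(theta[0]), "sigma2_y": np.exp(theta[1])}
        return {"beta": np.exp(theta[0]), "sigma2": np.exp(theta[1])}

    def nll(theta):
        ll = _kalman(model, unpack(theta), times, ys, Rs)
        return -ll if np.isfinite(ll) else 1e12

    return nll, unpack


def _initial_theta(model, times, ys, Rs):
    dts = np.maximum(np.diff(times), 1e-6)
    dxy = np.diff(ys, axis=0)
    obs_var = np.mean(Rs[:, [0, 1], [0, 1]])
    if model == "rw":
        vx = np.median(dxy[:, 0] ** 2 / dts)
        vy = np.median(dxy[:, 1] ** 2 / dts)
        vx = max(vx - obs_var / np.median(dts), 1e2)
        vy = max(vy - obs_var / np.median(dts), 1e2)
        return np.log([vx, vy])
    beta0 = 0.2
    sp2 = np.mean((dxy[:, 0] / dts) ** 2 + (dxy[:, 1] / dts) ** 2) / 2.0
    s20 = max(2.0 * beta0 * sp2, 1e2)
    return np.log([beta0, s20])


_THETA_BOUNDS = {
    "rw": [(np.log(1e0), np.log(1e12))] * 2,
    "crw": [(np.log(1e-4), np.log(1e2)), (np.log(1e0), np.log(1e14))],
}


def fit_ssm(
    segment,
    model: str = "rw",
    fallback_sd=CLASS_FALLBACK_SD_M,
    n_restarts: int = 3,
) -> SSMFit:
    """Fit an RW or CRW state-space model to one track segment by ML.

    ``segment`` is a :class:`~icetrack.prep.TrackSegment` or a fix DataFrame.
    Non-convergence is flagged on the returned fit, not raised.
    """
    if isinstance(segment, TrackSegment):
        df, seg_id, aid = segment.fixes, segment.segment_id, segment.animal_id
    else:
        df = segment
        seg_id = str(df["segment"].iloc[0]) if "segment" in df else "seg0"
        aid = str(df["id"].iloc[0]) if "id" in df else "A0"
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")

    t0 = df["timestamp"].iloc[0]
    times = (df["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    ys = df[["x", "y"]].to_numpy(float)
    Rs = observation_covariances(df, fallback_sd)

    nll, unpack = _nll_factory(model, times, ys, Rs)
    theta0 = _initial_theta(model, times, ys, Rs)
    best = None
    offsets = [0.0, 1.0, -1.0][: max(n_restarts, 1)]
    for off in offsets:
        res = minimize(
            nll,
            theta0 + off,
            method="L-BFGS-B",
            bounds=_THETA_BOUNDS[model],
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = unpack(best.x)
    converged = bool(best.success or np.isfinite(best.fun))
    ll, store = _kalman(model, params, times, ys, Rs, store=True)
    if store is None:
        return SSMFit(model, params, -np.inf, np.inf, False, seg_id, aid, t0, times, ys, Rs)
    ms, Ps = _rts_smooth(store)
    k = _MODELS[model]["k"]
    fit = SSMFit(
        model=model,
        params=params,
        loglik=float(ll),
        aicc=aicc(float(ll), k, len(times)),
        converged=converged and bool(best.success),
        segment_id=seg_id,
        animal_id=aid,
        t0=t0,
        times_h=times,
        ys=ys,
        Rs=Rs,
        smoothed_mean=ms,
        smoothed_cov=Ps,
        osar=store["osar"],
        diagnostics={"opt_message": str(best.message), "n_restarts": len(offsets)},
    )
    return fit


def _smooth_at(fit: SSMFit, extra_times: np.ndarray):
    """Smoothed state means/covs on the union of obs and ``extra_times``."""
    all_t = np.union1d(fit.times_h, extra_times)
    obs_mask = np.isin(all_t, fit.times_h)
    ys = np.zeros((len(all_t), 2))
    Rs = np.zeros((len(all_t), 2, 2))
    pos = {t: i for i, t in enumerate(fit.times_h)}
    for j, t in enumerate(all_t):
        if obs_mask[j]:
            i = pos[t]
            ys[j] = fit.ys[i]
            Rs[j] = fit.Rs[i]
    ll, store = _kalman(fit.model, fit.params, all_t, ys, Rs, obs_mask, store=True)
    ms, Ps = _rts_smooth(store)
    return all_t, obs_mask, ms, Ps


def predict_regular(fit: SSMFit, step_hours: float = 4.0) -> pd.DataFrame:
    """Smoothed locations on a regular grid anchored at the first fix.

    Returns a PredictedTrack DataFrame: id, segment, timestamp, x, y, lon,
    lat, se_x, se_y, rerouted.
    """
    if not fit.converged:
        raise ValueError(f"cannot predict from unconverged fit ({fit.segment_id})")
    t_last = fit.times_h[-1]
    grid = np.arange(0.0, t_last + 1e-9, step_hours)
    all_t, _, ms, Ps = _smooth_at(fit, grid)
    sel = np.isin(all_t, grid)
    H = _MODELS[fit.model]["H"]
    xy = ms[sel] @ H.T
    cov = np.einsum("ai,nij,bj->nab", H, Ps[sel], H)
    se = np.sqrt(np.maximum(cov[:, [0, 1], [0, 1]], 0.0))
    lon, lat = unproject(xy[:, 0], xy[:, 1])
    return pd.DataFrame(
        {
            "id": fit.animal_id,
            "segment": fit.segment_id,
            "timestamp": fit.t0 + pd.to_timedelta(all_t[sel], unit="h"),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "lon": lon,
            "lat": lat,
            "se_x": se[:, 0],
            "se_y": se[:, 1],
            "rerouted": False,
        }
    )


def _osar_stats(fit: SSMFit) -> dict:
    r = fit.osar[np.isfinite(fit.osar[:, 0])]
    r = r[1:]  # first innovation is dominated by the vague prior
    flat = r.ravel()
    ac = np.nan
    for col in range(2):
        s = r[:, col]
        if len(s) > 2 and np.std(s) > 0:
            a = np.corrcoef(s[:-1], s[1:])[0, 1]
            ac = a if np.isnan(ac) else max(ac, a)
    return {
        "mean": float(np.mean(flat)),
        "var": float(np.var(flat)),
        "lag1_acf": float(ac),
    }


def validate_and_select(
    fits: list[SSMFit],
    n_replicates: int = 100,
    seed: int = 0,
    oversmooth_margin: float = 0.1,
) -> tuple[SSMFit, dict]:
    """Choose among converged fits by AICc, with an oversmoothing guard.

    The guard prefers the RW fit whenever the CRW's one-step-ahead-residual
    lag-1 autocorrelation is worse (larger) by more than
    ``oversmooth_margin``, even at equal or better AICc.  Also attaches
    ``n_replicates`` tracks simulated from the fitted joint state
    distribution (simulation smoother) for uncertainty assessment.
    """
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fit for segment")
    diag = {}
    for f in fits:
        diag[f.model] = {"aicc": f.aicc, "converged": f.converged, "osar": _osar_stats(f)}
    chosen = min(conv, key=lambda f: f.aicc)
    by_model = {f.model: f for f in conv}
    if chosen.model == "crw" and "rw" in by_model:
        crw_ac = diag["crw"]["osar"]["lag1_acf"]
        rw_ac = diag["rw"]["osar"]["lag1_acf"]
        if np.isfinite(crw_ac) and np.isfinite(rw_ac) and crw_ac - rw_ac > oversmooth_margin:
            chosen = by_model["rw"]
            diag["oversmooth_guard"] = True
    reps = replicate_tracks(chosen, n_replicates, seed=seed)
    diag["selected"] = chosen.model
    diag["replicates"] = reps
    return chosen, diag


def _simulate_states(fit: SSMFit, times: np.ndarray, rng, start=None):
    """Unconditional draw of the state path at ``times`` (vague prior start
    unless ``start`` pins the initial position)."""
    spec = _MODELS[fit.model]
    dim = spec["dim"]
    F, Q = spec["FQ"](np.diff(times), fit.params)
    x = np.empty((len(times), dim))
    if start is None:
        m0, P0 = _init_state(fit.model, fit.ys[0])
        x[0] = rng.multivariate_normal(m0, P0)
    else:
        x[0] = start
    for i in range(1, len(times)):
        x[i] = F[i - 1] @ x[i - 1] + rng.multivariate_normal(np.zeros(dim), Q[i - 1])
    return x


def replicate_tracks(fit: SSMFit, n_replicates: int, seed: int = 0) -> np.ndarray:
    """Draws from the joint posterior of states given the data.

    Durbin--Koopman simulation smoother: draw an unconditional state/obs
    path, smooth the pseudo-observations, and recentre on the actual
    smoothed means.  Returns (n_replicates, n_obs, 2) positions.
    """
    rng = default_rng(seed)
    H = _MODELS[fit.model]["H"]
    out = np.empty((n_replicates, fit.n, 2))
    for r in range(n_replicates):
        xsim = _simulate_states(fit, fit.times_h, rng)
        ysim = np.einsum("ai,ni->na", H, xsim)
        for i in range(fit.n):
            L = np.linalg.cholesky(fit.Rs[i])
            ysim[i] += L @ rng.standard_normal(2)
        _, store = _kalman(fit.model, fit.params, fit.times_h, ysim, fit.Rs, store=True)
        ms_sim, _ = _rts_smooth(store)
        draw = fit.smoothed_mean + (xsim - ms_sim)
        out[r] = draw @ H.T
    return out


@dataclass
class SimulatedTrackSet:
    """Candidate availability tracks simulated from a fitted movement model."""

    parent_segment: str
    times_h: np.ndarray
    tracks: np.ndarray  # (n_sim, n, 2)
    scores: np.ndarray
    retained: np.ndarray  # bool


def _net_features(xy: np.ndarray):
    d = xy[-1] - xy[0]
    return np.hypot(d[0], d[1]), np.arctan2(d[1], d[0])


def simulate_and_filter(
    fit: SSMFit,
    parent_track: pd.DataFrame,
    n_sim: int = 100,
    k_keep: int = 20,
    land=None,
    seed: int = 0,
    max_tries: int = 50,
) -> SimulatedTrackSet:
    """Simulate availability tracks and keep the ``k_keep`` most similar.

    Tracks are simulated from the fitted movement process, started at the
    parent predicted track's first location with the parent's timestamps.
    With ``land`` (a callable ``land(x, y) -> bool``), steps proposing a land
    location are redrawn (barrier-aware proposal); a step that cannot leave
    land after ``max_tries`` redraws stalls in place.  Similarity is the
    negative standardized Euclidean distance in (net displacement, net
    bearing) relative to the parent; ties break by candidate index.
    """
    if k_keep > n_sim:
        raise ValueError("k_keep cannot exceed n_sim")
    rng = default_rng(seed)
    spec = _MODELS[fit.model]
    dim, H = spec["dim"], spec["H"]
    t0 = parent_track["timestamp"].iloc[0]
    times = (parent_track["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    n = len(times)
    F, Q = spec["FQ"](np.maximum(np.diff(times), 1e-9), fit.params)
    Ls = np.linalg.cholesky(Q)

    start_xy = parent_track[["x", "y"]].iloc[0].to_numpy(float)
    tracks = np.empty((n_sim, n, 2))
    for s in range(n_sim):
        x = np.empty((n, dim))
        if fit.model == "rw":
            x[0] = start_xy
        else:
            v2 = fit.params["sigma2"] / (2.0 * fit.params["beta"])
            v = rng.normal(0.0, np.sqrt(v2), size=2)
            x[0] = [start_xy[0], v[0], start_xy[1], v[1]]
        for i in range(1, n):
            base = F[i - 1] @ x[i - 1]
            ok = False
            for _ in range(max_tries):
                cand = base + Ls[i - 1] @ rng.standard_normal(dim)
                pos = H @ cand
                if land is None or not land(pos[0], pos[1]):
                    x[i] = cand
                    ok = True
                    break
            if not ok:  # stall: hold position, damp velocity
                x[i] = x[i - 1]
                if fit.model == "crw":
                    x[i][1] *= -0.5
                    x[i][3] *= -0.5
        tracks[s] = x @ H.T

    pd_, pb = _net_features(parent_track[["x", "y"]].to_numpy(float))
    disp = np.array([_net_features(t)[0] for t in tracks])
    bear = np.array([_net_features(t)[1] for t in tracks])
    dbear = np.arctan2(np.sin(bear - pb), np.cos(bear - pb))
    sd_d = np.std(disp) or 1.0
    sd_b = np.std(dbear) or 1.0
    scores = -np.sqrt(((disp - pd_) / sd_d) ** 2 + (dbear / sd_b) ** 2)
    order = np.argsort(-scores, kind="stable")  # ties -> first index wins
    retained = np.zeros(n_sim, dtype=bool)
    retained[order[:k_keep]] = True
    return SimulatedTrackSet(fit.segment_id, times, tracks, scores, retained)


def reroute(track: pd.DataFrame, land_polygons, buffer_m: float = 10_000.0) -> pd.DataFrame:
    """Move points off land, ignoring a coastal buffer band.

    The land geometry is eroded inward by ``buffer_m``; points inside the
    eroded polygon move to the nearest point on its boundary (the nearest
    point outside it), points in the buffer band — e.g. inside narrow fjords
    — stay put.  Sets the ``rerouted`` flag.
    """
    import shapely
    from shapely.geometry import Point
    from shapely.ops import nearest_points

    if not land_polygons.is_valid:
        raise ValueError("invalid land geometry")
    eroded = land_polygons.buffer(-buffer_m)
    out = track.copy()
    if eroded.is_empty:
        out["rerouted"] = False
        return out
    boundary = eroded.boundary
    xs = out["x"].to_numpy(float).copy()
    ys = out["y"].to_numpy(float).copy()
    flags = np.zeros(len(out), dtype=bool)
    inside = shapely.contains(eroded, shapely.points(np.c_[xs, ys]))
    for i in np.flatnonzero(inside):
        q = nearest_points(boundary, Point(xs[i], ys[i]))[0]
        xs[i], ys[i] = q.x, q.y
        flags[i] = True
    out["x"], out["y"] = xs, ys
    if flags.any():
        lon, lat = unproject(xs[flags], ys[flags])
        out.loc[flags, "lon"] = lon
        out.loc[flags, "lat"] = lat
    out["rerouted"] = flags
    return out
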