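import numpy as np
import pandas as pd
import pytest

from icetrack.seascape import generate_seascape


@pytest.fixture(scope="session")
def seascape():
    """A small deterministic seascape shared across tests."""
    return generate_seascape(nx=96, ny=96, cell=4000.0, seed=11, land_fraction=0.15)


def make_rw_track(
    n=100, sigma2=1.0e5, obs_sd=500.0, dt_h=1.0, seed=0, start=(0.0, 0.0)
):
    """Simulate a 2-D Brownian track observed with isotropic Gaussian error.

    Returns a fix DataFrame in the RawFix schema with exact (known) process
    variance ``sigma2`` (m^2/h).
    """
    rng = np.random.default_rng(seed)
    dts = np.full(n - 1, dt_h)
    pos = np.vstack(
        [start, np.cumsum(rng.normal(0, np.sqrt(sigma2 * dt_h), (n - 1, 2)), axis=0)]
    )
    pos[1:] += start
    obs = pos + rng.normal(0, obs_sd, (n, 2))
    t0 = pd.Timestamp("2021-09-01", tz="UTC")
    return pd.DataFrame(
        {
            "id": "W1",
            "segment": "s0",
            "timestamp": t0 + pd.to_timedelta(np.arange(n) * dt_h, unit="h"),
            "x": obs[:, 0],
            "y": obs[:, 1],
            "lc": "G",
            "smaj_m": obs_sd,
            "smin_m": obs_sd,
            "eor_deg": 0.0,
            "source": "gps",
        }
    )


def make_crw_track(n=200, beta=0.2, sigma2=2.0e5, obs_sd=500.0, dt_h=1.0, seed=0):
    """Simulate a CTCRW (OU-velocity) track with isotropic observation error."""
    rng = np.random.default_rng(seed)
    eb = np.exp(-beta * dt_h)
    qvv = sigma2 / (2 * beta) * (1 - np.exp(-2 * beta * dt_h))
    qxv = sigma2 / (2 * beta**2) * (1 - 2 * eb + np.exp(-2 * beta * dt_h))
    qxx = sigma2 / beta**2 * (
        dt_h - 2 * (1 - eb) / beta + (1 - np.exp(-2 * beta * dt_h)) / (2 * beta)
    )
    Q = np.array([[qxx, qxv], [qxv, qvv]])
    L = np.linalg.cholesky(Q + 1e-12 * np.eye(2))
    x = np.zeros((n, 2, 2))  # (time, axis, [pos, vel])
    x[0, :, 1] = rng.normal(0, np.sqrt(sigma2 / (2 * beta)), 2)
    F = np.array([[1.0, (1 - eb) / beta], [0.0, eb]])
    for i in range(1, n):
        for ax in range(2):
            x[i, ax] = F @ x[i - 1, ax] + L @ rng.standard_normal(2)
    obs = x[:, :, 0] + rng.normal(0, obs_sd, (n, 2))
    t0 = pd.Timestamp("2021-09-01", tz="UTC")
    return pd.DataFrame(
        {
            "id": "W1",
            "segment": "s0",
            "timestamp": t0 + pd.to_timedelta(np.arange(n) * dt_h, unit="h"),
            "x": obs[:, 0],
            "y": obs[:, 1],
            "lc": "G",
            "smaj_m": obs_sd,
            "smin_m": obs_sd,
            "eor_deg": 0.0,
            "source": "gps",
        }
    )


def joint_gaussian_oracle(model, params, times, ys, Rs):
    """Brute-force joint-Gaussian conditioning over all states at once.

    Independent of the Kalman implementation: builds the full prior
    covariance of the stacked state vector by propagating transition
    matrices, then conditions on the stacked observations.  Returns
    (smoothed_means, smoothed_covs, loglik).
    """
    from scipy.stats import multivariate_normal

    from icetrack import ssm as _ssm

    spec = _ssm._MODELS[model]
    dim, H = spec["dim"], spec["H"]
    n = len(times)
    F, Q = spec["FQ"](np.diff(times), params)
    m0, P0 = _ssm._init_state(model, ys[0])

    means = np.empty((n, dim))
    margs = np.empty((n, dim, dim))
    means[0], margs[0] = m0, P0
    for i in range(1, n):
        means[i] = F[i - 1] @ means[i - 1]
        margs[i] = F[i - 1] @ margs[i - 1] @ F[i - 1].T + Q[i - 1]
    C = np.zeros((n * dim, n * dim))
    for i in range(n):
        C[i * dim : (i + 1) * dim, i * dim : (i + 1) * dim] = margs[i]
        block = margs[i]
        for j in range(i + 1, n):
            block = block @ F[j - 1].T
            C[i * dim : (i + 1) * dim, j * dim : (j + 1) * dim] = block
            C[j * dim : (j + 1) * dim, i * dim : (i + 1) * dim] = block.T
    Hbig = np.zeros((n * 2, n * dim))
    Rbig = np.zeros((n * 2, n * 2))
    for i in range(n):
        Hbig[i * 2 : (i + 1) * 2, i * dim : (i + 1) * dim] = H
        Rbig[i * 2 : (i + 1) * 2, i * 2 : (i + 1) * 2] = Rs[i]
    mu = means.ravel()
    S = Hbig @ C @ Hbig.T + Rbig
    resid = ys.ravel() - Hbig @ mu
    K = np.linalg.solve(S.T, (C @ Hbig.T).T).T
    post_mean = (mu + K @ resid).reshape(n, dim)
    post_cov_full = C - K @ Hbig @ C
    post_covs = np.array(
        [post_cov_full[i * dim : (i + 1) * dim, i * dim : (i + 1) * dim] for i in range(n)]
    )
    ll = multivariate_normal.logpdf(ys.ravel(), mean=Hbig @ mu, cov=S)
    return post_mean, post_covs, float(ll)
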