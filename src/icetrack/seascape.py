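"""Synthetic seascapes and telemetry tracks with known ground truth.

This module builds the test bed for the whole pipeline: spatially
autocorrelated environmental covariate fields on a projected grid (depth with
a shelf/slope/basin structure, sea-surface temperature, sea-ice concentration
with a definable ice edge, sea-surface height, and derived distance layers),
a land mask, and movement tracks generated from a first-difference
correlated walk whose time-varying move persistence is driven by the
covariates through a known linear predictor plus AR1 noise.  Because every
generating parameter is recorded, downstream estimators can be checked by
parameter recovery rather than against withheld field data.

The fields are statistical stand-ins: Gaussian-smoothed noise plus
deterministic gradients.  They reproduce the shelf/slope/deep-basin and
ice-edge structure that shelf-associated Arctic whales key on, not any real
bathymetry or ice climatology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.special import expit

from icetrack.proj import unproject

__all__ = [
    "SeascapeStack",
    "SimTruth",
    "generate_seascape",
    "simulate_observed_track",
    "generate_rsf_testset",
    "ICE_EDGE_CONCENTRATION",
    "ARGOS_CLASS_SCALE_M",
]

#: Ice-edge definition: the 15 % concentration contour (community convention).
ICE_EDGE_CONCENTRATION = 0.15

#: Default 1-sigma semi-major axis scale (m) per Argos location class, plus GPS.
ARGOS_CLASS_SCALE_M = {
    "3": 250.0,
    "2": 500.0,
    "1": 1500.0,
    "0": 4000.0,
    "A": 4000.0,
    "B": 6000.0,
    "G": 30.0,
}

#: Default class mix for simulated Argos fixes (class B dominates real data).
ARGOS_CLASS_PROBS = {
    "3": 0.01,
    "2": 0.02,
    "1": 0.05,
    "0": 0.11,
    "A": 0.17,
    "B": 0.64,
}

MARINE_LAYERS = (
    "depth",
    "slope",
    "sst",
    "ice",
    "ssh",
    "dist_shelf",
    "dist_glacier",
    "dist_ice_edge",
)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SeascapeStack:
    """Co-registered covariate rasters on a projected-metre grid.

    Layers are (ny, nx) arrays indexed ``[row, col]`` with the cell centre of
    ``[0, 0]`` at ``(x0 + cell/2, y0 + cell/2)``.  Land cells hold NaN in all
    marine layers.  ``dist_ice_edge`` is signed, negative inside the ice edge.
    """

    x0: float
    y0: float
    cell: float
    layers: dict[str, np.ndarray]
    land: np.ndarray
    time_index: list | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.land.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.shape
        return (self.x0, self.x0 + nx * self.cell, self.y0, self.y0 + ny * self.cell)

    def cell_index(self, x, y):
        """Nearest-cell (row, col) for projected coordinates; errors outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = np.floor((y - self.y0) / self.cell).astype(int)
        ny, nx = self.shape
        bad = (col < 0) | (col >= nx) | (row < 0) | (row >= ny)
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))
            raise ValueError(
                f"{idx.size} location(s) outside raster extent "
                f"(first offenders at positions {idx[:5].tolist()})"
            )
        return row, col

    def sample(self, name: str, x, y):
        """Nearest-cell lookup of layer ``name`` at projected coordinates."""
        row, col = self.cell_index(x, y)
        return self.layers[name][row, col]

    def is_land(self, x, y):
        row, col = self.cell_index(x, y)
        return self.land[row, col]

    def in_bounds(self, x, y, margin_cells: int = 0) -> bool:
        """Whether a point lies inside the grid, at least ``margin_cells``
        from every edge."""
        ny, nx = self.shape
        m = margin_cells * self.cell
        return bool(
            (self.x0 + m <= x < self.x0 + nx * self.cell - m)
            and (self.y0 + m <= y < self.y0 + ny * self.cell - m)
        )

    def sea_values(self, name: str) -> np.ndarray:
        """Layer values on sea cells only (1-D)."""
        return self.layers[name][~self.land]

    def standardizer(self, names) -> dict[str, tuple[float, float]]:
        """Mean/SD per layer over sea cells, for z-scoring covariates."""
        out = {}
        for name in names:
            v = self.sea_values(name)
            out[name] = (float(np.mean(v)), float(np.std(v)))
        return out

    def to_dataset(self):
        """Export as an :class:`xarray.Dataset` (for NetCDF output)."""
        import xarray as xr

        ny, nx = self.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell
        data = {k: (("y", "x"), v) for k, v in self.layers.items()}
        data["land"] = (("y", "x"), self.land)
        return xr.Dataset(data, coords={"x": xs, "y": ys}, attrs={"cell_m": self.cell})


@dataclass
class SimTruth:
    """Ground truth for one simulated track (or used-point set)."""

    seed: int
    times: pd.DatetimeIndex | None
    path: np.ndarray | None  # (n, 2) projected metres, fine-step truth
    gamma: np.ndarray | None  # (n,) true move persistence
    behaviour_coefs: dict | None = None  # logit-gamma linear predictor
    movement: dict | None = None
    selection_beta: dict | None = None  # RSF truth, standardized-covariate scale
    scaling: dict | None = None  # covariate (mean, sd) used for standardization


def _smooth_noise(rng, shape, smoothness):
    """Unit-variance spatially autocorrelated Gaussian field."""
    z = gaussian_filter(rng.standard_normal(shape), smoothness, mode="reflect")
    s = z.std()
    return z / s if s > 0 else z


def generate_seascape(
    nx: int = 128,
    ny: int = 128,
    cell: float = 4000.0,
    seed: int = 0,
    land_fraction: float = 0.15,
    smoothness: float = 8.0,
    x0: float = 0.0,
    y0: float = -2_400_000.0,
) -> SeascapeStack:
    """Generate a synthetic covariate stack with a western coast and shelf.

    The coastline runs roughly north--south at a noisy easting chosen so the
    land-cell share matches ``land_fraction``.  Depth ramps from the coast
    across a ~200 m shelf, down a slope to a ~3,500 m basin; SST warms
    southward; ice concentration increases northward with a definable 15 %
    edge; distance layers (km) are derived by distance transforms.

    Deterministic for a given ``seed``.
    """
    if nx < 16 or ny < 16:
        raise ConfigurationError("grid must be at least 16x16")
    if not (0.0 <= land_fraction < 0.9):
        raise ConfigurationError("land_fraction must be in [0, 0.9)")
    if smoothness <= 0:
        raise ConfigurationError("smoothness must be positive")

    rng = default_rng(seed)

    # --- land mask: noisy meridional coastline with exact mean position
    coast_noise = gaussian_filter(rng.standard_normal(ny), smoothness, mode="reflect")
    cs = coast_noise.std()
    if cs > 0:
        coast_noise = coast_noise / cs
    coast_col = land_fraction * nx + 0.03 * nx * coast_noise
    coast_col = coast_col - coast_col.mean() + land_fraction * nx
    cols = np.arange(nx)[None, :]
    land = cols < coast_col[:, None]

    km = cell / 1000.0
    dist_coast_km = distance_transform_edt(~land) * km  # 0 on land

    # --- depth: shelf (to ~200 m), slope (to basin), basin plateau
    shelf_w, slope_w = 80.0, 120.0  # km
    d = dist_coast_km
    depth = np.where(
        d <= shelf_w,
        200.0 * d / shelf_w,
        np.where(
            d <= shelf_w + slope_w,
            200.0 + (3500.0 - 200.0) * (d - shelf_w) / slope_w,
            3500.0,
        ),
    )
    depth = depth + 120.0 * _smooth_noise(rng, (ny, nx), smoothness)
    depth = np.clip(depth, 0.0, None)
    depth[land] = np.nan

    # --- slope (degrees) from the depth gradient
    dfill = np.where(land, 0.0, depth)
    gy, gx = np.gradient(dfill, cell)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope[land] = np.nan

    # --- SST: meridional ramp (south warm) + noise, floored at freezing
    rows = np.arange(ny)[:, None] / max(ny - 1, 1)
    sst = 4.0 - 6.5 * rows + 0.8 * _smooth_noise(rng, (ny, nx), smoothness)
    sst = np.clip(sst, -1.9, None)
    sst = np.broadcast_to(sst, (ny, nx)).copy()
    sst[land] = np.nan

    # --- ice: northward ramp, clamped to [0, 1]
    ice = -0.35 + 1.7 * rows + 0.45 * _smooth_noise(rng, (ny, nx), smoothness)
    ice = np.clip(np.broadcast_to(ice, (ny, nx)).copy(), 0.0, 1.0)
    ice[land] = np.nan

    # --- signed distance to the ice edge (negative inside the edge)
    inside = np.where(land, True, ice >= ICE_EDGE_CONCENTRATION)
    dist_ice_edge = np.where(
        inside,
        -distance_transform_edt(inside) * km,
        distance_transform_edt(~inside) * km,
    )
    dist_ice_edge[land] = np.nan

    # --- distance to the 500 m isobath (shelf break), unsigned km
    shallow = np.where(land, True, dfill < 500.0)
    dist_shelf = np.where(
        shallow, distance_transform_edt(shallow) * km, distance_transform_edt(~shallow) * km
    )
    dist_shelf[land] = np.nan

    # --- distance to marine-terminating glacier fronts (coastal sites), km
    coast_sea = (~land) & (distance_transform_edt(~land) <= 1.5)
    rr, cc = np.nonzero(coast_sea)
    glacier = np.zeros((ny, nx), dtype=bool)
    if rr.size:
        picks = rng.choice(rr.size, size=min(3, rr.size), replace=False)
        glacier[rr[picks], cc[picks]] = True
        dist_glacier = distance_transform_edt(~glacier) * km
    else:  # no coast (land_fraction 0): measure from the western boundary
        dist_glacier = np.broadcast_to((cols + 0.5) * km, (ny, nx)).copy()
    dist_glacier[land] = np.nan

    # --- SSH: pure smoothed noise (dynamic topography stand-in), metres
    ssh = 0.12 * _smooth_noise(rng, (ny, nx), smoothness)
    ssh[land] = np.nan

    layers = {
        "depth": depth,
        "slope": slope,
        "sst": sst,
        "ice": ice,
        "ssh": ssh,
        "dist_shelf": dist_shelf,
        "dist_glacier": dist_glacier,
        "dist_ice_edge": dist_ice_edge,
    }
    return SeascapeStack(
        x0=x0,
        y0=y0,
        cell=cell,
        layers=layers,
        land=land,
        meta={
            "seed": seed,
            "land_fraction": land_fraction,
            "smoothness": smoothness,
            "glacier_cells": np.argwhere(glacier).tolist(),
        },
    )


def _draw_start(seascape: SeascapeStack, rng, min_coast_km: float = 60.0):
    """Random sea cell centre at least ``min_coast_km`` from land."""
    km = seascape.cell / 1000.0
    d = distance_transform_edt(~seascape.land) * km
    ok = np.argwhere((~seascape.land) & (d >= min_coast_km))
    if ok.size == 0:
        ok = np.argwhere(~seascape.land)
    r, c = ok[rng.integers(ok.shape[0])]
    return (
        seascape.x0 + (c + 0.5) * seascape.cell,
        seascape.y0 + (r + 0.5) * seascape.cell,
    )


def simulate_observed_track(
    seascape: SeascapeStack,
    movement: dict | None = None,
    behaviour: dict | None = None,
    obs_error: str = "argos",
    duration_days: float = 60.0,
    seed: int = 0,
    animal_id: str = "W1",
    start_xy: tuple[float, float] | None = None,
    start_time: str = "2021-08-15T00:00:00",
    thinning: dict | None = None,
    boundary_margin_cells: int = 6,
) -> tuple[SimTruth, pd.DataFrame]:
    """Simulate a fine-step track and irregular, error-perturbed observations.

    Movement is a first-difference correlated walk at a 1 h step:
    ``d_t = gamma_t * d_{t-1} + N(0, step_sd^2 I)`` with
    ``logit(gamma_t) = b0 + sum_k beta_k z_k(x_t) + e_t`` where ``z_k`` are
    covariates standardized over sea cells and ``e_t`` is AR1 noise
    (coefficient ``phi``, innovation SD ``sigma``).  Observations are thinned
    to irregular times and perturbed by class-dependent elliptical Gaussian
    error (Argos) or small circular error (GPS); ``obs_error='none'`` with
    ``thinning=None`` returns the exact fine-step path.

    Returns ``(SimTruth, fixes)`` where ``fixes`` has the raw-fix CSV schema:
    id, deployment, timestamp, lon, lat, x, y, lc, smaj_m, smin_m, eor_deg,
    source.
    """
    if duration_days < 2:
        raise ConfigurationError("duration must be at least 2 days")
    movement = {"step_sd_m": 300.0, **(movement or {})}
    behaviour = {
        "intercept": 1.2,
        "coefs": {"depth": -0.8, "ice": 0.0},
        "phi": 0.7,
        "sigma": 0.4,
        **(behaviour or {}),
    }
    rng = default_rng(seed)

    if start_xy is None:
        start_xy = _draw_start(seascape, rng)
    if seascape.is_land(*start_xy):
        raise ValueError("start location is on land")

    scaling = seascape.standardizer(behaviour["coefs"].keys())
    step_sd = movement["step_sd_m"]
    n = int(round(duration_days * 24)) + 1

    pos = np.empty((n, 2))
    gam = np.empty(n)
    pos[0] = start_xy
    theta = rng.uniform(0, 2 * np.pi)
    d_prev = 2.0 * step_sd * np.array([np.cos(theta), np.sin(theta)])
    e = rng.normal(0.0, behaviour["sigma"])

    def lin_pred(x, y):
        g = behaviour["intercept"]
        for name, b in behaviour["coefs"].items():
            mu, sd = scaling[name]
            v = seascape.sample(name, x, y)
            if np.isnan(v):
                v = mu
            g += b * (v - mu) / (sd if sd > 0 else 1.0)
        return g

    gam[0] = expit(lin_pred(*pos[0]) + e)
    for t in range(1, n):
        e = behaviour["phi"] * e + rng.normal(0.0, behaviour["sigma"])
        g_t = expit(lin_pred(*pos[t - 1]) + e)
        step = None
        for _ in range(30):
            cand = g_t * d_prev + rng.normal(0.0, step_sd, size=2)
            new = pos[t - 1] + cand
            if _at_sea(seascape, new, boundary_margin_cells):
                step = cand
                break
        if step is None:  # bounce back toward open water
            step = -0.5 * d_prev
            new = pos[t - 1] + step
            if not _at_sea(seascape, new, boundary_margin_cells):
                new = pos[t - 1]
                step = np.zeros(2)
        pos[t] = new
        d_prev = step if np.any(step) else d_prev
        gam[t] = g_t

    times = pd.date_range(start_time, periods=n, freq="1h", tz="UTC")
    truth = SimTruth(
        seed=seed,
        times=times,
        path=pos,
        gamma=gam,
        behaviour_coefs=dict(behaviour),
        movement=dict(movement),
        scaling=scaling,
    )

    # --- observation process
    if thinning is None and obs_error == "none":
        obs_idx = np.arange(n)
    else:
        thin = {"mean_interval_h": 1.5, "gap_prob": 0.01, "gap_hours": (12.0, 48.0)}
        thin.update(thinning or {})
        obs_idx = [0]
        t = 0.0
        while True:
            dt = rng.exponential(thin["mean_interval_h"])
            if rng.uniform() < thin["gap_prob"]:
                dt += rng.uniform(*thin["gap_hours"])
            t += max(dt, 1e-6)
            i = int(round(t))
            if i >= n:
                break
            if i != obs_idx[-1]:
                obs_idx.append(i)
        obs_idx = np.asarray(obs_idx)

    rows = []
    class_names = list(ARGOS_CLASS_PROBS)
    class_p = np.array([ARGOS_CLASS_PROBS[c] for c in class_names])
    class_p = class_p / class_p.sum()
    scales = dict(ARGOS_CLASS_SCALE_M)
    scales.update(movement.get("class_scale_m", {}))
    gps_frac = movement.get("gps_fraction", 0.002)

    for i in obs_idx:
        x, y = pos[i]
        if obs_error == "none":
            lc, smaj, smin, eor, src = "G", 0.0, 0.0, 0.0, "gps"
        elif obs_error == "gps" or rng.uniform() < gps_frac:
            lc, src = "G", "gps"
            smaj = smin = scales["G"]
            eor = 0.0
            x, y = x + rng.normal(0, smaj), y + rng.normal(0, smaj)
        else:
            lc = class_names[rng.choice(len(class_names), p=class_p)]
            src = "argos_kf"
            smaj = rng.gamma(4.0, scales[lc] / 4.0)  # mean = class scale
            smin = smaj * rng.uniform(0.3, 0.8)
            eor = rng.uniform(0.0, 180.0)
            th = np.radians(90.0 - eor)  # orientation measured from north
            u = np.array([np.cos(th), np.sin(th)])
            v = np.array([-np.sin(th), np.cos(th)])
            off = smaj * rng.standard_normal() * u + smin * rng.standard_normal() * v
            x, y = x + off[0], y + off[1]
        lon, lat = unproject(x, y)
        rows.append(
            (animal_id, f"{animal_id}-d1", times[i], float(lon), float(lat), x, y, lc, smaj, smin, eor, src)
        )

    fixes = pd.DataFrame(
        rows,
        columns=[
            "id",
            "deployment",
            "timestamp",
            "lon",
            "lat",
            "x",
            "y",
            "lc",
            "smaj_m",
            "smin_m",
            "eor_deg",
            "source",
        ],
    )
    return truth, fixes


def land_polygons(seascape: SeascapeStack):
    """Dissolve the land mask into a shapely geometry (cell squares)."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    cells = [
        box(
            seascape.x0 + c * seascape.cell,
            seascape.y0 + r * seascape.cell,
            seascape.x0 + (c + 1) * seascape.cell,
            seascape.y0 + (r + 1) * seascape.cell,
        )
        for r, c in np.argwhere(seascape.land)
    ]
    return unary_union(cells)


def _at_sea(seascape: SeascapeStack, p, margin_cells: int = 0) -> bool:
    if not seascape.in_bounds(p[0], p[1], margin_cells):
        return False
    return not bool(seascape.is_land(p[0], p[1]))


def generate_rsf_testset(
    seascape: SeascapeStack,
    selection_beta: dict,
    n_used: int = 5000,
    mode: str = "iid",
    seed: int = 0,
    n_segments: int = 20,
    candidate_pool: int = 200_000,
):
    """Habitat-selection-biased used locations with known coefficients.

    Covariates are standardized over sea cells (z-scores); ``selection_beta``
    is indexed by layer name on that standardized scale.  In ``iid`` mode,
    used points are drawn from an availability distribution (uniform over sea)
    reweighted by ``exp(beta' z)``, so a plain logistic regression of used
    versus available locations recovers ``beta`` asymptotically.  In
    ``movement`` mode a persistence walk is biased by per-step rejection
    sampling (approximate, sign-consistent recovery).

    Returns ``(used, draw_available, truth)`` where ``used`` is a DataFrame
    with x, y, segment and standardized covariate columns, and
    ``draw_available(n, seed)`` yields availability points with the same
    schema.
    """
    unknown = [k for k in selection_beta if k not in seascape.layers]
    if unknown:
        raise KeyError(f"unknown covariate name(s) in beta: {unknown}")
    if mode not in ("iid", "movement"):
        raise ConfigurationError("mode must be 'iid' or 'movement'")

    rng = default_rng(seed)
    names = list(selection_beta)
    scaling = seascape.standardizer(names)
    beta = np.array([selection_beta[k] for k in names])

    sea_rc = np.argwhere(~seascape.land)

    def _points_from_cells(idx, rng_):
        rc = sea_rc[idx]
        x = seascape.x0 + (rc[:, 1] + rng_.uniform(size=len(rc))) * seascape.cell
        y = seascape.y0 + (rc[:, 0] + rng_.uniform(size=len(rc))) * seascape.cell
        return x, y

    def _z(x, y):
        cols = {}
        for k in names:
            mu, sd = scaling[k]
            cols[k] = (seascape.sample(k, x, y) - mu) / (sd if sd > 0 else 1.0)
        return cols

    def draw_available(n, seed_=None):
        r = default_rng(seed_ if seed_ is not None else rng.integers(2**31))
        idx = r.integers(len(sea_rc), size=n)
        x, y = _points_from_cells(idx, r)
        df = pd.DataFrame({"x": x, "y": y, **_z(x, y)})
        return df

    if mode == "iid":
        idx = rng.integers(len(sea_rc), size=candidate_pool)
        x, y = _points_from_cells(idx, rng)
        z = _z(x, y)
        eta = sum(selection_beta[k] * z[k] for k in names)
        w = np.exp(eta - np.max(eta))
        pick = rng.choice(candidate_pool, size=n_used, replace=True, p=w / w.sum())
        used = pd.DataFrame(
            {"x": x[pick], "y": y[pick], **{k: z[k][pick] for k in names}}
        )
    else:
        # habitat-biased persistence walk: propose steps, accept by exp(beta'z)
        sx, sy = _draw_start(seascape, rng)
        step_sd = 3000.0
        pts = np.empty((n_used, 2))
        pos = np.array([sx, sy])
        th = rng.uniform(0, 2 * np.pi)
        d_prev = 2 * step_sd * np.array([np.cos(th), np.sin(th)])
        eta_max = float(np.abs(beta).sum()) * 4.0
        for i in range(n_used):
            accepted = False
            for _ in range(100):
                cand_step = 0.8 * d_prev + rng.normal(0, step_sd, 2)
                cand = pos + cand_step
                if not _at_sea(seascape, cand, 1):
                    continue
                zc = _z(cand[0], cand[1])
                eta = sum(selection_beta[k] * zc[k] for k in names)
                if np.log(rng.uniform() + 1e-300) < eta - eta_max:
                    pos, d_prev, accepted = cand, cand_step, True
                    break
            if not accepted:
                d_prev = -d_prev
            pts[i] = pos
        z = _z(pts[:, 0], pts[:, 1])
        used = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], **z})

    used["segment"] = np.arange(len(used)) % n_segments
    truth = SimTruth(
        seed=seed,
        times=None,
        path=None,
        gamma=None,
        selection_beta=dict(selection_beta),
        scaling=scaling,
    )
    return used, draw_available, truth
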