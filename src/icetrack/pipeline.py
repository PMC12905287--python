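"""End-to-end synthetic analysis pipeline.

Chains every stage on generated data: seascape -> simulated whales ->
ingestion/filtering/segmentation -> state-space fits and 4-h prediction ->
land re-routing -> joint move-persistence estimation -> Monte-Carlo RSF on
simulated availability tracks -> AR1 behaviour model -> kernel home ranges
with seasonal overlap and hotspot condition tests.  Used by the smoke test
and by the reproduction script; problem sizes default to desk scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from icetrack import behaviour, homerange, persistence, prep, rsf, ssm
from icetrack.seascape import generate_seascape, land_polygons, simulate_observed_track

__all__ = ["run_pipeline"]

BEHAVIOUR_COVARIATES = ("slope", "dist_shelf", "dist_glacier", "sst", "ssh")


def run_pipeline(
    seed: int = 1,
    n_whales: int = 10,
    duration_days: float = 45.0,
    n_sim: int = 100,
    k_keep: int = 20,
    step_hours: float = 4.0,
    min_length: int = 54,
    reroute_buffer_m: float = 10_000.0,
    h_mult: float = 0.6,
    stepwise: bool = False,
) -> dict:
    """Run the full chain on synthetic whales and return all stage outputs.

    Deterministic for a given ``seed``.  Returns a dict with the seascape,
    per-stage results and summary tables.
    """
    rng = np.random.default_rng(seed)
    sea = generate_seascape(seed=seed)
    land_geom = land_polygons(sea)

    def on_land(x, y):
        if not sea.in_bounds(x, y, margin_cells=2):
            return True
        return bool(sea.is_land(x, y))

    # --- simulate whales (behaviour tied to depth: slower over deep water);
    # deployments start over the shelf/slope, as taggings do, so tracks
    # traverse the depth gradient
    depth = sea.layers["depth"]
    shelf_rc = np.argwhere((~sea.land) & np.nan_to_num(depth > 100) & np.nan_to_num(depth < 800))
    truths, fix_frames = {}, []
    for w in range(n_whales):
        wid = f"SW{w:02d}"
        r, c = shelf_rc[rng.integers(len(shelf_rc))]
        start = (sea.x0 + (c + 0.5) * sea.cell, sea.y0 + (r + 0.5) * sea.cell)
        truth, fixes = simulate_observed_track(
            sea,
            behaviour={"intercept": 1.0, "coefs": {"depth": -0.8, "ssh": -0.3}},
            duration_days=duration_days,
            seed=int(rng.integers(2**31)),
            animal_id=wid,
            start_xy=start,
        )
        truths[wid] = truth
        fix_frames.append(fixes)
    raw = pd.concat(fix_frames, ignore_index=True)

    # --- prep
    fixes = prep.read_fixes(raw)
    segments, audit = prep.filter_and_segment(fixes, min_length=min_length)

    # --- SSM per segment: fit rw + crw, select, predict, reroute
    tracks, fits, selection = {}, {}, {}
    for seg in segments:
        cand = [ssm.fit_ssm(seg, m) for m in ("rw", "crw")]
        try:
            chosen, diag = ssm.validate_and_select(
                cand, n_replicates=0 if n_sim == 0 else 10, seed=int(rng.integers(2**31))
            )
        except ValueError:
            continue
        pt = ssm.predict_regular(chosen, step_hours=step_hours)
        pt = ssm.reroute(pt, land_geom, buffer_m=reroute_buffer_m)
        fits[seg.segment_id] = chosen
        selection[seg.segment_id] = diag["selected"]
        tracks[seg.segment_id] = pt

    # --- move persistence (joint, pooled variance)
    gamma = persistence.fit_mpm_joint(tracks)
    for sid, g in gamma.tracks.items():
        tracks[sid] = tracks[sid].join(g)

    # --- Monte-Carlo RSF on simulated availability tracks
    sims = {}
    for sid, fit in fits.items():
        sset = ssm.simulate_and_filter(
            fit, tracks[sid], n_sim=n_sim, k_keep=k_keep, land=on_land,
            seed=int(rng.integers(2**31)),
        )
        sims[sid] = [sset.tracks[i] for i in np.flatnonzero(sset.retained)]
    used = pd.concat(
        [t.assign(segment=sid)[["x", "y", "segment"]] for sid, t in tracks.items()],
        ignore_index=True,
    )
    design, scaling = rsf.build_design(used, sims, sea)
    if stepwise:
        rsf_result = rsf.backward_stepwise(design, seed=seed)
    else:
        rsf_result = rsf.fit_mc_rsf(design, n_fits=k_keep, seed=seed)

    # --- behaviour-environment LMM (AR1 + individual random intercept)
    beh = _behaviour_table(tracks, sea)
    Xb = beh[[c for c in beh.columns if c.startswith("dpth_") or c in BEHAVIOUR_COVARIATES]]
    Xb = Xb.copy()
    Xb.insert(0, "Intercept", 1.0)
    lmm = behaviour.fit_lmm_ar1(
        beh["gamma_logit"].to_numpy(),
        Xb,
        beh["id"].to_numpy(),
        blocks=beh["segment"].to_numpy(),
        mode="reml",
    )
    lmm_diag = behaviour.diagnostics(
        lmm, spline_blocks={"depth": [c for c in Xb.columns if c.startswith("dpth_")]}
    )
    cv = behaviour.loocv(lmm) if beh["id"].nunique() >= 3 else None

    # --- home range
    pts = used[["x", "y"]].to_numpy(float)
    h = h_mult * homerange.href(pts)
    ud = homerange.kde_ud(pts, h)
    contours = homerange.contour_areas(ud, (0.25, 0.50, 0.95), polygons=True)
    all_ts = pd.concat([t["timestamp"] for t in tracks.values()])
    seasons = homerange.season_of(all_ts).to_numpy()
    season_uds = {}
    for s in pd.unique(seasons):
        p = pts[seasons == s]
        if len(p) >= 50:
            season_uds[s] = homerange.kde_ud(p, h, cell=ud.cell, extent=(
                ud.x0, ud.x0 + ud.density.shape[1] * ud.cell,
                ud.y0, ud.y0 + ud.density.shape[0] * ud.cell))
    overlaps = []
    names = sorted(season_uds)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for lv in (0.95, 0.50):
                overlaps.append(homerange.bhattacharyya_overlap(
                    season_uds[a], season_uds[b], lv, labels=(a, b)))
    hotspot_table = None
    hot = contours.polygons[0.25]
    loc_cov = beh[["x", "y", "slope", "sst", "ssh"]].dropna()
    try:
        hotspot_table = homerange.compare_hotspot_conditions(
            loc_cov, hot, ["slope", "sst", "ssh"])
    except ValueError:
        pass

    gamma_norm = persistence.normalize_gamma(
        {sid: t["gamma"].to_numpy() for sid, t in tracks.items()}, mode="global")

    return {
        "seascape": sea,
        "truths": truths,
        "audit": audit,
        "segments": segments,
        "fits": fits,
        "model_selection": selection,
        "tracks": tracks,
        "gamma": gamma,
        "gamma_normalized": gamma_norm,
        "sims": sims,
        "design": design,
        "design_scaling": scaling,
        "rsf": rsf_result,
        "behaviour_data": beh,
        "lmm": lmm,
        "lmm_diagnostics": lmm_diag,
        "loocv": cv,
        "ud": ud,
        "bandwidth": h,
        "contours": contours,
        "season_overlaps": overlaps,
        "hotspot_table": hotspot_table,
    }


def _behaviour_table(tracks: dict, sea) -> pd.DataFrame:
    """Assemble the logit-persistence response with standardized covariates
    sampled at predicted locations (depth through the natural spline)."""
    frames = []
    for sid, t in tracks.items():
        d = t.copy()
        d["segment"] = sid
        frames.append(d)
    beh = pd.concat(frames, ignore_index=True)
    x, y = beh["x"].to_numpy(float), beh["y"].to_numpy(float)
    cov = {}
    for name in ("depth",) + BEHAVIOUR_COVARIATES:
        v = np.asarray(sea.sample(name, x, y), float)
        if np.isnan(v).any():
            v = np.where(np.isnan(v), np.nanmean(v), v)
        cov[name] = v
    spline = rsf.natural_spline_basis(cov["depth"])
    for j in range(spline.shape[1]):
        col = spline[:, j]
        beh[f"dpth_{j + 1}"] = (col - col.mean()) / col.std()
    for name in BEHAVIOUR_COVARIATES:
        v = cov[name]
        sd = v.std()
        beh[name] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return beh
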