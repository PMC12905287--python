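# icetrack

Movement-ecology analysis for satellite-tracked, ice-associated marine
mammals.  `icetrack` chains the standard telemetry workflow — from raw
Argos/GPS fixes to behaviour–environment inference and home ranges — as a
tested, seed-deterministic Python library, and ships a synthetic
seascape-and-track generator so every stage can be validated by parameter
recovery when the real data cannot be shared.

It is written for quantitative ecologists who would otherwise stitch this
chain together from R packages (state-space track filtering, move
persistence, `adehabitatHR`-style kernel ranges, `nlme`-style mixed
models) and want one auditable pipeline with known ground truth behind
every test.

## What it computes

* **Track preparation** (`icetrack.prep`) — speed filtering (default
  2 m/s), gap-based segmentation (72 h), a 54-location minimum segment
  length, duplicate-fix resolution and overlapping-deployment truncation,
  with a complete per-rule removal audit.
* **State-space models** (`icetrack.ssm`) — continuous-time random walk
  (diffusion σ², m²/h) and correlated random walk (Ornstein–Uhlenbeck
  velocity, reversion β /h) fitted by maximum likelihood through a Kalman
  filter that takes each fix's Argos error ellipse as its observation
  covariance; fixed-interval smoothing, regular 4-h prediction with
  standard errors, AICc selection with one-step-ahead-residual (OSAR)
  diagnostics and an oversmoothing guard, simulation-smoother replicate
  tracks, barrier-aware availability-track simulation with a
  displacement/bearing similarity filter (keep 20 of 100), and land
  re-routing with a 10-km fjord-sparing buffer.
* **Move persistence** (`icetrack.persistence`) — time-varying
  γ_t ∈ (0, 1) from the step process
  `s_i = γ_i s_{i−1} + N(0, σ² I)`, with latent logit(γ) a random walk
  whose variance is pooled across tracks in a joint hierarchical fit
  (Laplace approximation); γ near 0 reads as area-restricted movement,
  near 1 as directed travel.
* **Monte-Carlo resource selection** (`icetrack.rsf`) — used vs simulated
  availability locations in a logistic model
  `logit(η_ij) = β₀ + βᵀx_ij + v_j` with a per-segment random intercept;
  20 random-assignment datasets fitted separately, coefficients reported
  as the mean ± SD across fits with normal-theory p-values, backward
  stepwise selection treating the depth spline (natural cubic, knots at
  220/500/2,500 m) as one term.
* **Behaviour–environment model** (`icetrack.behaviour`) —
  `logit(γ_tj) = β₀ + βᵀx_tj + V_j + ε_tj` with an individual random
  intercept and AR1(φ) residuals; ML/AICc candidate selection, REML
  estimates, VIFs, whitened-residual diagnostics, partial-response curves
  and leave-one-individual-out cross-validation with 5–95 % quantile
  ranges and the estimated trend.
* **Home ranges** (`icetrack.homerange`) — kernel utilization
  distributions on an 8,000-m grid, the h_ref reference bandwidth with the
  shrink-until-fragmentation selection rule, 95/50/25 % contours (home
  range / core area / hotspots) with areas and polygons, seasonal
  Bhattacharyya overlap rescaled to [0, 1], and Wilcoxon rank-sum hotspot
  condition comparisons (exact by enumeration for small samples).
* **Synthetic world** (`icetrack.seascape`) — autocorrelated covariate
  fields (depth with shelf/slope/basin structure, SST, ice with a 15 %
  ice edge, SSH, distance layers), a land mask, and tracks whose move
  persistence is driven by covariates through known coefficients, observed
  through class-dependent Argos error ellipses.
* **End-to-end pipeline** (`icetrack.pipeline.run_pipeline`) — the whole
  chain on simulated whales, deterministic under a fixed seed.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from icetrack.seascape import generate_seascape, simulate_observed_track
from icetrack import prep, ssm, persistence

sea = generate_seascape(seed=7)
truth, fixes = simulate_observed_track(sea, duration_days=45, seed=11, animal_id="W1")
print(f"simulated fixes: {len(fixes)} (class B share: {(fixes['lc'] == 'B').mean():.2f})")

df = prep.read_fixes(fixes)
segments, audit = prep.filter_and_segment(df, max_speed=2.0, min_length=54)
print(f"audit: {audit}")

seg = segments[0]
fits = [ssm.fit_ssm(seg, m) for m in ("rw", "crw")]
chosen, diag = ssm.validate_and_select(fits, n_replicates=100, seed=11)
print(f"selected model: {chosen.model}  (AICc rw={diag['rw']['aicc']:.1f}, crw={diag['crw']['aicc']:.1f})")

track = ssm.predict_regular(chosen, step_hours=4.0)
print(f"predicted locations: {len(track)} at a 4-h step, median SE {track['se_x'].median():.0f} m")

gamma = persistence.fit_mpm_joint({seg.segment_id: track})
g = gamma.tracks[seg.segment_id]["gamma"]
print(f"move persistence gamma_t: mean {g.mean():.2f}, range [{g.min():.2f}, {g.max():.2f}]")
```

prints

```
simulated fixes: 456 (class B share: 0.62)
audit: {'input': 456, 'speed': 84, 'short_segment': 0, 'retained': 372}
selected model: crw  (AICc rw=14268.6, crw=14261.2)
predicted locations: 270 at a 4-h step, median SE 1061 m
move persistence gamma_t: mean 0.74, range [0.27, 0.82]
```

Reading it: of 456 raw fixes, 84 implied speeds above 2 m/s (Argos class-B
error of several km at ~1-h intervals does that) and were removed; the
correlated-random-walk model fits this track better by ~7 AICc units; the
regularized track has 270 four-hourly locations with ~1 km positional
uncertainty; and the estimated behavioural index spans directed travel
(γ ≈ 0.8) down to area-restricted movement (γ ≈ 0.3) — this whale's
generator slowed it over deep water, and the fitted γ_t recovers that
contrast.

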