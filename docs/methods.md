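# Methods

`icetrack` re-implements, as a tested library, the analysis chain commonly
used to characterise the space use of satellite-tracked, ice-associated
whales: track regularization by continuous-time state-space models,
behavioural inference through time-varying move persistence, used–available
resource selection with Monte-Carlo availability tracks, a linear mixed
model with AR1 errors for behaviour–environment relationships, and kernel
home-range estimation with Bhattacharyya overlap.  Because telemetry data of
this kind are rarely public, the package ships a synthetic seascape-and-track
generator with known parameters, so every estimator is validated by
parameter recovery and by independent oracles rather than against withheld
field data.

All spatial computation is planar, in projected metres.  Geographic input is
projected with spherical north-polar-stereographic formulas
(`icetrack.proj`); at high latitudes the datum approximation is far below
Argos location error and irrelevant for movement metrics.

## Synthetic seascape and tracks (`icetrack.seascape`)

The generator emulates a high-Arctic shelf sea: a noisy meridional
coastline whose land share matches the requested fraction; water depth
ramping from the coast across a ~200 m shelf (80 km), down a slope
(120 km) to a ~3,500 m basin; sea-floor slope derived from the depth
gradient; SST warming southward (floored at −1.9 °C); sea-ice concentration
increasing northward and clamped to [0, 1], with the ice edge defined as
the 15 % concentration contour (the community convention); SSH as smoothed
noise; and distance layers (to the 500-m isobath, to coastal
glacier-front sites, and signed distance to the ice edge, negative inside)
from Euclidean distance transforms.  All stochastic structure is
Gaussian-smoothed white noise plus deterministic gradients.  What the
fields do **not** emulate: real bathymetry, advection, seasonal ice
dynamics (a static climatology stands in), tides, or any covariance between
layers beyond what the shared gradients induce.  Tests that pass on these
fields therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to real-ocean structure.

Tracks follow a first-difference correlated walk at a 1-h step:
`d_t = γ_t d_{t−1} + N(0, σ_step² I)` with
`logit(γ_t) = β₀ + Σ β_k z_k(x_t) + e_t`, covariates z-scored over sea
cells and `e_t` AR1 noise.  Observations are thinned to irregular times
(exponential inter-fix intervals, occasional 12–48-h gaps) and perturbed by
Argos-class-dependent elliptical error (per-class mean semi-major scales:
3: 250 m, 2: 500 m, 1: 1,500 m, 0/A: 4,000 m, B: 6,000 m, drawn from a
Gamma with shape 4; axis ratio uniform 0.3–0.8; orientation uniform) or a
30-m circular GPS error.  The class mix is B-dominated, matching the
composition typical of whale-borne transmitters.  Because the turning-angle
geometry of any Gaussian AR1 step process is a function of γ alone, mean
absolute turning angle at γ = 0.982 is ≈ 10.4° regardless of the noise
scale — a useful closed-loop check on the generator (see the test against
a direct AR1-vector oracle).

For selection studies, `generate_rsf_testset` draws used points from an
availability distribution (uniform over sea cells with within-cell jitter)
reweighted by `exp(βᵀz)`; a plain logistic contrast of used vs available
then recovers β asymptotically.  A `movement` mode biases a persistence
walk by per-step rejection, which is only sign-consistent.

## Track preparation (`icetrack.prep`)

Quality control replaces manual vetting with declarative, audited rules: a
forward-pass speed filter against the last retained fix (default ceiling
2 m/s — roughly an order of magnitude above sustained bowhead travel speeds
near 0.3 m/s, so it removes only implausible Argos jumps), segmentation at
data gaps above 72 h, and removal of segments shorter than 54 locations
(the floor below which state-space fits are unreliable).  The speed filter
is deliberately a single forward pass rather than a forward/backward
consensus: it is idempotent, order-deterministic and leaves a complete
audit trail (every input fix lands in exactly one of
retained / removed-by-speed / removed-short-segment).  Duplicate timestamps
within a deployment collapse to the best location class
(G > 3 > 2 > 1 > 0 > A > B).  Overlapping deployments on one animal are
resolved by explicit priority: within an overlap window only the
highest-priority track's fixes are kept.

## State-space engine (`icetrack.ssm`)

Two linear-Gaussian continuous-time process models, discretized exactly for
irregular intervals (units: metres, hours):

* **RW** — Brownian position, per-axis diffusion variance σ² (m²/h).
* **CRW** — position integrating an Ornstein–Uhlenbeck velocity
  (`dv = −βv dt + σ dW`), reversion rate β (1/h) and noise rate σ²
  (m²/h³) shared across axes; velocity autocorrelation over Δt is
  `exp(−βΔt)`.

Each fix carries its own 2×2 observation covariance: the Argos error
ellipse rotated to grid axes (orientation clockwise from north, semi-axes
treated as 1-σ) when present, otherwise an isotropic per-class fallback
(same table as the generator's scales).  The initial state prior is vague:
position centred on the first fix with 10-km SD, velocity zero with
5,000 m/h SD — diffuse relative to observation error yet small enough that
brute-force joint-Gaussian conditioning (the test oracle) stays well
conditioned.

Likelihood maximization is quasi-Newton (L-BFGS-B) on log scales with three
deterministic restarts; β is bounded in [1e−4, 1e2] /h, so a straight
constant-velocity track drives β to its lower bound (velocity
autocorrelation at its upper bound) rather than diverging.  Smoothing is
fixed-interval (RTS).  Standardized Kalman innovations serve as
one-step-ahead prediction residuals (OSAR); the first innovation, dominated
by the vague prior, is excluded from their summaries.  Model selection
takes the lowest AICc among converged fits (k = 2 process parameters,
n = number of fixes), with an oversmoothing guard: if the CRW's OSAR lag-1
autocorrelation is worse than the RW's by more than 0.1, the RW is
preferred even at equal or better AICc — CRW fits oversmooth long,
densely-sampled tracks.  Prediction evaluates the smoother on a regular
grid (default 4 h) anchored at the first fix.

Uncertainty tracks are drawn with the Durbin–Koopman simulation smoother
(draw an unconditional state/observation path, smooth the pseudo-data,
recentre on the actual smoothed means), which samples the joint posterior
of the whole state path.  Availability tracks for the RSF are unconditional
simulations of the fitted process from the parent track's start and
timestamps; with a land barrier, proposals landing on land are redrawn (up
to 50 times, then the track stalls in place for that step) — a
barrier-aware proposal rather than post-hoc rerouting, which would pile
availability onto the coastline.  The similarity filter scores each
candidate by the negative standardized Euclidean distance to the parent in
(net displacement, net bearing) — the two features are standardized by
their SD across the candidate pool, bearing differences wrapped to ±π —
and retains the top k (default 20 of 100), ties broken by candidate index.
The exact similarity metric is a documented choice; the parent track, if
injected, always ranks first.

Re-routing moves points off land: the land polygons are eroded inward by a
buffer (default 10,000 m) and only points inside the eroded geometry move,
to the nearest point on its boundary.  Points in the buffer band — e.g.
inside narrow fjords — stay put by construction, because erosion removes
features narrower than twice the buffer.

## Move persistence (`icetrack.persistence`)

With steps `s_i` of a regular-step track, the behavioural model is
`s_i = γ_i s_{i−1} + N(0, σ² I₂)` with `logit(γ_i)` a latent Gaussian
random walk (innovation SD σ_g).  γ near 1 is directed travel; γ near 0 is
area-restricted movement, commonly read as apparent foraging.  A joint
(hierarchical) fit shares one pooled (σ, σ_g) across all tracks — in
particular a single pooled random-walk variance — while each track keeps
its own latent series.

Estimation is marginal ML with a Laplace approximation: the inner problem
(latents given variances) is solved by damped Gauss–Newton with a
tridiagonal Hessian (banded Cholesky, O(n) per iteration), converged on the
gradient (∞-norm < 1e−9) with a stagnation cut for saturated logits; the
outer 2-parameter problem runs L-BFGS-B followed by a Nelder-Mead polish on
a deterministic objective (every polish evaluation warm-starts from the
same frozen latent profile, removing evaluation-order hysteresis).  That
polish is what makes the smoothed γ profile reproducible to ~1e−6 under
rigid rotation/translation of the input — which the model ought to respect,
and which is additionally enforced by fitting in a canonical frame (first
step rotated onto +x).  Latent SEs come from the curvature of the Laplace
objective (diagonal of the inverse tridiagonal Hessian, delta-method to the
γ scale) and are reported only; they are not propagated into the behaviour
model, which uses point estimates.  The first latent carries a vague
N(0, 10²) prior.  γ for location t is driven by the step pair around it;
the two track endpoints repeat the nearest interior estimate so output
aligns with locations.  Tracks shorter than 10 locations are excluded.

Normalization for display is min–max, either global across individuals
(default; emphasizes between-individual contrast) or per individual; a
constant series maps to 0.5 with a warning.

## Monte-Carlo RSF (`icetrack.rsf`)

The design contrasts used (predicted) with available (simulated) locations.
Depth enters through a natural cubic spline with interior knots at 220,
500 and 2,500 m — the shelf break and basin transitions — and boundary
knots at the data range (widened minimally if the data do not span the
knots).  The basis is built from cubic B-splines projected onto the
zero-second-derivative subspace at the boundaries (the numerically stable
construction used by standard regression-spline implementations; the
classical truncated-power basis, used as the test oracle, spans the same
space but is catastrophically collinear on shelf-concentrated data).
`in_ice` is 1 where the signed ice-edge distance is negative.  All
continuous columns are centred/scaled on the pooled used+available rows
(one common scale across all 20 datasets, so coefficients are comparable);
`ice_sq` is the square of the standardized ice column, itself standardized
(the transform order is configurable in principle; this order is the
package's convention).

Used and available tracks are both autocorrelated, which makes the variance
of a single logistic fit unrealistically small.  The Monte-Carlo procedure
instead builds 20 datasets — each pairing all used rows with one simulated
track per segment, assigned by a per-segment permutation (each simulation
used exactly once across datasets, i.e. without replacement) — and fits
each as a logistic regression with a per-segment random intercept, by
Laplace approximation (vectorized inner Newton over group modes; if the
estimated random-effect variance collapses below 1e−8 the fit falls back to
plain IRLS).  The coefficient and its SE are the mean and SD across the 20
fits; CIs are mean ± 1.96 SE and p-values two-sided normal.  A fit with
coefficients beyond |30| on the standardized scale is treated as separated
and excluded with a warning; an all-identical-dataset degenerate
aggregation yields SD 0 and an undefined p, with a warning.  Backward
stepwise selection drops, at each pass, the term with the largest p above
α = 0.05 — the four spline columns are one term, droppable only if all
four exceed α (its ordering p is the block minimum) — then refits the whole
Monte-Carlo procedure with fresh assignment under a derived seed; ties drop
the later term in declaration order.  AIC-style selection is deliberately
unavailable: the aggregated estimates are not a likelihood.

## Behaviour–environment model (`icetrack.behaviour`)

logit(γ_t) is regressed on environmental covariates with a random intercept
per individual (variance V) and AR1 residuals (coefficient φ, variance σ²):
per-individual marginal covariance `V·J + σ²·AR1(φ)`.  AR1 is indexed by
observation order within individual — regular 4-h steps make order and lag
equivalent — and optional block ids (track segments) reset the correlation
across gaps while the random intercept spans the whole individual.
Likelihood evaluation is O(n) per individual: the analytic AR1 whitening
transform per block, a Woodbury rank-1 update for the intercept, and σ²
profiled out; the remaining (variance ratio V/σ², φ) problem is solved by
L-BFGS-B on (log, arctanh) scales with three restarts.  ML is used for
candidate comparison, REML for the reported fit.  AICc uses n = total
observations and k = fixed effects + φ + two variances.  Fixed-effect
p-values are normal-approximation (per-individual n is large here; no
denominator-df approximation).  A design condition number above 1e10 —
e.g. spline columns evaluated entirely beyond the last knot, where the
natural spline is exactly linear — raises immediately rather than
returning a garbage fit.

Candidate selection takes patsy right-hand-side formulas, fits all by ML,
ranks by AICc, and refits the winner by REML; the ranking table also
reports, per covariate, the length of the top-AICc run of models containing
it.  Diagnostics: VIFs from the predictor correlation matrix (generalized,
determinant-ratio VIF for the spline block), exact-collinearity errors that
name both offending columns, residuals whitened by the full fitted
covariance (eigendecomposition per individual) with mean/variance/lag-1
summaries, and partial-response curves varying one covariate over its
observed range with others at their means, with delta-method 95 % bands.
Leave-one-out cross-validation refits once per left-out individual and
reports the 5 %/95 % coefficient quantiles plus the estimated trend — the
percentage of refits whose coefficient lies inside the full model's 95 %
CI; non-convergent refits are excluded from the quantiles and reported.

## Home range (`icetrack.homerange`)

The utilization distribution is a bivariate Gaussian KDE on a regular grid
(default 8,000 m cells; separable kernel evaluation; renormalized so cell
density × cell area sums to 1).  The grid pads the point bounding box by 4
bandwidths, keeping truncated mass below the normalization tolerance.  The
reference bandwidth is the bivariate normal rule
`h_ref = sqrt((var_x + var_y)/2) · n^(−1/6)` (sample variances, ddof = 1).
The ad-hoc selection procedure evaluates multipliers 1.0, 0.9, …, 0.1 of
h_ref, counts connected components of the 95 % contour at each
(8-connectivity — a deterministic surrogate for the visual "began to
separate" judgement), and selects the smallest multiplier reached before
the count first exceeds the baseline at 1.0; small separated areas present
initially are thereby tolerated, and a never-fragmenting cluster runs to
the 0.1 limit.  The pipeline default is the fixed multiplier 0.6 with the
procedure always available and its trace logged.  Seasonal UDs share the
pooled-data bandwidth.

Contours are mass quantiles: the smallest set of cells whose summed mass
reaches the level (ties broken by flat cell index), with areas as cell
count × cell area and optional shapely polygons from dissolved cell
squares.  Home range, core area and hotspots are the 95/50/25 % levels.
Bhattacharyya affinity masks each UD to its own level contour, renormalizes
the retained mass to exactly the level (the cell set overshoots the level
by part of one cell; renormalizing makes the identity case exact), computes
`BA = Σ sqrt(p_a p_b)`, and rescales by the level so 1 is the attainable
maximum.  Hotspot condition comparisons use the two-sided Wilcoxon rank-sum
test: exact by enumeration with midranks when min(n) ≤ 10 (ties handled
exactly; p = 2·min(P(W≤w), P(W≥w)) capped at 1), normal approximation with
tie correction otherwise.  Seasons follow the meteorological convention:
spring MAM, summer JJA, fall SON, winter DJF.

## Problem sizes and determinism

Desk-scale defaults keep the full chain and its validation suite inside a
single-CPU coffee break: the end-to-end pipeline runs 10 whales × 45 days
(1-h simulation step, 4-h prediction step, 100 simulated availability
tracks per segment with 20 retained); parameter-recovery checks use 50
segments of 200 fixes (state-space), 20 individuals × 200 steps (mixed
model), 200 segments × 25 locations (RSF recovery) and 100 small replicates
(RSF null calibration).  Every stochastic routine takes an explicit seed
and is deterministic given it; optimizer restarts are deterministic
perturbations.

## Known limitations

* The move-persistence likelihood is this package's first-difference
  formulation; it is validated by simulation recovery and contrast/
  change-point behaviour, not by equation-level equivalence to any specific
  reference implementation.
* The Laplace approximations (move persistence, random-intercept logistic)
  are not exact marginal likelihoods; variance parameters inherit the usual
  small-sample Laplace bias.
* γ_t estimation uncertainty is not propagated into the behaviour model.
* Observation-error parameters are taken from the ellipse metadata or class
  table, never re-estimated.
* The projection helper is spherical; for geodesy-grade work substitute
  proper ellipsoidal projected coordinates upstream.
* Synthetic covariate fields are statistical stand-ins (see above); real
  covariate products must be supplied by the user as co-registered grids.
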