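# Methods

## Model

`vischool` simulates fish as discrete-time stochastic agents in a square
tank. Per agent and per decision interval δt the update is

```
X(t+δt) = X(t) + v(t+δt) · e(Θ(t+δt)) · δt
```

with the speed `v` drawn independently each step from a per-regime
distribution and the world heading `Θ` obtained by adding a body-frame
turn θ sampled from a circular probability density built that step. The
density is a normalized mixture of von Mises components:

* **Basic swimming** — far from walls the stimulus-free density is a
  single von Mises at θ = 0 (keep going) with concentration κ₀.
* **Wall following** — within the wall-interaction distance d_w the
  stimulus-free density becomes an equal-weight (½, ½) pair of von Mises
  components along the two body-frame directions parallel to the nearest
  wall, concentration κ_w. Both directions stay equally likely every
  step, so simulated wall-bound fish dither along the wall rather than
  commit to one circulation sense; this is a property of the model, not
  an artefact.
* **Stimuli** — every perceived fish or floating disc contributes a von
  Mises centred on its body-frame bearing. Components of one stimulus
  kind are mixed with weights A_i / A_T proportional to the solid angle
  each stimulus captures, and the kind as a whole enters the global
  density with weight α\*·A_Tf (fish) or β\*·A_Ts (spots), normalized so
  the result is a convex combination that integrates to one. α\* and β\*
  carry units sr⁻¹, switch between their off-wall and near-wall values
  with the same d_w threshold, and are divided by w_F and w_S when the
  scenario contains both stimulus kinds (a configuration-level switch:
  the mixed-condition calibration is per experiment, not per time step).

Sampling is by inverse transform on the numeric CDF: cumulative
trapezoidal integration of the density on a uniform angular grid,
renormalized to end at exactly 1, then linear interpolation of the
inverse at a uniform draw. Closed-form von Mises samplers are
deliberately not used on this path — the numeric-CDF route is the model's
decision mechanism and works for arbitrary mixtures.

## Perception geometry

Each agent's head sits at (x, y, 0); a neighbour's body is a six-vertex
solid (nose at the head position, four ±width/2 × ±height/2 corners at
40% body length behind the nose, a tail vertex a full length behind —
the minimal six-vertex shape with the stated 3.5 × 1 × 1 cm extents).
Floating discs have radius 0.1 m at height 0.05 m. Stimulus vertices are
projected on the observer's unit sphere; the outline is reduced to the
four extremal projections (min/max azimuth relative to the centroid
bearing, min/max elevation; indices forced distinct), ordered into a
quadrilateral and split into two spherical triangles whose excesses come
from L'Huilier's theorem. The four-point reduction slightly
underestimates the true outline area (it inscribes the silhouette), which
is why the on-axis disc check asserts the quad is bounded by the analytic
cap 2π(1 − h/√(h²+R²)).

Field-of-view inclusion is all-or-nothing on the centroid bearing
(|bearing| ≤ 135°, inclusive); there is no occlusion and no partial
clipping at the FOV edge. Bodies may overlap; from inside a target's
volume no solid angle is defined, so such a stimulus is skipped for that
step. Near-contact geometry can make the two split triangles overlap, so
the quad area is capped at 2π sr — the most a convex stimulus seen from
outside can subtend.

## Parameters

| symbol | default | meaning |
|---|---|---|
| κ₀ | 6.3 | basic-swimming concentration |
| κ_w, κ_f, κ_s | 20 | wall / fish / spot concentrations (independently configurable) |
| α₀ / α_W | 55 / 20 | fish weight per sr, off-wall / near-wall |
| β₀ / β_W | 0.15 / 0.01 | spot weight per sr, off-wall / near-wall |
| w_F, w_S | 2, 9 | division factors in mixed fish+spot scenarios |
| d_w | 0.05 m | wall-interaction distance |
| FOV | 270° | visual field |
| δt | 1/3 s | decision interval (one tail beat; 10 800 steps = 1 h) |
| arena | 1.20 m | square tank side |

Speed regimes (truncated-at-zero normals, mean ± sd in m/s): homogeneous
0.07 ± 0.03; outside spots 0.09 ± 0.06; under spots 0.03 ± 0.02. The
configured values are the pre-truncation normal parameters; truncation
raises the homogeneous mean ~1% and shrinks its sd ~3%. An empirical
sample pool can be supplied instead of a parametric family.

## Numerical choices

* Angular grid: 720 nodes spanning [−π, π], both endpoints included
  (0.5° spacing). Trapezoidal integration of the smooth periodic
  densities at this resolution is accurate far beyond the behavioural
  noise; every produced density integrates to 1 within 10⁻⁶.
* Inverse CDF: linear interpolation between grid nodes; ties in flat CDF
  regions resolve to the left node; u = 0 and u = 1 map to the grid
  endpoints −π and π.
* Wall collision: a step that would cross a wall is truncated at the
  boundary minus 10⁻⁴ m with the heading unchanged — no reflection, no
  resampling; the wall-following density takes over next step.
* Corner ties in nearest-wall search break deterministically in the
  order N, E, S, W.
* L'Huilier's formula clamps tiny negative products (flat triangles) to
  zero; triangle inequalities are enforced with a 10⁻⁹ margin.
* One RNG stream per run (`numpy` PCG64 seeded from the config); agents
  update in id order with a fixed draw order (speed, then heading), so
  runs are bit-reproducible.
* Update scheme is synchronous: all percepts are computed from time-t
  states before any position advances.

## Synthetic reference generator

The generator emulates *tracked* fish trajectories so analysis and
fitting are testable without video: a correlated random walk with von
Mises(0, κ = 6.3) heading increments per recording interval, per-regime
speeds at the current position, and wall truncation. A wall-dwell
fixture (on by default) steers the heading along the nearest wall inside
a 0.05 m band, tilted up to 0.4 rad towards the interior as the wall
nears; without it a truncated random walk grinds into the walls and the
three-point speed estimator collapses, which real (wall-following) fish
do not exhibit. The fixture reproduces wall-hugging statistics; it is
not a behavioural model. The generator does not emulate identity
switches, tracking noise, speed autocorrelation or burst-and-coast
kinematics — passing tests therefore show pipeline correctness and
statistical closure, not realism of those aspects.

Recording rates follow the experimental conditions the generator mimics:
1/15 s for single fish in the homogeneous tank, 1 s otherwise; the
analysis takes the recording interval as a parameter.

## Analysis conventions

* Three-point speed: |P(t+1) − P(t−1)| / (2·Δt); endpoints omitted;
  freezing filter removes speeds ≤ 1 mm/s (strict).
* Turning angle: signed angle between successive displacement vectors,
  positive counter-clockwise; samples touching a zero-length displacement
  are skipped; a reversal maps to −π.
* Regime-conditional speeds attribute a sample to under/outside-spot only
  when all three window positions share the regime; mixed windows are
  discarded to avoid blending across the disc rim.
* κ-calibration fits on turning samples whose full window stays ≥ 0.30 m
  from every wall, isolating intrinsic turning from wall effects.
* Occupancy bins default to 0.05 m (24 × 24 over the 1.2 m arena);
  per-individual statistics are not reported for groups (identity
  switches in tracked data make them unreliable), only group-level ones.

## Calibration protocol

`fit_kappa` minimizes the summed squared difference between the binned
empirical turning density (72 bins of 5°) and the theoretical von Mises
density at bin centres over a κ grid with step 0.1. Evaluating at bin
centres under-resolves very sharp peaks: at κ = 20 the 5° binning biases
the fit by ≈ −0.3, so high-κ fits should use finer bins (the bin count is
a parameter); at κ ≈ 6.3 the bias is far below one grid step.

`grid_search` evaluates a forward model (seeded replicate simulations,
pooled) on every point of a named parameter grid and scores it against
reference statistics by an unweighted sum of per-statistic squared
differences, each statistic first normalized to unit mass (turning
histogram, occupancy grid, pairwise-distance histogram). Failed grid
points are recorded as missing, warned about and excluded from the
argmin. Replicates default to 3 with seeds derived from a base seed.

## Problem sizes used in the shipped checks

Simulation-backed checks run at 20 simulated minutes per replicate
(3 replicates) for the 10-agent cohesion statistic, 1–2 simulated hours
for single-agent statistics, 10⁶ draws for the κ-recovery fit and 10⁵
draws for sampling goodness-of-fit — sizes at which every reported
statistic is stable to well within its stated tolerance.

## Known limitations

* Two-dimensional positions only; the third dimension exists solely in
  perception geometry (body height, disc height).
* No speed autocorrelation, alignment term, preferred inter-individual
  distance or collision avoidance; simulated groups are tighter than real
  ones (modal pairwise distance [0, 0.1) m rather than [0.1, 0.2) m).
* Homogeneous visual sensitivity across the field of view (no areae of
  acute vision); infinite perception radius; no occlusion.
* The four-point outline reduction underestimates solid angles of large
  nearby stimuli.
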