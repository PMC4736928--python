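# vischool

An agent-based model of zebrafish (*Danio rerio*) collective motion built
on **visual perception** rather than metric or topological neighbourhoods.
Each simulated fish carries a 270° spherical visual field; every stimulus
it can see — a congener (a 3.5 × 1 × 1 cm six-vertex body) or a floating
disc of interest — is measured by the **solid angle** its projection
captures on a unit sphere centred on the fish's head, computed from
spherical polygons via L'Huilier's theorem. Percepts are turned into a
probability density over candidate headings: a mixture of von Mises
distributions

```
f(θ) = ( f₀(θ) + α* A_Tf f_F(θ) + β* A_Ts f_S(θ) ) / ( 1 + α* A_Tf + β* A_Ts )
```

where `f₀` is the stimulus-free density (forward-peaked with concentration
κ₀ = 6.3 away from walls; bimodal along the nearest wall with κ_w = 20
inside the wall band d_w = 0.05 m), `f_F` and `f_S` are solid-angle-weighted
mixtures over perceived fish and spots (κ_f = κ_s = 20), `A_Tf`, `A_Ts` are
the total captured solid angles, and `α*`, `β*` are wall-dependent weights
(α₀ = 55 / α_W = 20, β₀ = 0.15 / β_W = 0.01, divided by w_F = 2 and
w_S = 9 when both stimulus kinds are present). The heading is drawn by
**inverse transform sampling** on the cumulative trapezoidal integral of
`f(θ)`; the position advances by one tail-beat interval (δt = 1/3 s) at a
speed drawn independently per step from the regime's distribution
(0.07 ± 0.03 m/s homogeneous; 0.09 ± 0.06 outside vs 0.03 ± 0.02 m/s
under the discs).

The package is aimed at researchers in collective animal behaviour who
want a perception-based alternative to force-summation schooling models,
plus the full measurement chain used to calibrate one: trajectory
statistics (three-point speeds, turning angles, freezing filter, occupancy
grids, pairwise distances), least-squares von Mises fitting and grid-search
calibration, and a synthetic reference generator so everything is testable
without video data.

## Worked example

```python
import numpy as np
from vischool import RunConfig, simulate, pairwise_distances

config = RunConfig(n_agents=10, duration=1200.0, seed=101, record_interval=1.0)
trajs = simulate(config)                       # 3600 updates, 1201 frames
d = pairwise_distances(trajs).ravel()          # 45 pairs x 1201 frames
counts, edges = np.histogram(d, bins=np.arange(0.0, 1.8, 0.1))
print(f"mean pairwise distance: {d.mean():.3f} m")
print(f"modal bin: [{edges[counts.argmax()]:.1f}, {edges[counts.argmax()+1]:.1f}) m")
```

```
mean pairwise distance: 0.266 m
modal bin: [0.0, 0.1) m
```

Ten agents released together stay tight: most pairs sit closer than
0.1 m, the cohesive regime the solid-angle attraction produces at the
fitted weights. A single agent instead spends most of its time in the
wall band (wall-following), and with two floating discs it slows down and
dwells beneath them.

The same runs are available from the shell:

```bash
vischool simulate --config run.yaml --out traj.csv
vischool analyze --input traj.csv --out stats/
vischool generate --config ref.yaml --out ref.csv
vischool fit --config fit.yaml --out surface.csv
```

An empty `run.yaml` gives the fitted defaults (all parameters above);
any key can be overridden.

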