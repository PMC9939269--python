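# swarmspace

Quantitative comparison of collective motion across animal groups — fish
shoals, bird flocks, ungulate herds, primate troops — from multi-individual
trajectory data.

Most tracking studies produce the same raw material (positions of group
members over time) yet collective behaviour is rarely compared across
species or time scales. `swarmspace` implements a complete, tested pipeline
for doing so:

1. **Ingestion** — read trajectory CSVs (planar metres or lon/lat GPS with a
   local equirectangular projection), interpolate onto a regular time grid,
   and derive per-member headings and smoothed speeds, group polarization
   and group speed.
2. **Event segmentation** — an *event* of collective motion is a maximal
   uninterrupted run of frames where group speed *V(t)* and polarization
   *P(t)* both exceed per-dataset quantile thresholds; events shorter than a
   minimum representative window (default 15 s) are discarded.
3. **Metrics** — per event, a 10-component vector: means of nearest-
   neighbour distance (NND), absolute bearing angle, polarization and group
   shape; temporal SDs of NND, polarization, shape and group speed; and mean
   within-group SDs of NND and frontness. Frontness is
   *f<sub>ij</sub>* = |β<sub>ij</sub>|/180°, where β<sub>ij</sub> is the
   signed angle from individual *i*'s heading to neighbour *j*'s position
   (0° directly ahead, ±180° directly behind). Group shape is the angle
   (0–90°) between the group heading and the short side of the minimum-area
   rotated bounding box, normalized by 90°.
4. **Swarm space** — standardize the metric table, eigendecompose its
   correlation matrix (eigenvalues, per-axis variance explained, loadings,
   factor-map contributions), drop metrics with negligible contribution to
   the leading axes, and complement the linear embedding with a t-SNE
   (perplexity 10) that preserves local neighbourhoods.
5. **Representativeness** — how long must a snapshot be for its means to
   agree with full-event means? Quantified with a two-way random-effects,
   absolute-agreement, single-measure intraclass correlation (ICC(A,1))
   between full-event and snapshot means across events.
6. **Reliability** — how many events until a metric's cumulative mean
   stabilizes? A broken-line model (slope *b* joined continuously to a
   slope-0 plateau at event index τ) is fitted by profiled least squares
   with a likelihood-ratio significance test and a profile-likelihood CI,
   cross-checked by an order-destroying bootstrap and a KPSS
   level-stationarity test.

A synthetic-trajectory module generates groups with known formation
(column, line abreast, diagonal, blob), NND scale, von-Mises heading noise
and alternating coordinated/uncoordinated regimes, so the whole pipeline is
testable without any animal data.

## Worked example

Generate a recording that alternates uncoordinated milling with two
coordinated marches, segment it, and compute event metrics:

```python
import numpy as np
import swarmspace as ss

cfg = ss.RegimeConfig(
    phases=[("uncoordinated", 30.0), ("collective", 60.0),
            ("uncoordinated", 30.0), ("collective", 60.0, {"speed_mean": 1.4}),
            ("uncoordinated", 30.0)],
    base=ss.FormationConfig(n_members=10, formation="column", nnd_target=2.0,
                            heading_noise_kappa=20.0, speed_mean=1.0,
                            dt=0.5, duration=60.0, seed=42))
tracks, truth = ss.generate_regime_sequence(cfg)
ks = ss.process_tracks(tracks, dt=0.5, smooth_window=1.0)
thr = ss.quantile_thresholds(ks, q=0.3)
events = ss.detect_events(ks, thr, min_duration=15.0)
events, n_removed = ss.filter_min_window(events, min_window=15.0)
print(f"thresholds: speed >= {thr.speed_thr:.3f} m/s, "
      f"polarization >= {thr.pol_thr:.3f}")
print(f"{len(events)} events detected ({n_removed} below 15 s)")
metrics = ss.compute_event_metrics(events, dataset="demo")
print(metrics[["event_id", "duration_s", "mean_nnd", "mean_polarization",
               "mean_shape", "sd_t_speed"]].round(3).to_string(index=False))
```

prints

```
thresholds: speed >= 0.068 m/s, polarization >= 0.413
2 events detected (0 below 15 s)
 event_id  duration_s  mean_nnd  mean_polarization  mean_shape  sd_t_speed
sim-e0004        60.5     1.799              0.989       0.954       0.065
sim-e0012        60.5     2.461              0.988       0.932       0.093
```

Exactly the two planted coordinated phases are recovered. Both events are
highly polarized (*P* ≈ 0.99) and strongly oblong (shape ≈ 0.93–0.95:
a single-file column is elongated along its direction of motion); the mean
NND sits near the configured 2 m lattice spacing, and the temporal speed SD
is small, as expected for steady marching.

From a metric table, `SwarmSpacePCA().fit(table)` exposes `eigenvalues_`,
`variance_explained_pct_`, `loadings_`, `contributions_pct_` and `scores_`;
`ss.build_swarm_space(metrics)` runs standardization, contribution-based
metric filtering and t-SNE in one call.

## Command line

```sh
swarmspace simulate -o demo --seed 1          # four-pseudo-species demo data
swarmspace run-all -c demo/demo_config.yaml   # full pipeline, CSV outputs
```

Stages (`ingest`, `space`, `window`, `reliability`) can be re-run
individually; every output directory carries a `manifest.json` with the
package version, config hash and seeds.

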