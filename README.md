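# sasmotility

Quantitative analysis of 3D leukocyte tracks from intravital two-photon
imaging of the spinal subarachnoid space (SAS), the CSF-filled compartment
where autoreactive T helper cells migrate during neuroinflammation. The
package turns manually- or automatically-tracked centroid tables into the
standard motility read-outs of the field, classifies cells by their behavior
relative to the meningeal vessel network, quantifies membrane protrusiveness
from 3D cell masks, and runs the associated statistics — plus a seeded
generator of synthetic cohorts with known ground truth for validating every
step.

It is aimed at imaging labs analyzing T-cell dynamics in inflamed tissue
(e.g. Th1 vs Th17 phenotypes in EAE, or adhesion-blockade experiments) and
at anyone needing a tested, scriptable reimplementation of the classic
Imaris-style track statistics.

## What it computes

For a track with centroid positions $p_1,\dots,p_n$ at times
$t_1<\dots<t_n$:

- **Instantaneous velocity** $v_i = |p_{i+1}-p_i| / (t_{i+1}-t_i)$
  (μm/min), and **track velocity** $\bar v = \frac{1}{n-1}\sum_i v_i$.
- **Arrest index**: duration-weighted fraction of intervals with
  $v_i \le 2$ μm/min (a cell below threshold is "not moving"), plus a count
  of discrete arrest episodes for stop-and-go behavior.
- **Meandering index** $= |p_n - p_1| \big/ \sum_i |p_{i+1}-p_i| \in [0,1]$:
  1 for a straight path, 0 for a closed loop.
- **Displacement and MSD curves**: cohort mean of $|p(\tau)-p(0)|$ (and its
  square) vs elapsed time $\tau$. A random walk gives mean displacement
  $\propto \sqrt{\tau}$ and MSD $= n\,\ell^2$ after $n$ fixed steps of
  length $\ell$; ballistic motion gives $v\tau$ and $v^2\tau^2$ — the
  diagnostic separating directed from diffusive migration.
- **Three-subset classification**: *stationary* (mean velocity ≤ 2 μm/min),
  *perivascular motile* (within 10 μm of a vessel surface for ≥ 80% of
  duration-weighted time; both thresholds explicit in every output), and
  *non-perivascular motile*. Population fractions are summarized per
  imaging field, mean ± SEM across fields.
- **Morphometry**: cell volume from voxel masks, surface vertex counts from
  a marching-cubes isosurface, and protrusion counts as connected
  high-mean-curvature surface patches.
- **Statistics**: Mann–Whitney (exact by enumeration for small tie-free
  samples), Kruskal–Wallis, pooled/Welch t-tests, linear regression of
  displacement on $\sqrt{\tau}$ with an equality-of-slopes test, and a
  single-outlier Grubbs screen.

The synthetic generator is a two-state (motile/arrested) persistent random
walk with von Mises–Fisher turning, optional sign-symmetric drift along an
anatomical axis, vessel-following and swarming modes, parameterized to the
acquisition geometry of spinal-cord two-photon time-lapse volumes
(100 × 120 × 70 μm, 35–40 s frame interval, ≤ 30 min).

## Worked example

```python
import sasmotility as sm

th1 = sm.SyntheticParams(mode="two_state", v_motile_mean=7.0, v_motile_sd=2.0,
                         p_stop=0.05, p_go=0.4, kappa=5.0, drift_bias=0.4,
                         n_tracks=100, n_points=49, seed=1, cell_type="Th1-like")
th17 = sm.SyntheticParams(mode="two_state", v_motile_mean=5.0, v_motile_sd=2.0,
                          p_stop=0.25, p_go=0.35, kappa=1.0, drift_bias=0.0,
                          n_tracks=100, n_points=49, seed=2, cell_type="Th17-like")
ma = sm.metrics_table(sm.generate_cohort(th1))
mb = sm.metrics_table(sm.generate_cohort(th17))
for name, m in [("Th1-like", ma), ("Th17-like", mb)]:
    print(f"{name}: velocity {m.mean_velocity.mean():.1f} um/min, "
          f"meandering {m.meandering_index.mean():.2f}, arrest {m.arrest_index.mean():.2f}")
res = sm.mann_whitney(ma.mean_velocity, mb.mean_velocity)
print(f"Mann-Whitney U={res.statistic:.0f}, p={res.p_value:.2e}")
```

prints

```
Th1-like: velocity 6.1 um/min, meandering 0.88, arrest 0.13
Th17-like: velocity 3.0 um/min, meandering 0.22, arrest 0.44
Mann-Whitney U=9998, p=2.72e-34
```

The "Th1-like" cohort (rare stops, strong turning persistence, axial drift)
moves faster and straighter; the "Th17-like" cohort (frequent stops, weak
persistence) shows the higher arrest index — and the velocity difference is
overwhelmingly significant at n = 100 tracks per group.

The same analyses are available from the shell via the `sasmotility` CLI
(`simulate`, `validate`, `metrics`, `classify`, `morph`, `compare`,
`analyze`); see `sasmotility --help`.

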