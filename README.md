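# finitek

Point-pattern clustering analysis for events that can only occur at a
**finite set of candidate locations** — residential parcel centroids,
addresses, network nodes — rather than anywhere in the plane, with explicit
handling of a spatially clustered covariate and of distance-metric bias.

The motivating application is small-area health research: deciding whether
events such as deliberate self-harm episodes cluster in space *beyond* what
the socio-economic structure of the study area (an area deprivation decile
attached to every address) already explains. Residual clustering at short
range is the classic signature of social contagion.

## The method

Let **x** = {x₁, …, xₙ} ⊂ W be the candidate locations, each carrying an
integer mark mᵢ ∈ M (e.g. deprivation deciles 1–10), and let **q** ⊆ **x**
be the q observed event sites (q ≪ n). The second-order statistic is
Ripley's K over a grid of distance thresholds r:

    K(r) = λ⁻¹ · E[# other events within distance r of an event]

estimated by the per-event mean pair count, with the intensity normaliser
λ = q / max pairwise Euclidean distance (a fixed shared constant, so the
test below is exactly invariant to it). No theoretical πr² benchmark and no
edge correction are used; instead the null distribution is simulated on the
same finite universe:

1. Build the empirical CDF F of the q observed marks.
2. Draw a null pattern: repeatedly pick a mark by inverse-CDF sampling of
   F, then a uniformly chosen candidate site carrying that mark; reject
   duplicates until q distinct sites are selected. This *mark-matched* null
   reproduces the covariate profile of the cases, so clustering that is
   merely inherited from a spatially clustered covariate is absorbed into
   the reference distribution.
3. Repeat n_sim times (default 1000), compute K for every simulated
   pattern, and sort each threshold column. At one-sided level α = 0.05 the
   observed K(r) is significant when it **strictly exceeds** the sorted
   reference value of rank n_sim − ⌊α·n_sim⌋ + 1 — the 951st of 1000.

Euclidean distance is an assumption, not a fact, in gridded street
networks. The sensitivity analysis recomputes the whole test with the
Manhattan metric L₁(a,b) = |x₁−x₂| + |y₁−y₂| while rotating observed and
simulated patterns together through θ ∈ [0°, 90°) (L₁ has period 90°):
conclusions that survive every rotation do not hinge on the metric.

Covariate clustering itself is quantified with lagged Moran's I and the
correlogram over a k-nearest-neighbour graph of area centroids (lag h =
graph shortest-path distance).

Because real address-level health data are confidential, the package ships
a synthetic generator with known ground truth: jittered-lattice parcels,
spatially correlated marks (decile-discretised smoothed noise), and case
sets whose odds rise linearly with mark, optionally with short-range
contagion of controllable probability and radius.

## Worked example

```python
import numpy as np
import finitek as fk

# ~1,800 parcels, clustered deprivation-like marks, 100 cases whose risk
# rises with mark AND with genuine contagion injected at 300 m
cfg = fk.SyntheticConfig(q=100, contagion_prob=0.4, contagion_radius=300.0, seed=7)
locations, cases, flags = fk.generate_dataset(cfg)

model = fk.FiniteRipleyK(locations, cases, thresholds=np.arange(100, 1100, 100))
res = model.fit(n_sim=999, seed=7)
print(res.summary())
```

```
Finite-location Ripley's K — Monte-Carlo envelope test
========================================================
Candidate locations (n):      1823
Observed cases (q):           100
Metric:                       L2
Null mode:                    mark-matched
Simulations:                  999
One-sided alpha:              0.05
Critical rank:                951 / 999
Intensity lambda:             0.0321504 (1/m)
Thresholds significant:       3 / 10
Clustering significant up to: 500 m
--------------------------------------------------------
   r  k_obs  scaled_k_obs  envelope_median  critical_value  excess_above_median  significant
 100  20.53       0.02122             16.8           21.77                3.732        False
 200  81.49       0.08423            70.29           82.74                 11.2        False
 300  192.2        0.1987            154.9           174.8                37.32         True
 ...
```

Even after the null absorbs the covariate structure, observed K exceeds the
one-sided 95% critical value at 300–500 m — the injected contagion scale —
and is indistinguishable from the null at longer range. The rotated sweep
confirms the verdict is not a Euclidean artefact:

```python
sweep = model.fit_rotations(rotations=[0.0, 22.5, 45.0, 67.5], n_sim=199, seed=7)
print(sweep.summary())
```

```
Rotated-L1 distance-bias sweep
========================================
Rotations: 4; n_sim = 199
 theta_deg  n_significant  max_significant_r_m
       0.0              3                500.0
      22.5              2                500.0
      45.0              3                500.0
      67.5              2                500.0
```

`res.plot()` / `res.plot_excess()` draw the λ²K(r) curves with envelope
median and critical line; `fk.correlogram` produces the covariate
lag-autocorrelation table.

The same pipeline is scriptable from the shell:

```bash
finitek simulate --out universe.csv --q 100 --seed 7
finitek analyze --input universe.csv --out-dir results/ --n-sim 999 --seed 7
finitek autocorr --input universe.csv --out lags.csv
```

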