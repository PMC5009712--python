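# Methods

This note records the statistical model, the numerical conventions, the
design choices that were genuinely open, and the limits of what the test
suite demonstrates.

## The estimator

For q events on a finite candidate universe of n marked sites, K is
estimated at each threshold r as

    K(r) = λ⁻¹ · C(r) / q,

where C(r) is the total ordered-pair count #{(j,k): j ≠ k, d(pⱼ,pₖ) ≤ r}
(each unordered pair counts twice, so C is even) and λ = q / D with D the
maximum pairwise Euclidean distance of a reference point set. Balls are
closed (`≤ r`), so integer-distance fixtures are unambiguous.

Two deliberate departures from the textbook estimator:

* **λ has units 1/length, not 1/area.** That is the finite-location
  convention adopted here; λ²K(r) is reported as "the expected number of
  events within r" for display. Because the envelope test is a rank test
  and λ is a shared positive constant, nothing in the inference depends on
  this convention — a property asserted by a dedicated test
  (`test_rank_against_simulations_invariant_to_lambda`).
* **No edge correction.** The null is simulated on the same bounded
  universe, so boundary effects are identical in observed and reference
  patterns and cancel in the comparison. This is a documented property of
  the method, not a configurable option.

λ's reference set defaults to the full candidate universe ("fixed λ"),
computed once and shared by the observed and every simulated pattern; this
makes the rank comparison *exactly* λ-invariant. Normalising each pattern
by its own diameter (`lambda_reference="cases"`) is available but changes
only the scale of reported K values, not the significance flags, whenever
the observed pattern's diameter is used consistently.

The diameter D is found by an exhaustive pair scan, restricted to convex
hull vertices above 500 points (the diameter of a planar set is attained on
its hull).

## The mark-matched null

The null hypothesis is not CSR on the plane but "the case pattern is a
mark-proportional random draw of q distinct sites from the universe". One
simulation draws a mark from the empirical case-mark CDF by inverse-CDF
lookup of a uniform deviate, then a site uniformly within that mark class;
duplicate sites are rejected and the draw restarts (sampling without
replacement at the site level — a set of index episodes cannot contain the
same address twice). Observed case sites remain eligible for null draws:
they are valid candidate sites like any other.

The sampler is batched for speed: a batch of mark draws is grouped by mark
and the within-class site draws vectorised; intra-batch duplicates are
rejected exactly as the sequential loop would reject them, so the sampled
law is unchanged. Rejected draws restart at the mark draw, which means
marks whose class nears exhaustion lose a little probability mass to other
marks; with q well below every class size (the regime the method assumes,
q ≪ n) the distortion is far inside binomial sampling error, as the
mark-preservation test verifies at q = 50 on ~180-site classes.

Errors are explicit: a CDF mark with no carrier in the universe raises
`UnsatisfiableMarkError`; q exceeding the number of eligible distinct sites
raises `CapacityError`.

The **uniform null** (`null_mode="uniform"`) replaces the case-mark CDF
with the candidate-set mark distribution, which is equivalent to drawing
sites uniformly without replacement; it exists to demonstrate what happens
when covariate structure is ignored.

## Envelope and significance

With n_sim simulations at one-sided level α, each threshold column of the
reference matrix is sorted ascending and the critical value is the entry of
1-based rank n_sim − ⌊α·n_sim⌋ + 1 (951 for 1000 at 5%; 191 for 199). The
configuration is rejected when α·n_sim < 1 — fewer simulations cannot
resolve the requested level. Significance is **strict** inequality;
observed K equal to the critical value is not significant. Ties are
possible because K values are scaled integer counts, which makes the test
slightly conservative; with exchangeable simulations the exact rejection
probability is ⌊α·n_sim⌋/(n_sim+1) (e.g. 9/200 = 4.5% for 199 simulations)
minus the tie deficit.

The trace also reports the envelope median and the observed excess above
it, the quantities used for significance-trace plots.

Two calibration caveats, both verified empirically by the acceptance suite:

* When replicate patterns are drawn from a *known* mark CDF and their
  envelopes simulate from that same CDF, replicate and reference are
  exchangeable and the rejection rate sits at the exact level above
  (measured 3.4–6% across seeds at nominal 4.5%).
* The *field procedure* re-estimates the CDF from the observed marks. On a
  strongly clustered mark field this conditioning makes the test mildly
  conservative (measured ≈2.7% at a 4% attainable level in the
  covariate-contrast study): the observed pattern defines the centre of
  the mark-composition distribution its own envelope simulates around.
  Conservatism costs power but never inflates false positives, so a
  significant verdict is trustworthy.

No correction is applied for testing many thresholds simultaneously; the
per-threshold trace is a scale-by-scale diagnostic and the family-wise
error over thresholds is larger than α. Users comparing "significant up
to X m" statements should read them as descriptive of the trace.

## Rotated-L1 distance-bias sweep

L1 distance depends on the frame orientation; rotating all points about the
origin by θ and recomputing K under L1 for a sweep of θ ∈ [0°, 90°) bounds
the sensitivity of conclusions to the metric (L1 has period 90°, and the
centre of rotation is immaterial because only pairwise distances are
consumed). Rotation commutes with site selection, so the implementation
rotates selected patterns rather than the universe. The same null site
draws are reused across rotations (common random numbers): differences
between traces reflect orientation only, not Monte-Carlo noise. The default
sweep is 0° to 90° in 11.25° steps. Angles are degrees throughout the API.

## Lagged Moran's I

Areas are joined by a symmetrised k-nearest-neighbour graph on centroids
(default k = 6, a common contiguity surrogate; the true adjacency rule of
any given study's areal units can be substituted by passing a different
graph). Pairs are stratified by exact graph distance h, and per lag:

    I(h) = (n / Σ wᵢⱼ) · Σ wᵢⱼ zᵢ zⱼ / Σ zᵢ²,   z = value − mean,

with binary weights wᵢⱼ = 1 for ordered pairs at lag exactly h
(row-standardised weights optional), alongside the Pearson correlation of
the ordered lag-h value pairs (the classic correlogram coefficient — the
literature's "autocorrelation coefficient" is not pinned down more
precisely, so the standard correlogram is used and documented). Under
random permutation of values E[I] = −1/(n−1); the suite checks this and
the exact hand-computed fixtures I = −1 for a two-node edge with values
±1 and for an alternating 4-cycle.

## Synthetic generator

What it emulates, and the defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| grid 45×45, spacing 50 m | ~2,000 parcels | desk-scale version of an urban parcel fabric |
| jitter_sd 5 m | lattice irregularity | parcels are not a perfect grid |
| removal_fraction 0.1 | contiguous voids | parks/schools/industrial exclusions |
| field_range 200 m | mark correlation length | marks act like a small-area index assigned over neighbourhood blocks; yields a lag-1 Moran's I ≈ 0.9 declining to ≈ 0 by lag 7, the qualitative correlogram shape of real deprivation fields |
| n_marks 10 | decile index | equal-count levels, n/10 ± 1 sites each |
| q 100 | cases | q ≪ n regime |
| risk_slope 0.5 | linear odds in mark | decile-10 site 5.5× decile-1; produces the strong mark–frequency gradient such studies report |
| contagion_prob 0, radius 300 m | optional mechanism | parent-uniform: pick an existing case, place the new one uniformly on a free parcel within the radius (fall back to the covariate draw if none) |

The latent mark field is white noise smoothed with a Gaussian kernel of
sd = field_range/2, giving spatial correlation ≈ exp(−d²/field_range²)
(1/e at field_range) — a cheap surrogate for Gaussian-process sampling
that induces controllable Moran's I, which is all the method needs from
it. Discretisation is by rank, so mark levels are exactly balanced across
the universe (real deprivation deciles are balanced across areas, not
across parcels — an accepted simplification).

Case placement is sequential; order effects are irrelevant to K, which
sees only the final site set. With risk_slope = 0 and no contagion the
mechanism reduces exactly to uniform sampling without replacement
(χ²-checked). Because the covariate weight is constant within a mark
class, covariate-only case sets conditioned on their mark composition are
uniform within classes — precisely the null the mark-matched test
simulates, which is why the adjusted test stays near its nominal level on
covariate-only data while the uniform test does not.

What the generator does **not** emulate: real parcel geometry and size
heterogeneity, multiple covariates, temporal structure, repeat episodes at
one address, and meshblock-shaped mark boundaries (marks vary smoothly
rather than piecewise-constantly). Passing tests demonstrate the method's
internal correctness and calibration under a realistic-but-idealised
mechanism, not external validity on any particular city's data.

## Problem sizes and numerical conventions

The suite and the calibration script run at desk scale by design: ~1,800
candidate sites, q = 100, envelopes of 199 (calibration replicates) or
999–1000 (single analyses) simulations, 500 calibration replicates. These
sizes put exact binomial 95% bands around every stochastic assertion;
enlarging them tightens the bands without changing any conclusion.
Distances compare with ≤; thresholds must be strictly increasing and
positive; all randomness flows through `numpy.random.Generator` seeded
from a single integer, and every result object is bit-reproducible given
its seed. Degenerate inputs (coincident reference points, zero-variance
covariates, empty lag classes, unsatisfiable marks) raise typed errors
rather than returning NaNs.

## I/O conventions

Coordinates must be planar projected metres; input whose coordinates all
fit inside |x| ≤ 180, |y| ≤ 90 is refused as likely lon/lat unless
explicitly overridden, because every distance in the method is metric.
CSV (columns `x,y,mark,is_case`) is canonical; GeoJSON Point/Polygon
features are accepted with polygons reduced to centroids. Parcel
area-percentile filtering (default: drop below the 5th and above the 95th
percentile, linear-interpolation percentiles with inclusive bounds so tied
typical areas are never discarded) mirrors the usual screen for
non-residential space-fillers.
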