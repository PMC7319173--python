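# Methods

This note documents the models, rules, and numerical choices behind
`sealtracks`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Movement model (track module)

The track estimator is the standard continuous-time correlated random walk
(CTCRW) state-space model of movement ecology. Per axis of an equal-area
plane, the state is (position x, velocity v) with

    dv = −β v dt + σ dW        dx = v dt

β (1/hr) is the inverse velocity-decorrelation time; σ (km/hr^1.5) the
velocity noise scale; the stationary speed scale per axis is σ/√(2β). The
exact discretization over a step Δ uses e = exp(−βΔ):

    F = [[1, (1−e)/β], [0, e]]
    Q_vv = σ²(1−e²)/(2β)
    Q_xv = σ²(1−e)²/(2β²)
    Q_xx = σ²/β² · (Δ − 2(1−e)/β + (1−e²)/(2β))

Observations are projected fix coordinates with isotropic class error SDs
(defaults 0.25 / 0.5 / 1.5 / 4 / 8 / 15 km for Argos classes 3/2/1/0/A/B;
class Z is never modelled, only rejected). The two axes share (β, σ) and
are filtered independently; the likelihood is the exact Kalman prediction
decomposition, maximized over (log β, log σ) by Nelder–Mead (xatol 1e-4,
fatol 1e-6). The filter initializes at the first fix with its own error
variance and a zero-velocity prior of variance max(σ²/(2β), 1). Smoothed
states come from a Rauch–Tung–Striebel pass in closed-form 2×2 arithmetic;
a degenerate (singular) prediction covariance leaves the filtered state
unchanged. The reported `se_km` is the RMS of the two per-axis posterior
position SDs. The smoother is verified against a dense joint-Gaussian
conditioning solve (an independent linear-algebra route) to 1e-6.

**Projection.** A spherical Lambert azimuthal equal-area projection
(IUGG mean radius 6371.0088 km) centered on the study area, implemented in
closed form; forward∘inverse round-trips to below 1 m. Habitat distances
use great-circle (haversine) distances on the sphere, not planar distances.

**Plausibility prefilter.** Order: drop class Z; de-duplicate timestamps
keeping the best class; drop on-land fixes; iteratively remove fixes
implying >10 km/hr to *both* neighbors (worst first); remove out-and-back
spikes (interior angle <15° with both legs >5 km/hr and >0.5 km). All
rejections are logged with reasons, and the filter is idempotent. The
thresholds are conventional pinniped plausibility values and configurable.

**Identifiability.** With mostly class-A/B fixes (8–15 km SD) at ~0.5-hr
gaps, per-step displacements (~1–2 km) are far below the error floor and
the likelihood is nearly flat in β: long-run diffusion σ²/β² stays well
determined but β and σ individually do not. This is a property of
error-dominated Argos streams, not of the estimator. The parameter-recovery
experiment therefore simulates high-quality classes (3/2/1), where ~2,000
fixes recover β and σ to a few percent and ~95% of true positions fall in
the 95% prediction ellipse; on the default class mix, only track locations
(not β itself) should be interpreted.

## Synthetic data (generator module)

The generator is the study-conditions oracle: every planted quantity is
exactly recoverable in principle, and its defaults encode the magnitudes of
a shelf-resident Arctic seal deployment:

- fix gaps exponential with mean 0.75 hr (median ≈ 0.52 hr) plus 2% long
  gaps of 6–24 hr; ~7% of fixes in classes 1–3; 5% class-Z outliers;
- behavior planted as an explicit non-overlapping interval schedule, not a
  Markov chain, so recovery tests have unambiguous truth: per day an
  hour-aligned haul-out window of 5–7 hr and a repetitive/mixed/resting
  fill giving ~16 hr/day diving, ~80% of it repetitive;
- repetitive intervals emit dives within ±6% of a target depth (well inside
  the ±15% classification tolerance, so planted episodes cannot straddle
  it), surface gaps lognormal with 0.7-min median truncated below 10 min;
- mixed intervals draw log-uniform depths with each new depth forced >20%
  away from both preceding depths, so mixed sequences cannot form spurious
  repetitive chains;
- resting intervals emit sparse shallow dips separated by 12–25 min
  surfaces; haul-out intervals emit no dives;
- dive durations follow a + b·ln(depth) + noise with a = 0.5 min,
  b = 1.1 min (≈3.8 min at 20 m, medians ~4 min), truncated to
  [0.5, 14] min; depths are quantized to the 0.5-m tag resolution and
  capped at 95% of the bathymetry under the concurrent true position;
- percent-dry values are drawn from two disjoint uniform modes (85–100 dry,
  0–20 wet), reproducing the strongly bimodal hourly distribution real
  conductivity sensors show;
- sensor dropout: hourly percent-dry records kept independently with
  probability 0.72; the dive stream observed in alternating on/off
  exponential windows (8-hr mean on-time) hitting a 0.30 coverage target,
  matching typical transmitted-data fractions;
- rasters on a 25-km equal-area grid: a southern mainland strip, a shelf
  island, a coastal band, a shelf (<300 m), a break ramp to 1,400 m and a
  basin to ~3,500 m, with smooth seeded relief; the daily ice edge follows
  a sinusoid of day-of-year (maximum advance mid-March well south of the
  coast, maximum retreat mid-September into the basin) with a 40-km
  logistic concentration ramp to 96%, smooth noise of ±8, so the mid-winter
  shelf sits at ≥80% concentration.

Not emulated: Argos duty-cycling firmware, CTD profiles, dive-shape
classes, ice motion, or real SSM/I vs AMSR product geometry. Passing
recovery tests therefore demonstrates correctness of the pipeline's rules
and estimators under realistic magnitudes — not robustness to every
artifact of real tag data (e.g., saltwater-sensor pooling failures are
deliberately out of scope).

## Behavior segmentation (operational rule)

The classification concepts — resting surfaces >10 min; repetitive = ≥5
sequential dives within ±15% of either of the two preceding dives, single
deviants allowable; mixed = the rest — leave several details open. The
package fixes them as follows (and the exhaustive reference implementation
used for validation encodes the same choices):

1. The record is split at surfaces >10 min; comparisons never cross a
   resting boundary.
2. The ±15% tolerance is relative to the *preceding* dive's depth, with a
   2-m floor on the denominator (tag depths below ~2 m are noise-scale).
3. Each dive (after the segment's first) gets a consistency flag against
   its two predecessors. An inconsistent dive is tolerated inside a chain
   only when isolated; wherever two inconsistencies are adjacent the chain
   is cut. A trailing inconsistent member is split off (a deviant must be
   *within* an episode).
4. A chain is repetitive when it retains ≥5 consistent members (the chain
   head counts; interior deviants belong to the episode but do not count
   toward the five). Everything else is mixed; adjacent mixed fragments
   merge into maximal mixed episodes.

On clean planted data this rule recovers >99% of repetitive dive-minutes
and mislabels <2% of mixed minutes; boundary dives at behavior transitions
are the only ambiguous cases.

## Habitat metrics

Ice components use 8-neighbor connectivity (diagonal floes are physically
contiguous). A periphery cell is a qualifying-ice cell with at least one
*sea* non-qualifying neighbor — land and the grid border do not create an
edge. The signed distance is the great-circle minimum to any qualifying
component's periphery cell centers, negative when the query point's cell
belongs to a qualifying component. Mainland distance uses the largest
connected land component only. The mean ice concentration averages sea
cells whose centers fall within 50 km (unweighted); an all-land disc is
missing. Zones: shelf <300 m, break 300–1,000 m inclusive, basin >1,000 m
(the boundary values land in the excluded break band, matching how the
zone day-counts partition). Forays are maximal runs of consecutive basin
days; a single sandwiched break-zone day bridges a run (shelf-break
transit should not split an occupancy) — configurable, and a documented
choice since the underlying definition is silent on it.

## Activity budgets

For seal-month m with observed percent-dry hours O and flagged haul-out
hours H: haulout_h = (H/O)·T where T is the month's hours (pro-rated to
the deployment span for partial first/last months). The remaining T −
haulout_h hours split by the diving : resting time ratio observed in the
dive record, where diving time is episode span time (repetitive + mixed,
including internal surfaces ≤10 min) and resting time is surfaces >10 min
that do not overlap a flagged haul-out hour (overlapping ones were already
counted as haul-out and are discarded). Diving hours split further by the
repetitive : mixed span ratio. All tallies intersect the dive-sensor
coverage windows — a surface spanning a sensor-off gap is unobserved, not
resting. Inclusion requires ≥10% dive-stream coverage and mean coast
distance ≥5 km; a month with no percent-dry data is excluded outright. The
identity haulout_h + dive_h + rest_h = T holds exactly by construction.
The first post-deployment week is removed before all behavior summaries.

## Validation experiments and problem sizes

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes:

- segmentation vs the plain-loop reference on 1,000 random ≤12-dive
  sequences drawn from a coarse depth alphabet (ties near the tolerance
  arise often) — exact agreement;
- ice-edge distance vs a brute-force flood-fill/periphery scan on 200
  random rasters up to 50×50 — exact agreement;
- CTCRW recovery: 20 replicates of ~2,000 fixes (87-day spans, quality
  classes), median |relative error| of β and σ and pooled 95%-ellipse
  coverage;
- budget recovery: 20 replicates of 4-seal one-month cohorts at 30%
  coverage of both streams; median (over replicates of within-cohort
  medians) |relative error| of haul-out and diving hours, and the worst
  conservation gap;
- exact recovery of duration = 2 + 1.5 ln(depth) from noiseless bin
  medians (S = 0);
- the median fix interval of a default two-month simulated stream.

These sizes give stable medians in a few minutes on one CPU; the same
experiments back `tests/test_acceptance.py`.

## Known limitations

- β is unidentifiable on error-dominated Argos streams (above); no error
  multiplier is fitted by default.
- The haul-out ratio estimator is binomial in the observed hours: at 30%
  hourly coverage of a month its sampling SD is ~10%, so single-seal-month
  haul-out extrapolations carry that noise irrespective of implementation.
- Diel profiles weight events (dives, episodes), not time-in-behavior.
- No uncertainty intervals accompany extrapolated budgets.
- The spherical projection ignores ellipsoidal effects (<0.4% in distance),
  consistent with the 25-km raster scale.
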