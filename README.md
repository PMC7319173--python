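# sealtracks

Analysis pipeline for satellite-tagged ice seals: from raw Argos location
fixes, time-depth-recorder dive records, and wet/dry sensor summaries to
interpolated tracks, sea-ice habitat metrics, dive-behavior classification,
diel activity profiles, and monthly activity budgets. Written for movement
ecologists working with Arctic pinniped biologging data (ringed seals on the
Chukchi/Bering shelf are the motivating system), and built around a seeded
synthetic-data generator so every stage can be validated against known
ground truth without field data.

## What it computes

**Track interpolation.** Argos fixes are cleaned with a plausibility filter
(on-land fixes, movement-rate > 10 km/hr to both neighbors, out-and-back
spike geometries below 15° at speed) and modelled with a continuous-time
correlated random walk (CTCRW): per axis of a Lambert equal-area plane, the
velocity is an Ornstein–Uhlenbeck process

> dv = −β v dt + σ dW,  dx = v dt

observed at fix times with Argos-class error SDs. β (1/hr) is the velocity
autocorrelation, σ (km/hr^1.5) the noise scale. Parameters are estimated by
exact Kalman-filter maximum likelihood; a Rauch–Tung–Striebel smoother
yields positions every 6 hr with standard errors, and estimates with
SE > 25 km are dropped.

**Habitat annotation.** Each day's midday-UTC position is annotated with
ocean depth, great-circle distance to the mainland (largest connected land
component; islands excluded), mean sea-ice concentration within 50 km, and
the signed distance to the ice edge — the periphery of ≥15%-concentration
ice components spanning ≥10 contiguous 25-km pixels, negative from inside
the pack. Days are partitioned into shelf (<300 m), shelf-break
(300–1,000 m), and basin (>1,000 m) zones, and multi-day basin occupancies
are reported as off-shelf forays.

**Dive behavior.** Hours ≥80% dry are haul-out hours. The dive series is
segmented into *resting* (surface intervals >10 min), *repetitive diving*
(≥5 sequential dives within ±15% of either of the two preceding dives, one
isolated deviant allowed), and *mixed diving*. Dives reaching ≥75% of the
mapped ocean depth are bottom dives (indeterminate under 10 m of water).
Hour-of-day × month proportion matrices (local time, UTC−10) describe diel
patterns, and bin-median dive/surface durations are regressed on ln(depth).

**Activity budgets.** Per seal-month, the observed haul-out fraction of the
wet/dry stream scales to total haul-out hours; remaining hours are split by
the observed diving : resting time ratio, and diving by the
repetitive : mixed ratio. Seal-months with <10% dive-stream coverage or a
mean coast distance <5 km are excluded.

## Worked example

`examples/` holds one narrative script per capability. For instance:

```bash
$ python examples/01_simulate_and_interpolate_track.py
simulated 492 fixes (median gap 0.52 hr)
prefilter kept 219; rejections: {'speed': 225, 'class_z': 26, 'spike': 22}
fitted CTCRW: beta=0.71/hr (true 1.0), sigma=1.58 km/hr^1.5 (true 2.0)
83 six-hour estimates (0 dropped for SE > 25 km); SE range 0.8-6.7 km
cumulative distance over 21 days: 335 km (16.0 km/day mean)
```

The median fix gap matches the ~0.5-hr cadence of real deployments; the
fitted β/σ land below truth here because most fixes carry 8–15 km class
errors, which dominate hourly displacements (see `docs/methods.md`). And:

```bash
$ python examples/04_monthly_activity_budget.py
seal     month    sample%  haulout_h (true)  diving_h/day (true)
seal01  2016-07    22.9     197.9 (186.0)       16.0 ( 16.5)
seal02  2016-07    23.4     188.4 (193.0)       15.7 ( 15.8)
...
```

— with under a third of each sensor stream observed, the extrapolated
haul-out and diving hours sit within a few percent of the planted truth,
and the components sum exactly to the month's hours.

A thin CLI wraps the same library calls:

```bash
sealtracks simulate --seed 3 --outdir data/
sealtracks validate --indir data/
sealtracks run-all --indir data/ --outdir out/   # or: track / habitat / behavior / budget
```

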