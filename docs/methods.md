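# Methods

This note records the model, its parameter conventions, and the design
choices made where the published description of the system leaves the
design open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Distribution-expression dialect

Fitted input models are strings of the form
`offset + scale * FAMILY(p1, p2, ...)`. The parameter conventions follow the
originating simulation dialect, because any other reading makes several of
the printed expressions nonsensical:

| Family | Parameters | Mean |
| --- | --- | --- |
| `BETA(α₁, α₂)` | shapes, on [0,1] before offset/scale | α₁/(α₁+α₂) |
| `LOGN(M, S)` | **arithmetic** mean and SD | M |
| `GAMM(β, α)` | scale, shape | αβ |
| `ERLA(β, k)` | exponential mean, integer stage count | kβ |
| `WEIB(β, α)` | scale, shape | β·Γ(1+1/α) |
| `NORM(μ, σ)`, `UNIF(a, b)`, `TRIA(min, mode, max)` | as written | standard |
| `POIS(λ)` | rate; integer minutes when used as a duration | λ |
| `DISC(c₁,v₁,…,1,vₖ)` | **cumulative** probability/value pairs | Σ(cᵢ−cᵢ₋₁)vᵢ |

`LOGN`'s internal (μ, σ) come from σ² = ln(1+(S/M)²), μ = ln M − σ²/2. A
normal used as a duration is resampled until nonnegative; rejection
preserves the shape on the positive axis better than clamping, and for the
packaged expressions the truncated mass is ≤ ~0.3%, so the induced bias is
far below sampling noise at the sizes used. Category codes in `DISC`
severity/vehicle columns are read as 1 = non-critical / wheelchair, 2 =
critical / bed; this mapping is inferred from the one station whose severity
is always 2 (the ICU, where every transfer is critical and by bed) and from
wheelchairs dominating the observed vehicle mix. It is a convention, not an
observed fact.

## Network and demand calibration

The default configuration has 26 stations. Nineteen carry the three fitted
expressions (severity, operated time, vehicle) and can originate requests;
seven are pass-through locations (drop points, exit, transfer bases) that
appear only as destinations or porter homes. Porters are homed at the two
transfer bases, ordered so the lowest staff indices sit at the base closest
(rate-weighted) to the bulk of demand — the emergency-side base — which is
how a real transfer center allocates its roster and avoids the pathological
default of sending the far porter to every job.

Arrivals are homogeneous Poisson within each shift (Night 00:00–08:00,
Morning 08:00–16:00, Afternoon 16:00–24:00; boundaries configurable). The
published record gives per-period daily totals (2.31 / 49.54 / 11.77
requests per day, ≈827 transfers over the 13-day campaign) but not the
per-station rates or the routing matrix, which were never released. The
packaged defaults are therefore calibrated stand-ins: station weights
concentrate demand on the emergency and outpatient departments (the flows
described for the study site — ED→radiology/wards, ward→ICU/OR, ICU→ward),
scaled so the per-period daily totals match the published means exactly in
expectation. The travel matrix is likewise synthetic: derived from plausible
blueprint coordinates at walking speed plus an elevator penalty per floor
change, giving 0.5–5 minute entries. Consequences:

* per-period demand volumes and all structural behaviour are faithful;
* absolute waiting-time levels are **not** comparable to the published
  per-scenario means (those depend on the unreleased calibration, under
  which the study hospital was far more congested than these defaults
  produce). The pipeline's claims about the engine are therefore structural:
  conservation, determinism, exact priority compliance, and the directions
  of the staffing/demand/policy contrasts — not their magnitudes.

## Dispatch model

A porter's job timeline: travel (empty) from current location to the
origin; `departure` when the patient starts moving; the origin station's
operated-time draw covers the loaded move to the destination (that is what
a stopwatch at the origin measures); then return to base, or — under policy
b — continue directly to the next queued job, returning only when the queue
is empty. Wait-and-return jobs (e.g. ward → imaging → ward) take the
origin's draw out, then the intermediate station's draw as the procedure
wait and again as the return leg, with the porter staying with the patient.
Waiting time is `departure − request`: queueing plus dispatch travel, the
only delay measure computable from every record of the field-log schema.

Policy semantics, where the published description is one sentence each:
policy a orders the queue (critical first, FIFO within class, ties by
request id); policy c compares idle porters by travel time to the origin
("most accessible" read as nearest-by-travel-time, not soonest-available);
policy d by cumulative busy minutes; the chaining porter under policy b
takes the head-of-queue job itself — c/d arbitrate only among idle porters
at dispatch events. The emergency flag is carried through but does not
affect priority beyond severity; nothing in the published description says
it should. Requests still in flight at the horizon are finished in overtime
and flagged rather than dropped, so generated = completed holds exactly and
waiting-time means are not truncation-biased.

## Randomness and pairing

Each replication derives from one integer seed. Every (station, shift, day)
arrival cell and every individual request gets its own keyed substream, so
a replication is bit-reproducible and — more importantly — contrasts are
paired: policy variants see the identical request stream, and a 120% demand
stream is the 100% stream plus an independent 20% superposed stream, so the
base jobs are bit-identical across demand levels. This common-random-number
structure is what makes the ordering checks (more staff ⇒ shorter waits,
more demand ⇒ longer waits, chaining ⇒ no worse) resolvable at 30
replications in a lightly loaded system; the demand contrast at the full
8-porter roster remains the weakest, its true effect being of the order of
tenths of a second under the default calibration.

## Input analysis

Support is estimated as `min − 0.5` to `max + 0.5` — the half-unit padding
that integer-minute stopwatch records produce, and visibly the convention
behind the printed offsets (2.5, 1.5, 0.5, …). Parameters are maximum
likelihood on the shifted data (method of moments as fallback); the Erlang
stage count is the gamma shape MLE rounded to the nearest positive integer
with the scale re-estimated at that k. Families are ranked by histogram
squared error (Sturges bins, configurable) then Kolmogorov–Smirnov — the
selection criterion of classical input-analysis tools, which do not
document their exact binning.

Limits of identifiability, which the tests respect: a gamma and an Erlang
of near-integer shape are not separable by goodness of fit; a Poisson with
rate ≈15 is practically normal, so count rows cannot be expected to beat a
fitted normal by histogram GOF at n = 20,000. Family-identification checks
therefore pit each continuous family against dissimilar alternatives, on
integer-rounded samples matching the recording convention.

## Statistical procedures

Both procedures work from summary statistics. The Welch df is truncated
(not rounded) to an integer, matching the reporting convention of the
statistics package the published tables came from; fractional df is
available via a flag. Tukey comparisons assume the balanced design the
experiment produces (equal n); MSE is the mean of group variances,
simultaneous CIs use the studentized-range quantile, adjusted p-values its
tail probability, floored at 0 and capped at 1, evaluated by scipy's
numerical integration. Reproduction from *printed, rounded* summary inputs
matches the published derived values to their printed rounding only — e.g.
a CI bound may differ by one unit in the last printed digit because the
original computation used unrounded internals.

## Synthetic observation logs

`generate_log` runs the baseline scenario (no policies, 100% demand,
8 porters) and renders the records in the hand-collected field-log CSV
schema: HH:MM clock times, N/M/A period codes, department names, vehicle,
porter ID, condition, emergency status, with lossless minutes-from-start
columns alongside. The emergency proportion (default 0.1) is configurable
and invented — no rate was published. The generator reproduces the schema
and the statistical structure the analysis assumes (Poisson per-period
volumes, per-station severity/vehicle/duration laws); it does not emulate
observer error, missing data, porter shift rosters, or elevator contention
(the travel matrix absorbs the elevator on average). Passing tests
demonstrate pipeline self-consistency on data with exactly the assumed
structure, not robustness to real-world recording artefacts.

## Sizes used by the tests and acceptance script

The experiment design is 13-day replications, 30 per scenario. The
acceptance script runs the full 20-scenario grid at that design (~45 s on
one CPU); the test suite runs the scenario subsets each property needs.
Distribution-layer checks use 10⁵ draws per expression (3-standard-error
bands); recovery checks use 20,000 draws per family (10% tolerance);
validation round trips use a 13-day synthetic log against a 30-day
simulation. Welch self-consistency p-values are uniform under the null by
construction, so any fixed seed has a ~5% per-period chance of dipping
below 0.05; the suite pins seeds, and the acceptance script reports the
p-values at whatever seed it is given.
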