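# Methods

This note documents the models, contracts, parameter choices and numerical
decisions behind fleetkit, and what the synthetic fixtures do and do not
establish about real deployments.

## Vessel lifecycle

A vessel is a state machine over {OFFLINE, LOADING, ONLINE}. `reload()`
runs the builder with the dependency component handles passed positionally
in declaration order, then the optional initializer; any raised error (or a
builder returning `None`, which is read as "no component matched") leaves
the vessel OFFLINE with a structured error record and exactly one logged
ERROR. If the initializer fails, the invalidator *is* run on the partially
built component before the build is declared failed: the component exists at
that point, so teardown is owed. Reloading an ONLINE vessel first
invalidates it (cause USER, without cascading) and rebuilds, so component
identity changes and the builder/invalidator counts stay balanced.

`execute_call(action)` is the only sanctioned path into component code.
On an OFFLINE vessel the action is never invoked and a "not available"
error is returned. A raising action invalidates the vessel with cause
LOCAL_FAILURE and returns the error; nothing propagates to the caller. This
gives the package-wide invariant that for counting builders/invalidators,
`#invalidator ≤ #builder` always, and `#builder = #invalidator + 1` exactly
when the vessel is ONLINE — provided builders themselves succeed (a builder
that raises consumes a builder invocation with no matching teardown, which
is why the conservation property is exercised with failures injected
through component calls, not through builders).

The activity flag is orthogonal to lifecycle state: an inactive vessel is
not polled, receives no messages, and leaves its queued messages untouched;
it can remain ONLINE throughout.

Defaults: `queue_capacity = 64`, QUEUED handling, active at creation,
stdout capture on. Capture reroutes writes on the calling thread to the
fleet logger (attributed to the vessel) via a reference-counted stdout
router, so concurrent captures compose and threads outside any capture pass
through untouched.

## Link graph

Edges derive exactly from declared dependencies (dependency → dependent).
Ranks are longest-path depth from the roots; ties within a rank are broken
alphabetically so startup, cascade and shutdown orders are deterministic.
Cycles are a fatal configuration error naming the vessels involved.

`cascade_invalidate` takes the origin down with the given cause and every
descendant with cause CASCADE, ascending rank. Vessels that were already
offline keep their previous cause and are not counted in the returned set
(the origin always is). `restore_segment` reloads the origin and then every
descendant that is OFFLINE *with cause CASCADE* and whose dependencies are
all online, ascending rank — one pass suffices because dependencies always
precede dependents in rank order. Vessels stopped by the user are never
auto-revived; this is the package's resolution of an ambiguity in how much
of an impacted segment a repair should restore — restoring cascade
collateral honours the repair, while respecting explicit user stops. Data
graph connections never carry failures in either direction.

Shutdown invalidates in descending rank (dependents first) with cause
SHUTDOWN and is idempotent.

## Data plane

Routes are computed from declared types: exact match, or a widening the
fleet explicitly registered. There is no implicit structural or subclass
acceptance — predictability over convenience. Same-vessel self-routing is
excluded so a transformer emitting its own input type cannot feed itself.
A consumer with a source filter that names specific origin vessels is
pruned at build time from routes leaving excluded *sources* (their origin
is statically known); routes from transformers are kept and filtered per
message at dispatch.

Dispatch is multicast: each compatible, online, active consuming vessel
receives the message once (all of its matching operations see it during
processing). QUEUED vessels get a non-blocking enqueue — a full inbox drops
the *newest* message, logs a warning and increments a per-vessel dropped
counter. Drop-newest was chosen because overload is a reportable failure
mode, not a condition to mask: the queue keeps its oldest (least replaceable)
backlog, the system stays live, and the counter plus occupancy make the
overload observable. DIRECT vessels process synchronously in the caller's
flow under the same per-vessel sequentiality lock.

Message ids come from one fleet-global atomic counter starting at 0, so
ids are strictly increasing in emission order across the whole fleet.
Timestamps are monotonic-clock nanoseconds; wall-clock time appears only in
log records. Transformer hops renew sender, id and timestamp while
preserving the original source and its rate. Sources are driven by
`generate_data`, re-invoked while the body reports `has_more`, capped at
`queue_capacity` invocations per call so a greedy source cannot starve the
scheduler. Polling threads use absolute deadlines (start + k·period) so a
slow emission does not accumulate drift. Messages queued at invalidation
are retained and processed after a restore.

## Services, settings, logging

The services pool maps service type → instance, constructed on first
request under a per-type lock (a failing constructor caches nothing; the
next request retries), with a per-instance access guard for callers that
need the service serialized. Settings use the nested-element XML dialect:
`fetch_setting(path, name)` walks child elements and reads an attribute,
returning `None` for anything missing; only a malformed file raises (with
line/column). The logger has eight ordered levels — TRACE < DEBUG < INFO <
NOTICE < WARNING < ERROR < CRITICAL < FATAL; the count is contractual, the
names are this package's choice — an in-memory ring (10 000 records) and an
optional `ISO8601<TAB>LEVEL<TAB>origin<TAB>text` file. Vessel state changes
are logged at NOTICE, framework-caught errors at ERROR, exactly once each.
Metadata collection snapshots requested component attributes through the
execute-call guard with a missing-attribute default, so an unknown
parameter reads as `<missing>` rather than as a component failure.

## Waveform sequencing

Synthesis renders `round(rate · duration)` samples (at least one).
SINE is `offset + A·sin(2πf·i/rate + φ)`; SQUARE is high
(`offset + A`) for the first `duty` fraction of each period and `offset`
otherwise; RAMP rises from `offset` to `offset + A` per period (or across
the whole duration when no frequency is given); CONSTANT holds `offset`;
SAMPLES passes an explicit list through after a length check. Indices are
0-based; virtual-event positions are half-open `[0, length)`. Digital
tracks are stored as 0/1 floats so every channel shares one array
representation. The sequencer requires one sample rate and one channel set
across the schedule and offsets virtual events by the cumulative position
of each repetition. `run_virtual` validates handler coverage up front,
fires events in absolute order on a simulated sample clock, and records a
raising handler in the fired log without stopping the run. Only a simulated
device exists; hardware adapters are out of scope by design.

## Synthetic tracking demo

The renderer draws a static smooth random texture (per-seed), a fixed head
blob, and a tail of `segment_count` straight segments whose absolute angles
follow a travelling wave `θ_k(t) = heading + A·sin(2πf·t/rate + kφ)`; the
generating angles ride along with each frame as hidden ground truth.
Defaults — 160×120 px, 100 frames/s, 5 segments of 14 px, A = 0.5 rad,
f = 2 Hz, φ = 0.4 rad/segment, Gaussian pixel noise σ = 3 — are a
scaled-down but kinematically faithful stand-in for a head-fixed larva
recording; they were chosen once as a realistic operating point and are not
tuned per test.

The background model is the per-pixel median of the first K = 50 frames
(the tail occupies any given pixel well under half the time, so the median
converges on the background); subtraction keeps |frame − model| above a
threshold (default 10 gray levels). The tracker is the classical sequential
arc search: from the head (known, the preparation is head-fixed) and the
resting heading, 31 candidate directions over ±0.7 rad are scored by summed
bilinear foreground intensity at radii {0.5, 0.75, 1.0}·L, and the next
angle is the intensity-weighted mean of the candidates with weights
squared (sharpening the centroid without the brittleness of a pure argmax).
A step whose total arc intensity falls below a floor marks the frame a
tracking failure in the result rather than raising.

What the fixture does *not* emulate: real optics (shading, vignetting,
motion blur), body pigmentation variation, occlusions, or drift of the head
position. Passing tests show the pipeline and its orchestration are
correct, and that the tracker recovers known kinematics through the whole
fleet; they do not certify accuracy on real video.

The demo fleet mirrors the interactive application: camera → background
subtractor → tracker, with a display stub, a binary frame writer
(16-byte header `SFRM`, width, height, frame index as little-endian uint32,
then raw uint8 pixels) and a text metrics writer
(`frame_index<TAB>angle_1..angle_N`), both depending on the
experiment-metadata vessel that creates one output folder per export and
owns the recording paths. The scripted protocol — configure, export,
reload writers and camera, record — reproduces the export-then-record
workflow.

## Overhead benchmark

The test operator is a pure multiply-add loop, `iters_per_unit × difficulty`
iterations, difficulty 1–10; `TestOperator.calibrated()` sizes the loop once
per machine so difficulty 1 lands near 2 ms (the 1–10 range then spans
roughly 2–20 ms). Reference times come from direct invocation with warmup
discarded. The framework path is a six-vessel chain — rate-limited request
source (one request per poll tick at 50 Hz by default), a timestamper
vessel, the operator vessel, a second timestamper, a difference calculator,
and a text writer — so the measured interval crosses real inter-vessel
dispatch. Queue saturation or drops during a run set an overload flag
rather than raising, reproducing overload as an observable failure mode.

Overhead is the slope of the no-intercept least-squares fit
`T_framework = a·T_ref`, computed in closed form `a = Σxy/Σx²`, reported as
`a − 1`. The fit pairs the per-difficulty *mean* framework time with the
per-difficulty *best-of* (minimum) reference time: scheduling noise only
ever inflates a timing sample, so the minimum is the least contaminated
estimate of the pure compute time. Absolute overhead percentages depend on
the host machine and are not comparable across hardware; the package
asserts only the mathematical exactness of the fit and that a live run
measures a slope of at least one.

## Problem sizes in the shipped checks

The test suite and the acceptance script use: 200 random DAGs of up to 20
vessels for ordering/containment properties; 25 randomized 40-step
fail/restore scripts for lifecycle conservation; 120–200 interleaved
emissions for FIFO checks; a 2 s live run at 50 Hz for producer isolation;
100 threads for the singleton race; 100 random schedules for sequencer
conservation; a 500-frame movie for tracker recovery; and 6 samples at
difficulties 1–3 for the live overhead floor. These sizes were chosen so
each property is exercised across a meaningful space while the whole suite
stays fast enough to run habitually.

## Known limitations

* In-process only: no cross-process or network transport, no message
  persistence.
* Routing is nominal (declared types plus registered widenings); two
  structurally identical payload classes do not route to each other.
* The per-vessel worker model processes one message at a time per vessel by
  design; a vessel cannot parallelize its own inbox.
* The stdout router attributes output by thread; component code that prints
  from private threads it spawned is logged as passthrough, not attributed.
* Timing-based guarantees (poll rates, isolation tolerances) are
  best-effort on a non-real-time OS; the shipped tolerances (±20%) reflect
  that.
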