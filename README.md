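# fleetkit

Fault-tolerant dataflow orchestration for desk-scale instrument control and
data acquisition, written for labs that run custom experimental rigs — a
camera, a stimulus display, a tracking algorithm, a couple of writers — as a
single desktop application and need the rig to *keep running* when one part
of it breaks.

## The model

Every system component (a camera driver, an image-processing stage, a file
writer) is wrapped in a **vessel**: a lifecycle guard holding the
component's *builder*, optional *initializer* and *invalidator* procedures,
an online/offline state, a user-controlled activity flag, and a bounded FIFO
**inbox queue**. All external code touching the component goes through a
guarded *execute call*: an exception raised inside component code never
propagates to the caller — it is logged, and the vessel is invalidated.

The set of vessels and their connections is a **fleet**, wired by two
distinct graphs:

* the **link graph** — a dependency DAG (edge *u → v* iff *v* declares *u*
  as a dependency). It orders startup (rank = longest-path depth; a vessel
  only starts once everything it depends on is online) and contains
  failures: invalidating a vessel cascades to all of its link-graph
  descendants, and *only* those. A repaired vessel can be restored together
  with the segment that went down as its collateral.
* the **data graph** — a multidigraph of typed message routes between data
  operations (*sources* produce payloads, *transformers* rewrite them,
  *sinks* consume them). Messages carry provenance metadata (declared
  payload type, sending vessel, original source, source polling rate, a
  fleet-global strictly increasing id, a monotonic timestamp) and are
  multicast to every type-compatible consumer. Consumers buffer messages in
  their own bounded inbox, so a slow or stalled consumer fills its own queue
  (overflow drops the newest message and counts it) and never delays the
  producer.

Around this core: a fleet-scoped **services pool** (lazily constructed
singletons with serialized access), an XML **settings** document, an
eight-level **logger** with per-vessel capture of component stdout, a
**metadata collector**, a text-command registry, a **waveform sequencer**
(parametric synthesis → aligned pattern blocks → concatenated device arrays
plus a virtual-instruction timeline fired on a simulated sample clock), a
self-contained synthetic **fish-tracking demo fleet** with ground-truth
kinematics, and a six-stage **overhead benchmark** whose framework cost is
the slope of the no-intercept fit `T_framework = a · T_ref`
(`a = Σxy / Σx²`, overhead = `a − 1`).

## Worked example

```python
import fleetkit as fk
from fleetkit import data

fleet = fk.Fleet("rig", settings_path=None)

provider = fleet.freight("CameraProvider", lambda: {"cams": ["SN_1"]})
camera = fleet.freight(
    "ImagingCamera",
    lambda prov: {"serial": prov["cams"][0], "frames": iter(range(3))},
    dependencies=[provider], source_rate=100.0)
data.add_source(camera, lambda cam: (next(cam["frames"], None), False),
                output_type=int)
saver = fleet.freight("FrameSaver", lambda: [])
data.add_sink(saver, lambda store, frame, md: store.append(frame),
              input_type=int)

report = fleet.launch(threaded=False)
print("all online:", report.all_online)
for _ in range(3):
    data.generate_data(camera)
fleet.pump()
print("saved frames:", saver.component)

camera.execute_call(lambda cam: 1 / 0)       # component malfunction
print("camera online:", camera.is_online)
print("provider online:", provider.is_online)
fk.restore_segment(fleet.link_graph, camera)  # repair the segment
print("camera online again:", camera.is_online)
fleet.shutdown()
```

prints

```
all online: True
saved frames: [0, 1, 2]
camera online: False
provider online: True
camera online again: True
```

The frames flowed from the camera's source operation into the saver's inbox
and were pumped through its sink; the injected failure took the camera
offline without touching its dependency or the saver; the restore rebuilt
it in place.

A command-line layer exposes the demo fleet and the benchmark:

```
fleetkit run-demo --frames 500 --out demo-output
fleetkit bench --difficulties 1,2,3 --rate 50 --samples 20
fleetkit status
fleetkit graph --dot fleet.dot
```

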