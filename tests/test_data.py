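"""Data plane: typed routing, multicast dispatch, FIFO inbox semantics,
metadata provenance, polling, and producer isolation."""

from __future__ import annotations

import itertools
import random
import time

import pytest

import fleetkit as fk
from fleetkit import data as fdata
from fleetkit.vessel import DataHandlingStrategy


class Frame:
    def __init__(self, n: int):
        self.n = n


class Coords:
    def __init__(self, n: int):
        self.n = n


class Wide(Frame):
    pass


@pytest.fixture
def fleet():
    f = fk.Fleet("t", settings_path=None)
    yield f
    f.shutdown()


def make_source(fleet, name, payload_type=Frame, values=None, **kw):
    values = values if values is not None else itertools.count()
    it = iter(values)

    def body(comp):
        try:
            return payload_type(next(it)), False
        except StopIteration:
            return None, False

    v = fleet.freight(name, lambda: object(), **kw)
    op = fdata.add_source(v, body, output_type=payload_type)
    return v, op


def make_sink(fleet, name, payload_type=Frame, **kw):
    received: list = []
    v = fleet.freight(name, lambda: received, **kw)
    fdata.add_sink(v, lambda lst, x, md: lst.append((x, md)), input_type=payload_type)
    return v, received


class TestRouting:
    def test_single_type_match_single_route(self, fleet):
        make_source(fleet, "camera")
        make_sink(fleet, "saver")
        graph = fleet.rebuild_data_graph()
        assert len(graph.routes) == 1

    def test_full_bipartite_type_routing(self, fleet):
        for i in range(3):
            make_source(fleet, f"s{i}")
        for i in range(2):
            make_sink(fleet, f"k{i}")
        graph = fleet.rebuild_data_graph()
        # brute-force: every producer x consumer pair with matching types
        assert len(graph.routes) == 3 * 2

    def test_unmatched_types_no_routes(self, fleet):
        make_source(fleet, "s", payload_type=Frame)
        make_sink(fleet, "k", payload_type=Coords)
        assert len(fleet.rebuild_data_graph().routes) == 0

    def test_two_sinks_one_vessel_both_attached(self, fleet):
        v = fleet.freight("multi", lambda: [])
        fdata.add_sink(v, lambda c, x, md: None, input_type=Frame)
        fdata.add_sink(v, lambda c, x, md: None, input_type=Frame)
        assert len(v.operations) == 2

    def test_registered_widening_creates_route(self, fleet):
        make_source(fleet, "s", payload_type=Wide)
        make_sink(fleet, "k", payload_type=Frame)
        assert len(fleet.rebuild_data_graph().routes) == 0  # no implicit subtyping
        fleet.register_widening(Wide, Frame)
        assert len(fleet.rebuild_data_graph().routes) == 1


class TestDispatch:
    def test_multicast_counts_all_compatible_active_consumers(self, fleet):
        src, _ = make_source(fleet, "producer")
        for i in range(3):
            make_sink(fleet, f"consumer{i}")
        fleet.launch(threaded=False)
        # dispatch is invoked inside generate_data; delivery = 3 queued copies
        assert fdata.generate_data(src) == 1
        assert sum(len(fleet.vessels[f"consumer{i}"].inbox) for i in range(3)) == 3

    def test_source_filter_excludes_other_origins(self, fleet):
        make_source(fleet, "CameraA")
        make_source(fleet, "CameraB")
        received = []
        k = fleet.freight("filtering_sink", lambda: object())
        fdata.add_sink(k, lambda c, x, md: received.append(md.original_source),
                       input_type=Frame, source_filter={"CameraA"})
        fleet.launch(threaded=False)
        fdata.generate_data(fleet.vessels["CameraA"])
        fdata.generate_data(fleet.vessels["CameraB"])
        fleet.pump()
        assert received == ["CameraA"]

    def test_full_inbox_drops_newest_and_counts(self, fleet):
        src, _ = make_source(fleet, "flood")
        snk, _ = make_sink(fleet, "stalled", queue_capacity=3)
        fleet.launch(threaded=False)
        for _ in range(5):  # no pumping: the consumer never drains
            fdata.generate_data(src)
        assert len(snk.inbox) == 3
        assert snk.dropped_count == 2
        assert snk.queue_occupancy() == 1.0
        assert any("dropping" in r.text for r in fleet.logger.records(fk.LogLevel.WARNING))

    def test_offline_consumer_skipped_harmlessly(self, fleet):
        src, _ = make_source(fleet, "src")
        snk, _ = make_sink(fleet, "snk")
        fleet.launch(threaded=False)
        snk.invalidate(fk.InvalidationCause.USER)
        assert fdata.generate_data(src) == 1  # emission unaffected
        assert len(snk.inbox) == 0


class TestProcessing:
    def test_fifo_order_single_producer(self, fleet):
        src, _ = make_source(fleet, "src", values=range(10))
        snk, received = make_sink(fleet, "snk")
        fleet.launch(threaded=False)
        for _ in range(3):
            fdata.generate_data(src)
        assert [fdata.process_inbox_step(snk).payload.n for _ in range(3)] == [0, 1, 2]
        assert [x.n for x, _ in received] == [0, 1, 2]

    def test_empty_inbox_returns_none(self, fleet):
        snk, received = make_sink(fleet, "snk")
        fleet.launch(threaded=False)
        assert fdata.process_inbox_step(snk) is None
        assert received == []

    def test_fifo_per_producer_under_random_interleaving(self, fleet):
        rng = random.Random(3)
        s1, _ = make_source(fleet, "p1", values=range(100))
        s2, _ = make_source(fleet, "p2", values=range(100))
        snk, received = make_sink(fleet, "snk", queue_capacity=500)
        fleet.launch(threaded=False)
        for _ in range(60):
            fdata.generate_data(rng.choice([s1, s2]))
        fleet.pump()
        for producer in ("p1", "p2"):
            ids = [md.message_id for _, md in received if md.sender == producer]
            assert ids == sorted(ids)
            payloads = [x.n for x, md in received if md.sender == producer]
            assert payloads == sorted(payloads)

    def test_metadata_provenance_through_transformer_chain(self, fleet):
        """original_source survives two transformer hops; sender updates at
        each hop; every hop gets a fresh, larger message id."""
        src, _ = make_source(fleet, "origin")
        t1 = fleet.freight("hop1", lambda: object())
        fdata.add_transformer(t1, lambda c, x, md: Coords(x.n),
                              input_type=Frame, output_type=Coords)
        t2 = fleet.freight("hop2", lambda: object())
        fdata.add_transformer(t2, lambda c, x, md: str(x.n),
                              input_type=Coords, output_type=str)
        seen = []
        snk = fleet.freight("end", lambda: object())
        fdata.add_sink(snk, lambda c, x, md: seen.append(md), input_type=str)
        fleet.launch(threaded=False)
        fdata.generate_data(src)
        fleet.pump()
        (md,) = seen
        assert md.original_source == "origin"
        assert md.sender == "hop2"
        assert md.payload_type is str

    def test_consecutive_ids_from_draining_source(self, fleet):
        values = iter(range(5))

        def body(comp):
            try:
                return Frame(next(values)), True
            except StopIteration:
                return None, False

        v = fleet.freight("burst", lambda: object())
        fdata.add_source(v, body, output_type=Frame)
        snk, received = make_sink(fleet, "snk")
        fleet.launch(threaded=False)
        assert fdata.generate_data(v) == 5
        fleet.pump()
        ids = [md.message_id for _, md in received]
        assert ids == sorted(ids) and len(set(ids)) == 5

    def test_raising_body_invalidates_but_retains_queue(self, fleet):
        src, _ = make_source(fleet, "src", values=range(10))
        v = fleet.freight("fragile", lambda: object(), queue_capacity=16)
        fdata.add_sink(v, lambda c, x, md: 1 / 0, input_type=Frame)
        fleet.launch(threaded=False)
        for _ in range(4):
            fdata.generate_data(src)
        fdata.process_inbox_step(v)  # consumes one message, then blows up
        assert not v.is_online
        assert len(v.inbox) == 3  # remaining messages retained for restore

    def test_direct_mode_equivalence(self):
        """A single-producer single-consumer chain delivers the same payload
        sequence whether the consumer queues or processes directly."""
        outputs = {}
        for strategy in (DataHandlingStrategy.QUEUED, DataHandlingStrategy.DIRECT):
            fleet = fk.Fleet("eq", settings_path=None)
            src, _ = make_source(fleet, "src", values=range(8))
            snk, received = make_sink(fleet, "snk", data_handling_strategy=strategy)
            fleet.launch(threaded=False)
            for _ in range(8):
                fdata.generate_data(src)
            fleet.pump()
            outputs[strategy] = [x.n for x, _ in received]
            fleet.shutdown()
        assert outputs[DataHandlingStrategy.QUEUED] == outputs[DataHandlingStrategy.DIRECT]

    def test_conservation_emitted_equals_processed_plus_queued_plus_dropped(self, fleet):
        src, _ = make_source(fleet, "src")
        snk, received = make_sink(fleet, "snk", queue_capacity=5)
        fleet.launch(threaded=False)
        emitted = 0
        for i in range(20):
            emitted += fdata.generate_data(src)
            if i % 3 == 0:
                fdata.process_inbox_step(snk)
        assert emitted == len(received) + len(snk.inbox) + snk.dropped_count


class TestPolling:
    def test_rate_recorded_in_metadata(self, fleet):
        src, _ = make_source(fleet, "cam", source_rate=100.0)
        snk, received = make_sink(fleet, "snk")
        fleet.launch(threaded=False)
        fdata.generate_data(src)
        fleet.pump()
        assert received[0][1].source_rate == 100.0

    def test_nonpositive_rate_rejected(self, fleet):
        src, _ = make_source(fleet, "cam")
        with pytest.raises(fk.ConfigurationError):
            fdata.set_source_rate(src, 0)

    def test_no_rate_means_manual_only(self, fleet):
        src, _ = make_source(fleet, "cam")
        snk, received = make_sink(fleet, "snk")
        fleet.launch(threaded=True)
        time.sleep(0.1)
        assert received == []
        fleet.shutdown()

    def test_polled_emission_rate(self, fleet):
        src, _ = make_source(fleet, "cam", source_rate=100.0)
        snk, received = make_sink(fleet, "snk", queue_capacity=256)
        fleet.launch(threaded=True)
        time.sleep(1.0)
        fleet.stop_runtime()
        # ~100 emissions in 1 s at 100 Hz, +-20%
        total = len(received) + len(snk.inbox) + snk.dropped_count
        assert 80 <= total <= 120

    def test_inactive_vessel_emits_nothing_when_polled(self, fleet):
        src, _ = make_source(fleet, "cam", source_rate=200.0)
        src.set_active(False)
        snk, received = make_sink(fleet, "snk")
        fleet.launch(threaded=True)
        time.sleep(0.2)
        fleet.stop_runtime()
        assert received == [] and len(snk.inbox) == 0


class TestIsolation:
    def test_stalled_consumer_never_delays_producer(self, fleet):
        """The core queuing claim: a consumer sleeping far longer than the
        production period leaves the producer's emission rate intact while
        its own queue saturates and drops accumulate."""
        src, _ = make_source(fleet, "cam", source_rate=50.0)
        stalled = fleet.freight("stalled", lambda: object(), queue_capacity=4)
        fdata.add_sink(stalled, lambda c, x, md: time.sleep(0.4), input_type=Frame)
        emitted = {"n": 0}
        probe = fleet.freight("probe", lambda: object(), queue_capacity=512)
        fdata.add_sink(probe, lambda c, x, md: emitted.__setitem__("n", emitted["n"] + 1),
                       input_type=Frame)
        fleet.launch(threaded=True)
        time.sleep(2.0)
        fleet.stop_runtime()
        produced = emitted["n"] + len(probe.inbox)
        assert 80 <= produced <= 120  # 50 Hz for 2 s, +-20%
        assert stalled.queue_occupancy() == 1.0
        assert stalled.dropped_count > 0
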