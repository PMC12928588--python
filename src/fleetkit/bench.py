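"""Framework-overhead micro-benchmark.

A pure, deterministic test operator (a repeated floating-point multiply-add
loop, iteration count proportional to an integer difficulty 1..10, calibrated
once per machine so the difficulty range spans a few to a few tens of
milliseconds) is timed two ways: directly (the reference time) and inside a
six-stage fleet — request source at a fixed rate, timestamper, the operator,
a second timestamper, a time-difference calculator, and a text writer. The
two timestampers are separate vessels, so the measured interval crosses real
framework dispatch. Framework overhead is the slope of the no-intercept
least-squares fit T_framework = a * T_ref, reported as the fraction a - 1;
the closed form of the slope is a = sum(x*y) / sum(x*x).
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import data as _data
from .errors import ConfigurationError
from .fleet import Fleet
from .vessel import DataHandlingStrategy


class TestOperator:
    """Deterministic CPU load: ``iters_per_unit * difficulty`` fused
    multiply-add iterations. Same difficulty, same arithmetic result."""

    def __init__(self, iters_per_unit: int = 200_000):
        if iters_per_unit < 1:
            raise ConfigurationError("iters_per_unit must be >= 1")
        self.iters_per_unit = int(iters_per_unit)

    def run(self, difficulty: int) -> float:
        if not 1 <= difficulty <= 10:
            raise ConfigurationError(f"difficulty must be in 1..10, got {difficulty}")
        x = 1.000001
        acc = 0.0
        for _ in range(self.iters_per_unit * difficulty):
            acc = acc * 0.9999999 + x
        return acc

    @classmethod
    def calibrated(cls, target_ms_per_unit: float = 2.0) -> "TestOperator":
        """Size the loop so difficulty 1 takes about ``target_ms_per_unit``
        milliseconds on this machine (so 1..10 spans roughly 2-20 ms)."""
        probe = cls(50_000)
        probe.run(1)  # warm up
        t0 = time.perf_counter()
        probe.run(1)
        per_iter = (time.perf_counter() - t0) / probe.iters_per_unit
        iters = max(1, int(target_ms_per_unit / 1000.0 / per_iter))
        return cls(iters)


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class TimingRecord:
    difficulty: int
    t_pre_ns: int
    t_post_ns: int

    @property
    def delta_ns(self) -> int:
        return self.t_post_ns - self.t_pre_ns


def run_reference(operator: TestOperator, difficulties: Sequence[int],
                  samples: int, warmup: int = 3) -> dict[int, np.ndarray]:
    """Reference times by direct invocation outside any fleet: per
    difficulty, ``samples`` timed runs after ``warmup`` discarded ones.
    Times in nanoseconds."""
    if samples < 1:
        raise ConfigurationError("samples must be >= 1")
    out: dict[int, np.ndarray] = {}
    for d in difficulties:
        for _ in range(warmup):
            operator.run(d)
        times = np.empty(samples)
        for i in range(samples):
            t0 = time.monotonic_ns()
            operator.run(d)
            times[i] = time.monotonic_ns() - t0
        out[d] = times
    return out


# -- the six-stage benchmark fleet -------------------------------------


@dataclass(frozen=True)
class _Request:
    difficulty: int


@dataclass(frozen=True)
class _Stamped:
    difficulty: int
    t_pre_ns: int


@dataclass(frozen=True)
class _Computed:
    difficulty: int
    t_pre_ns: int
    result: float


@dataclass(frozen=True)
class _Timed:
    difficulty: int
    t_pre_ns: int
    t_post_ns: int


class _RequestFeed:
    def __init__(self, schedule: list[int]):
        self.schedule = list(schedule)
        self.cursor = 0

    def next(self) -> Optional[_Request]:
        if self.cursor >= len(self.schedule):
            return None
        req = _Request(self.schedule[self.cursor])
        self.cursor += 1
        return req


class _RecordCollector:
    def __init__(self, path: Optional[Path]):
        self.records: list[TimingRecord] = []
        self.path = path
        self._fh = open(path, "w", newline="") if path else None
        if self._fh:
            self._writer = csv.writer(self._fh)
            self._writer.writerow(["difficulty", "sample", "t_pre_ns", "t_post_ns", "delta_ns"])

    def add(self, rec: TimingRecord) -> None:
        self.records.append(rec)
        if self._fh:
            self._writer.writerow([rec.difficulty, len(self.records) - 1,
                                   rec.t_pre_ns, rec.t_post_ns, rec.delta_ns])

    def close(self) -> None:
        if self._fh:
            self._fh.close()


@dataclass
class FrameworkRunResult:
    records: list[TimingRecord]
    overloaded: bool  # queue saturation observed during the run
    dropped: int
    max_occupancy: float


def build_bench_fleet(operator: TestOperator, schedule: list[int],
                      rate_hz: float = 50.0, csv_path: Optional[Path] = None,
                      queue_capacity: int = 64) -> tuple[Fleet, _RecordCollector]:
    """Six vessels in a chain: RequestSource -> Timestamper1 -> Operator ->
    Timestamper2 -> DiffCalculator -> TextWriter. Payload types make each
    stage route only to the next."""
    fleet = Fleet("bench", settings_path=None)
    collector = _RecordCollector(csv_path)

    source = fleet.freight("RequestSource", lambda: _RequestFeed(schedule),
                           source_rate=rate_hz, queue_capacity=queue_capacity)
    # one request per generate-data tick so the poller sets the pace
    _data.add_source(source, lambda feed: (feed.next(), False),
                     output_type=_Request, name="requests")

    stamp1 = fleet.freight("Timestamper1", lambda: object(),
                           queue_capacity=queue_capacity)
    _data.add_transformer(
        stamp1, lambda _c, req, md: _Stamped(req.difficulty, time.monotonic_ns()),
        input_type=_Request, output_type=_Stamped, name="stamp_pre")

    op_vessel = fleet.freight("Operator", lambda: operator,
                              queue_capacity=queue_capacity)
    _data.add_transformer(
        op_vessel,
        lambda op, stamped, md: _Computed(stamped.difficulty, stamped.t_pre_ns,
                                          op.run(stamped.difficulty)),
        input_type=_Stamped, output_type=_Computed, name="operate")

    stamp2 = fleet.freight("Timestamper2", lambda: object(),
                           queue_capacity=queue_capacity,
                           data_handling_strategy=DataHandlingStrategy.DIRECT)
    _data.add_transformer(
        stamp2, lambda _c, comp, md: _Timed(comp.difficulty, comp.t_pre_ns,
                                            time.monotonic_ns()),
        input_type=_Computed, output_type=_Timed, name="stamp_post")

    diff = fleet.freight("DiffCalculator", lambda: object(),
                         queue_capacity=queue_capacity,
                         data_handling_strategy=DataHandlingStrategy.DIRECT)
    _data.add_transformer(
        diff, lambda _c, timed, md: TimingRecord(timed.difficulty, timed.t_pre_ns,
                                                 timed.t_post_ns),
        input_type=_Timed, output_type=TimingRecord, name="diff")

    writer = fleet.freight("TextWriter", lambda: collector,
                           queue_capacity=max(queue_capacity, 4096),
                           data_handling_strategy=DataHandlingStrategy.DIRECT)
    _data.add_sink(writer, lambda coll, rec, md: coll.add(rec),
                   input_type=TimingRecord, name="write")

    return fleet, collector


def run_framework(operator: TestOperator, difficulties: Sequence[int],
                  rate_hz: float = 50.0, samples: int = 20,
                  csv_path: Optional[Path] = None,
                  live: bool = True) -> dict[int, FrameworkRunResult]:
    """Run the benchmark fleet once per difficulty. ``live`` runs the real
    polling scheduler at ``rate_hz``; otherwise requests are driven manually
    back to back (useful for overhead-only measurements without waiting on
    the request period)."""
    out: dict[int, FrameworkRunResult] = {}
    for d in difficulties:
        schedule = [d] * samples
        fleet, collector = build_bench_fleet(operator, schedule, rate_hz, csv_path)
        fleet.launch(threaded=live)
        source = fleet.vessels["RequestSource"]
        max_occ = 0.0
        try:
            if live:
                deadline = time.monotonic() + (samples / rate_hz) * 3 + 2.0
                while len(collector.records) < samples and time.monotonic() < deadline:
                    time.sleep(0.01)
                    max_occ = max(max_occ, *(v.queue_occupancy()
                                             for v in fleet.vessels.values()))
            else:
                while _data.generate_data(source) > 0:
                    max_occ = max(max_occ, *(v.queue_occupancy()
                                             for v in fleet.vessels.values()))
                    fleet.pump()
                fleet.pump()
        finally:
            fleet.shutdown()
            collector.close()
        dropped = sum(v.dropped_count for v in fleet.vessels.values())
        overloaded = dropped > 0 or max_occ >= 1.0
        out[d] = FrameworkRunResult(list(collector.records), overloaded,
                                    dropped, max_occ)
    return out


# ----------------------------------------------------------------------
# the no-intercept fit


def no_intercept_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y = a*x through the origin: sum(xy)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = float((x * x).sum())
    if denom == 0.0:
        raise ConfigurationError("degenerate fit: all reference times are zero")
    return float((x * y).sum() / denom)


@dataclass(frozen=True)
class OverheadEstimate:
    slope: float  # a in T_framework = a * T_ref
    overhead_fraction: float  # a - 1
    per_difficulty: dict[int, tuple[float, float, float, float]]
    # difficulty -> (ref mean, ref sd, framework mean, framework sd), ns

    @property
    def overhead_percent(self) -> float:
        return 100.0 * self.overhead_fraction


def estimate_overhead(framework_times: dict[int, np.ndarray],
                      reference_times: dict[int, np.ndarray]) -> OverheadEstimate:
    """Fit per-difficulty mean framework time against the best-of reference
    time with the no-intercept regression. Best-of (the minimum) is the
    standard micro-benchmark estimator for the pure compute time: scheduling
    noise only ever inflates a sample, so the minimum is the least
    contaminated reference."""
    common = sorted(set(framework_times) & set(reference_times))
    if not common:
        raise ConfigurationError("no common difficulties between the two runs")
    x = np.array([np.min(reference_times[d]) for d in common])
    y = np.array([np.mean(framework_times[d]) for d in common])
    slope = no_intercept_slope(x, y)
    per = {d: (float(np.mean(reference_times[d])), float(np.std(reference_times[d])),
               float(np.mean(framework_times[d])), float(np.std(framework_times[d])))
           for d in common}
    return OverheadEstimate(slope, slope - 1.0, per)


def summary_csv(estimate: OverheadEstimate, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["difficulty", "ref_mean_ns", "ref_sd_ns",
                         "framework_mean_ns", "framework_sd_ns"])
        for d, (rm, rs, fm, fs) in sorted(estimate.per_difficulty.items()):
            writer.writerow([d, f"{rm:.1f}", f"{rs:.1f}", f"{fm:.1f}", f"{fs:.1f}"])
        writer.writerow(["slope", f"{estimate.slope:.6f}", "", "", ""])
        writer.writerow(["overhead_percent", f"{estimate.overhead_percent:.2f}", "", "", ""])
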