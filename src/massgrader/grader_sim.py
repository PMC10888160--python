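"""Discrete-event simulation of the fixed-tray grading line's control law.

The physical line carries cucumbers on trays past a photoelectric sensor
(where the vision system's grade for the tray is latched into register D0),
then past two electromagnet-driven turnouts. Position tracking uses a
14-slot shift register (D10): every sensor trigger copies D0 into the entry
slot and shifts all slots one position toward the turnout end, so in normal
operation the slot index of a tray's grade equals its physical position in
tray pitches downstream of the sensor. The controller continuously reads
slot X (turnout 1: diverts grade-2 trays) and slot X+4 (turnout 2: diverts
grade-3 trays); grade-1 trays pass both turnouts and run to the end of the
line.

Sensor faults are the failure mechanism of interest: a *missed* read leaves
the register one shift behind the physical trays, and a *double* read
inserts a spurious slot — in both cases subsequent trays' grades land on
wrong slots and misroutes emerge mechanistically. The default error model
makes both fault probabilities zero up to 0.3 m/s and linearly increasing
above, an interpretive stand-in for vibration-induced sensor faults at
higher chain speeds; its parameters are fully exposed.

Capacity is W_F / T — tonnes of correctly graded fruit per hour of feeding
time; grading efficiency is the percentage of trays routed to their true
grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .grading_rules import (
    GRADES,
    GradeThresholds,
    GradingOutcome,
    assign_grade,
    tabulate_outcome,
)

__all__ = [
    "SimConfig",
    "ControlState",
    "TrayState",
    "SimResult",
    "sensor_trigger",
    "route_decision",
    "sensor_error_event",
    "error_probabilities",
    "run_simulation",
    "capacity",
    "capacity_curve",
    "default_mass_sampler",
]

SPEED_RANGE = (0.1, 0.5)  # m/s, the machine's adjustable range


@dataclass(frozen=True)
class SimConfig:
    """Grading-line configuration.

    ``error_slope`` k and ``error_onset`` v0 define the default
    speed-dependent fault model p_miss(v) = p_double(v) = max(0, k (v - v0));
    explicit ``p_miss``/``p_double`` override it.
    """

    chain_speed: float = 0.1  # m/s
    tray_pitch: float = 0.5  # m between tray leading edges
    tray_length: float = 0.4  # m
    register_width: int = 14  # slots in D10
    x_index: int = 8  # slot read for electromagnet 1; X+4 for electromagnet 2
    actuation_time_ms: float = 50.0  # turnout actuation window
    error_slope: float = 0.5  # per (m/s) above onset
    error_onset: float = 0.3  # m/s
    p_miss: float | None = None
    p_double: float | None = None
    n_trays: int = 500
    seed: int = 0
    thresholds: GradeThresholds = field(default_factory=GradeThresholds)

    def __post_init__(self):
        if not SPEED_RANGE[0] <= self.chain_speed <= SPEED_RANGE[1]:
            raise ValueError(
                f"chain_speed {self.chain_speed} outside machine range {SPEED_RANGE}"
            )
        if self.x_index < 0 or self.x_index + 4 >= self.register_width:
            raise ValueError(
                f"need x_index + 4 < register_width, got {self.x_index} + 4 "
                f">= {self.register_width}"
            )
        if self.actuation_time_ms > 100.0:
            raise ValueError("actuation_time_ms must not exceed 100 ms")
        if self.tray_pitch <= 0 or self.n_trays < 1:
            raise ValueError("tray_pitch must be positive and n_trays >= 1")

    @property
    def tray_interval_s(self) -> float:
        return self.tray_pitch / self.chain_speed

    def fault_probabilities(self) -> tuple[float, float]:
        return error_probabilities(
            self.chain_speed,
            slope=self.error_slope,
            onset=self.error_onset,
            p_miss=self.p_miss,
            p_double=self.p_double,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d


@dataclass(frozen=True)
class ControlState:
    """D0 capture register plus the D10 position shift register.

    Slot 0 is the entry (sensor) end; higher indices are closer to the
    turnouts. Slot value 0 means "empty tray / no grade".
    """

    d0: int = 0
    d10: tuple[int, ...] = (0,) * 14

    def __post_init__(self):
        if any(v not in (0, 1, 2, 3) for v in self.d10) or self.d0 not in (0, 1, 2, 3):
            raise ValueError("register slots must hold 0 (empty) or a grade 1-3")


@dataclass
class TrayState:
    tray_id: int
    position: int  # tray pitches downstream of the sensor
    carried_grade_truth: int
    carried_mass: float  # grams
    detected_grade: int
    routed_grade: int | None = None


@dataclass
class SimResult:
    """Aggregate of one simulated run."""

    w_f: float  # correctly graded mass, tonnes
    total_routed_mass: float  # tonnes over all routed trays
    elapsed_hr: float  # feeding time
    capacity: float  # t/hr, w_f / elapsed_hr
    outcome: GradingOutcome
    trays: list[TrayState]
    event_log: list[dict]
    config: SimConfig
    n_sensor_faults: int = 0


def sensor_trigger(state: ControlState, new_grade: int) -> ControlState:
    """One photoelectric trigger: latch the grade in D0, copy it into the
    entry slot of D10 and shift every slot one position toward the turnouts.
    The grade shifted off the far end has passed all turnouts and is dropped.
    """
    if new_grade not in (0, 1, 2, 3):
        raise ValueError(f"invalid grade {new_grade}")
    return ControlState(d0=new_grade, d10=(new_grade,) + state.d10[:-1])


def route_decision(state: ControlState, x: int) -> tuple[bool, bool]:
    """Electromagnet commands from the register: (EM1 on, EM2 on).

    EM1 diverts at turnout 1 when slot X holds grade 2; EM2 diverts at
    turnout 2 when slot X+4 holds grade 3. Grade 1 (or empty) at both slots
    leaves both electromagnets off.
    """
    if x < 0 or x + 4 >= len(state.d10):
        raise ValueError(f"x={x} invalid for register width {len(state.d10)}")
    return state.d10[x] == 2, state.d10[x + 4] == 3


def error_probabilities(
    speed: float,
    slope: float = 0.5,
    onset: float = 0.3,
    p_miss: float | None = None,
    p_double: float | None = None,
) -> tuple[float, float]:
    """Speed-dependent sensor fault probabilities (miss, double)."""
    base = max(0.0, slope * (speed - onset))
    pm = base if p_miss is None else p_miss
    pd = base if p_double is None else p_double
    if not (0 <= pm <= 1 and 0 <= pd <= 1 and pm + pd <= 1):
        raise ValueError(f"invalid fault probabilities ({pm}, {pd})")
    return pm, pd


def sensor_error_event(
    speed: float,
    rng: np.random.Generator,
    slope: float = 0.5,
    onset: float = 0.3,
    p_miss: float | None = None,
    p_double: float | None = None,
) -> str:
    """Draw one sensor event: 'normal', 'missed' or 'double'."""
    pm, pd = error_probabilities(speed, slope, onset, p_miss, p_double)
    u = rng.random()
    if u < pm:
        return "missed"
    if u < pm + pd:
        return "double"
    return "normal"


def capacity(w_f: float, t: float) -> float:
    """Capacity in t/hr from graded mass w_f (tonnes) and time t (hours)."""
    if t <= 0:
        raise ValueError("grading time must be positive")
    return w_f / t


def default_mass_sampler(
    rng: np.random.Generator, size: int, center: float = 170.0, sd: float = 38.0,
    lo: float = 95.0, hi: float = 248.0,
) -> np.ndarray:
    """Truncated-normal cucumber masses on [95, 248] g."""
    a, b = (lo - center) / sd, (hi - center) / sd
    return stats.truncnorm.rvs(a, b, loc=center, scale=sd, size=size, random_state=rng)


def run_simulation(
    config: SimConfig,
    masses: Sequence[float] | None = None,
    true_grades: Sequence[int] | None = None,
    detected_grades: Sequence[int] | None = None,
    mass_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> SimResult:
    """Simulate feeding, tracking and routing of ``n_trays`` trays.

    By default masses come from a truncated-normal sampler and detected
    grades equal true grades (a perfect vision stage); callers may supply
    explicit masses, true grades, or a detected-grade stream (e.g. CNN
    predictions) to study end-to-end behavior. Sensor faults desynchronize
    the shift register against the physical trays, so misroutes arise from
    the mechanism, never by fiat. After the last loaded tray the line runs
    on with empty trays until every loaded tray has been routed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trays
    if masses is None:
        sampler = mass_sampler or default_mass_sampler
        masses = np.asarray(sampler(rng, n), dtype=float)
    else:
        masses = np.asarray(masses, dtype=float)
        if len(masses) != n:
            raise ValueError(f"expected {n} masses, got {len(masses)}")
    if true_grades is None:
        true_grades = [assign_grade(m, config.thresholds) for m in masses]
    if detected_grades is None:
        detected_grades = list(true_grades)
    if not (len(true_grades) == len(detected_grades) == n):
        raise ValueError("grade streams must have length n_trays")

    pm, pd = config.fault_probabilities()
    interval = config.tray_interval_s
    if config.actuation_time_ms / 1000.0 > interval:
        # actuation slower than the tray cadence: log, do not fail
        timing_warning = (
            f"actuation window {config.actuation_time_ms} ms exceeds tray "
            f"interval {interval * 1000:.0f} ms at {config.chain_speed} m/s"
        )
    else:
        timing_warning = None

    state = ControlState(d10=(0,) * config.register_width)
    in_transit: list[TrayState] = []
    routed: list[TrayState] = []
    event_log: list[dict] = []
    n_faults = 0
    end_position = config.x_index + 5  # past turnout 2 -> grade-1 track
    tick = 0
    max_ticks = n + 50 * (config.register_width + 5)

    def log(event: str, tray_id: int | None, detail: str = ""):
        event_log.append(
            {"t_s": round(tick * interval, 6), "event": event,
             "tray_id": tray_id, "detail": detail}
        )

    while (tick < n or in_transit) and tick < max_ticks:
        loading = tick < n
        if loading:
            tray = TrayState(
                tray_id=tick,
                position=0,
                carried_grade_truth=int(true_grades[tick]),
                carried_mass=float(masses[tick]),
                detected_grade=int(detected_grades[tick]),
            )
            grade_in = tray.detected_grade
        else:
            tray = None
            grade_in = 0  # empty tray crosses the sensor during flush

        event = sensor_error_event(
            config.chain_speed, rng, config.error_slope, config.error_onset, pm, pd
        )
        if event == "normal":
            state = sensor_trigger(state, grade_in)
        elif event == "missed":
            n_faults += 1
            log("sensor_missed", tray.tray_id if tray else None)
        else:  # double read: a spurious extra shift
            n_faults += 1
            state = sensor_trigger(state, grade_in)
            state = sensor_trigger(state, grade_in)
            log("sensor_double", tray.tray_id if tray else None)

        for t in in_transit:
            t.position += 1
        if tray is not None:
            in_transit.append(tray)
            log("tray_loaded", tray.tray_id, f"grade={grade_in}")

        em1, em2 = route_decision(state, config.x_index)
        still = []
        for t in in_transit:
            if t.position == config.x_index and em1:
                t.routed_grade = 2
                routed.append(t)
                log("routed", t.tray_id, "turnout=1 grade=2")
            elif t.position == config.x_index + 4 and em2:
                t.routed_grade = 3
                routed.append(t)
                log("routed", t.tray_id, "turnout=2 grade=3")
            elif t.position >= end_position:
                t.routed_grade = 1
                routed.append(t)
                log("routed", t.tray_id, "end grade=1")
            else:
                still.append(t)
        in_transit = still
        tick += 1

    routed.sort(key=lambda t: t.tray_id)
    outcome = tabulate_outcome(
        [t.carried_grade_truth for t in routed], [t.routed_grade for t in routed]
    )
    total_mass_t = sum(t.carried_mass for t in routed) / 1e6
    correct_mass_t = (
        sum(t.carried_mass for t in routed if t.routed_grade == t.carried_grade_truth)
        / 1e6
    )
    elapsed_hr = n * interval / 3600.0
    if timing_warning:
        event_log.insert(0, {"t_s": 0.0, "event": "timing_warning",
                             "tray_id": None, "detail": timing_warning})
    return SimResult(
        w_f=correct_mass_t,
        total_routed_mass=total_mass_t,
        elapsed_hr=elapsed_hr,
        capacity=capacity(correct_mass_t, elapsed_hr),
        outcome=outcome,
        trays=routed,
        event_log=event_log,
        config=config,
        n_sensor_faults=n_faults,
    )


def capacity_curve(
    config: SimConfig, speeds: Sequence[float]
) -> list[tuple[float, float]]:
    """Capacity at each chain speed, other settings held fixed."""
    points = []
    for v in speeds:
        if not SPEED_RANGE[0] <= v <= SPEED_RANGE[1]:
            raise ValueError(f"speed {v} outside machine range {SPEED_RANGE}")
        result = run_simulation(replace(config, chain_speed=v))
        points.append((float(v), result.capacity))
    return points
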