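"""Synchronous threshold-fire-reset dynamics with sensory input and motor readout.

Every neuron carries a signed accumulator S_i.  At each discrete step
(1 s of simulated time) all neurons update simultaneously from the time-t
snapshot: a neuron whose value exceeds the firing threshold h fires —
delivering its synaptic weights to its targets and resetting to zero —
while every other neuron adds its incoming synaptic and external input:

    S_i(t+1) = S_i(t) + sum_j W_ij * Theta[S_j(t) - h] + I_i(t)   if S_i(t) <= h
    S_i(t+1) = 0                                                  otherwise

with Theta the strict step function (Theta(0) = 0, so a neuron sitting
exactly at threshold does not fire).  Inhibitory weights may drive states
negative; no floor is applied.

The optional arena embodiment replaces the physical vehicle: a unicycle
robot moves in a rectangular 2-D arena, a forward ray-cast distance sensor
stimulates avoidance sensory neurons when an obstacle is closer than the
trigger distance, and the signed left/right sums over fired motor neurons
choose the action at each step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .synthetic import StimulationProtocol

logger = logging.getLogger("wormnet")

ACTIONS = ("forward", "backward", "turn_left", "turn_right", "idle")


@dataclass
class SimConfig:
    """Simulation parameters.

    ``threshold`` is the firing threshold h (default 30); ``step_duration``
    is fixed at 1 s, giving 1 Hz sampling and a 0.5 Hz Nyquist bound on
    every signal.  ``sensor_trigger_distance`` (cm) and
    ``stimulus_magnitude`` control the avoidance sensor; ``food_drive`` is
    the constant baseline input to food-seeking sensory neurons.  The
    initial state is all zeros unless ``init="random"`` (uniform on [0, h],
    seeded) or explicit ``initial_values`` are supplied.
    """

    duration: int = 900
    threshold: float = 30.0
    step_duration: float = 1.0
    sensor_trigger_distance: float = 30.0
    stimulus_magnitude: float = 20.0
    food_drive: float = 1.0
    seed: int = 0
    init: str = "zeros"
    initial_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if self.sensor_trigger_distance <= 0:
            raise ValueError("sensor trigger distance must be positive")

    def initial_state(self, n: int) -> np.ndarray:
        if self.initial_values is not None:
            vals = np.asarray(self.initial_values, dtype=float)
            if vals.shape != (n,):
                raise ValueError("initial_values length must match neuron count")
            return vals.copy()
        if self.init == "random":
            rng = np.random.default_rng(self.seed)
            return rng.uniform(0.0, self.threshold, size=n)
        return np.zeros(n)


@dataclass
class NetworkState:
    """Per-neuron accumulators at one time step."""

    values: np.ndarray

    def fired_mask(self, h: float) -> np.ndarray:
        return self.values > h


@dataclass
class SimulationTrace:
    """State matrix (duration+1 rows, one column per neuron) plus firing times.

    A neuron fires at step t when its recorded state exceeds h at t; its
    accumulator is zero at t+1 (before that step's inputs of other neurons
    are even considered).
    """

    states: np.ndarray
    names: list[str]
    threshold: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.names):
            raise ValueError("state matrix shape does not match neuron roster")

    @property
    def duration(self) -> int:
        return self.states.shape[0] - 1

    def firing_times(self, neuron: str) -> np.ndarray:
        j = self.names.index(neuron)
        return np.nonzero(self.states[:, j] > self.threshold)[0]

    def firing_table(self) -> list[tuple[str, int]]:
        out = []
        for name in self.names:
            out.extend((name, int(t)) for t in self.firing_times(name))
        return out


@dataclass
class ActionLog:
    """Time-ordered (step, action, left_value, right_value) records."""

    events: list[tuple[int, str, float, float]]

    def __post_init__(self) -> None:
        steps = [e[0] for e in self.events]
        if steps != sorted(set(steps)):
            raise ValueError("action log steps must be strictly increasing")
        for _, action, _, _ in self.events:
            if action not in ACTIONS:
                raise ValueError(f"unknown action {action!r}")

    def action_at(self) -> dict[int, str]:
        return {step: action for step, action, _, _ in self.events}


def step_network(
    state: NetworkState,
    c: Connectome,
    h: float,
    external: np.ndarray,
) -> NetworkState:
    """One synchronous update of the threshold-fire-reset map."""
    values = state.values
    n = c.n_neurons
    if values.shape != (n,) or np.asarray(external).shape != (n,):
        raise ValueError("state/external length must equal neuron count")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite network state")
    fired = values > h
    incoming = c.weight_matrix @ fired.astype(float)
    nxt = np.where(fired, 0.0, values + incoming + external)
    return NetworkState(values=nxt)


def run_simulation(
    c: Connectome,
    cfg: SimConfig,
    protocol: StimulationProtocol | None = None,
) -> SimulationTrace:
    """Run the dynamics for ``cfg.duration`` steps under an external protocol.

    The stimulation scheduled at step t enters the update from S(t) to
    S(t+1), alongside synaptic input.  The trace records duration+1 rows,
    the initial state included.
    """
    n = c.n_neurons
    index = {name: i for i, name in enumerate(c.names)}
    if protocol is not None:
        unknown = protocol.neuron_names() - set(c.names)
        if unknown:
            raise ValueError(
                f"protocol stimulates neurons absent from connectome: {sorted(unknown)}"
            )
        if protocol.duration > cfg.duration:
            raise ValueError("protocol duration exceeds simulation duration")
        ext = protocol.external_matrix(index, cfg.duration)
    else:
        ext = np.zeros((cfg.duration, n))
    states = np.empty((cfg.duration + 1, n))
    state = NetworkState(values=cfg.initial_state(n))
    states[0] = state.values
    for t in range(cfg.duration):
        state = step_network(state, c, cfg.threshold, ext[t])
        states[t + 1] = state.values
    return SimulationTrace(states=states, names=list(c.names), threshold=cfg.threshold)


def motor_readout(
    fired_names: set[str],
    motor_map: dict[str, tuple[float, float]],
) -> tuple[float, float]:
    """Signed left/right sums over the motor neurons that fired.

    ``motor_map`` maps motor-neuron names to (left_weight, right_weight);
    excitatory weights are positive, inhibitory negative.
    """
    left = sum(motor_map[n][0] for n in fired_names if n in motor_map)
    right = sum(motor_map[n][1] for n in fired_names if n in motor_map)
    return float(left), float(right)


def classify_action(left_value: float, right_value: float) -> str:
    """Map the left/right accumulators to a discrete action.

    Both positive: forward.  Both negative: backward.  Both zero: idle.
    Otherwise turn toward the smaller side; a mixed-sign tie turns right.
    """
    if not (math.isfinite(left_value) and math.isfinite(right_value)):
        raise ValueError("non-finite motor values")
    if left_value > 0 and right_value > 0:
        return "forward"
    if left_value < 0 and right_value < 0:
        return "backward"
    if left_value == 0 and right_value == 0:
        return "idle"
    return "turn_left" if left_value < right_value else "turn_right"


@dataclass
class Arena:
    """Rectangular 2-D arena (cm) with circular/segment obstacles and a robot.

    The robot is a unicycle: forward/backward actions translate ``speed``
    cm along the heading, turn actions rotate ``turn_angle`` degrees in
    place.  The pose is clipped to the bounds (a collision is logged when
    clipping occurs).
    """

    bounds: tuple[float, float, float, float] = (0.0, 0.0, 500.0, 500.0)
    circles: list[tuple[float, float, float]] = field(default_factory=list)
    segments: list[tuple[float, float, float, float]] = field(default_factory=list)
    start_pose: tuple[float, float, float] = (250.0, 250.0, 0.0)  # x, y, heading deg
    speed: float = 5.0
    turn_angle: float = 30.0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bounds
        x, y, _ = self.start_pose
        if not (x0 <= x <= x1 and y0 <= y <= y1):
            raise ValueError("robot initial pose outside arena bounds")


def _ray_wall_distance(x, y, dx, dy, bounds):
    x0, y0, x1, y1 = bounds
    best = math.inf
    for (p, d, lo, hi) in ((x, dx, x0, x1), (y, dy, y0, y1)):
        if d > 1e-12:
            best = min(best, (hi - p) / d)
        elif d < -1e-12:
            best = min(best, (lo - p) / d)
    return best


def _ray_circle_distance(x, y, dx, dy, cx, cy, r):
    # |p + t d - c|^2 = r^2, smallest t >= 0
    ox, oy = x - cx, y - cy
    b = ox * dx + oy * dy
    disc = b * b - (ox * ox + oy * oy - r * r)
    if disc < 0:
        return math.inf
    sq = math.sqrt(disc)
    for t in (-b - sq, -b + sq):
        if t >= 0:
            return t
    return math.inf


def _ray_segment_distance(x, y, dx, dy, x1, y1, x2, y2):
    ex, ey = x2 - x1, y2 - y1
    denom = dx * ey - dy * ex
    if abs(denom) < 1e-12:
        return math.inf
    t = ((x1 - x) * ey - (y1 - y) * ex) / denom
    u = ((x1 - x) * dy - (y1 - y) * dx) / denom
    if t >= 0 and 0 <= u <= 1:
        return t
    return math.inf


def sensor_distance(arena: Arena, pose: tuple[float, float, float]) -> float:
    """Ray-cast distance (cm) from the robot along its heading to the nearest
    wall or obstacle."""
    x, y, heading = pose
    dx = math.cos(math.radians(heading))
    dy = math.sin(math.radians(heading))
    d = _ray_wall_distance(x, y, dx, dy, arena.bounds)
    for cx, cy, r in arena.circles:
        d = min(d, _ray_circle_distance(x, y, dx, dy, cx, cy, r))
    for x1, y1, x2, y2 in arena.segments:
        d = min(d, _ray_segment_distance(x, y, dx, dy, x1, y1, x2, y2))
    return d


def _advance_pose(pose, action, arena):
    x, y, heading = pose
    collided = False
    if action in ("forward", "backward"):
        sign = 1.0 if action == "forward" else -1.0
        x += sign * arena.speed * math.cos(math.radians(heading))
        y += sign * arena.speed * math.sin(math.radians(heading))
    elif action == "turn_left":
        heading = (heading + arena.turn_angle) % 360.0
    elif action == "turn_right":
        heading = (heading - arena.turn_angle) % 360.0
    x0, y0, x1, y1 = arena.bounds
    cx = min(max(x, x0), x1)
    cy = min(max(y, y0), y1)
    if cx != x or cy != y:
        collided = True
    return (cx, cy, heading), collided


def simulate_arena_run(
    c: Connectome,
    cfg: SimConfig,
    arena: Arena,
    avoidance_neurons: set[str],
    food_neurons: set[str] | None = None,
    motor_map: dict[str, tuple[float, float]] | None = None,
) -> tuple[SimulationTrace, ActionLog]:
    """Closed sensorimotor loop in the virtual arena.

    Per step t: the action chosen from the motor neurons firing at S(t)
    moves the robot; the distance sensor then ray-casts from the new pose,
    and if an obstacle lies closer than the trigger distance the avoidance
    neurons receive ``stimulus_magnitude`` in the update S(t) -> S(t+1).
    Food-seeking neurons receive the constant ``food_drive`` every step.
    Every step is logged with its action and left/right motor values.
    """
    roster = set(c.names)
    for label, group in (("avoidance", avoidance_neurons), ("food", food_neurons or set())):
        missing = set(group) - roster
        if missing:
            raise ValueError(f"{label} neurons not in connectome: {sorted(missing)}")
    motor_map = motor_map or {}
    index = {name: i for i, name in enumerate(c.names)}
    avoid_idx = [index[n] for n in sorted(avoidance_neurons)]
    food_idx = [index[n] for n in sorted(food_neurons)] if food_neurons else []

    n = c.n_neurons
    states = np.empty((cfg.duration + 1, n))
    state = NetworkState(values=cfg.initial_state(n))
    states[0] = state.values
    pose = arena.start_pose
    events: list[tuple[int, str, float, float]] = []
    for t in range(cfg.duration):
        fired = state.fired_mask(cfg.threshold)
        fired_names = {c.names[i] for i in np.nonzero(fired)[0]}
        left, right = motor_readout(fired_names, motor_map)
        action = classify_action(left, right)
        pose, collided = _advance_pose(pose, action, arena)
        if collided:
            logger.info("collision with arena boundary at step %d", t)
        events.append((t, action, left, right))
        external = np.zeros(n)
        if food_idx:
            external[food_idx] += cfg.food_drive
        if sensor_distance(arena, pose) < cfg.sensor_trigger_distance:
            external[avoid_idx] += cfg.stimulus_magnitude
        state = step_network(state, c, cfg.threshold, external)
        states[t + 1] = state.values
    trace = SimulationTrace(states=states, names=list(c.names), threshold=cfg.threshold)
    return trace, ActionLog(events=events)
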