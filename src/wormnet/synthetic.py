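"""Synthetic connectomes and stimulation protocols with known ground truth.

Two generators matter downstream: a directed configuration-model graph with
prescribed in/out degree sequences (mirroring the constraints of the
degree-preserving null model), and a "planted frequency" network whose
groups are driven at constant rates chosen so that every group fires with
an analytically exact period under the threshold-fire-reset update.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import (
    Connectome,
    ConnectomeError,
    Edge,
    RandomizationError,
    connectome_from_edges,
)


@dataclass
class StimulationProtocol:
    """External drive schedule: (step, neuron-name set, magnitude) triples."""

    schedule: list[tuple[int, frozenset[str], float]]
    duration: int

    def __post_init__(self) -> None:
        for step, names, mag in self.schedule:
            if not 0 <= step < self.duration:
                raise ValueError(
                    f"scheduled step {step} outside [0, {self.duration})"
                )
            if not math.isfinite(mag):
                raise ValueError(f"non-finite stimulation magnitude at step {step}")
            if not names:
                raise ValueError(f"empty neuron set at step {step}")

    def neuron_names(self) -> set[str]:
        return {name for _, names, _ in self.schedule for name in names}

    def external_matrix(self, name_index: dict[str, int], duration: int) -> np.ndarray:
        """Dense (duration, n) matrix of per-step external inputs."""
        ext = np.zeros((duration, len(name_index)))
        for step, names, mag in self.schedule:
            if step >= duration:
                continue
            for name in names:
                ext[step, name_index[name]] += mag
        return ext

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "neurons", "magnitude"])
            for step, names, mag in self.schedule:
                writer.writerow([step, ";".join(sorted(names)), repr(float(mag))])

    @classmethod
    def from_csv(cls, path: str, duration: int) -> "StimulationProtocol":
        schedule = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None:
                raise ValueError(f"{path}: empty protocol file")
            for row in reader:
                step, names, mag = row
                schedule.append((int(step), frozenset(names.split(";")), float(mag)))
        return cls(schedule=schedule, duration=duration)


@dataclass
class PlantedSpec:
    """Specification of a planted-frequency network.

    Each group ``g`` of ``group_sizes[g]`` neurons is driven every step with
    magnitude ``drive_per_group[g]``.  Starting from zero state, a driven
    neuron accumulates while its value stays at or below the threshold
    ``h``, exceeds it one step later, and resets on the step after that, so
    its period is exactly ``floor(h / c) + 2`` steps.  Groups carry a
    within-group ring of synaptic edges whose weights cycle through
    ``internal_coupling * {1, ..., 10}``, mimicking the mixed weight
    magnitudes of a real connectome; the coupling does not perturb the
    period, because group members fire in unison and a neuron that is
    itself firing ignores synaptic input while it resets.  The weight
    heterogeneity is what makes the degree-preserving null model a
    meaningful control: shuffling identical weights would be a no-op.
    """

    group_sizes: list[int] = field(default_factory=lambda: [20, 20])
    drive_per_group: list[float] = field(default_factory=lambda: [1.0, 2.0])
    threshold: float = 30.0
    internal_coupling: float = 1.0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.drive_per_group):
            raise ValueError("group_sizes and drive_per_group must align")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if any(c <= 0 for c in self.drive_per_group):
            raise ValueError("drive magnitudes must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def expected_period(h: float, drive: float) -> int:
    """Closed-form firing period of a constantly driven isolated neuron.

    The state climbs 0, c, 2c, ... while <= h (floor(h/c)+1 steps including
    the start), exceeds h on the next step, and is reset on the one after:
    floor(h/c) + 2 steps per cycle.
    """
    return int(math.floor(h / drive)) + 2


def generate_planted_frequency_network(
    spec: PlantedSpec, duration: int = 1024
) -> tuple[Connectome, StimulationProtocol, list[int]]:
    """Build a planted-frequency connectome, its drive protocol and ground truth.

    Returns the connectome (groups named G0N000, G0N001, ..., ring-coupled
    within groups, no cross-group edges), a protocol driving every group
    member at every step with the group's magnitude, and the exact expected
    period of each group.
    """
    periods = []
    edges: list[Edge] = []
    groups: list[list[str]] = []
    for g, (size, drive) in enumerate(zip(spec.group_sizes, spec.drive_per_group)):
        names = [f"G{g}N{k:03d}" for k in range(size)]
        groups.append(names)
        p = expected_period(spec.threshold, drive)
        if p == 2:
            warnings.warn(
                f"group {g}: drive {drive} >= threshold+1 collapses the period to 2",
                stacklevel=2,
            )
        periods.append(p)
        if spec.internal_coupling != 0.0 and size > 1:
            for k in range(size):
                edges.append(
                    Edge(
                        pre=names[k],
                        post=names[(k + 1) % size],
                        kind="chemical",
                        weight=spec.internal_coupling * (1 + k % 10),
                    )
                )
    all_names = [name for names in groups for name in names]
    if edges:
        conn = connectome_from_edges(edges)
    else:
        from .connectome import Neuron

        conn = Connectome(
            neurons=[Neuron.from_name(n) for n in sorted(all_names)],
            weight_matrix=np.zeros((len(all_names), len(all_names))),
        )
    schedule = [
        (t, frozenset(groups[g]), spec.drive_per_group[g])
        for t in range(duration)
        for g in range(len(groups))
    ]
    protocol = StimulationProtocol(schedule=schedule, duration=duration)
    return conn, protocol, periods


def planted_partition(spec: PlantedSpec) -> list[list[str]]:
    """The ground-truth group membership, as sorted name lists."""
    return [
        sorted(f"G{g}N{k:03d}" for k in range(size))
        for g, size in enumerate(spec.group_sizes)
    ]


def _sample_weights(n: int, sampler: dict | None, rng: np.random.Generator) -> np.ndarray:
    sampler = sampler or {}
    kind = sampler.get("kind", "uniform_int")
    if kind == "uniform_int":
        low = sampler.get("low", 1)
        high = sampler.get("high", 10)
        w = rng.integers(low, high + 1, size=n).astype(float)
    elif kind == "constant":
        w = np.full(n, float(sampler.get("value", 1.0)))
    else:
        raise ValueError(f"unknown weight sampler kind {kind!r}")
    neg = sampler.get("neg_fraction", 0.0)
    if neg > 0:
        flip = rng.random(n) < neg
        w[flip] *= -1
    return w


def generate_configuration_network(
    in_degrees: list[int],
    out_degrees: list[int],
    weight_sampler: dict | None = None,
    seed: int = 0,
    max_retries: int = 200,
) -> Connectome:
    """Directed configuration-model graph with exact degree sequences.

    Stub matching: out-stubs are randomly permuted against in-stubs;
    matchings producing self-loops or parallel edges are rejected and
    re-drawn up to ``max_retries`` times, after which the sequence is
    declared unrealizable.  Node ``k`` is named ``N{k:03d}``; weights come
    from ``weight_sampler`` (default: integers uniform on [1, 10], with an
    optional fraction flipped negative to mimic inhibitory connections).
    """
    if sum(in_degrees) != sum(out_degrees):
        raise ConnectomeError("in- and out-degree sums must match")
    if len(in_degrees) != len(out_degrees):
        raise ConnectomeError("degree sequences must have equal length")
    n = len(in_degrees)
    names = [f"N{k:03d}" for k in range(n)]
    rng = np.random.default_rng(seed)
    in_stubs = np.repeat(np.arange(n), in_degrees)
    out_stubs = np.repeat(np.arange(n), out_degrees)
    m = len(in_stubs)
    if m == 0:
        from .connectome import Neuron

        return Connectome(
            neurons=[Neuron.from_name(nm) for nm in names],
            weight_matrix=np.zeros((n, n)),
        )
    for _ in range(max_retries):
        perm = rng.permutation(m)
        src = out_stubs
        dst = in_stubs[perm]
        if np.any(src == dst):
            continue
        pairs = set(zip(src.tolist(), dst.tolist()))
        if len(pairs) != m:
            continue
        weights = _sample_weights(m, weight_sampler, rng)
        edges = [
            Edge(pre=names[s], post=names[d], kind="chemical", weight=float(w))
            for s, d, w in zip(src, dst, weights)
        ]
        return connectome_from_edges(edges)
    raise RandomizationError(
        f"could not realize degree sequence without self-loops or parallel "
        f"edges after {max_retries} attempts"
    )


def generate_stimulation_protocol(
    kind: str, params: dict, seed: int = 0
) -> StimulationProtocol:
    """Canned stimulation schedules: ``none``, ``periodic``, ``random_encounters``.

    ``periodic`` drives ``neurons`` every ``period`` steps with ``magnitude``;
    ``random_encounters`` draws Bernoulli(``rate``) obstacle-encounter events
    per step, each stimulating ``neurons`` for ``bout_length`` steps.
    """
    if kind not in ("none", "periodic", "random_encounters"):
        raise ValueError(f"unknown stimulation protocol kind {kind!r}")
    duration = int(params["duration"])
    if kind == "none":
        return StimulationProtocol(schedule=[], duration=duration)
    neurons = frozenset(params["neurons"])
    magnitude = float(params.get("magnitude", 20.0))
    if kind == "periodic":
        period = int(params["period"])
        schedule = [
            (t, neurons, magnitude) for t in range(0, duration, period)
        ]
        return StimulationProtocol(schedule=schedule, duration=duration)
    if kind == "random_encounters":
        rng = np.random.default_rng(seed)
        rate = float(params.get("rate", 0.05))
        bout = int(params.get("bout_length", 2))
        hits = np.nonzero(rng.random(duration) < rate)[0]
        steps = sorted({int(t) + k for t in hits for k in range(bout) if t + k < duration})
        schedule = [(t, neurons, magnitude) for t in steps]
        return StimulationProtocol(schedule=schedule, duration=duration)
    raise ValueError(f"unknown stimulation protocol kind {kind!r}")
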