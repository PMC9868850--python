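"""Weighted directed connectome graphs: loading, validation, null models, centrality.

The connectome is represented as a square weight matrix ``W`` over a
lexicographically ordered neuron roster, where ``W[i, j]`` is the summed
synaptic weight delivered to neuron *i* when neuron *j* fires.  Chemical
synapses and gap junctions between the same ordered pair are merged
additively into a single entry; weight sign encodes excitatory (+) versus
inhibitory (-) action.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("wormnet")

EDGE_KINDS = ("chemical", "gap")
ROLES = ("sensory", "inter", "motor", "unknown")
SIDE_SUFFIXES = ("L", "R", "D", "V")


class ConnectomeError(ValueError):
    """Malformed connectome input (parse or validation failure)."""


class RandomizationError(RuntimeError):
    """Degree sequence could not be realized within the retry budget."""


def _parse_side_suffix(name: str) -> str | None:
    # WormAtlas convention: radially symmetric cells carry a trailing
    # L/R/D/V after a >=2-letter class name (possibly with a number).
    if len(name) >= 3 and name[-1] in SIDE_SUFFIXES:
        return name[-1]
    return None


@dataclass(frozen=True)
class Neuron:
    """A named neuron with an optional functional role annotation."""

    name: str
    role: str = "unknown"
    side_suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConnectomeError("neuron name must be non-empty")
        if self.role not in ROLES:
            raise ConnectomeError(f"unknown neuron role {self.role!r}")

    @classmethod
    def from_name(cls, name: str, role: str = "unknown") -> "Neuron":
        return cls(name=name, role=role, side_suffix=_parse_side_suffix(name))


@dataclass(frozen=True)
class Edge:
    """A directed connection from ``pre`` to ``post`` of a given modality."""

    pre: str
    post: str
    kind: str
    weight: float

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ConnectomeError(f"unknown edge kind {self.kind!r}")
        if not np.isfinite(self.weight):
            raise ConnectomeError(f"non-finite weight on edge {self.pre}->{self.post}")


@dataclass
class Connectome:
    """Neuron roster plus merged weight matrix.

    ``weight_matrix[i, j]`` is the total signed weight neuron ``neurons[i]``
    receives when ``neurons[j]`` fires.  The roster is sorted by name so the
    matrix indexing is reproducible across runs.
    """

    neurons: list[Neuron]
    weight_matrix: np.ndarray
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.neurons)
        self.weight_matrix = np.asarray(self.weight_matrix, dtype=float)
        if self.weight_matrix.shape != (n, n):
            raise ConnectomeError(
                f"weight matrix shape {self.weight_matrix.shape} does not match "
                f"roster size {n}"
            )
        names = [nr.name for nr in self.neurons]
        if len(set(names)) != n:
            raise ConnectomeError("duplicate neuron names in roster")
        if names != sorted(names):
            raise ConnectomeError("neuron roster must be sorted by name")
        if np.any(np.diag(self.weight_matrix) != 0):
            raise ConnectomeError("weight matrix has non-zero diagonal (self-loops)")
        self._index = {name: i for i, name in enumerate(names)}

    @property
    def names(self) -> list[str]:
        return [nr.name for nr in self.neurons]

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def edge_count(self) -> int:
        """Number of directed connections in the merged simple digraph."""
        return int(np.count_nonzero(self.weight_matrix))

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConnectomeError(f"neuron {name!r} not in roster") from None

    def in_degrees(self) -> np.ndarray:
        """In-degree per neuron on the merged simple digraph."""
        return np.count_nonzero(self.weight_matrix, axis=1)

    def out_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.weight_matrix, axis=0)

    def weight_multiset(self) -> np.ndarray:
        """Sorted nonzero entries of the merged weight matrix."""
        w = self.weight_matrix[self.weight_matrix != 0]
        return np.sort(w)

    def to_digraph(self) -> nx.DiGraph:
        """Merged simple digraph with ``weight`` edge attributes."""
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        rows, cols = np.nonzero(self.weight_matrix)
        for i, j in zip(rows, cols):
            g.add_edge(self.names[j], self.names[i], weight=self.weight_matrix[i, j])
        return g


def connectome_from_edges(
    edges: list[Edge],
    roster: list[Neuron] | None = None,
) -> Connectome:
    """Assemble a :class:`Connectome` from parsed edges.

    When ``roster`` is given, edges referencing undeclared neurons are a
    validation error; otherwise the roster is inferred from the edges.
    Self-loops are dropped with a warning, and parallel edges (e.g. a
    chemical synapse plus a gap junction on the same pair) are summed.
    """
    if roster is not None:
        neurons = sorted(roster, key=lambda nr: nr.name)
        known = {nr.name for nr in neurons}
        for e in edges:
            for name in (e.pre, e.post):
                if name not in known:
                    raise ConnectomeError(
                        f"edge {e.pre}->{e.post} references neuron {name!r} "
                        "absent from the declared roster"
                    )
    else:
        names = sorted({name for e in edges for name in (e.pre, e.post)})
        neurons = [Neuron.from_name(name) for name in names]

    index = {nr.name: i for i, nr in enumerate(neurons)}
    n = len(neurons)
    w = np.zeros((n, n), dtype=float)
    kept: list[Edge] = []
    n_loops = 0
    for e in edges:
        if e.pre == e.post:
            n_loops += 1
            continue
        w[index[e.post], index[e.pre]] += e.weight
        kept.append(e)
    if n_loops:
        logger.warning("dropped %d self-loop edge(s) from connectome input", n_loops)
    return Connectome(neurons=neurons, weight_matrix=w, edges=kept)


def _load_roster(path: str) -> list[Neuron]:
    neurons = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if [c.strip().lower() for c in row[:2]] == ["name", "role"]:
                continue
            if len(row) < 2:
                raise ConnectomeError(f"{path}:{lineno}: expected name,role")
            neurons.append(Neuron.from_name(row[0].strip(), role=row[1].strip()))
    return neurons


def _load_edgelist_csv(path: str) -> list[Edge]:
    edges = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            cells = [c.strip() for c in row]
            if lineno == 1 and [c.lower() for c in cells[:4]] == [
                "pre", "post", "type", "weight",
            ]:
                continue
            if len(cells) != 4:
                raise ConnectomeError(
                    f"{path}:{lineno}: expected 4 columns (pre,post,type,weight), "
                    f"got {len(cells)}"
                )
            pre, post, kind, weight_s = cells
            try:
                weight = float(weight_s)
            except ValueError:
                raise ConnectomeError(
                    f"{path}:{lineno}: non-numeric weight {weight_s!r}"
                ) from None
            edges.append(Edge(pre=pre, post=post, kind=kind, weight=weight))
    return edges


def _load_graphml(path: str) -> list[Edge]:
    g = nx.read_graphml(path)
    edges = []
    for u, v, data in g.edges(data=True):
        kind = data.get("type", "chemical")
        try:
            weight = float(data.get("weight", 1.0))
        except (TypeError, ValueError):
            raise ConnectomeError(
                f"{path}: non-numeric weight on edge {u}->{v}"
            ) from None
        edges.append(Edge(pre=str(u), post=str(v), kind=kind, weight=weight))
    return edges


def load_connectome(
    path: str,
    dialect: str = "edgelist",
    roster_path: str | None = None,
) -> Connectome:
    """Load a connectome from an edge-list CSV or a GraphML file.

    Parameters
    ----------
    path
        Edge-list CSV with header ``pre,post,type,weight`` (``type`` in
        {chemical, gap}; ``#`` starts a comment line), or a GraphML file
        with ``type``/``weight`` edge attributes.
    dialect
        ``"edgelist"`` or ``"graphml"``.
    roster_path
        Optional neuron-roster CSV (``name,role``).  When given, the roster
        defines the neuron set and role annotations, and any edge naming an
        undeclared neuron is rejected.
    """
    if dialect == "edgelist":
        edges = _load_edgelist_csv(path)
    elif dialect == "graphml":
        edges = _load_graphml(path)
    else:
        raise ConnectomeError(f"unknown connectome dialect {dialect!r}")
    roster = _load_roster(roster_path) if roster_path else None
    return connectome_from_edges(edges, roster=roster)


def write_edgelist(c: Connectome, path: str) -> None:
    """Write the merged connectome as an edge-list CSV (one row per W entry)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pre", "post", "type", "weight"])
        rows, cols = np.nonzero(c.weight_matrix)
        for i, j in sorted(zip(rows, cols), key=lambda ij: (c.names[ij[1]], c.names[ij[0]])):
            writer.writerow(
                [c.names[j], c.names[i], "chemical", repr(float(c.weight_matrix[i, j]))]
            )


def randomize_null(
    c: Connectome,
    seed: int,
    swaps_per_edge: int = 10,
    max_tries_factor: int = 100,
) -> Connectome:
    """Degree- and weight-preserving randomization (Maslov-Sneppen).

    The merged simple digraph is rewired by double-edge swaps — two directed
    edges ``(a, b)`` and ``(c, d)`` become ``(a, d)`` and ``(c, b)`` — with
    any swap creating a self-loop or a parallel edge rejected, until
    ``swaps_per_edge * edge_count`` swaps have succeeded (or the attempt
    budget runs out, which happens only on rigid graphs where few or no
    legal swaps exist).  The weight multiset is then shuffled over the
    rewired edges.  The result has exactly the input's in-degree sequence,
    out-degree sequence and edge-weight multiset, with both topology and
    weights randomly reassigned.
    """
    if c.n_neurons < 2 or c.edge_count < 1:
        raise ConnectomeError("randomization needs >=2 neurons and >=1 edge")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(c.weight_matrix)
    # edges as (source j, target i) pairs on integer labels
    edges = [(int(j), int(i)) for i, j in zip(rows, cols)]
    edge_set = set(edges)
    m = len(edges)
    target_swaps = swaps_per_edge * m
    budget = max_tries_factor * target_swaps
    done = 0
    for _ in range(budget):
        if done >= target_swaps:
            break
        k1, k2 = rng.integers(0, m, size=2)
        if k1 == k2:
            continue
        a, b = edges[k1]
        cc, d = edges[k2]
        if a == d or cc == b:  # would create self-loops
            continue
        if (a, d) in edge_set or (cc, b) in edge_set:  # parallel edges
            continue
        edge_set.discard((a, b))
        edge_set.discard((cc, d))
        edge_set.add((a, d))
        edge_set.add((cc, b))
        edges[k1] = (a, d)
        edges[k2] = (cc, b)
        done += 1
    if done < target_swaps:
        logger.info(
            "randomize_null: %d/%d swaps achieved within budget (rigid graph)",
            done,
            target_swaps,
        )
    weights = c.weight_matrix[rows, cols]
    shuffled = weights[rng.permutation(m)]
    w = np.zeros_like(c.weight_matrix)
    for (j, i), wt in zip(edges, shuffled):
        w[i, j] = wt
    return Connectome(neurons=list(c.neurons), weight_matrix=w, edges=[])


def centrality_summary(c: Connectome) -> pd.DataFrame:
    """Per-neuron degree centrality, harmonic in-closeness and in-strength.

    Degree centrality is total (in+out) degree on the merged simple digraph
    normalized by ``n-1``.  In-closeness uses the harmonic convention on
    directed shortest paths into each node (unreachable pairs contribute
    zero), normalized by ``n-1``.  In-strength is the summed incoming
    weight.  Rows are sorted descending by degree centrality with ties
    broken by name.
    """
    if c.n_neurons == 0:
        raise ConnectomeError("centrality of an empty graph is undefined")
    g = c.to_digraph()
    deg = nx.degree_centrality(g)
    # harmonic_centrality sums 1/d(v, u) over incoming shortest paths
    harm = nx.harmonic_centrality(g)
    denom = max(c.n_neurons - 1, 1)
    table = pd.DataFrame(
        {
            "neuron": c.names,
            "degree_centrality": [deg[name] for name in c.names],
            "in_closeness": [harm[name] / denom for name in c.names],
            "in_strength": c.weight_matrix.sum(axis=1),
        }
    )
    table = table.sort_values(
        ["degree_centrality", "neuron"], ascending=[False, True]
    ).reset_index(drop=True)
    return table
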