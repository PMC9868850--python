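"""End-to-end orchestration: load/generate -> simulate -> analyze -> report.

Every stage writes a plain-text table into the output directory and the
run is summarized in a JSON manifest recording the parameters and seeds
that determine the outputs, so a saved configuration re-runs to identical
files.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import Connectome, centrality_summary, load_connectome, randomize_null
from .population import (
    action_correlation,
    conditional_coupling,
    normalize_series,
    pca_weights,
)
from .simulate import ActionLog, SimConfig, SimulationTrace, run_simulation
from .spectral import spectra_from_trace, summarize_trace
from .synthetic import PlantedSpec, generate_planted_frequency_network

logger = logging.getLogger("wormnet")


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    connectome_path: str | None = None
    dialect: str = "edgelist"
    roster_path: str | None = None
    synthetic: dict | None = None  # PlantedSpec fields, used when no file given
    duration: int = 900
    threshold: float = 30.0
    overlap_threshold: float = 0.9
    coupling_cutoff: float = 0.5
    n_components: int = 3
    run_null: bool = False
    seed: int = 0
    out_dir: str = "wormnet_out"
    extra_sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_trace(trace: SimulationTrace, path: str) -> None:
    """TSV with a neuron-name header and one row of states per second."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(trace.names) + "\n")
        for row in trace.states:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_trace(path: str, threshold: float = 30.0) -> SimulationTrace:
    """Read a trace TSV back; firing times are recomputed from the states."""
    p = Path(path)
    lines = p.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty trace file")
    names = lines[0].split("\t")
    if len(lines) < 2:
        raise ValueError(f"{path}: trace has a header but no state rows")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(names):
            raise ValueError(
                f"{path}:{lineno}: expected {len(names)} columns, got {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric state value") from None
    return SimulationTrace(states=np.array(rows), names=names, threshold=threshold)


def write_firing_events(trace: SimulationTrace, path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["neuron", "step"])
        writer.writerows(trace.firing_table())


def write_action_log(log: ActionLog, path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "action", "left", "right"])
        for step, action, left, right in log.events:
            writer.writerow([step, action, repr(left), repr(right)])


def read_action_log(path: str) -> ActionLog:
    events = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            events.append((int(row[0]), row[1], float(row[2]), float(row[3])))
    return ActionLog(events=events)


def _resolve_connectome(cfg: PipelineConfig):
    if cfg.connectome_path:
        conn = load_connectome(cfg.connectome_path, dialect=cfg.dialect, roster_path=cfg.roster_path)
        return conn, None, None
    spec = PlantedSpec(**(cfg.synthetic or {}))
    conn, protocol, periods = generate_planted_frequency_network(spec, duration=cfg.duration)
    return conn, protocol, periods


def _analyze(
    trace: SimulationTrace,
    cfg: PipelineConfig,
    out: Path,
    tag: str,
) -> dict:
    """Spectral + population analysis of one trace; returns summary facts."""
    spectra = spectra_from_trace(trace)
    summaries, clusters = summarize_trace(trace, overlap_threshold=cfg.overlap_threshold)
    pd.DataFrame(
        [
            {"neuron": sp.neuron, "frequency": f, "real_part": v}
            for sp in spectra
            for f, v in zip(sp.frequencies, sp.real_part)
        ]
    ).to_csv(out / f"spectra_{tag}.csv", index=False)
    omega = {s.neuron: s.omega for s in summaries}
    member = clusters.membership()
    pd.DataFrame(
        [
            {"neuron": n, "cluster_id": member.get(n, -1), "omega": omega[n]}
            for n in sorted(omega)
        ]
    ).to_csv(out / f"clusters_{tag}.csv", index=False)

    facts: dict = {
        "n_clusters": len(clusters.clusters),
        "cluster_sizes": [len(c) for c in clusters.clusters],
        "cluster_omega": clusters.cluster_omega,
        "max_omega": max(omega.values()) if omega else 0.0,
        "files": [f"spectra_{tag}.csv", f"clusters_{tag}.csv"],
    }
    try:
        nt = normalize_series(trace)
    except ValueError:
        facts["pca"] = None
        return facts
    n_comp = min(cfg.n_components, len(nt.names))
    pca = pca_weights(nt, n_components=n_comp)
    pd.DataFrame(
        pca.weights,
        index=pd.Index(pca.names, name="neuron"),
        columns=[f"pc{k+1}" for k in range(pca.weights.shape[1])],
    ).to_csv(out / f"pca_{tag}.csv")
    facts["explained_variance"] = pca.explained_variance.tolist()

    # nested coupling: fastest-cluster member conditioned on slowest-cluster member
    coupling_rows = []
    if len(clusters.clusters) >= 2:
        names_idx = {n: j for j, n in enumerate(trace.names)}
        ordered = sorted(
            range(len(clusters.clusters)), key=lambda k: clusters.cluster_omega[k][0]
        )
        slow_rep = clusters.clusters[ordered[0]][0]
        for k in ordered[1:]:
            fast_rep = clusters.clusters[k][0]
            try:
                res = conditional_coupling(
                    trace.states[:, names_idx[slow_rep]],
                    trace.states[:, names_idx[fast_rep]],
                    cutoff=cfg.coupling_cutoff,
                    slow_name=slow_rep,
                    fast_name=fast_rep,
                )
            except ValueError as exc:
                logger.info("coupling %s->%s skipped: %s", slow_rep, fast_rep, exc)
                continue
            coupling_rows.append(
                {
                    "slow": res.slow,
                    "fast": res.fast,
                    "R": res.R,
                    "n_events": res.n_events,
                    "coupled": res.coupled,
                }
            )
    pd.DataFrame(
        coupling_rows, columns=["slow", "fast", "R", "n_events", "coupled"]
    ).to_csv(out / f"coupling_{tag}.csv", index=False)
    facts["coupling"] = coupling_rows
    facts["files"] += [f"pca_{tag}.csv", f"coupling_{tag}.csv"]
    return facts


def run_full_pipeline(cfg: PipelineConfig, log: ActionLog | None = None) -> dict:
    """Run every stage and write the report bundle plus a manifest.

    With ``run_null`` set, the analysis is repeated on a degree- and
    weight-preserving randomization of the connectome under the same
    protocol, for a side-by-side cluster comparison.  An optional action
    log enables the firing-vs-action correlation stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conn, protocol, periods = _resolve_connectome(cfg)
    logger.info(
        "pipeline: %d neurons, %d edges, duration=%d, h=%s, seed=%d",
        conn.n_neurons,
        conn.edge_count,
        cfg.duration,
        cfg.threshold,
        cfg.seed,
    )
    sim_cfg = SimConfig(
        duration=cfg.duration, threshold=cfg.threshold, seed=cfg.seed, **cfg.extra_sim
    )
    trace = run_simulation(conn, sim_cfg, protocol)
    write_trace(trace, str(out / "trace.tsv"))
    write_firing_events(trace, str(out / "firing_events.csv"))
    centrality_summary(conn).to_csv(out / "centrality.csv", index=False)

    manifest: dict = {
        "wormnet_version": __version__,
        "config": asdict(cfg),
        "n_neurons": conn.n_neurons,
        "edge_count": conn.edge_count,
        "expected_periods": periods,
        "outputs": ["trace.tsv", "firing_events.csv", "centrality.csv"],
    }
    facts = _analyze(trace, cfg, out, tag="real")
    manifest["real"] = facts
    manifest["outputs"] += facts.pop("files")

    if log is not None:
        rows = []
        for name in trace.names:
            try:
                ac = action_correlation(trace, log, name)
            except ValueError:
                continue
            rows.append(
                {
                    "neuron": ac.neuron,
                    **{f"{k}_at_fire": ac.fractions_at_fire[c] for k, c in
                       zip(("fwd", "bwd", "other"), ("forward", "backward", "other"))},
                    **{f"{k}_overall": ac.fractions_overall[c] for k, c in
                       zip(("fwd", "bwd", "other"), ("forward", "backward", "other"))},
                    "chi2": ac.chi_square,
                    "p": ac.p_value,
                    "df": ac.df,
                }
            )
        pd.DataFrame(rows).to_csv(out / "action_correlation.csv", index=False)
        manifest["outputs"].append("action_correlation.csv")

    if cfg.run_null:
        null_conn = randomize_null(conn, seed=cfg.seed)
        null_trace = run_simulation(null_conn, sim_cfg, protocol)
        null_facts = _analyze(null_trace, cfg, out, tag="null")
        manifest["null"] = null_facts
        manifest["outputs"] += null_facts.pop("files")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"].append("manifest.json")
    return manifest
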