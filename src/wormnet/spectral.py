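"""Per-neuron Fourier spectra, characteristic frequencies and synchronized clusters.

At 1 Hz sampling every signal lives on the frequency grid k/N for
k = 0..N/2, bounded by the 0.5 Hz Nyquist frequency.  The characteristic
frequency Omega of a neuron is the location of the highest peak of the
magnitude of the real part of its mean-removed discrete Fourier transform.
Neurons whose full real-part spectra overlap (cosine similarity above a
threshold) *and* share the same peak bin form frequency-synchronized
clusters; a degree- and weight-preserving randomization of the connectome
is expected to destroy such clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .simulate import SimulationTrace

logger = logging.getLogger("wormnet")

NYQUIST_HZ = 0.5  # half the 1 Hz sampling rate


@dataclass
class Spectrum:
    """Real part of the mean-removed DFT of one neuron's signal."""

    neuron: str
    frequencies: np.ndarray
    real_part: np.ndarray

    @property
    def is_silent(self) -> bool:
        return bool(np.allclose(self.real_part, 0.0))


@dataclass
class SpectralSummary:
    """Characteristic frequency Omega and its peak amplitude."""

    neuron: str
    omega: float
    peak_amplitude: float


@dataclass
class ClusterAssignment:
    """Partition of analyzed neurons into frequency-synchronized clusters.

    ``clusters`` holds sorted member-name lists (size >= 2), ordered by the
    cluster mean Omega; ``cluster_omega`` gives (mean, population std) of
    member characteristic frequencies; silent neurons and singletons are in
    ``unassigned``.
    """

    clusters: list[list[str]]
    cluster_omega: list[tuple[float, float]]
    unassigned: list[str]

    def membership(self) -> dict[str, int]:
        return {n: k for k, names in enumerate(self.clusters) for n in names}


def real_spectrum(series: np.ndarray, neuron: str = "") -> Spectrum:
    """Mean-removed real-DFT of a 1 Hz-sampled series (rectangular window)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 16:
        raise ValueError("series must be 1-D with at least 16 samples")
    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0)
    if np.ptp(x) == 0.0:
        logger.warning("constant series for neuron %r: silent spectrum", neuron)
        return Spectrum(neuron=neuron, frequencies=freqs, real_part=np.zeros(freqs.size))
    rp = np.real(np.fft.rfft(x - x.mean()))
    return Spectrum(neuron=neuron, frequencies=freqs, real_part=rp)


def characteristic_frequency(sp: Spectrum) -> SpectralSummary:
    """Omega = frequency of the highest |real part| peak, zero bin excluded.

    Ties break toward the lower frequency.  Raises on a silent spectrum;
    silent neurons are excluded upstream.
    """
    if sp.is_silent:
        raise ValueError(f"neuron {sp.neuron!r} is silent: no characteristic frequency")
    mag = np.abs(sp.real_part)
    k = int(np.argmax(mag[1:])) + 1  # argmax returns the first (lowest-f) maximum
    return SpectralSummary(
        neuron=sp.neuron, omega=float(sp.frequencies[k]), peak_amplitude=float(sp.real_part[k])
    )


def _peak_bin(sp: Spectrum) -> int:
    return int(np.argmax(np.abs(sp.real_part)[1:])) + 1


def spectra_from_trace(trace: SimulationTrace) -> list[Spectrum]:
    """One spectrum per neuron, from the full state matrix."""
    return [
        real_spectrum(trace.states[:, j], neuron=name)
        for j, name in enumerate(trace.names)
    ]


def detect_frequency_clusters(
    spectra: list[Spectrum],
    overlap_threshold: float = 0.9,
) -> ClusterAssignment:
    """Group neurons whose full spectra overlap into synchronized clusters.

    Two non-silent neurons are linked when the cosine similarity of their
    real-part spectra is at least ``overlap_threshold`` and their peak bins
    coincide; clusters are the connected components of the link graph with
    at least two members.  Cluster frequency is reported as mean +/-
    population standard deviation of the member Omegas.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    active = [sp for sp in spectra if not sp.is_silent]
    silent = [sp.neuron for sp in spectra if sp.is_silent]
    if len(active) == 0:
        logger.warning("all neurons silent: empty cluster partition")
        return ClusterAssignment(clusters=[], cluster_omega=[], unassigned=sorted(silent))
    if len(active) < 2:
        return ClusterAssignment(
            clusters=[], cluster_omega=[], unassigned=sorted(silent + [sp.neuron for sp in active])
        )
    # deterministic processing order, independent of caller ordering
    active = sorted(active, key=lambda sp: sp.neuron)
    mat = np.vstack([sp.real_part for sp in active])
    norms = np.linalg.norm(mat, axis=1)
    cos = (mat @ mat.T) / np.outer(norms, norms)
    peaks = np.array([_peak_bin(sp) for sp in active])
    link = (cos >= overlap_threshold) & (peaks[:, None] == peaks[None, :])
    np.fill_diagonal(link, False)
    n_comp, labels = connected_components(csr_matrix(link), directed=False)
    omegas = np.array([characteristic_frequency(sp).omega for sp in active])
    clusters, cluster_omega, unassigned = [], [], list(silent)
    for comp in range(n_comp):
        members = np.nonzero(labels == comp)[0]
        if members.size < 2:
            unassigned.extend(active[i].neuron for i in members)
            continue
        names = sorted(active[i].neuron for i in members)
        om = omegas[members]
        clusters.append((float(om.mean()), names, (float(om.mean()), float(om.std()))))
    clusters.sort(key=lambda item: (item[0], item[1]))
    return ClusterAssignment(
        clusters=[names for _, names, _ in clusters],
        cluster_omega=[stats for _, _, stats in clusters],
        unassigned=sorted(unassigned),
    )


def summarize_trace(
    trace: SimulationTrace, overlap_threshold: float = 0.9
) -> tuple[list[SpectralSummary], ClusterAssignment]:
    """Spectra -> characteristic frequencies and synchronized clusters."""
    spectra = spectra_from_trace(trace)
    summaries = [characteristic_frequency(sp) for sp in spectra if not sp.is_silent]
    assignment = detect_frequency_clusters(spectra, overlap_threshold=overlap_threshold)
    return summaries, assignment
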