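"""Population-level analysis: PCA loadings, nested coupling, action correlation.

Signals are first standardized per neuron, s'(t) = (s(t) - mean) / sigma,
with the population (divide-by-n) standard deviation; silent neurons
(sigma = 0) are excluded.  Principal components come from the
eigendecomposition of the neuron-by-neuron covariance of the standardized
signals; opposite PC1 signs identify antiphase subpopulations.

Cross-frequency nesting is quantified by conditional sampling: the fast
signal is read off at each peak of the slow signal, and the ratio

    R = std(fast at slow peaks) / std(fast overall)

is near zero when the fast oscillation is phase-locked to the slow one and
near one when the two are unrelated.

Firing-vs-action association contrasts the actions in force at a neuron's
firing steps with the step-weighted action fractions of the whole run,
via a Pearson chi-square test on the fire-steps vs non-fire-steps
contingency over {forward, backward, other}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .simulate import ActionLog, SimulationTrace

logger = logging.getLogger("wormnet")

EVENT_CATEGORIES = ("forward", "backward", "other")


@dataclass
class NormalizedTrace:
    """Standardized (zero-mean, unit-std) signals with silent neurons removed."""

    values: np.ndarray  # (time, neuron)
    names: list[str]
    excluded: list[str]


@dataclass
class PCAResult:
    """Per-neuron loadings on each principal component.

    ``weights[:, k]`` is the unit-norm loading vector of component k
    (descending explained variance), oriented so its largest-magnitude
    entry is positive.
    """

    names: list[str]
    weights: np.ndarray  # (neuron, component)
    explained_variance: np.ndarray  # fraction per component
    sign_convention: str = "largest-magnitude-entry-positive"

    def pc1(self) -> dict[str, float]:
        return {n: float(w) for n, w in zip(self.names, self.weights[:, 0])}


@dataclass
class CouplingResult:
    """Conditional-dispersion coupling statistic for one (slow, fast) pair."""

    slow: str
    fast: str
    R: float
    n_events: int
    coupled: bool


@dataclass
class ActionCorrelation:
    """Action-event fractions at a neuron's firing steps vs the whole run."""

    neuron: str
    fractions_at_fire: dict[str, float]
    fractions_overall: dict[str, float]
    chi_square: float
    p_value: float
    df: int


def normalize_series(trace: SimulationTrace) -> NormalizedTrace:
    """Standardize each neuron's signal; exclude sigma = 0 neurons."""
    x = trace.states
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)  # population convention
    silent = sigma == 0.0
    if np.all(silent):
        raise ValueError("all neurons silent: nothing to normalize")
    keep = ~silent
    values = (x[:, keep] - mu[keep]) / sigma[keep]
    names = [n for n, k in zip(trace.names, keep) if k]
    excluded = [n for n, s in zip(trace.names, silent) if s]
    if excluded:
        logger.info("excluded %d silent neuron(s) from normalization", len(excluded))
    return NormalizedTrace(values=values, names=names, excluded=excluded)


def pca_weights(nt: NormalizedTrace, n_components: int | None = None) -> PCAResult:
    """Principal components of the neuron-by-neuron covariance.

    Components are ordered by descending explained variance and each is
    oriented so that its largest-magnitude entry is positive (eigenvector
    sign is otherwise arbitrary).
    """
    t, n = nt.values.shape
    if n < 2 or t < 3:
        raise ValueError("PCA needs >=2 neurons and >=3 time points")
    if n_components is None:
        n_components = n
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds neuron count {n}")
    cov = (nt.values.T @ nt.values) / t  # population covariance of standardized data
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1
    total = np.trace(cov)
    return PCAResult(
        names=list(nt.names),
        weights=evecs,
        explained_variance=evals / total,
    )


def find_peaks_strict(series: np.ndarray) -> np.ndarray:
    """Strict local maxima; on a plateau the earliest sample is the peak.

    A peak must be greater than the last differing value before it and the
    first differing value after it; endpoints cannot be peaks.
    """
    x = np.asarray(series, dtype=float)
    peaks = []
    i = 1
    n = x.size
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def conditional_coupling(
    slow: np.ndarray,
    fast: np.ndarray,
    cutoff: float = 0.5,
    slow_name: str = "slow",
    fast_name: str = "fast",
) -> CouplingResult:
    """Dispersion of the fast signal sampled at the slow signal's peaks.

    R is the population standard deviation of the fast signal at the slow
    peak times divided by that of the full fast signal; the pair is called
    coupled when R < cutoff.  Requires at least 3 slow peaks and a
    non-silent fast signal.  R is invariant under affine rescaling of the
    fast signal.
    """
    slow = np.asarray(slow, dtype=float)
    fast = np.asarray(fast, dtype=float)
    if slow.shape != fast.shape:
        raise ValueError("slow and fast series must share a time base")
    peaks = find_peaks_strict(slow)
    if peaks.size < 3:
        raise ValueError(
            f"insufficient events: {peaks.size} slow peak(s) detected, need >= 3"
        )
    denom = fast.std()
    if denom == 0.0:
        raise ValueError("fast series is silent (zero variance)")
    r = float(fast[peaks].std() / denom)
    return CouplingResult(
        slow=slow_name, fast=fast_name, R=r, n_events=int(peaks.size), coupled=r < cutoff
    )


def _categorize(action: str) -> str:
    if action in ("forward", "backward"):
        return action
    return "other"


def action_event_fractions(
    trace: SimulationTrace, log: ActionLog, neuron: str
) -> tuple[dict[str, float], dict[str, float], dict[str, int], dict[str, int]]:
    """Fractions of {forward, backward, other} at a neuron's firing steps
    and over the whole run (step-weighted).

    Returns (fractions_at_fire, fractions_overall, counts_at_fire,
    counts_overall).  Turns and idle are aggregated into "other", since
    the analysis focuses on forward/backward locomotion bouts.
    """
    if not log.events:
        raise ValueError("empty action log")
    fires = trace.firing_times(neuron)
    action_at = log.action_at()
    fires = np.asarray([t for t in fires if t in action_at], dtype=int)
    if fires.size == 0:
        raise ValueError(f"neuron {neuron!r} never fired during the logged run")
    counts_fire = dict.fromkeys(EVENT_CATEGORIES, 0)
    for t in fires:
        counts_fire[_categorize(action_at[int(t)])] += 1
    counts_all = dict.fromkeys(EVENT_CATEGORIES, 0)
    for _, action, _, _ in log.events:
        counts_all[_categorize(action)] += 1
    total_fire = sum(counts_fire.values())
    total_all = sum(counts_all.values())
    frac_fire = {k: v / total_fire for k, v in counts_fire.items()}
    frac_all = {k: v / total_all for k, v in counts_all.items()}
    return frac_fire, frac_all, counts_fire, counts_all


def chi_square_association(
    counts_at_fire: dict[str, int], counts_overall: dict[str, int]
) -> tuple[float, float, int]:
    """Pearson chi-square for firing-step vs non-firing-step action profiles.

    Builds the 2 x k contingency table whose rows are the action counts at
    firing steps and at the remaining steps (overall minus at-fire), with
    no continuity correction; df = k - 1.  Categories whose expected count
    is zero (absent from both rows) are collapsed out with a warning.
    """
    cats = [k for k in counts_overall if counts_overall.get(k, 0) > 0 or counts_at_fire.get(k, 0) > 0]
    dropped = [k for k in counts_overall if k not in cats]
    if dropped:
        logger.warning("collapsed empty action categories: %s", dropped)
    fire = np.array([counts_at_fire.get(k, 0) for k in cats], dtype=float)
    overall = np.array([counts_overall.get(k, 0) for k in cats], dtype=float)
    non_fire = overall - fire
    if np.any(non_fire < 0):
        raise ValueError("at-fire counts exceed overall counts")
    if fire.sum() == 0 or non_fire.sum() == 0:
        raise ValueError("both contingency rows need positive totals")
    table = np.vstack([fire, non_fire])
    keep = table.sum(axis=0) > 0
    if not np.all(keep):
        logger.warning("collapsed zero-expectation categories from contingency table")
        table = table[:, keep]
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p), int(df)


def action_correlation(
    trace: SimulationTrace, log: ActionLog, neuron: str
) -> ActionCorrelation:
    """Full firing-vs-action analysis for one neuron."""
    frac_fire, frac_all, counts_fire, counts_all = action_event_fractions(
        trace, log, neuron
    )
    stat, p, df = chi_square_association(counts_fire, counts_all)
    return ActionCorrelation(
        neuron=neuron,
        fractions_at_fire=frac_fire,
        fractions_overall=frac_all,
        chi_square=stat,
        p_value=p,
        df=df,
    )
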