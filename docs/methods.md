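# Methods

## Model and update rule

The simulator implements a synchronous threshold-fire-reset map on a
weighted directed graph. Every neuron holds a signed accumulator
$S_i$; at each step all neurons advance simultaneously from the time-$t$
snapshot. A neuron with $S_i(t) > h$ fires: its weights are delivered to
its targets and its own value is reset to zero (external input scheduled
for that step is discarded for a firing neuron — the reset branch is
absolute). A neuron with $S_i(t) \le h$ accumulates its incoming synaptic
input plus external drive. Conventions that the equation itself leaves
open, fixed here:

- $\Theta(0) = 0$: firing requires strictly $S > h$; the two update
  branches partition at $S \le h$.
- States may go negative under inhibition; no floor is applied.
- The initial state is all zeros by default (reproducible); a seeded
  uniform-random initialization on $[0, h]$ and explicit per-neuron
  initial values are available.
- Firing events are stamped at the step $t$ where $S(t) > h$; the reset
  lands at $t+1$.

With integer weights, drives and initial values every state stays integer,
so float64 arithmetic is exact and the vectorized implementation can be
compared bitwise against a scalar per-neuron re-implementation (done over
100 random networks in the tests).

Key parameters: threshold $h = 30$ (dimensionless accumulator units; the
emergent picture is insensitive to the exact value over roughly 10–100),
1 s per step (1 Hz sampling, 0.5 Hz Nyquist bound), sensor trigger
distance 30 cm, avoidance stimulus magnitude 20 per stimulated neuron per
step (configurable; the original controller's value is not documented),
food-seeking baseline drive 1 per step (configurable; chosen as the
smallest integer drive, giving the slowest sustained roaming rhythm).

## Connectome representation

Neurons are ordered lexicographically by name everywhere, so matrix
indexing is reproducible. $W_{ij}$ sums all edges from $j$ to $i$; a
chemical synapse and a gap junction on the same ordered pair merge
additively into one entry, and gap junctions are taken exactly as listed
(no forced symmetrization). Self-loops in input files are dropped with a
warning: the reset branch would erase their effect in the same step
anyway. Edge lists are CSV (`pre,post,type,weight`) or GraphML with
`type`/`weight` attributes; an optional `name,role` roster adds
sensory/inter/motor annotations and strict membership validation.

Centrality: degree centrality is total degree normalized by $n-1$;
in-closeness uses the *harmonic* convention on directed shortest paths
into each node (reciprocal distances summed, unreachable pairs contribute
zero), which is well-defined on disconnected digraphs; in-strength is the
summed incoming weight.

## Null model

Degree- and weight-preserving randomization uses Maslov–Sneppen double
edge swaps on the merged simple digraph — $10\times$ edge-count successful
swaps, rejecting any swap creating a self-loop or parallel edge — followed
by a shuffle of the weight multiset over the rewired edges. In- and
out-degree sequences and the weight multiset are preserved exactly. On
rigid graphs (e.g. a 3-cycle, where every swap would create a self-loop)
the procedure legitimately returns a weight-shuffled copy of the input
topology; the attempt budget is logged. Unrealizable degree sequences can
only arise in the synthetic configuration-model generator, which raises
after a bounded number of stub-matching retries.

## Synthetic ground truth

The planted-frequency generator is the package's main oracle. Group $g$
($n_g$ neurons) is driven every step with constant magnitude $c_g$; from a
zero start each driven neuron climbs $0, c, 2c, \dots$ while $\le h$,
exceeds $h$ one step later, and resets the step after, so its period is
exactly $\lfloor h/c \rfloor + 2$ steps ($h=30$: drive 1 → period 32,
drive 2 → period 17). Drives $\ge h+1$ collapse the period to 2 and emit a
warning.

Groups carry a within-group ring of edges whose weights cycle through
`internal_coupling` × {1,…,10}. Because group members fire in unison and a
firing neuron ignores synaptic input while it resets, the coupling
provably cannot perturb the planted periods — but it gives the null model
something real to destroy. The weight heterogeneity is essential: with
identical weights the null's weight shuffle is a no-op and randomized
networks retain spurious clusters built from the shared drive; with mixed
weights (mirroring the mixed integer weights of a real connectome) the
randomized network's extra kicks desynchronize the driven neurons and no
cluster of ≥ 5 members survives.

What the generator does *not* emulate: realistic worm-like topology (rich
clubs, motifs, reciprocity), broad degree distributions, or the actual
sensory-to-motor pathway structure. Passing tests on planted networks
therefore validate the machinery (simulation, spectral estimation,
clustering, null model, PCA, statistics) — they do not by themselves
certify claims about the real connectome, which requires running the
pipeline on the real edge-list file as input.

## Spectral analysis

Spectra are mean-removed real-part DFTs with a rectangular window and no
zero-padding, on the grid $k/N$, $k = 0..N/2$. The characteristic
frequency $\Omega$ is the highest peak of $|\mathrm{Re}\,\hat s|$ with the
zero bin excluded and ties broken toward lower frequency. The dominant
peak of the threshold-reset ramp lands at the fundamental $1/\text{period}$
within one DFT bin (verified at $N$ = 900 and 1024 for periods 32, 17
and 5). Constant signals are flagged silent and excluded downstream.

Clustering links two neurons when the cosine similarity of their full
real-part spectra is ≥ the overlap threshold (default 0.9, exposed and
swept over [0.8, 0.99] in tests) *and* their peak bins coincide; clusters
are connected components with ≥ 2 members, singletons go to unassigned.
Cosine similarity makes the detection invariant to uniform amplitude
rescaling, and inputs are re-sorted by name so the result is independent
of caller ordering.

## Population analysis

Standardization uses the population (divide-by-$n$) standard deviation
throughout, which keeps the $\sigma = 0$ exclusion rule clean. PCA is an
eigendecomposition of the covariance of the standardized signals;
components are ordered by descending explained variance and each is
oriented so its largest-magnitude entry is positive — a deterministic
convention, so any forward/backward sign association found later is an
empirical result, not an artifact of orientation. An independent
eigensolver (scikit-learn's PCA) serves as the oracle in tests.

Conditional coupling: slow-signal peaks are strict local maxima (greater
than the last differing value on each side; the earliest sample of a
plateau), at least 3 required. $R$ is the ratio of the conditional to the
unconditional population standard deviation of the fast signal; the
default coupling cutoff is $R < 0.5$, an operationalization of
"small fluctuations around a mean value" that is exposed in the
configuration. Exact harmonic locking gives $R = 0$; an enumerated
incommensurate pair (periods 7 and 16 over their LCM of 112 steps, where
the conditional samples visit every fast phase) gives $R \approx 0.854$.

Action correlation: the action in force at each firing step is counted
over {forward, backward, other}, with turns and idle aggregated into
"other" since locomotion bouts dominate; overall fractions are
step-weighted. The chi-square test is Pearson's on the 2×k table of
fire-steps versus non-fire-steps, no continuity correction, df = k−1;
categories empty in both rows are collapsed with a warning. Calibration:
with firing times drawn independently of a bout-structured action
schedule (600 steps, mean bout 20, 60 firing steps), the empirical
type-I error at α = 0.01 stays at or below ~1.5% over 1,000 replicates;
firing confined to backward bouts is rejected at p < 10⁻⁵ (power check).

## Virtual arena

The embodiment is a unicycle robot in a rectangular arena with circular
and segment obstacles: forward/backward translate ±speed (default 5
cm/step) along the heading, turns rotate ±turn-angle (default 30°) in
place. Per step, the action chosen from the motor neurons firing at
$S(t)$ moves the robot first; the distance sensor then ray-casts along
the new heading, and an obstacle closer than the trigger distance injects
the avoidance stimulus into the $S(t)\to S(t+1)$ update (so a wall 100 cm
ahead at 5 cm/step with a 30 cm trigger first stimulates at step 14).
Poses are clipped to the arena bounds with a logged collision. The action
rule — forward if both motor sums are positive, backward if both
negative, idle at (0, 0), otherwise turn toward the smaller side with
mixed-sign ties turning right — is a declared convention; the original
controller's exact wheel mapping is not documented, and the avoidance /
food-seeking neuron name lists are configuration inputs, not hard-coded
claims.

## Problem sizes and determinism

Default analysis runs use 900–1024 steps at 20–40 neurons for synthetic
studies; these are large enough that every frequency estimate is within
one DFT bin of its analytic value while the full test suite and the
acceptance script each complete in seconds. Every stochastic component
(network generation, randomization, protocols, initialization) takes an
explicit integer seed via `numpy.random.default_rng`, and a pipeline
configuration re-runs to byte-identical output tables.

## Known limitations

- Synchronized-cluster and centrality claims about the real *C. elegans*
  network depend on the actual connectome file, which is an input, not
  part of the package.
- Spectral estimation is a plain DFT: no multitaper or wavelet methods,
  and no peak-significance testing.
- The coupling cutoff and overlap threshold are qualitative conventions
  exposed as parameters; results should be reported alongside the values
  used.
- The arena is 2-D, kinematic and noise-free; it is a stand-in for
  embodiment, not a physics simulation.
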