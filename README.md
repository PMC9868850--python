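# wormnet

Connectome-driven neural dynamics: simulate threshold-fire-reset neurons on
the *C. elegans* wiring diagram (or a synthetic stand-in), embody the
network in a virtual sensorimotor arena, and analyze the oscillations that
emerge — frequency-synchronized clusters, population principal components,
nested cross-frequency coupling, and the association between single-neuron
firing and behavioral actions.

The package is aimed at researchers studying how much of an organism's
global neural dynamics is explained by connectome architecture alone: every
neuron here is an identical, featureless unit, so any structure in the
emergent dynamics (clusters, hierarchies, behavioral correlations) can only
come from the non-uniform synaptic wiring.

## Model

Each neuron carries a signed accumulator $S_i$. All neurons update
synchronously, once per second (1 Hz sampling, hence a 0.5 Hz Nyquist bound
on every signal):

$$
S_i(t+1) =
\begin{cases}
S_i(t) + \sum_j W_{ij}\,\Theta[S_j(t) - h] + I_i(t) & \text{if } S_i(t) \le h \\
0 & \text{otherwise}
\end{cases}
$$

where $W_{ij}$ is the summed synaptic weight delivered to neuron $i$ when
neuron $j$ fires (chemical synapses and gap junctions merged additively;
sign encodes excitation/inhibition), $h = 30$ is the firing threshold,
$\Theta$ is the strict step function ($\Theta(0) = 0$), and $I_i(t)$ is
external sensory input. A neuron whose value exceeds $h$ fires: it
distributes its weights to its targets and resets to zero.

Analysis stages:

- **Characteristic frequency** $\Omega$: the highest peak of the magnitude
  of the real part of each neuron's mean-removed DFT.
- **Synchronized clusters**: connected components of the graph linking
  neurons whose full real-part spectra have cosine similarity ≥ 0.9 and
  whose peak bins coincide (clusters need ≥ 2 members).
- **Null model**: Maslov–Sneppen double-edge swaps preserving both in- and
  out-degree sequences, plus a shuffle of the edge-weight multiset —
  clusters that survive randomization would be trivial, ones that vanish
  are genuine consequences of the wiring.
- **PCA**: signals standardized per neuron, $s'(t) = (s(t)-\bar s)/\sigma_s$,
  then eigendecomposition of the neuron-by-neuron covariance; opposite PC1
  signs mark antiphase subpopulations.
- **Nested coupling**: sample the fast signal at the slow signal's peaks;
  $R = \sigma(\text{fast at slow peaks}) / \sigma(\text{fast})$ is 0 under
  exact phase-locking and near 1 for unrelated oscillations.
- **Action correlation**: Pearson chi-square on the fire-steps versus
  non-fire-steps contingency over {forward, backward, other} actions.

## Worked example

A planted-frequency network provides exact ground truth: two groups of 20
neurons driven every step with magnitudes 1 and 2 under threshold $h = 30$
must fire with periods $\lfloor h/c \rfloor + 2 = 32$ and $17$ steps.

```python
import wormnet as wn

spec = wn.PlantedSpec(group_sizes=[20, 20], drive_per_group=[1.0, 2.0], threshold=30.0)
conn, protocol, periods = wn.generate_planted_frequency_network(spec, duration=1024)
print("expected periods:", periods)

trace = wn.run_simulation(conn, wn.SimConfig(duration=1024, threshold=30.0), protocol)
summaries, clusters = wn.summarize_trace(trace)
for k, (names, (mean, std)) in enumerate(zip(clusters.clusters, clusters.cluster_omega)):
    print(f"cluster {k}: Omega = {mean:.5f} +/- {std:.5f} Hz ({len(names)} neurons)")

null = wn.randomize_null(conn, seed=0)
_, null_clusters = wn.summarize_trace(
    wn.run_simulation(null, wn.SimConfig(duration=1024, threshold=30.0), protocol))
print("null-model cluster sizes:", [len(c) for c in null_clusters.clusters])
```

prints

```
expected periods: [32, 17]
cluster 0: Omega = 0.03122 +/- 0.00000 Hz (20 neurons)
cluster 1: Omega = 0.05854 +/- 0.00000 Hz (20 neurons)
null-model cluster sizes: []
```

The detected cluster frequencies sit within one DFT bin of the analytic
values $1/32 = 0.03125$ Hz and $1/17 \approx 0.05882$ Hz, the partition is
exactly the planted one, and the degree/weight-preserving randomization
destroys every cluster.

To analyze a real connectome, point the pipeline at an edge-list CSV
(`pre,post,type,weight`, type ∈ {chemical, gap}):

```sh
wormnet pipeline --connectome celegans.csv --steps 900 --seed 1 --null --out results/
```

which writes the trace, firing events, centrality table, spectra, cluster
and PCA tables, the coupling report, the same analysis for a randomized
control, and a JSON manifest of every parameter.

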