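# hbnet

Toolkit for analysing the conformational thermodynamics of
alternating-access membrane transporters: causal hydrogen-bond network
models of conformational states, minimal-RMSD alignment of discretized
transition paths across related systems, and umbrella-sampling
free-energy profiles with calibrated errors.

## Who this is for

Molecular simulation groups studying transporters (or any protein whose
function rides on a conformational equilibrium) who want to go beyond
"which H-bonds break" to *which interactions causally control the
balance between states*, and to compare free-energy profiles of
homologous systems on a common reaction coordinate.

## The model

Each residue is split into backbone (BB) and side-chain (SC) moieties.
The discrete random variable X_i counts the hydrogen bonds between one
moiety pair in a snapshot (geometric criterion: donor–acceptor distance
≤ 3.0 Å, donor-vertex angle ≤ 45°). From an ensemble of snapshots of
one conformational state, a discrete Bayesian network over the
nontrivial X_i is learned with a hybrid scheme — Semi-Interleaved
HITON-PC skeleton discovery (mutual-information tests with a
semi-parametric χ² null, α = 0.01) followed by tabu search maximizing
the BDe posterior (imaginary sample size 5) — restricted by a physical
contact blacklist. The network features are

    HB   = Σ_i E(X_i)                       expected total H-bond count
    ΔHB  = Σ_i [E(X_i | Evi) − E(X_i)]      response to a "mutation"
    ΔΔHB(OF→IF) = ΔHB_IF − ΔHB_OF           cross-state balance shift

where the evidence Evi forces the H-bond counts disabled by a residue
substitution to zero. ΔΔHB imitates the ΔΔG of a thermodynamic cycle:
a positive ΔΔHB(OF→IF) means the mutation favors the inward-facing
state. Robustness comes from 10×5-fold cross-validation (50 models):
consensus arcs need > 90 % support, directed arcs > 80 % orientation
agreement, and feature error bars are spreads over the model family.

Companion modules select a-priori transition paths from unbiased
trajectories (equal spacing on PC1, neighbour RMSD < 1.4 Å, minimal
boost energy), align discretized paths of different systems by monotone
minimal-RMSD routes through the inter-path RMSD matrix, and estimate
potentials of mean force from bias-exchange umbrella windows by
self-consistent WHAM with block-bootstrap error bars (blocks ≥ 2× the
measured autocorrelation time).

## Worked example

Learn a network from synthetic occupancy data with known ground truth
and probe it with an in-silico mutation:

```python
import numpy as np
from hbnet.synth import demo_spec_8node, gen_occupancy
from hbnet.learning import LearningConfig, learn_structure
from hbnet.bayesnet import fit_parameters
from hbnet.features import MutationSpec, mutation_to_evidence, compute_hb

spec = demo_spec_8node()                       # known causal network
table = gen_occupancy(spec, 5000, seed=42)     # frames x nodes counts
dag = learn_structure(table, None, LearningConfig(seed=42))
data = table.counts.to_numpy()
cards = {l: int(data[:, k].max()) + 1 for k, l in enumerate(table.labels)}
net = fit_parameters(dag, data, table.labels, cards, iss=5.0)
print(f"learned {len(net.structure.arcs)} arcs over {len(net.nodes)} nodes")
evidence = mutation_to_evidence(MutationSpec(1, "side_chain_all"), net)
print(f"HB = {compute_hb(net).hb:.3f}")
print(f"dHB after disabling Ser1 side-chain bonds = "
      f"{compute_hb(net, evidence).delta_hb:.3f}")
```

prints

```
learned 6 arcs over 8 nodes
HB = 3.991
dHB after disabling Ser1 side-chain bonds = -1.017
```

The learner recovered all 6 ground-truth edges. HB ≈ 3.99 is the
expected total H-bond count of the unperturbed network; forcing the
`Ser1_SC-Thr2_SC` interaction to zero costs about 1.02 bonds in
expectation — more than the node's own marginal (≈ 0.50), because the
perturbation propagates down the learned chain.

The same pipeline is scriptable from the shell:

```sh
hbnet --seed 11 synth-causal --n-frames 400 --out run/synth
hbnet --seed 11 extract run/synth/ensemble.pdb --out run/extract
hbnet --seed 11 learn run/extract/occupancy.tsv \
      --blacklist run/extract/blacklist.tsv --out run/model
hbnet --seed 11 infer run/model/network.json --out run/hb
```

Other subcommands: `screen` (mutation classification over per-state
networks), `average` (consensus networks), `path-align`, `wham`, and the
`synth-*` generators. All parameters can also come from a YAML config;
unknown keys are rejected.

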