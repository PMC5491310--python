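# Methods

`hbnet` analyses the conformational thermodynamics of alternating-access
membrane transporters (the sugar-porter MFS fold is the motivating case)
through three connected layers: a causal model of the hydrogen-bond
network of each conformational state, alignment of discretized transition
paths across related systems, and free-energy estimation from biased
umbrella-sampling windows. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic fixtures do
and do not establish.

## Hydrogen-bond network model

Each residue is split into a backbone (BB) and a side-chain (SC) moiety;
atom names `N, CA, C, O, H, HN, HA` are backbone, everything else side
chain. The random variable attached to an unordered moiety pair is the
number of simultaneous hydrogen bonds between them in a snapshot, e.g.
`Asn29_BB-Arg126_SC` with value range {0, 1, 2} for a bidentate contact.
A bond is counted when the donor–acceptor heavy-atom distance is at most
3.0 Å and the angle at the donor between the D→H and D→A vectors is at
most 45°. Donors are N/O/S atoms carrying a covalent hydrogen; the
covalent assignment pairs each hydrogen with the nearest heavy atom of
its own residue within 1.3 Å. This geometric assignment is deliberate:
it is well defined for any atom-naming scheme, including randomized test
topologies, where name-based pairing tables would be ambiguous.
Intra-moiety bonds are discarded — they cannot define an inter-moiety
variable.

Three filters shape the node set before learning:

- **Triviality** — nodes occupied in fewer than 10 % of snapshots are
  dropped (a node at exactly 10 % is kept).
- **Flexible loops** — nodes touching residues with RMSF above 2.0 Å, or
  inside explicitly excluded residue ranges, are dropped because short
  biased simulations cannot converge those loops.
- **Constant occupancy** — nodes with the same nonzero count in every
  snapshot carry no statistical signal; they are flagged, excluded from
  learning, and re-added afterwards as isolated point-mass variables so
  that their constant contribution still enters HB.

An arc blacklist encodes physical plausibility: two nodes may be
connected only if they share a moiety or some cross-node moiety pair is
in contact, where contact means strictly more than one heavy-atom pair
within 4.0 Å on average over frames, or an existing nontrivial H-bond.
Contact statistics are evaluated on the post-filter node set.

## Structure and parameter learning

Learning is hybrid, restrict-then-maximize:

- **Restrict** — Semi-Interleaved HITON-PC per target: candidates ranked
  by marginal association enter one at a time and are discarded as soon
  as some conditioning subset (size ≤ 3 by default) of the current
  parent–children set renders them independent of the target; a backward
  pass re-checks every member, and the final skeleton keeps an edge only
  when both endpoints recover each other (AND rule). Independence is
  tested with the G² = 2N·MI statistic. Because nominal contingency
  degrees of freedom are badly biased for sparse strata, the null df is
  estimated semi-parametrically as the mean of the statistic over 100
  within-stratum permutations of one variable, and the p-value taken
  from a χ² tail with that df. Significance level α = 0.01.
- **Maximize** — tabu search over single-arc add/delete/reverse moves
  restricted to skeleton-consistent, non-blacklisted arcs, scoring with
  the BDe (uniform Dirichlet) marginal likelihood at imaginary sample
  size 5. The tabu list stores the last 50 visited structures; the
  search stops after 50 non-improving iterations and returns the best
  structure seen, so its score is never below the empty graph's. Ties
  between moves break on a canonical (move, arc) ordering for
  determinism.

Parameters are posterior means under the same prior:
θ_ijk = (N_ijk + iss/(r q)) / (N_ij + iss/q), which reduces to a uniform
distribution for unseen parent configurations.

## Inference and mutation features

Inference is exact: variable elimination with barren-node pruning and a
min-fill ordering (the engine is an implementation detail; the contract
is exactness, verified against dense joint-tensor enumeration).
The network features are

- HB = Σ_i E(X_i), the expected total H-bond count;
- ΔHB = Σ_i [E(X_i | Evi) − E(X_i)] under hard evidence Evi, which
  encodes a mutation by forcing selected node counts to 0 (a
  polar-to-apolar substitution disables every SC node of the residue;
  `specific_pairs` disables only listed nodes);
- ΔΔHB(state2→state1) = ΔHB(state1) − ΔHB(state2), the cross-state
  difference that plays the role of a ΔΔG in a thermodynamic cycle.
  Positive ΔΔHB(OF→IF) marks an inward-facing-favoring perturbation.

Conditioning is observational (P(X|Evi)), not graph surgery: the
formulas the features are built from are conditional expectations, and
hard evidence on the mutated nodes is exactly what a disabled
interaction provides. Screening classifies a residue as IF-favoring
(OF-favoring) when ΔΔHB(OF→IF) exceeds +0.7 (falls below −0.7) in every
system analysed, and, when a transition-state network is available, as
barrier-creating/removing when both ΔΔHB(IF→TS) and ΔΔHB(OF→TS) fall
below −0.5 / rise above +0.5.

Model robustness comes from repeated cross-validation: 10 repeats of
5-fold CV give 50 models; folds are contiguous frame blocks by default
because trajectory frames are autocorrelated (iid shuffling is a flag).
An arc enters the consensus network only if present in more than 90 % of
models, and is drawn directed only when more than 80 % of its
occurrences agree on orientation (denominator: models containing the
arc). HB-feature error bars are the n−1 sample standard deviation over
the model family.

## Transition paths and window alignment

A-priori paths are selected from unbiased trajectories by three
criteria: (i) 50 equal intervals along the first principal component of
the Cα coordinates between the end states, with candidate frames within
20 % of the interval length around each juncture; (ii) neighbour Cα RMSD
below 1.4 Å; (iii) minimum total boost energy among feasible chains,
solved exactly by dynamic programming over the candidate sets. Cost
ties break on total projection distance from the junctures — an
intrinsic criterion that makes the selection invariant to frame order.
The accelerated-MD boost utility implements
ΔV = (E_p−V)²/(α_p+E_p−V) + (E_d−V_d)²/(α_d+E_d−V_d), each term active
only below its reference energy, with E_d = V̄_d(1+λ_d),
α_d = λ_d·V̄_d/5, E_p = V̄+λ_p·N_atom, α_p = λ_p·N_atom (the standard
dual-boost parameterization).

String-method image redistribution re-spaces images at equal arc length
by linear interpolation between the bracketing old images; endpoints are
preserved exactly.

Window alignment across systems works on the matrix A of pairwise RMSDs
between per-window representative structures (per-atom means after
superposition). The optimal route is the monotone staircase from (0,0)
to (n−1,m−1) minimizing Σ A[i,j], found by dynamic programming; ties
prefer advancing the first path's index. Three-way matching keeps
triplets whose three pairwise index pairs each lie on the corresponding
route, resolving one-to-many conflicts greedily by ascending total RMSD
with at most one triplet per window. Internally indices are 0-based;
serialized reports use 1-based window numbering.

## Free energies

Umbrella windows restrain the gate-distance coordinate with
U(ζ) = (k/2)(ζ−ζ_s)². Neighbouring windows may swap centers with
Metropolis probability min{1, exp(−Δ)},
Δ = [U_i(x_j)+U_j(x_i)−U_i(x_i)−U_j(x_j)]/k_BT, proposed on a
deterministic odd–even schedule. The PMF is recovered by self-consistent
WHAM iteration on binned samples with log-sum-exp stabilization;
convergence is declared when the largest offset change falls below
1e-7 kcal/mol, and the profile is anchored at minimum 0. k_B =
0.0019872041 kcal/mol/K; default temperature 310 K. Two-dimensional
gate-distance samples are projected onto the arc length of a
reconstructed transition curve before WHAM; the curve itself is a
principal-curve fit (iterative Gaussian-weighted local averaging of the
scatter around a polyline with fixed endpoints, light Laplacian
smoothing, equal-arc-length resampling).

Uncertainties come from a within-window block bootstrap: the integrated
autocorrelation time τ is measured per window (1 + 2Σρ with the
standard self-consistent truncation window, c = 5), the block length is
validated to be at least 2τ, blocks are resampled with replacement, and
WHAM is re-run per replicate (200 replicates by default); the per-bin
standard deviation is the error bar. Degenerate inputs are rejected
explicitly: fewer than two replicates, fewer than two blocks per window,
or blocks shorter than 2τ.

## Synthetic fixtures: what they establish

The generators provide ground truth, not physics:

- `gen_occupancy` forward-samples a specified causal network;
  `gen_causal_ensemble` realizes those counts geometrically, placing
  formed bonds at 2.8 Å / 10° and absent ones at 3.5 Å / 60°, i.e. with
  ≥ 0.2 Å / ≥ 15° safety margins around the detection cutoffs, on a
  20 Å lattice that precludes spurious bonds. The round-trip
  `build_occupancy ∘ gen_causal_ensemble` is exact by construction and
  is the module's core contract.
- `demo_spec_8node` is the canonical recovery benchmark: a chain, a
  collider, a fork and an isolated pair with strong CPTs; at 5,000
  samples the learner recovers the skeleton at F1 ≥ 0.9 and orients the
  collider.
- `gen_umbrella_series` samples a quadratic PMF + harmonic bias exactly
  as the implied Gaussian and other forms by seeded Metropolis
  (burn-in 1,000, thinning 10).
- `gen_helix` chains an ideal poly-Ala backbone from internal
  coordinates (φ = −57.8°, ψ = −47°), giving ~1.5 Å rise and ~100°
  twist; bends are exact rigid rotations about an axis through the
  junction Cα.
- `gen_matched_paths` morphs a random structure pair with monotone
  per-path index warps and coordinate noise, returning the true
  progress values for correspondence scoring.

Passing these tests shows the algorithms are implemented correctly
against their mathematical definitions; it does not show that real
trajectories satisfy the models' assumptions (converged sampling,
stationarity within windows, absence of unmodelled interactions), and
results on real transporter data inherit those caveats.

## Problem sizes and defaults

The shipped tests and the acceptance script use deliberately compact
problem sizes — 8-node networks at 5,000 samples, 10 windows × 2,000
samples for WHAM, 50-atom random frames for detection — chosen so each
check isolates one property at high statistical power. All thresholds
above (3.0 Å/45°, 10 %, 2.0 Å, 4.0 Å/>1 pair, α = 0.01, ISS = 5, tabu
50, 10×5 CV, 90 %/80 % averaging, 0.7/0.5 screening, 51 images, 1.4 Å,
30 windows, 310 K) are the package defaults and are exposed through
`hbnet.config` / the CLI.

## Known limitations

- No MD engine integration: the package analyses ensembles and time
  series; it does not run dynamics, build systems, or assign
  protonation states.
- Exact inference scales exponentially with treewidth; for the
  400–500-node networks of a full transporter the per-state graphs are
  sparse and the blacklist keeps families small, but pathological dense
  graphs would need approximate inference, which is out of scope.
- WHAM is 1-D (along the reconstructed path or window index); no MBAR
  or 2-D surface estimation.
- The semi-parametric df estimate makes the CI test stochastic;
  p-values near α can flip between seeds. All stochastic steps are
  seeded and reproducible.
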