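# Methods

## Model

`rolegraph` represents the large-scale structure of an undirected weighted
network by a small binary *image graph* on `q` roles together with a mapping
σ of every node to one role.  An edge (r, s) of the image graph means "nodes
of role r predominantly interact with nodes of role s"; a diagonal image
graph (self-links only) expresses the classical picture of cohesive modules,
while off-diagonal links express bipartite and mediator structure (e.g.
transmembrane receptors, which interact with extracellular ligands and
cytoplasmic transmitters but rarely with each other).  This is regular
equivalence made operational: roles are defined by how they connect to other
roles, not by internal density.

### Error function and balanced penalty

For adjacency weights `w_ij`, image graph `B` and assignment σ, the fit error
counts mismatches of both kinds over unordered node pairs i < j:

    E(B, σ) = (1/M) [ Σ_{edges} w_ij (1 − B_{σi σj})  +  p Σ_{absent pairs} B_{σi σj} ]

An edge in a forbidden block costs its weight; an absent pair in a permitted
block costs the penalty `p`.  `p` is *balanced*: with total edge weight `W`
and `Z` absent pairs, `p = W/Z`, so the total error weight available on edges
equals that available on absent pairs, and `M = W + pZ = 2W` bounds E by 1.
`E` is undefined for complete graphs (Z = 0).  With the diagonal image graph
this objective is the modularity-style quality function for graph clustering
with a uniform null model.

All scores are reported in the canonical frame `S = 1 − 2E ∈ [−1, 1]`:
perfect fit 1, the structureless single-role assignment exactly 0 (that
normalization is a direct consequence of the balance condition).

### Block sums and the optimal image graph

Collecting the per-role-pair aggregates

    m_rs = (edge weight inside block {r,s}) − p · (absent pairs inside block {r,s})

gives `S(B, σ) = (1/M) Σ_{r≤s} (2B_rs − 1) m_rs` and the exact conservation
`Σ_{r≤s} m_rs = 0` under the balanced penalty.  For a fixed σ the optimal
image graph is read off block-wise — `B_rs = 1` iff `m_rs > 0` (zero maps to
"no link") — so the best-over-all-image-graphs score is available in closed
form, `S*(σ) = (1/M) Σ_{r≤s} |m_rs|`.  The joint search over (B, σ) therefore
reduces to a search over assignments alone.  The test suite verifies the
closed form against explicit enumeration of all image graphs for q ≤ 4.

## Optimization

`anneal` runs simulated annealing over single-node role moves.  The state
keeps per-block edge weights and counts, so the score change of moving one
node costs O(degree + q); the hot loop is compiled with numba.  Moves are
accepted by the Metropolis rule (always if ΔS ≥ 0, else with probability
exp(ΔS/T)) under geometric cooling.  Defaults, all overridable in
`AnnealConfig`:

- **Cooling factor** 0.99 for q < 10 and 0.999 otherwise; `sweeps_per_T = 3`
  sweeps (one proposed move per node, random order) per temperature step.
- **Initial temperature**: auto-calibrated to the mean |ΔS| of one
  proposal sweep from the random initial state, i.e. a typical downhill move
  starts out acceptable with probability ≈ 1/e.  This choice is deliberate
  and load-bearing.  The objective is *exactly flat* across all ways of
  splitting two merged classes whose union is held by permitted blocks — an
  entropy barrier rather than an energy barrier — so a search that spends
  long at high temperature equilibrates onto that entropically dominant
  merged plateau and then cannot leave it by local moves.  Starting just
  above the ordering transition instead lets block order nucleate directly:
  on the 128-node planted benchmark at zero noise the per-restart success
  rate of exact recovery was 0–3/20 with a hot start (calibrated to 80%
  move acceptance) versus 9–10/20 with this rule.
- **Stopping**: a run ends when T < 1e−6 or when 20 consecutive temperature
  steps pass in which no accepted move changed the score (frozen state).
- **Restarts**: `restarts` independent runs from uniform-random assignments
  (seeds from a counter-based substream of the master seed, so restart k is
  reproducible regardless of the restart count); the best final score wins,
  ties keeping the first.  The returned score is always re-evaluated from
  scratch on the winning assignment.
- `q` is a maximum: unused roles are legal, so the best joint score is
  non-decreasing in q.  `q_scan` makes the monotonicity structural by warm-
  starting each q with the previous optimum embedded as one initial state.

## Baselines

Both baselines see the binarized adjacency by default (`binary=False` feeds
weights) and pick the best of `n_seeds` runs by their own objective.

**Symmetric NMF tri-factorization** minimizes the generalized KL divergence
between A and `H S Hᵀ` (H: n×q, S: q×q, nonnegative) by multiplicative
updates.  The S-update is the standard majorize-minimize step (the model is
linear in S); the H-update, whose factor appears twice, takes the 1/2-power
of the multiplicative ratio, which kept the divergence monotone on every
random instance tested.  Self-pairs do not exist in a simple graph, so the
divergence is taken over off-diagonal entries only.  Nodes are assigned to
the class with the largest row entry of H (ties to the lowest index).

**Mixture model (Newman–Leicht)**: each latent class r has prior π_r and a
distribution θ_r over link targets; node i's likelihood under class r is
Π_j θ_rj^{A_ij}, applied symmetrically to the undirected edges.  Standard EM:
responsibilities in the E-step (log-space), closed-form π and θ in the
M-step; the log-likelihood trace is non-decreasing by the EM guarantee.
With q = 1 the fit reduces to θ ∝ degree.

## Synthetic data

**Planted benchmark** (`make_benchmark`): 128 nodes in four classes of 32;
classes 1 and 2 are cohesive, classes 3 and 4 form a bipartite pair, so the
designed image graph is {(1,1), (2,2), (3,4)}.  Every unordered pair inside a
permitted block is an edge with one probability `p_in`, every other pair with
`p_out`, fixed so the expected mean degree is exactly k = 16 and a fraction ε
(the noise level) of edge ends falls outside the designed blocks.  A single
density for all permitted blocks and a single density for all forbidden
blocks keeps the task deliberately signal-free apart from the block pattern
itself; because within-class blocks have 31 potential partners per node and
cross-class blocks 32, per-node expected degrees deviate from k by < 2%.
Edges have unit weight.  The design is configurable (sizes, k, image pairs);
designs in which classes touch several image-graph links (e.g. the
mediator-chain pattern used in the generalization experiment) are allowed by
setting `single_link_per_class=False`.

This generator draws each pair independently (Bernoulli), so degrees
fluctuate binomially; it does not emulate heavy-tailed degree distributions,
evidence-category mixtures, or the sparse periphery of curated interaction
data.  Recovery results on it therefore speak to the identifiability of
block structure under symmetric noise, not to performance on real
interactomes.

**Toy network** (`make_toy_fig1`): 18 nodes in four types — A (5, cohesive),
B (4, linking A and C but never each other), C (5, cohesive), D (4, linked
only to C).  The idealized variant fills every permitted block completely,
so the designed 4-role image graph fits with zero error while no diagonal
4-role model can (merging pays absent-pair penalties inside the merged
blocks).  The non-idealized variant thins the permitted blocks
deterministically (every third pair dropped) and stays connected.

## Evaluation procedures

- **NMI** between partitions from the confusion matrix, natural logs,
  0·log 0 = 0, arithmetic normalization; cross-checked against scikit-learn.
- **Randomization control**: repeated two-edge swaps within each evidence
  category (rejected if they would create self-loops or duplicate edges),
  preserving every node's per-category degree exactly; 10 accepted swaps per
  edge per category by default.  Annealed scores on rewired copies quantify
  how much of the fit is explained by the degree/type sequence alone.
- **Held-out links**: a uniform random test set of links is removed (their
  endpoints remain), the assignment is re-annealed on the training links
  with the image graph held fixed, and the test links are scored as the
  matched-weight fraction (weight of test links landing in permitted blocks
  over total test weight).  Only edge terms enter this score: a set of links
  has no well-defined complement of absent pairs, and normalizing by the
  subset's own weight makes scores of different subsets comparable.  Welch's
  two-sided t-test (configurable to pooled) compares non-diagonal against
  diagonal test scores; with one repetition the p-value is undefined.
- **Per-type profiles**: each evidence category's edges are scored the same
  way under a fit, normalized by the full-network value, and averaged over a
  scan of q.  A category whose interactions ignore the global block
  structure (the yeast-two-hybrid coverage-bias situation) shows a ratio
  well below the other categories.

## Numerical choices and degenerate inputs

- Scores are exact sums of floats; conservation holds to ~1e−9 on random
  instances and the incremental move deltas match from-scratch rescoring to
  the same tolerance.
- `m_rs = 0` reads off as "no link" (strict positivity rule).
- Duplicate input edges keep the single highest-weight evidence category
  (the weights encode a ranking of belief; the strongest evidence subsumes
  weaker reports).  Self-loops are dropped with a logged count.
- Component-size ties in `largest_component` resolve to the component
  containing the lexicographically smallest node identifier.
- ε floors (1e−12) guard logs and divisions in both baselines.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` substreams; every experiment rerun with the
  same master seed reproduces its output bit-for-bit.

## Problem sizes used by scripts/acceptance.py

The acceptance script reruns the full pipeline at the package's standard
study sizes: the 18-node toy; the 128-node benchmark with 10 realizations at
noise 0 and the standard 50 realizations at noise 0.5 (best of 10 restarts
per realization, the annealed methods on the benchmark using a
near-convergence schedule: cooling 0.998, 3 sweeps per temperature step);
200 random instances for the conservation check; 30 tiny instances against
exhaustive enumeration; 10 rewired copies for the randomization control; and
10 train/test splits (100 held-out links) of a mediator-chain planted
network at noise 0.1 for the generalization comparison.

## Known limitations

- The annealer guarantees only locally optimal assignments; the entropy
  barrier discussed above means merged-class traps exist for any schedule,
  and reliability comes from restarts.  Benchmarks here use best-of-10 to
  best-of-20.
- The NMF H-update's monotonicity is an empirical property of the damped
  step, not a theorem; the trace is checked in the tests.
- The per-type profile and the held-out score ignore absent-pair terms by
  construction; they measure coverage of present interactions only.
- The uniform balanced penalty is the only null model implemented (no
  degree-product/configuration-model penalty).
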