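# Methods

## Model overview

`lexinet` simulates a population of agents that negotiate a shared system
of perceptual categories and a shared vocabulary through repeated pairwise
language games scheduled on an interaction graph. The model has three
layers:

1. **Perception/categorization.** A stimulus is a point in CIE LAB space.
   An agent's category is an adaptive network of Gaussian reactive units;
   unit *u* with center **m** and weight w_u contributes
   w_u · exp(−‖x − m‖²/2σ²) to the category response, and classification
   is argmax over categories. Categories are created and extended only
   through game failures; unit weights grow by β·z_u(topic) on success and
   shrink multiplicatively by forgetting.
2. **Lexicon.** A bidirectional association table between categories (or,
   in the ungrounded naming game, discrete stimulus ids) and word tokens
   shared across the population. Strengths live in [0, 1] and move in
   ±0.1 steps with winner-take-all lateral inhibition.
3. **Social structure.** An undirected interaction graph plus a role
   policy. One game is played per iteration on a uniformly drawn edge;
   roles are assigned by a fair coin, except for role-biased stars where
   the hub of degree d takes the biased role with probability (d−1)/d.

### Assumptions

- Perceptual distance is plain Euclidean distance in (L, a, b); no
  perceptual color-difference formula is applied.
- Word tokens are transmitted noiselessly and recognized exactly.
- Agents are homogeneous: identical parameters, no memory limits other
  than the 50-game success window, no death/birth.
- One game per iteration; games are atomic and sequential.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| σ (kernel scale) | 1 LAB unit | Width of reactive-unit Gaussians |
| β (learning rate) | 1 | Unit-weight reinforcement gain on success |
| δ (forgetting rate) | 0.01 | Multiplicative weight decay per forgetting event |
| initial unit weight | 1.0 | Weight of a newly recruited reactive unit |
| association step | ±0.1 | Lexicon update magnitude |
| initial association | 0.5 | Strength of a newly created word link |
| CS threshold | 0.95 | Trailing CS above which a misclassified topic is absorbed into an existing category instead of founding a new one |
| CS window | 50 games | Per-agent trailing success window |
| iterations per node | 625 | Training length per phase (complete graph of 16 ⇒ 10 000 games) |
| replicates | 10 | Independent repetitions per condition |

With σ = 1 and LAB-scale separations (contexts guarantee pairwise
distances > 50), cross-stimulus activations underflow to exactly 0 in
double precision: each unit effectively detects one stimulus and its
immediate neighborhood. This is intended — units specialize — and makes
classification of a familiar stimulus depend only on its own units'
weights. σ is configurable for studying wider kernels.

δ is a package choice (the decay magnitude is otherwise unconstrained):
multiplicative decay is scale-free and preserves relative unit importance
within a category, so forgetting never reorders a category's own units.

The initial association strength 0.5 applies both to the hearer's
unknown-word link and to a word freshly minted by a speaker; the speaker
side is a package choice made for symmetry.

## Synthetic environments

The chip universe is a jittered grid of 1269 distinct points covering
L ∈ [10, 95], a, b ∈ [−80, 80] — a stand-in with the same coverage and
scale as a Munsell chip table, without reproducing true Munsell
colorimetry. A real chip table can be supplied as `L,a,b` CSV and is used
verbatim.

Frequency-biased environments A and B are built by resampling 600 chips
(with replacement) from the universe with uncorrelated trivariate-normal
weights around focal colors p₁ = (66.97, 18.65, 38.36) and
p₂ = (46.24, −16.46, −1.41). The per-dimension scale defaults to
10·|p₁_d − p₂_d| ≈ (207.3, 351.1, 397.7); an alternative reading
(10× the Euclidean focal distance, ≈ 569.6 in every dimension) and a
free-floating Gaussian mode (draws not constrained to the chip table) are
available as options. Note a consequence of the default scales: they are
large relative to the chip box, so the A/B weights differ only mildly and
the two environments are strongly overlapping multisets — an environment
switch is a gentle perturbation, not a wholesale replacement. Game
contexts are rejection-sampled (4 stimuli, all pairwise distances > 50,
topic uniform among the four) with a 10 000-attempt cap that turns
degenerate environments into an explicit error instead of a hang.

The naming game uses two 16-identifier discrete environments sharing
exactly 5 identifiers; the identifiers carry no internal structure.

What the generator does **not** emulate: real Munsell chip spacing,
perceptual non-uniformity of LAB, observer noise, or correlated stimulus
dimensions. Passing tests therefore demonstrate properties of the model
dynamics on idealized stimuli, not claims about human color perception.

## Topologies

"Size n" star means n leaves plus a hub (n+1 nodes) everywhere in this
package; under this convention the 16-leaf star has mean closeness
9.2581/17 ≈ 0.54 and mean betweenness 1/17 ≈ 0.06. Betweenness is
normalized per node by (n−1)(n−2)/2; closeness is (n−1)/Σdist; clustering
is triangle density (0 for degree < 2); constraint is Burt's measure with
p_ij = 1/deg(i).

Degree-3 optimized topologies are found by simulated annealing over
double-edge swaps ((a,b),(c,d) → (a,c),(b,d)), which preserve the degree
sequence; moves breaking simplicity or connectivity are rejected. The
schedule is geometric cooling from T = 0.02 with factor 0.9995 over a
default budget of 20 000 proposed swaps, returning the best graph seen.
The budget was sized so that at n = 8 the annealer reproduces the exact
optimum known from exhaustive enumeration in both directions, and at
n = 48 the minimum-average-betweenness objective reaches 0.05 (the mean
normalized betweenness of a cubic graph is exactly (d̄ − 1)/(n − 2) for
average distance d̄, so this objective is equivalent to minimizing average
distance, and random cubic graphs already start near the optimum).
Exhaustive enumeration of connected cubic graphs (one representative per
isomorphism class) is available for n ≤ 10 as an oracle; it uses
backtracking with the symmetry reduction that node 0's neighbors are
fixed to {1, 2, 3}, spectral bucketing, and exact isomorphism checks.

## Experiments and measurement

Three designs: (1) single-phase training on a topology; (2) phase 2 swaps
the topology for the complete graph, same agents; (3) phase 2 swaps the
stimulus environment from A to B, same topology. Each phase runs 625
iterations per node; each condition is repeated 10 times with replicate
seed streams derived from a master seed (independent streams for topology
construction, environment sampling, game scheduling and probing).

CS_S is the population mean of trailing-window CS — it costs nothing and
reflects the games actually played. CS_G / CS_A / CS_B are measured by
**frozen probes**: evaluation games with `learn=False` that provably leave
every agent bit-identical (asserted by serialization comparison in the
tests). Probes draw pairs from the complete graph (CS_G) or the training
topology (CS_A/CS_B); edge probes apply the topology's own role policy,
since the direction of information flow is part of the condition being
measured. Default probe size is 20 games per agent; cadence is
configurable, and the bundled experiment checks probe at phase boundaries
only. Probe games never enter the 50-game training windows.

### Numerical and tie-break conventions

- argmax ties everywhere resolve to the earliest-created object (category
  id order, word-token creation order, lowest context index for an
  all-zero pointing response). This makes seeded runs fully reproducible.
- Association strengths clamp to [0, 1]; lateral inhibition touches only
  existing associations (missing pairs are not created at 0 and driven
  negative).
- The speaker-discrimination failure branch aborts the game before the
  hearer is involved: the hearer neither learns nor records the outcome.
- An agent with no game history has CS 0, forcing the new-category branch
  on its first failures.
- Zero-weight units and empty categories are never pruned during normal
  operation.

## Statistics

End-of-phase scores across conditions are compared with a one-way ANOVA
(F from the between/within decomposition, p from the F distribution),
Bartlett's equal-variance check, and Tukey's HSD using studentized-range
quantiles (Tukey–Kramer standard errors for unequal group sizes).
A Bartlett violation is flagged in the report but does not block the
ANOVA — with the very large between-condition mean differences these
simulations produce, the omnibus test remains informative. Convergence of
the fully connected baseline is checked with a paired t-test between
scores at successive checkpoints (df = 9 at 10 replicates).

## Known limitations

- The degree-3 graphs are regenerated by optimization, not copied from
  any specific published adjacency matrices; objectives other than
  average betweenness may admit ties with differing secondary measures.
- Under the default environment scales the A→B switch is mild (strongly
  overlapping environments), so retention losses after an environment
  change are small at the simulated sizes; centralized-authority
  (star-speaker) populations, whose hub imposes a global vocabulary,
  retain the old environment at least as well as decentralized ones in
  this regime.
- Category counts grow with the number of distinct stimuli encountered;
  very long runs on large chip sets grow memory and per-game cost roughly
  linearly in total units (an optional garbage-collection pass can prune
  zero-weight units).
- Replicates are run sequentially; parallelization is left to the caller.
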