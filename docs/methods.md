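# Methods

`cogmap` simulates how a simple feed-forward network can acquire a
predictive map — a successor representation (SR) — of a state space by
observing transitions, and how the standard place-cell / grid-cell /
word-class analyses fall out of that representation. This note records the
model, the defaults, and the design choices that were genuinely open.

## Successor representation

For a row-stochastic one-step transition matrix `T` over `N` discrete
states, the SR is the discounted expected-occupancy matrix

    M = sum_{t=0}^{h} gamma^t T^t,

with discount `gamma ∈ [0, 1]` and horizon `h` (the `t = 0` identity term is
always included, so `M[s, s] >= 1`). For `h = ∞` and `gamma < 1` the closed
form `(I − gamma T)^{-1}` is used. State values follow as `V = M R` for a
per-state reward vector `R`; for reward-free tasks `R = 1` reduces `V` to
SR row sums. Terminal rows of `T` (walls, rule-final words) are all-zero and
propagate through the powers without renormalization.

Defaults: `gamma = 1.0` with finite horizon `h = 10` for the spatial tasks
(the discount for the spatial ground truth is not uniquely determined by the
task; an undiscounted 10-step window is the package default and exposed in
configuration), and `gamma = 1, h = 2` (`M = I + T + T²`) for the language
task.

## Environments

States live on the full `height × width` lattice in row-major order; wall
cells keep their flat indices so any `N × N` matrix reshapes directly onto
the room. Successor states are the Moore neighborhood (8-connected) of a
cell, *including the cell itself* by default: an interior cell of the open
10×10 room then has 9 potential successors, an edge cell 6, a corner 4.
With self-moves excluded the counts are the familiar 8/5/3. The
self-inclusive default is what makes the measured accuracy ceiling ≈ 0.134
(see below) consistent with the observed plateau ≈ 0.13–0.14; both variants
are exposed through `NeighborhoodSpec`. Diagonal moves across wall corners
are permitted (pure 8-connectivity); the maze geometry does not obviously
forbid them and the alternative would complicate the action model for no
measurable gain.

The maze is a hand-authored, versioned 15×15 fixture (packaged as JSON rows
of `#`/`.`/`R`): a central corridor (row 7) with a food tray (+10 reward) at
each end and six U-shaped detour arms, exactly 94 traversable cells of 225,
fully connected. It is a synthetic stand-in emulating the published rat-maze
topology — corridor, detour arms, trays — not a tracing of the original
apparatus.

The random-walk transition matrix puts a uniform row over each cell's
allowed successors; wall rows and wall columns are zero. Training pairs are
sampled with a uniform input state over allowed cells and a uniform
successor among its neighbors.

## Supervised learner

A three-layer network maps a one-hot state to a distribution over all
states: `N` inputs, ReLU hidden layer of size `round(f·N)` (default `f = 1`),
softmax output of size `N`. Training minimizes cross-entropy against the
sampled successor labels with Adam (`lr = 0.01`, β = 0.9/0.999). He
(fan-in-scaled normal) initialization with an explicit seed. The networks
are small enough that they are implemented directly in NumPy.

Because the label for input `s` is a draw from row `s` of `T`, the
cross-entropy optimum at `s` is the *row itself*, not a one-hot: at
convergence, concatenating the predictions recovers `T` (this is the
"parameter recovery" property, RMSE < 0.02 at n = 10,000 pairs).

Batching: the default is exact full-batch gradient descent, computed by
reducing the epoch to a weighted pass over the (at most `N`) unique one-hot
inputs with their empirical label distributions — algebraically identical to
the mean pairwise gradient and orders of magnitude faster. Mini-batches are
available in configuration; both reach the same plateau on these tasks.

Early stopping: training stops once the epoch loss changes by less than
`1e-4` over 50 consecutive epochs ("plateau"); the spatial task plateaus
well inside 500 epochs, the language task inside its fixed 50.

Accuracy bookkeeping. Top-1 accuracy against stochastically sampled labels
has a Bayes ceiling of `mean_s 1/k_s` (`k_s` = successor count): ≈ 0.1344
for the self-inclusive 10×10 room and ≈ 0.1167 for the grammar. Two
estimates are reported per run: accuracy on the 20 % held-out split, and
(in tests and the acceptance script) accuracy on a large freshly sampled
set. Training-*set* accuracy of a converged network is systematically
higher (≈ 0.19 at n = 10,000 on the room) because the argmax locks onto the
sampling noise of the finite label sample — it estimates the empirical-mode
ceiling `mean_s max_s' P̂[s, s']`, not generalization, and exceeding the
Bayes ceiling on the training set is expected, not a bug. The held-out
numbers are the scientifically meaningful plateau: ≈ 0.134 (spatial) and
≈ 0.117 (language).

## Language

40 synthetic word tokens in five classes — adjectives (states 0–9), verbs
(10–19), nouns (20–29), pronouns (30–34), question words (35–39) — with
three construction templates: adjective→noun, pronoun→verb→adjective,
question→pronoun→verb. (A class partition of 10/10/10/5/5 is the unique way
to reconcile the stated 40-state space with those index ranges.) The
ground-truth word transition matrix is uniform within the successor class;
nouns are rule-final everywhere, so their rows are zero and they never occur
as training inputs — which is exactly why a trained network's noun rows are
free to drift toward non-grammatical successors. Pair sampling draws a rule
uniformly, then one of its consecutive class pairs uniformly, then words
uniformly within class; sampling whole sentences instead would change the
input-class weights slightly (and the ceiling from 0.1167 to 0.12) without
changing the support.

## Navigation agent

A DQN-style agent on the maze: the same three-layer body with 9 outputs —
one Q-value per action ("stay" plus 8 compass moves; a fixed action set
rather than per-state arity, so that one output layer serves all states).
Invalid actions are handled behaviorally: choosing a wall (or leaving the
grid) ends the episode with a −1 penalty and a new random start; reaching a
food tray (+10) ends it too, as does the 30-step cap. Training runs 10,000
environment steps with 300 random warmup steps, Adam at `lr = 0.001`, purely
greedy action selection afterwards (exploration comes from random starts,
warmup, and penalty feedback), experience replay (capacity 2,000, batch 32),
a target network refreshed every 200 steps, and Q-discount 0.9. The reward
magnitudes (+10 tray, −1 wall, 0 per step) and the Q-learning constants are
package choices, all exposed in `AgentConfig`.

The learned policy's transition matrix is obtained by softmaxing the action
values at temperature 1 and scattering each action's probability onto the
cell it reaches; mass aimed at walls is dropped and the row renormalized by
default (keeping it stochastic for the SR formula), with an unmasked variant
available. Both the uniform-random-walk SR and the policy-weighted SR of the
maze are produced, since "ground truth" for a goal-directed task can
reasonably mean either. Within the default 10,000-step budget the reward
trend (positive slope over the first ~600 episodes; late episodes beating
early ones) is robust across seeds, but mid-corridor Q-values — visited ever
more rarely as the greedy policy converges near the trays — may still be
diffuse; detour-arm suppression in the policy SR is therefore asserted on a
longer (20,000-step) run in the tests.

## Analyses

**Eigenmaps.** `eig` of the (generally non-symmetric) SR matrix; eigenpairs
sorted by the real part of the eigenvalue (descending by default, i.e.
coarsest first; ascending exposed), real parts of eigenvectors reshaped
row-major onto the lattice. Near-degenerate complex pairs may mix; mixing
within an eigenvalue pair leaves the spatial frequency of the field intact.

**Spatial frequency.** The "mesh size" of an eigenmap is measured as the
radius (in cycles per field) of the dominant bin of its 2-D type-II DCT.
Cosine modes are the eigenbasis of a walk with reflecting boundaries, so the
half-cycle boundary modes land on single DCT bins; a periodic FFT leaks
their power across the spectrum and scrambles the ordering. The
coarse-to-fine law "larger eigenvalue ⇒ coarser map" holds as a strong
monotone trend (rank correlation < −0.9, strictly increasing decile means
across the first 30 maps) but not strictly pair-by-pair: diagonal and axial
modes with nearly equal eigenvalues (e.g. a (3,3)-type vs a (4,1)-type mode)
can order oppositely in Euclidean frequency radius, a genuine property of
the walk's spectrum rather than a measurement artifact.

**MDS.** Classical (Torgerson) scaling — eigendecomposition of the
double-centered squared-distance matrix — is the deterministic default for
coordinates. Cluster diagnostics, however, run on the stress embedding
(metric SMACOF initialized from the classical solution, so its raw stress
can only improve): for the ground-truth language TP rows the exact classical
2-D solution is degenerate — the top-2 Gram eigenpair spans the
adjective/verb/pronoun "equilateral triangle" plane and both the noun and
question-word clusters collapse onto the origin — whereas the stress
refinement keeps all five classes distinct (k = 5 purity 1.0, zero
within-class spread, since identical rows initialized identically stay
coincident under SMACOF).

For the SR rows at `t = 2, gamma = 1` the identity term gives every word an
own-state occupancy of 1, making the within-class row distance `sqrt(2)`
nearly equal to the between-class distances (≈ `sqrt(2.2)`). No
2-D embedding that respects those distances can keep the classes cleanly
separated: the stress embedding shows five *overlapping*, spread-out clouds
(purity ≈ 0.58, within-class spread ≈ 0.49), and the classical projection
achieves purity 1.0 only because it annihilates the within-class simplex
directions entirely (spread at floating-point zero). The package reports
purity and spread for the stress embedding and treats "SR clusters are
looser and closer together than TP clusters" — which holds sharply — as the
robust qualitative statement; a high *and* spread-out SR purity is not
attainable under this SR definition, and the corresponding acceptance check
is expected to flag it.

**Purity.** k-means (10 restarts, fixed seed) on the 2-D coordinates;
purity is the fraction of items whose cluster's majority label matches
their own, majority ties breaking toward the lexicographically smaller
label.

## What the generators do and do not emulate

The synthetic environments are exactly the study conditions: a 10×10 open
room explored by a uniform random walk, a 94-cell maze with two terminal
food trays, and a 40-word artificial grammar with uniform within-class
transitions. They contain no measurement noise, no continuous space, no
head direction or theta dynamics, and no naturalistic word statistics.
Passing tests therefore demonstrate that the learning machinery recovers
the generative structure it was pointed at — not that it would survive
real trajectories or corpora.

## Problem sizes and numerics

Tests and the acceptance script run the tasks at their native sizes
(10,000 / 5,000 pairs; 10,000 agent steps), with supervised training capped
at 500 epochs by the plateau rule — the loss curve is flat long before the
cap. Fresh-sample accuracy uses 100,000 evaluation pairs (standard error
≈ 0.001). Transition-matrix rows are validated to sum to 1 (or 0) within
1e-9; SR truncation error against the closed form is bounded by the
geometric tail `gamma^{h+1}/(1−gamma)`. Matrices are exchanged as
header-free CSV; environments, vocabularies and manifests as JSON.

## Known limitations

- Tabular one-hot states only; no feature generalization, no TD-style
  online SR updates, no multi-scale SR stacks.
- The greedy DQN explores poorly far from rewards; policies at rarely
  visited cells stay diffuse within the default step budget.
- Eigenmap sign/orientation (and mixing within degenerate pairs) is
  arbitrary, as inherent to eigendecomposition.
- The classical-MDS degeneracy discussion above is specific to this
  grammar's symmetric geometry; other state spaces need not collapse.
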