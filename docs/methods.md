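# Methods

## The model

Agents optimize *subjective* reward: the scalar product of a physical reward
vector and an internal motivation (drive) vector,

    r~_t = mu_t · r_t ,

so the value of an outcome depends on the agent's current needs.  The
action-value function carries motivation as an explicit argument,

    Q(s_t, a_t, mu_t) = E[ Σ_τ γ^τ r~_{t+τ} ],

and is approximated with small feedforward networks trained by one-step
temporal-difference learning.  Each update backpropagates the TD error

    δ = r~ + γ max_a' Q(s', a', mu') − Q(s, a, mu)

through the output head of the selected action only, with δ held constant in
the gradient (semi-gradient TD).  There are no replay buffers, target
networks, or eligibility traces anywhere in the package; every agent learns
from its current transition with a geometrically annealed learning rate.

All randomness flows through a single `numpy.random.Generator` per
experiment; a config plus seed reproduces a run bit for bit.

## Four Demands grid world

A 6×6 grid is divided into four 3×3 rooms, each dispensing one resource.
The four drives grow by 1 per step up to the saturation cap θ and reset to
zero on the step their room pays out; occupying room *n* pays `mu_n`.  The
update order is: read the reward at the new position, reset the consumed
component (if the reward was nonzero), then grow every component that paid
nothing.  This order is what makes the one-room binge pay 0, 1, 0, 1, … and
the 12-step migration cycle pay 9, 0, 1 per room.

**Interior walls.** Rooms are separated by walls with a single doorway in
the middle of each shared boundary (the four-rooms layout this environment
descends from).  The choice is load-bearing: with fully open boundaries a
period-4 cycle through the four center cells (one step per room, rate 3 at
large θ) dominates learning for motivated *and* motivation-blinded agents
alike, a strategy outside the canonical taxonomy.  With doorways the
shortest four-room cycle is exactly the 12-step migration, and two-room
binging survives as per-step alternation across a doorway.

**Canonical strategies and rates.** For cap θ, the closed-form mean
subjective rewards per step are

| strategy | rate |
|---|---|
| one-room binge | 1/2 |
| two-room binge | min(θ, 1) |
| delayed two-room binge | 2·min(θ, 2)/3 |
| migration | (min(θ, 9) + 1)/3 |
| delayed migration | (3·(min(θ, 11) + 1) + min(θ, 9) + 2)/14 |

`strategy_rate` evaluates these in exact rational arithmetic, and
`steady_state_rate` reproduces them by replaying the canonical trajectories
through the environment — the agreement is asserted exactly, not to a
tolerance.  `classify_strategy` labels a rollout by the minimal period of
its room-visit sequence and the cyclic run-length structure of one period.

**Input encoding.** The Q-network input concatenates a centered position
one-hot (36 channels, scaled to unit variance each) and the centered
motivation (4 channels, scaled to variance 9 each); the 9:1 per-channel
variance ratio offsets the 36:4 channel count so both blocks contribute
equal total variance.  Motivation moments are calibrated from a 10⁴-step
random-walk rollout at the configured θ and stored in the config.  The
motivation-blinded control replaces the four motivation channels with
zeros while the true drives still generate the rewards.  The θ-as-input
variant appends the cap as a 41st channel (centered/scaled by the moments
of the uniform 1..10 training range) and redraws θ every 10 training
iterations.

**Training.** 40(41)-100-100-100-5 network, three sigmoid hidden layers,
linear outputs; Xavier initialization with gain 4 on the sigmoid layers —
stacked logistic sigmoids attenuate signal variance by σ′(0)² = 1/16 per
layer, and without the gain the deep trunk collapses toward constant
activations and the agent cannot learn the doorway-alternation values.
One continuing rollout of 4·10⁵ iterations (γ = 0.9), ε-greedy with ε
annealing 0.5 → 0.05 and learning rate 3·10⁻³ → 3·10⁻⁵, both geometric per
iteration.  Evaluation is a deterministic 500-step rollout with a 100-step
burn-in.  The addiction variant sets caps (1, 1, 1, 10); the mean interval
between visits to the high-cap room grows with γ (immediate re-entry at
γ = 0.5, long excursions at γ = 0.95).

## Transport network

Ten cities are drawn from the standard normal in the plane (degenerate
draws resampled); roads are the Delaunay edges with Euclidean lengths, and
all-pairs shortest paths are precomputed (`scipy.sparse.csgraph`).  An
episode starts at a fixed origin city with three random target cities
(sampled among the other nine) carrying binary motivation; entering a city
with a set component pays +5 and clears it, every road traversal costs its
length, and the episode ends when all components are clear.  The return is
therefore 15 − (traveled length): maximizing return is minimizing length.

`shortest_tour` is the exact oracle — the minimum over the 3! target
orderings of chained shortest-path distances, ties broken by lexicographic
route — and is cross-checked in the tests against an independent Dijkstra
over the (city, visited-subset) state space.

The agent is a 20-200-10 network (one leaky-ReLU hidden layer and leaky-
ReLU outputs, leak 0.2) over (position one-hot, motivation).  Training uses
softmax(β = 0.5) behavior over adjacent cities, γ = 0.9, 10⁵ episodes, and
a per-episode learning rate 10⁻² → 10⁻⁴; evaluation uses softmax(β = 10) on
100 fresh target sets.  Two caveats shape the attainable scores: the
γ = 0.9-optimal policy is not exactly the minimum-length policy (discounting
prefers nearer rewards), and β = 10 evaluation is stochastic, so the
fraction of episodes matching the oracle has a ceiling below 1 that varies
with the world geometry.  The fraction-optimal comparison uses a 10⁻⁹
relative tolerance, since both lengths are sums over the same edge table.

## Manager–agent hierarchy

The trained agent acts on a motivation *estimate* maintained by a manager
network (20-200-200-200-11, leaky-ReLU) that, once per agent step, either
zeroes one estimate component or does nothing.  The manager is a Q-learner
(γ = 0.9, ε-greedy ε = 0.1) rewarded

* **supervised**: +2 when its action reproduces the true motivation
  transition recorded from agent episodes, −2 otherwise, softened to −1
  when the erroneous action was "do nothing"; zeroing an already-zero
  component counts as an error so the scoring has a unique maximizer — the
  true transition function.  Training replays freshly recorded episodes
  with teacher forcing (the manager always sees the true next motivation),
  learning rate 10⁻³ → 10⁻⁶ per episode.
* **unsupervised**: only the *sign* of the agent's environment reward is
  propagated: +5 when positive, −2 otherwise (−1 for "do nothing"), in the
  live closed loop with the estimate initialized to the episode's true
  targets.  Training episodes terminate when the *estimate* empties — the
  belief is the only motivation signal the manager-agent system carries, and
  terminating on it makes the manager's decision process Markov in its own
  state — with a hard 50-step cap for runs the manager fails to wind down.
  Semi-gradients are accumulated over minibatches of 50 manager steps and
  applied summed (as if the steps had been taken individually); the learning
  rate anneals 10⁻² → 10⁻⁵, clipped at 10⁻³ while the annealed value is
  larger.

Manager episodes start at the same fixed origin as the agent's training, so
manager and agent always operate on the same state distribution.  The
evaluation harness is shared with the flat agent — a motivation *provider*
supplies what the agent's network sees each step — so a manager replaced by
the true dynamics is bit-identical to the agent-only evaluation under the
same seeds, which the tests assert.  Evaluation episodes count as done only
when every *true* target has been visited (200-step cap): ending them when
the estimate empties would let an over-zeroing manager stop early and
record traveled lengths below the oracle's, silently flattering the
mean-excess metric.

The two training signals are not equally learnable here.  The supervised
manager's reward is a deterministic function of its own state and action,
and it reliably reaches perfect one-step accuracy — the closed-loop
hierarchy then matches the flat agent exactly.  The sign-only signal is
generated by the hidden true motivation, which decorrelates from the
manager's state the moment an exploratory edit goes wrong; in our runs the
sign-trained manager's one-step accuracy plateaus well below the supervised
manager's and oscillates (as it improves, the belief-mismatch states that
carry its teaching signal leave the data distribution and the learned
rankings decay), and its closed-loop tours degrade accordingly.  The
acceptance script reports the measured closed-loop excess of both managers
as they are.

## Pavlovian conditioning network

Each 20-step trial presents a cue (steps 6–10) and a subjective reward
(steps 14–18) whose signed magnitudes coincide (0, ±0.5, ±1); a constant
motivation input (±1) marks reward versus punishment blocks and is the only
feature separating the two zero-magnitude trial types.  A 40-unit sigmoid
recurrent network reads (cue, motivation, reward) — the reward trace is a
network input, mirroring how the unconditioned stimulus reaches a real
circuit — and a linear unit reads out the value V_t.

Training is TD(0) with γ = 0.9 on batches of 20 uniformly sampled trials,
3·10⁵ batches, learning rate 10⁻² → 10⁻⁴, errors backpropagated through
time within the trial.  Input weights are frozen at their Xavier
initialization; recurrent and readout weights start at U(−10⁻⁵, 10⁻⁵).
Two structural facts are worth recording:

* With only (cue, motivation) as inputs, the network provably cannot begin
  to form cue memory: near the zero-recurrent initialization, every TD
  error within one-step gradient reach of cue-driven activity is identical
  across same-block trial types, so the memoryless solution is first-order
  stable.  The reward input breaks this: outcome-time activity becomes
  trial-specific immediately, and TD bootstrapping can then grow the
  recurrent bridge across the cue–outcome delay.
* One-step-truncated credit (kept as an option) cannot bridge the 3-step
  silent gap between cue offset and reward onset; full within-trial
  backpropagation is the default.

**Value oracles.** `v_star` is the per-trial ground truth
V*_t = Σ γ^τ r_{t+τ} (the current step's reward included).  Before cue
onset the three same-valence trial types are indistinguishable from the
network's inputs, so the TD fixed point there is the magnitude-averaged
V*, not the per-trial one; `expected_value_trace` implements exactly this
fixed point (equal to V* from cue onset onward) and is the convergence
oracle used in the tests.  Pre-cue, the per-trial V* retains an
irreducible mean-squared gap of about 0.07 against *any* causal value
estimate — comparing against it over the full trial would be a category
error, not a stricter test.

The motivation-blinded control (motivation channel zeroed, rewards
unchanged) produces exactly identical traces for the two zero-magnitude
trial types, since their inputs coincide.

## Population analysis

Unit activity from the strong-reward and strong-punishment trials is
z-scored per unit across the concatenated condition traces, reduced to
three principal components, and clustered by complete-linkage hierarchical
agglomeration on Euclidean distances (constant-rate units are excluded
with a warning).  The default cut is three clusters — positive-valence,
negative-valence, and mixed — and the two largest are treated as the
valence clusters.  Connectivity is summarized as the mean ± SEM recurrent
weight within each valence cluster versus between them (diagonal
excluded); trained networks show the push-pull motif, net excitation
within and net inhibition between.  Weight-based similarity uses each
unit's outgoing recurrent-weight vector (column of W, since
h_t = σ(W h_{t−1} + …)); the incoming-vector alternative is a switch.  The
t-SNE embedding of the weight-correlation structure is visualization only;
no quantitative result depends on it.

## What the generators do and do not emulate

Every input in this package is generated: grid worlds, road networks,
trials.  The Pavlovian generator reproduces the trial *timing* and the
block structure of the conditioning experiment the model targets, but not
licking behavior, block-transition kinetics, inter-trial intervals, or the
actual ventral pallidum recordings (which are not bundled and are not an
input anywhere).  Passing tests therefore demonstrate internal consistency
of the model family — that motivation-conditioned TD learners develop the
claimed behaviors and population structure — not a fit to biological data.

## Numerical choices

* Xavier draws are uniform ±√(6/(fan_in+fan_out)); multi-layer trunks use
  variance-preserving init gains — 4 for sigmoid stacks (σ′(0) = 1/4), and
  √(2/(1+α²)) ≈ 1.39 for the manager's leaky-ReLU stack, without which
  individual output heads can stay mis-ranked indefinitely.  Biases start
  at zero.
* Semi-gradient rank-1 weight updates run in place through BLAS `ger`.
* Argmax ties resolve to the lowest index; tour-length ties to the
  lexicographically smallest route.
* Degenerate city layouts (Qhull failures) are resampled, up to 100 draws.
* RNN training raises a RuntimeError when the batch TD loss exceeds 10³ or
  turns non-finite.
* Geometric annealing start·(end/start)^(t/T) everywhere a rate decays.

## Problem sizes used by the test suite and acceptance script

Training lengths in the checked runs are package choices balancing
statistical resolution against runtime on a single core: Four Demands
4·10⁵ iterations for the θ = 1 run and 2·10⁵ per seed for the θ = 100
motivated/blinded comparison (5 seeds each); transport 10⁵ episodes for
the primary agent and 6·10⁴ for replicate seeds; 10⁵ supervised-manager
and 5·10⁴ unsupervised-manager episodes; value RNN 2·10⁵ batches for the
convergence check and 6·10⁴ per seed
for the five-seed population analysis.  The full-length settings
(4·10⁵ iterations, 2·10⁵ manager episodes, 3·10⁵ batches) are the library
defaults.

## Known limitations

* Trained outcomes at intermediate caps (the exact θ phase boundaries of
  the behavioral diagram) are stochastic across seeds and are reported,
  not asserted.
* The transport fraction-optimal depends on the sampled world's geometry
  through the discounting ceiling discussed above.
* The manager is two-level by construction; deeper hierarchies are out of
  scope.
* The sign-only (unsupervised) manager does not reach the supervised
  manager's reliability in this implementation; see the hierarchy section.
* The recurrent model freezes input weights; training them changes
  baseline-activity tuning quantitatively (not explored here).
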