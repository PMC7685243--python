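# Methods

This note documents the models, the synthetic data, the numerical
choices, and the limitations of the package. It is written for a reader
who wants to know exactly what is computed and why each default is what
it is.

## Task

The oculomotor sequence task is a chain of three binary saccade
decisions: center left/right, then up/down from the reached lateral
position, then a final left/right within the reached visual hemifield.
The ten movement directions are indexed canonically as

    0 center-L, 1 center-R, 2 left-up, 3 left-down, 4 right-up,
    5 right-down, 6 upper-L, 7 upper-R, 8 lower-L, 9 lower-R

and the five reward-delivery points as center, upwards, downwards,
upper, lower. Eight sequences S1-S8 exhaust the 2x2x2 branch structure;
S1, S2, S5, S6 terminate in the upper hemifield, the rest in the lower.
A wrong choice is unrewarded and forces a repeat of the same stage; a
correct choice is rewarded (reward magnitude 1 per decision). A block
keeps one sequence fixed until eight error-free trials have accumulated,
then switches to a sequence drawn uniformly from all eight.

Two choices here deserve comment. First, the published figure with the
concrete move-triples is not machine-readable, so the shipped sequence
table (`data/sequences.json`) is a synthetic reconstruction constrained
by everything the text states: full coverage of the branch structure,
the hemifield partition, every direction in at least two sequences, and
the concretely described sequences (S2, S4, S5 and the first moves of S1
and S8). Only the S3/S7 assignment within the remaining two triples is a
free choice. All analyses are invariant to this residual freedom.
Second, the block switch draw includes the previous sequence. Because
first moves split 4/4 between center-L and center-R, a uniform draw
makes the first decision of a block exactly uncorrelated with anything
the agent has learned, which is what produces the observed chance-level
(50%) accuracy on the first decision; excluding the previous sequence
would anti-correlate the draw with the learned action and push that
statistic to roughly 44%. Exclusion remains available via
`exclude_prev=True`.

## Behavioral value model

Action values live in a single 10-vector indexed by direction; the
stage/branch structure enters through availability masking, so the ten
slots double as the state-action table. After each attempted decision,

    Q(a) <- Q(a) + alpha * (r + gamma * max_{a'} Q(a') - Q(a)),

the max running over the actions available at the next decision point
(zero after a trial's third correct decision), followed by a
whole-table decay Q <- tau_q * Q applied once per decision. Choices are
softmax(beta * Q) over the available pair. Defaults are the session-fit
values alpha = 0.8100, gamma = 0.2010, beta = 3.050, tau_q = 0.95. The
per-decision (rather than per-time-step) decay grain is a modeling
choice; it is what makes tau_q meaningful alongside pulse-level network
time.

Maximum-likelihood fitting uses a Nelder-Mead simplex in an
unconstrained reparametrization (logit for alpha, gamma, tau_q; log for
beta), ten random restarts by default, tau_q held fixed during fitting.
The likelihood is evaluated through a pre-compiled replay of the choice
log, so a 500-block fit stays in the tens of seconds.

## Synthetic behavior

The default generator is the fitted Q-learning agent playing the task;
its learning curve — the fraction of first-attempt-correct decisions per
trial-in-block — starts at 50% on the first decision after a switch and
exceeds 90% by the fifth trial, which is the behavioral profile the
networks are trained to reproduce. A parametric mode draws decision
correctness from an arbitrary 8-entry per-trial Bernoulli profile
(repeats of a failed binary choice are then deterministically correct,
since the error reveals the alternative). Synthetic sessions emulate
block structure and error statistics only; they contain no reaction
times, no fixation breaks, and no session-level nonstationarity, so
tests passing on them say nothing about those aspects of real behavior.

Certainty levels 50%, 76% and 88-91% are position-in-block labels
calibrated on the behavioral learning curve: a trial's label is the
curve value at its trial-in-block index, binned to the nearest level.
With the fitted agent the curve jumps above 85% from the second trial
on, so the mid (76%) bin is unpopulated and analyses stratify into
block-start (50%) versus late-block (88-91%) representations.

## Task coding

Each attempted decision occupies one window of length
L = 2P + R + G time steps (action pulse P = 50, reward pulse
R = 0.2 P = 10, gap G = 10, dt = 1 ms by default; the scaled preset uses
P = 10). Window j carries, in order: the previous decision's action
pulse on its direction channel, that decision's reward pulse on its
decision-point channel (absent after errors), a gap, and the choice
segment in which the prefrontal target pulses the action of decision j.
This layout makes every signal causal: the reward for decision j-1 is
presented before the choice pulse for decision j, and the striatal value
target is a step function that jumps to the post-update Q table exactly
at the end of each reward pulse. The executed (possibly wrong) action is
both the striatal input pulse and the prefrontal target, so the error
statistics of the behavior are part of the supervised signal.

The 10 instruction channels pair a Fixate and a Move+Hold unit per
decision point. During a decision's choice segment the Move+Hold units
of the visible targets are active; during the preceding fixation the
matching Fixate units are. At the up/down stage both candidate points
are cued — cueing only the correct one would leak the answer the network
is supposed to learn from rewards. The hemifield unit of the prefrontal
target is +1/-1 throughout a block. The value target is held
zero-order between updates.

## Networks

Two tanh rate networks with leaky dynamics
tau dx/dt = -x + W_rr r + W_ir u + eta, r = tanh(x), integrated by
explicit Euler with dt = 1 ms and tau = 10 ms (Euler factor 0.1). The
striatal network (1300 units at full scale; 260 in the 5x reduced
default) receives the 15-D action/reward input and reads the 10-D value
vector linearly from its synaptic currents; the prefrontal network
(1000 / 200 units) receives that value readout concatenated with the 10
instruction channels and reads out the 11-D action vector. Readouts are
taken from currents, not rates. Recurrent weights are initialized
N(0, 1) * g / sqrt(N) with g = 1; input and readout weights
N(0, 1) / sqrt(fan-in), with fan-in the true input dimensionality (15
and 20). Every unit receives independent N(0, 0.01^2) white noise inside
the Euler bracket each step.

## Training

The joint loss is the sum over batch blocks, time and channels of the
squared output-target difference, the striatal term weighted twice.
Gradients flow by backpropagation through time through both networks,
including the value-readout coupling from striatal currents into the
prefrontal input; the backward pass is hand-derived (a closed-form
adjoint recursion through the Euler updates) and verified against
central finite differences at relative error below 1e-4. State noise is
treated as an additive constant during differentiation. Batches are 10
blocks sampled with replacement; blocks are zero-padded to a common
length with a loss mask. The schedule is 10 outer steps of 1000
iterations, initial rate 1e-3 multiplied by 2/3 per outer step; the
optimizer is Adam (plain SGD available). Training at reduced scale
(e.g. 100/80 units, ~2400 iterations, ~200 training blocks with
augmentation) reaches the qualitative regime analyzed below in minutes
on one CPU; reported analyses state the sizes they used.

## Autonomous mode

After training, weights are frozen and blocks run closed-loop at
decision granularity: the striatal network receives the previously
executed action pulse and its reward pulse (white noise of SD 0.01 on
the action channels at block start and on the reward channels after
errors), the live value readout drives the prefrontal network together
with the current stage's instructions, and the next action is sampled
from a softmax over the time-averaged choice-segment outputs restricted
to the available options. The decoding temperature defaults to
1/beta = 1/3.050, the sharpness of the fitted behavioral softmax: with
unit-amplitude choice pulses a temperature-1 softmax would cap
per-decision accuracy at sigma(1) = 73% even for a perfect network,
below the asymptotic accuracy the system is meant to reproduce, so the
decoder reuses the behavioral choice rule's scale instead. Wrong
decodes force stage repeats exactly as in the task; a configurable
repeat guard (50 by default, larger for untrained networks) keeps runs
finite.

## Population analyses

Analysis datasets are built from closed-loop runs with recorded hidden
states. Each trial contributes the rate traces of its three correct
decisions' choice windows, giving exactly aligned (units x 3L) trials;
cells are (sequence, certainty-level) averages. Because cell means carry
sampling noise that inflates Euclidean distances by an amount shrinking
with trial count, distance comparisons across levels must equalize
trials per cell (`n_per_cell="min"`); analyses that skip this conflate
noise with geometry.

Demixed PCA decomposes the centered tensor into ANOVA-style
marginalizations over time, sequence, certainty and their pairwise
interactions (the three-way term is the noise component; the partition
is exact to machine precision) and fits, per marginalization, an
encoder/decoder pair by ridge-regularized reduced-rank regression: the
ridge solution's fitted values are rank-reduced by SVD, the top left
singular vectors forming the encoder and the decoder rows the demixed
components. The default ridge is 1e-6 * ||X||_F^2; zero recovers plain
least squares. Trajectories are Gaussian-smoothed (sigma = 2 time bins
by default) before projection.

Inter-sequence distance is the time-averaged pointwise Euclidean
distance between two sequences' trajectories, restricted to pairs
within a hemifield cluster for prefrontal data; compactness is the
time-averaged distance of a trajectory to its own time-centroid. For
the small simulated populations shipped here these metrics are computed
in full unit space (the pipeline default); a 10-D sequence-dPC mode is
available for large populations. Level contrasts use paired t-tests
across sequence pairs (or sequences), Bonferroni-corrected where
several levels are tested.

Balanced analysis sessions replay the eight sequences as a freshly
shuffled deck per cycle rather than a fixed rotation: a deterministic
cyclic order gives every block the same predecessor, and the residue of
the previous sequence then masquerades as block-start sequence coding.

## Potential surfaces and paths

A surface is computed on a GxG mesh (G = 60 default; 30-40 in reduced
analyses) spanning the bounding box of the relevant latent trajectories
padded by 25%. Mesh points are lifted to unit space through the first
two sequence-encoder columns as firing rates, clipped to +-(1 - 1e-6)
and inverted through arctanh to currents; the network is stepped once,
noise-free, with the input frozen at the analysis moment, and the
surface value is the Euclidean magnitude of the current change. Local
minima qualify as fixed points when ten further frozen-input iterations
move the latent projection by less than 1e-3. The frozen moment is
anchored to a trial's first movement: mid choice pulse for the
prefrontal network, mid feedback pulse for the striatal network (whose
input is silent during the choice segment). Joint surfaces are
pointwise minima; the minimal path between two sequences' troughs is
the Dijkstra shortest path on the 8-connected mesh with Euclidean edge
lengths in (latent-1, latent-2, value) space. An alternative pure-cost
edge weight (mean endpoint value times planar step) is available.

## Canonical correlation analysis

Datasets (units x time) are trial-averaged, Gaussian-smoothed, reduced
to 15 principal dimensions, whitened with an 1e-8 ridge, and the
singular values of the whitened cross-covariance give the canonical
correlation spectrum (first 10 coefficients by default). Sequential
Wilks-lambda tests (Bartlett approximation) assess joint significance;
Fisher z-transforms compare two spectra per coefficient. Because the
original electrophysiological recordings are not public, shipped
comparisons use model-generated surrogate references (labeled as such);
the interface accepts any units x time array so real recordings can be
dropped in. With few time samples relative to the reduced
dimensionality CCA overfits toward coefficients near 1; discriminating
comparisons at small scale should lower `d_reduce`.

## Known limitations

- The sequence table is a constrained reconstruction, not the published
  figure; per-sequence identities beyond the textual constraints are
  conventional.
- The instruction-channel semantics (5x2 Fixate/Move+Hold layout, both
  up/down points cued) are one consistent reading of a loosely specified
  coding.
- The mid (76%) certainty bin is unpopulated under the fitted behavioral
  parameters; level contrasts are block-start versus late-block.
- Small trained models reproduce the qualitative learning signatures
  (error decreasing over the block, behavioral curve rising from chance,
  separating representations, lengthening inter-attractor paths,
  compacting striatal trajectories); coefficient-level agreement with
  the published full-scale values is not expected at reduced scale, and
  statements about the real corticostriatal system rest on the original
  recordings, which this package cannot access.
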