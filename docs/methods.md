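# Methods

## Generative model

The agent's model is a two-level discrete-state hierarchy. One slow-level
time step (an *epoch*) spans a whole fast-level trial; the two timescales
are updated asynchronously under an adiabatic mean-field assumption: the
fast level runs to its horizon with fixed empirical priors, then the slow
level updates once from the completed trial.

**Fast level.** Seven factors: location (4; the only controllable factor),
context/reward side (2), queried-move slot (2), knowledge (2), verb (4),
destination (4), syntax (12: silent, four query-frame positions, seven
answer-frame positions). The context factor *is* the side semantic slot —
the word spoken in the answer's side position is read from the same hidden
state that sets the maze's reward contingencies, so there is one belief, not
two to be kept consistent. Transitions: location moves to the action's
target except from the absorbing arms; syntax advances deterministically
along its frame; every other factor has identity dynamics. The ten
allowable policies are all two-move sequences from the centre honouring the
absorbing arms.

**Outcomes.** Maze view (5), reward (3: neutral/attractive/aversive), heard
word and spoken word (21 tokens each). Heard carries the query frame,
spoken the answer frame; the two are separate modalities. All likelihood
columns are deltas. Whenever syntax is non-silent the maze modalities are
pinned to centre + neutral (sensory attenuation): linguistic epochs carry no
information about the maze, which both fixes the agent to the spot in
practice and frees its location beliefs to re-express prior information —
the replay mechanism.

**Slow level.** Narrative (solve → query → answer, answer absorbing), first
move (4), second move (4), reward side (2), query type (2); no policies or
preferences of its own, only the fixed narrative dynamics. The link to the
fast level supplies: initial location (always centre), context (= reward
side), query slot (= query type), initial syntax (by narrative stage), the
three story slots (knowledge/verb/destination; only when the narrative is
"answer"), and the policy bias E.

**Story mapping.** A queried move implies a story: going to the cue ⇒
(did-not-know, explored, cue); the rewarded arm ⇒ (knew, exploited, that
arm); the wrong arm ⇒ (did-not-know, guessed, that arm); staying put ⇒
(did-not-know, waited, centre).

## Inference

Per policy, the state posterior is optimised by coordinate ascent that is
mean-field **across factors** but keeps each factor's trajectory as an
exact chain: each sweep re-smooths every factor by forward–backward (log
space, `logsumexp`) against the expected log likelihood under the other
factors' marginals. Each update is an exact coordinate minimisation of F,
so F is non-increasing across sweeps, and for a single-factor model one
sweep equals exact enumeration — which is how the scheme is validated
(tolerance 1e-6 against brute-force sums over all state sequences).
Iteration stops when |ΔF| < 1e-4, with a cap of 16 sweeps (a warning, not
an error, if the cap is hit; the last iterate is still a valid bound).
Future steps beyond the observed window are pure forward predictions and
contribute no likelihood terms to F.

Policies are scored by softmax(ln E − G − F) with no temperature
parameter. F is the free energy accumulated over *all* observations so far
under that policy (not just the current step): past evidence about where
the agent has been should keep disfavouring policies it contradicts.
G sums risk + ambiguity per remaining step over all four modalities; with
flat word preferences the word terms are policy-independent constants, so
they change no decision. Actions follow the action *marginal* of Q(π)
(robust to ties; equal to the MAP policy's action when Q(π) is
concentrated). Spoken outcomes are generated reflexively as the token with
the highest expected log likelihood under the policy-averaged predictive
beliefs at that step, and the environment echoes them back as observations.

At each epoch's end the slow level receives, for every slow tuple, the
expected log probability of the fast level's inferred *initial* states and
of its policy posterior under that tuple's predictions (initial states and
policy are what the link predicts; later states follow from them). The slow
posterior is softmax(ln prior + evidence) over the 192-tuple joint, then
projected onto per-factor marginals (the slow factors are treated
independently everywhere else), and propagated through the narrative
dynamics as the next epoch's prior. Ascending messages flow once per epoch
(single pass), not iteratively to joint convergence — the adiabatic
scheduling, and the cheaper of the two defensible choices.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| preference, attractive reward | +3 nats | high prior probability of reward; sets exploitation drive |
| preference, aversive outcome | −6 nats | strongly avoided; makes an uncued arm visit risky |
| preference, centre view | −1 nats | the maze centre is mildly aversive, discouraging waiting |
| κ (policy-bias concentration) | 2 | sharpness of exp(κ·move matches) in the slow-to-policy bias; 2 makes the enacted policy dominate its neighbours without excluding them |
| link confidence | 0.9 | probability the slow tuple's story slots are spoken as predicted; see below |
| horizons | solve 3, query 4, answer 7 | sentence lengths of the frames; solve needs two moves |
| convergence | |ΔF| < 1e-4, ≤ 16 sweeps | standard discrete-scheme practice |
| probability tolerance | 1e-10 | table-invariant checks |
| log guard | ln(x + 1e-16) | keeps structural zeros finite in KL and messages |

All preferences are in log-probability units (nats); only differences
matter. Magnitudes reproduce cue-first behaviour robustly (the explore
policy beats every direct-arm policy by > 1 nat of expected free energy at
step 1) and are exposed in `TaskConfig`.

## Numerical choices

- **Ties break to the lowest index**, with near-ties (within 1e-12)
  treated as exact, so that float summation order cannot flip a decision.
  Level orderings therefore matter in exactly one place: what an
  *unconstrained* narrator says. Sides order (left, right): with nothing
  known, the agent asserts "left". Verbs order (explored, guessed,
  exploited, waited): a narrator with symmetric beliefs about the reward
  side has exactly tied evidence for "guessed" and "exploited", and the
  ordering resolves the dead heat toward the uninformed reading — the
  self-description an agent without maze experience converges to.
- **Soft story slots, hard structural links.** The story mapping is a
  strong but defeasible heuristic (confidence 0.9); the structural links
  (context = reward side, query slot = query type, narrative = syntax) are
  deterministic. This grades story revisions: contradicting one spoken
  story slot costs ~ln(0.9/0.033) ≈ 3.3 nats, contradicting a structural
  identity ~37. When the first confabulated answer is self-contradictory,
  the cheapest consistent revision flips the story's destination rather
  than the asserted reward side, yielding the wrong-guess story. With
  all-delta links every violation would cost the same and the revision
  would be an arbitrary tie.
- **Entropy and KL** use the exact 0·ln 0 = 0 convention (delta columns
  have exactly zero ambiguity; KL(p‖p) is exactly 0); only logs of model
  parameters are guarded.
- **Exclusions are exact**: a zero policy-bias weight maps to −∞ in the
  softmax, not to the guarded log, so an excluded policy has probability
  exactly 0 regardless of G and F.
- Beliefs are recorded twice per trial: the final smoothed posteriors, and
  the *online* beliefs as held at each step (the raster an experimenter
  would record). Transcripts and the replay score use the online beliefs —
  the pre-cue 50/50 context belief exists only there, since smoothing
  propagates the cue backwards through the context's identity dynamics.

## What the environment emulates — and what it does not

The generative process mirrors the model's tables with the true context
fixed: deterministic moves and percepts, a scripted interlocutor that
utters the query frame, and an echo of the agent's spoken tokens during
answer epochs. The agent is physically held at the centre outside the
solve stage. A seed is threaded through for reproducibility, but with
delta tables every run is deterministic; identical configurations yield
byte-identical transcripts. Consequently, passing tests show that the
*belief dynamics* produce the explanation, replay and confabulation
phenomena — they say nothing about robustness to sensory noise,
probabilistic cue reliability, or learned (rather than built-in)
vocabularies and contingencies, none of which the environment models.

The confabulation session is realised by starting the narrative prior (and
the environment) at the query stage — functionally a disconnection from
any memory of a solve epoch.

## Problem sizes

The shipped sessions are desk-scale: 3 epochs of horizons 3/4/7, 10
policies, 6144 fast-level states, 192 slow-level tuples; a full session
runs in a few seconds on one CPU. Oracle comparisons use 100 random
single-factor chain models with ≤ 3 states, ≤ 3 outcomes and ≤ 3 steps,
where exhaustive enumeration is exact and cheap.

## Known limitations

- No learning: likelihoods, transitions and the story mapping are fixed.
- The slow level keeps only per-factor marginals between epochs; joint
  structure in a multimodal story posterior is lost at each projection
  (mitigated, in practice, by the agent hearing its own answer, which
  collapses the slots it has already spoken).
- Mean-field across factors is approximate whenever several uncertain
  factors jointly shape one observation; the exactness guarantee covers
  the within-factor chains.
- One conversational turn only: a single query and its answer(s); no
  extended dialogue, no "I don't know" response option, and no second
  agent.
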