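# mazetalk

A deep temporal active-inference agent that solves a cued T-maze and then
**explains its own moves in simple language** — including the emergent
phenomena that come with that ability: hippocampal-style replay of the maze
trajectory while the agent sits still, and internally consistent
confabulation when it is asked to explain a course of action it never took.

The package is aimed at computational-neuroscience and explainable-AI
researchers who want a small, fully inspectable discrete-state model of
"insight as inference": explanations are not read out of a log of past
decisions, they are *inferred* over a space of counterfactual stories, and
hearing one's own explanation is itself evidence that reshapes the story.

## The model

Both levels are discrete-state POMDPs. The **fast level** factorises into
maze states (location over {centre, left arm, right arm, cue}, and the
reward-side context) and linguistic states (a syntactic chain covering a
silent state, a four-word query frame and a seven-word answer frame, plus
semantic slot factors). Four outcome modalities — maze view, reward, heard
word, spoken word — are generated from factor combinations; whenever the
syntax is not silent the maze modalities are pinned to "centre, neutral"
(sensory attenuation). The **slow level** carries the narrative stage
(solve → query → answer), the two maze moves, the reward side, and the
query type across epochs; its factor tuple supplies the fast level's
initial-state priors and a bias *E* over the ten allowable two-move
policies.

Inference minimises the variational free energy *F* recursively across the
two levels. Per policy π, state posteriors are optimised by a scheme that
is mean-field across factors but exact (forward–backward) along each
factor's time chain. Policies are scored by

    Q(π) = softmax( ln E(π) − G(π) − F(π) ),

where the expected free energy decomposes as risk plus ambiguity,

    G(π) = Σ_τ  D_KL[ Q(o_τ|π) ‖ softmax(C) ]  +  E_Q[ H[P(o_τ|s_τ)] ].

Maze moves follow the action marginal of Q(π); spoken words are generated
reflexively, as the outcome with the highest expected log likelihood under
current beliefs — and are then heard, feeding back into inference. At each
epoch boundary the fast level's posterior over initial states and policies
becomes log evidence for the slow tuple, and the updated slow beliefs
propagate forward as the next epoch's empirical priors.

## Worked example

```
$ mazetalk run --mode standard --query second --context right --seed 0 --out out/
replay score: 1.000
epoch 0 [solve] heard: (silence)
epoch 0 [solve] spoke: (silence)
epoch 1 [query] heard: Please explain second move
epoch 1 [query] spoke: (silence)
epoch 2 [answer] heard: (silence)
epoch 2 [answer] spoke: I knew reward-was right so-I exploited the-right-arm
```

The agent first explores (centre → cue, because resolving the reward-side
uncertainty carries epistemic value), sees the cue indicating "right", and
exploits (cue → right arm). Asked about its *second* move it answers that
it **knew** the reward side and **exploited**; asked about the first move
it instead answers `I did-not-know reward-was right so-I explored the-cue`.
The replay score of 1.000 means the believed location during the query and
answer epochs retraces centre → cue → right-arm step for step, even though
the agent physically stays put.

The confabulation session starts the narrative at the query stage, so there
is no maze experience to constrain the story:

```
$ mazetalk run --mode confabulation --seed 0 --out out/
answer in epoch 1: inconsistent
answer in epoch 2: consistent
epoch 1 [answer] spoke: I did-not-know reward-was left so-I guessed the-left-arm
epoch 2 [answer] spoke: I did-not-know reward-was left so-I guessed the-right-arm
```

The first answer contradicts itself (claiming not to have known the side
while heading straight to the claimed reward arm). Having heard itself say
it, the agent revises at the slow level and produces a perfectly
consistent — if entirely confabulated — wrong-guess story.

`out/` receives `transcript.json`, `beliefs_level1.csv`,
`beliefs_level2.csv` (state × time belief rasters) and a `run.log` echoing
the configuration.

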