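"""The T-maze-with-language task model.

Fast level: a four-location T-maze (centre, left arm, right arm, cue) whose
reward side is set by a hidden context, plus linguistic factors — a
syntactic chain (silent, a four-word query frame, a seven-word answer
frame) and semantic slot factors (which move is queried; whether the reward
side was known; the verb describing the move; the move's destination). The
context factor doubles as the "side" semantic slot: the word spoken in the
answer's side position is read from the same hidden state that sets the
maze's reward contingencies.

Slow level: the narrative (solve -> query -> answer, answer absorbing), the
first and second maze moves, the reward side and the query type. The slow
tuple predicts the fast level's initial states, its starting syntax, its
semantic slots (when answering), and a bias over the ten allowable
two-move policies.

Outcomes: an exteroceptive maze view, a reward modality (neutral /
attractive / aversive), heard words (query frame) and spoken words (answer
frame). Whenever the syntax is anything but silent the maze modalities are
pinned to centre + neutral — sensory attenuation: linguistic epochs carry
no information about the maze, which is what lets prior (slow-level)
information re-express itself as replay.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .categorical import Categorical, ConditionalTable
from .hierarchy import HierarchicalModel, LevelLink
from .mdp import (
    Factor,
    LikelihoodModel,
    MDPModel,
    Modality,
    Policy,
    Preferences,
    StateSpace,
    TransitionModel,
)


class ConfigError(ValueError):
    """Raised for invalid task configuration values."""


# --- fast-level factor levels ---------------------------------------------

LOCATIONS = ("centre", "left", "right", "cue")
CONTEXTS = ("left", "right")
QUERY_SLOTS = ("first", "second")
KNOWLEDGE = ("knew", "did-not-know")
# order matters only through lowest-index tie-breaking of unconstrained
# speech; "guessed" before "exploited" selects the wrong-guess reading of a
# dead-heat between the two, which is the story an unconstrained narrator
# converges to (see docs/methods.md)
VERBS = ("explored", "guessed", "exploited", "waited")
DESTINATIONS = ("cue", "left-arm", "right-arm", "centre")
SYNTAX = (
    "silent",
    "q1-please",
    "q2-explain",
    "q3-which",
    "q4-move",
    "a1-i",
    "a2-knowledge",
    "a3-reward-was",
    "a4-side",
    "a5-so-i",
    "a6-verb",
    "a7-destination",
)

FACTOR_ORDER = (
    "location",
    "context",
    "query_slot",
    "knowledge",
    "verb",
    "destination",
    "syntax",
)

# --- outcome levels --------------------------------------------------------

EXTERO = ("centre", "left", "right", "cue-left", "cue-right")
REWARDS = ("neutral", "attractive", "aversive")

SILENCE = "~"
TOKENS = (
    SILENCE,
    "Please",
    "explain",
    "first",
    "second",
    "move",
    "I",
    "knew",
    "did-not-know",
    "reward-was",
    "left",
    "right",
    "so-I",
    "explored",
    "guessed",
    "exploited",
    "waited",
    "the-cue",
    "the-left-arm",
    "the-right-arm",
    "the-centre",
)

#: maze move level -> destination semantic level
MOVE_TO_DESTINATION = {"centre": "centre", "left": "left-arm", "right": "right-arm", "cue": "cue"}
DESTINATION_TOKEN = {
    "cue": "the-cue",
    "left-arm": "the-left-arm",
    "right-arm": "the-right-arm",
    "centre": "the-centre",
}

# --- slow-level factor levels ----------------------------------------------

NARRATIVES = ("solve", "query", "answer")
LEVEL2_ORDER = ("narrative", "first_move", "second_move", "reward", "query")


@dataclass(frozen=True)
class Vocabulary:
    """Sentence frames and the token inventory shared by both word
    modalities."""

    query_frame: tuple[str, ...] = ("Please", "explain", "<query>", "move")
    answer_frame: tuple[str, ...] = (
        "I",
        "<knowledge>",
        "reward-was",
        "<side>",
        "so-I",
        "<verb>",
        "<destination>",
    )
    silence: str = SILENCE
    tokens: tuple[str, ...] = TOKENS

    def __post_init__(self) -> None:
        frames = {w for w in self.query_frame + self.answer_frame if not w.startswith("<")}
        slots = set(self.tokens) - frames - {self.silence}
        if frames & slots:
            raise ConfigError("slot tokens must be disjoint from frame tokens")

    def index(self, token: str) -> int:
        return self.tokens.index(token)


@dataclass(frozen=True)
class TaskConfig:
    """Everything that defines one task instance.

    Preference magnitudes follow the required ordering attractive >
    neutral > aversive, with the maze centre mildly aversive; ``kappa``
    sets how sharply the slow-level move beliefs bias the fast-level
    policies, and ``link_confidence`` how strongly the slow tuple predicts
    the answer's semantic slots (the structural links — reward to context,
    query to slot, narrative to syntax — are deterministic).
    """

    context: str = "right"
    query: str = "first"
    epochs: tuple[str, ...] = ("solve", "query", "answer")
    preference_attractive: float = 3.0
    preference_aversive: float = -6.0
    preference_neutral: float = 0.0
    preference_centre: float = -1.0
    kappa: float = 2.0
    link_confidence: float = 0.9
    horizons: dict[str, int] = field(
        default_factory=lambda: {"solve": 3, "query": 4, "answer": 7}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ConfigError(f"context must be one of {CONTEXTS}")
        if self.query not in QUERY_SLOTS:
            raise ConfigError(f"query must be one of {QUERY_SLOTS}")
        if any(e not in NARRATIVES for e in self.epochs) or not self.epochs:
            raise ConfigError("epochs must be a non-empty tuple of narrative stages")
        if not (
            self.preference_attractive > self.preference_neutral > self.preference_aversive
        ):
            raise ConfigError("need attractive > neutral > aversive preference")
        if not 0.0 < self.link_confidence <= 1.0:
            raise ConfigError("link_confidence must be in (0, 1]")
        if any(self.horizons[e] < 3 for e in NARRATIVES):
            raise ConfigError("every epoch horizon must be at least 3")
        if self.horizons["query"] < 4 or self.horizons["answer"] < 7:
            raise ConfigError("query needs >= 4 steps, answer >= 7")


# ---------------------------------------------------------------------------
# policies
# ---------------------------------------------------------------------------


def enumerate_policies() -> tuple[Policy, ...]:
    """All two-move sequences from the centre honouring absorbing arms.

    A first move into an arm forces the second move to stay there, which
    leaves exactly ten allowable policies.
    """
    arms = {LOCATIONS.index("left"), LOCATIONS.index("right")}
    out = []
    for m1 in range(len(LOCATIONS)):
        seconds = [m1] if m1 in arms else list(range(len(LOCATIONS)))
        for m2 in seconds:
            out.append(Policy(({"location": m1}, {"location": m2})))
    return tuple(out)


def policy_moves(policy: Policy) -> tuple[int, int]:
    return policy.moves[0]["location"], policy.moves[1]["location"]


# ---------------------------------------------------------------------------
# semantic link rule
# ---------------------------------------------------------------------------


def semantic_link_table(
    queried_move_destination: str, reward_location: str
) -> tuple[str, str, str]:
    """(knowledge, verb, destination) implied by a queried move.

    Going to the cue means the reward side was not known and the move was
    exploratory; going straight to the rewarded arm is taken as evidence
    the side was known (exploitation); the wrong arm is an uninformed
    guess; staying in the centre is waiting.
    """
    if queried_move_destination not in LOCATIONS:
        raise ConfigError(f"unknown move destination {queried_move_destination!r}")
    if reward_location not in CONTEXTS:
        raise ConfigError(f"unknown reward location {reward_location!r}")
    dest = MOVE_TO_DESTINATION[queried_move_destination]
    if queried_move_destination == "cue":
        return ("did-not-know", "explored", dest)
    if queried_move_destination == "centre":
        return ("did-not-know", "waited", dest)
    if queried_move_destination == reward_location:
        return ("knew", "exploited", dest)
    return ("did-not-know", "guessed", dest)


# ---------------------------------------------------------------------------
# fast-level model tables
# ---------------------------------------------------------------------------


def _soft_delta(n: int, idx: int, confidence: float) -> np.ndarray:
    if confidence >= 1.0:
        v = np.zeros(n)
        v[idx] = 1.0
        return v
    v = np.full(n, (1.0 - confidence) / (n - 1))
    v[idx] = confidence
    return v


def build_level1_space() -> StateSpace:
    return StateSpace(
        (
            Factor("location", LOCATIONS, controllable=True),
            Factor("context", CONTEXTS),
            Factor("query_slot", QUERY_SLOTS),
            Factor("knowledge", KNOWLEDGE),
            Factor("verb", VERBS),
            Factor("destination", DESTINATIONS),
            Factor("syntax", SYNTAX),
        )
    )


def _location_transition() -> np.ndarray:
    n = len(LOCATIONS)
    arms = {LOCATIONS.index("left"), LOCATIONS.index("right")}
    b = np.zeros((n, n, n))  # (action, next, prev)
    for a in range(n):
        for prev in range(n):
            nxt = prev if prev in arms else a
            b[a, nxt, prev] = 1.0
    return b


def _syntax_transition() -> np.ndarray:
    n = len(SYNTAX)
    nxt_of = {i: i for i in range(n)}  # default: absorbing
    chain = ["q1-please", "q2-explain", "q3-which", "q4-move"]
    for a, b in zip(chain[:-1], chain[1:]):
        nxt_of[SYNTAX.index(a)] = SYNTAX.index(b)
    chain = ["a1-i", "a2-knowledge", "a3-reward-was", "a4-side", "a5-so-i", "a6-verb", "a7-destination"]
    for a, b in zip(chain[:-1], chain[1:]):
        nxt_of[SYNTAX.index(a)] = SYNTAX.index(b)
    b = np.zeros((1, n, n))
    for prev, nxt in nxt_of.items():
        b[0, nxt, prev] = 1.0
    return b


def _identity_transition(n: int) -> np.ndarray:
    return np.eye(n)[None, :, :]


def build_likelihood() -> LikelihoodModel:
    shape = (
        len(LOCATIONS),
        len(CONTEXTS),
        len(QUERY_SLOTS),
        len(KNOWLEDGE),
        len(VERBS),
        len(DESTINATIONS),
        len(SYNTAX),
    )
    a_ext = np.zeros((len(EXTERO),) + shape)
    a_rew = np.zeros((len(REWARDS),) + shape)
    a_heard = np.zeros((len(TOKENS),) + shape)
    a_spoken = np.zeros((len(TOKENS),) + shape)
    silent = SYNTAX.index("silent")
    tok = TOKENS.index

    for loc in range(len(LOCATIONS)):
        for c in range(len(CONTEXTS)):
            for syn in range(len(SYNTAX)):
                # maze modalities: attenuated to centre + neutral unless silent
                if syn != silent:
                    ext, rew = EXTERO.index("centre"), REWARDS.index("neutral")
                elif LOCATIONS[loc] == "cue":
                    ext = EXTERO.index("cue-left" if CONTEXTS[c] == "left" else "cue-right")
                    rew = REWARDS.index("neutral")
                elif LOCATIONS[loc] in CONTEXTS:  # an arm
                    ext = EXTERO.index(LOCATIONS[loc])
                    rew = REWARDS.index(
                        "attractive" if LOCATIONS[loc] == CONTEXTS[c] else "aversive"
                    )
                else:
                    ext, rew = EXTERO.index("centre"), REWARDS.index("neutral")
                a_ext[ext, loc, c, :, :, :, :, syn] = 1.0
                a_rew[rew, loc, c, :, :, :, :, syn] = 1.0

    # word modalities: heard carries the query frame, spoken the answer frame
    for syn, name in enumerate(SYNTAX):
        if name == "q1-please":
            a_heard[tok("Please"), :, :, :, :, :, :, syn] = 1.0
        elif name == "q2-explain":
            a_heard[tok("explain"), :, :, :, :, :, :, syn] = 1.0
        elif name == "q3-which":
            for q, slot in enumerate(QUERY_SLOTS):
                a_heard[tok(slot), :, :, q, :, :, :, syn] = 1.0
        elif name == "q4-move":
            a_heard[tok("move"), :, :, :, :, :, :, syn] = 1.0
        else:
            a_heard[tok(SILENCE), :, :, :, :, :, :, syn] = 1.0

        if name == "a1-i":
            a_spoken[tok("I"), :, :, :, :, :, :, syn] = 1.0
        elif name == "a2-knowledge":
            for k, word in enumerate(KNOWLEDGE):
                a_spoken[tok(word), :, :, :, k, :, :, syn] = 1.0
        elif name == "a3-reward-was":
            a_spoken[tok("reward-was"), :, :, :, :, :, :, syn] = 1.0
        elif name == "a4-side":
            # the side slot reads the context factor: one and the same state
            for c, word in enumerate(CONTEXTS):
                a_spoken[tok(word), :, c, :, :, :, :, syn] = 1.0
        elif name == "a5-so-i":
            a_spoken[tok("so-I"), :, :, :, :, :, :, syn] = 1.0
        elif name == "a6-verb":
            for v, word in enumerate(VERBS):
                a_spoken[tok(word), :, :, :, :, v, :, syn] = 1.0
        elif name == "a7-destination":
            for d, dest in enumerate(DESTINATIONS):
                a_spoken[tok(DESTINATION_TOKEN[dest]), :, :, :, :, :, d, syn] = 1.0
        else:
            a_spoken[tok(SILENCE), :, :, :, :, :, :, syn] = 1.0

    return LikelihoodModel(
        (
            Modality("extero", EXTERO, ConditionalTable(a_ext)),
            Modality("reward", REWARDS, ConditionalTable(a_rew)),
            Modality("heard", TOKENS, ConditionalTable(a_heard)),
            Modality("spoken", TOKENS, ConditionalTable(a_spoken)),
        )
    )


def build_preferences(config: TaskConfig) -> Preferences:
    c_ext = np.zeros(len(EXTERO))
    c_ext[EXTERO.index("centre")] = config.preference_centre
    c_rew = np.array(
        [config.preference_neutral, config.preference_attractive, config.preference_aversive]
    )
    return Preferences(
        {
            "extero": c_ext,
            "reward": c_rew,
            "heard": np.zeros(len(TOKENS)),
            "spoken": np.zeros(len(TOKENS)),
        }
    )


# ---------------------------------------------------------------------------
# slow-level model and link
# ---------------------------------------------------------------------------


def build_level2_space() -> StateSpace:
    return StateSpace(
        (
            Factor("narrative", NARRATIVES),
            Factor("first_move", LOCATIONS),
            Factor("second_move", LOCATIONS),
            Factor("reward", CONTEXTS),
            Factor("query", QUERY_SLOTS),
        )
    )


def build_level2_transitions() -> TransitionModel:
    n = len(NARRATIVES)
    b_narr = np.zeros((1, n, n))
    b_narr[0, NARRATIVES.index("query"), NARRATIVES.index("solve")] = 1.0
    b_narr[0, NARRATIVES.index("answer"), NARRATIVES.index("query")] = 1.0
    b_narr[0, NARRATIVES.index("answer"), NARRATIVES.index("answer")] = 1.0
    return TransitionModel(
        {
            "narrative": b_narr,
            "first_move": _identity_transition(len(LOCATIONS)),
            "second_move": _identity_transition(len(LOCATIONS)),
            "reward": _identity_transition(len(CONTEXTS)),
            "query": _identity_transition(len(QUERY_SLOTS)),
        }
    )


def build_link(config: TaskConfig, policies: tuple[Policy, ...]) -> LevelLink:
    shape = (
        len(NARRATIVES),
        len(LOCATIONS),
        len(LOCATIONS),
        len(CONTEXTS),
        len(QUERY_SLOTS),
    )
    answer = NARRATIVES.index("answer")

    loc = np.zeros((len(LOCATIONS),) + shape)
    loc[LOCATIONS.index("centre")] = 1.0  # every epoch starts at the centre

    ctx = np.zeros((len(CONTEXTS),) + shape)
    for r in range(len(CONTEXTS)):
        ctx[r, :, :, :, r, :] = 1.0  # fast context is the slow reward side

    qsl = np.zeros((len(QUERY_SLOTS),) + shape)
    for q in range(len(QUERY_SLOTS)):
        qsl[q, :, :, :, :, q] = 1.0

    syn = np.zeros((len(SYNTAX),) + shape)
    syn[SYNTAX.index("silent"), NARRATIVES.index("solve")] = 1.0
    syn[SYNTAX.index("q1-please"), NARRATIVES.index("query")] = 1.0
    syn[SYNTAX.index("a1-i"), NARRATIVES.index("answer")] = 1.0

    kno = np.zeros((len(KNOWLEDGE),) + shape)
    vrb = np.zeros((len(VERBS),) + shape)
    dst = np.zeros((len(DESTINATIONS),) + shape)
    # outside the answer stage the slow level says nothing about semantics
    for arr in (kno, vrb, dst):
        for nr in range(len(NARRATIVES)):
            if nr != answer:
                arr[:, nr] = 1.0 / arr.shape[0]
    conf = config.link_confidence
    for m1 in range(len(LOCATIONS)):
        for m2 in range(len(LOCATIONS)):
            for r in range(len(CONTEXTS)):
                for q in range(len(QUERY_SLOTS)):
                    queried = LOCATIONS[m1] if QUERY_SLOTS[q] == "first" else LOCATIONS[m2]
                    k_name, v_name, d_name = semantic_link_table(queried, CONTEXTS[r])
                    kno[:, answer, m1, m2, r, q] = _soft_delta(
                        len(KNOWLEDGE), KNOWLEDGE.index(k_name), conf
                    )
                    vrb[:, answer, m1, m2, r, q] = _soft_delta(
                        len(VERBS), VERBS.index(v_name), conf
                    )
                    dst[:, answer, m1, m2, r, q] = _soft_delta(
                        len(DESTINATIONS), DESTINATIONS.index(d_name), conf
                    )

    pol = np.zeros((len(policies),) + shape)
    for i, p in enumerate(policies):
        m1, m2 = policy_moves(p)
        for g2 in range(len(LOCATIONS)):
            for g3 in range(len(LOCATIONS)):
                w = np.exp(config.kappa * ((m1 == g2) + (m2 == g3)))
                pol[i, :, g2, g3, :, :] = w
    pol /= pol.sum(axis=0, keepdims=True)

    return LevelLink(
        state_links={
            "location": ConditionalTable(loc),
            "context": ConditionalTable(ctx),
            "query_slot": ConditionalTable(qsl),
            "knowledge": ConditionalTable(kno),
            "verb": ConditionalTable(vrb),
            "destination": ConditionalTable(dst),
            "syntax": ConditionalTable(syn),
        },
        policy_link=ConditionalTable(pol),
    )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_model(config: TaskConfig | None = None) -> HierarchicalModel:
    """The full two-level task model for one configuration."""
    config = config or TaskConfig()
    policies = enumerate_policies()
    level1 = MDPModel(
        space=build_level1_space(),
        likelihood=build_likelihood(),
        transitions=TransitionModel(
            {
                "location": _location_transition(),
                "context": _identity_transition(len(CONTEXTS)),
                "query_slot": _identity_transition(len(QUERY_SLOTS)),
                "knowledge": _identity_transition(len(KNOWLEDGE)),
                "verb": _identity_transition(len(VERBS)),
                "destination": _identity_transition(len(DESTINATIONS)),
                "syntax": _syntax_transition(),
            }
        ),
        preferences=build_preferences(config),
        policies=policies,
    )
    space2 = build_level2_space()
    priors2 = {}
    for f in space2.factors:
        if f.name == "narrative":
            p = np.zeros(f.n)
            p[f.index(config.epochs[0])] = 1.0
        else:
            p = np.full(f.n, 1.0 / f.n)
        priors2[f.name] = Categorical(p)
    return HierarchicalModel(
        level2_space=space2,
        level2_transitions=build_level2_transitions(),
        level2_priors=priors2,
        level1_model=level1,
        link=build_link(config, policies),
        epoch_horizons=dict(config.horizons),
        speak_modality="spoken",
    )


class TMazeEnvironment:
    """Generative process: the true maze plus the scripted interlocutor.

    Mirrors the model's tables with the true context fixed. During the
    solve epoch actions move the agent and the maze modalities report its
    true position; during query epochs the interlocutor utters the query
    frame; during answer epochs the agent's spoken token is echoed back as
    its observation and the maze modalities stay attenuated (the agent
    physically remains at the centre).
    """

    def __init__(self, config: TaskConfig):
        self.config = config
        self.vocabulary = Vocabulary()
        self.epoch_plan = tuple(config.epochs)
        self.true_context = CONTEXTS.index(config.context)
        self.rng = np.random.default_rng(config.seed)
        self.epoch_type = self.epoch_plan[0]
        self.true_location = LOCATIONS.index("centre")
        self.true_locations: list[int] = []

    def begin_epoch(self, index: int, epoch_type: str) -> None:
        self.epoch_type = epoch_type
        self.true_location = LOCATIONS.index("centre")

    def agent_speaks(self, t: int) -> bool:
        return self.epoch_type == "answer"

    def observe(self, t: int, spoken: int | None) -> dict[str, int]:
        tok = self.vocabulary.index
        if self.epoch_type == "solve":
            name = LOCATIONS[self.true_location]
            if name == "cue":
                ext = EXTERO.index("cue-" + CONTEXTS[self.true_context])
                rew = REWARDS.index("neutral")
            elif name in CONTEXTS:
                ext = EXTERO.index(name)
                rew = REWARDS.index(
                    "attractive" if name == CONTEXTS[self.true_context] else "aversive"
                )
            else:
                ext = EXTERO.index("centre")
                rew = REWARDS.index("neutral")
        else:
            ext = EXTERO.index("centre")
            rew = REWARDS.index("neutral")

        heard = tok(SILENCE)
        if self.epoch_type == "query":
            script = ("Please", "explain", self.config.query, "move")
            if 1 <= t <= len(script):
                heard = tok(script[t - 1])

        spoken_obs = tok(SILENCE)
        if self.epoch_type == "answer" and spoken is not None:
            spoken_obs = spoken  # the agent hears itself speak

        self.true_locations.append(self.true_location)
        return {"extero": ext, "reward": rew, "heard": heard, "spoken": spoken_obs}

    def apply_action(self, actions: dict[str, int]) -> None:
        if self.epoch_type != "solve":
            return  # fixed to the spot outside the maze-solving stage
        prev = self.true_location
        arms = {LOCATIONS.index("left"), LOCATIONS.index("right")}
        self.true_location = prev if prev in arms else actions["location"]


def build_environment(config: TaskConfig | None = None) -> TMazeEnvironment:
    return TMazeEnvironment(config or TaskConfig())


# ---------------------------------------------------------------------------
# human-readable reference of the built tables
# ---------------------------------------------------------------------------


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def reference_text(config: TaskConfig | None = None) -> str:
    """Structural, diff-stable description of every built table.

    Small tables are printed in full; the large likelihood tensors are
    described by their generating rules and pinned by checksums.
    """
    config = config or TaskConfig()
    model = build_model(config)
    l1 = model.level1_model
    lines = ["# mazetalk task model reference", ""]
    lines.append("## Fast-level factors")
    for f in l1.space.factors:
        ctrl = " (controllable)" if f.controllable else ""
        lines.append(f"- {f.name}{ctrl}: {', '.join(f.levels)}")
    lines.append("")
    lines.append("## Outcome modalities")
    for m in l1.likelihood.modalities:
        lines.append(f"- {m.name} ({len(m.levels)} levels): sha256[:16]={_sha(m.table.table)}")
    lines.append("")
    lines.append("## Policies (first move, second move)")
    for i, p in enumerate(l1.policies):
        m1, m2 = policy_moves(p)
        lines.append(f"- {i}: ({LOCATIONS[m1]}, {LOCATIONS[m2]})")
    lines.append("")
    lines.append("## Location transitions (next <- prev under action)")
    b = l1.transitions.tables["location"]
    for a in range(b.shape[0]):
        for prev in range(b.shape[2]):
            nxt = int(np.argmax(b[a, :, prev]))
            lines.append(f"- go-{LOCATIONS[a]} : {LOCATIONS[prev]} -> {LOCATIONS[nxt]}")
    lines.append("")
    lines.append("## Syntax chain")
    bs = l1.transitions.tables["syntax"][0]
    for prev in range(bs.shape[1]):
        nxt = int(np.argmax(bs[:, prev]))
        lines.append(f"- {SYNTAX[prev]} -> {SYNTAX[nxt]}")
    lines.append("")
    lines.append("## Preferences (log)")
    for k, v in l1.preferences.log_c.items():
        if np.any(v != 0):
            lines.append(f"- {k}: {np.array2string(v, precision=3)}")
        else:
            lines.append(f"- {k}: flat (all zero)")
    lines.append("")
    lines.append("## Slow-level factors")
    for f in model.level2_space.factors:
        lines.append(f"- {f.name}: {', '.join(f.levels)}")
    lines.append("")
    lines.append("## Narrative transitions")
    bn = model.level2_transitions.tables["narrative"][0]
    for prev in range(bn.shape[1]):
        nxt = int(np.argmax(bn[:, prev]))
        lines.append(f"- {NARRATIVES[prev]} -> {NARRATIVES[nxt]}")
    lines.append("")
    lines.append("## Semantic link rule (queried move, reward side) -> slots")
    for move in LOCATIONS:
        for reward in CONTEXTS:
            k, v, d = semantic_link_table(move, reward)
            lines.append(f"- ({move}, {reward}) -> ({k}, {v}, {d})")
    lines.append(f"- link confidence: {config.link_confidence}")
    lines.append(f"- policy bias concentration kappa: {config.kappa}")
    lines.append("")
    lines.append("## Link table checksums")
    for f, t in model.link.state_links.items():
        lines.append(f"- {f}: sha256[:16]={_sha(t.table)}")
    lines.append(f"- policy link: sha256[:16]={_sha(model.link.policy_link.table)}")
    lines.append("")
    return "\n".join(lines)
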