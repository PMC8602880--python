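"""Scripted task runs and behavioural read-outs.

``run_standard`` reproduces the canonical three-stage session (solve the
maze, hear the query, speak the answer); ``run_confabulation`` starts the
narrative at the query stage, so the agent must explain a course of action
it never took and is given two answer epochs to settle its story. The
read-outs are numeric: a replay score over the location beliefs, the
context-belief trace, and an internal-consistency verdict on each spoken
answer.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .categorical import tie_break_argmax
from .hierarchy import EpochRecord, HierarchicalModel, LevelLink, run_hierarchy
from .mdp import model_to_dict
from .tmaze import (
    CONTEXTS,
    DESTINATION_TOKEN,
    DESTINATIONS,
    KNOWLEDGE,
    LOCATIONS,
    MOVE_TO_DESTINATION,
    SILENCE,
    TOKENS,
    TaskConfig,
    VERBS,
    ConfigError,
    build_environment,
    build_model,
    semantic_link_table,
)
from .categorical import ConditionalTable

TRANSCRIPT_SCHEMA_VERSION = 1

#: answer-frame positions (0-based) of the four semantic slots
ANSWER_SLOT_STEPS = {"knowledge": 1, "side": 3, "verb": 5, "destination": 6}


@dataclass
class EpochTranscript:
    epoch_type: str
    heard: list[str]
    spoken: list[str]
    actions: list[str]
    map_locations: list[str]
    context_posterior: list[list[float]]

    def to_dict(self) -> dict:
        return {
            "epoch_type": self.epoch_type,
            "heard": self.heard,
            "spoken": self.spoken,
            "actions": self.actions,
            "map_locations": self.map_locations,
            "context_posterior": self.context_posterior,
        }


@dataclass
class Transcript:
    """What was heard, said and done, epoch by epoch."""

    config: dict
    epochs: list[EpochTranscript]

    def to_dict(self) -> dict:
        return {
            "schema_version": TRANSCRIPT_SCHEMA_VERSION,
            "config": self.config,
            "epochs": [e.to_dict() for e in self.epochs],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def answer_slots(self, epoch_index: int) -> tuple[str, str, str, str]:
        """(knowledge, side, verb, destination) tokens of an answer epoch."""
        ep = self.epochs[epoch_index]
        if ep.epoch_type != "answer":
            raise ValueError(f"epoch {epoch_index} is {ep.epoch_type!r}, not an answer")
        s = ep.spoken
        return (
            s[ANSWER_SLOT_STEPS["knowledge"]],
            s[ANSWER_SLOT_STEPS["side"]],
            s[ANSWER_SLOT_STEPS["verb"]],
            s[ANSWER_SLOT_STEPS["destination"]],
        )


@dataclass
class ConsistencyVerdict:
    """Whether an answer tells a realizable story.

    ``realizable`` lists the (queried move, reward side) pairs under which
    the spoken slots are exactly what the semantic link would predict.
    """

    consistent: bool
    realizable: list[tuple[str, str]] = field(default_factory=list)


def _token_to_destination(token: str) -> str:
    if token in DESTINATIONS:
        return token
    for dest, tok in DESTINATION_TOKEN.items():
        if tok == token:
            return dest
    raise ValueError(f"unknown destination token {token!r}")


def consistency_check(answer_slots: tuple[str, str, str, str]) -> ConsistencyVerdict:
    """Is the answer the story the model itself would tell of some move?

    The answer asserts: knowledge of the reward side, the side, a verb and
    a destination. It is consistent exactly when the semantic link,
    applied to the asserted destination (as the queried move) and the
    asserted side (as the reward location), reproduces the asserted
    (knowledge, verb, destination) triple.
    """
    knowledge, side, verb, destination_tok = answer_slots
    if knowledge not in KNOWLEDGE:
        raise ValueError(f"unknown knowledge token {knowledge!r}")
    if side not in CONTEXTS:
        raise ValueError(f"unknown side token {side!r}")
    if verb not in VERBS:
        raise ValueError(f"unknown verb token {verb!r}")
    destination = _token_to_destination(destination_tok)
    realizable = []
    for move in LOCATIONS:
        for reward in CONTEXTS:
            if reward != side:
                continue
            if semantic_link_table(move, reward) == (knowledge, verb, destination):
                realizable.append((move, reward))
    return ConsistencyVerdict(consistent=bool(realizable), realizable=realizable)


def make_transcript(records: list[EpochRecord], config: TaskConfig) -> Transcript:
    epochs = []
    for rec in records:
        trial = rec.trial
        heard = [TOKENS[o["heard"]] for o in trial.observations]
        spoken = [TOKENS[s] if s is not None else SILENCE for s in trial.spoken]
        actions = ["go-" + LOCATIONS[a["location"]] for a in trial.actions]
        loc = trial.online_marginals["location"]
        map_locations = [LOCATIONS[tie_break_argmax(loc[t])] for t in range(trial.horizon)]
        ctx = trial.online_marginals["context"]
        context_posterior = [[float(x) for x in ctx[t]] for t in range(trial.horizon)]
        epochs.append(
            EpochTranscript(
                epoch_type=rec.epoch_type,
                heard=heard,
                spoken=spoken,
                actions=actions,
                map_locations=map_locations,
                context_posterior=context_posterior,
            )
        )
    cfg = {
        "context": config.context,
        "query": config.query,
        "epochs": list(config.epochs),
        "seed": config.seed,
    }
    return Transcript(config=cfg, epochs=epochs)


# ---------------------------------------------------------------------------
# scripted runs
# ---------------------------------------------------------------------------


def run_standard(
    query_type: str = "first",
    true_context: str = "right",
    seed: int = 0,
    config: TaskConfig | None = None,
) -> tuple[Transcript, list[EpochRecord]]:
    """Solve the maze, hear the query, answer it (three epochs)."""
    if config is None:
        config = TaskConfig(context=true_context, query=query_type, seed=seed)
    model = build_model(config)
    env = build_environment(config)
    records = run_hierarchy(model, env)
    return make_transcript(records, config), records


def run_confabulation(
    seed: int = 0,
    query_type: str = "first",
    true_context: str = "right",
) -> tuple[Transcript, list[EpochRecord], list[ConsistencyVerdict]]:
    """Query an agent that never solved the maze; two chances to answer.

    Returns the transcript, epoch records and one consistency verdict per
    answer epoch.
    """
    config = TaskConfig(
        context=true_context,
        query=query_type,
        epochs=("query", "answer", "answer"),
        seed=seed,
    )
    model = build_model(config)
    env = build_environment(config)
    records = run_hierarchy(model, env)
    transcript = make_transcript(records, config)
    verdicts = [
        consistency_check(transcript.answer_slots(i))
        for i, rec in enumerate(records)
        if rec.epoch_type == "answer"
    ]
    return transcript, records, verdicts


def replay_score(records: list[EpochRecord]) -> float:
    """Fraction of later-epoch MAP locations replaying the solve sequence.

    Compares the believed (MAP) location over the first three steps of
    every later epoch with the first epoch's; 1.0 means the maze
    trajectory is re-expressed perfectly while the agent sits still.
    """
    if len(records) < 2:
        raise ConfigError("replay needs at least two epochs")
    for rec in records:
        if rec.trial.horizon < 3:
            raise ConfigError("replay needs at least three steps per epoch")
    seqs = []
    for rec in records:
        loc = rec.trial.online_marginals["location"]
        seqs.append([tie_break_argmax(loc[t]) for t in range(3)])
    base = seqs[0]
    agree = [int(s[t] == base[t]) for s in seqs[1:] for t in range(3)]
    return float(np.mean(agree))


def sever_link(model: HierarchicalModel) -> HierarchicalModel:
    """Negative control: slow level no longer biases the fast policies."""
    n = model.link.policy_link.n_outcomes
    flat = np.full((n,) + model.level2_space.shape, 1.0 / n)
    link = LevelLink(
        state_links=dict(model.link.state_links),
        policy_link=ConditionalTable(flat),
    )
    return HierarchicalModel(
        level2_space=model.level2_space,
        level2_transitions=model.level2_transitions,
        level2_priors=model.level2_priors,
        level1_model=model.level1_model,
        link=link,
        epoch_horizons=model.epoch_horizons,
        speak_modality=model.speak_modality,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_run(outdir, transcript: Transcript, records: list[EpochRecord], config: TaskConfig) -> None:
    """transcript.json + per-level belief CSVs + a run log with the config."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "transcript.json").write_text(transcript.to_json() + "\n")

    model = build_model(config)
    with open(out / "beliefs_level1.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        cols = [
            f"epoch{k}_t{t + 1}"
            for k, rec in enumerate(records)
            for t in range(rec.trial.horizon)
        ]
        w.writerow(["state"] + cols)
        for f in model.level1_model.space.factors:
            for i, level in enumerate(f.levels):
                row = [f"{f.name}:{level}"]
                for rec in records:
                    m = rec.trial.mixture_marginals[f.name]
                    row += [f"{m[t, i]:.6g}" for t in range(rec.trial.horizon)]
                w.writerow(row)
    with open(out / "beliefs_level2.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        cols = [f"epoch{k}_{kind}" for k in range(len(records)) for kind in ("prior", "posterior")]
        w.writerow(["state"] + cols)
        for f in model.level2_space.factors:
            for i, level in enumerate(f.levels):
                row = [f"{f.name}:{level}"]
                for rec in records:
                    row.append(f"{rec.prior_marginals[f.name].probs[i]:.6g}")
                    row.append(f"{rec.posterior_marginals[f.name].probs[i]:.6g}")
                w.writerow(row)
    log = {
        "config": transcript.config,
        "horizons": dict(config.horizons),
        "kappa": config.kappa,
        "link_confidence": config.link_confidence,
        "n_epochs": len(records),
        "map_story_per_epoch": [rec.joint_map for rec in records],
        "map_story_prob_per_epoch": [rec.joint_map_prob for rec in records],
    }
    (out / "run.log").write_text(json.dumps(log, indent=2) + "\n")


def write_model_json(path, config: TaskConfig | None = None) -> None:
    """Full fast-level table set in the plain-data model format."""
    model = build_model(config or TaskConfig())
    with open(path, "w") as fh:
        json.dump(model_to_dict(model.level1_model), fh)


def plot_rasters(records: list[EpochRecord], path, config: TaskConfig | None = None) -> None:
    """Optional belief-raster heatmaps (states/policies x time)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    model = build_model(config or TaskConfig())
    factors = model.level1_model.space.factors
    times = sum(rec.trial.horizon for rec in records)
    fig, axes = plt.subplots(len(factors) + 1, 1, figsize=(0.6 * times + 2, 2 * (len(factors) + 1)))
    boundaries = np.cumsum([rec.trial.horizon for rec in records])[:-1]
    for ax, f in zip(axes, factors):
        arr = np.hstack([rec.trial.mixture_marginals[f.name].T for rec in records])
        ax.imshow(1 - arr, cmap="gray", aspect="auto", vmin=0, vmax=1)
        ax.set_yticks(range(f.n), f.levels, fontsize=6)
        ax.set_title(f.name, fontsize=8)
        for b in boundaries:
            ax.axvline(b - 0.5, ls="--", c="r", lw=0.8)
    q = np.hstack(
        [
            np.stack([qp.probs for qp in rec.trial.q_pi_per_time], axis=1)
            for rec in records
        ]
    )
    # policy beliefs are per decision time, not per state time; show as-is
    axes[-1].imshow(1 - q, cmap="gray", aspect="auto", vmin=0, vmax=1)
    axes[-1].set_title("policies", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
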