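"""Tiger Task environments: states, actions, observation channels, payouts,
and trial/session mechanics.

The task is a two-door problem: one door hides a tiger (large loss), the
other a pot of gold (reward). Each round an agent may listen (``L``), paying
one point for a noisy growl that reports the tiger's side with accuracy
``p_growl`` (default 0.70), or open a door (``OL``/``OR``). Opening ends the
*tiger-trial*: the outcome is paid and tiger/gold are re-randomized with
probability 0.5 per side. A session is a fixed number of tiger-trials
(default 10).

In the interactive (dyadic) version both agents act each round, predictions
of the partner's action are recorded before choices, and every round emits a
*social* observation — a creak on the left/right or silence (``CL``/``CR``/
``S``) — reporting the partner's action class with accuracy ``p_creak``
(default 0.80). A tiger-trial ends as soon as either agent opens a door.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

# Canonical string codes (also used in the CSV serialization).
L, OL, OR = "L", "OL", "OR"
GL, GR = "GL", "GR"
CL, CR, S = "CL", "CR", "S"
TL, TR = "TL", "TR"

ACTIONS = (L, OL, OR)
OPEN_ACTIONS = (OL, OR)
GROWLS = (GL, GR)
CREAKS = (CL, CR, S)
SIDES = (TL, TR)

VARIANTS = ("original", "modified")
CONTEXTS = ("solo", "cooperative", "competitive")

_MIRROR = {L: L, OL: OR, OR: OL, GL: GR, GR: GL, CL: CR, CR: CL, S: S,
           TL: TR, TR: TL}


def mirror(code: str) -> str:
    """Left/right relabeling of any state/action/observation code."""
    return _MIRROR[code]


def gold_action(tiger_side: str) -> str:
    """The open action that hits the gold door (the door without the tiger)."""
    return OR if tiger_side == TL else OL


def tiger_action(tiger_side: str) -> str:
    return OL if tiger_side == TL else OR


# ---------------------------------------------------------------------------
# Payouts
# ---------------------------------------------------------------------------

#: base single-agent payouts per variant: (listen, gold, tiger)
BASE_PAYOUTS = {
    "original": (-1.0, 10.0, -100.0),
    "modified": (-1.0, 20.0, -50.0),
}


@dataclass(frozen=True)
class PayoutSpec:
    """Reward mapping for a (variant, context) pair.

    ``table`` maps ``(own_action, other_action_or_None, tiger_side)`` to
    ``(own_points, other_points)``. In the solo context the second action
    slot is ``None`` and the partner's points are 0.
    """

    variant: str
    context: str
    table: Mapping[tuple, tuple]

    def joint(self, own: str, other: Optional[str], side: str) -> tuple:
        return self.table[(own, other, side)]

    def reward(self, own: str, other: Optional[str], side: str) -> float:
        return self.table[(own, other, side)][0]

    @property
    def is_solo(self) -> bool:
        return self.context == "solo"

    def base(self, action: str, side: str) -> float:
        """Single-agent (base) payout of ``action`` given the tiger side."""
        r_listen, r_gold, r_tiger = BASE_PAYOUTS[self.variant]
        if action == L:
            return r_listen
        return r_gold if action == gold_action(side) else r_tiger


def make_payout(variant: str, context: str) -> PayoutSpec:
    """Build the payout table for a task variant and interactional context.

    Base (single-agent) values: listening costs 1 point; the modified
    variant pays +20 for gold and -50 for the tiger, the original +10/-100.

    Dyadic tables are derived from the base values:

    * ``original``: each agent receives its own base payout plus (cooperative)
      or minus (competitive) half the other's base payout, in every cell.
    * ``modified``: the same sharing rule, but the half-share applies only
      when the other agent opened a *different* door; identical joint actions
      and a listening partner leave the base payout unchanged. This keeps all
      entries whole numbers, prices a shared listen at -1 each, pays +20 each
      when both hit gold and -50 each when both hit the tiger, and yields
      (+45, -60) when one agent finds the gold while the other finds the
      tiger in the competitive context.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")

    r_listen, r_gold, r_tiger = BASE_PAYOUTS[variant]

    def base(action: str, side: str) -> float:
        if action == L:
            return r_listen
        return r_gold if action == gold_action(side) else r_tiger

    table = {}
    if context == "solo":
        for side in SIDES:
            for a in ACTIONS:
                table[(a, None, side)] = (base(a, side), 0.0)
        return PayoutSpec(variant, context, table)

    sign = 1.0 if context == "cooperative" else -1.0
    for side in SIDES:
        for a_own, a_oth in itertools.product(ACTIONS, repeat=2):
            b_own, b_oth = base(a_own, side), base(a_oth, side)
            if variant == "original":
                own = b_own + sign * 0.5 * b_oth
                oth = b_oth + sign * 0.5 * b_own
            else:
                own = b_own + (sign * 0.5 * b_oth
                               if a_oth in OPEN_ACTIONS and a_oth != a_own else 0.0)
                oth = b_oth + (sign * 0.5 * b_own
                               if a_own in OPEN_ACTIONS and a_own != a_oth else 0.0)
            table[(a_own, a_oth, side)] = (own, oth)
    return PayoutSpec(variant, context, table)


# ---------------------------------------------------------------------------
# Observation channels
# ---------------------------------------------------------------------------

def sample_physical_obs(tiger_side: str, p_growl: float,
                        rng: np.random.Generator) -> str:
    """Noisy growl: matches the tiger's side with probability ``p_growl``."""
    if not 0.0 <= p_growl <= 1.0:
        raise ValueError(f"p_growl must be in [0, 1], got {p_growl}")
    if tiger_side not in SIDES:
        raise ValueError(f"invalid tiger side {tiger_side!r}")
    true = GL if tiger_side == TL else GR
    return true if rng.random() < p_growl else mirror(true)


_TRUE_SIGNAL = {L: S, OL: CL, OR: CR}


def sample_social_obs(other_action: str, p_creak: float,
                      rng: np.random.Generator) -> str:
    """Noisy creak/silence: reports the partner's action class with
    probability ``p_creak``; errors split evenly over the two wrong signals.
    """
    if not 0.0 <= p_creak <= 1.0:
        raise ValueError(f"p_creak must be in [0, 1], got {p_creak}")
    if other_action not in ACTIONS:
        raise ValueError(f"invalid action {other_action!r}")
    true = _TRUE_SIGNAL[other_action]
    u = rng.random()
    if u < p_creak:
        return true
    wrong = [c for c in CREAKS if c != true]
    return wrong[0] if u < p_creak + (1 - p_creak) / 2 else wrong[1]


def social_obs_prob(obs: str, other_action: str, p_creak: float) -> float:
    """Likelihood P(creak signal | partner action) under the uniform-error
    confusion model."""
    return p_creak if obs == _TRUE_SIGNAL[other_action] else (1 - p_creak) / 2


def physical_obs_prob(obs: str, tiger_side: str, p_growl: float) -> float:
    true = GL if tiger_side == TL else GR
    return p_growl if obs == true else 1 - p_growl


# ---------------------------------------------------------------------------
# Events and session logs
# ---------------------------------------------------------------------------

@dataclass
class TrialEvent:
    """One agent's record of one round."""

    trial: int
    round_index: int
    own_action: str
    reward: float
    tiger_side: str
    prediction: Optional[str] = None
    social_obs: Optional[str] = None
    physical_obs: Optional[str] = None
    trial_ended: bool = False
    rt_ms: Optional[float] = None
    forced: bool = False


@dataclass
class SessionLog:
    """Ordered rounds of one agent in one session, grouped into tiger-trials."""

    agent_id: str
    dyad_id: Optional[str]
    session_index: int
    variant: str
    context: str
    events: list = field(default_factory=list)
    rng_seed: Optional[int] = None

    def trials(self) -> list:
        """Events grouped by tiger-trial, in order."""
        out: dict = {}
        for ev in self.events:
            out.setdefault(ev.trial, []).append(ev)
        return [out[k] for k in sorted(out)]

    @property
    def n_trials(self) -> int:
        return sum(1 for tr in self.trials() if tr[-1].trial_ended)

    @property
    def total_score(self) -> float:
        return sum(ev.reward for ev in self.events)

    def validate(self) -> None:
        for tr in self.trials():
            sides = {ev.tiger_side for ev in tr}
            if len(sides) != 1:
                raise ValueError(
                    f"tiger side changed within trial {tr[0].trial}")
            for ev in tr[:-1]:
                if ev.trial_ended:
                    raise ValueError(
                        f"trial {ev.trial} has a non-final ending round")


# ---------------------------------------------------------------------------
# Agent protocol helpers
# ---------------------------------------------------------------------------

@dataclass
class AgentHistory:
    """What an agent is allowed to see when choosing: its own event stream."""

    payout: PayoutSpec
    p_growl: float
    p_creak: float
    events: list = field(default_factory=list)        # whole session so far
    trial_events: list = field(default_factory=list)  # current trial only


class Agent:
    """Base duck-type for simulated agents.

    Subclasses override :meth:`act` and, for the interactive task,
    :meth:`predict`. Stateful agents may also use the trial hooks.
    """

    def begin_session(self, history: AgentHistory, rng: np.random.Generator) -> None:
        pass

    def begin_trial(self, rng: np.random.Generator) -> None:
        pass

    def predict(self, history: AgentHistory, rng: np.random.Generator) -> Optional[str]:
        return None

    def act(self, history: AgentHistory, rng: np.random.Generator) -> str:
        raise NotImplementedError

    def observe(self, event: TrialEvent, rng: np.random.Generator) -> None:
        pass


class FixedAgent(Agent):
    """Always plays the same action (test and baseline plumbing)."""

    def __init__(self, action: str = L):
        self.action = action

    def act(self, history, rng):
        return self.action


class UniformRandomAgent(Agent):
    def act(self, history, rng):
        return ACTIONS[rng.integers(3)]

    def predict(self, history, rng):
        return ACTIONS[rng.integers(3)]


# ---------------------------------------------------------------------------
# Environment stepping
# ---------------------------------------------------------------------------

@dataclass
class EnvState:
    tiger_side: str
    trial: int = 0
    round_in_trial: int = 0
    round_index: int = 0


def draw_side(rng: np.random.Generator) -> str:
    return TL if rng.random() < 0.5 else TR


def step(state: EnvState, joint_actions: Sequence[Optional[str]],
         payout: PayoutSpec, rng: np.random.Generator,
         p_growl: float = 0.7, p_creak: float = 0.8,
         predictions: Sequence[Optional[str]] = (None, None)):
    """Advance the environment one round.

    ``joint_actions`` is ``(action_X, action_Y)``; ``action_Y`` is ``None``
    in the solo task. Returns ``(events, rewards, trial_ended)`` where
    ``events`` holds one :class:`TrialEvent` per agent. Social observations
    are emitted every dyadic round; a growl is emitted only to a listener in
    a round where no door was opened (an opening ends the trial and replaces
    the physical observation with the outcome).
    """
    aX, aY = joint_actions
    for a in (aX, aY):
        if a is not None and a not in ACTIONS:
            raise ValueError(f"agent returned an out-of-set action {a!r}")
    side = state.tiger_side
    trial_ended = aX in OPEN_ACTIONS or (aY in OPEN_ACTIONS if aY else False)

    if aY is None:
        rewards = (payout.reward(aX, None, side), 0.0)
    else:
        rX, rY = payout.joint(aX, aY, side)
        rewards = (rX, rY)

    events = []
    for i, (own, other, pred) in enumerate(
            ((aX, aY, predictions[0]), (aY, aX, predictions[1]))):
        if own is None:
            events.append(None)
            continue
        social = (sample_social_obs(other, p_creak, rng)
                  if other is not None else None)
        growl = (sample_physical_obs(side, p_growl, rng)
                 if own == L and not trial_ended else None)
        events.append(TrialEvent(
            trial=state.trial, round_index=state.round_in_trial,
            own_action=own, reward=rewards[i], tiger_side=side,
            prediction=pred, social_obs=social, physical_obs=growl,
            trial_ended=trial_ended))

    if trial_ended:
        state.tiger_side = draw_side(rng)
        state.trial += 1
        state.round_in_trial = 0
    else:
        state.round_in_trial += 1
    state.round_index += 1
    return events, rewards, trial_ended


def run_session(agentX: Agent, agentY: Optional[Agent], payout: PayoutSpec,
                n_trials: int = 10, rng: Optional[np.random.Generator] = None,
                p_growl: float = 0.7, p_creak: float = 0.8,
                agent_ids: Sequence[str] = ("X", "Y"),
                dyad_id: Optional[str] = None, session_index: int = 1,
                seed: Optional[int] = None,
                max_rounds_per_trial: int = 1000):
    """Simulate one session of ``n_trials`` tiger-trials.

    Returns a single :class:`SessionLog` in the solo task and a pair of
    coupled logs in the interactive task. Each agent only ever sees its own
    observation stream.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    solo = agentY is None
    state = EnvState(tiger_side=draw_side(rng))
    logs = [SessionLog(agent_ids[0], dyad_id, session_index, payout.variant,
                       payout.context, rng_seed=seed)]
    agents = [agentX]
    if not solo:
        logs.append(SessionLog(agent_ids[1], dyad_id, session_index,
                               payout.variant, payout.context, rng_seed=seed))
        agents.append(agentY)

    hists = [AgentHistory(payout, p_growl, p_creak) for _ in agents]
    for ag, h in zip(agents, hists):
        ag.begin_session(h, rng)
        ag.begin_trial(rng)

    while state.trial < n_trials:
        if state.round_in_trial >= max_rounds_per_trial:
            raise RuntimeError(
                f"trial {state.trial} exceeded {max_rounds_per_trial} rounds")
        preds = [None, None]
        if not solo:
            preds = [ag.predict(h, rng) for ag, h in zip(agents, hists)]
        actions = [ag.act(h, rng) for ag, h in zip(agents, hists)]
        if solo:
            actions.append(None)
        events, _, ended = step(state, actions, payout, rng,
                                p_growl=p_growl, p_creak=p_creak,
                                predictions=preds)
        for ag, h, log, ev in zip(agents, hists, logs, events):
            log.events.append(ev)
            h.events.append(ev)
            h.trial_events.append(ev)
            ag.observe(ev, rng)
        if ended:
            for ag, h in zip(agents, hists):
                h.trial_events = []
                ag.begin_trial(rng)

    for log in logs:
        log.validate()
    return logs[0] if solo else (logs[0], logs[1])
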