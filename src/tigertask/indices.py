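"""Behavioral indices computed from session logs.

All indices are defined identically for human participants, synthetic
participants, and model agents, so the same report can be produced for any
:class:`~tigertask.task_env.SessionLog`.

Choice indices: listen actions per tiger-trial, the evidence difference at
the trial's end, the fraction of correct (gold-door) opens, and — for dyads
— identical open actions and identical joint actions. Prediction indices
(interactive task only): listen predictions per trial, prediction accuracy,
logically consistent actions (own action equals the action predicted for
the partner), and the correctly-predicted subset of consistent actions.

Fractions are reported in [0, 1]; a presentation layer may multiply by 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task_env import (GL, GR, L, OPEN_ACTIONS, SessionLog, TL,
                       gold_action)

EVIDENCE_MODES = ("abs", "truth", "chosen")


def _trials(session: SessionLog) -> list:
    trials = [t for t in session.trials() if t]
    if not trials:
        raise ValueError("session contains no rounds")
    return trials


def _completed_trials(session: SessionLog) -> list:
    trials = [t for t in _trials(session) if t[-1].trial_ended]
    if not trials:
        raise ValueError("session contains no completed tiger-trials")
    return trials


def n_listen(session: SessionLog) -> float:
    """Mean number of this agent's listen actions per tiger-trial."""
    trials = _completed_trials(session)
    return float(np.mean([sum(1 for e in t if e.own_action == L)
                          for t in trials]))


def n_listen_predictions(session: SessionLog) -> float:
    """Mean number of predicted listen actions per tiger-trial."""
    trials = _completed_trials(session)
    if any(e.prediction is None for t in trials for e in t):
        raise ValueError("session carries no predictions (solo log?)")
    return float(np.mean([sum(1 for e in t if e.prediction == L)
                          for t in trials]))


def evidence_difference(session: SessionLog, mode: str = "abs") -> float:
    """Mean per-trial difference between growl counts from the two doors.

    Modes:

    * ``"abs"`` (default): |nGL - nGR| at the trial's end — the agent's
      realized evidence threshold. A net-evidence threshold-d agent scores
      exactly d on every trial it ends itself.
    * ``"truth"``: growls from the tiger's true side minus growls from the
      other side (wrong-side-heavy trials contribute negatively).
    * ``"chosen"``: signed toward the door the agent opened; trials ended
      by the partner fall back to the absolute difference.

    Trials with zero listens contribute 0.
    """
    if mode not in EVIDENCE_MODES:
        raise ValueError(f"mode must be one of {EVIDENCE_MODES}")
    trials = _completed_trials(session)
    vals = []
    for t in trials:
        growls = [e.physical_obs for e in t if e.physical_obs is not None]
        n_gl = growls.count(GL)
        n_gr = growls.count(GR)
        if mode == "abs":
            vals.append(abs(n_gl - n_gr))
        elif mode == "truth":
            tiger = t[0].tiger_side
            vals.append((n_gl - n_gr) if tiger == TL else (n_gr - n_gl))
        else:
            opened = t[-1].own_action if t[-1].own_action in OPEN_ACTIONS \
                else None
            if opened is None:
                vals.append(abs(n_gl - n_gr))
            else:
                # evidence supports the opened door when growls come from
                # the opposite side (growl left => tiger left => open right)
                vals.append((n_gr - n_gl) if opened == "OL" else (n_gl - n_gr))
    return float(np.mean(vals))


def correct_open(session: SessionLog) -> float:
    """Fraction of this agent's open actions that hit the gold door."""
    opens = [e for t in _trials(session) for e in t
             if e.own_action in OPEN_ACTIONS]
    if not opens:
        raise ValueError("session contains no open actions")
    hits = sum(1 for e in opens if e.own_action == gold_action(e.tiger_side))
    return hits / len(opens)


def total_score(session: SessionLog) -> float:
    return session.total_score


def _aligned_rounds(sessX: SessionLog, sessY: SessionLog) -> list:
    evX, evY = sessX.events, sessY.events
    if len(evX) != len(evY):
        raise ValueError(f"misaligned logs: {len(evX)} vs {len(evY)} rounds")
    for i, (a, b) in enumerate(zip(evX, evY)):
        if (a.trial, a.round_index) != (b.trial, b.round_index):
            raise ValueError(f"misaligned logs at round {i}")
    return list(zip(evX, evY))


def identical_actions(sessX: SessionLog, sessY: SessionLog) -> float:
    """Fraction of rounds on which both agents chose the same action."""
    rounds = _aligned_rounds(sessX, sessY)
    return sum(1 for a, b in rounds if a.own_action == b.own_action) \
        / len(rounds)


def identical_open(sessX: SessionLog, sessY: SessionLog) -> float:
    """Fraction of tiger-trials ending with both agents opening the same
    door on the ending round."""
    rounds = _aligned_rounds(sessX, sessY)
    ending = [(a, b) for a, b in rounds if a.trial_ended]
    if not ending:
        raise ValueError("no completed tiger-trials")
    same = sum(1 for a, b in ending
               if a.own_action in OPEN_ACTIONS
               and a.own_action == b.own_action)
    return same / len(ending)


def prediction_accuracy(session: SessionLog, partner: SessionLog) -> float:
    """Fraction of rounds where this agent's prediction matched the
    partner's actual action."""
    rounds = _aligned_rounds(session, partner)
    if any(a.prediction is None for a, _ in rounds):
        raise ValueError("session carries no predictions (solo log?)")
    return sum(1 for a, b in rounds if a.prediction == b.own_action) \
        / len(rounds)


def consistent_actions(session: SessionLog) -> float:
    """Fraction of rounds whose own action equals the action predicted for
    the partner (the identity reading of logical consistency)."""
    events = [e for t in _trials(session) for e in t]
    if any(e.prediction is None for e in events):
        raise ValueError("session carries no predictions (solo log?)")
    return sum(1 for e in events if e.own_action == e.prediction) \
        / len(events)


def correctly_predicted_consistent(session: SessionLog,
                                   partner: SessionLog) -> float:
    """Among consistent rounds, the fraction whose prediction was also
    correct; NaN (flagged) when there are no consistent rounds."""
    rounds = _aligned_rounds(session, partner)
    if any(a.prediction is None for a, _ in rounds):
        raise ValueError("session carries no predictions (solo log?)")
    consistent = [(a, b) for a, b in rounds if a.own_action == a.prediction]
    if not consistent:
        return math.nan
    return sum(1 for a, b in consistent if a.prediction == b.own_action) \
        / len(consistent)


@dataclass
class IndexReport:
    """Per-session values of every behavioral index.

    Dyadic and prediction indices are ``None`` for solo sessions.
    """

    agent_id: str
    session_index: int
    variant: str
    context: str
    n_listen: float
    evidence_difference: float
    correct_open: Optional[float]
    total_score: float
    n_listen_predictions: Optional[float] = None
    prediction_accuracy: Optional[float] = None
    consistent_actions: Optional[float] = None
    correctly_predicted_consistent: Optional[float] = None
    identical_open: Optional[float] = None
    identical_actions: Optional[float] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def index_report(session: SessionLog,
                 partner: Optional[SessionLog] = None) -> IndexReport:
    """All indices of one session; dyadic indices need the partner's log."""
    try:
        corr = correct_open(session)
    except ValueError:
        corr = None
    rep = IndexReport(
        agent_id=session.agent_id,
        session_index=session.session_index,
        variant=session.variant,
        context=session.context,
        n_listen=n_listen(session),
        evidence_difference=evidence_difference(session),
        correct_open=corr,
        total_score=session.total_score,
    )
    if partner is not None:
        rep.n_listen_predictions = n_listen_predictions(session)
        rep.prediction_accuracy = prediction_accuracy(session, partner)
        rep.consistent_actions = consistent_actions(session)
        rep.correctly_predicted_consistent = \
            correctly_predicted_consistent(session, partner)
        rep.identical_open = identical_open(session, partner)
        rep.identical_actions = identical_actions(session, partner)
    return rep


def learning_curves(reports: Sequence[IndexReport]) -> pd.DataFrame:
    """Per-session index series (sessions as columns), for the learning
    analyses; needs at least two distinct sessions."""
    if len({r.session_index for r in reports}) < 2:
        raise ValueError("learning curves need at least two sessions")
    df = pd.DataFrame([r.to_dict() for r in reports])
    value_cols = [c for c in df.columns
                  if c not in ("agent_id", "session_index", "variant",
                               "context")]
    return df.groupby("session_index")[value_cols].mean()


def reports_frame(reports: Sequence[IndexReport]) -> pd.DataFrame:
    """Tidy per-(agent, session) table of all indices, suitable for export
    to off-the-shelf mixed-model tooling."""
    return pd.DataFrame([r.to_dict() for r in reports])
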