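"""Human-like synthetic participants.

The undeposited human data are replaced by populations of *net-evidence
threshold agents*: each agent listens until the absolute difference between
left and right growls reaches its personal threshold ``d``, then opens the
door away from the believed tiger. Occasional lapses (uniform random
actions), a tendency to copy one's own prediction of the partner, simple
prediction strategies, and slow per-session drifts give the logs the
statistical structure the analysis pipeline assumes: cooperative
populations listen longer, accumulate more evidence, coordinate and predict
better than competitive ones, and their realized evidence thresholds sit
near the participant means reported for each task variant and context.

Population defaults (see :func:`make_population`) were chosen once to place
the population mean evidence-difference near the reported participant
values — about 2.05 for the modified solo task, 2.43 original solo, 2.32
cooperative and 1.56 competitive — with higher copy probabilities under
cooperation (consistency ~0.98 vs ~0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .task_env import (ACTIONS, CL, CR, GL, GR, L, OL, OPEN_ACTIONS, OR, S,
                       Agent, SessionLog, make_payout, run_session)

PREDICTION_STRATEGIES = ("creak_modal", "mirror_self", "uniform")


@dataclass
class ThresholdAgentParams:
    """Parameters of one synthetic participant."""

    evidence_threshold: int          # net-growl criterion d >= 1
    lapse: float = 0.02              # probability of a uniform random action
    copy_prob: float = 1.0           # prediction/action coupling, see below
    min_open_round: int = 0          # no opens before this round (convention)
    prediction_strategy: str = "mirror_self"
    d_drift: float = 0.0             # additive change to d per session
    copy_drift: float = 0.0          # additive change to copy_prob per session
    lapse_drift: float = 0.0         # additive change to lapse per session
    agent_id: str = "synthetic"

    def __post_init__(self):
        if self.evidence_threshold < 1:
            raise ValueError("evidence threshold must be >= 1")
        for p in (self.lapse, self.copy_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.min_open_round < 0:
            raise ValueError("min_open_round must be nonnegative")
        if self.prediction_strategy not in PREDICTION_STRATEGIES:
            raise ValueError(
                f"prediction_strategy must be one of {PREDICTION_STRATEGIES}")

    def at_session(self, session_index: int) -> "ThresholdAgentParams":
        """Parameters after (session_index - 1) sessions of drift."""
        k = session_index - 1
        d = max(1, int(round(self.evidence_threshold + k * self.d_drift)))
        c = float(np.clip(self.copy_prob + k * self.copy_drift, 0.0, 1.0))
        lap = float(np.clip(self.lapse + k * self.lapse_drift, 0.0, 1.0))
        return replace(self, evidence_threshold=d, copy_prob=c, lapse=lap,
                       d_drift=0.0, copy_drift=0.0, lapse_drift=0.0)


class ThresholdAgent(Agent):
    """Session-protocol agent driven by :class:`ThresholdAgentParams`.

    The intended action of a round is the threshold rule, withheld until
    ``min_open_round`` — the round convention through which cooperative
    agents synchronize joint door openings. ``copy_prob`` couples stated
    predictions and actions: a mirror-self predictor states its intended
    action with probability ``copy_prob`` (and a decoy otherwise — the
    unpredictable play of competitive participants); for the other
    prediction strategies it is the probability of enacting one's own
    open-prediction.
    """

    def __init__(self, params: ThresholdAgentParams):
        self.params = params
        self.net = 0           # (left growls - right growls) this trial
        self.round = 0
        self.creaks: list = []
        self._last_prediction: Optional[str] = None

    def begin_trial(self, rng):
        self.net = 0
        self.round = 0
        self.creaks = []
        self._last_prediction = None

    def _threshold_action(self) -> str:
        d = self.params.evidence_threshold
        if self.net >= d:
            return OR    # tiger believed left -> gold right
        if self.net <= -d:
            return OL
        return L

    def _intended_action(self) -> str:
        a = self._threshold_action()
        if a in OPEN_ACTIONS and self.round < self.params.min_open_round:
            return L    # holding to the dyad's opening-round convention
        return a

    def predict(self, history, rng) -> str:
        strat = self.params.prediction_strategy
        if strat == "uniform":
            pred = ACTIONS[rng.integers(3)]
        elif strat == "mirror_self":
            pred = self._intended_action()
            if rng.random() >= self.params.copy_prob:
                decoys = [a for a in ACTIONS if a != pred]
                pred = decoys[rng.integers(2)]
        else:  # creak_modal: most common signal class this trial, ties -> L
            counts = {S: 0, CL: 0, CR: 0}
            for c in self.creaks:
                counts[c] += 1
            best = max(counts.values())
            if counts[S] == best:
                pred = L
            elif counts[CL] == best:
                pred = OL
            else:
                pred = OR
        self._last_prediction = pred
        return pred

    def act(self, history, rng) -> str:
        intended = self._intended_action()
        if rng.random() < self.params.lapse:
            return ACTIONS[rng.integers(3)]
        pred = self._last_prediction
        if (pred in OPEN_ACTIONS
                and self.params.prediction_strategy != "mirror_self"
                and rng.random() < self.params.copy_prob):
            return pred
        return intended

    def observe(self, event, rng):
        if event.physical_obs == GL:
            self.net += 1
        elif event.physical_obs == GR:
            self.net -= 1
        if event.social_obs is not None:
            self.creaks.append(event.social_obs)
        self.round += 1


#: per-(variant, context) population defaults: mixture over evidence
#: thresholds, lapse, copy probability, prediction strategy, session drifts.
POPULATION_DEFAULTS: Dict[Tuple[str, str], dict] = {
    ("modified", "solo"): dict(
        d_mixture={2: 0.80, 3: 0.20}, lapse=0.02, copy_prob=1.0,
        prediction_strategy="mirror_self", d_drift=0.0, copy_drift=0.0),
    ("original", "solo"): dict(
        d_mixture={2: 0.40, 3: 0.60}, lapse=0.02, copy_prob=1.0,
        prediction_strategy="mirror_self", d_drift=0.0, copy_drift=0.0),
    ("modified", "cooperative"): dict(
        d_mixture={2: 0.40, 3: 0.60}, lapse=0.01, copy_prob=0.98,
        min_open_round=5, prediction_strategy="mirror_self",
        d_drift=-0.5, copy_drift=0.005),
    ("modified", "competitive"): dict(
        d_mixture={2: 0.50, 3: 0.50}, lapse=0.02, copy_prob=0.95,
        min_open_round=0, prediction_strategy="mirror_self",
        d_drift=0.0, copy_drift=-0.05, lapse_drift=0.04),
    ("original", "cooperative"): dict(
        d_mixture={3: 0.50, 4: 0.50}, lapse=0.01, copy_prob=0.98,
        min_open_round=6, prediction_strategy="mirror_self",
        d_drift=-0.5, copy_drift=0.005),
    ("original", "competitive"): dict(
        d_mixture={2: 0.50, 3: 0.50}, lapse=0.02, copy_prob=0.95,
        min_open_round=0, prediction_strategy="mirror_self",
        d_drift=0.0, copy_drift=-0.05, lapse_drift=0.04),
}


def make_population(context: str, variant: str, n_agents: int,
                    rng: np.random.Generator) -> List[ThresholdAgentParams]:
    """Draw a population of synthetic-participant parameters.

    Thresholds are drawn from the per-condition mixture in
    :data:`POPULATION_DEFAULTS`; dyadic contexts require an even number of
    agents.
    """
    key = (variant, context)
    if key not in POPULATION_DEFAULTS:
        raise ValueError(f"unknown (variant, context) pair {key}")
    if context != "solo" and n_agents % 2:
        raise ValueError("dyadic contexts need an even number of agents")
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    spec = POPULATION_DEFAULTS[key]
    ds = np.array(sorted(spec["d_mixture"]))
    probs = np.array([spec["d_mixture"][d] for d in ds], dtype=float)
    probs /= probs.sum()
    out = []
    for i in range(n_agents):
        d = int(rng.choice(ds, p=probs))
        out.append(ThresholdAgentParams(
            evidence_threshold=d, lapse=spec["lapse"],
            copy_prob=spec["copy_prob"],
            min_open_round=spec.get("min_open_round", 0),
            prediction_strategy=spec["prediction_strategy"],
            d_drift=spec["d_drift"], copy_drift=spec["copy_drift"],
            lapse_drift=spec.get("lapse_drift", 0.0),
            agent_id=f"{variant[:3]}-{context[:4]}-{i:03d}"))
    return out


@dataclass
class StudyConfig:
    """Size and conditions of a generated synthetic study."""

    variants: Sequence[str] = ("modified", "original")
    contexts: Sequence[str] = ("cooperative", "competitive")
    n_dyads: int = 31            # per (variant, context) cell
    n_sessions: int = 3
    n_trials: int = 10
    p_growl: float = 0.7
    p_creak: float = 0.8
    include_solo: bool = True


def generate_study(config: StudyConfig, rng: np.random.Generator):
    """Generate a full synthetic study.

    Every participant first completes solo sessions (if ``include_solo``)
    and each dyad then completes ``n_sessions`` interactive sessions of
    ``n_trials`` tiger-trials. Returns ``(logs, manifest)`` where
    ``manifest`` records the true generator parameters per agent for
    parameter-recovery tests.
    """
    logs: List[SessionLog] = []
    manifest: Dict[str, dict] = {}
    for variant in config.variants:
        for context in config.contexts:
            n_agents = 2 * config.n_dyads
            pop = make_population(context, variant, n_agents, rng)
            for p in pop:
                manifest[p.agent_id] = {
                    "evidence_threshold": p.evidence_threshold,
                    "lapse": p.lapse, "copy_prob": p.copy_prob,
                    "min_open_round": p.min_open_round,
                    "prediction_strategy": p.prediction_strategy,
                    "d_drift": p.d_drift, "copy_drift": p.copy_drift,
                    "lapse_drift": p.lapse_drift,
                    "variant": variant, "context": context,
                }
            if config.include_solo:
                solo_pay = make_payout(variant, "solo")
                for p in pop:
                    log = run_session(
                        ThresholdAgent(p), None, solo_pay,
                        n_trials=config.n_trials, rng=rng,
                        p_growl=config.p_growl, p_creak=config.p_creak,
                        agent_ids=(p.agent_id, ""), session_index=1)
                    logs.append(log)
            pay = make_payout(variant, context)
            for i in range(config.n_dyads):
                pX, pY = pop[2 * i], pop[2 * i + 1]
                dyad_id = f"{variant[:3]}-{context[:4]}-d{i:03d}"
                for s in range(1, config.n_sessions + 1):
                    lx, ly = run_session(
                        ThresholdAgent(pX.at_session(s)),
                        ThresholdAgent(pY.at_session(s)),
                        pay, n_trials=config.n_trials, rng=rng,
                        p_growl=config.p_growl, p_creak=config.p_creak,
                        agent_ids=(pX.agent_id, pY.agent_id),
                        dyad_id=dyad_id, session_index=s)
                    logs.extend([lx, ly])
    return logs, manifest
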