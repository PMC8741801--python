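"""Level-1 I-POMDP agents for the interactive Tiger Task.

An interactive POMDP augments the physical state with a model of the other
agent: the interactive state is the pair ``(tiger_side, other-agent
belief)``. A Level-1 agent models its counterpart as a Level-0 agent — by
default a solo noisy-rational POMDP agent that reasons only about the
physical observations — and maintains a posterior over interactive states
with an interactive particle filter. Each particle carries a hypothesis
about the tiger's side and about the belief the other agent has reached
through its own (unobserved) growl stream; particles are propagated by
sampling the other's growls, weighted by the likelihood of this agent's own
observations, and systematically resampled every round.

Action selection evaluates each own action at planning horizon 1 (current
round's expected payoff, marginalized over particles and the other's
predicted action distribution) or horizon 2 (adding a discounted exact
one-step lookahead over both agents' actions and the agent's own possible
observations), and passes the values through a quantal-response (softmax)
function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import pomdp
from .task_env import (ACTIONS, GL, GR, L, OPEN_ACTIONS, TL, TR, Agent,
                       PayoutSpec, make_payout, physical_obs_prob,
                       sample_physical_obs, sample_social_obs,
                       social_obs_prob)

_AIDX = {a: i for i, a in enumerate(ACTIONS)}


# ---------------------------------------------------------------------------
# Level-0 models of the counterpart
# ---------------------------------------------------------------------------

class Level0Model:
    """Model of the other agent as a Level-0 (no theory-of-mind) player.

    ``subintentional_fixed`` plays a fixed action distribution regardless
    of history (an unintentional player; uniform by default).
    ``pomdp_noisy`` treats the other as a solo POMDP agent on physical
    observations only, softened by a quantal-response function (a Level-0
    agent in the interactive hierarchy is essentially a POMDP agent).
    """

    def __init__(self, kind: str = "pomdp_noisy",
                 policy: Optional[pomdp.Policy] = None,
                 qre_lambda: float = 0.22,
                 probs: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)):
        if kind not in ("pomdp_noisy", "subintentional_fixed"):
            raise ValueError(f"unknown Level-0 kind {kind!r}")
        if kind == "pomdp_noisy" and policy is None:
            raise ValueError("pomdp_noisy Level-0 model needs a solo policy")
        self.kind = kind
        self.policy = policy
        self.qre_lambda = qre_lambda
        self.probs = np.asarray(probs, dtype=float)
        if self.kind == "subintentional_fixed":
            if self.probs.min() < 0 or abs(self.probs.sum() - 1) > 1e-9:
                raise ValueError("fixed action probabilities must be a "
                                 "distribution over (L, OL, OR)")

    def action_probs(self, beliefs: np.ndarray) -> np.ndarray:
        """(n, 3) action distribution (L, OL, OR order) at each belief."""
        beliefs = np.atleast_1d(np.asarray(beliefs, dtype=float))
        if self.kind == "subintentional_fixed":
            return np.tile(self.probs, (beliefs.size, 1))
        q = _q_values_array(self.policy, beliefs)
        z = self.qre_lambda * (q - q.max(axis=1, keepdims=True))
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def _q_values_array(policy: pomdp.Policy, b: np.ndarray) -> np.ndarray:
    """Vectorized Q(b, a) of a solved solo policy, columns in ACTIONS order."""
    b = np.asarray(b, dtype=float)
    arr = np.array([[a.v_tl, a.v_tr] for a in policy.alphas])

    def value(x):
        return (np.outer(arr[:, 0], x) + np.outer(arr[:, 1], 1 - x)).max(axis=0)

    v05 = value(np.array([0.5]))[0]
    pay = policy.payout
    q = np.empty((b.size, 3))
    for a in OPEN_ACTIONS:
        q[:, _AIDX[a]] = (b * pay.reward(a, None, TL)
                          + (1 - b) * pay.reward(a, None, TR)
                          + policy.gamma * v05)
    p = policy.p_growl
    p_gl = p * b + (1 - p) * (1 - b)
    b_gl = np.where(p_gl > 0, p * b / np.clip(p_gl, 1e-300, None), 0.5)
    b_gr = np.where(p_gl < 1,
                    (1 - p) * b / np.clip(1 - p_gl, 1e-300, None), 0.5)
    ev = p_gl * value(b_gl) + (1 - p_gl) * value(b_gr)
    q[:, _AIDX[L]] = pay.reward(L, None, TL) + policy.gamma * ev
    return q


def level0_action_probs(model: Level0Model, belief: float) -> Dict[str, float]:
    """Level-0 action distribution at one hypothesized belief of the other."""
    row = model.action_probs(np.array([belief]))[0]
    return {a: float(row[_AIDX[a]]) for a in ACTIONS}


# ---------------------------------------------------------------------------
# Configuration and particles
# ---------------------------------------------------------------------------

_solo_policy_cache: Dict[tuple, pomdp.Policy] = {}


def _solo_policy(variant: str, gamma: float, p_growl: float) -> pomdp.Policy:
    key = (variant, round(gamma, 12), round(p_growl, 12))
    if key not in _solo_policy_cache:
        _solo_policy_cache[key] = pomdp.solve(make_payout(variant, "solo"),
                                              gamma=gamma, p_growl=p_growl)
    return _solo_policy_cache[key]


@dataclass
class IPOMDPConfig:
    """Level-1 I-POMDP agent configuration.

    ``qre_lambda`` is the quantal-response inverse temperature of the
    agent's own action selection (the package's frozen calibration).
    ``level0_kind`` selects how the counterpart is modeled: the default
    ``subintentional_fixed`` treats it as an unintentional player with a
    fixed (uniform) action distribution; ``pomdp_noisy`` treats it as a
    solo noisy-rational POMDP agent, whose temperature ``level0_lambda``
    matches the solo behavioral model's frozen value.
    """

    payout: PayoutSpec
    horizon: int = 1
    level: int = 1
    n_particles: int = 1000
    qre_lambda: float = 2.0
    p_growl: float = 0.7
    p_creak: float = 0.8
    gamma: float = 0.95
    level0_kind: str = "subintentional_fixed"
    level0_lambda: float = 0.22
    level0_probs: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if self.horizon not in (1, 2):
            raise ValueError(f"horizon must be 1 or 2, got {self.horizon}")
        if self.level != 1:
            raise ValueError("only Level-1 agents are implemented")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.qre_lambda < 0:
            raise ValueError("qre_lambda must be nonnegative")
        if self.payout.is_solo:
            raise ValueError("interactive agents need a dyadic payout table")

    def make_level0(self) -> Level0Model:
        if self.level0_kind == "subintentional_fixed":
            return Level0Model("subintentional_fixed", probs=self.level0_probs)
        return Level0Model("pomdp_noisy",
                           policy=_solo_policy(self.payout.variant,
                                               self.gamma, self.p_growl),
                           qre_lambda=self.level0_lambda)


@dataclass
class ParticleSet:
    """Weighted hypotheses over interactive states (tiger side, other belief)."""

    tiger_left: np.ndarray   # bool
    other_belief: np.ndarray
    weights: np.ndarray

    @classmethod
    def prior(cls, n: int) -> "ParticleSet":
        # balanced initialization: exactly half the particles per side
        tl = np.zeros(n, dtype=bool)
        tl[: n // 2] = True
        return cls(tiger_left=tl,
                   other_belief=np.full(n, 0.5),
                   weights=np.full(n, 1.0 / n))

    @property
    def n(self) -> int:
        return self.weights.size

    def normalized(self) -> "ParticleSet":
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("total particle weight is zero")
        return ParticleSet(self.tiger_left, self.other_belief,
                           self.weights / total)

    def p_tiger_left(self) -> float:
        return float(self.weights[self.tiger_left].sum())

    def resample_systematic(self, n: int, rng: np.random.Generator) -> "ParticleSet":
        cum = np.cumsum(self.weights)
        cum /= cum[-1]
        u = (rng.random() + np.arange(n)) / n
        idx = np.searchsorted(cum, u)
        return ParticleSet(self.tiger_left[idx], self.other_belief[idx],
                           np.full(n, 1.0 / n))

    def copy(self) -> "ParticleSet":
        return ParticleSet(self.tiger_left.copy(), self.other_belief.copy(),
                           self.weights.copy())


# ---------------------------------------------------------------------------
# Interactive particle filter
# ---------------------------------------------------------------------------

def _propagate_other_belief(particles: ParticleSet, listened: np.ndarray,
                            p_growl: float, rng: np.random.Generator) -> None:
    """Sample the other's unobserved growl and Bayes-update its belief,
    for particles hypothesizing the other listened (in place)."""
    if not listened.any():
        return
    b = particles.other_belief[listened]
    tl = particles.tiger_left[listened]
    u = rng.random(b.size)
    growl_left = np.where(tl, u < p_growl, u < 1 - p_growl)
    like_l = np.where(growl_left, p_growl, 1 - p_growl)
    like_r = 1 - like_l
    particles.other_belief[listened] = like_l * b / (like_l * b
                                                     + like_r * (1 - b))


def ipf_update(particles: ParticleSet, own_action: str,
               social_obs: Optional[str], physical_obs: Optional[str],
               config: IPOMDPConfig, rng: np.random.Generator,
               level0: Optional[Level0Model] = None,
               trial_continues: bool = True) -> ParticleSet:
    """One round of the interactive particle filter.

    Each particle (i) draws the other's action from its Level-0 model at the
    particle's hypothesized belief, (ii) is weighted by the likelihood of
    the observed creak given that action, of the observed growl given the
    hypothesized tiger side, and of the public trial-continuation event (a
    continuing round proves nobody opened), (iii) propagates the other's
    belief with a sampled growl, and is then systematically resampled back
    to ``n_particles``. If every particle is inconsistent with the
    observations the set is rejuvenated from the prior with a warning.
    """
    level0 = level0 or config.make_level0()
    ps = particles.copy()
    probs = level0.action_probs(ps.other_belief)          # (n, 3)
    u = rng.random(ps.n)
    cum = np.cumsum(probs, axis=1)
    a_idx = (u[:, None] > cum).sum(axis=1)                # sampled other action
    w = ps.weights.copy()

    if social_obs is not None:
        like = np.array([social_obs_prob(social_obs, a, config.p_creak)
                         for a in ACTIONS])
        w *= like[a_idx]
    if physical_obs is not None:
        w *= np.where(ps.tiger_left,
                      physical_obs_prob(physical_obs, TL, config.p_growl),
                      physical_obs_prob(physical_obs, TR, config.p_growl))
    other_listened = a_idx == _AIDX[L]
    if trial_continues:
        w *= other_listened
    elif own_action == L:
        # the trial ended but this agent listened: the other must have opened
        w *= ~other_listened

    if w.sum() <= 0:
        warnings.warn("interactive particle filter weight collapse; "
                      "rejuvenating from the prior")
        return ParticleSet.prior(config.n_particles)

    ps.weights = w
    _propagate_other_belief(ps, other_listened, config.p_growl, rng)
    return ps.normalized().resample_systematic(config.n_particles, rng)


# ---------------------------------------------------------------------------
# Action valuation
# ---------------------------------------------------------------------------

def _immediate_values(particles: ParticleSet, payout: PayoutSpec,
                      other_probs: np.ndarray) -> np.ndarray:
    """Expected immediate payoff of each own action, marginalized over the
    particle posterior and the other's action distribution; ACTIONS order."""
    w = particles.weights
    tl = particles.tiger_left
    vals = np.empty(3)
    for a in ACTIONS:
        total = 0.0
        for a_oth in ACTIONS:
            r = np.where(tl, payout.reward(a, a_oth, TL),
                         payout.reward(a, a_oth, TR))
            total += float((w * other_probs[:, _AIDX[a_oth]] * r).sum())
        vals[_AIDX[a]] = total
    return vals


_fresh_value_cache: Dict[tuple, float] = {}


def _fresh_trial_value(config: IPOMDPConfig, level0: Level0Model) -> float:
    """Horizon-1 value of a freshly reset tiger-trial (belief 0.5 on both
    the tiger and the other's belief); the continuation value used after
    any door opening."""
    key = (config.payout.variant, config.payout.context, level0.qre_lambda,
           config.gamma, config.p_growl, config.p_creak, level0.kind)
    if key not in _fresh_value_cache:
        fresh = ParticleSet(tiger_left=np.array([True, False]),
                            other_belief=np.array([0.5, 0.5]),
                            weights=np.array([0.5, 0.5]))
        probs = level0.action_probs(fresh.other_belief)
        _fresh_value_cache[key] = float(
            _immediate_values(fresh, config.payout, probs).max())
    return _fresh_value_cache[key]


def action_values(particles: ParticleSet, config: IPOMDPConfig,
                  level0: Optional[Level0Model] = None,
                  horizon: Optional[int] = None) -> Dict[str, float]:
    """Value of each own action at planning horizon 1 or 2.

    Horizon 1 is the expected immediate payout. Horizon 2 adds the
    discounted expectation of the best next-round horizon-1 value,
    marginalized exactly over the other's action (open ends the trial and
    yields the fresh-trial continuation value) and, when both agents
    listen, over this agent's possible observations. The three creak
    signals and two growls give six observation branches; the creak
    branches share one posterior because mid-trial the creak likelihood
    P(signal | other listened) does not depend on the interactive state, so
    only the growl branches reweight the particles.
    """
    level0 = level0 or config.make_level0()
    horizon = config.horizon if horizon is None else horizon
    probs = level0.action_probs(particles.other_belief)
    imm = _immediate_values(particles, config.payout, probs)
    if horizon == 1:
        return {a: float(imm[_AIDX[a]]) for a in ACTIONS}
    if horizon != 2:
        raise ValueError(f"horizon must be 1 or 2, got {horizon}")

    v_fresh = _fresh_trial_value(config, level0)
    w = particles.weights
    p_other_listen = float((w * probs[:, _AIDX[L]]).sum())

    # posterior over interactive states given the other listened, with the
    # other's growl marginalized by splitting each particle in two
    if p_other_listen > 1e-12:
        w_l = w * probs[:, _AIDX[L]] / p_other_listen
        tl = particles.tiger_left
        b = particles.other_belief
        p = config.p_growl
        p_gl_other = np.where(tl, p, 1 - p)
        split_w = np.concatenate([w_l * p_gl_other, w_l * (1 - p_gl_other)])
        split_tl = np.concatenate([tl, tl])
        like_l = np.concatenate([np.full(b.size, p), np.full(b.size, 1 - p)])
        split_b = like_l * np.concatenate([b, b]) / (
            like_l * np.concatenate([b, b])
            + (1 - like_l) * (1 - np.concatenate([b, b])))
        cont = ParticleSet(split_tl, split_b, split_w)

        # own growl branches
        ev_listen = 0.0
        p_gl_own = np.where(cont.tiger_left, p, 1 - p)
        for like in (p_gl_own, 1 - p_gl_own):      # GL branch, GR branch
            bw = cont.weights * like
            pb = bw.sum()
            if pb <= 1e-15:
                continue
            post = ParticleSet(cont.tiger_left, cont.other_belief, bw / pb)
            post_probs = level0.action_probs(post.other_belief)
            ev_listen += pb * float(
                _immediate_values(post, config.payout, post_probs).max())
    else:
        ev_listen = 0.0

    out = {}
    for a in ACTIONS:
        if a in OPEN_ACTIONS:
            cont_val = v_fresh
        else:
            cont_val = ((1 - p_other_listen) * v_fresh
                        + p_other_listen * ev_listen)
        out[a] = float(imm[_AIDX[a]] + config.gamma * cont_val)
    return out


def qre_probs(values, lam: float):
    """Quantal-response choice probabilities (re-exported from the solo
    model so both agents share one definition)."""
    return pomdp.qre_probs(values, lam)


def predict_other(particles: ParticleSet, config: IPOMDPConfig,
                  level0: Optional[Level0Model] = None) -> str:
    """Modal predicted action of the other agent; ties resolve to listen."""
    level0 = level0 or config.make_level0()
    probs = level0.action_probs(particles.other_belief)
    marginal = particles.weights @ probs
    best = float(marginal.max())
    if marginal[_AIDX[L]] >= best - 1e-12:
        return L
    return ACTIONS[int(marginal.argmax())]


# ---------------------------------------------------------------------------
# Agents, dyads, replay
# ---------------------------------------------------------------------------

class IPOMDPAgent(Agent):
    """Session-protocol adapter around the Level-1 interactive model."""

    def __init__(self, config: IPOMDPConfig):
        self.config = config
        self.level0 = config.make_level0()
        self.particles = ParticleSet.prior(config.n_particles)

    def begin_trial(self, rng):
        self.particles = ParticleSet.prior(self.config.n_particles)

    def predict(self, history, rng):
        return predict_other(self.particles, self.config, self.level0)

    def act(self, history, rng):
        vals = action_values(self.particles, self.config, self.level0)
        p = qre_probs([vals[a] for a in ACTIONS], self.config.qre_lambda)
        return ACTIONS[rng.choice(3, p=p)]

    def observe(self, event, rng):
        if event.trial_ended:
            return  # particles reset at the next begin_trial
        self.particles = ipf_update(
            self.particles, event.own_action, event.social_obs,
            event.physical_obs, self.config, rng, level0=self.level0)


def simulate_dyad(configX: IPOMDPConfig, configY: IPOMDPConfig,
                  n_trials: int = 10,
                  rng: Optional[np.random.Generator] = None,
                  seed: Optional[int] = None, dyad_id: str = "dyad",
                  session_index: int = 1):
    """Simulate a coupled pair of Level-1 agents; returns paired SessionLogs."""
    from .task_env import run_session
    if (configX.payout.variant, configX.payout.context) != \
            (configY.payout.variant, configY.payout.context):
        raise ValueError("both agents must share the environment")
    if rng is None:
        rng = np.random.default_rng(seed)
    return run_session(IPOMDPAgent(configX), IPOMDPAgent(configY),
                       configX.payout, n_trials=n_trials, rng=rng,
                       p_growl=configX.p_growl, p_creak=configX.p_creak,
                       dyad_id=dyad_id, session_index=session_index,
                       seed=seed)


def replay_model(recorded_session, config: IPOMDPConfig,
                 n_completions: int = 30,
                 rng: Optional[np.random.Generator] = None,
                 cap: int = 100) -> List[dict]:
    """Score the interactive model against a recorded session.

    For each recorded tiger-trial the model is fed the participant's actual
    observation stream (creaks and growls) and chooses actions freely. If
    the model opens while recorded rounds remain, its listen count for the
    trial is the number of rounds it listened; when the recording ends
    first (the participant or partner ended the trial), the trial is
    continued with observations sampled from the task's channels (growls
    from the recorded tiger side; creaks for a still-listening partner)
    until the model opens. Because action selection is quantal-response the
    whole procedure is repeated ``n_completions`` times and averaged.

    Returns one dict per trial: ``{"nlisten", "evidence", "open_action"}``
    where ``evidence`` is the absolute growl-count difference the model had
    accumulated when it opened.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    level0 = config.make_level0()
    results = []
    for trial in recorded_session.trials():
        if not trial:
            raise ValueError("empty recorded trial")
        side = trial[0].tiger_side
        counts, evidences, opens = [], [], []
        for _ in range(n_completions):
            particles = ParticleSet.prior(config.n_particles)
            n_listen = 0
            n_gl = n_gr = 0
            opened = None
            for rnd in range(cap):
                vals = action_values(particles, config, level0)
                p = qre_probs([vals[a] for a in ACTIONS], config.qre_lambda)
                a = ACTIONS[rng.choice(3, p=p)]
                if a in OPEN_ACTIONS:
                    opened = a
                    break
                n_listen += 1
                if rnd < len(trial) and not trial[rnd].trial_ended:
                    ev = trial[rnd]
                    social, growl = ev.social_obs, ev.physical_obs
                    if growl is None:
                        growl = sample_physical_obs(side, config.p_growl, rng)
                else:
                    social = sample_social_obs(L, config.p_creak, rng)
                    growl = sample_physical_obs(side, config.p_growl, rng)
                n_gl += growl == GL
                n_gr += growl == GR
                particles = ipf_update(particles, L, social, growl, config,
                                       rng, level0=level0)
            counts.append(n_listen)
            evidences.append(abs(n_gl - n_gr))
            opens.append(opened)
        results.append({"nlisten": float(np.mean(counts)),
                        "evidence": float(np.mean(evidences)),
                        "open_action": opens[0]})
    return results
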