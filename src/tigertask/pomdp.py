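"""Exact solution of the single-agent tiger POMDP and the replay scorer.

The belief state is ``b = P(tiger behind the left door)``. Listening yields
a growl matching the tiger's side with accuracy ``p_growl`` and the belief
is updated by Bayes' rule; opening a door pays out, resets the world (tiger
re-randomized at 0.5) and hence the belief to 0.5.

The infinite-horizon discounted problem is solved by exact value iteration
on alpha-vectors (lines over the 1-D belief simplex), pruned to the upper
envelope each sweep. The induced policy is a symmetric pair of belief
thresholds: listen on an interval around 0.5, open at the extremes.

Two behavioral read-outs of a solved policy are provided:

* the deterministic threshold policy (``Policy.act``), whose mean listen
  count per trial obeys the exact two-sided first-passage law of a
  net-evidence threshold d (wrong-side crossings end trials too); and
* the noisy-rational model (:class:`QREPolicy`), which filters the solved
  action values through a quantal-response (softmax) function. The latter
  is the behavioral model scored against recorded sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .task_env import (ACTIONS, GL, GR, L, OL, OPEN_ACTIONS, OR, TL, TR,
                       Agent, PayoutSpec, sample_physical_obs)


# ---------------------------------------------------------------------------
# Beliefs
# ---------------------------------------------------------------------------

def belief_update(b: float, observation: str, p_growl: float) -> float:
    """Bayes posterior of P(tiger left) after one growl."""
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"belief must be in [0, 1], got {b}")
    if observation not in (GL, GR):
        raise ValueError(f"expected a growl observation, got {observation!r}")
    like_left = p_growl if observation == GL else 1 - p_growl
    like_right = 1 - like_left
    num = like_left * b
    den = num + like_right * (1 - b)
    return num / den


def belief_after_net(k: int, p_growl: float) -> float:
    """Belief after a net of ``k`` left-growls from a symmetric prior
    (odds-form posterior (p/(1-p))^k / (1 + (p/(1-p))^k))."""
    odds = (p_growl / (1 - p_growl)) ** k
    return odds / (1 + odds)


# ---------------------------------------------------------------------------
# Alpha vectors and the solver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaVector:
    """A linear value segment: value(b) = b*v_tl + (1-b)*v_tr."""

    action: str
    v_tl: float
    v_tr: float

    def value(self, b):
        return np.asarray(b) * self.v_tl + (1.0 - np.asarray(b)) * self.v_tr


_PRUNE_GRID = np.linspace(0.0, 1.0, 4097)


def _values_at(alphas: List[AlphaVector], b: np.ndarray) -> np.ndarray:
    arr = np.array([[a.v_tl, a.v_tr] for a in alphas])
    return np.outer(arr[:, 0], b) + np.outer(arr[:, 1], 1.0 - b)


def _upper_envelope(alphas: List[AlphaVector],
                    tol: float = 1e-9) -> List[AlphaVector]:
    """Prune to the vectors attaining the upper envelope over b in [0, 1].

    Pairwise-dominated vectors never win anywhere and are removed; among
    near-ties (within relative ``tol``, the epsilon-pruning that keeps the
    tiger problem's notorious crowd of near-duplicate vectors in check) one
    representative per winning belief region is kept.
    """
    if len(alphas) <= 1:
        return list(alphas)
    vals = _values_at(alphas, _PRUNE_GRID)
    scale = max(1.0, float(np.abs(vals).max()))
    winners = np.unique(np.round(vals / (scale * tol)).argmax(axis=0))
    return [alphas[i] for i in winners]


@dataclass
class Policy:
    """Solved tiger policy: alpha-vector set plus derived belief thresholds.

    ``b_low``/``b_high`` bound the listen region; the policy listens for
    beliefs strictly inside and opens outside, ties breaking toward opening.
    By mirror symmetry ``b_low == 1 - b_high``.
    """

    alphas: List[AlphaVector]
    gamma: float
    p_growl: float
    payout: PayoutSpec
    b_low: float = 0.0
    b_high: float = 1.0
    residual: float = 0.0
    iterations: int = 0

    def value(self, b):
        b = np.asarray(b, dtype=float)
        return np.max(np.stack([a.value(b) for a in self.alphas]), axis=0)

    def _open_reward(self, action: str, b: float) -> float:
        pay = self.payout
        return (b * pay.reward(action, None, TL)
                + (1 - b) * pay.reward(action, None, TR))

    def q_values(self, b: float) -> dict:
        """Q(b, a) for the three actions under the solved value function."""
        v05 = float(self.value(0.5))
        q = {}
        for a in OPEN_ACTIONS:
            q[a] = self._open_reward(a, b) + self.gamma * v05
        p = self.p_growl
        p_gl = p * b + (1 - p) * (1 - b)
        ev = 0.0
        for obs, pobs in ((GL, p_gl), (GR, 1 - p_gl)):
            if pobs > 0:
                ev += pobs * float(self.value(belief_update(b, obs, p)))
        q[L] = self.payout.reward(L, None, TL) + self.gamma * ev
        return q

    def act(self, b: float) -> str:
        """Deterministic optimal action; ties at a threshold open the door."""
        q = self.q_values(b)
        best_open = OR if q[OR] >= q[OL] else OL
        return L if q[L] > q[best_open] + 1e-12 else best_open

    @property
    def net_evidence_threshold(self) -> int:
        """Smallest net growl count d whose belief leaves the listen region."""
        d = 0
        while belief_after_net(d, self.p_growl) < self.b_high - 1e-12:
            d += 1
            if d > 1000:
                raise RuntimeError("listen region spans the whole simplex")
        return d

    def to_dict(self) -> dict:
        return {
            "alphas": [{"action": a.action, "v_tl": a.v_tl, "v_tr": a.v_tr}
                       for a in self.alphas],
            "gamma": self.gamma, "p_growl": self.p_growl,
            "b_low": self.b_low, "b_high": self.b_high,
            "variant": self.payout.variant,
        }


def _backup(alphas: List[AlphaVector], payout: PayoutSpec, gamma: float,
            p: float, prune_tol: float = 1e-9) -> List[AlphaVector]:
    """One alpha-vector backup sweep.

    Listen vectors are built from observation-conditional maximizer pairs:
    for each belief on a dense grid, the growl-left and growl-right
    posteriors select their best current vectors, and each distinct
    ``(GL-choice, GR-choice)`` pair contributes one candidate. This
    enumerates exactly the pairs that are optimal somewhere on the grid —
    the useful vectors of the exact cross-sum backup — without forming the
    full |Gamma|^2 cross product.
    """
    v05 = max(a.value(0.5) for a in alphas)
    out = []
    for a in OPEN_ACTIONS:
        out.append(AlphaVector(a,
                               payout.reward(a, None, TL) + gamma * v05,
                               payout.reward(a, None, TR) + gamma * v05))
    r_listen = payout.reward(L, None, TL)
    arr = np.array([[a.v_tl, a.v_tr] for a in alphas])
    b = _PRUNE_GRID
    # P(GL | TL) = p, P(GL | TR) = 1 - p; state unchanged by listening.
    p_gl = p * b + (1 - p) * (1 - b)
    b_gl = np.where(p_gl > 0, p * b / np.clip(p_gl, 1e-300, None), 0.5)
    b_gr = np.where(p_gl < 1, (1 - p) * b / np.clip(1 - p_gl, 1e-300, None), 0.5)
    w_gl = _values_at(alphas, b_gl).argmax(axis=0)
    w_gr = _values_at(alphas, b_gr).argmax(axis=0)
    pairs = np.unique(np.column_stack([w_gl, w_gr]), axis=0)
    v_tl = r_listen + gamma * (p * arr[pairs[:, 0], 0]
                               + (1 - p) * arr[pairs[:, 1], 0])
    v_tr = r_listen + gamma * ((1 - p) * arr[pairs[:, 0], 1]
                               + p * arr[pairs[:, 1], 1])
    out.extend(AlphaVector(L, tl, tr) for tl, tr in zip(v_tl, v_tr))
    return _upper_envelope(out, prune_tol)


def solve(payout: PayoutSpec, gamma: float = 0.95, p_growl: float = 0.7,
          tolerance: float = 1e-6, max_iter: int = 20000,
          horizon: Optional[int] = None,
          prune_tol: Optional[float] = None) -> Policy:
    """Solve the solo tiger POMDP by alpha-vector value iteration.

    With ``horizon=None`` sweeps continue until the value function changes
    by less than ``tolerance`` in sup-norm; a finite ``horizon`` performs
    exactly that many backups from the zero value function (used by the
    expectimax cross-check, with much tighter pruning since the small
    finite-horizon vector sets need no epsilon control).
    """
    if not payout.is_solo:
        raise ValueError("solve() expects a solo payout table")
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    if prune_tol is None:
        prune_tol = 1e-9 if horizon is None else 1e-13
    grid = np.linspace(0.0, 1.0, 2049)
    alphas = [AlphaVector(L, 0.0, 0.0)]
    vals = np.zeros_like(grid)
    residual = math.inf
    n_iter = max_iter if horizon is None else horizon
    it = 0
    for it in range(1, n_iter + 1):
        alphas = _backup(alphas, payout, gamma, p_growl, prune_tol)
        new = np.max(np.stack([a.value(grid) for a in alphas]), axis=0)
        residual = float(np.max(np.abs(new - vals)))
        vals = new
        if horizon is None and residual < tolerance:
            break
    else:
        if horizon is None:
            raise RuntimeError(
                f"value iteration did not converge in {max_iter} sweeps "
                f"(residual {residual:.3e})")

    pol = Policy(alphas=alphas, gamma=gamma, p_growl=p_growl, payout=payout,
                 residual=residual, iterations=it)
    pol.b_low, pol.b_high = _listen_thresholds(pol, grid)
    return pol


def _listen_thresholds(pol: Policy, grid) -> Tuple[float, float]:
    listen = np.array([pol.act(b) == L for b in grid])
    if not listen.any():
        return 0.5, 0.5
    lo_i, hi_i = np.where(listen)[0][[0, -1]]

    def bisect(b_open, b_listen):
        # returns the open-side bracket end, so act(threshold) opens
        for _ in range(60):
            mid = 0.5 * (b_open + b_listen)
            if pol.act(mid) == L:
                b_listen = mid
            else:
                b_open = mid
        return b_open

    lo = bisect(grid[max(lo_i - 1, 0)], grid[lo_i]) if lo_i > 0 else 0.0
    hi = bisect(grid[min(hi_i + 1, len(grid) - 1)], grid[hi_i]) \
        if hi_i < len(grid) - 1 else 1.0
    return lo, hi


def solve_on_grid(payout: PayoutSpec, gamma: float = 0.95,
                  p_growl: float = 0.7, n_grid: int = 10001,
                  tolerance: float = 1e-10, max_iter: int = 20000):
    """Independent belief-grid value-iteration cross-check.

    Returns ``(grid, V)``; used in tests to validate the alpha-vector
    solver, never as the primary solution path.
    """
    b = np.linspace(0.0, 1.0, n_grid)
    V = np.zeros(n_grid)
    p = p_growl
    p_gl = p * b + (1 - p) * (1 - b)
    b_gl = np.divide(p * b, np.clip(p_gl, 1e-300, None))
    b_gr = np.divide((1 - p) * b, np.clip(1 - p_gl, 1e-300, None))
    r_or = b * payout.reward(OR, None, TL) + (1 - b) * payout.reward(OR, None, TR)
    r_ol = b * payout.reward(OL, None, TL) + (1 - b) * payout.reward(OL, None, TR)
    r_listen = payout.reward(L, None, TL)
    i05 = n_grid // 2
    for _ in range(max_iter):
        ev = p_gl * np.interp(b_gl, b, V) + (1 - p_gl) * np.interp(b_gr, b, V)
        new = np.maximum(r_listen + gamma * ev,
                         np.maximum(r_or, r_ol) + gamma * V[i05])
        if np.max(np.abs(new - V)) < tolerance:
            V = new
            break
        V = new
    return b, V


def expectimax_value(payout: PayoutSpec, b: float, horizon: int,
                     gamma: float = 0.95, p_growl: float = 0.7) -> float:
    """Brute-force finite-horizon value by enumeration over observation
    sequences; independent oracle for the alpha-vector backup (small h)."""
    if horizon == 0:
        return 0.0
    best = -math.inf
    for a in ACTIONS:
        r = (b * payout.reward(a, None, TL)
             + (1 - b) * payout.reward(a, None, TR))
        if a in OPEN_ACTIONS:
            q = r + gamma * expectimax_value(payout, 0.5, horizon - 1,
                                             gamma, p_growl)
        else:
            p_gl = p_growl * b + (1 - p_growl) * (1 - b)
            q = r
            for obs, pobs in ((GL, p_gl), (GR, 1 - p_gl)):
                if pobs > 0:
                    q += gamma * pobs * expectimax_value(
                        payout, belief_update(b, obs, p_growl), horizon - 1,
                        gamma, p_growl)
        best = max(best, q)
    return best


# ---------------------------------------------------------------------------
# Noisy-rational (QRE) read-out
# ---------------------------------------------------------------------------

def qre_probs(values: Sequence[float], lam: float) -> np.ndarray:
    """Quantal-response (softmax) choice probabilities with inverse
    temperature ``lam``; invariant to adding a constant to all values."""
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("action values must be finite")
    z = lam * (v - v.max())
    e = np.exp(z)
    return e / e.sum()


class QREPolicy:
    """The solved policy filtered through a quantal-response function.

    Beliefs are mapped to action probabilities via a softmax over the
    optimal action values; this is the behavioral model whose simulated
    listen counts are compared with recorded sessions.
    """

    def __init__(self, policy: Policy, qre_lambda: float):
        if qre_lambda < 0:
            raise ValueError("qre_lambda must be nonnegative")
        self.policy = policy
        self.qre_lambda = qre_lambda
        self._cache: dict = {}

    @property
    def p_growl(self) -> float:
        return self.policy.p_growl

    def action_probs(self, b: float) -> Tuple[Tuple[str, ...], np.ndarray]:
        key = round(b, 12)
        if key not in self._cache:
            q = self.policy.q_values(b)
            self._cache[key] = qre_probs([q[a] for a in ACTIONS],
                                         self.qre_lambda)
        return ACTIONS, self._cache[key]

    def act(self, b: float, rng: np.random.Generator) -> str:
        acts, probs = self.action_probs(b)
        return acts[rng.choice(len(acts), p=probs)]


# ---------------------------------------------------------------------------
# Simulation and replay
# ---------------------------------------------------------------------------

def _policy_act(policy, b, rng):
    if isinstance(policy, QREPolicy):
        return policy.act(b, rng)
    return policy.act(b)


def _run_trial(policy, tiger_side: str, rng: np.random.Generator,
               recorded_growls: Sequence[str] = (), cap: int = 100,
               env_p_growl: Optional[float] = None):
    """Walk one tiger-trial; returns (n_listen, opened_action, censored).

    Recorded growls are consumed first; once exhausted, fresh growls are
    sampled given the true tiger side. ``env_p_growl`` lets the environment
    accuracy differ from the accuracy the policy assumes.
    """
    p = policy.p_growl
    env_p = p if env_p_growl is None else env_p_growl
    b = 0.5
    n = 0
    while n < cap:
        a = _policy_act(policy, b, rng)
        if a in OPEN_ACTIONS:
            return n, a, False
        if n < len(recorded_growls):
            obs = recorded_growls[n]
        else:
            obs = sample_physical_obs(tiger_side, env_p, rng)
        b = belief_update(b, obs, p)
        n += 1
    return n, None, True


def replay_nlisten(policy, recorded_trial, n_completions: int = 30,
                   rng: Optional[np.random.Generator] = None) -> float:
    """Optimal-agent listen count for one recorded tiger-trial.

    ``recorded_trial`` carries the participant's growl sequence and the true
    tiger side (a ``(growls, tiger_side)`` pair or a list of
    :class:`~tigertask.task_env.TrialEvent`). If the policy opens at or
    before the recorded open, its own listen count is returned (for the
    deterministic policy this consumes no randomness). Otherwise the trial
    is continued with freshly sampled growls, ``n_completions`` times, and
    the mean listen count over completions is returned.
    """
    if isinstance(recorded_trial, tuple):
        growls, side = recorded_trial
    else:
        events = list(recorded_trial)
        if not events:
            raise ValueError("empty recorded trial")
        side = events[0].tiger_side
        growls = [ev.physical_obs for ev in events if ev.physical_obs]
    growls = list(growls)

    deterministic = not isinstance(policy, QREPolicy)
    if deterministic:
        n, opened, censored = _run_trial(policy, side, np.random.default_rng(0),
                                         recorded_growls=growls,
                                         cap=len(growls))
        if opened is not None:
            return float(n)
    if rng is None:
        raise ValueError("rng is required when completions must be sampled")
    counts = []
    for _ in range(n_completions):
        n, opened, censored = _run_trial(policy, side, rng,
                                         recorded_growls=growls)
        if not censored:
            counts.append(n)
    if not counts:
        raise RuntimeError("all completions hit the round cap")
    return float(np.mean(counts))


def replay_session(policy, session, n_completions: int = 30,
                   rng: Optional[np.random.Generator] = None) -> list:
    """Per-trial optimal listen counts for a recorded solo session."""
    return [replay_nlisten(policy, tr, n_completions, rng)
            for tr in session.trials()]


def mean_optimal_nlisten(policy, p_growl: Optional[float] = None,
                         n_trials: int = 500,
                         rng: Optional[np.random.Generator] = None,
                         cap: int = 100) -> dict:
    """Mean listens/trial of the policy acting in a fresh environment.

    Returns ``{"mean", "se", "n", "n_censored"}``; trials hitting the round
    cap are flagged and excluded from the mean.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    counts = []
    n_censored = 0
    for _ in range(n_trials):
        side = TL if rng.random() < 0.5 else TR
        n, opened, censored = _run_trial(policy, side, rng, cap=cap,
                                         env_p_growl=p_growl)
        if censored:
            n_censored += 1
        else:
            counts.append(n)
    counts = np.asarray(counts, dtype=float)
    mean = float(counts.mean()) if counts.size else math.nan
    se = float(counts.std(ddof=1) / math.sqrt(counts.size)) \
        if counts.size > 1 else math.nan
    return {"mean": mean, "se": se, "n": int(counts.size),
            "n_censored": n_censored}


class POMDPAgent(Agent):
    """Session-protocol adapter: tracks its belief from its own growls and
    acts by the (deterministic or QRE) policy."""

    def __init__(self, policy):
        self.policy = policy
        self.b = 0.5

    def begin_trial(self, rng):
        self.b = 0.5

    def act(self, history, rng):
        return _policy_act(self.policy, self.b, rng)

    def observe(self, event, rng):
        if event.physical_obs is not None:
            self.b = belief_update(self.b, event.physical_obs,
                                   self.policy.p_growl)
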