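"""Replay the optimal models against recorded sessions.

The reference analysis of this task family scores each model by feeding it the observation
stream a participant actually experienced: when the model opens first, its
listen count stands; when the recording ends first, the trial is completed
with freshly sampled observations (30 completions) and the counts averaged.
Here synthetic participants stand in for the undeposited human data.
"""

import numpy as np

from tigertask import pomdp
from tigertask.config import QRE_LAMBDA_SOLO
from tigertask.ipomdp import IPOMDPConfig, replay_model
from tigertask.synthetic_participants import (ThresholdAgent,
                                              ThresholdAgentParams)
from tigertask.task_env import make_payout, run_session

rng = np.random.default_rng(5)

# --- solo: noisy-rational POMDP model vs a threshold-2 participant -------
pay = make_payout("modified", "solo")
participant = run_session(ThresholdAgent(ThresholdAgentParams(2)), None,
                          pay, n_trials=10, rng=rng)
model = pomdp.QREPolicy(pomdp.solve(pay), QRE_LAMBDA_SOLO)
counts = pomdp.replay_session(model, participant, n_completions=30, rng=rng)
print(f"solo modified: participant {np.mean([sum(e.own_action == 'L' for e in t) for t in participant.trials()]):.2f} "
      f"listens/trial, model {np.mean(counts):.2f}")

# --- interactive: Level-1 horizon-2 model over the same kind of stream ---
icfg = IPOMDPConfig(payout=make_payout("modified", "competitive"),
                    horizon=2, n_particles=500)
dyad_member = run_session(
    ThresholdAgent(ThresholdAgentParams(2)),
    ThresholdAgent(ThresholdAgentParams(2)),
    make_payout("modified", "competitive"), n_trials=5, rng=rng)[0]
res = replay_model(dyad_member, icfg, n_completions=10, rng=rng)
print("competitive L1H2 per-trial model listens:",
      [round(r["nlisten"], 1) for r in res])

# Each value is the model's own stopping time given the recorded growls
# and creaks; differences from the participant's counts quantify the
# departure from (noisy-)optimal evidence gathering.
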