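"""Session event-log CSV reading and writing.

One row per (agent, round):

    dyad_id, agent_id, session, trial, round, variant, context, prediction,
    action, social_obs, physical_obs, tiger_side, reward, cum_score, rt_ms,
    forced, seed

Missing values (solo predictions, suppressed growls) serialize as empty
fields. The dialect is comma-separated UTF-8 with LF line endings and a
mandatory header; a write/read round-trip is lossless.
"""

from __future__ import annotations

import math
from typing import List, Sequence

import pandas as pd

from .task_env import (ACTIONS, CREAKS, GROWLS, SIDES, SessionLog,
                       TrialEvent)

COLUMNS = ["dyad_id", "agent_id", "session", "trial", "round", "variant",
           "context", "prediction", "action", "social_obs", "physical_obs",
           "tiger_side", "reward", "cum_score", "rt_ms", "forced", "seed"]

_CODE_SETS = {
    "prediction": set(ACTIONS),
    "action": set(ACTIONS),
    "social_obs": set(CREAKS),
    "physical_obs": set(GROWLS),
    "tiger_side": set(SIDES),
}


def sessions_to_frame(logs: Sequence[SessionLog]) -> pd.DataFrame:
    """Flatten session logs into the tidy event table."""
    rows = []
    for log in logs:
        cum = 0.0
        for ev in log.events:
            cum += ev.reward
            rows.append({
                "dyad_id": log.dyad_id or "",
                "agent_id": log.agent_id,
                "session": log.session_index,
                "trial": ev.trial,
                "round": ev.round_index,
                "variant": log.variant,
                "context": log.context,
                "prediction": ev.prediction or "",
                "action": ev.own_action,
                "social_obs": ev.social_obs or "",
                "physical_obs": ev.physical_obs or "",
                "tiger_side": ev.tiger_side,
                "reward": ev.reward,
                "cum_score": cum,
                "rt_ms": "" if ev.rt_ms is None else ev.rt_ms,
                "forced": int(ev.forced),
                "seed": "" if log.rng_seed is None else log.rng_seed,
            })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_session_csv(logs: Sequence[SessionLog], path) -> None:
    sessions_to_frame(logs).to_csv(path, index=False, lineterminator="\n")


def _parse_optional(value, row: int, column: str):
    if value is None or (isinstance(value, float) and math.isnan(value)) \
            or value == "":
        return None
    value = str(value)
    allowed = _CODE_SETS[column]
    if value not in allowed:
        raise ValueError(
            f"row {row}: invalid {column} code {value!r} "
            f"(expected one of {sorted(allowed)})")
    return value


def read_session_csv(path) -> List[SessionLog]:
    """Read an event-log CSV back into session logs.

    Invalid codes and non-contiguous round indices are rejected with the
    offending row number (0-based data row, as in the file minus header).
    An empty file yields an empty list.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    logs: List[SessionLog] = []
    for (dyad, agent, sess, variant, context, seed), g in df.groupby(
            ["dyad_id", "agent_id", "session", "variant", "context", "seed"],
            sort=False):
        log = SessionLog(
            agent_id=agent, dyad_id=dyad or None, session_index=int(sess),
            variant=variant, context=context,
            rng_seed=None if seed == "" else int(seed))
        prev = {}
        for row_idx, row in g.iterrows():
            trial = int(row["trial"])
            rnd = int(row["round"])
            expected = prev.get(trial, -1) + 1
            if rnd != expected:
                raise ValueError(
                    f"row {row_idx}: non-contiguous round index {rnd} "
                    f"in trial {trial} (expected {expected})")
            prev[trial] = rnd
            action = row["action"]
            if action not in ACTIONS:
                raise ValueError(f"row {row_idx}: invalid action code "
                                 f"{action!r}")
            side = row["tiger_side"]
            if side not in SIDES:
                raise ValueError(f"row {row_idx}: invalid tiger_side code "
                                 f"{side!r}")
            log.events.append(TrialEvent(
                trial=trial, round_index=rnd, own_action=action,
                reward=float(row["reward"]), tiger_side=side,
                prediction=_parse_optional(row["prediction"], row_idx,
                                           "prediction"),
                social_obs=_parse_optional(row["social_obs"], row_idx,
                                           "social_obs"),
                physical_obs=_parse_optional(row["physical_obs"], row_idx,
                                             "physical_obs"),
                rt_ms=None if row["rt_ms"] == "" else float(row["rt_ms"]),
                forced=bool(int(row["forced"])) if row["forced"] != "" else False,
            ))
        # ending rounds: a trial ends when its last round opened a door or
        # the next trial index begins
        for i, ev in enumerate(log.events):
            nxt = log.events[i + 1] if i + 1 < len(log.events) else None
            ev.trial_ended = nxt is None or nxt.trial != ev.trial
        logs.append(log)
    return logs
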