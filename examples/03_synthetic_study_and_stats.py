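"""Generate a synthetic-participant study and run the inferential pipeline.

Creates cooperative and competitive dyads of threshold agents, writes and
re-reads the session CSV, computes per-agent behavioral indices, and
compares contexts with Welch t-tests under the Bonferroni gate.
"""

import numpy as np

from tigertask import indices, stats
from tigertask.session_io import read_session_csv, write_session_csv
from tigertask.synthetic_participants import StudyConfig, generate_study

cfg = StudyConfig(variants=("modified",),
                  contexts=("cooperative", "competitive"), n_dyads=12,
                  n_sessions=3, include_solo=False)
logs, manifest = generate_study(cfg, np.random.default_rng(2))
write_session_csv(logs, "/tmp/synthetic_sessions.csv")
logs = read_session_csv("/tmp/synthetic_sessions.csv")

pairs = {}
for log in logs:
    pairs.setdefault((log.dyad_id, log.session_index), []).append(log)
reports = []
for pair in pairs.values():
    reports.append(indices.index_report(pair[0], pair[1]))
    reports.append(indices.index_report(pair[1], pair[0]))

for name in ("n_listen", "evidence_difference", "prediction_accuracy",
             "consistent_actions"):
    coop = [getattr(r, name) for r in reports if r.context == "cooperative"]
    comp = [getattr(r, name) for r in reports if r.context == "competitive"]
    res = stats.welch_t(coop, comp)
    flag = "*" if stats.bonferroni_gate(res.p) else " "
    print(f"{name:>22}: coop {np.mean(coop):5.2f} vs comp "
          f"{np.mean(comp):5.2f}  t({res.df:5.1f}) = {res.t:6.2f}, "
          f"p = {res.p:.2e}{flag}  d = {res.cohen_d:.2f}")

# Cooperative populations listen longer, gather more evidence, and predict
# their partner better; the asterisk marks context differences surviving
# the Bonferroni-corrected threshold (0.05/8).
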