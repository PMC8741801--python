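"""Shared fixtures: solved policies are expensive, so they are built once
per session; an exact first-passage oracle for threshold-stopping walks is
provided for cross-checks."""

from __future__ import annotations

import numpy as np
import pytest

from tigertask import pomdp
from tigertask.task_env import make_payout


@pytest.fixture(scope="session")
def policy_modified():
    return pomdp.solve(make_payout("modified", "solo"), gamma=0.95,
                       p_growl=0.7)


@pytest.fixture(scope="session")
def policy_original():
    return pomdp.solve(make_payout("original", "solo"), gamma=0.95,
                       p_growl=0.7)


def exact_mean_first_passage(d: int, p: float) -> float:
    """Expected steps of a +/-1 random walk (step +1 w.p. p) started at 0
    and absorbed at +/-d, via a linear-system solve (independent oracle)."""
    n = 2 * d - 1  # transient states -d+1 .. d-1
    A = np.eye(n)
    b = np.ones(n)
    for i in range(n):
        if i + 1 < n:
            A[i, i + 1] -= p
        if i - 1 >= 0:
            A[i, i - 1] -= 1 - p
    return float(np.linalg.solve(A, b)[d - 1])


@pytest.fixture(scope="session")
def first_passage_oracle():
    return exact_mean_first_passage
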