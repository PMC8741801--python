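"""Inferential statistics used by the analysis pipeline.

Welch's two-sample t-test (with Satterthwaite degrees of freedom, a 95%
confidence interval for the mean difference, and Cohen's d on the pooled
standard deviation), the Bonferroni significance gate, and the Fisher
z-test for the difference between two correlation coefficients,

    z_observed = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)),

judged against the +/-1.96 critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    ci95: Tuple[float, float]
    cohen_d: float
    mean_diff: float
    degenerate: bool = False  # zero pooled variance


@dataclass(frozen=True)
class FisherZResult:
    z_observed: float
    significant: bool


def welch_t(sample1: Sequence[float], sample2: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test of ``mean(sample1) - mean(sample2)``.

    Cohen's d uses the pooled standard deviation. Samples with zero total
    variance are flagged degenerate (infinite t).
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    diff = float(x.mean() - y.mean())
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = x.size, y.size
    pooled = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if v1 == 0 and v2 == 0:
        t = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
        return WelchResult(t=t, df=float(n1 + n2 - 2),
                           p=1.0 if diff == 0 else 0.0,
                           ci95=(diff, diff), cohen_d=math.nan,
                           mean_diff=diff, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False)
    df = float(res.df)
    se = math.sqrt(v1 / n1 + v2 / n2)
    half = sps.t.ppf(0.975, df) * se
    d = diff / pooled if pooled > 0 else math.nan
    return WelchResult(t=float(res.statistic), df=df, p=float(res.pvalue),
                       ci95=(diff - half, diff + half), cohen_d=d,
                       mean_diff=diff)


def bonferroni_gate(p: float, m: int = 8, alpha: float = 0.05) -> bool:
    """True iff ``p`` survives the Bonferroni-corrected threshold
    ``alpha / m`` (strict inequality; the default 0.05/8 gives p < 0.00625)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < alpha / m


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int,
                     critical: float = 1.96) -> FisherZResult:
    """Compare two independent correlation coefficients via Fisher's
    z-transformation; significance when |z| exceeds ``critical``."""
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError(f"correlations must lie strictly in (-1, 1), got {r}")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError(f"sample sizes must exceed 3, got {n}")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return FisherZResult(z_observed=z, significant=abs(z) > critical)
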