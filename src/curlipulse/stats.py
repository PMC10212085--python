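"""Inferential statistics used across the package.

Two small tools: the unpaired two-sample t-test assuming normal distributions
with unknown and unequal variances (Welch's test), used to compare induction
features between strains, and the replicate mean +/- SEM summary used for
fractions of positive cells across biological replicates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

__all__ = ["WelchResult", "welch_t_test", "replicate_sem"]


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    dof: float          # Welch-Satterthwaite degrees of freedom
    p_value: float      # two-sided
    n1: int
    n2: int


def welch_t_test(x: np.ndarray, y: np.ndarray) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean x - mean y) / sqrt(s1^2/n1 + s2^2/n2), with degrees of freedom
    from the Welch-Satterthwaite approximation. Two samples that are both
    constant with equal means yield t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("welch_t_test: need >= 2 values per sample")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("welch_t_test: non-finite values")
    v1 = x.var(ddof=1) / n1
    v2 = y.var(ddof=1) / n2
    se2 = v1 + v2
    if se2 == 0.0:
        t = 0.0 if x.mean() == y.mean() else math.inf * math.copysign(1, x.mean() - y.mean())
        dof = float(n1 + n2 - 2)
        p = 1.0 if t == 0.0 else 0.0
        return WelchResult(t, dof, p, n1, n2)
    t = float((x.mean() - y.mean()) / math.sqrt(se2))
    dof = float(se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1)))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return WelchResult(t, dof, p, n1, n2)


def replicate_sem(values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error of the mean across biological replicates.

    SEM uses the (n-1) sample standard deviation over sqrt(n); a single
    replicate has SEM 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("replicate_sem: empty input")
    mean = float(values.mean())
    if values.size == 1:
        return mean, 0.0
    sem = float(values.std(ddof=1) / math.sqrt(values.size))
    return mean, sem
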