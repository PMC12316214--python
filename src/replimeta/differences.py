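"""Per-pair effect-size differences and Cochran-type homogeneity tests.

For pair *i* the difference is ``Delta_i = theta_o_i - theta_r_i`` with
standard error ``sqrt(se_o^2 + se_r^2)`` (the two studies are
independent).  The standardized difference ``delta_i = Delta_i / se`` is
standard normal under homogeneity, so its square is a chi-square(1)
Q-statistic, and the sum over a project of n pairs is chi-square(n).
A positive pooled difference indicates shrinkage: replications finding
smaller effects than the originals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import InvalidInputError, ReplicationDataset, StudyPair

__all__ = ["PairDifference", "HomogeneityTest", "pair_difference", "overall_q_test"]

logger = logging.getLogger("replimeta")


@dataclass(frozen=True)
class PairDifference:
    """Difference in effect size for one pair and its Q-test."""

    pair_id: str
    delta_hat: float
    se_delta: float
    std_diff: float
    q_stat: float
    p_value: float


@dataclass(frozen=True)
class HomogeneityTest:
    """Overall between-study-pair heterogeneity test for a project."""

    q_total: float
    df: int
    p_value: float


def pair_difference(pair: StudyPair) -> PairDifference:
    """Compute the (standardized) difference and per-pair Q-test."""
    so = pair.original.standard_error
    sr = pair.replication.standard_error
    delta = pair.original.estimate - pair.replication.estimate
    se = float(np.hypot(so, sr))
    std = delta / se
    q = std * std
    return PairDifference(
        pair_id=pair.pair_id,
        delta_hat=delta,
        se_delta=se,
        std_diff=std,
        q_stat=q,
        p_value=float(stats.chi2.sf(q, df=1)),
    )


def overall_q_test(dataset: ReplicationDataset) -> HomogeneityTest:
    """Sum per-pair Q-statistics into an overall chi-square(n) test.

    The p-value is upper-tail only: the test is directed at excess
    variation between study pairs.
    """
    if len(dataset) == 0:
        raise InvalidInputError("overall Q-test needs at least one study pair")
    qs = [pair_difference(p).q_stat for p in dataset.pairs]
    q_total = float(np.sum(qs))
    df = len(qs)
    return HomogeneityTest(q_total=q_total, df=df, p_value=float(stats.chi2.sf(q_total, df=df)))
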